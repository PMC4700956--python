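"""Complementarity expectation scoring of miRNA target sites in CDS.

Scoring follows the additive penalty scheme of plant small-RNA target
servers: per aligned position, Watson-Crick match 0, G·U wobble 0.5,
mismatch 1.0, gap 2.0, with every penalty doubled inside the seed
(miRNA positions 2-13, 1-based from the miRNA 5' end). The expectation
of a duplex is the sum; lower means stronger predicted targeting.

Stringency cutoffs: strict keeps expectation <= 2.0, relaxed keeps
expectation <= 3.0 (sites scoring in (2.0, 3.0] are classed "relaxed").

Pairing strings are indexed from miRNA 5' position 1 using the symbols
``|`` (match), ``o`` (G·U), ``x`` (mismatch), ``m`` (gap in the miRNA
strand: an unpaired extra target base) and ``t`` (gap in the target
strand: an unpaired miRNA base). At most one gap per duplex by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from ._fold import can_pair

STRICT_CUTOFF = 2.0
RELAXED_CUTOFF = 3.0

_WC = {"A": "T", "C": "G", "G": "C", "T": "A", "U": "A"}


@dataclass(frozen=True)
class ScoringConfig:
    mismatch: float = 1.0
    gu: float = 0.5
    gap: float = 2.0
    seed_span: tuple[int, int] = (2, 13)  # 1-based, inclusive
    seed_factor: float = 2.0
    max_gaps: int = 1


DEFAULT_SCORING = ScoringConfig()


@dataclass(frozen=True)
class DuplexAlignment:
    mirna_id: str
    gene_id: str
    offset: tuple[int, int]  # target-strand coordinates on the CDS
    pairing: str  # indexed from miRNA 5' position 1
    expectation: float

    @property
    def n_gaps(self) -> int:
        return self.pairing.count("m") + self.pairing.count("t")


@dataclass(frozen=True)
class TargetSite:
    duplex: DuplexAlignment
    stringency: str  # 'strict' | 'relaxed'


def _norm(seq: str) -> str:
    return seq.upper().replace("U", "T")


def _is_wc(mi: str, tg: str) -> bool:
    return _WC.get(mi) == tg


def _is_gu(mi: str, tg: str) -> bool:
    return (mi == "G" and tg == "T") or (mi == "T" and tg == "G")


def _col_penalty(symbol: str, mirna_pos: int, config: ScoringConfig) -> float:
    base = {"|": 0.0, "o": config.gu, "x": config.mismatch,
            "m": config.gap, "t": config.gap}[symbol]
    lo, hi = config.seed_span
    if lo <= mirna_pos <= hi:
        base *= config.seed_factor
    return base


def score_pairing(pairing: str, mirna_positions: list[int],
                  config: ScoringConfig = DEFAULT_SCORING) -> float:
    """Recompute the expectation of a pairing string (invariant check)."""
    return sum(
        _col_penalty(sym, pos, config)
        for sym, pos in zip(pairing, mirna_positions)
    )


def duplex_penalty(mirna: str, window: str,
                   config: ScoringConfig = DEFAULT_SCORING) -> float:
    """Expectation of the ungapped duplex miRNA vs target window.

    The window is given 5'→3' on the target strand; miRNA position 1 (5')
    pairs the window's 3'-terminal base. Lengths must match.
    """
    expectation, _ = duplex_align(mirna, window, config)
    return expectation


def duplex_align(mirna: str, window: str,
                 config: ScoringConfig = DEFAULT_SCORING) -> tuple[float, str]:
    """Ungapped expectation plus pairing string."""
    mi, tg = _norm(mirna), _norm(window)
    if not mi or not tg:
        raise ValueError("empty miRNA or window")
    if len(mi) != len(tg):
        raise ValueError("ungapped duplex requires equal lengths")
    total = 0.0
    pairing = []
    for i in range(len(mi)):  # i: 0-based miRNA position
        t_base = tg[len(tg) - 1 - i]
        if _is_wc(mi[i], t_base):
            sym = "|"
        elif _is_gu(mi[i], t_base):
            sym = "o"
        else:
            sym = "x"
        pairing.append(sym)
        total += _col_penalty(sym, i + 1, config)
    return total, "".join(pairing)


def _gap_t_penalty(mi: str, tg_rev: str, gap_at: int, config: ScoringConfig):
    """miRNA position ``gap_at`` (0-based) unpaired against a target gap.

    ``tg_rev`` is the window reversed so index 0 faces miRNA position 1;
    the window is one base shorter than the miRNA.
    """
    total, pairing = 0.0, []
    ti = 0
    for i in range(len(mi)):
        if i == gap_at:
            pairing.append("t")
            total += _col_penalty("t", i + 1, config)
            continue
        t_base = tg_rev[ti]
        ti += 1
        sym = "|" if _is_wc(mi[i], t_base) else ("o" if _is_gu(mi[i], t_base) else "x")
        pairing.append(sym)
        total += _col_penalty(sym, i + 1, config)
    return total, "".join(pairing)


def _gap_m_penalty(mi: str, tg_rev: str, gap_at: int, config: ScoringConfig):
    """Extra target base opposite a miRNA gap before miRNA position ``gap_at``.

    The gap column is charged at the seed status of the next miRNA position
    (1-based index ``gap_at + 1``). Window is one base longer than the miRNA.
    """
    total, pairing = 0.0, []
    mi_i = 0
    for col in range(len(mi) + 1):
        if col == gap_at:
            pairing.append("m")
            total += _col_penalty("m", min(gap_at + 1, len(mi)), config)
            continue
        t_base = tg_rev[col]
        b = mi[mi_i]
        mi_i += 1
        sym = "|" if _is_wc(b, t_base) else ("o" if _is_gu(b, t_base) else "x")
        pairing.append(sym)
        total += _col_penalty(sym, mi_i, config)
    return total, "".join(pairing)


def enumerate_duplexes(mirna: str, cds: str, mirna_id: str = "mirna",
                       gene_id: str = "gene",
                       config: ScoringConfig = DEFAULT_SCORING):
    """Every candidate duplex: all ungapped windows plus single-gap variants.

    Gaps are internal only (a terminal gap is just a shorter duplex).
    """
    mi, tg = _norm(mirna), _norm(cds)
    L = len(mi)
    if len(tg) < L:
        return []
    out: list[DuplexAlignment] = []
    for s in range(len(tg) - L + 1):
        exp, pairing = duplex_align(mi, tg[s:s + L], config)
        out.append(DuplexAlignment(mirna_id, gene_id, (s, s + L), pairing, exp))
    if config.max_gaps >= 1:
        # gap in target strand: window length L-1
        for s in range(len(tg) - (L - 1) + 1):
            tg_rev = tg[s:s + L - 1][::-1]
            for g in range(1, L - 1):
                exp, pairing = _gap_t_penalty(mi, tg_rev, g, config)
                out.append(DuplexAlignment(mirna_id, gene_id, (s, s + L - 1), pairing, exp))
        # gap in miRNA strand: window length L+1
        for s in range(len(tg) - (L + 1) + 1):
            tg_rev = tg[s:s + L + 1][::-1]
            for g in range(1, L):
                exp, pairing = _gap_m_penalty(mi, tg_rev, g, config)
                out.append(DuplexAlignment(mirna_id, gene_id, (s, s + L + 1), pairing, exp))
    return out


def scan_cds(mirna: str, cds: str, max_expectation: float = RELAXED_CUTOFF,
             mirna_id: str = "mirna", gene_id: str = "gene",
             config: ScoringConfig = DEFAULT_SCORING) -> list[DuplexAlignment]:
    """Best duplex per non-overlapping locus with expectation <= cutoff.

    Candidates are ranked (expectation, offset, n_gaps); a candidate is kept
    if its window does not overlap an already-kept one. Result sorted by
    offset.
    """
    if len(_norm(cds)) < len(_norm(mirna)):
        raise ValueError("CDS shorter than miRNA")
    candidates = [
        d for d in enumerate_duplexes(mirna, cds, mirna_id, gene_id, config)
        if d.expectation <= max_expectation + 1e-9
    ]
    candidates.sort(key=lambda d: (d.expectation, d.offset[0], d.n_gaps))
    kept: list[DuplexAlignment] = []
    for d in candidates:
        if all(d.offset[1] <= k.offset[0] or d.offset[0] >= k.offset[1] for k in kept):
            kept.append(d)
    kept.sort(key=lambda d: d.offset)
    return kept


def classify(expectation: float) -> Optional[str]:
    if expectation <= STRICT_CUTOFF + 1e-9:
        return "strict"
    if expectation <= RELAXED_CUTOFF + 1e-9:
        return "relaxed"
    return None


def central_mismatch(duplex: DuplexAlignment) -> bool:
    """Translation-inhibition flag: any non-match at miRNA positions 9-11.

    Reported for information only; never used to filter.
    """
    pos = 0
    for sym in duplex.pairing:
        if sym != "m":
            pos += 1
        if 9 <= pos <= 11 and sym != "|":
            return True
    return False


def predict_targets(mirnas: dict[str, str], cds_set: dict[str, str],
                    mode: str = "relaxed",
                    config: ScoringConfig = DEFAULT_SCORING) -> list[TargetSite]:
    """All target sites passing the mode's cutoff, for every miRNA x CDS.

    ``mode='strict'`` keeps expectation <= 2.0; ``'relaxed'`` keeps <= 3.0.
    All sites are retained; use :func:`best_sites` for the one-per-gene view.
    """
    if mode not in ("strict", "relaxed"):
        raise ValueError("mode must be 'strict' or 'relaxed'")
    if len(set(mirnas)) != len(mirnas) or len(set(cds_set)) != len(cds_set):
        raise ValueError("duplicate ids")
    cutoff = STRICT_CUTOFF if mode == "strict" else RELAXED_CUTOFF
    sites: list[TargetSite] = []
    for mid in sorted(mirnas):
        for gid in sorted(cds_set):
            for d in scan_cds(mirnas[mid], cds_set[gid], cutoff, mid, gid, config):
                sites.append(TargetSite(duplex=d, stringency=classify(d.expectation)))
    return sites


def best_sites(sites: list[TargetSite]) -> dict[tuple[str, str], TargetSite]:
    """Best (lowest-expectation) site per (miRNA, gene) pair."""
    best: dict[tuple[str, str], TargetSite] = {}
    for s in sites:
        key = (s.duplex.mirna_id, s.duplex.gene_id)
        prev = best.get(key)
        if prev is None or s.duplex.expectation < prev.duplex.expectation:
            best[key] = s
    return best


def sites_table(sites: list[TargetSite]) -> pd.DataFrame:
    rows = [{
        "mirna_id": s.duplex.mirna_id,
        "gene_id": s.duplex.gene_id,
        "start": s.duplex.offset[0],
        "end": s.duplex.offset[1],
        "expectation": s.duplex.expectation,
        "pairing": s.duplex.pairing,
        "stringency": s.stringency,
        "central_mismatch": central_mismatch(s.duplex),
    } for s in sites]
    cols = ["mirna_id", "gene_id", "start", "end", "expectation",
            "pairing", "stringency", "central_mismatch"]
    return pd.DataFrame(rows, columns=cols)


def best_score_matrix(sites: list[TargetSite], mirnas, genes) -> pd.DataFrame:
    """Gene x miRNA matrix of best expectations (NaN where no site)."""
    mat = pd.DataFrame(float("nan"), index=sorted(genes), columns=sorted(mirnas))
    for (mid, gid), s in best_sites(sites).items():
        mat.loc[gid, mid] = s.duplex.expectation
    return mat
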