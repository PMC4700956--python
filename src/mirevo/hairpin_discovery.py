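"""Candidate locus discovery and hairpin validation.

The pipeline mirrors a manual annotation workflow made deterministic:
scan a genome for near-matches to a mature miRNA query (both strands,
Hamming distance only), cut a flanking window around each hit, fold the
window, trim to a minimal hairpin covering the miR/miR* duplex, validate
it, and place the miR* span by the Dicer 2-nt 3' overhang convention.

All coordinates are 0-based half-open. Minus-strand candidate windows are
stored query-oriented (reverse-complemented) with exact back-mapping to
forward-strand genome coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import _fold
from .io import revcomp

_VALID_QUERY = set("ACGTU")


@dataclass(frozen=True)
class GenomeHit:
    query_id: str
    contig: str
    span: tuple[int, int]  # forward-strand coordinates
    strand: str  # '+' or '-'
    mismatches: int


@dataclass(frozen=True)
class CandidateWindow:
    hit: GenomeHit
    window_span: tuple[int, int]  # forward-strand coordinates on the contig
    sequence: str  # query-strand orientation
    mature_offset: tuple[int, int]  # within `sequence`


@dataclass
class Precursor:
    id: str
    sequence: str
    structure: str
    mature_span: tuple[int, int]
    star_span: tuple[int, int]
    arm: str  # 'five_prime' | 'three_prime'
    fold_energy: float = float("nan")
    # provenance (filled by fold_and_trim when derived from a window)
    contig: Optional[str] = None
    genome_span: Optional[tuple[int, int]] = None
    strand: Optional[str] = None
    query_id: Optional[str] = None
    mismatches: Optional[int] = None

    def pairing_map(self) -> np.ndarray:
        return _fold.pairing_map(self.structure)


@dataclass(frozen=True)
class Rejection:
    reason: str  # window_too_short | no_stem | mature_in_loop | duplex_too_weak | multiloop
    detail: str = ""


@dataclass(frozen=True)
class ValidationConfig:
    """Hairpin acceptance thresholds (annotation-practice defaults)."""

    min_mature_paired: int = 15
    max_bulge: int = 4
    min_window: int = 50
    trim_flank: int = 5
    min_loop: int = 3
    # windows up to this length are folded whole; longer windows are first
    # shortened to regions around complementary star candidates (the
    # deterministic stand-in for manual shortening of ~900 bp windows)
    full_fold_max: int = 200


DEFAULT_CONFIG = ValidationConfig()


def _encode_upper(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def scan_genome(query: str, genome: dict[str, str], max_mismatches: int = 3,
                query_id: str = "query") -> list[GenomeHit]:
    """All windows on both strands within Hamming distance ``max_mismatches``.

    ``query`` must be over A/C/G/T/U (U treated as T); no gapped matches.
    Hits are sorted by (contig, start, strand).
    """
    q = query.upper().replace("U", "T")
    if not q or set(q) - _VALID_QUERY:
        raise ValueError(f"query contains invalid letters: {sorted(set(q) - _VALID_QUERY)}")
    if not 1 <= len(q):
        raise ValueError("empty query")
    qf = _encode_upper(q)
    qr = _encode_upper(revcomp(q))
    hits: list[GenomeHit] = []
    for contig in genome:
        seq = genome[contig].upper().replace("U", "T")
        if len(seq) < len(q):
            continue
        arr = _encode_upper(seq)
        windows = np.lib.stride_tricks.sliding_window_view(arr, len(q))
        for qe, strand in ((qf, "+"), (qr, "-")):
            mm = (windows != qe).sum(axis=1)
            for start in np.nonzero(mm <= max_mismatches)[0]:
                hits.append(
                    GenomeHit(query_id, contig, (int(start), int(start) + len(q)),
                              strand, int(mm[start]))
                )
    hits.sort(key=lambda h: (h.contig, h.span[0], h.strand))
    return hits


def extract_candidate(hit: GenomeHit, genome: dict[str, str], flank: int = 450) -> CandidateWindow:
    """Cut a ±``flank`` window around a hit, clipped at contig bounds.

    For minus-strand hits the window sequence is reverse-complemented so the
    mature always reads 5'→3' within it.
    """
    contig_seq = genome[hit.contig]
    start, end = hit.span
    w_lo = max(0, start - flank)
    w_hi = min(len(contig_seq), end + flank)
    forward = contig_seq[w_lo:w_hi].upper()
    if hit.strand == "+":
        seq = forward
        mat = (start - w_lo, end - w_lo)
    else:
        seq = revcomp(forward)
        mat = (w_hi - end, w_hi - start)
    return CandidateWindow(hit=hit, window_span=(w_lo, w_hi), sequence=seq, mature_offset=mat)


def validate_hairpin(p: Precursor, config: ValidationConfig = DEFAULT_CONFIG):
    """Apply the hairpin acceptance rules to a precursor.

    Returns ``(ok, diagnostics)`` where diagnostics carries ``n_paired`` and,
    on failure, a machine-readable ``reason``:

    * mature entirely within one arm (no position inside a terminal loop);
    * at least ``min_mature_paired`` of the mature positions base-paired;
    * no asymmetric bulge longer than ``max_bulge`` within the duplex;
    * single hairpin between mature and star (no multiloop).
    """
    partner = p.pairing_map()
    a, b = p.mature_span
    mat_partners = [(m, int(partner[m])) for m in range(a, b) if partner[m] >= 0]
    n_paired = len(mat_partners)
    diag = {"n_paired": n_paired}

    # (d) single hairpin: all partners on one side of the mature, antiparallel
    sides = {pp > m for m, pp in mat_partners}
    if len(sides) > 1:
        diag["reason"] = "multiloop"
        return False, diag
    pps = [pp for _, pp in mat_partners]
    if any(p2 >= p1 for p1, p2 in zip(pps, pps[1:])):
        diag["reason"] = "multiloop"
        return False, diag

    # (a) mature not inside a terminal loop
    loop_hits = 0
    paired_idx = np.nonzero(partner >= 0)[0]
    for i in paired_idx:
        j = int(partner[i])
        if j > i and not np.any(partner[i + 1:j] >= 0):  # hairpin-closing pair
            lo, hi = i + 1, j  # terminal loop interior
            loop_hits = max(loop_hits, max(0, min(b, hi) - max(a, lo)))
    if loop_hits > config.max_bulge:
        diag["reason"] = "mature_in_loop"
        return False, diag

    # (b) duplex strength
    if n_paired < config.min_mature_paired:
        diag["reason"] = "duplex_too_weak"
        return False, diag

    # (c) asymmetric bulges within the duplex
    for (m1, p1), (m2, p2) in zip(mat_partners, mat_partners[1:]):
        gap_m = m2 - m1 - 1
        gap_p = abs(p1 - p2) - 1
        if abs(gap_m - gap_p) > config.max_bulge:
            diag["reason"] = "duplex_too_weak"
            diag["bulge"] = abs(gap_m - gap_p)
            return False, diag
    # compactness: the partner block must not exceed the mature by more than
    # the bulge allowance (scattered max-pairing artifacts fail here)
    star_extent = max(pps) - min(pps) + 1
    if star_extent > (b - a) + config.max_bulge:
        diag["reason"] = "duplex_too_weak"
        diag["star_extent"] = star_extent
        return False, diag
    return True, diag


def locate_mir_star(p: Precursor, min_loop: int = 3) -> tuple[int, int]:
    """miR* span from the pairing map with 2-nt 3' overhangs (Dicer rule).

    The star is the block pairing with the mature (its 3'-terminal two
    positions excluded, being the mature 3' overhang), extended by 2 nt at
    the star 3' end. Bulges shift coordinates via the actual pairing map.
    """
    partner = p.pairing_map()
    a, b = p.mature_span
    block = [int(partner[m]) for m in range(a, max(a, b - 2)) if partner[m] >= 0]
    if not block:
        raise ValueError("mature fully unpaired; cannot place miR*")
    lo, hi = min(block), max(block) + 1
    hi = min(hi + 2, len(p.sequence))  # star 3' overhang (always the high end)
    # never let the star run into the mature
    if lo < a < hi:
        hi = min(hi, a)
    if lo < b <= hi or (lo >= a and lo < b):
        lo = max(lo, b)
    return (lo, hi)


def _duplex_score(mature: str, window: str, offset: int) -> int:
    """Pairs formed between the mature and the antiparallel block at offset."""
    L = len(mature)
    return sum(
        1
        for i in range(L)
        if _fold.can_pair(mature[i], window[offset + L - 1 - i])
    )


def _star_candidates(window: CandidateWindow, config: ValidationConfig, n_best: int):
    """Offsets in the window whose antiparallel block best pairs the mature.

    This is the deterministic replacement for manually shortening a ~900 bp
    window: the full-size fold is dominated by the mature/star duplex, so we
    localise the star arm first and fold only the enclosing region.
    """
    seq = window.sequence
    a, b = window.mature_offset
    mature = seq[a:b]
    L = b - a
    scored = []
    for off in range(0, len(seq) - L + 1):
        # star block must be disjoint from the mature and leave a loop
        if off + L + config.min_loop > a and off < b + config.min_loop:
            continue
        s = _duplex_score(mature, seq, off)
        if s >= config.min_mature_paired:
            scored.append((-s, abs(off - a), off))
    scored.sort()
    return [off for _, _, off in scored[:n_best]]


def _attempt(seq: str, mat: tuple[int, int], structure: str, energy: float,
             config: ValidationConfig):
    p = Precursor(id="candidate", sequence=seq, structure=structure,
                  mature_span=mat, star_span=(0, 0), arm="", fold_energy=energy)
    ok, diag = validate_hairpin(p, config)
    if not ok:
        return None, diag.get("reason", "duplex_too_weak")
    star = locate_mir_star(p, config.min_loop)
    p.star_span = star
    p.arm = "three_prime" if mat[0] > star[0] else "five_prime"
    return p, None


def fold_and_trim(window: CandidateWindow, n_suboptimal: int = 10,
                  config: ValidationConfig = DEFAULT_CONFIG,
                  seed: int = 0):
    """Fold a candidate window and trim it to a minimal valid hairpin.

    Returns a :class:`Precursor` (with genome provenance filled in) or a
    :class:`Rejection` whose reason is one of ``window_too_short``,
    ``no_stem``, ``mature_in_loop``, ``duplex_too_weak``, ``multiloop``.
    """
    seq = window.sequence
    if len(seq) < config.min_window:
        return Rejection("window_too_short")
    a, b = window.mature_offset
    offsets = _star_candidates(window, config, n_best=max(1, n_suboptimal // 2))
    if not offsets:
        return Rejection("no_stem", "no complementary block pairs >= "
                                    f"{config.min_mature_paired}/{b - a} mature positions")
    reasons: list[str] = []
    L = b - a
    if len(seq) <= config.full_fold_max:
        spans = [(0, len(seq))]
    else:
        spans = []
        for off in offsets:
            lo = max(0, min(off, a) - 2 * config.trim_flank)
            hi = min(len(seq), max(off + L, b) + 2 * config.trim_flank)
            spans.append((lo, hi))
    for lo, hi in spans:
        sub = seq[lo:hi]
        mat = (a - lo, b - lo)
        for structure, energy in _fold.fold(sub, n_suboptimal=n_suboptimal, seed=seed):
            p, reason = _attempt(sub, mat, structure, energy, config)
            if p is None:
                reasons.append(reason)
                continue
            # symmetric inward trim to duplex span + flanks, then refold
            t_lo = max(0, min(p.mature_span[0], p.star_span[0]) - config.trim_flank)
            t_hi = min(len(sub), max(p.mature_span[1], p.star_span[1]) + config.trim_flank)
            trimmed = sub[t_lo:t_hi]
            t_mat = (mat[0] - t_lo, mat[1] - t_lo)
            t_struct, t_energy = _fold.fold(trimmed, n_suboptimal=0)[0]
            tp, t_reason = _attempt(trimmed, t_mat, t_struct, t_energy, config)
            if tp is None:
                # trimmed fold degenerate: keep the untrimmed valid hairpin
                tp, t_lo, t_hi = p, 0, len(sub)
            final_lo, final_hi = lo + t_lo, lo + t_hi  # window coords
            hit = window.hit
            w_lo, w_hi = window.window_span
            if hit.strand == "+":
                g_span = (w_lo + final_lo, w_lo + final_hi)
            else:
                g_span = (w_hi - final_hi, w_hi - final_lo)
            tp.id = f"{hit.query_id}|{hit.contig}:{g_span[0]}-{g_span[1]}({hit.strand})"
            tp.contig = hit.contig
            tp.genome_span = g_span
            tp.strand = hit.strand
            tp.query_id = hit.query_id
            tp.mismatches = hit.mismatches
            return tp
    # pick the most informative rejection reason observed
    for r in ("multiloop", "mature_in_loop", "duplex_too_weak"):
        if r in reasons:
            return Rejection(r)
    return Rejection("no_stem")


def discover_precursors(matures: dict[str, str], genome: dict[str, str],
                        max_mismatches: int = 3, flank: int = 450,
                        n_suboptimal: int = 10,
                        config: ValidationConfig = DEFAULT_CONFIG,
                        seed: int = 0):
    """End-to-end discovery: scan, extract, fold/trim, merge duplicate loci.

    Multiple queries resolving to one genomic locus are merged (keyed by
    genome span and strand), keeping the hit with fewest mismatches.
    Returns ``(precursors, hits, rejections)``.
    """
    all_hits: list[GenomeHit] = []
    for qid, qseq in matures.items():
        all_hits.extend(scan_genome(qseq, genome, max_mismatches, query_id=qid))
    precursors: dict[tuple, Precursor] = {}
    rejections: list[tuple[GenomeHit, Rejection]] = []
    for hit in all_hits:
        window = extract_candidate(hit, genome, flank=flank)
        result = fold_and_trim(window, n_suboptimal=n_suboptimal, config=config, seed=seed)
        if isinstance(result, Rejection):
            rejections.append((hit, result))
            continue
        key = (result.contig, result.genome_span, result.strand)
        prev = precursors.get(key)
        if prev is None or result.mismatches < prev.mismatches:
            precursors[key] = result
    ordered = sorted(precursors.values(),
                     key=lambda p: (p.contig, p.genome_span, p.strand))
    return ordered, all_hits, rejections
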