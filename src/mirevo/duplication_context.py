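"""Flanking-gene synteny: tandem and segmental duplication calls.

For each miRNA locus the k (default 10) nearest protein-coding genes on
either side are collected. Two loci are a tandem pair when they sit on
the same chromosome with no protein-coding gene between them and carry
identical flanking-gene sets. A segmental (large-scale) duplication is
called when the ordered flanking lists of two loci contain a colinear
run of >= min_run (default 3) homologous genes (homology supplied as a
precomputed pair table filtered at an e-value cutoff; inversions are not
matched).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd


@dataclass(frozen=True)
class GeneInterval:
    chrom: str
    start: int
    end: int
    gene_id: str

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class SyntenyContext:
    locus_id: str
    chromosome: str
    upstream: list[str]  # nearest first
    downstream: list[str]  # nearest first
    truncated: bool = False  # fewer than k on some side (chromosome end)

    @property
    def flank_set(self) -> frozenset:
        return frozenset(self.upstream) | frozenset(self.downstream)

    @property
    def ordered(self) -> list[str]:
        """Flanking genes in chromosomal order (left to right)."""
        return list(reversed(self.upstream)) + list(self.downstream)


@dataclass(frozen=True)
class DuplicationCall:
    locus_a: str
    locus_b: str
    kind: str  # 'tandem' | 'segmental'
    evidence: tuple  # matched gene pairs (segmental) / shared flank genes (tandem)

    @property
    def run_length(self) -> int:
        return len(self.evidence)


def flanking_context(locus, annotation: Iterable[GeneInterval], k: int = 10) -> SyntenyContext:
    """Nearest ``k`` protein-coding genes strictly up/downstream of a locus.

    ``locus`` is ``(chrom, start, end, locus_id)``. Distance is by interval
    midpoint; ties break toward the lower start coordinate. Near chromosome
    ends fewer than k genes are returned and ``truncated`` is set.
    """
    chrom, start, end, locus_id = locus
    genes = sorted(
        (g for g in annotation if g.chrom == chrom),
        key=lambda g: (g.start, g.end),
    )
    if not any(True for _ in genes) and chrom not in {g.chrom for g in annotation}:
        raise ValueError(f"locus chromosome {chrom!r} absent from annotation")
    mid = (start + end) / 2.0
    up = [g for g in genes if g.midpoint < mid]
    down = [g for g in genes if g.midpoint > mid]
    up.sort(key=lambda g: (mid - g.midpoint, g.start))
    down.sort(key=lambda g: (g.midpoint - mid, g.start))
    ctx = SyntenyContext(
        locus_id=locus_id,
        chromosome=chrom,
        upstream=[g.gene_id for g in up[:k]],
        downstream=[g.gene_id for g in down[:k]],
        truncated=len(up) < k or len(down) < k,
    )
    return ctx


def call_tandem(locus_a, locus_b, annotation: Iterable[GeneInterval],
                contexts: dict[str, SyntenyContext]) -> Optional[DuplicationCall]:
    """Tandem call: same chromosome, no coding gene between, equal flank sets."""
    chrom_a, start_a, end_a, id_a = locus_a
    chrom_b, start_b, end_b, id_b = locus_b
    if chrom_a != chrom_b:
        return None
    gap_lo = min(end_a, end_b)
    gap_hi = max(start_a, start_b)
    for g in annotation:
        if g.chrom == chrom_a and gap_lo < g.midpoint < gap_hi:
            return None
    ctx_a, ctx_b = contexts[id_a], contexts[id_b]
    if ctx_a.flank_set != ctx_b.flank_set:
        return None
    a, b = sorted((id_a, id_b))
    return DuplicationCall(a, b, "tandem", tuple(sorted(ctx_a.flank_set)))


def load_homology(table, max_evalue: float = 1e-4) -> frozenset:
    """Symmetric homologous-pair set from a (gene_a, gene_b, evalue) table.

    Accepts a DataFrame, a path to a TSV, or an iterable of triples. Pairs
    at or above ``max_evalue`` are dropped; the closure is symmetric and
    identity (a gene with itself) is always homologous.
    """
    if isinstance(table, (str, bytes)) or hasattr(table, "read"):
        table = pd.read_csv(table, sep="\t")
    if isinstance(table, pd.DataFrame):
        if table.shape[1] < 3:
            raise ValueError("homology table needs >= 3 columns (a, b, evalue)")
        rows = table.iloc[:, :3].itertuples(index=False)
    else:
        rows = table
    pairs = set()
    for a, b, ev in rows:
        try:
            ev = float(ev)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed homology row ({a}, {b}, {ev!r})") from exc
        if ev < max_evalue:
            pairs.add(frozenset((str(a), str(b))))
    return frozenset(pairs)


def _homologous(a: str, b: str, pairs: frozenset) -> bool:
    return a == b or frozenset((a, b)) in pairs


def call_segmental(ctx_a: SyntenyContext, ctx_b: SyntenyContext,
                   homology: frozenset, min_run: int = 3) -> Optional[DuplicationCall]:
    """Segmental call from colinear runs of homologous flanking genes.

    The ordered flanking lists are compared at every relative offset; a run
    is a maximal block of consecutive positions whose gene pairs are
    homologous. The longest run wins; >= ``min_run`` is a call.
    """
    a_genes, b_genes = ctx_a.ordered, ctx_b.ordered
    best: tuple = ()
    for shift in range(-(len(b_genes) - 1), len(a_genes)):
        run: list[tuple[str, str]] = []
        for i in range(len(a_genes)):
            j = i - shift
            if 0 <= j < len(b_genes) and _homologous(a_genes[i], b_genes[j], homology):
                run.append((a_genes[i], b_genes[j]))
            else:
                if len(run) > len(best):
                    best = tuple(run)
                run = []
        if len(run) > len(best):
            best = tuple(run)
    if len(best) < min_run:
        return None
    a, b = sorted((ctx_a.locus_id, ctx_b.locus_id))
    if a != ctx_a.locus_id:
        best = tuple((y, x) for x, y in best)
    return DuplicationCall(a, b, "segmental", best)


def annotation_from_bed(rows) -> list[GeneInterval]:
    """BED rows (chrom, start, end, name, ...) to gene intervals."""
    return [GeneInterval(r[0], int(r[1]), int(r[2]), r[3]) for r in rows]


def call_all(loci, annotation: list[GeneInterval], homology: frozenset,
             k: int = 10, min_run: int = 3,
             chromosomes: Optional[set[str]] = None) -> tuple[list[DuplicationCall], dict]:
    """Pairwise duplication calls over all loci.

    ``chromosomes`` optionally whitelists which chromosomes participate.
    Tandem takes precedence over segmental for a pair. Returns the calls and
    the contexts used.
    """
    if chromosomes is not None:
        loci = [l for l in loci if l[0] in chromosomes]
    contexts = {l[3]: flanking_context(l, annotation, k=k) for l in loci}
    calls: list[DuplicationCall] = []
    for i in range(len(loci)):
        for j in range(i + 1, len(loci)):
            a, b = loci[i], loci[j]
            call = call_tandem(a, b, annotation, contexts)
            if call is None:
                call = call_segmental(contexts[a[3]], contexts[b[3]],
                                      homology, min_run=min_run)
            if call is not None:
                calls.append(call)
    return calls, contexts


def _fmt_evidence(e) -> str:
    return f"{e[0]}|{e[1]}" if isinstance(e, tuple) else str(e)


def calls_table(calls: list[DuplicationCall]) -> pd.DataFrame:
    rows = [{
        "locus_a": c.locus_a,
        "locus_b": c.locus_b,
        "kind": c.kind,
        "run_length": c.run_length,
        "evidence": ";".join(_fmt_evidence(e) for e in c.evidence),
    } for c in calls]
    cols = ["locus_a", "locus_b", "kind", "run_length", "evidence"]
    return pd.DataFrame(rows, columns=cols)
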