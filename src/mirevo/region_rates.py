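"""Structure-partitioned substitution rates for precursor groups.

Each precursor is tiled into five regions -- 5'-stem, miR*, loop, miR,
3'-stem -- and pairwise per-region substitution rates are computed inside
orthologous precursor groups as

    rate = differences / max(len_a, len_b) / (2 * divergence_time_Myr)

with divergence times read off a chronogram (ultrametric tree with node
ages in Myr) or supplied as a table. Differences are raw (uncorrected)
counts by default; an optional Jukes-Cantor correction is available for
simulation work where the raw estimator saturates.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional

import dendropy
import numpy as np
import pandas as pd

REGIONS = ("five_prime", "mir_star", "loop", "mir", "three_prime")

GAP_CHARS = set("-.")


@dataclass(frozen=True)
class RegionPartition:
    """The five tiling structural spans of a precursor (0-based half-open)."""

    spans: dict[str, tuple[int, int]]

    def __post_init__(self):
        if set(self.spans) != set(REGIONS):
            raise ValueError(f"partition must have exactly regions {REGIONS}")
        ordered = sorted(self.spans.values())
        pos = 0
        for lo, hi in ordered:
            if lo != pos:
                raise ValueError("partition spans must tile the precursor")
            pos = hi

    def length(self, region: str) -> int:
        lo, hi = self.spans[region]
        return hi - lo


@dataclass
class GroupMember:
    id: str
    species: str
    aligned_seq: str
    partition: Optional[RegionPartition] = None  # ungapped member coordinates


@dataclass
class PrecursorGroup:
    group_id: str
    members: list[GroupMember]
    times: dict[tuple[str, str], float]  # keyed by sorted (id_a, id_b)
    reference_id: Optional[str] = None

    def __post_init__(self):
        lengths = {len(m.aligned_seq) for m in self.members}
        if len(lengths) > 1:
            raise ValueError("alignment rows must be of equal length")

    def time(self, a: str, b: str) -> Optional[float]:
        if a == b:
            return 0.0
        return self.times.get((min(a, b), max(a, b)))


def partition_regions(p) -> RegionPartition:
    """Partition a precursor into the five structural regions.

    ``p`` needs ``sequence``, ``mature_span``, ``star_span`` and ``arm``.
    The loop is the span strictly between the two duplex spans; the 5'/3'
    regions are everything before the first and after the last.
    """
    n = len(p.sequence)
    (ma, mb), (sa, sb) = p.mature_span, p.star_span
    if max(ma, sa) < min(mb, sb):
        raise ValueError("mature and star spans overlap")
    if p.arm == "three_prime":
        first, second = ("mir_star", (sa, sb)), ("mir", (ma, mb))
    else:
        first, second = ("mir", (ma, mb)), ("mir_star", (sa, sb))
    if first[1][0] > second[1][0]:
        raise ValueError(f"arm={p.arm} inconsistent with span order")
    spans = {
        "five_prime": (0, first[1][0]),
        first[0]: first[1],
        "loop": (first[1][1], second[1][0]),
        second[0]: second[1],
        "three_prime": (second[1][1], n),
    }
    return RegionPartition(spans)


def project_mask(partition: RegionPartition, aligned_ref: str) -> list[str]:
    """Region label per alignment column, via the reference row.

    Columns where the reference is gapped inherit the label of the last
    preceding reference base (leading gap columns get the first region), so
    every column is labeled and the tiling survives projection.
    """
    labels: list[str] = []
    by_pos: dict[int, str] = {}
    for region, (lo, hi) in partition.spans.items():
        for i in range(lo, hi):
            by_pos[i] = region
    pos = 0
    last = "five_prime"
    for c in aligned_ref:
        if c in GAP_CHARS:
            labels.append(last)
        else:
            last = by_pos.get(pos, last)
            labels.append(last)
            pos += 1
    return labels


def count_region_differences(row_a: str, row_b: str, mask: list[str]) -> dict[str, int]:
    """Per-region substitution counts between two aligned rows.

    A column counts iff both rows carry non-gap bases and they differ;
    columns with a gap in either row contribute nothing.
    """
    if not (len(row_a) == len(row_b) == len(mask)):
        raise ValueError("rows and mask must be of equal length")
    counts = {r: 0 for r in REGIONS}
    for ca, cb, region in zip(row_a.upper(), row_b.upper(), mask):
        if ca in GAP_CHARS or cb in GAP_CHARS:
            continue
        if ca != cb:
            counts[region] += 1
    return counts


def pairwise_rate(diffs: int, len_a: int, len_b: int, t_myr: float) -> float:
    """``diffs / max(len_a, len_b) / (2 * t_myr)`` substitutions/site/Myr."""
    if t_myr <= 0:
        raise ValueError("divergence time must be positive")
    longer = max(len_a, len_b)
    if longer == 0:
        return float("nan")
    return diffs / longer / (2.0 * t_myr)


def jc_corrected_rate(diffs: int, len_a: int, len_b: int, t_myr: float) -> float:
    """Jukes-Cantor corrected variant of :func:`pairwise_rate`."""
    if t_myr <= 0:
        raise ValueError("divergence time must be positive")
    longer = max(len_a, len_b)
    if longer == 0:
        return float("nan")
    p = diffs / longer
    if p >= 0.75:
        return float("nan")  # saturated
    return -0.75 * math.log1p(-4.0 * p / 3.0) / (2.0 * t_myr)


def _region_length(member: GroupMember, region: str, mask: list[str]) -> int:
    if member.partition is not None:
        return member.partition.length(region)
    return sum(
        1
        for c, r in zip(member.aligned_seq, mask)
        if r == region and c not in GAP_CHARS
    )


def group_region_rates(group: PrecursorGroup, cross_species_only: bool = False,
                       jc_correction: bool = False) -> pd.DataFrame:
    """Mean/sd of pairwise per-region rates over member pairs of a group.

    Pairs with undefined or zero divergence time (same-species duplicates
    under a species-level chronogram) are excluded; their count is reported
    in the ``n_excluded`` column. Rows with no valid pair carry NaN means.
    """
    ref = _reference_member(group)
    if ref.partition is None:
        raise ValueError("reference member needs a partition to project the mask")
    mask = project_mask(ref.partition, ref.aligned_seq)
    rate_fn = jc_corrected_rate if jc_correction else pairwise_rate
    per_region: dict[str, list[float]] = {r: [] for r in REGIONS}
    n_excluded = 0
    for ma, mb in itertools.combinations(group.members, 2):
        t = group.time(ma.id, mb.id)
        if t is None or t <= 0 or (cross_species_only and ma.species == mb.species):
            n_excluded += 1
            continue
        diffs = count_region_differences(ma.aligned_seq, mb.aligned_seq, mask)
        for region in REGIONS:
            la = _region_length(ma, region, mask)
            lb = _region_length(mb, region, mask)
            r = rate_fn(diffs[region], la, lb, t)
            if not math.isnan(r):
                per_region[region].append(r)
    rows = []
    for region in REGIONS:
        vals = per_region[region]
        rows.append({
            "group_id": group.group_id,
            "region": region,
            "mean_rate": float(np.mean(vals)) if vals else float("nan"),
            "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else
                  (0.0 if len(vals) == 1 else float("nan")),
            "n_pairs": len(vals),
            "n_excluded": n_excluded,
        })
    return pd.DataFrame(rows)


def _reference_member(group: PrecursorGroup) -> GroupMember:
    if group.reference_id is not None:
        for m in group.members:
            if m.id == group.reference_id:
                return m
        raise ValueError(f"reference {group.reference_id} not in group")
    # longest ungapped sequence; ties broken by id for determinism
    return max(
        group.members,
        key=lambda m: (sum(1 for c in m.aligned_seq if c not in GAP_CHARS), m.id),
    )


def times_from_chronogram(tree, tolerance: float = 1e-6) -> dict[tuple[str, str], float]:
    """Pairwise divergence times (MRCA ages) from an ultrametric tree.

    ``tree`` may be a Newick string, a path, or a ``dendropy.Tree``. Times
    are keyed both ways plus ``(a, a) = 0``. Raises on trees whose tip
    depths spread more than ``tolerance`` (relative to depth).
    """
    t = _as_tree(tree)
    t.calc_node_ages(ultrametricity_precision=False)
    depths = [leaf.distance_from_root() for leaf in t.leaf_node_iter()]
    depth = max(depths)
    if depth > 0 and (depth - min(depths)) > tolerance * max(1.0, depth):
        raise ValueError("tree is not ultrametric within tolerance")
    taxa = [leaf.taxon.label for leaf in t.leaf_node_iter()]
    pdm = t.phylogenetic_distance_matrix()
    times: dict[tuple[str, str], float] = {}
    tx = {leaf.taxon.label: leaf.taxon for leaf in t.leaf_node_iter()}
    for a, b in itertools.combinations(taxa, 2):
        mrca = pdm.mrca(tx[a], tx[b])
        age = float(mrca.age)
        times[(a, b)] = age
        times[(b, a)] = age
    for a in taxa:
        times[(a, a)] = 0.0
    return times


def _as_tree(tree) -> "dendropy.Tree":
    if isinstance(tree, dendropy.Tree):
        return tree
    s = str(tree)
    if "(" in s:
        return dendropy.Tree.get(data=s, schema="newick")
    return dendropy.Tree.get(path=s, schema="newick")


def times_from_table(path_or_df) -> dict[tuple[str, str], float]:
    """Load a pairwise time table (columns: a, b, time_myr)."""
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(
        path_or_df, sep="\t")
    times: dict[tuple[str, str], float] = {}
    for _, row in df.iterrows():
        a, b, t = str(row.iloc[0]), str(row.iloc[1]), float(row.iloc[2])
        times[(a, b)] = t
        times[(b, a)] = t
    return times
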