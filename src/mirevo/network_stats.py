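"""Bipartite miRNA-target network with homology edges, plus redundancy stats.

The network holds directed targeting edges (miRNA -> gene, weighted by
expectation) and undirected homology edges between genes of the same
family: "paralog" within a species, "ortholog" across species. Genes
with no predicted miRNA stay in the graph as isolated nodes so targeted
fractions keep the correct denominator.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .target_scoring import RELAXED_CUTOFF, STRICT_CUTOFF, TargetSite


@dataclass
class TargetingNetwork:
    genes: dict[str, tuple[str, str]]  # gene_id -> (species, family_id)
    mirnas: set[str]
    targeting: dict[tuple[str, str], float]  # (mirna, gene) -> best expectation
    homology: list[tuple[str, str, str]]  # (gene_a, gene_b, relation), a < b

    def incoming(self, gene: str, cutoff: float = float("inf")) -> set[str]:
        return {m for (m, g), e in self.targeting.items()
                if g == gene and e <= cutoff + 1e-9}

    def targets_of(self, mirna: str, cutoff: float = float("inf")) -> set[str]:
        return {g for (m, g), e in self.targeting.items()
                if m == mirna and e <= cutoff + 1e-9}


@dataclass
class SharingSummary:
    relation: str
    n_pairs: int
    frac_share_any: Optional[float]
    frac_identical: Optional[float]
    n_excluded: int
    per_species: dict[str, dict] = field(default_factory=dict)


def build_network(sites: list[TargetSite], family_map: dict[str, str],
                  species_map: dict[str, str],
                  extra_genes: Optional[list[str]] = None) -> TargetingNetwork:
    """Assemble the network from target sites plus family/species labels.

    One targeting edge per (miRNA, gene): the best (lowest) expectation.
    ``extra_genes`` adds never-targeted genes (they must also appear in the
    family and species maps).
    """
    missing = sorted({s.duplex.gene_id for s in sites} - set(family_map))
    if missing:
        raise ValueError(f"genes missing from family map: {missing}")
    gene_ids = set(family_map)
    if extra_genes:
        gene_ids |= set(extra_genes)
        missing = sorted(set(extra_genes) - set(family_map))
        if missing:
            raise ValueError(f"genes missing from family map: {missing}")
    genes = {}
    for g in sorted(gene_ids):
        if g not in species_map:
            raise ValueError(f"gene missing from species map: {g}")
        genes[g] = (species_map[g], family_map[g])
    targeting: dict[tuple[str, str], float] = {}
    mirnas: set[str] = set()
    for s in sites:
        key = (s.duplex.mirna_id, s.duplex.gene_id)
        mirnas.add(key[0])
        e = s.duplex.expectation
        if key not in targeting or e < targeting[key]:
            targeting[key] = e
    homology = []
    for a, b in itertools.combinations(sorted(genes), 2):
        sp_a, fam_a = genes[a]
        sp_b, fam_b = genes[b]
        if fam_a != fam_b:
            continue
        homology.append((a, b, "paralog" if sp_a == sp_b else "ortholog"))
    return TargetingNetwork(genes=genes, mirnas=mirnas,
                            targeting=targeting, homology=homology)


def unique_shared_counts(net: TargetingNetwork) -> dict[str, tuple[int, int]]:
    """Per miRNA: (n_unique_targets, n_shared_targets).

    A target is unique to miRNA m iff m is its only incoming miRNA; the two
    counts partition each miRNA's target set.
    """
    indeg = {g: len(net.incoming(g)) for g in net.genes}
    out: dict[str, tuple[int, int]] = {}
    for m in sorted(net.mirnas):
        targets = net.targets_of(m)
        unique = sum(1 for g in targets if indeg[g] == 1)
        out[m] = (unique, len(targets) - unique)
    return out


def homolog_sharing(net: TargetingNetwork, relation: str,
                    unit: str = "pair") -> SharingSummary:
    """Fraction of homolog pairs sharing >=1 miRNA / having identical sets.

    ``unit='pair'``: statistics over all unordered same-family gene pairs of
    the requested relation. ``unit='gene'``: a gene "shares" if any of its
    homologs of that relation shares with it. Pairs (or genes) where both
    sides have empty miRNA sets are excluded and counted.
    """
    if relation not in ("ortholog", "paralog"):
        raise ValueError("relation must be 'ortholog' or 'paralog'")
    if unit not in ("pair", "gene"):
        raise ValueError("unit must be 'pair' or 'gene'")
    incoming = {g: net.incoming(g) for g in net.genes}
    pairs = [(a, b) for a, b, rel in net.homology if rel == relation]

    if unit == "pair":
        included = [(a, b) for a, b in pairs if incoming[a] or incoming[b]]
        n_excluded = len(pairs) - len(included)
        if not included:
            return SharingSummary(relation, 0, None, None, n_excluded)
        share = [bool(incoming[a] & incoming[b]) for a, b in included]
        ident = [incoming[a] == incoming[b] for a, b in included]
        summary = SharingSummary(
            relation, len(included),
            sum(share) / len(included), sum(ident) / len(included), n_excluded)
        for sp in sorted({s for s, _ in net.genes.values()}):
            sp_pairs = [(a, b) for a, b in included
                        if net.genes[a][0] == sp and net.genes[b][0] == sp]
            if relation == "paralog" and sp_pairs:
                summary.per_species[sp] = {
                    "n_pairs": len(sp_pairs),
                    "frac_share_any": sum(
                        bool(incoming[a] & incoming[b]) for a, b in sp_pairs
                    ) / len(sp_pairs),
                    "frac_identical": sum(
                        incoming[a] == incoming[b] for a, b in sp_pairs
                    ) / len(sp_pairs),
                }
        assert summary.frac_identical <= summary.frac_share_any + 1e-12
        return summary

    # unit == 'gene'
    partners: dict[str, set[str]] = {g: set() for g in net.genes}
    for a, b in pairs:
        partners[a].add(b)
        partners[b].add(a)
    with_rel = [g for g in sorted(net.genes) if partners[g]]
    included = [g for g in with_rel
                if incoming[g] or any(incoming[p] for p in partners[g])]
    n_excluded = len(with_rel) - len(included)
    if not included:
        return SharingSummary(relation, 0, None, None, n_excluded)
    share = [any(incoming[g] & incoming[p] for p in partners[g]) for g in included]
    ident = [any(incoming[g] == incoming[p] for p in partners[g]) for g in included]
    summary = SharingSummary(relation, len(included),
                             sum(share) / len(included),
                             sum(ident) / len(included), n_excluded)
    return summary


def spearman_exact_p(x, y) -> tuple[float, float]:
    """Spearman rho with an exact two-sided permutation p-value.

    Enumerates all n! permutations of one rank vector; ties are mid-ranked.
    Intended for n <= 10.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return float("nan"), float("nan")
    rho_obs = float(np.corrcoef(rx, ry)[0, 1])
    perms = np.array(list(itertools.permutations(ry)))
    rx_c = rx - rx.mean()
    py = perms - ry.mean()
    denom = math.sqrt((rx_c ** 2).sum() * ((ry - ry.mean()) ** 2).sum())
    rhos = (py @ rx_c) / denom
    p = float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))
    return rho_obs, p


def family_size_vs_mirna_count(net: TargetingNetwork, per_species: bool = False,
                               exact_max_n: int = 10):
    """Spearman correlation of family size vs #distinct targeting miRNAs.

    Family size is genes per family (pooled across species by default, or
    per (family, species) with ``per_species=True``). The p-value is an
    exact permutation enumeration when the number of families <= 10, a
    t-approximation otherwise. Returns ``(rho, p_value, table)``.
    """
    rows = []
    if per_species:
        keys = sorted({(fam, sp) for sp, fam in net.genes.values()})
    else:
        keys = sorted({fam for _, fam in net.genes.values()})
    for key in keys:
        if per_species:
            fam, sp = key
            members = [g for g, (s, f) in net.genes.items() if f == fam and s == sp]
        else:
            members = [g for g, (_, f) in net.genes.items() if f == key]
        mirnas = set()
        for g in members:
            mirnas |= net.incoming(g)
        rows.append({"family": key, "size": len(members), "n_mirnas": len(mirnas)})
    if len(rows) < 3:
        raise ValueError("need at least 3 families")
    table = pd.DataFrame(rows)
    sizes = table["size"].to_numpy(dtype=float)
    counts = table["n_mirnas"].to_numpy(dtype=float)
    if np.ptp(sizes) == 0 or np.ptp(counts) == 0:
        return float("nan"), float("nan"), table
    if len(rows) <= exact_max_n:
        rho, p = spearman_exact_p(sizes, counts)
    else:
        res = stats.spearmanr(sizes, counts)
        rho, p = float(res.statistic), float(res.pvalue)
    return rho, p, table


def targeted_fraction(net: TargetingNetwork, species: str,
                      mode: str = "relaxed") -> tuple[int, int, float]:
    """(n_targeted, n_total, fraction) for one species at a mode's cutoff."""
    cutoff = STRICT_CUTOFF if mode == "strict" else RELAXED_CUTOFF
    genes = [g for g, (sp, _) in net.genes.items() if sp == species]
    if not genes:
        raise ValueError(f"no genes for species {species!r}")
    n_targeted = sum(1 for g in genes if net.incoming(g, cutoff))
    return n_targeted, len(genes), n_targeted / len(genes)


def to_networkx(net: TargetingNetwork) -> nx.DiGraph:
    g = nx.DiGraph()
    for m in sorted(net.mirnas):
        g.add_node(m, kind="mirna")
    for gene, (sp, fam) in sorted(net.genes.items()):
        g.add_node(gene, kind="gene", species=sp, family=fam)
    for (m, gene), e in sorted(net.targeting.items()):
        g.add_edge(m, gene, relation="targets", expectation=float(e))
    for a, b, rel in net.homology:
        g.add_edge(a, b, relation=rel)
    return g


def export_network(net: TargetingNetwork, path, fmt: str = "tsv") -> None:
    """Write the network: native ``tsv`` edge list, ``graphml``, or ``sif``.

    The TSV export is lossless: ``import_network`` reads it back to an
    identical network, and re-exporting is byte-identical.
    """
    if fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("# mirevo network v1\n")
            fh.write("record\ta\tb\trelation\texpectation\tspecies\tfamily\n")
            for m in sorted(net.mirnas):
                fh.write(f"node\t{m}\t.\tmirna\t.\t.\t.\n")
            for gene, (sp, fam) in sorted(net.genes.items()):
                fh.write(f"node\t{gene}\t.\tgene\t.\t{sp}\t{fam}\n")
            for (m, gene), e in sorted(net.targeting.items()):
                fh.write(f"edge\t{m}\t{gene}\ttargets\t{e!r}\t.\t.\n")
            for a, b, rel in net.homology:
                fh.write(f"edge\t{a}\t{b}\t{rel}\t.\t.\t.\n")
    elif fmt == "graphml":
        nx.write_graphml(to_networkx(net), path)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for (m, gene), _ in sorted(net.targeting.items()):
                fh.write(f"{m}\ttargets\t{gene}\n")
            for a, b, rel in net.homology:
                fh.write(f"{a}\t{rel}\t{b}\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def import_network(path) -> TargetingNetwork:
    """Read back the native TSV edge list written by :func:`export_network`."""
    genes: dict[str, tuple[str, str]] = {}
    mirnas: set[str] = set()
    targeting: dict[tuple[str, str], float] = {}
    homology: list[tuple[str, str, str]] = []
    with open(path) as fh:
        for ln in fh:
            if ln.startswith("#") or ln.startswith("record\t"):
                continue
            rec, a, b, rel, exp, sp, fam = ln.rstrip("\n").split("\t")
            if rec == "node":
                if rel == "mirna":
                    mirnas.add(a)
                else:
                    genes[a] = (sp, fam)
            else:
                if rel == "targets":
                    targeting[(a, b)] = float(exp)
                else:
                    homology.append((a, b, rel))
    return TargetingNetwork(genes=genes, mirnas=mirnas,
                            targeting=targeting, homology=homology)


def summary_table(net: TargetingNetwork) -> pd.DataFrame:
    """One-row-per-statistic summary (sharing fractions per relation)."""
    rows = []
    for relation in ("paralog", "ortholog"):
        s = homolog_sharing(net, relation)
        rows.append({
            "statistic": f"{relation}_sharing", "n_pairs": s.n_pairs,
            "frac_share_any": s.frac_share_any,
            "frac_identical": s.frac_identical, "n_excluded": s.n_excluded,
        })
    return pd.DataFrame(rows)
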