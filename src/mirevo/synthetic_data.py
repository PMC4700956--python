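"""Synthetic inputs with known ground truth for every pipeline stage.

Simulators emit the same file formats the analysis consumes (FASTA, TSV,
Newick) together with a :class:`SimTruth` record so recovery can be
asserted exactly: hairpin templates with a designed miR/miR* duplex,
families of precursors evolved under region-specific Jukes-Cantor rates
along an ultrametric tree, genome backgrounds with planted loci and
dinucleotide-shuffled decoys, and two-species CDS sets carrying target
sites edited to an exact designed penalty.

Every operation is a pure function of its seed and arguments.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import asdict, dataclass, field
from typing import Optional

import dendropy
import numpy as np

from . import _fold
from .io import revcomp
from .region_rates import REGIONS, partition_regions
from .target_scoring import (DEFAULT_SCORING, ScoringConfig, duplex_align,
                             enumerate_duplexes, scan_cds)

BASES = "ACGT"
_WC = {"A": "T", "C": "G", "G": "C", "T": "A"}
_WOBBLE = {"G": "T", "T": "G"}  # miRNA base -> target base giving G·U


@dataclass
class HairpinTemplate:
    id: str
    sequence: str
    structure: str
    mature_span: tuple[int, int]
    star_span: tuple[int, int]
    arm: str  # 'five_prime' | 'three_prime'

    def pairing_map(self) -> np.ndarray:
        return _fold.pairing_map(self.structure)

    @property
    def mature(self) -> str:
        return self.sequence[self.mature_span[0]:self.mature_span[1]]


@dataclass
class PlantedLocus:
    contig: str
    span: tuple[int, int]  # full hairpin, forward-strand coordinates
    strand: str
    n_mismatches: int
    mature_span: tuple[int, int]  # forward-strand coordinates
    template_id: str


@dataclass
class PlantedSite:
    mirna_id: str
    gene_id: str
    offset: tuple[int, int]
    designed_penalty: float


@dataclass
class SimTruth:
    planted_loci: list[PlantedLocus] = field(default_factory=list)
    decoy_loci: list[dict] = field(default_factory=list)
    true_region_rates: dict[str, float] = field(default_factory=dict)
    planted_sites: list[PlantedSite] = field(default_factory=list)
    tree_ages: dict[str, float] = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path) as fh:
            d = json.load(fh)
        truth = cls()
        truth.planted_loci = [
            PlantedLocus(l["contig"], tuple(l["span"]), l["strand"],
                         l["n_mismatches"], tuple(l["mature_span"]), l["template_id"])
            for l in d.get("planted_loci", [])
        ]
        truth.decoy_loci = d.get("decoy_loci", [])
        truth.true_region_rates = d.get("true_region_rates", {})
        truth.planted_sites = [
            PlantedSite(s["mirna_id"], s["gene_id"], tuple(s["offset"]),
                        s["designed_penalty"])
            for s in d.get("planted_sites", [])
        ]
        truth.tree_ages = d.get("tree_ages", {})
        return truth


def _random_seq(rng, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n))


# ---------------------------------------------------------------------------
# hairpin templates


def make_hairpin(stem_len: int, loop_len: int, n_wobbles: int = 0,
                 n_bulges: int = 0, mature_arm: str = "3p", seed: int = 0,
                 template_id: str = "hp") -> HairpinTemplate:
    """Construct a hairpin with a designed duplex and a 22-nt mature.

    The 3' arm is the reverse complement of the 5' arm except at
    ``n_wobbles`` G·U columns (still drawn paired) and ``n_bulges``
    single-nucleotide unpaired insertions placed outside the mature block.
    The mature sits centred in ``mature_arm``; the star span follows the
    2-nt 3' overhang convention via the designed pairing map.
    """
    if stem_len < 22:
        raise ValueError("mature cannot fit in arm")
    if loop_len < 3:
        raise ValueError("loop must be at least 3 nt")
    if mature_arm not in ("5p", "3p"):
        raise ValueError("mature_arm must be '5p' or '3p'")
    rng = np.random.default_rng(seed)
    left = list(_random_seq(rng, stem_len))
    right = [_WC[b] for b in left]  # column i pairs left[i] with right[i]
    wob_cols = rng.choice(stem_len, size=n_wobbles, replace=False) if n_wobbles else []
    for col in wob_cols:
        if rng.integers(2) == 0:
            left[col], right[col] = "G", "T"
        else:
            left[col], right[col] = "T", "G"
    c0 = (stem_len - 22) // 2  # mature occupies columns [c0, c0+22)
    mature_cols = set(range(c0, c0 + 22))

    five = [(b, "(", i) for i, b in enumerate(left)]
    loop = [(b, ".", None) for b in _random_seq(rng, loop_len)]
    three = [(right[i], ")", i) for i in range(stem_len - 1, -1, -1)]
    mature_tokens = three if mature_arm == "3p" else five
    def _legal_slots(arm):
        return [
            k for k in range(1, len(arm))
            if not (arm is mature_tokens
                    and arm[k - 1][2] in mature_cols and arm[k][2] in mature_cols)
        ]

    for _ in range(n_bulges):
        arm = [five, three][int(rng.integers(2))]
        legal = _legal_slots(arm)
        if not legal:
            arm = three if arm is five else five
            legal = _legal_slots(arm)
        k = int(rng.choice(legal))
        arm.insert(k, (str(rng.choice(list(BASES))), ".", None))

    tokens = five + loop + three
    sequence = "".join(t[0] for t in tokens)
    structure = "".join(t[1] for t in tokens)
    arm_offset = 0 if mature_arm == "5p" else len(five) + len(loop)
    positions = [arm_offset + k for k, t in enumerate(mature_tokens)
                 if t[2] in mature_cols]
    mature_span = (min(positions), max(positions) + 1)
    if mature_span[1] - mature_span[0] != 22:
        raise AssertionError("bulge placement split the mature block")
    tpl = HairpinTemplate(id=template_id, sequence=sequence, structure=structure,
                          mature_span=mature_span, star_span=(0, 0),
                          arm="three_prime" if mature_arm == "3p" else "five_prime")
    from .hairpin_discovery import locate_mir_star

    tpl.star_span = locate_mir_star(tpl)
    return tpl


# ---------------------------------------------------------------------------
# sequence evolution


def random_ultrametric_tree(n_tips: int, depth: float, seed: int = 0) -> str:
    """Random ultrametric Newick with branch lengths in Myr (root age=depth)."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    ages = sorted(rng.uniform(0, depth, size=n_tips - 1))
    ages[-1] = depth
    nodes = [(f"t{i}", 0.0) for i in range(n_tips)]  # (newick, age)
    for age in ages:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        (nwk_j, age_j) = nodes.pop(j)
        (nwk_i, age_i) = nodes.pop(i)
        merged = f"({nwk_i}:{age - age_i:.6f},{nwk_j}:{age - age_j:.6f})"
        nodes.append((merged, age))
    return nodes[0][0] + ";"


def _check_ultrametric(tree: dendropy.Tree, tolerance: float = 1e-6):
    depths = [leaf.distance_from_root() for leaf in tree.leaf_node_iter()]
    depth = max(depths)
    if depth > 0 and (depth - min(depths)) > tolerance * max(1.0, depth):
        raise ValueError("tree is not ultrametric")


def evolve_family(ancestor, tree, region_rates: dict[str, float],
                  seed: int = 0) -> tuple[dict[str, str], SimTruth]:
    """Evolve an ancestral hairpin along an ultrametric tree.

    Each site belongs to one of the five structural regions of the ancestor;
    on a branch of length ``t`` Myr a site in region r substitutes with the
    Jukes-Cantor probability ``(3/4)(1 - exp(-(4/3) * rate_r * t))``, the
    new base uniform over the other three. No indels. Returns the tip
    sequences and a truth record with the rates and node ages.
    """
    if set(region_rates) != set(REGIONS):
        raise ValueError(f"region_rates keys must be exactly {REGIONS}")
    for r, k in region_rates.items():
        if k < 0:
            raise ValueError(f"negative rate for region {r}")
    t = tree if isinstance(tree, dendropy.Tree) else dendropy.Tree.get(
        data=str(tree), schema="newick")
    tips = list(t.leaf_node_iter())
    if len(tips) < 2:
        raise ValueError("tree must have at least 2 tips")
    _check_ultrametric(t)

    part = partition_regions(ancestor)
    site_rate = np.empty(len(ancestor.sequence))
    for region, (lo, hi) in part.spans.items():
        site_rate[lo:hi] = region_rates[region]

    rng = np.random.default_rng(seed)
    idx = {b: i for i, b in enumerate(BASES)}
    seqs: dict[int, np.ndarray] = {}
    root = t.seed_node
    seqs[id(root)] = np.array([idx[b] for b in ancestor.sequence], dtype=np.int8)
    out: dict[str, str] = {}
    for node in t.preorder_node_iter():
        if node is root:
            pass
        else:
            parent_seq = seqs[id(node.parent_node)]
            blen = node.edge.length or 0.0
            p_sub = 0.75 * (1.0 - np.exp(-(4.0 / 3.0) * site_rate * blen))
            hit = rng.random(len(parent_seq)) < p_sub
            child = parent_seq.copy()
            if hit.any():
                shifts = rng.integers(1, 4, size=int(hit.sum()))
                child[hit] = (child[hit] + shifts) % 4
            seqs[id(node)] = child
        if node.is_leaf():
            label = node.taxon.label if node.taxon else f"tip{len(out)}"
            out[label] = "".join(BASES[i] for i in seqs[id(node)])

    t.calc_node_ages(ultrametricity_precision=False)
    ages = {}
    for node in t.preorder_internal_node_iter():
        key = ",".join(sorted(l.taxon.label for l in node.leaf_iter()))
        ages[key] = float(node.age)
    truth = SimTruth(true_region_rates=dict(region_rates), tree_ages=ages)
    return out, truth


# ---------------------------------------------------------------------------
# genome planting


def dinucleotide_shuffle(seq: str, rng) -> str:
    """Altschul-Erikson dinucleotide shuffle (preserves doublet counts)."""
    s = seq.upper()
    if len(s) < 3:
        return s
    edges: dict[str, list[str]] = defaultdict(list)
    for a, b in zip(s, s[1:]):
        edges[a].append(b)
    last = s[-1]
    vertices = [v for v in edges if v != last]
    for _ in range(2000):
        last_edge = {v: edges[v][int(rng.integers(len(edges[v])))] for v in vertices}
        ok = True
        for v in vertices:
            seen = {v}
            cur = v
            while cur != last:
                cur = last_edge.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - practically unreachable
        raise RuntimeError("dinucleotide shuffle failed to converge")
    order: dict[str, list[str]] = {}
    for v, pool in edges.items():
        pool = list(pool)
        if v in last_edge:
            pool.remove(last_edge[v])
        rng.shuffle(pool)
        if v in last_edge:
            pool.append(last_edge[v])
        order[v] = pool
    walk = [s[0]]
    nxt = {v: 0 for v in edges}
    cur = s[0]
    for _ in range(len(s) - 1):
        b = order[cur][nxt[cur]]
        nxt[cur] += 1
        walk.append(b)
        cur = b
    return "".join(walk)


def _mutate_mature(template: HairpinTemplate, n_mismatches: int, rng) -> str:
    seq = list(template.sequence)
    a, b = template.mature_span
    pos = rng.choice(np.arange(a, b), size=n_mismatches, replace=False)
    for p in pos:
        choices = [c for c in BASES if c != seq[p]]
        seq[p] = str(rng.choice(choices))
    return "".join(seq)


def plant_genome(templates: list[HairpinTemplate],
                 mutated_copies: list[tuple[HairpinTemplate, int]],
                 n_decoys: int, bg_len: int, seed: int = 0,
                 contig: str = "contig1",
                 min_gap: int = 30) -> tuple[dict[str, str], SimTruth]:
    """Plant hairpins (and shuffled decoys) in a uniform random background.

    Each template is planted exactly once with 0 mature mismatches; each
    ``(template, n)`` in ``mutated_copies`` adds a copy with exactly ``n``
    substitutions inside the mature. Every second insert (by order) is
    reverse-complemented. Decoys are dinucleotide-shuffled template
    sequences. Returns ``({contig: genome}, truth)``.
    """
    rng = np.random.default_rng(seed)
    inserts: list[tuple[str, Optional[HairpinTemplate], int]] = []
    for tpl in templates:
        inserts.append((tpl.sequence, tpl, 0))
    for tpl, n_mm in mutated_copies:
        inserts.append((_mutate_mature(tpl, n_mm, rng), tpl, n_mm))
    for i in range(n_decoys):
        tpl = templates[i % len(templates)]
        inserts.append((dinucleotide_shuffle(tpl.sequence, rng), None, -1))

    total = sum(len(s) for s, _, _ in inserts) + min_gap * (len(inserts) + 1)
    if total > bg_len:
        raise ValueError("background too short to hold all inserts without overlap")
    genome = list(_random_seq(rng, bg_len))
    placed: list[tuple[int, int]] = []
    truth = SimTruth()
    for i, (seq, tpl, n_mm) in enumerate(inserts):
        L = len(seq)
        for _ in range(10000):
            start = int(rng.integers(0, bg_len - L + 1))
            if all(start + L + min_gap <= lo or start >= hi + min_gap
                   for lo, hi in placed):
                break
        else:
            raise ValueError("could not place insert without overlap")
        placed.append((start, start + L))
        strand = "+" if i % 2 == 0 else "-"
        genome[start:start + L] = list(seq if strand == "+" else revcomp(seq))
        if tpl is not None:
            ma, mb = tpl.mature_span
            if strand == "+":
                mat = (start + ma, start + mb)
            else:
                mat = (start + L - mb, start + L - ma)
            truth.planted_loci.append(PlantedLocus(
                contig=contig, span=(start, start + L), strand=strand,
                n_mismatches=n_mm, mature_span=mat, template_id=tpl.id))
        else:
            truth.decoy_loci.append(
                {"contig": contig, "span": [start, start + L], "strand": strand})
    return {contig: "".join(genome)}, truth


# ---------------------------------------------------------------------------
# target sets


_NONSEED = lambda L: [1] + list(range(14, L + 1))  # 1-based miRNA positions
_SEED = list(range(2, 14))


def _achievable_units(mirna: str, config: ScoringConfig) -> set[int]:
    L = len(mirna)
    ns = _NONSEED(L)
    w_ns = sum(1 for p in ns if mirna[p - 1] in _WOBBLE)
    w_s = sum(1 for p in _SEED if mirna[p - 1] in _WOBBLE)
    units = set()
    for a in range(0, len(_SEED) + 1):          # seed mismatches (4 units)
        for b in range(0, w_s + 1):             # seed wobbles (2 units)
            if a + b > len(_SEED):
                continue
            for c in range(0, len(ns) + 1):     # non-seed mismatches (2 units)
                for d in range(0, w_ns + 1):    # non-seed wobbles (1 unit)
                    if c + d > len(ns):
                        continue
                    units.add(4 * a + 2 * b + 2 * c + d)
    return units


def _design_combo(mirna: str, penalty: float, config: ScoringConfig):
    """Pick (seed_mm, seed_wob, ns_mm, ns_wob) counts reaching the penalty.

    Fewest edits wins; ties prefer edits outside the seed.
    """
    units = penalty / (config.mismatch / 2.0)
    if abs(units - round(units)) > 1e-9 or penalty < 0:
        raise ValueError(f"penalty must be a multiple of {config.mismatch / 2.0}")
    units = int(round(units))
    L = len(mirna)
    ns = _NONSEED(L)
    w_ns = sum(1 for p in ns if mirna[p - 1] in _WOBBLE)
    w_s = sum(1 for p in _SEED if mirna[p - 1] in _WOBBLE)
    best = None
    for a in range(0, min(len(_SEED), units // 4) + 1):
        for b in range(0, w_s + 1):
            if a + b > len(_SEED):
                continue
            for c in range(0, len(ns) + 1):
                rem = units - 4 * a - 2 * b - 2 * c
                if rem < 0:
                    break
                d = rem
                if d > w_ns or c + d > len(ns):
                    continue
                key = (a + b + c + d, a + b, a, b)
                if best is None or key < best[0]:
                    best = (key, (a, b, c, d))
    if best is None:
        achievable = _achievable_units(mirna, config)
        closest = min(achievable, key=lambda u: abs(u - units))
        raise ValueError(
            f"penalty {penalty} unreachable for this miRNA; "
            f"closest achievable is {closest * config.mismatch / 2.0}")
    return best[1]


def design_site(mirna: str, penalty: float, rng,
                config: ScoringConfig = DEFAULT_SCORING) -> str:
    """A target window whose duplex with ``mirna`` scores exactly ``penalty``.

    Starts from the exact reverse complement and applies the fewest edits
    (preferring positions outside the seed): G·U wobbles and mismatches,
    seed-doubled per the scoring rule.
    """
    mi = mirna.upper().replace("U", "T")
    L = len(mi)
    a, b, c, d = _design_combo(mi, penalty, config)
    window = list(revcomp(mi))
    ns = _NONSEED(L)

    def target_index(pos_1based: int) -> int:
        return L - pos_1based

    ns_wob_pool = [p for p in ns if mi[p - 1] in _WOBBLE]
    s_wob_pool = [p for p in _SEED if mi[p - 1] in _WOBBLE]
    chosen_ns_wob = list(rng.choice(ns_wob_pool, size=d, replace=False)) if d else []
    chosen_s_wob = list(rng.choice(s_wob_pool, size=b, replace=False)) if b else []
    ns_mm_pool = [p for p in ns if p not in chosen_ns_wob]
    s_mm_pool = [p for p in _SEED if p not in chosen_s_wob]
    chosen_ns_mm = list(rng.choice(ns_mm_pool, size=c, replace=False)) if c else []
    chosen_s_mm = list(rng.choice(s_mm_pool, size=a, replace=False)) if a else []
    for p in chosen_ns_wob + chosen_s_wob:
        window[target_index(p)] = _WOBBLE[mi[p - 1]]
    for p in chosen_ns_mm + chosen_s_mm:
        bad = {_WC[mi[p - 1]], _WOBBLE.get(mi[p - 1], "")}
        window[target_index(p)] = next(x for x in BASES if x not in bad)
    site = "".join(window)
    got, _ = duplex_align(mi, site, config)
    if abs(got - penalty) > 1e-9:  # pragma: no cover - internal consistency
        raise AssertionError(f"designed site scores {got}, wanted {penalty}")
    return site


def make_target_set(n_families: int, family_sizes: list[int],
                    mirnas: list[str],
                    planted: list[tuple[int, int, int, float]],
                    cds_len: int = 120, seed: int = 0,
                    config: ScoringConfig = DEFAULT_SCORING):
    """Two-species CDS sets with planted sites of exact designed penalty.

    Families ``fam0..`` each have ``family_sizes[f]`` members per species
    (``spA``/``spB``); members are enumerated spA first, so ``member_idx``
    in a planted tuple ``(mirna_idx, family_idx, member_idx, penalty)``
    ranges over ``[0, 2 * family_sizes[f])``. Background CDS is verified to
    contain no window scoring <= 3.0 against any miRNA.

    Returns ``(cds, family_table, truth)`` where ``cds`` maps gene id to
    sequence and ``family_table`` is a list of (gene_id, species, family_id).
    """
    if len(family_sizes) != n_families:
        raise ValueError("family_sizes length must equal n_families")
    if cds_len < 22:
        raise ValueError("cds_len must be >= 22")
    mirnas = [m.upper().replace("U", "T") for m in mirnas]
    rng = np.random.default_rng(seed)
    genes: list[tuple[str, str, str]] = []  # (gene_id, species, family_id)
    member_ids: dict[int, list[str]] = {}
    for f, size in enumerate(family_sizes):
        members = []
        for sp in ("spA", "spB"):
            for k in range(size):
                gid = f"{sp}_fam{f}_g{k}"
                genes.append((gid, sp, f"fam{f}"))
                members.append(gid)
        member_ids[f] = members

    def clean_background() -> str:
        for _ in range(50):
            s = _random_seq(rng, cds_len)
            if all(
                min((dpx.expectation for dpx in enumerate_duplexes(m, s, config=config)),
                    default=99.0) > 3.0
                for m in mirnas
            ):
                return s
        raise RuntimeError("could not generate clean background CDS")

    cds = {gid: clean_background() for gid, _, _ in genes}
    truth = SimTruth()
    used: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for mirna_idx, family_idx, member_idx, penalty in planted:
        mirna = mirnas[mirna_idx]
        gid = member_ids[family_idx][member_idx]
        site = design_site(mirna, penalty, rng, config)
        L = len(site)
        for _ in range(200):
            start = int(rng.integers(0, cds_len - L + 1))
            if all(start + L + 2 <= lo or start >= hi + 2 for lo, hi in used[gid]):
                break
        else:
            raise ValueError(f"no room for another site in {gid}")
        used[gid].append((start, start + L))
        cds[gid] = cds[gid][:start] + site + cds[gid][start + L:]
        truth.planted_sites.append(PlantedSite(
            mirna_id=f"mir{mirna_idx}", gene_id=gid,
            offset=(start, start + L), designed_penalty=penalty))

    # round-trip check: the scanner sees exactly the planted sites
    expected = defaultdict(set)
    for s in truth.planted_sites:
        expected[(s.mirna_id, s.gene_id)].add((s.offset[0], s.designed_penalty))
    for i, m in enumerate(mirnas):
        for gid, _, _ in genes:
            found = {(dpx.offset[0], dpx.expectation)
                     for dpx in scan_cds(m, cds[gid], 3.0, f"mir{i}", gid, config)}
            if found != expected.get((f"mir{i}", gid), set()):  # pragma: no cover
                raise AssertionError(
                    f"planted-site round trip failed for mir{i} x {gid}: "
                    f"{found} != {expected.get((f'mir{i}', gid), set())}")
    return cds, genes, truth
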