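# mirevo

Analysis toolkit for a clustered plant miRNA gene family that regulates
NBS-LRR disease-resistance genes. The pipeline covers:

- **hairpin discovery** — scan genomic sequence for near-matches to mature
  miRNA queries (both strands, up to 3 mismatches per 22-nt hit), cut
  ±450 bp flanking windows, fold them, trim to a minimal validated hairpin
  and place the miR* span by the 2-nt 3' overhang convention;
- **region rates** — tile each precursor into the five structural regions
  (5'-stem, miR*, loop, miR, 3'-stem) and estimate per-region substitution
  rates (differences / longer sequence length / 2·divergence time, in
  substitutions·site⁻¹·Myr⁻¹) within precursor groups against a chronogram;
- **target scoring** — expectation-scored miRNA→CDS target prediction
  (match 0, G·U 0.5, mismatch 1, gap 2, doubled at miRNA positions 2–13;
  strict ≤ 2.0, relaxed ≤ 3.0);
- **network stats** — bipartite miRNA→gene targeting network with
  ortholog/paralog homology edges; unique/shared target counts, homolog
  sharing fractions, family-size vs miRNA-count Spearman correlation
  (exact permutation p for n ≤ 10), targeted fractions, GraphML/SIF export;
- **duplication context** — flanking-gene synteny: tandem calls (no
  intervening coding gene, identical flank sets) and segmental calls
  (colinear runs of ≥ 3 homologous flanking genes at e-value < 1e-4);
- **synthetic data** — seeded generators for every input with ground
  truth: designed hairpin templates, families evolved under region-specific
  Jukes–Cantor rates on ultrametric trees, genomes with planted loci and
  dinucleotide-shuffled decoys, and two-species CDS sets with target sites
  edited to an exact designed penalty.

Folding uses a built-in Nussinov-style maximum-pairing engine (minimum
loop 3, G·U allowed) behind a narrow interface, so no external RNA-folding
dependency is required.

## CLI

All stages are exposed through one entry point:

```bash
mirevo simulate genome   --seed 1 --out sim/          # planted loci + decoys
mirevo simulate hairpins --seed 1 --out fam/          # evolved family + tree
mirevo simulate targets  --seed 1 --out tgt/          # CDS set + families

mirevo discover --mature sim/matures.fasta --genome sim/genome.fasta \
    --max-mismatch 3 --flank 450 --out disc/
mirevo rates    --alignment fam/family_aln.fasta \
    --structures fam/ancestor.struct --tree fam/tree.nwk --out rates.tsv
mirevo targets  --mirna tgt/mirnas.fasta --cds tgt/cds.fasta \
    --mode relaxed --out targets/
mirevo network  --sites targets/sites.tsv --families tgt/families.tsv \
    --out network/
mirevo synteny  --loci loci.bed --genes genes.bed --homology hom.tsv \
    --min-run 3 --k 10 --out calls.tsv
```

Outputs are plain text: FASTA, BED, TSV, Newick, JSON, GraphML and SIF.
Precursor structures are written as a FASTA-like file with a metadata
header, the sequence line and the dot-bracket line.

## Acceptance

`tests/test_acceptance.py` implements the property-based acceptance
criteria (scanner ≡ brute force, 100% recall / 0 decoys on planted
genomes, rate-formula value and parameter recovery, scoring ≡ exhaustive
enumeration, network statistics ≡ brute-force recomputation, synteny
oracle agreement, end-to-end run). The report script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

runs the full pipeline on the default synthetic scenario and writes the
(empty) numeric-target report: published reference values for this kind of
analysis depend on external genome annotations that cannot be recomputed
offline.
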