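# barcode-audit

Audit toolkit for DNA barcode reference libraries.

Large barcode libraries — thousands of ~658-bp CO1 sequences spanning the
fauna of a continent — are only useful for specimen identification if named
species actually correspond to distinct clusters of sequence variation.
`barcode-audit` implements the full analytical audit such a library needs,
for curators and systematists who want to flag taxa deserving further study:
potential cryptic species (deep intraspecific splits), potentially over-split
taxa (species merging into one cluster), and species whose identification is
compromised by barcode sharing (identical sequences in two or more species,
e.g. through mitochondrial introgression after Pleistocene range shifts).

## What it computes

* **Quality control** — minimum unambiguous-length filter (default ≥500 bp of
  A/C/G/T) and a stop-codon screen under the invertebrate mitochondrial code
  (translation table 5) that flags probable NUMTs.
* **K2P distances** — Kimura two-parameter distances with pairwise deletion:
  `d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q)` with *P*, *Q* the transition and
  transversion proportions over pairwise-complete sites.
* **Barcode gap** — per species, the maximum intraspecific distance versus
  the nearest-neighbour (minimum interspecific) distance; a gap is present
  iff `max_intra < d_NN`.
* **Haplotype completeness** — haplotype collapsing plus the bias-corrected
  Chao1 asymptotic richness `Ĥ = H + ((n−1)/n)·f₁²/(2f₂)`, reporting the
  fraction of haplotype diversity retrieved `R = H/Ĥ` and the number of
  haplotypes left to sample `L = Ĥ − H`.
* **Trees & monophyly** — NJ and ultrametric UPGMA trees from K2P distances,
  strict-clock calibration (1.5% pairwise divergence per Myr), and per-species
  classification as mono-, para- or polyphyletic.
* **MOTU delimitation** — single-linkage clustering at a fixed 2.5%
  threshold, and a single-threshold GMYC (General Mixed Yule Coalescent)
  model that locates the transition age between Yule (between-species) and
  coalescent (within-species) branching on an ultrametric tree by maximum
  likelihood, with an LR test against a one-process coalescent null.
* **Concordance** — each species versus any MOTU partition:
  **Match** (one MOTU, exclusive), **Merge** (one MOTU, shared),
  **Split** (several MOTUs, exclusive), **Mixture** (several, ≥1 shared).
* **Barcode sharing** — cross-species identical sequences, per-species
  diagnosability (fixed diagnostic sites), and sharing summaries stratified
  by Last-Glacial-Maximum region (north/alpine, mid-latitude, south), family
  (with a Pearson χ² test) and genus (Spearman rank correlation with genus
  size).
* **Synthetic data** — a generator with full ground truth (Yule species tree,
  within-species coalescents, K80 substitution with a purifying-selection
  stop-codon constraint, injected introgression / deep splits / over-splits)
  so the entire pipeline is testable without downloading anything.

## Worked example

```python
from barcode_audit import SimulationConfig, generate_dataset, run_audit

config = SimulationConfig(n_species=20, specimens_per_species=10)
records, truth = generate_dataset(config, seed=7)
report = run_audit(records=records)

print(f"barcode gap: {report.gap['n_with_gap']}/{report.gap['n_species_assessed']} "
      f"species ({report.gap['pct_with_gap']:.1f}%)")
```

Output for this seed:

```
records kept after QC : 200/200
barcode gap           : 16/20 species (80.0%)
mean max intra / NN   : 1.14% / 2.80%
monophyletic species  : 95.0%
haplotype recovery R  : 0.58
2.5% threshold MOTUs  : 13 ({'Match': 7, 'Merge': 13, 'Split': 0, 'Mixture': 0})
GMYC entities         : 8 ({'Match': 3, 'Merge': 17, 'Split': 0, 'Mixture': 0})
barcode sharing       : 0/20 species
```

Reading it: all 200 simulated records pass QC; 16 of 20 species show a
barcode gap; intraspecific variation averages a quarter of the distance to
the nearest neighbour; and because this simulation draws many recent
speciations from a Yule process, several young species pairs fall under the
2.5% threshold and merge — the audit reports them as Merge cases exactly as
it would flag potentially over-split taxa in a real library.

The same analyses are available from the shell:

```bash
barcode-audit simulate --n-species 20 --seed 7 --out data/
barcode-audit run --fasta data/sequences.fasta --meta data/metadata.tsv --out audit/
barcode-audit gap --fasta data/sequences.fasta --meta data/metadata.tsv --plot gap.png
```

Real datasets enter through `read_dataset(fasta, metadata_tsv)`: a FASTA on
a common 658-position frame plus a tab-separated table with columns
`specimen_id, species, genus, family, region` (optionally `country,
latitude, longitude, offset`).

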