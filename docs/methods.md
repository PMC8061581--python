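# Methods

This note documents the models behind `barcode-audit`, their assumptions,
the defaults and why they were chosen, and the numerical conventions that
matter when interpreting results.

## Coordinate frame and quality control

All sequences live on a fixed aligned frame (default 658 positions, the
standard CO1 barcode amplicon), 1-based inclusive coordinates.  Partial
sequences are placed on the frame via an explicit per-record `offset` column
(1-based position of the first base; default 1) and padded with `-`.  The
reading frame of the amplicon is not assumed: the stop-codon screen
translates all three frames, takes the frame with the fewest stops (ties go
to the lowest frame index) and flags the record when even that frame
contains a stop.  This auto-detection is robust to primer-offset variants,
at the cost that a single stop in the true frame can be masked when another
frame happens to be stop-free — which is why the screen targets NUMTs
(which typically carry several stops) rather than single nonsense mutations.
Codons containing gaps or ambiguity codes are untranslatable and never count
as stops.  The genetic code is the invertebrate mitochondrial code
(translation table 5; stop codons TAA and TAG only — AGA/AGG code for
serine).  The length filter requires ≥500 unambiguous (A/C/G/T) positions;
both thresholds are configurable, the length filter is applied first.

## K2P distances

Distances use the Kimura two-parameter model,
`d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q)`, with transition proportion *P* and
transversion proportion *Q* computed by **pairwise deletion**: only sites
where both sequences are unambiguous enter a pair's counts.  A distance is
reported only when at least `min_overlap` (default 100) sites are pairwise
complete; pairs beyond the model's correctable range (a log argument ≤ 0)
raise a saturation error rather than being clamped, and appear as missing in
the matrix.  Pairwise deletion matches common barcode-database practice;
complete-case deletion would discard most sites in libraries with ragged
ends.

## Barcode gap

Per species with ≥2 specimens: `max_intra` is the maximum conspecific K2P
distance, `d_NN` the minimum distance from any member to any heterospecific
specimen (whose species is reported as the nearest neighbour).  The gap flag
is `max_intra < d_NN`; an exact tie counts as **no** gap (the diagonal of
the gap scatter is conservatively treated as absence).  Singletons get an NN
distance but no gap call.

## Haplotypes and Chao1 completeness

Two sequences are "identical" iff they disagree at zero jointly-unambiguous
positions and share at least `min_overlap` (default 500) such positions —
the same relation is used for haplotype collapsing, barcode sharing and the
diagnosability fallback, so the three analyses cannot disagree about what
"the same barcode" means.  The 500-site floor mirrors the QC length
threshold.  Because identity over partial sequences is non-transitive,
collapsing is greedy and deterministic: sequences are processed in
decreasing order of unambiguous length (ties by specimen id) and join the
first existing haplotype whose representative (its founder, the most
complete member) they match.

Sampling completeness per species uses the bias-corrected Chao1 estimator
on haplotype abundances: `Ĥ = H + ((n−1)/n) f₁²/(2f₂)` when doubletons
exist, `Ĥ = H + ((n−1)/n) f₁(f₁−1)/2` when `f₂ = 0`.  Reported per species:
N, H, Ĥ, `R = H/Ĥ`, `L = Ĥ − H`.  Species with fewer than 6 specimens are
excluded (too little information for an asymptote).  The pooled summary
reports both the pooled ratio `ΣH/ΣĤ` (used in the consolidated report) and
the unweighted mean of per-species R, since the two differ under uneven
sampling.  Chao1 is a lower-bound-style estimator: simulation shows it is
accurate (mean error <10%) when the observed fraction of haplotypes is
≳0.7, and increasingly negatively biased below that — interpolation/
extrapolation curves and coverage-based estimators are out of scope.

## Trees, calibration, monophyly

NJ follows Saitou–Nei agglomeration; a negative branch-length estimate is
clamped to zero with the deficit moved to the sister branch so the pair sum
is preserved, and the unrooted result is midpoint-rooted.  UPGMA
(average linkage, heights = half the merge distance) provides the
ultrametric trees used for calibration and GMYC; `scipy`'s average-linkage
implementation stands behind it.  Trees are built per family to bound
matrix sizes; distances, sharing and threshold clustering are global.

Calibration assumes a strict molecular clock with pairwise divergence
accumulating at 1.5%/Myr (a conventional arthropod mitochondrial rate), so a
node at per-lineage height *h* substitutions/site has age `2h/0.015` Myr.

A species is **monophyletic** iff the leaves under its MRCA are exactly its
members; otherwise **paraphyletic** when the intruding leaves form a single
clade and **polyphyletic** when they do not.  The para/poly distinction has
no universally agreed operational definition; the single-intruder-clade rule
used here is the simplest one consistent with the terms.  Monophyly on
distance trees (UPGMA/NJ) approximates what model-based trees would give;
a user-supplied newick tree can be substituted.  Where sequences are
available the classifier also reports whether a species shares a barcode
with any of its intruders — useful to separate sharing-driven
non-monophyly from mere branch overlap.

## MOTU delimitation

**Fixed threshold.** Single-linkage connected components under
`d < 0.025`; a distance exactly at the threshold does not link.  Single
linkage is the natural graph formulation of "any conspecific path below the
threshold", and 2.5% is the conventional intra/interspecific cutoff for
Lepidoptera-scale barcoding.  Specimens with missing distances become
singleton MOTUs (logged) since their linkage cannot be assessed.  The
threshold flags (`deep_split`: max_intra **>** 2.5%; `shallow_neighbor`:
d_NN **<** 2.5%) use strict inequalities.

**GMYC (single threshold).**  On an ultrametric binary tree, internal nodes
older than a threshold age *T* are speciation (Yule) events; younger nodes
are coalescent events inside the clusters subtended at *T*.  Both processes
are formulated backward in time from the tips.  Each inter-event interval
*x_i* contributes `ln b_i − b_i x_i`, with `b_i = λ_yule·k_i` above the
threshold (*k_i* species lineages) and `b_i = λ_coal·Σ_j n_ij(n_ij−1)`
below (*n_ij* lineages in cluster *j*); the event closing an interval takes
its `ln b_i` from that interval, and the likelihood is conditioned on the
root event (no ln-term for the root), the standard convention for
genealogical likelihoods.  The scaling exponents of the general model are
fixed at 1; only the two rates are estimated, in closed form as
events / lineage-weighted-time per process.  Candidate thresholds are the
midpoints between consecutive internal-node ages plus one candidate above
the root — which reproduces the one-process coalescent null exactly, so
`logL_mixed ≥ logL_null` holds by construction — and one below the youngest
node (pure Yule).  Exact age ties (e.g. zero-length branches after
haplotype collapsing) are broken by a deterministic jitter of
1e−12 × (reverse preorder index), which keeps parent ages strictly above
child ages.

The LR statistic `2(logL_mixed − logL_null)` is referred to χ² with **3**
degrees of freedom (the threshold plus the two process parameters).  This
df was chosen by calibration: on 200 single-population coalescent trees
(n = 20, three independent seed sets) df = 2 rejects a true null at
0.075–0.17 at α = 0.05 — the threshold maximisation makes the test
anti-conservative — while the root-conditioned df = 3 test rejects at
0.02–0.05 and still recovers two clusters, with significance, in 100% of
two-cluster trees whose stem is 50× the within-cluster depth.  The GMYC
stage runs per family on unique haplotypes (collapsing first is the
documented best practice and removes the zero-length branches that degrade
the fit); assignments are mapped back to specimens afterwards.

**Concordance.**  For any MOTU partition, per species: one MOTU and no
other species in it → Match; one MOTU, shared → Merge; several MOTUs, none
shared → Split; several MOTUs, at least one shared → Mixture.  The four
categories partition the classified species by construction.  Proprietary
barcode-database clustering systems are proxied by the threshold method;
their counts are not comparable one-to-one.

## Barcode sharing and diagnosability

Two specimens of different species share a barcode iff they are identical
under the relation above.  Species-level flags, the supporting species-pair
list, and summaries by LGM region, family and genus are reported.  Region
assignment is an input column — range-map judgement, not automatic
georeferencing.  The family (or genus) k×2 table (sharing / not) is tested
with Pearson's χ², df = k−1, no continuity correction (standard for k > 2);
empty groups are dropped with a warning, and a degenerate all-zero column
yields statistic 0.  The genus analysis reports Spearman's rank correlation
(average ranks for ties, t-approximation p-value) between genus size and
sharing count.

A position is diagnostic for a species iff all its unambiguous states there
equal one state that no other species' unambiguous record carries.  A
species with no such site is still diagnosable when it shares no haplotype
with any other species (a diagnostic combination of states); this makes
"has a diagnostic site" and "appears in a sharing pair" mutually exclusive
by construction.

## Synthetic data: what it emulates, what it does not

The generator produces an ultrametric genealogy — a Yule species tree
(forward simulation at `yule_rate` events/Myr) whose terminal branches are
extended by a stem (`species_stem_myr`), with a Kingman coalescent grafted
at each species tip — and evolves sequences along it under K80 with
transition/transversion rate ratio κ.  Parameterisation is deliberately
minimal: within-species coalescent depths are scaled directly in
substitutions/site (`within_species_depth` = expected pairwise TMRCA; no
separate Nₑ and µ), and the species tree is converted to substitutions/site
through the same 1.5%/Myr pairwise clock the audit assumes.  Coalescents
are conditioned (by rejection) to fit under the species' terminal branch.
Substitutions are conditioned on never creating a frame-1 stop codon and the
root sequence is drawn stop-free — mimicking purifying selection so that
simulated barcodes pass the NUMT screen, as real functional CO1 does.

Defaults (20 species × 10 specimens, `yule_rate` 0.5/Myr, stem 1.5 Myr,
depth 0.003 subs/site, κ = 4) give expected intraspecific pairwise
divergence ≈0.6% and interspecific divergence ≥~4.5% with a realistic tail
of young species pairs below the 2.5% threshold — i.e. an audit of these
conditions shows a mostly clean library with some Merge cases, comparable
to continental-scale insect libraries.  κ = 4 is a typical mitochondrial
transition bias.  Tests that assert *perfect* recovery use an explicitly
well-separated configuration (stem 4 Myr, depth 0.0015) where the stem
dominates the crown by more than an order of magnitude.

Injected events create the phenomena the audit is designed to flag:
*sharing* copies a donor haplotype into recipient specimens
(mitochondrial introgression); *deep split* replaces part of a species with
a haplogroup evolved an extra `extra_depth` away (cryptic divergence);
*over-split* relabels part of one true cluster as a second nominal species.
The emitted ground truth records the original partition, the label map, and
every injected event.

Not emulated: recombination, selection beyond the stop-codon constraint,
rate variation among lineages or sites, migration/isolation-by-distance
within species, misidentification noise, and alignment error (sequences are
born aligned).  Passing tests on synthetic data therefore demonstrate the
*algorithms* recover known truth under the stated model — not that real
libraries satisfy that model.

## Determinism and numerics

Every stochastic component takes an explicit seed or `numpy.random.Generator`
and threads a single generator through all stages, so identical
configuration + seed gives byte-identical FASTA/TSV/JSON outputs.  Haplotype
collapsing, MOTU numbering (first-occurrence order) and concordance are
deterministic given the input order.  Ultrametricity is verified to a
relative 1e−9 before calibration or GMYC; UPGMA heights are clamped at 0
against floating-point underflow.  The audit report stores numerators and
denominators alongside every percentage so all summary values can be
recomputed from the per-species tables written next to it.

## Known limitations

* Monophyly percentages from UPGMA/NJ trees approximate, not reproduce,
  what Bayesian relaxed/strict-clock trees would give.
* The GMYC implementation is single-threshold with fixed scaling exponents;
  multiple-threshold variants and Bayesian GMYC are out of scope.
* Chao1 under-estimates true richness under sparse or very uneven sampling;
  R values for weakly sampled species are optimistic about completeness.
* Threshold clustering is a proxy for proprietary clustering systems, not a
  reimplementation; absolute MOTU counts differ.
* The sharing analysis treats identity over ≥500 shared sites as "the same
  barcode"; libraries with many short fragments may over-link.
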