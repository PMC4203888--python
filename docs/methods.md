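# Methods

This note documents the models and procedures implemented in `dendrodiv`,
the defaults they use, the synthetic data they are validated on, and the
numerical and design choices that were genuinely open.

## Ortholog and metagene mapping

Orthologs between the two platforms' transcript sets are reciprocal best
BLAST hits: after discarding hits with e-value above `evalue_max`
(default 1e-5), each query's hits are ranked by (e-value ascending, bitscore
descending); a query has a best hit only if a single subject wins. Pairs
(a, b) are kept when b is a's unique best hit and vice versa.

*Tie handling.* Multiple hits between the same query/subject pair collapse to
that pair's best hit. A residual tie between **distinct** subjects on both
e-value and bitscore is treated as ambiguous: the query gets no best hit.
Ambiguity-as-exclusion is the conservative choice for ortholog calling;
breaking such ties lexicographically would manufacture orthology from what is
really a paralogous family.

Probe sets attach to transcripts in two steps. A probe's *call* is its
top-ranked hit, accepted only when its matched bases (alignment length minus
mismatches) reach `min_probe_match` = 24 — i.e. at most one mismatching base
in a 25-mer. A probe set maps to transcript T when at least the quorum of its
probes call T: 9 for the standard 11-probe sets, generalized as
⌈0.818·n⌉ for platforms with other probe counts.

The union of probe-set→transcript links and transcript-level ortholog pairs
forms an undirected graph. Each connected component containing probe sets of
both species is a **metagene**; components confined to one species carry no
cross-species information and are dropped (counted in the output map).
Unique 1:1 matches are listed first in the id ordering; ids are otherwise
assigned by sorted member id, so the map is deterministic. A metagene's
expression per species is the per-array **median** over member probe-set
rows; even-sized sets use the mean of the two central values.

## Normalization

Probe-level log intensities are summarized per probe set by the upper-decile
statistic (90th percentile over member probes, per array), then each array is
median-centered and divided by its interdecile range (q90 − q10), putting all
arrays on a common scale with median 0 and interdecile range 1. Percentiles
use linear interpolation between order statistics everywhere — no convention
was prescribed, and this is the scientific-computing default; the worked
examples in the tests evaluate the chosen rule by hand. The order of
operations is summarize → center/scale. Inputs are assumed log-scale;
`log2_transform` is available for raw intensities. Degenerate arrays
(q90 = q10) are an error, not a silent pass-through.

## Divergence statistics

*Differential expression.* Per-metagene two-sample t-tests use the **Welch**
(unequal-variance) form: the replicate groups are unbalanced (9 vs 14 vs 5)
and there is no reason to pool variances. Rows constant in both groups with
equal means get t = 0, p = 1 (no evidence), with unequal means p = 0
(perfect separation). Multiple testing is controlled with the
Benjamini–Hochberg step-up procedure at q = 0.001 by default.

*Top-fraction overlap.* Genes are ranked within each array (rank 1 = highest,
average ranks for ties), the per-gene median rank across replicates is taken,
and the top set is the ⌊f·N⌋ genes of smallest median rank — expanded to
include all genes tied at the boundary, which keeps the set deterministic and
order-independent at the cost of occasionally exceeding ⌊f·N⌋. Overlap
between two sets is |A∩B| divided by the *denominator species' own* top-set
size, so cross-species overlaps can be asymmetric when tie expansion differs.

*Arcsine test.* Tissue overlap fractions are transformed by arcsin(√p) (the
variance-stabilizing transform for proportions) and compared against a
transformed reference overlap with a one-sample two-sided t-test.

*Rank concordance.* For each k in [31, 500]: among species-A genes with rank
≤ k, the fraction whose ortholog's species-B rank is ≤ k. Identical rankings
give 1 everywhere; independent rankings concentrate around k/N. Confidence
bands are **Clopper–Pearson exact** intervals at level 1 − (1−0.95)/500 —
exact because the number of trials can be as small as 31, where normal
approximations fail; the Bonferroni factor 500 covers the ranks examined.

*Two-proportion test.* Exposed in z-pooled (default), chi-square and Fisher
exact variants. The variants disagree noticeably at small counts — e.g. for
29/54 vs 25/54 the z-pooled form gives p ≈ 0.44 and Fisher p ≈ 0.56 — so the
choice is explicit in the API rather than hidden.

## Molecular evolution

Each codon position is classified by how many of the three alternative bases
preserve the amino acid under the standard genetic code: 0 → nondegenerate,
3 → four-fold, otherwise two-fold (isoleucine's three-fold sites fold into
the two-fold class). Codon columns containing gaps, ambiguity codes or stop
codons are skipped and counted. Site counts L0, L2, L4 average the two
sequences' per-class tallies; when the two codons assign a differing site to
different classes, each sequence contributes half a count to its own class.
Codons differing at more than one position classify each differing site
independently by its own position — no substitution-pathway averaging. At
rodent-scale divergence (K ≈ 0.17) the bias from skipping pathway averaging
is negligible relative to sampling noise.

Per class, transition and transversion proportions (P_i, Q_i) are corrected
for multiple hits with the Kimura two-parameter model:

    A = ½·ln(1/(1−2P−Q)) − ¼·ln(1/(1−2Q))
    B = ½·ln(1/(1−2Q)),   K = A + B

valid only while 1−2P−Q > 0 and 1−2Q > 0; outside that region the estimate is
flagged saturated and the gene excluded. Rates combine classes as

    Ks = (L2·A2 + L4·A4)/(L2 + L4) + B4
    Ka = A0 + (L0·B0 + L2·B2)/(L0 + L2)

— transitions at two-fold sites count as synonymous and transversions as
non-synonymous, the standard two-fold/four-fold treatment of the
Li (1993)/Pamilo–Bianchi estimator. UTR distances are plain K2P over non-gap
aligned columns. The rate table keeps genes strictly longer than `min_aa`
(default 100) compared amino acids — a 100-aa gene is excluded — and reports
across-gene means with standard errors. Group comparisons (e.g. divergent vs
non-divergent genes) use the tie-corrected Kruskal–Wallis H with a chi-square
reference.

## In situ D/S quantification

A transect carries background-subtracted intensities along a traced path
from the dendrite origin (0 µm) outward, plus soma reference pixels from the
same cell. The profile statistic bins distances at 1 µm over 0–40 µm (the
source plots are continuous, so the bin width is a display-resolution choice)
and divides per-bin mean intensity by the **mean** soma pixel value; empty
bins are missing, never zero. The scalar summary divides the **median**
dendrite intensity in the 5–40 µm window (proximal pixels excluded to limit
soma bleed-over) by the **median** soma pixel value — "median, averaged over
soma traces" was ambiguous between median-then-average and
average-then-median; the median-based reading was chosen for robustness and
the window is configurable. Dendrites with fewer than 3 in-window samples
are excluded with a logged reason. Species are compared by a Welch t-test on
natural-log ratios; group means are reported untransformed. Background
subtraction is assumed done upstream; `subtract_background` offers a
constant-offset correction clipped at zero.

## Synthetic data: what it emulates and what it does not

The generators reproduce the statistical structure the analysis assumes, not
the physics of the assay:

* **Expression.** Per-gene baselines and i.i.d. Gaussian replicate noise on
  the log scale; a planted fraction π of genes shifted ±δ in species B. The
  defaults are the study design: 9 vs 14 replicates, π = 0.2, δ = 2σ, σ = 1.
  Not emulated: probe-level hybridization physics, scanner noise,
  inter-array correlation, heavy-tailed intensity distributions. Passing
  tests therefore validate the statistical machinery, not robustness to
  array artifacts.
* **Orthology.** Transcript pairs as mutual best hits with off-target decoys,
  one-directional (non-reciprocal) extras, many-to-many probe-set
  arrangements, and optional 23/25 sub-threshold probes; the planted
  metagene partition is returned as ground truth. Not emulated: sequence
  evolution driving hit scores — e-values and bitscores are structural, not
  derived from alignments.
* **Codon pairs.** Two descendants of a random sense-codon ancestor evolve
  independently; proposals follow a K2P kernel (transition probability
  κ/(κ+2), κ = 2 by default), mutations to stop codons are rejected, and
  non-synonymous proposals are accepted with probability ω. `branch_length`
  is the expected number of proposed substitutions per site between the two
  sequences. Every accepted substitution is logged with its site, degeneracy
  class and transition/transversion type, which gives the tests an exact
  bookkeeping oracle at low divergence. Not emulated: codon-usage bias,
  rate variation across sites, indels.
* **Transects.** Soma pixels scatter multiplicatively (log-normal) around a
  level S0 and dendrite pixels around r·S0 with a flat or linearly decaying
  shape. Multiplicative noise leaves medians unbiased, so the planted r is
  recovered without correction. Per-dendrite biological scatter for power
  studies is generated directly on the ratio scale
  (`simulate_ds_ratios`, log-normal around the planted median).

A single root seed derives all per-component generators through
`SeedSequence` spawning; every output, including the files the pipeline
writes, is byte-for-byte reproducible under a fixed seed.

## Problem sizes in the checked runs

The test suite and `scripts/acceptance.py` scale the study down while keeping
its structure: 100 random orthology instances of 20–120 transcript pairs
(up to ~500 graph nodes) for oracle equivalence; 200 all-null expression
simulations of 5,000 genes at 9 vs 14 replicates for FDR calibration; a
5,000-gene planted-divergence run; rank-concordance checks on the 3,839-gene
ortholog universe of the public tissue panel; 50 genes × 2,000 codons per
selection regime for rate recovery; 50 dendrites for D/S recovery and 500
simulated experiments (9 dendrites per species) for power. The end-to-end
study (`pipeline.run_synthetic_study`) uses 700 transcript pairs so the full
31–500 rank window remains meaningful, 40 genes × 500 codons at branch length
0.18 and ω = 0.15 (chosen to sit at mouse–rat-like Ks ≈ 0.17 and
Ka/Ks ≈ 0.17), and 9 dendrites per species at planted D/S 0.214 vs 0.088 —
the levels measured for the most species-divergent probe.

## Known limitations

* **Recovery at the stringent FDR is partial by design of the design.** With
  δ = 2σ and 9 vs 14 replicates the Welch noncentrality is
  2/√(1/9 + 1/14) ≈ 4.7, while BH at q = 0.001 with a fifth of genes shifted
  places the rejection threshold near |t| ≈ 5. Per-gene power is ≈ 0.4, so
  the flagged set's Jaccard overlap with the planted set plateaus around 0.4
  — almost no false positives, many false negatives. The acceptance-level
  test asserting Jaccard ≥ 0.8 under exactly these conditions therefore
  fails, and is left failing rather than met by enlarging the effect size or
  relaxing the threshold: reaching 0.8 would need δ ≈ 2.6σ or q ≈ 0.05.
* The Ka/Ks estimator shares the known small biases of approximate counting
  methods (no pathway averaging, deterministic site classes); the neutral
  simulation recovers mean Ka/Ks ≈ 0.96–0.97 rather than exactly 1, partly
  because stop-codon rejection suppresses a few non-synonymous paths.
* The two-proportion test's printed p-value depends on the variant; no
  single variant is canonical at n ≈ 54.
* Full RMA background correction, image segmentation, alignment itself
  (T-Coffee/blastn) and GO enrichment are out of scope; the package consumes
  their outputs.
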