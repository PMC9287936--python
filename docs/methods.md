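# Methods

## The model

`mqtlmap` treats the projected peaks of literature QTLs on one linkage
group as noisy observations of a small number of underlying loci. With
x_i the peak of QTL i on the consensus map (cM) and σ_i its known standard
deviation, the likelihood of K meta-QTLs at positions μ_1..μ_K with mixing
proportions π_1..π_K is

    ln L = Σ_i ln Σ_k π_k N(x_i; μ_k, σ_i²).

The per-observation variances are *fixed*, not estimated: σ_i is derived
from the QTL's 95% CI as σ_i = width/3.92, the normal-interval convention.
Consequently precise QTLs (narrow CIs) dominate both the component means
and the assignment, which is the point of weighting by mapping precision.

K is selected by minimising AIC = −2 ln L + 2p with p = 2K−1 free
parameters (K means, K−1 proportions), over K = 1..min(10, n); ties go to
the smaller K. The parameter count is a configurable convention — the
criterion family has variants (AICc, BIC, ...) and the free-proportion
count is the standard mixture choice.

After selection, QTLs are hard-assigned to the component with maximal
posterior responsibility (ties toward the left-most component, so member
lists are disjoint and deterministic). Each non-empty component becomes a
meta-QTL with

* position = inverse-variance weighted mean of its members,
* se = (Σ 1/σ_i²)^(−1/2), 95% CI = position ± 1.96 se,
* PVE (%) = arithmetic mean of member R² × 100 (a reporting convention;
  the weighted alternative changes little and is not what summary tables
  in this literature appear to use),
* supporting-experiment count = number of distinct experiment ids among
  members.

Only meta-QTLs supported by ≥ 2 independent experiments (configurable)
are reported as final — a single experiment re-detecting its own QTL in
several environments is not independent evidence.

## EM optimisation and determinism

The likelihood is maximised by EM with the means' M-step an
inverse-variance weighted average under the responsibilities. Numerical
choices: proportions floored at 1e−6 (prevents log-underflow of emptied
components), convergence at |Δ ln L| < 1e−10 or 1000 sweeps, K=1 returned
in closed form (the global weighted mean — no iteration, no start
dependence).

Multi-start schedule: in 1-D the clusters of any optimal hard assignment
are contiguous in position, so for small n (all contiguous partitions
numbering ≤ 512, i.e. roughly n ≤ 12 at moderate K) EM is started from
*every* contiguous partition of the sorted peaks — the global optimum is
then found deterministically, and the test-suite's independent exhaustive
search agrees with the fitted log-likelihood to 1e−6 on hundreds of random
instances. For larger n the schedule is quantile split + largest-gap split
+ 5 seeded jittered starts, with a coarse 60-sweep pass pruning the start
bank to the best 8 before full convergence. Everything operates on the
sorted positions with a fixed internal seed, so results are invariant to
the input order of QTLs.

## Upstream: harmonisation, consensus map, projection

* Missing LOD → 2.5. Missing CI → imputed from population size and R²:
  530/(N·R²) for {BC, F2, F2:3, F3:4, TC} (F2-derived recombination
  structure) and 163/(N·R²) for {RIL, DH} (fully inbred). Assigning TC and
  advanced F-generations to the F2 family and DH to the RIL family is a
  judgement call, logged per record. An R² supplied as a percent (> 1) is
  rescaled with a warning.
* Consensus map: the reference scale is authoritative; each study map is
  merged against it independently (star topology, so input order is
  irrelevant). Shared markers whose order disagrees are resolved by keeping
  a maximum-size order-consistent subset (longest increasing subsequence of
  reference ranks along the study order; among equal-length solutions the
  lexicographically smallest reference-index sequence, a deterministic
  tie-break). Study-only markers are interpolated homothetically between
  their flanking retained shared markers; beyond the terminal shared
  markers the nearest interval's ratio is extended and the marker flagged
  "extrapolated".
* Projection transfers the peak and both CI endpoints *independently*,
  each through its own flanking shared interval (piecewise, not a single
  width scaling). QTLs known only by flanking-marker names are placed by
  locating those names on the consensus; with only one flank placeable the
  imputed CI width is laid out from the known flank and the peak put at the
  CI midpoint (the symmetric choice; the source peak is unknown in that
  situation). SNP-study QTLs given in bp are converted through the map's
  physical anchors. A projected position extrapolating beyond 20% of the
  group length outside the shared span discards the QTL (configurable cap;
  prevents wild extrapolation), and every discard is recorded with its
  reason so inputs are conserved: projected + discarded = accepted.

## Physical anchoring, genes, enrichment, expression

Genetic→physical conversion interpolates linearly between the nearest
anchors carrying both cM and bp (p = p1 + (p2−p1)(g−g1)/(g2−g1)), after
dropping the minimal set of bp-inverted anchors (again an LIS rule —
reference maps contain inversions relative to the assembly). Results are
rounded to integer bp for reporting; an exact mode backs the
round-trip-inverse property. Candidate genes are all annotation genes
overlapping the meta-QTL's physical interval by ≥ 1 bp (the inclusive
convention; containment is stricter than interval uncertainty warrants).
GO over-representation uses the one-sided hypergeometric upper tail with a
raw P < 0.01 call and no multiple-testing correction by default (a
Benjamini–Hochberg switch exists but is off, matching the raw-P practice
of this literature's enrichment services). Expression profiles are FPKM
over 0–38 days after pollination, normalised per gene by the profile
maximum; a gene is "expressed in grain" when max FPKM ≥ 1 and a
developmental window (before 10 DAP / 10–30 DAP / after 30 DAP) is "high"
when its mean normalised value is ≥ 0.5. Both thresholds are config keys;
the source literature classifies without defining them, so the category
counts there are not exactly reproducible and these defaults are our
explicit operationalisation. Window combinations other than the named
early/mid/late/early-and-late patterns fall into a residual category.

## The synthetic-data generator

The generator emulates the published study's scale and missing-data
structure: 10 linkage groups, 25 experiments of mixed population types
(14 publishing their own maps, 2 SNP-based reporting physical
coordinates), 87 + 195 QTLs around 21 + 47 planted true loci, R²
log-uniform on 1–90%, per-QTL σ log-uniform on 0.19–120 cM (95% CI widths
≈ 0.7–470 cM), 30% of CIs and LODs blanked so the imputation paths are
exercised, study maps warped by a smooth monotone distortion (±10%
amplitude) of the reference scale with half the markers shared, and a
monotone-cubic cM→bp curve per chromosome so anchoring is invertible by
construction. All randomness flows from one seed through named generator
streams; bundles are byte-identical across runs.

What it does *not* emulate: genotype/phenotype data (QTL peaks are
sampled, not mapped), linkage-disequilibrium structure, non-normal peak
errors, systematically biased study maps, or annotation complexity
(single-exon genes, uniform tiling). Passing tests therefore demonstrate
the correctness of the integration/clustering machinery under the stated
noise model, not robustness to violations of it.

The K-recovery study uses its own, cleaner conditions: 2–4 true loci per
chromosome separated by ≥ 5× the typical σ (σ uniform on 1.5–2.5 cM,
separation ≥ 10 cM), 4–8 member QTLs each, 200 replicates. Under these
conditions AIC recovers the true K in ≈ 94% of replicates and the reported
95% CIs cover the true positions at ≈ 93% — close to nominal; the residual
shortfall comes from replicates where K is mis-selected and from the hard
assignment discarding ambiguous members.

## Problem sizes and runtime

Default test and acceptance sizes are chosen for single-CPU runs: 500
random instances for the exhaustive-search comparison (n ≤ 8, where
exhaustive enumeration is exact and cheap), 200 replicates for the
recovery study, and the full 282-QTL synthetic corpus for the end-to-end
pipeline. The whole suite runs in a few minutes.

## Known limitations

* The published meta-QTL tables depend on the exact EM variant and
  selection rule of the original GUI software and on supplementary per-QTL
  tables not redistributed here; this package reproduces the *method* and
  verifies it against ground truth and exhaustive search, not against
  those tables bit-for-bit.
* The consensus map inherits the reference map's marker order; no
  re-estimation of a joint map is attempted.
* One cM scale per linkage group is assumed; QTLs spanning multiple
  groups are not representable.
* PVE aggregation and the expression "high window" rule are reporting
  conventions, flagged as such above.
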