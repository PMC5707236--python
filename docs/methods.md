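# Methods

This note documents the models and procedures `genconn` implements, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Genotypes

**Markers.** 5-HTTLPR is treated as biallelic S/L after collapsing the
low-expressing Lg variant into S and La into L. COMT rs4680 alleles are
written Met (=A) and Val (=G); rs165599 alleles A and G. Genotype
strings are unordered and case-insensitive; `NA` and empty fields are
missing.

**Hardy-Weinberg equilibrium.** Expected genotype counts are n·p²,
2n·p·q, n·q² at the observed allele frequencies; the statistic
Σ(obs−exp)²/exp is referred to a chi-square distribution with one degree
of freedom, without continuity correction. The test is undefined for
monomorphic samples. Report tables round to two decimals, half away
from zero.

**Haplotype phasing.** The two COMT markers are phased with the
standard two-locus EM estimator: haplotype frequencies maximize the
multinomial likelihood under random mating, with only double
heterozygotes phase-ambiguous. Initialization is the
linkage-equilibrium product of allele frequencies, which is
deterministic; the EM log-likelihood is checked to be non-decreasing at
every iteration, and convergence means a maximum frequency change below
`tol` (default 1e-10, `max_iter` 1000). Posterior probabilities of
compatible haplotype pairs are proportional to products of haplotype
frequencies (×2 for heterozygous pairs). A pair is assigned only when
its posterior is strictly greater than 0.80; otherwise the subject's
phase is missing. In an all-double-heterozygote sample the likelihood
is symmetric between the two phase configurations; the EM is left at
that symmetric fixed point (posteriors 0.5, nothing assigned) rather
than breaking the tie arbitrarily. This estimator replaces a Bayesian
phasing program as a matter of design: at two markers the posterior
ordering, and hence the 0.80 assignment behaviour, is the same, and no
external binary is needed.

**Risk groups.** S-carrier vs L-homozygote for 5-HTTLPR; COMT risk when
rs4680 = Val/Val and/or rs165599 = A/A, non-risk when both markers are
genotyped and neither condition holds, missing when the available
genotypes cannot decide (e.g. rs4680 missing, rs165599 not A/A).

## Time-series cleanup

Cleaning operates on ROI-level series. Voxel-level nuisance regression
followed by ROI averaging commutes with ROI-level regression for
mean-based ROI signals (both are linear), so this is an approximation
only insofar as real extraction is not exactly mean-based.

**Nuisance regression.** Least-squares residualization against
[intercept | regressors | backward-difference first derivatives], the
regressors being the six rigid-body motion parameters and global/WM/CSF
signals supplied by the caller. The derivative of the first volume is
defined as 0. Exact duplicate columns are dropped; a design that
remains rank-deficient is an error naming the offending columns.

**Band-pass (0.008–0.08 Hz, TR 2 s).** Implemented as the exact
orthogonal projection onto the subspace of signals that are both
band-limited (binary FFT mask over [low, high]) and free of a linear
trend (the component along the masked trend direction is removed inside
the band). A projector is exactly idempotent; a graded (e.g. cosine)
roll-off was rejected because refiltering would re-attenuate
transition-band content — several percent RMS change on broadband
signals — violating idempotency. A pure linear ramp maps exactly to
zero; stop-band frequencies are removed entirely; the operation is
order-free and bit-reproducible.

**Scrubbing.** Framewise displacement is the sum of absolute backward
differences of the six motion parameters, rotations converted to arc
length on a 50 mm sphere. Volumes with FD above the threshold (default
0.5 mm) are removed together with 1 preceding and 2 following volumes
(all configurable). A subject is excluded when strictly more than one
third of volumes are removed. Scrubbed volumes are dropped before
correlation, not interpolated. The pipeline order is regression →
filtering → scrubbing-by-deletion; the order is configurable because
the original procedure's ordering is not fully specified.

## Network construction

Pearson correlations over retained volumes; pairs of ROIs whose centers
lie strictly less than 20 mm apart are zeroed (shared non-biological
signal between adjacent spheres), as is the diagonal. Constant ROI
series yield zero rows with a warning rather than aborting the subject.

**Proportional thresholding.** At density τ the k = round(τ·M) largest
edges are kept, with M = N(N−1)/2 counting *all* pairs — distance-zeroed
pairs simply hold value 0 and never rank among the strongest, mirroring
the sequencing of zeroing before thresholding. Rounding is half away
from zero; ties at the cutoff break by (row, column) lexicographic
order. Edges are ranked by signed value, so negative correlations never
enter at the studied densities; if fewer than k positive edges exist,
all positive edges are kept with a warning (an error only when none
exist). The density grid (default 1%…30% in 1% steps) produces nested
edge sets by construction, and the weighted and binary graphs share
each density's support.

## Community detection

**Modularity.** Classic weighted Newman modularity at resolution 1,
Q = Σ_c (e_cc − a_c²), computed from weight fractions; aggregated graphs
carry self-loops whose weight counts once in both the internal weight
and the strength.

**Louvain.** Two-phase greedy optimization with the node-visit order
shuffled by a seed; local moves only accept strict improvements
(tolerance 1e-12), ties between candidate communities break to the
lowest community index, and Q is non-decreasing across passes.

**Fine-tuning.** A steepest single-node refinement: all moves of any
node to any other module or a new singleton are scored, the single best
positive-gain move is applied, and the process repeats to a local
optimum. Q strictly increases over a finite move space, so termination
is guaranteed. This is a documented surrogate for a fine-tuning step
whose original specifics are not publicly available.

**Density selection.** The group partition is derived at one density,
chosen by a stability criterion (also a documented surrogate, and
injectable): at each candidate density Louvain (+ fine-tuning) runs with
a fixed seed set on the group-mean graph, and the density's score is the
mean pairwise normalized mutual information among all partitions from
that density and its grid neighbours. Densities whose graph leaves
nodes with zero degree are ineligible — an isolated node cannot be
assigned to any module — unless every candidate is fragmented. Ties go
to the lowest density. The final decomposition at the selected density
is best-of-50 seeded Louvain runs (highest Q; ties to the lowest seed),
and that single group-level partition is reused for every subject's
per-module measures.

## Network measures

Weighted shortest paths use connection lengths 1/w; unreachable pairs
contribute 0 to efficiency (never infinity). Binary variants use unit
lengths on the same support.

* **Global efficiency**: mean inverse shortest-path length over ordered
  pairs.
* **Local efficiency**: per node, the efficiency among its neighbours
  with paths confined to the neighbour subgraph. The weighted form
  follows the established weighted formulation with cube-root weighting:
  E(u) = Σ_{j≠h∈V(u)} (w_uj·w_uh·e_jh)^{1/3} / (k(k−1)), where e_jh is
  the inverse neighbour-subgraph path length. Nodes with fewer than two
  neighbours score 0. Note the cube root means the weighted variant
  does not reduce to the binary one on 0/1 weights unless all neighbour
  pairs are directly connected.
* **Participation coefficient**: P_i = 1 − Σ_m (κ_im/κ_i)² with κ the
  strength (weighted) or degree (binary); connectionless nodes score 0.
  Invariant under uniform rescaling of weights.
* **Maximized modularity**: best of 10 seeded Louvain + fine-tuning runs
  per subject graph (the seed count is configurable; single-run vs
  best-of-runs was an open choice and best-of-10 is the documented
  default).

The measure suite evaluates, at every grid density and for both
variants: whole-brain global efficiency, mean local efficiency and
maximized modularity, plus per-module mean local efficiency and
participation, using the fixed group partition.

## Inference

Per measure, the per-subject values across densities form a curve; the
trapezoidal AUC over the grid summarizes it into one
threshold-independent scalar. Two statistics are computed per density:
the group mean difference (risk − non-risk) and the difference of
within-group OLS slopes of measure on raw neuroticism score. The slope
is the tested interaction statistic, implemented in closed form (a
bivariate regression refit 5000 times per test makes the
normal-equations slope the practical choice; it is cross-checked against
standard regression software in the tests). Group labels are permuted
with group sizes preserved; the two-tailed p-value ranks |observed AUC|
against the permutation null with the +1 correction, so p ∈ (0, 1] and
a fixed seed makes the whole result bit-reproducible. No
multiple-testing correction is applied, matching the analysis this
pipeline reproduces; the result table records how many tests were run.

## Synthetic cohorts

The generator emulates the study conditions the pipeline assumes:
111 subjects, 259 ROIs, 300 volumes at TR 2 s, six near-equal modules;
HWE genotype draws at allele frequencies S = 0.50 (5-HTTLPR),
Met = 0.53 (rs4680), A = 0.69 (rs165599), with an optional two-marker
LD term for COMT; neuroticism ~ Normal(135.5, 18.9), independent of
genotype.

Time series are Gaussian draws from a per-subject block covariance:
within-module correlation 0.5, between-module 0.1 by default, ROI
coordinates scattered (25 mm jitter) around six well-separated anchors
in an MNI-like box so a realistic ~1–3% of pairs violates the 20 mm
rule without isolating any ROI. Global/WM/CSF components, random-walk
motion and occasional motion spikes (with matching signal artifacts) are
added so the cleanup stage has real work; all amplitudes are
configurable and zero disables them. An AR(1) option exists because
band-pass filtering induces autocorrelation in real data; the default is
white innovations.

**Planted effects live in the covariance**, not in the metrics, so the
entire chain — cleanup, correlation, thresholding, decomposition,
measures, inference — is exercised:

* S-carriers: between-module correlations involving the two designated
  "participation" modules are reduced by `effect_participation`
  (a group participation deficit);
* COMT-risk subjects: within-module correlation of the two designated
  "slope" modules is shifted by −`effect_slope`·z(neuroticism)
  (a genotype-moderated negative slope).

A covariance rendered non-positive-definite by effect injection is
shrunk toward the identity in 5% steps with a warning.

**Effect-size calibration.** The emulated study reports only p-values,
so planted effect sizes are calibration parameters, not reproductions.
Power of the S-carrier participation contrast (n = 111 subjects, 48
ROIs, 500 permutations, 16 seeds per point) as a function of
`effect_participation`: 0.01 → 0.56, 0.02 → 0.94, 0.03 → 1.00,
0.05 → 1.00. The default is frozen at 0.03, the smallest size with
power comfortably above 0.8. `effect_slope` defaults to 0.10 (a
within-module correlation shift of ±0.25 across ±2.5 SD of
neuroticism), which reliably reproduces the planted slope direction at
modest cohort sizes.

**What passing tests do and do not show.** The generator draws
stationary Gaussian signals with block-constant correlations; it does
not emulate hemodynamics, scanner drift spectra, spatially structured
noise, inter-subject variability in module topography, or
gene-by-environment structure. Recovery and power results therefore
validate the pipeline's statistical machinery under its own model
assumptions; they are not predictions about effect sizes in real
cohorts, and the original cohort's fMRI-dependent p-values are not
reproducible without its (undeposited) data.

## Validation studies and problem sizes

`genconn.validation` packages the standard checks at sizes chosen to
run comfortably on a single CPU:

* **Type-I error**: 1000 replicate cohorts with measure curves
  independent of labels (group sizes 80/31, n_perm = 500); the
  rejection rate at α = 0.05 matches the exact-test expectation
  25/501 ≈ 0.0499 within binomial spread (SD ≈ 0.007 at 1000
  replicates).
* **Power**: 50 replicate cohorts at the full n = 111 with a reduced
  ROI count (48; six modules of eight) and the ground-truth partition,
  running covariance → correlation → thresholding → participation →
  AUC → permutation. Using the true partition isolates the sensitivity
  of the statistics; community detection has its own exact-recovery
  checks.
* **End-to-end**: the full CLI chain on a seeded 40-subject, 48-ROI
  cohort with default (strong) modular contrast, checking recovery of
  the planted module count and of both planted effect directions.

## Known limitations

* Starts at ROI time series: no image-space preprocessing, no
  voxel-level eigenvariate extraction (synthetic mode generates nuisance
  series directly).
* Two-marker phasing only; no imputation or stratification control.
* The fine-tuning and density-selection procedures are documented
  surrogates for steps whose original specifics are unavailable; the
  selection strategy is pluggable for that reason.
* Louvain is a greedy heuristic; best-of-seeds mitigates but does not
  eliminate local optima on weakly modular graphs.
* The module-count and anatomical identity of real subnetworks require
  human inspection; the pipeline emits indices and coordinates only.
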