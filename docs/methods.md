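# Methods

This note records the models, conventions and numerical choices behind
`netprog`, and what the synthetic cohort generator does and does not
emulate.

## Pattern expression scoring

A network pattern is a weight vector `w` over its membership regions,
constructed zero-mean and unit-norm.  The raw score of subject `s` is

    raw_s = Σ_r w_r · (q_{s,r} − q̄_s − ref_r),

where `q` is the log regional profile restricted to the membership,
`q̄_s` its subject mean, and `ref` the healthy reference group's mean
centred log profile.  Because `w` sums to zero the subject-mean centring
makes scores invariant to any global rescaling of a subject's scan, and
scoring is linear in the residual log profile.  Scores are z-scored
against the healthy group's raw scores using the sample SD (ddof = 1;
the convention is recorded on every score set), so controls score
0 ± 1 by construction.  Single-region patterns are rejected at
calibration (the reference SD is then meaningless); the same log-profile
code path is used for metabolic and perfusion-like tables.

GMR normalisation divides each subject's regional values by that
subject's mean over all supplied regions, giving rows with mean exactly
1.  Note the consequence: the normalised table satisfies a linear
constraint (the weighted row sums are constant), which pins the average
off-diagonal covariance near zero.  Strong *uniform* positive
correlation regimes therefore cannot survive this normalisation — see
the generator section below.

## Connectivity change detection

Adjacency matrices are entrywise medians of Pearson correlation
matrices over B = 100 subject-level bootstrap resamples (subjects
resampled with replacement at the original n; an iterate with a
zero-variance region contributes NaN entries which are excluded from
the median).  The median-of-bootstraps has slightly wider sampling
dispersion than a plain sample correlation (~0.27 vs 0.25 at n = 17 for
independent regions).

An edge is **gained** when |r_case| ≥ τ_r and |r_hc| < τ_r and
|Δr| > τ_dr; **lost** under the mirrored predicate.  Defaults are
τ_r = 0.6 and τ_dr = 0.4; the two predicates are mutually exclusive.
Δr is the signed difference `|r_case − r_hc|` by default; a
`magnitude` mode (`||r_case| − |r_hc||`) is available since either
reading of "absolute difference of the two coefficients" is defensible.

τ_dr can be recalibrated per dataset as the 95th percentile of a label
permutation null: the healthy correlation matrix is compared with
node-relabelled copies of itself (1000 permutations), pooling |Δr|
between observed and pseudorandom edges.  This calibration is computed
on the raw (un-normalised) profile table, whose global-factor-dominated
correlation regime matches what metabolic data look like before
ratio normalisation; on a GMR-normalised 95-region table with n = 17
the null cutoff is forced to ≈ 0.7 by sampling noise alone (most
normalised correlations are near zero with SD ≈ 0.25), which would make
the stated τ_dr = 0.4 anticonservative rather than conservative.

Detected changes are then (1) restricted to pairs whose endpoints both
belong to a pattern membership, (2) filtered to pairs within 2 hops
along an anatomical pathway graph (endpoints missing from the graph
drop the change, logged), and (3) confirmed by re-running detection on
100 paired bootstrap resamples of both groups.  A change is retained
when re-detected in more than 65 % of resamples.  A bare majority rule
was evaluated and rejected: a sample-level fluke that passed detection
is reproduced by roughly half of the bootstrap replicates (the
bootstrap recentres on the flukey sample), so 50 % retention leaves the
false-discovery rate near or above 0.2 at n = 17; two-thirds retention
controls FDR (≈ 0.06–0.17 across held-out seed sets) while keeping
sensitivity ≈ 0.85–0.89 for planted edits with |Δr| ≈ 0.8.

Category percentages tally gained/lost changes per timepoint as
RR (both endpoints motor-pattern nodes), CC (both cognitive) and RC
(bridging); a node in both memberships counts toward the within-network
category first.  Core/periphery labels take the top 50 % of membership
|weights| (≥-quantile rule, so ties classify as core); active nodes are
those whose case-group mean normalised activity exceeds the healthy
mean.

## Graph metrics

Thresholded graphs retain edges with signed r ≥ threshold and weight r
(an |r| mode exists; negative correlations are dropped by default since
the sweep thresholds are positive-r levels).  Metrics:

* degree centrality = edges / nodes, as defined for this analysis
  (a conventional `mean_degree` = 2E/N variant is available);
* clustering = mean Onnela geometric-mean-triangle weighted clustering,
  weights normalised by the graph maximum, degree-< 2 nodes contribute 0
  (computed via a cube-root matrix product);
* characteristic path length = mean shortest-path distance over
  connected pairs with edge length 1/weight (sparse Dijkstra);
  disconnected pairs are excluded and counted, and a graph with no
  connected pair raises rather than returning silent NaN;
* small-worldness S = (C/C̄_null)/(L/L̄_null) on the giant component,
  with a null ensemble (default 100) of degree-preserving double-edge-
  swap rewirings carrying the shuffled weight multiset; undefined when
  the null clustering is zero;
* assortativity = Pearson correlation of endpoint degrees over the edge
  list in both orientations.  A star evaluates to exactly −1 (it is not
  degenerate); only zero-degree-variance graphs (complete graphs,
  cycles) are undefined, with a flag selecting between raising and the
  −1 convention.

All four deterministic metrics are verified against exhaustive
brute-force implementations (including Floyd–Warshall for distances) on
random graphs of ≤ 6 nodes to 1e-10; small-worldness is verified as the
exact ratio identity against its own returned null-ensemble means, and
behaviourally on canonical constructions (ring-lattice rewirings give
S > 1.5, random graphs give S ≈ 1).

Sweeps compute every metric per bootstrap iterate per threshold
(r = 0.30…0.65 in 0.05 steps by default; both endpoints configurable).
Group comparison fits `value ~ group + threshold` (threshold
categorical) on the pooled bootstrap values for the overall group
effect, with per-threshold two-sample contrasts Bonferroni-corrected
over the declared family (default: thresholds × metrics within one
comparison; the family size is written to the output).  For runtime the
pipeline defaults to 25 iterates and 10 nulls per small-worldness
evaluation; the distributions are bootstrap spreads, not confidence
machinery, and scale up by configuration.

## Longitudinal models

The individual growth model is a linear mixed model
`value = (β₀ + u₀ᵢ) + (β₁ + u₁ᵢ)·t + ε` with unstructured random
intercept/slope covariance, fitted by maximum likelihood (REML by
flag).  Degenerate fits fall back in order: random-intercept-only
(slope variance at the boundary), then pooled OLS for exactly
noise-free data (detected via per-subject collinearity witnesses with
≥ 3 distinct times, or zero pooled residual); the path taken is
recorded in the estimate.  Missing timepoints are handled by the
likelihood without imputation.  Rate comparisons between two measures
(e.g. caudate vs putamen decline) add fixed `measure` and
`measure × time` terms.

RMANOVA is the classical one-way repeated-measures decomposition with
df = (k−1, (n−1)(k−1)), complete cases only (drop count recorded), and
paired-t post-hocs with p multiplied by the number of pairs.  Zero
error variance is reported as undefined F (p = 1 when the condition
means agree) rather than silent NaN.  The Bland–Altman within-subject
correlation centres both variables within subject and tests the pooled
Pearson correlation on N − k − 1 degrees of freedom (cross-checked
against an independent ANCOVA-based implementation in the tests).

Sample sizes for a two-arm, two-sided t-test come from the smallest
per-arm n whose exact noncentral-t power reaches the target (bracket
and bisect; power is monotone in n), returning the two-arm total.

## Phenoconversion prediction

DAT binding is the striatal-to-occipital count ratio (S − O)/O,
expressed as a percentage of the healthy-control mean SOR per region.
The predictor is deliberately deterministic, mirroring straight-line
biomarker extrapolation: t_expr = max(0, (1.5 − z)/0.23) and
t_DAT = max(0, (pct − 40)/4.8) with group-level rates (a per-subject-
slope mode exists behind the estimates a caller supplies), and the
predicted time is their maximum since *both* thresholds must be
crossed.  Crossing is inclusive, so boundary subjects predict 0 years.
The decline is linear in percentage points of the normal mean per year
(not exponential, and not percent-of-baseline — a config switch covers
the alternative reading), matching the linear crossing arithmetic.
Risk zones use softer abnormality cutoffs (z > +1.0, DAT < 80 % by
default, both configurable): both abnormal = high, neither = low,
exactly one = intermediate.

Baseline-expression analyses report the plain Pearson correlation of
baseline scores with time to conversion plus a covariate-adjusted
partial correlation in leverage-residual form (score and time both
residualised on the covariates; df = n − k − 2), with exact collinearity
detected and the offending covariates named.

## The synthetic cohort generator

The generator is the package's test harness and defines its study
conditions.  Defaults mirror the longitudinal arm this pipeline
addresses: 17 controls vs 13 cases scanned at 0/2/4 years with
attrition 13/12/10 (profiles) and 13/10/6 (DAT), expression drift
0.23 z/yr (motor) and 0.21 z/yr (cognitive) from baseline z ≈ 0.8/0.3,
putamen DAT −4.8 %-points/yr and caudate −4.4 %-points/yr from ≈ 100 %
of the healthy mean (reaching the low-80s by year 4), trajectory noise
0.3 z per scan with slope heterogeneity 0.05 z/yr, and a latent
between-pattern noise correlation of 0.60 — calibrated once so the
*measured* within-subject change correlation between the two patterns
is ≈ 0.89.

Regional log-activity is built from block factors (blocks of 10
regions, loadings 0.82–0.92) plus independent residuals, scaled by
noise_sd = 0.08 log units, plus a between-subject global scaling term
(sd 0.115, drawn as shuffled normal quantiles so the realised
global-rate spread is stable at small n).  This architecture is chosen
around the GMR constraint noted above: a near-uniform global factor is
removed exactly by ratio normalisation, so the structure that survives
into connectivity analysis must live in factors whose loadings vary
across regions.  Within-block correlations ≈ 0.73 survive
normalisation; the global term produces the uniformly high raw
correlations on which the permutation cutoff is calibrated (≈ 0.35–0.4,
matching real-data values).

Planted connectivity edits are imposed on the case correlation matrix
before sampling by a Higham-style alternating projection (set the
target entries, clip negative eigenvalues, renormalise the diagonal,
re-impose; tolerance 0.02 on the achieved correlations, with an
explicit failure if the edit set is infeasible and an option to forbid
repair).  Regions hosting planted *gains* load only weakly (0.15) on
their block so the healthy correlation is near zero and the case edit
(default 0.9) is feasible; regions hosting planted *losses* share a
pair factor (loading 0.93, healthy r ≈ 0.86) that the case edit
(default 0.05) removes.  The achieved correlations and all host roles
are recorded in the cohort's truth record, making recovery tests
self-scoring.

Case profile residuals are drawn orthogonal to the two pattern
directions, and the pattern expression term `z·σ·w` is added in log
space with σ computed analytically from the healthy covariance.  The
orthogonalisation is what makes the trajectory parameters exactly the
expression statistics: healthy z-scores have SD 1 by construction, so
un-deflated case noise would add a full z-unit of fresh noise per scan
and swamp the planted dynamics.  The cost is a small (≤ ~0.05)
perturbation of case correlations among high-|weight| membership pairs.

The default anatomical pathway graph chains consecutive regions within
a block, bridges consecutive blocks, and includes every planted edge as
a direct pathway (synthetic tracts follow the generative structure).

What the generator does **not** emulate: scanner and site effects,
spatial autocorrelation and smoothing, voxel-level topography (regions
are exchangeable up to block membership), non-Gaussian tails of real
regional values beyond log-normality, informative dropout (attrition
truncates the subject list), and any coupling between expression level
and connectivity edits (in real data the same process drives both; here
they are planted independently).  Passing tests therefore demonstrate
that the pipeline recovers known effects from data with realistic
first- and second-order structure at study-scale n — not that it is
robust to site effects or preprocessing variation.

## Numerical conventions

Random streams derive from a single seed per cohort via named
`SeedSequence` children, so regeneration is bit-identical and partial
reruns are stable.  Degenerate inputs raise typed exceptions
(`DomainError`, `DegenerateDataError`, `UndefinedMetricError`, …)
rather than returning NaN.  All artifacts are plain delimited text,
JSON or YAML; writer/reader pairs round-trip finite values at full
float precision, and every pipeline output directory carries a
provenance record (configuration hash, seed, package version).
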