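# Methods

## Model and procedure

The pipeline operationalises a cross-sectional brain–behaviour analysis
on three inputs per cohort: per-subject ROI time-series tables
(timepoints × regions), a region→network partition, and a phenotype table
(handgrip strength, raw cognitive test scores, demographic covariates).

**Connectivity.** Functional connectivity between two regions is the
Pearson correlation of their time courses, Fisher-transformed
(z = atanh r) to stabilise variance. The contract starts at *cleaned*
time series: band-pass filtering, motion correction and nuisance
regression are upstream preprocessing concerns and are out of scope.
Because atanh diverges at |r| = 1, correlations are clipped to
1 − 10⁻⁷ in magnitude before the transform; a clip is logged and raised
as a `RuntimeWarning` rather than an error, since perfectly collinear
pairs arise legitimately in degenerate synthetic inputs. Symmetry is
enforced by construction (the upper triangle is computed and mirrored),
so no floating-point asymmetry can propagate.

**Segregation.** On the prepared matrix (diagonal and negative entries
set to 0), system segregation is (Z̄w − Z̄b)/Z̄w. Two conventions matter
and are fixed here:

* all means run over *unordered region pairs counted once*, and the
  global quantities are pooled-edge means (every within-network pair
  across networks, every between-network pair), not averages of
  per-network averages;
* zeroed negative edges remain in the denominators — they are values of
  0, not missing data.

Network-level Z̄b for network k averages the pairs joining k to all other
regions. The implementation uses indicator-matrix block sums
(O(R²K)), and tests verify it against a brute-force double loop over all
pairs. Segregation is undefined at Z̄w = 0 (all-zero prepared matrix) and
raises with the offending scope named, and a partition needs at least two
networks and at least two regions per network. Intra-/inter-network mean
FC is computed on the same prepared matrix used for segregation, keeping
one consistent matrix state per subject; `within_between_means` also
accepts unprepared input rejection so the raw-z alternative can be built
explicitly by the caller if ever needed.

**Phenotypes.** Handgrip = mean over hands of the per-hand maximum
reading; readings must be positive. T-scores use the population SD
(ddof 0) across the analysis sample; direction flags flip timed tests
(Trail Making A/B) before standardisation, since a composite in which
longer completion times raise the score would be incoherent — the flag is
configurable per test in the battery config. SM-MMSE is analysed raw.
Sex is encoded 0 = female / 1 = male, recorded in the run log.

**Associations.** OLS with intercept and classical (non-robust) standard
errors; two-sided p from the t distribution on the residual degrees of
freedom. BH-FDR (step-up, p̃(i) = min over the suffix of p(j)·m/j) is
applied within each family exactly as the study design groups them;
global segregation is reported alongside the nine network-level measures
but excluded from that nine-member correction. Statsmodels provides the
OLS fit and the `fdr_bh` adjustment; both are cross-checked in the test
suite against hand-written normal-equations and min-over-suffix oracles.
Rows missing any variable of a given model are dropped listwise for that
model with a logged count.

**Mediation.** Covariates are regressed out of x, m and y first; the
a/b/c/c′ paths are then fit on the residuals, so the residuals are
treated as data, including under resampling. The bootstrap resamples
subjects with replacement (default 5000 resamples) and recomputes a·b;
the default interval is the percentile CI — the simplest faithful reading
of "bootstrapped confidence intervals" — with a bias-corrected-accelerated
(BCa) variant exposed via `method="bca"`. The bootstrap p is the
two-sided sign-crossing fraction, 2·min(P(a·b ≤ 0), P(a·b ≥ 0)), capped
at 1. The OLS path identity c = c′ + a·b holds to numerical tolerance on
any one sample. The proportion mediated a·b/c is undefined near c = 0 and
is returned as NaN with an `proportion_unstable` flag instead of a bare
ratio.

## Synthetic cohorts

The generator emulates the *statistical skeleton* the analysis assumes,
not fMRI physics. Per subject i it draws a within-network correlation
w_i ~ N(0.45, 0.08) truncated to (0.05, 0.85) and a between-network
correlation b_i ~ N(0.12, 0.04) truncated to [0, w_i − 0.02], builds the
block correlation matrix (within-network off-diagonals w_i, between b_i —
always positive-definite for 0 ≤ b < w < 1, and checked by Cholesky), and
either samples T multivariate-normal timepoints or emits the exact
Fisher-z block matrix. The latent segregation
s_i = 1 − atanh(b_i)/atanh(w_i) is defined on the Fisher-z scale to match
the pipeline's measurement scale, and for the exact-matrix route the
pipeline's empirical segregation equals s_i to machine precision — for
every network and globally, since (w_i, b_i) are homogeneous across
networks. Subject heterogeneity entering through (w_i, b_i) is the
minimal structure under which between-subject segregation–phenotype
associations are well-defined.

Phenotype couplings are linear: handgrip = α₀ + α₁·s + demographic
loadings + noise; cognition = β₀ + β₁·(handgrip − 22.3) + β₂·(s − 0.75) +
loadings + noise, with β₂ giving a direct segregation→cognition path for
mediation structure. Defaults reproduce the published cohort's summary
scale — n = 148 subjects, 235 usable volumes of an 8-minute TR-2s scan,
142 regions over nine networks with a 22-region salience/ventral-attention
analogue (hence 231 intra-network pairs), age 72.8 ± 3.9 y, 44% male,
education 7.3 ± 4.0 y, handgrip ≈ 22.3 ± 7 kg with trial-level
dynamometer jitter (two readings per hand, scored max-then-mean), and
α₁ = 19 kg per segregation unit, which yields a handgrip–segregation
correlation of ≈ 0.27. Covariate loadings (sex +8 kg, age −0.2 kg/y on
grip; age −0.35, education +0.5 T-units on cognition) are plausible-scale
defaults; no acceptance check depends on them.

What the generator does **not** emulate: temporal autocorrelation, motion
and physiological noise, network-specific connectivity levels, spatial
parcel geometry, or non-Gaussian phenotype distributions. Passing tests
therefore demonstrate correctness of the estimators and calibration of
the inference under the assumed model, not robustness to realistic fMRI
artefacts.

## Calibration and recovery checks

* **Type-I control** uses 500 replicate null cohorts (α₁ = β₁ = β₂ = 0)
  at the study size n = 148 through the exact-matrix route, counting
  uncorrected p < 0.05 over the nine-network segregation family; the rate
  must sit in [0.03, 0.07].
* **Slope recovery** programs α₁ = 30 with handgrip noise SD 2 kg at
  n = 2000 — a scenario chosen so the sampling SE of the estimate
  (≈ 2.5% of α₁) sits well inside the 10% acceptance band, making the
  check a test of estimator correctness rather than of luck — and runs on
  the exact-matrix route so finite-scan attenuation does not confound the
  estimate. The time-series route's attenuation is separately bounded in
  the tests (empirical vs latent segregation within 0.05 at T = 3000).
* **Mediation recovery** uses the balanced chain a = b = 0.5, c′ = 0.25,
  unit noise, n = 2000 (true proportion mediated 0.5, tolerance ±0.1).

## Numerical and design choices

* Correlation clip at 1 − 10⁻⁷; matrix text I/O at 17 significant digits
  with round-trip float parsing, giving bit-stable round trips.
* Deterministic lexicographic region-pair ordering everywhere.
* All randomness flows through `numpy.random.default_rng(seed)`; seeds
  are mandatory in the cohort spec and recorded in outputs. Identical
  config + seed ⇒ byte-identical run directories (run logs carry versions
  and seeds, never wall-clock time).
* Empty mediation tables are still written with full headers so the
  result bundle shape is invariant.
* The `fc_cognition` family and mediation candidates are selected by
  FDR significance (α = 0.05) in the upstream families, mirroring the
  two-stage design; on null cohorts these tables are typically empty.
* Problem sizes in tests and the acceptance script (cohorts of 24–148
  subjects for orchestration checks, 2000 for recovery, 500 null
  replicates) were chosen as the smallest sizes at which each check is
  statistically meaningful.

## Known limitations

* Classical SEs only; no robust/sandwich errors, permutation inference,
  mixed models or interaction terms.
* Single-mediator mediation without causal sensitivity analysis; the
  bootstrap p definition (sign-crossing) is one of several reasonable
  conventions and published mediation p-values also depend on the
  original data, so no numeric mediation result is treated as a target.
* The partition is user-supplied; nothing validates its neuroanatomical
  sensibility, only its formal consistency with the matrices.
* Graph-theoretic alternatives (modularity, participation coefficient),
  thresholded/binarised graphs and negative-weight schemes other than
  zeroing are out of scope.
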