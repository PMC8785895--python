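# Methods

## Problem and scope

The package quantifies how within-network functional connectivity (FC) of
the default-mode network (DMN) changes with age, and whether that change
differs between depressed patients (MDD) and healthy controls (HC). It
operates on region-of-interest (ROI) time series — one volumes × ROIs
matrix per subject, TR in seconds — never on raw images: slice timing,
realignment, normalization, nuisance regression and manual quality review
are upstream of this package and out of scope.

Two per-subject outcomes are computed over a fixed 58-region DMN:

* **Static FC strength** — the mean Pearson correlation over all
  58·57/2 = 1653 unordered region pairs (diagonal excluded).
* **Dynamic FC (dFC) temporal variability** — the scan is cut into T
  overlapping sliding windows (default width 100 s, step 6 s); a windowed
  FC matrix is computed in each. Region k's connectivity profile in window
  i, F(i, k), is its correlation to the other 57 regions (self entry
  excluded). Node variability is

      V_k = 1 − mean_{i<j} corr(F(i, k), F(j, k)),

  averaged over all T(T−1)/2 unordered window pairs (identical to the
  symmetric i≠j average), and the network statistic V is the mean of V_k
  over regions. V ∈ [0, 2]: 0 for perfectly stable windowed connectivity,
  above 1 for anti-correlated profiles.

Group inference is an OLS regression per outcome:

    outcome ~ intercept + diagnosis + age + diagnosis×age
              + sex + education + site dummies + mean FD

with diagnosis coded MDD = 0 / HC = 1, sex male = 0 / female = 1, the
lexicographically first site as dummy reference, and the interaction formed
as diagnosis × mean-centered age (with both main effects present the
interaction t and p are invariant to that centering; we assert this on
random data). Standardized coefficients follow the β = b·SD(x)/SD(y)
convention for every non-intercept term, dummies included. Within-group
age–outcome Pearson correlations are compared between groups with the
Fisher r-to-z statistic for independent samples,

    z = (atanh r₁ − atanh r₂) / sqrt(1/(n₁−3) + 1/(n₂−3)),

two-tailed normal p. Clinical associations use partial Pearson correlations
(residualize both variables on age, sex, education, site dummies and mean
FD plus an intercept; p from t with df = n − 2 − k), and a two-level ANCOVA
(first-episode vs recurrent) where F is the squared t of the factor term.
All tests are two-tailed at α = 0.05 with no multiple-testing correction.

## Quality control

Subjects are excluded by the first failing criterion, in order: age < 18;
incomplete demographics (age, education or mean FD missing); scan TR ≠ 2 s;
mean framewise displacement > 0.2 mm; any zero-variance ROI series (a
computable proxy for signal loss / bad mask coverage). Manual image-quality
review has no computable definition and is logged as not applied. The
bookkeeping identity n_retained + Σ excluded = n_input holds by
construction and is property-tested.

## Window planning

Width and step must be exact positive multiples of the TR. Windows are
0-based half-open volume ranges; T = ⌊(n_volumes − width_vol)/step_vol⌋ + 1
and must be ≥ 2; trailing volumes that do not fill a window are dropped (no
partial or tapered windows). The validation grid re-runs the dFC regression
for widths {80, 100, 120} s × steps {6, 8, 10} s; the (100 s, 6 s) cell
reuses the primary fit, so it matches it exactly.

## Numerical choices

* Raw Pearson r is averaged in the main analysis; an optional Fisher
  r-to-z switch transforms every FC/dFC matrix element-wise for the
  sensitivity variant. Under the transform, |r| = 1 is clipped to
  1 − 1e−7 with a warning so atanh stays finite.
* A zero-variance ROI series is an error naming the region (and, inside a
  window, the window index), not silent NaN propagation.
* V_k is clamped to [0, 2] against last-bit rounding from `corrcoef`.
* The log refit of an outcome (triggered when the Spearman correlation
  between age and |residuals| has p < 0.05) takes the natural logarithm and
  refuses non-positive outcomes rather than silently shifting them.
* Rank-deficient designs are rejected with the collinear columns named
  (pivoted-QR identification).
* Result tables are written with fixed float formatting, so identical
  inputs reproduce output files byte-for-byte.

## Synthetic cohort generator

The generator exists so every pipeline stage is testable without access to
consortium data. Per subject, ROI signals follow a one-factor model: at
volume t, region k's signal is

    x_tk = sqrt(ρ_k(t))·c_t + sqrt(1 − ρ_k(t))·e_tk,
    ρ_k(t) = clip(ρ_target + s_k·α_target·sin(2πt/P + φ)),

with c_t a shared standard-normal signal, e_tk independent noise, φ a
random per-subject phase, and s_k = +1 for one half of the regions and −1
for the other (antiphase modulation). Each series then passes an AR(1)
filter (coefficient 0.3, emulating hemodynamic autocorrelation — sliding
window estimates on white noise are unrealistically stable) and is
re-standardized; the common filter preserves the zero-lag correlation
structure, so the expected full-scan pairwise correlation equals ρ_target
at α = 0 (we verify ±0.05 at 2000 volumes).

Two generator choices are deliberate and load-bearing:

* **Antiphase rather than global modulation.** A single shared ρ(t) shifts
  all entries of a windowed connectivity profile by the same amount, and
  the profile-wise Pearson correlation inside V removes uniform shifts —
  V would be provably blind to the fluctuation. Antiphase modulation makes
  the *pattern* fluctuate (same-sign pairs track ρ + a(t) while cross-sign
  pairs track sqrt((ρ+a)(ρ−a))), which V detects. The cost is a
  second-order downward bias ≈ α²/(2ρ) on cross-half pairs' static FC.
* **Period P = 180 s.** The period must exceed the widest analysis window
  (120 s in the validation grid): a fluctuation faster than the window is
  averaged away inside each window and never reaches the windowed FC
  matrices. A sinusoid (rather than a random walk) keeps the amplitude
  bounded by construction and directly interpretable.

Cohort structure: two groups of `n_per_group` subjects (default 150, the
scale used for the replication experiments; configurable to the full
971/902); age uniform on 18–65; sex Bernoulli(0.5); education
N(12, 4) truncated at 0; mean FD truncated-normal(0.07, 0.03) on [0, 0.2];
four sites with scan lengths 150–240 volumes at TR = 2 s. The correlation
target is ρ_target = clip(ρ₀ + slope_group·(age − 41.5) + N(0, 0.05)) with
ρ₀ = 0.40, control slope −0.0010/yr and patient slope −0.0025/yr; the
fluctuation amplitude is α_target = clip(0.15 + 0.002·(age − 41.5) +
N(0, 0.05)). Clip bounds keep targets inside (0.02, 0.95) and
ρ ± α inside (0, 1). The published analyses report no effect sizes in
generator-native units, so the slopes were chosen once so that the
diagnosis-by-age interaction (implied coefficient slope_hc − slope_mdd =
+0.0015 per year on the HC = 1 coding) is reliably detectable at 150 per
group; the induced age–FC correlations (≈ −0.5 MDD, ≈ −0.25 HC) are
somewhat stronger than the published ones, a deliberate trade of realism
for test sharpness. All randomness descends from one root seed via spawned
child streams, so cohorts are bit-reproducible.

What the generator does **not** emulate: realistic spatial covariance of
the atlas (all pairs are exchangeable), motion artifacts, site differences
beyond scan length, scanner drift, or any physiological signal model.
Passing tests therefore show that the estimators and inference behave
correctly under a known, idealized data-generating process — not that the
published effect sizes would be recovered from real consortium data.

## Replication experiments

* **Interaction sign recovery** — 20 independent cohorts at 150 per group,
  full time-series simulation; per cohort: QC → static FC strength →
  interaction fit. Pass: ≥ 90% of replicates recover the generator-implied
  positive interaction sign.
* **Type-I error** — 500 replicates at 200 per group with equal group
  slopes, run at the phenotype level (the noisy per-subject correlation
  target serves as the outcome directly); the rejection rate of the
  interaction test at α = 0.05 must land in [0.03, 0.07]. The reduced
  (phenotype-level) design isolates the inferential null behaviour from
  estimation noise and keeps 500 replicates cheap.

Problem sizes throughout (cohort of 150–300 per group for end-to-end runs,
20 and 500 replicates for the two experiments, 25 per group for pipeline
structure tests) are the package's chosen desk-scale defaults.

## Known limitations

* A stationary equicorrelated scan yields V ≈ 0.7–0.96, not 0: windowed
  profiles differ by estimation noise that is nearly uncorrelated across
  distant windows. V is therefore a relative, not absolute, fluctuation
  measure, and comparisons should hold scan length and window parameters
  fixed (the pipeline always does).
* The packaged 58-region DMN table carries synthetic stand-in coordinates
  (anatomically plausible MNI positions); coordinates are bookkeeping only
  and never enter computation.
* Site is modeled with fixed dummy covariates, not random effects; no
  robust/sandwich errors; no voxel-wise or graph-theoretic extensions.
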