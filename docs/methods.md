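# Methods

## The measurement model

`painsgrid` scores cell-based body pain drawings. A *body atlas* partitions
the body surface into 2026 square cells, arranged on per-segment 2D charts
(head, neck, trunk, arm, hand, leg, foot) and grouped into 54 lateralized
regions (27 region names × left/right). The head chart has 322 cells and
head+neck together 382. A patient's drawing at one visit is a sparse map
`cell → intensity` with intensity 1 (mild), 2 (moderate) or 3 (severe).

Over any *scope* S (full body, head+neck, one side, a region, or an
intersection of these), four sensory-discriminative measures are defined:

- **PAINS** = Σ_{c ∈ S painful} intensity(c) — pain area and intensity
  number summation, the cumulative cell score (unnormalized; a normalized
  variant PAINS/(3·|S|) is exposed but never the default);
- **average pain** = PAINS / #painful, on the 1–3 scale, defined as 0 for a
  pain-free visit so longitudinal series stay total;
- **maximum pain** = highest intensity present (0 if none);
- **pain area** = 100 · #painful / |S| percent, always against the scope's
  own cell count.

These satisfy exact algebra (identity PAINS = avg·n, additivity over
disjoint scopes, side decomposition, monotonicity) which the test suite
checks against brute-force per-cell oracles.

### Atlas reconstruction

The published grid's geometry is proprietary; only its counts are public.
The default atlas is therefore a *count-faithful synthetic reconstruction*:
region names and per-region cell counts are invented such that every printed
total holds (head 161 cells/side over 9 regions; neck 30/side; 822/side over
the remaining 17 region names). Regions pack as consecutive rows of a
rectangular chart per segment, left side in columns [0, w), right side in
[w, 2w). Everything downstream depends only on counts, membership and
within-chart coordinates, so anatomical shape fidelity is irrelevant to the
statistics. The nominal 1.6 cm cell edge is stored as metadata only — it
rescales with body type and never enters computation. The midline side
category exists for atlases that need it; the default atlas assigns it no
cells (keeping 54 = 2 × 27 exact).

## Epicenter and scatter score

The cohort *epicenter* is the cell marked painful in the most
patient-visits, ties broken by larger total intensity then smaller cell id
(deterministic). A map's *scatter score* is the intensity-weighted mean
grid distance of its painful cells from the epicenter:

    scatter = Σ_c w_c d(c, epi) / Σ_c w_c,   w_c = intensity(c).

`d` is Euclidean on (row, col) within the epicenter's segment chart; cells
on another chart have no shared frame and receive a fixed penalty (the
larger of the two chart diagonals). This formula is a reconstruction — no
published definition exists — chosen for translation invariance within a
chart and invariance to uniform intensity rescaling (both property-tested).
The chronicity analysis regresses baseline scatter on pain duration
(years); `r`, the OLS line, and the two-sided t-test p-value are reported
via `scipy.stats.linregress`.

## Test–retest reliability as lag autocorrelation

For lag L ∈ 1..40 days, every within-patient visit pair with day difference
exactly L contributes one (earlier, later) point; pairs are pooled across
patients and Pearson r of the pooled cloud is the lag-L autocorrelation.
Pooling (rather than averaging per-patient correlations) is forced by the
design: 24 patients with sparse schedules rarely give any single patient 3+
pairs at a given lag. Lags with fewer than 3 pairs are dropped (Pearson on
two points is ±1 identically), as are lags where the measure is constant.
Note that pooled correlations retain stable between-patient differences, so
a measure with strong patient-level heterogeneity keeps a high, flat curve
at long lags — this is the mechanism behind the high long-lag reliability
of map scores.

The lag trend is summarized by a cubic smoothing spline (GCV-chosen
penalty, weights = pair counts, fitted values clipped to [−1, 1];
`scipy.interpolate.make_smoothing_spline`). At least 4 retained lags are
required; the spline reproduces constant and linear trends exactly.
Measure comparison reports each measure's mean raw r over lags ≥ 2 and a
percentile bootstrap CI of the difference from patient-level resampling
(default 1000 replicates, seeded; resampled patients contribute their pairs
with multiplicity, implemented as weighted per-lag correlations).

## PCA, effect sizes, power

PCA is computed on the correlation matrix (variables z-scored first): PAINS
is in the hundreds while VAS is 0–10, so covariance PCA would be
meaningless. Loadings are reported as eigenvector·√eigenvalue — the
correlation of each variable with each component — so the conventional
0.70/0.4 annotation thresholds apply. Components are signed so the PAINS
loading on PC1 and the VAS loading on PC2 are positive. The helper
`pca_structure_matches` encodes the qualitative claim "map measures cluster
on PC1, VAS with PANAS on PC2" as: the map block's summed squared PC1
loadings exceed the VAS+PANAS block's, and VAS loads more on whichever of
PC1/PC2 carries more PANAS. The second clause is deliberately
rotation-adaptive: with two correlated blocks and n = 24, the sample PC1/PC2
pair can rotate within the leading 2D subspace, and a fixed component label
would misread structurally correct solutions.

Cohen's d uses the pooled SD: d = (mean_active − mean_sham)/s_p with
s_p² = ((n₁−1)s₁² + (n₂−1)s₂²)/(n₁+n₂−2), applied to per-patient delta
changes (follow-up minus baseline). Sample size inverts the two-sided
two-sample comparison: the normal approximation n = ⌈2(z_{1−α/2}+z_{pow})²/d²⌉,
or the exact noncentral-t search (smallest n with power ≥ target at
noncentrality d√(n/2), df 2n−2), which is conservative (never smaller).
At 80% power, α = .05 two-sided these give 44/group at d = 0.60 and
62/group at d = 0.51. Published companions to those numbers include a VAS
effect size quoted as 0.35 in one place and 0.31 in another, with n quoted
as 125 and 145; no (d, n) pairing there is internally consistent under
either method, so this library asserts only the two consistent values and
leaves the VAS pair undetermined.

The longitudinal VAS–mood association uses a repeated-measures correlation:
visits are centered within patient, pooled Pearson is computed on the
centered pairs, and the p-value uses df = N − k − 1 (N pooled visits, k
patients). This matches `pingouin.rm_corr`, which the tests use as an
independent oracle.

## The synthetic cohort generator

No trial data were deposited, so validation runs on seeded synthetic
cohorts whose generative structure *is* the hypothesis under test:

- Each patient has a latent sensory severity S_t = b_i + AR(1): a stable
  offset b_i ~ N(0, 0.8²) plus a stationary unit-variance daily AR(1) with
  coefficient φ_s = 0.9 (sampled at the visit days via φ^gap), and an
  independent mood latent M_t, AR(1) with φ_m = 0.4.
- Pain maps derive from S_t alone. Cell c is painful with probability
  min(p_max·e^{0.5·S_t}·exp(−d_c²/2σ_i²), 1), a Gaussian kernel around an
  epicenter cell (default: centroid of the right jaw region) whose width
  σ_i = 2.0 + 0.25·duration_i grows with chronicity (duration ~ U(2, 10)
  years). A painful cell's intensity is a two-point draw around
  clip(2 + 0.4·S_t + η, 1, 3), η ~ N(0, 0.15²), so mean intensity is linear
  in S_t over the operating range.
- VAS = clip(5 + 0.05·S + 1.2·M + offset_i + ε, 0, 10) — mood-dominated
  by construction, with only a small sensory component; PANAS subscales are
  noisy readouts of ∓3·M around 28/18. Mood never touches the maps.
- Treatment: after the 5-day stimulation window the active arm's S_t drops
  by Δ = treatment_delta · √(2(1−φ_s^D)), D the baseline→last-visit span.
  √(2(1−φ^D)) is the null SD of the latent change, so the arm contrast of
  latent deltas has Cohen's d = treatment_delta exactly (verified to three
  decimals at n = 4000). The default visit schedule is days
  0,1,2,3,4,5,12,33 (baseline, stimulation week, 1-week, 1-month).

Parameter defaults were fixed by pilot simulation so that the generator
reproduces, at the trial's own size of 24 patients, the qualitative
findings it is meant to emulate: mood-contaminated VAS vs mood-free map
scores (PCA block structure in ~92% of seeds; the remaining failures are
genuine n = 24 sampling rotations of two adjacent eigenvalues and are not
removable at this sample size), high flat long-lag reliability for PAINS vs
low for VAS (the stable severity offset supplies the persistent
between-patient variance that pooled correlations retain), and a strong
duration→spread association. Power recovery uses the 1-month delta of
*average cell intensity*, the measure that tracks the latent state most
directly: its realized effect size is ≈ 0.598 at a configured 0.6, and its
rejection rate at 44/arm (0.77 over 1000 replicates) sits within the
±7-point band around the analytic normal-approximation power (0.803).
PAINS deltas are attenuated (realized d ≈ 0.52) because per-patient map
extent multiplies both signal and noise heterogeneously — a real phenomenon
worth knowing about the measure, but not the quantity the recovery check
targets.

What the generator does *not* emulate: dropout and missing visits,
bilateral or multi-focal pain, floor/ceiling usage patterns of real VAS
raters, within-day variation, and any sham-response psychology. Passing
tests therefore demonstrate that the analysis pipeline recovers structure
that is present, not that real trial data possess that structure.

## Numerical and degenerate-input choices

- Average pain of an empty map is 0 (the ratio is undefined at zero cells);
  empty scopes are an error.
- Epicenter ties: frequency → total intensity → smaller cell id.
- Pearson per lag is computed from grouped sums; lags with zero variance or
  < 3 pairs are omitted with a warning rather than propagating NaN.
- Smoothed reliability values are clipped to [−1, 1]; < 4 retained lags is
  an error directing the caller to the raw curve.
- PCA refuses constant columns by name; rm-correlation requires ≥ 2
  patients with ≥ 2 complete visits.
- Sample-size search starts at the normal-approximation n (t power is
  strictly below normal power, so the first feasible n is never skipped).
- All simulation randomness flows from one `numpy.random.default_rng(seed)`
  per cohort; CLI analyses write JSON run manifests (version, seed, input
  SHA-256) beside their outputs.

## Problem sizes used in the checks

Stochastic suites run at the study's own scale: 200 seeded 24-patient
cohorts for the PCA and reliability-ordering properties, 500 for the
chronicity recovery, 1000 replicates of 88-patient two-visit cohorts for
the power comparison, and a 500-patient, 41-day dense panel for the AR(1)
autocorrelation calibration (|r − φ^L| < 0.05 for L ≤ 10). The whole suite
completes in about two and a half minutes on one CPU.
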