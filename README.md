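# painsgrid

Grid-based scoring of body pain drawings, and the statistics used to show
that such scores are valid, reliable outcome measures.

Chronic-pain trials still lean on the visual analog scale (VAS): one 0–10
number for "overall pain". Digital body maps record where it hurts and how
much, cell by cell, on a fixed grid — but a map is only useful as a trial
endpoint if its derived scores behave like good measurements: internally
consistent, stable on retest, sensitive to treatment, and not secretly
tracking the patient's mood. `painsgrid` implements both halves of that
story for researchers in pain measurement and patient-reported outcomes:

**Scoring.** A body atlas of 2026 square cells (382 in the head and neck,
322 in the head) in 54 lateralized regions. From a sparse map of cell
intensities (1 = mild, 2 = moderate, 3 = severe) over any scope S it
computes

- `PAINS = Σ_{c∈S} intensity(c)` — pain area and intensity number summation,
- `avg_pain = PAINS / #painful` (1–3 scale),
- `max_pain`, and
- `area_pct = 100 · #painful / |S|`,

with exact algebraic structure (additivity over disjoint scopes,
left+right+midline decomposition, `PAINS = avg·n`).

**Validation statistics.**

- *Epicenter & spread*: the cohort's most-marked cell, each patient's
  intensity-weighted mean grid distance from it (scatter score), and its
  association with pain chronicity (Pearson/OLS).
- *Test–retest reliability*: lag-L autocorrelations (L = 1..40 days) from
  within-patient visit pairs pooled across the cohort, with a GCV smoothing
  spline over the lag trend and a patient-bootstrap comparison between
  measures.
- *Measure clustering*: correlation-matrix PCA of baseline measures with
  √eigenvalue-scaled loadings.
- *Effect size & power*: pooled-SD Cohen's d of 1-month delta changes,
  and per-group sample size by normal approximation
  `n = ⌈2(z_{1−α/2}+z_{pow})²/d²⌉` or exact noncentral-t search.
- *Synthetic cohorts*: a seeded generator of two-arm longitudinal trials
  (latent AR(1) sensory state, independent mood process contaminating only
  the VAS, Gaussian-kernel pain maps whose spread grows with chronicity)
  so every stage can be exercised and calibrated without patient data.

## Worked example

Simulate a 24-patient trial (two arms, visits on days 0–5, 12 and 33) and
run the full validation pipeline on the head-and-neck scope:

```sh
$ painsgrid simulate --seed 7 --out-dir demo
$ painsgrid score --maps demo/painmaps.csv --scope head_neck --out demo/scores.csv
wrote 192 score rows to demo/scores.csv

$ painsgrid epicenter --maps demo/painmaps.csv --meta demo/meta.csv \
      --scope head_neck --out demo/scatter.csv
epicenter cell: 257
chronicity association: r=0.799 p=0.0000 slope=0.208 (n=24)

$ painsgrid reliability --maps demo/painmaps.csv --scales demo/scales.csv \
      --out demo/reliability.csv --seed 7
mean r (lag>1) pains: 0.428
mean r (lag>1) vas: 0.081
difference pains-vas: 0.346 [95% CI 0.186, 0.540]

$ painsgrid pca --maps demo/painmaps.csv --scales demo/scales.csv \
      --out demo/loadings.csv
             PC1    PC2
pains      0.956 -0.065
avg_pain   0.961 -0.074
max_pain   0.822  0.077
area_pct   0.953 -0.050
vas        0.090  0.929
panas_pos -0.180 -0.859
panas_neg -0.137  0.883
explained variance ratio: PC1=0.497 PC2=0.343
```

Reading the output: the most-marked cell (257, in the right jaw region of
the default atlas) is the cohort's pain epicenter, and patients with longer
pain histories show pain spread farther from it (r = 0.80 across 24
patients). PAINS is far more stable across days than the VAS (mean lag>1
autocorrelation 0.43 vs 0.08, bootstrap CI excluding zero), and the four
map-derived measures load a single first component while the VAS clusters
with both PANAS mood subscales on the second — the map scores measure
sensory pain; the VAS co-varies with mood.

Effect size and sample-size planning:

```sh
$ painsgrid effect-size --maps demo/painmaps.csv --meta demo/meta.csv --measure pains
Cohen's d (pains, head_neck, day 0->33): -0.770 (active mean -64.92,
sham mean -2.58, pooled SD 80.98, n=12+12)

$ painsgrid power --d 0.6 --power 0.8 --method normal
n per group: 44 (d=0.6, power=0.8, alpha=0.05, method=normal)

$ painsgrid power --d 0.51 --method t
n per group: 62 (d=0.51, power=0.8, alpha=0.05, method=t)
```

The negative d says the active arm's PAINS dropped more than sham's by one
month; detecting a 0.60 SD effect with 80% power needs 44 patients per
group (normal approximation), and 0.51 SD needs 62 per group under the
exact t computation.

Every analysis subcommand writes a `*.manifest.json` beside its output with
the package version, seed and SHA-256 of each input, so runs are auditable.

The same pipeline is available as a library (`painsgrid.score_series`,
`painsgrid.lag_autocorrelation`, `painsgrid.pca_measures`, ...); see
`docs/methods.md` for the model, formulas, generator design and known
limitations.

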