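# metricbounds

Statistically valid prediction intervals for **clinical metrics derived from
probabilistic image reconstructions**, with retrieval of the reconstructions
that visualize the bounds.

Modern generative reconstruction algorithms (e.g. diffusion models for
sparse-view CT) produce, for one subject, an ensemble of ns plausible scans —
all of which may look realistic while some are quietly wrong. For a scalar
metric of interest f(·): image → ℝ (fat volume of a slice, an organ volume,
a dose statistic), the ensemble's raw metric quantiles are a tempting
interval for the subject's true value, but a biased or mis-dispersed
reconstruction pipeline makes them invalid. `metricbounds` repairs this with
**split conformal prediction**: given a calibration set of n subjects with
reconstruction ensembles *and* known ground-truth metrics, it learns quantile
adjustments and emits intervals with a finite-sample marginal coverage
guarantee under exchangeability — for *any* black-box reconstruction
algorithm and *any* deterministic metric.

## The method

Per calibration subject i, with predicted metric samples Ŷᵢ and truth Yᵢ,
compute one-sided non-conformity scores

    s_lo,i = Q_αlo(Ŷᵢ) − Yᵢ        s_hi,i = Yᵢ − Q_{1−αhi}(Ŷᵢ)

where Q_α is the empirical quantile (lower order statistic,
k = max(1, ⌈α·m⌉)). With finite-sample adjusted levels
α̂ = ⌊α(n+1)⌋ / n, the adjustments are

    q_lo = Q_{1−α̂lo}({s_lo,i})      q_hi = Q_{1−α̂hi}({s_hi,i})

and the prediction interval for a new subject with samples Ŷ is

    C(Ŷ) = [ Q_αlo(Ŷ) − q_lo ,  Q_{1−αhi}(Ŷ) + q_hi ]

which satisfies P(Y ∈ C(Ŷ)) ≥ 1 − αlo − αhi marginally. The interval maps
back to images: the reconstructions whose metrics are nearest the two
endpoints visualize the bounds, ensemble members with metrics inside the
closed interval are **inliers**, and the rest are flagged **outliers** —
plausible-looking scans with statistically unlikely metric values.

Shipped metrics include `fat_volume` (count of pixels in the closed adipose
window [−150, −50] HU × slice thickness); any callable image → scalar plugs
in. Baselines for comparison: uncalibrated metric quantiles, per-pixel
intensity quantiles, and per-pixel conformal ("pixel CP") bounds.

## Worked example

Simulate a mis-calibrated pipeline (250 subjects, ns=100 samples each;
predictions biased by +7.5 and over-dispersed ×1.5 around truths
~ N(100, 15²)), calibrate, and evaluate over 500 random 75/25 splits:

```sh
metricbounds simulate --n-subjects 250 --ns 100 --seed 7 --out-dir data
metricbounds calibrate --samples data/samples.csv --truths data/truths.csv \
    --alpha-lo 0.05 --alpha-hi 0.05 --out adjustments.json
metricbounds evaluate --samples data/samples.csv --truths data/truths.csv \
    --n-splits 500 --seed 1 --out report.csv
```

prints

```
INFO metricbounds: calibrated on n=250 subjects: alpha_hat=(0.048, 0.048), q_lo=-2.88722, q_hi=-17.1827 -> adjustments.json
INFO metricbounds: metric    coverage=1.0000 mean_length=24.4 normalized=5.579
INFO metricbounds: metric_cp coverage=0.8941 mean_length=4.374 normalized=1.000
```

Both adjustments are negative: the over-dispersed ensembles were too wide,
so calibration *tightens* the bounds (the asymmetric q's also absorb the
+7.5 bias). The calibrated interval (`metric_cp`) attains the nominal 0.9
coverage while being 5.6× shorter than the raw quantile interval, whose
1.000 coverage here is the uninformative kind that comes from excess width.
Predicting one subject then yields its interval and retrieval report:

```sh
metricbounds predict --adjustments adjustments.json --samples data/samples.csv \
    --subject s0007 --out s0007.json
# INFO metricbounds: subject s0007: interval [115.834, 123.477], 20 inliers / 80 outliers
```

(subject s0007's simulated ground truth is 120.1, inside the interval; the
80 flagged outliers reflect how strongly this generator mis-calibrates the
ensembles). The same workflow runs on image stacks: pass
`--images subject.nii.gz --metric fat_volume --metric-param slice_thickness=3`
and the metric is computed per reconstruction before calibration/retrieval,
with `--export-bounds` writing the two bound images as NIfTI.

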