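# Methods

## Model and assumptions

`metricbounds` treats the reconstruction algorithm as a black box that, for
subject i's observations, emits ns sampled scans Îᵢ = {Îᵢⱼ}. A deterministic
metric f reduces each scan to a scalar, giving the predicted-metric ensemble
Ŷᵢ = {f(Îᵢⱼ)}. The only statistical assumption is **exchangeability**: the
calibration subjects (with known ground truths Yᵢ) and the test subject are
draws whose joint distribution is invariant to reordering. Nothing is assumed
about the reconstruction algorithm's bias, dispersion, or noise law — that is
the point of conformalizing.

The calibrated interval

    C(Ŷ) = [Q_αlo(Ŷ) − q_lo, Q_{1−αhi}(Ŷ) + q_hi]

carries a *marginal* guarantee: P(Y ∈ C(Ŷ)) ≥ 1 − αlo − αhi averaged over
random (calibration, test) draws. It is not a per-subject or per-subgroup
guarantee, and conditional on one finite calibration pool the realized
coverage fluctuates around the nominal level with standard deviation roughly
√(α(1−α)/n) (≈ 0.02 for n ≈ 190, α = αlo + αhi = 0.1). Tests and the
reproduction script account for this Monte-Carlo tolerance explicitly
(0.01–0.02 below the nominal 0.9) rather than expecting the bound to hold
split-by-split.

## Numerical conventions

- **Empirical quantile.** Q_level of m values is the k-th order statistic
  with k = max(1, ⌈level·m⌉) — the lower empirical quantile, no
  interpolation. Every returned quantile is an observed sample value, which
  keeps the discrete finite-sample argument exact and makes every worked
  example integer-indexable. The product level·m is rounded to 9 decimals
  before ⌈·⌉/⌊·⌋ so binary float representation (0.9·10 = 9.000…002) cannot
  shift the index.
- **Small calibration sets.** If ⌊α(n+1)⌋ = 0 the adjusted level is 0 and the
  adjustment becomes the score maximum — the most conservative choice. This
  logs a warning (n too small for the requested α) rather than raising.
- **Signed scores.** Non-conformity scores may be negative (the raw
  quantiles already bracket the truth with margin); they are used as-is, so
  adjustments can be negative and *tighten* the interval. The two sides are
  calibrated independently from their own score sets.
- **No domain clamping by default.** Endpoints are not clipped to the
  metric's natural domain (e.g. volume ≥ 0); `predict_interval(...,
  domain=(lo, hi))` opts in. Interval *length* is always reported as
  max(0, U − L), so a crossed (empty) interval has length 0.
- **Closed membership and ties.** Interval membership (coverage, the
  inlier/outlier partition) is closed at both endpoints. Nearest-bound
  retrieval is exhaustive argmin of |metric − bound| with ties broken to the
  smallest index; an empty interval makes every ensemble member an outlier
  (logged, not raised).
- **Indices.** All retrieval and partition indices are 0-based positions in
  the ensemble's sample order.

## Baselines

- `metric`: the raw [Q_αlo, Q_{1−αhi}] ensemble quantiles, no calibration.
- `pixel`: per-pixel intensity quantiles across the sampled images, same
  quantile convention applied independently at each pixel.
- `pixel_cp`: per-pixel *independent* split conformal calibration with the
  same one-sided score form as the scalar method — each pixel is its own
  scalar metric. This is the most direct reading of "conformally adjusted
  pixel quantiles"; pooled-adjustment and risk-controlling variants exist
  but are not implemented. On 1×1 images the construction reduces exactly
  (bit-for-bit, tested) to the scalar pipeline.
- Pixel bounds are scored on the metric scale by applying f to both bound
  images and ordering the two results. The min/max ordering matters: a
  metric that is non-monotone in pixel intensity (HU-window counting is the
  canonical example) can rank the "lower" image above the "upper" one.

Pixel methods never consult the metric function when forming bounds, and
metric methods never touch pixels.

## Evaluation harness

`run_split_experiment` repeats random 75/25 (configurable) splits of a
subject pool: calibrate on ⌊cal_fraction·N⌋ subjects, score each method on
the rest, aggregate by arithmetic mean across splits. Interval lengths are
also reported normalized by the calibrated metric method's mean length.
Per-subject ensembles are fixed across splits — reconstruction sampling is
expensive in the motivating setting, so splits re-partition the same
ensembles rather than redrawing them. Since rates are fixed too, each
subject's base quantiles are precomputed once and the per-split work is just
score quantiles; a test pins this fast path to the naive per-split
`calibrate` + `predict_interval` composition. All splitting derives from one
explicit seed; identical seeds give bit-identical reports.

The `evaluate` CLI subcommand exposes the `metric` and `metric_cp` methods
(the CSV pool format carries no image stacks); the pixel methods are
available through the library API, which accepts pools with attached images.

## Synthetic data

The generator emulates a mis-calibrated probabilistic pipeline on the metric
scale. Truths Yᵢ are drawn from a population distribution (normal by
default; a scaled Student-t option stresses the outlier-flagging path), and
samples follow

    Ŷᵢⱼ = Yᵢ + bias + dispersion_factor · εᵢⱼ,   εᵢⱼ ~ N(0, noise_sd²)

with optional contamination: with probability `outlier_rate` a sample is
displaced a further ±`outlier_scale`·noise_sd. Calibration and test subjects
come from one pool, hence are exchangeable by construction, and generation
is a pure function of the config including its seed.

Default conditions model a fat-mass-like task: 250 subjects, ns = 100,
truths ~ N(100, 15²), bias 7.5 (1.5× the noise sd of 5) and dispersion ×1.5
— a pipeline whose raw quantiles are wrong in both location and scale.

The phantom path plants an exact number of fat pixels (at −100 HU, the
adipose window center) on a 0 HU background, so the fat-volume metric of the
truth image is known by construction; each "reconstruction" replants a fat
region whose pixel count follows the scalar law above (rounded, clipped to
the image). The phantom study in the reproduction script uses 100 subjects,
64×64 slices, truth counts ~ N(800, 120²), ns = 20 reconstructions biased
+60 with count noise sd 40, slice thickness 3 — sizes chosen so the full
image pipeline (image synthesis → HU windowing → calibration → 200 splits)
completes in seconds while leaving split-level Monte-Carlo error near 0.01.

What the phantoms do **not** emulate: projection geometry, reconstruction
artifacts, anatomy, partial-volume effects, or any spatial correlation
between reconstructions beyond the shared fat count. Passing coverage on
phantoms validates the statistical machinery end to end through real image
arrays and the real metric implementation; it says nothing about how well a
particular clinical reconstruction model is calibrated.

## Known limitations

- One metric at a time; simultaneous multi-metric bounds are future work.
- Marginal, not conditional, coverage.
- Bound-image retrieval is only as good as the ensemble: if ns is small or
  the algorithm's bias is large, no member may have a metric near the
  interval endpoints, and the retrieved "bound images" can mislead.
- The RT-style dose metrics require a dose engine and contours; only a toy
  volume-above-threshold stand-in ships here.
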