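"""Comparison methods: raw metric quantiles and pixel-space bounding.

Three baselines accompany the calibrated metric interval ("Metric CP"):

``metric``
    Raw ensemble quantiles of the metric, no conformal adjustment.

``pixel``
    Per-pixel quantiles of intensity values across the sampled images.

``pixel_cp``
    Per-pixel independent split conformal calibration: every pixel is
    treated as its own scalar metric with the same one-sided score form as
    the metric method, so on 1x1 images the construction reduces exactly to
    the scalar calibrate/predict path.

Pixel methods never consult the metric function; to score them on metric
coverage, ``metric_interval_from_pixel_bounds`` maps a bound-image pair to a
metric interval by applying f to both images and ordering the results (the
bound images need not be ordered under a non-monotone metric, so crossing
endpoints are reordered rather than trusted).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .conformal import (
    MetricEnsemble,
    MiscoverageRates,
    PredictionInterval,
    adjusted_levels,
    empirical_quantile,
    quantile_index,
)

__all__ = [
    "PixelBoundPair",
    "metric_baseline_interval",
    "pixel_quantile",
    "pixel_baseline_bounds",
    "pixel_cp_bounds",
    "metric_interval_from_pixel_bounds",
]


@dataclass(frozen=True)
class PixelBoundPair:
    """Lower/upper bound images of identical shape.

    ``lower_image <= upper_image`` element-wise is *not* guaranteed once
    conformal adjustments are applied per pixel.
    """

    lower_image: np.ndarray
    upper_image: np.ndarray

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower_image, dtype=float)
        hi = np.asarray(self.upper_image, dtype=float)
        if lo.shape != hi.shape:
            raise ValueError(f"bound shapes differ: {lo.shape} vs {hi.shape}")
        object.__setattr__(self, "lower_image", lo)
        object.__setattr__(self, "upper_image", hi)


def metric_baseline_interval(
    test: MetricEnsemble, rates: MiscoverageRates
) -> PredictionInterval:
    """Uncalibrated interval: raw alpha_lo / (1-alpha_hi) ensemble quantiles."""
    return PredictionInterval(
        lower=empirical_quantile(test.values, rates.alpha_lo),
        upper=empirical_quantile(test.values, 1.0 - rates.alpha_hi),
    )


def _stack(images: Sequence[np.ndarray] | np.ndarray) -> np.ndarray:
    arr = [np.asarray(im, dtype=float) for im in images]
    if len(arr) == 0:
        raise ValueError("empty image list")
    shape = arr[0].shape
    for j, im in enumerate(arr):
        if im.shape != shape:
            raise ValueError(f"image {j} has shape {im.shape}, expected {shape}")
    return np.stack(arr, axis=0)


def pixel_quantile(stack: np.ndarray, level: float) -> np.ndarray:
    """Per-pixel ``level``-th quantile across the leading sample axis.

    Same order-statistic convention as the scalar ``empirical_quantile``,
    applied independently at every pixel.
    """
    k = quantile_index(level, stack.shape[0])
    return np.partition(stack, k - 1, axis=0)[k - 1]


def pixel_baseline_bounds(
    images: Sequence[np.ndarray] | np.ndarray, rates: MiscoverageRates
) -> PixelBoundPair:
    """Per-pixel alpha_lo-th and (1-alpha_hi)-th intensity quantiles."""
    stack = _stack(images)
    return PixelBoundPair(
        lower_image=pixel_quantile(stack, rates.alpha_lo),
        upper_image=pixel_quantile(stack, 1.0 - rates.alpha_hi),
    )


def pixel_cp_bounds(
    cal_images: Sequence[Sequence[np.ndarray] | np.ndarray],
    cal_truth_images: Sequence[np.ndarray],
    test_images: Sequence[np.ndarray] | np.ndarray,
    rates: MiscoverageRates,
) -> PixelBoundPair:
    """Per-pixel split-conformal adjusted intensity bounds.

    Each pixel runs the scalar machinery independently: per calibration
    subject, scores ``s_lo = Q_alpha_lo(pixel samples) - truth pixel`` and
    ``s_hi = truth pixel - Q_{1-alpha_hi}(pixel samples)``; adjustments are
    the per-pixel ``(1 - alpha_hat)``-th score quantiles across subjects.
    """
    if len(cal_images) != len(cal_truth_images):
        raise ValueError(
            f"{len(cal_images)} calibration ensembles but "
            f"{len(cal_truth_images)} truth images"
        )
    if len(cal_images) == 0:
        raise ValueError("empty calibration set")

    shape = np.asarray(cal_truth_images[0], dtype=float).shape
    s_lo, s_hi = [], []
    for ens, truth in zip(cal_images, cal_truth_images):
        stack = _stack(ens)
        truth = np.asarray(truth, dtype=float)
        if stack.shape[1:] != shape or truth.shape != shape:
            raise ValueError(
                f"calibration shapes differ: {stack.shape[1:]} / {truth.shape} "
                f"vs {shape}"
            )
        s_lo.append(pixel_quantile(stack, rates.alpha_lo) - truth)
        s_hi.append(truth - pixel_quantile(stack, 1.0 - rates.alpha_hi))

    n = len(cal_images)
    a_lo, a_hi = adjusted_levels(n, rates)
    q_lo = pixel_quantile(np.stack(s_lo), 1.0 - a_lo)
    q_hi = pixel_quantile(np.stack(s_hi), 1.0 - a_hi)

    test_stack = _stack(test_images)
    if test_stack.shape[1:] != shape:
        raise ValueError(
            f"test image shape {test_stack.shape[1:]} does not match "
            f"calibration shape {shape}"
        )
    return PixelBoundPair(
        lower_image=pixel_quantile(test_stack, rates.alpha_lo) - q_lo,
        upper_image=pixel_quantile(test_stack, 1.0 - rates.alpha_hi) + q_hi,
    )


def metric_interval_from_pixel_bounds(
    bounds: PixelBoundPair, metric: Callable[[np.ndarray], float]
) -> PredictionInterval:
    """Score a pixel-space bound pair on the metric scale.

    Applies the metric to both bound images and orders the two values, since
    a non-monotone metric (or crossing pixel bounds) can rank them either way.
    """
    a = float(metric(bounds.lower_image))
    b = float(metric(bounds.upper_image))
    return PredictionInterval(lower=min(a, b), upper=max(a, b))
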