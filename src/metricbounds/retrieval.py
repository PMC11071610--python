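"""Map metric bounds back to reconstructed images.

A prediction interval on the metric is interpretable on its own, but a
clinician also wants to *see* what the bounds look like.  Retrieval picks,
from the test subject's reconstruction ensemble, the images whose metric
values are nearest the lower and upper interval endpoints (nearest neighbors
in metric space, never pixel space), and partitions the ensemble into
inliers — members whose metric falls inside the closed interval — and
outliers, which are plausible-looking reconstructions with statistically
unlikely metric values.

All indices are 0-based positions into the ensemble's sample axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .conformal import PredictionInterval

logger = logging.getLogger(__name__)

__all__ = [
    "ReconstructionEnsemble",
    "RetrievalResult",
    "nearest_bound_indices",
    "partition_indices",
    "retrieve_bound_images",
    "partition_inliers_outliers",
    "retrieve",
]


@dataclass(frozen=True)
class ReconstructionEnsemble:
    """A test subject's sampled reconstructions with aligned metric values.

    ``images`` is an array of shape ``(ns, ...)`` (2-D or 3-D images stacked
    on the leading axis, Hounsfield units for CT); ``metrics[j]`` is the
    metric of ``images[j]``.
    """

    subject_id: str
    images: np.ndarray
    metrics: np.ndarray

    def __post_init__(self) -> None:
        images = np.asarray(self.images, dtype=float)
        metrics = np.asarray(self.metrics, dtype=float).ravel()
        if images.ndim < 2 or images.shape[0] < 1:
            raise ValueError("images must be a nonempty stack of arrays")
        if images.shape[0] != metrics.size:
            raise ValueError(
                f"{images.shape[0]} images but {metrics.size} metric values"
            )
        if not np.all(np.isfinite(metrics)):
            raise ValueError("non-finite metric value in ensemble")
        object.__setattr__(self, "images", images)
        object.__setattr__(self, "metrics", metrics)

    @property
    def ns(self) -> int:
        return self.images.shape[0]


@dataclass(frozen=True)
class RetrievalResult:
    """Indices of the bound images and the inlier/outlier partition."""

    lower_index: int
    upper_index: int
    inlier_indices: np.ndarray
    outlier_indices: np.ndarray


def nearest_bound_indices(
    metrics: Sequence[float] | np.ndarray, interval: PredictionInterval
) -> tuple[int, int]:
    """Indices of the metric values nearest the lower and upper bounds.

    Exhaustive ``argmin_j |y_j - L|`` / ``argmin_j |y_j - U|``; ties resolve
    to the smallest index.
    """
    arr = np.asarray(metrics, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("empty ensemble")
    lo = int(np.argmin(np.abs(arr - interval.lower)))
    hi = int(np.argmin(np.abs(arr - interval.upper)))
    return lo, hi


def partition_indices(
    metrics: Sequence[float] | np.ndarray, interval: PredictionInterval
) -> tuple[np.ndarray, np.ndarray]:
    """Split sample indices into inliers (metric in [L, U], closed) and outliers.

    If the calibrated interval is empty (U < L) every sample is an outlier;
    this is logged as a warning rather than raised, since negative-length
    intervals are an acknowledged outcome of the calibration.
    """
    arr = np.asarray(metrics, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("empty ensemble")
    if interval.upper < interval.lower:
        logger.warning(
            "empty prediction interval (U=%g < L=%g): all %d samples "
            "flagged as outliers",
            interval.upper,
            interval.lower,
            arr.size,
        )
    inside = (arr >= interval.lower) & (arr <= interval.upper)
    idx = np.arange(arr.size)
    return idx[inside], idx[~inside]


def retrieve_bound_images(
    ens: ReconstructionEnsemble, interval: PredictionInterval
) -> tuple[int, int]:
    """Indices of the reconstructions nearest the lower and upper bounds."""
    return nearest_bound_indices(ens.metrics, interval)


def partition_inliers_outliers(
    ens: ReconstructionEnsemble, interval: PredictionInterval
) -> tuple[np.ndarray, np.ndarray]:
    """Inlier/outlier index sets of the ensemble under the interval."""
    return partition_indices(ens.metrics, interval)


def retrieve(
    ens: ReconstructionEnsemble, interval: PredictionInterval
) -> RetrievalResult:
    """Bound-image retrieval and inlier/outlier partition in one call."""
    lo, hi = retrieve_bound_images(ens, interval)
    inl, outl = partition_inliers_outliers(ens, interval)
    return RetrievalResult(
        lower_index=lo, upper_index=hi, inlier_indices=inl, outlier_indices=outl
    )
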