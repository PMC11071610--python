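"""Scalar metric functions f: image -> real behind one pluggable interface.

The conformal machinery is metric-agnostic: anything that deterministically
reduces an image to one number can be calibrated.  Shipped here:

``fat_volume``
    Fat quantification on a CT slice: count pixels whose Hounsfield value
    lies in the closed adipose window [-150, -50] HU and multiply by slice
    thickness (and optionally by physical pixel area).

``region_volume_above_threshold``
    A toy stand-in for radiotherapy-style structural metrics (e.g. organ
    volume receiving more than a dose threshold): count of voxels above a
    threshold times voxel volume.  Real dose metrics need a dose engine and
    contours and are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .conformal import MetricEnsemble

__all__ = [
    "MetricFunction",
    "FAT_HU_WINDOW",
    "fat_volume",
    "region_volume_above_threshold",
    "make_metric",
    "apply_metric",
]

#: closed Hounsfield-unit window for adipose tissue
FAT_HU_WINDOW = (-150.0, -50.0)


@dataclass(frozen=True)
class MetricFunction:
    """A named, parameterized, deterministic image -> scalar map."""

    name: str
    parameters: Mapping[str, float]
    fn: Callable[[np.ndarray], float] = field(compare=False)

    def __call__(self, image: np.ndarray) -> float:
        return float(self.fn(image))


def fat_volume(
    image: np.ndarray,
    slice_thickness: float = 1.0,
    pixel_area: float = 1.0,
    hu_window: tuple[float, float] = FAT_HU_WINDOW,
) -> float:
    """Fat volume of a CT slice by Hounsfield-unit windowing.

    Counts pixels with value in the closed window ``hu_window`` (both
    endpoints inclusive) and multiplies by ``slice_thickness`` (mm) and
    ``pixel_area``.  ``pixel_area`` defaults to 1, i.e. fat volume is the
    fat-pixel count times thickness; pass the physical in-plane pixel area
    (mm^2) to get a true mm^3 volume.
    """
    if slice_thickness <= 0:
        raise ValueError(f"slice_thickness must be positive, got {slice_thickness!r}")
    img = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    lo, hi = hu_window
    count = int(np.count_nonzero((img >= lo) & (img <= hi)))
    return count * slice_thickness * pixel_area


def region_volume_above_threshold(
    image: np.ndarray, threshold: float, voxel_volume: float = 1.0
) -> float:
    """Volume of the region whose values exceed ``threshold`` (strictly)."""
    img = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    return int(np.count_nonzero(img > threshold)) * voxel_volume


_REGISTRY: dict[str, Callable[..., float]] = {
    "fat_volume": fat_volume,
    "region_volume_above_threshold": region_volume_above_threshold,
}


def make_metric(name: str, **parameters: float) -> MetricFunction:
    """Build a :class:`MetricFunction` from the registry by name.

    >>> m = make_metric("fat_volume", slice_thickness=3.0)
    >>> m(np.full((10, 10), -100.0))
    300.0
    """
    try:
        base = _REGISTRY[name]
    except KeyError:
        raise ValueError(
            f"unknown metric {name!r}; available: {sorted(_REGISTRY)}"
        ) from None
    return MetricFunction(
        name=name,
        parameters=dict(parameters),
        fn=lambda image: base(image, **parameters),
    )


def apply_metric(
    metric: MetricFunction | Callable[[np.ndarray], float],
    ensemble_images: Sequence[np.ndarray] | np.ndarray,
    subject_id: str = "subject",
) -> MetricEnsemble:
    """Vectorize a metric over a stack of sampled reconstructions.

    Returns a :class:`MetricEnsemble` whose values align index-for-index
    with the image order.  All images must share one shape.
    """
    images = [np.asarray(im, dtype=float) for im in ensemble_images]
    if len(images) == 0:
        raise ValueError("empty image list")
    shape = images[0].shape
    for j, im in enumerate(images):
        if im.shape != shape:
            raise ValueError(
                f"image {j} has shape {im.shape}, expected {shape}"
            )
    values = np.array([float(metric(im)) for im in images])
    return MetricEnsemble(subject_id=subject_id, values=values)
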