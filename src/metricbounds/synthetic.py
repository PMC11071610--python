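"""Exchangeable synthetic subjects: metric ensembles and CT-like phantoms.

Stands in for an expensive probabilistic reconstruction pipeline so every
other module is testable without clinical data.  Each subject i gets a
ground-truth metric ``Y_i`` drawn from a population distribution, and an
ensemble of ``ns`` predicted metrics

    Y_hat_{i,j} = Y_i + bias + dispersion_factor * eps_{i,j},
    eps_{i,j} ~ Normal(0, noise_sd^2)

optionally contaminated: with probability ``outlier_rate`` a sample is
displaced by a further ``+/- outlier_scale * noise_sd``.  ``bias`` emulates a
systematically mis-centered reconstruction, ``dispersion_factor`` a mis-
scaled ensemble spread (both make raw ensemble quantiles invalid, which is
exactly the failure conformal calibration repairs).  Calibration and test
subjects are drawn from one pool, hence exchangeable by construction, and
all generation is a pure function of the config (including its seed).

The phantom path builds square CT-like images whose fat-volume metric is
known by construction: ``fat_pixel_count`` pixels at -100 HU (the adipose
window center) on a 0 HU background, so the windowed pixel count equals the
planted count exactly.  Each "reconstruction" perturbs the fat-pixel count
by the same bias/noise law as the scalar generator.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .conformal import CalibrationRecord, MetricEnsemble
from .metrics import fat_volume
from .retrieval import ReconstructionEnsemble

__all__ = [
    "GeneratorConfig",
    "PhantomSpec",
    "generate_metric_pool",
    "generate_phantom_ensemble",
    "generate_phantom_pool",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic pool.

    Defaults describe a mis-calibrated pipeline on a fat-mass-like scale:
    250 subjects with truths ~ Normal(100, 15^2), ns=100 samples per subject,
    prediction bias 7.5 (1.5 noise sd) and spread inflated by 1.5, no outlier
    contamination.
    """

    n_subjects: int = 250
    ns: int = 100
    truth_distribution: str = "normal"  # "normal" or "student_t"
    truth_mean: float = 100.0
    truth_sd: float = 15.0
    truth_df: float = 3.0  # student_t only
    bias: float = 7.5
    noise_sd: float = 5.0
    dispersion_factor: float = 1.5
    outlier_rate: float = 0.0
    outlier_scale: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.ns < 1:
            raise ValueError("ns must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 <= self.outlier_rate < 1.0):
            raise ValueError("outlier_rate must lie in [0, 1)")
        if self.truth_distribution not in ("normal", "student_t"):
            raise ValueError(
                f"unknown truth_distribution {self.truth_distribution!r}"
            )


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of the CT-like phantom slices.

    ``fat_region_pixels`` is the planted in-window pixel count of the truth
    image; ``slice_thickness`` (mm) scales the fat-volume metric.
    """

    image_size: int = 64
    background_hu: float = 0.0
    fat_hu: float = -100.0
    fat_region_pixels: int = 800
    slice_thickness: float = 3.0

    def __post_init__(self) -> None:
        if self.image_size < 1:
            raise ValueError("image_size must be >= 1")
        if not (0 <= self.fat_region_pixels <= self.image_size**2):
            raise ValueError(
                f"fat_region_pixels={self.fat_region_pixels} exceeds the "
                f"{self.image_size}x{self.image_size} image"
            )
        if self.slice_thickness <= 0:
            raise ValueError("slice_thickness must be positive")


def _draw_truths(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    if config.truth_distribution == "normal":
        return rng.normal(config.truth_mean, config.truth_sd, config.n_subjects)
    return config.truth_mean + config.truth_sd * rng.standard_t(
        config.truth_df, config.n_subjects
    )


def _draw_samples(
    truths: np.ndarray, config: GeneratorConfig, rng: np.random.Generator
) -> np.ndarray:
    n, ns = truths.size, config.ns
    eps = rng.normal(0.0, config.noise_sd, (n, ns))
    samples = truths[:, None] + config.bias + config.dispersion_factor * eps
    if config.outlier_rate > 0:
        hit = rng.random((n, ns)) < config.outlier_rate
        sign = rng.choice([-1.0, 1.0], size=(n, ns))
        samples = samples + hit * sign * config.outlier_scale * config.noise_sd
    return samples


def generate_metric_pool(config: GeneratorConfig) -> list[CalibrationRecord]:
    """Draw an exchangeable pool of scalar calibration records."""
    rng = np.random.default_rng(config.seed)
    truths = _draw_truths(config, rng)
    samples = _draw_samples(truths, config, rng)
    return [
        CalibrationRecord(
            ensemble=MetricEnsemble(subject_id=f"s{i:04d}", values=samples[i]),
            truth=float(truths[i]),
        )
        for i in range(config.n_subjects)
    ]


def _phantom_image(
    spec: PhantomSpec, count: int, rng: np.random.Generator
) -> np.ndarray:
    img = np.full((spec.image_size, spec.image_size), spec.background_hu)
    if count > 0:
        flat = rng.choice(spec.image_size**2, size=count, replace=False)
        img.flat[flat] = spec.fat_hu
    return img


def generate_phantom_ensemble(
    spec: PhantomSpec,
    config: GeneratorConfig,
    subject_id: str = "phantom",
    rng: np.random.Generator | None = None,
) -> tuple[ReconstructionEnsemble, np.ndarray]:
    """One phantom subject: truth image plus ``ns`` perturbed reconstructions.

    The truth image has exactly ``spec.fat_region_pixels`` in-window pixels;
    each reconstruction replants a fat region whose pixel count follows the
    scalar generator's bias/noise law (rounded and clipped to the image).
    Metrics are fat volumes at the spec's slice thickness.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    truth_image = _phantom_image(spec, spec.fat_region_pixels, rng)
    max_pixels = spec.image_size**2
    counts = np.clip(
        np.rint(
            spec.fat_region_pixels
            + config.bias
            + config.dispersion_factor * rng.normal(0.0, config.noise_sd, config.ns)
        ).astype(int),
        0,
        max_pixels,
    )
    images = np.stack([_phantom_image(spec, int(c), rng) for c in counts])
    metrics = np.array(
        [fat_volume(im, slice_thickness=spec.slice_thickness) for im in images]
    )
    ens = ReconstructionEnsemble(
        subject_id=subject_id, images=images, metrics=metrics
    )
    return ens, truth_image


def generate_phantom_pool(
    spec: PhantomSpec, config: GeneratorConfig
) -> list[CalibrationRecord]:
    """Phantom subjects with image stacks attached, ready for any method.

    Per subject, the truth fat-pixel count is drawn from the config's truth
    distribution (rounded, clipped to the image); the record's scalar truth
    and ensemble are fat volumes of the truth image and reconstructions.
    """
    rng = np.random.default_rng(config.seed)
    raw = _draw_truths(config, rng)
    max_pixels = spec.image_size**2
    counts = np.clip(np.rint(raw).astype(int), 0, max_pixels)
    records = []
    for i, count in enumerate(counts):
        subj_spec = replace(spec, fat_region_pixels=int(count))
        ens, truth_image = generate_phantom_ensemble(
            subj_spec, config, subject_id=f"p{i:04d}", rng=rng
        )
        records.append(
            CalibrationRecord(
                ensemble=MetricEnsemble(
                    subject_id=ens.subject_id, values=ens.metrics
                ),
                truth=fat_volume(
                    truth_image, slice_thickness=spec.slice_thickness
                ),
                images=ens.images,
                truth_image=truth_image,
            )
        )
    return records
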