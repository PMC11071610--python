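"""Split conformal calibration of scalar-metric prediction intervals.

A probabilistic reconstruction algorithm produces, for each subject, an
ensemble of ``ns`` plausible images; a metric function reduces each image to
one scalar (e.g. fat volume of a CT slice).  The ensemble's empirical
quantiles are a natural interval for the subject's true metric, but a biased
or over/under-dispersed reconstruction pipeline makes those raw quantiles
invalid.  Given a calibration set of subjects with known ground-truth
metrics, split conformal prediction learns additive quantile adjustments
``(q_lo, q_hi)`` such that the adjusted interval

    [ Q_alpha_lo(Y_hat) - q_lo ,  Q_{1-alpha_hi}(Y_hat) + q_hi ]

contains the truth with probability at least ``1 - alpha_lo - alpha_hi``
marginally over exchangeable (calibration, test) draws.

Two one-sided non-conformity scores are computed per calibration subject:

    s_lo = Q_alpha_lo(Y_hat) - Y        (how far the lower quantile overshoots)
    s_hi = Y - Q_{1-alpha_hi}(Y_hat)    (how far the upper quantile undershoots)

and the adjustments are the ``(1 - alpha_hat)``-th empirical quantiles of the
score sets, where ``alpha_hat = floor(alpha * (n + 1)) / n`` is the
finite-sample corrected mis-coverage level.

Empirical quantiles use the lower order statistic ``k = max(1, ceil(level*m))``
(no interpolation), so every quantity is an element of the sample set and the
finite-sample argument applies exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: tag written into adjustment files so downstream consumers can detect a
#: convention mismatch
QUANTILE_CONVENTION = "lower-order-statistic;k=max(1,ceil(level*m))"

__all__ = [
    "QUANTILE_CONVENTION",
    "MetricEnsemble",
    "CalibrationRecord",
    "NonconformityScores",
    "MiscoverageRates",
    "QuantileAdjustments",
    "PredictionInterval",
    "empirical_quantile",
    "quantile_index",
    "nonconformity_scores",
    "adjusted_levels",
    "calibrate",
    "predict_interval",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MetricEnsemble:
    """One subject's ``ns`` predicted metric values.

    Parameters
    ----------
    subject_id
        Opaque identifier.
    values
        The metric value of each sampled reconstruction, in metric units
        (e.g. mm^3 of fat).  At least one value; all finite.
    """

    subject_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("ensemble must hold at least one metric value")
        if not np.all(np.isfinite(arr)):
            raise ValueError(
                f"non-finite metric value in ensemble {self.subject_id!r}"
            )
        arr.flags.writeable = False
        object.__setattr__(self, "values", arr)

    @property
    def ns(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class CalibrationRecord:
    """A metric ensemble paired with the subject's ground-truth metric.

    ``images`` / ``truth_image`` are optional per-subject image stacks used
    only by pixel-space baselines and retrieval demos; the scalar conformal
    machinery never reads them.
    """

    ensemble: MetricEnsemble
    truth: float
    images: np.ndarray | None = field(default=None, compare=False)
    truth_image: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not math.isfinite(self.truth):
            raise ValueError(
                f"non-finite truth for subject {self.ensemble.subject_id!r}"
            )


@dataclass(frozen=True)
class NonconformityScores:
    """Signed lower/upper scores for one calibration subject (may be negative)."""

    s_lo: float
    s_hi: float


@dataclass(frozen=True)
class MiscoverageRates:
    """Lower and upper mis-coverage rates; nominal coverage is 1 - alpha_lo - alpha_hi."""

    alpha_lo: float
    alpha_hi: float

    def __post_init__(self) -> None:
        for name, a in (("alpha_lo", self.alpha_lo), ("alpha_hi", self.alpha_hi)):
            if not (0.0 <= a < 1.0):
                raise ValueError(f"{name} must lie in [0, 1), got {a!r}")
        if self.alpha_lo + self.alpha_hi >= 1.0:
            raise ValueError("alpha_lo + alpha_hi must be < 1")


@dataclass(frozen=True)
class QuantileAdjustments:
    """Calibrated quantile offsets plus the levels and sample size that produced them."""

    q_lo: float
    q_hi: float
    alpha_hat_lo: float
    alpha_hat_hi: float
    n: int


@dataclass(frozen=True)
class PredictionInterval:
    """Lower/upper metric bounds.  ``upper`` may fall below ``lower`` after
    calibration; the interval is then empty and its reported length is 0."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lower) and math.isfinite(self.upper)):
            raise ValueError("interval endpoints must be finite")

    def contains(self, value: float) -> bool:
        """Closed-interval membership test."""
        return self.lower <= value <= self.upper


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def quantile_index(level: float, m: int) -> int:
    """1-based order-statistic index for the ``level``-th quantile of ``m`` values.

    ``k = max(1, ceil(level * m))``; the product is rounded to 9 decimals
    first so that binary representation error (e.g. ``0.9 * 10 ->
    9.000000000000002``) cannot bump the index.
    """
    if not (0.0 <= level <= 1.0):
        raise ValueError(f"quantile level must lie in [0, 1], got {level!r}")
    return max(1, math.ceil(round(level * m, 9)))


def empirical_quantile(values: Sequence[float] | np.ndarray, level: float) -> float:
    """The ``level``-th empirical quantile: the k-th smallest sample value.

    Uses ``k = max(1, ceil(level * m))`` with no interpolation, so level 0 is
    the minimum and level 1 the maximum and the result is always an observed
    value.
    """
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("empty sample set")
    k = quantile_index(level, arr.size)
    return float(np.partition(arr, k - 1)[k - 1])


def nonconformity_scores(
    record: CalibrationRecord, rates: MiscoverageRates
) -> NonconformityScores:
    """Lower/upper non-conformity scores of one calibration subject.

    ``s_lo = Q_alpha_lo(Y_hat) - Y`` and ``s_hi = Y - Q_{1-alpha_hi}(Y_hat)``.
    Positive scores mean the raw ensemble quantile misses the truth on that
    side; negative scores mean it is already conservative.
    """
    lo_q = empirical_quantile(record.ensemble.values, rates.alpha_lo)
    hi_q = empirical_quantile(record.ensemble.values, 1.0 - rates.alpha_hi)
    return NonconformityScores(s_lo=lo_q - record.truth, s_hi=record.truth - hi_q)


def adjusted_levels(n: int, rates: MiscoverageRates) -> tuple[float, float]:
    """Finite-sample corrected mis-coverage levels ``floor(alpha*(n+1)) / n``.

    When ``floor(alpha*(n+1)) == 0`` the corrected level is 0 and the
    corresponding adjustment quantile degenerates to the score maximum (the
    most conservative choice); a warning is logged that ``n`` is too small
    for the requested ``alpha``.
    """
    if n < 1:
        raise ValueError(f"need at least one calibration subject, got n={n}")
    out = []
    for a in (rates.alpha_lo, rates.alpha_hi):
        k = math.floor(round(a * (n + 1), 9))
        if k == 0 and a > 0.0:
            logger.warning(
                "calibration size n=%d too small for alpha=%g "
                "(finite-sample level is 0; using the score maximum)",
                n,
                a,
            )
        out.append(k / n)
    return out[0], out[1]


def calibrate(
    records: Sequence[CalibrationRecord], rates: MiscoverageRates
) -> QuantileAdjustments:
    """Learn quantile adjustments from a calibration set.

    Computes per-subject non-conformity scores, then takes the
    ``(1 - alpha_hat)``-th empirical quantile of each one-sided score set.
    The two sides are calibrated independently.
    """
    if len(records) == 0:
        raise ValueError("empty calibration set")
    n = len(records)
    scores = [nonconformity_scores(r, rates) for r in records]
    a_lo, a_hi = adjusted_levels(n, rates)
    q_lo = empirical_quantile([s.s_lo for s in scores], 1.0 - a_lo)
    q_hi = empirical_quantile([s.s_hi for s in scores], 1.0 - a_hi)
    return QuantileAdjustments(
        q_lo=q_lo, q_hi=q_hi, alpha_hat_lo=a_lo, alpha_hat_hi=a_hi, n=n
    )


def predict_interval(
    test: MetricEnsemble,
    adj: QuantileAdjustments,
    rates: MiscoverageRates,
    *,
    domain: tuple[float, float] | None = None,
) -> PredictionInterval:
    """Calibrated prediction interval for a test subject.

    ``[Q_alpha_lo(Y_hat) - q_lo, Q_{1-alpha_hi}(Y_hat) + q_hi]``.  Endpoints
    are not clamped to the metric's natural domain unless ``domain=(lo, hi)``
    is given explicitly (off by default: a nominally impossible endpoint such
    as a negative volume is still statistically informative).
    """
    lower = empirical_quantile(test.values, rates.alpha_lo) - adj.q_lo
    upper = empirical_quantile(test.values, 1.0 - rates.alpha_hi) + adj.q_hi
    if domain is not None:
        lower = min(max(lower, domain[0]), domain[1])
        upper = min(max(upper, domain[0]), domain[1])
    return PredictionInterval(lower=lower, upper=upper)
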