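"""Coverage / interval-length evaluation and the repeated random-split harness.

Statistical bounding methods trade *test coverage* — the probability that a
test subject's ground-truth metric falls inside the predicted interval —
against *interval length*.  The harness repeats a random calibration/test
split of a subject pool many times, calibrates on the calibration part,
scores every requested method on the test part, and reports mean coverage
and mean interval length per method, with lengths additionally normalized by
the calibrated metric method's mean length to remove the metric's arbitrary
scale.

Per-subject ensembles are fixed across splits (reconstruction sampling is
expensive in practice, so the same samples are re-partitioned, not redrawn).
Because the mis-coverage rates are also fixed, each subject's base ensemble
quantiles are precomputed once; the per-split work is then just score
quantiles and membership tests, which keeps a 500-split experiment on
hundreds of subjects to well under a second.  A test pins this fast path to
the naive per-split ``calibrate`` + ``predict_interval`` composition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .baselines import (
    metric_interval_from_pixel_bounds,
    pixel_baseline_bounds,
    pixel_cp_bounds,
)
from .conformal import (
    CalibrationRecord,
    MiscoverageRates,
    PredictionInterval,
    adjusted_levels,
    empirical_quantile,
)

__all__ = [
    "METHODS",
    "EvaluationReport",
    "interval_length",
    "coverage",
    "normalized_length",
    "run_split_experiment",
]

#: recognized method names, in canonical report order
METHODS = ("metric", "metric_cp", "pixel", "pixel_cp")


@dataclass(frozen=True)
class EvaluationReport:
    """Aggregate performance of one bounding method across random splits."""

    method: str
    coverage: float
    mean_interval_length: float
    normalized_interval_length: float
    n_splits: int
    seed: int


def interval_length(interval: PredictionInterval) -> float:
    """``max(0, U - L)``: an empty (crossed) interval has length 0."""
    return max(0.0, interval.upper - interval.lower)


def coverage(
    intervals: Sequence[PredictionInterval], truths: Sequence[float]
) -> float:
    """Fraction of truths inside their closed interval [L, U]."""
    if len(intervals) != len(truths):
        raise ValueError(
            f"{len(intervals)} intervals but {len(truths)} truths"
        )
    if len(intervals) == 0:
        raise ValueError("empty evaluation set")
    hits = sum(iv.contains(t) for iv, t in zip(intervals, truths))
    return hits / len(intervals)


def normalized_length(method_mean: float, reference_mean: float) -> float:
    """Mean interval length relative to the reference method's mean length."""
    if reference_mean <= 0:
        raise ValueError("degenerate reference")
    return method_mean / reference_mean


def _pixel_interval(
    record: CalibrationRecord,
    method: str,
    rates: MiscoverageRates,
    metric,
    cal_records: Sequence[CalibrationRecord],
) -> PredictionInterval:
    if record.images is None:
        raise ValueError(
            f"method {method!r} needs per-subject images; subject "
            f"{record.ensemble.subject_id!r} has none"
        )
    if method == "pixel":
        bounds = pixel_baseline_bounds(record.images, rates)
    else:  # pixel_cp
        bounds = pixel_cp_bounds(
            [r.images for r in cal_records],
            [r.truth_image for r in cal_records],
            record.images,
            rates,
        )
    return metric_interval_from_pixel_bounds(bounds, metric)


def run_split_experiment(
    pool: Sequence[CalibrationRecord],
    rates: MiscoverageRates,
    n_splits: int,
    cal_fraction: float = 0.75,
    methods: Sequence[str] = ("metric", "metric_cp"),
    seed: int = 0,
    metric=None,
    return_splits: bool = False,
) -> list[EvaluationReport] | tuple[list[EvaluationReport], pd.DataFrame]:
    """Repeat random calibration/test splits and score each method.

    Parameters
    ----------
    pool
        Subjects with ensembles and ground truths (images attached for the
        pixel methods).
    rates
        Lower/upper mis-coverage rates.
    n_splits
        Number of independent random splits.
    cal_fraction
        Fraction (exclusive 0..1) of the pool used for calibration; the
        calibration part has ``floor(cal_fraction * N)`` subjects.
    methods
        Any of ``metric``, ``metric_cp``, ``pixel``, ``pixel_cp``.  Pixel
        methods additionally require ``metric`` (a callable image -> scalar)
        to score their bound images on the metric scale.
    seed
        Seeds the split permutations; identical seeds give bit-identical
        reports.
    return_splits
        Also return the per-split coverage/length table (one row per split
        and method).

    Returns
    -------
    One :class:`EvaluationReport` per method (normalized length is relative
    to ``metric_cp`` when present, else to the first method), and optionally
    the per-split DataFrame.
    """
    N = len(pool)
    if N < 4:
        raise ValueError(f"pool too small ({N} subjects; need at least 4)")
    if not (0.0 < cal_fraction < 1.0):
        raise ValueError(f"cal_fraction must lie in (0, 1), got {cal_fraction!r}")
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods {sorted(unknown)}; choose from {METHODS}")
    n_cal = math.floor(cal_fraction * N)
    n_test = N - n_cal
    if n_cal < 1 or n_test < 1:
        raise ValueError(
            f"cal_fraction={cal_fraction} leaves an empty side for N={N}"
        )
    pixel_methods = [m for m in methods if m in ("pixel", "pixel_cp")]
    if pixel_methods and metric is None:
        raise ValueError(f"methods {pixel_methods} require a metric function")

    # base quantiles depend only on the fixed ensembles and rates
    truths = np.array([r.truth for r in pool])
    base_lo = np.array(
        [empirical_quantile(r.ensemble.values, rates.alpha_lo) for r in pool]
    )
    base_hi = np.array(
        [empirical_quantile(r.ensemble.values, 1.0 - rates.alpha_hi) for r in pool]
    )
    a_lo, a_hi = adjusted_levels(n_cal, rates)

    rng = np.random.default_rng(seed)
    rows = []
    for split in range(n_splits):
        perm = rng.permutation(N)
        cal_idx, test_idx = perm[:n_cal], perm[n_cal:]
        cal_records = [pool[i] for i in cal_idx]

        for method in methods:
            if method in ("metric", "metric_cp"):
                if method == "metric_cp":
                    q_lo = empirical_quantile(
                        base_lo[cal_idx] - truths[cal_idx], 1.0 - a_lo
                    )
                    q_hi = empirical_quantile(
                        truths[cal_idx] - base_hi[cal_idx], 1.0 - a_hi
                    )
                else:
                    q_lo = q_hi = 0.0
                L = base_lo[test_idx] - q_lo
                U = base_hi[test_idx] + q_hi
                t = truths[test_idx]
                cov = float(np.mean((t >= L) & (t <= U)))
                mean_len = float(np.mean(np.maximum(0.0, U - L)))
            else:
                ivs = [
                    _pixel_interval(pool[i], method, rates, metric, cal_records)
                    for i in test_idx
                ]
                cov = coverage(ivs, truths[test_idx])
                mean_len = float(np.mean([interval_length(iv) for iv in ivs]))
            rows.append(
                {
                    "split": split,
                    "method": method,
                    "coverage": cov,
                    "mean_interval_length": mean_len,
                }
            )

    table = pd.DataFrame(rows)
    agg = table.groupby("method", sort=False).mean(numeric_only=True)
    reference = "metric_cp" if "metric_cp" in methods else methods[0]
    ref_mean = float(agg.loc[reference, "mean_interval_length"])
    reports = []
    for m in methods:
        mean_len = float(agg.loc[m, "mean_interval_length"])
        # a degenerate (all-zero-length) reference leaves normalization undefined
        norm = (
            normalized_length(mean_len, ref_mean) if ref_mean > 0 else float("nan")
        )
        reports.append(
            EvaluationReport(
                method=m,
                coverage=float(agg.loc[m, "coverage"]),
                mean_interval_length=mean_len,
                normalized_interval_length=norm,
                n_splits=n_splits,
                seed=seed,
            )
        )
    if return_splits:
        return reports, table
    return reports
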