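"""File formats: long-format metric CSVs, adjustment/report JSON, image stacks.

Calibration tables are delimited text in long format — one row per sampled
reconstruction (``subject_id, sample_id, metric_value``) plus a truth table
(``subject_id, truth_value``) — so they round-trip through any spreadsheet
or pandas without custom tooling.  Headers are validated strictly and
malformed rows are reported by row number.

Image ensembles travel either as NIfTI (one file per subject, samples
stacked on the trailing axis, read via nibabel) or as a NumPy ``.npz``
archive with keys ``images`` (ns on the leading axis) and ``metrics``.

Adjustment files are small JSON documents carrying the calibrated offsets,
the levels and sample size that produced them, the quantile-convention tag,
and a SHA-256 of the calibration table so a stale calibration can be
detected at predict time.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .conformal import (
    QUANTILE_CONVENTION,
    CalibrationRecord,
    MetricEnsemble,
    MiscoverageRates,
    QuantileAdjustments,
)
from .retrieval import ReconstructionEnsemble

__all__ = [
    "read_samples_csv",
    "read_truths_csv",
    "load_calibration_records",
    "write_pool_csv",
    "sha256_file",
    "write_adjustments",
    "read_adjustments",
    "load_image_ensemble",
    "save_image_ensemble_npz",
    "save_nifti_stack",
    "load_nifti_stack",
]

SAMPLE_COLUMNS = ["subject_id", "sample_id", "metric_value"]
TRUTH_COLUMNS = ["subject_id", "truth_value"]


def _read_table(path: str | Path, columns: list[str], value_cols: list[str]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str})
    if list(df.columns) != columns:
        raise ValueError(
            f"{path}: expected columns {columns}, found {list(df.columns)}"
        )
    for col in value_cols:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[values.isna()]
        if len(bad):
            # +2: header line plus 1-based counting
            raise ValueError(
                f"{path}: non-numeric {col} at row {bad[0] + 2}: "
                f"{df.loc[bad[0], col]!r}"
            )
        df[col] = values.astype(float)
    return df


def read_samples_csv(path: str | Path) -> pd.DataFrame:
    """Long-format predicted-metric table (subject_id, sample_id, metric_value)."""
    return _read_table(path, SAMPLE_COLUMNS, ["metric_value"])


def read_truths_csv(path: str | Path) -> pd.DataFrame:
    """Ground-truth table (subject_id, truth_value)."""
    return _read_table(path, TRUTH_COLUMNS, ["truth_value"])


def load_calibration_records(
    samples_path: str | Path, truths_path: str | Path
) -> list[CalibrationRecord]:
    """Join a samples table with a truth table into calibration records.

    Every subject in the truth table must appear in the samples table;
    samples keep their file order within each subject.
    """
    samples = read_samples_csv(samples_path)
    truths = read_truths_csv(truths_path)
    if truths["subject_id"].duplicated().any():
        dup = truths.loc[truths["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValueError(f"{truths_path}: duplicate subject {dup!r} in truth table")
    grouped = {sid: g["metric_value"].to_numpy() for sid, g in samples.groupby("subject_id", sort=False)}
    records = []
    for row in truths.itertuples(index=False):
        if row.subject_id not in grouped:
            raise ValueError(
                f"subject {row.subject_id!r} in truth table has no samples in "
                f"{samples_path}"
            )
        records.append(
            CalibrationRecord(
                ensemble=MetricEnsemble(
                    subject_id=row.subject_id, values=grouped[row.subject_id]
                ),
                truth=float(row.truth_value),
            )
        )
    return records


def write_pool_csv(
    records: list[CalibrationRecord],
    samples_path: str | Path,
    truths_path: str | Path,
) -> None:
    """Write a record pool as the samples + truths CSV pair."""
    sample_rows = [
        {
            "subject_id": r.ensemble.subject_id,
            "sample_id": j,
            "metric_value": v,
        }
        for r in records
        for j, v in enumerate(r.ensemble.values)
    ]
    pd.DataFrame(sample_rows, columns=SAMPLE_COLUMNS).to_csv(samples_path, index=False)
    truth_rows = [
        {"subject_id": r.ensemble.subject_id, "truth_value": r.truth}
        for r in records
    ]
    pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS).to_csv(truths_path, index=False)


def sha256_file(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_adjustments(
    path: str | Path,
    adj: QuantileAdjustments,
    rates: MiscoverageRates,
    calibration_sha256: str | None = None,
) -> None:
    """Persist calibrated adjustments with full provenance."""
    doc = {
        "q_lo": adj.q_lo,
        "q_hi": adj.q_hi,
        "alpha_hat_lo": adj.alpha_hat_lo,
        "alpha_hat_hi": adj.alpha_hat_hi,
        "n": adj.n,
        "alpha_lo": rates.alpha_lo,
        "alpha_hi": rates.alpha_hi,
        "quantile_convention": QUANTILE_CONVENTION,
        "calibration_sha256": calibration_sha256,
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_adjustments(
    path: str | Path,
) -> tuple[QuantileAdjustments, MiscoverageRates, dict]:
    """Load an adjustment file; returns (adjustments, rates, raw document)."""
    doc = json.loads(Path(path).read_text())
    if doc.get("quantile_convention") != QUANTILE_CONVENTION:
        raise ValueError(
            f"{path}: quantile convention {doc.get('quantile_convention')!r} "
            f"does not match this package's {QUANTILE_CONVENTION!r}"
        )
    adj = QuantileAdjustments(
        q_lo=float(doc["q_lo"]),
        q_hi=float(doc["q_hi"]),
        alpha_hat_lo=float(doc["alpha_hat_lo"]),
        alpha_hat_hi=float(doc["alpha_hat_hi"]),
        n=int(doc["n"]),
    )
    rates = MiscoverageRates(
        alpha_lo=float(doc["alpha_lo"]), alpha_hi=float(doc["alpha_hi"])
    )
    return adj, rates, doc


def save_nifti_stack(path: str | Path, images: np.ndarray) -> None:
    """Write an (ns, H, W) image stack as NIfTI with samples on the trailing axis."""
    stack = np.asarray(images, dtype=np.float64)
    nib.save(nib.Nifti1Image(np.moveaxis(stack, 0, -1), affine=np.eye(4)), str(path))


def load_nifti_stack(path: str | Path) -> np.ndarray:
    """Read a NIfTI stack back to (ns, H, W) with samples on the leading axis."""
    data = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    return np.moveaxis(data, -1, 0)


def save_image_ensemble_npz(path: str | Path, ens: ReconstructionEnsemble) -> None:
    np.savez_compressed(path, images=ens.images, metrics=ens.metrics)


def load_image_ensemble(
    path: str | Path,
    metric=None,
    metrics: np.ndarray | None = None,
    subject_id: str | None = None,
) -> ReconstructionEnsemble:
    """Load a subject's reconstruction ensemble from NIfTI or ``.npz``.

    Metric values are taken from (in precedence order) the explicit
    ``metrics`` array, the archive's ``metrics`` key, or by applying
    ``metric`` to each image; at least one source must be available.
    """
    path = Path(path)
    sid = subject_id or path.stem.replace(".nii", "")
    if path.suffix == ".npz":
        with np.load(path) as archive:
            images = np.asarray(archive["images"], dtype=float)
            if metrics is None and "metrics" in archive:
                metrics = np.asarray(archive["metrics"], dtype=float)
    elif path.suffix == ".nii" or path.name.endswith(".nii.gz"):
        images = load_nifti_stack(path)
    else:
        raise ValueError(f"unsupported image format: {path}")
    if metrics is None:
        if metric is None:
            raise ValueError(
                f"{path}: no metric values stored and no metric function given"
            )
        metrics = np.array([float(metric(im)) for im in images])
    return ReconstructionEnsemble(subject_id=sid, images=images, metrics=metrics)
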