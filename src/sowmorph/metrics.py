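"""Regression evaluation for the six body metrics.

The target vector is (BW, CW, HW, BL, CH, HH): body weight in kg and
chest width, hip width, body length, chest height, hip height in cm.
For each metric the suite reports MSE, RMSE, MAE, MAPE (in percent) and
the signed per-sample relative error (y - y')/y, whose sign convention
makes under-prediction positive.  The mean of the true values is also
reported (it enables an optional R^2) together with the aggregate total
MSE, the quantity the training loss sums.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["METRIC_NAMES", "METRIC_UNITS", "BodyMetrics", "MetricReport", "regression_report"]

METRIC_NAMES = ("BW", "CW", "HW", "BL", "CH", "HH")
METRIC_UNITS = {"BW": "kg", "CW": "cm", "HW": "cm", "BL": "cm", "CH": "cm", "HH": "cm"}


@dataclass(frozen=True)
class BodyMetrics:
    """Six-element morphometric target: weight (kg) and five sizes (cm)."""

    BW: float
    CW: float
    HW: float
    BL: float
    CH: float
    HH: float

    def __post_init__(self):
        for name in METRIC_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} is not finite: {v}")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in METRIC_NAMES], dtype=np.float64)

    @classmethod
    def from_array(cls, arr) -> "BodyMetrics":
        arr = np.asarray(arr, dtype=np.float64).reshape(-1)
        if arr.shape[0] != 6:
            raise ValueError(f"expected 6 values, got {arr.shape[0]}")
        return cls(**dict(zip(METRIC_NAMES, map(float, arr))))


@dataclass
class MetricReport:
    """Per-metric error suite plus aggregate total MSE."""

    n: int
    mse: dict[str, float]
    rmse: dict[str, float]
    mae: dict[str, float]
    mape: dict[str, float]               # percent; nan if any truth is 0
    relative_errors: dict[str, np.ndarray]  # signed, (y - y')/y per sample
    mean_truth: dict[str, float]
    total_mse: float = field(init=False)

    def __post_init__(self):
        self.total_mse = float(sum(self.mse.values()))

    def to_dict(self):
        out = {"n": self.n, "total_mse": self.total_mse}
        for stat, table in (("MSE", self.mse), ("RMSE", self.rmse),
                            ("MAE", self.mae), ("MAPE", self.mape)):
            for m, v in table.items():
                out[f"{m}_{stat}"] = v
        return out


def regression_report(truth, pred, names=METRIC_NAMES) -> MetricReport:
    """Compute the error suite for a (n_samples, 6) truth/prediction pair.

    One-metric input may be passed as 1-D arrays with a single name.
    MAPE and relative error are undefined (nan) for samples whose true
    value is zero; such samples are excluded from the MAPE mean and
    flagged as nan in the per-sample relative errors.
    """
    truth = np.atleast_2d(np.asarray(truth, dtype=np.float64))
    pred = np.atleast_2d(np.asarray(pred, dtype=np.float64))
    if truth.shape != pred.shape:
        raise ValueError(f"shape mismatch: truth {truth.shape} vs pred {pred.shape}")
    if truth.shape[1] != len(names):
        raise ValueError(f"expected {len(names)} metric columns, got {truth.shape[1]}")
    if truth.shape[0] < 1:
        raise ValueError("need at least one sample")
    mse, rmse, mae, mape, rel, mean_truth = {}, {}, {}, {}, {}, {}
    for j, name in enumerate(names):
        y, yp = truth[:, j], pred[:, j]
        err = y - yp
        mse[name] = float(np.mean(err**2))
        rmse[name] = float(np.sqrt(mse[name]))
        mae[name] = float(np.mean(np.abs(err)))
        nonzero = y != 0
        r = np.full_like(y, np.nan)
        r[nonzero] = err[nonzero] / y[nonzero]
        rel[name] = r
        mape[name] = float(np.mean(np.abs(r[nonzero])) * 100.0) if nonzero.any() else float("nan")
        mean_truth[name] = float(np.mean(y))
    return MetricReport(n=truth.shape[0], mse=mse, rmse=rmse, mae=mae, mape=mape,
                        relative_errors=rel, mean_truth=mean_truth)


def relative_error_histogram(report: MetricReport, bins: int = 20):
    """Histogram data (edges, counts) of signed relative errors per metric."""
    out = {}
    for name, r in report.relative_errors.items():
        r = r[np.isfinite(r)]
        counts, edges = np.histogram(r, bins=bins)
        out[name] = {"edges": edges.tolist(), "counts": counts.tolist()}
    return out
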