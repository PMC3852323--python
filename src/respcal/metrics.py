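"""Agreement statistics between predicted and reference airflow.

Covers the coefficient of determination R^2 (which may be negative when a
model transfers badly across breathing styles), RMSE, relative RMSE as a
percentage of the reference RMS, the signed relative error of integrated
respiratory volume, and Bland-Altman agreement data (reference value vs
prediction error, with bias and 1.96*SD limits of agreement).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .calibration import PredictionResult
from .errors import UndefinedMetricError


def _pair(y, y_hat) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.ndim != 1:
        raise ValueError("y and y_hat must be 1-D with equal length")
    return y, y_hat


def r_squared(y: Sequence[float], y_hat: Sequence[float], about_mean: bool = True) -> float:
    """Coefficient of determination ``1 - SS_res / SS_tot``.

    ``SS_tot`` is taken about the reference mean by default (``about_mean=False``
    uses raw sums of squares; for near-zero-mean airflow the two nearly
    coincide).  Values below zero indicate predictions worse than the mean.
    """
    y, y_hat = _pair(y, y_hat)
    if y.size < 2:
        raise ValueError("need at least two samples")
    center = y.mean() if about_mean else 0.0
    ss_tot = float(np.sum((y - center) ** 2))
    if ss_tot == 0.0:
        raise UndefinedMetricError("reference signal is constant; R^2 undefined")
    ss_res = float(np.sum((y - y_hat) ** 2))
    return 1.0 - ss_res / ss_tot


def rmse(y: Sequence[float], y_hat: Sequence[float]) -> float:
    """Root-mean-square error in the units of the flow signal."""
    y, y_hat = _pair(y, y_hat)
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def relative_rmse(y: Sequence[float], y_hat: Sequence[float]) -> float:
    """RMSE as a percentage of the reference RMS (raw samples, not centered)."""
    y, y_hat = _pair(y, y_hat)
    rms = float(np.sqrt(np.mean(y**2)))
    if rms == 0.0:
        raise UndefinedMetricError("reference RMS is zero; relative RMSE undefined")
    return 100.0 * rmse(y, y_hat) / rms


def integrated_volume(flow: Sequence[float], fs: float) -> float:
    """Total moved air volume ``(1/2) * integral |flow| dt`` by trapezoid.

    Halving avoids double-counting: over closed breaths the inspired and
    expired volumes are equal, so half the rectified integral is the volume
    that passed in each direction.
    """
    flow = np.asarray(flow, dtype=float)
    if flow.size == 0:
        raise ValueError("empty flow signal")
    return 0.5 * float(np.trapezoid(np.abs(flow), dx=1.0 / fs))


def relative_volume_error(
    y_flow: Sequence[float], y_hat_flow: Sequence[float], fs: float
) -> float:
    """Signed relative error [%] of integrated volume; over-prediction positive."""
    v_ref = integrated_volume(y_flow, fs)
    if v_ref == 0.0:
        raise UndefinedMetricError("reference volume is zero")
    v_hat = integrated_volume(y_hat_flow, fs)
    return 100.0 * (v_hat - v_ref) / v_ref


@dataclasses.dataclass
class BlandAltmanData:
    """Sample-wise agreement data: reference on x, error (ref - pred) on y."""

    reference_values: np.ndarray
    errors: np.ndarray
    bias: float
    loa_low: float
    loa_high: float


def bland_altman(y: Sequence[float], y_hat: Sequence[float]) -> BlandAltmanData:
    """Bland-Altman pairs with bias and 1.96*SD limits of agreement."""
    y, y_hat = _pair(y, y_hat)
    if y.size < 3:
        raise ValueError("need at least three samples")
    err = y - y_hat
    bias = float(err.mean())
    sd = float(err.std(ddof=1))
    return BlandAltmanData(
        reference_values=y.copy(),
        errors=err,
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
    )


@dataclasses.dataclass
class MetricsReport:
    """Bundle of the waveform-agreement statistics for one evaluation."""

    r_squared: float
    rmse: float
    relative_rmse_pct: float
    relative_volume_error_pct: float
    n_samples: int

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def compute_report(
    pred: PredictionResult, ss_tot_about_mean: bool = True
) -> MetricsReport:
    """All waveform metrics for a prediction evaluated against its reference."""
    if pred.y_ref is None:
        raise ValueError("prediction carries no reference signal")
    y = pred.y_ref.samples
    y_hat = pred.y_hat.samples
    return MetricsReport(
        r_squared=r_squared(y, y_hat, about_mean=ss_tot_about_mean),
        rmse=rmse(y, y_hat),
        relative_rmse_pct=relative_rmse(y, y_hat),
        relative_volume_error_pct=relative_volume_error(y, y_hat, pred.y_ref.fs),
        n_samples=int(y.size),
    )
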