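"""Comparison calibration methods.

Two baselines accompany the FIR filter-bank calibration:

* the *standard method*: multiple linear regression of airflow on one sample
  of each belt signal, ``y = b1*x1 + b2*x2``, the classical two-degrees-of-
  freedom belt calibration;
* the five-feature minute-ventilation regression of Liu and colleagues,
  which predicts minute ventilation (not the waveform) from the 10th/90th
  percentiles of the two belt signals over a segment plus the breathing
  frequency.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .calibration import (
    CalibrationModel,
    PredictionResult,
    fit_least_squares,
    predict as _predict_model,
)
from .errors import NoBreathError
from .signal_io import PairedRecording, UniformSignal

LIU_FEATURE_NAMES = (
    "abdomen_p10",
    "abdomen_p90",
    "ribcage_p10",
    "ribcage_p90",
    "breathing_frequency_hz",
)


def fit_standard(rec: PairedRecording, center: bool = True) -> CalibrationModel:
    """Fit the standard two-coefficient regression calibration.

    Returns a degenerate FIR model (N = 1, D = 0) so that prediction and
    evaluation share one code path with the proposed method.
    """
    x1 = rec.ribcage.samples.astype(float)
    x2 = rec.abdomen.samples.astype(float)
    y = rec.spirometer.samples.astype(float)
    X = np.column_stack([x1, x2])
    col_mu = X.mean(axis=0) if center else np.zeros(2)
    y_mu = float(y.mean()) if center else 0.0
    beta = fit_least_squares(X - col_mu, y - y_mu)
    r = (y - y_mu) - (X - col_mu) @ beta
    return CalibrationModel(
        beta1=beta[:1],
        beta2=beta[1:2],
        N=1,
        D=0,
        fs=rec.fs,
        col_means=col_mu,
        y_mean=y_mu,
        training_residual_rms=float(np.sqrt(np.mean(r**2))),
    )


def predict_standard(
    model: CalibrationModel, rec: PairedRecording
) -> PredictionResult:
    """Elementwise prediction ``b1*x1 + b2*x2`` against the spirometer."""
    return _predict_model(model, rec.ribcage, rec.abdomen, y_ref=rec.spirometer)


# ---------------------------------------------------------------------------
# Liu et al. five-feature minute-ventilation model
# ---------------------------------------------------------------------------


def breathing_frequency(
    ribcage: Sequence[float],
    abdomen: Sequence[float],
    fs: float,
    band: tuple[float, float] = (0.05, 1.0),
    method: str = "welch",
) -> float:
    """Dominant breathing rate [Hz] of the mean-removed belt-sum signal.

    ``method="welch"`` picks the peak of a Welch periodogram inside ``band``;
    ``method="zero_crossings"`` counts rising zero crossings instead.
    """
    s = np.asarray(ribcage, dtype=float) + np.asarray(abdomen, dtype=float)
    s = s - s.mean()
    if not np.any(np.abs(s) > 0):
        raise NoBreathError("belt-sum signal is constant; no breathing detected")
    if method == "welch":
        nperseg = min(s.size, max(256, int(round(fs / band[0] * 2))))
        f, pxx = sps.welch(s, fs=fs, nperseg=nperseg)
        mask = (f >= band[0]) & (f <= band[1])
        if not mask.any() or not np.any(pxx[mask] > 0):
            raise NoBreathError("no spectral energy in the breathing band")
        return float(f[mask][np.argmax(pxx[mask])])
    if method == "zero_crossings":
        rising = np.flatnonzero((s[:-1] < 0) & (s[1:] >= 0))
        if rising.size < 2:
            raise NoBreathError("fewer than two breaths detected")
        return float((rising.size - 1) / ((rising[-1] - rising[0]) / fs))
    raise ValueError(f"unknown method {method!r}")


def extract_liu_features(
    rec: PairedRecording,
    segment_s: float = 60.0,
    min_segment_s: float = 10.0,
    frequency_method: str = "welch",
) -> np.ndarray:
    """Feature vector [P10(ab), P90(ab), P10(rc), P90(rc), f_breath].

    Percentiles use linear interpolation between order statistics.  The
    first ``segment_s`` seconds of the recording are used.
    """
    n = int(round(segment_s * rec.fs))
    if n < int(round(min_segment_s * rec.fs)):
        raise ValueError(f"segment shorter than the {min_segment_s} s minimum")
    ab = rec.abdomen.samples[:n]
    rc = rec.ribcage.samples[:n]
    if ab.size < n:
        raise ValueError("recording shorter than the requested segment")
    fb = breathing_frequency(rc, ab, rec.fs, method=frequency_method)
    return np.array(
        [
            np.percentile(ab, 10),
            np.percentile(ab, 90),
            np.percentile(rc, 10),
            np.percentile(rc, 90),
            fb,
        ]
    )


@dataclasses.dataclass
class LiuModel:
    """Least-squares regression of minute ventilation on the 5 Liu features."""

    coefficients: np.ndarray  # length 5
    intercept: float
    feature_names: tuple[str, ...] = LIU_FEATURE_NAMES

    def predict(self, features: Sequence[float]) -> float:
        f = np.asarray(features, dtype=float)
        return float(f @ self.coefficients + self.intercept)

    def to_dict(self) -> dict:
        return {
            "model": "liu_minute_ventilation",
            "coefficients": self.coefficients.tolist(),
            "intercept": self.intercept,
            "feature_names": list(self.feature_names),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "LiuModel":
        return cls(
            coefficients=np.asarray(d["coefficients"], dtype=float),
            intercept=float(d["intercept"]),
            feature_names=tuple(d.get("feature_names", LIU_FEATURE_NAMES)),
        )


def fit_liu(
    segments: Sequence[tuple[Sequence[float], float]],
    weights: Sequence[float] | None = None,
) -> LiuModel:
    """Fit the Liu model from (feature-vector, measured MV [l/min]) pairs.

    Needs at least 6 segments (five slopes plus the intercept).  Optional
    per-segment weights perform weighted least squares.
    """
    if len(segments) < 6:
        raise ValueError(f"need >= 6 training segments, got {len(segments)}")
    F = np.array([np.asarray(f, dtype=float) for f, _ in segments])
    mv = np.array([float(v) for _, v in segments])
    if F.shape[1] != 5:
        raise ValueError("feature vectors must have length 5")
    A = np.column_stack([F, np.ones(len(mv))])
    if weights is not None:
        w = np.sqrt(np.asarray(weights, dtype=float))
        A = A * w[:, None]
        mv = mv * w
    beta = fit_least_squares(A, mv)
    return LiuModel(coefficients=beta[:5], intercept=float(beta[5]))


@dataclasses.dataclass
class VentilationEstimate:
    """Minute ventilation [l/min] measured or predicted over one segment."""

    minute_ventilation: float
    segment_length_s: float


def minute_ventilation_from_flow(
    flow: UniformSignal, segment_s: float | None = None
) -> VentilationEstimate:
    """Minute ventilation from an airflow signal in l/s.

    ``MV = (1/2) * integral |flow| dt`` scaled to one minute; the halving
    keeps inspired and expired volume from being double-counted.
    """
    samples = flow.samples
    if segment_s is not None:
        samples = samples[: int(round(segment_s * flow.fs))]
    if samples.size == 0:
        raise ValueError("empty flow signal")
    seg_len = samples.size / flow.fs
    vol = 0.5 * float(np.trapezoid(np.abs(samples), dx=1.0 / flow.fs))
    return VentilationEstimate(
        minute_ventilation=vol * 60.0 / seg_len, segment_length_s=seg_len
    )
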