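"""MISO FIR calibration of effort belts against spirometer airflow.

The calibration model predicts airflow from windows of N consecutive samples
of each belt signal,

    y[i + D] = beta1 . x1[i : i+N] + beta2 . x2[i : i+N] + eps,

i.e. a two-input FIR filter bank followed by an integer delay D that absorbs
device and anatomical latency.  The taps are estimated by ordinary least
squares on the lagged design matrix; the delay by a grid search that refits
the regression at every candidate shift and keeps the one with minimal
residual RMS.  With N = 1 and D = 0 the model degenerates to the classical
two-coefficient multiple linear regression calibration.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import linalg as sla

from .errors import InsufficientDataError, SamplingRateError
from .signal_io import PairedRecording, UniformSignal

MODEL_SCHEMA_VERSION = 1


class RankDeficiencyWarning(UserWarning):
    """Design matrix was rank deficient; a minimum-norm solution was returned."""


@dataclasses.dataclass(frozen=True)
class ExtraTerms:
    """Optional nonlinear design-matrix columns.

    ``intercept`` appends an all-ones column; ``squares`` the squared belt
    samples and ``cross`` their product, both evaluated at the first sample
    of each lag window.  All off by default: for inductive/piezo belts the
    linear filter bank suffices.
    """

    intercept: bool = False
    squares: bool = False
    cross: bool = False

    @property
    def n_columns(self) -> int:
        return int(self.intercept) + 2 * int(self.squares) + int(self.cross)

    def describe(self) -> list[str]:
        names = []
        if self.intercept:
            names.append("intercept")
        if self.squares:
            names += ["x1_sq", "x2_sq"]
        if self.cross:
            names.append("x1_x2")
        return names

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict | None) -> "ExtraTerms":
        return cls(**d) if d else cls()


NO_EXTRAS = ExtraTerms()


@dataclasses.dataclass
class DesignMatrix:
    """Lagged observation matrix.

    Row i is ``[x1[i..i+N-1], x2[i..i+N-1]]`` plus any extra columns, so a
    pair of signals of length L yields ``n = L - N + 1`` rows.
    """

    X: np.ndarray
    n: int
    N: int
    extra: ExtraTerms = NO_EXTRAS

    @property
    def extra_terms(self) -> list[str]:
        return self.extra.describe()


def window_to_taps(window_s: float, fs: float) -> int:
    """Number of FIR taps for a time window: ``N = floor(window_s * fs) + 1``.

    The inclusive-endpoint convention reproduces the reference pairs
    0.3 s -> 16 taps and 0.15 s -> 8 taps at 50 Hz.
    """
    if not window_s > 0 or not fs > 0:
        raise ValueError("window_s and fs must be positive")
    return int(np.floor(window_s * fs)) + 1


def build_design_matrix(
    x1: Sequence[float],
    x2: Sequence[float],
    N: int,
    extra: ExtraTerms = NO_EXTRAS,
) -> DesignMatrix:
    """Build the lagged design matrix from the two belt signals."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape or x1.ndim != 1:
        raise ValueError("x1 and x2 must be 1-D and equally long")
    if N < 1:
        raise ValueError("N must be >= 1")
    if x1.size < N:
        raise InsufficientDataError(f"need at least N={N} samples, got {x1.size}")
    w1 = sliding_window_view(x1, N)
    w2 = sliding_window_view(x2, N)
    cols = [w1, w2]
    n = w1.shape[0]
    if extra.intercept:
        cols.append(np.ones((n, 1)))
    if extra.squares:
        cols.append(x1[:n, None] ** 2)
        cols.append(x2[:n, None] ** 2)
    if extra.cross:
        cols.append((x1[:n] * x2[:n])[:, None])
    X = np.ascontiguousarray(np.hstack(cols))
    return DesignMatrix(X=X, n=n, N=N, extra=extra)


def fit_least_squares(X: DesignMatrix | np.ndarray, y: Sequence[float]) -> np.ndarray:
    """Least-squares tap estimate, solved by SVD (never an explicit inverse).

    Returns the coefficient vector minimising ``||y - X beta||``; for rank-
    deficient X the minimum-norm solution is returned and a
    :class:`RankDeficiencyWarning` is emitted.
    """
    A = X.X if isinstance(X, DesignMatrix) else np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size != A.shape[0]:
        raise ValueError(f"y has length {y.size}, expected {A.shape[0]}")
    beta, _, rank, _ = sla.lstsq(A, y, lapack_driver="gelsd")
    if rank < A.shape[1]:
        warnings.warn(
            f"design matrix rank {rank} < {A.shape[1]} columns; "
            "returning minimum-norm solution",
            RankDeficiencyWarning,
            stacklevel=2,
        )
    return beta


@dataclasses.dataclass
class CalibrationModel:
    """Fitted MISO FIR calibration: taps, delay, and training means."""

    beta1: np.ndarray
    beta2: np.ndarray
    N: int
    D: int
    fs: float
    beta_extra: np.ndarray = dataclasses.field(default_factory=lambda: np.zeros(0))
    extra: ExtraTerms = NO_EXTRAS
    col_means: np.ndarray | None = None
    y_mean: float = 0.0
    center_per_segment: bool = False
    training_residual_rms: float = float("nan")

    def __post_init__(self) -> None:
        self.beta1 = np.asarray(self.beta1, dtype=float)
        self.beta2 = np.asarray(self.beta2, dtype=float)
        self.beta_extra = np.asarray(self.beta_extra, dtype=float)
        if self.beta1.size != self.N or self.beta2.size != self.N:
            raise ValueError("tap vectors must both have length N")
        if self.col_means is None:
            self.col_means = np.zeros(self.beta.size)
        else:
            self.col_means = np.asarray(self.col_means, dtype=float)
        if self.col_means.size != self.beta.size:
            raise ValueError("col_means must match the coefficient vector length")
        if not self.fs > 0:
            raise SamplingRateError(f"fs must be positive, got {self.fs}")

    @property
    def beta(self) -> np.ndarray:
        """Concatenated coefficient vector ``[beta1; beta2; beta_extra]``."""
        return np.concatenate([self.beta1, self.beta2, self.beta_extra])

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema_version": MODEL_SCHEMA_VERSION,
            "model": "fir_miso",
            "N": self.N,
            "D": self.D,
            "fs": self.fs,
            "beta1": self.beta1.tolist(),
            "beta2": self.beta2.tolist(),
            "beta_extra": self.beta_extra.tolist(),
            "extra": self.extra.to_dict(),
            "col_means": self.col_means.tolist(),
            "y_mean": self.y_mean,
            "center_per_segment": self.center_per_segment,
            "training_residual_rms": self.training_residual_rms,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        if d.get("schema_version", 1) != MODEL_SCHEMA_VERSION:
            raise ValueError(f"unsupported model schema {d.get('schema_version')}")
        return cls(
            beta1=np.asarray(d["beta1"]),
            beta2=np.asarray(d["beta2"]),
            N=int(d["N"]),
            D=int(d["D"]),
            fs=float(d["fs"]),
            beta_extra=np.asarray(d.get("beta_extra", [])),
            extra=ExtraTerms.from_dict(d.get("extra")),
            col_means=np.asarray(d["col_means"]) if "col_means" in d else None,
            y_mean=float(d.get("y_mean", 0.0)),
            center_per_segment=bool(d.get("center_per_segment", False)),
            training_residual_rms=float(d.get("training_residual_rms", float("nan"))),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "CalibrationModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclasses.dataclass
class PredictionResult:
    """Predicted airflow with, when a reference is given, the aligned
    spirometer segment and the residual (reference minus prediction)."""

    y_hat: UniformSignal
    y_ref: UniformSignal | None = None
    residual: np.ndarray | None = None


def _valid_rows(n_rows: int, d: int, len_y: int) -> tuple[int, int]:
    """Inclusive row range [lo, hi] with both the window and target in bounds."""
    lo = max(0, -d)
    hi = min(n_rows - 1, len_y - 1 - d)
    if hi < lo:
        raise InsufficientDataError("no overlap between windows and shifted target")
    return lo, hi


def estimate_delay(
    x1: Sequence[float],
    x2: Sequence[float],
    y: Sequence[float],
    N: int,
    search: int,
    extra: ExtraTerms = NO_EXTRAS,
    center: bool = True,
    full_output: bool = False,
):
    """Grid-search the integer device delay D in samples.

    For every candidate shift ``d`` in ``[-search, +search]`` the spirometer
    signal is slid against the belt windows, the least-squares problem is
    re-solved, and the residual RMS recorded; the returned D minimises it.
    Numerical ties are broken toward the smallest ``|d|``, then toward
    negative d.  All candidates are scored on the same fixed set of rows so
    the residuals are comparable.
    """
    if search < 0:
        raise ValueError("search must be >= 0")
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    y = np.asarray(y, dtype=float)
    if center:
        x1 = x1 - x1.mean()
        x2 = x2 - x2.mean()
        y = y - y.mean()
    dm = build_design_matrix(x1, x2, N, extra)
    lo = search
    hi = min(dm.n - 1, y.size - 1 - search)
    n_rows = hi - lo + 1
    if n_rows < 10 * (2 * N + extra.n_columns):
        raise InsufficientDataError(
            f"delay search needs >= {10 * (2 * N + extra.n_columns)} shared rows, "
            f"got {n_rows}"
        )
    Xs = dm.X[lo : hi + 1]
    candidates = np.arange(-search, search + 1)
    scores = np.empty(candidates.size)
    G = Xs.T @ Xs
    try:
        cho = sla.cho_factor(G)

        def solve(c: np.ndarray) -> np.ndarray:
            return sla.cho_solve(cho, c)

        fast = True
    except sla.LinAlgError:
        fast = False
    for k, d in enumerate(candidates):
        yd = y[lo + d : hi + d + 1]
        if fast:
            c = Xs.T @ yd
            beta = solve(c)
            rss = max(float(yd @ yd - c @ beta), 0.0)
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RankDeficiencyWarning)
                beta = fit_least_squares(Xs, yd)
            r = yd - Xs @ beta
            rss = float(r @ r)
        scores[k] = np.sqrt(rss / n_rows)
    tie_tol = 1e-8 * max(np.sqrt(float(y @ y) / y.size), np.finfo(float).tiny)
    best = scores.min()
    tied = candidates[scores <= best + tie_tol]
    D = int(min(tied, key=lambda d: (abs(d), d)))
    if full_output:
        return D, dict(zip((int(d) for d in candidates), scores.tolist()))
    return D


def _fit_at_delay(
    x1: np.ndarray,
    x2: np.ndarray,
    y: np.ndarray,
    N: int,
    D: int,
    extra: ExtraTerms,
    center: bool = True,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Refit taps on all rows valid at delay D.

    With ``center`` the design-matrix columns and the target are centered by
    their means over the training rows (an intercept column is left raw, and
    is then exactly inert).  Returns (beta, column means, target mean,
    residual RMS).
    """
    dm = build_design_matrix(x1, x2, N, extra)
    lo, hi = _valid_rows(dm.n, D, y.size)
    Xv = dm.X[lo : hi + 1]
    yv = y[lo + D : hi + D + 1]
    if center:
        col_mu = Xv.mean(axis=0)
        if extra.intercept:
            col_mu[2 * N] = 0.0  # leave the intercept column as ones
        y_mu = float(yv.mean())
    else:
        col_mu = np.zeros(Xv.shape[1])
        y_mu = 0.0
    beta = fit_least_squares(Xv - col_mu, yv - y_mu)
    r = (yv - y_mu) - (Xv - col_mu) @ beta
    return beta, col_mu, y_mu, float(np.sqrt(r @ r / r.size))


def fit_proposed(
    rec: PairedRecording,
    window_s: float = 0.3,
    delay_search_s: float = 1.0,
    extra: ExtraTerms = NO_EXTRAS,
    center: bool = True,
    N: int | None = None,
) -> CalibrationModel:
    """Fit the full proposed calibration: taps + delay on one recording.

    ``window_s`` sets the FIR length via :func:`window_to_taps` (override with
    ``N``); ``delay_search_s`` bounds the delay grid (0 disables the search).
    With ``center`` the training means of all three channels are removed
    before regression and stored on the model.
    """
    fs = rec.fs
    if N is None:
        N = window_to_taps(window_s, fs)
    x1 = rec.ribcage.samples.astype(float)
    x2 = rec.abdomen.samples.astype(float)
    y = rec.spirometer.samples.astype(float)
    search = int(round(delay_search_s * fs))
    if search > 0:
        D = estimate_delay(x1, x2, y, N, search, extra, center=center)
    else:
        D = 0
    beta, col_mu, y_mu, rms = _fit_at_delay(x1, x2, y, N, D, extra, center=center)
    return CalibrationModel(
        beta1=beta[:N],
        beta2=beta[N : 2 * N],
        beta_extra=beta[2 * N :],
        N=N,
        D=D,
        fs=fs,
        extra=extra,
        col_means=col_mu,
        y_mean=y_mu,
        training_residual_rms=rms,
    )


def predict(
    model: CalibrationModel,
    x1: Sequence[float] | UniformSignal,
    x2: Sequence[float] | UniformSignal,
    y_ref: Sequence[float] | UniformSignal | None = None,
    fs: float | None = None,
    units: str = "l/s",
) -> PredictionResult:
    """Predict airflow from belt signals with a fitted model.

    When a reference spirometer signal is supplied, the prediction and the
    reference are aligned using the model delay D and the elementwise
    residual (reference - prediction) is returned alongside.
    """
    if isinstance(x1, UniformSignal):
        fs = x1.fs if fs is None else fs
        x1 = x1.samples
    if isinstance(x2, UniformSignal):
        fs = x2.fs if fs is None else fs
        x2 = x2.samples
    if isinstance(y_ref, UniformSignal):
        units = y_ref.units
        y_ref = y_ref.samples
    if fs is not None and abs(fs - model.fs) > 1e-9 * model.fs:
        raise SamplingRateError(f"model fitted at {model.fs} Hz, signals at {fs} Hz")
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    dm = build_design_matrix(x1, x2, model.N, model.extra)
    if model.center_per_segment:
        col_mu = dm.X.mean(axis=0)
        if model.extra.intercept:
            col_mu[2 * model.N] = 0.0
        y_mu = float(np.mean(y_ref)) if y_ref is not None else 0.0
    else:
        col_mu, y_mu = model.col_means, model.y_mean
    y_hat_all = (dm.X - col_mu) @ model.beta + y_mu
    if y_ref is None:
        sig = UniformSignal(y_hat_all, fs=model.fs, units=units)
        return PredictionResult(y_hat=sig)
    y_ref = np.asarray(y_ref, dtype=float)
    lo, hi = _valid_rows(dm.n, model.D, y_ref.size)
    y_hat = y_hat_all[lo : hi + 1]
    ref = y_ref[lo + model.D : hi + model.D + 1]
    return PredictionResult(
        y_hat=UniformSignal(y_hat, fs=model.fs, units=units),
        y_ref=UniformSignal(ref, fs=model.fs, units=units),
        residual=ref - y_hat,
    )


def evaluate(model: CalibrationModel, rec: PairedRecording) -> PredictionResult:
    """Predict on a recording's belts against its own spirometer channel."""
    return predict(model, rec.ribcage, rec.abdomen, y_ref=rec.spirometer)
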