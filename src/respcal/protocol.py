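"""Experiment orchestration: cross-step testing and leave-one-subject-out.

Mirrors the measurement-protocol designs: train a calibration on one
protocol step and test it on another (within subject), or pool all but one
subject's data for a subject-independent model and test on the held-out
subject.  Emits tidy result tables with the conventional ``mean +/- SD``
aggregation.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import metrics as met
from .calibration import (
    CalibrationModel,
    build_design_matrix,
    estimate_delay,
    evaluate,
    fit_least_squares,
    fit_proposed,
    window_to_taps,
)
from .errors import InsufficientDataError
from .reference_methods import (
    extract_liu_features,
    fit_liu,
    fit_standard,
    minute_ventilation_from_flow,
)
from .signal_io import PairedRecording

#: canonical method identifiers
METHOD_STANDARD = "standard"
METHOD_PROPOSED_N8 = "proposed_N8"
METHOD_PROPOSED_N16 = "proposed_N16"
METHOD_LIU = "liu"

#: FIR window (seconds) behind each proposed-method variant
_PROPOSED_WINDOWS = {METHOD_PROPOSED_N8: 0.15, METHOD_PROPOSED_N16: 0.3}

WAVEFORM_METHODS = (METHOD_STANDARD, METHOD_PROPOSED_N8, METHOD_PROPOSED_N16)

METRIC_FIELDS = ("r_squared", "rmse", "relative_rmse_pct", "relative_volume_error_pct")


@dataclasses.dataclass
class CrossTestResult:
    """Metrics of one (train step, test step, method, subject) evaluation."""

    train_step: str
    test_step: str
    method: str
    metrics: met.MetricsReport
    subject_id: str = ""

    def as_row(self) -> dict:
        row = {
            "subject_id": self.subject_id,
            "train_step": self.train_step,
            "test_step": self.test_step,
            "method": self.method,
        }
        row.update(self.metrics.as_dict())
        return row


def fit_method(
    method: str, rec: PairedRecording, delay_search_s: float = 1.0
) -> CalibrationModel:
    """Fit one named waveform method on a single recording."""
    if method == METHOD_STANDARD:
        return fit_standard(rec)
    if method in _PROPOSED_WINDOWS:
        return fit_proposed(
            rec, window_s=_PROPOSED_WINDOWS[method], delay_search_s=delay_search_s
        )
    if method == METHOD_LIU:
        raise ValueError(
            "the Liu minute-ventilation model needs multiple training segments; "
            "use compare_minute_ventilation"
        )
    raise ValueError(f"unknown method {method!r}")


def cross_test(
    recordings: Mapping[str, PairedRecording],
    methods: Sequence[str] = WAVEFORM_METHODS,
    pairs: Iterable[tuple[str, str]] | None = None,
    delay_search_s: float = 1.0,
    subject_id: str = "",
) -> list[CrossTestResult]:
    """Train on one step, test on another, for every requested pair/method.

    ``pairs`` defaults to all ordered pairs of distinct steps.  Metrics are
    always computed on the test step only.
    """
    if pairs is None:
        ids = list(recordings)
        pairs = [(a, b) for a in ids for b in ids if a != b]
    pairs = list(pairs)
    for a, b in pairs:
        if a not in recordings or b not in recordings:
            raise ValueError(f"unknown step id in pair ({a!r}, {b!r})")
    results: list[CrossTestResult] = []
    for method in methods:
        fitted = {
            train: fit_method(method, recordings[train], delay_search_s)
            for train in {a for a, _ in pairs}
        }
        for train, test in pairs:
            pred = evaluate(fitted[train], recordings[test])
            results.append(
                CrossTestResult(
                    train_step=train,
                    test_step=test,
                    method=method,
                    metrics=met.compute_report(pred),
                    subject_id=subject_id,
                )
            )
    return results


def _mode_delay(delays: Sequence[int]) -> int:
    counts = Counter(delays)
    return min(counts, key=lambda d: (-counts[d], abs(d), d))


def fit_pooled(
    recs: Sequence[PairedRecording],
    method: str,
    delay_search_s: float = 1.0,
) -> CalibrationModel:
    """Subject-independent fit on several recordings.

    Each recording is mean-centered on its own (removing inter-subject
    baseline offsets), a single delay is chosen as the mode of the
    per-recording optima, and one regression is solved on the concatenated
    design-matrix rows.  The returned model re-centers at prediction time.
    """
    if len(recs) < 1:
        raise ValueError("need at least one training recording")
    fs = recs[0].fs
    if any(abs(r.fs - fs) > 1e-9 for r in recs):
        raise ValueError("all recordings must share a sampling rate")
    if method == METHOD_STANDARD:
        N, search = 1, 0
    elif method in _PROPOSED_WINDOWS:
        N = window_to_taps(_PROPOSED_WINDOWS[method], fs)
        search = int(round(delay_search_s * fs))
    else:
        raise ValueError(f"unknown method {method!r}")

    signals = [
        (r.ribcage.samples, r.abdomen.samples, r.spirometer.samples) for r in recs
    ]
    if search > 0:
        delays = [
            estimate_delay(x1, x2, y, N, search, center=True)
            for x1, x2, y in signals
        ]
        D = _mode_delay(delays)
    else:
        D = 0

    # per-recording centering removes inter-subject baseline offsets
    X_blocks, y_blocks = [], []
    for x1, x2, y in signals:
        dm = build_design_matrix(x1, x2, N)
        lo = max(0, -D)
        hi = min(dm.n - 1, y.size - 1 - D)
        if hi < lo:
            raise InsufficientDataError("recording too short at pooled delay")
        Xv = dm.X[lo : hi + 1]
        yv = y[lo + D : hi + D + 1]
        X_blocks.append(Xv - Xv.mean(axis=0))
        y_blocks.append(yv - yv.mean())
    X = np.vstack(X_blocks)
    yy = np.concatenate(y_blocks)
    beta = fit_least_squares(X, yy)
    r = yy - X @ beta
    return CalibrationModel(
        beta1=beta[:N],
        beta2=beta[N : 2 * N],
        N=N,
        D=D,
        fs=fs,
        center_per_segment=True,
        training_residual_rms=float(np.sqrt(np.mean(r**2))),
    )


def leave_one_subject_out(
    cohort: Mapping[str, Mapping[str, PairedRecording]],
    train_step: str,
    test_step: str,
    methods: Sequence[str] = WAVEFORM_METHODS,
    delay_search_s: float = 1.0,
) -> list[CrossTestResult]:
    """Hold out each subject; train pooled on the rest; test on the holdout."""
    subjects = list(cohort)
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    results: list[CrossTestResult] = []
    for held_out in subjects:
        train_recs = [
            cohort[s][train_step] for s in subjects if s != held_out
        ]
        for method in methods:
            model = fit_pooled(train_recs, method, delay_search_s)
            pred = evaluate(model, cohort[held_out][test_step])
            results.append(
                CrossTestResult(
                    train_step=train_step,
                    test_step=test_step,
                    method=method,
                    metrics=met.compute_report(pred),
                    subject_id=str(held_out),
                )
            )
    return results


def results_frame(results: Sequence[CrossTestResult]) -> pd.DataFrame:
    cols = ["subject_id", "train_step", "test_step", "method", *METRIC_FIELDS, "n_samples"]
    if not results:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([r.as_row() for r in results])[cols]


def aggregate(
    results: Sequence[CrossTestResult], by: Sequence[str] = ("method",)
) -> pd.DataFrame:
    """Mean and SD of every metric over the stated grouping."""
    df = results_frame(results)
    if df.empty:
        cols = [f"{m}_{s}" for m in METRIC_FIELDS for s in ("mean", "sd")]
        return pd.DataFrame(columns=[*by, *cols])
    out = df.groupby(list(by))[list(METRIC_FIELDS)].agg(["mean", "std"])
    out.columns = [f"{m}_{'sd' if s == 'std' else s}" for m, s in out.columns]
    return out.reset_index()


def report(
    results: Sequence[CrossTestResult],
    by: Sequence[str] = ("method",),
    path: str | Path | None = None,
    decimals: int = 3,
) -> pd.DataFrame:
    """Aggregate table in the ``mean +/- SD`` layout; optionally saved as CSV."""
    agg = aggregate(results, by)
    table = agg[list(by)].copy() if not agg.empty else agg.copy()
    for m in METRIC_FIELDS:
        if agg.empty:
            table[m] = pd.Series(dtype=str)
            continue
        mean = agg[f"{m}_mean"]
        sd = agg[f"{m}_sd"].fillna(0.0)
        table[m] = [
            f"{mu:.{decimals}f} ± {s:.{decimals}f}" for mu, s in zip(mean, sd)
        ]
    if path is not None:
        table.to_csv(path, index=False)
    return table


def export_bland_altman(
    results_pred, path: str | Path
) -> None:
    """Write Bland-Altman pairs (reference, error) of a prediction to CSV."""
    ba = met.bland_altman(results_pred.y_ref.samples, results_pred.y_hat.samples)
    pd.DataFrame(
        {"reference": ba.reference_values, "error": ba.errors}
    ).to_csv(path, index=False)


def compare_minute_ventilation(
    cohort: Mapping[str, Mapping[str, PairedRecording]],
    steps: Sequence[str] = ("step5", "step6", "step7", "step8", "step9", "step10"),
    methods: Sequence[str] = (METHOD_LIU, METHOD_STANDARD, METHOD_PROPOSED_N8),
    delay_search_s: float = 1.0,
) -> pd.DataFrame:
    """Leave-one-subject-out minute-ventilation error comparison.

    For every held-out subject the remaining subjects' segments over
    ``steps`` train each method; minute ventilation is then predicted for
    each of the held-out subject's segments and the signed relative error
    [%] against the spirometer-measured value recorded.  Returns per-method
    Average / SD / Median / MAD of the errors over all subject-step cases.
    """
    subjects = list(cohort)
    if len(subjects) < 2:
        raise ValueError("needs at least 2 subjects")
    errors: dict[str, list[float]] = {m: [] for m in methods}
    feats = {
        s: {
            step: extract_liu_features(cohort[s][step], segment_s=_seg_s(cohort[s][step]))
            for step in steps
        }
        for s in subjects
    }
    mv_meas = {
        s: {
            step: minute_ventilation_from_flow(
                cohort[s][step].spirometer
            ).minute_ventilation
            for step in steps
        }
        for s in subjects
    }
    for held_out in subjects:
        others = [s for s in subjects if s != held_out]
        train_recs = [cohort[s][step] for s in others for step in steps]
        liu_model = None
        if METHOD_LIU in methods:
            liu_model = fit_liu(
                [(feats[s][step], mv_meas[s][step]) for s in others for step in steps]
            )
        fitted = {
            m: fit_pooled(train_recs, m, delay_search_s)
            for m in methods
            if m != METHOD_LIU
        }
        for step in steps:
            rec = cohort[held_out][step]
            measured = mv_meas[held_out][step]
            for m in methods:
                if m == METHOD_LIU:
                    pred_mv = liu_model.predict(feats[held_out][step])
                else:
                    pred = evaluate(fitted[m], rec)
                    pred_mv = minute_ventilation_from_flow(
                        pred.y_hat
                    ).minute_ventilation
                errors[m].append(100.0 * (pred_mv - measured) / measured)
    rows = []
    for m in methods:
        e = np.array(errors[m])
        rows.append(
            {
                "method": m,
                "average": e.mean(),
                "sd": e.std(ddof=1),
                "median": float(np.median(e)),
                "mad": float(np.median(np.abs(e - np.median(e)))),
                "n_cases": e.size,
            }
        )
    return pd.DataFrame(rows)


def _seg_s(rec: PairedRecording) -> float:
    return len(rec.spirometer) / rec.fs
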