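"""Reading, writing, aligning and resampling paired spirometer/belt recordings.

A recording holds three uniformly sampled channels: spirometer airflow (the
calibration reference, typically l/s) and the rib-cage and abdomen effort-belt
signals (arbitrary units).  The CSV dialect is a header row with columns
``time_s`` (optional), ``flow``, ``ribcage``, ``abdomen``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import (
    ChannelMissingError,
    EmptyRecordingError,
    FormatError,
    ResamplingError,
)

SPIROMETER = "spirometer_flow"
BELT_RIBCAGE = "belt_ribcage"
BELT_ABDOMEN = "belt_abdomen"

#: default CSV column -> channel-role mapping
DEFAULT_COLUMNS: Mapping[str, str] = {
    "flow": SPIROMETER,
    "ribcage": BELT_RIBCAGE,
    "abdomen": BELT_ABDOMEN,
}


@dataclasses.dataclass
class UniformSignal:
    """One uniformly sampled channel.

    Parameters
    ----------
    samples
        1-D float array; must contain no NaNs.
    fs
        Sampling rate in Hz, > 0.
    units
        Free-text unit label, e.g. ``"l/s"`` or ``"a.u."``.
    channel_role
        One of :data:`SPIROMETER`, :data:`BELT_RIBCAGE`, :data:`BELT_ABDOMEN`.
    """

    samples: np.ndarray
    fs: float
    units: str = "a.u."
    channel_role: str = SPIROMETER

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise FormatError("signal must be a 1-D array")
        if not self.fs > 0:
            raise FormatError(f"sampling rate must be positive, got {self.fs}")
        if np.isnan(self.samples).any():
            raise FormatError("signal contains missing values")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return len(self) / self.fs


@dataclasses.dataclass
class PairedRecording:
    """Spirometer + two belt channels from one protocol step."""

    spirometer: UniformSignal
    ribcage: UniformSignal
    abdomen: UniformSignal
    subject_id: str = ""
    step_id: str = ""

    @property
    def channels(self) -> tuple[UniformSignal, UniformSignal, UniformSignal]:
        return (self.spirometer, self.ribcage, self.abdomen)

    @property
    def fs(self) -> float:
        return self.spirometer.fs


def _frame_to_recording(
    df: pd.DataFrame,
    fs: float,
    columns: Mapping[str, str],
    subject_id: str,
    step_id: str,
    interpolate_missing: bool,
    flow_units: str,
) -> PairedRecording:
    role_to_col = {role: col for col, role in columns.items()}
    chans: dict[str, UniformSignal] = {}
    for role in (SPIROMETER, BELT_RIBCAGE, BELT_ABDOMEN):
        col = role_to_col.get(role)
        if col is None or col not in df.columns:
            raise ChannelMissingError(f"channel {role!r} (column {col!r}) not found")
        x = df[col].to_numpy(dtype=float)
        if np.isnan(x).any():
            if not interpolate_missing:
                raise FormatError(
                    f"column {col!r} contains missing samples; pass "
                    "interpolate_missing=True to linearly interpolate"
                )
            x = pd.Series(x).interpolate(limit_direction="both").to_numpy()
        units = flow_units if role == SPIROMETER else "a.u."
        chans[role] = UniformSignal(x, fs=fs, units=units, channel_role=role)
    return PairedRecording(
        spirometer=chans[SPIROMETER],
        ribcage=chans[BELT_RIBCAGE],
        abdomen=chans[BELT_ABDOMEN],
        subject_id=subject_id,
        step_id=step_id,
    )


def load_recording(
    path: str | Path,
    format: str = "csv",
    fs: float | None = None,
    columns: Mapping[str, str] | None = None,
    subject_id: str = "",
    step_id: str = "",
    interpolate_missing: bool = False,
    time_tolerance: float = 0.01,
    flow_units: str = "l/s",
) -> PairedRecording:
    """Load a paired spirometer/belt recording from CSV or EDF.

    For CSV, ``fs`` is required unless a ``time_s`` column is present, in
    which case the rate is inferred and validated (relative tolerance
    ``time_tolerance``) against the supplied one.  ``columns`` overrides the
    default column-name -> channel-role mapping.  EDF files are read through
    MNE; ``columns`` then maps EDF channel labels to roles.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    columns = dict(columns or DEFAULT_COLUMNS)
    if format == "csv":
        df = pd.read_csv(path, float_precision="round_trip")
        if len(df) == 0:
            raise FormatError(f"{path} contains no samples")
        if "time_s" in df.columns:
            t = df["time_s"].to_numpy(dtype=float)
            if t.size < 2:
                raise FormatError("time column needs at least two samples")
            dt = np.diff(t)
            if np.any(dt <= 0) or np.ptp(dt) > time_tolerance * np.median(dt):
                raise FormatError("time axis is not uniform within tolerance")
            fs_inferred = 1.0 / float(np.median(dt))
            if fs is not None and abs(fs_inferred - fs) > time_tolerance * fs:
                raise FormatError(
                    f"time column implies fs={fs_inferred:.4g} Hz, expected {fs} Hz"
                )
            fs = fs if fs is not None else fs_inferred
        if fs is None:
            raise FormatError("fs must be given when the CSV has no time_s column")
        return _frame_to_recording(
            df, fs, columns, subject_id, step_id, interpolate_missing, flow_units
        )
    if format == "edf":
        try:
            import mne
        except ImportError as exc:  # pragma: no cover - environment guard
            raise ImportError("EDF support requires the 'mne' package") from exc
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        df = pd.DataFrame({ch: raw.get_data(picks=[ch])[0] for ch in raw.ch_names})
        missing = [c for c in columns if c not in df.columns]
        if missing:
            raise ChannelMissingError(f"EDF labels not found: {missing}")
        return _frame_to_recording(
            df,
            float(raw.info["sfreq"]),
            columns,
            subject_id,
            step_id,
            interpolate_missing,
            flow_units,
        )
    raise ValueError(f"unknown format {format!r}")


def save_recording(
    rec: PairedRecording, path: str | Path, include_time: bool = True
) -> None:
    """Write a recording to the standard CSV layout at full float precision."""
    rec = align_lengths(rec)
    data: dict[str, np.ndarray] = {}
    if include_time:
        data["time_s"] = np.arange(len(rec.spirometer)) / rec.fs
    data["flow"] = rec.spirometer.samples
    data["ribcage"] = rec.ribcage.samples
    data["abdomen"] = rec.abdomen.samples
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def decimate_signal(s: UniformSignal, target_fs: float) -> UniformSignal:
    """Decimate to ``target_fs`` with a zero-phase anti-alias low-pass.

    The decimation factor must be an integer.  The anti-alias filter is a
    windowed-sinc FIR cut off at 0.8x the target Nyquist rate and applied
    forward-backward (zero phase, so the resampling cannot bias later delay
    estimation); its length is chosen so the transition band closes before
    the new Nyquist frequency.
    """
    if not target_fs > 0:
        raise ResamplingError("target_fs must be positive")
    factor = s.fs / target_fs
    q = int(round(factor))
    if abs(factor - q) > 1e-9 or q < 1:
        raise ResamplingError(
            f"decimation from {s.fs} Hz to {target_fs} Hz is not an integer factor"
        )
    if q == 1:
        return dataclasses.replace(s, samples=s.samples.copy())
    numtaps = int(np.ceil(33 * s.fs / target_fs)) | 1
    taps = sps.firwin(numtaps, 0.8 * (target_fs / 2), fs=s.fs)
    padlen = min(3 * numtaps, s.samples.size - 1)
    filtered = sps.filtfilt(taps, [1.0], s.samples, padlen=padlen)
    return UniformSignal(
        filtered[::q], fs=target_fs, units=s.units, channel_role=s.channel_role
    )


def decimate_recording(rec: PairedRecording, target_fs: float) -> PairedRecording:
    """Bring all three channels to a common rate, then align lengths."""
    out = PairedRecording(
        spirometer=decimate_signal(rec.spirometer, target_fs),
        ribcage=decimate_signal(rec.ribcage, target_fs),
        abdomen=decimate_signal(rec.abdomen, target_fs),
        subject_id=rec.subject_id,
        step_id=rec.step_id,
    )
    return align_lengths(out)


def align_lengths(rec: PairedRecording) -> PairedRecording:
    """Truncate all channels to the common minimum length from the start."""
    rates = {c.fs for c in rec.channels}
    if len(rates) != 1:
        raise FormatError(f"channels disagree on sampling rate: {sorted(rates)}")
    n = min(len(c) for c in rec.channels)
    if n == 0:
        raise EmptyRecordingError("no overlapping samples across channels")

    def cut(c: UniformSignal) -> UniformSignal:
        return dataclasses.replace(c, samples=c.samples[:n])

    return PairedRecording(
        spirometer=cut(rec.spirometer),
        ribcage=cut(rec.ribcage),
        abdomen=cut(rec.abdomen),
        subject_id=rec.subject_id,
        step_id=rec.step_id,
    )
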