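"""Synthetic paired spirometer/belt recordings for testing and simulation.

The generator realises the two-compartment picture of tidal breathing: the
lung volume excursion splits into rib-cage and abdominal compartments with
weights summing to one; airflow at the mouth is the time derivative of the
total volume, delayed by an integer device latency; each belt observes its
compartment volume through a short sensor FIR kernel (waveform distortion),
a posture-dependent gain, low-frequency baseline drift and additive noise.
Thoracoabdominal asynchrony is modelled as a time lag of the abdominal
compartment behind the rib cage.

Each breath is a raised-cosine inspiration followed by an exponential-decay
expiration, which gives the asymmetric, harmonic-rich flow shapes a pure
sinusoid would not exercise.  Volume returns exactly to baseline at the end
of every breath, so integrated flow over a breath closes.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .signal_io import (
    BELT_ABDOMEN,
    BELT_RIBCAGE,
    SPIROMETER,
    PairedRecording,
    UniformSignal,
)

#: default minimum-phase sensor kernels (unit sum), one per belt
DEFAULT_KERNEL_RC = (0.55, 0.25, 0.12, 0.06, 0.02)
DEFAULT_KERNEL_AB = (0.45, 0.30, 0.15, 0.07, 0.03)

#: posture-dependent belt gains (g_ribcage, g_abdomen): supine breathing is
#: abdomen-dominant, standing rib-cage-dominant
POSTURE_GAINS = {
    "supine": (0.85, 1.20),
    "sitting": (1.00, 1.00),
    "standing": (1.15, 0.80),
}

DRIFT_FREQ_HZ = 0.01


@dataclasses.dataclass
class SyntheticScenario:
    """Generative parameters for one protocol step.

    ``breathing_schedule`` is a list of ``(start_s, rate, tidal_volume_l)``
    where ``rate`` is a metronome frequency in Hz or ``"free"``; each entry
    governs breathing from its start until the next entry.
    ``posture_gain_schedule`` is a list of ``(start_s, g_ribcage, g_abdomen)``
    piecewise-constant belt gains.
    """

    duration_s: float = 60.0
    fs: float = 50.0
    breathing_schedule: tuple = ((0.0, "free", 0.5),)
    compartment_weights: tuple[float, float] = (0.45, 0.55)
    sensor_kernels: tuple = (DEFAULT_KERNEL_RC, DEFAULT_KERNEL_AB)
    device_delay_samples: int = 5
    taa_lag_samples: int = 0
    posture_gain_schedule: tuple = ((0.0, 1.0, 1.0),)
    noise_sd: float = 0.002
    drift: float = 0.02
    seed: int = 0
    inspiratory_fraction: float = 0.4
    free_rate_hz: float = 0.23
    free_rate_jitter: float = 0.08
    tidal_volume_jitter: float = 0.05

    def __post_init__(self) -> None:
        w = self.compartment_weights
        if abs(w[0] + w[1] - 1.0) > 1e-9:
            raise ValueError("compartment weights must sum to 1")
        if not self.fs > 0 or not self.duration_s > 0:
            raise ValueError("fs and duration_s must be positive")
        for start, _rate, _vt in self.breathing_schedule:
            if not 0.0 <= start < self.duration_s:
                raise ValueError(
                    f"breathing schedule start {start}s outside [0, {self.duration_s})"
                )
        for start, *_ in self.posture_gain_schedule:
            if not 0.0 <= start < self.duration_s:
                raise ValueError(
                    f"posture schedule start {start}s outside [0, {self.duration_s})"
                )


@dataclasses.dataclass
class Breath:
    """One breath: raised-cosine inspiration, exponential expiration."""

    start_s: float
    period_s: float
    tidal_volume_l: float
    inspiratory_fraction: float

    @property
    def t_insp(self) -> float:
        return self.period_s * self.inspiratory_fraction

    @property
    def t_exp(self) -> float:
        return self.period_s - self.t_insp


@dataclasses.dataclass
class SyntheticRecording:
    """A generated recording plus the noiseless ground truth behind it."""

    recording: PairedRecording
    scenario: SyntheticScenario
    breaths: list[Breath]
    volume_ribcage: np.ndarray
    volume_abdomen: np.ndarray
    flow_clean: np.ndarray


def _build_breaths(sc: SyntheticScenario, rng: np.random.Generator) -> list[Breath]:
    schedule = sorted(sc.breathing_schedule, key=lambda e: e[0])
    breaths: list[Breath] = []
    for k, (start, rate, vt) in enumerate(schedule):
        seg_end = schedule[k + 1][0] if k + 1 < len(schedule) else sc.duration_s
        t = start
        while t < seg_end - 1e-12:
            if rate == "free":
                r = sc.free_rate_hz * (1.0 + sc.free_rate_jitter * rng.standard_normal())
                r = float(np.clip(r, 0.08, 0.5))
            else:
                r = float(rate)
            # breathing depth varies breath to breath even under a metronome
            v = vt * (1.0 + sc.tidal_volume_jitter * rng.standard_normal())
            v = max(v, 0.05)
            breaths.append(Breath(t, 1.0 / r, v, sc.inspiratory_fraction))
            t += 1.0 / r
    return breaths


def _volume_flow(times: np.ndarray, breaths: list[Breath]) -> tuple[np.ndarray, np.ndarray]:
    """Analytic compartment volume and its derivative at arbitrary times."""
    v = np.zeros_like(times)
    dv = np.zeros_like(times)
    if not breaths:
        return v, dv
    starts = np.array([b.start_s for b in breaths])
    periods = np.array([b.period_s for b in breaths])
    vts = np.array([b.tidal_volume_l for b in breaths])
    tis = np.array([b.t_insp for b in breaths])
    tes = np.array([b.t_exp for b in breaths])
    idx = np.searchsorted(starts, times, side="right") - 1
    ok = idx >= 0
    idx = np.clip(idx, 0, len(breaths) - 1)
    phase = times - starts[idx]
    in_breath = ok & (phase < periods[idx]) & (phase >= 0)
    i = np.flatnonzero(in_breath)
    ph, vt = phase[i], vts[idx[i]]
    ti, te = tis[idx[i]], tes[idx[i]]
    tau = te / 4.0
    insp = ph < ti
    # inspiration: raised cosine 0 -> VT
    pi_ti = np.pi / ti[insp]
    v[i[insp]] = 0.5 * vt[insp] * (1.0 - np.cos(pi_ti * ph[insp]))
    dv[i[insp]] = 0.5 * vt[insp] * pi_ti * np.sin(pi_ti * ph[insp])
    # expiration: gamma-like decay (1 + u/tau) exp(-u/tau), normalized to end
    # at zero volume; expiratory flow starts at zero, peaks early, then decays
    exp = ~insp
    u = ph[exp] - ti[exp]
    tau_e = tau[exp]
    g_end = (1.0 + te[exp] / tau_e) * np.exp(-te[exp] / tau_e)
    g = (1.0 + u / tau_e) * np.exp(-u / tau_e)
    v[i[exp]] = vt[exp] * (g - g_end) / (1.0 - g_end)
    dv[i[exp]] = -vt[exp] * (u / tau_e**2) * np.exp(-u / tau_e) / (1.0 - g_end)
    return v, dv


def _piecewise_gains(
    times: np.ndarray, schedule: Sequence[tuple]
) -> tuple[np.ndarray, np.ndarray]:
    entries = sorted(schedule, key=lambda e: e[0])
    starts = np.array([e[0] for e in entries])
    g_rc = np.array([e[1] for e in entries])
    g_ab = np.array([e[2] for e in entries])
    idx = np.clip(np.searchsorted(starts, times, side="right") - 1, 0, len(entries) - 1)
    return g_rc[idx], g_ab[idx]


def generate(scenario: SyntheticScenario) -> SyntheticRecording:
    """Generate one paired recording; fully reproducible from the seed."""
    sc = scenario
    streams = np.random.SeedSequence(sc.seed).spawn(3)
    rng_breaths = np.random.default_rng(streams[0])
    rng_noise = np.random.default_rng(streams[1])
    rng_drift = np.random.default_rng(streams[2])

    n = int(round(sc.duration_s * sc.fs))
    t = np.arange(n) / sc.fs
    breaths = _build_breaths(sc, rng_breaths)

    w_rc, w_ab = sc.compartment_weights
    taa_dt = sc.taa_lag_samples / sc.fs
    delay_dt = sc.device_delay_samples / sc.fs

    v_rc = w_rc * _volume_flow(t, breaths)[0]
    v_ab = w_ab * _volume_flow(t - taa_dt, breaths)[0]
    flow_clean = (
        w_rc * _volume_flow(t - delay_dt, breaths)[1]
        + w_ab * _volume_flow(t - delay_dt - taa_dt, breaths)[1]
    )

    h_rc = np.asarray(sc.sensor_kernels[0], dtype=float)
    h_ab = np.asarray(sc.sensor_kernels[1], dtype=float)
    belt_rc = np.convolve(v_rc, h_rc)[:n]
    belt_ab = np.convolve(v_ab, h_ab)[:n]
    g_rc, g_ab = _piecewise_gains(t, sc.posture_gain_schedule)
    belt_rc *= g_rc
    belt_ab *= g_ab
    if sc.drift:
        ph = rng_drift.uniform(0, 2 * np.pi, size=2)
        belt_rc += sc.drift * np.sin(2 * np.pi * DRIFT_FREQ_HZ * t + ph[0])
        belt_ab += sc.drift * np.sin(2 * np.pi * DRIFT_FREQ_HZ * t + ph[1])
    spiro = flow_clean.copy()
    if sc.noise_sd:
        belt_rc = belt_rc + rng_noise.normal(0, sc.noise_sd, n)
        belt_ab = belt_ab + rng_noise.normal(0, sc.noise_sd, n)
        spiro = spiro + rng_noise.normal(0, sc.noise_sd, n)

    rec = PairedRecording(
        spirometer=UniformSignal(spiro, sc.fs, "l/s", SPIROMETER),
        ribcage=UniformSignal(belt_rc, sc.fs, "a.u.", BELT_RIBCAGE),
        abdomen=UniformSignal(belt_ab, sc.fs, "a.u.", BELT_ABDOMEN),
    )
    return SyntheticRecording(
        recording=rec,
        scenario=sc,
        breaths=breaths,
        volume_ribcage=v_rc,
        volume_abdomen=v_ab,
        flow_clean=flow_clean,
    )


def known_fir_recording(
    scenario: SyntheticScenario,
    b1: Sequence[float],
    b2: Sequence[float],
    shift: int = 0,
) -> tuple[PairedRecording, dict]:
    """Recording whose spirometer channel is an exact FIR mixture of its belts.

    The flow channel is constructed as
    ``y[i + shift] = b1 . x1[i : i+L] + b2 . x2[i : i+L]`` (edge samples are
    held), so a MISO FIR fit with ``N >= L`` and delay ``shift`` in range is
    exact by construction.  Used for known-system recovery checks where the
    physiological derivative-of-smoothed-volume map would not be finite FIR.
    """
    b1 = np.asarray(b1, dtype=float)
    b2 = np.asarray(b2, dtype=float)
    if b1.size != b2.size:
        raise ValueError("b1 and b2 must have equal length")
    L = b1.size
    syn = generate(scenario)
    x1 = syn.recording.ribcage.samples
    x2 = syn.recording.abdomen.samples
    n = x1.size
    y0 = sliding_window_view(x1, L) @ b1 + sliding_window_view(x2, L) @ b2
    idx = np.clip(np.arange(n) - shift, 0, n - L)
    y = y0[idx]
    rec = PairedRecording(
        spirometer=UniformSignal(y, scenario.fs, "l/s", SPIROMETER),
        ribcage=syn.recording.ribcage,
        abdomen=syn.recording.abdomen,
    )
    truth = {"b1": b1, "b2": b2, "shift": int(shift), "L": int(L)}
    return rec, truth


# ---------------------------------------------------------------------------
# Measurement-protocol presets
# ---------------------------------------------------------------------------


def _step(
    posture: str | Sequence[tuple],
    rate,
    duration_s: float,
    fs: float,
    seed: int,
    taa_lag_samples: int = 0,
) -> SyntheticScenario:
    if isinstance(posture, str):
        g = POSTURE_GAINS[posture]
        gains = ((0.0, g[0], g[1]),)
    else:
        gains = tuple(
            (start, *POSTURE_GAINS[name]) for start, name in posture
        )
    return SyntheticScenario(
        duration_s=duration_s,
        fs=fs,
        breathing_schedule=((0.0, rate, 0.5),),
        posture_gain_schedule=gains,
        taa_lag_samples=taa_lag_samples,
        seed=seed,
    )


def protocol_presets(
    fs: float = 50.0, duration_s: float = 60.0, seed: int = 0
) -> dict[str, SyntheticScenario]:
    """The twelve measurement-protocol steps plus one asynchrony variant.

    Steps 1-5 and 10 are free breathing in supine/sitting/standing; steps
    6-9 are metronome-controlled sitting breathing at 0.25, 0.15, 0.33 and
    0.10 Hz; steps 11-12 change posture mid-step.  ``step9_taa`` repeats the
    0.10 Hz step with a thoracoabdominal lag of 0.2 s.
    """
    base = int(seed)
    steps = {
        "step1": _step("supine", "free", duration_s, fs, base + 1),
        "step2": _step("supine", "free", duration_s, fs, base + 2),
        "step3": _step("sitting", "free", duration_s, fs, base + 3),
        "step4": _step("standing", "free", duration_s, fs, base + 4),
        "step5": _step("sitting", "free", duration_s, fs, base + 5),
        "step6": _step("sitting", 0.25, duration_s, fs, base + 6),
        "step7": _step("sitting", 0.15, duration_s, fs, base + 7),
        "step8": _step("sitting", 0.33, duration_s, fs, base + 8),
        "step9": _step("sitting", 0.10, duration_s, fs, base + 9),
        "step10": _step("sitting", "free", duration_s, fs, base + 10),
        "step11": _step(
            ((0.0, "sitting"), (duration_s / 2, "standing")),
            "free",
            duration_s,
            fs,
            base + 11,
        ),
        "step12": _step(
            (
                (0.0, "sitting"),
                (duration_s / 3, "standing"),
                (2 * duration_s / 3, "sitting"),
            ),
            "free",
            duration_s,
            fs,
            base + 12,
        ),
        "step9_taa": _step(
            "sitting",
            0.10,
            duration_s,
            fs,
            base + 13,
            taa_lag_samples=int(round(0.2 * fs)),
        ),
    }
    return steps


@dataclasses.dataclass
class CohortVariability:
    """Between-subject spread of the generative parameters."""

    kernel_sd: float = 0.15
    weight_sd: float = 0.05
    gain_sd: float = 0.05
    delay_jitter_samples: int = 3


def generate_cohort(
    n_subjects: int,
    base: dict[str, SyntheticScenario] | None = None,
    variability: CohortVariability | None = None,
    seed: int = 0,
) -> list[dict[str, SyntheticScenario]]:
    """Per-subject preset maps with randomised sensor physics.

    Each subject gets its own sensor kernels, compartment weights, belt
    gains and device delay, drawn around the base presets; everything is
    deterministic given the seed.
    """
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    if base is None:
        base = protocol_presets(seed=seed * 1000)
    var = variability or CohortVariability()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    cohort: list[dict[str, SyntheticScenario]] = []
    for _subj in range(n_subjects):
        ref = next(iter(base.values()))
        kernels = []
        for h in ref.sensor_kernels:
            h = np.asarray(h, dtype=float)
            h2 = np.abs(h * (1.0 + var.kernel_sd * rng.standard_normal(h.size)))
            kernels.append(tuple(h2 / h2.sum()))
        w_rc = float(
            np.clip(
                ref.compartment_weights[0] + var.weight_sd * rng.standard_normal(),
                0.2,
                0.8,
            )
        )
        g_mult = 1.0 + var.gain_sd * rng.standard_normal(2)
        delay = int(
            ref.device_delay_samples
            + rng.integers(-var.delay_jitter_samples, var.delay_jitter_samples + 1)
        )
        subj_map: dict[str, SyntheticScenario] = {}
        for step_id, sc in base.items():
            gains = tuple(
                (start, g_rc * g_mult[0], g_ab * g_mult[1])
                for start, g_rc, g_ab in sc.posture_gain_schedule
            )
            subj_map[step_id] = dataclasses.replace(
                sc,
                sensor_kernels=(kernels[0], kernels[1]),
                compartment_weights=(w_rc, 1.0 - w_rc),
                posture_gain_schedule=gains,
                device_delay_samples=delay,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        cohort.append(subj_map)
    return cohort
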