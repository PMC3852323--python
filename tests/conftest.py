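import struct

import numpy as np
import pytest

from respcal import PairedRecording, SyntheticScenario, UniformSignal, generate
from respcal.signal_io import BELT_ABDOMEN, BELT_RIBCAGE, SPIROMETER


def make_recording(x1, x2, y, fs=50.0) -> PairedRecording:
    """Assemble a PairedRecording from raw arrays."""
    return PairedRecording(
        spirometer=UniformSignal(np.asarray(y, float), fs, "l/s", SPIROMETER),
        ribcage=UniformSignal(np.asarray(x1, float), fs, "a.u.", BELT_RIBCAGE),
        abdomen=UniformSignal(np.asarray(x2, float), fs, "a.u.", BELT_ABDOMEN),
    )


@pytest.fixture
def step8_recording():
    """One controlled 0.33 Hz synthetic recording, 60 s at 50 Hz."""
    sc = SyntheticScenario(
        breathing_schedule=((0.0, 0.33, 0.5),), duration_s=60.0, fs=50.0, seed=42
    )
    return generate(sc).recording


@pytest.fixture
def free_recording():
    """Free-breathing synthetic recording, 60 s at 50 Hz."""
    return generate(SyntheticScenario(seed=7)).recording


def write_minimal_edf(path, channels: dict[str, np.ndarray], fs: int) -> None:
    """Write a minimal EDF file (synthetic test fixture, 1-second records)."""
    ns = len(channels)
    names = list(channels)
    n = min(len(v) for v in channels.values())
    n_records = n // fs
    phys_max = max(float(np.abs(v).max()) for v in channels.values()) * 1.1 + 1e-9

    def pad(s, width):
        return s[:width].ljust(width).encode("ascii")

    hdr = b"".join(
        [
            pad("0", 8),
            pad("synthetic subject", 80),
            pad("synthetic recording", 80),
            pad("01.01.20", 8),
            pad("00.00.00", 8),
            pad(str(256 * (ns + 1)), 8),
            pad("", 44),
            pad(str(n_records), 8),
            pad("1", 8),
            pad(str(ns), 4),
        ]
    )
    fields = [
        (16, names),
        (80, [""] * ns),
        (8, ["a.u."] * ns),
        (8, [f"{-phys_max:.5f}"[:8]] * ns),
        (8, [f"{phys_max:.5f}"[:8]] * ns),
        (8, ["-32768"] * ns),
        (8, ["32767"] * ns),
        (80, [""] * ns),
        (8, [str(fs)] * ns),
        (32, [""] * ns),
    ]
    for width, values in fields:
        hdr += b"".join(pad(v, width) for v in values)
    scale = 32767 / phys_max
    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(n_records):
            for name in names:
                seg = channels[name][r * fs : (r + 1) * fs]
                dig = np.round(seg * scale).astype("<i2")
                fh.write(struct.pack(f"<{fs}h", *dig))
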