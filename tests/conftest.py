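from __future__ import annotations

import numpy as np
import pytest

import csrdemod as cd


@pytest.fixture(scope="session")
def mild_csr_signal() -> cd.TimeSeries:
    """Cosine-carrier recording with mild modulation (h=0.5, 20 mHz)."""
    return cd.modulate(cd.CSRParams(a_c=1.0, h=0.5, f_m=0.02), 300.0, 25.0)


@pytest.fixture(scope="session")
def breath_recording() -> cd.SyntheticRecording:
    """Breath-shaped, jittered, mildly noisy two-regime recording."""
    schedule = (
        cd.Segment(0.0, 120.0, cd.CSRParams(h=0.0, f_m=0.01)),
        cd.Segment(120.0, 420.0, cd.CSRParams(h=0.5, f_m=0.01)),
    )
    return cd.build_recording(
        schedule, fs=25.0, noise_sd=0.05, breath_jitter=0.1, seed=3,
        carrier="breath",
    )


@pytest.fixture(scope="session")
def model_envelope() -> cd.TimeSeries:
    """Exact noiseless model envelope at 1 Hz (h=0.5, 15 mHz), 600 s."""
    t = np.arange(600.0)
    return cd.TimeSeries(1.0 + 0.5 * np.cos(2 * np.pi * 0.015 * t), 1.0)
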