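"""Shared fixtures: synthetic waveform builders and (cached) short Shannon
simulations, so expensive stiff-ODE work is done once per session."""

from __future__ import annotations

import numpy as np
import pytest

from apsens.shannon import (
    PacingProtocol, ScalingVector, simulate_train, simulate_unpaced,
)
from apsens.trace import Trace


def make_beat_train(a90_list, bcl=500.0, dt=1.0, rest=-85.0, amp=125.0,
                    upstroke=1.0, with_ca=False):
    """Synthetic multi-beat trace: each beat is a quartic-exponential AP
    whose A90 is (approximately, to interpolation tolerance) the requested
    value; ``None`` entries produce a non-excited (flat) beat."""
    ln10_4 = np.log(10.0) ** 0.25
    t = np.arange(0.0, bcl * len(a90_list) + dt / 2, dt)
    V = np.full(t.size, rest)
    onsets = []
    for b, a90 in enumerate(a90_list):
        t0 = b * bcl
        onsets.append(t0)
        if a90 is None:
            continue
        tau = (a90 - upstroke) / ln10_4
        mask = (t >= t0) & (t <= t0 + bcl)
        tl = t[mask] - t0
        shape = np.where(
            tl <= upstroke, tl / upstroke,
            np.exp(-(np.maximum(tl - upstroke, 0.0) / tau) ** 4),
        )
        V[mask] = rest + amp * shape
    ca = None
    if with_ca:
        ca = np.full(t.size, 1e-4)
    return Trace(t=t, V=V, Cai=ca, stimulus_onsets=np.array(onsets), bcl=bcl)


@pytest.fixture(scope="session")
def baseline_protocol():
    return PacingProtocol(n_beats=5, record_last=2)


@pytest.fixture(scope="session")
def baseline_trace(baseline_protocol):
    """Short baseline pacing train (5 beats, last 2 recorded)."""
    return simulate_train(ScalingVector(), baseline_protocol)


@pytest.fixture(scope="session")
def quiescent_state():
    """Quiescent steady state, found by long (600 s) unstimulated
    integration; the membrane and slow Na/Ca pools are fully relaxed."""
    _, out = simulate_unpaced(ScalingVector(), duration=600_000.0)
    return out[-1]
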