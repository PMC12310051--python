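"""Time-course container shared by the ODE engine and the fast AP surrogate.

A :class:`Trace` holds the sampled membrane potential (and, when recorded,
the intracellular calcium concentration) for a train of paced beats,
together with the stimulus onset times that anchor per-beat analysis
windows.  Biomarker extraction and regime classification operate on this
container only, so downstream stages are agnostic to whether the waveform
came from the Shannon model or from a synthetic surrogate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Trace"]


@dataclass
class Trace:
    """Voltage / calcium time course for one or more paced beats.

    Parameters
    ----------
    t : ndarray
        Sample times in ms, strictly increasing.
    V : ndarray
        Membrane potential in mV, same length as ``t``.
    Cai : ndarray or None
        Bulk cytosolic calcium concentration in mM (optional).
    stimulus_onsets : ndarray
        Onset time of each recorded stimulus, ms.  Beat ``i`` occupies the
        window ``[stimulus_onsets[i], stimulus_onsets[i] + bcl]``.
    bcl : float
        Basic cycle length in ms.
    """

    t: np.ndarray
    V: np.ndarray
    Cai: np.ndarray | None
    stimulus_onsets: np.ndarray
    bcl: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        if self.Cai is not None:
            self.Cai = np.asarray(self.Cai, dtype=float)
            if self.Cai.shape != self.t.shape:
                raise ValueError("Cai and t must have the same length")
        self.stimulus_onsets = np.atleast_1d(
            np.asarray(self.stimulus_onsets, dtype=float)
        )
        if self.V.shape != self.t.shape:
            raise ValueError("V and t must have the same length")
        if self.t.size < 2 or np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing with >= 2 samples")
        if self.bcl <= 0:
            raise ValueError("bcl must be positive")
        # every recorded beat window must be covered by the samples
        for t0 in self.stimulus_onsets:
            if t0 < self.t[0] - 1e-9 or t0 + self.bcl > self.t[-1] + 1e-9:
                raise ValueError(
                    f"beat window [{t0}, {t0 + self.bcl}] not covered by trace "
                    f"span [{self.t[0]}, {self.t[-1]}]"
                )

    @property
    def n_beats(self) -> int:
        return int(self.stimulus_onsets.size)

    def beat_window(self, beat_index: int) -> tuple[float, np.ndarray, np.ndarray]:
        """Return ``(t0, t, V)`` for one recorded beat.

        ``beat_index`` follows Python indexing (negative values count from
        the final recorded beat).  The returned sample arrays cover
        ``[t0, t0 + bcl]`` inclusively.
        """
        t0 = float(self.stimulus_onsets[beat_index])
        lo = np.searchsorted(self.t, t0 - 1e-9)
        hi = np.searchsorted(self.t, t0 + self.bcl + 1e-9)
        return t0, self.t[lo:hi], self.V[lo:hi]

    def beat_window_ca(self, beat_index: int) -> tuple[float, np.ndarray, np.ndarray]:
        """Like :meth:`beat_window` but returning the calcium samples."""
        if self.Cai is None:
            raise ValueError("trace has no recorded Cai")
        t0 = float(self.stimulus_onsets[beat_index])
        lo = np.searchsorted(self.t, t0 - 1e-9)
        hi = np.searchsorted(self.t, t0 + self.bcl + 1e-9)
        return t0, self.t[lo:hi], self.Cai[lo:hi]

    def shifted(self, dt: float) -> "Trace":
        """Uniform time translation (used by invariance checks)."""
        return Trace(
            t=self.t + dt,
            V=self.V.copy(),
            Cai=None if self.Cai is None else self.Cai.copy(),
            stimulus_onsets=self.stimulus_onsets + dt,
            bcl=self.bcl,
            meta=dict(self.meta),
        )

    def to_frame(self) -> pd.DataFrame:
        data = {"t": self.t, "V": self.V}
        if self.Cai is not None:
            data["Cai"] = self.Cai
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        """Write the tidy (t, V[, Cai]) table."""
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, stimulus_onsets, bcl: float) -> "Trace":
        df = pd.read_csv(path)
        return cls(
            t=df["t"].to_numpy(),
            V=df["V"].to_numpy(),
            Cai=df["Cai"].to_numpy() if "Cai" in df else None,
            stimulus_onsets=np.asarray(stimulus_onsets, dtype=float),
            bcl=bcl,
        )
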