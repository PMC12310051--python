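"""Action-potential and calcium-transient biomarkers, and pacing-regime
classification.

Six AP biomarkers are extracted from each analysed beat window
``[t0, t0 + bcl]`` (t0 = stimulus onset):

========  =====================================================================
Vmax      peak potential, ``max V`` (mV)
Vrest     resting potential, ``V(t0 + bcl)`` (mV)
A90       time from stimulus to 90% repolarization of the peak-to-rest
          amplitude (ms)
A30       ditto at 30% repolarization (ms)
Vplt      plateau potential, ``V(t0 + A90/2)`` (mV)
B         bulk, ``integral |V - Vrest| dt`` over the window (mV ms)
========  =====================================================================

Four calcium biomarkers: ED (end-diastolic [Ca]i), PSV (peak systolic
[Ca]i), Tpeak (stimulus-to-peak time) and D50 (time spent above the 50%
recovery level between peak and resting value).

Level crossings and Vplt are located by linear interpolation between
samples; B uses trapezoidal quadrature.  The first crossing *after the
peak* defines A30/A90, guarding against early-repolarization notches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trace import Trace

__all__ = [
    "APBiomarkers",
    "CaBiomarkers",
    "ResponseLabel",
    "NoAPError",
    "DegenerateTransientError",
    "AP_BIOMARKER_NAMES",
    "CA_BIOMARKER_NAMES",
    "extract_ap_biomarkers",
    "extract_ca_biomarkers",
    "ap_detected",
    "classify_response",
    "restitution_curve",
    "pacing_convergence",
]

AP_BIOMARKER_NAMES = ("Vmax", "Vrest", "A90", "A30", "Vplt", "B")
CA_BIOMARKER_NAMES = ("ED", "PSV", "Tpeak", "D50")

#: AP-detection predicate defaults: beat peak must exceed this level (mV) ...
DETECTION_LEVEL = 0.0
#: ... and the peak-to-takeoff amplitude must exceed this (mV).
MIN_AMPLITUDE = 30.0
#: relative A90 beat-to-beat difference above which 1:1 is called alternans
ALTERNANS_RTOL = 0.05
#: minimum run length of consecutive APs/failures to call intermittency
MIN_RUN = 3


class NoAPError(ValueError):
    """The analysed beat contains no action potential (no repolarization
    crossing); distinct from numerical failure."""


class DegenerateTransientError(ValueError):
    """The calcium signal has no usable transient."""


@dataclass(frozen=True)
class APBiomarkers:
    Vmax: float
    Vrest: float
    A90: float
    A30: float
    Vplt: float
    B: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in AP_BIOMARKER_NAMES])


@dataclass(frozen=True)
class CaBiomarkers:
    ED: float
    PSV: float
    Tpeak: float
    D50: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in CA_BIOMARKER_NAMES])


@dataclass(frozen=True)
class ResponseLabel:
    """Pacing-regime label with the per-beat evidence that produced it."""

    regime: str  # normal_1_1 | alternans_2_2 | block_2_1 | intermittent | non_excitable | other
    Q: float | None = None  # mean run length for intermittent responses
    beat_flags: tuple = ()  # per-beat AP-detected flags


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _interp_crossing(t, v, level, start_idx):
    """First downward crossing of ``level`` at or after ``start_idx``,
    located by linear interpolation; returns None if never crossed."""
    below = v[start_idx:] <= level
    if not below.any():
        return None
    k = start_idx + int(np.argmax(below))
    if k == start_idx or v[k] == level:
        return float(t[k])
    t0_, t1_, v0_, v1_ = t[k - 1], t[k], v[k - 1], v[k]
    return float(t0_ + (level - v0_) * (t1_ - t0_) / (v1_ - v0_))


def _interp_at(t, v, tq):
    return float(np.interp(tq, t, v))


def ap_detected(V, detection_level=DETECTION_LEVEL, min_amplitude=MIN_AMPLITUDE) -> bool:
    """Per-beat AP detection: peak above ``detection_level`` mV and
    peak-to-takeoff amplitude above ``min_amplitude`` mV."""
    V = np.asarray(V, float)
    peak = float(V.max())
    return peak > detection_level and (peak - float(V[0])) > min_amplitude


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------


def extract_ap_biomarkers(trace: Trace, beat_index: int = -1) -> APBiomarkers:
    """Extract the six AP biomarkers from one recorded beat.

    Raises :class:`NoAPError` when the beat never repolarizes through the
    90% level after its peak (non-excited or degenerate beat).
    """
    t0, t, V = trace.beat_window(beat_index)
    if t.size < 3:
        raise ValueError("beat window has too few samples")
    Vmax = float(V.max())
    ipk = int(V.argmax())
    Vrest = float(V[-1])
    amp = abs(Vmax - Vrest)
    if amp < 1e-9:
        raise NoAPError("constant voltage in beat window: no AP")

    lvl90 = Vmax - 0.9 * amp
    lvl30 = Vmax - 0.3 * amp
    c90 = _interp_crossing(t, V, lvl90, ipk)
    if c90 is None:
        raise NoAPError("no 90% repolarization crossing after the peak: no AP")
    c30 = _interp_crossing(t, V, lvl30, ipk)
    if c30 is None:  # can only happen through interpolation edge effects
        raise NoAPError("no 30% repolarization crossing after the peak: no AP")
    A90 = c90 - t0
    A30 = c30 - t0
    Vplt = _interp_at(t, V, t0 + A90 / 2.0)
    B = float(np.trapezoid(np.abs(V - Vrest), t))
    return APBiomarkers(Vmax=Vmax, Vrest=Vrest, A90=A90, A30=A30, Vplt=Vplt, B=B)


def extract_ca_biomarkers(trace: Trace, beat_index: int = -1) -> CaBiomarkers:
    """Extract the four calcium biomarkers from one recorded beat.

    ED is [Ca]i at the stimulus (end of diastole); PSV the peak systolic
    value; Tpeak the stimulus-to-peak time; D50 the total time spent above
    the midpoint between PSV and the end-of-beat resting value (interpolated
    crossings).  Raises :class:`DegenerateTransientError` when there is no
    transient (flat or non-rising signal).
    """
    t0, t, ca = trace.beat_window_ca(beat_index)
    if t.size < 3:
        raise ValueError("beat window has too few samples")
    ED = float(ca[0])
    PSV = float(ca.max())
    ipk = int(ca.argmax())
    resting = float(ca[-1])
    if PSV - max(ED, resting) < 1e-12 or ipk == 0:
        raise DegenerateTransientError("no calcium transient in beat window")
    Tpeak = float(t[ipk]) - t0
    level = 0.5 * (PSV + resting)
    above = ca > level
    # total time above the level, with interpolated entry/exit times
    total = 0.0
    i = 0
    n = t.size
    while i < n:
        if not above[i]:
            i += 1
            continue
        # entry time
        if i == 0:
            t_in = t[0]
        else:
            t_in = t[i - 1] + (level - ca[i - 1]) * (t[i] - t[i - 1]) / (ca[i] - ca[i - 1])
        # find exit
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        if j + 1 >= n:
            t_out = t[-1]
        else:
            t_out = t[j] + (level - ca[j]) * (t[j + 1] - t[j]) / (ca[j + 1] - ca[j])
        total += t_out - t_in
        i = j + 1
    return CaBiomarkers(ED=ED, PSV=PSV, Tpeak=Tpeak, D50=float(total))


# ---------------------------------------------------------------------------
# regime classification
# ---------------------------------------------------------------------------


def _run_lengths(flags):
    runs = []
    cur = flags[0]
    n = 1
    for f in flags[1:]:
        if f == cur:
            n += 1
        else:
            runs.append((cur, n))
            cur, n = f, 1
    runs.append((cur, n))
    return runs


def classify_response(trace: Trace, min_beats: int = 40) -> ResponseLabel:
    """Classify the pacing regime of a multi-beat trace.

    Decision rules, applied to the per-beat AP-detected flags and per-beat
    A90 values:

    * no beat detected -> ``non_excitable``
    * all detected, A90 alternating beyond ``ALTERNANS_RTOL`` -> ``alternans_2_2``
    * strict AP/no-AP alternation -> ``block_2_1``
    * runs of >= ``MIN_RUN`` consecutive APs alternating with runs of
      >= ``MIN_RUN`` failures -> ``intermittent`` (Q = mean run length)
    * all detected with stable A90 -> ``normal_1_1``
    * anything else -> ``other``
    """
    W = trace.n_beats
    if W < min_beats:
        raise ValueError(f"need >= {min_beats} recorded beats, got {W}")
    flags = []
    a90 = []
    for i in range(W):
        _, t, V = trace.beat_window(i)
        det = ap_detected(V)
        flags.append(det)
        if det:
            try:
                a90.append(extract_ap_biomarkers(trace, i).A90)
            except NoAPError:
                flags[-1] = False
                a90.append(np.nan)
        else:
            a90.append(np.nan)
    flags_t = tuple(flags)

    if not any(flags):
        return ResponseLabel("non_excitable", beat_flags=flags_t)

    if all(flags):
        a = np.asarray(a90)
        d = np.abs(np.diff(a)) / np.maximum(a[:-1], 1e-12)
        if np.all(d > ALTERNANS_RTOL):
            # consistent beat-to-beat alternation of long/short APs
            odd, even = a[1::2], a[0::2]
            if (np.std(odd) / max(np.mean(odd), 1e-12) < ALTERNANS_RTOL
                    and np.std(even) / max(np.mean(even), 1e-12) < ALTERNANS_RTOL):
                return ResponseLabel("alternans_2_2", beat_flags=flags_t)
        if np.all(d <= ALTERNANS_RTOL):
            return ResponseLabel("normal_1_1", beat_flags=flags_t)
        return ResponseLabel("other", beat_flags=flags_t)

    # mixed detected / not detected
    alternating = all(flags[i] != flags[i + 1] for i in range(W - 1))
    if alternating:
        return ResponseLabel("block_2_1", beat_flags=flags_t)
    runs = _run_lengths(flags)
    interior = runs[1:-1] if len(runs) > 2 else runs
    if interior and all(n >= MIN_RUN for _, n in interior):
        Q = float(np.mean([n for _, n in interior]))
        return ResponseLabel("intermittent", Q=Q, beat_flags=flags_t)
    return ResponseLabel("other", beat_flags=flags_t)


# ---------------------------------------------------------------------------
# diagnostics built on simulation
# ---------------------------------------------------------------------------


def restitution_curve(p, bcl_list, protocol, simulate=None, classify_beats=40):
    """A90 restitution: final-beat A90 as a function of basic cycle length.

    For each BCL the pacing train is re-run and the final beat analysed;
    non-1:1 regimes are flagged, never silently averaged.  Per-point
    simulation errors are recorded and the sweep continues.

    Returns a list of dicts with keys ``bcl``, ``A90``, ``regime``,
    ``error``.
    """
    from .shannon import simulate_train as _sim

    simulate = simulate or _sim
    out = []
    for bcl in bcl_list:
        if bcl <= 0:
            raise ValueError("bcl values must be positive")
        proto = protocol.replace(bcl=float(bcl),
                                 record_last=max(classify_beats, protocol.record_last))
        row = {"bcl": float(bcl), "A90": np.nan, "regime": None, "error": None}
        try:
            tr = simulate(p, proto)
            label = classify_response(tr, min_beats=min(classify_beats, tr.n_beats))
            row["regime"] = label.regime
            if label.beat_flags and label.beat_flags[-1]:
                row["A90"] = extract_ap_biomarkers(tr, -1).A90
        except Exception as exc:  # propagate per point, continue others
            row["error"] = repr(exc)
        out.append(row)
    return out


def pacing_convergence(p, protocol, n_ref, simulate=None, include_ca=True):
    """Percentage deviation of each biomarker from its value at beat ``n_ref``.

    Simulates ``n_ref`` beats recording all of them, then reports
    ``100 |y(b) - y(n_ref)| / |y(n_ref)|`` for each biomarker and every
    recorded beat b (1-based beat numbers).  A biomarker with a zero
    reference value is reported as NaN (undefined).
    """
    from .shannon import simulate_train as _sim

    simulate = simulate or _sim
    if n_ref > protocol.n_beats:
        raise ValueError("n_ref exceeds the number of simulated beats")
    proto = protocol.replace(n_beats=n_ref, record_last=n_ref)
    tr = simulate(p, proto)
    names = list(AP_BIOMARKER_NAMES) + (list(CA_BIOMARKER_NAMES) if include_ca and tr.Cai is not None else [])

    def beat_vector(i):
        vals = list(extract_ap_biomarkers(tr, i).to_array())
        if include_ca and tr.Cai is not None:
            vals += list(extract_ca_biomarkers(tr, i).to_array())
        return np.array(vals)

    ref = beat_vector(n_ref - 1)
    rows = {}
    for b in range(1, n_ref + 1):
        y = beat_vector(b - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            dev = 100.0 * np.abs(y - ref) / np.abs(ref)
        dev[ref == 0] = np.nan
        rows[b] = dict(zip(names, dev))
    return rows
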