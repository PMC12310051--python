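"""One-at-a-time scan of the normal-response (1:1) parameter region.

Starting from the baseline model (all scaling factors at 1), one factor is
varied over a log-spaced grid spanning [1e-4, 10] while all others stay at
baseline; the pacing response is classified at each grid point and the
first transitions away from the normal 1:1 regime on either side of the
anchor are refined by bisection.  The detected interval is the maximal
contiguous normal run containing the anchor.

Scan trains are shortened relative to the paper-scale protocol
(configurable pre-pacing + classification window) with the option of a
full-length confirmation run at the reported boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .biomarkers import classify_response, extract_ap_biomarkers, NoAPError
from .shannon import PacingProtocol, ScalingVector

__all__ = ["RegimeScan", "scan_normal_range"]

#: default coarse grid: 25 log-spaced points over [1e-4, 10] plus the anchor
SCAN_LO = 1e-4
SCAN_HI = 10.0
N_GRID = 25
#: bisection refinement tolerance; matches the two-decimal precision at
#: which the normal-response ranges are reported
REFINE_TOL = 0.01


@dataclass
class RegimeScan:
    """Result of a one-parameter regime scan."""

    param: str
    values: np.ndarray        # tested values (grid + refinement points), sorted
    regimes: list             # regime label per tested value
    A90: np.ndarray           # final-beat A90 per tested value (NaN if no AP)
    normal_interval: tuple    # (lo, hi) of the detected normal range
    anchor: float
    refine_tol: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "parameter": self.param,
            "value": self.values,
            "regime": self.regimes,
            "A90": self.A90,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _default_simulate(p, protocol):
    from .shannon import simulate_train
    return simulate_train(p, protocol)


def scan_normal_range(
    param: str,
    p_base: ScalingVector,
    protocol: PacingProtocol,
    grid=None,
    refine_tol: float = REFINE_TOL,
    simulate=None,
    classify_beats: int = 60,
    scan_prepace: int = 200,
):
    """Detect the normal-response interval of one scaling factor.

    Parameters
    ----------
    param : str
        Name of the factor to vary (e.g. ``"pNaK"``).
    p_base : ScalingVector
        Baseline configuration; must itself produce a normal 1:1 response
        (precondition of the whole procedure).
    protocol : PacingProtocol
        Pacing protocol; for scanning, ``scan_prepace`` pre-pacing beats
        plus a ``classify_beats`` classification window replace the
        full-length train.
    grid : array-like, optional
        Coarse grid of factor values; default 25 log-spaced points over
        [1e-4, 10] plus the anchor.
    simulate : callable, optional
        ``simulate(p, protocol) -> Trace`` (injectable for testing).

    Returns
    -------
    RegimeScan
    """
    simulate = simulate or _default_simulate
    if not hasattr(p_base, param):
        raise ValueError(f"unknown scaling factor {param!r}")
    anchor = float(getattr(p_base, param))
    proto = protocol.replace(
        n_beats=scan_prepace + classify_beats, record_last=classify_beats
    )

    tested: dict[float, tuple[str, float]] = {}

    def classify_at(value: float) -> str:
        value = float(value)
        if value in tested:
            return tested[value][0]
        p = p_base.replace(**{param: value})
        try:
            tr = simulate(p, proto)
            label = classify_response(tr, min_beats=min(classify_beats, tr.n_beats))
            regime = label.regime
            try:
                a90 = extract_ap_biomarkers(tr, -1).A90
            except (NoAPError, ValueError):
                a90 = np.nan
        except Exception:
            regime, a90 = "failed", np.nan
        tested[value] = (regime, a90)
        return regime

    if classify_at(anchor) != "normal_1_1":
        raise ValueError(
            f"baseline configuration ({param}={anchor}) is not normal 1:1 "
            f"(got {tested[anchor][0]}); scan precondition violated"
        )

    if grid is None:
        grid = np.geomspace(SCAN_LO, SCAN_HI, N_GRID)
    values = np.unique(np.concatenate([np.asarray(grid, float), [anchor]]))
    for v in values:
        classify_at(v)

    # maximal contiguous normal run containing the anchor
    normal = [tested[v][0] == "normal_1_1" for v in values]
    ia = int(np.searchsorted(values, anchor))
    lo_i = ia
    while lo_i - 1 >= 0 and normal[lo_i - 1]:
        lo_i -= 1
    hi_i = ia
    while hi_i + 1 < len(values) and normal[hi_i + 1]:
        hi_i += 1

    # refine each boundary by bisection (grid edge = open boundary)
    lo = float(values[lo_i])
    if lo_i > 0:
        bad, good = float(values[lo_i - 1]), lo
        while good - bad > refine_tol:
            mid = 0.5 * (bad + good)
            if classify_at(mid) == "normal_1_1":
                good = mid
            else:
                bad = mid
        lo = good
    hi = float(values[hi_i])
    if hi_i < len(values) - 1:
        good, bad = hi, float(values[hi_i + 1])
        while bad - good > refine_tol:
            mid = 0.5 * (good + bad)
            if classify_at(mid) == "normal_1_1":
                good = mid
            else:
                bad = mid
        hi = good

    all_values = np.array(sorted(tested))
    return RegimeScan(
        param=param,
        values=all_values,
        regimes=[tested[v][0] for v in all_values],
        A90=np.array([tested[v][1] for v in all_values]),
        normal_interval=(lo, hi),
        anchor=anchor,
        refine_tol=refine_tol,
    )
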