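"""Hierarchy of reduced models by parameter-ranking truncation.

A reduced model at level M keeps the M highest-ranked scaling factors free
and hard-fixes all others to their baseline value 1; no re-fitting or
re-calibration is involved.  Discrepancy from the full model is measured
point-wise by the mean relative error over biomarkers,

.. math:: e^{\\langle M\\rangle}_j
    = \\frac{1}{K}\\sum_k \\left| \\frac{y^{\\langle M\\rangle}_{jk}
      - y_{jk}}{y_{jk}} \\right|,

globally by its average :math:`E^{\\langle M\\rangle}` over L quasi-random
sample points, and by the coefficient of determination R^2 (full-model
values as reference, reduced values as predictions).

The reduced evaluation path reuses the same evaluator as the full model,
so at level N the reduction is the identity bitwise.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .gsa import GrandRanking, ParameterRanges

__all__ = [
    "ReductionReport",
    "ReductionStudy",
    "reduced_points",
    "evaluate_reduced",
    "discrepancy",
    "r_squared",
    "minimal_sets",
    "quasi_random_points",
]


def quasi_random_points(ranges: ParameterRanges, L: int, seed: int = 0) -> np.ndarray:
    """L quasi-random points over the box (scrambled Sobol' sequence,
    truncated to L when L is not a power of two)."""
    m = int(np.ceil(np.log2(max(L, 2))))
    eng = qmc.Sobol(d=ranges.dim, scramble=True, seed=seed)
    u = eng.random_base2(m)[:L]
    return ranges.scale01(u)


def reduced_points(param_names, keep, points) -> np.ndarray:
    """Fix every parameter not in ``keep`` to baseline 1.

    ``param_names`` gives the column order of ``points``; ``keep`` is the
    set/sequence of names left free.
    """
    points = np.atleast_2d(np.asarray(points, float))
    keep = set(keep)
    unknown = keep - set(param_names)
    if unknown:
        raise ValueError(f"unknown parameters in keep set: {sorted(unknown)}")
    out = points.copy()
    for col, name in enumerate(param_names):
        if name not in keep:
            out[:, col] = 1.0
    return out


def evaluate_reduced(evaluator, ranking: GrandRanking, level: int,
                     points, param_names) -> np.ndarray:
    """Evaluate the level-``level`` reduced model at ``points``.

    The top-``level`` ranked parameters take their values from ``points``;
    all others are hard-set to 1.  The same ``evaluator`` as the full model
    is used (level = N therefore reproduces the full evaluation exactly).
    """
    N = len(param_names)
    if not 0 <= level <= N:
        raise ValueError(f"level must be in [0, {N}]")
    keep = ranking.top(level)
    return np.asarray(evaluator(reduced_points(param_names, keep, points)), float)


def discrepancy(full, reduced, return_per_point: bool = False):
    """Relative error between reduced and full outputs.

    Per point: mean over biomarkers of |(reduced - full)/full|; aggregate
    E = mean over points.  Biomarkers with a zero full-model value are
    excluded from the average with a warning count (division guard).

    Returns ``E`` or ``(e_per_point, E, n_zero_excluded)``.
    """
    y = np.atleast_2d(np.asarray(full, float))
    yr = np.atleast_2d(np.asarray(reduced, float))
    if y.shape != yr.shape:
        raise ValueError("full and reduced output matrices misaligned")
    zero = y == 0.0
    n_zero = int(zero.sum())
    if n_zero:
        warnings.warn(f"{n_zero} zero full-model biomarker values excluded "
                      "from relative error", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs((yr - y) / y)
    rel = np.ma.masked_array(rel, mask=zero)
    e = rel.mean(axis=1).filled(np.nan)
    E = float(np.nanmean(e))
    if return_per_point:
        return e, E, n_zero
    return E


def r_squared(full, reduced):
    """Coefficient of determination per biomarker, plus aggregates.

    R^2 = 1 - SS_res/SS_tot with the full-model values as reference and
    the reduced-model values as predictions.  Returns a dict with
    ``per_biomarker`` (array), ``aggregate`` (mean of per-biomarker R^2,
    the package's headline convention) and ``pooled`` (single R^2 over all
    z-scored biomarker columns stacked, reported alongside).
    """
    y = np.atleast_2d(np.asarray(full, float))
    yr = np.atleast_2d(np.asarray(reduced, float))
    if y.shape != yr.shape:
        raise ValueError("full and reduced output matrices misaligned")
    if y.shape[0] < 2:
        raise ValueError("need at least 2 points for R^2")
    mu = y.mean(axis=0)
    ss_tot = ((y - mu) ** 2).sum(axis=0)
    if np.any(ss_tot == 0):
        raise ValueError("constant full-model biomarker: R^2 undefined")
    ss_res = ((y - yr) ** 2).sum(axis=0)
    per = 1.0 - ss_res / ss_tot
    sd = y.std(axis=0, ddof=1)
    z = (y - mu) / sd
    zr = (yr - mu) / sd
    pooled = 1.0 - float(((z - zr) ** 2).sum()) / float(((z - z.mean(axis=0)) ** 2).sum())
    return {
        "per_biomarker": per,
        "aggregate": float(per.mean()),
        "pooled": pooled,
    }


def minimal_sets(evaluator, param_names, ST_matrix: pd.DataFrame,
                 points, full_outputs, threshold: float = 0.9):
    """Smallest ranked parameter prefix per biomarker reaching R^2 >= threshold.

    For each biomarker, parameters are ranked by their total-order index
    for *that* biomarker (largest first, alphabetical tie-break) and the
    prefix is grown until the specialised reduced model achieves the
    threshold.  If even the full prefix misses it, all N parameters are
    returned with ``reached=False``.

    Returns ``{biomarker: {"parameters": [...], "R2": float, "reached": bool}}``.
    """
    points = np.atleast_2d(np.asarray(points, float))
    full = np.atleast_2d(np.asarray(full_outputs, float))
    names = list(param_names)
    cache: dict[frozenset, np.ndarray] = {}

    def reduced_eval(keep):
        key = frozenset(keep)
        if key not in cache:
            cache[key] = np.asarray(
                evaluator(reduced_points(names, keep, points)), float
            )
        return cache[key]

    out = {}
    for k, biomarker in enumerate(ST_matrix.columns):
        st = ST_matrix[biomarker]
        order = sorted(names, key=lambda n: (-st[n], n))
        result = None
        for size in range(1, len(names) + 1):
            keep = order[:size]
            yr = reduced_eval(keep)
            r2 = r_squared(full[:, [k]], yr[:, [k]])["per_biomarker"][0]
            if r2 >= threshold:
                result = {"parameters": keep, "R2": float(r2), "reached": True}
                break
        if result is None:
            result = {"parameters": order, "R2": float(r2), "reached": False}
        out[biomarker] = result
    return out


@dataclass
class ReductionReport:
    """Discrepancy of the reduced-model hierarchy from the full model."""

    ranking: GrandRanking
    levels: pd.DataFrame          # level, E, R2_<biomarker>..., R2_aggregate, R2_pooled
    L: int
    output_names: list
    minimal: dict | None = None   # per-biomarker minimal sets
    n_zero_excluded: int = 0

    def summary(self) -> pd.DataFrame:
        return self.levels

    def to_csv(self, path) -> None:
        self.levels.to_csv(path, index=False)

    def minimal_sets_json(self, path=None) -> str:
        s = json.dumps(self.minimal, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


class ReductionStudy:
    """Reduced-model hierarchy study over a quasi-random sample.

    Parameters
    ----------
    evaluator : callable
        Maps (n_rows, N) parameter points to (n_rows, K) biomarkers; the
        *same* callable serves full and reduced evaluations (full-model
        evaluations are computed once and shared across all levels).
    ranges : ParameterRanges
    ranking : GrandRanking
        Grand-total ranking that defines the hierarchy.
    levels : sequence of int, optional
        Hierarchy levels to evaluate (default 0..N).
    L : int
        Number of quasi-random sample points (the paper-scale default of
        the pipeline configuration is 2000; scale down for desk runs).
    """

    def __init__(self, evaluator, ranges: ParameterRanges, ranking: GrandRanking,
                 levels=None, L: int = 2000, seed: int = 0, output_names=None):
        self.evaluator = evaluator
        self.ranges = ranges
        self.ranking = ranking
        N = ranges.dim
        self.levels = list(range(N + 1)) if levels is None else sorted(levels)
        if any(not 0 <= l <= N for l in self.levels):
            raise ValueError(f"levels must lie in [0, {N}]")
        self.L = L
        self.seed = seed
        self.output_names = output_names

    def fit(self, minimal_threshold: float | None = None,
            ST_matrix: pd.DataFrame | None = None) -> ReductionReport:
        names = list(self.ranges.names)
        pts = quasi_random_points(self.ranges, self.L, seed=self.seed)
        full = np.atleast_2d(np.asarray(self.evaluator(pts), float))
        K = full.shape[1]
        out_names = list(self.output_names) if self.output_names else [
            f"y{k}" for k in range(K)
        ]
        rows = []
        n_zero_total = 0
        for level in self.levels:
            reduced = evaluate_reduced(self.evaluator, self.ranking, level, pts, names)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, E, n_zero = discrepancy(full, reduced, return_per_point=True)
            n_zero_total = max(n_zero_total, n_zero)
            r2 = r_squared(full, reduced)
            row = {"level": level, "E": E,
                   "R2_aggregate": r2["aggregate"], "R2_pooled": r2["pooled"]}
            for k, nm in enumerate(out_names):
                row[f"R2_{nm}"] = r2["per_biomarker"][k]
            rows.append(row)
        minimal = None
        if minimal_threshold is not None:
            if ST_matrix is None:
                raise ValueError("minimal sets need the per-biomarker ST matrix")
            st = ST_matrix.copy()
            st.columns = out_names[:st.shape[1]]
            minimal = minimal_sets(self.evaluator, names, st, pts, full,
                                   threshold=minimal_threshold)
        return ReductionReport(
            ranking=self.ranking,
            levels=pd.DataFrame(rows),
            L=self.L,
            output_names=out_names,
            minimal=minimal,
            n_zero_excluded=n_zero_total,
        )
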