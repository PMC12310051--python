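"""Variance-based global sensitivity analysis.

Quasi-random Saltelli sampling over a box of parameter ranges, Jansen
estimators of first- and total-order Sobol indices, the Saltelli estimator
of second-order indices, bootstrap confidence intervals, a grand-total
index for ranking parameters across biomarkers, and binned conditional
expectations.

The estimator is exposed in the usual model/results idiom:
``SobolSensitivity(func, ranges, M=...)`` describes the analysis;
``.fit(seed=...)`` evaluates the design and returns a
:class:`SobolResults` carrying index estimates, bootstrap half-widths and
a ``summary()`` table.

Notation: for a scalar output :math:`y = f(p_1, \\dots, p_N)` with
independent inputs, the variance decomposes into main effects and
interactions; the first-order index :math:`S_i` is the fraction of output
variance explained by :math:`p_i` alone and the total-order index
:math:`S_{Ti}` adds every interaction involving :math:`p_i`.  With base
matrices A, B and column-swapped matrices :math:`A_B^{(i)}` the Jansen
estimators are

.. math::

    S_{Ti} = \\frac{\\tfrac{1}{2M}\\sum_m (f(A)_m - f(A_B^{(i)})_m)^2}{V},
    \\qquad
    S_i = \\frac{V - \\tfrac{1}{2M}\\sum_m (f(B)_m - f(A_B^{(i)})_m)^2}{V}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import qmc

__all__ = [
    "ParameterRanges",
    "SaltelliSample",
    "GrandRanking",
    "SobolSensitivity",
    "SobolResults",
    "generate_saltelli",
    "zscore_standardize",
    "estimate_sobol",
    "bootstrap_intervals",
    "grand_total_and_rank",
    "conditional_expectation",
    "TABLE4_RANGES",
]


# ---------------------------------------------------------------------------
# parameter ranges
# ---------------------------------------------------------------------------

#: One-at-a-time normal-response (1:1) ranges of the fifteen scaling
#: factors under the standard protocol (9.5 A/F, BCL 500 ms).
TABLE4_RANGES = {
    "pNaK": (0.0001, 1.07),
    "pK1": (0.03, 1.01),
    "pCaL": (0.7, 1.6),
    "pCap": (0.0001, 4.5),
    "pNa": (1.0, 10.0),
    "pKr": (0.0001, 3.2),
    "pNaCa": (0.6, 3.0),
    "pKs": (0.0001, 10.0),
    "pClCa": (0.0001, 10.0),
    "pNab": (0.0001, 10.0),
    "ptos": (0.0001, 2.5),
    "pClb": (0.0001, 10.0),
    "pCab": (0.34, 10.0),
    "pKp": (0.0001, 10.0),
    "ptof": (0.0001, 4.0),
}


@dataclass(frozen=True)
class ParameterRanges:
    """Closed interval [lo, hi] per parameter (dimensionless factors)."""

    names: tuple
    lo: np.ndarray
    hi: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "lo", np.asarray(self.lo, float))
        object.__setattr__(self, "hi", np.asarray(self.hi, float))
        if not (len(self.names) == self.lo.size == self.hi.size):
            raise ValueError("names, lo, hi must have equal length")
        if np.any(self.lo >= self.hi):
            raise ValueError("every range must satisfy lo < hi")

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterRanges":
        names = tuple(d.keys())
        lo = np.array([d[n][0] for n in names])
        hi = np.array([d[n][1] for n in names])
        return cls(names=names, lo=lo, hi=hi)

    @classmethod
    def normal_response_box(cls, order=None) -> "ParameterRanges":
        """The default sensitivity box (one-at-a-time 1:1 ranges)."""
        if order is None:
            from .shannon import CURRENT_NAMES
            order = ["p" + n for n in CURRENT_NAMES]
        return cls.from_dict({n: TABLE4_RANGES[n] for n in order})

    @property
    def dim(self) -> int:
        return len(self.names)

    def contains(self, x) -> bool:
        x = np.asarray(x, float)
        return bool(np.all(x >= self.lo - 1e-12) and np.all(x <= self.hi + 1e-12))

    def scale01(self, u: np.ndarray) -> np.ndarray:
        """Affine map of points in [0,1]^N onto the box."""
        return self.lo + u * (self.hi - self.lo)


# ---------------------------------------------------------------------------
# Saltelli design
# ---------------------------------------------------------------------------


@dataclass
class SaltelliSample:
    """Saltelli block design: base matrices A, B (each M x N), the
    column-swapped cross matrices AB_i (A with column i from B) and, when
    ``second_order``, BA_i (B with column i from A)."""

    ranges: ParameterRanges
    M: int
    A: np.ndarray
    B: np.ndarray
    AB: np.ndarray  # (N, M, N)
    BA: np.ndarray | None
    seed: int
    second_order: bool

    @property
    def dim(self) -> int:
        return self.ranges.dim

    @property
    def n_evaluations(self) -> int:
        N = self.dim
        return self.M * (2 * N + 2) if self.second_order else self.M * (N + 2)

    def all_rows(self) -> np.ndarray:
        """Stack every design row in the fixed block order
        [A, B, AB_1..AB_N, (BA_1..BA_N)]."""
        blocks = [self.A, self.B] + [self.AB[i] for i in range(self.dim)]
        if self.second_order:
            blocks += [self.BA[i] for i in range(self.dim)]
        return np.vstack(blocks)

    def split_outputs(self, y: np.ndarray):
        """Split a flat output vector (aligned with :meth:`all_rows`) into
        (f_A, f_B, f_AB [N,M], f_BA [N,M] or None)."""
        y = np.asarray(y, float)
        if y.shape[0] != self.n_evaluations:
            raise ValueError(
                f"outputs have {y.shape[0]} rows, design has {self.n_evaluations}"
            )
        M, N = self.M, self.dim
        fA = y[:M]
        fB = y[M:2 * M]
        fAB = y[2 * M:(2 + N) * M].reshape(N, M)
        fBA = y[(2 + N) * M:].reshape(N, M) if self.second_order else None
        return fA, fB, fAB, fBA


def generate_saltelli(
    ranges: ParameterRanges,
    M: int,
    second_order: bool = True,
    seed: int = 0,
) -> SaltelliSample:
    """Build the Saltelli design from a scrambled Sobol' sequence.

    ``M`` must be a power of two (balance property of the Sobol'
    sequence).  Total model evaluations: ``M (N+2)`` without second-order
    blocks, ``M (2N+2)`` with them.  Deterministic given ``seed``.
    """
    if M < 1 or (M & (M - 1)) != 0:
        raise ValueError(f"base sample size M must be a power of two, got {M}")
    N = ranges.dim
    eng = qmc.Sobol(d=2 * N, scramble=True, seed=seed)
    u = eng.random(M)  # M x 2N in [0,1)
    A = ranges.scale01(u[:, :N])
    B = ranges.scale01(u[:, N:])
    AB = np.empty((N, M, N))
    for i in range(N):
        AB[i] = A
        AB[i][:, i] = B[:, i]
    BA = None
    if second_order:
        BA = np.empty((N, M, N))
        for i in range(N):
            BA[i] = B
            BA[i][:, i] = A[:, i]
    return SaltelliSample(ranges=ranges, M=M, A=A, B=B, AB=AB, BA=BA,
                          seed=seed, second_order=second_order)


# ---------------------------------------------------------------------------
# z-score and estimators
# ---------------------------------------------------------------------------


def zscore_standardize(values):
    """Standardize to mean 0, sample SD 1; returns (z, mu, sigma).

    Raises on constant input (indices are undefined when the output does
    not vary).
    """
    v = np.asarray(values, float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    mu = float(np.mean(v))
    sigma = float(np.std(v, ddof=1))
    if sigma == 0.0 or not np.isfinite(sigma):
        raise ValueError("constant output: z-score (and Sobol indices) undefined")
    return (v - mu) / sigma, mu, sigma


def _jansen_indices(fA, fB, fAB, fBA=None):
    """Point estimates from evaluated blocks (outputs already z-scored).

    Returns (S1[N], ST[N], S2[N,N] or None).  Variance is taken over the
    pooled A and B evaluations.
    """
    M = fA.size
    N = fAB.shape[0]
    pooled = np.concatenate([fA, fB])
    f0 = pooled.mean()
    V = pooled.var()
    if V <= 0:
        raise ValueError("zero output variance")
    S1 = np.empty(N)
    ST = np.empty(N)
    for i in range(N):
        S1[i] = (V - 0.5 * np.mean((fB - fAB[i]) ** 2)) / V
        ST[i] = 0.5 * np.mean((fA - fAB[i]) ** 2) / V
    S2 = None
    if fBA is not None:
        S2 = np.full((N, N), np.nan)
        for i in range(N):
            for j in range(i + 1, N):
                Vij = np.mean(fBA[i] * fAB[j]) - np.mean(fA * fB)
                S2[i, j] = S2[j, i] = Vij / V - S1[i] - S1[j]
    return S1, ST, S2


def estimate_sobol(sample: SaltelliSample, outputs, which=("first", "total", "second")):
    """Jansen first/total (and Saltelli second-order) index estimates.

    ``outputs`` is the flat vector of model outputs aligned with
    ``sample.all_rows()``; it is z-scored internally (a mathematical no-op
    for variance ratios, kept for numerical comparability).  Any
    non-finite output raises (strict mode) — dropping failed base points is
    the caller's policy, see :meth:`SobolSensitivity.fit`.

    Estimates are reported unclipped: sampling noise may push them
    slightly below 0 or above 1.
    """
    y = np.asarray(outputs, float)
    if not np.all(np.isfinite(y)):
        bad = int(np.where(~np.isfinite(y))[0][0])
        raise ValueError(f"non-finite model output at design row {bad} (strict mode)")
    z, _, _ = zscore_standardize(y)
    fA, fB, fAB, fBA = sample.split_outputs(z)
    S1, ST, S2 = _jansen_indices(fA, fB, fAB, fBA)
    out = {}
    if "first" in which:
        out["S1"] = S1
    if "total" in which:
        out["ST"] = ST
    if "second" in which:
        if fBA is None:
            raise ValueError("design has no second-order blocks")
        out["S2"] = S2
    return out


def bootstrap_intervals(
    sample: SaltelliSample,
    outputs,
    B_reps: int = 1000,
    seed: int = 0,
    second_order: bool | None = None,
):
    """Bootstrap half-widths for the Sobol index estimates.

    Base-point indices are resampled with replacement jointly across the
    A/B/AB(/BA) blocks, the indices are recomputed per replicate, and the
    2-standard-deviation half-width (the empirical 68-95-99.7 rule: about
    95% of estimates within two SDs) is returned along with the replicate
    SD.  The z-score location/scale is computed once on the full evaluation
    set and reused inside replicates.  Deterministic given ``seed``.
    """
    if B_reps < 100:
        raise ValueError("need at least 100 bootstrap replicates")
    y = np.asarray(outputs, float)
    z, _, _ = zscore_standardize(y)
    fA, fB, fAB, fBA = sample.split_outputs(z)
    if second_order is None:
        second_order = fBA is not None
    M, N = sample.M, sample.dim
    rng = np.random.default_rng(seed)
    s1_reps = np.empty((B_reps, N))
    st_reps = np.empty((B_reps, N))
    s2_reps = np.empty((B_reps, N, N)) if second_order else None
    for r in range(B_reps):
        idx = rng.integers(0, M, size=M)
        S1, ST, S2 = _jansen_indices(
            fA[idx], fB[idx], fAB[:, idx],
            fBA[:, idx] if (second_order and fBA is not None) else None,
        )
        s1_reps[r] = S1
        st_reps[r] = ST
        if second_order:
            s2_reps[r] = S2
    out = {
        "S1_half_width": 2.0 * s1_reps.std(axis=0, ddof=1),
        "ST_half_width": 2.0 * st_reps.std(axis=0, ddof=1),
        "S1_sd": s1_reps.std(axis=0, ddof=1),
        "ST_sd": st_reps.std(axis=0, ddof=1),
        "n_replicates": B_reps,
    }
    if second_order:
        out["S2_half_width"] = 2.0 * s2_reps.std(axis=0, ddof=1)
        out["S2_sd"] = s2_reps.std(axis=0, ddof=1)
    return out


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------


class SobolSensitivity:
    """Sobol sensitivity analysis of a vector-output function over a box.

    Parameters
    ----------
    func : callable
        Maps an (n_rows, N) array of parameter points to an
        (n_rows, K) array of outputs (one column per biomarker), or a
        1-D vector for scalar output.  Rows that fail may be NaN.
    ranges : ParameterRanges
    M : int
        Base sample size (power of two).
    second_order : bool
        Include the BA blocks needed for second-order indices.
    output_names : sequence of str, optional
    failure_policy : {"strict", "drop"}
        ``strict`` raises on any non-finite output; ``drop`` removes the
        whole base point across all blocks and records the count.
    """

    def __init__(self, func, ranges, M, second_order=True,
                 output_names=None, failure_policy="strict",
                 bootstrap_reps=1000):
        if failure_policy not in ("strict", "drop"):
            raise ValueError("failure_policy must be 'strict' or 'drop'")
        self.func = func
        self.ranges = ranges
        self.M = M
        self.second_order = second_order
        self.output_names = output_names
        self.failure_policy = failure_policy
        self.bootstrap_reps = bootstrap_reps

    def fit(self, seed: int = 0, bootstrap: bool = True) -> "SobolResults":
        sample = generate_saltelli(self.ranges, self.M,
                                   second_order=self.second_order, seed=seed)
        rows = sample.all_rows()
        Y = np.asarray(self.func(rows), float)
        if Y.ndim == 1:
            Y = Y[:, None]
        K = Y.shape[1]
        names = list(self.output_names) if self.output_names else [
            f"y{k}" for k in range(K)
        ]
        n_blocks = (2 * sample.dim + 2) if self.second_order else (sample.dim + 2)
        bad_rows = ~np.all(np.isfinite(Y), axis=1)
        n_failed = 0
        if bad_rows.any():
            if self.failure_policy == "strict":
                bad = int(np.where(bad_rows)[0][0])
                raise ValueError(
                    f"model evaluation failed at design row {bad} (strict mode); "
                    f"point: {rows[bad]}"
                )
            # drop the whole base point across all blocks
            bad_base = np.unique(np.where(bad_rows)[0] % sample.M)
            keep = np.setdiff1d(np.arange(sample.M), bad_base)
            n_failed = int(bad_base.size)
            sub = SaltelliSample(
                ranges=sample.ranges, M=keep.size,
                A=sample.A[keep], B=sample.B[keep],
                AB=sample.AB[:, keep],
                BA=None if sample.BA is None else sample.BA[:, keep],
                seed=sample.seed, second_order=sample.second_order,
            )
            Y = Y.reshape(n_blocks, sample.M, K)[:, keep].reshape(-1, K)
            sample = sub
        per_output = {}
        for k in range(K):
            est = estimate_sobol(
                sample, Y[:, k],
                which=("first", "total", "second") if self.second_order
                else ("first", "total"),
            )
            if bootstrap:
                est.update(bootstrap_intervals(
                    sample, Y[:, k], B_reps=self.bootstrap_reps,
                    seed=seed + 1 + k,
                ))
            per_output[names[k]] = est
        return SobolResults(
            model=self, sample=sample, outputs=Y, output_names=names,
            per_output=per_output, n_failed=n_failed, seed=seed,
        )


@dataclass
class SobolResults:
    """Estimated Sobol indices with bootstrap uncertainty.

    ``per_output[name]`` holds S1, ST (length-N vectors), S2 (N x N, upper
    and lower triangle mirrored) and the corresponding ``*_half_width``
    2-SD bootstrap half-widths.  Indices are unclipped.
    """

    model: SobolSensitivity
    sample: SaltelliSample
    outputs: np.ndarray
    output_names: list
    per_output: dict
    n_failed: int
    seed: int

    @property
    def param_names(self):
        return list(self.sample.ranges.names)

    def first_order(self, output):
        return self.per_output[output]["S1"]

    def total_order(self, output):
        return self.per_output[output]["ST"]

    def second_order(self, output):
        return self.per_output[output].get("S2")

    def total_matrix(self) -> pd.DataFrame:
        """Total-order indices, parameters x biomarkers."""
        return pd.DataFrame(
            {name: self.per_output[name]["ST"] for name in self.output_names},
            index=self.param_names,
        )

    def grand_ranking(self, weights=None) -> "GrandRanking":
        return grand_total_and_rank(self.total_matrix(), weights=weights)

    def summary(self, top: int | None = None) -> pd.DataFrame:
        """Tidy index table: one row per (biomarker, parameter) with
        first/total estimates and their 95% CI half-widths."""
        rows = []
        for name in self.output_names:
            d = self.per_output[name]
            order = np.argsort(d["ST"])[::-1]
            sel = order[:top] if top else order
            for i in sel:
                rows.append({
                    "biomarker": name,
                    "parameter": self.param_names[i],
                    "S1": d["S1"][i],
                    "S1_ci_half_width": d.get("S1_half_width", [np.nan] * len(order))[i],
                    "ST": d["ST"][i],
                    "ST_ci_half_width": d.get("ST_half_width", [np.nan] * len(order))[i],
                })
        return pd.DataFrame(rows)

    def second_order_table(self, positive_only: bool = False) -> pd.DataFrame:
        """Second-order indices as tidy rows; optionally only pairs whose
        CI lower limit is positive (significant interactions)."""
        rows = []
        for name in self.output_names:
            S2 = self.per_output[name].get("S2")
            if S2 is None:
                continue
            hw = self.per_output[name].get("S2_half_width")
            N = S2.shape[0]
            for i in range(N):
                for j in range(i + 1, N):
                    h = hw[i, j] if hw is not None else np.nan
                    if positive_only and not (S2[i, j] - h > 0):
                        continue
                    rows.append({
                        "biomarker": name,
                        "pair": (self.param_names[i], self.param_names[j]),
                        "S2": S2[i, j],
                        "S2_ci_half_width": h,
                    })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# grand total ranking and conditional expectations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GrandRanking:
    """Parameters ordered by non-increasing grand-total index
    (ties broken alphabetically)."""

    names: tuple          # ranked parameter names
    SG: np.ndarray        # grand-total index, in ranked order
    weights: np.ndarray   # biomarker weights used

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"parameter": self.names, "SG": self.SG})

    def top(self, M: int) -> tuple:
        return self.names[:M]


def grand_total_and_rank(ST_matrix: pd.DataFrame, weights=None) -> GrandRanking:
    """Weighted sum of total-order indices across biomarkers, ranked.

    ``ST_matrix`` is parameters x biomarkers (as from
    :meth:`SobolResults.total_matrix`).  Default weights are all ones
    (every biomarker of equal interest).
    """
    if ST_matrix.isna().any().any():
        raise ValueError("ST matrix has missing biomarker columns/values")
    K = ST_matrix.shape[1]
    w = np.ones(K) if weights is None else np.asarray(weights, float)
    if w.size != K:
        raise ValueError(f"need {K} weights, got {w.size}")
    SG = ST_matrix.to_numpy() @ w
    names = list(ST_matrix.index)
    # sort by decreasing SG, alphabetical tie-break
    order = sorted(range(len(names)), key=lambda i: (-SG[i], names[i]))
    return GrandRanking(
        names=tuple(names[i] for i in order),
        SG=SG[[*order]],
        weights=w,
    )


def conditional_expectation(points, outputs, param_index, n_bins=20):
    """Binned conditional expectation E[y | p_i] on the scaled abscissa.

    The parameter axis is scaled to [0,1] by (p - pmin)/(pmax - pmin)
    using the observed extremes; equal-width bins; per-bin mean and count
    (empty bins reported as NaN gaps, never interpolated).  Bin counts sum
    to the number of points.

    Returns a DataFrame with columns ``bin_center``, ``mean``, ``count``.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    x = np.asarray(points, float)
    if x.ndim == 2:
        x = x[:, param_index]
    y = np.asarray(outputs, float)
    if x.size != y.size:
        raise ValueError("points and outputs misaligned")
    pmin, pmax = x.min(), x.max()
    if pmax <= pmin:
        raise ValueError("parameter does not vary")
    xs = (x - pmin) / (pmax - pmin)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(xs, edges[1:-1]), 0, n_bins - 1)
    means = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        mask = idx == b
        counts[b] = mask.sum()
        if counts[b]:
            means[b] = y[mask].mean()
    return pd.DataFrame({
        "bin_center": 0.5 * (edges[:-1] + edges[1:]),
        "mean": means,
        "count": counts,
    })
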