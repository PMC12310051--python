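"""Synthetic validation surfaces: analytic test functions with closed-form
Sobol indices, and a fast parametric AP-waveform surrogate.

These make every pipeline stage testable without long stiff-ODE runs: the
estimators are checked against functions whose variance decomposition is
known exactly, and the biomarker/GSA/reduction chain is exercised end to
end on a waveform generator whose biomarkers depend on pseudo-parameters
in closed form.  The surrogate is not a physiological model and makes no
claim about Shannon-model index values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gamma as _gamma_fn, gammainc as _gammainc

from .biomarkers import APBiomarkers, CaBiomarkers
from .trace import Trace

__all__ = [
    "AnalyticTestFunction",
    "ishigami",
    "g_function",
    "linear_test_function",
    "ishigami_test_function",
    "g_test_function",
    "SurrogateAPModel",
]


# ---------------------------------------------------------------------------
# analytic benchmark functions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnalyticTestFunction:
    """A benchmark function with exactly known variance decomposition.

    The closed-form indices are evaluated from the published formulas by
    this module (they serve as the oracle for the estimator tests).
    """

    name: str
    dim: int
    lo: np.ndarray
    hi: np.ndarray
    func: callable          # (n_rows, dim) -> (n_rows,)
    S1: np.ndarray
    ST: np.ndarray
    S2: np.ndarray          # dense N x N, zero where no pair interaction

    def __post_init__(self):
        s_full = self.S1.sum() + np.triu(self.S2, 1).sum()
        # the decomposition must be a proper partition of unity when all
        # interactions are pairwise or captured in ST
        if np.any(self.S1 < -1e-12) or np.any(self.ST > 1 + 1e-12):
            raise ValueError("closed-form indices out of [0,1]")
        if s_full > 1 + 1e-9:
            raise ValueError("closed-form indices exceed total variance")

    @property
    def ranges(self):
        from .gsa import ParameterRanges
        return ParameterRanges(
            names=tuple(f"x{i + 1}" for i in range(self.dim)),
            lo=self.lo, hi=self.hi,
        )


def ishigami(x, a: float = 7.0, b: float = 0.1):
    """Ishigami function sin(x1) + a sin^2(x2) + b x3^4 sin(x1) on [-pi, pi]^3."""
    x = np.atleast_2d(np.asarray(x, float))
    return np.sin(x[:, 0]) + a * np.sin(x[:, 1]) ** 2 + b * x[:, 2] ** 4 * np.sin(x[:, 0])


def g_function(x, a):
    """Sobol' g-function prod_i (|4 x_i - 2| + a_i)/(1 + a_i) on [0,1]^N."""
    x = np.atleast_2d(np.asarray(x, float))
    a = np.asarray(a, float)
    if np.any(a < 0):
        raise ValueError("g-function coefficients must be >= 0")
    return np.prod((np.abs(4.0 * x - 2.0) + a) / (1.0 + a), axis=1)


def linear_test_function() -> AnalyticTestFunction:
    """f(x1, x2) = x1 + 2 x2 on [0,1]^2.

    V = 1/12 + 4/12 = 5/12, so S1 = 1/5, S2 = 4/5, no interaction.
    """
    S1 = np.array([0.2, 0.8])
    return AnalyticTestFunction(
        name="linear", dim=2,
        lo=np.zeros(2), hi=np.ones(2),
        func=lambda x: np.atleast_2d(x)[:, 0] + 2.0 * np.atleast_2d(x)[:, 1],
        S1=S1, ST=S1.copy(), S2=np.zeros((2, 2)),
    )


def ishigami_test_function(a: float = 7.0, b: float = 0.1) -> AnalyticTestFunction:
    """Ishigami with the closed-form decomposition.

    V1 = (1 + b pi^4 / 5)^2 / 2, V2 = a^2 / 8, V13 = 8 b^2 pi^8 / 225,
    all other terms zero; V = V1 + V2 + V13.
    """
    pi4 = math.pi ** 4
    pi8 = math.pi ** 8
    V1 = 0.5 * (1.0 + b * pi4 / 5.0) ** 2
    V2 = a * a / 8.0
    V13 = 8.0 * b * b * pi8 / 225.0
    V = V1 + V2 + V13
    S1 = np.array([V1 / V, V2 / V, 0.0])
    ST = np.array([(V1 + V13) / V, V2 / V, V13 / V])
    S2 = np.zeros((3, 3))
    S2[0, 2] = S2[2, 0] = V13 / V
    return AnalyticTestFunction(
        name="ishigami", dim=3,
        lo=np.full(3, -math.pi), hi=np.full(3, math.pi),
        func=lambda x: ishigami(x, a=a, b=b),
        S1=S1, ST=ST, S2=S2,
    )


def g_test_function(a) -> AnalyticTestFunction:
    """Sobol' g-function with V_i = (1/3)/(1+a_i)^2 and
    V = prod_i (1 + V_i) - 1 (all interaction orders present)."""
    a = np.asarray(a, float)
    N = a.size
    Vi = (1.0 / 3.0) / (1.0 + a) ** 2
    V = np.prod(1.0 + Vi) - 1.0
    S1 = Vi / V
    ST = np.empty(N)
    S2 = np.zeros((N, N))
    for i in range(N):
        ST[i] = Vi[i] * np.prod(np.delete(1.0 + Vi, i)) / V
        for j in range(i + 1, N):
            S2[i, j] = S2[j, i] = Vi[i] * Vi[j] / V
    return AnalyticTestFunction(
        name="g_function", dim=N,
        lo=np.zeros(N), hi=np.ones(N),
        func=lambda x: g_function(x, a),
        S1=S1, ST=ST, S2=S2,
    )


# ---------------------------------------------------------------------------
# parametric AP-waveform surrogate
# ---------------------------------------------------------------------------

_G14 = _gamma_fn(0.25)


def _decay_integral(S: float) -> float:
    """integral_0^S exp(-s^4) ds = Gamma(1/4)/4 * P(1/4, S^4)."""
    return _G14 / 4.0 * _gammainc(0.25, S ** 4)


@dataclass
class SurrogateAPModel:
    """Fast parametric AP + calcium waveform with closed-form biomarkers.

    One beat over ``[0, bcl]``: a 1 ms linear upstroke from the resting
    potential to the peak, followed by a quartic-exponential plateau/
    repolarization ``V = Vr + A exp(-((t-1)/tau)^4)``; the calcium
    transient is a biexponential.  Six pseudo-parameters on ``[0.5, 2]``
    (baseline all ones):

    * q1 scales the AP amplitude A (baseline 125 mV)
    * q2 scales the repolarization time constant tau (baseline 150 ms) and,
      in step, the calcium decay time constant (slow repolarization goes
      with slow calcium extrusion)
    * q3 shifts the resting potential, Vr = -85 + 10 (q3 - 1) mV
    * q4 scales the calcium-transient amplitude (baseline 4e-4 mM) and
      mildly lifts the diastolic level, ED = 1e-4 (1 + 0.2 (q4 - 1)) mM
    * q5, q6 are inert (exactly zero effect, by construction)

    Biomarkers of the generated waveform match the closed-form map to
    quadrature/interpolation tolerance; at all-ones the template is
    returned exactly.
    """

    bcl: float = 500.0
    upstroke_ms: float = 1.0
    base_amplitude: float = 125.0
    base_tau: float = 150.0
    base_vrest: float = -85.0
    vrest_shift: float = 10.0
    ca_ed: float = 1.0e-4
    ca_base_amp: float = 4.0e-4
    ca_tau_rise: float = 20.0
    ca_tau_decay: float = 150.0
    noise_sd: float = 0.0
    dt: float = 0.1
    lo: float = 0.5
    hi: float = 2.0

    n_params: int = 6
    param_names: tuple = ("q1", "q2", "q3", "q4", "q5", "q6")

    @property
    def ranges(self):
        from .gsa import ParameterRanges
        return ParameterRanges(
            names=self.param_names,
            lo=np.full(self.n_params, self.lo),
            hi=np.full(self.n_params, self.hi),
        )

    #: pseudo-parameters with any effect on any biomarker
    active_set = ("q1", "q2", "q3", "q4")
    #: pseudo-parameters with any effect on the six AP biomarkers
    ap_active_set = ("q1", "q2", "q3")

    def _check(self, q):
        q = np.asarray(q, float)
        if q.shape != (self.n_params,):
            raise ValueError(f"expected {self.n_params} pseudo-parameters")
        if np.any(q < self.lo - 1e-12) or np.any(q > self.hi + 1e-12):
            raise ValueError(f"pseudo-parameters outside [{self.lo}, {self.hi}]")
        return q

    # -- closed-form biomarker map -----------------------------------------

    def _shape(self, q):
        A = self.base_amplitude * q[0]
        tau = self.base_tau * q[1]
        Vr = self.base_vrest + self.vrest_shift * (q[2] - 1.0)
        return A, tau, Vr

    def _ca_shape(self, q):
        ed = self.ca_ed * (1.0 + 0.2 * (q[3] - 1.0))
        amp = self.ca_base_amp * q[3]
        return ed, amp, self.ca_tau_rise, self.ca_tau_decay * q[1]

    def closed_form_ap(self, q) -> APBiomarkers:
        """Exact AP biomarkers of the waveform (analytic oracle)."""
        q = self._check(q)
        A, tau, Vr = self._shape(q)
        u = self.upstroke_ms
        Send = (self.bcl - u) / tau
        e_end = math.exp(-Send ** 4)
        vrest_m = Vr + A * e_end
        # repolarization crossing of Vmax - frac * (Vmax - vrest_m)
        def crossing(frac):
            target = (1.0 - frac) + frac * e_end  # exp(-s^4) at the level
            return u + tau * (-math.log(target)) ** 0.25
        A90 = crossing(0.9)
        A30 = crossing(0.3)
        Vplt = Vr + A * math.exp(-((A90 / 2.0 - u) / tau) ** 4)
        # B = integral |V - vrest_m|: upstroke triangle pieces + decay tail
        Bup = A * (e_end ** 2 + (1.0 - e_end) ** 2) / 2.0 * u
        Bdecay = A * (tau * _decay_integral(Send) - (self.bcl - u) * e_end)
        return APBiomarkers(
            Vmax=Vr + A, Vrest=vrest_m, A90=A90, A30=A30, Vplt=Vplt,
            B=Bup + Bdecay,
        )

    def closed_form_ca(self, q) -> CaBiomarkers:
        """Exact ED / PSV / Tpeak of the biexponential transient; D50 is
        found by root-bracketing on the exact waveform (the crossing has no
        elementary closed form)."""
        q = self._check(q)
        ed, amp, tr_, td_ = self._ca_shape(q)
        tpeak = math.log(td_ / tr_) / (1.0 / tr_ - 1.0 / td_)
        gpeak = math.exp(-tpeak / td_) - math.exp(-tpeak / tr_)
        c = amp / gpeak

        def g(t):
            return math.exp(-t / td_) - math.exp(-t / tr_)

        resting = ed + c * g(self.bcl)
        level_g = (ed + amp + resting) / 2.0
        target = (level_g - ed) / c

        from scipy.optimize import brentq

        t_in = brentq(lambda t: g(t) - target, 0.0, tpeak, xtol=1e-12)
        t_out = brentq(lambda t: g(t) - target, tpeak, self.bcl, xtol=1e-12)
        return CaBiomarkers(
            ED=ed, PSV=ed + amp, Tpeak=tpeak, D50=t_out - t_in,
        )

    def biomarker_matrix(self, rows, include_ca: bool = False) -> np.ndarray:
        """Closed-form biomarkers for many pseudo-parameter points
        (fast path used by large GSA designs)."""
        rows = np.atleast_2d(np.asarray(rows, float))
        out = []
        for q in rows:
            y = list(self.closed_form_ap(q).to_array())
            if include_ca:
                y += list(self.closed_form_ca(q).to_array())
            out.append(y)
        return np.asarray(out)

    # -- waveform generation -------------------------------------------------

    def evaluate(self, q, rng=None) -> Trace:
        """Generate the one-beat waveform as a :class:`Trace` (same
        container and conventions as the ODE engine)."""
        q = self._check(q)
        A, tau, Vr = self._shape(q)
        u = self.upstroke_ms
        t = np.arange(0.0, self.bcl + self.dt / 2, self.dt)
        V = np.where(
            t <= u,
            Vr + A * (t / u),
            Vr + A * np.exp(-(np.maximum(t - u, 0.0) / tau) ** 4),
        )
        ed, amp, tr_, td_ = self._ca_shape(q)
        tpeak = math.log(td_ / tr_) / (1.0 / tr_ - 1.0 / td_)
        gpeak = math.exp(-tpeak / td_) - math.exp(-tpeak / tr_)
        c = amp / gpeak
        Ca = ed + c * (np.exp(-t / td_) - np.exp(-t / tr_))
        if self.noise_sd > 0:
            rng = np.random.default_rng(rng)
            V = V + rng.normal(0.0, self.noise_sd, V.size)
        return Trace(
            t=t, V=V, Cai=Ca, stimulus_onsets=np.array([0.0]), bcl=self.bcl,
            meta={"model": "surrogate", "q": np.array(q)},
        )

    def surrogate_evaluate(self, q, rng=None):
        """Waveform plus the analytically known biomarker vector."""
        return self.evaluate(q, rng=rng), self.closed_form_ap(q), self.closed_form_ca(q)
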