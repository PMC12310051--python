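"""Shannon rabbit ventricular myocyte action-potential model with per-current
scaling factors.

The model is the Shannon et al. (2004) description of the rabbit ventricular
myocyte: a stiff system of 40 ordinary differential equations for the membrane
potential, channel gating variables, calcium-handling machinery (junctional
cleft, sub-sarcolemmal space, bulk cytosol, sarcoplasmic reticulum) and ionic
concentrations.  The equations and constants below are hand-coded from the
published formulation / its CellML encoding, in units of mV, ms, mM and A/F.

For sensitivity analysis every one of the fifteen transmembrane currents is
multiplied by a dimensionless scaling factor ``p_i`` (all ones = baseline
model).  The factor multiplies the current everywhere it appears, including
the ionic concentration balance equations.

Intracellular Cl- and K+ are held constant, exactly as in the model
formulation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields

import numpy as np
from numba import njit
from scipy.integrate import odeint

from .trace import Trace

__all__ = [
    "CURRENT_NAMES",
    "STATE_NAMES",
    "ScalingVector",
    "PacingProtocol",
    "SolverSettings",
    "SimulationError",
    "NonFiniteStateError",
    "stimulus_current",
    "ionic_rhs",
    "simulate_train",
    "simulate_unpaced",
    "find_excitation_threshold",
    "baseline_initial_state",
    "constants_json",
]

# ---------------------------------------------------------------------------
# Parameter / state bookkeeping
# ---------------------------------------------------------------------------

#: The fifteen scaled transmembrane currents, in the fixed package order.
CURRENT_NAMES = (
    "CaL", "Cab", "Cap", "ClCa", "K1", "Kp", "Kr", "Ks",
    "Clb", "Na", "NaCa", "NaK", "Nab", "tof", "tos",
)

STATE_NAMES = (
    "V",
    "m", "h", "j",
    "Xr", "Xs",
    "Xtos", "Ytos", "Rtos",
    "Xtof", "Ytof",
    "d", "f", "fCaBj", "fCaBsl",
    "RyRr", "RyRo", "RyRi",
    "NaBj", "NaBsl",
    "TnCL", "TnCHc", "TnCHm", "CaM", "Myoc", "Myom", "SRB",
    "SLLj", "SLLsl", "SLHj", "SLHsl",
    "Csqnb", "CaSR",
    "Naj", "Nasl", "Nai",
    "Ki",
    "Caj", "Casl", "Cai",
)

N_STATES = len(STATE_NAMES)
N_CURRENTS = len(CURRENT_NAMES)

_IDX = {name: i for i, name in enumerate(STATE_NAMES)}


@dataclass(frozen=True)
class ScalingVector:
    """Relative strengths of the fifteen ionic currents (dimensionless).

    Baseline model: all ones.  Values must be finite and non-negative.
    """

    pCaL: float = 1.0
    pCab: float = 1.0
    pCap: float = 1.0
    pClCa: float = 1.0
    pK1: float = 1.0
    pKp: float = 1.0
    pKr: float = 1.0
    pKs: float = 1.0
    pClb: float = 1.0
    pNa: float = 1.0
    pNaCa: float = 1.0
    pNaK: float = 1.0
    pNab: float = 1.0
    ptof: float = 1.0
    ptos: float = 1.0

    def __post_init__(self):
        for f_ in fields(self):
            v = getattr(self, f_.name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{f_.name} must be finite and >= 0, got {v}")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, "p" + n) for n in CURRENT_NAMES], float)

    @classmethod
    def from_array(cls, arr) -> "ScalingVector":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (N_CURRENTS,):
            raise ValueError(f"expected {N_CURRENTS} factors, got shape {arr.shape}")
        return cls(**{"p" + n: float(v) for n, v in zip(CURRENT_NAMES, arr)})

    def replace(self, **kwargs) -> "ScalingVector":
        d = {f_.name: getattr(self, f_.name) for f_ in fields(self)}
        d.update(kwargs)
        return ScalingVector(**d)


@dataclass(frozen=True)
class PacingProtocol:
    """Periodic rectangular stimulus protocol.

    ``stim_amplitude`` is the depolarizing magnitude in A/F; the stimulus
    enters the membrane equation as an inward (negative) current.  The pulse
    is on for ``stim_duration`` ms at the start of each cycle of length
    ``bcl`` ms.  ``n_beats`` cycles are simulated and the final
    ``record_last`` are recorded densely.
    """

    stim_amplitude: float = 9.5
    stim_duration: float = 5.0
    bcl: float = 500.0
    n_beats: int = 1000
    record_last: int = 1

    def __post_init__(self):
        if not (self.stim_amplitude >= 0 and np.isfinite(self.stim_amplitude)):
            raise ValueError("stim_amplitude must be finite and >= 0")
        if self.stim_duration <= 0 or self.bcl <= 0:
            raise ValueError("stim_duration and bcl must be positive")
        if self.stim_duration >= self.bcl:
            raise ValueError("stim_duration must be < bcl")
        if not (self.n_beats >= self.record_last >= 1):
            raise ValueError("need n_beats >= record_last >= 1")

    def replace(self, **kwargs) -> "PacingProtocol":
        d = {f_.name: getattr(self, f_.name) for f_ in fields(self)}
        d.update(kwargs)
        return PacingProtocol(**d)


@dataclass(frozen=True)
class SolverSettings:
    """Stiff-solver (LSODA) tolerances and recording grid.

    Biomarker reproducibility depends on these, so they are explicit
    configuration rather than hidden defaults: relative tolerance 1e-6,
    absolute tolerance 1e-8 for concentrations and 1e-6 elsewhere, dense
    output at 0.1 ms for recorded beats.
    """

    rtol: float = 1e-6
    atol_gating: float = 1e-6
    atol_conc: float = 1e-8
    record_dt: float = 0.1
    mxstep: int = 200_000

    def atol_vector(self) -> np.ndarray:
        atol = np.full(N_STATES, self.atol_gating)
        for name in ("Csqnb", "CaSR", "Naj", "Nasl", "Nai", "Ki",
                     "Caj", "Casl", "Cai", "NaBj", "NaBsl",
                     "TnCL", "TnCHc", "TnCHm", "CaM", "Myoc", "Myom", "SRB",
                     "SLLj", "SLLsl", "SLHj", "SLHsl"):
            atol[_IDX[name]] = self.atol_conc
        return atol


class SimulationError(RuntimeError):
    """Raised when the stiff solver fails; carries the offending sample."""

    def __init__(self, message, p=None, t_fail=None):
        super().__init__(message)
        self.p = p
        self.t_fail = t_fail


class NonFiniteStateError(ValueError):
    """Raised when a state vector contains a non-finite component."""


# ---------------------------------------------------------------------------
# Model constants (single source of truth for theta)
# ---------------------------------------------------------------------------

# Physical
_F = 96485.0          # C/mol
_R = 8314.3           # mJ/(mol K)
_T = 310.0            # K
_FoRT = _F / (_R * _T)   # 1/mV

# Geometry (cell modelled as a cylinder, lengths in um -> volumes in litre)
_CELL_LENGTH = 100.0
_CELL_RADIUS = 10.25
_V_CELL = math.pi * _CELL_RADIUS ** 2 * _CELL_LENGTH * 1e-15
_V_MYO = 0.65 * _V_CELL
_V_SR = 0.035 * _V_CELL
_V_SL = 0.02 * _V_CELL
_V_JUNC = 0.000539 * _V_CELL
_CM = 1.381e-10       # F

# Membrane fractions
_FJUNC = 0.11
_FSL = 1.0 - _FJUNC
_FJUNC_CAL = 0.9
_FSL_CAL = 1.0 - _FJUNC_CAL

# Inter-compartment diffusion (litre/ms)
_J_CA_JUNCSL = 8.2413e-13
_J_CA_SLMYO = 3.7243e-12
_J_NA_JUNCSL = 1.8313e-14
_J_NA_SLMYO = 1.6386e-12

# Fixed ion concentrations (mM)
_NAO = 140.0
_KO = 5.4
_CAO = 1.8
_CLI = 15.0
_CLO = 150.0
_MGI = 1.0

# Maximal conductances / fluxes
_GNA = 16.0               # mS/uF
_GNAB = 0.297e-3
_IBAR_NAK = 1.90719       # A/F
_KM_NAIP = 11.0
_KM_KO = 1.5
_GKR = 0.03 * math.sqrt(_KO / 5.4)
_PKNA = 0.01833
_GKP = 0.001
_GK1 = 0.9 * math.sqrt(_KO / 5.4)
_GTOS = 0.06
_GTOF = 0.02
_GCLCA = 0.109625
_KD_CLCA = 0.1
_GCLB = 9e-3
_PCA = 5.4e-4             # cm/s
_PNA = 1.5e-8
_PK = 2.7e-7
_Q10_CAL_FAC = 0.45       # empirical scaling of the GHK flux (model as published)
_IBAR_NCX = 9.0           # A/F
_KD_ACT = 0.256e-3
_KM_CAI = 3.59e-3
_KM_CAO = 1.3
_KM_NAI = 12.29
_KM_NAO = 87.5
_KSAT = 0.27
_ETA = 0.35
_IBAR_SLCAP = 0.0673      # A/F
_KM_PCA = 0.5e-3
_H_PCA = 1.6
_GCAB = 2.513e-4

# SR calcium handling
_VMAX_SRCAP = 5.3114e-3   # mM/ms (SR volume units)
_KMF = 0.246e-3
_KMR = 1.7
_HILL_SRCAP = 1.787
_KS_REL = 25.0            # 1/ms
_KO_CA = 10.0             # 1/(mM^2 ms)
_KOM = 0.06
_KI_CA = 0.5              # 1/(mM ms)
_KIM = 0.005
_EC50_SR = 0.45
_HSR = 2.5
_MAX_SR = 15.0
_MIN_SR = 1.0
_KSR_LEAK = 5.348e-6      # 1/ms

# Buffering (mM and ms^-1 / mM^-1 ms^-1)
_BMAX_NAJ = 7.561
_BMAX_NASL = 1.65
_KON_NA = 0.1e-3
_KOFF_NA = 1e-3
_BMAX_TNCLOW = 70e-3
_KON_TNCL = 32.7
_KOFF_TNCL = 19.6e-3
_BMAX_TNCHIGH = 140e-3
_KON_TNCHCA = 2.37
_KOFF_TNCHCA = 0.032e-3
_KON_TNCHMG = 3e-3
_KOFF_TNCHMG = 3.33e-3
_BMAX_CAM = 24e-3
_KON_CAM = 34.0
_KOFF_CAM = 238e-3
_BMAX_MYOSIN = 140e-3
_KON_MYOCA = 13.8
_KOFF_MYOCA = 0.46e-3
_KON_MYOMG = 0.0157
_KOFF_MYOMG = 0.057e-3
_BMAX_SRB = 19 * 0.9e-3
_KON_SR = 100.0
_KOFF_SR = 60e-3
_BMAX_SLL_SL = 37.4e-3 * _V_MYO / _V_SL
_BMAX_SLL_J = 4.6e-3 * _V_MYO / _V_JUNC * 0.1
_BMAX_SLH_SL = 13.4e-3 * _V_MYO / _V_SL
_BMAX_SLH_J = 1.65e-3 * _V_MYO / _V_JUNC * 0.1
_KON_SLL = 100.0
_KOFF_SLL = 1.3
_KON_SLH = 100.0
_KOFF_SLH = 30e-3
_BMAX_CSQN = 140e-3 * _V_MYO / _V_SR
_KON_CSQN = 100.0
_KOFF_CSQN = 65.0

CONSTANTS = {
    "F": _F, "R": _R, "T": _T,
    "cell_length_um": _CELL_LENGTH, "cell_radius_um": _CELL_RADIUS,
    "V_cell_L": _V_CELL, "V_myo_L": _V_MYO, "V_SR_L": _V_SR,
    "V_SL_L": _V_SL, "V_junc_L": _V_JUNC, "Cm_F": _CM,
    "Fjunc": _FJUNC, "Fjunc_CaL": _FJUNC_CAL,
    "J_ca_juncsl": _J_CA_JUNCSL, "J_ca_slmyo": _J_CA_SLMYO,
    "J_na_juncsl": _J_NA_JUNCSL, "J_na_slmyo": _J_NA_SLMYO,
    "Nao": _NAO, "Ko": _KO, "Cao": _CAO, "Cli": _CLI, "Clo": _CLO, "Mgi": _MGI,
    "GNa": _GNA, "GNaB": _GNAB, "IbarNaK": _IBAR_NAK, "KmNaip": _KM_NAIP,
    "KmKo": _KM_KO, "GKr": _GKR, "pKNa": _PKNA, "GKp": _GKP, "GK1": _GK1,
    "Gtos": _GTOS, "Gtof": _GTOF, "GClCa": _GCLCA, "KdClCa": _KD_CLCA,
    "GClB": _GCLB, "PCa": _PCA, "PNa": _PNA, "PK": _PK,
    "IbarNCX": _IBAR_NCX, "Kd_act": _KD_ACT, "KmCai": _KM_CAI,
    "KmCao": _KM_CAO, "KmNai": _KM_NAI, "KmNao": _KM_NAO,
    "ksat": _KSAT, "eta": _ETA,
    "IbarSLCaP": _IBAR_SLCAP, "KmPCa": _KM_PCA, "H_PCa": _H_PCA, "GCaB": _GCAB,
    "Vmax_SRCaP": _VMAX_SRCAP, "Kmf": _KMF, "Kmr": _KMR,
    "hillSRCaP": _HILL_SRCAP, "ks_rel": _KS_REL, "koCa": _KO_CA, "kom": _KOM,
    "kiCa": _KI_CA, "kim": _KIM, "ec50SR": _EC50_SR, "HSR": _HSR,
    "MaxSR": _MAX_SR, "MinSR": _MIN_SR, "KSRleak": _KSR_LEAK,
    "Bmax_Naj": _BMAX_NAJ, "Bmax_Nasl": _BMAX_NASL,
    "Bmax_TnClow": _BMAX_TNCLOW, "Bmax_TnChigh": _BMAX_TNCHIGH,
    "Bmax_CaM": _BMAX_CAM, "Bmax_myosin": _BMAX_MYOSIN, "Bmax_SRB": _BMAX_SRB,
    "Bmax_SLlow_sl": _BMAX_SLL_SL, "Bmax_SLlow_j": _BMAX_SLL_J,
    "Bmax_SLhigh_sl": _BMAX_SLH_SL, "Bmax_SLhigh_j": _BMAX_SLH_J,
    "Bmax_Csqn": _BMAX_CSQN,
}


def constants_json(path=None) -> str:
    """Dump the model constant table theta as JSON (for audit)."""
    s = json.dumps(CONSTANTS, indent=1, sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s)
    return s


# ---------------------------------------------------------------------------
# Initial state (published initial values of the CellML encoding)
# ---------------------------------------------------------------------------

_INITIAL = {
    "V": -85.56885,
    "m": 1.405627e-3, "h": 0.9867005, "j": 0.991562874,
    "Xr": 8.641386e-3, "Xs": 5.412034e-3,
    "Xtos": 4.051574e-3, "Ytos": 0.9945511, "Rtos": 0.9946,
    "Xtof": 4.051574e-3, "Ytof": 0.9945511,
    "d": 7.175662e-6, "f": 1.000681, "fCaBj": 0.02421991, "fCaBsl": 0.01452605,
    "RyRr": 0.8884332, "RyRo": 8.156628e-7, "RyRi": 1.024274e-7,
    "NaBj": 3.539892, "NaBsl": 0.7720854,
    "TnCL": 8.773191e-3, "TnCHc": 0.1078283, "TnCHm": 0.01524002,
    "CaM": 2.911916e-4, "Myoc": 1.298754e-3, "Myom": 0.1381982,
    "SRB": 2.143165e-3,
    "SLLj": 9.566355e-3, "SLLsl": 0.0110363,
    "SLHj": 7.347888e-2, "SLHsl": 7.297378e-2,
    "Csqnb": 1.242988, "CaSR": 0.5545201,
    "Naj": 8.80329, "Nasl": 8.80733, "Nai": 8.80853,
    "Ki": 135.0,
    "Caj": 1.737475e-4, "Casl": 1.031812e-4, "Cai": 8.597401e-5,
}


def baseline_initial_state() -> np.ndarray:
    """The documented initial state vector (published initial values)."""
    return np.array([_INITIAL[name] for name in STATE_NAMES], dtype=float)


# ---------------------------------------------------------------------------
# Right-hand side (compiled)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _derivs(t, y, p, istim, dy, cur):  # pragma: no cover - exercised via wrappers
    """Fill dy (40 derivatives) and cur (15 scaled currents, A/F).

    ``istim`` is the stimulus term already carrying its inward sign
    (i.e. -amplitude during the pulse, 0 otherwise).
    """
    V = y[0]
    m = y[1]; h = y[2]; jg = y[3]
    Xr = y[4]; Xs = y[5]
    Xtos = y[6]; Ytos = y[7]; Rtos = y[8]
    Xtof = y[9]; Ytof = y[10]
    d = y[11]; f = y[12]; fCaBj = y[13]; fCaBsl = y[14]
    RyRr = y[15]; RyRo = y[16]; RyRi = y[17]
    NaBj = y[18]; NaBsl = y[19]
    TnCL = y[20]; TnCHc = y[21]; TnCHm = y[22]
    CaM = y[23]; Myoc = y[24]; Myom = y[25]; SRB = y[26]
    SLLj = y[27]; SLLsl = y[28]; SLHj = y[29]; SLHsl = y[30]
    Csqnb = y[31]; CaSR = y[32]
    Naj = y[33]; Nasl = y[34]; Nai = y[35]
    Ki = y[36]
    Caj = y[37]; Casl = y[38]; Cai = y[39]

    pCaL = p[0]; pCab = p[1]; pCap = p[2]; pClCa = p[3]; pK1 = p[4]
    pKp = p[5]; pKr = p[6]; pKs = p[7]; pClb = p[8]; pNa = p[9]
    pNaCa = p[10]; pNaK = p[11]; pNab = p[12]; ptof = p[13]; ptos = p[14]

    # --- reversal potentials -------------------------------------------------
    ENa_j = (1.0 / _FoRT) * math.log(_NAO / Naj)
    ENa_sl = (1.0 / _FoRT) * math.log(_NAO / Nasl)
    EK = (1.0 / _FoRT) * math.log(_KO / Ki)
    ECa_j = (0.5 / _FoRT) * math.log(_CAO / Caj)
    ECa_sl = (0.5 / _FoRT) * math.log(_CAO / Casl)
    ECl = (1.0 / _FoRT) * math.log(_CLI / _CLO)

    # --- fast Na current -----------------------------------------------------
    vm47 = V + 47.13
    if abs(vm47) < 1e-7:
        am = 3.2
    else:
        am = 0.32 * vm47 / (1.0 - math.exp(-0.1 * vm47))
    bm = 0.08 * math.exp(-V / 11.0)
    if V >= -40.0:
        ah = 0.0
        bh = 1.0 / (0.13 * (1.0 + math.exp(-(V + 10.66) / 11.1)))
        aj = 0.0
        bj = 0.3 * math.exp(-2.535e-7 * V) / (1.0 + math.exp(-0.1 * (V + 32.0)))
    else:
        ah = 0.135 * math.exp(-(80.0 + V) / 6.8)
        bh = 3.56 * math.exp(0.079 * V) + 3.1e5 * math.exp(0.35 * V)
        aj = ((-1.2714e5 * math.exp(0.2444 * V) - 3.474e-5 * math.exp(-0.04391 * V))
              * (V + 37.78) / (1.0 + math.exp(0.311 * (V + 79.23))))
        bj = 0.1212 * math.exp(-0.01052 * V) / (1.0 + math.exp(-0.1378 * (V + 40.14)))
    dy[1] = am * (1.0 - m) - bm * m
    dy[2] = ah * (1.0 - h) - bh * h
    dy[3] = aj * (1.0 - jg) - bj * jg

    m3hj = m * m * m * h * jg
    INa_j = _FJUNC * _GNA * m3hj * (V - ENa_j)
    INa_sl = _FSL * _GNA * m3hj * (V - ENa_sl)

    # --- background Na -------------------------------------------------------
    INab_j = _FJUNC * _GNAB * (V - ENa_j)
    INab_sl = _FSL * _GNAB * (V - ENa_sl)

    # --- Na/K pump -----------------------------------------------------------
    sigma = (math.exp(_NAO / 67.3) - 1.0) / 7.0
    fnak = 1.0 / (1.0 + 0.1245 * math.exp(-0.1 * V * _FoRT)
                  + 0.0365 * sigma * math.exp(-V * _FoRT))
    INaK_j = (_FJUNC * _IBAR_NAK * fnak * _KO
              / (1.0 + (_KM_NAIP / Naj) ** 4) / (_KO + _KM_KO))
    INaK_sl = (_FSL * _IBAR_NAK * fnak * _KO
               / (1.0 + (_KM_NAIP / Nasl) ** 4) / (_KO + _KM_KO))
    INaK = INaK_j + INaK_sl

    # --- rapid delayed rectifier K ------------------------------------------
    Xr_inf = 1.0 / (1.0 + math.exp(-(V + 50.0) / 7.5))
    v7 = V + 7.0
    if abs(v7) < 1e-7:
        a_xr = 0.00138 / 0.123
    else:
        a_xr = 0.00138 * v7 / (1.0 - math.exp(-0.123 * v7))
    v10 = V + 10.0
    if abs(v10) < 1e-7:
        b_xr = 6.1e-4 / 0.145
    else:
        b_xr = 6.1e-4 * v10 / (math.exp(0.145 * v10) - 1.0)
    tau_xr = 1.0 / (a_xr + b_xr)
    dy[4] = (Xr_inf - Xr) / tau_xr
    rkr = 1.0 / (1.0 + math.exp((V + 33.0) / 22.4))
    IKr = _GKR * Xr * rkr * (V - EK)

    # --- slow delayed rectifier K (Ca-dependent conductance) -----------------
    Xs_inf = 1.0 / (1.0 + math.exp(-(V - 1.5) / 16.7))
    v30 = V + 30.0
    if abs(v30) < 1e-7:
        a_xs = 7.19e-5 / 0.148
        b_xs = 1.31e-4 / 0.0687
    else:
        a_xs = 7.19e-5 * v30 / (1.0 - math.exp(-0.148 * v30))
        b_xs = 1.31e-4 * v30 / (math.exp(0.0687 * v30) - 1.0)
    tau_xs = 1.0 / (a_xs + b_xs)
    dy[5] = (Xs_inf - Xs) / tau_xs
    EKs = (1.0 / _FoRT) * math.log((_KO + _PKNA * _NAO) / (Ki + _PKNA * Nai))
    pCa_j = -math.log10(Caj) + 3.0
    pCa_sl = -math.log10(Casl) + 3.0
    gks_j = 0.07 * (0.057 + 0.19 / (1.0 + math.exp((-7.2 + pCa_j) / 0.6)))
    gks_sl = 0.07 * (0.057 + 0.19 / (1.0 + math.exp((-7.2 + pCa_sl) / 0.6)))
    IKs = (_FJUNC * gks_j + _FSL * gks_sl) * Xs * Xs * (V - EKs)

    # --- plateau K -----------------------------------------------------------
    kp = 1.0 / (1.0 + math.exp(7.488 - V / 5.98))
    IKp = _GKP * kp * (V - EK)

    # --- transient outward (slow and fast) -----------------------------------
    xto_inf = 1.0 / (1.0 + math.exp(-(V + 3.0) / 15.0))
    yto_inf = 1.0 / (1.0 + math.exp((V + 33.5) / 10.0))
    tau_xtos = 9.0 / (1.0 + math.exp((V + 3.0) / 15.0)) + 0.5
    tau_ytos = 3000.0 / (1.0 + math.exp((V + 60.0) / 10.0)) + 30.0
    tau_rtos = 2800.0 / (1.0 + math.exp((V + 60.0) / 10.0)) + 220.0
    dy[6] = (xto_inf - Xtos) / tau_xtos
    dy[7] = (yto_inf - Ytos) / tau_ytos
    dy[8] = (yto_inf - Rtos) / tau_rtos
    Itos = _GTOS * Xtos * (Ytos + 0.5 * Rtos) * (V - EK)
    tau_xtof = 3.5 * math.exp(-(V / 30.0) ** 2) + 1.5
    tau_ytof = 20.0 / (1.0 + math.exp((V + 33.5) / 10.0)) + 20.0
    dy[9] = (xto_inf - Xtof) / tau_xtof
    dy[10] = (yto_inf - Ytof) / tau_ytof
    Itof = _GTOF * Xtof * Ytof * (V - EK)

    # --- inward rectifier K --------------------------------------------------
    vek = V - EK
    aK1 = 1.02 / (1.0 + math.exp(0.2385 * (vek - 59.215)))
    bK1 = ((0.49124 * math.exp(0.08032 * (vek + 5.476))
            + math.exp(0.06175 * (vek - 594.31)))
           / (1.0 + math.exp(-0.5143 * (vek + 4.753))))
    IK1 = _GK1 * aK1 / (aK1 + bK1) * vek

    # --- Ca-activated Cl and background Cl -----------------------------------
    IClCa = (_GCLCA * (_FJUNC / (1.0 + _KD_CLCA / Caj)
                       + _FSL / (1.0 + _KD_CLCA / Casl)) * (V - ECl))
    IClb = _GCLB * (V - ECl)

    # --- L-type Ca current (GHK) ---------------------------------------------
    d_inf = 1.0 / (1.0 + math.exp(-(V + 14.5) / 6.0))
    v145 = V + 14.5
    if abs(v145) < 1e-7:
        tau_d = d_inf * (1.0 / 6.0) / 0.035
    else:
        tau_d = d_inf * (1.0 - math.exp(-v145 / 6.0)) / (0.035 * v145)
    f_inf = (1.0 / (1.0 + math.exp((V + 35.06) / 3.6))
             + 0.6 / (1.0 + math.exp((50.0 - V) / 20.0)))
    tau_f = 1.0 / (0.0197 * math.exp(-(0.0337 * v145) ** 2) + 0.02)
    dy[11] = (d_inf - d) / tau_d
    dy[12] = (f_inf - f) / tau_f
    dy[13] = 1.7 * Caj * (1.0 - fCaBj) - 11.9e-3 * fCaBj
    dy[14] = 1.7 * Casl * (1.0 - fCaBsl) - 11.9e-3 * fCaBsl

    q1 = V * _FoRT
    if abs(q1) < 1e-6:
        Ve1 = 1.0 / _FoRT       # limit of V / (exp(V FoRT) - 1)
        Ve2 = 0.5 / _FoRT       # limit of V / (exp(2 V FoRT) - 1)
        e1 = 1.0
        e2 = 1.0
    else:
        e1 = math.exp(q1)
        e2 = math.exp(2.0 * q1)
        Ve1 = V / (e1 - 1.0)
        Ve2 = V / (e2 - 1.0)
    fCa_j = 1.0 - fCaBj
    fCa_sl = 1.0 - fCaBsl
    df45 = _Q10_CAL_FAC * d * f
    ibarca_j = _PCA * 4.0 * _F * _FoRT * Ve2 * (0.341 * Caj * e2 - 0.341 * _CAO)
    ibarca_sl = _PCA * 4.0 * _F * _FoRT * Ve2 * (0.341 * Casl * e2 - 0.341 * _CAO)
    ibarna_j = _PNA * _F * _FoRT * Ve1 * (0.75 * Naj * e1 - 0.75 * _NAO)
    ibarna_sl = _PNA * _F * _FoRT * Ve1 * (0.75 * Nasl * e1 - 0.75 * _NAO)
    ibark = _PK * _F * _FoRT * Ve1 * (0.75 * Ki * e1 - 0.75 * _KO)
    ICa_j = df45 * fCa_j * _FJUNC_CAL * ibarca_j
    ICa_sl = df45 * fCa_sl * _FSL_CAL * ibarca_sl
    ICaNa_j = df45 * fCa_j * _FJUNC_CAL * ibarna_j
    ICaNa_sl = df45 * fCa_sl * _FSL_CAL * ibarna_sl
    ICaK = df45 * (fCa_j * _FJUNC_CAL + fCa_sl * _FSL_CAL) * ibark

    # --- Na/Ca exchanger -----------------------------------------------------
    Ka_j = 1.0 / (1.0 + (_KD_ACT / Caj) ** 3)
    Ka_sl = 1.0 / (1.0 + (_KD_ACT / Casl) ** 3)
    expV1 = math.exp(_ETA * q1)
    expV2 = math.exp((_ETA - 1.0) * q1)
    Naj3 = Naj ** 3
    Nasl3 = Nasl ** 3
    s1_j = expV1 * Naj3 * _CAO
    s2_j = expV2 * _NAO ** 3 * Caj
    s3_j = (_KM_CAI * _NAO ** 3 * (1.0 + (Naj / _KM_NAI) ** 3)
            + _KM_NAO ** 3 * Caj * (1.0 + Caj / _KM_CAI)
            + _KM_CAO * Naj3 + Naj3 * _CAO + _NAO ** 3 * Caj)
    INaCa_j = (_FJUNC * _IBAR_NCX * Ka_j * (s1_j - s2_j)
               / s3_j / (1.0 + _KSAT * expV2))
    s1_sl = expV1 * Nasl3 * _CAO
    s2_sl = expV2 * _NAO ** 3 * Casl
    s3_sl = (_KM_CAI * _NAO ** 3 * (1.0 + (Nasl / _KM_NAI) ** 3)
             + _KM_NAO ** 3 * Casl * (1.0 + Casl / _KM_CAI)
             + _KM_CAO * Nasl3 + Nasl3 * _CAO + _NAO ** 3 * Casl)
    INaCa_sl = (_FSL * _IBAR_NCX * Ka_sl * (s1_sl - s2_sl)
                / s3_sl / (1.0 + _KSAT * expV2))

    # --- sarcolemmal Ca pump and background Ca -------------------------------
    caj_h = Caj ** _H_PCA
    casl_h = Casl ** _H_PCA
    km_h = _KM_PCA ** _H_PCA
    ICap_j = _FJUNC * _IBAR_SLCAP * caj_h / (km_h + caj_h)
    ICap_sl = _FSL * _IBAR_SLCAP * casl_h / (km_h + casl_h)
    ICab_j = _FJUNC * _GCAB * (V - ECa_j)
    ICab_sl = _FSL * _GCAB * (V - ECa_sl)

    # --- SR fluxes -----------------------------------------------------------
    kCaSR = _MAX_SR - (_MAX_SR - _MIN_SR) / (1.0 + (_EC50_SR / CaSR) ** _HSR)
    koSRCa = _KO_CA / kCaSR
    kiSRCa = _KI_CA * kCaSR
    RI = 1.0 - RyRr - RyRo - RyRi
    dy[15] = (_KIM * RI - kiSRCa * Caj * RyRr) - (koSRCa * Caj * Caj * RyRr - _KOM * RyRo)
    dy[16] = (koSRCa * Caj * Caj * RyRr - _KOM * RyRo) - (kiSRCa * Caj * RyRo - _KIM * RyRi)
    dy[17] = (kiSRCa * Caj * RyRo - _KIM * RyRi) - (_KOM * RyRi - koSRCa * Caj * Caj * RI)
    J_SRCarel = _KS_REL * RyRo * (CaSR - Caj)          # mM/ms (SR volume)
    cf = (Cai / _KMF) ** _HILL_SRCAP
    cr = (CaSR / _KMR) ** _HILL_SRCAP
    J_serca = _VMAX_SRCAP * (cf - cr) / (1.0 + cf + cr)  # mM/ms (SR volume)
    J_SRleak = _KSR_LEAK * (CaSR - Caj)                # mM/ms (myoplasm volume)

    # --- buffering -----------------------------------------------------------
    dy[18] = _KON_NA * Naj * (_BMAX_NAJ - NaBj) - _KOFF_NA * NaBj
    dy[19] = _KON_NA * Nasl * (_BMAX_NASL - NaBsl) - _KOFF_NA * NaBsl

    dy[20] = _KON_TNCL * Cai * (_BMAX_TNCLOW - TnCL) - _KOFF_TNCL * TnCL
    dy[21] = _KON_TNCHCA * Cai * (_BMAX_TNCHIGH - TnCHc - TnCHm) - _KOFF_TNCHCA * TnCHc
    dy[22] = _KON_TNCHMG * _MGI * (_BMAX_TNCHIGH - TnCHc - TnCHm) - _KOFF_TNCHMG * TnCHm
    dy[23] = _KON_CAM * Cai * (_BMAX_CAM - CaM) - _KOFF_CAM * CaM
    dy[24] = _KON_MYOCA * Cai * (_BMAX_MYOSIN - Myoc - Myom) - _KOFF_MYOCA * Myoc
    dy[25] = _KON_MYOMG * _MGI * (_BMAX_MYOSIN - Myoc - Myom) - _KOFF_MYOMG * Myom
    dy[26] = _KON_SR * Cai * (_BMAX_SRB - SRB) - _KOFF_SR * SRB
    J_CaB_cytosol = dy[20] + dy[21] + dy[23] + dy[24] + dy[26]

    dy[27] = _KON_SLL * Caj * (_BMAX_SLL_J - SLLj) - _KOFF_SLL * SLLj
    dy[28] = _KON_SLL * Casl * (_BMAX_SLL_SL - SLLsl) - _KOFF_SLL * SLLsl
    dy[29] = _KON_SLH * Caj * (_BMAX_SLH_J - SLHj) - _KOFF_SLH * SLHj
    dy[30] = _KON_SLH * Casl * (_BMAX_SLH_SL - SLHsl) - _KOFF_SLH * SLHsl
    J_CaB_junc = dy[27] + dy[29]
    J_CaB_sl = dy[28] + dy[30]

    dy[31] = _KON_CSQN * CaSR * (_BMAX_CSQN - Csqnb) - _KOFF_CSQN * Csqnb

    # --- scaled current totals ----------------------------------------------
    INa_tot_j = (pNa * INa_j + pNab * INab_j + 3.0 * pNaCa * INaCa_j
                 + 3.0 * pNaK * INaK_j + pCaL * ICaNa_j)
    INa_tot_sl = (pNa * INa_sl + pNab * INab_sl + 3.0 * pNaCa * INaCa_sl
                  + 3.0 * pNaK * INaK_sl + pCaL * ICaNa_sl)
    IK_tot = (ptos * Itos + ptof * Itof + pKr * IKr + pKs * IKs
              + pK1 * IK1 + pKp * IKp - 2.0 * pNaK * INaK + pCaL * ICaK)
    ICa_tot_j = (pCaL * ICa_j + pCab * ICab_j + pCap * ICap_j
                 - 2.0 * pNaCa * INaCa_j)
    ICa_tot_sl = (pCaL * ICa_sl + pCab * ICab_sl + pCap * ICap_sl
                  - 2.0 * pNaCa * INaCa_sl)
    ICl_tot = pClCa * IClCa + pClb * IClb

    # --- concentration balances ----------------------------------------------
    dy[33] = (-INa_tot_j * _CM / (_V_JUNC * _F)
              + _J_NA_JUNCSL / _V_JUNC * (Nasl - Naj) - dy[18])
    dy[34] = (-INa_tot_sl * _CM / (_V_SL * _F)
              + _J_NA_JUNCSL / _V_SL * (Naj - Nasl)
              + _J_NA_SLMYO / _V_SL * (Nai - Nasl) - dy[19])
    dy[35] = _J_NA_SLMYO / _V_MYO * (Nasl - Nai)
    dy[36] = 0.0  # intracellular K+ held constant (model as formulated)

    dy[32] = J_serca - (J_SRleak * _V_MYO / _V_SR + J_SRCarel) - dy[31]
    dy[37] = (-ICa_tot_j * _CM / (2.0 * _V_JUNC * _F)
              + _J_CA_JUNCSL / _V_JUNC * (Casl - Caj) - J_CaB_junc
              + J_SRCarel * _V_SR / _V_JUNC + J_SRleak * _V_MYO / _V_JUNC)
    dy[38] = (-ICa_tot_sl * _CM / (2.0 * _V_SL * _F)
              + _J_CA_JUNCSL / _V_SL * (Caj - Casl)
              + _J_CA_SLMYO / _V_SL * (Cai - Casl) - J_CaB_sl)
    dy[39] = (-J_serca * _V_SR / _V_MYO - J_CaB_cytosol
              + _J_CA_SLMYO / _V_MYO * (Casl - Cai))

    # --- membrane potential --------------------------------------------------
    I_tot = (INa_tot_j + INa_tot_sl + IK_tot + ICa_tot_j + ICa_tot_sl + ICl_tot)
    dy[0] = -(I_tot + istim)

    # --- named (scaled) current report, package order ------------------------
    cur[0] = pCaL * (ICa_j + ICa_sl + ICaNa_j + ICaNa_sl + ICaK)
    cur[1] = pCab * (ICab_j + ICab_sl)
    cur[2] = pCap * (ICap_j + ICap_sl)
    cur[3] = pClCa * IClCa
    cur[4] = pK1 * IK1
    cur[5] = pKp * IKp
    cur[6] = pKr * IKr
    cur[7] = pKs * IKs
    cur[8] = pClb * IClb
    cur[9] = pNa * (INa_j + INa_sl)
    cur[10] = pNaCa * (INaCa_j + INaCa_sl)
    cur[11] = pNaK * INaK
    cur[12] = pNab * (INab_j + INab_sl)
    cur[13] = ptof * Itof
    cur[14] = ptos * Itos


@njit(cache=True)
def _rhs(y, t, p, istim):  # pragma: no cover - hot loop
    dy = np.empty(N_STATES)
    cur = np.empty(N_CURRENTS)
    _derivs(t, y, p, istim, dy, cur)
    return dy


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def stimulus_current(t: float, protocol: PacingProtocol) -> float:
    """Depolarizing stimulus magnitude (A/F) at time ``t`` (ms).

    Periodic rectangular pulse: ``stim_amplitude`` during the first
    ``stim_duration`` ms of each cycle, 0 otherwise.  Sign convention: the
    returned value is the depolarizing magnitude; the membrane equation uses
    ``Istim = -stimulus_current(t)`` (inward).
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    phase = math.fmod(t, protocol.bcl)
    return protocol.stim_amplitude if phase < protocol.stim_duration else 0.0


def ionic_rhs(state, t: float, p: ScalingVector, protocol: PacingProtocol):
    """Evaluate the model right-hand side and the named scaled currents.

    Returns ``(dydt, currents)`` where ``currents`` is a dict keyed by the
    Table-2 current names, each value the p-scaled total current in A/F.
    """
    y = np.asarray(state, dtype=float)
    if y.shape != (N_STATES,):
        raise ValueError(f"state must have {N_STATES} components")
    bad = np.where(~np.isfinite(y))[0]
    if bad.size:
        raise NonFiniteStateError(
            f"non-finite state component '{STATE_NAMES[bad[0]]}' (index {bad[0]})"
        )
    parr = p.to_array() if isinstance(p, ScalingVector) else np.asarray(p, float)
    istim = -stimulus_current(t, protocol)
    dy = np.empty(N_STATES)
    cur = np.empty(N_CURRENTS)
    _derivs(t, y, parr, istim, dy, cur)
    return dy, dict(zip(CURRENT_NAMES, cur))


def _integrate_segment(y, t_grid, parr, istim, settings, p_for_err, t_offset):
    """odeint over one constant-stimulus segment; raises on solver failure."""
    out, info = odeint(
        _rhs, y, t_grid, args=(parr, istim),
        rtol=settings.rtol, atol=settings.atol_vector(),
        mxstep=settings.mxstep, full_output=True,
    )
    if info["message"] != "Integration successful.":
        raise SimulationError(
            f"stiff solver failed: {info['message']}",
            p=p_for_err, t_fail=t_offset + float(info["tcur"][-1]),
        )
    if not np.all(np.isfinite(out[-1])):
        raise SimulationError(
            "non-finite state after integration segment",
            p=p_for_err, t_fail=t_offset + float(t_grid[-1]),
        )
    return out


def simulate_train(
    p: ScalingVector | np.ndarray,
    protocol: PacingProtocol,
    settings: SolverSettings | None = None,
    initial_state: np.ndarray | None = None,
    return_final_state: bool = False,
):
    """Integrate the paced model for ``protocol.n_beats`` cycles.

    Starts from the documented initial state (published initial values)
    unless ``initial_state`` is given.  The final ``protocol.record_last``
    beats are recorded on a dense 0.1 ms grid (``settings.record_dt``) with
    stimulus onsets marked; earlier beats are integrated without dense
    output.  Deterministic given identical inputs and tolerances.

    Solver failures raise :class:`SimulationError` carrying the sample's
    ``p`` and the failure time; a partial trace is never returned.
    """
    settings = settings or SolverSettings()
    parr = p.to_array() if isinstance(p, ScalingVector) else np.asarray(p, float)
    if parr.shape != (N_CURRENTS,):
        raise ValueError(f"p must have {N_CURRENTS} factors")
    if not np.all(np.isfinite(parr)) or np.any(parr < 0):
        raise ValueError("scaling factors must be finite and >= 0")

    y = baseline_initial_state() if initial_state is None else np.array(initial_state, float)
    if not np.all(np.isfinite(y)):
        raise NonFiniteStateError("initial state contains non-finite components")

    bcl, dur, amp = protocol.bcl, protocol.stim_duration, protocol.stim_amplitude
    first_recorded = protocol.n_beats - protocol.record_last

    t_list, v_list, ca_list, onsets = [], [], [], []
    for beat in range(protocol.n_beats):
        t0 = beat * bcl
        record = beat >= first_recorded
        if record:
            n1 = max(int(round(dur / settings.record_dt)), 2)
            grid1 = np.linspace(0.0, dur, n1 + 1)
            n2 = max(int(round((bcl - dur) / settings.record_dt)), 2)
            grid2 = np.linspace(dur, bcl, n2 + 1)
        else:
            grid1 = np.array([0.0, dur])
            grid2 = np.array([dur, bcl])
        out1 = _integrate_segment(y, grid1, parr, -amp, settings, parr, t0)
        y = out1[-1]
        out2 = _integrate_segment(y, grid2, parr, 0.0, settings, parr, t0)
        y = out2[-1]
        if record:
            # drop the duplicated junction sample between the two segments,
            # and the duplicated beat-start sample for all but the first
            # recorded beat (it equals the previous beat's end sample)
            seg_t = np.concatenate([grid1, grid2[1:]]) + t0
            seg = np.concatenate([out1, out2[1:]], axis=0)
            if onsets:
                seg_t, seg = seg_t[1:], seg[1:]
            onsets.append(t0)
            t_list.append(seg_t)
            v_list.append(seg[:, _IDX["V"]])
            ca_list.append(seg[:, _IDX["Cai"]])

    trace = Trace(
        t=np.concatenate(t_list),
        V=np.concatenate(v_list),
        Cai=np.concatenate(ca_list),
        stimulus_onsets=np.array(onsets),
        bcl=bcl,
        meta={"model": "shannon", "protocol": protocol, "p": parr.copy()},
    )
    if return_final_state:
        return trace, y
    return trace


def simulate_unpaced(
    p: ScalingVector | np.ndarray,
    duration: float,
    settings: SolverSettings | None = None,
    initial_state: np.ndarray | None = None,
    n_out: int = 2,
):
    """Integrate without any stimulus for ``duration`` ms; returns the state
    trajectory sampled at ``n_out`` points (used for quiescent steady-state
    searches and conservation checks)."""
    settings = settings or SolverSettings()
    parr = p.to_array() if isinstance(p, ScalingVector) else np.asarray(p, float)
    y = baseline_initial_state() if initial_state is None else np.array(initial_state, float)
    grid = np.linspace(0.0, duration, max(n_out, 2))
    out = _integrate_segment(y, grid, parr, 0.0, settings, parr, 0.0)
    return grid, out


def _elicits_ap(t, V, detection_level=0.0, min_amplitude=30.0) -> bool:
    """AP-detection predicate: peak V above ``detection_level`` mV and
    amplitude (peak minus take-off potential) above ``min_amplitude`` mV."""
    peak = float(np.max(V))
    return peak > detection_level and (peak - float(V[0])) > min_amplitude


def find_excitation_threshold(
    p: ScalingVector | np.ndarray,
    protocol: PacingProtocol,
    bracket=(5.0, 15.0),
    tol: float = 0.05,
    settings: SolverSettings | None = None,
) -> float:
    """Smallest stimulus amplitude (A/F) eliciting an AP, by bisection.

    The cell is pre-paced for ``protocol.n_beats - 1`` beats at the
    protocol's amplitude; each candidate amplitude is then applied for a
    single test beat from that state and judged by the AP-detection
    predicate.  Precondition: the bracket must straddle the threshold
    (no AP at the bottom, AP at the top).
    """
    settings = settings or SolverSettings()
    lo, hi = float(bracket[0]), float(bracket[1])
    if not lo < hi:
        raise ValueError("bracket must satisfy lo < hi")

    state = baseline_initial_state()
    if protocol.n_beats > 1:
        pre = protocol.replace(n_beats=protocol.n_beats - 1, record_last=1)
        _, state = simulate_train(p, pre, settings, return_final_state=True)

    probe_proto = protocol.replace(n_beats=1, record_last=1)

    def excited(amp: float) -> bool:
        tr = simulate_train(
            p, probe_proto.replace(stim_amplitude=amp), settings,
            initial_state=state,
        )
        t0, t, V = tr.beat_window(-1)
        return _elicits_ap(t, V)

    if excited(lo):
        raise ValueError(f"bracket bottom {lo} A/F already elicits an AP")
    if not excited(hi):
        raise ValueError(f"bracket top {hi} A/F does not elicit an AP")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if excited(mid):
            hi = mid
        else:
            lo = mid
    return hi
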