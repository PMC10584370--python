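"""Human ventricular ionic models for genotype-specific ARVC simulation.

The baseline ("GE", gene-elusive) myocyte is the ten Tusscher–Panfilov 2006
epicardial human ventricular model augmented with a two-gate late sodium
current (I_NaL, O'Hara–Rudy-style formulation).  Two pathological variants are
expressed purely as parameter transformations of that baseline:

``PKP2``
    Plakophilin-2 loss-of-function remodeling: fast sodium conductance reduced
    by 70%, L-type calcium conductance halved, background calcium current
    upregulated fivefold (Cx43-hemichannel-mediated calcium entry), Na/Ca
    exchanger downregulated by 20%, RyR2-mediated SR release and leak maximal
    rates reduced by 20%, and the SR (calsequestrin) buffering half-saturation
    constant reduced by 40% (0.3 -> 0.18 mM).

``FIBROSIS``
    Diffuse-fibrosis electrical remodeling (Coppini-type HCM data): I_NaL
    +107%, I_CaL +19%, I_Kr -34%, I_Ks -27%, I_to -85%, I_K1 -15%, Na/Ca
    exchanger +34%, SERCA uptake -43%.

All membrane currents are in pA/pF, SR/subspace fluxes in mM/ms, potentials in
mV, concentrations in mM and time in ms.  Gates are integrated with the
Rush–Larsen exponential scheme; voltage and concentrations with forward Euler.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit

__all__ = [
    "PARAM_NAMES",
    "STATE_NAMES",
    "BASELINE_PARAMS",
    "VariantParameterSet",
    "CellState",
    "CurrentSet",
    "CURRENT_NAMES",
    "load_baseline",
    "make_variant",
    "compute_currents",
    "step",
    "run_cell",
    "relax_to_rest",
]

# ---------------------------------------------------------------------------
# Physical constants (not part of the tunable parameter set)
R_GAS = 8314.472   # J / (kmol K)
TEMP = 310.0       # K
FARADAY = 96485.3415  # C / mmol
RTONF = R_GAS * TEMP / FARADAY  # ~26.71 mV

# ---------------------------------------------------------------------------
# Parameter vector layout.  Order is the array layout used by the kernels.
PARAM_NAMES: tuple[str, ...] = (
    "g_Na",      # fast sodium maximal conductance, nS/pF
    "g_NaL",     # late sodium maximal conductance, nS/pF
    "g_CaL",     # L-type Ca maximal conductance, cm^3 uF^-1 ms^-1
    "g_Kr",      # rapid delayed rectifier, nS/pF
    "g_Ks",      # slow delayed rectifier, nS/pF
    "g_to",      # transient outward, nS/pF
    "g_K1",      # inward rectifier, nS/pF
    "g_bNa",     # background sodium, nS/pF
    "g_bCa",     # background calcium, nS/pF
    "g_pCa",     # sarcolemmal Ca pump maximal current, pA/pF
    "g_pK",      # plateau potassium, nS/pF
    "P_NaK",     # Na/K pump maximal current, pA/pF
    "k_NaCa",    # Na/Ca exchanger scale, pA/pF
    "K_mNai",    # NCX Nai half-saturation, mM
    "K_mCa",     # NCX Cai half-saturation, mM
    "k_sat",     # NCX saturation factor
    "alpha_NaCa",  # NCX outward enhancement factor
    "gamma_NaCa",  # NCX voltage-dependence position
    "K_mK",      # Na/K pump Ko half-saturation, mM
    "K_mNa",     # Na/K pump Nai half-saturation, mM
    "K_pCa",     # sarcolemmal Ca pump half-saturation, mM
    "p_KNa",     # IKs Na/K permeability ratio
    "V_maxup",   # SERCA maximal uptake, mM/ms
    "K_up",      # SERCA half-saturation, mM
    "V_rel",     # RyR2 maximal SR release rate, 1/ms
    "V_leak",    # SR leak maximal rate, 1/ms
    "V_xfer",    # subspace->cytosol transfer rate, 1/ms
    "k1_prime",  # RyR2 opening rate scale, 1/(mM^2 ms)
    "k2_prime",  # RyR2 inactivation rate scale, 1/(mM ms)
    "k3",        # RyR2 closing rate, 1/ms
    "k4",        # RyR2 recovery rate, 1/ms
    "EC50_SR",   # CaSR half-saturation of release modulation, mM
    "max_SR",    # release modulation upper bound
    "min_SR",    # release modulation lower bound
    "Buf_c",     # cytosolic buffer concentration, mM
    "K_bufc",    # cytosolic buffer half-saturation, mM
    "Buf_sr",    # SR (calsequestrin) buffer concentration, mM
    "K_bufsr",   # SR buffer half-saturation, mM
    "Buf_ss",    # subspace buffer concentration, mM
    "K_bufss",   # subspace buffer half-saturation, mM
    "Na_o",      # extracellular Na, mM
    "K_o",       # extracellular K, mM
    "Ca_o",      # extracellular Ca, mM
    "Cm",        # membrane capacitance factor, uF/cm^2
    "V_c",       # cytosolic volume factor
    "V_sr",      # SR volume factor
    "V_ss",      # subspace volume factor
    "tau_hL",    # I_NaL inactivation time constant, ms
)

# Published TT2006 epicardial constants plus the late-sodium addition.
BASELINE_PARAMS: dict[str, float] = {
    "g_Na": 14.838,
    "g_NaL": 0.0065,
    "g_CaL": 3.98e-5,
    "g_Kr": 0.153,
    "g_Ks": 0.392,
    "g_to": 0.294,
    "g_K1": 5.405,
    "g_bNa": 2.9e-4,
    "g_bCa": 5.92e-4,
    "g_pCa": 0.1238,
    "g_pK": 0.0146,
    "P_NaK": 2.724,
    "k_NaCa": 1000.0,
    "K_mNai": 87.5,
    "K_mCa": 1.38,
    "k_sat": 0.1,
    "alpha_NaCa": 2.5,
    "gamma_NaCa": 0.35,
    "K_mK": 1.0,
    "K_mNa": 40.0,
    "K_pCa": 0.0005,
    "p_KNa": 0.03,
    "V_maxup": 0.006375,
    "K_up": 0.00025,
    "V_rel": 0.102,
    "V_leak": 3.6e-4,
    "V_xfer": 0.0038,
    "k1_prime": 0.15,
    "k2_prime": 0.045,
    "k3": 0.06,
    "k4": 0.005,
    "EC50_SR": 1.5,
    "max_SR": 2.5,
    "min_SR": 1.0,
    "Buf_c": 0.2,
    "K_bufc": 0.001,
    "Buf_sr": 10.0,
    "K_bufsr": 0.3,
    "Buf_ss": 0.4,
    "K_bufss": 0.00025,
    "Na_o": 140.0,
    "K_o": 5.4,
    "Ca_o": 2.0,
    "Cm": 0.185,
    "V_c": 0.016404,
    "V_sr": 0.001094,
    "V_ss": 5.468e-5,
    "tau_hL": 200.0,
}

VARIANT_NAMES = ("GE", "PKP2", "FIBROSIS")

# PKP2 remodeling: multiplicative scalings of the GE baseline plus three
# absolute calcium-handling constants.
_PKP2_SCALE = {"g_Na": 0.30, "g_CaL": 0.50, "g_bCa": 5.0, "k_NaCa": 0.80}
_PKP2_ABSOLUTE = {"V_rel": 0.0816, "V_leak": 2.88e-4, "K_bufsr": 0.18}

# Diffuse-fibrosis remodeling (all multiplicative).
_FIBROSIS_SCALE = {
    "g_NaL": 2.07,
    "g_CaL": 1.19,
    "g_Kr": 0.66,
    "g_Ks": 0.73,
    "g_to": 0.15,
    "g_K1": 0.85,
    "k_NaCa": 1.34,
    "V_maxup": 0.57,
}

# ---------------------------------------------------------------------------
# State vector layout
STATE_NAMES: tuple[str, ...] = (
    "V", "m", "h", "j", "d", "f", "f2", "fcass", "xr1", "xr2", "xs",
    "r", "s", "mL", "hL", "Rq", "Nai", "Ki", "Cai", "CaSS", "CaSR", "t",
)
NS = len(STATE_NAMES)
_GATE_IDX = tuple(range(1, 16))  # m .. Rq inclusive

# Approximate 1 Hz paced state of the epicardial model; exact fixed points are
# obtained with relax_to_rest().
_INITIAL_STATE = {
    "V": -85.23, "m": 0.00172, "h": 0.7444, "j": 0.7045,
    "d": 3.373e-5, "f": 0.7888, "f2": 0.9755, "fcass": 0.9953,
    "xr1": 0.00621, "xr2": 0.4712, "xs": 0.0095,
    "r": 2.42e-8, "s": 0.999998, "mL": 0.0, "hL": 0.6,
    "Rq": 0.9073, "Nai": 8.604, "Ki": 136.89,
    "Cai": 0.000126, "CaSS": 0.00036, "CaSR": 3.64, "t": 0.0,
}

CURRENT_NAMES: tuple[str, ...] = (
    "I_Na", "I_NaL", "I_CaL", "I_Kr", "I_Ks", "I_to", "I_K1",
    "I_NaCa", "I_NaK", "I_bNa", "I_bCa", "I_pCa", "I_pK",
    "I_rel", "I_leak", "I_up", "I_xfer",
)
N_MEMBRANE_CURRENTS = 13


class ParameterError(ValueError):
    """Raised when a parameter file or variant request is invalid."""


@dataclass(frozen=True)
class VariantParameterSet:
    """A complete, named ionic parameter set.

    ``values`` holds every baseline constant, with the variant's scalings
    already applied.  Use :func:`make_variant` to derive PKP2 / FIBROSIS sets
    from a GE baseline.
    """

    name: str
    values: dict[str, float] = field(default_factory=lambda: dict(BASELINE_PARAMS))

    def __post_init__(self) -> None:
        missing = [k for k in PARAM_NAMES if k not in self.values]
        if missing:
            raise ParameterError(f"missing parameters: {missing}")
        unknown = [k for k in self.values if k not in PARAM_NAMES]
        if unknown:
            raise ParameterError(f"unknown parameters: {unknown}")
        for k, v in self.values.items():
            if not math.isfinite(v):
                raise ParameterError(f"parameter {k!r} is not finite: {v}")
            if v < 0:
                raise ParameterError(f"parameter {k!r} is negative: {v}")

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def asarray(self) -> np.ndarray:
        return np.array([self.values[k] for k in PARAM_NAMES], dtype=np.float64)

    def with_overrides(self, **overrides: float) -> "VariantParameterSet":
        vals = dict(self.values)
        for k, v in overrides.items():
            if k not in PARAM_NAMES:
                raise ParameterError(f"unknown parameter {k!r}")
            vals[k] = float(v)
        return VariantParameterSet(self.name, vals)

    def to_file(self, path: str | Path) -> None:
        payload = {"name": self.name, **self.values}
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=False))


@dataclass
class CellState:
    """Full ionic state of one myocyte (see STATE_NAMES for units)."""

    values: np.ndarray

    @classmethod
    def initial(cls) -> "CellState":
        return cls(np.array([_INITIAL_STATE[k] for k in STATE_NAMES], dtype=np.float64))

    def copy(self) -> "CellState":
        return CellState(self.values.copy())

    def __getattr__(self, name: str):
        try:
            return self.values[STATE_NAMES.index(name)]
        except ValueError:
            raise AttributeError(name) from None

    def as_dict(self) -> dict[str, float]:
        return dict(zip(STATE_NAMES, self.values.tolist()))

    def validate(self) -> None:
        if not np.all(np.isfinite(self.values)):
            bad = [n for n, v in zip(STATE_NAMES, self.values) if not math.isfinite(v)]
            raise ValueError(f"non-finite state variables: {bad}")
        gates = self.values[list(_GATE_IDX)]
        if np.any(gates < -1e-12) or np.any(gates > 1 + 1e-12):
            bad = [STATE_NAMES[i] for i in _GATE_IDX
                   if not -1e-12 <= self.values[i] <= 1 + 1e-12]
            raise ValueError(f"gate variables outside [0, 1]: {bad}")
        conc = self.values[16:21]
        if np.any(conc <= 0):
            bad = [STATE_NAMES[16 + i] for i in range(5) if conc[i] <= 0]
            raise ValueError(f"non-positive concentrations: {bad}")


@dataclass(frozen=True)
class CurrentSet:
    """All membrane current densities (pA/pF) and SR calcium fluxes (mM/ms)."""

    values: dict[str, float]

    def __getattr__(self, name: str):
        try:
            return self.values[name]
        except KeyError:
            raise AttributeError(name) from None

    @property
    def I_total(self) -> float:
        """Signed sum of the membrane currents (excludes SR fluxes)."""
        return sum(self.values[k] for k in CURRENT_NAMES[:N_MEMBRANE_CURRENTS])


# ---------------------------------------------------------------------------
# Loading / variants

def load_baseline(param_file: str | Path) -> VariantParameterSet:
    """Load the GE (baseline) parameter set from a flat JSON file.

    The file must contain every constant in PARAM_NAMES (an optional "name"
    key is honored); unknown or non-finite entries raise ParameterError.
    """
    try:
        raw = json.loads(Path(param_file).read_text())
    except json.JSONDecodeError as exc:
        raise ParameterError(f"cannot parse {param_file}: {exc}") from exc
    name = raw.pop("name", "GE")
    values = {}
    for k, v in raw.items():
        if k not in PARAM_NAMES:
            raise ParameterError(f"unknown parameter {k!r} in {param_file}")
        if not isinstance(v, (int, float)) or not math.isfinite(v):
            raise ParameterError(f"parameter {k!r} is not a finite number: {v!r}")
        values[k] = float(v)
    missing = [k for k in PARAM_NAMES if k not in values]
    if missing:
        raise ParameterError(f"missing parameters in {param_file}: {missing}")
    return VariantParameterSet(name, values)


def baseline_ge() -> VariantParameterSet:
    """The packaged GE baseline (TT2006 epicardial + late sodium current)."""
    return VariantParameterSet("GE", dict(BASELINE_PARAMS))


def make_variant(base: VariantParameterSet, name: str) -> VariantParameterSet:
    """Derive a named variant (GE | PKP2 | FIBROSIS) from a GE baseline."""
    if name not in VARIANT_NAMES:
        raise ParameterError(f"unknown variant {name!r}; expected one of {VARIANT_NAMES}")
    vals = dict(base.values)
    if name == "PKP2":
        for k, s in _PKP2_SCALE.items():
            vals[k] *= s
        vals.update(_PKP2_ABSOLUTE)
    elif name == "FIBROSIS":
        for k, s in _FIBROSIS_SCALE.items():
            vals[k] *= s
    return VariantParameterSet(name, vals)


# ---------------------------------------------------------------------------
# Numba kernels.  P indexing follows PARAM_NAMES; S indexing follows
# STATE_NAMES.  The index constants below must stay in sync with the tuples.

iV, im, ih, ij, id_, if_, if2, ifcass, ixr1, ixr2, ixs, ir, is_, imL, ihL, iRq, \
    iNai, iKi, iCai, iCaSS, iCaSR, it_ = range(NS)

(pg_Na, pg_NaL, pg_CaL, pg_Kr, pg_Ks, pg_to, pg_K1, pg_bNa, pg_bCa, pg_pCa,
 pg_pK, pP_NaK, pk_NaCa, pK_mNai, pK_mCa, pk_sat, palpha, pgamma, pK_mK,
 pK_mNa, pK_pCa, pp_KNa, pV_maxup, pK_up, pV_rel, pV_leak, pV_xfer, pk1p,
 pk2p, pk3, pk4, pEC50, pmaxSR, pminSR, pBuf_c, pK_bufc, pBuf_sr, pK_bufsr,
 pBuf_ss, pK_bufss, pNa_o, pK_o, pCa_o, pCm, pV_c, pV_sr, pV_ss, ptau_hL) = \
    range(len(PARAM_NAMES))

NP = len(PARAM_NAMES)


@njit(cache=True)
def _currents(S, P, out):
    """Fill `out` (len 17) with membrane currents and SR fluxes."""
    V = S[iV]
    Nai, Ki, Cai, CaSS, CaSR = S[iNai], S[iKi], S[iCai], S[iCaSS], S[iCaSR]

    ENa = RTONF * math.log(P[pNa_o] / Nai)
    EK = RTONF * math.log(P[pK_o] / Ki)
    EKs = RTONF * math.log((P[pK_o] + P[pp_KNa] * P[pNa_o]) /
                           (Ki + P[pp_KNa] * Nai))
    ECa = 0.5 * RTONF * math.log(P[pCa_o] / Cai)

    INa = P[pg_Na] * S[im] ** 3 * S[ih] * S[ij] * (V - ENa)
    INaL = P[pg_NaL] * S[imL] * S[ihL] * (V - ENa)

    vf = (V - 15.0) * FARADAY / (R_GAS * TEMP)
    if abs(vf) < 1e-7:
        coeff = 2.0 * FARADAY
    else:
        coeff = 4.0 * (V - 15.0) * FARADAY * FARADAY / (R_GAS * TEMP) / \
            (math.exp(2.0 * vf) - 1.0)
    ICaL = P[pg_CaL] * S[id_] * S[if_] * S[if2] * S[ifcass] * coeff * \
        (0.25 * CaSS * math.exp(2.0 * vf) - P[pCa_o])

    IKr = P[pg_Kr] * math.sqrt(P[pK_o] / 5.4) * S[ixr1] * S[ixr2] * (V - EK)
    IKs = P[pg_Ks] * S[ixs] * S[ixs] * (V - EKs)
    Ito = P[pg_to] * S[ir] * S[is_] * (V - EK)

    u = V - EK
    aK1 = 0.1 / (1.0 + math.exp(0.06 * (u - 200.0)))
    bK1 = (3.0 * math.exp(0.0002 * (u + 100.0)) + math.exp(0.1 * (u - 10.0))) / \
        (1.0 + math.exp(-0.5 * u))
    IK1 = P[pg_K1] * math.sqrt(P[pK_o] / 5.4) * aK1 / (aK1 + bK1) * u

    vfrt = V * FARADAY / (R_GAS * TEMP)
    e1 = math.exp(P[pgamma] * vfrt)
    e2 = math.exp((P[pgamma] - 1.0) * vfrt)
    INaCa = P[pk_NaCa] * \
        (e1 * Nai ** 3 * P[pCa_o] - e2 * P[pNa_o] ** 3 * Cai * P[palpha]) / \
        ((P[pK_mNai] ** 3 + P[pNa_o] ** 3) * (P[pK_mCa] + P[pCa_o]) *
         (1.0 + P[pk_sat] * e2))

    INaK = P[pP_NaK] * P[pK_o] * Nai / \
        ((P[pK_o] + P[pK_mK]) * (Nai + P[pK_mNa])) / \
        (1.0 + 0.1245 * math.exp(-0.1 * vfrt) + 0.0353 * math.exp(-vfrt))

    IbNa = P[pg_bNa] * (V - ENa)
    IbCa = P[pg_bCa] * (V - ECa)
    IpCa = P[pg_pCa] * Cai / (Cai + P[pK_pCa])
    IpK = P[pg_pK] * (V - EK) / (1.0 + math.exp((25.0 - V) / 5.98))

    # SR / subspace calcium fluxes
    kcasr = P[pmaxSR] - (P[pmaxSR] - P[pminSR]) / \
        (1.0 + (P[pEC50] / CaSR) ** 2)
    k1 = P[pk1p] / kcasr
    O = k1 * CaSS * CaSS * S[iRq] / (P[pk3] + k1 * CaSS * CaSS)
    Irel = P[pV_rel] * O * (CaSR - CaSS)
    Ileak = P[pV_leak] * (CaSR - Cai)
    Iup = P[pV_maxup] / (1.0 + (P[pK_up] / Cai) ** 2)
    Ixfer = P[pV_xfer] * (CaSS - Cai)

    out[0] = INa
    out[1] = INaL
    out[2] = ICaL
    out[3] = IKr
    out[4] = IKs
    out[5] = Ito
    out[6] = IK1
    out[7] = INaCa
    out[8] = INaK
    out[9] = IbNa
    out[10] = IbCa
    out[11] = IpCa
    out[12] = IpK
    out[13] = Irel
    out[14] = Ileak
    out[15] = Iup
    out[16] = Ixfer


@njit(cache=True)
def _gate_rates(V, P, inf, tau):
    """Voltage-gate steady states and time constants (order: m..hL)."""
    # I_Na gates
    inf[0] = 1.0 / (1.0 + math.exp((-56.86 - V) / 9.03)) ** 2
    am = 1.0 / (1.0 + math.exp((-60.0 - V) / 5.0))
    bm = 0.1 / (1.0 + math.exp((V + 35.0) / 5.0)) + \
        0.10 / (1.0 + math.exp((V - 50.0) / 200.0))
    tau[0] = am * bm

    inf[1] = 1.0 / (1.0 + math.exp((V + 71.55) / 7.43)) ** 2
    if V >= -40.0:
        ah = 0.0
        bh = 0.77 / (0.13 * (1.0 + math.exp(-(V + 10.66) / 11.1)))
    else:
        ah = 0.057 * math.exp(-(V + 80.0) / 6.8)
        bh = 2.7 * math.exp(0.079 * V) + 3.1e5 * math.exp(0.3485 * V)
    tau[1] = 1.0 / (ah + bh)

    inf[2] = inf[1]
    if V >= -40.0:
        aj = 0.0
        bj = 0.6 * math.exp(0.057 * V) / (1.0 + math.exp(-0.1 * (V + 32.0)))
    else:
        aj = (-2.5428e4 * math.exp(0.2444 * V) - 6.948e-6 *
              math.exp(-0.04391 * V)) * (V + 37.78) / \
            (1.0 + math.exp(0.311 * (V + 79.23)))
        bj = 0.02424 * math.exp(-0.01052 * V) / \
            (1.0 + math.exp(-0.1378 * (V + 40.14)))
    tau[2] = 1.0 / (aj + bj)

    # I_CaL voltage gates
    inf[3] = 1.0 / (1.0 + math.exp((-8.0 - V) / 7.5))
    ad = 1.4 / (1.0 + math.exp((-35.0 - V) / 13.0)) + 0.25
    bd = 1.4 / (1.0 + math.exp((V + 5.0) / 5.0))
    gd = 1.0 / (1.0 + math.exp((50.0 - V) / 20.0))
    tau[3] = ad * bd + gd

    inf[4] = 1.0 / (1.0 + math.exp((V + 20.0) / 7.0))
    tau[4] = 1102.5 * math.exp(-((V + 27.0) ** 2) / 225.0) + \
        200.0 / (1.0 + math.exp((13.0 - V) / 10.0)) + \
        180.0 / (1.0 + math.exp((V + 30.0) / 10.0)) + 20.0

    inf[5] = 0.67 / (1.0 + math.exp((V + 35.0) / 7.0)) + 0.33
    tau[5] = 562.0 * math.exp(-((V + 27.0) ** 2) / 240.0) + \
        31.0 / (1.0 + math.exp((25.0 - V) / 10.0)) + \
        80.0 / (1.0 + math.exp((V + 30.0) / 10.0))

    # I_Kr
    inf[6] = 1.0 / (1.0 + math.exp((-26.0 - V) / 7.0))
    axr1 = 450.0 / (1.0 + math.exp((-45.0 - V) / 10.0))
    bxr1 = 6.0 / (1.0 + math.exp((V + 30.0) / 11.5))
    tau[6] = axr1 * bxr1

    inf[7] = 1.0 / (1.0 + math.exp((V + 88.0) / 24.0))
    axr2 = 3.0 / (1.0 + math.exp((-60.0 - V) / 20.0))
    bxr2 = 1.12 / (1.0 + math.exp((V - 60.0) / 20.0))
    tau[7] = axr2 * bxr2

    # I_Ks
    inf[8] = 1.0 / (1.0 + math.exp((-5.0 - V) / 14.0))
    axs = 1400.0 / math.sqrt(1.0 + math.exp((5.0 - V) / 6.0))
    bxs = 1.0 / (1.0 + math.exp((V - 35.0) / 15.0))
    tau[8] = axs * bxs + 80.0

    # I_to (epicardial phenotype)
    inf[9] = 1.0 / (1.0 + math.exp((20.0 - V) / 6.0))
    tau[9] = 9.5 * math.exp(-((V + 40.0) ** 2) / 1800.0) + 0.8

    inf[10] = 1.0 / (1.0 + math.exp((V + 20.0) / 5.0))
    tau[10] = 85.0 * math.exp(-((V + 45.0) ** 2) / 320.0) + \
        5.0 / (1.0 + math.exp((V - 20.0) / 5.0)) + 3.0

    # I_NaL (O'Hara–Rudy-style)
    inf[11] = 1.0 / (1.0 + math.exp(-(V + 42.85) / 5.264))
    tau[11] = 1.0 / (6.765 * math.exp((V + 11.64) / 34.77) +
                     8.552 * math.exp(-(V + 77.42) / 5.955))
    inf[12] = 1.0 / (1.0 + math.exp((V + 87.61) / 7.488))
    tau[12] = P[ptau_hL]


_VGATE_STATE_IDX = np.array(
    [im, ih, ij, id_, if_, if2, ixr1, ixr2, ixs, ir, is_, imL, ihL],
    dtype=np.int64)


@njit(cache=True)
def _step_inplace(S, P, dt, istim, cur, inf, tau):
    """Advance the state by one dt.  cur/inf/tau are scratch arrays."""
    _currents(S, P, cur)
    V = S[iV]
    CaSS = S[iCaSS]
    Cai = S[iCai]
    CaSR = S[iCaSR]

    _gate_rates(V, P, inf, tau)
    for k in range(13):
        si = _VGATE_STATE_IDX[k]
        S[si] = inf[k] + (S[si] - inf[k]) * math.exp(-dt / tau[k])

    # CaSS-dependent gates, exact exponential update
    fcass_inf = 0.6 / (1.0 + (CaSS / 0.05) ** 2) + 0.4
    tau_fcass = 80.0 / (1.0 + (CaSS / 0.05) ** 2) + 2.0
    S[ifcass] = fcass_inf + (S[ifcass] - fcass_inf) * math.exp(-dt / tau_fcass)

    kcasr = P[pmaxSR] - (P[pmaxSR] - P[pminSR]) / (1.0 + (P[pEC50] / CaSR) ** 2)
    k2 = P[pk2p] * kcasr
    rq_rate = k2 * CaSS + P[pk4]
    rq_inf = P[pk4] / rq_rate
    S[iRq] = rq_inf + (S[iRq] - rq_inf) * math.exp(-dt * rq_rate)

    INa, INaL, ICaL, IKr, IKs, Ito, IK1 = cur[0], cur[1], cur[2], cur[3], cur[4], cur[5], cur[6]
    INaCa, INaK, IbNa, IbCa, IpCa, IpK = cur[7], cur[8], cur[9], cur[10], cur[11], cur[12]
    Irel, Ileak, Iup, Ixfer = cur[13], cur[14], cur[15], cur[16]

    Cm, Vc, Vsr, Vss = P[pCm], P[pV_c], P[pV_sr], P[pV_ss]
    inv2F = 1.0 / (2.0 * FARADAY)

    bufc = 1.0 / (1.0 + P[pBuf_c] * P[pK_bufc] / (Cai + P[pK_bufc]) ** 2)
    dCai = bufc * ((-(IbCa + IpCa - 2.0 * INaCa) * Cm * inv2F / Vc) +
                   (Ileak - Iup) * Vsr / Vc + Ixfer)
    bufsr = 1.0 / (1.0 + P[pBuf_sr] * P[pK_bufsr] / (CaSR + P[pK_bufsr]) ** 2)
    dCaSR = bufsr * (Iup - Irel - Ileak)
    bufss = 1.0 / (1.0 + P[pBuf_ss] * P[pK_bufss] / (CaSS + P[pK_bufss]) ** 2)
    dCaSS = bufss * (-Ixfer * Vc / Vss + Irel * Vsr / Vss -
                     ICaL * Cm * inv2F / Vss)

    dNai = -(INa + INaL + IbNa + 3.0 * INaK + 3.0 * INaCa) * Cm / (Vc * FARADAY)
    dKi = -(IK1 + Ito + IKr + IKs - 2.0 * INaK + IpK + istim) * Cm / (Vc * FARADAY)

    Itot = INa + INaL + ICaL + IKr + IKs + Ito + IK1 + INaCa + INaK + \
        IbNa + IbCa + IpCa + IpK

    S[iCai] = Cai + dt * dCai
    S[iCaSR] = CaSR + dt * dCaSR
    S[iCaSS] = CaSS + dt * dCaSS
    S[iNai] += dt * dNai
    S[iKi] += dt * dKi
    S[iV] = V - dt * (Itot + istim)
    S[it_] += dt


@njit(cache=True)
def _run_cell(S, P, dt, n_steps, stim_on, stim_off, stim_amp,
              sample_every_steps, outV, outCai, outI):
    """Run a single cell with a rectangular stimulus schedule.

    stim_on/stim_off/stim_amp: parallel arrays of stimulus windows (absolute
    time, ms).  Samples V, Cai and all currents every sample_every_steps
    steps into the out arrays (row 0 = initial condition).
    """
    cur = np.empty(17)
    inf = np.empty(13)
    tau = np.empty(13)
    n_stim = stim_on.shape[0]
    ns = 0
    _currents(S, P, cur)
    outV[0] = S[iV]
    outCai[0] = S[iCai]
    for c in range(17):
        outI[0, c] = cur[c]
    for step_i in range(n_steps):
        t = S[it_]
        istim = 0.0
        for k in range(n_stim):
            if stim_on[k] <= t < stim_off[k]:
                istim += stim_amp[k]
        _step_inplace(S, P, dt, istim, cur, inf, tau)
        if not math.isfinite(S[iV]) or abs(S[iV]) > 300.0:
            return -S[it_]  # signal blow-up with negative timestamp
        if (step_i + 1) % sample_every_steps == 0:
            ns += 1
            if ns < outV.shape[0]:
                _currents(S, P, cur)
                outV[ns] = S[iV]
                outCai[ns] = S[iCai]
                for c in range(17):
                    outI[ns, c] = cur[c]
    return S[it_]


# ---------------------------------------------------------------------------
# Public wrappers

def compute_currents(state: CellState, params: VariantParameterSet) -> CurrentSet:
    """All membrane current densities and SR fluxes at the given state."""
    state.validate()
    out = np.empty(17)
    _currents(state.values, params.asarray(), out)
    return CurrentSet(dict(zip(CURRENT_NAMES, out.tolist())))


def step(state: CellState, params: VariantParameterSet, dt: float,
         I_stim: float = 0.0) -> CellState:
    """One integration step (Rush–Larsen gates, forward-Euler V and ions)."""
    if not 0.0 < dt <= 0.05:
        raise ValueError(f"dt must be in (0, 0.05] ms, got {dt}")
    new = state.copy()
    cur = np.empty(17)
    inf = np.empty(13)
    tau = np.empty(13)
    _step_inplace(new.values, params.asarray(), dt, I_stim, cur, inf, tau)
    if not np.isfinite(new.values[iV]):
        raise FloatingPointError(
            f"state became non-finite at t={state.values[it_]:.3f} ms")
    return new


@dataclass
class CellTrace:
    """Sampled single-cell recording."""

    t: np.ndarray       # ms
    V: np.ndarray       # mV
    Cai: np.ndarray     # mM
    currents: np.ndarray  # (n_samples, 17), CURRENT_NAMES order

    def current(self, name: str) -> np.ndarray:
        return self.currents[:, CURRENT_NAMES.index(name)]


def run_cell(state: CellState, params: VariantParameterSet, t_end: float,
             stimuli: list[tuple[float, float, float]] | None = None,
             dt: float = 0.02, sample_every: float = 0.1) -> tuple[CellTrace, CellState]:
    """Integrate a single cell for t_end ms.

    stimuli: list of (t_on, duration, amplitude) rectangular current pulses
    in pA/pF (depolarizing pulses are negative, e.g. -52).
    Returns the sampled trace and the final state.
    """
    if stimuli is None:
        stimuli = []
    n_steps = int(round(t_end / dt))
    sample_steps = max(1, int(round(sample_every / dt)))
    n_samples = n_steps // sample_steps + 1
    outV = np.empty(n_samples)
    outCai = np.empty(n_samples)
    outI = np.empty((n_samples, 17))
    stim_on = np.array([s[0] for s in stimuli], dtype=np.float64)
    stim_off = np.array([s[0] + s[1] for s in stimuli], dtype=np.float64)
    stim_amp = np.array([s[2] for s in stimuli], dtype=np.float64)
    new = state.copy()
    t0 = new.values[it_]
    t_final = _run_cell(new.values, params.asarray(), dt, n_steps,
                        stim_on, stim_off, stim_amp, sample_steps,
                        outV, outCai, outI)
    if t_final < 0:
        raise FloatingPointError(f"simulation blew up at t={-t_final:.3f} ms")
    t = t0 + np.arange(n_samples) * sample_steps * dt
    return CellTrace(t, outV, outCai, outI), new


def relax_to_rest(params: VariantParameterSet, t_relax: float = 10_000.0,
                  dt: float = 0.02) -> CellState:
    """Let the unstimulated model settle to its resting fixed point."""
    state = CellState.initial()
    _, final = run_cell(state, params, t_relax, stimuli=[], dt=dt,
                        sample_every=t_relax)
    final.values[it_] = 0.0
    return final
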