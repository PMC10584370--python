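"""2D anisotropic monodomain reaction-diffusion solver.

The transmembrane potential on a regular 2D sheet obeys

    dV/dt = div( D grad V ) - I_ion(state)/Cm_ion - I_stim

with D the 2x2 conductivity-derived diffusion tensor, D = sigma / (beta * Cm),
rotated per-node by the local fiber angle.  Tissue heterogeneity enters
through a label map: NORMAL and FIBROSIS nodes carry an ionic model variant
each (e.g. GE or PKP2 myocardium, Coppini-remodeled fibrotic myocardium);
SCAR and VOID nodes are non-conductive and excluded from the solved system,
which yields no-flux internal boundaries.  Outer boundaries are no-flux.

Discretization: 9-point finite-difference stencil (harmonic-mean face
conductivities for the axial terms, centered cross-derivative terms for
fiber rotation), operator-split forward-Euler diffusion plus the ionic
reaction step.  The ionic reaction uses voltage lookup tables for all gate
rates and voltage-dependent current coefficients, which makes the kernel
fast enough for desk-scale reentry studies; the tables reproduce the exact
single-cell kernel to interpolation accuracy (see the zero-diffusion test).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from . import ionic
from .ionic import (
    NS, iV, ifcass, iRq, iNai, iKi, iCai, iCaSS, iCaSR, it_,
    pg_Na, pg_NaL, pg_CaL, pg_Kr, pg_Ks, pg_to, pg_K1, pg_bNa, pg_bCa,
    pg_pCa, pg_pK, pP_NaK, pk_NaCa, pK_mNai, pK_mCa, pk_sat, palpha, pgamma,
    pK_mK, pK_mNa, pK_pCa, pp_KNa, pV_maxup, pK_up, pV_rel, pV_leak,
    pV_xfer, pk1p, pk2p, pk3, pk4, pEC50, pmaxSR, pminSR, pBuf_c, pK_bufc,
    pBuf_sr, pK_bufsr, pBuf_ss, pK_bufss, pNa_o, pK_o, pCa_o, pCm, pV_c,
    pV_sr, pV_ss,
    RTONF, FARADAY, R_GAS, TEMP,
    _gate_rates, _VGATE_STATE_IDX,
    VariantParameterSet,
)

__all__ = [
    "NORMAL", "FIBROSIS", "SCAR", "VOID",
    "TissueGrid", "MonodomainConfig", "Stimulus", "TissueRecord",
    "ActivationMap", "simulate", "activation_map", "conduction_velocity",
]

# tissue labels
VOID = 0
NORMAL = 1
FIBROSIS = 2
SCAR = 3

REGION_NAMES = (
    "basal-anterior", "basal-lateral", "basal-posterior",
    "mid-anterior", "mid-lateral", "mid-posterior",
    "apical-anterior", "apical-lateral", "apical-posterior",
)


class SimulationError(RuntimeError):
    pass


@dataclass
class TissueGrid:
    """2D tissue sheet: labels, fiber angles, AHA-analog regions, pacing sites.

    labels: int array (ny, nx) with values NORMAL/FIBROSIS/SCAR/VOID.
    fiber_angle: radians, same shape.  dx: node spacing in micrometers.
    region_map: int array (ny, nx), values 1..9 (0 = unassigned); rows of the
    sheet map to basal/mid/apical thirds, columns to anterior/lateral/
    posterior thirds (an RV free-wall analog of the AHA segments).
    pacing_sites: name -> (row, col) node.
    """

    labels: np.ndarray
    fiber_angle: np.ndarray
    dx: float
    region_map: np.ndarray | None = None
    pacing_sites: dict = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.fiber_angle = np.asarray(self.fiber_angle, dtype=np.float64)
        if self.labels.shape != self.fiber_angle.shape:
            raise ValueError("labels and fiber_angle shapes differ")
        if self.dx <= 0:
            raise ValueError("dx must be positive")
        if self.region_map is not None:
            self.region_map = np.asarray(self.region_map, dtype=np.int8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @classmethod
    def uniform(cls, ny: int, nx: int, dx: float = 250.0,
                fiber_angle: float = 0.0, with_regions: bool = True
                ) -> "TissueGrid":
        labels = np.full((ny, nx), NORMAL, dtype=np.int8)
        fa = np.full((ny, nx), fiber_angle, dtype=np.float64)
        g = cls(labels, fa, dx)
        if with_regions:
            g.assign_regions()
            g.default_pacing_sites()
        return g

    def assign_regions(self) -> None:
        """3x3 tiling: row thirds = basal (bottom) / mid / apical (top),
        column thirds = anterior / lateral / posterior (left to right)."""
        ny, nx = self.shape
        rm = np.zeros((ny, nx), dtype=np.int8)
        for iy in range(ny):
            band = min(2, 3 * (ny - 1 - iy) // ny)  # 0 basal at bottom
            for ix in range(nx):
                col = min(2, 3 * ix // nx)
                rm[iy, ix] = 1 + 3 * band + col
        self.region_map = rm

    def region_name(self, region_id: int) -> str:
        return REGION_NAMES[region_id - 1]

    def default_pacing_sites(self) -> None:
        """One pacing node at the center of each of the 9 regions (moved to
        the nearest conducting node if the center is scar/void)."""
        if self.region_map is None:
            self.assign_regions()
        sites = {}
        conducting = (self.labels == NORMAL) | (self.labels == FIBROSIS)
        ys, xs = np.nonzero(conducting)
        for rid in range(1, 10):
            ry, rx = np.nonzero(self.region_map == rid)
            if len(ry) == 0:
                continue
            cy, cx = ry.mean(), rx.mean()
            if conducting[int(round(cy)), int(round(cx))]:
                sites[REGION_NAMES[rid - 1]] = (int(round(cy)), int(round(cx)))
            else:
                d2 = (ys - cy) ** 2 + (xs - cx) ** 2
                k = int(np.argmin(d2))
                sites[REGION_NAMES[rid - 1]] = (int(ys[k]), int(xs[k]))
        self.pacing_sites = sites

    def site_nodes(self, site: str | tuple[int, int], radius_um: float
                   ) -> np.ndarray:
        """Conducting (row, col) nodes within radius_um of a pacing site."""
        if isinstance(site, str):
            if site not in self.pacing_sites:
                raise KeyError(f"unknown pacing site {site!r}")
            cy, cx = self.pacing_sites[site]
        else:
            cy, cx = site
        r = max(1.0, radius_um / self.dx)
        ny, nx = self.shape
        y0, y1 = max(0, int(cy - r)), min(ny, int(cy + r) + 1)
        x0, x1 = max(0, int(cx - r)), min(nx, int(cx + r) + 1)
        out = []
        for iy in range(y0, y1):
            for ix in range(x0, x1):
                if (iy - cy) ** 2 + (ix - cx) ** 2 <= r * r and \
                        self.labels[iy, ix] in (NORMAL, FIBROSIS):
                    out.append((iy, ix))
        if not out:
            raise SimulationError(f"no conducting nodes at site {site!r}")
        return np.array(out, dtype=np.int64)


@dataclass(frozen=True)
class MonodomainConfig:
    """Solver configuration.

    sigma_l / sigma_t: longitudinal / transverse monodomain conductivities
    (S/m); beta: surface-to-volume ratio (1/cm); Cm: membrane capacitance
    (uF/cm^2); dt in ms; fibrosis_sigma_scale multiplies the conductivity
    tensor inside FIBROSIS-labeled nodes (1.0 = cell-level remodeling only).
    """

    sigma_l: float = 0.171  # S/m; default tuned for ~65 cm/s GE longitudinal CV
    sigma_t: float = 0.0428  # S/m; ~29 cm/s transverse
    beta: float = 1400.0    # 1/cm
    Cm: float = 1.0         # uF/cm^2
    dt: float = 0.05        # ms
    fibrosis_sigma_scale: float = 1.0

    def __post_init__(self):
        if not (self.sigma_l >= self.sigma_t > 0):
            raise ValueError("need sigma_l >= sigma_t > 0")

    def diffusivity(self) -> tuple[float, float]:
        """(D_l, D_t) in cm^2/ms."""
        f = 10.0 / (self.beta * self.Cm)  # S/m -> mS/cm, then /(beta Cm)
        return self.sigma_l * f, self.sigma_t * f

    def check_stability(self, dx_um: float) -> None:
        dx_cm = dx_um * 1e-4
        d_max = max(self.diffusivity())
        # spectral bound of the (up to 6th-order) 2D stencil
        dt_max = 0.165 * dx_cm * dx_cm / d_max
        if self.dt > dt_max:
            raise ValueError(
                f"dt={self.dt} ms violates diffusion stability bound "
                f"{dt_max:.4f} ms at dx={dx_um} um")


@dataclass(frozen=True)
class Stimulus:
    """Transmembrane current over a disk at a pacing site."""

    site: str | tuple[int, int]
    t_on: float                 # ms
    duration: float = 2.0       # ms
    amplitude: float = -150.0   # pA/pF
    radius_um: float = 1250.0


# ---------------------------------------------------------------------------
# Lookup tables

V_MIN, V_MAX, DV = -120.0, 400.0, 0.025
U_MIN, U_MAX = -60.0, 520.0  # V - EK grid for IK1

N_GATES = 13
# LUT columns: [0:13] gate_inf, [13:26] gate rlfac, 26 ical_coeff,
# 27 ical_e2, 28 ncx_e1, 29 ncx_e2, 30 nak_rec, 31 ipk_rec
NCOL = 32

_lut_cache: dict[float, tuple[np.ndarray, np.ndarray]] = {}


@njit(cache=True)
def _fill_lut(lut, k1lut, dt, tau_hL):
    nv = lut.shape[0]
    inf = np.empty(13)
    tau = np.empty(13)
    P = np.zeros(1)  # placeholder; only tau_hL is read via closure-free arg
    for iv in range(nv):
        V = V_MIN + iv * DV
        _gate_rates_lut(V, tau_hL, inf, tau)
        for k in range(13):
            lut[iv, k] = inf[k]
            lut[iv, 13 + k] = math.exp(-dt / tau[k])
        vf = (V - 15.0) * FARADAY / (R_GAS * TEMP)
        if abs(vf) < 1e-7:
            coeff = 2.0 * FARADAY
        else:
            coeff = 4.0 * (V - 15.0) * FARADAY * FARADAY / (R_GAS * TEMP) / \
                (math.exp(2.0 * vf) - 1.0)
        lut[iv, 26] = coeff
        lut[iv, 27] = math.exp(2.0 * vf)
        vfrt = V * FARADAY / (R_GAS * TEMP)
        lut[iv, 28] = math.exp(0.35 * vfrt)
        lut[iv, 29] = math.exp(-0.65 * vfrt)
        lut[iv, 30] = 1.0 / (1.0 + 0.1245 * math.exp(-0.1 * vfrt) +
                             0.0353 * math.exp(-vfrt))
        lut[iv, 31] = 1.0 / (1.0 + math.exp((25.0 - V) / 5.98))
    nu = k1lut.shape[0]
    for iu in range(nu):
        u = U_MIN + iu * DV
        aK1 = 0.1 / (1.0 + math.exp(0.06 * (u - 200.0)))
        bK1 = (3.0 * math.exp(0.0002 * (u + 100.0)) +
               math.exp(0.1 * (u - 10.0))) / (1.0 + math.exp(-0.5 * u))
        k1lut[iu] = aK1 / (aK1 + bK1) * u


@njit(cache=True)
def _gate_rates_lut(V, tau_hL, inf, tau):
    # same rates as ionic._gate_rates but with tau_hL passed explicitly
    P = np.empty(48)
    P[47] = tau_hL
    _gate_rates(V, P, inf, tau)


def build_lut(dt: float, tau_hL: float = ionic.BASELINE_PARAMS["tau_hL"]
              ) -> tuple[np.ndarray, np.ndarray]:
    """Voltage lookup tables for the tissue kernel at a fixed dt."""
    key = (round(dt, 6), round(tau_hL, 6))
    if key in _lut_cache:
        return _lut_cache[key]
    nv = int(round((V_MAX - V_MIN) / DV)) + 1
    nu = int(round((U_MAX - U_MIN) / DV)) + 1
    lut = np.empty((nv, NCOL))
    k1lut = np.empty(nu)
    _fill_lut(lut, k1lut, dt, tau_hL)
    _lut_cache[key] = (lut, k1lut)
    return lut, k1lut


# ---------------------------------------------------------------------------
# Kernel

@njit(cache=True, fastmath=True)
def _run_kernel(S, Ptab, pidx, nbrs, wts, dt, t0, n_steps,
                stim_ptr, stim_nodes, stim_t0, stim_t1, stim_amp,
                act_thr, act_times, act_count,
                stop_after, v_quiesce, check_every,
                snap_every, snapV, snap_t,
                rev, refresh_every, lut, k1lut):
    """Integrate the monodomain system.

    Returns (status, t_end, n_snaps): status 0 = ran to n_steps, 1 = early
    quiescence stop, -1 = numerical blow-up.
    """
    N = S.shape[0]
    maxact = act_times.shape[1]
    lap = np.empty(N)
    inv_dv = 1.0 / DV
    n_stim = stim_t0.shape[0]
    t = t0
    nsnap = 0
    if snap_every > 0:
        for i in range(N):
            snapV[0, i] = S[i, iV]
        snap_t[0] = t
        nsnap = 1
    for step_i in range(n_steps):
        if step_i % refresh_every == 0:
            for i in range(N):
                P = Ptab[pidx[i]]
                rev[i, 0] = RTONF * math.log(P[pNa_o] / S[i, iNai])
                rev[i, 1] = RTONF * math.log(P[pK_o] / S[i, iKi])
                rev[i, 2] = RTONF * math.log(
                    (P[pK_o] + P[pp_KNa] * P[pNa_o]) /
                    (S[i, iKi] + P[pp_KNa] * S[i, iNai]))
                rev[i, 3] = 0.5 * RTONF * math.log(P[pCa_o] / S[i, iCai])
        # diffusion term
        for i in range(N):
            v = S[i, iV]
            acc = 0.0
            for k in range(16):
                jn = nbrs[i, k]
                if jn >= 0:
                    acc += wts[i, k] * (S[jn, iV] - v)
            lap[i] = acc
        # reaction + stimulus + activation detection
        for i in range(N):
            P = Ptab[pidx[i]]
            V = S[i, iV]
            Nai = S[i, iNai]
            Ki = S[i, iKi]
            Cai = S[i, iCai]
            CaSS = S[i, iCaSS]
            CaSR = S[i, iCaSR]

            x = (V - V_MIN) * inv_dv
            if x < 0.0:
                x = 0.0
            elif x > lut.shape[0] - 2:
                x = float(lut.shape[0] - 2)
            ix0 = int(x)
            fx = x - ix0
            r0 = lut[ix0]
            r1 = lut[ix0 + 1]

            ENa = rev[i, 0]
            EK = rev[i, 1]
            EKs = rev[i, 2]
            ECa = rev[i, 3]

            INa = P[pg_Na] * S[i, 1] ** 3 * S[i, 2] * S[i, 3] * (V - ENa)
            INaL = P[pg_NaL] * S[i, 13] * S[i, 14] * (V - ENa)
            coeff = r0[26] + fx * (r1[26] - r0[26])
            e2 = r0[27] + fx * (r1[27] - r0[27])
            ICaL = P[pg_CaL] * S[i, 4] * S[i, 5] * S[i, 6] * S[i, 7] * \
                coeff * (0.25 * CaSS * e2 - P[pCa_o])
            IKr = P[pg_Kr] * math.sqrt(P[pK_o] / 5.4) * S[i, 8] * S[i, 9] * (V - EK)
            IKs = P[pg_Ks] * S[i, 10] * S[i, 10] * (V - EKs)
            Ito = P[pg_to] * S[i, 11] * S[i, 12] * (V - EK)
            u = (V - EK - U_MIN) * inv_dv
            if u < 0.0:
                u = 0.0
            elif u > k1lut.shape[0] - 2:
                u = float(k1lut.shape[0] - 2)
            iu0 = int(u)
            fu = u - iu0
            IK1 = P[pg_K1] * math.sqrt(P[pK_o] / 5.4) * \
                (k1lut[iu0] + fu * (k1lut[iu0 + 1] - k1lut[iu0]))
            ncx1 = r0[28] + fx * (r1[28] - r0[28])
            ncx2 = r0[29] + fx * (r1[29] - r0[29])
            INaCa = P[pk_NaCa] * \
                (ncx1 * Nai ** 3 * P[pCa_o] -
                 ncx2 * P[pNa_o] ** 3 * Cai * P[palpha]) / \
                ((P[pK_mNai] ** 3 + P[pNa_o] ** 3) *
                 (P[pK_mCa] + P[pCa_o]) * (1.0 + P[pk_sat] * ncx2))
            nak = r0[30] + fx * (r1[30] - r0[30])
            INaK = P[pP_NaK] * P[pK_o] * Nai / \
                ((P[pK_o] + P[pK_mK]) * (Nai + P[pK_mNa])) * nak
            IbNa = P[pg_bNa] * (V - ENa)
            IbCa = P[pg_bCa] * (V - ECa)
            IpCa = P[pg_pCa] * Cai / (Cai + P[pK_pCa])
            ipk_r = r0[31] + fx * (r1[31] - r0[31])
            IpK = P[pg_pK] * (V - EK) * ipk_r

            kcasr = P[pmaxSR] - (P[pmaxSR] - P[pminSR]) / \
                (1.0 + (P[pEC50] / CaSR) ** 2)
            k1r = P[pk1p] / kcasr
            O = k1r * CaSS * CaSS * S[i, iRq] / (P[pk3] + k1r * CaSS * CaSS)
            Irel = P[pV_rel] * O * (CaSR - CaSS)
            Ileak = P[pV_leak] * (CaSR - Cai)
            Iup = P[pV_maxup] / (1.0 + (P[pK_up] / Cai) ** 2)
            Ixfer = P[pV_xfer] * (CaSS - Cai)

            # gates via LUT Rush-Larsen
            for k in range(13):
                si = _VGATE_STATE_IDX[k]
                ginf = r0[k] + fx * (r1[k] - r0[k])
                grl = r0[13 + k] + fx * (r1[13 + k] - r0[13 + k])
                S[i, si] = ginf + (S[i, si] - ginf) * grl

            css2 = (CaSS / 0.05) ** 2
            fcass_inf = 0.6 / (1.0 + css2) + 0.4
            xfc = dt * (1.0 + css2) / (80.0 + 2.0 * (1.0 + css2))
            efc = 1.0 - xfc + 0.5 * xfc * xfc
            S[i, ifcass] = fcass_inf + (S[i, ifcass] - fcass_inf) * efc

            k2 = P[pk2p] * kcasr
            rq_rate = k2 * CaSS + P[pk4]
            rq_inf = P[pk4] / rq_rate
            xrq = dt * rq_rate
            erq = 1.0 - xrq + 0.5 * xrq * xrq
            S[i, iRq] = rq_inf + (S[i, iRq] - rq_inf) * erq

            Cm = P[pCm]
            Vc = P[pV_c]
            Vsr = P[pV_sr]
            Vss = P[pV_ss]
            inv2F = 1.0 / (2.0 * FARADAY)
            bufc = 1.0 / (1.0 + P[pBuf_c] * P[pK_bufc] / (Cai + P[pK_bufc]) ** 2)
            dCai = bufc * ((-(IbCa + IpCa - 2.0 * INaCa) * Cm * inv2F / Vc) +
                           (Ileak - Iup) * Vsr / Vc + Ixfer)
            bufsr = 1.0 / (1.0 + P[pBuf_sr] * P[pK_bufsr] /
                           (CaSR + P[pK_bufsr]) ** 2)
            dCaSR = bufsr * (Iup - Irel - Ileak)
            bufss = 1.0 / (1.0 + P[pBuf_ss] * P[pK_bufss] /
                           (CaSS + P[pK_bufss]) ** 2)
            dCaSS = bufss * (-Ixfer * Vc / Vss + Irel * Vsr / Vss -
                             ICaL * Cm * inv2F / Vss)

            istim = 0.0
            for ks in range(n_stim):
                if stim_t0[ks] <= t < stim_t1[ks]:
                    for q in range(stim_ptr[ks], stim_ptr[ks + 1]):
                        if stim_nodes[q] == i:
                            istim += stim_amp[ks]
                            break
            # voltage-limited injection: a depolarizing electrode cannot
            # drive the membrane far beyond physiologic overshoot
            if istim < 0.0 and V > 40.0:
                istim = 0.0

            dNai = -(INa + INaL + IbNa + 3.0 * INaK + 3.0 * INaCa) * \
                Cm / (Vc * FARADAY)
            dKi = -(IK1 + Ito + IKr + IKs - 2.0 * INaK + IpK + istim) * \
                Cm / (Vc * FARADAY)
            Itot = INa + INaL + ICaL + IKr + IKs + Ito + IK1 + INaCa + \
                INaK + IbNa + IbCa + IpCa + IpK

            S[i, iCai] = Cai + dt * dCai
            S[i, iCaSR] = CaSR + dt * dCaSR
            S[i, iCaSS] = CaSS + dt * dCaSS
            S[i, iNai] = Nai + dt * dNai
            S[i, iKi] = Ki + dt * dKi
            Vnew = V + dt * (-(Itot + istim) + lap[i])
            S[i, iV] = Vnew
            if V < act_thr and Vnew >= act_thr:
                c = act_count[i]
                # refractory guard: threshold jitter within 25 ms of the
                # previous upstroke is not a new activation
                if c == 0 or (c <= maxact and
                              t + dt - act_times[i, min(c, maxact) - 1] > 25.0):
                    if c < maxact:
                        act_times[i, c] = t + dt
                    act_count[i] = c + 1
        t = t0 + (step_i + 1) * dt
        if snap_every > 0 and (step_i + 1) % snap_every == 0 and \
                nsnap < snapV.shape[0]:
            for i in range(N):
                snapV[nsnap, i] = S[i, iV]
            snap_t[nsnap] = t
            nsnap += 1
        if (step_i + 1) % check_every == 0:
            vmax = -1.0e30
            for i in range(N):
                vi = S[i, iV]
                if vi > vmax:
                    vmax = vi
            if not math.isfinite(vmax) or vmax > 480.0:
                return -1, t, nsnap
            if vmax < v_quiesce and t > stop_after:
                return 1, t, nsnap
    return 0, t, nsnap


# stimulus membership above is O(n_stim_nodes) per node; rewritten driver
# passes per-step stimulus via a dense helper instead when profiling demands.


@dataclass
class TissueRecord:
    """Result of a tissue simulation."""

    grid: TissueGrid
    cfg: MonodomainConfig
    active_idx: np.ndarray      # (N, 2) row/col of active nodes
    flat_of_node: np.ndarray    # (ny, nx) -> active index or -1
    act_times: np.ndarray       # (N, maxact) ms
    act_count: np.ndarray       # (N,)
    act_threshold: float
    t_start: float
    t_end: float
    status: int                 # 0 full run, 1 early quiescence
    states: np.ndarray          # (N, NS) final states
    snap_t: np.ndarray | None = None
    snap_V: np.ndarray | None = None   # (n_snaps, N)

    def v_trace(self, node: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        if self.snap_V is None:
            raise SimulationError("no snapshots recorded")
        k = self.flat_of_node[node]
        if k < 0:
            raise SimulationError(f"node {node} is not in the solved system")
        return self.snap_t, self.snap_V[:, k]


@dataclass
class ActivationMap:
    LAT: np.ndarray        # (ny, nx), NaN where undefined
    threshold: float
    window: tuple[float, float]


def _build_stencil(grid: TissueGrid, cfg: MonodomainConfig
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Active-node list, flat index map, neighbor indices and weights."""
    ny, nx = grid.shape
    active_mask = (grid.labels == NORMAL) | (grid.labels == FIBROSIS)
    ys, xs = np.nonzero(active_mask)
    N = len(ys)
    if N == 0:
        raise SimulationError("no conducting tissue in grid")
    flat = -np.ones((ny, nx), dtype=np.int64)
    flat[ys, xs] = np.arange(N)

    d_l, d_t = cfg.diffusivity()
    th = grid.fiber_angle
    scale = np.where(grid.labels == FIBROSIS, cfg.fibrosis_sigma_scale, 1.0)
    c, s = np.cos(th), np.sin(th)
    Dxx = (d_l * c * c + d_t * s * s) * scale
    Dyy = (d_l * s * s + d_t * c * c) * scale
    Dxy = ((d_l - d_t) * s * c) * scale

    dx_cm = grid.dx * 1e-4
    inv_dx2 = 1.0 / (dx_cm * dx_cm)
    # neighbor order: E, W, N, S, NE, NW, SE, SW, then axial reach-2 and
    # reach-3 pairs (N = +y row index direction).  Axial terms upgrade to a
    # 6th- (or 4th-) order Laplacian wherever the wider axis stencil is
    # fully interior and the local conductivity is homogeneous; this keeps
    # the sharp sodium upstroke well resolved at coarse spacings.
    nbrs = -np.ones((N, 16), dtype=np.int64)
    wts = np.zeros((N, 16))
    offs = [(0, 1), (0, -1), (1, 0), (-1, 0), (1, 1), (1, -1), (-1, 1), (-1, -1)]

    def _ok(jy, jx):
        return 0 <= jy < ny and 0 <= jx < nx and flat[jy, jx] >= 0

    # (w1, w2, w3) per order, units of D/dx^2
    W4 = (16.0 / 12.0, -1.0 / 12.0, 0.0)
    W6 = (3.0 / 2.0, -3.0 / 20.0, 1.0 / 90.0)

    for n in range(N):
        iy, ix = ys[n], xs[n]
        for axis, (k1a, k1b, k2a, k2b, k3a, k3b) in (
                ("x", (0, 1, 8, 9, 12, 13)),
                ("y", (2, 3, 10, 11, 14, 15))):
            Dc = Dxx if axis == "x" else Dyy
            if axis == "x":
                nn = [(iy, ix + 1), (iy, ix - 1), (iy, ix + 2), (iy, ix - 2),
                      (iy, ix + 3), (iy, ix - 3)]
            else:
                nn = [(iy + 1, ix), (iy - 1, ix), (iy + 2, ix), (iy - 2, ix),
                      (iy + 3, ix), (iy - 3, ix)]
            d0 = Dc[iy, ix]

            def homog(pts):
                return all(_ok(*p) and
                           abs(Dc[p] - d0) <= 1e-12 * max(d0, 1e-30)
                           for p in pts)

            if homog(nn):
                w = W6
                reach = 3
            elif homog(nn[:4]):
                w = W4
                reach = 2
            else:
                w = None
                reach = 1
            if w is not None:
                keys = [k1a, k1b, k2a, k2b, k3a, k3b][: 2 * reach]
                ww = [w[0], w[0], w[1], w[1], w[2], w[2]][: 2 * reach]
                for kk, p, wv in zip(keys, nn, ww):
                    nbrs[n, kk] = flat[p]
                    wts[n, kk] = d0 * inv_dx2 * wv
            else:
                for kk, p in ((k1a, nn[0]), (k1b, nn[1])):
                    if _ok(*p):
                        nbrs[n, kk] = flat[p]
                        a, b = d0, Dc[p]
                        wts[n, kk] = (2.0 * a * b / (a + b)) * inv_dx2 \
                            if a + b > 0 else 0.0
        # cross-derivative terms only when the full diagonal set is present
        diag_ok = all(_ok(iy + oy, ix + ox) for oy, ox in offs[4:])
        if diag_ok:
            w = Dxy[iy, ix] * 0.5 * inv_dx2
            for k, (oy, ox) in enumerate(offs[4:], start=4):
                jy, jx = iy + oy, ix + ox
                nbrs[n, k] = flat[jy, jx]
                wts[n, k] = w if oy * ox > 0 else -w
    return np.stack([ys, xs], axis=1), flat, nbrs, wts


def _initial_states(grid: TissueGrid, active_idx: np.ndarray,
                    variant_map: dict, param_rows: dict
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-node parameter row index and initial states (1 Hz-conditioned)."""
    N = active_idx.shape[0]
    names = sorted(param_rows)
    Ptab = np.stack([param_rows[n].asarray() for n in names])
    name_row = {n: i for i, n in enumerate(names)}
    pidx = np.empty(N, dtype=np.int64)
    init = ionic.CellState.initial().values
    S = np.tile(init, (N, 1))
    for n in range(N):
        lbl = int(grid.labels[active_idx[n, 0], active_idx[n, 1]])
        pidx[n] = name_row[variant_map[lbl]]
    return Ptab, pidx, S


def simulate(grid: TissueGrid, cfg: MonodomainConfig,
             variant_map: dict[int, VariantParameterSet],
             stimuli: list[Stimulus], t_end: float,
             sample_every: float = 0.0,
             initial_states: np.ndarray | None = None,
             t_start: float = 0.0,
             act_threshold: float = 0.0,
             stop_when_quiescent: bool = True,
             quiescent_level: float = -65.0,
             max_activations: int = 40) -> TissueRecord:
    """Run the monodomain model on a heterogeneous substrate.

    variant_map maps tissue labels (NORMAL, FIBROSIS) to parameter sets.
    Upward crossings of ``act_threshold`` are recorded per node during the
    whole run.  When ``stop_when_quiescent``, the run ends early once every
    node is below ``quiescent_level`` after the last stimulus.
    Set sample_every > 0 (ms) to store V snapshots.
    """
    cfg.check_stability(grid.dx)
    params_by_label = {}
    for lbl in (NORMAL, FIBROSIS):
        if np.any(grid.labels == lbl):
            if lbl not in variant_map:
                raise SimulationError(
                    f"variant_map missing entry for label {lbl}")
            params_by_label[lbl] = variant_map[lbl]
    rows = {p.name + f"@{lbl}": p for lbl, p in params_by_label.items()}
    active_idx, flat, nbrs, wts = _build_stencil(grid, cfg)
    N = active_idx.shape[0]

    names = sorted(rows)
    Ptab = np.stack([rows[n].asarray() for n in names])
    row_of = {n: i for i, n in enumerate(names)}
    pidx = np.empty(N, dtype=np.int64)
    lbl_row = {lbl: row_of[p.name + f"@{lbl}"]
               for lbl, p in params_by_label.items()}
    lbls = grid.labels[active_idx[:, 0], active_idx[:, 1]]
    for n in range(N):
        pidx[n] = lbl_row[int(lbls[n])]

    if initial_states is None:
        S = np.tile(ionic.CellState.initial().values, (N, 1))
    else:
        S = initial_states.copy()
        if S.shape != (N, NS):
            raise SimulationError("initial_states shape mismatch")

    # stimuli in CSR form
    stim_nodes_l, stim_ptr = [], [0]
    stim_t0, stim_t1, stim_amp = [], [], []
    for st in stimuli:
        nodes = grid.site_nodes(st.site, st.radius_um)
        fl = flat[nodes[:, 0], nodes[:, 1]]
        fl = fl[fl >= 0]
        stim_nodes_l.append(fl)
        stim_ptr.append(stim_ptr[-1] + len(fl))
        stim_t0.append(st.t_on)
        stim_t1.append(st.t_on + st.duration)
        stim_amp.append(st.amplitude)
    stim_nodes = np.concatenate(stim_nodes_l) if stim_nodes_l else \
        np.empty(0, dtype=np.int64)
    stim_ptr = np.array(stim_ptr, dtype=np.int64)
    stim_t0 = np.array(stim_t0)
    stim_t1 = np.array(stim_t1)
    stim_amp = np.array(stim_amp)

    dt = cfg.dt
    n_steps = int(round((t_end - t_start) / dt))
    act_times = np.full((N, max_activations), np.nan)
    act_count = np.zeros(N, dtype=np.int64)
    last_stim_end = max(stim_t1) if len(stim_t1) else t_start
    stop_after = (last_stim_end + 100.0) if stop_when_quiescent else np.inf
    check_every = max(1, int(round(25.0 / dt)))
    if sample_every > 0:
        snap_every = max(1, int(round(sample_every / dt)))
        n_snaps = n_steps // snap_every + 1
        snapV = np.empty((n_snaps, N), dtype=np.float64)
        snap_t = np.empty(n_snaps)
    else:
        snap_every = 0
        snapV = np.empty((1, 1))
        snap_t = np.empty(1)

    rev = np.empty((N, 4))
    refresh_every = max(1, int(round(1.0 / dt)))
    lut, k1lut = build_lut(dt, params_by_label[
        NORMAL if NORMAL in params_by_label else FIBROSIS]["tau_hL"])

    status, t_fin, nsnap = _run_kernel(
        S, Ptab, pidx, nbrs, wts, dt, t_start, n_steps,
        stim_ptr, stim_nodes, stim_t0, stim_t1, stim_amp,
        act_threshold, act_times, act_count,
        stop_after, quiescent_level, check_every,
        snap_every, snapV, snap_t,
        rev, refresh_every, lut, k1lut)
    if status < 0:
        raise SimulationError(f"numerical instability at t={t_fin:.2f} ms "
                              f"(|V| > 480 mV)")
    return TissueRecord(
        grid=grid, cfg=cfg, active_idx=active_idx, flat_of_node=flat,
        act_times=act_times, act_count=act_count,
        act_threshold=act_threshold, t_start=t_start, t_end=t_fin,
        status=status, states=S,
        snap_t=snap_t[:nsnap] if snap_every > 0 else None,
        snap_V=snapV[:nsnap] if snap_every > 0 else None)


def activation_map(record: TissueRecord, threshold: float = 0.0,
                   window: tuple[float, float] | None = None) -> ActivationMap:
    """Local activation times: first upward crossing of threshold per node."""
    if window is None:
        window = (record.t_start, record.t_end)
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("empty activation window")
    ny, nx = record.grid.shape
    lat = np.full((ny, nx), np.nan)
    if threshold == record.act_threshold:
        at = record.act_times
        for n in range(at.shape[0]):
            k = min(record.act_count[n], at.shape[1])
            times = at[n, :k]
            hit = times[(times >= t0) & (times <= t1)]
            if len(hit):
                lat[record.active_idx[n, 0], record.active_idx[n, 1]] = hit[0]
    else:
        if record.snap_V is None:
            raise SimulationError(
                "non-default threshold requires V snapshots (sample_every>0)")
        ts = record.snap_t
        m = (ts >= t0) & (ts <= t1)
        V = record.snap_V[m]
        tt = ts[m]
        up = (V[:-1] < threshold) & (V[1:] >= threshold)
        for n in range(V.shape[1]):
            idx = np.nonzero(up[:, n])[0]
            if len(idx):
                lat[record.active_idx[n, 0], record.active_idx[n, 1]] = \
                    tt[idx[0] + 1]
    return ActivationMap(LAT=lat, threshold=threshold, window=window)


def conduction_velocity(record: TissueRecord,
                        path: list[tuple[int, int]] | np.ndarray) -> float:
    """Plane-wave conduction velocity (cm/s) from a linear LAT fit along a
    path of nodes aligned with propagation."""
    path = np.asarray(path)
    amap = activation_map(record)
    lat = amap.LAT[path[:, 0], path[:, 1]]
    ok = np.isfinite(lat)
    if ok.sum() < 3:
        raise SimulationError("fewer than 3 activated nodes on path")
    d = np.sqrt(((path - path[0]) ** 2).sum(axis=1)) * record.grid.dx * 1e-4
    slope = np.polyfit(lat[ok], d[ok], 1)[0]  # cm/ms
    return float(slope * 1000.0)
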