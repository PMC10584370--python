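"""Rapid-pacing VT induction, reentry detection and localization.

Implements the clinical-style programmed stimulation protocol used to probe
arrhythmia inducibility on a substrate: six S1 stimuli at 600 ms cycle
length, then a premature S2 delivered 300 ms after the last S1 and
decremented in 10 ms steps until reentry is induced or the S2 fails to
capture; if the S2 stage is exhausted, S3 (and S4) extrastimuli are added
the same way, each riding on the shortest captured coupling of the previous
stage.  Induced VT is defined as reentry sustained for at least 2 cycles at
the same critical site.  Reentries induced from different pacing sites with
the same location and morphology are counted once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .tissue import (
    TissueGrid, MonodomainConfig, Stimulus, TissueRecord,
    simulate, SimulationError, REGION_NAMES,
)

__all__ = [
    "PacingProtocol", "ReentryRecord", "InductionSummary",
    "rapid_pacing_protocol", "detect_reentry", "dedupe_morphologies",
    "run_induction", "run_genotype_experiment",
]


@dataclass(frozen=True)
class PacingProtocol:
    """Programmed-stimulation parameters (defaults follow the clinical
    rapid-pacing protocol: 6 x S1 @ 600 ms, S2 from 300 ms in -10 ms steps,
    up to 3 extrastimuli)."""

    n_S1: int = 6
    S1_cl: float = 600.0             # ms
    S2_initial_coupling: float = 300.0  # ms
    decrement: float = 10.0          # ms
    max_extrastimuli: int = 3        # S2..S4
    stim_amplitude: float = -150.0   # pA/pF
    stim_duration: float = 2.0       # ms
    stim_radius_um: float = 1250.0
    observe: float = 2000.0          # post-pacing observation window, ms
    min_coupling: float = 120.0      # absolute floor of the coupling search
    capture_radius_um: float = 5000.0
    capture_window: float = 50.0     # ms after stimulus onset
    # if the initial coupling sits inside the tissue refractory period, walk
    # it upward (by `decrement` steps, up to max_initial_coupling) until the
    # extrastimulus captures, then decrement as usual
    auto_extend_initial: bool = True
    max_initial_coupling: float = 500.0


@dataclass(frozen=True)
class ReentryRecord:
    critical_site: tuple[int, int]
    n_cycles: int
    period: float                  # ms
    region: str
    morphology_signature: tuple
    inducing_site: str
    inducing_coupling: float       # ms (coupling of the last extrastimulus)


@dataclass
class Attempt:
    stage: int                     # 2 = S2, 3 = S3, 4 = S4
    coupling: float
    captured: bool
    reentry: ReentryRecord | None
    n_reexcited: int = 0           # nodes activating >= 2x after the stimulus


@dataclass
class InductionSummary:
    site_outcomes: dict            # site name -> list[Attempt]
    reentries: list                # all ReentryRecord found (<=1 per site)
    unique: list                   # de-duplicated records
    region_counts: dict            # region name -> unique VT count

    @property
    def n_unique(self) -> int:
        return len(self.unique)


# ---------------------------------------------------------------------------
# Reentry detection

def detect_reentry(record: TissueRecord, after_t: float,
                   max_period: float = 600.0,
                   min_period: float = 100.0,
                   site_merge_um: float = 2000.0,
                   min_cycles: int = 2) -> ReentryRecord | None:
    """Find a sustained reentrant activation pattern after the last stimulus.

    A node is a critical-site candidate when it activates >= min_cycles + 1
    times after ``after_t`` with a consistent period (coefficient of
    variation of its inter-activation intervals < 20%) shorter than
    ``max_period``.  Candidates within ``site_merge_um`` collapse to one
    site; the site with the highest repeat count is reported.
    Returns None when no node meets the definition.
    """
    at = record.act_times
    counts = record.act_count
    N = at.shape[0]
    best = None  # (n_acts, node, period)
    cand = []
    for n in range(N):
        k = min(counts[n], at.shape[1])
        times = at[n, :k]
        times = times[np.isfinite(times) & (times > after_t)]
        if len(times) < min_cycles + 1:
            continue
        iv = np.diff(times)
        period = float(iv.mean())
        if period < min_period or period >= max_period:
            continue
        if iv.std() / period >= 0.20:
            continue
        cand.append((len(times), n, period))
    if not cand:
        return None
    cand.sort(key=lambda c: (-c[0], c[1]))
    n_acts, node, period = cand[0]
    iy, ix = record.active_idx[node]
    region_id = int(record.grid.region_map[iy, ix]) \
        if record.grid.region_map is not None else 0
    region = REGION_NAMES[region_id - 1] if region_id else ""
    sig = _morphology_signature(record, after_t, (int(iy), int(ix)), period)
    return ReentryRecord(
        critical_site=(int(iy), int(ix)),
        n_cycles=n_acts - 1,
        period=period,
        region=region,
        morphology_signature=sig,
        inducing_site="",
        inducing_coupling=float("nan"),
    )


def _first_acts_after(record: TissueRecord, after_t: float) -> np.ndarray:
    at = record.act_times
    counts = record.act_count
    N = at.shape[0]
    out = np.full(N, np.nan)
    for n in range(N):
        k = min(counts[n], at.shape[1])
        t = at[n, :k]
        t = t[np.isfinite(t) & (t > after_t)]
        if len(t):
            out[n] = t[0]
    return out


def _morphology_signature(record: TissueRecord, after_t: float,
                          site: tuple[int, int], period: float) -> tuple:
    """Ordered region-activation sequence plus rotation chirality."""
    first = _first_acts_after(record, after_t)
    grid = record.grid
    # region order of first activation
    order = []
    if grid.region_map is not None:
        reg_first = {}
        for n, t in enumerate(first):
            if not np.isfinite(t):
                continue
            iy, ix = record.active_idx[n]
            rid = int(grid.region_map[iy, ix])
            if rid and (rid not in reg_first or t < reg_first[rid]):
                reg_first[rid] = t
        order = [r for r, _ in sorted(reg_first.items(), key=lambda kv: kv[1])]
    chir = _chirality(record, site, period, after_t)
    return (tuple(order), chir)


def _chirality(record: TissueRecord, site: tuple[int, int], period: float,
               after_t: float) -> int:
    """Rotation sense of activation around a site: +1 counterclockwise,
    -1 clockwise, 0 undetermined (e.g. focal or planar pattern)."""
    first = _first_acts_after(record, after_t)
    cy, cx = site
    r_in, r_out = 2.0, 8.0
    pts = []
    for n, t in enumerate(first):
        if not np.isfinite(t):
            continue
        iy, ix = record.active_idx[n]
        r = math.hypot(iy - cy, ix - cx)
        if r_in <= r <= r_out:
            pts.append((math.atan2(iy - cy, ix - cx), t))
    if len(pts) < 8:
        return 0
    s = 0.0
    m = len(pts)
    for a in range(m):
        for b in range(a + 1, m):
            dth = pts[b][0] - pts[a][0]
            # wrap to (-pi, pi]
            while dth <= -math.pi:
                dth += 2 * math.pi
            while dth > math.pi:
                dth -= 2 * math.pi
            dt_ = pts[b][1] - pts[a][1]
            # compare only pairs within half a rotation period
            if abs(dt_) < 0.5 * period and abs(dth) > 1e-9:
                s += math.copysign(1.0, dth * dt_)
    if s > 0:
        return 1
    if s < 0:
        return -1
    return 0


def dedupe_morphologies(records: list) -> list:
    """One representative per (critical-site region, morphology signature)."""
    seen = {}
    for r in records:
        key = (r.region, r.morphology_signature)
        if key not in seen:
            seen[key] = r
    return list(seen.values())


# ---------------------------------------------------------------------------
# Protocol driver

def _merge_activations(rec1: TissueRecord, rec2: TissueRecord) -> TissueRecord:
    """Combine the activation logs of two back-to-back segments (rec2 is the
    continuation of rec1, same grid and node ordering)."""
    from dataclasses import replace as _dc_replace

    at1, c1 = rec1.act_times, rec1.act_count
    at2, c2 = rec2.act_times, rec2.act_count
    N, maxact = at1.shape
    merged = np.full((N, maxact), np.nan)
    counts = np.zeros(N, dtype=np.int64)
    for n in range(N):
        k1 = min(c1[n], maxact)
        k2 = min(c2[n], maxact)
        t = np.concatenate([at1[n, :k1], at2[n, :k2]])
        k = min(len(t), maxact)
        merged[n, :k] = t[:k]
        counts[n] = len(t)
    return _dc_replace(rec2, act_times=merged, act_count=counts)


def _count_reexcited(record: TissueRecord, after_t: float) -> int:
    """Number of nodes with at least two activations after ``after_t`` -
    re-excited tissue, the footprint of a re-entrant return even when the
    two-cycle sustained-VT definition is not met."""
    at = record.act_times
    counts = record.act_count
    n_re = 0
    for n in range(at.shape[0]):
        k = min(counts[n], at.shape[1])
        t = at[n, :k]
        if np.count_nonzero(np.isfinite(t) & (t > after_t)) >= 2:
            n_re += 1
    return n_re


def _capture_check(record: TissueRecord, grid: TissueGrid, site,
                   t_stim: float, protocol: PacingProtocol) -> bool:
    """A stimulus captured if tissue within capture_radius of the pacing
    site — beyond the directly stimulated disk — activates within
    capture_window of stimulus onset.  This is a propagated response (the
    clinical meaning of capture); the forced depolarization of the
    electrode region itself does not count."""
    nodes = grid.site_nodes(site, protocol.capture_radius_um)
    cy, cx = grid.pacing_sites[site] if isinstance(site, str) else site
    r_stim = (protocol.stim_radius_um + grid.dx) / grid.dx
    d2 = (nodes[:, 0] - cy) ** 2 + (nodes[:, 1] - cx) ** 2
    nodes = nodes[d2 > r_stim * r_stim]
    fl = record.flat_of_node[nodes[:, 0], nodes[:, 1]]
    fl = fl[fl >= 0]
    at = record.act_times
    for n in fl:
        k = min(record.act_count[n], at.shape[1])
        t = at[n, :k]
        if np.any((t > t_stim) & (t <= t_stim + protocol.capture_window)):
            return True
    return False


def rapid_pacing_protocol(grid: TissueGrid, cfg: MonodomainConfig,
                          variant_map: dict, site: str,
                          protocol: PacingProtocol = PacingProtocol(),
                          s1_cache: dict | None = None,
                          ) -> tuple[list, ReentryRecord | None]:
    """Run the full rapid-pacing induction protocol from one pacing site.

    Returns (attempts, reentry-or-None).  The search stops at the first
    sustained reentry; each extrastimulus stage decrements its coupling
    until local non-capture (or the protocol's coupling floor), after which
    the next extrastimulus is added on top of the shortest captured
    couplings of the previous stages.

    ``s1_cache`` (optional dict) memoizes the S1-train end state per
    (site, variant) so repeated runs on one substrate stay affordable.
    """
    if site not in grid.pacing_sites:
        raise SimulationError(f"unknown pacing site {site!r}")
    p = protocol

    def stim(t_on, amplitude=None):
        return Stimulus(site=site, t_on=t_on, duration=p.stim_duration,
                        amplitude=amplitude or p.stim_amplitude,
                        radius_um=p.stim_radius_um)

    t_last_s1 = (p.n_S1 - 1) * p.S1_cl
    cache_key = (site, id(variant_map.get(1)), id(variant_map.get(2)))
    if s1_cache is not None and cache_key in s1_cache:
        s1_states, s1_ok = s1_cache[cache_key]
    else:
        s1_stims = [stim(i * p.S1_cl) for i in range(p.n_S1)]
        rec = simulate(grid, cfg, variant_map, s1_stims,
                       t_end=t_last_s1 + p.capture_window + 2.0,
                       stop_when_quiescent=False)
        s1_ok = _capture_check(rec, grid, site, t_last_s1, p)
        s1_states = rec.states
        if s1_cache is not None:
            s1_cache[cache_key] = (s1_states, s1_ok)
    if not s1_ok:
        raise SimulationError(f"S1 non-capture at site {site!r}")

    attempts: list[Attempt] = []
    fixed: list[float] = []   # shortest captured couplings of previous stages
    # prefix = state just after S1 train + the fixed extrastimuli
    prefix_states = s1_states
    prefix_t = t_last_s1 + p.capture_window + 2.0
    prefix_last_stim = t_last_s1

    for stage in range(2, 2 + p.max_extrastimuli):
        coupling = p.S2_initial_coupling
        shortest_captured = None
        extending = p.auto_extend_initial
        while coupling >= p.min_coupling:
            t_probe = prefix_last_stim + coupling
            # short capture-probe segment first
            rec1 = simulate(grid, cfg, variant_map, [stim(t_probe)],
                            t_end=t_probe + p.capture_window + 10.0,
                            initial_states=prefix_states, t_start=prefix_t,
                            stop_when_quiescent=False)
            captured = _capture_check(rec1, grid, site, t_probe, p)
            if not captured and extending and shortest_captured is None:
                # initial coupling is inside the refractory period: walk
                # upward to just above ERP before starting the decrement
                attempts.append(Attempt(stage, coupling, False, None))
                coupling += p.decrement
                if coupling > p.max_initial_coupling:
                    break
                continue
            extending = False
            if not captured:
                attempts.append(Attempt(stage, coupling, False, None))
                break
            shortest_captured = coupling
            # observation run, terminated early once the sheet is quiescent
            rec2 = simulate(grid, cfg, variant_map, [],
                            t_end=t_probe + p.observe,
                            initial_states=rec1.states, t_start=rec1.t_end,
                            stop_when_quiescent=True)
            merged = _merge_activations(rec1, rec2)
            after_probe = t_probe + p.stim_duration + p.capture_window
            n_reexc = _count_reexcited(merged, after_probe)
            reentry = detect_reentry(merged, after_t=after_probe,
                                     max_period=p.S1_cl)
            if reentry is not None:
                reentry = ReentryRecord(
                    critical_site=reentry.critical_site,
                    n_cycles=reentry.n_cycles, period=reentry.period,
                    region=reentry.region,
                    morphology_signature=reentry.morphology_signature,
                    inducing_site=site, inducing_coupling=coupling)
                attempts.append(Attempt(stage, coupling, True, reentry,
                                        n_reexc))
                return attempts, reentry
            attempts.append(Attempt(stage, coupling, True, None, n_reexc))
            coupling -= p.decrement
        if shortest_captured is None:
            # this extrastimulus never captured; deeper stages cannot either
            break
        fixed.append(shortest_captured)
        # advance the prefix past the new fixed extrastimulus
        t_fix = prefix_last_stim + shortest_captured
        recp = simulate(grid, cfg, variant_map, [stim(t_fix)],
                        t_end=t_fix + p.stim_duration + 1.0,
                        initial_states=prefix_states, t_start=prefix_t,
                        stop_when_quiescent=False)
        prefix_states = recp.states
        prefix_t = recp.t_end
        prefix_last_stim = t_fix
    return attempts, None


def run_induction(grid: TissueGrid, cfg: MonodomainConfig, variant_map: dict,
                  protocol: PacingProtocol = PacingProtocol(),
                  sites: list[str] | None = None) -> InductionSummary:
    """Apply the rapid-pacing protocol at each pacing site and summarize."""
    if sites is None:
        sites = list(grid.pacing_sites)
    outcomes = {}
    reentries = []
    s1_cache: dict = {}
    for site in sites:
        attempts, reentry = rapid_pacing_protocol(
            grid, cfg, variant_map, site, protocol, s1_cache=s1_cache)
        outcomes[site] = attempts
        if reentry is not None:
            reentries.append(reentry)
    unique = dedupe_morphologies(reentries)
    counts = {name: 0 for name in REGION_NAMES}
    for r in unique:
        if r.region:
            counts[r.region] += 1
    return InductionSummary(site_outcomes=outcomes, reentries=reentries,
                            unique=unique, region_counts=counts)


def run_genotype_experiment(grid: TissueGrid,
                            matched_variant_map: dict,
                            mismatched_variant_map: dict,
                            cfg: MonodomainConfig,
                            protocol: PacingProtocol = PacingProtocol(),
                            sites: list[str] | None = None
                            ) -> tuple[InductionSummary, InductionSummary]:
    """Induction with genotype-matched vs genotype-mismatched cell models
    on one fixed structural substrate."""
    matched = run_induction(grid, cfg, matched_variant_map, protocol, sites)
    mismatched = run_induction(grid, cfg, mismatched_variant_map, protocol,
                               sites)
    return matched, mismatched
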