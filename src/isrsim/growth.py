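"""Biological state evolution: cell cycle, mitosis and re-endothelialization.

Smooth muscle cells activated by the stenting injury traverse a stochastic
cell cycle (normally distributed duration, mean 32 h, SD 2 h) and divide into
the lumen.  Growth is inhibited by nitric oxide where a cell is covered by
functional endothelium experiencing sufficient wall shear stress, and by
contact when a cell is surrounded by neighbours.  The endothelium itself is
represented implicitly: a per-SMC coverage flag that is switched on by a
thinning process tuned to follow a prescribed coverage-versus-time scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree

from .mechanics import (BioState, Kind, MechanicsParams, TissueState,
                        equilibrate)

__all__ = [
    "ScenarioSchedule",
    "GrowthParams",
    "coverage_target",
    "endothelium_update",
    "sample_cycle_duration",
    "update_cell_states",
    "attempt_mitosis",
]


@dataclass
class ScenarioSchedule:
    """Target endothelium-coverage curve c(t).

    Scenario "S1": fast partial recovery (to ``fast_recovery_degree`` by
    ``fast_recovery_time`` days), then linear to full coverage at the total
    recovery time T.  Scenario "S2": linear from zero to full coverage at T.
    T is the campaign's uncertain regeneration-time input (15-23 days).
    """

    scenario: str = "S1"
    total_recovery_time: float = 19.0   # days
    fast_recovery_time: float = 3.0     # days
    fast_recovery_degree: float = 0.59  # fraction

    def __post_init__(self) -> None:
        if self.scenario not in ("S1", "S2"):
            raise ValueError("scenario must be 'S1' or 'S2'")
        if not 0.0 < self.fast_recovery_time < self.total_recovery_time:
            raise ValueError("need 0 < fast_recovery_time < total_recovery_time")
        if not 0.0 <= self.fast_recovery_degree <= 1.0:
            raise ValueError("fast_recovery_degree must be in [0, 1]")

    def coverage(self, t: float) -> float:
        return coverage_target(self, t)


def coverage_target(sched: ScenarioSchedule, t: float) -> float:
    """Scheduled coverage fraction at time ``t`` (days); clamped at 1."""
    if t < 0:
        raise ValueError("time must be >= 0")
    T = sched.total_recovery_time
    if t >= T:
        return 1.0
    if sched.scenario == "S2":
        return t / T
    t1, c1 = sched.fast_recovery_time, sched.fast_recovery_degree
    if t <= t1:
        return c1 * t / t1
    return c1 + (1.0 - c1) * (t - t1) / (T - t1)


@dataclass
class GrowthParams:
    """Cell-cycle and inhibition parameters.

    ``wss_no_threshold`` is the wall shear stress (Pa) above which a covered
    cell is NO-inhibited; ``None`` means "derive from the baseline
    plane-Poiseuille wall stress" (done by the simulation engine, so that
    unobstructed-lumen cells are inhibited once covered).
    """

    cycle_mean: float = 32.0            # hours
    cycle_sd: float = 2.0               # hours
    wss_no_threshold: float | None = None   # Pa
    contact_neighbor_limit: int = 6
    step: float = 1.0                   # hours
    neighbor_tolerance: float = 0.1     # contact slack, fraction of r_i + r_j
    relax_max_iters: int = 200          # post-mitosis relaxation budget

    def __post_init__(self) -> None:
        if self.cycle_mean <= 0 or self.cycle_sd < 0 or self.step <= 0:
            raise ValueError("cycle_mean > 0, cycle_sd >= 0, step > 0 required")


def sample_cycle_duration(params: GrowthParams, rng: np.random.Generator,
                          size: int | None = None) -> float | np.ndarray:
    """Cell-cycle durations from Normal(mean, sd) truncated to positive."""
    n = 1 if size is None else int(size)
    out = rng.normal(params.cycle_mean, params.cycle_sd, size=n)
    while True:
        bad = out <= 0
        if not np.any(bad):
            break
        out[bad] = rng.normal(params.cycle_mean, params.cycle_sd, size=int(bad.sum()))
    return float(out[0]) if size is None else out


def endothelium_update(state: TissueState, sched: ScenarioSchedule, t: float,
                       dt: float, rng: np.random.Generator,
                       exposed_ids=None) -> TissueState:
    """Cover uncovered flow-exposed SMCs with probability p = dc / (1 - c).

    With ``c = c(t)`` and ``c2 = c(t + dt)``, each uncovered exposed cell is
    covered independently with ``p = max(0, (c2 - c) / (1 - c))`` (p = 1 once
    c = 1), which makes the expected realized coverage of an always-exposed
    cohort track the schedule exactly.  Coverage is never revoked.  Mutates
    and returns ``state``.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    c1 = coverage_target(sched, t)
    c2 = coverage_target(sched, t + dt)
    p = 1.0 if c1 >= 1.0 else max(0.0, (c2 - c1) / (1.0 - c1))
    smc = state.kind == int(Kind.SMC)
    eligible = smc & ~state.covered
    if exposed_ids is not None:
        exposed_ids = np.asarray(sorted(exposed_ids), dtype=np.int64)
        eligible &= np.isin(state.ids, exposed_ids)
    idx = np.flatnonzero(eligible)
    if len(idx) == 0 or p <= 0.0:
        return state
    hits = rng.random(len(idx)) < p
    state.covered[idx[hits]] = True
    return state


def neighbor_counts(state: TissueState, params: GrowthParams) -> np.ndarray:
    """Number of touching neighbours (within contact slack) per agent."""
    counts = np.zeros(state.n, dtype=np.int64)
    if state.n < 2:
        return counts
    slack = 1.0 + params.neighbor_tolerance
    cutoff = 2.0 * float(state.radius.max()) * slack
    pairs = cKDTree(state.pos).query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return counts
    i, j = pairs[:, 0], pairs[:, 1]
    d = np.linalg.norm(state.pos[i] - state.pos[j], axis=1)
    touch = d < (state.radius[i] + state.radius[j]) * slack
    np.add.at(counts, i[touch], 1)
    np.add.at(counts, j[touch], 1)
    return counts


def update_cell_states(state: TissueState, wss: dict[int, float],
                       params: GrowthParams) -> TissueState:
    """Assign each SMC its biological state for this step.

    NO-inhibited iff endothelium-covered and local WSS is at or above the
    threshold; else contact-inhibited iff the touching-neighbour count reaches
    the limit; else synthetic (proliferating) if the cell was activated by the
    injury (or descends from one), else contractile.  Inhibited and
    contractile cells do not advance their cycle clock.  Mutates and returns
    ``state``.
    """
    if params.wss_no_threshold is None:
        raise ValueError("wss_no_threshold unset; resolve it before stepping")
    smc = state.kind == int(Kind.SMC)
    wss_arr = np.zeros(state.n)
    has_wss = np.zeros(state.n, dtype=bool)
    if wss:
        wids = np.asarray(sorted(wss.keys()), dtype=np.int64)
        widx = state.index_of(wids)
        wss_arr[widx] = [wss[int(i)] for i in wids]
        has_wss[widx] = True
    counts = neighbor_counts(state, params)
    no_inh = smc & state.covered & has_wss & (wss_arr >= params.wss_no_threshold)
    contact = smc & ~no_inh & (counts >= params.contact_neighbor_limit)
    synth = smc & ~no_inh & ~contact & state.activated
    contractile = smc & ~no_inh & ~contact & ~state.activated
    state.bio_state[no_inh] = int(BioState.NO_INHIBITED)
    state.bio_state[contact] = int(BioState.CONTACT_INHIBITED)
    state.bio_state[synth] = int(BioState.SYNTHETIC)
    state.bio_state[contractile] = int(BioState.CONTRACTILE)
    return state


def attempt_mitosis(state: TissueState, params: GrowthParams,
                    mech: MechanicsParams, rng: np.random.Generator) -> TissueState:
    """Advance synthetic cells' cycle clocks; divide those that complete.

    A completing cell places its daughter at one radius away at a uniformly
    random angle; both get fresh cycle durations and a zero clock, and the
    daughter inherits the mother's activation.  A bounded mechanical
    relaxation then resolves the overlaps (struts stay fixed).
    """
    synth = state.bio_state == int(BioState.SYNTHETIC)
    state.cycle_clock[synth] += params.step
    due = np.flatnonzero(synth & (state.cycle_clock >= state.cycle_duration))
    if len(due) == 0:
        return state
    angles = rng.uniform(0.0, 2.0 * np.pi, size=len(due))
    offsets = state.radius[due, None] * np.column_stack([np.cos(angles), np.sin(angles)])
    daughters = state.pos[due] + offsets
    state.cycle_clock[due] = 0.0
    state.cycle_duration[due] = sample_cycle_duration(params, rng, size=len(due))
    d_dur = sample_cycle_duration(params, rng, size=len(due))
    state.append_smcs(daughters, state.radius[due], state.activated[due], d_dur)
    relax = replace(mech, max_equilibration_iters=params.relax_max_iters,
                    equilibration_tolerance=10.0 * mech.equilibration_tolerance)
    # relax only the neighbourhood of the new daughters: agents within the
    # free radius may move, a surrounding fixed ring absorbs the push
    rmax = float(state.radius.max())
    r_free = 4.0 * rmax
    r_ring = r_free + 2.0 * rmax + mech.tether_range
    tree = cKDTree(state.pos)
    free_idx = np.unique(np.concatenate(
        [np.asarray(lst, dtype=np.intp)
         for lst in tree.query_ball_point(daughters, r_free)]
        + [np.empty(0, dtype=np.intp)]))
    ring_idx = np.unique(np.concatenate(
        [np.asarray(lst, dtype=np.intp)
         for lst in tree.query_ball_point(daughters, r_ring)]
        + [np.empty(0, dtype=np.intp)]))
    local = np.zeros(state.n, dtype=bool)
    local[ring_idx] = True
    sub = state.subset(local)
    free = np.zeros(state.n, dtype=bool)
    free[free_idx] = True
    fixed_ids = np.concatenate([state.ids[local & ~free],
                                state.ids[local & (state.strut_dir != 0.0)]])
    relaxed_sub, _ = equilibrate(sub, relax, fixed_ids=fixed_ids)
    state.pos[local] = relaxed_sub.pos
    return state
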