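"""Coupled time-stepped in-stent restenosis simulation.

A run initializes a straight two-walled artery section (tunica media of SMC
layers plus an IEL layer per wall, square stent struts in the lumen), deploys
the stent by stepwise strut displacement with force equilibration, then
advances the tissue in fixed steps.  Each step rasterizes the agents, solves
the steady flow at constant flux, maps wall shear stress onto the
flow-adjacent SMCs, updates the biological states, realizes the
re-endothelialization schedule and attempts mitosis.

The headline output is the neointimal area over time: the lumen is reduced to
its mean width, converted to the area of a circle of that diameter, and
subtracted from the post-stenting baseline.  Restenosis is declared when the
final neointimal area exceeds half the original lumen area.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import hemodynamics as hemo
from . import growth as gr
from . import mechanics as mech
from .growth import GrowthParams, ScenarioSchedule
from .hemodynamics import FlowParams, LatticeMap
from .mechanics import Kind, MechanicsParams, TissueState

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "initialize_vessel",
    "mean_lumen_width",
    "neointimal_area",
    "restenosis_flag",
    "run_simulation",
]


@dataclass
class SimulationConfig:
    """Complete description of one simulation run.

    Geometry defaults describe the porcine coronary section used throughout:
    1.5 mm long, 1 mm lumen, five SMC layers per wall plus the IEL.
    """

    vessel_length: float = 1.5      # mm
    lumen_diameter: float = 1.0     # mm
    media_layers: int = 5
    cell_radius: float = 0.015      # mm
    deployment_depth: float = 0.110  # mm
    deploy_steps: int = 10
    strut_size: float = 0.09        # mm, square side
    total_days: float = 30.0
    master_seed: int = 0
    snapshot_days: tuple[float, ...] | None = None  # None: weekly + final
    scenario: ScenarioSchedule = field(default_factory=ScenarioSchedule)
    growth: GrowthParams = field(default_factory=GrowthParams)
    mechanics: MechanicsParams = field(default_factory=MechanicsParams)
    flow: FlowParams = field(default_factory=FlowParams)

    def __post_init__(self) -> None:
        for name in ("vessel_length", "lumen_diameter", "cell_radius",
                     "strut_size", "total_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.media_layers < 1:
            raise ValueError("media_layers must be >= 1")
        if self.deployment_depth < 0:
            raise ValueError("deployment_depth must be >= 0")

    def resolved_snapshot_days(self) -> tuple[float, ...]:
        if self.snapshot_days is not None:
            return tuple(self.snapshot_days)
        days = [float(d) for d in np.arange(7.0, self.total_days, 7.0)]
        days.append(float(self.total_days))
        return tuple(days)


@dataclass
class Trajectory:
    """Time series and snapshots produced by one run."""

    times: np.ndarray               # days
    neointimal_area: np.ndarray     # mm^2
    mean_lumen_width: np.ndarray    # mm
    coverage: np.ndarray            # realized endothelium coverage fraction
    baseline_lumen_area: float      # mm^2, post-stenting
    original_lumen_area: float      # mm^2, pre-stenting nominal
    restenosis: bool
    closed: bool                    # lumen closed before total_days
    snapshots: dict[float, np.ndarray]  # day -> solid mask
    lattice_spacing: float          # mm


# ---------------------------------------------------------------------------
# Vessel construction
# ---------------------------------------------------------------------------

def initialize_vessel(config: SimulationConfig) -> TissueState:
    """Deterministic initial artery: two walls, IEL chains, square struts.

    Each wall is ``media_layers`` rows of SMCs plus an innermost IEL row, in
    a regular touching-disc packing; one square strut sits against each IEL
    surface at mid-length, ready to be deployed into its wall.  Cells in the
    first and last columns are flagged as horizontally constrained.
    """
    r = config.cell_radius
    length = config.vessel_length
    m = config.media_layers
    n_cols = int(length // (2 * r))
    if n_cols < 3:
        raise ValueError("vessel too short for the configured cell radius")
    offset = (length - 2 * r * n_cols) / 2
    xs = offset + r * (2 * np.arange(n_cols) + 1)
    wall_rows = m + 1
    wall_thickness = 2 * r * wall_rows
    height = 2 * wall_thickness + config.lumen_diameter
    y_lumen_lo = wall_thickness
    y_lumen_hi = wall_thickness + config.lumen_diameter

    ids, kinds, posx, posy = [], [], [], []
    next_id = 0
    row_of: dict[int, tuple[str, int, int]] = {}  # id -> (wall, row, col)
    for wall, sign in (("lower", +1), ("upper", -1)):
        for k in range(wall_rows):
            y = r * (2 * k + 1) if wall == "lower" else height - r * (2 * k + 1)
            kind = Kind.SMC if k < m else Kind.IEL
            for c in range(n_cols):
                ids.append(next_id)
                kinds.append(kind)
                posx.append(xs[c])
                posy.append(y)
                row_of[next_id] = (wall, k, c)
                next_id += 1

    n_s = max(1, int(round(config.strut_size / (2 * r))))
    strut_x = length / 2 + 2 * r * (np.arange(n_s) - (n_s - 1) / 2)
    strut_info: list[tuple[int, float]] = []
    for wall, y_edge, direction in (("lower", y_lumen_lo, -1.0),
                                    ("upper", y_lumen_hi, +1.0)):
        for k in range(n_s):
            y = (y_edge + r * (2 * k + 1)) if wall == "lower" \
                else (y_edge - r * (2 * k + 1))
            for x in strut_x:
                ids.append(next_id)
                kinds.append(Kind.STRUT)
                posx.append(float(x))
                posy.append(float(y))
                strut_info.append((next_id, direction))
                next_id += 1

    agents = [mech.Agent(id=i, kind=k, position=np.array([x, y]), radius=r)
              for i, k, x, y in zip(ids, kinds, posx, posy)]
    state = TissueState.from_agents(agents, domain_length=length,
                                    domain_height=height)
    for sid, direction in strut_info:
        state.strut_dir[state.index_of(np.array([sid]))[0]] = direction

    # horizontal constraint on the first and last columns of each wall row;
    # the outermost row of each wall is anchored (the surrounding tissue the
    # model does not represent keeps the artery from translating outward)
    for aid, (_, k, c) in row_of.items():
        i = state.index_of(np.array([aid]))[0]
        if c == 0 or c == n_cols - 1:
            state.edge_constrained[i] = True
        if k == 0:
            state.anchored[i] = True

    # IEL chain links between horizontal neighbours, rest length as built
    for aid, (wall, k, c) in row_of.items():
        if k != m:
            continue
        i = state.index_of(np.array([aid]))[0]
        for slot, cc in ((0, c - 1), (1, c + 1)):
            if 0 <= cc < n_cols:
                nbr = [a for a, rc in row_of.items() if rc == (wall, k, cc)]
                j = state.index_of(np.array([nbr[0]]))[0]
                state.link_ids[i, slot] = state.ids[j]
                state.link_rest[i, slot] = float(
                    np.linalg.norm(state.pos[i] - state.pos[j]))
    return state


def expected_agent_count(config: SimulationConfig) -> int:
    """Closed-form row-packing count for the configured geometry."""
    r = config.cell_radius
    n_cols = int(config.vessel_length // (2 * r))
    n_s = max(1, int(round(config.strut_size / (2 * r))))
    return 2 * (config.media_layers + 1) * n_cols + 2 * n_s * n_s


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def mean_lumen_width(lat: LatticeMap) -> float:
    """Mean over columns of (fluid-node count) * spacing, in mm."""
    if lat.nx < 1:
        raise ValueError("lattice has no columns")
    fluid_per_col = (~lat.solid).sum(axis=0)
    return float(fluid_per_col.mean() * lat.spacing)


def neointimal_area(width: float, baseline_lumen_area: float) -> float:
    """Neointimal cross-section: baseline circle area minus the current one.

    The lumen of mean width w is treated as a circle of diameter w.
    """
    if width < 0:
        raise ValueError("width must be >= 0")
    return max(0.0, baseline_lumen_area - np.pi * (width / 2.0) ** 2)


def restenosis_flag(final_area: float, original_lumen_area: float) -> bool:
    """True iff the neointima exceeds 50% of the original lumen area."""
    if final_area < 0 or original_lumen_area < 0:
        raise ValueError("areas must be >= 0")
    return final_area > 0.5 * original_lumen_area


def _surface_wss_map(field: hemo.FlowField, lum: LatticeMap,
                     state: TissueState, margin: float) -> dict[int, float]:
    """WSS (Pa) for every SMC whose disc lies within ``margin`` of the lumen.

    The node-ownership map under-counts the hydrodynamic surface: a cell can
    sit at the lumen boundary without owning an interface node (rasterization
    roughness).  Here exposure is geometric — distance from the cell's disc
    to its column's open-lumen band — and each exposed cell receives the mean
    interface shear of its column and wall side, so the whole surface layer
    sees the endothelium and NO-inhibition rules.
    """
    s = lum.spacing
    starts, counts = hemo._column_runs(lum.solid)
    rows, cols, node_wss = hemo.interface_shear(field, lum)
    mid = lum.ny // 2
    lo_sum = np.zeros(lum.nx)
    lo_cnt = np.zeros(lum.nx)
    hi_sum = np.zeros(lum.nx)
    hi_cnt = np.zeros(lum.nx)
    lower = rows < mid
    np.add.at(lo_sum, cols[lower], node_wss[lower])
    np.add.at(lo_cnt, cols[lower], 1)
    np.add.at(hi_sum, cols[~lower], node_wss[~lower])
    np.add.at(hi_cnt, cols[~lower], 1)
    with np.errstate(invalid="ignore"):
        lo_wss = np.where(lo_cnt > 0, lo_sum / np.maximum(lo_cnt, 1), 0.0)
        hi_wss = np.where(hi_cnt > 0, hi_sum / np.maximum(hi_cnt, 1), 0.0)

    smc = np.flatnonzero(state.kind == int(Kind.SMC))
    if len(smc) == 0:
        return {}
    x = state.pos[smc, 0]
    y = state.pos[smc, 1]
    r = state.radius[smc]
    c = np.clip((x / s).astype(np.int64), 0, lum.nx - 1)
    open_col = counts[c] > 0
    y_lo = starts[c] * s               # lower lumen boundary (wall position)
    y_hi = (starts[c] + counts[c]) * s
    on_lower = y <= (y_lo + y_hi) / 2
    near = np.where(on_lower, y_lo - y, y - y_hi) < (r + margin)
    cand = open_col & near

    iel = np.flatnonzero(state.kind == int(Kind.IEL))
    if len(iel) and np.any(cand):
        # shielded if a lamina element sits laterally over the cell on its
        # lumen side: the wall there is not ruptured
        ip = state.pos[iel]
        ir = state.radius[iel]
        ci = np.flatnonzero(cand)
        dx = np.abs(ip[None, :, 0] - x[ci, None])
        lateral = dx < (r[ci, None] + ir[None, :]) * 0.8
        dy = ip[None, :, 1] - y[ci, None]
        reach = 4.0 * r[ci, None]
        quarter = 0.25 * r[ci, None]
        between = np.where(on_lower[ci, None],
                           (dy >= -quarter) & (dy < reach),
                           (dy <= quarter) & (dy > -reach))
        shielded = np.any(lateral & between, axis=1)
        cand[ci[shielded]] = False

    wss_val = np.where(on_lower, lo_wss[c], hi_wss[c])
    return {int(state.ids[smc[i]]): float(wss_val[i])
            for i in np.flatnonzero(cand)}




# ---------------------------------------------------------------------------
# The run loop
# ---------------------------------------------------------------------------

def run_simulation(config: SimulationConfig,
                   inputs: dict[str, float] | None = None,
                   seed: int | None = None) -> Trajectory:
    """Run one full simulation; bit-identical for identical arguments.

    ``inputs`` may override the three campaign-level uncertain inputs:
    ``flow_velocity`` (m/s), ``deployment_depth`` (mm) and ``regen_time``
    (days).  ``seed`` drives the run's single RNG stream (cell-cycle draws,
    mitosis orientations, coverage realization) and defaults to
    ``config.master_seed``.
    """
    inputs = dict(inputs or {})
    depth = float(inputs.pop("deployment_depth", config.deployment_depth))
    regen_time = float(inputs.pop("regen_time",
                                  config.scenario.total_recovery_time))
    d_m = config.lumen_diameter * 1e-3
    default_u = (config.flow.velocity if config.flow.velocity is not None
                 else reynolds_mean_velocity(config))
    velocity = float(inputs.pop("flow_velocity", default_u))
    if inputs:
        raise ValueError(f"unknown inputs: {sorted(inputs)}")
    rng = np.random.default_rng(config.master_seed if seed is None else seed)

    sched = replace(config.scenario, total_recovery_time=regen_time)
    gparams = config.growth
    if gparams.wss_no_threshold is None:
        baseline_wss = 6.0 * config.flow.viscosity * velocity / d_m
        gparams = replace(gparams, wss_no_threshold=0.85 * baseline_wss)

    pristine = initialize_vessel(config)
    state = mech.deploy_stent(pristine, depth, config.deploy_steps,
                              config.mechanics)

    # stenting injury: wherever a lamina element was torn out, the smooth
    # muscle cells of that wall under its longitudinal window switch from
    # contractile to synthetic (descendants inherit the activation)
    iel0 = (pristine.kind == int(Kind.IEL))
    torn = iel0 & ~np.isin(pristine.ids, state.ids)
    half_h = pristine.domain_height / 2.0
    smc_now = state.kind == int(Kind.SMC)
    for x0, y0 in pristine.pos[torn]:
        same_wall = (state.pos[:, 1] < half_h) == (y0 < half_h)
        window = np.abs(state.pos[:, 0] - x0) <= 2.0 * config.cell_radius
        state.activated |= smc_now & same_wall & window

    spacing = config.flow.spacing
    lat = hemo.rasterize(state, spacing)
    lum = hemo.extract_lumen(lat)
    baseline_width = mean_lumen_width(lum)
    baseline_area = float(np.pi * (baseline_width / 2.0) ** 2)
    original_area = float(np.pi * (config.lumen_diameter / 2.0) ** 2)
    target_flux = velocity * d_m  # constant 2D flux, m^2/s

    # every SMC starts its cycle simultaneously with an individual duration
    smc = state.kind == int(Kind.SMC)
    state.cycle_duration[smc] = gr.sample_cycle_duration(
        gparams, rng, size=int(smc.sum()))
    state.cycle_clock[smc] = 0.0

    step_h = gparams.step
    n_steps = int(round(config.total_days * 24.0 / step_h))
    snapshot_days = sorted(config.resolved_snapshot_days())
    times = np.zeros(n_steps + 1)
    areas = np.zeros(n_steps + 1)
    widths = np.zeros(n_steps + 1)
    coverages = np.zeros(n_steps + 1)
    snapshots: dict[float, np.ndarray] = {}
    closed = False
    k_stop = n_steps + 1

    def record(k: int, lum_k: LatticeMap, t_days: float) -> None:
        w = mean_lumen_width(lum_k)
        times[k] = t_days
        widths[k] = w
        areas[k] = neointimal_area(w, baseline_area)
        smc_now = state.kind == int(Kind.SMC)
        covered = int(np.sum(smc_now & state.covered))
        exposed_unc = len(_current_exposed)
        denom = covered + exposed_unc
        coverages[k] = covered / denom if denom else 1.0

    _current_exposed: set[int] = set()
    _sticky_wss: dict[int, float] = {}

    snap_idx = 0
    for k in range(n_steps):
        t_days = k * step_h / 24.0
        if k > 0:
            lat = hemo.rasterize(state, spacing, with_owner=False)
            lum = hemo.extract_lumen(lat)
        _, counts = hemo._column_runs(lum.solid)
        if np.any(counts == 0):
            closed = True
            k_stop = k
            break
        field = hemo.solve_flow(lum, config.flow, target_flux)
        wss = _surface_wss_map(field, lum, state,
                               margin=spacing + config.cell_radius)
        exp_ids = set(wss.keys())
        # the regenerated endothelium is an attribute of the covered cell:
        # its nitric-oxide exposure persists even after the cell is buried
        # by later growth, so covered cells keep their last-known wall shear
        for cid, val in list(_sticky_wss.items()):
            wss.setdefault(cid, val)
        for cid in exp_ids:
            _sticky_wss[cid] = wss[cid]
        if exp_ids:
            exp_arr = np.asarray(sorted(exp_ids), dtype=np.int64)
            unc = ~state.covered[state.index_of(exp_arr)]
            _current_exposed = set(int(i) for i in exp_arr[unc])
        else:
            _current_exposed = set()
        record(k, lum, t_days)
        gr.update_cell_states(state, wss, gparams)
        gr.endothelium_update(state, sched, t_days, step_h / 24.0, rng,
                              exposed_ids=exp_ids)
        state = gr.attempt_mitosis(state, gparams, config.mechanics, rng)
        state.time += step_h
        while (snap_idx < len(snapshot_days)
               and snapshot_days[snap_idx] <= (k + 1) * step_h / 24.0):
            snapshots[snapshot_days[snap_idx]] = hemo.rasterize(
                state, spacing, with_owner=False).solid.copy()
            snap_idx += 1

    if not closed:
        lat = hemo.rasterize(state, spacing, with_owner=False)
        lum = hemo.extract_lumen(lat)
        record(n_steps, lum, config.total_days)
    else:
        # truncate-and-hold: freeze the last valid metrics to run's end
        hold = max(k_stop - 1, 0)
        for k in range(k_stop, n_steps + 1):
            times[k] = k * step_h / 24.0 if k < n_steps else config.total_days
            areas[k] = areas[hold]
            widths[k] = widths[hold]
            coverages[k] = coverages[hold]
    final_day = float(config.total_days)
    if final_day not in snapshots:
        snapshots[final_day] = hemo.rasterize(
            state, spacing, with_owner=False).solid.copy()

    final_area = float(areas[-1])
    resten = closed or restenosis_flag(final_area, original_area)
    return Trajectory(times=times, neointimal_area=areas,
                      mean_lumen_width=widths, coverage=coverages,
                      baseline_lumen_area=baseline_area,
                      original_lumen_area=original_area,
                      restenosis=resten, closed=closed, snapshots=snapshots,
                      lattice_spacing=spacing)


def reynolds_mean_velocity(config: SimulationConfig) -> float:
    """Mean inlet velocity implied by the configured Reynolds number."""
    return hemo.reynolds_velocity(config.flow.reynolds, config.flow.viscosity,
                                  config.flow.density,
                                  config.lumen_diameter * 1e-3)
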