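"""Force-based agent mechanics of the arterial wall.

Smooth muscle cells (SMC), internal elastic lamina elements (IEL) and stent
strut elements are modelled as freely moving soft discs.  Touching discs repel
through a Hertzian contact law with a small adhesive offset; nearby but
non-touching discs attract through a Hookean tether that stands in for the
extracellular matrix.  The wall deforms by overdamped relaxation of these
forces, and elements that sustain excessive stress (or, for IEL, strain) are
removed — this is how stent deployment ruptures the lamina and exposes the
media.

Pairwise force law, for centre distance ``d`` and contact distance
``r_a + r_b`` (positive magnitude = repulsion along the centre line):

* overlap ``delta = r_a + r_b - d > 0``:
  ``F = k_h * delta**1.5 - a_c * k_h``  (Hertz repulsion, adhesive offset)
* separation ``s = d - (r_a + r_b)`` in ``[0, tether_range)``:
  ``F = -k_t * s``  (Hookean attraction, rest length at contact)
* beyond the tether range: zero.

An isolated pair therefore equilibrates at an overlap of
``a_c ** (2/3)`` (mm), the closed-form root of the combined law.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Kind",
    "BioState",
    "Agent",
    "MechanicsParams",
    "TissueState",
    "DegenerateGeometryError",
    "MediaDestroyedError",
    "pair_force",
    "compute_forces",
    "iel_strain",
    "equilibrate",
    "remove_overloaded",
    "deploy_stent",
]


class Kind(IntEnum):
    SMC = 0
    IEL = 1
    STRUT = 2


class BioState(IntEnum):
    CONTRACTILE = 0
    SYNTHETIC = 1
    NO_INHIBITED = 2
    CONTACT_INHIBITED = 3


class DegenerateGeometryError(ValueError):
    """Two agents have (numerically) coincident centres."""


class MediaDestroyedError(RuntimeError):
    """Stent deployment removed so much tissue that the media is gone."""


@dataclass
class MechanicsParams:
    """Parameters of the contact/tether force model and its relaxation.

    Stiffnesses are in arbitrary but consistent "cell force" units; lengths in
    mm.  Removal thresholds are calibrated once (see the default vessel
    presets) so that a nominal 110 um deployment ruptures the IEL near the
    strut without destroying the media.
    """

    hertz_stiffness: float = 1.0          # force / mm^1.5
    adhesion_coefficient: float = 1e-5    # fraction of hertz_stiffness
    tether_stiffness: float = 0.05        # force / mm
    tether_range: float = 0.010           # mm
    smc_stress_threshold: float = 5e-3    # force units
    iel_stress_threshold: float = 4e-3    # force units
    iel_strain_threshold: float = 0.25    # relative link extension
    iel_displacement_threshold: float = float("inf")  # mm from rest position
    equilibration_tolerance: float = 1e-5  # force units
    max_equilibration_iters: int = 2000
    anchor_stiffness: float = 0.3         # force/mm, elastic outer support
    relax_gain: float = 1.0               # mm displacement per unit force
    max_step_fraction: float = 0.2        # per-iteration move cap, x min radius

    def __post_init__(self) -> None:
        for name in ("hertz_stiffness", "tether_stiffness", "tether_range",
                     "smc_stress_threshold", "iel_stress_threshold",
                     "iel_strain_threshold", "equilibration_tolerance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class Agent:
    """A single freely-moving element (view object; storage is array-based)."""

    id: int
    kind: Kind
    position: np.ndarray          # (2,) mm: x longitudinal, y transmural
    radius: float                 # mm
    bio_state: BioState = BioState.CONTRACTILE
    endothelium_covered: bool = False
    activated: bool = False
    cycle_clock: float = 0.0      # hours
    cycle_duration: float = 32.0  # hours

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.radius <= 0:
            raise ValueError("radius must be > 0")


@dataclass
class TissueState:
    """The full agent population plus the simulation clock.

    Stored as parallel arrays for speed; ``agent(id)`` gives an :class:`Agent`
    view.  ``ids`` is strictly increasing (new agents always get fresh,
    larger ids), which keeps id lookup a binary search even after removals.
    """

    ids: np.ndarray               # (N,) int64, strictly increasing
    kind: np.ndarray              # (N,) int8
    pos: np.ndarray               # (N, 2) float64, mm
    pos0: np.ndarray              # (N, 2) float64, rest (as-built) positions
    radius: np.ndarray            # (N,) float64, mm
    bio_state: np.ndarray         # (N,) int8
    covered: np.ndarray           # (N,) bool (SMC only meaningful)
    activated: np.ndarray         # (N,) bool
    cycle_clock: np.ndarray       # (N,) float64, hours
    cycle_duration: np.ndarray    # (N,) float64, hours
    edge_constrained: np.ndarray  # (N,) bool: held horizontally
    anchored: np.ndarray          # (N,) bool: on the elastic outer support
    strut_dir: np.ndarray         # (N,) float64: +-1 deployment direction, 0 else
    link_ids: np.ndarray          # (N, 2) int64, IEL chain neighbours, -1 none
    link_rest: np.ndarray         # (N, 2) float64, rest lengths, mm
    domain_length: float          # mm
    domain_height: float          # mm
    time: float = 0.0             # hours
    removed_count: int = 0
    next_id: int = 0

    # -- construction ------------------------------------------------------

    @classmethod
    def from_agents(cls, agents: Sequence[Agent], domain_length: float,
                    domain_height: float) -> "TissueState":
        agents = sorted(agents, key=lambda a: a.id)
        n = len(agents)
        st = cls(
            ids=np.array([a.id for a in agents], dtype=np.int64),
            kind=np.array([int(a.kind) for a in agents], dtype=np.int8),
            pos=np.array([a.position for a in agents], dtype=float).reshape(n, 2),
            pos0=np.array([a.position for a in agents], dtype=float).reshape(n, 2),
            radius=np.array([a.radius for a in agents], dtype=float),
            bio_state=np.array([int(a.bio_state) for a in agents], dtype=np.int8),
            covered=np.array([a.endothelium_covered for a in agents], dtype=bool),
            activated=np.array([a.activated for a in agents], dtype=bool),
            cycle_clock=np.array([a.cycle_clock for a in agents], dtype=float),
            cycle_duration=np.array([a.cycle_duration for a in agents], dtype=float),
            edge_constrained=np.zeros(n, dtype=bool),
            anchored=np.zeros(n, dtype=bool),
            strut_dir=np.zeros(n, dtype=float),
            link_ids=np.full((n, 2), -1, dtype=np.int64),
            link_rest=np.zeros((n, 2), dtype=float),
            domain_length=domain_length,
            domain_height=domain_height,
        )
        st.next_id = int(st.ids.max()) + 1 if n else 0
        if n and np.any(np.diff(st.ids) <= 0):
            raise ValueError("agent ids must be unique")
        return st

    # -- basic queries -----------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, ids: np.ndarray) -> np.ndarray:
        """Indices of the given ids (which must all be present)."""
        ids = np.asarray(ids, dtype=np.int64)
        idx = np.searchsorted(self.ids, ids)
        if np.any(idx >= self.n) or np.any(self.ids[np.minimum(idx, self.n - 1)] != ids):
            raise KeyError("unknown agent id")
        return idx

    def agent(self, agent_id: int) -> Agent:
        i = int(self.index_of(np.array([agent_id]))[0])
        return Agent(
            id=int(self.ids[i]), kind=Kind(int(self.kind[i])),
            position=self.pos[i].copy(), radius=float(self.radius[i]),
            bio_state=BioState(int(self.bio_state[i])),
            endothelium_covered=bool(self.covered[i]),
            activated=bool(self.activated[i]),
            cycle_clock=float(self.cycle_clock[i]),
            cycle_duration=float(self.cycle_duration[i]),
        )

    def copy(self) -> "TissueState":
        return TissueState(
            ids=self.ids.copy(), kind=self.kind.copy(), pos=self.pos.copy(),
            pos0=self.pos0.copy(),
            radius=self.radius.copy(), bio_state=self.bio_state.copy(),
            covered=self.covered.copy(), activated=self.activated.copy(),
            cycle_clock=self.cycle_clock.copy(),
            cycle_duration=self.cycle_duration.copy(),
            edge_constrained=self.edge_constrained.copy(),
            anchored=self.anchored.copy(),
            strut_dir=self.strut_dir.copy(),
            link_ids=self.link_ids.copy(), link_rest=self.link_rest.copy(),
            domain_length=self.domain_length, domain_height=self.domain_height,
            time=self.time, removed_count=self.removed_count,
            next_id=self.next_id,
        )

    def subset(self, mask: np.ndarray) -> "TissueState":
        """A copy containing only the masked agents (cross-links cleared)."""
        st = self.copy()
        keep_ids = st.ids[mask]
        for name in ("ids", "kind", "pos", "pos0", "radius", "bio_state", "covered",
                     "activated", "cycle_clock", "cycle_duration",
                     "edge_constrained", "anchored", "strut_dir",
                     "link_ids", "link_rest"):
            setattr(st, name, getattr(st, name)[mask])
        gone = ~np.isin(st.link_ids, keep_ids)
        st.link_ids[gone] = -1
        st.link_rest[gone] = 0.0
        return st

    # -- mutation helpers --------------------------------------------------

    def remove_mask(self, mask: np.ndarray) -> np.ndarray:
        """Drop the masked agents in place; returns their ids."""
        removed_ids = self.ids[mask]
        keep = ~mask
        for name in ("ids", "kind", "pos", "pos0", "radius", "bio_state", "covered",
                     "activated", "cycle_clock", "cycle_duration",
                     "edge_constrained", "anchored", "strut_dir",
                     "link_ids", "link_rest"):
            setattr(self, name, getattr(self, name)[keep])
        if len(removed_ids):
            gone = np.isin(self.link_ids, removed_ids)
            self.link_ids[gone] = -1
            self.link_rest[gone] = 0.0
        self.removed_count += int(mask.sum())
        return removed_ids

    def append_smcs(self, positions: np.ndarray, radius: np.ndarray,
                    activated: np.ndarray, cycle_duration: np.ndarray) -> np.ndarray:
        """Append newborn SMC daughters; returns their new ids."""
        m = len(positions)
        new_ids = self.next_id + np.arange(m, dtype=np.int64)
        self.next_id += m
        self.ids = np.concatenate([self.ids, new_ids])
        self.kind = np.concatenate([self.kind, np.full(m, int(Kind.SMC), dtype=np.int8)])
        self.pos = np.concatenate([self.pos, np.asarray(positions, dtype=float)])
        self.pos0 = np.concatenate([self.pos0, np.asarray(positions, dtype=float)])
        self.radius = np.concatenate([self.radius, np.asarray(radius, dtype=float)])
        self.bio_state = np.concatenate(
            [self.bio_state, np.full(m, int(BioState.SYNTHETIC), dtype=np.int8)])
        self.covered = np.concatenate([self.covered, np.zeros(m, dtype=bool)])
        self.activated = np.concatenate([self.activated, np.asarray(activated, dtype=bool)])
        self.cycle_clock = np.concatenate([self.cycle_clock, np.zeros(m)])
        self.cycle_duration = np.concatenate(
            [self.cycle_duration, np.asarray(cycle_duration, dtype=float)])
        self.edge_constrained = np.concatenate([self.edge_constrained, np.zeros(m, dtype=bool)])
        self.anchored = np.concatenate([self.anchored, np.zeros(m, dtype=bool)])
        self.strut_dir = np.concatenate([self.strut_dir, np.zeros(m)])
        self.link_ids = np.concatenate([self.link_ids, np.full((m, 2), -1, dtype=np.int64)])
        self.link_rest = np.concatenate([self.link_rest, np.zeros((m, 2))])
        return new_ids


# ---------------------------------------------------------------------------
# Forces
# ---------------------------------------------------------------------------

def _scalar_force(dist: np.ndarray, rsum: np.ndarray,
                  params: MechanicsParams) -> np.ndarray:
    """Signed force magnitude along the centre line (>0 repulsive)."""
    dist = np.asarray(dist, dtype=float)
    rsum = np.asarray(rsum, dtype=float)
    mag = np.zeros_like(dist)
    overlap = rsum - dist
    contact = overlap > 0
    mag[contact] = (params.hertz_stiffness * overlap[contact] ** 1.5
                    - params.adhesion_coefficient * params.hertz_stiffness)
    sep = -overlap
    teth = (~contact) & (sep < params.tether_range)
    mag[teth] = -params.tether_stiffness * sep[teth]
    return mag


def pair_force(a: Agent, b: Agent, params: MechanicsParams) -> np.ndarray:
    """Force exerted on ``a`` by ``b``; the force on ``b`` is the negation."""
    if a.id == b.id:
        raise ValueError("pair_force requires two distinct agents")
    dvec = a.position - b.position
    dist = float(np.hypot(dvec[0], dvec[1]))
    if dist < 1e-12:
        raise DegenerateGeometryError("coincident agent centres")
    mag = _scalar_force(np.array([dist]), np.array([a.radius + b.radius]), params)[0]
    return mag * dvec / dist


def _pairs(state: TissueState, params: MechanicsParams,
           brute: bool = False) -> np.ndarray:
    """Candidate interacting pairs (i < j), within the force cutoff."""
    n = state.n
    if n < 2:
        return np.empty((0, 2), dtype=np.intp)
    cutoff = 2.0 * float(state.radius.max()) + params.tether_range
    if brute:
        i, j = np.triu_indices(n, k=1)
        d = np.linalg.norm(state.pos[i] - state.pos[j], axis=1)
        keep = d < cutoff
        return np.column_stack([i[keep], j[keep]])
    pairs = cKDTree(state.pos).query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return np.empty((0, 2), dtype=np.intp)
    # canonical order so brute/tree paths are bit-identical
    pairs = np.sort(pairs, axis=1)
    order = np.lexsort((pairs[:, 1], pairs[:, 0]))
    return pairs[order]


def compute_forces(state: TissueState, params: MechanicsParams,
                   brute: bool = False,
                   pairs: np.ndarray | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Net force vector and contact-stress scalar for every agent.

    Stress is the sum of the magnitudes of the contact (touching) pair forces
    on the agent; tether forces do not contribute.  ``pairs`` may supply a
    precomputed candidate list (a superset of interacting pairs is fine,
    since the force law is zero beyond the tether range).
    """
    n = state.n
    if pairs is None:
        pairs = _pairs(state, params, brute=brute)
    if len(pairs) == 0:
        return np.zeros((n, 2)), np.zeros(n)
    i, j = pairs[:, 0], pairs[:, 1]
    dvec = state.pos[i] - state.pos[j]
    dist = np.sqrt(dvec[:, 0] ** 2 + dvec[:, 1] ** 2)
    if dist.min(initial=np.inf) < 1e-12:
        raise DegenerateGeometryError("coincident agent centres")
    rsum = state.radius[i] + state.radius[j]
    mag = _scalar_force(dist, rsum, params)
    scaled = mag / dist
    fx = scaled * dvec[:, 0]
    fy = scaled * dvec[:, 1]
    forces = np.column_stack([
        np.bincount(i, weights=fx, minlength=n) - np.bincount(j, weights=fx, minlength=n),
        np.bincount(i, weights=fy, minlength=n) - np.bincount(j, weights=fy, minlength=n),
    ])
    contact = (rsum - dist) > 0
    cmag = np.abs(mag[contact])
    stress = (np.bincount(i[contact], weights=cmag, minlength=n)
              + np.bincount(j[contact], weights=cmag, minlength=n))
    return forces, stress


def iel_strain(state: TissueState) -> np.ndarray:
    """Max relative extension of each IEL agent's chain links (0 elsewhere)."""
    strain = np.zeros(state.n)
    for col in (0, 1):
        nbr = state.link_ids[:, col]
        have = nbr >= 0
        if not np.any(have):
            continue
        idx = state.index_of(nbr[have])
        d = np.linalg.norm(state.pos[have] - state.pos[idx], axis=1)
        rest = state.link_rest[have, col]
        s = np.where(rest > 0, (d - rest) / np.where(rest > 0, rest, 1.0), 0.0)
        strain[have] = np.maximum(strain[have], s)
    return strain


# ---------------------------------------------------------------------------
# Relaxation, removal, deployment
# ---------------------------------------------------------------------------

def equilibrate(state: TissueState, params: MechanicsParams,
                fixed_ids: Iterable[int] = ()) -> tuple[TissueState, bool]:
    """Overdamped relaxation until residual forces fall below tolerance.

    Positions are updated by ``force * gain`` with the gain halved whenever the
    residual grows (overshoot) and slowly restored otherwise; per-iteration
    displacements are capped at a fraction of the smallest radius.  Agents in
    ``fixed_ids`` never move; edge-constrained agents move only vertically.
    Returns ``(state, converged)``; non-convergence is flagged, not fatal.
    """
    st = state.copy()
    fixed_ids = np.asarray(sorted(set(int(i) for i in fixed_ids)), dtype=np.int64)
    fixed = np.isin(st.ids, fixed_ids) if len(fixed_ids) else np.zeros(st.n, dtype=bool)
    if st.n == 0 or np.all(fixed):
        return st, True
    gain = params.relax_gain
    cap = params.max_step_fraction * float(st.radius.min())
    prev_res = np.inf
    converged = False
    # pair list refreshed every few iterations; the cutoff slack covers the
    # largest possible drift between refreshes, so no pair is ever missed
    refresh = 8
    slack = 2.0 * refresh * cap
    pairs: np.ndarray | None = None
    for it in range(params.max_equilibration_iters):
        if it % refresh == 0:
            cutoff = 2.0 * float(st.radius.max()) + params.tether_range + slack
            pairs = cKDTree(st.pos).query_pairs(cutoff, output_type="ndarray")
            if len(pairs):
                pairs = np.sort(pairs, axis=1)
                pairs = pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]
        forces, _ = compute_forces(st, params, pairs=pairs)
        # outer wall rows sit on an elastic foundation: the surrounding
        # tissue (not modelled as agents) resists their displacement
        if np.any(st.anchored):
            forces[st.anchored] -= params.anchor_stiffness * (
                st.pos[st.anchored] - st.pos0[st.anchored])
        forces[fixed] = 0.0
        forces[st.edge_constrained, 0] = 0.0
        res = float(np.sqrt((forces ** 2).sum(axis=1)).max()) if st.n else 0.0
        if res < params.equilibration_tolerance:
            converged = True
            break
        if res > prev_res:
            gain = max(gain * 0.5, 1e-6 * params.relax_gain)
        else:
            gain = min(gain * 1.05, params.relax_gain)
        prev_res = res
        step = forces * gain
        mx = float(np.sqrt((step ** 2).sum(axis=1)).max())
        if mx > cap:
            step *= cap / mx
        st.pos = st.pos + step
    return st, converged


def remove_overloaded(state: TissueState,
                      params: MechanicsParams) -> tuple[TissueState, np.ndarray]:
    """Remove SMCs over the stress threshold and IELs over stress or strain.

    Strut agents are never removed.  Returns the new state and removed ids.
    """
    _, stress = compute_forces(state, params)
    strain = iel_strain(state)
    smc = state.kind == int(Kind.SMC)
    iel = state.kind == int(Kind.IEL)
    # the lamina also tears when dragged bodily from its rest position
    # (rotation of broken chain ends produces no link strain, but a real
    # membrane cannot follow such deformation); off when threshold is inf
    displacement = np.linalg.norm(state.pos - state.pos0, axis=1)
    doomed = ((smc & (stress > params.smc_stress_threshold))
              | (iel & ((stress > params.iel_stress_threshold)
                        | (strain > params.iel_strain_threshold)
                        | (displacement > params.iel_displacement_threshold))))
    st = state.copy()
    # the lamina is a membrane, not loose beads: when an element ruptures,
    # its chain neighbours are re-linked across the gap (rest lengths add),
    # so subsequent drape or stretch of the remaining chain still strains it
    for idx in np.flatnonzero(doomed & iel):
        (a_id, b_id) = st.link_ids[idx]
        bridge_rest = float(st.link_rest[idx].sum())
        for my_id, other_id in ((a_id, b_id), (b_id, a_id)):
            if my_id < 0:
                continue
            my = int(st.index_of(np.array([my_id]))[0])
            slot = np.flatnonzero(st.link_ids[my] == st.ids[idx])
            if len(slot) == 0:
                continue
            st.link_ids[my, slot[0]] = other_id
            st.link_rest[my, slot[0]] = bridge_rest if other_id >= 0 else 0.0
    removed = st.remove_mask(doomed)
    return st, removed


def deploy_stent(state: TissueState, depth: float, n_steps: int,
                 params: MechanicsParams) -> TissueState:
    """Push the strut(s) into the wall in equal increments.

    After each increment the struts are held fixed, forces are equilibrated so
    the wall conforms, and overloaded agents are removed.  Deterministic.
    """
    if depth < 0:
        raise ValueError("deployment depth must be >= 0")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    st = state.copy()
    strut = st.strut_dir != 0.0
    strut_ids = st.ids[strut]
    n_tissue0 = int(np.sum(st.kind != int(Kind.STRUT)))
    per_step = depth / n_steps
    for _ in range(n_steps):
        sm = st.strut_dir != 0.0
        st.pos[sm, 1] += st.strut_dir[sm] * per_step
        # rupture changes the force balance, so relax and cull repeatedly
        # until the configuration is stable for this strut position
        for _round in range(10):
            st, _ = equilibrate(st, params, fixed_ids=strut_ids)
            st, removed = remove_overloaded(st, params)
            if len(removed) == 0:
                break
    if depth > 0 and n_tissue0:
        remaining = int(np.sum(st.kind != int(Kind.STRUT)))
        if remaining < 0.5 * n_tissue0:
            raise MediaDestroyedError(
                f"deployment depth {depth} mm removed {n_tissue0 - remaining} of "
                f"{n_tissue0} tissue agents")
    return st
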