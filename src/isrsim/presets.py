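"""Ready-made simulation configurations.

``porcine_default`` is the study geometry: a 1.5 mm section of healthy
porcine coronary artery with a 1 mm lumen, five SMC layers per wall, a bare
metal stent deployed to a mean depth of 110 um, steady flow at Re = 120
(mean velocity 0.48 m/s) solved with the reference lattice Boltzmann method,
and a 30-day growth phase at 1 h steps.

``coarse_demo`` is a desk-scale variant for tests, examples and small
campaigns: a shorter, narrower vessel with larger cells, 3 h steps over
12 days and the quasi-1D lubrication flow mode.  It preserves the model
structure and the uncertain-input ranges while keeping a single run well
under a second of compute.
"""

from __future__ import annotations

from .engine import SimulationConfig
from .growth import GrowthParams, ScenarioSchedule
from .hemodynamics import FlowParams
from .mechanics import MechanicsParams


def porcine_default(scenario: str = "S1") -> SimulationConfig:
    """Full-fidelity configuration of the porcine coronary study."""
    return SimulationConfig(
        vessel_length=1.5,
        lumen_diameter=1.0,
        media_layers=5,
        cell_radius=0.015,
        deployment_depth=0.110,
        deploy_steps=10,
        strut_size=0.09,
        total_days=30.0,
        scenario=ScenarioSchedule(scenario=scenario),
        growth=GrowthParams(step=1.0),
        mechanics=MechanicsParams(),
        flow=FlowParams(mode="lbm", spacing=0.010),
    )


def coarse_demo(scenario: str = "S2") -> SimulationConfig:
    """Desk-scale configuration used by the test-suite campaigns."""
    return SimulationConfig(
        vessel_length=0.8,
        lumen_diameter=0.7,
        media_layers=3,
        cell_radius=0.02,
        deployment_depth=0.110,
        deploy_steps=5,
        strut_size=0.08,
        total_days=26.0,
        scenario=ScenarioSchedule(scenario=scenario),
        growth=GrowthParams(step=4.0, contact_neighbor_limit=5,
                            neighbor_tolerance=0.25, relax_max_iters=60),
        mechanics=MechanicsParams(
            smc_stress_threshold=1.5e-2,
            iel_stress_threshold=1.2e-2,
            iel_displacement_threshold=0.06,
            max_equilibration_iters=400,
        ),
        flow=FlowParams(mode="lubrication", spacing=0.02),
    )
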