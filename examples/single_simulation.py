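"""Run one desk-scale in-stent restenosis simulation.

Deploys a bare-metal strut 110 um into each wall of a small artery section,
then grows the neointima for 26 days under re-endothelialization Scenario 2.
Prints the neointimal area over time and the restenosis verdict.
"""

from isrsim import run_simulation
from isrsim.presets import coarse_demo

config = coarse_demo()
inputs = {"flow_velocity": 0.48,       # m/s, Re = 120 equivalent
          "deployment_depth": 0.11,    # mm
          "regen_time": 19.0}          # days to full endothelium recovery

trajectory = run_simulation(config, inputs=inputs, seed=1)

print("day   neointimal area (mm^2)   mean lumen width (mm)")
for k in range(0, len(trajectory.times), 24):
    print(f"{trajectory.times[k]:4.0f}   {trajectory.neointimal_area[k]:8.4f}"
          f"               {trajectory.mean_lumen_width[k]:8.4f}")
print(f"final {trajectory.neointimal_area[-1]:8.4f}"
      f"               {trajectory.mean_lumen_width[-1]:8.4f}")
print(f"\npost-stent baseline lumen area: "
      f"{trajectory.baseline_lumen_area:.4f} mm^2")
print(f"restenosis (neointima > 50% of the original lumen): "
      f"{trajectory.restenosis}")
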