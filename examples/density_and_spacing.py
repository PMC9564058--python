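"""Enumerate mast cells in a rendered field and derive density statistics.

Renders a noise-free steady-state field, segments the red channel,
applies the planar-density formula and the square-lattice spacing rule,
and walks the depletion/repopulation curve.
"""

from mastreg.detect import characteristic_spacing, enumerate_density
from mastreg.pipeline import RunConfig, analyze_stack
from mastreg.scenegen import (
    NoiseConfig,
    homeostasis_scenario,
    mc_repopulation_density,
    simulate_scene,
)

config = homeostasis_scenario(seed=1, noise=NoiseConfig.off())
stack, truth = simulate_scene(config)
analysis = analyze_stack(stack, RunConfig(scenario=config))

area_um2 = config.field_size_um[0] * config.field_size_um[1]
result = enumerate_density(len(analysis.mc_detections[0]), area_um2)
print(f"cells counted: {result.n_cells} in {result.area_um2:.0f} um^2")
print(f"density: {result.density_per_mm2:.1f} cells/mm^2 "
      f"(seeded {truth.densities_seeded['red_tdt']:.1f})")
print(f"characteristic spacing: "
      f"{characteristic_spacing(result.density_per_mm2):.1f} um")
# At ~360 cells/mm^2 the spacing is ~53 um: the mast-cell network mesh size.

print("\nrepopulation after conditional ablation (baseline 360/mm^2):")
for day in (0, 6, 11, 30, 90, 120):
    print(f"  day {day:3d}: {mc_repopulation_density(day, 360.0):6.1f} cells/mm^2")
# Density collapses by day 6, reappears by day 11, and recovers to only
# ~150 cells/mm^2 at three months - repopulation is slow and partial.
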