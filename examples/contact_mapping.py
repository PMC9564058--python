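"""Detect mast cell-Treg contacts via local correlation maps.

Renders an anaphylaxis-arm contact video, computes the Gaussian-windowed
local Pearson coefficient between the red and green channels, extracts
the negative component as contact sites, links them over time, and
classifies event durations.
"""

from mastreg.contacts import classify_contacts
from mastreg.pipeline import (
    RunConfig,
    analyze_stack,
    score_contact_recovery,
)
from mastreg.scenegen import NoiseConfig, contact_scenario, simulate_scene

config = contact_scenario(pca=True, seed=5, noise=NoiseConfig.off())
stack, truth = simulate_scene(config)
analysis = analyze_stack(stack, RunConfig(scenario=config))

dt = config.meta.frame_interval_min
counts = classify_contacts(analysis.events)
print(f"{len(truth.contacts)} contact episodes seeded, "
      f"{len(analysis.events)} events recovered")
print(f"duration classes: short (0-10 min) = {counts['short']}, "
      f"intermediate (10-50 min) = {counts['intermediate']}, "
      f"long (>50 min) = {counts['long']}")

records = score_contact_recovery(analysis, truth, dt)
errors = [r["duration_error_min"] for r in records]
print(f"per-episode duration error: max {max(errors):.1f} min "
      f"(one frame = {dt:.0f} min)")
# After IgE/antigen challenge the modal contact class is 10-50 min with
# a tail beyond 50 min; in the control arm (pca=False) nearly all
# contacts are short-lived.
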