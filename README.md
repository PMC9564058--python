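# mastreg

Analysis of intravital confocal time-lapse movies of mast cell–Treg
dynamics in mouse ear skin — with a synthetic movie generator that makes
every measurement verifiable against exact ground truth.

Dermal mast cells (MCs, tdTomato-red) form a sessile network that
regulatory T cells (Tregs, eGFP-green) infiltrate and contact after
IgE-mediated activation.  Quantifying that interaction from 5-D
(x, y, z, color, time) confocal recordings takes a chain of image
operations: Z-projection, cell segmentation with autofluorescence
exclusion, density statistics, track linking with velocities in µm/min,
and contact detection via local correlation maps.  `mastreg` implements
that chain as a reusable, deterministic library for imaging scientists
and immunologists, and — since such recordings are rarely shareable —
ships a generator that renders realistic two/three-channel skin movies
(sessile elongated MCs with tdT-negative nuclear holes, motile Tregs,
yellow autofluorescent follicles, scheduled contact episodes) from known
parameters, so the whole pipeline can be validated end to end without a
microscope.

## The quantities it computes

* **Planar density** of a cell population, by the counting formula
  ρ = n / A(µm²) × 10⁶ cells/mm², and the **characteristic spacing** of
  a network at that density, 1000/√ρ µm (360 MCs/mm² ⇒ 52.7 ≈ 53 µm).
* **Depletion/repopulation kinetics** of the MC network after
  conditional ablation (piecewise-linear density curve, baseline → 5 →
  30 → 150 cells/mm² at days 0/6/11/90).
* **Motility**: greedy nearest-neighbor track linking and mean
  frame-to-frame speed v = Σ|Δx| / Σ Δt in µm/min; temporal RGB triad
  encoding (blue = t−1, green = t, red = t+1) that renders immobile
  structures white and motion as red leading / blue trailing color.
* **Contacts**: the local Pearson coefficient of the red and green
  channels under a 5-pixel Gaussian window (±3.6 µm at the default
  0.72 µm/px calibration),
  r(x) = S(RG)−S(R)S(G) / √((S(R²)−S(R)²)(S(G²)−S(G)²)),
  whose **negative component** marks juxtaposed membranes; gated,
  region-linked over time, and classified into short (0–10 min),
  intermediate (10–50 min) and long (>50 min) contact events.

## A worked example

```python
from mastreg.contacts import classify_contacts
from mastreg.pipeline import RunConfig, analyze_stack, score_contact_recovery
from mastreg.scenegen import NoiseConfig, contact_scenario, simulate_scene

config = contact_scenario(pca=True, seed=5, noise=NoiseConfig.off())
stack, truth = simulate_scene(config)          # render + ground truth
analysis = analyze_stack(stack, RunConfig(scenario=config))
print(classify_contacts(analysis.events))
```

This simulates a 0.42 × 0.42 mm anaphylaxis-arm video (30 frames, 4 min
duty cycle), runs the full measurement chain, and recovers the seeded
contact episodes (`examples/contact_mapping.py` prints the comparison):

```
48 contact episodes seeded, 51 events recovered
duration classes: short (0-10 min) = 9, intermediate (10-50 min) = 31, long (>50 min) = 11
per-episode duration error: max 0.0 min (one frame = 4 min)
```

Every seeded episode is recovered as one event with its duration exact
to the frame; the three extra events are brief encounters outside the
scheduled episodes.  The modal class after challenge is 10–50 min with a
sustained >50 min tail — in a control arm (`pca=False`) nearly all
contacts are short-lived.  `examples/` holds one such script per
capability (simulation, density and spacing, RGB motility encoding,
velocities, contact mapping, arm comparison); each prints the numbers it
computes and what they mean.

A thin CLI wraps the same pipeline for shell use:

```
mastreg simulate --outdir scene/ --seed 1
mastreg run-all --outdir run/ --arm pca --seed 1
mastreg compare run_control/summary.json run_pca/summary.json
```

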