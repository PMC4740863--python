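# mwbrain

Wideband microwave radar head imaging for intracranial hemorrhage (ICH)
detection: a delay-and-sum (DAS) back-projection imager driven by a
point-of-entry, distance-dependent effective head permittivity model,
together with its signal-processing chain, image-quality metrics, a
synthetic layered-head forward model, and radiation/thermal safety
calculators.

## The problem

Intracranial bleeding is a medical emergency whose on-the-spot detection
is out of reach for MRI/CT. A portable microwave scanner exploits the
dielectric contrast between blood and brain tissue: a single ultra-wideband
antenna sweeps 0.75–2.55 GHz at N positions around the head (monostatic
S₁₁ acquisition), and an image of the scanned 2-D layer is reconstructed by
back-projection. The catch is the propagation model: classic DAS assumes a
single constant head permittivity ε_avg, but the head is a stack of very
different tissues (skin ≈ 50, fat ≈ 5, skull ≈ 12, CSF ≈ 69, gray ≈ 52,
white ≈ 39), so a constant ε mislocates deep scatterers. This package
implements the improved algorithm in which the effective permittivity seen
by a signal entering the skin at entry point *e* grows with penetration
depth *d*:

```
ε_eff(d) = ε_max · (1 − c₁ · exp(−c₂ · d / a)),
```

where *a* is the distance from the entry point to the head centre and
(ε_max, c₁, c₂) are fitted to per-angle permittivity curves extracted from
differential signal-arrival times, ε_eff = (c·Δt/d)². The monostatic
round-trip delay to a grid cell **r** is

```
τ(n, r) = 2 · min over entry points e of [ |x_n − e|/c + |e − r|·√ε_eff(|e−r|)/c ],
```

with the entry search restricted to the boundary arc the directional
antenna actually illuminates, and the image is

```
I(r) = | Σ_n ŝ_n( τ(n, r) ) |,   max-normalised to 1,
```

where ŝ_n are the scattered signals after inverse-DFT range conversion,
adjacent-average (Woody) skin-clutter subtraction, and per-position gain
normalisation. Image quality is quantified by γ (max target intensity /
max clutter intensity; γ > 1 ⇔ correct localization), Q (mean target /
mean clutter) and δ (distance from the true bleed centre to the image
argmax).

Because no scattering data are deposited with the original system, the
package ships a first-class synthetic forward model: a 2-D elliptic
layered head (skin/fat/skull/CSF, gray shell, white core) with an optional
rectangular blood target, producing per-position reflection sweeps from a
Born-type ray model with exact ground-truth delays — deliberately a
*different* propagation model than the imager assumes, so model-mismatch
experiments are meaningful.

## Worked example

```python
import numpy as np
import mwbrain as m
from mwbrain.phantom import (make_head_phantom, insert_target,
                             simulate_reflection, ForwardConfig,
                             permittivity_curves_from_phantom)

base = make_head_phantom()                       # 90 x 110 mm layered head
curves = permittivity_curves_from_phantom(base, np.arange(0, 360, 45))
model = m.fit_permittivity_model(curves).model   # calibrate eps_eff(d)

geometry = m.make_offset_scan(base.boundary, 15.0, 32)   # 32 pos, 15 mm standoff
grid = m.ImagingGrid(extent=(300.0, 300.0), cell_size=1.0)

phantom = insert_target(base, (0.0, 65.0), 20.0, 20.0)   # 20x20 mm bleed
data = simulate_reflection(phantom, geometry, m.FrequencySweep(),
                           ForwardConfig(seed=1))
res = m.reconstruct_pipeline(data, base.boundary, grid, model)

region = m.rectangle_target(grid, (0.0, 65.0), 20.0, 20.0,
                            head=res.table.mask)
print(m.evaluate_image(res.image, region))
```

prints

```
ImageMetrics(gamma=1.7474..., q_ratio=5.8298..., delta_mm=0.7071...,
             argmax_location=array([ 0.5, 65.5]), localized_correctly=True)
```

i.e. the image maximum falls inside the true 20×20 mm bleed (γ ≈ 1.75 > 1),
the bleed region is on average ≈ 5.8× brighter than the rest of the head,
and the peak sits 0.71 mm from the true centre (one cell diagonal at the
1 mm grid). Re-running with `m.PermittivityModel(kind="fixed", eps_fixed=1.0)`
mislocates the target by > 100 mm, which is the point of the variable
model. A command-line interface wraps the same flow:

```sh
mwbrain simulate -c cfg.yaml -o run/
mwbrain reconstruct run/ --model proposed
mwbrain evaluate run/
mwbrain reconstruct run/ --model fixed --eps 30..50step5   # legacy sweep
mwbrain safety -o thermal.csv
```

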