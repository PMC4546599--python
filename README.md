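# xdfict

Analyzer-based X-ray phase-contrast CT simulation and dense-object
(beam-deflection) artefact suppression.

## The problem

X-ray dark-field imaging (XDFI) measures the refraction angle θ_r a
specimen imparts on a monochromatic beam: a Laue-case analyzer crystal
converts the angle into an intensity modulation through the slope of its
rocking curve (working point A), while the flat top of the curve (point B)
yields a registered pure-absorption image.  Since θ_r(ξ, θ) = ∂/∂ξ (ℜ_θ δ)
— the ξ-derivative of the Radon transform of the refractive-index
decrement δ(x, y) — tomographic inversion of the extracted refraction
sinogram recovers a δ map with soft-tissue contrast far beyond
attenuation CT.

Soft tissue deflects the beam by ~10⁻⁷ rad and stays inside the
analyzer's one-to-one (measurable) range.  Dense structures —
calcifications in atherosclerotic arteries, bone — deflect by far more;
the analyzer response saturates and every ray crossing them carries
invalid refraction data, producing severe streak artefacts that destroy
the soft-tissue detail *around* the dense object.  `xdfict` simulates
this acquisition physics on synthetic specimens and removes the artefact
with an iterative missing-data reconstruction.

## The algorithm

With p(0)(ξ, θ) the measured differential refraction sinogram and R_θ the
per-angle detector intervals whose rays cross dense structures (located
by thresholding the absorption tomogram and projecting the dense mask):

1. zero the invalid entries of p(0) on R_θ; segment the object support S
   from the initial phase tomogram;
2. initialize f(1) by conventional reconstruction, smoothed;
3. reproject: p(n) = ∂/∂ξ (ℜ_θ f(n));
4. blend: keep measured data outside R_θ, and inside use k·p(n) with the
   per-angle factor k chosen so each angle's total ξ-sum vanishes — the
   identity ∫ p dξ = 0 that any derivative of a compactly supported
   projection must satisfy;
5. invert by convolving each angle with the signum function (which
   integrates the derivative) followed by algebraic reconstruction (ART);
6. zero pixels outside S, then remove accumulated noise by
   total-variation denoising, min_{f≥0} ‖f − f̃‖² + λ·TV(f);
7. repeat 3–6 until ‖f(n+1) − f(n)‖/‖f(n)‖ ≤ 10⁻³.

The package provides every stage as a library: phantom generation
(`phantoms`), the projector/ART primitives (`projector`), the XDFI
forward model and refraction extraction (`forward`), segmentation
(`segmentation`), signum+ART phase reconstruction (`recon`), TV
denoising (`tv`), the suppression loop as a model/results pair
(`suppression`), evaluation metrics (`metrics`), and TIFF I/O plus a CLI
(`io`, `cli`).

## Worked example

```python
import dataclasses
import numpy as np
import xdfict as x
from xdfict import phantoms
from xdfict.forward import log_absorption

# arterial-wall phantom with a calcification-like inclusion (1 cm field)
spec = dataclasses.replace(phantoms.artery_preset(0), grid_size=128, pixel_pitch=78.0)
pair = phantoms.make_phantom(spec)
rc = x.RockingCurveModel()                     # FWHM 2e-6 rad, point A on the flank
angles = np.linspace(0.0, 180.0, 180, endpoint=False)

i_refr, i_abs = x.simulate_acquisition(pair, None, rc, angles, photons=1e6, seed=0)
p0, saturated = x.extract_refraction(i_refr, i_abs, rc)
print(f"saturated sinogram fraction: {saturated.mean():.3f}")

abs_tomo = x.fbp(log_absorption(i_abs))
abs_tomo = x.TomogramGrid(abs_tomo.values, abs_tomo.pixel_pitch, "mu")

naive = x.reconstruct_phase(p0)                # streaked
result = x.ArtefactSuppressionModel(p0, abs_tomo).fit()
print(result.summary())

rmse_naive = x.band_rmse(naive, pair.delta_map, pair.dense_mask_truth, band_px=10)
rmse_fixed = x.band_rmse(result.tomogram, pair.delta_map, pair.dense_mask_truth, band_px=10)
print(f"near-inclusion band RMSE: naive {rmse_naive:.2e}  suppressed {rmse_fixed:.2e}  "
      f"reduction {(1 - rmse_fixed / rmse_naive) * 100:.0f}%")
```

Output:

```
saturated sinogram fraction: 0.080
Beam-deflection artefact suppression
====================================================
grid: 128 x 128 px @ 78 um
angles: 180 over [0, 179] deg
dense pixels: 106, support pixels: 5583, missing sinogram fraction: 0.159
iterations: 13 (max 30), converged: True (tol 0.001)
final rel_change: 8.835e-04, k range: [0.962, 1.067], TV: 0.002628
near-inclusion band RMSE: naive 3.89e-08  suppressed 4.57e-09  reduction 88%
```

8% of the sinogram saturates at the calcification; the loop converges in
13 iterations with per-angle rescale factors settling near 1, and the
RMSE of the soft tissue within 10 px of the inclusion drops by 88%
relative to naively reconstructing the corrupted data.

The same pipeline is scriptable from the shell:

```sh
xdfict simulate --preset artery --seed 0 --out sim/
xdfict suppress --refraction sim/p0.tif --absorption sim/i_abs.tif --out run/
xdfict evaluate --recon run/suppressed.tif --truth sim/delta_truth.tif \
    --dense-mask sim/dense_truth.tif --out metrics.csv
```

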