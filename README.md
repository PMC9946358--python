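# bioink-optics

Light-transport analysis for high-cell-density DLP bioprinting inks.

Encapsulated cells scatter the projector's 405-nm light (refractive-index
mismatch between cytoplasm, n ≈ 1.36–1.39, and a water-like hydrogel,
n ≈ 1.33), which blurs the projected cross-sections and destroys printable
resolution at cell densities of 10⁷–10⁸ cells/ml. Adding iodixanol (IDX), an
iso-osmolar biocompatible index-raising agent, matches the bioink toward the
cytoplasm and suppresses the scattering roughly ten-fold. This package
implements the optical analysis behind that result, for bioprinting and
tissue-optics researchers who want to quantify and predict the effect:

- **Forward Monte Carlo transport** in a plane-parallel bioink slab
  (Henyey–Greenstein scattering with anisotropy g, Fresnel/Snell
  boundaries): total transmittance/reflectance/absorptance
  (T + R + A = 1), exit-angle distributions, and depth-resolved scattering
  point-spread functions (PSFs) of a pencil beam.
- **Inverse estimation** of the scattering coefficient μs and anisotropy g
  (μs′ = μs(1−g)) from integrating-sphere (T, R) and goniometer (angular
  scan) data, by particle swarm optimization over the forward model under
  common random numbers.
- **Projection blurring**: the printed light field at depth z is
  pattern ⊛ PSF(z); line-pair ladders and spoke targets quantify the
  smallest resolvable feature via Michelson contrast
  (Imax − Imin)/(Imax + Imin).
- **Critical-angle refractometry**: reduction of TIR-boundary readings from
  a high-index prism (N-SF11, n = 1.8421 at 405 nm) to sample indices via a
  two-standard linear calibration, plus the linear IDX mixing model
  n(c) and its inverse (what concentration hits a target index).
- **Synthetic data**: every measurement the pipeline consumes can be
  generated from the forward model with an explicit noise model and the
  generating truth embedded, including presets for the two published ink
  conditions (0% IDX: μs = 11.76 mm⁻¹, μs′ = 0.164 mm⁻¹; 30% IDX:
  μs = 1.377 mm⁻¹, μs′ = 0.014 mm⁻¹).

See `docs/methods.md` for the model details, defaults, and limitations.

## Worked example

Simulate the untuned ink, fit its properties back from a synthetic
measurement, and ask what feature size survives at the bottom of a 250-μm
print layer:

```python
import numpy as np
from bioink_optics import (
    PRESETS, SlabGeometry, TallyConfig, FitConfig,
    run_forward, fit_optical_properties, resolution_at_depth,
)
from bioink_optics.synthetic_data import NOISE_FREE, synth_measurement

geom = SlabGeometry(thickness=1.0, n_ambient=1.0)   # 1-mm slab in air
props = PRESETS["IDX0"].props                       # mu_s=11.76, g=0.98605

# forward run with PSF tallies every 25 um
cfg = TallyConfig(n_photons=100_000, seed=424,
                  depth_slices=tuple(np.arange(25.0, 251.0, 25.0)))
res = run_forward(props, geom, cfg)
print(f"T={res.T_total:.3f} R={res.R_total:.3f}")
print(f"PSF RMS radius at 250 um: {res.psf_stack.rms_radius(250.0):.1f} um")

# invert a noise-free synthetic measurement back to (mu_s, g)
meas = synth_measurement(props, geom, NOISE_FREE, seed=11, n_photons=2_000_000)
fit = fit_optical_properties(meas, FitConfig(seed=1))
print(f"recovered mu_s={fit.mu_s_hat:.2f} mm^-1, mu_s'={fit.mu_s_prime_hat:.3f} mm^-1")

# printable feature size at the bottom of a 250-um structure
rep = resolution_at_depth(res.psf_stack, 250.0, threshold=0.1)
print(f"min resolved feature at 250 um: {rep.min_resolved} um")
```

Output:

```
T=0.888 R=0.112
PSF RMS radius at 250 um: 38.8 um
recovered mu_s=11.70 mm^-1, mu_s'=0.164 mm^-1
min resolved feature at 250 um: 10.0 um
```

T + R = 1 because the dye-free ink absorbs nothing; the recovered μs and μs′
sit within a percent of the generating truth (11.76 and 0.164 mm⁻¹); and the
untuned ink's PSF has spread to ~39 μm RMS by 250 μm depth. Running the same
lines with `PRESETS["IDX30"]` gives an RMS radius of ~12 μm at the same
depth — the optical statement of why index matching rescues print fidelity.

A command line mirrors the library:

```sh
bioink-optics synth --preset IDX30 --seed 7 --out work/
bioink-optics fit --measurement work/measurement_IDX30.json --seed 1 --out work/
bioink-optics psf --mu-s 11.76 --g 0.98605 --n 1.34 --out work/
bioink-optics refract --standards standards.json --reading 800
```

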