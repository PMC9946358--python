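# Methods

This package models how light propagates through cell-laden bioinks during
digital-light-processing (DLP) bioprinting, and how tuning the bioink's
refractive index with iodixanol (IDX) suppresses cell-induced scattering and
restores printable resolution. It has four computational parts: a forward
Monte Carlo transport model, an inverse estimator of optical properties, a
projection-blur/resolution predictor, and a critical-angle refractometry
reduction, with a synthetic-data generator that emulates every measurement
the pipeline consumes.

## Physical setting and parameters

A bioink slab of thickness `d` (default 1 mm, the measurement geometry) with
refractive index `n` sits in an ambient medium (default air, `n_amb = 1`,
matching a goniometer measurement of the bare sample). Its optics at the
printer's 405-nm working wavelength are summarized by:

- `mu_a` (mm⁻¹) — absorption coefficient. Dye-free measurement inks absorb
  negligibly, so `mu_a = 0` is the default and the inverse fit holds it
  fixed unless asked otherwise.
- `mu_s` (mm⁻¹) — scattering coefficient. Encapsulated cells are large,
  weakly contrasted Mie scatterers; measured values run from 11.76 mm⁻¹
  (untuned ink, 40 M cells/ml) down to 1.377 mm⁻¹ with 30% w/v IDX.
- `g` — anisotropy, the mean cosine of the single-scattering deflection.
  Cell scattering is strongly forward-peaked (`g ≈ 0.986–0.990` for the two
  bundled conditions, derived from the published (`mu_s`, `mu_s'`) pairs as
  `g = 1 − mu_s'/mu_s`).
- `mu_s' = mu_s (1 − g)` (mm⁻¹) — reduced scattering coefficient, the
  isotropic-equivalent rate that governs diffuse spread. The headline
  effect is its ~11.7-fold drop (0.164 → 0.014 mm⁻¹) on index matching.

The refractive-index mixing model is linear between two anchors, by default
(0%, 1.333) — a water-like untuned hydrogel — and (60%, 1.45), the stock
IDX solution. Only those two index values are stated quantities; linearity
is empirically supported on 20–35% w/v, so a warning is emitted outside that
window. Users with measured anchors should supply them.

## Forward Monte Carlo (photon_mc)

Weighted-photon transport in a plane-parallel slab, in the standard layered
tissue-optics formulation:

- free paths `s = −ln(1−u)/mu_t`, `mu_t = mu_a + mu_s`; `mu_t = 0`
  propagates ballistically to the boundary;
- fractional absorption `mu_a/mu_t` of the packet weight per interaction;
- Henyey–Greenstein (HG) scattering sampled by its closed-form inverse CDF,
  uniform azimuth, and the standard direction rotation with a special case
  for `|dz| > 1 − 1e−6`. HG is the field's default one-parameter phase
  function and makes `g` exactly its parameter;
- boundary events: unpolarized Fresnel reflectance, one stochastic
  accept/reject per crossing (no weight splitting), Snell refraction of exit
  directions; exit polar angles are tallied in the ambient medium in 1° bins
  over [0°, 90°). Specular entry reflection is handled stochastically at the
  first interface, counted in `R_total` and also reported as `R_specular`;
- Russian roulette below weight 1e−4 with survival 0.1, and — because
  absorption-free packets never lose weight — an additional unbiased
  roulette on trajectory length (survival 0.5 with weight ×2, applied every
  250 events beyond 500). Physically plausible inks never reach it; it
  exists to bound the cost of strongly diffusive corners of the inverse
  search space (high `mu_s'` with total internal reflection trapping), at
  the price of extra weight variance there. A 10⁶-event hard cap guards
  against pathological trajectories.
- uncertainty: the photon budget is split into 10 equal batches with
  sub-seeds spawned from the run seed; `batch_se` reports standard errors of
  T and R from batch means. Runs are bit-reproducible given (seed, config).

Point-spread functions: for a pencil beam at normal incidence, packet weight
is accumulated at each downward crossing of configured depth planes into a
lateral grid (5 μm pitch, ±320 μm, planes every 10 μm to 250 μm by default —
250 μm being the printed test-structure thickness). Kernels are normalized
to unit sum per depth.

Default photon budget for reported forward runs: 10⁶.

## Inverse estimation (inverse_fit)

The measurement is (T_total, R_total, angular scan) of one slab. The misfit
of a candidate (`mu_s`, `g`) is

    w_T ((T_sim − T_meas)/max(T_meas, ε))²
  + w_R ((R_sim − R_meas)/max(R_meas, ε))²
  + w_ang · N · mean_b (a_sim(b) − a_meas(b))² / (a_meas(b) + ε_N)

with weights (1, 1, 1): the angular term is a Pearson chi-square per bin
against the evaluation run's own shot noise (`N` = transmitted photon
count, ε_N = half a photon's fraction). This weighting is a deliberate
choice: with `mu_a = 0`, T and R depend on (`mu_s`, `g`) essentially only
through `mu_s'` — the classical similarity relation — so the information
separating `mu_s` from `g` lives in a small quasi-ballistic excess in the
first few degrees of the scan. Variance weighting amplifies exactly those
residuals, whereas uniform per-bin metrics (a log-intensity form and a
cumulative Cramér–von Mises form remain available via `angular_metric`)
drown the signal in wide-angle shot noise or dilute it over all bins.

Each evaluation reruns the forward model at `photons_per_eval` (2×10⁴)
photons with a fixed sub-seed (common random numbers), making the objective
a deterministic function of the parameters.

Optimization proceeds in three stages:

1. **Global PSO** with the Clerc constriction constants (inertia 0.729,
   cognitive = social = 1.49445), 20 particles × 50 iterations, positions
   clipped to bounds with velocity reflection, non-finite evaluations
   resampled. The swarm searches (log10 `mu_s`, log10(1 − `g`)): scattering
   strength spans decades, anisotropy varies on the scale of (1 − g), and in
   these coordinates the similarity ridge is a straight valley — in linear
   coordinates it is so thin in `g` that the swarm stagnates before finding
   it. This stage localizes the objective basin but can stop ±0.1 dex off
   in `mu_s'` and dex-scale distances along the ridge.
2. **Deterministic profile scans** in the valley-aligned coordinates
   u = log10 `mu_s'` (stiff) and v = log10 `mu_s` − log10(1 − `g`) (sloppy,
   motion along the ridge). The objective is exquisitely sensitive to u (a
   few percent error in `mu_s'` multiplies the misfit) and the optimal u
   drifts with v, so raw v-scans at fixed u are biased and small PSO swarms
   miss a valley occupying a few percent of any sufficiently wide box.
   Instead each candidate v is scored at its own u optimum — located by a
   three-point parabola in u (stiff and convex, three points suffice) —
   and the profiled minima are compared: a coarse round (v ± 2.0, 13
   points at 4× photons, extended past an edge while the minimum lands
   there) then a fine round (v ± 0.33, 9 points at 15×).
3. **Response-surface polish.** A frozen-seed objective surface is rugged
   at fine parameter scales; its spurious minima displace even an exact
   minimizer of that surface by several percent in `mu_s` at practical
   photon budgets. The fit therefore finishes with widely spaced grids
   whose fitted vertices are insensitive to that ruggedness (objective
   averaged over two fixed sub-seeds at 50× photons): a u parabola
   (± 0.025), a v parabola (± 0.075), and finally a 9-point star fit to a
   full 2-D quadratic (u ± 0.012 × v ± 0.035) whose joint vertex absorbs
   the diagonal u–v coupling of the trough that one-dimensional vertices
   leave behind.

With these defaults, noise-free synthetic measurements at both bundled
conditions are recovered with `mu_s` errors of ~1–4% across PSO seeds and
`mu_s'` errors below 1% (`mu_s'` is the well-conditioned direction). Bounds
default to `mu_s ∈ [0.01, 100]` mm⁻¹, `g ∈ [0, 0.999]`, and `mu_a ∈ [0, 5]`
when fitted.

Identifiability depends on the regime. The quasi-ballistic low-angle excess
that separates `mu_s` from `g` survives only while the forward-peaked
single-scattering chain is not fully randomized. For an optically thick,
weakly anisotropic slab (e.g. `mu_s` = 12 mm⁻¹, g = 0.5: transport depth 6)
the similarity equivalence is effectively exact for these observables —
direct objective probes along `mu_s`(1−`g`) = const are flat within noise
at any practical photon budget — and only `mu_s'` is recoverable, best by
dropping the (shape-less, noisy) angular term and fitting T and R alone.
The cell-laden inks this package targets are strongly forward-peaked
(g ≈ 0.99) with moderate optical depth, squarely in the identifiable
regime.

## Projection blurring and resolution (projection)

The projected pattern is treated as perfectly collimated, so the light field
at depth z is the 2D convolution of the mask with the depth's PSF kernel
(FFT convolution, zero-padded to the full linear size; an explicit
direct-sum convolution is kept as the test oracle). Total intensity is
conserved exactly by the full convolution. Kernels are bilinearly resampled
when pattern and PSF pitches differ (within a 10× tolerance).

Resolution is quantified on binary bar-target ladders (periods 20–400 μm by
default, duty 1/2, feature = half-period): each rung is blurred, the
Michelson contrast (Imax − Imin)/(Imax + Imin) of the central profile is
measured inside the convolution's full-support region, and the smallest
feature with contrast ≥ 0.1 (configurable) is reported. For a *sinusoidal*
grating a Gaussian kernel of width σ attenuates contrast by exactly
exp(−2π²σ²/p²), which is the analytic oracle used in tests; a binary bar
target retains odd harmonics (fundamental amplitude 4/π), so its blurred
contrast follows the harmonic sum rather than the bare exponential — the
test oracle for ladders evaluates that sum directly.

Note that both bundled ink conditions keep a quasi-ballistic kernel core
(the HG median deflection at g ≈ 0.99 is under 2°), which sustains fine
contrast at moderate depth; comparisons between the two conditions at the
full 250-μm depth therefore use a finer ladder (features from 5 μm,
2.5 μm sampling) and a firmer cutoff of 0.25 to resolve the ordering that
coarser settings saturate. A dose-threshold step (default 0.5 of the
unblurred lit-region dose) converts blurred fields to predicted printed
masks; photopolymerization kinetics are out of scope.

The spoke test pattern is a wheel of equal lit/dark wedges (duty 1/2), so
the local gap width at radius r is πr/n_spokes and a single image probes a
continuum of feature sizes. A decorative 6-fold snowflake generator is
included for qualitative use only.

## Refractometry (refractometry)

A high-index prism (N-SF11, n = 1.8421 at 405 nm) in contact with the
sample produces a camera image with a sharp boundary at the total-internal-
reflection critical angle θc = asin(n_sample/n_prism). The pixel → angle map
of the collimating-lens geometry is taken as linear — two standards
determine exactly a line, and the small angular range involved makes
curvature negligible — and is calibrated from two known standards (water
and isopropanol by convention; their 405-nm index values are user-supplied
inputs, referenced to standard databases, not constants of this package).
A sample index follows as n = n_prism·sin(θ(pixel)). Readings farther than
50% of the standards' span outside the calibrated interval are rejected by
default. Raw-frame edge detection is out of scope; boundary positions are
scalar inputs.

## Synthetic data (synthetic_data)

The generator runs the forward model at high photon count (default 10⁶) and
applies an explicit noise model: multiplicative Gaussian noise of 1% on T
and R and 2% per angular bin (an instrument-grade convention for a
three-replicate mean; the real instruments' replicate variance is unknown),
or a Poisson-counts mode scaled to the peak bin. Every record embeds its
generating truth, seeds, and noise parameters, so parameter-recovery scoring
is automatic. Absorption-free records whose tallied T+R lands a hair above 1
(trajectory-roulette weight variance) are rescaled to the physical bound.

What the generator does *not* emulate: instrument port geometry and stray
light, detector nonlinearity, sample inhomogeneity and cuvette walls,
wavelength drift, and any systematic (non-random) error. Passing
recovery tests therefore demonstrate the *estimator's* correctness and
conditioning under the stated noise, not robustness to systematic
instrument effects in real data.

Bundled condition presets:

| preset | mu_s (mm⁻¹) | mu_s' (mm⁻¹) | g (derived) | n (assumed) |
|--------|-------------|--------------|-------------|-------------|
| IDX0   | 11.76       | 0.164        | 0.98605     | 1.34        |
| IDX30  | 1.377       | 0.014        | 0.98983     | 1.39        |

The preset indices 1.34/1.39 reflect a water-like untuned ink and an ink
matched toward cytoplasm (1.36–1.39); both are stated assumptions and
user-overridable.

## Numerical choices and problem sizes

- Tolerances: angular histograms unit-sum to 1e−9; kernel unit-sum to
  1e−9; intensity conservation checked to 1e−6 relative; energy conservation
  asserted within 3× combined batch SE.
- Degenerate inputs: `mu_t = 0` short-circuits to ballistic propagation;
  `T_total = 0` yields an all-zero angular sentinel; empty PSF weight
  leaves a zero kernel rather than dividing by zero.
- Depth selection is nearest-slice within half a spacing; no inter-slice
  interpolation (slices are 10 μm apart by default).
- Problem sizes used by the test suite and acceptance script — synthetic
  measurements at 2×10⁶ photons, physics-limit checks at 1–5×10⁵, PSF
  stacks at 10⁵ with 25-μm slices, reduced PSO strength (12×30 particles ×
  iterations at 8×10³ photons/eval) for the recovery grid — are chosen to
  make the whole suite run in tens of minutes on one core while leaving
  every assertion's noise floor well below its tolerance. The two headline
  condition fits always use the full default protocol.

## Known limitations

- Single homogeneous slab; no cuvette/coverslip glass, no voxelized
  heterogeneity, no polarization or coherence, no spectral resolution.
- `g` enters only through the HG phase function; real cell phase functions
  deviate in the backward hemisphere.
- The similarity degeneracy limits how precisely `mu_s` and `g` can be
  separated when no ballistic peak survives (optically thick, highly
  forward regime); the angular scan's first few degrees carry almost all of
  that information, so real-instrument stray light near 0° would degrade it.
- Resolution metrics are purely optical; gelation chemistry, oxygen
  inhibition, and z-axis cure depth are not modeled.
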