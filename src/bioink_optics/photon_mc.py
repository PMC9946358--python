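"""Forward 3D Monte Carlo photon transport in a plane-parallel bioink slab.

Weighted-photon transport in the style long established for layered tissue
optics: exponential free paths with the total interaction coefficient
``mu_t = mu_a + mu_s``, fractional weight absorption ``mu_a/mu_t`` per
interaction, Henyey-Greenstein (HG) single scattering, stochastic unpolarized
Fresnel reflection/refraction at both slab faces, and Russian roulette for
low-weight photons.  Tallies: total transmittance/reflectance/absorptance,
the exit-angle histogram of transmitted light (in the ambient medium, after
refraction), and optional depth-resolved lateral point-spread kernels for a
pencil beam at normal incidence.

All lengths are mm inside the kernel; tally grids are specified in μm at the
API surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .optics_core import OpticalProperties

__all__ = [
    "SlabGeometry",
    "TallyConfig",
    "TransportResult",
    "PSFStack",
    "sample_hg",
    "run_forward",
    "angular_distribution",
    "psf_stack",
    "default_depth_slices",
]


@dataclass(frozen=True)
class SlabGeometry:
    """Plane-parallel slab: ``thickness`` mm of bioink in an ambient medium.

    The cuvette/coverslip glass is not modeled; the ambient index defaults to
    air, matching a goniometer measurement of the bare sample.
    """

    thickness: float = 1.0
    n_ambient: float = 1.0
    wavelength: float = 405.0  # nm, metadata only

    def __post_init__(self) -> None:
        if not self.thickness > 0:
            raise ValueError("thickness must be > 0")
        if self.n_ambient < 1:
            raise ValueError("n_ambient must be >= 1")


def default_depth_slices(spacing_um: float = 10.0, max_um: float = 250.0) -> np.ndarray:
    """Depth planes every ``spacing_um`` down to ``max_um`` (the printed
    test-structure thickness)."""
    return np.arange(spacing_um, max_um + 0.5 * spacing_um, spacing_um)


@dataclass(frozen=True)
class TallyConfig:
    """Photon budget, random seed, and tally geometry for one forward run.

    ``depth_slices`` (μm) are the z planes at which lateral PSF kernels are
    accumulated; leave empty to skip PSF tallies.  ``lateral_pitch`` and
    ``lateral_half_extent`` (μm) set the PSF grid: cells of ``lateral_pitch``
    spanning ±``lateral_half_extent`` around the beam axis.
    """

    n_photons: int = 1_000_000
    seed: int = 0
    angular_bin_deg: float = 1.0
    lateral_pitch: float = 5.0
    lateral_half_extent: float = 320.0
    depth_slices: tuple[float, ...] = ()
    roulette_threshold: float = 1e-4
    roulette_survival: float = 0.1
    n_batches: int = 10
    # unbiased roulette on trajectory length: without absorption the weight
    # roulette never fires, and strongly diffusive parameter corners (high
    # mu_s', TIR-trapped) would otherwise scatter for thousands of events
    event_roulette_start: int = 500
    event_roulette_interval: int = 250
    event_roulette_survival: float = 0.5

    def __post_init__(self) -> None:
        if self.n_photons < 1:
            raise ValueError("n_photons must be >= 1")
        if not 0 < self.angular_bin_deg <= 90:
            raise ValueError("angular_bin_deg must lie in (0, 90]")
        if self.lateral_pitch <= 0 or self.lateral_half_extent <= 0:
            raise ValueError("lateral grid parameters must be positive")
        if not 0 < self.roulette_survival <= 1:
            raise ValueError("roulette_survival must lie in (0, 1]")
        if self.n_batches < 1 or self.n_batches > self.n_photons:
            raise ValueError("n_batches must lie in [1, n_photons]")

    def validate_against(self, geom: SlabGeometry) -> None:
        thick_um = geom.thickness * 1000.0
        for z in self.depth_slices:
            if not 0 < z < thick_um:
                raise ValueError(
                    f"depth slice {z} μm outside the open slab (0, {thick_um}) μm"
                )


@dataclass
class PSFStack:
    """Depth-resolved lateral spread kernels of a normally incident pencil beam.

    ``kernels[k]`` is the unit-sum lateral weight distribution at
    ``depths[k]`` μm; cell size is ``pitch`` μm, beam axis at the central cell.
    """

    depths: np.ndarray  # μm
    kernels: np.ndarray  # (n_depth, ny, nx), each unit sum
    pitch: float  # μm

    def kernel_at(self, depth_um: float) -> tuple[int, np.ndarray]:
        """Nearest-slice kernel; errors if no slice is within half a spacing."""
        idx = int(np.argmin(np.abs(self.depths - depth_um)))
        if len(self.depths) > 1:
            spacing = float(np.min(np.diff(np.sort(self.depths))))
            if abs(self.depths[idx] - depth_um) > 0.5 * spacing + 1e-9:
                raise ValueError(
                    f"no PSF slice within half a slice spacing of {depth_um} μm"
                )
        return idx, self.kernels[idx]

    def rms_radius(self, depth_um: float) -> float:
        """Weight-RMS lateral radius (μm) of the kernel nearest ``depth_um``."""
        _, k = self.kernel_at(depth_um)
        ny, nx = k.shape
        y, x = np.mgrid[0:ny, 0:nx]
        cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
        r2 = ((x - cx) ** 2 + (y - cy) ** 2) * self.pitch**2
        return float(np.sqrt(np.sum(k * r2)))


@dataclass
class TransportResult:
    """Tallies of one forward run; fractions of launched photon weight."""

    T_total: float
    R_total: float
    R_specular: float
    A_total: float
    angular_edges_deg: np.ndarray
    angular_hist: np.ndarray  # per-bin fraction of transmitted weight
    batch_se: dict
    seed: int
    n_photons: int
    psf_stack: PSFStack | None = None

    def to_dict(self) -> dict:
        return {
            "schema": "bioink-optics/transport-result/1",
            "T_total": self.T_total,
            "R_total": self.R_total,
            "R_specular": self.R_specular,
            "A_total": self.A_total,
            "angular_edges_deg": self.angular_edges_deg.tolist(),
            "angular_hist": self.angular_hist.tolist(),
            "batch_se": self.batch_se,
            "seed": self.seed,
            "n_photons": self.n_photons,
        }


def sample_hg(g: float, u):
    """Inverse-CDF sample of the HG deflection cosine from uniform ``u``.

    For ``g != 0`` returns ``(1/(2g))·[1 + g² − ((1−g²)/(1−g+2gu))²]``;
    for ``g = 0`` the isotropic ``2u − 1``.  Vectorized over ``u``.
    """
    if not -1.0 < g < 1.0:
        raise ValueError(f"g must lie in (-1, 1), got {g}")
    u = np.asarray(u, dtype=float)
    if g == 0.0:
        out = 2.0 * u - 1.0
    else:
        frac = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
        out = (1.0 + g * g - frac * frac) / (2.0 * g)
    out = np.clip(out, -1.0, 1.0)
    return float(out) if out.ndim == 0 else out


@njit(cache=True)
def _fresnel(n1, n2, cos_i):
    """Scalar unpolarized Fresnel reflectance and transmitted cosine."""
    if n1 == n2:
        return 0.0, cos_i
    sin2_t = (n1 / n2) * (n1 / n2) * (1.0 - cos_i * cos_i)
    if sin2_t >= 1.0:
        return 1.0, 0.0
    cos_t = np.sqrt(1.0 - sin2_t)
    rs = (n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)
    rp = (n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)
    return 0.5 * (rs * rs + rp * rp), cos_t


@njit(cache=True)
def _hg_cos(g):
    u = np.random.random()
    if g == 0.0:
        return 2.0 * u - 1.0
    frac = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    c = (1.0 + g * g - frac * frac) / (2.0 * g)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return c


@njit(cache=True)
def _transport_batch(
    n_photons,
    seed,
    mu_a,
    mu_s,
    g,
    n_samp,
    n_amb,
    thickness,
    n_ang_bins,
    ang_bin_rad,
    depths,  # mm, sorted ascending; may be empty
    psf_half,  # cells on each side of axis
    psf_pitch,  # mm
    roulette_threshold,
    roulette_survival,
    ev_start,
    ev_interval,
    ev_survival,
):
    np.random.seed(seed)
    mu_t = mu_a + mu_s
    nd = depths.shape[0]
    npx = 2 * psf_half + 1
    psf = np.zeros((nd, npx, npx))
    ang = np.zeros(n_ang_bins)
    T = 0.0
    R_spec = 0.0
    R_diff = 0.0
    A = 0.0

    # normal-incidence specular reflectance at the entry face
    r_entry = ((n_amb - n_samp) / (n_amb + n_samp)) ** 2

    for _ in range(n_photons):
        if np.random.random() < r_entry:
            R_spec += 1.0
            continue
        x = 0.0
        y = 0.0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        w = 1.0
        alive = True
        events = 0
        while alive:
            events += 1
            if events > 1_000_000:  # pathological trajectory guard
                break
            if mu_t > 0.0:
                s = -np.log(1.0 - np.random.random()) / mu_t
            else:
                s = 1e30
            # advance, handling boundary hits (possibly several per step)
            while True:
                if uz > 0.0:
                    db = (thickness - z) / uz
                elif uz < 0.0:
                    db = -z / uz
                else:
                    db = 1e30
                seg = s if s < db else db
                # PSF tally: downward crossings of configured planes
                if nd > 0 and uz > 0.0:
                    z_end = z + uz * seg
                    for k in range(nd):
                        zp = depths[k]
                        if zp <= z:
                            continue
                        if zp > z_end + 1e-15:
                            break
                        t = (zp - z) / uz
                        xi = x + ux * t
                        yi = y + uy * t
                        ix = int(np.floor(xi / psf_pitch + 0.5)) + psf_half
                        iy = int(np.floor(yi / psf_pitch + 0.5)) + psf_half
                        if 0 <= ix < npx and 0 <= iy < npx:
                            psf[k, iy, ix] += w
                if s < db:
                    x += ux * s
                    y += uy * s
                    z += uz * s
                    break  # interact in the bulk
                # reached a face
                x += ux * db
                y += uy * db
                z = thickness if uz > 0.0 else 0.0
                s -= db
                cos_i = uz if uz > 0.0 else -uz
                refl, cos_t = _fresnel(n_samp, n_amb, cos_i)
                if np.random.random() < refl:
                    uz = -uz  # internal reflection; continue remaining path
                    continue
                # transmit out of the slab, refracting the exit direction
                if uz > 0.0:
                    T += w
                    theta = np.arccos(cos_t)
                    b = int(theta / ang_bin_rad)
                    if b >= n_ang_bins:
                        b = n_ang_bins - 1
                    ang[b] += w
                else:
                    R_diff += w
                alive = False
                break
            if not alive:
                break
            if mu_t <= 0.0:
                break  # cannot happen: ballistic photons always exit
            # absorb
            if mu_a > 0.0:
                dw = w * mu_a / mu_t
                A += dw
                w -= dw
            # scatter (HG polar angle, uniform azimuth)
            cos_th = _hg_cos(g)
            sin_th = np.sqrt(1.0 - cos_th * cos_th)
            phi = 2.0 * np.pi * np.random.random()
            cos_phi = np.cos(phi)
            sin_phi = np.sin(phi)
            if uz > 1.0 - 1e-6 or uz < -(1.0 - 1e-6):
                ux = sin_th * cos_phi
                uy = sin_th * sin_phi
                uz = cos_th if uz > 0.0 else -cos_th
            else:
                denom = np.sqrt(1.0 - uz * uz)
                ux_n = sin_th * (ux * uz * cos_phi - uy * sin_phi) / denom + ux * cos_th
                uy_n = sin_th * (uy * uz * cos_phi + ux * sin_phi) / denom + uy * cos_th
                uz_n = -sin_th * cos_phi * denom + uz * cos_th
                norm = np.sqrt(ux_n * ux_n + uy_n * uy_n + uz_n * uz_n)
                ux = ux_n / norm
                uy = uy_n / norm
                uz = uz_n / norm
            # Russian roulette on weight
            if w < roulette_threshold:
                if np.random.random() < roulette_survival:
                    w /= roulette_survival
                else:
                    break
            # unbiased roulette on trajectory length
            if events >= ev_start and (events - ev_start) % ev_interval == 0:
                if np.random.random() < ev_survival:
                    w /= ev_survival
                else:
                    break
    return T, R_spec, R_diff, A, ang, psf


def _batch_seeds(seed: int, n_batches: int) -> np.ndarray:
    ss = np.random.SeedSequence(seed)
    return ss.generate_state(n_batches, dtype=np.uint32) >> np.uint32(1)


def run_forward(
    props: OpticalProperties, geom: SlabGeometry, cfg: TallyConfig
) -> TransportResult:
    """Run the forward Monte Carlo and return populated tallies.

    Deterministic given ``(cfg.seed, cfg, props, geom)``: the photon budget is
    split into ``cfg.n_batches`` equal batches with sub-seeds spawned from
    ``cfg.seed``; batch-to-batch spread yields the standard errors reported in
    ``batch_se``.
    """
    cfg.validate_against(geom)
    vals = [props.mu_a, props.mu_s, props.g, props.n, geom.thickness, geom.n_ambient]
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite transport inputs")

    n_ang_bins = int(np.ceil(90.0 / cfg.angular_bin_deg))
    ang_bin_rad = np.deg2rad(cfg.angular_bin_deg)
    depths_mm = np.sort(np.asarray(cfg.depth_slices, dtype=float)) / 1000.0
    psf_half = int(np.ceil(cfg.lateral_half_extent / cfg.lateral_pitch))
    pitch_mm = cfg.lateral_pitch / 1000.0

    per_batch = cfg.n_photons // cfg.n_batches
    counts = np.full(cfg.n_batches, per_batch, dtype=np.int64)
    counts[: cfg.n_photons - per_batch * cfg.n_batches] += 1
    seeds = _batch_seeds(cfg.seed, cfg.n_batches)

    npx = 2 * psf_half + 1
    tot = {"T": 0.0, "Rs": 0.0, "Rd": 0.0, "A": 0.0}
    ang = np.zeros(n_ang_bins)
    psf = np.zeros((len(depths_mm), npx, npx))
    bT = np.zeros(cfg.n_batches)
    bR = np.zeros(cfg.n_batches)
    for i in range(cfg.n_batches):
        T, Rs, Rd, A, a, p = _transport_batch(
            counts[i],
            seeds[i],
            props.mu_a,
            props.mu_s,
            props.g,
            props.n,
            geom.n_ambient,
            geom.thickness,
            n_ang_bins,
            ang_bin_rad,
            depths_mm,
            psf_half,
            pitch_mm,
            cfg.roulette_threshold,
            cfg.roulette_survival,
            cfg.event_roulette_start,
            cfg.event_roulette_interval,
            cfg.event_roulette_survival,
        )
        tot["T"] += T
        tot["Rs"] += Rs
        tot["Rd"] += Rd
        tot["A"] += A
        ang += a
        psf += p
        bT[i] = T / counts[i]
        bR[i] = (Rs + Rd) / counts[i]

    n = float(cfg.n_photons)
    nb = cfg.n_batches
    se_T = float(np.std(bT, ddof=1) / np.sqrt(nb)) if nb > 1 else float("nan")
    se_R = float(np.std(bR, ddof=1) / np.sqrt(nb)) if nb > 1 else float("nan")

    ang_sum = ang.sum()
    ang_hist = ang / ang_sum if ang_sum > 0 else ang
    edges = np.arange(n_ang_bins + 1) * cfg.angular_bin_deg

    stack = None
    if len(depths_mm) > 0:
        sums = psf.sum(axis=(1, 2), keepdims=True)
        sums[sums == 0] = 1.0
        stack = PSFStack(
            depths=depths_mm * 1000.0,
            kernels=psf / sums,
            pitch=cfg.lateral_pitch,
        )

    return TransportResult(
        T_total=tot["T"] / n,
        R_total=(tot["Rs"] + tot["Rd"]) / n,
        R_specular=tot["Rs"] / n,
        A_total=tot["A"] / n,
        angular_edges_deg=edges,
        angular_hist=ang_hist,
        batch_se={"T": se_T, "R": se_R},
        seed=cfg.seed,
        n_photons=cfg.n_photons,
        psf_stack=stack,
    )


def angular_distribution(
    result: TransportResult, *, per_solid_angle: bool = False
) -> np.ndarray:
    """Exit-angle distribution of transmitted light.

    Per-bin fractions of transmitted weight (unit sum).  With
    ``per_solid_angle`` the fractions are divided by each annular bin's solid
    angle (sr), giving a radiance-style quantity that no longer sums to 1.
    Returns an all-zero sentinel when nothing was transmitted.
    """
    if result.T_total <= 0:
        return np.zeros_like(result.angular_hist)
    h = result.angular_hist.copy()
    if per_solid_angle:
        e = np.deg2rad(result.angular_edges_deg)
        omega = 2.0 * np.pi * (np.cos(e[:-1]) - np.cos(e[1:]))
        h = h / omega
    return h


def psf_stack(
    props: OpticalProperties, geom: SlabGeometry, cfg: TallyConfig
) -> PSFStack:
    """Depth-resolved PSF kernels for a pencil beam at normal incidence.

    Convenience wrapper around :func:`run_forward`; ``cfg.depth_slices`` must
    be nonempty.
    """
    if len(cfg.depth_slices) == 0:
        raise ValueError("cfg.depth_slices must be nonempty for a PSF run")
    res = run_forward(props, geom, cfg)
    assert res.psf_stack is not None
    return res.psf_stack
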