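"""DLP projection blurring and printable-resolution prediction.

The projected pattern is assumed perfectly collimated, so the light field at
depth z inside the ink is the 2D convolution of the mask with the scattering
point-spread function (PSF) at that depth.  Resolution is quantified on
bar-target (line-pair) ladders via Michelson contrast
(Imax - Imin)/(Imax + Imin) of the blurred profile; a feature (half-period)
counts as resolved when its contrast meets a configurable cutoff, 0.1 by
default.

FFT convolution (scipy) is the production path; a direct-sum convolution is
retained as an independent oracle for tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .photon_mc import PSFStack

__all__ = [
    "PatternImage",
    "ResolutionReport",
    "make_spoke_pattern",
    "make_line_pairs",
    "make_snowflake_pattern",
    "make_sine_grating",
    "blur_at_depth",
    "blur_with_kernel",
    "direct_convolve",
    "michelson_contrast",
    "resolution_at_depth",
    "threshold_print",
    "UNRESOLVED",
    "DEFAULT_LADDER_PERIODS",
]

UNRESOLVED = "unresolved"

# half-periods 10-200 μm: brackets the ~50-μm printable-feature scale
DEFAULT_LADDER_PERIODS = (20.0, 30.0, 40.0, 50.0, 60.0, 80.0, 100.0, 140.0, 200.0, 280.0, 400.0)


@dataclass
class PatternImage:
    """2D projection mask with a physical pixel pitch (μm per pixel)."""

    grid: np.ndarray
    pitch: float
    normalization: str = "binary"  # "binary" | "relative"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise ValueError("pattern grid must be 2D")
        if not np.all(np.isfinite(self.grid)) or np.any(self.grid < 0):
            raise ValueError("pattern values must be finite and nonnegative")
        if not self.pitch > 0:
            raise ValueError("pitch must be > 0")
        if self.normalization not in ("binary", "relative"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.normalization == "binary" and not np.all(
            np.isin(self.grid, (0.0, 1.0))
        ):
            raise ValueError("binary patterns may contain only {0, 1}")

    @property
    def total(self) -> float:
        return float(self.grid.sum())


@dataclass
class ResolutionReport:
    """Contrast-vs-feature table at one depth and the smallest resolved feature."""

    depth: float  # μm
    contrast_by_feature: dict  # feature size μm -> Michelson contrast
    min_resolved: float | str  # μm, or the "unresolved" sentinel
    threshold: float

    def to_dict(self) -> dict:
        return {
            "schema": "bioink-optics/resolution-report/1",
            "depth_um": self.depth,
            "threshold": self.threshold,
            "contrast_by_feature_um": {
                f"{k:g}": v for k, v in self.contrast_by_feature.items()
            },
            "min_resolved_um": self.min_resolved,
        }


def make_spoke_pattern(n_spokes: int, diameter: float, pitch: float) -> PatternImage:
    """Binary wheel of ``n_spokes`` lit wedges alternating with equal gaps.

    Angular duty cycle 1/2, so the gap arc width at radius r is
    pi*r/n_spokes — the feature size shrinks linearly toward the hub, which
    is what makes the spoke target a convenient single-image resolution probe.
    """
    if n_spokes < 2:
        raise ValueError("n_spokes must be >= 2")
    if diameter <= 0:
        raise ValueError("diameter must be > 0")
    npx = int(round(diameter / pitch))
    if npx < 4:
        raise ValueError("diameter must span at least 4 pixels")
    c = (npx - 1) / 2.0
    y, x = np.mgrid[0:npx, 0:npx]
    dx, dy = x - c, y - c
    r = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)  # [-pi, pi)
    wedge = np.mod(theta * n_spokes / (2.0 * np.pi), 1.0) < 0.5
    grid = (wedge & (r <= npx / 2.0)).astype(float)
    return PatternImage(grid=grid, pitch=pitch, normalization="binary")


def make_line_pairs(periods, pitch: float, *, n_periods: int = 6, height_um: float | None = None) -> PatternImage:
    """Bar-target ladder: one block of vertical bars per period, duty 1/2.

    Blocks are laid out left to right in the given order, separated by one
    largest-period dark gap.  Bars run the full image height.
    """
    periods = [float(p) for p in periods]
    if not periods:
        raise ValueError("need at least one period")
    for p in periods:
        if p < 2 * pitch:
            raise ValueError(f"period {p} μm below the Nyquist limit 2*pitch={2*pitch}")
    gap_px = int(round(max(periods) / pitch))
    height = int(round((height_um or 4 * max(periods)) / pitch))
    cols = []
    for p in periods:
        ppx = p / pitch
        block_w = int(round(n_periods * ppx))
        xs = np.arange(block_w)
        bars = np.mod(xs / ppx, 1.0) < 0.5
        cols.append(np.repeat(bars[None, :], height, axis=0).astype(float))
        cols.append(np.zeros((height, gap_px)))
    grid = np.concatenate(cols[:-1], axis=1)
    return PatternImage(grid=grid, pitch=pitch, normalization="binary")


def make_sine_grating(period: float, pitch: float, *, n_periods: int = 8, height_um: float | None = None) -> PatternImage:
    """Sinusoidal grating 0.5 + 0.5*sin(2*pi*x/period), unit Michelson contrast.

    A pure spatial frequency: Gaussian blur of std sigma attenuates its
    contrast by exactly exp(-2*pi^2*sigma^2/period^2), making this the
    analytic test target for the blur stage.
    """
    ppx = period / pitch
    if ppx < 4:
        raise ValueError("period must span at least 4 pixels")
    w = int(round(n_periods * ppx))
    h = int(round((height_um or 2 * period) / pitch))
    xs = np.arange(w)
    row = 0.5 + 0.5 * np.sin(2.0 * np.pi * xs / ppx)
    return PatternImage(
        grid=np.repeat(row[None, :], h, axis=0), pitch=pitch, normalization="relative"
    )


def make_snowflake_pattern(
    diameter: float, pitch: float, *, n_fold: int = 6, branch_width: float | None = None
) -> PatternImage:
    """Six-fold branched snowflake, rasterized from a replicated polyline arm.

    Decorative companion to the spoke target (its exact branch geometry is
    cosmetic); excluded from quantitative resolution metrics.
    """
    npx = int(round(diameter / pitch))
    if npx < 16:
        raise ValueError("diameter must span at least 16 pixels")
    c = (npx - 1) / 2.0
    R = npx / 2.0
    bw = (branch_width or diameter / 40.0) / pitch
    y, x = np.mgrid[0:npx, 0:npx]
    grid = np.zeros((npx, npx), dtype=bool)
    # one arm: trunk plus two side branchlets at 60 deg, replicated n_fold times
    segments = [
        ((0.0, 0.0), (R * 0.95, 0.0)),
        ((R * 0.45, 0.0), (R * 0.45 + R * 0.25 * np.cos(np.pi / 3), R * 0.25 * np.sin(np.pi / 3))),
        ((R * 0.45, 0.0), (R * 0.45 + R * 0.25 * np.cos(np.pi / 3), -R * 0.25 * np.sin(np.pi / 3))),
        ((R * 0.7, 0.0), (R * 0.7 + R * 0.18 * np.cos(np.pi / 3), R * 0.18 * np.sin(np.pi / 3))),
        ((R * 0.7, 0.0), (R * 0.7 + R * 0.18 * np.cos(np.pi / 3), -R * 0.18 * np.sin(np.pi / 3))),
    ]
    for k in range(n_fold):
        a = 2.0 * np.pi * k / n_fold
        ca, sa = np.cos(a), np.sin(a)
        for (x0, y0), (x1, y1) in segments:
            p0 = np.array([x0 * ca - y0 * sa + c, x0 * sa + y0 * ca + c])
            p1 = np.array([x1 * ca - y1 * sa + c, x1 * sa + y1 * ca + c])
            d = p1 - p0
            L2 = float(d @ d)
            t = np.clip(((x - p0[0]) * d[0] + (y - p0[1]) * d[1]) / L2, 0.0, 1.0)
            dist = np.hypot(x - (p0[0] + t * d[0]), y - (p0[1] + t * d[1]))
            grid |= dist <= bw / 2.0
    return PatternImage(grid=grid.astype(float), pitch=pitch, normalization="binary")


def direct_convolve(pattern: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Zero-padded full convolution by explicit summation (test oracle)."""
    ph, pw = pattern.shape
    kh, kw = kernel.shape
    out = np.zeros((ph + kh - 1, pw + kw - 1))
    for i in range(kh):
        for j in range(kw):
            out[i : i + ph, j : j + pw] += kernel[i, j] * pattern
    return out


def blur_with_kernel(pattern: PatternImage, kernel: np.ndarray) -> PatternImage:
    """Full (zero-padded) FFT convolution of a pattern with a unit-sum kernel."""
    out = signal.fftconvolve(pattern.grid, kernel, mode="full")
    out = np.clip(out, 0.0, None)
    return PatternImage(grid=out, pitch=pattern.pitch, normalization="relative")


def _resampled_kernel(psf: PSFStack, depth: float, pattern_pitch: float) -> np.ndarray:
    _, kernel = psf.kernel_at(depth)
    ratio = psf.pitch / pattern_pitch
    if abs(ratio - 1.0) < 1e-9:
        return kernel
    if not 0.1 <= ratio <= 10.0:
        raise ValueError(
            f"kernel pitch {psf.pitch} μm and pattern pitch {pattern_pitch} μm "
            "differ beyond the resampling tolerance (10x)"
        )
    k = ndimage.zoom(kernel, ratio, order=1)
    k = np.clip(k, 0.0, None)
    s = k.sum()
    if s <= 0:
        raise ValueError("kernel resampling produced an empty kernel")
    return k / s


def blur_at_depth(pattern: PatternImage, psf: PSFStack, depth: float) -> PatternImage:
    """Predicted light field at ``depth`` μm: pattern (*) PSF kernel.

    The nearest PSF slice within half a slice spacing is used; kernels are
    resampled to the pattern pitch when the two differ.  The output is the
    full zero-padded convolution, so total intensity is conserved.
    """
    return blur_with_kernel(pattern, _resampled_kernel(psf, depth, pattern.pitch))


def michelson_contrast(profile: np.ndarray) -> float:
    """(max - min)/(max + min) of an intensity profile; 0 for a dark profile."""
    hi, lo = float(np.max(profile)), float(np.min(profile))
    if hi + lo <= 0:
        return 0.0
    return (hi - lo) / (hi + lo)


def _block_contrast(kernel: np.ndarray, period: float, pitch: float) -> float:
    """Blurred Michelson contrast of one binary bar block.

    The grating is made wide enough that a full-support core region exists
    (no zero-padding edge falloff), and the contrast is read off the central
    row of that core only.
    """
    kh, kw = kernel.shape
    ppx = max(int(round(period / pitch)), 2)
    # pattern width: kernel support on both sides plus >= 3 clean periods
    n_per = int(np.ceil((2 * kw + 3 * ppx) / ppx)) + 1
    pat = make_line_pairs(
        [period], pitch, n_periods=n_per, height_um=(2 * kh + 4) * pitch
    )
    blurred = blur_with_kernel(pat, kernel)
    g = blurred.grid
    row = g[g.shape[0] // 2]
    # full convolution support: output j in [kw-1, W-1]; trim one extra period
    lo = (kw - 1) + ppx
    hi = pat.grid.shape[1] - ppx
    core = row[lo:hi]
    if core.size < ppx:
        return 0.0
    return michelson_contrast(core)


def resolution_at_depth(
    psf: PSFStack,
    depth: float,
    threshold: float = 0.1,
    *,
    periods=DEFAULT_LADDER_PERIODS,
    pattern_pitch: float | None = None,
) -> ResolutionReport:
    """Smallest line-pair feature (half-period, μm) resolved at ``depth``.

    Each ladder period is blurred with the depth's kernel and its central
    profile's Michelson contrast compared against ``threshold``; the report
    carries the full contrast table and the ``"unresolved"`` sentinel when no
    rung passes.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    pitch = pattern_pitch or psf.pitch
    kernel = _resampled_kernel(psf, depth, pitch)
    table: dict[float, float] = {}
    for p in sorted(float(p) for p in periods):
        table[p / 2.0] = _block_contrast(kernel, p, pitch)
    resolved = [f for f, c in table.items() if c >= threshold]
    return ResolutionReport(
        depth=depth,
        contrast_by_feature=table,
        min_resolved=min(resolved) if resolved else UNRESOLVED,
        threshold=threshold,
    )


def threshold_print(blurred: PatternImage, *, rel_threshold: float = 0.5, reference: float | None = None) -> PatternImage:
    """Binary predicted-print mask: dose >= ``rel_threshold`` x reference.

    ``reference`` defaults to the unblurred lit-region intensity (1.0 for a
    binary mask convolved with a unit-sum kernel).  Gel-point chemistry is out
    of scope; this is a purely optical cutoff.
    """
    ref = 1.0 if reference is None else reference
    return PatternImage(
        grid=(blurred.grid >= rel_threshold * ref).astype(float),
        pitch=blurred.pitch,
        normalization="binary",
    )
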