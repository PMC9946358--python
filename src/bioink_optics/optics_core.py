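"""Shared optics types and closed-form relations.

Conventions used throughout the package: lengths in mm, iodixanol (IDX)
concentrations in % w/v, interface angles in degrees at the user surface and
direction cosines internally. The working wavelength is 405 nm (the DLP
bioprinter's source); no dispersion model is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OpticalProperties",
    "MixingModel",
    "reduced_scattering",
    "anisotropy_from",
    "fresnel_unpolarized",
    "mix_refractive_index",
    "required_idx_for_target",
    "DEFAULT_MIXING_MODEL",
]


@dataclass(frozen=True)
class OpticalProperties:
    """Bulk optical properties of one bioink condition at 405 nm.

    Parameters
    ----------
    mu_a : float
        Absorption coefficient, mm^-1.
    mu_s : float
        Scattering coefficient, mm^-1.
    g : float
        Scattering anisotropy (mean cosine of the single-scattering
        deflection), dimensionless, in (-1, 1).
    n : float
        Refractive index of the bulk medium.
    """

    mu_a: float
    mu_s: float
    g: float
    n: float = 1.34

    def __post_init__(self) -> None:
        if not np.isfinite([self.mu_a, self.mu_s, self.g, self.n]).all():
            raise ValueError("optical properties must be finite")
        if self.mu_a < 0:
            raise ValueError(f"mu_a must be >= 0, got {self.mu_a}")
        if self.mu_s < 0:
            raise ValueError(f"mu_s must be >= 0, got {self.mu_s}")
        if not -1.0 < self.g < 1.0:
            raise ValueError(f"g must lie in (-1, 1), got {self.g}")
        if self.n < 1.0:
            raise ValueError(f"n must be >= 1, got {self.n}")

    @property
    def mu_s_prime(self) -> float:
        """Reduced scattering coefficient mu_s * (1 - g), mm^-1."""
        return reduced_scattering(self.mu_s, self.g)

    @property
    def mu_t(self) -> float:
        """Total interaction coefficient mu_a + mu_s, mm^-1."""
        return self.mu_a + self.mu_s


# Empirical guidance window in which index-matching toward cytoplasm
# (n ~ 1.36-1.39) is expected; linear mixing is best supported here.
IDX_GUIDANCE_RANGE = (20.0, 35.0)


@dataclass(frozen=True)
class MixingModel:
    """Two-anchor linear model of bioink refractive index vs IDX concentration.

    ``anchors`` are two (concentration % w/v, refractive index) pairs; the
    index is linearly interpolated between them.  The default anchors are the
    water-like untuned bioink (0%, 1.333) and the stock 60% iodixanol solution
    (60%, 1.45); supply measured anchors when available.
    """

    anchors: tuple[tuple[float, float], tuple[float, float]] = (
        (0.0, 1.333),
        (60.0, 1.45),
    )
    valid_range: tuple[float, float] = (0.0, 60.0)

    def __post_init__(self) -> None:
        (c0, n0), (c1, n1) = self.anchors
        if c0 == c1:
            raise ValueError("anchor concentrations must be distinct")
        if (n1 - n0) * (c1 - c0) <= 0:
            raise ValueError("refractive index must increase with concentration")
        lo, hi = self.valid_range
        if not (0.0 <= lo < hi <= 60.0):
            raise ValueError("valid_range must be an interval within [0, 60] % w/v")

    @property
    def slope(self) -> float:
        (c0, n0), (c1, n1) = self.anchors
        return (n1 - n0) / (c1 - c0)

    @property
    def intercept(self) -> float:
        (c0, n0), _ = self.anchors
        return n0 - self.slope * c0

    def to_dict(self) -> dict:
        return {
            "anchors": [list(a) for a in self.anchors],
            "valid_range": list(self.valid_range),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MixingModel":
        a = d["anchors"]
        return cls(
            anchors=((a[0][0], a[0][1]), (a[1][0], a[1][1])),
            valid_range=tuple(d.get("valid_range", (0.0, 60.0))),
        )


DEFAULT_MIXING_MODEL = MixingModel()


def reduced_scattering(mu_s: float, g: float) -> float:
    """Reduced scattering coefficient mu_s' = mu_s * (1 - g), mm^-1.

    mu_s' is the isotropic-equivalent scattering rate that governs diffuse
    spread; for the forward-peaked cell-laden inks (g near 1) it is orders of
    magnitude below mu_s.
    """
    mu_s = float(mu_s)
    g = float(g)
    if mu_s < 0:
        raise ValueError(f"mu_s must be >= 0, got {mu_s}")
    if not -1.0 < g < 1.0:
        raise ValueError(f"g must lie in (-1, 1), got {g}")
    return mu_s * (1.0 - g)


def anisotropy_from(mu_s: float, mu_s_prime: float) -> float:
    """Anisotropy g = 1 - mu_s'/mu_s from a (mu_s, mu_s') pair."""
    mu_s = float(mu_s)
    mu_s_prime = float(mu_s_prime)
    if mu_s <= 0:
        raise ValueError(f"mu_s must be > 0, got {mu_s}")
    if mu_s_prime < 0 or mu_s_prime > mu_s:
        raise ValueError(
            f"mu_s_prime must lie in [0, mu_s]; got {mu_s_prime} with mu_s={mu_s}"
        )
    return 1.0 - mu_s_prime / mu_s


def fresnel_unpolarized(n_in, n_out, cos_theta_in):
    """Unpolarized Fresnel power reflectance at a planar dielectric interface.

    Average of the s- and p-polarized reflectances.  Returns exactly 1 beyond
    the critical angle when ``n_in > n_out`` (total internal reflection).
    Accepts scalars or numpy arrays (broadcast).

    Parameters
    ----------
    n_in, n_out : float
        Refractive indices of the incident and transmitting media (>= 1).
    cos_theta_in : float
        Cosine of the incidence angle, in (0, 1].
    """
    n_in = np.asarray(n_in, dtype=float)
    n_out = np.asarray(n_out, dtype=float)
    ci = np.asarray(cos_theta_in, dtype=float)
    if np.any(n_in < 1) or np.any(n_out < 1):
        raise ValueError("refractive indices must be >= 1")
    if np.any(ci <= 0) or np.any(ci > 1):
        raise ValueError("cos_theta_in must lie in (0, 1]")

    sin2_t = (n_in / n_out) ** 2 * (1.0 - ci**2)
    tir = sin2_t >= 1.0
    ct = np.sqrt(np.clip(1.0 - sin2_t, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        rs = ((n_in * ci - n_out * ct) / (n_in * ci + n_out * ct)) ** 2
        rp = ((n_in * ct - n_out * ci) / (n_in * ct + n_out * ci)) ** 2
    r = 0.5 * (rs + rp)
    r = np.where(tir, 1.0, r)
    r = np.where(n_in == n_out, 0.0, r)
    if r.ndim == 0:
        return float(r)
    return r


def mix_refractive_index(
    c_idx: float, model: MixingModel = DEFAULT_MIXING_MODEL, *, extrapolate: bool = False
) -> float:
    """Bioink refractive index at an IDX concentration (linear two-anchor model).

    Emits a warning outside the empirically supported 20-35 % w/v window, and a
    range error outside ``model.valid_range`` unless ``extrapolate`` is set.
    """
    c_idx = float(c_idx)
    lo, hi = model.valid_range
    if not extrapolate and not (lo <= c_idx <= hi):
        raise ValueError(
            f"concentration {c_idx}% outside model range [{lo}, {hi}]%; "
            "pass extrapolate=True to override"
        )
    glo, ghi = IDX_GUIDANCE_RANGE
    if not (glo <= c_idx <= ghi) and c_idx != model.anchors[0][0] and c_idx != model.anchors[1][0]:
        warnings.warn(
            f"IDX concentration {c_idx}% is outside the {glo}-{ghi}% window where "
            "linear index mixing is empirically supported",
            stacklevel=2,
        )
    return model.intercept + model.slope * c_idx


def required_idx_for_target(
    n_target: float, model: MixingModel = DEFAULT_MIXING_MODEL
) -> float:
    """IDX concentration (% w/v) needed to reach a target refractive index.

    Exact inverse of :func:`mix_refractive_index` on the anchor-bounded
    interval; warns when the answer falls outside the 20-35% guidance window.
    """
    n_target = float(n_target)
    (c0, n0), (c1, n1) = model.anchors
    n_lo, n_hi = min(n0, n1), max(n0, n1)
    if not (n_lo <= n_target <= n_hi):
        raise ValueError(
            f"target index {n_target} outside anchor range [{n_lo}, {n_hi}]"
        )
    c = (n_target - model.intercept) / model.slope
    glo, ghi = IDX_GUIDANCE_RANGE
    if not (glo <= c <= ghi):
        warnings.warn(
            f"required concentration {c:.1f}% lies outside the empirically "
            f"supported {glo}-{ghi}% window",
            stacklevel=2,
        )
    return c
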