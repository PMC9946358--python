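"""Critical-angle (TIR-boundary) prism refractometry.

A converging 405-nm beam enters the hypotenuse of a high-index prism
(N-SF11, n = 1.8421 at 405 nm) in contact with the sample; rays beyond the
critical angle are totally internally reflected, and the camera image of the
reflected fan shows a sharp boundary at the critical angle
theta_c = asin(n_sample/n_prism).  Two standards of known index (water and
isopropanol by convention) calibrate the linear pixel -> angle map of the
collimating-lens geometry; a sample's index then follows from its boundary
pixel via n = n_prism * sin(theta_c).

Boundary positions are scalar pixel inputs; raw camera frames are out of
scope.  Reference index values for the standards are user-supplied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RefractometerCalibration",
    "critical_angle",
    "calibrate",
    "index_from_boundary",
    "N_PRISM_NSF11",
]

N_PRISM_NSF11 = 1.8421  # N-SF11 glass at 405 nm


def critical_angle(n_sample: float, n_prism: float = N_PRISM_NSF11) -> float:
    """TIR critical angle asin(n_sample/n_prism), degrees."""
    n_sample = float(n_sample)
    if not 1.0 <= n_sample < n_prism:
        raise ValueError(
            f"n_sample must lie in [1, n_prism={n_prism}): no TIR otherwise"
        )
    return float(np.degrees(np.arcsin(n_sample / n_prism)))


@dataclass(frozen=True)
class RefractometerCalibration:
    """Two-standard linear pixel -> angle calibration of one prism setup."""

    n_prism: float
    standards: tuple[tuple[float, float], tuple[float, float]]  # (pixel, index)
    slope: float  # deg / pixel
    intercept: float  # deg at pixel 0

    def angle_at(self, pixel: float) -> float:
        return self.slope * float(pixel) + self.intercept

    @property
    def pixel_span(self) -> float:
        return abs(self.standards[1][0] - self.standards[0][0])

    def to_dict(self) -> dict:
        return {
            "schema": "bioink-optics/refractometer-calibration/1",
            "n_prism": self.n_prism,
            "standards": [list(s) for s in self.standards],
            "slope_deg_per_px": self.slope,
            "intercept_deg": self.intercept,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RefractometerCalibration":
        s = d["standards"]
        return cls(
            n_prism=d["n_prism"],
            standards=((s[0][0], s[0][1]), (s[1][0], s[1][1])),
            slope=d["slope_deg_per_px"],
            intercept=d["intercept_deg"],
        )


def calibrate(
    standards, n_prism: float = N_PRISM_NSF11
) -> RefractometerCalibration:
    """Fit the unique pixel -> angle line through two known standards.

    ``standards`` is two (boundary pixel, known index) pairs; each index is
    converted to its critical angle and the line through the two
    (pixel, angle) points is returned.  Order-independent.
    """
    (p0, n0), (p1, n1) = standards
    if p0 == p1:
        raise ValueError("standard pixel positions must be distinct")
    for n in (n0, n1):
        if not n < n_prism:
            raise ValueError(f"standard index {n} must be below n_prism={n_prism}")
    a0, a1 = critical_angle(n0, n_prism), critical_angle(n1, n_prism)
    slope = (a1 - a0) / (p1 - p0)
    intercept = a0 - slope * p0
    # canonical standard order (by pixel) so swapped input yields the same map
    st = ((p0, n0), (p1, n1)) if p0 < p1 else ((p1, n1), (p0, n0))
    return RefractometerCalibration(
        n_prism=float(n_prism), standards=st, slope=slope, intercept=intercept
    )


def index_from_boundary(
    pixel: float,
    cal: RefractometerCalibration,
    *,
    extrapolation_window: float = 0.5,
) -> float:
    """Sample refractive index from its TIR-boundary pixel position.

    Maps pixel -> angle with the calibration line, then
    n = n_prism * sin(theta_c).  Pixels farther than
    ``extrapolation_window`` x the standards' span outside the calibrated
    interval are rejected, as is any mapped angle outside (0, 90) degrees.
    """
    pixel = float(pixel)
    lo = min(s[0] for s in cal.standards)
    hi = max(s[0] for s in cal.standards)
    pad = extrapolation_window * cal.pixel_span
    if not lo - pad <= pixel <= hi + pad:
        raise ValueError(
            f"pixel {pixel} outside the calibrated window "
            f"[{lo - pad}, {hi + pad}]"
        )
    theta = cal.angle_at(pixel)
    if not 0.0 < theta < 90.0:
        raise ValueError(f"mapped angle {theta} deg outside (0, 90)")
    return float(cal.n_prism * np.sin(np.radians(theta)))
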