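"""Surveillance-style continuous clinical-risk surface (synthetic surrogate).

The published Surveillance Error Grid assigns every (reference, sensor)
glucose pair a continuous clinical-risk score in [0, 4] with color-coded
risk zones. Its full-resolution surface is distributed as external software
and is not replicated here bit-exactly; this module provides a *synthetic*
surrogate with the same documented structure: risk 0 on the identity
diagonal, risk growing monotonically as the sensor value moves away from
the reference, steep penalties for missed hypoglycemia and large
discordance, and the standard five color zones (none < 0.5, slight,
moderate, great, extreme >= 3.5).

The surface is separable: each glucose value g is mapped through a
piecewise-linear clinical-severity coordinate H(g) (steep below 70 mg/dl,
gentle in the 70-180 target region, moderate above), and risk is
``clip(|H(sensor) - H(reference)|, 0, 4)``. The signed surface
H(sensor) - H(reference) is bundled as a coarse anchor grid whose axes
include every breakpoint of H, so bilinear interpolation over the grid
reproduces the surface exactly — in particular it is exactly zero on the
diagonal and monotone away from it, which non-separable coarse grids lose
under interpolation.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.interpolate import RegularGridInterpolator

DOMAIN = (20.0, 600.0)  # mg/dl; inputs outside are clamped with a warning

# clinical-severity coordinate: (glucose mg/dl, H in risk units)
_H_BREAKPOINTS = np.array(
    [
        (20.0, 0.0),   # profound hypoglycemia
        (40.0, 1.2),
        (50.0, 1.8),
        (70.0, 3.0),   # hypoglycemia threshold: steepest region below here
        (90.0, 3.6),
        (110.0, 4.0),  # centre of the euglycemic band
        (140.0, 4.45),
        (180.0, 5.0),  # hyperglycemia threshold
        (215.0, 5.5),
        (250.0, 6.0),
        (325.0, 6.5),
        (400.0, 7.0),
        (500.0, 7.35),
        (600.0, 7.6),
    ]
)

RISK_MAX = 4.0
#: zone upper edges as in surveillance-grid practice
ZONE_EDGES = {"none": 0.5, "slight": 1.5, "moderate": 2.5, "great": 3.5, "extreme": RISK_MAX}
ZONE_NAMES = list(ZONE_EDGES)

_AXIS = _H_BREAKPOINTS[:, 0]
_H = _H_BREAKPOINTS[:, 1]
# signed anchor surface D[i, j] = H(sensor_j) - H(reference_i)
_SIGNED_SURFACE = _H[None, :] - _H[:, None]
_INTERP = RegularGridInterpolator((_AXIS, _AXIS), _SIGNED_SURFACE, method="linear")


def _clamp(value: float, name: str) -> float:
    lo, hi = DOMAIN
    if value < lo or value > hi:
        warnings.warn(f"{name} value {value} mg/dl clamped to SEG domain [{lo}, {hi}]",
                      stacklevel=3)
        return min(max(value, lo), hi)
    return float(value)


def risk(reference: float, sensor: float) -> float:
    """Continuous risk score in [0, 4]; 0 iff sensor == reference (in-domain)."""
    r = _clamp(reference, "reference")
    s = _clamp(sensor, "sensor")
    signed = float(_INTERP((r, s)))
    return float(min(abs(signed), RISK_MAX))


def risk_grid(reference: np.ndarray, sensor: np.ndarray) -> np.ndarray:
    """Vectorised risk over same-shape arrays."""
    r = np.clip(np.asarray(reference, dtype=float), *DOMAIN)
    s = np.clip(np.asarray(sensor, dtype=float), *DOMAIN)
    pts = np.stack([r.ravel(), s.ravel()], axis=-1)
    return np.minimum(np.abs(_INTERP(pts)), RISK_MAX).reshape(r.shape)


def color_zone(risk_score: float) -> str:
    """Map a risk score to its color zone (none/slight/moderate/great/extreme)."""
    for name, edge in ZONE_EDGES.items():
        if risk_score < edge:
            return name
    return "extreme"
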