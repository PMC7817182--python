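"""Closed-form experimental quantifications.

These are the small arithmetic steps of the imaging analyses, implemented
so they are testable without images:

* TIRF depth correction — the evanescent excitation field decays as
  exp(-h/d) with penetration depth d (180 nm here), so a molecule measured
  at height h above the coverslip appears dimmer by that factor; the
  corrected (coverslip-equivalent) intensity is i * exp(+h/d).  The upscaling
  direction follows from the attenuation model: corrected ratios are larger
  than measured ones.
* Expansion-microscopy mean MT length — total network fluorescence divided
  by the per-micron MT intensity and by the MT count.
* The 2-µm polarization classifier for experimental centrosome/lysosome
  distances (strict inequality at the threshold).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["IntensityMeasurement", "ExmShellMeasurement",
           "depth_corrected_intensity", "exm_mean_mt_length",
           "classify_polarized"]


@dataclass
class IntensityMeasurement:
    """Fluorescence intensity (units of the monomeric-GFP mean) at height h."""

    i: float            # measured intensity
    h: float            # nm above the coverslip
    d: float = 180.0    # nm, evanescent penetration depth

    def __post_init__(self):
        if self.h < 0:
            raise ValueError("height h must be non-negative")
        if self.d <= 0:
            raise ValueError("penetration depth d must be positive")


@dataclass
class ExmShellMeasurement:
    total_intensity: float      # a.u., whole MT network
    intensity_per_micron: float  # a.u. per µm of single MT
    n_mts: int                  # MT count at the centrosome


def depth_corrected_intensity(m: IntensityMeasurement) -> float:
    """Intensity scaled up to its coverslip value: i * exp(h / d)."""
    return m.i * math.exp(m.h / m.d)


def exm_mean_mt_length(m: ExmShellMeasurement) -> float:
    """Mean MT length = total intensity / (intensity per µm * MT count)."""
    if m.intensity_per_micron <= 0:
        raise ValueError("intensity_per_micron must be positive")
    if m.n_mts < 1:
        raise ValueError("need at least one MT")
    return m.total_intensity / (m.intensity_per_micron * m.n_mts)


def classify_polarized(distance: float, threshold: float = 2.0) -> bool:
    """True iff the distance to the interface is strictly below threshold."""
    if distance < 0:
        raise ValueError("distance must be non-negative")
    return distance < threshold
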