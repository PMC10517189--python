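"""Leaf absorptance and absorbed photon flux.

The actinic source is 90% red (625 nm) and 10% blue (475 nm); incident PFD
is converted to absorbed PFD with a source-weighted scalar absorptance
L_abs = 1 - T_s - R_s measured on a diffuse sample at those two bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

RED_NM = 625.0
BLUE_NM = 475.0
RED_WEIGHT = 0.9
BLUE_WEIGHT = 0.1


@dataclass(frozen=True)
class SpectralSample:
    """Transmittance/reflectance of a diffuse leaf sample at one band."""

    wavelength_nm: float
    t_s: float  # transmittance, fraction
    r_s: float  # reflectance, fraction

    def __post_init__(self) -> None:
        if self.t_s < 0 or self.r_s < 0:
            raise ValueError("transmittance and reflectance must be >= 0")
        if self.t_s + self.r_s > 1:
            raise ValueError("t_s + r_s may not exceed 1")


def leaf_absorptance(sample: SpectralSample) -> float:
    """L_abs = 1 - T_s - R_s, always in [0, 1]."""
    return 1.0 - sample.t_s - sample.r_s


def source_weighted_absorptance(l_red: float, l_blue: float) -> float:
    """Absorptance weighted by the 90/10 red/blue source composition."""
    for v in (l_red, l_blue):
        if not 0 < v <= 1:
            raise ValueError("band absorptance must be in (0, 1]")
    return RED_WEIGHT * l_red + BLUE_WEIGHT * l_blue


def absorbed_pfd(pfd_in, l_abs: float):
    """Convert incident to absorbed PFD (umol m-2 s-1)."""
    pfd_in = np.asarray(pfd_in, dtype=float)
    if np.any(pfd_in < 0):
        raise ValueError("incident PFD must be >= 0")
    if not 0 < l_abs <= 1:
        raise ValueError("absorptance must be in (0, 1]")
    out = pfd_in * l_abs
    return float(out) if out.ndim == 0 else out


def bands_from_spectrum(spectrum: pd.DataFrame) -> tuple[SpectralSample, SpectralSample]:
    """Pick the red/blue source bands from a (wavelength_nm, t_s, r_s) table.

    The nearest measured wavelength to each band is used.
    """
    wl = spectrum["wavelength_nm"].to_numpy(float)
    samples = []
    for target in (RED_NM, BLUE_NM):
        row = spectrum.iloc[int(np.argmin(np.abs(wl - target)))]
        samples.append(SpectralSample(float(row["wavelength_nm"]),
                                      float(row["t_s"]), float(row["r_s"])))
    return samples[0], samples[1]
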