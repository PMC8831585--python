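"""Per-channel point-spread-function parameters.

Diffraction-limited dots are modelled as 3D Gaussians.  The predicted
lateral FWHM per dye follows from its emission wavelength and the imaging
optics (100x/1.45 NA widefield); axial extent is broader by a fixed
anisotropy factor.  Pixel conversions use the camera sampling of
130 nm laterally and 200 nm between focal planes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "PsfParams",
    "channel_psf_params",
    "FWHM_PER_SIGMA",
    "LATERAL_NM",
    "AXIAL_NM",
    "VOXEL_NM",
]

#: FWHM = 2 sqrt(2 ln 2) * sigma for a Gaussian profile.
FWHM_PER_SIGMA: float = 2.0 * math.sqrt(2.0 * math.log(2.0))

LATERAL_NM: float = 130.0
AXIAL_NM: float = 200.0
#: voxel size as (z, y, x) nm
VOXEL_NM: tuple[float, float, float] = (AXIAL_NM, LATERAL_NM, LATERAL_NM)

#: Axial FWHM / lateral FWHM for the widefield PSF model used throughout.
AXIAL_FACTOR: float = 2.0

#: (emission wavelength nm, predicted lateral FWHM nm) per channel.
_PREDICTED: dict[str, tuple[float, float]] = {
    "a488": (525.0, 282.0),
    "tmr": (562.0, 302.0),
    "a594": (617.0, 332.0),
    "cy5": (664.0, 357.0),
    "a700": (723.0, 389.0),
    "ir800": (814.0, 438.0),
}


@dataclass(frozen=True)
class PsfParams:
    """Predicted PSF geometry for one channel."""

    channel: str
    emission_nm: float
    predicted_fwhm_nm: float

    @property
    def predicted_fwhm_px(self) -> float:
        return self.predicted_fwhm_nm / LATERAL_NM

    @property
    def expected_sigma_px(self) -> float:
        """Lateral Gaussian sigma in lateral pixels."""
        return self.predicted_fwhm_px / FWHM_PER_SIGMA

    @property
    def expected_sigma_nm(self) -> float:
        return self.predicted_fwhm_nm / FWHM_PER_SIGMA

    @property
    def expected_sigma_z_nm(self) -> float:
        """Axial Gaussian sigma in nm (lateral sigma x anisotropy factor)."""
        return self.expected_sigma_nm * AXIAL_FACTOR

    @property
    def expected_sigma_z_px(self) -> float:
        """Axial Gaussian sigma in axial pixels (focal-plane units)."""
        return self.expected_sigma_z_nm / AXIAL_NM


def channel_psf_params(channel: str) -> PsfParams:
    """Predicted PSF parameters for a dye channel.

    >>> round(channel_psf_params("cy5").predicted_fwhm_px, 2)
    2.75
    """
    try:
        em, fwhm = _PREDICTED[channel]
    except KeyError:
        raise KeyError(f"unknown channel {channel!r}") from None
    return PsfParams(channel, em, fwhm)
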