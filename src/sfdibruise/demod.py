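"""Three-phase demodulation and reference calibration.

The AC amplitude envelope of three phase-shifted structured-illumination
images (phases 0, 2pi/3, 4pi/3) is extracted pixelwise as

    M_AC = (2/3) * sqrt((I1-I2)**2 + (I2-I3)**2 + (I3-I1)**2)

The 2/3 prefactor is kept as used by the applied SFDI literature; it differs
from the sqrt(2)/3 of the textbook derivation by a constant factor that
cancels exactly under reference calibration, so calibrated reflectance is
invariant to the choice (asserted in the test suite).

Calibration against a reference of known reflectivity (0.99 by default)
converts amplitude to quantitative diffuse reflectance:

    Rd = (M_sample / M_reference) * R_ref
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AmplitudeMap",
    "DiffuseReflectanceMap",
    "demodulate_ac",
    "demodulate_dc",
    "calibrate",
    "REFERENCE_REFLECTIVITY",
    "SATURATION_LEVEL",
]

#: Reflectivity of the standard calibration reference.
REFERENCE_REFLECTIVITY = 0.99
#: Calibrated Rd above this level is flagged as saturated.
SATURATION_LEVEL = 1.05


@dataclass
class AmplitudeMap:
    """Demodulated amplitude envelope at one spatial frequency."""

    M: np.ndarray
    fx: float

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        if np.any(self.M < 0):
            raise ValueError("amplitude must be nonnegative")


@dataclass
class DiffuseReflectanceMap:
    """Calibrated diffuse reflectance at one spatial frequency.

    ``valid`` marks pixels with a usable reference signal; ``saturated``
    marks calibrated values above :data:`SATURATION_LEVEL`.
    """

    Rd: np.ndarray
    fx: float
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]
    saturated: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.Rd = np.asarray(self.Rd, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.Rd.shape, dtype=bool)
        if self.saturated is None:
            self.saturated = self.Rd > SATURATION_LEVEL


def _check_shapes(*imgs: np.ndarray) -> None:
    shapes = {img.shape for img in imgs}
    if len(shapes) != 1:
        raise ValueError(f"image shapes differ: {sorted(shapes)}")


def demodulate_ac(I1, I2, I3, fx: float, prefactor: float = 2.0 / 3.0) -> AmplitudeMap:
    """Demodulate the AC amplitude from three phase-shifted images.

    Parameters
    ----------
    I1, I2, I3 : array_like
        Intensity images at phase shifts 0, 2pi/3, 4pi/3.
    fx : float
        Spatial frequency of the projected pattern, mm^-1.
    prefactor : float
        Demodulation prefactor; the default 2/3 follows the applied
        convention, ``sqrt(2)/3`` the textbook one.  Either choice cancels
        under calibration.
    """
    I1, I2, I3 = (np.asarray(I, dtype=float) for I in (I1, I2, I3))
    _check_shapes(I1, I2, I3)
    M = prefactor * np.sqrt((I1 - I2) ** 2 + (I2 - I3) ** 2 + (I3 - I1) ** 2)
    return AmplitudeMap(M=M, fx=fx)


def demodulate_dc(I_dc) -> AmplitudeMap:
    """DC (fx = 0) amplitude: the planar-illumination image itself.

    The same treatment is applied to sample and reference frames, so the
    common gain cancels under calibration.
    """
    return AmplitudeMap(M=np.asarray(I_dc, dtype=float), fx=0.0)


def calibrate(
    M_sample: AmplitudeMap,
    M_reference: AmplitudeMap,
    R_ref: float = REFERENCE_REFLECTIVITY,
) -> DiffuseReflectanceMap:
    """Convert a demodulated amplitude to quantitative diffuse reflectance.

    Pixels where the reference amplitude is zero cannot be calibrated and are
    flagged invalid rather than divided.
    """
    _check_shapes(M_sample.M, M_reference.M)
    if M_sample.fx != M_reference.fx:
        raise ValueError(
            f"frequency mismatch: sample fx={M_sample.fx}, reference fx={M_reference.fx}"
        )
    valid = M_reference.M > 0
    Rd = np.zeros_like(M_sample.M)
    np.divide(M_sample.M, M_reference.M, out=Rd, where=valid)
    Rd *= R_ref
    return DiffuseReflectanceMap(Rd=Rd, fx=M_sample.fx, valid=valid)
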