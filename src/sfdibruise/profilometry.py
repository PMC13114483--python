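"""Four-step phase-shifting profilometry and curved-surface correction.

Fringe patterns projected at phases 0, pi/2, pi, 3pi/2 deform over a curved
sample; the wrapped phase is recovered with the four-step arctangent
estimator, unwrapped, and converted to surface height through a linear
calibration constant.  The height map yields a per-pixel correction
coefficient ``c = h / h_max`` by which demodulated diffuse reflectance is
divided, flattening the center-bright / edge-dark falloff of dome-shaped
fruit before optical-property prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synth import FringeStack

__all__ = [
    "HeightMap",
    "CorrectionField",
    "wrapped_phase",
    "unwrap_phase",
    "phase_to_height",
    "correction_field",
    "correct_reflectance",
    "profile_pipeline",
    "C_MIN",
]

#: Lower clamp of the correction coefficient (avoids rim blow-up).
C_MIN = 0.05


@dataclass
class HeightMap:
    """Surface height above the reference plane, mm."""

    h: np.ndarray
    h_max: float

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        if self.h_max <= 0:
            raise ValueError("h_max must be > 0")


@dataclass
class CorrectionField:
    """Per-pixel reflectance correction coefficient c in [C_MIN, 1]."""

    c: np.ndarray
    low_confidence: np.ndarray

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=float)


def wrapped_phase(stack: FringeStack):
    """Wrapped phase in (-pi, pi] from four phase-shifted fringe images.

    Uses the four-step identity ``phi = atan2(F4 - F2, F1 - F3)``.  Pixels
    with no fringe modulation (both differences zero) are undefined and
    returned in the accompanying flag mask.
    """
    F1, F2, F3, F4 = (np.asarray(F, dtype=float) for F in stack.frames)
    num = F4 - F2
    den = F1 - F3
    undefined = (num == 0) & (den == 0)
    phi = np.arctan2(num, den)
    # atan2 returns [-pi, pi]; map -pi to +pi for the (-pi, pi] convention
    phi[phi == -np.pi] = np.pi
    return phi, undefined


def _fill_undefined(phi, undefined):
    """Replace flagged pixels by the nearest defined value along rows."""
    if not undefined.any():
        return phi
    out = phi.copy()
    for r in range(out.shape[0]):
        bad = undefined[r]
        if bad.all():
            out[r] = 0.0
            continue
        if bad.any():
            idx = np.arange(out.shape[1])
            good = ~bad
            out[r, bad] = np.interp(idx[bad], idx[good], out[r, good])
    return out


def unwrap_phase(wrapped, undefined=None):
    """Remove 2pi discontinuities: row-wise unwrap, then column-seam alignment.

    Every output pixel differs from its wrapped input by an exact multiple
    of 2pi (flagged pixels excepted, which are interpolated from neighbors).
    """
    wrapped = np.asarray(wrapped, dtype=float)
    if undefined is not None:
        wrapped = _fill_undefined(wrapped, np.asarray(undefined, dtype=bool))
    rows = np.unwrap(wrapped, axis=1)
    # reconcile rows through the unwrapped first column
    col0 = np.unwrap(rows[:, 0])
    return rows + (col0 - rows[:, 0])[:, None]


def phase_to_height(delta_phi, k_height: float) -> HeightMap:
    """Linear phase-to-height conversion ``h = k_height * delta_phi`` (mm).

    ``delta_phi`` is the unwrapped phase minus the reference-plane phase;
    negative heights (noise below the reference plane) are floored at 0.
    """
    if k_height <= 0:
        raise ValueError("k_height must be > 0")
    h = np.maximum(k_height * np.asarray(delta_phi, dtype=float), 0.0)
    h_max = float(h.max())
    return HeightMap(h=h, h_max=h_max if h_max > 0 else 1.0)


def correction_field(height: HeightMap, c_min: float = C_MIN) -> CorrectionField:
    """Correction coefficient ``c = h / max(h)`` clamped to [c_min, 1]."""
    peak = float(height.h.max())
    if peak <= 0:
        raise ValueError("height map is identically zero; no correction defined")
    c = np.clip(height.h / peak, c_min, 1.0)
    return CorrectionField(c=c, low_confidence=c <= c_min)


def correct_reflectance(R_uncorrect, field: CorrectionField):
    """Divide reflectance by the correction coefficient pixelwise."""
    R_uncorrect = np.asarray(R_uncorrect, dtype=float)
    if R_uncorrect.shape != field.c.shape:
        raise ValueError("reflectance and correction field shapes differ")
    return R_uncorrect / field.c


def profile_pipeline(
    fringes: FringeStack,
    reference_fringes: FringeStack,
    k_height: float,
    c_min: float = C_MIN,
):
    """Full profilometry chain: fringes -> height -> correction field.

    The reference-plane phase is obtained by running the identical
    wrap/unwrap steps on the flat-scene fringe stack, so systematic phase
    offsets cancel in the difference.
    """
    phi_w, und = wrapped_phase(fringes)
    phi = unwrap_phase(phi_w, und)
    ref_w, ref_und = wrapped_phase(reference_fringes)
    ref = unwrap_phase(ref_w, ref_und)
    height = phase_to_height(phi - ref, k_height)
    return height, correction_field(height, c_min)
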