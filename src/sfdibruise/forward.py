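"""Diffusion-approximation forward model for structured illumination.

Maps the optical transport coefficients of a turbid medium — the absorption
coefficient ``mu_a`` and the reduced scattering coefficient ``mu_s_prime``,
both in mm^-1 — together with the spatial frequency ``fx`` of a sinusoidal
illumination pattern to the diffuse reflectance ``Rd(fx)``.  The model is the
standard semi-infinite diffusion approximation used in spatial frequency
domain imaging (SFDI):

    Rd(fx) = 3*A * (mu_s'/mu_tr) / ((mu_eff'/mu_tr + 1) * (mu_eff'/mu_tr + 3*A))

with ``mu_tr = mu_a + mu_s'`` the transport coefficient,
``mu_eff' = sqrt(3*mu_a*mu_tr + (2*pi*fx)**2)`` the frequency-dependent
effective attenuation, and ``A`` a proportionality constant determined by the
internal reflection at the sample boundary through the effective reflection
coefficient ``Reff(n)``.

Two dialects are offered for the effective attenuation.  The default
``"squared"`` dialect uses ``(2*pi*fx)**2`` inside the square root, the
dimensionally consistent form.  The ``"printed"`` dialect uses ``2*pi*fx``
unsquared, reproducing a variant that circulates in the applied literature;
at ``fx = 0`` the two coincide exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MediumPoint",
    "ForwardDerived",
    "effective_reflection_coefficient",
    "proportionality_constant",
    "diffuse_reflectance",
    "derive",
    "DEFAULT_N",
    "DEFAULT_FX_AC",
]

#: Default refractive index of fruit tissue.
DEFAULT_N = 1.43
#: Default AC spatial frequency in mm^-1.
DEFAULT_FX_AC = 0.2


@dataclass(frozen=True)
class MediumPoint:
    """Optical transport coefficients of a homogeneous turbid medium.

    Parameters
    ----------
    mu_a : float
        Absorption coefficient, mm^-1, >= 0.
    mu_s_prime : float
        Reduced scattering coefficient, mm^-1, > 0.
    n : float
        Refractive index, >= 1.
    """

    mu_a: float
    mu_s_prime: float
    n: float = DEFAULT_N

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu_a) or self.mu_a < 0:
            raise ValueError(f"mu_a must be finite and >= 0, got {self.mu_a}")
        if not np.isfinite(self.mu_s_prime) or self.mu_s_prime <= 0:
            raise ValueError(
                f"mu_s_prime must be finite and > 0, got {self.mu_s_prime}"
            )
        if not np.isfinite(self.n) or self.n < 1:
            raise ValueError(f"n must be finite and >= 1, got {self.n}")


@dataclass(frozen=True)
class ForwardDerived:
    """Derived quantities of the diffusion forward model at one evaluation."""

    mu_tr: float
    mu_eff_prime: float
    K: float
    Reff: float
    A: float


def effective_reflection_coefficient(n):
    """Effective reflection coefficient ``Reff`` from the refractive index.

    Uses the polynomial fit ``Reff = 0.0636*n + 0.668 + 0.71/n - 1.44/n**2``.
    """
    n = np.asarray(n, dtype=float)
    if np.any(n < 1):
        raise ValueError("refractive index must be >= 1")
    out = 0.0636 * n + 0.668 + 0.71 / n - 1.44 / n**2
    return float(out) if out.ndim == 0 else out


def proportionality_constant(Reff):
    """Boundary proportionality constant ``A = (1 - Reff) / (2*(1 + Reff))``."""
    Reff = np.asarray(Reff, dtype=float)
    if np.any(Reff >= 1) or np.any(Reff < 0):
        raise ValueError("Reff must lie in [0, 1)")
    out = (1.0 - Reff) / (2.0 * (1.0 + Reff))
    return float(out) if out.ndim == 0 else out


def _mu_eff_prime(mu_a, mu_tr, fx, dialect):
    K = 2.0 * np.pi * np.asarray(fx, dtype=float)
    if dialect == "squared":
        return np.sqrt(3.0 * mu_a * mu_tr + K**2)
    if dialect == "printed":
        return np.sqrt(3.0 * mu_a * mu_tr + K)
    raise ValueError(f"unknown mueff dialect: {dialect!r}")


def diffuse_reflectance(mu_a, mu_s_prime, fx, n=DEFAULT_N, dialect="squared"):
    """Diffuse reflectance ``Rd(fx)`` of a semi-infinite turbid medium.

    Accepts scalars or broadcastable arrays for ``mu_a``, ``mu_s_prime`` and
    ``fx``.  Values are unitless and lie in ``(0, 1]``; ``Rd = 1`` only in the
    lossless limit ``mu_a = 0`` at ``fx = 0``.

    Parameters
    ----------
    mu_a, mu_s_prime : array_like
        Absorption and reduced scattering coefficients, mm^-1.
    fx : array_like
        Spatial frequency of the illumination, mm^-1, >= 0.
    n : float
        Refractive index of the sample.
    dialect : {"squared", "printed"}
        Form of the effective attenuation; see module docstring.
    """
    mu_a = np.asarray(mu_a, dtype=float)
    mu_s_prime = np.asarray(mu_s_prime, dtype=float)
    fx = np.asarray(fx, dtype=float)
    if np.any(mu_a < 0):
        raise ValueError("mu_a must be >= 0")
    if np.any(mu_s_prime <= 0):
        raise ValueError("degenerate medium: mu_s_prime must be > 0")
    if np.any(fx < 0):
        raise ValueError("fx must be >= 0")
    A = proportionality_constant(effective_reflection_coefficient(n))
    mu_tr = mu_a + mu_s_prime
    mu_eff = _mu_eff_prime(mu_a, mu_tr, fx, dialect)
    ratio = mu_eff / mu_tr
    Rd = 3.0 * A * (mu_s_prime / mu_tr) / ((ratio + 1.0) * (ratio + 3.0 * A))
    return float(Rd) if Rd.ndim == 0 else Rd


def derive(point: MediumPoint, fx: float, dialect: str = "squared") -> ForwardDerived:
    """Derived model quantities for one medium point at one frequency."""
    Reff = effective_reflection_coefficient(point.n)
    A = proportionality_constant(Reff)
    mu_tr = point.mu_a + point.mu_s_prime
    K = 2.0 * np.pi * fx
    mu_eff = float(_mu_eff_prime(point.mu_a, mu_tr, fx, dialect))
    return ForwardDerived(mu_tr=mu_tr, mu_eff_prime=mu_eff, K=K, Reff=float(Reff), A=float(A))
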