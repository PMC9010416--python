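"""Buckling mechanics of a stiff oxidized skin on a soft elastomer.

A thin stiff layer (Young's modulus ``E_p``, thickness ``h``) bonded to a
compliant elastomer (``E_m``) buckles sinusoidally under in-plane
compression.  Linear stability gives a wavelength set only by the stiffness
ratio,

    lambda / h = 2 pi (E_p / (3 E_m))^(1/3),

an onset (critical) compressive strain

    eps_c = -(1/4) (3 E_m / E_p)^(2/3),

and a post-onset amplitude

    A / h = (eps / eps_c - 1)^(1/2).

Compressive strains are carried as negative numbers throughout.  Because
the wrinkle-generation condition depends only on ``E_p / E_m``, a traction
field inferred on one substrate transfers to another with the same
stiffness ratio by rescaling forces by the modulus ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import VectorField2D

_TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class BilayerSubstrate:
    """Stiff-skin-on-elastomer substrate.

    Parameters
    ----------
    E_m : float
        Elastomer Young's modulus, Pa.
    E_p : float
        Oxidized-layer Young's modulus, Pa (must exceed ``E_m``).
    h : float
        Oxidized-layer thickness, micrometres (typically ~0.1).
    nu : float
        Poisson's ratio, shared by both layers.
    """

    E_m: float
    E_p: float
    h: float = 0.1
    nu: float = 0.5

    def __post_init__(self) -> None:
        if not (self.E_p > self.E_m > 0):
            raise ValueError(f"need E_p > E_m > 0, got E_p={self.E_p}, E_m={self.E_m}")
        if not self.h > 0:
            raise ValueError(f"need h > 0, got {self.h}")

    @property
    def wavelength(self) -> float:
        """Buckling wavelength in micrometres."""
        return self.h * wavelength_ratio(self.E_p, self.E_m)

    @property
    def critical_strain_value(self) -> float:
        return critical_strain(self.E_p, self.E_m)


def _check_moduli(E_p: float, E_m: float) -> None:
    if not (E_p > 0 and E_m > 0):
        raise ValueError(f"moduli must be positive, got E_p={E_p}, E_m={E_m}")


def wavelength_ratio(E_p: float, E_m: float) -> float:
    """Wavelength-to-thickness ratio lambda/h = 2 pi (E_p/(3 E_m))^(1/3)."""
    _check_moduli(E_p, E_m)
    return _TWO_PI * (E_p / (3.0 * E_m)) ** (1.0 / 3.0)


def stiffness_ratio_from_wavelength(lambda_over_h: float) -> float:
    """Invert the wavelength relation: E_p/E_m = 3 (lambda/h / 2 pi)^3.

    Measuring lambda/h ~ 30 on the plasma-oxidized silicone substrate
    pins the stiffness ratio near 300.
    """
    if not lambda_over_h > 0:
        raise ValueError(f"lambda/h must be positive, got {lambda_over_h}")
    return 3.0 * (lambda_over_h / _TWO_PI) ** 3


def critical_strain(E_p: float, E_m: float) -> float:
    """Onset strain eps_c = -(1/4) (3 E_m/E_p)^(2/3); always negative."""
    _check_moduli(E_p, E_m)
    return -0.25 * (3.0 * E_m / E_p) ** (2.0 / 3.0)


def amplitude(strain: float, eps_c: float, h: float) -> float:
    """Wrinkle amplitude A = h (eps/eps_c - 1)^(1/2), 0 below onset.

    Both ``strain`` and ``eps_c`` are compressive, hence negative; the ratio
    eps/eps_c is positive and the square root is evaluated literally above
    onset.  Sub-critical strain (|eps| <= |eps_c|) returns 0 rather than a
    complex amplitude.
    """
    if strain > 0 or eps_c >= 0:
        raise ValueError(
            f"compressive (negative) strains expected, got eps={strain}, eps_c={eps_c}"
        )
    ratio = strain / eps_c
    if ratio <= 1.0:
        return 0.0
    return h * float(np.sqrt(ratio - 1.0))


def rescale_prediction(
    traction: VectorField2D, E_ref: float, E_new: float
) -> VectorField2D:
    """Transfer a predicted traction field to a substrate of different modulus.

    Valid only when the skin/elastomer stiffness ratio is unchanged between
    the two conditions, in which case the wrinkle-generation criteria are
    identical and every force component simply scales by ``E_new / E_ref``.
    """
    if not (E_ref > 0 and E_new > 0):
        raise ValueError(f"moduli must be positive, got {E_ref}, {E_new}")
    return traction * (E_new / E_ref)
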