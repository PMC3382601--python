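"""FRET photophysics arithmetic.

Efficiency from donor intensities with labeling-efficiency correction,
the Foerster efficiency/distance relation and the Foerster radius:

    E     = (1 - I_DA / I_D) / f_A
    r     = R0 * (1/E - 1)^(1/6)
    E(r)  = 1 / (1 + (r/R0)^6)
    R0[A] = 0.2108 * (kappa^2 * n^-4 * Phi_D * J)^(1/6),  J in M^-1 cm^-1 nm^4

The apparent efficiency is corrected by dividing by the acceptor labeling
efficiency f_A = c_D/c_P (dye over protein concentration), the standard
ensemble correction for incompletely labeled acceptor populations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import FORSTER_PREFACTOR

__all__ = [
    "FRETMeasurement",
    "FRETPairParams",
    "efficiency_from_intensities",
    "distance_from_efficiency",
    "efficiency_from_distance",
    "forster_radius",
]

#: Manufacturer Foerster radius for the A350/A488 donor-acceptor pair, A.
R0_A350_A488 = 50.0


@dataclass
class FRETMeasurement:
    i_da: float  # donor intensity with acceptor present, arbitrary units
    i_d: float  # donor-only intensity, same units
    f_a: float = 1.0  # acceptor labeling efficiency in (0, 1]

    def __post_init__(self):
        if self.i_d <= 0:
            raise ValueError("donor-only intensity I_D must be positive")
        if not (0.0 < self.f_a <= 1.0):
            raise ValueError(f"labeling efficiency f_A must be in (0,1], got {self.f_a}")


@dataclass
class FRETPairParams:
    kappa2: float = 2.0 / 3.0  # orientation factor, isotropic average
    n: float = 1.33  # refractive index
    phi_d: float = 0.5  # donor quantum yield
    j_overlap: float = 1.0e15  # overlap integral, M^-1 cm^-1 nm^4

    def __post_init__(self):
        if not (0.0 <= self.kappa2 <= 4.0):
            raise ValueError("kappa^2 must lie in [0, 4]")
        if not (0.0 < self.phi_d <= 1.0):
            raise ValueError("Phi_D must lie in (0, 1]")
        if self.n <= 0 or self.j_overlap < 0:
            raise ValueError("n must be positive and J non-negative")


def efficiency_from_intensities(m: FRETMeasurement) -> float:
    """Measured FRET efficiency E = (1 - I_DA/I_D) / f_A.

    Raises on I_DA > I_D (negative apparent efficiency: intensities are
    inconsistent). Values at the edges of (0, 1) are returned with a
    warning since they carry no distance information.
    """
    if m.i_da > m.i_d:
        raise ValueError(
            f"I_DA = {m.i_da} exceeds I_D = {m.i_d}: apparent efficiency "
            "would be negative; check donor-only reference"
        )
    e = (1.0 - m.i_da / m.i_d) / m.f_a
    if e <= 0.0:
        warnings.warn("efficiency 0: donor quenching out of dynamic range")
        return 0.0
    if e >= 1.0:
        warnings.warn(
            f"labeling-corrected efficiency {e:.3f} >= 1 clipped to 1"
        )
        return 1.0
    return float(e)


def distance_from_efficiency(e: float, r0: float = R0_A350_A488) -> float:
    """Donor-acceptor distance from a transfer efficiency, Angstrom."""
    if not (0.0 < e < 1.0):
        raise ValueError(f"efficiency must be in (0, 1), got {e}")
    if r0 <= 0:
        raise ValueError("R0 must be positive")
    return float(r0 * (1.0 / e - 1.0) ** (1.0 / 6.0))


def efficiency_from_distance(r: float, r0: float = R0_A350_A488) -> float:
    """Transfer efficiency at separation r; exact inverse of
    :func:`distance_from_efficiency`."""
    if r <= 0:
        raise ValueError("distance must be positive")
    if r0 <= 0:
        raise ValueError("R0 must be positive")
    return float(1.0 / (1.0 + (r / r0) ** 6))


def forster_radius(p: FRETPairParams) -> float:
    """Foerster radius in Angstrom from spectroscopic parameters."""
    return float(
        FORSTER_PREFACTOR
        * (p.kappa2 * p.n**-4 * p.phi_d * p.j_overlap) ** (1.0 / 6.0)
    )
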