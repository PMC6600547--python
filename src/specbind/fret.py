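"""Förster resonance energy transfer between a tryptophan donor and a bound ligand.

The chain of quantities is: spectral overlap integral J (M^-1 cm^3) from the
donor-emission and acceptor-extinction spectra; Förster radius R0 (nm) from J
and the photophysical constants (kappa^2, refractive index n, quantum yield
Phi); transfer efficiency E from the donor-intensity drop; and finally the
donor–acceptor distance r from E and R0.

Unit convention: the prefactor 8.79e-25 of the R0^6 relation requires lambda
in cm inside the overlap integrand (J in M^-1 cm^3); R0 then emerges in cm.
This module owns those conversions and exposes nanometres externally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import trapezoid

from .constants import (
    FORSTER_PREFACTOR,
    KAPPA2_DEFAULT,
    N_REFRACTIVE_DEFAULT,
    PHI_DONOR_DEFAULT,
)
from .core import Spectrum

__all__ = [
    "FretResult",
    "FretValidity",
    "overlap_integral",
    "forster_radius",
    "transfer_efficiency",
    "donor_acceptor_distance",
    "fret_validity",
    "compute_fret",
]

_NM_TO_CM = 1e-7


@dataclass(frozen=True)
class FretValidity:
    """Sanity flags for a FRET distance estimate."""

    ratio_ok: bool  # 0.5 R0 < r < 1.5 R0
    range_ok: bool  # both R0 and r within the 2-8 nm FRET window


@dataclass(frozen=True)
class FretResult:
    """Full FRET parameter set with the constants used to derive it."""

    j: float  # M^-1 cm^3
    r0: float  # nm
    efficiency: float
    r: float  # nm
    kappa2: float
    n_refractive: float
    phi: float
    validity: FretValidity


def overlap_integral(donor_emission: Spectrum, acceptor_extinction: Spectrum) -> float:
    """Spectral overlap integral J = ∫ F(λ) ε(λ) λ⁴ dλ / ∫ F(λ) dλ, M^-1 cm^3.

    Both spectra are linearly interpolated onto the union of their wavelength
    grids, with zero extension outside each measured range, and integrated by
    the trapezoidal rule. λ is converted to cm inside the numerator so that
    J carries the units required by :func:`forster_radius`.
    """
    if acceptor_extinction.kind != "extinction":
        raise ValueError("acceptor spectrum must be of kind 'extinction'")
    d_wl, a_wl = donor_emission.wavelength, acceptor_extinction.wavelength
    if d_wl[-1] <= a_wl[0] or a_wl[-1] <= d_wl[0]:
        raise ValueError("donor and acceptor wavelength ranges do not overlap")
    grid = np.union1d(d_wl, a_wl)
    f = np.interp(grid, d_wl, donor_emission.values, left=0.0, right=0.0)
    eps = np.interp(grid, a_wl, acceptor_extinction.values, left=0.0, right=0.0)
    denom = trapezoid(f, grid)
    if denom <= 0:
        raise ValueError("donor emission spectrum integrates to zero")
    numer = trapezoid(f * eps * (grid * _NM_TO_CM) ** 4, grid)
    return float(numer / denom)


def forster_radius(
    j: float,
    kappa2: float = KAPPA2_DEFAULT,
    n_refractive: float = N_REFRACTIVE_DEFAULT,
    phi: float = PHI_DONOR_DEFAULT,
) -> float:
    """Förster critical distance R0 (nm) at which transfer efficiency is 50%.

    R0^6 = 8.79e-25 * kappa^2 * n^-4 * Phi * J with J in M^-1 cm^3 gives R0
    in cm; the result is returned in nm.
    """
    if j < 0:
        raise ValueError("overlap integral must be non-negative")
    if kappa2 <= 0 or n_refractive <= 0 or phi <= 0:
        raise ValueError("kappa2, n, and Phi must be positive")
    r0_cm = (FORSTER_PREFACTOR * kappa2 * n_refractive**-4 * phi * j) ** (1.0 / 6.0)
    return float(r0_cm / _NM_TO_CM)


def transfer_efficiency(f: float, f0: float) -> float:
    """Energy-transfer efficiency E = 1 - F/F0 from the donor intensity drop."""
    if f0 <= 0:
        raise ValueError("F0 must be positive")
    if not 0 < f <= f0:
        raise ValueError("require 0 < F <= F0")
    return 1.0 - f / f0


def donor_acceptor_distance(efficiency: float, r0: float) -> float:
    """Donor–acceptor distance r = R0 * ((1-E)/E)^(1/6), nm."""
    if not 0 < efficiency < 1:
        raise ValueError("efficiency must lie strictly between 0 and 1")
    if r0 <= 0:
        raise ValueError("R0 must be positive")
    return float(r0 * ((1.0 - efficiency) / efficiency) ** (1.0 / 6.0))


def fret_validity(r0: float, r: float) -> FretValidity:
    """Check 0.5 R0 < r < 1.5 R0 and that both distances sit in the 2-8 nm window."""
    if r0 <= 0 or r <= 0:
        raise ValueError("distances must be positive")
    return FretValidity(
        ratio_ok=bool(0.5 * r0 < r < 1.5 * r0),
        range_ok=bool(2.0 <= r0 <= 8.0 and 2.0 <= r <= 8.0),
    )


def compute_fret(
    donor_emission: Spectrum,
    acceptor_extinction: Spectrum,
    f: float,
    f0: float,
    kappa2: float = KAPPA2_DEFAULT,
    n_refractive: float = N_REFRACTIVE_DEFAULT,
    phi: float = PHI_DONOR_DEFAULT,
) -> FretResult:
    """Run the full FRET chain: J → R0, E → r, plus validity flags.

    ``f`` and ``f0`` are the donor intensities with and without acceptor at
    matched (equimolar) donor/acceptor concentrations.
    """
    j = overlap_integral(donor_emission, acceptor_extinction)
    r0 = forster_radius(j, kappa2, n_refractive, phi)
    e = transfer_efficiency(f, f0)
    r = donor_acceptor_distance(e, r0)
    return FretResult(
        j=j,
        r0=r0,
        efficiency=e,
        r=r,
        kappa2=kappa2,
        n_refractive=n_refractive,
        phi=phi,
        validity=fret_validity(r0, r),
    )
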