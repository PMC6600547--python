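"""Seeded synthetic-data generators with known ground truth.

Every input modality the pipeline consumes can be simulated here: static
1:1 quenching titrations, Gaussian donor/acceptor spectral pairs, two-state
denaturation curves, one-site ITC thermograms, and CD 222 nm measurements.
Each generator returns the simulated object(s) together with a ground-truth
dictionary echoing every parameter used, and is bit-reproducible for a fixed
seed. Noise is additive i.i.d. Gaussian; levels are expressed relative to a
natural signal scale per modality.

Defaults mirror the experimental conditions of the serum-albumin study the
pipeline targets: quencher 0-56 uM, four temperatures 298-315 K, a VP-ITC
style 25 uM cell / 1.25 mM syringe schedule, and GdmCl grids spanning both
plateaus around a midpoint near 2.4 M.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .cd import CDParams
from .constants import CHEN_OFFSET, CHEN_SCALE, HSA_MOLAR_MASS, MRW_HSA, R_KCAL
from .core import Spectrum, Titration
from .cd import DenaturationCurve
from .itc import ITCExperiment, injection_heats

__all__ = [
    "simulate_quenching_series",
    "simulate_spectra_pair",
    "simulate_denaturation_curve",
    "simulate_itc",
    "simulate_cd222",
]

#: Default quencher grid: 0 to 56 uM in 8 evenly spaced points (molar).
DEFAULT_CONC_GRID = np.linspace(0.0, 56e-6, 8)

#: Default temperature series, K.
DEFAULT_TEMPERATURES = (298.0, 303.0, 310.0, 315.0)

#: Default unquenched intensity (arbitrary units; only ratios matter).
DEFAULT_F0 = 1000.0


def _kb_from_thermo(dh: float, ds: float, temperature: float) -> float:
    """Binding constant from van't Hoff parameters: ln K = -dH/RT + dS/R."""
    return float(np.exp(-dh / (R_KCAL * temperature) + ds / R_KCAL))


def simulate_quenching_series(
    ksv_by_temperature: dict[float, float] | None = None,
    dh: float | None = None,
    ds: float | None = None,
    temperatures: Sequence[float] = DEFAULT_TEMPERATURES,
    conc_grid: np.ndarray | None = None,
    f0: float = DEFAULT_F0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[dict[float, Titration], dict]:
    """Simulate static-quenching titrations at one or more temperatures.

    The forward model is the 1:1 static complex, F = F0 / (1 + Ksv [Q]),
    so the Stern–Volmer constant and the association constant coincide.
    Either pass ``ksv_by_temperature`` explicitly, or pass van't Hoff
    parameters ``dh`` (kcal mol^-1) and ``ds`` (kcal mol^-1 K^-1) from which
    Kb(T) is generated at ``temperatures``. ``noise_sd`` is the Gaussian
    noise standard deviation as a fraction of F0.
    """
    if ksv_by_temperature is None:
        if dh is None or ds is None:
            raise ValueError("supply either ksv_by_temperature or both dh and ds")
        ksv_by_temperature = {t: _kb_from_thermo(dh, ds, t) for t in temperatures}
    grid = DEFAULT_CONC_GRID if conc_grid is None else np.asarray(conc_grid, dtype=float)
    if grid[0] != 0.0 or np.any(np.diff(grid) <= 0):
        raise ValueError("concentration grid must start at 0 and increase strictly")
    rng = np.random.default_rng(seed)
    titrations: dict[float, Titration] = {}
    for t in sorted(ksv_by_temperature):
        ksv = ksv_by_temperature[t]
        f = f0 / (1.0 + ksv * grid)
        if noise_sd > 0:
            f = f + rng.normal(0.0, noise_sd * f0, size=grid.size)
            f[0] = f0  # F0 defines the reference point
            f = np.maximum(f, 1e-9 * f0)
        titrations[t] = Titration(grid, f, temperature=t)
    truth = {
        "model": "static_1to1",
        "ksv_by_temperature": dict(ksv_by_temperature),
        "dh": dh,
        "ds": ds,
        "f0": f0,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return titrations, truth


def simulate_spectra_pair(
    donor_center: float = 340.0,
    donor_sigma: float = 20.0,
    donor_amplitude: float = 1000.0,
    acceptor_center: float = 330.0,
    acceptor_sigma: float = 15.0,
    acceptor_eps_max: float = 500.0,
    grid: np.ndarray | None = None,
) -> tuple[Spectrum, Spectrum, dict]:
    """Simulate a Gaussian donor-emission / acceptor-extinction band pair.

    Returns noiseless analytic bands on a common nm grid (default 250-450 nm
    at 1 nm), suitable for overlap-integral validation against fine-grid
    quadrature.
    """
    if donor_sigma <= 0 or acceptor_sigma <= 0:
        raise ValueError("band widths must be positive")
    wl = np.arange(250.0, 451.0, 1.0) if grid is None else np.asarray(grid, dtype=float)
    donor = Spectrum(
        wl,
        donor_amplitude * np.exp(-0.5 * ((wl - donor_center) / donor_sigma) ** 2),
        kind="emission",
    )
    acceptor = Spectrum(
        wl,
        acceptor_eps_max * np.exp(-0.5 * ((wl - acceptor_center) / acceptor_sigma) ** 2),
        kind="extinction",
    )
    truth = {
        "donor": {"center": donor_center, "sigma": donor_sigma, "amplitude": donor_amplitude},
        "acceptor": {"center": acceptor_center, "sigma": acceptor_sigma, "eps_max": acceptor_eps_max},
    }
    return donor, acceptor, truth


def simulate_denaturation_curve(
    dg_d: float = 4.94,
    m: float = 2.05,
    native_baseline: tuple[float, float] = (0.0, 0.0),
    denatured_baseline: tuple[float, float] = (1.0, 0.0),
    temperature: float = 298.0,
    grid: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[DenaturationCurve, dict]:
    """Simulate a two-state GdmCl denaturation curve.

    Defaults are free-HSA-like (dG_D = 4.94 kcal mol^-1, m = 2.05
    kcal mol^-1 M^-1, midpoint 2.41 M) with unit-normalised flat baselines
    on a 0-5 M grid of 15 points. ``noise_sd`` is the Gaussian noise SD as a
    fraction of the baseline separation at the midpoint.
    """
    if m <= 0:
        raise ValueError("m-value must be positive")
    g = np.linspace(0.0, 5.0, 15) if grid is None else np.asarray(grid, dtype=float)
    rt = R_KCAL * temperature
    ex = np.exp(np.clip(-(dg_d - m * g) / rt, -500, 500))
    fd = ex / (1.0 + ex)
    yn = native_baseline[0] + native_baseline[1] * g
    yd = denatured_baseline[0] + denatured_baseline[1] * g
    y = yn * (1.0 - fd) + yd * fd
    if noise_sd > 0:
        cm = dg_d / m
        scale = abs(
            (denatured_baseline[0] + denatured_baseline[1] * cm)
            - (native_baseline[0] + native_baseline[1] * cm)
        )
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd * scale, size=g.size)
    truth = {
        "dg_d": dg_d,
        "m": m,
        "cm": dg_d / m,
        "native_baseline": native_baseline,
        "denatured_baseline": denatured_baseline,
        "temperature": temperature,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return DenaturationCurve(g, y), truth


def simulate_itc(
    n: float = 1.0,
    ka: float = 2.1e3,
    dh: float = -14.4,
    cell_volume: float = 1.4e-3,
    cell_macromolecule_conc: float = 25e-6,
    syringe_ligand_conc: float = 1.25e-3,
    injection_volumes: np.ndarray | None = None,
    temperature: float = 298.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[ITCExperiment, dict]:
    """Simulate a one-site ITC thermogram.

    Defaults emulate the study conditions: 25 uM macromolecule in a 1.4 mL
    cell titrated with 1.25 mM ligand in 25 x 10 uL injections at 298 K, with
    Table-2-like parameters (n = 1, Ka = 2.1e3 M^-1, dH = -14.4 kcal mol^-1).
    ``noise_sd`` is the Gaussian noise SD as a fraction of the largest
    absolute injection heat.
    """
    vols = (
        np.full(25, 10e-6)
        if injection_volumes is None
        else np.asarray(injection_volumes, dtype=float)
    )
    exp = ITCExperiment(
        cell_volume=cell_volume,
        cell_macromolecule_conc=cell_macromolecule_conc,
        syringe_ligand_conc=syringe_ligand_conc,
        injection_volumes=vols,
        temperature=temperature,
    )
    heats = injection_heats(exp, n, ka, dh)
    if noise_sd > 0 and np.any(heats != 0):
        rng = np.random.default_rng(seed)
        heats = heats + rng.normal(0.0, noise_sd * np.max(np.abs(heats)), size=heats.size)
    exp = ITCExperiment(
        cell_volume=cell_volume,
        cell_macromolecule_conc=cell_macromolecule_conc,
        syringe_ligand_conc=syringe_ligand_conc,
        injection_volumes=vols,
        temperature=temperature,
        observed_heats=heats,
    )
    truth = {
        "n": n,
        "ka": ka,
        "dh": dh,
        "c_value": n * ka * cell_macromolecule_conc,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return exp, truth


def simulate_cd222(
    helix_pct: float = 53.0,
    mrw: float = MRW_HSA,
    conc: float = 4e-6 * HSA_MOLAR_MASS * 1e-3,  # 4 uM protein in mg/cm^3
    path_length: float = 0.1,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[CDParams, dict]:
    """Simulate a 222 nm CD measurement at a given alpha-helix content.

    The Chen relation is inverted to the target MRE222, then the raw
    ellipticity is back-computed for the stated cell parameters. ``noise_sd``
    is the Gaussian noise SD as a fraction of |theta|.
    """
    if not 0.0 <= helix_pct <= 100.0:
        raise ValueError("helix content must be within [0, 100] percent")
    mre222 = -(helix_pct / 100.0 * CHEN_SCALE + CHEN_OFFSET)
    theta = mre222 * 10.0 * conc * path_length / mrw
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        theta = theta + rng.normal(0.0, noise_sd * abs(theta))
    params = CDParams(theta=theta, mrw=mrw, conc=conc, path_length=path_length)
    truth = {
        "helix_pct": helix_pct,
        "mre222": mre222,
        "mrw": mrw,
        "conc": conc,
        "path_length": path_length,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return params, truth
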