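"""One-site (Wiseman) isothermal titration calorimetry model and fitting.

A single set of identical, independent sites binding a ligand titrated from
a syringe into a perfusion cell. The cumulative heat after each injection
follows the closed-form solution of the 1:1 mass-action quadratic; observed
per-injection heats are successive differences with a displaced-volume
correction for the liquid pushed out of the active cell volume.

The fit recovers stoichiometry n, association constant Ka (M^-1), and molar
binding enthalpy dH (kcal mol^-1); dG = -RT ln Ka and TdS = dH - dG follow.
For weakly binding systems the Wiseman c-value, c = n*Ka*[M], can fall well
below 1, in which case n and Ka are poorly separable and the fit flags it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import curve_fit

from .constants import R_KCAL
from .quenching import gibbs_from_k

__all__ = [
    "ITCExperiment",
    "OneSiteFit",
    "wiseman_total_heat",
    "injection_heats",
    "one_site_fit",
    "thermo_from_fit",
]


@dataclass(frozen=True)
class ITCExperiment:
    """An ITC injection schedule, optionally with observed integrated heats.

    Volumes in litres, concentrations molar, heats in kcal (per injection,
    already integrated over the power peak), temperature in Kelvin.
    """

    cell_volume: float
    cell_macromolecule_conc: float
    syringe_ligand_conc: float
    injection_volumes: np.ndarray
    temperature: float = 298.0
    observed_heats: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.injection_volumes, dtype=float)
        if self.cell_volume <= 0 or self.cell_macromolecule_conc <= 0 or self.syringe_ligand_conc <= 0:
            raise ValueError("cell volume and concentrations must be positive")
        if v.ndim != 1 or v.size == 0 or np.any(v < 0):
            raise ValueError("injection volumes must be a non-empty 1-D non-negative array")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (Kelvin)")
        object.__setattr__(self, "injection_volumes", v)
        if self.observed_heats is not None:
            q = np.asarray(self.observed_heats, dtype=float)
            if q.size != v.size:
                raise ValueError("observed heats must match the number of injections")
            object.__setattr__(self, "observed_heats", q)

    def __len__(self) -> int:
        return self.injection_volumes.size

    def cell_concentrations(self) -> tuple[np.ndarray, np.ndarray]:
        """Total macromolecule and ligand concentrations after each injection.

        Standard perfusion-cell dilution bookkeeping: with cumulative injected
        volume v, Mt = M0 (1 - v/2V0)/(1 + v/2V0) and
        Xt = Xs (v/V0)(1 - v/2V0).
        """
        v0 = self.cell_volume
        cum = np.cumsum(self.injection_volumes)
        half = cum / (2.0 * v0)
        mt = self.cell_macromolecule_conc * (1.0 - half) / (1.0 + half)
        xt = self.syringe_ligand_conc * (cum / v0) * (1.0 - half)
        return mt, xt


@dataclass(frozen=True)
class OneSiteFit:
    """Fitted one-site parameters with derived thermodynamics.

    ``dg_from_ka`` is -RT ln Ka; ``tds`` is derived as dH - dG with the dG
    route used recorded in ``dg``. ``low_c`` warns that n and Ka are nearly
    degenerate when the Wiseman c-value is below 1.
    """

    n: float
    ka: float  # M^-1
    dh: float  # kcal mol^-1
    temperature: float
    std_errors: dict[str, float]
    chi_square: float
    c_value: float

    def __post_init__(self) -> None:
        if self.ka <= 0:
            raise ValueError("Ka must be positive")

    @property
    def dg_from_ka(self) -> float:
        return gibbs_from_k(self.ka, self.temperature)

    @property
    def dg(self) -> float:
        return self.dg_from_ka

    @property
    def tds(self) -> float:
        return self.dh - self.dg

    @property
    def low_c(self) -> bool:
        return self.c_value < 1.0


def wiseman_total_heat(
    xt: float, mt: float, n: float, ka: float, dh: float, cell_volume: float
):
    """Cumulative heat content Q (kcal) of the cell at total concentrations Xt, Mt.

    Closed-form root of the 1:1 mass-action quadratic for a single set of n
    identical sites:

    Q = (n Mt dH V0 / 2) [1 + Xt/(n Mt) + 1/(n Ka Mt)
        - sqrt((1 + Xt/(n Mt) + 1/(n Ka Mt))^2 - 4 Xt/(n Mt))]
    """
    if n <= 0 or ka <= 0 or mt <= 0 or cell_volume <= 0:
        raise ValueError("n, Ka, Mt, and V0 must be positive")
    xt = np.asarray(xt, dtype=float)
    if np.any(xt < 0):
        raise ValueError("total ligand concentration must be non-negative")
    b = 1.0 + xt / (n * mt) + 1.0 / (n * ka * mt)
    disc = b**2 - 4.0 * xt / (n * mt)
    assert np.all(disc >= 0), "mass-action discriminant went negative"
    q = (n * mt * dh * cell_volume / 2.0) * (b - np.sqrt(disc))
    return float(q) if q.ndim == 0 else q


def injection_heats(
    experiment: ITCExperiment,
    n: float,
    ka: float,
    dh: float,
    displaced_volume_correction: bool = True,
) -> np.ndarray:
    """Predicted per-injection heats (kcal) for a one-site model.

    Each injection's heat is the change in cell heat content plus, when the
    displaced-volume correction is on, the heat carried out by the liquid the
    injection pushes from the active volume:

    dQ_i = Q_i - Q_{i-1} + (dV_i/V0) * (Q_i + Q_{i-1}) / 2
    """
    v0 = experiment.cell_volume
    mt, xt = experiment.cell_concentrations()
    q = np.array(
        [wiseman_total_heat(x, m, n, ka, dh, v0) for x, m in zip(xt, mt)]
    )
    q_prev = np.concatenate([[0.0], q[:-1]])
    dq = q - q_prev
    if displaced_volume_correction:
        dq = dq + (experiment.injection_volumes / v0) * (q + q_prev) / 2.0
    return dq


def one_site_fit(experiment: ITCExperiment) -> OneSiteFit:
    """Least-squares fit of (n, Ka, dH) to the observed injection heats.

    Derived quantities (dG, TdS, c-value, low-c flag) are attached to the
    result. Raises on fewer than 10 injections, missing or all-zero heats,
    or optimizer failure.
    """
    if experiment.observed_heats is None:
        raise ValueError("experiment carries no observed heats to fit")
    if len(experiment) < 10:
        raise ValueError("one-site fit needs at least 10 injections")
    q_obs = experiment.observed_heats
    if not np.any(q_obs):
        raise ValueError("all observed heats are zero; nothing to fit")

    m0 = experiment.cell_macromolecule_conc
    v0 = experiment.cell_volume
    # Fit on heats normalised to their largest magnitude and on log10(Ka):
    # absolute heats are ~1e-9 kcal and Ka spans decades, so the raw
    # parameterisation stalls the optimizer's relative tolerances.
    scale = float(np.max(np.abs(q_obs)))
    dh0 = float(np.sum(q_obs) / (m0 * v0))
    if dh0 == 0.0:
        dh0 = float(q_obs[np.argmax(np.abs(q_obs))] / (m0 * v0))
    p0 = [1.0, 3.0, dh0]

    def model(_idx, n, log_ka, dh):
        return injection_heats(experiment, n, 10.0**log_ka, dh) / scale

    idx = np.arange(len(experiment))
    try:
        popt, pcov = curve_fit(
            model,
            idx,
            q_obs / scale,
            p0=p0,
            bounds=([1e-6, -6.0, -np.inf], [np.inf, 12.0, np.inf]),
            method="trf",
            maxfev=40000,
        )
    except RuntimeError as exc:  # pragma: no cover - exercised via degenerate inputs
        raise RuntimeError(f"one-site ITC fit did not converge: {exc}") from exc
    n_fit, log_ka_fit, dh_fit = popt
    ka_fit = 10.0**log_ka_fit
    perr = np.sqrt(np.diag(pcov))
    resid = (q_obs / scale - model(idx, *popt)) * scale
    return OneSiteFit(
        n=float(n_fit),
        ka=float(ka_fit),
        dh=float(dh_fit),
        temperature=experiment.temperature,
        std_errors={
            "n": float(perr[0]),
            "ka": float(ka_fit * np.log(10.0) * perr[1]),  # delta method from log10 Ka
            "log10_ka": float(perr[1]),
            "dh": float(perr[2]),
        },
        chi_square=float(np.sum(resid**2)),
        c_value=float(n_fit * ka_fit * m0),
    )


def thermo_from_fit(dh: float, tds: float) -> float:
    """Gibbs free energy dG = dH - TdS (kcal mol^-1)."""
    return dh - tds
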