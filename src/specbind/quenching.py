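"""Fluorescence-quenching binding analysis and van't Hoff thermodynamics.

Implements the Stern–Volmer treatment of tryptophan quenching titrations:

- the linear Stern–Volmer fit  F0/F = 1 + Ksv [Q]  with the bimolecular
  quenching rate constant kq = Ksv / tau0;
- the double-log ("modified Stern–Volmer") fit
  log10((F0-F)/F) = log10 Kb + n log10 [Q]
  yielding the association constant Kb and apparent stoichiometry n;
- the quenching-mechanism classification (static vs dynamic) from the
  temperature trend of Ksv and the magnitude of kq;
- van't Hoff analysis of Kb(T) for dH, dS, and per-temperature dG.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .constants import DIFFUSION_LIMIT, R_KCAL, TAU0_HSA
from .core import Titration

__all__ = [
    "QuenchFit",
    "BindingFit",
    "VantHoffResult",
    "stern_volmer_fit",
    "bimolecular_rate",
    "modified_sv_fit",
    "classify_quenching",
    "vant_hoff_fit",
    "gibbs_from_k",
]


@dataclass(frozen=True)
class QuenchFit:
    """Result of a linear Stern–Volmer fit at one temperature."""

    ksv: float  # M^-1
    intercept: float  # ideally 1
    temperature: float  # K
    r_squared: float
    std_errors: dict[str, float]
    kq: float | None = None  # M^-1 s^-1, when tau0 supplied
    tau0: float | None = None  # s


@dataclass(frozen=True)
class BindingFit:
    """Result of the double-log binding fit at one temperature."""

    kb: float  # M^-1
    n: float  # apparent stoichiometry
    temperature: float  # K
    r_squared: float
    std_errors: dict[str, float]

    def __post_init__(self) -> None:
        if self.kb <= 0 or self.n <= 0:
            raise ValueError("Kb and n must be positive")


@dataclass(frozen=True)
class VantHoffResult:
    """Thermodynamic parameters from a van't Hoff plot of ln Kb vs 1/T.

    ``dh`` and ``ds`` are the fitted enthalpy (kcal mol^-1) and entropy
    (kcal mol^-1 K^-1); ``table`` tabulates T, TdS, and dG = dH - T dS at
    each input temperature. dS is treated as temperature-independent over
    the fitted range.
    """

    dh: float
    ds: float
    std_errors: dict[str, float]
    r_squared: float
    temperatures: np.ndarray = field(repr=False)

    def dg(self, temperature: float) -> float:
        """Gibbs free energy dG = dH - T*dS, kcal mol^-1."""
        return self.dh - temperature * self.ds

    @property
    def table(self) -> pd.DataFrame:
        t = np.asarray(self.temperatures, dtype=float)
        return pd.DataFrame(
            {
                "T_K": t,
                "TdS_kcal_mol": t * self.ds,
                "dG_kcal_mol": self.dh - t * self.ds,
            }
        )


def _linregress(x: np.ndarray, y: np.ndarray):
    res = stats.linregress(x, y)
    return res


def stern_volmer_fit(
    titration: Titration, tau0: float | None = TAU0_HSA
) -> QuenchFit:
    """Ordinary least-squares Stern–Volmer fit of F0/F against [Q].

    The slope is Ksv (M^-1); the intercept is reported as a diagnostic and
    should be ~1 for well-behaved data. When ``tau0`` (s) is supplied the
    bimolecular quenching rate constant kq = Ksv/tau0 is attached.
    """
    if len(titration) < 3:
        raise ValueError("Stern-Volmer fit needs at least 3 titration points")
    q = titration.quencher_conc
    ratio = titration.f0 / titration.intensity
    res = _linregress(q, ratio)
    se = {"ksv": float(res.stderr), "intercept": float(res.intercept_stderr)}
    kq = bimolecular_rate(res.slope, tau0) if tau0 is not None else None
    return QuenchFit(
        ksv=float(res.slope),
        intercept=float(res.intercept),
        temperature=titration.temperature,
        r_squared=float(res.rvalue**2),
        std_errors=se,
        kq=kq,
        tau0=tau0,
    )


def bimolecular_rate(ksv: float, tau0: float) -> float:
    """kq = Ksv / tau0 (M^-1 s^-1)."""
    if tau0 <= 0:
        raise ValueError("tau0 must be positive")
    return ksv / tau0


def modified_sv_fit(titration: Titration) -> BindingFit:
    """Double-log binding fit: log10((F0-F)/F) regressed on log10 [Q].

    The [Q]=0 point is excluded (its logarithm is undefined); every quenched
    point must satisfy F < F0. The slope is the apparent stoichiometry n and
    the intercept is log10 Kb; the standard error of Kb follows from the
    intercept's by the delta method.
    """
    q = titration.quencher_conc
    f = titration.intensity
    f0 = titration.f0
    mask = q > 0
    if mask.sum() < 3:
        raise ValueError("double-log fit needs at least 3 points with [Q] > 0")
    if np.any(f[mask] >= f0):
        raise ValueError("all quenched points must have F < F0 (log undefined otherwise)")
    x = np.log10(q[mask])
    y = np.log10((f0 - f[mask]) / f[mask])
    res = _linregress(x, y)
    kb = 10.0**res.intercept
    se = {
        "n": float(res.stderr),
        "kb": float(kb * np.log(10.0) * res.intercept_stderr),
        "log10_kb": float(res.intercept_stderr),
    }
    return BindingFit(
        kb=float(kb),
        n=float(res.slope),
        temperature=titration.temperature,
        r_squared=float(res.rvalue**2),
        std_errors=se,
    )


def classify_quenching(
    fits: list[QuenchFit], diffusion_limit: float = DIFFUSION_LIMIT
) -> str:
    """Classify the quenching mechanism from multi-temperature Ksv and kq.

    - ``static``: Ksv strictly decreases with temperature (ground-state
      complex dissociates on heating) and every kq exceeds the diffusion
      limit;
    - ``dynamic``: Ksv strictly increases with temperature and every kq is
      at or below the diffusion limit;
    - ``indeterminate`` otherwise.
    """
    if len(fits) < 2:
        raise ValueError("classification needs fits at two or more temperatures")
    if any(f.kq is None for f in fits):
        raise ValueError("all fits must carry kq (supply tau0 to stern_volmer_fit)")
    ordered = sorted(fits, key=lambda f: f.temperature)
    ksv = np.array([f.ksv for f in ordered])
    kq = np.array([f.kq for f in ordered])
    if np.all(np.diff(ksv) < 0) and np.all(kq > diffusion_limit):
        return "static"
    if np.all(np.diff(ksv) > 0) and np.all(kq <= diffusion_limit):
        return "dynamic"
    return "indeterminate"


def vant_hoff_fit(
    points: list[tuple[float, float]], gas_constant: float = R_KCAL
) -> VantHoffResult:
    """Van't Hoff analysis: OLS of ln Kb on 1/T.

    ln Kb = -(dH/R)(1/T) + dS/R, so dH = -slope*R and dS = intercept*R.
    dG = dH - T*dS is tabulated at each input temperature.
    """
    if len(points) < 3:
        raise ValueError("van't Hoff fit needs at least 3 temperatures")
    t = np.array([p[0] for p in points], dtype=float)
    kb = np.array([p[1] for p in points], dtype=float)
    if np.unique(t).size != t.size:
        raise ValueError("temperatures must be distinct")
    if np.any(kb <= 0):
        raise ValueError("all binding constants must be positive")
    res = _linregress(1.0 / t, np.log(kb))
    return VantHoffResult(
        dh=float(-res.slope * gas_constant),
        ds=float(res.intercept * gas_constant),
        std_errors={
            "dh": float(res.stderr * gas_constant),
            "ds": float(res.intercept_stderr * gas_constant),
        },
        r_squared=float(res.rvalue**2),
        temperatures=np.sort(t),
    )


def gibbs_from_k(k: float, temperature: float, gas_constant: float = R_KCAL) -> float:
    """Gibbs free energy of association, dG = -R T ln K (kcal mol^-1)."""
    if k <= 0 or temperature <= 0:
        raise ValueError("K and T must be positive")
    return -gas_constant * temperature * np.log(k)
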