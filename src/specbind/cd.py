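"""Circular-dichroism secondary structure and two-state chemical denaturation.

Covers two CD-based measurements on serum albumin:

- secondary-structure content: raw ellipticity (mdeg) is normalised to mean
  residue ellipticity (MRE, deg cm^2 dmol^-1) and the alpha-helix fraction is
  read off the 222 nm band by the Chen relation;
- conformational stability: guanidinium-chloride denaturation curves are fit
  to the two-state linear extrapolation model (LEM), yielding the unfolding
  free energy dG_D, the m-value, and the midpoint Cm = dG_D / m.

The LEM free energy is dG(g) = dG_D - m*[g]: positive m means the denaturant
destabilises the native state, and the observable is a population-weighted
mix of two linear baselines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .constants import CHEN_OFFSET, CHEN_SCALE, R_KCAL

__all__ = [
    "CDParams",
    "DenaturationCurve",
    "TwoStateFit",
    "mre_from_ellipticity",
    "helix_percent",
    "fraction_denatured",
    "two_state_fit",
    "cm_from_params",
]


@dataclass(frozen=True)
class CDParams:
    """A single CD measurement with the normalisation parameters of the cell."""

    theta: float  # observed ellipticity, mdeg
    mrw: float  # mean residue weight, g mol^-1
    conc: float  # protein concentration, mg cm^-3
    path_length: float  # cm

    def __post_init__(self) -> None:
        if self.mrw <= 0 or self.conc <= 0 or self.path_length <= 0:
            raise ValueError("mean residue weight, concentration, and path length must be positive")

    @property
    def mre(self) -> float:
        return mre_from_ellipticity(self.theta, self.mrw, self.conc, self.path_length)


@dataclass(frozen=True)
class DenaturationCurve:
    """Observed ellipticity (or MRE) at 222 nm versus denaturant molarity."""

    denaturant: np.ndarray  # M GdmCl, strictly increasing, >= 0
    y: np.ndarray
    replicate: str | None = None

    def __post_init__(self) -> None:
        g = np.asarray(self.denaturant, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if g.ndim != 1 or g.size != y.size:
            raise ValueError("denaturant and y must be equal-length 1-D arrays")
        if np.any(g < 0) or np.any(np.diff(g) <= 0):
            raise ValueError("denaturant concentrations must be non-negative and strictly increasing")
        object.__setattr__(self, "denaturant", g)
        object.__setattr__(self, "y", y)

    def __len__(self) -> int:
        return self.denaturant.size


@dataclass(frozen=True)
class TwoStateFit:
    """Fitted LEM parameters with both linear baselines.

    ``native_baseline`` and ``denatured_baseline`` are (intercept, slope)
    pairs in the units of the observable per molar denaturant.
    """

    dg_d: float  # kcal mol^-1
    m: float  # kcal mol^-1 M^-1
    native_baseline: tuple[float, float]
    denatured_baseline: tuple[float, float]
    std_errors: dict[str, float]
    temperature: float
    n_points: int
    residual_norm: float

    def __post_init__(self) -> None:
        if self.m <= 0:
            raise ValueError("fitted m-value must be positive for a destabilising denaturant")

    @property
    def cm(self) -> float:
        """Denaturation midpoint Cm = dG_D / m, molar."""
        return cm_from_params(self.dg_d, self.m)

    def fraction_denatured(self, g) -> np.ndarray:
        """Model denatured fraction at denaturant concentration(s) g."""
        rt = R_KCAL * self.temperature
        ex = np.exp(np.clip(-(self.dg_d - self.m * np.asarray(g, dtype=float)) / rt, -500, 500))
        return ex / (1.0 + ex)

    def predict(self, g) -> np.ndarray:
        g = np.asarray(g, dtype=float)
        fd = self.fraction_denatured(g)
        yn = self.native_baseline[0] + self.native_baseline[1] * g
        yd = self.denatured_baseline[0] + self.denatured_baseline[1] * g
        return yn * (1.0 - fd) + yd * fd


def mre_from_ellipticity(theta: float, mrw: float, conc: float, path_length: float) -> float:
    """Mean residue ellipticity [θ] = θ * M0 / (10 * c * l), deg cm^2 dmol^-1.

    ``theta`` in mdeg, ``mrw`` the mean residue weight (g mol^-1), ``conc``
    in mg cm^-3, ``path_length`` in cm.
    """
    if mrw <= 0 or conc <= 0 or path_length <= 0:
        raise ValueError("mean residue weight, concentration, and path length must be positive")
    return theta * mrw / (10.0 * conc * path_length)


def helix_percent(mre222: float) -> float:
    """Alpha-helix content (%) from the 222 nm MRE by the Chen relation.

    helix% = 100 * (-[θ]222 - 2340) / 30300, clamped to [0, 100] with a
    warning when the raw value falls outside the calibrated range.
    """
    pct = 100.0 * (-mre222 - CHEN_OFFSET) / CHEN_SCALE
    if pct < 0.0 or pct > 100.0:
        warnings.warn(
            f"helix content {pct:.1f}% outside [0, 100]; clamping "
            "(MRE222 outside the Chen calibration range)",
            stacklevel=2,
        )
        pct = float(np.clip(pct, 0.0, 100.0))
    return pct


def fraction_denatured(y, y_native: float, y_denatured: float):
    """Normalise an observable to the denatured fraction f_D = (y-yN)/(yD-yN)."""
    if y_native == y_denatured:
        raise ValueError("native and denatured baselines must differ")
    out = (np.asarray(y, dtype=float) - y_native) / (y_denatured - y_native)
    return float(out) if out.ndim == 0 else out


def _lem_model(g, a_n, b_n, a_d, b_d, dg_d, m, rt):
    ex = np.exp(np.clip(-(dg_d - m * g) / rt, -500, 500))
    return (a_n + b_n * g + (a_d + b_d * g) * ex) / (1.0 + ex)


def two_state_fit(curve: DenaturationCurve, temperature: float) -> TwoStateFit:
    """Nonlinear least-squares fit of the six-parameter two-state LEM model.

    y(g) = [yN(g) + yD(g) exp(-(dG_D - m g)/RT)] / [1 + exp(-(dG_D - m g)/RT)]

    with linear baselines yN(g) and yD(g). Initial baselines come from OLS on
    the first and last three points, the midpoint from where the roughly
    normalised curve crosses 0.5, and m starts at 2 kcal mol^-1 M^-1.
    Requires at least two points on each plateau (initial denatured fraction
    below 0.2 / above 0.8).
    """
    if len(curve) < 8:
        raise ValueError("two-state fit needs at least 8 points spanning both plateaus")
    if temperature <= 0:
        raise ValueError("temperature must be positive (Kelvin)")
    g, y = curve.denaturant, curve.y
    rt = R_KCAL * temperature

    b_n0, a_n0 = np.polyfit(g[:3], y[:3], 1)
    b_d0, a_d0 = np.polyfit(g[-3:], y[-3:], 1)
    yn0 = a_n0 + b_n0 * g
    yd0 = a_d0 + b_d0 * g
    span = yd0 - yn0
    mid = len(g) // 2
    if abs(span[mid]) < 1e-12 * max(1.0, np.abs(y).max()):
        raise ValueError("insufficient baseline separation: curve does not span both states")
    fd0 = np.clip((y - yn0) / span, -0.5, 1.5)
    # 3-point moving average stabilises the 0.5-crossing under noise
    kernel = np.ones(3) / 3.0
    fd_smooth = np.convolve(fd0, kernel, mode="same")
    fd_smooth[0], fd_smooth[-1] = fd0[0], fd0[-1]
    if (fd_smooth < 0.2).sum() < 2 or (fd_smooth > 0.8).sum() < 2:
        raise ValueError(
            "insufficient baseline coverage: need at least 2 points on each plateau"
        )
    above = np.nonzero(fd_smooth >= 0.5)[0]
    if above.size and above[0] > 0:
        i = above[0]
        f1, f2 = fd_smooth[i - 1], fd_smooth[i]
        cm0 = g[i - 1] + (0.5 - f1) / (f2 - f1) * (g[i] - g[i - 1])
    else:
        cm0 = float(np.median(g))
    m0 = 2.0
    p0 = [a_n0, b_n0, a_d0, b_d0, m0 * cm0, m0]

    popt, pcov = curve_fit(
        lambda gg, a_n, b_n, a_d, b_d, dg_d, m: _lem_model(gg, a_n, b_n, a_d, b_d, dg_d, m, rt),
        g,
        y,
        p0=p0,
        maxfev=20000,
    )
    perr = np.sqrt(np.diag(pcov))
    a_n, b_n, a_d, b_d, dg_d, m = popt
    # the fitted transition itself must be bracketed by the data: at least
    # two points on each fitted plateau, else the curve never left one state
    ex_fit = np.exp(np.clip(-(dg_d - m * g) / rt, -500, 500))
    fd_fit = ex_fit / (1.0 + ex_fit)
    if (fd_fit < 0.2).sum() < 2 or (fd_fit > 0.8).sum() < 2:
        raise ValueError(
            "insufficient baseline coverage: fitted transition is not bracketed "
            "by at least 2 points on each plateau"
        )
    resid = y - _lem_model(g, *popt, rt)
    names = ["a_n", "b_n", "a_d", "b_d", "dg_d", "m"]
    se = {k: float(v) for k, v in zip(names, perr)}
    # delta-method SE for the derived midpoint Cm = dG_D/m
    jac = np.array([1.0 / m, -dg_d / m**2])
    se["cm"] = float(np.sqrt(jac @ pcov[4:, 4:] @ jac))
    return TwoStateFit(
        dg_d=float(dg_d),
        m=float(m),
        native_baseline=(float(a_n), float(b_n)),
        denatured_baseline=(float(a_d), float(b_d)),
        std_errors=se,
        temperature=temperature,
        n_points=len(curve),
        residual_norm=float(np.sqrt(np.sum(resid**2))),
    )


def cm_from_params(dg_d: float, m: float) -> float:
    """Denaturation midpoint Cm = dG_D / m (M)."""
    if m <= 0:
        raise ValueError("m-value must be positive")
    return dg_d / m
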