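"""Shared data types, CSV I/O, inner-filter correction, and spectral metrics.

The containers here (:class:`Spectrum`, :class:`Titration`) are the common
currency of every analysis stage: fluorescence-quenching titrations, FRET
spectra, CD traces, and denaturation curves all arrive as simple tabular CSV
and are validated into these types on read.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "Titration",
    "PeakMetrics",
    "read_titration_table",
    "write_titration_table",
    "read_spectrum_table",
    "write_spectrum_table",
    "inner_filter_correct",
    "percent_quench",
    "stokes_shift",
    "peak_locate",
]

SpectrumKind = Literal["emission", "extinction", "cd_mdeg"]

#: Default CSV column names; override via the ``columns`` mapping of the readers.
DEFAULT_COLUMNS: Mapping[str, str] = {
    "conc": "conc_uM",
    "intensity": "intensity",
    "A_ex": "A_ex",
    "A_em": "A_em",
    "wavelength": "wavelength_nm",
    "value": "value",
}

#: Multiplicative factors taking a declared concentration unit to molar.
_CONC_FACTORS = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "nM": 1e-9}


@dataclass(frozen=True)
class Spectrum:
    """A wavelength-resolved trace on a strictly increasing nm grid.

    ``kind`` declares the physical meaning of ``values``:

    - ``"emission"``: fluorescence intensity, arbitrary units;
    - ``"extinction"``: molar extinction coefficient, M^-1 cm^-1 (non-negative);
    - ``"cd_mdeg"``: raw circular-dichroism ellipticity, mdeg.
    """

    wavelength: np.ndarray
    values: np.ndarray
    kind: SpectrumKind = "emission"

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or wl.size == 0:
            raise ValueError("wavelength grid must be a non-empty 1-D array")
        if wl.size != vals.size:
            raise ValueError("wavelength and values must have equal length")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if self.kind == "extinction" and np.any(vals < 0):
            raise ValueError("extinction values must be non-negative")
        object.__setattr__(self, "wavelength", wl)
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.wavelength.size


@dataclass(frozen=True)
class Titration:
    """A fluorescence-quenching titration at a single temperature.

    ``quencher_conc`` is molar, strictly increasing, and starts at zero so
    that ``intensity[0]`` is the unquenched intensity F0. Optional per-point
    absorbances at the excitation and emission wavelengths enable the
    inner-filter correction.
    """

    quencher_conc: np.ndarray
    intensity: np.ndarray
    temperature: float
    absorbance_ex: np.ndarray | None = None
    absorbance_em: np.ndarray | None = None

    def __post_init__(self) -> None:
        q = np.asarray(self.quencher_conc, dtype=float)
        f = np.asarray(self.intensity, dtype=float)
        if q.ndim != 1 or q.size != f.size:
            raise ValueError("quencher_conc and intensity must be equal-length 1-D arrays")
        if q[0] != 0.0:
            raise ValueError("first titration point must have [Q] = 0 (defines F0)")
        if np.any(q < 0) or np.any(np.diff(q) <= 0):
            raise ValueError("quencher concentrations must be non-negative and strictly increasing")
        if np.any(f <= 0):
            raise ValueError("fluorescence intensities must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (Kelvin)")
        object.__setattr__(self, "quencher_conc", q)
        object.__setattr__(self, "intensity", f)
        for name in ("absorbance_ex", "absorbance_em"):
            a = getattr(self, name)
            if a is not None:
                a = np.asarray(a, dtype=float)
                if a.size != q.size:
                    raise ValueError(f"{name} must match the number of titration points")
                if np.any(a < 0):
                    raise ValueError("absorbances must be non-negative")
                object.__setattr__(self, name, a)

    @property
    def f0(self) -> float:
        """Unquenched fluorescence intensity."""
        return float(self.intensity[0])

    def __len__(self) -> int:
        return self.quencher_conc.size

    def corrected(self) -> "Titration":
        """Return an inner-filter-corrected copy.

        Requires both absorbance columns; if absent the titration is returned
        unchanged (the correction is optional because raw absorbances are not
        always recorded).
        """
        if self.absorbance_ex is None or self.absorbance_em is None:
            return self
        f_corr = inner_filter_correct(self.intensity, self.absorbance_ex, self.absorbance_em)
        return dataclasses.replace(self, intensity=f_corr)


@dataclass(frozen=True)
class PeakMetrics:
    """Summary metrics of one emission peak relative to a reference spectrum."""

    peak_wavelength: float
    peak_intensity: float
    percent_quench: float
    stokes_shift: float
    shift: float  # signed nm shift of the peak; negative = blue shift

    def __post_init__(self) -> None:
        if self.percent_quench > 100.0:
            raise ValueError("percent quench cannot exceed 100%")


# ---------------------------------------------------------------------------
# CSV I/O


def _read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", skip_blank_lines=True)


def read_titration_table(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
    conc_unit: str = "uM",
    temperature: float = 298.0,
) -> Titration:
    """Read a quenching titration from CSV.

    The file must contain a header row; the concentration and intensity
    columns are resolved through ``columns`` (defaults ``conc_uM`` /
    ``intensity``). Concentrations are converted to molar according to
    ``conc_unit``. Optional absorbance columns are picked up when present.
    """
    cols = {**DEFAULT_COLUMNS, **(columns or {})}
    if conc_unit not in _CONC_FACTORS:
        raise ValueError(f"unknown concentration unit {conc_unit!r}; use one of {sorted(_CONC_FACTORS)}")
    df = _read_csv(path)
    for key in ("conc", "intensity"):
        if cols[key] not in df.columns:
            raise ValueError(f"column {cols[key]!r} not found in {path}")
    conc = df[cols["conc"]].to_numpy(dtype=float) * _CONC_FACTORS[conc_unit]
    intensity = df[cols["intensity"]].to_numpy(dtype=float)
    kwargs = {}
    for key, attr in (("A_ex", "absorbance_ex"), ("A_em", "absorbance_em")):
        if cols[key] in df.columns:
            kwargs[attr] = df[cols[key]].to_numpy(dtype=float)
    return Titration(conc, intensity, temperature, **kwargs)


def write_titration_table(
    titration: Titration,
    path: str | Path,
    columns: Mapping[str, str] | None = None,
    conc_unit: str = "uM",
) -> None:
    """Write a titration in the same CSV dialect :func:`read_titration_table` reads."""
    cols = {**DEFAULT_COLUMNS, **(columns or {})}
    data = {
        cols["conc"]: titration.quencher_conc / _CONC_FACTORS[conc_unit],
        cols["intensity"]: titration.intensity,
    }
    if titration.absorbance_ex is not None:
        data[cols["A_ex"]] = titration.absorbance_ex
    if titration.absorbance_em is not None:
        data[cols["A_em"]] = titration.absorbance_em
    pd.DataFrame(data).to_csv(path, index=False)


def read_spectrum_table(
    path: str | Path,
    kind: SpectrumKind = "emission",
    columns: Mapping[str, str] | None = None,
) -> Spectrum:
    """Read a wavelength/value spectrum from CSV (defaults ``wavelength_nm`` / ``value``)."""
    cols = {**DEFAULT_COLUMNS, **(columns or {})}
    df = _read_csv(path)
    for key in ("wavelength", "value"):
        if cols[key] not in df.columns:
            raise ValueError(f"column {cols[key]!r} not found in {path}")
    return Spectrum(
        df[cols["wavelength"]].to_numpy(dtype=float),
        df[cols["value"]].to_numpy(dtype=float),
        kind=kind,
    )


def write_spectrum_table(
    spectrum: Spectrum,
    path: str | Path,
    columns: Mapping[str, str] | None = None,
) -> None:
    cols = {**DEFAULT_COLUMNS, **(columns or {})}
    pd.DataFrame(
        {cols["wavelength"]: spectrum.wavelength, cols["value"]: spectrum.values}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Point operations


def inner_filter_correct(f_obs, a_ex, a_em):
    """Correct observed fluorescence for the inner-filter effect.

    F_corr = F_obs * 10^((A_ex + A_em) / 2), the standard multiplicative
    correction for attenuation of the excitation and emission beams by the
    sample's own absorbance. Accepts scalars or arrays.
    """
    a_ex = np.asarray(a_ex, dtype=float)
    a_em = np.asarray(a_em, dtype=float)
    if np.any(a_ex < 0) or np.any(a_em < 0):
        raise ValueError("absorbances must be non-negative")
    out = np.asarray(f_obs, dtype=float) * 10.0 ** ((a_ex + a_em) / 2.0)
    return float(out) if out.ndim == 0 else out


def percent_quench(f0: float, f: float) -> float:
    """Percent reduction of fluorescence relative to the unquenched intensity."""
    if f0 <= 0:
        raise ValueError("F0 must be positive")
    return 100.0 * (f0 - f) / f0


def stokes_shift(excitation: float, emission_peak: float) -> float:
    """Stokes shift in nm: emission-peak wavelength minus excitation wavelength."""
    if excitation <= 0 or emission_peak <= 0:
        raise ValueError("wavelengths must be positive")
    return emission_peak - excitation


def peak_locate(spectrum: Spectrum) -> tuple[float, float]:
    """Wavelength and value of the global maximum on the raw grid.

    Ties are broken toward the lowest wavelength; no sub-grid interpolation
    is attempted.
    """
    idx = int(np.argmax(spectrum.values))
    return float(spectrum.wavelength[idx]), float(spectrum.values[idx])
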