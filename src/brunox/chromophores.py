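"""Chromophore absorption data and tissue optical-property spectra.

Tissue absorption in the near-infrared window is modelled as a linear
combination of oxyhaemoglobin (HbO2), deoxyhaemoglobin (HHb) and water:

    mu_a(lambda) = c_HbO2 * alpha_HbO2(lambda)
                 + c_HHb  * alpha_HHb(lambda)
                 + WF     * mu_a,H2O(lambda)

with concentrations in uM, the water fraction WF dimensionless in [0, 1],
and all coefficients in natural-log mm^-1 convention.  Reduced scattering
follows either the power law mu_s'(lambda) = a * (lambda/1000)^-b or, for
slope-based spectroscopy, the linear approximation
mu_s'(lambda) = k * (1 - h*lambda).

The packaged table (``data/hb_water_extinction_synthetic.tsv``) is a smooth
1-nm synthetic reconstruction of the standard published haemoglobin
extinction and pure-water absorption compilations; see
``scripts/make_chromophore_table.py`` for its provenance and conversion.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ChromophoreTable",
    "TissueParams",
    "load_default_table",
    "load_table",
    "resample",
    "mu_a",
    "mu_s_powerlaw",
    "mu_s_linear",
]

_COLUMNS = ("wavelength_nm", "alpha_hbo2", "alpha_hhb", "mua_water")


@dataclass(frozen=True)
class ChromophoreTable:
    """Wavelength-indexed specific absorption spectra.

    Attributes
    ----------
    wavelength : ndarray
        Strictly ascending grid, nm.
    alpha_hbo2, alpha_hhb : ndarray
        Specific absorption of HbO2 / HHb, mm^-1 per uM (natural log).
    mua_water : ndarray
        Absorption coefficient of pure water, mm^-1 (natural log).
    """

    wavelength: np.ndarray
    alpha_hbo2: np.ndarray
    alpha_hhb: np.ndarray
    mua_water: np.ndarray

    def __post_init__(self) -> None:
        for name in ("wavelength", "alpha_hbo2", "alpha_hhb", "mua_water"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        wl = self.wavelength
        if wl.ndim != 1 or wl.size < 1:
            raise ValueError("wavelength grid must be a non-empty 1-d array")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly ascending")
        for name in ("alpha_hbo2", "alpha_hhb", "mua_water"):
            vals = getattr(self, name)
            if vals.shape != wl.shape:
                raise ValueError(f"{name} shape {vals.shape} != grid shape {wl.shape}")
            if not np.all(np.isfinite(vals)) or np.any(vals < 0):
                raise ValueError(f"{name} must be finite and non-negative")

    @property
    def span(self) -> tuple[float, float]:
        return float(self.wavelength[0]), float(self.wavelength[-1])


@dataclass(frozen=True)
class TissueParams:
    """Homogeneous tissue parameter vector.

    c_hbo2, c_hhb : uM; wf : water fraction in [0, 1];
    a : scattering amplitude, mm^-1; b : scattering power, dimensionless.
    """

    c_hbo2: float
    c_hhb: float
    wf: float
    a: float
    b: float

    def __post_init__(self) -> None:
        if self.c_hbo2 < 0 or self.c_hhb < 0:
            raise ValueError("haemoglobin concentrations must be >= 0")
        if not 0.0 <= self.wf <= 1.0:
            raise ValueError("water fraction must lie in [0, 1]")
        if self.a < 0:
            raise ValueError("scattering amplitude must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.wf, self.c_hbo2, self.c_hhb, self.a, self.b])


def load_table(path: str | Path) -> ChromophoreTable:
    """Read a chromophore table from delimited text.

    Expects tab- (or whitespace-) separated columns ``wavelength_nm``,
    ``alpha_hbo2``, ``alpha_hhb``, ``mua_water`` with a header row.
    """
    df = pd.read_csv(path, sep=r"\s+|\t", engine="python")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"chromophore table {path} missing columns: {missing}")
    return ChromophoreTable(
        wavelength=df["wavelength_nm"].to_numpy(),
        alpha_hbo2=df["alpha_hbo2"].to_numpy(),
        alpha_hhb=df["alpha_hhb"].to_numpy(),
        mua_water=df["mua_water"].to_numpy(),
    )


def load_default_table() -> ChromophoreTable:
    """Load the table packaged with brunox (650-1000 nm, 1 nm spacing)."""
    ref = resources.files("brunox").joinpath("data/hb_water_extinction_synthetic.tsv")
    with resources.as_file(ref) as path:
        return load_table(path)


def resample(table: ChromophoreTable, grid: np.ndarray) -> ChromophoreTable:
    """Linearly interpolate a chromophore table onto a new wavelength grid.

    Raises if any grid point falls outside the table's span (no
    extrapolation), naming the offending wavelength.
    """
    grid = np.asarray(grid, dtype=float)
    lo, hi = table.span
    out_of_range = grid[(grid < lo) | (grid > hi)]
    if out_of_range.size:
        raise ValueError(
            f"cannot resample: wavelength {out_of_range[0]:g} nm outside "
            f"table span [{lo:g}, {hi:g}] nm"
        )
    wl = table.wavelength
    return ChromophoreTable(
        wavelength=grid,
        alpha_hbo2=np.interp(grid, wl, table.alpha_hbo2),
        alpha_hhb=np.interp(grid, wl, table.alpha_hhb),
        mua_water=np.interp(grid, wl, table.mua_water),
    )


def mu_a(params: TissueParams, table: ChromophoreTable,
         grid: np.ndarray | None = None) -> np.ndarray:
    """Absorption spectrum mu_a(lambda) in mm^-1 from a parameter vector."""
    if grid is not None:
        table = resample(table, grid)
    return (params.c_hbo2 * table.alpha_hbo2
            + params.c_hhb * table.alpha_hhb
            + params.wf * table.mua_water)


def mu_s_powerlaw(a: float, b: float, grid: np.ndarray) -> np.ndarray:
    """Power-law reduced scattering mu_s'(lambda) = a * (lambda/1000)^-b."""
    if a < 0:
        raise ValueError("scattering amplitude a must be >= 0")
    grid = np.asarray(grid, dtype=float)
    return a * (grid / 1000.0) ** (-b)


def mu_s_linear(k: float, h: float, grid: np.ndarray) -> np.ndarray:
    """Linear reduced-scattering approximation mu_s'(lambda) = k*(1 - h*lambda).

    h is the assumed normalised spectral gradient of mu_s' (mm^-1 nm^-1).
    Raises where h*lambda >= 1 (non-positive scattering is unphysical).
    """
    grid = np.asarray(grid, dtype=float)
    if np.any(h * grid >= 1.0):
        bad = grid[h * grid >= 1.0][0]
        raise ValueError(f"h*lambda >= 1 at {bad:g} nm: non-physical scattering")
    return k * (1.0 - h * grid)
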