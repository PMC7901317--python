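"""File formats and run configuration.

Spectra files are tab-separated text: column 1 ``wavelength_nm``
(ascending), then one attenuation column per separation named ``A_<d>mm``
(optical density) and optionally matching intensity columns ``I_<d>mm``.
A JSON sidecar (same path + ``.json``) records geometry and provenance
metadata.  All writes are atomic (temp file + rename).

Run configuration is YAML with a bounds block following the conventional
start/LB/UB layout (WF in percent); defaults reproduce the simulation
(NIRFAST-context) bound set.
"""

from __future__ import annotations

import json
import os
import re
import tempfile
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .algorithms import FitBounds, PARAM_NAMES, standard_bounds
from .forward import MultidistanceSpectra, ProbeGeometry

__all__ = ["read_spectra", "write_spectra", "RunConfig", "load_config"]

_DIST_COL = re.compile(r"^([AI])_([0-9.]+)mm$")


def _atomic_write(path: Path, text: str) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_spectra(meas: MultidistanceSpectra, path: str | Path) -> None:
    """Write a multidistance record as TSV plus a JSON sidecar."""
    path = Path(path)
    dists = meas.geometry.distances
    cols = {"wavelength_nm": meas.wavelength}
    for i, d in enumerate(dists):
        cols[f"A_{d:g}mm"] = meas.attenuation[i]
    if meas.intensity is not None:
        for i, d in enumerate(dists):
            cols[f"I_{d:g}mm"] = meas.intensity[i]
    df = pd.DataFrame(cols)
    _atomic_write(path, df.to_csv(sep="\t", index=False, float_format="%.8g"))
    sidecar = {"distances_mm": list(dists),
               "meta": {k: v for k, v in meas.meta.items()
                        if isinstance(v, (str, int, float, bool, type(None)))}}
    _atomic_write(Path(str(path) + ".json"), json.dumps(sidecar, indent=1))


def read_spectra(path: str | Path) -> MultidistanceSpectra:
    """Read a spectra file back into a validated record.

    Raises descriptive errors on non-ascending wavelength grids, missing
    attenuation columns, NaN cells, or a sidecar/column geometry mismatch.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if "wavelength_nm" not in df.columns:
        raise ValueError(f"{path}: missing wavelength_nm column")
    wl = df["wavelength_nm"].to_numpy(dtype=float)
    if np.any(np.diff(wl) <= 0):
        i = int(np.argmax(np.diff(wl) <= 0))
        raise ValueError(
            f"{path}: wavelengths not strictly ascending at row {i + 1} "
            f"({wl[i]:g} -> {wl[i + 1]:g} nm)")

    a_cols, i_cols = {}, {}
    for col in df.columns:
        m = _DIST_COL.match(col)
        if m:
            (a_cols if m.group(1) == "A" else i_cols)[float(m.group(2))] = col
    if len(a_cols) < 2:
        raise ValueError(f"{path}: need >= 2 attenuation columns A_<d>mm, "
                         f"found {sorted(a_cols)}")
    if df[list(a_cols.values())].isna().any().any():
        raise ValueError(f"{path}: NaN cells in attenuation columns")

    dists = sorted(a_cols)
    meta = {}
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        side = json.loads(sidecar.read_text())
        side_d = [float(d) for d in side.get("distances_mm", [])]
        if side_d and sorted(side_d) != dists:
            raise ValueError(
                f"{path}: sidecar distances {side_d} disagree with "
                f"columns {dists}")
        meta = side.get("meta", {})

    attenuation = np.stack([df[a_cols[d]].to_numpy(dtype=float) for d in dists])
    intensity = None
    if set(i_cols) == set(a_cols):
        intensity = np.stack([df[i_cols[d]].to_numpy(dtype=float) for d in dists])
    return MultidistanceSpectra(
        wavelength=wl, attenuation=attenuation, intensity=intensity,
        geometry=ProbeGeometry(tuple(dists)), meta=meta)


@dataclass
class RunConfig:
    """Validated analysis configuration (YAML-serialisable)."""

    algorithm: str = "bruno"
    fit_range: tuple[float, float] | None = None
    bounds_context: str = "simulation"
    water: bool = True
    bounds: FitBounds | None = None
    smoothing_window: int = 5
    noise_fraction: float = 0.01
    seed: int = 0
    quality_threshold: float = 2.0
    srs_h: float = 0.00063

    def __post_init__(self) -> None:
        if self.algorithm not in ("bruno", "bf", "srs"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.bounds is None:
            self.bounds = standard_bounds(self.bounds_context, self.water)
        if self.smoothing_window < 1:
            raise ValueError("smoothing window must be >= 1")
        if self.noise_fraction < 0:
            raise ValueError("noise_fraction must be >= 0")


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration.

    The optional ``bounds`` block maps parameter name (wf in percent,
    c_hbo2, c_hhb, a, b) to ``{start, lb, ub}``; unspecified parameters
    keep the context defaults.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    bounds_block = raw.pop("bounds", None)
    fit_range = raw.pop("fit_range", None)
    cfg = RunConfig(**raw)
    if fit_range is not None:
        cfg.fit_range = (float(fit_range[0]), float(fit_range[1]))
    if bounds_block:
        base = cfg.bounds
        start, lower, upper = (list(base.start), list(base.lower),
                               list(base.upper))
        for name, row in bounds_block.items():
            if name not in PARAM_NAMES:
                raise ValueError(f"unknown bounds parameter {name!r}; "
                                 f"expected one of {PARAM_NAMES}")
            i = PARAM_NAMES.index(name)
            start[i] = float(row.get("start", start[i]))
            lower[i] = float(row.get("lb", lower[i]))
            upper[i] = float(row.get("ub", upper[i]))
        cfg.bounds = FitBounds(tuple(start), tuple(lower), tuple(upper))
    return cfg
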