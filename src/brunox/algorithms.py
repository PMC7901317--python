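"""StO2 recovery algorithms: SRS, broadband fitting (BF) and BRUNO.

All three invert continuous-wave broadband NIRS measurements of a
semi-infinite homogeneous medium:

* SRS (spatially resolved spectroscopy) converts the multidistance
  attenuation slope into a scaled absorption spectrum k*mu_a(lambda)
  under a linear scattering approximation mu_s' = k (1 - h lambda), then
  solves a linear two-chromophore system for scaled concentrations.  The
  unknown scattering amplitude k cancels in the saturation ratio.
* BF (broadband fitting) fits the extrapolated-boundary diffusion
  reflectance model at a single separation to the measured spectrum in
  first- and second-wavelength-derivative space (710-850 nm), searching
  over (WF, c_HbO2, c_HHb, a, b) with a bounded simplex.
* BRUNO (broadband multidistance oximetry) fits the ZBC attenuation-slope
  model to the measured slope in first-derivative space (710-900 nm) over
  the same parameter vector, combining the multidistance geometry of SRS
  with the full spectral model of BF.

The bounded simplex optimizer reproduces the sinusoidal variable
transformation of the classic bounded Nelder-Mead routine: each bounded
parameter is mapped through x = lb + (sin(y)+1)/2 (ub-lb) and the search
runs unconstrained in y.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.optimize import minimize

from .chromophores import (ChromophoreTable, TissueParams, mu_a,
                           mu_s_powerlaw, resample)
from .forward import MultidistanceSpectra, ebc_reflectance, zbc_slope_model
from .quality import QualityReport, quality_score

__all__ = [
    "SlopeSpectrum",
    "FitBounds",
    "FitResult",
    "PARAM_NAMES",
    "standard_bounds",
    "attenuation_slope",
    "sto2",
    "srs_fit",
    "bf_fit",
    "bruno_fit",
    "bounded_minimize",
    "DEFAULT_H",
]

#: assumed normalised spectral gradient of mu_s' in SRS, mm^-1 nm^-1
DEFAULT_H = 0.00063

#: parameter order used throughout the fitters
PARAM_NAMES = ("wf", "c_hbo2", "c_hhb", "a", "b")

BRUNO_FIT_RANGE = (710.0, 900.0)
BF_FIT_RANGE = (710.0, 850.0)
SMOOTH_WINDOW = 5


@dataclass
class SlopeSpectrum:
    """Per-wavelength attenuation-vs-distance gradient with its geometry."""

    wavelength: np.ndarray
    slope: np.ndarray          # OD/mm
    d_s: float
    d_l: float
    n_distances: int

    def __post_init__(self) -> None:
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.slope = np.asarray(self.slope, dtype=float)
        if self.slope.shape != self.wavelength.shape:
            raise ValueError("slope and wavelength shapes differ")
        if not np.all(np.isfinite(self.slope)):
            raise ValueError("slope must be finite")
        if self.d_l <= self.d_s:
            raise ValueError("d_l must exceed d_s")


@dataclass(frozen=True)
class FitBounds:
    """Start / lower / upper per parameter, in the conventional units of
    the fit-configuration tables: WF in percent, concentrations in uM,
    a in mm^-1, b dimensionless.  Rows ordered (WF, c_HbO2, c_HHb, a, b).
    A parameter with lower == upper is held fixed at that value.
    """

    start: tuple[float, ...]
    lower: tuple[float, ...]
    upper: tuple[float, ...]

    def __post_init__(self) -> None:
        for name in ("start", "lower", "upper"):
            object.__setattr__(self, name,
                               tuple(float(v) for v in getattr(self, name)))
        if not len(self.start) == len(self.lower) == len(self.upper) == 5:
            raise ValueError("bounds need 5 entries: WF, c_HbO2, c_HHb, a, b")
        for s, lo, up in zip(self.start, self.lower, self.upper):
            if not lo <= s <= up:
                raise ValueError(f"start {s} outside [{lo}, {up}]")


# Standard bound sets for the three measurement contexts (WF in percent).
_STANDARD_BOUNDS = {
    "simulation": FitBounds(start=(70, 50, 50, 1.0, 1.0),
                            lower=(60, 0, 0, 0.3, 0.5),
                            upper=(95, 100, 100, 2.0, 3.0)),
    "phantom": FitBounds(start=(100, 20, 20, 1.0, 3.0),
                         lower=(97, 0, 0, 0.0, 0.0),
                         upper=(100, 40, 40, 2.0, 4.0)),
    "neonate": FitBounds(start=(80, 100, 40, 0.5, 0.5),
                         lower=(50, 0, 0, 0.1, 0.1),
                         upper=(95, 160, 70, 2.0, 3.0)),
}


def standard_bounds(context: str = "simulation", water: bool = True) -> FitBounds:
    """Published bound sets for simulation, phantom and neonatal fits.

    With ``water=False`` the water fraction is pinned to 0 (used for
    simulated media that contain no water absorber).
    """
    base = _STANDARD_BOUNDS[context]
    if water:
        return base
    return FitBounds(start=(0.0,) + base.start[1:],
                     lower=(0.0,) + base.lower[1:],
                     upper=(0.0,) + base.upper[1:])


@dataclass
class FitResult:
    """Outcome of an StO2 inversion."""

    sto2: float                      # percent; NaN when undefined
    params: TissueParams | None      # BRUNO / BF recovered parameters
    scaled: dict | None              # SRS scaled concentrations (k c_X)
    objective: float
    converged: bool
    iterations: int
    flags: list[str] = field(default_factory=list)
    quality: QualityReport | None = None

    @property
    def sto2_defined(self) -> bool:
        return np.isfinite(self.sto2)


def sto2(c_hbo2: float, c_hhb: float) -> float:
    """Tissue oxygen saturation, percent: 100 * c_HbO2 / (c_HbO2 + c_HHb).

    Invariant to common scaling of both concentrations.  Returns NaN when
    both are zero (saturation undefined).
    """
    if c_hbo2 < 0 or c_hhb < 0:
        raise ValueError("concentrations must be >= 0")
    total = c_hbo2 + c_hhb
    if total == 0:
        return float("nan")
    return 100.0 * c_hbo2 / total


def attenuation_slope(meas: MultidistanceSpectra) -> SlopeSpectrum:
    """Per-wavelength ordinary-least-squares gradient of attenuation
    against source-detector distance across all detectors."""
    dists = meas.geometry.as_array()
    if dists.size < 2:
        raise ValueError("need at least 2 distances for a slope")
    slope = np.polyfit(dists, meas.attenuation, 1)[0]
    return SlopeSpectrum(wavelength=meas.wavelength, slope=slope,
                         d_s=meas.geometry.d_s, d_l=meas.geometry.d_l,
                         n_distances=dists.size)


# --- bounded simplex --------------------------------------------------------

def bounded_minimize(objective, start, lower, upper,
                     xatol: float = 1e-6, fatol: float = 1e-6,
                     max_iter_per_param: int = 2000,
                     restart: bool = True):
    """Derivative-free bounded minimization (Nelder-Mead with sinusoidal
    variable transformation).

    Parameters with lower == upper are held fixed.  Deterministic given
    the start point.  If the simplex fails to converge within the
    iteration cap, restarts once from the best point found.

    Returns ``(x, fval, converged, iterations)``.
    """
    start = np.asarray(start, dtype=float)
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    if np.any(start < lower) or np.any(start > upper):
        raise ValueError("start point outside bounds")
    free = upper > lower
    x_fixed = start.copy()

    if not np.any(free):
        val = float(objective(x_fixed))
        return x_fixed, val, True, 0

    lo, up = lower[free], upper[free]

    def to_x(y: np.ndarray) -> np.ndarray:
        x = x_fixed.copy()
        x[free] = lo + (np.sin(y) + 1.0) * 0.5 * (up - lo)
        return x

    def to_y(xf: np.ndarray) -> np.ndarray:
        frac = np.clip(2.0 * (xf - lo) / (up - lo) - 1.0, -1.0, 1.0)
        return np.arcsin(frac)

    def wrapped(y: np.ndarray) -> float:
        return float(objective(to_x(y)))

    n = int(np.count_nonzero(free))
    cap = max_iter_per_param * n
    y0 = to_y(start[free])
    total_iter = 0
    res = minimize(wrapped, y0, method="Nelder-Mead",
                   options={"xatol": xatol, "fatol": fatol,
                            "maxiter": cap, "maxfev": cap})
    total_iter += res.nit
    if not res.success and restart:
        res2 = minimize(wrapped, res.x, method="Nelder-Mead",
                        options={"xatol": xatol, "fatol": fatol,
                                 "maxiter": cap, "maxfev": cap})
        total_iter += res2.nit
        if res2.fun <= res.fun:
            res = res2
    return to_x(res.x), float(res.fun), bool(res.success), int(total_iter)


# --- shared spectral pipeline ----------------------------------------------

def _smooth(y: np.ndarray, window: int = SMOOTH_WINDOW) -> np.ndarray:
    """Centered moving average; endpoints use shrinking (nearest) windows."""
    return uniform_filter1d(y, size=window, mode="nearest")


def _window_mask(wl: np.ndarray, lo: float, hi: float,
                 smooth_window: int = SMOOTH_WINDOW) -> np.ndarray:
    """Fit-range mask excluding the edge points whose smoothed derivative
    relies on one-sided differences."""
    edge = smooth_window // 2 + 1
    mask = (wl >= lo) & (wl <= hi)
    mask[:edge] = False
    mask[-edge:] = False
    if not np.any(mask):
        raise ValueError(f"no interior grid points inside [{lo}, {hi}] nm")
    return mask


def _first_deriv(y: np.ndarray, wl: np.ndarray,
                 window: int = SMOOTH_WINDOW) -> np.ndarray:
    return np.gradient(_smooth(y, window), wl)


# --- SRS --------------------------------------------------------------------

def srs_fit(slope: SlopeSpectrum, table: ChromophoreTable,
            h: float = DEFAULT_H,
            wavelengths: np.ndarray | None = None,
            include_water: bool = False) -> FitResult:
    """Spatially resolved spectroscopy StO2 from an attenuation slope.

    Inverts the slope model for a scaled absorption spectrum

        k mu_a(lambda) = (ln 10 * dA/drho - G)^2 / (3 (1 - h lambda)),
        G = 2 ln(d_L/d_S) / (d_L - d_S),

    then solves the overdetermined linear system
    [alpha_HHb, alpha_HbO2] [k c_HHb, k c_HbO2]^T = k mu_a over the
    wavelength grid (all of it by default; pass ``wavelengths`` for a
    discrete-wavelength device emulation).  Water absorption is not
    modelled unless ``include_water`` adds the pure-water column, whose
    coefficient is then a scaled water fraction.
    """
    wl = slope.wavelength
    sl = slope.slope
    if wavelengths is not None:
        wavelengths = np.asarray(wavelengths, dtype=float)
        idx = np.searchsorted(wl, wavelengths)
        idx = np.clip(idx, 0, wl.size - 1)
        if not np.allclose(wl[idx], wavelengths):
            raise ValueError("requested SRS wavelengths not on the slope grid")
        wl, sl = wl[idx], sl[idx]
    tab = resample(table, wl)

    geom = 2.0 * np.log(slope.d_l / slope.d_s) / (slope.d_l - slope.d_s)
    bracket = np.log(10.0) * sl - geom
    flags = []
    if np.any(bracket < 0):
        n_bad = int(np.sum(bracket < 0))
        flags.append(f"negative_slope_bracket:{n_bad}")
    k_mua = bracket**2 / (3.0 * (1.0 - h * wl))

    cols = [tab.alpha_hhb, tab.alpha_hbo2]
    if include_water:
        cols.append(tab.mua_water)
    design = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(design, k_mua, rcond=None)
    k_chhb, k_chbo2 = float(coef[0]), float(coef[1])
    scaled = {"k_c_hhb": k_chhb, "k_c_hbo2": k_chbo2}
    if include_water:
        scaled["k_wf"] = float(coef[2])
    if k_chhb < 0 or k_chbo2 < 0:
        flags.append("negative_scaled_concentration")

    total = k_chbo2 + k_chhb
    sat = float("nan") if total == 0 else 100.0 * k_chbo2 / total
    resid = float(np.sum((design @ coef - k_mua) ** 2))
    return FitResult(sto2=sat, params=None, scaled=scaled, objective=resid,
                     converged=True, iterations=0, flags=flags)


# --- parameterized model fits (BF, BRUNO) -----------------------------------

def _unpack(theta: np.ndarray, grid: np.ndarray,
            table: ChromophoreTable) -> tuple[np.ndarray, np.ndarray]:
    """(WF%, c_HbO2, c_HHb, a, b) -> (mu_a, mu_s') spectra on ``grid``."""
    wf_pct, c1, c2, a, b = theta
    params = TissueParams(c_hbo2=max(c1, 0.0), c_hhb=max(c2, 0.0),
                          wf=min(max(wf_pct / 100.0, 0.0), 1.0), a=max(a, 0.0), b=b)
    return mu_a(params, table), mu_s_powerlaw(params.a, params.b, grid)


def _result_from_theta(theta: np.ndarray, fval: float, converged: bool,
                       iterations: int, bounds: FitBounds) -> FitResult:
    wf_pct, c1, c2, a, b = theta
    params = TissueParams(c_hbo2=c1, c_hhb=c2, wf=wf_pct / 100.0, a=a, b=b)
    flags = []
    # concentrations pinned at a bound are reported but marked
    tol = 1e-6
    for i, name in ((1, "c_hbo2"), (2, "c_hhb")):
        lo, up = bounds.lower[i], bounds.upper[i]
        if up > lo and (abs(theta[i] - lo) < tol * (up - lo)
                        or abs(theta[i] - up) < tol * (up - lo)):
            flags.append(f"{name}_at_bound")
    return FitResult(sto2=sto2(c1, c2), params=params, scaled=None,
                     objective=fval, converged=converged,
                     iterations=iterations, flags=flags)


def bruno_fit(slope: SlopeSpectrum, table: ChromophoreTable,
              bounds: FitBounds | None = None,
              fit_range: tuple[float, float] = BRUNO_FIT_RANGE,
              smooth_window: int = SMOOTH_WINDOW,
              with_quality: bool = True,
              quality_threshold: float = 2.0) -> FitResult:
    """Broadband multidistance oximetry: fit the ZBC attenuation-slope
    model to a measured slope spectrum in first-derivative space.

    The measured slope is smoothed (5-point moving average) and
    differentiated with respect to wavelength; the model slope
    (``zbc_slope_model`` with mu_a and mu_s' built from the candidate
    parameter vector) goes through the identical pipeline.  The bounded
    simplex minimizes the sum of squared derivative residuals over the
    fit range (default 710-900 nm, edge points excluded).
    """
    if bounds is None:
        bounds = standard_bounds("simulation")
    wl = slope.wavelength
    lo, hi = fit_range
    if wl[0] > lo or wl[-1] < hi:
        raise ValueError(
            f"slope grid [{wl[0]:g}, {wl[-1]:g}] nm does not cover the "
            f"fit range [{lo:g}, {hi:g}] nm")
    tab = resample(table, wl)
    mask = _window_mask(wl, lo, hi, smooth_window)
    meas_deriv = _first_deriv(slope.slope, wl, smooth_window)

    def objective(theta: np.ndarray) -> float:
        mua, mus = _unpack(theta, wl, tab)
        model = zbc_slope_model(mua, mus, slope.d_s, slope.d_l)
        model_deriv = _first_deriv(model, wl, smooth_window)
        r = (meas_deriv - model_deriv)[mask]
        return float(r @ r)

    theta, fval, converged, n_iter = bounded_minimize(
        objective, bounds.start, bounds.lower, bounds.upper)
    result = _result_from_theta(theta, fval, converged, n_iter, bounds)
    if with_quality:
        mua, mus = _unpack(theta, wl, tab)
        model = zbc_slope_model(mua, mus, slope.d_s, slope.d_l)
        model_deriv = _first_deriv(model, wl, smooth_window)
        result.quality = quality_score(meas_deriv[mask], model_deriv[mask],
                                       wl[mask], threshold=quality_threshold)
    return result


def bf_fit(reflectance: np.ndarray, rho: float, wavelength: np.ndarray,
           table: ChromophoreTable,
           bounds: FitBounds | None = None,
           fit_range: tuple[float, float] = BF_FIT_RANGE,
           smooth_window: int = SMOOTH_WINDOW) -> FitResult:
    """Broadband fitting: single-distance derivative-space fit of the EBC
    reflectance model.

    The measured reflectance (arbitrary units; an unknown multiplicative
    source-coupling factor is profiled out analytically each objective
    evaluation) is smoothed and differentiated twice with respect to
    wavelength; the model reflectance goes through the identical
    pipeline.  The objective sums first- and second-derivative squared
    residuals, each normalised by the variance of the corresponding
    measured derivative over the fit range so both scales contribute.
    """
    if bounds is None:
        bounds = standard_bounds("simulation")
    wavelength = np.asarray(wavelength, dtype=float)
    reflectance = np.asarray(reflectance, dtype=float)
    lo, hi = fit_range
    if wavelength[0] > lo or wavelength[-1] < hi:
        raise ValueError(
            f"reflectance grid [{wavelength[0]:g}, {wavelength[-1]:g}] nm "
            f"does not cover the fit range [{lo:g}, {hi:g}] nm")
    fit_mask = (wavelength >= lo) & (wavelength <= hi)
    if np.any(reflectance[fit_mask] <= 0):
        raise ValueError("reflectance must be strictly positive on the fit range")
    tab = resample(table, wavelength)
    mask = _window_mask(wavelength, lo, hi, smooth_window)

    d1_meas = _first_deriv(reflectance, wavelength, smooth_window)
    d2_meas = np.gradient(d1_meas, wavelength)
    v1 = float(np.var(d1_meas[mask])) or 1.0
    v2 = float(np.var(d2_meas[mask])) or 1.0
    m1, m2 = d1_meas[mask], d2_meas[mask]

    def model_derivs(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mua, mus = _unpack(theta, wavelength, tab)
        model = ebc_reflectance(mua, mus, rho)
        t1 = _first_deriv(model, wavelength, smooth_window)
        t2 = np.gradient(t1, wavelength)
        return t1[mask], t2[mask]

    def objective(theta: np.ndarray) -> float:
        t1, t2 = model_derivs(theta)
        denom = (t1 @ t1) / v1 + (t2 @ t2) / v2
        if denom <= 0:
            return float((m1 @ m1) / v1 + (m2 @ m2) / v2)
        scale = ((m1 @ t1) / v1 + (m2 @ t2) / v2) / denom
        if scale <= 0:
            scale = np.finfo(float).tiny
        r1 = m1 - scale * t1
        r2 = m2 - scale * t2
        return float((r1 @ r1) / v1 + (r2 @ r2) / v2)

    theta, fval, converged, n_iter = bounded_minimize(
        objective, bounds.start, bounds.lower, bounds.upper)
    return _result_from_theta(theta, fval, converged, n_iter, bounds)
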