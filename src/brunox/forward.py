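"""Analytic diffusion forward models for continuous-wave reflectance.

These models generate the synthetic multidistance measurements used to
benchmark the oximetry algorithms:

* ``zbc_reflectance`` / ``zbc_slope_model`` — semi-infinite homogeneous
  medium with zero boundary conditions (ZBC): the fluence vanishes at the
  physical surface.  The slope model is the large-separation asymptote of
  the attenuation gradient,

      dA/drho = (1/ln 10) * ( sqrt(3 mu_a mu_s') + 2 ln(d_L/d_S)/(d_L - d_S) )

  which is the model BRUNO and SRS invert.
* ``ebc_reflectance`` — the same medium with extrapolated boundary
  conditions (EBC): an image source mirrored about the extrapolated
  boundary at z = -z_b, with z_b set by the internal-reflection parameter
  for relative refractive index n (default 1.4).  This is the model
  broadband fitting (BF) inverts.
* ``two_layer_reflectance`` — a two-layer semi-infinite medium solved in
  the spatial-frequency (Hankel) domain with an extrapolated boundary,
  inverted numerically; the surrogate for superficial-layer contamination
  studies.

Conventions: mu_a and mu_s' in natural-log mm^-1; attenuation in base-10
optical density; reflectance is the detected photon current per unit area
(mm^-2) for a unit point source.  The ZBC model uses the scattering-only
diffusion coefficient D = 1/(3 mu_s'), so its attenuation-slope asymptote
carries mu_eff = sqrt(3 mu_a mu_s') exactly; the EBC and two-layer models
use D = 1/(3 (mu_a + mu_s')).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.polynomial.legendre import leggauss

from .chromophores import ChromophoreTable, TissueParams, mu_a, mu_s_powerlaw, resample

__all__ = [
    "ProbeGeometry",
    "MultidistanceSpectra",
    "TwoLayerParams",
    "internal_reflection_parameter",
    "zbc_slope_model",
    "zbc_reflectance",
    "ebc_reflectance",
    "two_layer_reflectance",
    "simulate_multidistance",
    "simulate_phantom_cycles",
    "phantom_trajectory",
]

DIFFUSION_RHO_MIN_MM = 5.0


@dataclass(frozen=True)
class ProbeGeometry:
    """Source-detector separations on the tissue surface, mm, ascending."""

    distances: tuple[float, ...] = (15.0, 20.0, 25.0, 30.0)

    def __post_init__(self) -> None:
        d = tuple(float(x) for x in self.distances)
        object.__setattr__(self, "distances", d)
        if len(d) < 2:
            raise ValueError("need at least 2 source-detector separations")
        if any(x <= 0 for x in d) or any(b <= a for a, b in zip(d, d[1:])):
            raise ValueError("distances must be positive and strictly ascending")

    @property
    def d_s(self) -> float:
        return self.distances[0]

    @property
    def d_l(self) -> float:
        return self.distances[-1]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.distances)


@dataclass
class MultidistanceSpectra:
    """Broadband attenuation (and optionally intensity) per separation."""

    wavelength: np.ndarray
    attenuation: np.ndarray          # (n_distances, n_wavelengths), OD
    geometry: ProbeGeometry
    intensity: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.attenuation = np.asarray(self.attenuation, dtype=float)
        nd = len(self.geometry.distances)
        if self.attenuation.shape != (nd, self.wavelength.size):
            raise ValueError(
                f"attenuation shape {self.attenuation.shape} does not match "
                f"{nd} distances x {self.wavelength.size} wavelengths"
            )
        if not np.all(np.isfinite(self.attenuation)):
            raise ValueError("attenuation must be finite")
        if self.intensity is not None:
            self.intensity = np.asarray(self.intensity, dtype=float)
            if self.intensity.shape != self.attenuation.shape:
                raise ValueError("intensity shape must match attenuation")


@dataclass(frozen=True)
class TwoLayerParams:
    """Two-layer medium: a superficial layer of finite thickness over a
    semi-infinite bottom layer."""

    top: TissueParams
    bottom: TissueParams
    top_thickness: float  # mm

    def __post_init__(self) -> None:
        if self.top_thickness <= 0:
            raise ValueError("top_thickness must be > 0")


def internal_reflection_parameter(n_rel: float = 1.4) -> float:
    """Boundary mismatch parameter A = (1+R_eff)/(1-R_eff).

    R_eff from the standard polynomial fit to the Fresnel-integral
    effective reflection coefficient for relative refractive index n.
    """
    r_eff = -1.440 / n_rel**2 + 0.710 / n_rel + 0.668 + 0.0636 * n_rel
    return (1.0 + r_eff) / (1.0 - r_eff)


def zbc_slope_model(mua, mus, d_s: float, d_l: float):
    """Asymptotic multidistance attenuation slope, OD/mm (ZBC model).

    Vectorized over wavelength.  Depends on absorption and scattering only
    through the product mu_a * mu_s'.
    """
    mua = np.asarray(mua, dtype=float)
    mus = np.asarray(mus, dtype=float)
    if d_l <= d_s or d_s <= 0:
        raise ValueError("require d_l > d_s > 0")
    if np.any(mua < 0) or np.any(mus <= 0):
        raise ValueError("require mu_a >= 0 and mu_s' > 0")
    geom = 2.0 * np.log(d_l / d_s) / (d_l - d_s)
    return (np.sqrt(3.0 * mua * mus) + geom) / np.log(10.0)


def _dipole_flux(mua, mus, rho, z_pos: np.ndarray, mu_eff: np.ndarray,
                 signs: Sequence[float]) -> np.ndarray:
    """Detected current at the surface from image dipoles at depths z_pos."""
    rho = np.asarray(rho, dtype=float)
    out = 0.0
    for z, sgn in zip(z_pos, signs):
        r = np.sqrt(rho**2 + z**2)
        out = out + sgn * z * (mu_eff + 1.0 / r) * np.exp(-mu_eff * r) / r**2
    return out / (4.0 * np.pi)


def _check_rho(rho) -> None:
    if np.any(np.asarray(rho, dtype=float) < DIFFUSION_RHO_MIN_MM):
        warnings.warn(
            f"separation below {DIFFUSION_RHO_MIN_MM} mm: diffusion "
            "approximation may be invalid", stacklevel=3)


def zbc_reflectance(mua, mus, rho):
    """Semi-infinite CW reflectance with zero boundary conditions, mm^-2.

    Far-field form of the ZBC dipole solution (source at depth
    z0 = 1/mu_s', negative image at -z0, D = 1/(3 mu_s')):

        R(rho) = (z0 mu_eff / 2 pi) exp(-mu_eff r) / r^2,
        r = sqrt(rho^2 + z0^2),  mu_eff = sqrt(3 mu_a mu_s').

    Its attenuation gradient over the 15-30 mm window is the slope model
    ``zbc_slope_model`` up to small geometric curvature, which makes this
    the natural generator for slope-based inversions.  Requires mu_a > 0
    (the far-field form degenerates for a non-absorbing medium).
    """
    mua = np.asarray(mua, dtype=float)
    mus = np.asarray(mus, dtype=float)
    if np.any(mus <= 0):
        raise ValueError("mu_s' must be > 0")
    if np.any(mua <= 0):
        raise ValueError("mu_a must be > 0 for the far-field ZBC form")
    _check_rho(rho)
    rho = np.asarray(rho, dtype=float)
    z0 = 1.0 / mus
    mu_eff = np.sqrt(3.0 * mua * mus)
    r = np.sqrt(rho**2 + z0**2)
    return z0 * mu_eff * np.exp(-mu_eff * r) / (2.0 * np.pi * r**2)


def ebc_reflectance(mua, mus, rho, n_rel: float = 1.4):
    """Semi-infinite CW reflectance with extrapolated boundary conditions.

    Image-source pair about the extrapolated boundary z = -z_b,
    z_b = 2 A D with A the internal-reflection parameter for relative
    refractive index ``n_rel``; D = 1/(3 (mu_a + mu_s')).
    """
    mua = np.asarray(mua, dtype=float)
    mus = np.asarray(mus, dtype=float)
    if np.any(mus <= 0):
        raise ValueError("mu_s' must be > 0")
    _check_rho(rho)
    mu_t = mua + mus
    z0 = 1.0 / mu_t
    d_coef = 1.0 / (3.0 * mu_t)
    zb = 2.0 * internal_reflection_parameter(n_rel) * d_coef
    mu_eff = np.sqrt(mua / d_coef)
    return _dipole_flux(mua, mus, rho, [z0, z0 + 2.0 * zb], mu_eff, [1.0, 1.0])


# --- two-layer medium -------------------------------------------------------

_PANEL_EDGES = np.concatenate([
    np.arange(0.0, 2.0, 0.25),
    np.arange(2.0, 8.0, 0.5),
    np.arange(8.0, 16.0, 1.0),
    np.arange(16.0, 64.0 + 1.0, 2.0),
])
_TAIL_EDGES = np.arange(64.0, 80.0 + 1.0, 2.0)
_GL_ORDER = 48


def _gauss_nodes(edges: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x, w = leggauss(_GL_ORDER)
    nodes, weights = [], []
    for a, b in zip(edges[:-1], edges[1:]):
        nodes.append(0.5 * (b - a) * x + 0.5 * (b + a))
        weights.append(0.5 * (b - a) * w)
    return np.concatenate(nodes), np.concatenate(weights)


_S_NODES, _S_WEIGHTS = _gauss_nodes(_PANEL_EDGES)
_S_TAIL, _W_TAIL = _gauss_nodes(_TAIL_EDGES)


def _two_layer_flux_hat(s: np.ndarray, mua1, mus1, mua2, mus2,
                        thickness: float, n_rel: float) -> np.ndarray:
    """Hankel-domain surface current for a unit source at z0 in the top layer.

    Overflow-safe closed form of the layered diffusion Green's function
    with an extrapolated boundary at z = -z_b.
    """
    mua1 = np.atleast_1d(np.asarray(mua1, dtype=float))[:, None]
    mus1 = np.atleast_1d(np.asarray(mus1, dtype=float))[:, None]
    mua2 = np.atleast_1d(np.asarray(mua2, dtype=float))[:, None]
    mus2 = np.atleast_1d(np.asarray(mus2, dtype=float))[:, None]
    s = np.asarray(s, dtype=float)[None, :]

    d1 = 1.0 / (3.0 * (mua1 + mus1))
    d2 = 1.0 / (3.0 * (mua2 + mus2))
    z0 = 1.0 / (mua1 + mus1)
    if np.any(z0 >= thickness):
        raise ValueError(
            "top layer thinner than one transport mean free path "
            f"(z0 = {float(np.max(z0)):.3f} mm >= {thickness} mm): "
            "source would sit in the bottom layer")
    zb = 2.0 * internal_reflection_parameter(n_rel) * d1

    a1 = np.sqrt(s**2 + mua1 / d1)
    a2 = np.sqrt(s**2 + mua2 / d2)
    beta = (d2 * a2) / (d1 * a1)
    ell = thickness - z0  # source depth below interface distance

    # flux_hat = D1 * a1 * A * cosh(a1*zb) with
    # A = (cosh(a1*ell) + beta*sinh(a1*ell)) /
    #     (D1*a1*(cosh(a1*(L+zb)) + beta*sinh(a1*(L+zb))))
    # rearranged so every exponential argument is <= 0.
    e_z0 = np.exp(-a1 * z0)
    e_z0zb = np.exp(-a1 * (z0 + 2.0 * zb))
    e_far = np.exp(-a1 * (ell + thickness))
    e_farzb = np.exp(-a1 * (ell + thickness + 2.0 * zb))
    e_tot = np.exp(-2.0 * a1 * (thickness + zb))
    num = (1.0 + beta) * (e_z0 + e_z0zb) + (1.0 - beta) * (e_far + e_farzb)
    den = (1.0 + beta) + (1.0 - beta) * e_tot
    return 0.5 * num / den


def two_layer_reflectance(top_mua, top_mus, bottom_mua, bottom_mus,
                          thickness: float, rho,
                          n_rel: float = 1.4,
                          tail_rtol: float = 1e-5):
    """CW reflectance of a two-layer semi-infinite medium, mm^-2.

    Layered diffusion Green's function in the spatial-frequency domain,
    inverted with a fixed composite Gauss-Legendre quadrature over the
    radial frequency.  Optical-property arguments broadcast over
    wavelength; ``rho`` may be scalar or array (result shape
    ``rho.shape + wavelength.shape``).

    Truncation of the frequency integral is checked with an extension
    band beyond the quadrature range: if its contribution exceeds
    ``tail_rtol`` of the largest computed reflectance the inversion is
    declared non-convergent (raises).  Also raises if the top layer is
    thinner than one transport mean free path (the isotropic source would
    sit in the bottom layer).
    """
    _check_rho(rho)
    rho_arr = np.atleast_1d(np.asarray(rho, dtype=float))
    flux_hat = _two_layer_flux_hat(_S_NODES, top_mua, top_mus,
                                   bottom_mua, bottom_mus, thickness, n_rel)
    flux_tail = _two_layer_flux_hat(_S_TAIL, top_mua, top_mus,
                                    bottom_mua, bottom_mus, thickness, n_rel)
    from scipy.special import j0
    # R(rho) = (1/2pi) * int flux_hat(s) J0(s rho) s ds
    kern = j0(_S_NODES[None, :] * rho_arr[:, None]) * (_S_NODES * _S_WEIGHTS)
    kern_tail = j0(_S_TAIL[None, :] * rho_arr[:, None]) * (_S_TAIL * _W_TAIL)
    main = kern @ flux_hat.T / (2.0 * np.pi)
    tail = kern_tail @ flux_tail.T / (2.0 * np.pi)
    total = main
    rel_tail = np.max(np.abs(tail)) / np.max(np.abs(total))
    if rel_tail > tail_rtol:
        raise RuntimeError(
            f"two-layer Hankel inversion not converged: extension band "
            f"contributes {rel_tail:.2e} > {tail_rtol:.0e} of the peak "
            "reflectance; increase quadrature range")
    if np.any(total <= 0):
        raise RuntimeError("two-layer inversion produced non-positive "
                           "reflectance: quadrature did not converge")
    return np.squeeze(total)


# --- synthetic measurement generation ---------------------------------------

def _reflectance_matrix(params, table: ChromophoreTable, grid: np.ndarray,
                        geometry: ProbeGeometry, model: str) -> np.ndarray:
    """(n_distances, n_wavelengths) reflectance for homogeneous or layered."""
    table = resample(table, grid)
    dists = geometry.as_array()
    if isinstance(params, TwoLayerParams):
        mua1 = mu_a(params.top, table)
        mus1 = mu_s_powerlaw(params.top.a, params.top.b, grid)
        mua2 = mu_a(params.bottom, table)
        mus2 = mu_s_powerlaw(params.bottom.a, params.bottom.b, grid)
        refl = two_layer_reflectance(mua1, mus1, mua2, mus2,
                                     params.top_thickness, dists)
        return np.atleast_2d(refl)
    mua = mu_a(params, table)
    mus = mu_s_powerlaw(params.a, params.b, grid)
    fn = {"zbc": zbc_reflectance, "ebc": ebc_reflectance}[model]
    return np.stack([fn(mua, mus, d) for d in dists])


def simulate_multidistance(params, table: ChromophoreTable, grid: np.ndarray,
                           geometry: ProbeGeometry | None = None,
                           noise_fraction: float = 0.01,
                           n_replicates: int = 1,
                           seed: int | np.random.Generator | None = None,
                           model: str = "zbc") -> list[MultidistanceSpectra]:
    """Generate noisy broadband multidistance measurements.

    Intensity is the model reflectance (unit source, I0 = 1 reference);
    per replicate, additive noise is drawn uniformly from
    +-noise_fraction * max(I) — the maximum taken over the spectrum of each
    detector — independently per (distance, wavelength).  Attenuation is
    A = -log10(I).  Draws that would make the intensity non-positive are
    redrawn and counted in ``meta['n_resampled']``.

    ``model`` selects the homogeneous boundary treatment ('zbc' or 'ebc');
    it is ignored for ``TwoLayerParams`` input (extrapolated boundary).
    """
    if geometry is None:
        geometry = ProbeGeometry()
    if noise_fraction < 0:
        raise ValueError("noise_fraction must be >= 0")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    grid = np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    clean = _reflectance_matrix(params, table, grid, geometry, model)
    amp = noise_fraction * np.max(clean, axis=1, keepdims=True)

    out = []
    for rep in range(n_replicates):
        noisy = clean + rng.uniform(-amp, amp, size=clean.shape)
        n_resampled = 0
        bad = noisy <= 0
        while np.any(bad):
            n_resampled += int(bad.sum())
            redraw = clean + rng.uniform(-amp, amp, size=clean.shape)
            noisy = np.where(bad, redraw, noisy)
            bad = noisy <= 0
        out.append(MultidistanceSpectra(
            wavelength=grid,
            attenuation=-np.log10(noisy),
            intensity=noisy,
            geometry=geometry,
            meta={"replicate": rep, "noise_fraction": noise_fraction,
                  "model": model, "n_resampled": n_resampled},
        ))
    return out


def phantom_trajectory(n_cycles: int = 4, plateau_points: int = 4,
                       ramp_points: int = 6, tau: float = 2.0) -> np.ndarray:
    """Piecewise saturation trajectory emulating oxygenation/deoxygenation
    cycles of a stirred blood-yeast liquid phantom.

    Each cycle: plateau at 0, exponential rise to 1, plateau at 1,
    exponential fall to 0.  Returns StO2 as a fraction in [0, 1].
    """
    t = np.arange(1, ramp_points + 1) / ramp_points
    rise = (1 - np.exp(-t * tau)) / (1 - np.exp(-tau))
    seg = np.concatenate([
        np.zeros(plateau_points), rise,
        np.ones(plateau_points), 1.0 - rise,
    ])
    traj = np.tile(seg, n_cycles)
    return np.clip(traj, 0.0, 1.0)


def simulate_phantom_cycles(c_thb: float, scattering: tuple[float, float],
                            wf: float, trajectory: np.ndarray,
                            table: ChromophoreTable, grid: np.ndarray,
                            geometry: ProbeGeometry | None = None,
                            noise_fraction: float = 0.01,
                            seed: int | None = None,
                            model: str = "zbc"
                            ) -> tuple[list[MultidistanceSpectra], np.ndarray]:
    """Time series of noisy measurements along a saturation trajectory.

    At each time point the medium is homogeneous with
    c_HbO2 = StO2 * c_THb and c_HHb = (1 - StO2) * c_THb; water fraction
    and scattering stay fixed (total haemoglobin is conserved).  Returns
    the measurements and the true StO2 trajectory in percent.
    """
    trajectory = np.asarray(trajectory, dtype=float)
    if np.any(trajectory < 0) or np.any(trajectory > 1):
        raise ValueError("trajectory StO2 must lie in [0, 1]")
    a, b = scattering
    rng = np.random.default_rng(seed)
    series = []
    for i, s in enumerate(trajectory):
        params = TissueParams(c_hbo2=s * c_thb, c_hhb=(1.0 - s) * c_thb,
                              wf=wf, a=a, b=b)
        meas = simulate_multidistance(params, table, grid, geometry,
                                      noise_fraction, 1, rng, model)[0]
        meas.meta.update({"time_index": i, "true_sto2_percent": 100.0 * s})
        series.append(meas)
    return series, 100.0 * trajectory
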