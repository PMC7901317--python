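"""Automated data-quality score for derivative slope spectra.

Differentiation amplifies measurement noise, and a derivative-space fit
can converge to a plausible-looking optimum on data that carry no usable
chromophore structure.  The score quantifies how well the fitted model
derivative matches the measured derivative exactly where the informative
spectral features live — around the 760 nm deoxyhaemoglobin band
(750-770 nm) and the ~830 nm water feature (825-840 nm) — and penalises
featureless model spectra through the reciprocal of the model's range:

    score = (SSR_750-770 * SSR_825-840) / (max(model) - min(model))

with both spectra z-score normalised over the full fit range first.
Lower is better; a score below the threshold (default 2, an empirical
operating point from clinical broadband measurements) marks the spectrum
as suitable for analysis.  The score is advisory: nothing is discarded
automatically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["QualityReport", "quality_score", "RESIDUAL_WINDOWS"]

RESIDUAL_WINDOWS = ((750.0, 770.0), (825.0, 840.0))


@dataclass(frozen=True)
class QualityReport:
    resid_750_770: float
    resid_825_840: float
    prod_r: float
    range_r: float
    score: float
    threshold: float
    passed: bool


def _zscore(y: np.ndarray) -> np.ndarray:
    sd = np.std(y)
    if sd == 0:
        return np.zeros_like(y)
    return (y - np.mean(y)) / sd


def quality_score(measured_deriv: np.ndarray, model_deriv: np.ndarray,
                  grid: np.ndarray, threshold: float = 2.0) -> QualityReport:
    """Score a measured derivative spectrum against its fitted model.

    Both spectra must share ``grid`` (nm), which has to cover 750-840 nm.
    A flat model (zero range) yields an infinite score and a failed
    report.  Affine rescaling of either spectrum leaves the score
    unchanged (z-score normalisation).
    """
    grid = np.asarray(grid, dtype=float)
    measured = np.asarray(measured_deriv, dtype=float)
    model = np.asarray(model_deriv, dtype=float)
    if measured.shape != grid.shape or model.shape != grid.shape:
        raise ValueError("spectra and grid must share one shape")
    if grid[0] > RESIDUAL_WINDOWS[0][0] or grid[-1] < RESIDUAL_WINDOWS[1][1]:
        raise ValueError("grid must cover 750-840 nm for quality scoring")

    zm = _zscore(measured)
    zt = _zscore(model)
    resid_sq = (zm - zt) ** 2
    sums = []
    for lo, hi in RESIDUAL_WINDOWS:
        inside = (grid >= lo) & (grid <= hi)
        sums.append(float(np.sum(resid_sq[inside])))
    prod_r = sums[0] * sums[1]
    range_r = float(np.max(zt) - np.min(zt))
    if range_r == 0:
        return QualityReport(sums[0], sums[1], prod_r, 0.0, float("inf"),
                             threshold, False)
    score = prod_r / range_r
    return QualityReport(sums[0], sums[1], prod_r, range_r, score,
                         threshold, score < threshold)
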