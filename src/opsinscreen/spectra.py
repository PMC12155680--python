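"""Rhodopsin-regeneration quantification from UV/Vis absorption spectra.

Regeneration of the pigment from opsin and 9-cis-retinal is read out as
the absorbance band that bleaches on light exposure: subtracting the
light-adapted spectrum from the dark-adapted one isolates the pigment
band, which is fitted with a Gaussian A*exp(-(l-mu)^2/(2*sigma^2)) over
the 360-600 nm window. The area under the fitted curve, A*sigma*sqrt(2*pi),
quantifies the amount of regenerated pigment; conditions are normalized
to the mean AUC of the retinal-only control, so a competing ligand shows
a normalized AUC below 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares


@dataclass
class Spectrum:
    """Absorbance versus wavelength on a strictly increasing nm grid."""

    wavelengths: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavelengths.ndim != 1 or self.wavelengths.shape != self.absorbance.shape:
            raise ValueError("wavelength and absorbance arrays must match")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.wavelengths)):
            raise ValueError("wavelengths must be finite")


def difference_spectrum(dark: Spectrum, light: Spectrum) -> Spectrum:
    """Pointwise dark - light; offset grids are linearly regridded onto
    the overlapping support of the dark grid."""
    if np.array_equal(dark.wavelengths, light.wavelengths):
        return Spectrum(dark.wavelengths.copy(), dark.absorbance - light.absorbance)
    lo = max(dark.wavelengths[0], light.wavelengths[0])
    hi = min(dark.wavelengths[-1], light.wavelengths[-1])
    if lo >= hi:
        raise ValueError("spectra have disjoint wavelength ranges")
    mask = (dark.wavelengths >= lo) & (dark.wavelengths <= hi)
    grid = dark.wavelengths[mask]
    light_interp = np.interp(grid, light.wavelengths, light.absorbance)
    return Spectrum(grid, dark.absorbance[mask] - light_interp)


@dataclass
class GaussianFitResult:
    """Parameters of the Gaussian fitted to a difference spectrum."""

    amplitude: float
    center: float
    sigma: float
    baseline: float
    residual_norm: float
    converged: bool


def _initial_guess(wl: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    i0 = int(np.argmax(y))
    a0 = float(y[i0])
    mu0 = float(wl[i0])
    half = a0 / 2.0
    above = np.where(y >= half)[0]
    if len(above) >= 2:
        fwhm = wl[above[-1]] - wl[above[0]]
        sigma0 = max(float(fwhm) / 2.355, 1e-3)
    else:
        sigma0 = max((wl[-1] - wl[0]) / 10.0, 1e-3)
    return a0, mu0, sigma0


def fit_gaussian(diff: Spectrum, baseline: bool = False,
                 loss: str = "linear") -> GaussianFitResult:
    """Nonlinear least-squares Gaussian fit of a difference spectrum.

    Initialization: center at the argmax, amplitude at the maximum,
    sigma from the half-maximum width. Degenerate input (all zero, all
    NaN, too few points) or solver failure yields ``converged=False``
    with zero amplitude rather than an exception; a negative fitted
    amplitude is likewise reported as non-converged, since regeneration
    cannot be negative. ``loss='soft_l1'`` enables a robust fit.
    """
    wl = diff.wavelengths
    y = diff.absorbance
    finite = np.isfinite(y)
    wl, y = wl[finite], y[finite]
    degenerate = GaussianFitResult(0.0, float(wl[len(wl) // 2]) if len(wl) else 0.0,
                                   1.0, 0.0, float("inf"), False)
    if len(wl) < 10 or np.allclose(y, 0.0):
        return degenerate
    a0, mu0, sigma0 = _initial_guess(wl, y)
    if a0 <= 0:
        return degenerate

    def model(p):
        a, mu, sigma, b = p
        return a * np.exp(-((wl - mu) ** 2) / (2.0 * sigma ** 2)) + b

    p0 = [a0, mu0, sigma0, 0.0]
    lb = [-np.inf, wl[0], 1e-6, -np.inf]
    ub = [np.inf, wl[-1], np.inf, np.inf]
    if not baseline:
        lb[3], ub[3] = -1e-12, 1e-12
    try:
        res = least_squares(lambda p: model(p) - y, p0, bounds=(lb, ub),
                            loss=loss, xtol=1e-14, ftol=1e-14, gtol=1e-14)
    except Exception:
        return degenerate
    a, mu, sigma, b = res.x
    converged = bool(res.success) and a > 0 and np.isfinite(res.cost)
    if a <= 0:
        a = 0.0
    return GaussianFitResult(float(a), float(mu), float(abs(sigma)),
                             float(b) if baseline else 0.0,
                             float(np.linalg.norm(res.fun)), converged)


def auc(fit: GaussianFitResult) -> float:
    """Analytic area under the fitted Gaussian, A*sigma*sqrt(2*pi).

    The baseline term is excluded. Raises on non-converged fits; a
    converged fit with zero amplitude has zero area.
    """
    if not fit.converged:
        raise ValueError("no AUC for failed fit")
    return fit.amplitude * fit.sigma * math.sqrt(2.0 * math.pi)


@dataclass
class RegenerationResult:
    """Per-condition AUC summary, normalized to the control mean."""

    condition: str
    auc_mean: float
    auc_sd: float
    normalized_mean: float
    normalized_sd: float
    n_replicates: int


def normalize_conditions(aucs: Mapping[str, Sequence[float]],
                         control: str) -> list[RegenerationResult]:
    """Normalize replicate AUCs of every condition by the control mean.

    Returns one result per condition (control included; its normalized
    mean is 1 by construction). SD is the sample SD (n-1 denominator),
    zero for single replicates.
    """
    if control not in aucs or len(aucs[control]) == 0:
        raise ValueError(f"control condition {control!r} missing or empty")
    control_mean = float(np.mean(aucs[control]))
    if control_mean == 0:
        raise ValueError("control mean AUC is zero; cannot normalize")
    out = []
    for cond, values in aucs.items():
        v = np.asarray(values, dtype=float)
        norm = v / control_mean
        sd = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
        nsd = float(np.std(norm, ddof=1)) if len(v) > 1 else 0.0
        out.append(RegenerationResult(cond, float(v.mean()), sd,
                                      float(norm.mean()), nsd, len(v)))
    return out


def quantify_replicates(pairs: Sequence[tuple[Spectrum, Spectrum]],
                        baseline: bool = False) -> list[float]:
    """AUC for each (dark, light) replicate pair via difference + fit."""
    out = []
    for dark, light in pairs:
        fit = fit_gaussian(difference_spectrum(dark, light), baseline=baseline)
        out.append(auc(fit))
    return out
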