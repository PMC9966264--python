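"""Spectral preprocessing: autofluorescence baseline, spikes, normalization.

Tissue Raman spectra sit on a broad autofluorescence background.  It is
removed here by an iterative peak-suppressing polynomial fit of order 18:
fit a polynomial, clip the working signal to the fitted curve wherever it
exceeds it, refit, and repeat until the coefficients stop moving.  Peaks
are progressively excluded from the fit while baseline channels anchor it.
The fit runs in a Chebyshev basis on the wavenumber axis rescaled to
[-1, 1]; raw cm^-1 powers at order 18 would overflow double precision.

Cosmic-ray spikes are detected per spectrum as deviations from a 5-point
running median exceeding ``k`` times the MAD of all deviations, and the
whole spectrum is discarded (spikes invalidate a single accumulation, and
the acquisition protocol discards such spectra rather than repairing them).

Normalization defaults to the Euclidean (vector) norm, which is scale-free
and preserves band-area ratios; per-band and total-area variants are
available behind the ``method`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from numpy.polynomial import chebyshev as cheb
from scipy.ndimage import median_filter

from .spectra_core import RamanSpectrum, SampleMeta, SpectrumSet

__all__ = [
    "BaselineModel",
    "fit_baseline",
    "subtract_baseline",
    "flag_cosmic",
    "normalize",
    "mean_sd",
    "difference_vs_healthy",
    "preprocess_set",
]


@dataclass(frozen=True)
class BaselineModel:
    """Fitted autofluorescence background for one spectrum.

    ``coefficients`` are Chebyshev coefficients (length ``order + 1``) on the
    wavenumber domain rescaled to [-1, 1]; ``fit_mask`` marks channels still
    treated as baseline (never clipped) at convergence.
    """

    order: int
    coefficients: np.ndarray
    grid: np.ndarray
    fit_mask: np.ndarray
    converged: bool
    n_iter: int

    def evaluate(self, wavenumbers: np.ndarray | None = None) -> np.ndarray:
        w = self.grid if wavenumbers is None else np.asarray(wavenumbers, float)
        x = _rescale(w, self.grid[0], self.grid[-1])
        return cheb.chebval(x, self.coefficients)


def _rescale(w: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return 2.0 * (w - lo) / (hi - lo) - 1.0


def _clipped_polyfit(
    y: np.ndarray,
    V: np.ndarray,
    pinv: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, bool, int]:
    """Shared core of the clip-to-curve iteration (V, pinv precomputed)."""
    work = y.astype(float).copy()
    coeff_prev = None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        coeff = pinv @ work
        curve = V @ coeff
        work = np.minimum(work, curve)
        if coeff_prev is not None:
            scale = 1.0 + np.max(np.abs(coeff))
            if np.max(np.abs(coeff - coeff_prev)) < tol * scale:
                converged = True
                break
        coeff_prev = coeff
    # The clip iteration drifts toward the lower envelope of the signal;
    # treat it as peak identification and refit on baseline channels, i.e.
    # channels whose residual above the curve is within the robust scatter.
    r = y - V @ coeff
    s_rob = 1.4826 * np.median(np.abs(r - np.median(r)))
    thresh = np.median(r) + 3.0 * s_rob + 1e-12 * (1.0 + np.max(np.abs(y)))
    mask = r <= thresh
    if mask.sum() > V.shape[1]:
        coeff = np.linalg.lstsq(V[mask], y[mask], rcond=None)[0]
    return coeff, mask, converged, it


def fit_baseline(
    s: RamanSpectrum,
    order: int = 18,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> BaselineModel:
    """Iterative peak-suppressing polynomial baseline fit (default order 18).

    Convergence is declared when the maximum coefficient change drops below
    ``tol`` relative to the coefficient scale; non-convergence is flagged on
    the result, not raised.
    """
    if len(s) <= order + 1:
        raise ValueError(
            f"spectrum length {len(s)} too short for an order-{order} baseline"
        )
    x = _rescale(s.wavenumbers, s.wavenumbers[0], s.wavenumbers[-1])
    V = cheb.chebvander(x, order)
    pinv = np.linalg.pinv(V)
    coeff, mask, converged, it = _clipped_polyfit(s.intensities, V, pinv, max_iter, tol)
    return BaselineModel(order, coeff, s.wavenumbers, mask, converged, it)


def subtract_baseline(s: RamanSpectrum, b: BaselineModel) -> RamanSpectrum:
    """Subtract a fitted baseline; the metadata is preserved."""
    if not np.array_equal(s.wavenumbers, b.grid):
        raise ValueError("baseline was fitted on a different wavenumber grid")
    return s.with_intensities(s.intensities - b.evaluate())


def flag_cosmic(s: RamanSpectrum, k: float = 8.0) -> bool:
    """True iff the spectrum contains a cosmic-ray-like spike.

    A channel is spike-like when its deviation from a 5-point running median
    exceeds ``k`` robust standard deviations, the robust SD being the
    MAD-based estimate 1.4826 * MAD of all deviations.  A constant spectrum
    (MAD = 0) is never flagged.
    """
    if len(s) < 5:
        raise ValueError("spike detection needs at least 5 channels")
    smooth = median_filter(s.intensities, size=5, mode="nearest")
    dev = s.intensities - smooth
    mad = np.median(np.abs(dev - np.median(dev)))
    if mad == 0.0:
        return False
    return bool(np.max(np.abs(dev)) > k * 1.4826 * mad)


def normalize(
    s: RamanSpectrum,
    method: str = "vector",
    reference: float = 1445.0,
) -> RamanSpectrum:
    """Rescale a spectrum to a common interpretable scale.

    vector
        divide by the Euclidean norm (default);
    band
        divide by the intensity at the grid channel nearest ``reference``;
    area
        divide by the trapezoidal integral over the full axis.

    All methods satisfy normalize(c*s) = normalize(s) for c > 0.
    """
    y = s.intensities
    if method == "vector":
        denom = float(np.linalg.norm(y))
    elif method == "band":
        denom = float(y[np.argmin(np.abs(s.wavenumbers - reference))])
    elif method == "area":
        denom = float(np.trapezoid(y, s.wavenumbers))
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    if denom == 0.0:
        raise ZeroDivisionError(f"{method} normalization denominator is zero")
    return s.with_intensities(y / denom)


def mean_sd(
    sset: SpectrumSet,
    selector: Callable[[SampleMeta], bool] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Channelwise sample mean and SD (n-1 denominator) of a cohort subset."""
    if selector is not None:
        idx = sset.indices(where=selector)
        if idx.size == 0:
            raise ValueError("selector matches no spectra")
        m = sset.matrix[idx]
    else:
        m = sset.matrix
    mean = m.mean(axis=0)
    sd = m.std(axis=0, ddof=1) if m.shape[0] > 1 else np.zeros_like(mean)
    return mean, sd


def difference_vs_healthy(
    sset: SpectrumSet,
    healthy_mean: np.ndarray,
    rng_lohi: tuple[float, float] | None = None,
) -> SpectrumSet:
    """Each spectrum minus the healthy mean, optionally cropped to a range."""
    healthy_mean = np.asarray(healthy_mean, dtype=float)
    if healthy_mean.shape != sset.grid.shape:
        raise ValueError("healthy mean is not on the cohort grid")
    diff = SpectrumSet(sset.grid, sset.matrix - healthy_mean, sset.metas)
    if rng_lohi is not None:
        diff = diff.crop(*rng_lohi)
    return diff


def preprocess_set(
    sset: SpectrumSet,
    baseline_order: int = 18,
    max_iter: int = 100,
    tol: float = 1e-8,
    spike_k: float = 8.0,
    norm_method: str = "vector",
    drop_spikes: bool = True,
) -> tuple[SpectrumSet, pd.DataFrame]:
    """Cohort pipeline: spike rejection -> baseline subtraction -> normalize.

    Returns the processed set and a per-spectrum QC table (spike flag,
    baseline convergence, iterations).  Flagged spectra are dropped from the
    returned set when ``drop_spikes`` (the default); the QC table always
    covers every input spectrum.  The Chebyshev design matrix is factorized
    once for the shared grid.
    """
    x = _rescale(sset.grid, sset.grid[0], sset.grid[-1])
    V = cheb.chebvander(x, baseline_order)
    pinv = np.linalg.pinv(V)

    rows = []
    keep = []
    processed = []
    for i, s in enumerate(sset.spectra()):
        spike = flag_cosmic(s, k=spike_k)
        coeff, _, converged, it = _clipped_polyfit(s.intensities, V, pinv, max_iter, tol)
        corrected = s.intensities - V @ coeff
        rows.append(
            {
                "index": i,
                "group": s.meta.group,
                "day": s.meta.day,
                "mouse_id": s.meta.mouse_id,
                "point_id": s.meta.point_id,
                "cosmic_spike": spike,
                "baseline_converged": converged,
                "baseline_iterations": it,
            }
        )
        if spike and drop_spikes:
            continue
        out = normalize(s.with_intensities(corrected), method=norm_method)
        processed.append(out.intensities)
        keep.append(i)
    if not keep:
        raise ValueError("all spectra were flagged as cosmic-contaminated")
    out_set = SpectrumSet(sset.grid, np.vstack(processed), [sset.metas[i] for i in keep])
    return out_set, pd.DataFrame(rows)
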