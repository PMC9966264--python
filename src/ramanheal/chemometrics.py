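"""PCA subspace scoring and the Mahalanobis healing-distance table.

The healing-progress score works in a two-dimensional principal-component
subspace of a spectral sub-range (PC2-PC3 of the 2800-3000 cm^-1 CH-stretch
region by default).  The space is first rescaled so that the healthy-skin
group has unit score SD on each axis, i.e. its radius

    r = sqrt(sigma2'^2 + sigma3'^2) = sqrt(2),

and the Mahalanobis quadratic form

    dM(x_i, x_j) = (x_i - x_j)^T C^{-1} (x_i - x_j)

is then taken with C the variance-covariance matrix of the scaled healthy
coordinates.  The printed convention is the squared form (no square root);
a square-root variant sits behind a flag.  Point-to-set and set-to-set
distances are plain arithmetic means of dM over the healthy reference set
and over the wound set respectively, yielding one distance d(S, S_H) per
(group, day) cell — the healing-distance table.  Distances drop toward the
healthy self-distance baseline as a wound's spectra approach healthy skin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .spectra_core import DEFAULT_DAYS, SampleMeta, SpectrumSet

__all__ = [
    "PCASubspace",
    "ScaledPCSpace",
    "HealthyReference",
    "DistanceTable",
    "fit_pca",
    "scale_pc23",
    "build_reference",
    "mahalanobis_pair",
    "point_to_set",
    "set_to_set",
    "distance_table",
]

#: Row order of the distance table (treated arms first, control last).
TABLE_GROUP_ORDER = ("ALA1", "ALA4", "MB1", "MB4", "control")


@dataclass(frozen=True)
class PCASubspace:
    """PCA of a cropped spectral sub-range (mean-centered, unscaled)."""

    range: tuple[float, float]
    grid: np.ndarray
    mean_spectrum: np.ndarray
    loadings: np.ndarray          # components x channels, rows orthonormal
    scores: np.ndarray            # spectra x components
    explained_variance_ratio: np.ndarray
    metas: tuple[SampleMeta, ...]


@dataclass(frozen=True)
class ScaledPCSpace:
    """PC2-PC3 plane rescaled so the healthy group has radius sqrt(2)."""

    components: tuple[int, int]   # 1-based component indices
    sigma2: float
    sigma3: float
    scale2: float
    scale3: float
    r: float
    coords: np.ndarray            # spectra x 2, scaled
    metas: tuple[SampleMeta, ...]


@dataclass(frozen=True)
class HealthyReference:
    """Healthy-skin coordinate cloud and its (inverse) covariance."""

    healthy_coords: np.ndarray
    C: np.ndarray
    C_inv: np.ndarray
    regularized: bool


@dataclass(frozen=True)
class DistanceTable:
    """d(S, S_H) per treatment group (rows) per observation day (columns)."""

    table: pd.DataFrame
    sigma2: float
    sigma3: float
    regularized: bool


def fit_pca(sset: SpectrumSet, rng_lohi: tuple[float, float]) -> PCASubspace:
    """Mean-centered PCA on a wavenumber sub-range (no variance scaling).

    Deterministic sign convention: each loading's largest-magnitude element
    is made positive (scores flipped accordingly).
    """
    if len(sset) < 3:
        raise ValueError("PCA needs at least 3 spectra")
    cropped = sset.crop(*rng_lohi)
    X = cropped.matrix
    if np.allclose(X, X[0], atol=0.0):
        raise ValueError("constant matrix: PCA undefined")
    pca = PCA(n_components=min(X.shape), svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.copy()
    for k in range(loadings.shape[0]):
        j = np.argmax(np.abs(loadings[k]))
        if loadings[k, j] < 0:
            loadings[k] *= -1.0
            scores[:, k] *= -1.0
    return PCASubspace(
        range=tuple(rng_lohi),
        grid=cropped.grid,
        mean_spectrum=pca.mean_,
        loadings=loadings,
        scores=scores,
        explained_variance_ratio=pca.explained_variance_ratio_,
        metas=cropped.metas,
    )


def _healthy_mask(
    metas: Sequence[SampleMeta],
    selector: Callable[[SampleMeta], bool] | None,
) -> np.ndarray:
    sel = selector or (lambda m: m.group == "healthy")
    return np.asarray([sel(m) for m in metas], dtype=bool)


def scale_pc23(
    p: PCASubspace,
    healthy_selector: Callable[[SampleMeta], bool] | None = None,
    components: tuple[int, int] = (2, 3),
) -> ScaledPCSpace:
    """Rescale the PC2-PC3 plane by the healthy group's score SDs.

    With scale_k = 1/sigma_k applied to every score, the scaled healthy SDs
    are both 1 and the healthy radius r = sqrt(1 + 1) = sqrt(2).
    Component indices are 1-based (PC2, PC3 are the 2nd and 3rd).
    """
    i2, i3 = components[0] - 1, components[1] - 1
    if max(i2, i3) >= p.scores.shape[1]:
        raise ValueError(
            f"PCA has only {p.scores.shape[1]} components; cannot take {components}"
        )
    mask = _healthy_mask(p.metas, healthy_selector)
    if mask.sum() < 2:
        raise ValueError("healthy subset needs at least 2 spectra")
    healthy = p.scores[mask][:, [i2, i3]]
    sigma2 = float(healthy[:, 0].std(ddof=1))
    sigma3 = float(healthy[:, 1].std(ddof=1))
    if sigma2 == 0.0 or sigma3 == 0.0:
        raise ValueError("healthy group has zero score variance on PC axis")
    scale2, scale3 = 1.0 / sigma2, 1.0 / sigma3
    coords = p.scores[:, [i2, i3]] * np.array([scale2, scale3])
    scaled_healthy = coords[mask]
    r = float(np.hypot(scaled_healthy[:, 0].std(ddof=1),
                       scaled_healthy[:, 1].std(ddof=1)))
    return ScaledPCSpace(
        components=components,
        sigma2=sigma2,
        sigma3=sigma3,
        scale2=scale2,
        scale3=scale3,
        r=r,
        coords=coords,
        metas=p.metas,
    )


def build_reference(
    s: ScaledPCSpace,
    healthy_selector: Callable[[SampleMeta], bool] | None = None,
    ridge: float = 1e-8,
    cond_threshold: float = 1e10,
) -> HealthyReference:
    """Covariance (n-1) of the scaled healthy coordinates, inverted.

    Near-singular covariances (condition number above ``cond_threshold``)
    get ``ridge * trace(C)/2`` added to the diagonal before inversion.
    """
    mask = _healthy_mask(s.metas, healthy_selector)
    coords = s.coords[mask]
    if coords.shape[0] < 3:
        raise ValueError("healthy reference needs at least 3 spectra")
    C = np.cov(coords, rowvar=False, ddof=1)
    regularized = False
    if np.linalg.cond(C) > cond_threshold:
        C = C + ridge * np.trace(C) / 2.0 * np.eye(2)
        regularized = True
    return HealthyReference(coords, C, np.linalg.inv(C), regularized)


def mahalanobis_pair(
    x_i: np.ndarray,
    x_j: np.ndarray,
    ref: HealthyReference,
    squared: bool = True,
) -> float:
    """Mahalanobis form d^T C^{-1} d between two coordinate pairs.

    The default is the squared quadratic form; ``squared=False`` takes the
    square root.
    """
    d = np.asarray(x_i, float) - np.asarray(x_j, float)
    if d.shape != (2,):
        raise ValueError(f"expected 2-vectors, got difference shape {d.shape}")
    q = float(d @ ref.C_inv @ d)
    return q if squared else float(np.sqrt(q))


def point_to_set(
    x_i: np.ndarray,
    S_H: np.ndarray,
    ref: HealthyReference,
    squared: bool = True,
) -> float:
    """Mean Mahalanobis form from one point to every member of S_H."""
    S_H = np.atleast_2d(np.asarray(S_H, float))
    if S_H.shape[0] == 0:
        raise ValueError("S_H is empty")
    diffs = S_H - np.asarray(x_i, float)
    q = np.einsum("ij,jk,ik->i", diffs, ref.C_inv, diffs)
    if not squared:
        q = np.sqrt(q)
    return float(q.mean())


def set_to_set(
    S: np.ndarray,
    S_H: np.ndarray,
    ref: HealthyReference,
    squared: bool = True,
) -> float:
    """Mean over S of point-to-set distances: the grand mean of all pairs."""
    S = np.atleast_2d(np.asarray(S, float))
    if S.shape[0] == 0:
        raise ValueError("S is empty")
    return float(np.mean([point_to_set(x, S_H, ref, squared=squared) for x in S]))


def distance_table(
    sset: SpectrumSet,
    rng_lohi: tuple[float, float] = (2800.0, 3000.0),
    components: tuple[int, int] = (2, 3),
    squared: bool = True,
    days: Sequence[int] | None = None,
) -> DistanceTable:
    """Full healing-distance pipeline for one cohort.

    PCA is fitted once, pooled over all spectra (wound groups and healthy)
    in the sub-range, so every cell shares one coordinate system; scores
    are then sliced per (group, day) and averaged against the healthy
    reference.  Requires healthy spectra in the cohort.
    """
    if sset.indices(group="healthy").size == 0:
        raise ValueError("cohort contains no healthy spectra")
    p = fit_pca(sset, rng_lohi)
    sp = scale_pc23(p, components=components)
    ref = build_reference(sp)

    groups = [g for g in TABLE_GROUP_ORDER
              if any(m.group == g for m in sset.metas)]
    if not groups:  # non-standard group labels: keep whatever wound groups exist
        groups = sorted({m.group for m in sset.metas if m.group != "healthy"})
    if days is None:
        days = sorted({m.day for m in sset.metas if m.day is not None})

    mask_h = _healthy_mask(sp.metas, None)
    values = np.full((len(groups), len(days)), np.nan)
    for gi, g in enumerate(groups):
        for di, d in enumerate(days):
            idx = [k for k, m in enumerate(sp.metas)
                   if m.group == g and m.day == d]
            if idx:
                values[gi, di] = set_to_set(
                    sp.coords[idx], sp.coords[mask_h], ref, squared=squared
                )
    table = pd.DataFrame(values, index=list(groups),
                         columns=[f"day {d}" for d in days])
    return DistanceTable(table, sp.sigma2, sp.sigma3, ref.regularized)
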