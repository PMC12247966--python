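"""Topographic mapping between soma positions and axon-arbor centroids.

For a set of cells from one source area projecting to one target region,
the somata ``S`` and the per-cell arbor centroids ``C`` are each projected
onto their own first principal axis (the leading eigenvector of the
covariance matrix, i.e. the Hotelling transform's first component), and
the Spearman rank correlation ρ of the two projections measures how well
the spatial order of somata is preserved (ρ > 0), reversed (ρ < 0), or
lost (ρ ≈ 0) in the target.

Arbor centroids are computed from uniformly resampled segments so node
density does not bias them.  The sign of each principal axis is fixed by
making its largest-magnitude component positive; otherwise the sign of ρ
would be arbitrary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

from .morphology import Arbor, resample_segments

__all__ = ["TopographyResult", "arbor_centroid", "principal_axis", "topography_rho"]


@dataclass
class TopographyResult:
    rho: float
    n_cells: int
    axis_s: np.ndarray
    axis_c: np.ndarray
    somas: np.ndarray
    centroids: np.ndarray
    projecting_fraction: float = 1.0
    ok: bool = True
    source_area: str | None = None
    target_region: int | str | None = None
    hemisphere: str | None = None


def arbor_centroid(arbor, parent=None, step: float = 1.0) -> np.ndarray:
    """Centroid of an arbor as the mean of uniformly resampled points.

    Accepts an :class:`Arbor` (its stored points and local segment
    structure are used) or an ``(N, 3)`` point array together with a
    ``parent`` index array.  Converges to the length-weighted segment
    centroid as ``step`` -> 0; without segment structure it degrades to
    the unweighted node mean.
    """
    if isinstance(arbor, Arbor):
        xyz = arbor.points
        if parent is None:
            parent = arbor.local_parent
    else:
        xyz = np.asarray(arbor, dtype=np.float64)
    if len(xyz) == 0:
        raise ValueError("empty arbor")
    if parent is None:
        return xyz.mean(axis=0)
    pts = resample_segments(xyz, parent, step)
    return pts.mean(axis=0)


def principal_axis(points: np.ndarray) -> tuple[np.ndarray, bool]:
    """First principal axis of a point set (unit vector), sign-fixed.

    The axis is the covariance eigenvector with the largest eigenvalue,
    its sign chosen so the component of largest magnitude is positive.
    Returns (axis, ok); ``ok`` is False when the two leading eigenvalues
    tie (the smallest-index eigenvector is then returned
    deterministically).
    """
    pts = np.asarray(points, dtype=np.float64)
    if len(pts) < 3:
        raise ValueError("need >= 3 points")
    cov = np.cov(pts.T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    axis = evecs[:, order[0]]
    ok = not np.isclose(evals[order[0]], evals[order[1]])
    k = int(np.argmax(np.abs(axis)))
    if axis[k] < 0:
        axis = -axis
    return axis, ok


def topography_rho(somas: np.ndarray, centroids: np.ndarray,
                   projecting_fraction: float = 1.0,
                   source_area=None, target_region=None,
                   hemisphere=None) -> TopographyResult:
    """Spearman ρ between principal-axis projections of somata and centroids.

    ``somas`` and ``centroids`` are paired (N, 3) arrays, one row per
    projecting cell.  Ties get average ranks.  ρ = 1 when the centroid
    order along the target axis matches the soma order along the source
    axis, −1 when it is exactly reversed; constant projections yield
    ``ok=False`` with ρ = NaN.
    """
    s = np.asarray(somas, dtype=np.float64)
    c = np.asarray(centroids, dtype=np.float64)
    if s.shape != c.shape or len(s) < 3:
        raise ValueError("somas and centroids must be paired with >= 3 cells")
    axis_s, _ = principal_axis(s)
    axis_c, _ = principal_axis(c)
    s_proj = s @ axis_s
    c_proj = c @ axis_c
    if np.ptp(s_proj) == 0 or np.ptp(c_proj) == 0:
        return TopographyResult(float("nan"), len(s), axis_s, axis_c, s, c,
                                projecting_fraction, ok=False,
                                source_area=source_area,
                                target_region=target_region,
                                hemisphere=hemisphere)
    rho = float(spearmanr(s_proj, c_proj).statistic)
    return TopographyResult(rho, len(s), axis_s, axis_c, s, c,
                            projecting_fraction, ok=True,
                            source_area=source_area,
                            target_region=target_region,
                            hemisphere=hemisphere)
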