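"""Convergence analysis of axonal clouds in a shared target region.

Implements a scatter-matrix class-separability overlap score between two
axon point clouds, pairwise overlap matrices across source areas, Gaussian
kernel-density cloud volume / mean axon density, and composition-based
similarity clustering of convergent regions.

Overlap score
-------------
Treating each axon cloud as a class, the separability is

    S = tr(S_B) / tr(S_W)

with between-class scatter ``S_B = sum_i n_i (m_i - m)(m_i - m)^T`` and
within-class scatter ``S_W = sum_i sum_j (x_ij - m_i)(x_ij - m_i)^T``
(``m_i`` per-cloud mean, ``m`` pooled mean).  The overlap is
``O = max(0, 1 - S)``: 1 for coincident clouds, 0 for fully separable
ones.  Clouds should be pre-interpolated onto the Cartesian grid (see
:func:`projectomics.morphology.rasterize_segments`) so node density does
not bias the means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import gaussian_kde

__all__ = [
    "AxonCloud",
    "OverlapResult",
    "overlap_score",
    "overlap_matrix",
    "kde_cloud",
    "cloud_volume",
    "composition_cluster",
]


@dataclass
class AxonCloud:
    """Grid-interpolated axon point cloud from one source area in a region."""

    source_area: str
    region_id: int
    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=np.float64))
        if len(self.points) < 1:
            raise ValueError("empty axon cloud")

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def mean(self) -> np.ndarray:
        return self.points.mean(axis=0)


@dataclass
class OverlapResult:
    source_a: str
    source_b: str
    region_id: int
    separability: float
    overlap: float
    pooled_mean: np.ndarray
    degenerate: bool = False


def overlap_score(cloud_a: AxonCloud, cloud_b: AxonCloud) -> OverlapResult:
    """Class-separability overlap O = max(0, 1 - tr(S_B)/tr(S_W)).

    Degenerate case: if the within-class scatter vanishes (all points of
    each cloud identical), O is 1 when the two cloud means coincide and 0
    otherwise, flagged as degenerate.
    """
    xa, xb = cloud_a.points, cloud_b.points
    ma, mb = cloud_a.mean, cloud_b.mean
    pooled = np.vstack([xa, xb]).mean(axis=0)
    tr_b = len(xa) * float(np.sum((ma - pooled) ** 2)) \
        + len(xb) * float(np.sum((mb - pooled) ** 2))
    tr_w = float(np.sum((xa - ma) ** 2)) + float(np.sum((xb - mb) ** 2))
    if tr_w == 0.0:
        overlap = 1.0 if np.allclose(ma, mb) else 0.0
        return OverlapResult(cloud_a.source_area, cloud_b.source_area,
                             cloud_a.region_id, np.inf if tr_b > 0 else 0.0,
                             overlap, pooled, degenerate=True)
    s = tr_b / tr_w
    return OverlapResult(cloud_a.source_area, cloud_b.source_area,
                         cloud_a.region_id, s, max(0.0, 1.0 - s), pooled)


def overlap_matrix(clouds: dict, region_id: int | None = None):
    """Symmetric matrix of pairwise overlap scores over source areas.

    ``clouds`` maps source area -> :class:`AxonCloud` (or point array).
    The diagonal is 1 (a cloud fully overlaps itself).  Returns
    (DataFrame, summary dict) where the summary reports the off-diagonal
    mean +/- SE, the fraction of pairs with O > 0.5, and the fraction with
    O = 0.
    """
    sources = list(clouds)
    if len(sources) < 2:
        raise ValueError("need >= 2 source areas")
    norm = {}
    for s, c in clouds.items():
        norm[s] = c if isinstance(c, AxonCloud) else AxonCloud(s, region_id or 0, c)
    mat = pd.DataFrame(np.eye(len(sources)), index=sources, columns=sources)
    vals = []
    for a, b in combinations(sources, 2):
        o = overlap_score(norm[a], norm[b]).overlap
        mat.loc[a, b] = mat.loc[b, a] = o
        vals.append(o)
    vals = np.array(vals)
    summary = {
        "mean": float(vals.mean()),
        "se": float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0,
        "frac_above_half": float((vals > 0.5).mean()),
        "frac_zero": float((vals == 0.0).mean()),
        "n_pairs": len(vals),
    }
    return mat, summary


def kde_cloud(points: np.ndarray, bandwidth: float = 0.3,
              grid_spacing: float = 10.0, bounds=None):
    """Gaussian KDE of an axon cloud evaluated on a voxel grid.

    The bandwidth is unitless: points are centered and scaled to unit
    per-axis variance before estimation, so 0.3 means 0.3 standard
    deviations (a raw-μm bandwidth can be emulated by pre-scaling).
    Returns (density grid, grid origin, spacing); the grid covers the
    cloud's bounding box (or explicit ``bounds``) at ``grid_spacing`` μm.
    """
    pts = np.asarray(points, dtype=np.float64)
    if len(pts) < 10:
        raise ValueError("need >= 10 points for a density estimate")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    center = pts.mean(axis=0)
    scale = pts.std(axis=0)
    scale[scale == 0] = 1.0
    z = (pts - center) / scale
    kde = gaussian_kde(z.T, bw_method=bandwidth)
    if bounds is None:
        lo = pts.min(axis=0) - 2 * grid_spacing
        hi = pts.max(axis=0) + 2 * grid_spacing
    else:
        lo, hi = (np.asarray(b, dtype=np.float64) for b in bounds)
    axes = [np.arange(lo[d] + grid_spacing / 2, hi[d], grid_spacing)
            for d in range(3)]
    mesh = np.meshgrid(*axes, indexing="ij")
    coords = np.stack([m.ravel() for m in mesh], axis=0)
    zcoords = (coords - center[:, None]) / scale[:, None]
    density = kde(zcoords).reshape([len(a) for a in axes])
    return density, lo, float(grid_spacing)


def cloud_volume(density: np.ndarray, grid_spacing: float,
                 total_axon_length: float | None = None,
                 rel_threshold: float = 0.01, mode: str = "absolute"):
    """Thresholded cloud volume and mean axon density.

    Volume = (number of voxels whose density clears the 1% cut) x voxel
    volume, in μm^3.  In the default ``mode='absolute'`` the cut is
    ``rel_threshold`` on the standardized density itself (the KDE grid
    integrates to 1 in standardized coordinates, so 0.01 means "1%
    density"); this keeps the estimate stable in the bandwidth and
    recovers the geometric volume of compact uniform clouds.  With
    ``mode='relative'`` the cut is ``rel_threshold`` x the maximum
    density, which grows with the bandwidth's Gaussian halo.  If
    ``total_axon_length`` (μm) is given, the mean axon density
    length/volume (μm/μm^3) is returned too, else ``None``; a zero volume
    flags the density as undefined (NaN).
    """
    if not (0 < rel_threshold <= 1):
        raise ValueError("rel_threshold must be in (0, 1]")
    if mode == "relative":
        peak = float(density.max())
        cut = rel_threshold * peak if peak > 0 else np.inf
    elif mode == "absolute":
        cut = rel_threshold
    else:
        raise ValueError(f"unknown mode {mode!r}")
    volume = int((density >= cut).sum()) * grid_spacing ** 3
    if total_axon_length is None:
        return volume, None
    return volume, (total_axon_length / volume if volume > 0 else float("nan"))


def composition_cluster(composition: pd.DataFrame, k: int | None = None):
    """Cluster convergent-region targets by axonal-length composition.

    ``composition`` has one row per target (sub)region and one column per
    (cell type, source area) with summed axonal length.  Rows are
    normalized to proportions, clustered hierarchically with the
    one-minus-Pearson metric and average linkage, and cosine similarity
    matrices are computed for the targets (rows) and for the contributing
    cell types/sources (columns).

    Returns a dict with ``proportions``, ``linkage``, ``labels`` (if ``k``
    given), ``target_similarity`` and ``type_similarity``.
    """
    comp = composition.astype(float)
    if (comp.to_numpy() < 0).any():
        raise ValueError("composition must be nonnegative")
    zero = comp.sum(axis=1) == 0
    if zero.any():
        warnings.warn(f"dropping {int(zero.sum())} all-zero composition rows")
        comp = comp[~zero]
    prop = comp.div(comp.sum(axis=1), axis=0)

    def _cosine(df: pd.DataFrame) -> pd.DataFrame:
        x = df.to_numpy(float)
        norm = np.linalg.norm(x, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        sim = (x / norm) @ (x / norm).T
        np.fill_diagonal(sim, 1.0)
        return pd.DataFrame(sim, index=df.index, columns=df.index)

    if len(prop) < 2:
        z = None
    else:
        d = pdist(prop.to_numpy(), metric="correlation")
        d[~np.isfinite(d)] = 1.0  # constant rows: treat as uncorrelated
        z = linkage(d, method="average")
    out = {
        "proportions": prop,
        "linkage": z,
        "target_similarity": _cosine(prop),
        "type_similarity": _cosine(prop.T),
    }
    if k is not None:
        lab = np.ones(len(prop), dtype=int) if z is None else fcluster(
            z, t=k, criterion="maxclust"
        )
        out["labels"] = pd.Series(lab, index=prop.index, name="cluster")
    return out
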