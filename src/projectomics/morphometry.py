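"""Morphometric features, cell-type clustering and classification.

Extracts per-compartment skeleton features from SWC trees, min-max
normalizes feature tables, clusters cells hierarchically (one-minus-
Pearson metric, average linkage), scores clustering accuracy against
known type labels via optimal cluster-to-type assignment, and trains a
random-forest cell-type classifier on a stratified 80/20 split.

The nine core (apical) features are: height, max distance from soma, max
pathway length from soma, total pathway efficiency, average bifurcation
angle, average segment length, number of segments, number of bifurcations
and number of tips.  "Height" is the extent along a declared cortical-
depth axis; "total pathway efficiency" is the mean over tips of the
Euclidean-to-path-length ratio (inverse tortuosity), both defined here
explicitly since the feature names alone do not pin them down.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .morphology import NeuronReconstruction, _compartment_code

__all__ = [
    "FEATURE_NAMES",
    "extract_features",
    "feature_table",
    "minmax_normalize",
    "hcluster",
    "clustering_accuracy",
    "train_classifier",
]

FEATURE_NAMES = [
    "height",
    "max_distance_from_soma",
    "max_pathway_length",
    "total_pathway_efficiency",
    "avg_bifurcation_angle",
    "avg_segment_length",
    "n_segments",
    "n_bifurcations",
    "n_tips",
]


def extract_features(neuron: NeuronReconstruction, compartment,
                     depth_axis: int = 1) -> pd.Series:
    """The nine skeleton features of one compartment subtree.

    ``depth_axis`` declares the cortical-depth coordinate used for
    "height" (extent of the compartment along that axis).  A tree without
    bifurcations reports the average bifurcation angle as NaN.
    """
    code = _compartment_code(compartment)
    mask = neuron.compartment == code
    if not mask.any():
        raise ValueError(f"no nodes in compartment {compartment!r}")
    xyz = neuron.xyz
    soma = neuron.soma_position
    idx = np.flatnonzero(mask)

    kids: dict[int, list[int]] = {int(i): [] for i in idx}
    entries = []
    for i in idx:
        p = int(neuron.parent[i])
        if p >= 0 and p in kids:
            kids[p].append(int(i))
        else:
            entries.append(int(i))

    # path length from the soma, accumulated down the tree (the entry
    # node's attachment segment counts toward the path)
    path = {}
    stack = list(entries)
    for e in entries:
        p = int(neuron.parent[e])
        path[e] = float(np.linalg.norm(xyz[e] - xyz[p])) if p >= 0 else 0.0
    while stack:
        node = stack.pop()
        for c in kids[node]:
            path[c] = path[node] + float(np.linalg.norm(xyz[c] - xyz[node]))
            stack.append(c)

    tips = [i for i in idx if len(kids[int(i)]) == 0]
    bifs = [i for i in idx if len(kids[int(i)]) >= 2]

    euclid = np.linalg.norm(xyz[idx] - soma, axis=1)
    tip_euclid = np.linalg.norm(xyz[tips] - soma, axis=1)
    tip_path = np.array([path[int(t)] for t in tips])
    with np.errstate(divide="ignore", invalid="ignore"):
        eff = np.where(tip_path > 0, tip_euclid / tip_path, 1.0)

    # unbranched runs: one segment per edge leaving a branch point / entry,
    # ending at the next branch point or tip
    seg_lengths = []
    for start in entries + [c for b in bifs for c in kids[int(b)]]:
        length = 0.0
        node = start
        parent = int(neuron.parent[node]) if neuron.parent[node] >= 0 else -1
        if parent >= 0:  # the edge into the run's first node
            length += float(np.linalg.norm(xyz[node] - xyz[parent]))
        while len(kids[node]) == 1:
            nxt = kids[node][0]
            length += float(np.linalg.norm(xyz[nxt] - xyz[node]))
            node = nxt
        seg_lengths.append(length)
    # entry runs that start at a bifurcation are zero-length artifacts
    seg_lengths = [s for s in seg_lengths if s > 0] or [0.0]

    angles = []
    for b in bifs:
        dirs = []
        for c in kids[int(b)]:
            v = xyz[c] - xyz[b]
            n = np.linalg.norm(v)
            if n > 0:
                dirs.append(v / n)
        for i in range(len(dirs)):
            for j in range(i + 1, len(dirs)):
                cosang = np.clip(np.dot(dirs[i], dirs[j]), -1.0, 1.0)
                angles.append(np.degrees(np.arccos(cosang)))

    return pd.Series(
        {
            "height": float(np.ptp(xyz[idx, depth_axis])),
            "max_distance_from_soma": float(euclid.max()),
            "max_pathway_length": float(max(path.values())),
            "total_pathway_efficiency": float(np.mean(eff)) if len(tips) else np.nan,
            "avg_bifurcation_angle": float(np.mean(angles)) if angles else np.nan,
            "avg_segment_length": float(np.mean(seg_lengths)),
            "n_segments": float(len(seg_lengths)),
            "n_bifurcations": float(len(bifs)),
            "n_tips": float(len(tips)),
        }
    )[FEATURE_NAMES]


def feature_table(neurons, compartment, depth_axis: int = 1) -> pd.DataFrame:
    """Feature matrix, one row per neuron (indexed by cell id)."""
    return pd.DataFrame(
        {n.cell_id: extract_features(n, compartment, depth_axis) for n in neurons}
    ).T


def minmax_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Min-max scale every feature column to [0, 1].

    Constant (or all-NaN) columns carry no contrast and are dropped with
    a warning.
    """
    lo, hi = table.min(), table.max()
    keep = (hi - lo) > 0
    if not keep.all():
        warnings.warn(
            f"dropping constant features: {list(table.columns[~keep])}"
        )
    t = table.loc[:, keep]
    return (t - lo[keep]) / (hi[keep] - lo[keep])


def hcluster(table: pd.DataFrame, k: int) -> pd.Series:
    """Cut an average-linkage, one-minus-Pearson dendrogram at k clusters."""
    if k > len(table):
        raise ValueError(f"k={k} exceeds {len(table)} cells")
    z = linkage(pdist(table.to_numpy(float), metric="correlation"),
                method="average")
    return pd.Series(fcluster(z, t=k, criterion="maxclust"),
                     index=table.index, name="cluster")


def clustering_accuracy(true_labels, clusters) -> float:
    """Fraction of correctly clustered cells under optimal assignment.

    Clusters are matched one-to-one to type labels by maximizing the
    contingency-table trace (Hungarian algorithm); accuracy is the matched
    count over the total.  Invariant under cluster relabeling.
    """
    true_labels = pd.Series(list(true_labels))
    clusters = pd.Series(list(clusters))
    tab = pd.crosstab(clusters, true_labels)
    rows, cols = linear_sum_assignment(-tab.to_numpy())
    return float(tab.to_numpy()[rows, cols].sum() / len(true_labels))


def train_classifier(features: pd.DataFrame, labels, test_size: float = 0.2,
                     seed: int = 0, n_estimators: int = 500,
                     areas=None):
    """Random-forest cell-type classifier with a stratified 80/20 split.

    Returns (overall accuracy, per-area accuracy Series or None, fitted
    model).  Deterministic for a fixed seed.  Requires >= 2 classes with
    >= 2 cells each so the stratified split can hold every class.
    """
    y = pd.Series(list(labels), index=features.index)
    counts = y.value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise ValueError("need >= 2 classes with >= 2 cells each")
    x_train, x_test, y_train, y_test = train_test_split(
        features, y, test_size=test_size, stratify=y, random_state=seed
    )
    clf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    clf.fit(x_train, y_train)
    pred = pd.Series(clf.predict(x_test), index=x_test.index)
    accuracy = float((pred == y_test).mean())
    per_area = None
    if areas is not None:
        areas = pd.Series(list(areas), index=features.index)
        per_area = pred.eq(y_test).groupby(areas.loc[x_test.index]).mean()
    return accuracy, per_area, clf
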