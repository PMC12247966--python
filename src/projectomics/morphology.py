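"""Core SWC morphology handling and atlas-based arbor decomposition.

This module owns the low-level plumbing of the pipeline: reading and
validating SWC neuron reconstructions, computing branch orders and
terminals on compartment subtrees, resampling and rasterizing segments,
looking up atlas regions, and splitting an axon into per-(region,
hemisphere) arbors whose lengths, terminal counts and branch orders feed
the projection-target filter.

Conventions
-----------
* Coordinates are micrometres in a right-handed frame.
* Voxel ``i`` of the atlas covers the half-open interval
  ``[origin + i * voxel_size, origin + (i + 1) * voxel_size)``.
* Branch order: the entry node of a compartment subtree has order 0 and
  the order increases by one in the daughters of every bifurcation
  (a node with >= 2 children in the compartment).
* Hemispheres are split by a configurable midline plane; "ipsi" and
  "contra" are always relative to the hemisphere of the soma.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SOMA",
    "AXON",
    "BASAL",
    "APICAL",
    "SWCParseError",
    "SWCStructureError",
    "NeuronReconstruction",
    "RegionAtlas",
    "Arbor",
    "read_swc",
    "write_swc",
    "branch_orders",
    "terminal_nodes",
    "total_length",
    "resample_segments",
    "rasterize_segments",
    "decompose_arbors",
]

# SWC compartment type codes
SOMA, AXON, BASAL, APICAL = 1, 2, 3, 4

_COMPARTMENT_NAMES = {"soma": SOMA, "axon": AXON, "basal": BASAL, "apical": APICAL}


class SWCParseError(ValueError):
    """A malformed SWC record (reports the offending line number)."""


class SWCStructureError(ValueError):
    """An SWC file whose records do not form a valid rooted tree."""


def _compartment_code(compartment) -> int:
    if isinstance(compartment, str):
        try:
            return _COMPARTMENT_NAMES[compartment.lower()]
        except KeyError:
            raise ValueError(f"unknown compartment {compartment!r}") from None
    code = int(compartment)
    if code not in (SOMA, AXON, BASAL, APICAL):
        raise ValueError(f"unknown compartment code {code}")
    return code


@dataclass
class NeuronReconstruction:
    """A rooted tree of typed nodes with 3D coordinates in micrometres.

    ``parent`` holds array *indices* (-1 for the root); the original SWC
    node ids are preserved in ``node_id``.
    """

    cell_id: str
    node_id: np.ndarray
    compartment: np.ndarray
    xyz: np.ndarray
    radius: np.ndarray
    parent: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.node_id = np.asarray(self.node_id, dtype=np.int64)
        self.compartment = np.asarray(self.compartment, dtype=np.int64)
        self.xyz = np.asarray(self.xyz, dtype=np.float64)
        self.radius = np.asarray(self.radius, dtype=np.float64)
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.validate()

    # -- structure ---------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.node_id)

    def validate(self) -> None:
        n = self.n_nodes
        if n == 0:
            raise SWCStructureError("empty reconstruction")
        if self.xyz.shape != (n, 3):
            raise SWCStructureError("coordinate array must be (n, 3)")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise SWCStructureError(f"expected exactly one root, found {len(roots)}")
        if self.parent.max() >= n:
            raise SWCStructureError("parent index out of range")
        if not np.all(np.isfinite(self.xyz)):
            raise SWCStructureError("non-finite coordinates")
        if np.any(self.radius < 0):
            raise SWCStructureError("negative radius")
        # acyclicity: walk each node to the root, bounded by n steps
        depth = np.full(n, -1, dtype=np.int64)
        depth[roots[0]] = 0
        for i in range(n):
            chain = []
            j = i
            while depth[j] < 0:
                chain.append(j)
                j = self.parent[j]
                if len(chain) > n:
                    raise SWCStructureError("cycle in parent links")
            base = depth[j]
            for k, node in enumerate(reversed(chain)):
                depth[node] = base + k + 1

    def children(self) -> list[list[int]]:
        """Adjacency: children()[i] lists the indices of i's children."""
        kids: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                kids[p].append(i)
        return kids

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    @property
    def soma_position(self) -> np.ndarray:
        soma = np.flatnonzero(self.compartment == SOMA)
        idx = soma[0] if len(soma) else self.root
        return self.xyz[idx]

    def compartment_mask(self, compartment) -> np.ndarray:
        return self.compartment == _compartment_code(compartment)

    def segment_lengths(self) -> np.ndarray:
        """Per-node length of the parent->node segment (0 for the root)."""
        out = np.zeros(self.n_nodes)
        has = self.parent >= 0
        out[has] = np.linalg.norm(self.xyz[has] - self.xyz[self.parent[has]], axis=1)
        return out


def read_swc(path, cell_id: str | None = None) -> NeuronReconstruction:
    """Parse a 7-column SWC file into a validated :class:`NeuronReconstruction`.

    Lines starting with ``#`` are comments.  Malformed records raise
    :class:`SWCParseError` naming the line; a parent id that references a
    missing node raises :class:`SWCStructureError`.
    """
    path = Path(path)
    ids, comps, xyzs, radii, parents = [], [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 7:
                raise SWCParseError(
                    f"{path.name}:{lineno}: expected 7 columns, got {len(fields)}"
                )
            try:
                ids.append(int(fields[0]))
                comps.append(int(fields[1]))
                xyzs.append([float(v) for v in fields[2:5]])
                radii.append(float(fields[5]))
                parents.append(int(fields[6]))
            except ValueError as exc:
                raise SWCParseError(f"{path.name}:{lineno}: {exc}") from None
    if not ids:
        raise SWCParseError(f"{path.name}: no node records")
    index = {nid: i for i, nid in enumerate(ids)}
    if len(index) != len(ids):
        raise SWCStructureError(f"{path.name}: duplicate node ids")
    parent_idx = np.empty(len(ids), dtype=np.int64)
    for i, pid in enumerate(parents):
        if pid == -1:
            parent_idx[i] = -1
        elif pid in index:
            parent_idx[i] = index[pid]
        else:
            raise SWCStructureError(
                f"{path.name}: node {ids[i]} references missing parent {pid}"
            )
    return NeuronReconstruction(
        cell_id=cell_id or path.stem,
        node_id=np.array(ids),
        compartment=np.array(comps),
        xyz=np.array(xyzs),
        radius=np.array(radii),
        parent=parent_idx,
    )


def write_swc(neuron: NeuronReconstruction, path) -> None:
    """Write a neuron as standard 7-column SWC (original node ids kept)."""
    with open(path, "w") as fh:
        fh.write(f"# id type x y z radius parent\n# cell {neuron.cell_id}\n")
        for i in range(neuron.n_nodes):
            pid = -1 if neuron.parent[i] < 0 else neuron.node_id[neuron.parent[i]]
            x, y, z = neuron.xyz[i]
            fh.write(
                f"{neuron.node_id[i]} {neuron.compartment[i]} "
                f"{x:.17g} {y:.17g} {z:.17g} {neuron.radius[i]:.17g} {pid}\n"
            )


# ---------------------------------------------------------------------------
# branch orders / terminals
# ---------------------------------------------------------------------------

def _orders_in_subset(neuron: NeuronReconstruction, subset: np.ndarray) -> dict[int, int]:
    """Branch orders restricted to a node subset (bool mask over indices).

    Entry nodes (parent absent from the subset) start at order 0; each
    bifurcation inside the subset increments the order of its daughters.
    Returns {node index -> order}.
    """
    idx = np.flatnonzero(subset)
    in_set = set(idx.tolist())
    kids: dict[int, list[int]] = {i: [] for i in in_set}
    entries = []
    for i in idx:
        p = neuron.parent[i]
        if p >= 0 and p in in_set:
            kids[int(p)].append(int(i))
        else:
            entries.append(int(i))
    orders: dict[int, int] = {}
    stack = [(e, 0) for e in entries]
    while stack:
        node, order = stack.pop()
        orders[node] = order
        child_order = order + 1 if len(kids[node]) >= 2 else order
        for c in kids[node]:
            stack.append((c, child_order))
    return orders


def branch_orders(neuron: NeuronReconstruction, compartment) -> dict[int, int]:
    """Branch order per node of a compartment subtree, keyed by SWC node id."""
    mask = neuron.compartment_mask(compartment)
    orders = _orders_in_subset(neuron, mask)
    return {int(neuron.node_id[i]): o for i, o in orders.items()}


def terminal_nodes(neuron: NeuronReconstruction, compartment) -> np.ndarray:
    """Indices of compartment nodes with no children in the compartment."""
    mask = neuron.compartment_mask(compartment)
    n_children = np.zeros(neuron.n_nodes, dtype=np.int64)
    valid = (neuron.parent >= 0) & mask
    np.add.at(n_children, neuron.parent[valid], 1)
    return np.flatnonzero(mask & (n_children == 0))


def total_length(neuron: NeuronReconstruction, compartment) -> float:
    """Summed length of segments whose child node lies in the compartment."""
    mask = neuron.compartment_mask(compartment) & (neuron.parent >= 0)
    seg = neuron.segment_lengths()
    return float(seg[mask].sum())


# ---------------------------------------------------------------------------
# resampling & rasterization
# ---------------------------------------------------------------------------

def resample_segments(xyz: np.ndarray, parent: np.ndarray, step: float) -> np.ndarray:
    """Uniformly resample every parent->child segment at spacing <= ``step``.

    Each segment contributes both endpoints plus interior points spaced at
    most ``step`` apart; isolated roots contribute their single point.  The
    output point count is therefore >= the input node count, and the mean of
    the points converges to the length-weighted centroid as step -> 0.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    xyz = np.asarray(xyz, dtype=np.float64)
    parent = np.asarray(parent, dtype=np.int64)
    is_parent = np.zeros(len(xyz), dtype=bool)
    is_parent[parent[parent >= 0]] = True
    pieces = []
    for i in range(len(xyz)):
        p = parent[i]
        if p < 0:
            if not is_parent[i]:  # isolated node
                pieces.append(xyz[i : i + 1])
            continue
        a, b = xyz[p], xyz[i]
        length = float(np.linalg.norm(b - a))
        n = max(1, math.ceil(length / step))
        t = np.linspace(0.0, 1.0, n + 1)[:, None]
        pieces.append(a + t * (b - a))
    if not pieces:
        return xyz.copy()
    return np.vstack(pieces)


def _traverse_voxels(p0: np.ndarray, p1: np.ndarray, spacing: np.ndarray,
                     origin: np.ndarray) -> list[tuple[int, int, int]]:
    """3D DDA voxel traversal (Amanatides-Woo) for one straight segment."""
    a = (p0 - origin) / spacing
    b = (p1 - origin) / spacing
    v = np.floor(a).astype(np.int64)
    v_end = np.floor(b).astype(np.int64)
    cells = [tuple(v)]
    d = b - a
    step = np.sign(d).astype(np.int64)
    t_max = np.full(3, np.inf)
    t_delta = np.full(3, np.inf)
    for ax in range(3):
        if d[ax] > 0:
            t_max[ax] = (v[ax] + 1 - a[ax]) / d[ax]
            t_delta[ax] = 1.0 / d[ax]
        elif d[ax] < 0:
            t_max[ax] = (v[ax] - a[ax]) / d[ax]
            t_delta[ax] = -1.0 / d[ax]
    max_iter = int(np.abs(v_end - v).sum()) + 6
    for _ in range(max_iter):
        if np.array_equal(v, v_end):
            break
        ax = int(np.argmin(t_max))
        if t_max[ax] > 1.0 + 1e-12:
            break
        v = v.copy()
        v[ax] += step[ax]
        t_max[ax] += t_delta[ax]
        cells.append(tuple(v))
    return cells


def rasterize_segments(xyz: np.ndarray, parent: np.ndarray, grid_spacing,
                       origin=(0.0, 0.0, 0.0)) -> set[tuple[int, int, int]]:
    """Set of grid cells traversed by every parent->child straight segment.

    Every Cartesian grid cell on the straight path between a node and its
    child is included (exact 3D voxel walk); a zero-length segment
    contributes its single cell.  Deterministic for fixed input.
    """
    spacing = np.broadcast_to(np.asarray(grid_spacing, dtype=np.float64), (3,)).copy()
    if np.any(spacing <= 0):
        raise ValueError("grid_spacing must be > 0")
    origin = np.asarray(origin, dtype=np.float64)
    xyz = np.asarray(xyz, dtype=np.float64)
    parent = np.asarray(parent, dtype=np.int64)
    cells: set[tuple[int, int, int]] = set()
    for i in range(len(xyz)):
        p = parent[i]
        if p < 0:
            cells.add(tuple(np.floor((xyz[i] - origin) / spacing).astype(np.int64)))
            continue
        cells.update(_traverse_voxels(xyz[p], xyz[i], spacing, origin))
    return cells


# ---------------------------------------------------------------------------
# atlas
# ---------------------------------------------------------------------------

@dataclass
class RegionAtlas:
    """A 3D integer label volume with region metadata and a midline plane.

    ``regions`` is indexed by region id with columns ``name``, ``area``,
    ``layer``, ``group``, ``hemisphere`` and ``hierarchy_level`` (NaN where
    not applicable).  Label 0 is background.
    """

    labels: np.ndarray
    voxel_size: np.ndarray
    origin: np.ndarray
    midline: float
    regions: pd.DataFrame
    midline_axis: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.voxel_size = np.broadcast_to(
            np.asarray(self.voxel_size, dtype=np.float64), (3,)
        ).copy()
        self.origin = np.asarray(self.origin, dtype=np.float64)
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel_size must be > 0")
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.regions.index.tolist())
        if missing:
            raise ValueError(f"labels missing from region table: {sorted(missing)}")

    def lookup(self, points) -> np.ndarray:
        """Region label of each point; 0 for out-of-bounds points."""
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        idx = np.floor((pts - self.origin) / self.voxel_size).astype(np.int64)
        out = np.zeros(len(pts), dtype=self.labels.dtype)
        inb = np.all((idx >= 0) & (idx < np.array(self.labels.shape)), axis=1)
        if inb.any():
            ii = idx[inb]
            out[inb] = self.labels[ii[:, 0], ii[:, 1], ii[:, 2]]
        return out

    def hemisphere_side(self, points) -> np.ndarray:
        """'left' or 'right' per point, split at the midline plane."""
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        return np.where(pts[:, self.midline_axis] < self.midline, "left", "right")

    # -- I/O ---------------------------------------------------------------
    def save(self, directory) -> None:
        """Write the label volume as NIfTI and the region table as TSV."""
        import nibabel as nib

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        affine = np.diag(list(self.voxel_size) + [1.0])
        affine[:3, 3] = self.origin
        nib.save(
            nib.Nifti1Image(self.labels.astype(np.int32), affine),
            directory / "atlas_labels.nii",
        )
        self.regions.to_csv(directory / "regions.tsv", sep="\t", index_label="region_id")
        meta = pd.Series(
            {"midline": self.midline, "midline_axis": self.midline_axis}
        )
        meta.to_csv(directory / "atlas_meta.tsv", sep="\t", header=False)

    @classmethod
    def load(cls, directory) -> "RegionAtlas":
        import nibabel as nib

        directory = Path(directory)
        img = nib.load(directory / "atlas_labels.nii")
        affine = img.affine
        regions = pd.read_csv(directory / "regions.tsv", sep="\t", index_col="region_id")
        meta = pd.read_csv(
            directory / "atlas_meta.tsv", sep="\t", header=None, index_col=0
        )[1]
        return cls(
            labels=np.asarray(img.dataobj),
            voxel_size=np.diag(affine)[:3],
            origin=affine[:3, 3],
            midline=float(meta["midline"]),
            midline_axis=int(meta["midline_axis"]),
            regions=regions,
        )


# ---------------------------------------------------------------------------
# arbor decomposition
# ---------------------------------------------------------------------------

@dataclass
class Arbor:
    """The axonal subforest of one cell inside one (region, hemisphere).

    ``hemisphere`` is 'ipsi' or 'contra' relative to the soma's side of the
    midline.  ``axon_length`` sums the parent->child segment lengths whose
    child node lies in the region; branch orders are recomputed from the
    arbor's own entry nodes.
    """

    cell_id: str
    region_id: int
    hemisphere: str
    axon_length: float
    n_terminals: int
    max_branch_order_within: int
    node_idx: np.ndarray
    points: np.ndarray
    local_parent: np.ndarray | None = None  # parent index within node_idx, -1 at entries


def decompose_arbors(neuron: NeuronReconstruction, atlas: RegionAtlas) -> list[Arbor]:
    """Split a neuron's axon into per-(region, hemisphere) arbors.

    Each axonal segment's length is assigned to the region and hemisphere of
    its child node, so lengths are conserved exactly across any atlas
    partition.  Out-of-bounds nodes map to region 0 and are dropped.
    """
    axon = neuron.compartment_mask(AXON)
    if not axon.any():
        return []
    region = atlas.lookup(neuron.xyz)
    side = atlas.hemisphere_side(neuron.xyz)
    soma_side = atlas.hemisphere_side(neuron.soma_position[None, :])[0]
    rel = np.where(side == soma_side, "ipsi", "contra")

    seg_len = neuron.segment_lengths()
    # terminals: axon nodes with no axon children
    n_children = np.zeros(neuron.n_nodes, dtype=np.int64)
    valid = (neuron.parent >= 0) & axon
    np.add.at(n_children, neuron.parent[valid], 1)

    keys = {}
    for i in np.flatnonzero(axon):
        keys.setdefault((int(region[i]), rel[i]), []).append(i)

    arbors = []
    for (reg, hemi), nodes in sorted(keys.items()):
        if reg == 0:
            continue
        nodes = np.array(nodes)
        mask = np.zeros(neuron.n_nodes, dtype=bool)
        mask[nodes] = True
        orders = _orders_in_subset(neuron, mask)
        length = float(seg_len[nodes[neuron.parent[nodes] >= 0]].sum())
        terminals = int((n_children[nodes] == 0).sum())
        local = {int(n): k for k, n in enumerate(nodes)}
        local_parent = np.array(
            [local.get(int(neuron.parent[n]), -1) for n in nodes], dtype=np.int64
        )
        arbors.append(
            Arbor(
                cell_id=neuron.cell_id,
                region_id=reg,
                hemisphere=hemi,
                axon_length=length,
                n_terminals=terminals,
                max_branch_order_within=max(orders.values()) if orders else 0,
                node_idx=nodes,
                points=neuron.xyz[nodes],
                local_parent=local_parent,
            )
        )
    return arbors
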