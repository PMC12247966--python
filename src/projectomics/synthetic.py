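"""Synthetic atlases and neuron populations with planted ground truth.

Generates toy block-partitioned region atlases (layered cortical areas in
two hemispheres plus subcortical blocks) and SWC neuron populations whose
statistical structure mirrors what the pipeline measures on real
reconstructions: per-cell-type projection profiles (target sets,
probabilities, mean axonal lengths, laminar preferences, ipsi/contra
ratios), smooth soma-to-target topographic gradients (aligned or
reversed), a planted region hierarchy driving targeting probabilities,
and distinct dendritic templates per cell type for morphometric
clustering.

Axonal arbors are grown as confined branching random walks (a fixed
depth-2 binary topology over reflecting polyline walks), which guarantees
every intended target arbor has terminals and a second-order bifurcation
and therefore passes the projection-target filter, while the straight
paths routed from the soma to each target read out as passing fibers
(unbranched, terminal-free) in intervening regions.  Biological realism
is deliberately limited to what the analyses consume: lengths, terminal
counts, branch orders and point clouds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .morphology import (
    APICAL,
    AXON,
    BASAL,
    SOMA,
    NeuronReconstruction,
    RegionAtlas,
    write_swc,
)

__all__ = [
    "AtlasSpec",
    "ProjectionTarget",
    "CellTypeSpec",
    "GeneratorConfig",
    "SyntheticPopulation",
    "generate_atlas",
    "generate_population",
    "write_population",
    "default_config",
    "topography_config",
    "hierarchy_config",
    "clustering_config",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class AtlasSpec:
    """Block layout of the toy atlas.

    Cortical areas are laid out along z, layers stacked along y (y = 0 at
    the pia), hemispheres mirrored about the midline plane x = W.
    Subcortical blocks sit below the deepest layer.
    """

    areas: tuple = ("A1", "A2", "A3", "A4", "A5")
    layers: tuple = ("L2/3", "L5")
    subcortical: tuple = ("TH", "CP")
    area_size: float = 400.0          # μm along z
    layer_thickness: float = 200.0    # μm along y
    subcortical_thickness: float = 400.0
    hemisphere_width: float = 600.0   # μm along x
    voxel_size: float = 20.0
    hierarchy_levels: dict = field(default_factory=dict)   # area -> level h
    groups: dict = field(default_factory=dict)             # area -> group

    @property
    def z_extent(self) -> float:
        return len(self.areas) * self.area_size

    @property
    def cortex_depth(self) -> float:
        return len(self.layers) * self.layer_thickness

    def area_box(self, area: str, hemisphere: str, layer: str | None = None):
        """(lo, hi) bounds of an area block (one layer or full region)."""
        w = self.hemisphere_width
        x0, x1 = (0.0, w) if hemisphere == "left" else (w, 2 * w)
        if area in self.areas:
            k = self.areas.index(area)
            z0, z1 = k * self.area_size, (k + 1) * self.area_size
            if layer is None:
                y0, y1 = 0.0, self.cortex_depth
            else:
                m = self.layers.index(layer)
                y0 = m * self.layer_thickness
                y1 = y0 + self.layer_thickness
        else:
            k = self.subcortical.index(area)
            width = self.z_extent / len(self.subcortical)
            z0, z1 = k * width, (k + 1) * width
            y0 = self.cortex_depth
            y1 = y0 + self.subcortical_thickness
        return np.array([x0, y0, z0]), np.array([x1, y1, z1])


@dataclass
class ProjectionTarget:
    """One entry of a cell type's projection profile."""

    area: str
    probability: float                 # per-cell chance of targeting (ipsi)
    mean_axl: float                    # planted mean in-region axon length, μm
    laminar_weights: dict | None = None  # layer -> weight (cortical targets)
    contra_probability: float = 0.0
    contra_ratio: float = 1.0          # contra mean AxL = ratio x ipsi mean
    via: str | None = None             # route the path through this area


@dataclass
class CellTypeSpec:
    name: str
    n_cells: int
    source_area: str
    targets: list = field(default_factory=list)
    dendrite_template: str = "tufted"  # tufted/untufted/inverted/horizontal/stellate
    soma_layer: str = "L5"
    local_axl: float = 3000.0          # local axon near the soma, μm
    axl_cv: float = 0.1                # lognormal-ish spread of arbor lengths
    topography: str = "none"           # aligned / reversed / none
    topography_sigma: float = 30.0     # μm noise on the planted gradient


@dataclass
class GeneratorConfig:
    seed: int = 0
    atlas: AtlasSpec = field(default_factory=AtlasSpec)
    cell_types: list = field(default_factory=list)


@dataclass
class SyntheticPopulation:
    neurons: list
    atlas: RegionAtlas
    cell_meta: pd.DataFrame            # indexed by cell_id
    planted_targets: pd.DataFrame      # per (cell_type, area, hemisphere)
    realized_targets: pd.DataFrame     # per cell realized target draws
    config: GeneratorConfig


# ---------------------------------------------------------------------------
# atlas generation
# ---------------------------------------------------------------------------

def generate_atlas(spec: AtlasSpec) -> RegionAtlas:
    """Build the block-partitioned label volume and region table."""
    v = spec.voxel_size
    shape = (
        int(round(2 * spec.hemisphere_width / v)),
        int(round((spec.cortex_depth + (spec.subcortical_thickness
                                        if spec.subcortical else 0.0)) / v)),
        int(round(spec.z_extent / v)),
    )
    labels = np.zeros(shape, dtype=np.int32)
    rows = []
    label = 0
    for hemi in ("left", "right"):
        for area in spec.areas:
            for layer in spec.layers:
                label += 1
                lo, hi = spec.area_box(area, hemi, layer)
                _fill(labels, lo, hi, v, label)
                rows.append((label, f"{area}_{layer}_{hemi}", area, layer,
                             spec.groups.get(area, "cortex"), hemi,
                             spec.hierarchy_levels.get(area, np.nan)))
        for area in spec.subcortical:
            label += 1
            lo, hi = spec.area_box(area, hemi)
            _fill(labels, lo, hi, v, label)
            rows.append((label, f"{area}_{hemi}", area, None,
                         spec.groups.get(area, "subcortical"), hemi,
                         spec.hierarchy_levels.get(area, np.nan)))
    regions = pd.DataFrame(
        rows,
        columns=["region_id", "name", "area", "layer", "group",
                 "hemisphere", "hierarchy_level"],
    ).set_index("region_id")
    return RegionAtlas(
        labels=labels,
        voxel_size=v,
        origin=np.zeros(3),
        midline=spec.hemisphere_width,
        regions=regions,
    )


def _fill(labels, lo, hi, v, value) -> None:
    i0 = np.round(lo / v).astype(int)
    i1 = np.round(hi / v).astype(int)
    block = labels[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]]
    if (block != 0).any():
        raise ValueError("overlapping region blocks in atlas spec")
    block[:] = value


# ---------------------------------------------------------------------------
# neuron construction
# ---------------------------------------------------------------------------

class _Builder:
    """Incremental SWC node list (ids dense from 1)."""

    def __init__(self, cell_id: str):
        self.cell_id = cell_id
        self.comp: list[int] = []
        self.xyz: list[np.ndarray] = []
        self.parent: list[int] = []

    def add(self, parent: int, pos, comp: int) -> int:
        self.comp.append(comp)
        self.xyz.append(np.asarray(pos, dtype=np.float64))
        self.parent.append(parent)
        return len(self.comp) - 1

    def build(self, metadata: dict) -> NeuronReconstruction:
        n = len(self.comp)
        return NeuronReconstruction(
            cell_id=self.cell_id,
            node_id=np.arange(1, n + 1),
            compartment=np.array(self.comp),
            xyz=np.array(self.xyz),
            radius=np.full(n, 0.5),
            parent=np.array(self.parent),
            metadata=metadata,
        )


def _unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _walk(rng, b: _Builder, parent: int, start, n_steps: int, step: float,
          lo, hi, comp: int = AXON) -> int:
    """Reflecting persistent random walk; returns the last node index."""
    pos = np.asarray(start, dtype=np.float64).copy()
    direction = _unit(rng)
    node = parent
    for _ in range(n_steps):
        direction = direction + 0.8 * _unit(rng)
        direction /= np.linalg.norm(direction)
        for ax in range(3):
            nxt = pos[ax] + step * direction[ax]
            if nxt < lo[ax] or nxt > hi[ax]:
                direction[ax] = -direction[ax]
        pos = pos + step * direction
        pos = np.clip(pos, lo, hi)
        node = b.add(node, pos, comp)
    return node


def _grow_arbor(rng, b: _Builder, parent: int, entry, lo, hi,
                budget: float) -> None:
    """Depth-2 binary branching walk of total length ~ ``budget``.

    Topology: trunk -> bifurcation -> 2 branches -> bifurcations -> 4
    leaves, guaranteeing >= 1 terminal and a second-order bifurcation so
    intended targets pass the projection filter.
    """
    n_edges = 7
    n_steps = max(2 * n_edges, int(round(budget / 15.0)))
    step = budget / n_steps
    extra = rng.multinomial(n_steps - 2 * n_edges, np.full(n_edges, 1 / n_edges))
    alloc = 2 + extra
    trunk_end = _walk(rng, b, parent, entry, int(alloc[0]), step, lo, hi)
    e = 1
    for _ in range(2):
        branch_end = _walk(rng, b, trunk_end, b.xyz[trunk_end],
                           int(alloc[e]), step, lo, hi)
        e += 1
        for _ in range(2):
            _walk(rng, b, branch_end, b.xyz[branch_end],
                  int(alloc[e]), step, lo, hi)
            e += 1


def _path(rng, b: _Builder, parent: int, start, end, step: float = 50.0) -> int:
    """Straight subdivided polyline (a passing fiber en route)."""
    start = np.asarray(start, float)
    end = np.asarray(end, float)
    length = float(np.linalg.norm(end - start))
    n = max(1, int(np.ceil(length / step)))
    node = parent
    for k in range(1, n + 1):
        node = b.add(node, start + (end - start) * k / n, AXON)
    return node


def _seg_length_in_box(points: np.ndarray, lo, hi) -> float:
    """Length of polyline segments whose child endpoint lies in the box."""
    if len(points) < 2:
        return 0.0
    child = points[1:]
    inside = np.all((child >= lo) & (child < hi), axis=1)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return float(seg[inside].sum())


# dendrite templates: (trunk direction, trunk length, tuft depth, tuft spread)
_DENDRITE_TEMPLATES = {
    "tufted": {"trunk": 260.0, "direction": -1, "depth": 2, "spread": 70.0},
    "untufted": {"trunk": 180.0, "direction": -1, "depth": 1, "spread": 25.0},
    "inverted": {"trunk": 120.0, "direction": +1, "depth": 1, "spread": 45.0},
    "horizontal": {"trunk": 150.0, "direction": 0, "depth": 1, "spread": 35.0},
    "stellate": {"trunk": 35.0, "direction": -1, "depth": 0, "spread": 50.0},
}


def _grow_dendrites(rng, b: _Builder, soma_idx: int, soma, template: str,
                    lo, hi) -> None:
    t = _DENDRITE_TEMPLATES[template]
    scale = 1.0 + 0.05 * rng.normal()
    # apical: trunk along the depth axis (y), then a binary tuft
    if t["direction"] == 0:
        axis = np.array([0.0, 0.0, 1.0])
    else:
        axis = np.array([0.0, float(t["direction"]), 0.0])
    trunk_len = t["trunk"] * scale
    n_seg = 5
    node = soma_idx
    pos = soma.copy()
    for k in range(n_seg):
        pos = np.clip(pos + axis * trunk_len / n_seg
                      + rng.normal(scale=2.0, size=3), lo, hi)
        node = b.add(node, pos, APICAL)
    frontier = [node]
    for _ in range(t["depth"] if t["depth"] else 1):
        new = []
        k = 2 if t["depth"] else 4  # stellate: one whorl of 4 short branches
        for f in frontier:
            for _ in range(k):
                d = _unit(rng)
                d = d - (d @ axis) * axis * 0.5  # open the tuft sideways
                d /= np.linalg.norm(d)
                tip = np.clip(b.xyz[f] + d * t["spread"] * scale, lo, hi)
                mid = np.clip(b.xyz[f] + d * t["spread"] * scale * 0.5, lo, hi)
                m = b.add(f, mid, APICAL)
                new.append(b.add(m, tip, APICAL))
        frontier = new
    # basal: three short bifurcating branches around the soma
    for _ in range(3):
        d = _unit(rng)
        d[1] = abs(d[1]) * 0.5  # bias away from the pia
        d /= np.linalg.norm(d)
        m = b.add(soma_idx, np.clip(soma + d * 40 * scale, lo, hi), BASAL)
        for _ in range(2):
            e = _unit(rng)
            b.add(m, np.clip(b.xyz[m] + e * 30 * scale, lo, hi), BASAL)


# ---------------------------------------------------------------------------
# population generation
# ---------------------------------------------------------------------------

def generate_population(config: GeneratorConfig) -> SyntheticPopulation:
    """Realize the configured cell types as SWC neuron trees.

    Somata are placed in the left hemisphere of their source area; each
    profile entry is drawn per cell (Bernoulli on the targeting
    probability, arbor length lognormal around the planted mean), arbors
    are confined branching walks inside the target block, and topographic
    modes map the soma's position along the area-layout axis onto the
    arbor center (aligned), its mirror (reversed), or uniformly (none).
    Seeded runs are bit-reproducible.
    """
    rng = np.random.default_rng(config.seed)
    spec = config.atlas
    atlas = generate_atlas(spec)
    vol_lo = np.zeros(3)
    vol_hi = np.array([2 * spec.hemisphere_width,
                       spec.cortex_depth + (spec.subcortical_thickness
                                            if spec.subcortical else 0.0),
                       spec.z_extent])

    neurons, meta_rows, realized_rows = [], [], []
    planted_rows = []
    counter = 0
    known = set(spec.areas) | set(spec.subcortical)
    for ct in config.cell_types:
        unknown = {t.area for t in ct.targets} - known
        if unknown or ct.source_area not in known:
            raise ValueError(
                f"cell type {ct.name!r} references areas absent from the "
                f"atlas: {sorted(unknown | ({ct.source_area} - known))}"
            )
        for tgt in ct.targets:
            planted_rows.append((ct.name, tgt.area, "ipsi",
                                 tgt.probability, tgt.mean_axl))
            if tgt.contra_probability > 0:
                planted_rows.append((ct.name, tgt.area, "contra",
                                     tgt.contra_probability,
                                     tgt.mean_axl * tgt.contra_ratio))
        src_lo, src_hi = spec.area_box(ct.source_area, "left", ct.soma_layer)
        for _ in range(ct.n_cells):
            counter += 1
            cell_id = f"{ct.name}_{counter:04d}"
            b = _Builder(cell_id)
            margin = 20.0
            soma = rng.uniform(src_lo + margin, src_hi - margin)
            soma_idx = b.add(-1, soma, SOMA)
            _grow_dendrites(rng, b, soma_idx, soma, ct.dendrite_template,
                            vol_lo, vol_hi)

            # plan distal targets first so local budget can be corrected
            # for path length spent inside the source block
            plans = []
            for tgt in ct.targets:
                for hemi, prob, mean_axl in (
                    ("left", tgt.probability, tgt.mean_axl),
                    ("right", tgt.contra_probability,
                     tgt.mean_axl * tgt.contra_ratio),
                ):
                    if rng.random() >= prob:
                        continue
                    layer = None
                    if tgt.area in spec.areas:
                        weights = tgt.laminar_weights or {
                            la: 1.0 for la in spec.layers
                        }
                        names = list(weights)
                        w = np.array([weights[n] for n in names], float)
                        layer = names[rng.choice(len(names), p=w / w.sum())]
                    lo, hi = spec.area_box(tgt.area, hemi, layer)
                    axl = float(mean_axl * np.exp(
                        rng.normal(0.0, ct.axl_cv) - ct.axl_cv ** 2 / 2))
                    center = _arbor_center(rng, ct, spec, soma, src_lo,
                                           src_hi, lo, hi, axl)
                    plans.append((tgt, hemi, layer, lo, hi, center, axl))
                    realized_rows.append(
                        {"cell_id": cell_id, "cell_type": ct.name,
                         "area": tgt.area,
                         "hemisphere": "ipsi" if hemi == "left" else "contra",
                         "planted_axl": axl})

            used_in_source = 0.0
            for tgt, hemi, layer, lo, hi, (center, hw), axl in plans:
                entry = _box_entry(center, hw, soma)
                # pre-trace the path to correct arbor budget for the length
                # the path itself deposits inside the target block
                if tgt.via is not None:
                    via_lo, via_hi = spec.area_box(tgt.via, hemi)
                    waypoint = (via_lo + via_hi) / 2
                    pts = np.vstack([
                        _polyline_points(soma, waypoint, step=50.0),
                        _polyline_points(waypoint, entry, step=50.0)[1:],
                    ])
                else:
                    pts = _polyline_points(soma, entry, step=50.0)
                tgt_lo, tgt_hi = spec.area_box(tgt.area, hemi)
                in_target = _seg_length_in_box(pts, tgt_lo, tgt_hi)
                used_in_source += _seg_length_in_box(
                    pts, *spec.area_box(ct.source_area, "left"))
                node = soma_idx
                for p in pts[1:]:
                    node = b.add(node, p, AXON)
                budget = max(60.0, axl - in_target)
                _grow_arbor(rng, b, node, entry, center - hw, center + hw,
                            budget)

            # local axonal arbor in the soma's own block
            local_budget = max(200.0, ct.local_axl - used_in_source)
            loc_lo, loc_hi = spec.area_box(ct.source_area, "left")
            hw = np.minimum((loc_hi - loc_lo) / 2 - 5, 120.0)
            c = np.clip(soma, loc_lo + hw, loc_hi - hw)
            _grow_arbor(rng, b, soma_idx, soma, c - hw, c + hw, local_budget)

            neurons.append(b.build({"cell_type": ct.name,
                                    "source_area": ct.source_area}))
            meta_rows.append({"cell_id": cell_id, "cell_type": ct.name,
                              "source_area": ct.source_area,
                              "soma_x": soma[0], "soma_y": soma[1],
                              "soma_z": soma[2], "hemisphere": "left"})

    cell_meta = pd.DataFrame(meta_rows).set_index("cell_id")
    planted = pd.DataFrame(
        planted_rows,
        columns=["cell_type", "area", "hemisphere", "probability", "mean_axl"],
    )
    return SyntheticPopulation(
        neurons=neurons, atlas=atlas, cell_meta=cell_meta,
        planted_targets=planted,
        realized_targets=pd.DataFrame(realized_rows), config=config,
    )


def _arbor_center(rng, ct: CellTypeSpec, spec: AtlasSpec, soma, src_lo,
                  src_hi, lo, hi, axl):
    """Arbor sub-box (center, half-width) honoring the topography mode."""
    hw_scalar = float(np.clip(axl / 25.0, 25.0, 140.0))
    hw = np.minimum((hi - lo) / 2 - 5.0, hw_scalar)
    center = rng.uniform(lo + hw, hi - hw)
    if ct.topography in ("aligned", "reversed"):
        # plant the gradient from the widest source axis (the soma set's
        # principal direction) onto the widest target axis, so the
        # principal-axis projections of the analysis see the mapping
        src_ax = int(np.argmax(src_hi - src_lo))
        tgt_ax = int(np.argmax(hi - lo))
        rel = (soma[src_ax] - src_lo[src_ax]) / (src_hi[src_ax] - src_lo[src_ax])
        if ct.topography == "reversed":
            rel = 1.0 - rel
        z = lo[tgt_ax] + hw[tgt_ax] + rel * (hi[tgt_ax] - lo[tgt_ax] - 2 * hw[tgt_ax])
        z += rng.normal(0.0, ct.topography_sigma)
        center[tgt_ax] = float(np.clip(z, lo[tgt_ax] + hw[tgt_ax],
                                       hi[tgt_ax] - hw[tgt_ax]))
    return center, hw


def _box_entry(center, hw, soma) -> np.ndarray:
    """Point on the arbor sub-box surface nearest-aligned with the soma."""
    delta = soma - center
    scale = np.inf
    for ax in range(3):
        if abs(delta[ax]) > 1e-9:
            scale = min(scale, hw[ax] / abs(delta[ax]))
    if not np.isfinite(scale):
        return center.copy()
    return center + delta * min(1.0, scale)


def _polyline_points(start, end, step: float) -> np.ndarray:
    start = np.asarray(start, float)
    end = np.asarray(end, float)
    n = max(1, int(np.ceil(np.linalg.norm(end - start) / step)))
    t = np.linspace(0.0, 1.0, n + 1)[:, None]
    return start + t * (end - start)


def write_population(pop: SyntheticPopulation, outdir) -> None:
    """Emit SWC files, the atlas and the ground-truth tables."""
    outdir = Path(outdir)
    (outdir / "swc").mkdir(parents=True, exist_ok=True)
    for n in pop.neurons:
        write_swc(n, outdir / "swc" / f"{n.cell_id}.swc")
    pop.atlas.save(outdir / "atlas")
    pop.cell_meta.to_csv(outdir / "cell_meta.tsv", sep="\t")
    pop.planted_targets.to_csv(outdir / "planted_targets.tsv", sep="\t",
                               index=False)
    pop.realized_targets.to_csv(outdir / "realized_targets.tsv", sep="\t",
                                index=False)


# ---------------------------------------------------------------------------
# scenario factories (the study conditions of the synthetic experiments)
# ---------------------------------------------------------------------------

def default_config(seed: int = 0, n_cells: int = 200) -> GeneratorConfig:
    """Mixed-population scenario: two cell types with cortical and
    subcortical profiles, bilateral projections and laminar preferences."""
    atlas = AtlasSpec(hierarchy_levels={f"A{i}": float(i) for i in range(1, 6)})
    ct_it = CellTypeSpec(
        name="IT_like", n_cells=n_cells, source_area="A1",
        dendrite_template="tufted",
        targets=[
            ProjectionTarget("A3", probability=0.9, mean_axl=2500.0,
                             laminar_weights={"L2/3": 0.6, "L5": 0.4},
                             contra_probability=0.6, contra_ratio=0.5),
            ProjectionTarget("A5", probability=0.3, mean_axl=800.0),
            ProjectionTarget("CP", probability=0.6, mean_axl=1500.0),
        ],
    )
    ct_et = CellTypeSpec(
        name="ET_like", n_cells=n_cells, source_area="A2",
        dendrite_template="untufted",
        targets=[
            ProjectionTarget("TH", probability=0.9, mean_axl=3000.0),
            ProjectionTarget("CP", probability=0.5, mean_axl=1200.0),
            ProjectionTarget("A4", probability=0.25, mean_axl=600.0),
        ],
    )
    return GeneratorConfig(seed=seed, atlas=atlas, cell_types=[ct_it, ct_et])


def topography_config(mode: str, seed: int = 0, n_cells: int = 50,
                      sigma: float = 30.0) -> GeneratorConfig:
    """One type projecting to one target with a planted soma->target
    gradient along the area-layout axis (aligned or reversed)."""
    atlas = AtlasSpec()
    ct = CellTypeSpec(
        name=f"topo_{mode}", n_cells=n_cells, source_area="A1",
        topography=mode, topography_sigma=sigma,
        targets=[ProjectionTarget("TH", probability=1.0, mean_axl=2000.0)],
    )
    return GeneratorConfig(seed=seed, atlas=atlas, cell_types=[ct])


def hierarchy_config(seed: int = 0, n_cells: int = 200,
                     n_levels: int = 5) -> GeneratorConfig:
    """Planted hierarchy: each area's level drives how often it is
    targeted by every other area (P from 0.1 up to 0.9 with level)."""
    areas = tuple(f"A{i}" for i in range(1, n_levels + 1))
    levels = {a: float(i + 1) for i, a in enumerate(areas)}
    atlas = AtlasSpec(areas=areas, subcortical=("TH",),
                      hierarchy_levels=levels)
    types = []
    for src in areas:
        targets = [
            ProjectionTarget(
                a,
                probability=0.1 + 0.8 * (levels[a] - 1) / (n_levels - 1),
                mean_axl=1500.0,
            )
            for a in areas if a != src
        ]
        types.append(CellTypeSpec(name=f"{src}_pyr", n_cells=n_cells,
                                  source_area=src, targets=targets))
    return GeneratorConfig(seed=seed, atlas=atlas, cell_types=types)


def clustering_config(seed: int = 0, n_cells: int = 60) -> GeneratorConfig:
    """Three cell types with well-separated dendritic templates for the
    morphometric clustering and classification checks."""
    atlas = AtlasSpec()
    templates = [("tufted_type", "tufted"), ("stellate_type", "stellate"),
                 ("inverted_type", "inverted")]
    types = [
        CellTypeSpec(name=name, n_cells=n_cells, source_area="A1",
                     dendrite_template=tpl,
                     targets=[ProjectionTarget("A3", 0.5, 1500.0)])
        for name, tpl in templates
    ]
    return GeneratorConfig(seed=seed, atlas=atlas, cell_types=types)
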