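"""Projection-target calling and connectome matrices.

Turns per-(cell, region, hemisphere) axonal arbors into called projection
targets and aggregates them into targeting-probability / targeting-strength
matrices:

* **TargProb** — percentage of cells of a (cell type, source area) group
  whose arbor in a (target region, hemisphere) column passes the target
  filter.
* **TargStren** (AxL/C, μm) — mean axonal length over the passing cells.

The target filter is designed to exclude passing fibers and tracing
artefacts while keeping weak but genuine projections: long arborizations
(> 1000 μm) need at least one terminal node; intermediate ones
(20–1000 μm) need a terminal node and a second-order bifurcation; anything
under 20 μm is rejected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .morphology import Arbor, RegionAtlas

__all__ = [
    "call_target",
    "projection_records",
    "ConnectomeMatrix",
    "build_connectome",
    "weak_target_summary",
    "laminar_profile",
    "hemispheric_symmetry",
]

LONG_THRESHOLD_UM = 1000.0
SHORT_THRESHOLD_UM = 20.0


def call_target(axon_length, n_terminals, max_branch_order,
                long_threshold: float = LONG_THRESHOLD_UM,
                short_threshold: float = SHORT_THRESHOLD_UM):
    """Decide whether an arbor counts as a genuine projection target.

    Vectorized over array inputs.  Rules:

    * ``AxL > long_threshold``  -> pass iff >= 1 terminal node;
    * ``short_threshold <= AxL <= long_threshold`` -> pass iff >= 1 terminal
      node and a second-order bifurcation (max within-arbor branch
      order >= 2);
    * ``AxL < short_threshold`` -> fail.
    """
    axl = np.asarray(axon_length, dtype=np.float64)
    term = np.asarray(n_terminals)
    order = np.asarray(max_branch_order)
    long_pass = (axl > long_threshold) & (term >= 1)
    mid_pass = (axl >= short_threshold) & (axl <= long_threshold) \
        & (term >= 1) & (order >= 2)
    out = long_pass | mid_pass
    return bool(out) if out.ndim == 0 else out


def projection_records(arbors: list[Arbor], cell_meta: pd.DataFrame,
                       atlas: RegionAtlas,
                       long_threshold: float = LONG_THRESHOLD_UM,
                       short_threshold: float = SHORT_THRESHOLD_UM) -> pd.DataFrame:
    """Tidy table of projection records, one row per arbor.

    ``cell_meta`` is indexed by cell id with columns ``cell_type`` and
    ``source_area``.  Target regions are reported by the atlas ``area``
    grouping (hemisphere-paired labels collapse onto one area, with the
    ipsi/contra tag carrying the side), and the atlas ``layer`` column is
    propagated for laminar profiles.
    """
    rows = []
    reg = atlas.regions
    for a in arbors:
        meta = cell_meta.loc[a.cell_id]
        area = reg.at[a.region_id, "area"] if "area" in reg.columns \
            else reg.at[a.region_id, "name"]
        layer = reg.at[a.region_id, "layer"] if "layer" in reg.columns else None
        rows.append(
            {
                "cell_id": a.cell_id,
                "cell_type": meta["cell_type"],
                "source_area": meta["source_area"],
                "region_id": a.region_id,
                "target_region": area,
                "layer": layer,
                "hemisphere": a.hemisphere,
                "axon_length": a.axon_length,
                "n_terminals": a.n_terminals,
                "max_branch_order": a.max_branch_order_within,
            }
        )
    records = pd.DataFrame(rows)
    if len(records):
        records["passes_filter"] = call_target(
            records["axon_length"], records["n_terminals"],
            records["max_branch_order"], long_threshold, short_threshold,
        )
    return records


@dataclass
class ConnectomeMatrix:
    """(cell type, source area) x (target region, hemisphere) connectome.

    ``table`` is the tidy long form with TargProb (percent), TargStren
    (mean AxL over passing cells, μm) and the passing-cell count;
    ``n_cells`` and ``target_number`` are per row group.
    """

    table: pd.DataFrame
    n_cells: pd.Series
    target_number: pd.Series

    def targprob(self) -> pd.DataFrame:
        return self.table.pivot_table(
            index=["cell_type", "source_area"],
            columns=["target_region", "hemisphere"],
            values="TargProb", fill_value=0.0,
        )

    def targstren(self) -> pd.DataFrame:
        return self.table.pivot_table(
            index=["cell_type", "source_area"],
            columns=["target_region", "hemisphere"],
            values="TargStren",
        )


def build_connectome(records: pd.DataFrame, cell_meta: pd.DataFrame) -> ConnectomeMatrix:
    """Aggregate projection records into a :class:`ConnectomeMatrix`.

    TargProb = 100 x (passing cells in column) / (cells in row group);
    TargStren = mean axon length over the passing cells only.  Cells with a
    missing type label are excluded (with a warning); groups with no cells
    are dropped.
    """
    meta = cell_meta.copy()
    unlabeled = meta["cell_type"].isna()
    if unlabeled.any():
        warnings.warn(f"excluding {int(unlabeled.sum())} cells with no type label")
        meta = meta[~unlabeled]
    group_sizes = meta.groupby(["cell_type", "source_area"], observed=True).size()

    recs = records[records["cell_id"].isin(meta.index)]
    passing = recs[recs["passes_filter"]]
    rows = []
    grouped = passing.groupby(
        ["cell_type", "source_area", "target_region", "hemisphere"], observed=True
    )
    for (ctype, src, target, hemi), g in grouped:
        n = int(group_sizes.get((ctype, src), 0))
        if n == 0:
            continue
        n_pass = g["cell_id"].nunique()
        rows.append(
            {
                "cell_type": ctype,
                "source_area": src,
                "target_region": target,
                "hemisphere": hemi,
                "TargProb": 100.0 * n_pass / n,
                "TargStren": g.groupby("cell_id")["axon_length"].sum().mean(),
                "n_pass": n_pass,
            }
        )
    table = pd.DataFrame(
        rows, columns=["cell_type", "source_area", "target_region",
                       "hemisphere", "TargProb", "TargStren", "n_pass"]
    )
    target_number = (
        table[table["TargProb"] > 0]
        .groupby(["cell_type", "source_area"], observed=True)
        .size()
        .reindex(group_sizes.index, fill_value=0)
    )
    return ConnectomeMatrix(table=table, n_cells=group_sizes,
                            target_number=target_number)


def weak_target_summary(matrix: ConnectomeMatrix,
                        axl_cut: float = 1000.0,
                        prob_cut: float = 2.4) -> tuple[float, float]:
    """Fractions of called targets stronger than the weak-target cuts.

    A target is a (row group, target region, hemisphere) entry with
    TargProb > 0.  Returns (fraction with TargStren > ``axl_cut`` μm,
    fraction with TargProb > ``prob_cut`` percent).
    """
    t = matrix.table[matrix.table["TargProb"] > 0]
    if not len(t):
        raise ValueError("empty connectome matrix")
    return (
        float((t["TargStren"] > axl_cut).mean()),
        float((t["TargProb"] > prob_cut).mean()),
    )


def laminar_profile(records: pd.DataFrame, target_area, n_cells: int | None = None,
                    hemisphere: str = "ipsi") -> tuple[pd.Series, bool]:
    """Per-layer TargProb in a target area, normalized to the maximum layer.

    Returns (profile, ok).  Values lie in [0, 1] with the most-targeted
    layer exactly 1; an all-zero profile is returned unchanged with
    ``ok=False``.
    """
    recs = records[(records["target_region"] == target_area)
                   & (records["hemisphere"] == hemisphere)]
    layers = sorted(recs["layer"].dropna().unique().tolist())
    if not layers:
        raise ValueError(f"target area {target_area!r} has no layer subregions")
    if n_cells is None:
        n_cells = records["cell_id"].nunique()
    prob = pd.Series(0.0, index=pd.Index(layers, name="layer"))
    for layer in layers:
        g = recs[(recs["layer"] == layer) & recs["passes_filter"]]
        prob[layer] = 100.0 * g["cell_id"].nunique() / n_cells
    peak = prob.max()
    if peak <= 0:
        return prob, False
    return prob / peak, True


def hemispheric_symmetry(matrix: ConnectomeMatrix, cell_type, source_area,
                         n_perm: int = 10_000, seed: int = 0):
    """Pearson r between ipsi- and contralateral TargProb over paired regions.

    Target areas present on either side enter the paired vectors (absent
    side filled with 0).  Returns (r, permutation p-value, ok); a
    zero-variance vector yields (nan, nan, False).
    """
    t = matrix.table
    t = t[(t["cell_type"] == cell_type) & (t["source_area"] == source_area)]
    wide = t.pivot_table(index="target_region", columns="hemisphere",
                         values="TargProb", fill_value=0.0)
    for side in ("ipsi", "contra"):
        if side not in wide.columns:
            wide[side] = 0.0
    if len(wide) < 3:
        raise ValueError("need >= 3 paired target regions")
    x = wide["ipsi"].to_numpy(float)
    y = wide["contra"].to_numpy(float)
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan"), False
    r = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        rp = np.corrcoef(x, rng.permutation(y))[0, 1]
        if abs(rp) >= abs(r) - 1e-12:
            count += 1
    return r, (count + 1) / (n_perm + 1), True
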