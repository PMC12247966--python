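"""Region hierarchy scores and feedforward/feedback bias of cell types.

Hierarchy score
---------------
If a region sits higher in the flow of information it should be targeted
more often by lower regions, so the hierarchy score of target region ``j``
aggregates the targeting probability from every source ``i``, normalized
by the average targeting length (the spatial extent of the axonal
clusters, which removes region-size bias):

    score(j) = sum_{i != j} P(i -> j) / Lbar(i -> j)

with ``P`` a fraction in [0, 1] and ``Lbar`` in μm (mean axon length over
the cells that pass the target filter).

Feedforward/feedback classification
-----------------------------------
Given externally supplied hierarchy levels ``h`` per region, each
connection j -> i contributes a hierarchy difference ``Δh = h_i − h_j``.
Per cell type, the Δh distribution is compared against variance-matched
zero-mean Gaussian reference samples with the two-sample Wilcoxon
rank-sum test (median p over seeded reference draws), p-values are
Benjamini–Hochberg corrected across types, and a type is called FF when
the adjusted p is below α with mean Δh > 0 (FB when the mean is
negative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata, wilcoxon
from statsmodels.stats.multitest import multipletests

from .projectome import ConnectomeMatrix

__all__ = [
    "hierarchy_score",
    "connectome_score_inputs",
    "score_correlates",
    "FFFBResult",
    "fffb_classify",
    "ranksum_pvalues",
]


def hierarchy_score(targprob: pd.DataFrame, mean_length: pd.DataFrame) -> pd.DataFrame:
    """Hierarchy score per target region from P and Lbar matrices.

    ``targprob`` holds targeting-probability fractions (source regions in
    rows, target regions in columns) and ``mean_length`` the matching
    average targeting lengths in μm.  Entries with ``P > 0`` but no
    length raise an error naming the pair; the ``i = j`` diagonal is
    excluded.  Returns a table with ``score`` and dense ``rank``
    (1 = highest score).
    """
    p = targprob.astype(float)
    lbar = mean_length.reindex(index=p.index, columns=p.columns).astype(float)
    bad = (p > 0) & ~(lbar > 0)
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"P > 0 with missing mean length for pair ({p.index[i]!r}, {p.columns[j]!r})"
        )
    scores = {}
    for target in p.columns:
        mask = p[target] > 0
        if target in p.index:
            mask = mask & (p.index != target)
        scores[target] = float((p[target][mask] / lbar[target][mask]).sum())
    table = pd.DataFrame({"score": pd.Series(scores)})
    table["rank"] = table["score"].rank(ascending=False, method="dense").astype(int)
    return table.sort_values("score", ascending=False)


def connectome_score_inputs(matrix: ConnectomeMatrix, hemisphere: str = "ipsi"):
    """P (fraction) and Lbar matrices for :func:`hierarchy_score`.

    Rows are source areas (cell types pooled by weighted mean over cells),
    columns target regions of the requested hemisphere.
    """
    t = matrix.table[matrix.table["hemisphere"] == hemisphere].copy()
    n = matrix.n_cells.rename("n_cells")
    t = t.join(n, on=["cell_type", "source_area"])
    t["n_pass_w"] = t["TargProb"] / 100.0 * t["n_cells"]
    grp = t.groupby(["source_area", "target_region"], observed=True)
    n_src = matrix.n_cells.groupby("source_area").sum()
    p = (grp["n_pass_w"].sum() / n_src).unstack(fill_value=0.0)
    t["_len_sum"] = t["TargStren"] * t["n_pass"]
    grp = t.groupby(["source_area", "target_region"], observed=True)
    lbar = (grp["_len_sum"].sum() / grp["n_pass"].sum()).unstack()
    p.index.name = lbar.index.name = "source_area"
    return p, lbar


def score_correlates(table: pd.DataFrame, covariates: pd.DataFrame,
                     n_perm: int = 10_000, seed: int = 0) -> pd.DataFrame:
    """Pearson correlation of the hierarchy score with targeting covariates.

    ``covariates`` (indexed like ``table``) typically holds target number,
    mean TargProb and mean TargStren per region.  Permutation p-values
    (two-sided, seeded).  Constant vectors are flagged with NaN.
    """
    if len(table) < 5:
        raise ValueError("need >= 5 regions")
    score = table["score"].to_numpy(float)
    rng = np.random.default_rng(seed)
    rows = {}
    for col in covariates.columns:
        y = covariates.reindex(table.index)[col].to_numpy(float)
        if np.std(score) == 0 or np.std(y) == 0:
            rows[col] = {"r": float("nan"), "p": float("nan")}
            continue
        r = float(np.corrcoef(score, y)[0, 1])
        perm = np.array([
            np.corrcoef(score, rng.permutation(y))[0, 1] for _ in range(n_perm)
        ])
        rows[col] = {"r": r, "p": float(((np.abs(perm) >= abs(r) - 1e-12).sum() + 1)
                                        / (n_perm + 1))}
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# FF/FB classification
# ---------------------------------------------------------------------------

def ranksum_pvalues(sample: np.ndarray, refs: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p of ``sample`` vs each row of ``refs``.

    Vectorized normal-approximation rank-sum test, identical to
    ``scipy.stats.ranksums`` applied row by row.
    """
    sample = np.asarray(sample, dtype=np.float64)
    refs = np.atleast_2d(np.asarray(refs, dtype=np.float64))
    n1, (m, n2) = len(sample), refs.shape
    combined = np.concatenate(
        [np.broadcast_to(sample, (m, n1)), refs], axis=1
    )
    ranks = rankdata(combined, axis=1)
    s = ranks[:, :n1].sum(axis=1)
    expected = n1 * (n1 + n2 + 1) / 2.0
    sd = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    z = (s - expected) / sd
    return 2 * norm.sf(np.abs(z))


@dataclass
class FFFBResult:
    cell_type: str
    mean: float
    se: float
    p_value: float
    p_adjusted: float = float("nan")
    verdict: str = "none"
    n: int = 0
    degenerate: bool = False


def fffb_classify(connections: dict, levels: pd.Series | dict,
                  alpha: float = 0.05, n_ref: int = 1000, seed: int = 0,
                  mode: str = "gaussian_ref") -> pd.DataFrame:
    """Classify each cell type's projection bias as FF, FB or none.

    ``connections`` maps cell type -> list of (source, target) region
    pairs (or a pre-computed Δh array); ``levels`` maps region -> hierarchy
    level.  Each type's Δh = h_target − h_source sample is tested against
    zero-mean Gaussians with matched SD and size (``n_ref`` seeded draws,
    median two-sample rank-sum p) — or, with ``mode='signed_rank'``, a
    one-sample Wilcoxon signed-rank test against zero.  P-values are BH
    adjusted across types; verdict FF iff adjusted p < α and mean Δh > 0,
    FB iff adjusted p < α and mean Δh < 0.
    """
    if isinstance(levels, dict):
        levels = pd.Series(levels)
    rng = np.random.default_rng(seed)
    results: list[FFFBResult] = []
    for ctype, conns in connections.items():
        conns = np.asarray(conns)
        if conns.ndim == 2:
            missing = [r for pair in conns for r in pair if r not in levels.index]
            if missing:
                raise KeyError(f"no hierarchy level for regions {sorted(set(missing))}")
            dh = levels[conns[:, 1]].to_numpy(float) - levels[conns[:, 0]].to_numpy(float)
        else:
            dh = conns.astype(float)
        if len(dh) < 5:
            raise ValueError(f"cell type {ctype!r}: need >= 5 connections")
        sd = float(np.std(dh, ddof=1))
        mean = float(np.mean(dh))
        if sd == 0:
            # a point mass needs no rank test: the verdict is forced by its
            # sign (p = 0 enters the BH correction), a mass at zero is null
            p0 = float("nan") if mean == 0 else 0.0
            r = FFFBResult(ctype, mean, 0.0, p0, n=len(dh), degenerate=True)
            results.append(r)
            continue
        if mode == "signed_rank":
            p = float(wilcoxon(dh).pvalue)
        elif mode == "gaussian_ref":
            refs = rng.normal(0.0, sd, size=(n_ref, len(dh)))
            p = float(np.median(ranksum_pvalues(dh, refs)))
        else:
            raise ValueError(f"unknown mode {mode!r}")
        results.append(FFFBResult(ctype, mean, sd / np.sqrt(len(dh)), p, n=len(dh)))

    testable = [r for r in results if not np.isnan(r.p_value)]
    if testable:
        rej, adj, _, _ = multipletests(
            [r.p_value for r in testable], alpha=alpha, method="fdr_bh"
        )
        for r, rj, a in zip(testable, rej, adj):
            r.p_adjusted = float(a)
            if rj:
                r.verdict = "FF" if r.mean > 0 else ("FB" if r.mean < 0 else "none")
    return pd.DataFrame(
        [
            {
                "cell_type": r.cell_type, "n": r.n, "mean": r.mean, "se": r.se,
                "p_value": r.p_value, "p_adjusted": r.p_adjusted,
                "verdict": r.verdict, "degenerate": r.degenerate,
            }
            for r in results
        ]
    ).set_index("cell_type")
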