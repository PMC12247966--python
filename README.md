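# projectomics

Single-neuron projectome analysis for whole-neuron SWC reconstructions
registered into an annotated 3D region atlas. The package is aimed at
neuroanatomists and neuroinformaticians working with full morphologies
(fMOST/MouseLight-style reconstructions in a CCF-like atlas) who want
reproducible, tested implementations of the projection statistics that are
usually re-derived ad hoc per study:

* **Target calling** — each axonal arbor (the axon inside one region and
  hemisphere) passes the projection filter iff AxL > 1000 μm with ≥ 1
  terminal, or 20 ≤ AxL ≤ 1000 μm with ≥ 1 terminal and a second-order
  bifurcation; passing fibers and tracing spikes fail.
* **Connectome matrices** — TargProb (% of cells of a type/source group
  with a passing arbor per target) and TargStren (mean AxL over passing
  cells, μm), plus laminar profiles, weak-target summaries and hemispheric
  symmetry correlations.
* **Convergence** — the scatter-matrix overlap score
  O = max(0, 1 − tr(S_B)/tr(S_W)) between axon clouds from different
  source areas, Gaussian-KDE cloud volumes and densities, and
  composition-based similarity clustering of convergent regions.
* **Topography** — Spearman ρ between soma positions and arbor centroids,
  each projected onto its set's first principal axis; ρ > 0 means the
  spatial order of somata is preserved in the target, ρ < 0 that it is
  mirrored.
* **Hierarchy** — region scores Σ_{i≠j} P(i→j)/L̄(i→j) and
  feedforward/feedback classification of cell types from hierarchy-level
  differences Δh (Wilcoxon rank-sum vs. variance-matched zero-mean
  Gaussians, Benjamini–Hochberg corrected).
* **Morphometry** — nine skeleton features per compartment, min-max
  scaling, one-minus-Pearson average-linkage clustering with
  optimal-assignment accuracy, and a random-forest cell-type classifier.
* **Synthetic populations** — a seeded generator of toy atlases and SWC
  populations with planted projection profiles, topographic gradients,
  hierarchies and dendritic templates, so every stage is testable without
  any download.

See `docs/methods.md` for the model definitions, parameter defaults and
design decisions.

## Worked example

```python
import numpy as np
import projectomics as pj

# generate a small two-type population with planted projection profiles
pop = pj.generate_population(pj.synthetic.default_config(seed=7, n_cells=50))

# decompose every axon into per-(region, hemisphere) arbors, call targets
arbors = [a for n in pop.neurons for a in pj.decompose_arbors(n, pop.atlas)]
records = pj.projection_records(arbors, pop.cell_meta, pop.atlas)
conn = pj.build_connectome(records, pop.cell_meta)
print(conn.table.round(1).to_string(index=False))
```

```
cell_type source_area target_region hemisphere  TargProb  TargStren  n_pass
  ET_like          A2            A2       ipsi     100.0     2671.7      50
  ET_like          A2            A4       ipsi      26.0      608.9      13
  ET_like          A2            CP       ipsi      48.0     1209.9      24
  ET_like          A2            TH       ipsi      84.0     3133.5      42
  IT_like          A1            A1       ipsi     100.0     2623.9      50
  IT_like          A1            A3     contra      58.0     1244.3      29
  IT_like          A1            A3       ipsi      98.0     2533.2      49
  IT_like          A1            A5       ipsi      28.0      764.2      14
  IT_like          A1            CP       ipsi      54.0     1459.3      27
```

Each row is one called target: the soma-resident areas (A1, A2) show the
expected ~100% local TargProb, the planted distal targets are recovered
near their configured probabilities and mean arbor lengths (e.g. the
IT-like type was planted at 90% → A3 with 2500 μm arbors and a bilateral
branch at half strength — recovered as 98% ipsi / 58% contra with
2533 / 1244 μm), and the routing fibers that merely pass through other
areas are correctly rejected.

```python
frac_len, frac_prob = pj.weak_target_summary(conn)
print(f"targets with TargStren > 1000 um: {frac_len:.0%}, "
      f"TargProb > 2.4%: {frac_prob:.0%}")

tpop = pj.generate_population(pj.synthetic.topography_config("aligned", seed=7))
somas, cents = [], []
for n in tpop.neurons:
    for a in pj.decompose_arbors(n, tpop.atlas):
        if tpop.atlas.regions.at[a.region_id, "area"] == "TH" and \
           pj.call_target(a.axon_length, a.n_terminals, a.max_branch_order_within):
            somas.append(n.soma_position)
            cents.append(pj.arbor_centroid(a))
res = pj.topography_rho(np.array(somas), np.array(cents))
print(f"topography rho = {res.rho:.2f} over {res.n_cells} cells")
```

```
targets with TargStren > 1000 um: 78%, TargProb > 2.4%: 100%
topography rho = 0.97 over 50 cells
```

The planted soma→target gradient is recovered with ρ = 0.97; the reversed
generator mode yields ρ ≈ −0.97 (see the tests).

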