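# Methods

`projectomics` quantifies the long-range projection organization of single
reconstructed neurons: given SWC whole-neuron morphologies registered into an
annotated 3D region atlas, it calls genuine projection targets per axonal
arbor, aggregates them into connectome matrices, and derives convergence,
topography, hierarchy and morphometric-typing statistics. This note records
the models, the parameters that matter, and the design choices that were
genuinely open.

## Arbor decomposition and target calling

An *arbor* is the set of a cell's axonal nodes inside one (region,
hemisphere) of the atlas. Each axonal parent→child segment is assigned
entirely to the region of its **child** node — no sub-segment clipping — so
summed arbor lengths conserve the neuron's total axonal length exactly, for
any atlas partition (this conservation is asserted to 1e-6 μm in the test
suite). Hemispheres are split by a configurable midline plane; *ipsi* and
*contra* are always relative to the soma's side.

Branch orders restart at each arbor's own entry nodes: an entry has order 0
and order increases by one in the daughters of every node with ≥ 2 children
inside the arbor. A *second-order bifurcation* is then a bifurcation lying
downstream of another bifurcation in the same arbor, i.e. the arbor's
maximum branch order reaches 2. Where the arbor entry for order counting is
ambiguous (first in-region node vs. soma), we count from the first in-region
node; this changes which 20–1000 μm arbors pass the filter and is a declared
choice.

The target filter, designed to exclude passing fibers and tracing spikes
while keeping weak but genuine projections:

* axon length > 1000 μm → pass iff ≥ 1 terminal node;
* 20 μm ≤ length ≤ 1000 μm → pass iff ≥ 1 terminal **and** one second-order
  bifurcation (boundary values fall in this band);
* < 20 μm → fail.

**TargProb** is the percentage of cells of a (cell type, source area) group
with a passing arbor in a (target region, hemisphere) column; **TargStren**
is the mean axonal length over the *passing* cells only (per-cell "AxL/C",
μm) — averaging over all cells is available as an option. Weak-target
summaries default to the 1000 μm length cut and the 2.4% (cortico-cortical)
/ 6% (cortico-subcortical) TargProb cuts. Laminar profiles are per-layer
TargProb normalized to the maximum layer within each target area.
Hemispheric symmetry is the Pearson r between paired ipsi-/contralateral
TargProb vectors with a seeded permutation p-value (10⁴ permutations).

## Overlap score

Two axon clouds in the same region are treated as classes; separability is
S = tr(S_B)/tr(S_W) with the usual between-/within-class scatter matrices
(class sizes n_i weight S_B as written — no subsampling of unequal clouds),
and the overlap is O = max(0, 1 − S) ∈ [0, 1]. Clouds are pre-interpolated
onto the Cartesian grid (every grid cell on each node→child straight path,
by exact 3D voxel traversal) so node density does not bias the class means.
Degenerate case tr(S_W) = 0: O = 1 if the class means coincide, else 0,
flagged. The implementation is the direct trace form; tests pin it to an
independent double-loop computation at 1e-9.

## Cloud volume (KDE)

Axon clouds are smoothed with a Gaussian KDE, bandwidth 0.3 in per-axis
standardized coordinates (points centered and scaled to unit variance; the
bandwidth is unitless, and a raw-μm bandwidth can be emulated by
pre-scaling). The estimated volume counts voxels whose density clears a 1%
cut, times the voxel volume; mean axon density is total in-region axonal
length divided by that volume (μm/μm³).

The 1% cut is applied, by default, **absolutely** to the standardized
density (which integrates to 1), not relative to the maximum density. The
relative reading inflates volumes by the Gaussian halo — the region above
1% of the max extends ≈ 2.3 kernel sigmas beyond the cloud's support, a
+55–70% error on a uniform cube at any usable bandwidth — whereas the
absolute cut recovers the geometric volume of compact uniform clouds to a
few percent and is stable in the bandwidth. `mode="relative"` restores the
relative behavior (whose volume grows monotonically with bandwidth).

## Topography ρ

For cells of one source area projecting to one target, the somata S and the
per-cell arbor centroids C are projected onto their own first principal
axes (leading covariance eigenvectors — the first Hotelling component), and
ρ is the Spearman rank correlation of the projections (average ranks on
ties). Centroids are means of uniformly resampled segments (default step
1 μm), which converge to the length-weighted segment centroid. The sign of
each axis is fixed by making its largest-magnitude component positive;
without a convention the eigenvector sign — and hence the sign of ρ — is
arbitrary. One centroid enters per (cell, target region, hemisphere);
non-projecting cells are excluded from the pairing and reported as the
projecting fraction.

## Hierarchy score and FF/FB bias

The hierarchy score of target region j is Σ_{i≠j} P(i→j)/L̄(i→j), with P
the targeting-probability fraction and L̄ the mean targeting length (over
passing cells, consistent with TargStren), which normalizes away the size
advantage of large regions. Score correlates (target number, mean TargProb,
mean TargStren) are Pearson r with seeded permutation p-values.

FF/FB classification takes externally supplied hierarchy levels h per
region (the synthetic generator plants them; deriving them from bulk
tracing is out of scope). Each connection j→i contributes Δh = h_i − h_j;
connections are weighted uniformly. Per cell type the Δh sample is compared
against zero-mean Gaussian references with matched SD and sample size: 1000
seeded draws by default, a two-sample Wilcoxon rank-sum test per draw, and
the **median p** across draws (the reference sample size and aggregation
are not fixed by the method's description; a one-sample signed-rank test
against zero is provided as `mode="signed_rank"`). P-values are
Benjamini–Hochberg adjusted across types; verdict FF iff adjusted p < α
(default 0.05) and mean Δh > 0, FB for a negative mean. A zero-variance Δh
sample gets no rank test: it is flagged degenerate, and a nonzero-mean
point mass enters the correction with p = 0 (its verdict is forced by
sign), while a mass at zero is null. The rank-sum reference loop is
computed vectorized (ranks + normal approximation, identical to SciPy's
rank-sum p-values, pinned by test). Under the symmetric null the median-p
aggregation is conservative: measured type-I error ≈ 0.01 at α = 0.05.

## Morphometric typing

Nine skeleton features per compartment subtree: height (extent along a
declared cortical-depth axis — rotation therefore changes it, translation
does not), max Euclidean distance from soma, max along-tree path length
from soma (the entry attachment segment counts), total pathway efficiency,
average bifurcation angle (between daughter directions at each branch
point, degrees), average segment length (unbranched runs between branch
points/tips, including the run's entry edge), and counts of segments,
bifurcations and tips. "Height" and "total pathway efficiency" are named
but not defined in the literature we follow; here efficiency is the mean
over tips of the Euclidean-to-path-length ratio (inverse tortuosity) and
both definitions are declared stand-ins. Features are min-max scaled
(constant columns dropped with a warning), clustered with the
one-minus-Pearson metric and average linkage, and clustering accuracy is
the matched fraction under an optimal one-to-one cluster↔type assignment
(Hungarian algorithm; majority-label mapping would be the looser
alternative). The random-forest classifier uses 500 trees, a stratified
80/20 split and a fixed seed; hyperparameter tuning is out of scope.

## Synthetic populations

The generator emulates exactly the statistical structure the analyses
consume, nothing more: block atlases (layered cortical areas along one
axis, two mirrored hemispheres, subcortical blocks below), somata placed
uniformly in their source block, dendrites from five parametric templates
(tufted / untufted / inverted / horizontal / stellate, ~5% per-cell size
jitter), and axons realized per profile. Each intended target arbor is a
confined branching random walk with a fixed depth-2 binary topology —
guaranteeing a terminal and a second-order bifurcation, so intended
targets always pass the filter — with total length set by a lognormal draw
around the planted mean (CV 10%). Straight soma→target paths are passing
fibers in intervening regions (unbranched, no terminals), and the arbor's
length budget is corrected for the path length the route deposits inside
the target block. Topographic modes map the soma's position along the
widest source-box axis onto the widest target-box axis (aligned),
its mirror (reversed), or uniformly (none), with Gaussian noise (default
σ = 30 μm). Seeded runs are byte-reproducible, including written SWC.

What the generator does **not** emulate: realistic dendritic geometry or
electrotonus, curved anatomical boundaries, registration error, laminar
termination gradients within an arbor, or correlated targeting across
cells. Passing tests therefore demonstrate the correctness of the
measurement pipeline under planted truth, not biological fidelity of the
toy populations.

### Study conditions used in the acceptance suite

* Overlap / topography limit cases: analytic configurations (50–200 point
  clouds, 10 paired somata/centroids).
* Topography sign recovery: 50 cells per run, σ = 30 μm, 10 seeded runs
  per direction.
* Hierarchy recovery: 5 areas with levels 1–5, targeting probability
  0.1 → 0.9 with level, 200 cells/type (1000 cells), recovery measured as
  Spearman(score, level).
* FF/FB calibration: 500 null replicates (Δh ~ N(0, 1), n = 100) and 200
  power replicates (Δh ~ N(0.5, 1), n = 100), 200 Gaussian reference draws
  per test.
* Connectome recovery: the mixed two-type scenario at 200 cells/type;
  TargProb is compared against the generator's emitted per-cell ground
  truth and TargStren against the planted means.
* Morphometric typing: three dendritic templates × 60 cells; class-mean
  separation ≥ 3 within-class SDs is asserted as a precondition.

## Known limitations

* Segment→region assignment by child node means a segment straddling a
  boundary is credited wholly to one region; at 10–20 μm voxels this is a
  sub-voxel effect and preserves exact length conservation.
* Radius-aware (frustum) lengths are not computed; lengths are polyline
  lengths.
* The overlap score compares first and second moments via traces; two
  clouds with equal means and very different shapes can still score near 1.
* The hierarchy score ranks regions; its absolute scale (1/μm) follows the
  units of L̄ and is not comparable across atlases with different length
  scales.
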