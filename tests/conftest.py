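import numpy as np
import pandas as pd
import pytest

from projectomics.morphology import NeuronReconstruction, RegionAtlas


def make_neuron(xyz, parent, compartment, cell_id="cell", radius=0.5):
    """Assemble a NeuronReconstruction from plain lists."""
    xyz = np.asarray(xyz, dtype=float)
    n = len(xyz)
    comp = np.broadcast_to(np.asarray(compartment), (n,)).copy()
    return NeuronReconstruction(
        cell_id=cell_id,
        node_id=np.arange(1, n + 1),
        compartment=comp,
        xyz=xyz,
        radius=np.full(n, radius),
        parent=np.asarray(parent),
    )


def random_tree(rng, n_nodes=30, compartment=2, step=25.0):
    """Random rooted tree: each node attaches to a uniformly chosen earlier node."""
    xyz = [np.zeros(3)]
    parent = [-1]
    comp = [1] + [compartment] * (n_nodes - 1)
    for i in range(1, n_nodes):
        p = int(rng.integers(0, i))
        xyz.append(xyz[p] + rng.normal(scale=step, size=3))
        parent.append(p)
    return make_neuron(np.array(xyz), parent, comp)


@pytest.fixture
def two_region_atlas():
    """Two regions split at x = 100 within a 200x100x100 μm box (voxel 10)."""
    labels = np.zeros((20, 10, 10), dtype=np.int32)
    labels[:10] = 1
    labels[10:] = 2
    regions = pd.DataFrame(
        {
            "name": ["R1", "R2"],
            "area": ["R1", "R2"],
            "layer": [None, None],
            "group": ["g", "g"],
            "hemisphere": ["left", "right"],
            "hierarchy_level": [1.0, 2.0],
        },
        index=pd.Index([1, 2], name="region_id"),
    )
    return RegionAtlas(labels=labels, voxel_size=10.0, origin=np.zeros(3),
                       midline=100.0, regions=regions)


@pytest.fixture(scope="session")
def default_population():
    """Mixed two-type population at the standard 200 cells/type."""
    from projectomics.synthetic import default_config, generate_population

    return generate_population(default_config(seed=1, n_cells=200))


@pytest.fixture(scope="session")
def default_connectome(default_population):
    from projectomics.morphology import decompose_arbors
    from projectomics.projectome import build_connectome, projection_records

    pop = default_population
    arbors = [a for n in pop.neurons for a in decompose_arbors(n, pop.atlas)]
    records = projection_records(arbors, pop.cell_meta, pop.atlas)
    return build_connectome(records, pop.cell_meta), records, arbors
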