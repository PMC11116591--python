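import itertools

import numpy as np
import pytest

from accelcne import phylo
from accelcne.phylo import BranchScaling, PhyloModel, SubstModel, read_newick
from accelcne.simulate import SimConfig, default_tree_newick


@pytest.fixture(scope="session")
def jc() -> SubstModel:
    return SubstModel.jc69()


@pytest.fixture(scope="session")
def hky() -> SubstModel:
    return SubstModel.hky85(2.0, [0.3, 0.2, 0.2, 0.3])


@pytest.fixture(scope="session")
def pm16() -> PhyloModel:
    """The frozen 16-taxon mammal-like model used by the simulator."""
    return SimConfig().phylo_model()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


# ---------------------------------------------------------------------------
# independent likelihood oracle: exhaustive sum over unobserved node states
# ---------------------------------------------------------------------------


def brute_force_column_loglik(pm: PhyloModel, column: dict,
                              scaling: BranchScaling | None = None) -> float:
    """Sum the joint probability over every assignment of unobserved nodes.

    Exponential in tree size; usable only for <= ~6 free nodes. Kept
    deliberately independent of the pruning implementation.
    """
    tree = pm.tree
    t_eff = phylo.effective_lengths(pm, scaling)
    P = [pm.model.transition_matrix(t_eff[i]) for i in range(tree.n_nodes)]
    fixed = {}
    free = []
    for node in range(tree.n_nodes):
        if tree.is_leaf(node):
            base = phylo.encode_base(column.get(tree.names[node], "N"))
            if base == phylo.MISSING:
                free.append(node)
            else:
                fixed[node] = base
        else:
            free.append(node)
    total = 0.0
    for assign in itertools.product(range(4), repeat=len(free)):
        state = dict(fixed)
        state.update(zip(free, assign))
        prob = pm.model.pi[state[tree.root]]
        for node in range(tree.n_nodes):
            if node == tree.root:
                continue
            prob *= P[node][state[tree.parent[node]], state[node]]
        total += prob
    return float(np.log(total))


def random_tree_newick(rng: np.random.Generator, n_leaves: int) -> str:
    """A random rooted binary tree over leaves L0..L{n-1} with U(0.02,0.5)
    branch lengths."""
    parts = [f"L{i}" for i in range(n_leaves)]
    while len(parts) > 1:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        a, b = parts[i], parts[j]
        la, lb = rng.uniform(0.02, 0.5, size=2)
        merged = f"({a}:{la:.4f},{b}:{lb:.4f})"
        parts = [p for k, p in enumerate(parts) if k not in (i, j)] + [merged]
    return parts[0] + ";"


def random_model(rng: np.random.Generator) -> SubstModel:
    pi = rng.dirichlet(np.full(4, 8.0))
    kappa = rng.uniform(1.0, 4.0)
    return SubstModel.hky85(kappa, pi)


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A small written synthetic dataset shared across I/O-level tests."""
    from accelcne.simulate import simulate

    outdir = tmp_path_factory.mktemp("smallsim")
    cfg = SimConfig(genome_length=12_000, block_size=4_000, n_elements=18,
                    n_accel_all=2, n_accel_subset=4, n_cds=6, n_genes=10,
                    seed=7)
    return simulate(cfg, outdir)
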