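import numpy as np
import pytest

from coevosite.phylo import Phylogeny


def random_tree(rng: np.random.Generator, n_nodes: int = 7, ref: int | None = None) -> Phylogeny:
    """Random topology with beta, h drawn in [-1, 1] (not the realistic
    generator — this exercises the engine on arbitrary parameters)."""
    parent = [-1]
    for v in range(1, n_nodes):
        parent.append(int(rng.integers(0, v)))
    parent = np.asarray(parent)
    beta = rng.uniform(-1, 1, n_nodes)
    beta[0] = 0.0
    h = rng.uniform(-1, 1, n_nodes)
    leaves = [v for v in range(n_nodes) if v not in set(parent.tolist())]
    ref_node = leaves[0] if ref is None else ref
    names = tuple(f"n{i}" for i in range(n_nodes))
    return Phylogeny(names, parent, beta, h, ref_node)


def random_leaf_pattern(rng: np.random.Generator, tree: Phylogeny) -> np.ndarray:
    """Random observed pattern with the reference clamped present."""
    lv = rng.integers(0, 2, tree.leaves.size).astype(np.int8)
    ref_col = int(np.flatnonzero(tree.leaves == tree.reference)[0])
    lv[ref_col] = 1
    return lv


@pytest.fixture
def star_tree():
    """Root + reference + 4 independent leaves, no coupling, zero fields."""
    parent = np.array([-1, 0, 0, 0, 0, 0])
    return Phylogeny(
        ("root", "ref", "a", "b", "c", "d"),
        parent,
        np.zeros(6),
        np.zeros(6),
        1,
    )


@pytest.fixture(scope="session")
def toy_bundle(tmp_path_factory):
    """Session-wide synthetic input bundle (files + manifest + tree)."""
    from coevosite.io import read_tree
    from coevosite.synthetic import SimulationSpec, emit_toy_bundle

    d = tmp_path_factory.mktemp("bundle")
    spec = SimulationSpec(n_leaves=8, n_genes=6, sites_per_gene=4, sigma_true=3.0, rng_seed=7)
    manifest = emit_toy_bundle(spec, d)
    tree = read_tree(d / "tree.nwk", d / "tree_params.tsv")
    return {"dir": d, "manifest": manifest, "tree": tree, "spec": spec}
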