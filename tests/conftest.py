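import warnings

import numpy as np
import pandas as pd
import pytest

from limnoecol.features import AbundanceMatrix, to_absolute, to_relative, merge_replicates
from limnoecol.phylo import parse_newick
from limnoecol.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=11, n_taxa=150, n_stations=4)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def merged_counts(small_dataset):
    """Replicate-merged, control-free counts of the session dataset."""
    ds = small_dataset
    counts = ds.counts.drop_controls()
    return merge_replicates(counts, {c: ds.metadata.loc[c, "merged_id"]
                                     for c in counts.sample_ids})


@pytest.fixture(scope="session")
def absolute_abund(small_dataset, merged_counts):
    """Truth-concentration-scaled absolute abundance of the session dataset."""
    rel = to_relative(merged_counts)
    return to_absolute(rel, small_dataset.sample_truth["cells_per_ml"])


@pytest.fixture
def cherry_tree():
    return parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


def random_tree(rng, n_tips, prefix="T"):
    """Random binary tree with uniform branch lengths (test helper)."""
    from skbio import TreeNode

    nodes = [TreeNode(name=f"{prefix}{i}", length=float(rng.uniform(0.1, 1.0)))
             for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b, a = nodes.pop(j), nodes.pop(i)
        parent = TreeNode(length=float(rng.uniform(0.1, 1.0)))
        parent.extend([a, b])
        nodes.append(parent)
    nodes[0].length = None
    return nodes[0]


def random_abundance(rng, tree, n_samples, mode="relative", sparsity=0.3):
    tips = sorted(t.name for t in tree.tips())
    vals = rng.gamma(0.7, size=(len(tips), n_samples))
    vals[rng.random(vals.shape) < sparsity] = 0.0
    # keep every column non-empty
    for k in range(n_samples):
        if vals[:, k].sum() == 0:
            vals[int(rng.integers(len(tips))), k] = 1.0
    if mode == "relative":
        vals = vals / vals.sum(axis=0, keepdims=True)
    df = pd.DataFrame(vals, index=tips,
                      columns=[f"s{k}" for k in range(n_samples)])
    return AbundanceMatrix(df, mode)
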