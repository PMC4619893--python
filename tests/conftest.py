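import numpy as np
import pytest

from templix.weighting import PhyloTree, TreeNode


def fig5a_tree(tau_h=0.8, tau_1=0.5, tau_2=0.9, tau_3=1.1) -> PhyloTree:
    """Query root; templates t1, t2 under a hidden node; t3 attached directly."""
    root = TreeNode(name="q")
    hidden = root.add(TreeNode(length=tau_h))
    hidden.add(TreeNode(name="t1", length=tau_1, weight=1.0))
    hidden.add(TreeNode(name="t2", length=tau_2, weight=1.0))
    root.add(TreeNode(name="t3", length=tau_3, weight=1.0))
    return PhyloTree(root)


def random_query_tree(rng, n_leaves: int) -> PhyloTree:
    """Random query-rooted binary-ish tree with positive edge lengths."""
    nodes = [TreeNode(name=f"t{k + 1}", length=float(rng.uniform(0.1, 1.0)), weight=1.0)
             for k in range(n_leaves)]
    while len(nodes) > 2:
        a = nodes.pop(int(rng.integers(len(nodes))))
        b = nodes.pop(int(rng.integers(len(nodes))))
        parent = TreeNode(length=float(rng.uniform(0.1, 1.0)))
        parent.add(a)
        parent.add(b)
        nodes.append(parent)
    root = TreeNode(name="q")
    for n in nodes:
        root.add(n)
    return PhyloTree(root)


@pytest.fixture(scope="session")
def trained_tm_predictor():
    """TMscore predictor fitted once on a simulated hit pool."""
    from templix.selection import train_tmpredictor
    from templix.simulate import SimulationConfig, hit_pool_training_table, simulate_hit_pool

    hits, truth = simulate_hit_pool(SimulationConfig(seed=11, n_hits=60))
    X, y = hit_pool_training_table(hits, truth)
    return train_tmpredictor(X, y, seed=1, n_restarts=5)


@pytest.fixture(scope="session")
def small_mdn():
    """Mixture density network fitted once on a mid-sized synthetic set."""
    from templix.mdn import train_mdn
    from templix.simulate import SimulationConfig, simulate_restraint_tuples

    df = simulate_restraint_tuples(SimulationConfig(seed=5, n_examples=8000))
    X = df[["log_dt", "pp", "sim"]].to_numpy()
    y = df["log_d"].to_numpy()
    return train_mdn(X, y, n_restarts=2, seed=7, max_iter=300)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
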