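"""Synthetic data with known ground truth.

Everything the package needs to verify itself is generated here: Brownian
(diffusive) evolution of inter-atomic distances along a tree, alignment-error
contaminated restraint training tuples with the two-component mixture
structure, template-hit pools for the selection heuristics, and toy
helix-like 3D structures with good and bad templates.  All generators are
pure functions of (config, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.special import expit

from templix.weighting import DiffusionModel, PhyloTree, TreeNode

logger = logging.getLogger(__name__)


def _default_w(pp, sim):
    # probability that both residue pairs are correctly aligned rises with
    # local posterior and global similarity
    return expit(-2.0 + 3.5 * pp + 1.0 * sim)


def _default_sigma(pp, sim):
    # signal spread (log-Angstrom) shrinks for reliable, similar alignments
    return 0.25 - 0.12 * pp * np.minimum(sim, 1.0)


@dataclass
class SimulationConfig:
    """Conditions under which synthetic fixtures are generated.

    The restraint-tuple generator draws template log distances from
    ``N(log_dt_mean, log_dt_sd^2)`` (centred near 9 Angstrom, the typical
    scale of residue-pair distances), alignment quality ``pp ~ Beta(2, 1)``
    and similarity ``sim ~ U(0, 1.5)`` bits, then emits the query log
    distance from the signal component ``N(log_dt + drift, sigma^2)`` with
    probability ``w(pp, sim)`` and from the template-independent background
    ``N(mu_bg, sigma_bg^2)`` otherwise.
    """

    seed: int = 0
    gamma: float = 0.25  # diffusion rate, Angstrom^2 per unit tau
    n_examples: int = 10_000
    log_dt_mean: float = 2.2
    log_dt_sd: float = 0.35
    drift: float = 0.0
    mu_bg: float = 2.2
    sigma_bg: float = 0.55
    w_fn: Callable = field(default=_default_w)
    sigma_fn: Callable = field(default=_default_sigma)
    # hit pools
    n_hits: int = 20
    query_length: int = 50
    hit_noise: float = 0.03
    # toy structures
    chain_length: int = 12
    perturbation: float = 0.3  # Angstrom, per-coordinate
    n_good: int = 2
    n_bad: int = 1


# ---------------------------------------------------------------------------
# diffusive distances on trees


def simulate_tree_distances(
    tree: PhyloTree,
    d_root: float,
    model: DiffusionModel,
    n_replicates: int,
    seed: int | None = None,
) -> pd.DataFrame:
    """Brownian evolution of a distance down a tree.

    Starting from ``d_root`` at the root, each edge of length tau adds
    independent ``N(0, gamma * tau)`` noise, so a leaf's marginal variance is
    ``gamma *`` (root-to-leaf path length) and two leaves covary by ``gamma *``
    (shared path length).  Negative distances are rejected and the edge noise
    resampled (physical distances are nonnegative); the resampling rate is
    logged.  Returns one column per leaf.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    n_resampled = 0

    def _walk(node: TreeNode, values: np.ndarray) -> None:
        nonlocal n_resampled
        for child in node.children:
            sd = np.sqrt(model.gamma * child.length)
            child_vals = values + rng.normal(0.0, sd, size=n_replicates) if sd > 0 else values.copy()
            bad = child_vals < 0.0
            while np.any(bad):
                n_resampled += int(bad.sum())
                child_vals[bad] = values[bad] + rng.normal(0.0, sd, size=int(bad.sum()))
                bad = child_vals < 0.0
            if child.is_leaf:
                out[child.name] = child_vals
            else:
                _walk(child, child_vals)

    root_vals = np.full(n_replicates, float(d_root))
    _walk(tree.root, root_vals)
    if n_resampled:
        logger.info(
            "resampled %d negative distance draws (%.3g per replicate)",
            n_resampled,
            n_resampled / n_replicates,
        )
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# restraint training tuples


def simulate_restraint_tuples(config: SimulationConfig) -> pd.DataFrame:
    """Alignment-error contaminated training tuples.

    Returns a DataFrame with columns ``log_dt, pp, sim, log_d`` plus the
    generating ground truth ``true_w`` (mixture weight at the drawn features)
    and ``from_signal`` (which component each example came from).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_examples
    log_dt = rng.normal(config.log_dt_mean, config.log_dt_sd, size=n)
    pp = rng.beta(2.0, 1.0, size=n)
    sim = rng.uniform(0.0, 1.5, size=n)
    w = np.clip(np.asarray(config.w_fn(pp, sim), dtype=float), 0.0, 1.0)
    sigma = np.maximum(np.asarray(config.sigma_fn(pp, sim), dtype=float), 1e-3)
    from_signal = rng.random(n) < w
    log_d = np.where(
        from_signal,
        log_dt + config.drift + rng.normal(0.0, 1.0, size=n) * sigma,
        rng.normal(config.mu_bg, config.sigma_bg, size=n),
    )
    return pd.DataFrame(
        {
            "log_dt": log_dt,
            "pp": pp,
            "sim": sim,
            "log_d": log_d,
            "true_w": w,
            "from_signal": from_signal,
        }
    )


def tuples_to_tsv(df: pd.DataFrame, path, atom_class: str = "CA_CA") -> None:
    """Training-table TSV with header log_dt, pp, sim, log_d, class."""
    out = df[["log_dt", "pp", "sim", "log_d"]].copy()
    out["class"] = atom_class
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# template-hit pools


def simulate_hit_pool(config: SimulationConfig):
    """Hit pool with known true TMscores.

    Each hit gets a latent quality q ~ U(0.3, 0.9); the four global features
    are noisy monotone transforms of q and the true TMscore is q plus noise.
    Aligned columns cover a contiguous window of the query whose extent and
    posteriors also grow with q.  Returns (hits, true_tmscores dict).
    """
    from templix.selection import TemplateHit

    rng = np.random.default_rng(config.seed)
    hits, truth = [], {}
    L = config.query_length
    for k in range(config.n_hits):
        q = rng.uniform(0.3, 0.9)
        noise = config.hit_noise
        tid = f"T{k:03d}"
        start = int(rng.integers(0, max(1, int(L * (1 - q) * 0.8) + 1)))
        span = max(5, int(L * (0.4 + 0.6 * q)))
        cols = []
        for i in range(start + 1, min(start + span, L) + 1):
            pp = float(np.clip(q + rng.normal(0.0, 0.1), 0.05, 0.99))
            cols.append((i, i, pp))
        hits.append(
            TemplateHit(
                template_id=tid,
                p_hom=float(np.clip(q + rng.normal(0, noise), 0.0, 1.0)),
                raw_score=float(100.0 * q + rng.normal(0.0, 100.0 * noise)),
                ss_score_norm=float(np.clip(q * 0.8 + rng.normal(0, noise), 0, 1)),
                exp_correct_norm=float(np.clip(q * 0.9 + rng.normal(0, noise), 0, 1)),
                resolution=float(rng.uniform(1.0, 3.5)),
                aligned_pairs=cols,
            )
        )
        truth[tid] = float(np.clip(q + rng.normal(0.0, noise), 0.0, 1.0))
    return hits, truth


def hit_pool_training_table(hits, truth, resolution_impute: float = 3.5):
    """Feature matrix / target vector for the TMscore predictor."""
    from templix.selection import hit_features

    X = np.array([hit_features(h, resolution_impute) for h in hits])
    y = np.array([truth[h.template_id] for h in hits])
    return X, y


# ---------------------------------------------------------------------------
# toy structures


def _helix(n: int, radius: float = 2.3, rise: float = 1.5, turn_deg: float = 100.0) -> np.ndarray:
    """Idealized alpha-helical C-alpha trace."""
    t = np.arange(n)
    ang = np.deg2rad(turn_deg) * t
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang), rise * t])


def _random_chain(n: int, rng, step: float = 3.8) -> np.ndarray:
    """Self-avoiding-ish random walk with fixed step length (a 'bad' template)."""
    coords = [np.zeros(3)]
    direction = np.array([1.0, 0.0, 0.0])
    for _ in range(n - 1):
        proposal = direction + rng.normal(0.0, 0.6, size=3)
        direction = proposal / np.linalg.norm(proposal)
        coords.append(coords[-1] + step * direction)
    return np.asarray(coords)


def make_toy_structures(config: SimulationConfig):
    """Query truth plus good (perturbed) and bad (unrelated) template chains.

    Returns a dict with the true query coordinates, per-template coordinate
    arrays, identity alignments (every template residue aligned to the same
    query index) and labels marking which templates are good.
    """
    if config.chain_length < 5:
        raise ValueError("chain length must be >= 5")
    rng = np.random.default_rng(config.seed)
    n = config.chain_length
    query = _helix(n)
    templates: dict[str, np.ndarray] = {}
    good: dict[str, bool] = {}
    for k in range(config.n_good):
        tid = f"good{k + 1}"
        templates[tid] = query + rng.normal(0.0, config.perturbation, size=query.shape)
        good[tid] = True
    for k in range(config.n_bad):
        tid = f"bad{k + 1}"
        # grossly misaligned template: the residues aligned to consecutive
        # query positions are scattered across an unrelated fold, so template
        # distances carry no information about query distances (row r holds
        # the coordinates of the template residue aligned to query residue r)
        templates[tid] = _random_chain(n, rng)[rng.permutation(n)]
        good[tid] = False
    alignment = [(i, i) for i in range(1, n + 1)]
    return {
        "query": query,
        "templates": templates,
        "alignment": alignment,
        "is_good": good,
    }
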