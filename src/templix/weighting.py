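"""Redundancy-correcting template weights from a phylogenetic tree.

Templates related through a shared ancestor do not contribute independent
distance information.  Under a Brownian (diffusive) model of inter-atomic
distance evolution — variance growing linearly with evolutionary time,
``p(d_l | d_k, tau) = N(d_l | d_k, gamma * tau)`` — any query-rooted tree can
be transformed into an equivalent star topology in which every template hangs
directly off the query.  One internal node is removed per step; the template
weights below it are updated by the closed-form elementary step

    w'_k = [(1/tau_0 + 1/tau_k) / (1/tau_0 + sum_l w_l / tau_l)] * w_k

where ``tau_0`` is the edge above the collapsed node and ``tau_k`` the edges
to its children.  The star tree preserves every query-to-template path length
and yields the same restraint odds for the query distance as the original
tree; its leaf weights are the redundancy-correcting exponents used in
:func:`templix.restraints.combined_log_odds`.

The initial tree is built by UPGMA on ``-log(TMscore_pred)`` distances and
rerooted at the query.  :func:`numeric_tree_odds` provides a brute-force
numerical-integration check of the tree/star equivalence.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

TAU_MIN = 1e-6  # floor on edge lengths; identical templates share weight ~1/m


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0  # edge length to parent (ignored at the root)
    weight: float | None = None  # template weight, leaves only
    children: list["TreeNode"] = field(default_factory=list)
    parent: "TreeNode | None" = field(default=None, repr=False)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child


class PhyloTree:
    """Rooted tree with edge lengths and per-leaf template weights."""

    def __init__(self, root: TreeNode):
        self.root = root

    # -- traversal helpers -------------------------------------------------

    def nodes(self):
        stack = [self.root]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(n.children)

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.nodes() if n.is_leaf]

    def find_leaf(self, name: str) -> TreeNode:
        for leaf in self.leaves():
            if leaf.name == name:
                return leaf
        raise KeyError(f"no leaf named {name!r}")

    def path_length(self, name: str) -> float:
        """Root-to-leaf path length."""
        node = self.find_leaf(name)
        total = 0.0
        while node.parent is not None:
            total += node.length
            node = node.parent
        return total

    def copy(self) -> "PhyloTree":
        def _clone(n: TreeNode) -> TreeNode:
            c = TreeNode(name=n.name, length=n.length, weight=n.weight)
            for ch in n.children:
                c.add(_clone(ch))
            return c

        return PhyloTree(_clone(self.root))

    def is_star(self) -> bool:
        return all(c.is_leaf for c in self.root.children)

    # -- Newick ------------------------------------------------------------

    def to_newick(self) -> str:
        """Newick string; leaf weights carried as ``[&weight=...]`` comments."""

        def _fmt(n: TreeNode) -> str:
            if n.is_leaf:
                tag = n.name or ""
                if n.weight is not None:
                    tag += f"[&weight={float(n.weight)!r}]"
            else:
                tag = "(" + ",".join(_fmt(c) for c in n.children) + ")" + (n.name or "")
            if n.parent is not None:
                tag += f":{float(n.length)!r}"
            return tag

        return _fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        import dendropy

        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=False,
            extract_comment_metadata=False,
        )

        def _convert(dnode) -> TreeNode:
            name = dnode.taxon.label if dnode.taxon is not None else dnode.label
            node = TreeNode(
                name=name,
                length=float(dnode.edge.length) if dnode.edge.length is not None else 0.0,
            )
            for comment in dnode.comments:
                if comment.startswith("&weight="):
                    node.weight = float(comment.split("=", 1)[1])
            for child in dnode.child_nodes():
                node.add(_convert(child))
            if node.is_leaf and node.weight is None:
                node.weight = 1.0
            return node

        return cls(_convert(dtree.seed_node))


@dataclass(frozen=True)
class DiffusionModel:
    """Brownian evolution of an inter-atomic distance.

    ``gamma`` is the diffusion rate constant: the variance of the distance
    change accumulated along an edge of length ``tau`` is ``gamma * tau``
    (Angstrom^2 per unit evolutionary distance).
    """

    gamma: float

    def __post_init__(self) -> None:
        if not self.gamma > 0.0:
            raise ValueError("gamma must be positive")


@dataclass
class WeightedTemplateSet:
    """Final star-topology weights, one entry per template."""

    entries: list[tuple[str, float, float]]  # (template_id, weight, path_length)

    def weight(self, template_id: str) -> float:
        for tid, w, _ in self.entries:
            if tid == template_id:
                return w
        raise KeyError(template_id)

    def path_length(self, template_id: str) -> float:
        for tid, _, pl in self.entries:
            if tid == template_id:
                return pl
        raise KeyError(template_id)

    def to_tsv(self) -> str:
        lines = ["template_id\tweight\tpath_length"]
        for tid, w, pl in self.entries:
            lines.append(f"{tid}\t{w!r}\t{pl!r}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# tree construction


def tm_distance(tm_pred: float) -> float:
    """Evolutionary distance from a predicted TMscore: ``-log(TMscore_pred)``."""
    if not 0.0 < tm_pred <= 1.0:
        raise ValueError(f"TMscore must be in (0, 1], got {tm_pred}")
    return -math.log(tm_pred)


def upgma_tree(dist, labels=None) -> PhyloTree:
    """Average-linkage (UPGMA) hierarchical clustering into an ultrametric tree.

    Accepts a square symmetric matrix with zero diagonal (ndarray, or a
    pandas DataFrame whose index supplies the labels).  Ties between cluster
    pairs at the same distance are broken in favour of the pair whose member
    clusters were created earliest (lowest creation index), so trees are
    reproducible.
    """
    try:  # pandas DataFrame carries its own labels
        import pandas as pd

        if isinstance(dist, pd.DataFrame):
            if labels is None:
                labels = [str(x) for x in dist.index]
            dist = dist.to_numpy()
    except ImportError:  # pragma: no cover
        pass
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if np.any(d < 0) or not np.allclose(np.diag(d), 0.0):
        raise ValueError("distances must be nonnegative with zero diagonal")
    if labels is None:
        labels = [f"t{k + 1}" for k in range(n)]
    if len(labels) != n:
        raise ValueError("need one label per row")

    # active clusters: (creation_index, node, height, size)
    clusters: dict[int, tuple[TreeNode, float, int]] = {
        k: (TreeNode(name=str(labels[k]), weight=1.0), 0.0, 1) for k in range(n)
    }
    dmat = {frozenset((a, b)): d[a, b] for a, b in itertools.combinations(range(n), 2)}
    next_index = n
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = min(
            ((dmat[frozenset((a, b))], a, b) for a, b in itertools.combinations(keys, 2)),
            key=lambda t: (t[0], t[1], t[2]),
        )
        dist_ab, a, b = best
        node_a, h_a, n_a = clusters.pop(a)
        node_b, h_b, n_b = clusters.pop(b)
        height = dist_ab / 2.0
        parent = TreeNode()
        node_a.length = height - h_a
        node_b.length = height - h_b
        parent.add(node_a)
        parent.add(node_b)
        for k in clusters:
            d_ak = dmat.pop(frozenset((a, k)))
            d_bk = dmat.pop(frozenset((b, k)))
            dmat[frozenset((next_index, k))] = (n_a * d_ak + n_b * d_bk) / (n_a + n_b)
        dmat.pop(frozenset((a, b)))
        clusters[next_index] = (parent, height, n_a + n_b)
        next_index += 1
    (root, _, _), = clusters.values()
    return PhyloTree(root)


def reroot_at_query(tree: PhyloTree, query_label: str) -> PhyloTree:
    """Reroot so the query leaf becomes the root; template weights reset to 1.

    Edge lengths are preserved, so every query-to-template path length is
    unchanged.  Idempotent when the query is already the root.
    """
    tree = tree.copy()
    query = None
    for n in tree.nodes():
        if n.name == query_label:
            query = n
            break
    if query is None:
        raise KeyError(f"no node named {query_label!r}")
    if query is tree.root:
        out = tree
    else:
        # reverse the parent chain above the query; the edge between chain[i]
        # and chain[i+1] keeps its length but flips direction
        chain = []
        node = query
        while node is not None:
            chain.append(node)
            node = node.parent
        lengths = [n.length for n in chain]
        for child, parent in zip(chain, chain[1:]):
            parent.children.remove(child)
        for i, (child, parent) in enumerate(zip(chain, chain[1:])):
            child.add(parent)
            parent.length = lengths[i]
        query.parent = None
        query.length = 0.0
        out = PhyloTree(query)
    _drop_unary(out.root)
    for leaf in out.leaves():
        if leaf is not out.root:
            leaf.weight = 1.0
    out.root.weight = None
    return out


def _drop_unary(node: TreeNode) -> None:
    """Splice out internal nodes with a single child (created by rerooting)."""
    for child in list(node.children):
        _drop_unary(child)
    if len(node.children) == 1 and node.parent is not None:
        (only,) = node.children
        only.length += node.length
        parent = node.parent
        idx = parent.children.index(node)
        parent.children[idx] = only
        only.parent = parent


# ---------------------------------------------------------------------------
# the elementary step and the star transformation


def elementary_step(tau0: float, taus, ws):
    """Collapse one hidden node: update the weights of its child templates.

    ``tau0`` is the edge above the hidden node, ``taus`` the edges to the K
    children, ``ws`` their current weights.  Returns the updated weights

        w'_k = [(1/tau0 + 1/tau_k) / (1/tau0 + sum_l w_l / tau_l)] * w_k.

    For K = 1 with w = 1 this is exactly 1.  The sum of updated weights tends
    to 1 as tau0 >> max(tau_k) (fully redundant templates) and to sum(w) as
    tau0 << min(tau_k) (independent templates).
    """
    taus = np.asarray(taus, dtype=float)
    ws = np.asarray(ws, dtype=float)
    if taus.size == 0:
        raise ValueError("elementary step needs at least one child")
    if taus.shape != ws.shape:
        raise ValueError("taus and ws must have equal length")
    tau0 = max(float(tau0), TAU_MIN)
    taus = np.maximum(taus, TAU_MIN)
    denom = 1.0 / tau0 + np.sum(ws / taus)
    return (1.0 / tau0 + 1.0 / taus) / denom * ws


def star_transform(tree: PhyloTree, order: str = "deepest") -> PhyloTree:
    """Iteratively collapse hidden nodes until the tree is a star around the root.

    Each step removes one internal node all of whose children are leaves and
    re-attaches those leaves to the node's parent with edge length
    ``tau0 + tau_k`` (preserving root-to-leaf path lengths) and weights from
    :func:`elementary_step`.  ``order`` selects which eligible node is
    collapsed first (``deepest``, ``shallowest`` or ``first``); the final
    weights do not depend on it.  Idempotent on star trees.
    """
    if order not in ("deepest", "shallowest", "first"):
        raise ValueError(f"unknown collapse order {order!r}")
    tree = tree.copy()
    for leaf in tree.leaves():
        if leaf.weight is None:
            leaf.weight = 1.0

    def _depth(n: TreeNode) -> int:
        d = 0
        while n.parent is not None:
            d += 1
            n = n.parent
        return d

    while not tree.is_star():
        eligible = [
            n
            for n in tree.nodes()
            if n.parent is not None and not n.is_leaf and all(c.is_leaf for c in n.children)
        ]
        if not eligible:  # pragma: no cover - unreachable on well-formed trees
            raise RuntimeError("no collapsible node found; is the input acyclic?")
        if order == "deepest":
            node = max(eligible, key=_depth)
        elif order == "shallowest":
            node = min(eligible, key=_depth)
        else:
            node = eligible[0]
        tau0 = max(node.length, TAU_MIN)
        taus = [max(c.length, TAU_MIN) for c in node.children]
        ws = [c.weight for c in node.children]
        new_ws = elementary_step(tau0, taus, ws)
        parent = node.parent
        parent.children.remove(node)
        for child, w_new in zip(node.children, new_ws):
            child.length = tau0 + child.length
            child.weight = float(w_new)
            parent.add(child)
    return tree


def template_weights(tree: PhyloTree, order: str = "deepest") -> WeightedTemplateSet:
    """Star-transform ``tree`` and read off (template_id, weight, path_length)."""
    star = star_transform(tree, order=order)
    entries = [
        (leaf.name, float(leaf.weight), float(leaf.length)) for leaf in star.root.children
    ]
    return WeightedTemplateSet(entries=entries)


# ---------------------------------------------------------------------------
# numerical-integration equivalence oracle


def numeric_tree_odds(
    tree: PhyloTree,
    leaf_distances: dict[str, float],
    model: DiffusionModel,
    grid: np.ndarray,
    check_convergence: bool = True,
    tol: float = 1e-4,
) -> np.ndarray:
    """Restraint curve on the query distance ``d_0`` by brute-force integration.

    Messages are passed from the leaves to the root on ``grid``: a leaf with
    observed distance ``d_k``, weight ``w_k`` and edge ``tau`` sends
    ``N(x | d_k, gamma * tau)^{w_k}``; an internal node convolves the product
    of its children's messages with its own edge kernel (trapezoidal rule).
    The product of the root's incoming messages, normalized to integrate to
    one over the grid, is returned.  With a flat background this normalized
    posterior is proportional to the odds ratio ``p(d_0 | d_1..d_K) / p(d_0)``,
    so two trees are equivalent iff their curves coincide.

    With ``check_convergence`` the computation is repeated on the
    half-resolution grid; if the curves drift by more than ``tol`` the grid is
    declared too coarse and a ValueError is raised.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 8:
        raise ValueError("grid must be a 1-D array with at least 8 points")

    def _posterior(g: np.ndarray) -> np.ndarray:
        def _message(node: TreeNode, tau: float) -> np.ndarray:
            # message from `node` to its parent, evaluated on parent grid g
            var = model.gamma * max(tau, TAU_MIN)
            if node.is_leaf:
                d_k = leaf_distances[node.name]
                w_k = 1.0 if node.weight is None else node.weight
                logk = -0.5 * (g - d_k) ** 2 / var - 0.5 * np.log(2 * np.pi * var)
                return np.exp(w_k * logk)
            inner = np.ones_like(g)
            for child in node.children:
                inner = inner * _message(child, child.length)
            kernel = np.exp(
                -0.5 * (g[:, None] - g[None, :]) ** 2 / var
            ) / math.sqrt(2 * np.pi * var)
            return np.trapezoid(kernel * inner[None, :], g, axis=1)

        post = np.ones_like(g)
        for child in tree.root.children:
            post = post * _message(child, child.length)
        area = np.trapezoid(post, g)
        if not area > 0:
            raise ValueError("posterior mass vanished on the grid; widen it")
        return post / area

    curve = _posterior(grid)
    if check_convergence:
        coarse = _posterior(grid[::2])
        drift = np.max(np.abs(coarse - curve[::2]))
        if drift > tol * max(np.max(curve), 1.0):
            raise ValueError(
                f"integration grid too coarse: drift {drift:.3g} when halving resolution"
            )
    return curve
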