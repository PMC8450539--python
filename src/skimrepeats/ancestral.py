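"""ML ancestral genome-size reconstruction under Brownian motion.

Under Brownian motion a continuous trait accumulates variance linearly
along branches, so tip values are jointly Gaussian with covariance
equal to shared root-to-tip path length times the rate sigma^2. The ML
(equivalently GLS/BLUE) ancestral state at any node is the GLS mean of
the tree re-rooted at that node; the same re-rooting view gives the
estimate's variance, which is how confidence intervals are reported
here. Estimates depend only on relative branch lengths.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Optional

import dendropy
import numpy as np

__all__ = ["PhyloTree", "AncestralStateResult", "ml_ancestral_bm", "branch_deltas"]


@dataclass
class PhyloTree:
    """A rooted tree with branch lengths and tip 1C values (Mb)."""

    tree: dendropy.Tree
    tip_values: dict[str, float]

    @classmethod
    def from_newick(
        cls,
        newick: str,
        tip_values: dict[str, float],
        polytomy_epsilon_fraction: float = 1e-8,
    ) -> "PhyloTree":
        """Parse a Newick string (or path contents) and validate.

        Polytomies are resolved arbitrarily with epsilon-length
        branches (a fixed fraction of tree height): the ML solution is
        continuous in branch lengths, so the resolution is harmless.
        """
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        had_polytomy = any(
            len(n.child_nodes()) > 2 for n in tree.preorder_node_iter()
        )
        if had_polytomy:
            height = max(
                leaf.distance_from_root() for leaf in tree.leaf_node_iter()
            )
            tree.resolve_polytomies()
            for edge in tree.preorder_edge_iter():
                if edge.head_node is tree.seed_node:
                    continue
                if edge.length is None or edge.length == 0:
                    edge.length = polytomy_epsilon_fraction * height
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(labels) < 2:
            raise ValueError("tree must have at least 2 tips")
        missing = set(labels) - set(tip_values)
        if missing:
            raise ValueError(f"missing tip values for {sorted(missing)}")
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None or edge.length <= 0:
                raise ValueError(
                    f"non-positive branch length above {edge.head_node}"
                )
        return cls(tree=tree, tip_values={l: float(tip_values[l]) for l in labels})

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]


@dataclass
class AncestralStateResult:
    """Per-node BM estimates plus the ML rate and per-tip deltas."""

    node_estimates: dict[str, float]  # node id -> estimate (Mb)
    node_variances: dict[str, float]  # re-rooting variance of the estimate
    sigma_squared: float
    tip_values: dict[str, float]
    root_id: str

    def estimate(self, node_id: str) -> float:
        return self.node_estimates[node_id]


def _node_label(node: dendropy.Node, counter: dict) -> str:
    if node.taxon is not None:
        return node.taxon.label
    if node.label:
        return node.label
    counter["n"] += 1
    return f"node{counter['n']}"


def ml_ancestral_bm(phylo: PhyloTree) -> AncestralStateResult:
    """ML ancestral states under Brownian motion.

    For each internal node ``a`` the estimate is the GLS mean of the
    tip values under the tree re-rooted at ``a``:

        ahat = (1' C_a^-1 x) / (1' C_a^-1 1),
        var(ahat) = sigma^2 / (1' C_a^-1 1),

    where C_a[i, j] is the shared path length of tips i and j measured
    from ``a``. sigma^2 is the ML estimate from the residuals at the
    root. Estimates are independent of tip input order.
    """
    tree = phylo.tree
    tips = list(tree.leaf_node_iter())
    labels = [t.taxon.label for t in tips]
    x = np.array([phylo.tip_values[l] for l in labels], dtype=float)
    n = len(tips)
    if n < 2:
        raise ValueError("need at least 2 tips")

    pdm = tree.phylogenetic_distance_matrix()
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(tips[i].taxon, tips[j].taxon)
            dist[i, j] = dist[j, i] = d

    counter = {"n": 0}
    estimates: dict[str, float] = {}
    variances: dict[str, float] = {}
    root_id: Optional[str] = None
    sigma2: Optional[float] = None
    ones = np.ones(n)

    # distance from every node to every tip, via root-to-node depths:
    # d(a, tip_i) = depth(tip_i) + depth(a) - 2 * depth(mrca(a, tip_i));
    # computed directly by traversal instead.
    node_tip_dist = _node_to_tip_distances(tree, tips)

    for node in tree.preorder_node_iter():
        nid = _node_label(node, counter)
        if node.is_leaf():
            estimates[nid] = phylo.tip_values[nid]
            variances[nid] = 0.0
            continue
        d_a = node_tip_dist[id(node)]
        # re-rooted covariance: shared path length from node a
        c_a = 0.5 * (d_a[:, None] + d_a[None, :] - dist)
        np.fill_diagonal(c_a, d_a)
        cinv = np.linalg.inv(c_a)
        denom = ones @ cinv @ ones
        ahat = (ones @ cinv @ x) / denom
        estimates[nid] = float(ahat)
        variances[nid] = float(1.0 / denom)  # scaled by sigma^2 below
        if node is tree.seed_node:
            root_id = nid
            resid = x - ahat
            sigma2 = float(resid @ cinv @ resid) / n

    assert root_id is not None and sigma2 is not None
    variances = {k: v * sigma2 for k, v in variances.items()}
    return AncestralStateResult(
        node_estimates=estimates,
        node_variances=variances,
        sigma_squared=sigma2,
        tip_values=dict(phylo.tip_values),
        root_id=root_id,
    )


def _node_to_tip_distances(tree: dendropy.Tree, tips) -> dict[int, np.ndarray]:
    """Distance from each node to every tip, by two traversals."""
    tip_index = {id(t): k for k, t in enumerate(tips)}
    n = len(tips)
    # downward: distances to tips within each node's subtree
    down: dict[int, dict[int, float]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            down[id(node)] = {tip_index[id(node)]: 0.0}
        else:
            d = {}
            for child in node.child_nodes():
                bl = child.edge.length or 0.0
                for k, v in down[id(child)].items():
                    d[k] = v + bl
            down[id(node)] = d
    # upward sweep completes distances to tips outside the subtree
    full: dict[int, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        arr = np.zeros(n)
        for k, v in down[id(node)].items():
            arr[k] = v
        parent = node.parent_node
        if parent is not None:
            bl = node.edge.length or 0.0
            parr = full[id(parent)]
            inside = set(down[id(node)])
            for k in range(n):
                if k not in inside:
                    arr[k] = parr[k] + bl
        full[id(node)] = arr
    return full


def branch_deltas(
    result: AncestralStateResult, reference_node: str
) -> dict[str, float]:
    """Signed per-tip change versus a reference (usually MRCA) node.

    Positive = genome expansion since the reference node; negative =
    reduction.
    """
    if reference_node not in result.node_estimates:
        raise KeyError(f"unknown node {reference_node!r}")
    ref = result.node_estimates[reference_node]
    return {tip: value - ref for tip, value in result.tip_values.items()}
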