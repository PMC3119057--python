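"""Rooted, branch-length-bearing phylogenies and the distance services built on them.

The analyses in this package consume a phylogeny through two derived
matrices: the tip variance–covariance matrix (shared root-to-MRCA path
lengths, the quantity Brownian-motion trait models and Blomberg's K are
defined on) and the cophenetic distance matrix (total tip-to-tip path
length, the quantity MPD/MNTD-style community metrics are defined on).
:class:`Phylogeny` wraps a :class:`dendropy.Tree` and caches both.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "yule_tree",
    "brownian_trait",
    "ultrametricize",
    "taxonomy_tree",
]


class Phylogeny:
    """A rooted tree with branch lengths, indexed by tip label.

    Parameters
    ----------
    tree:
        A rooted :class:`dendropy.Tree`. Every edge except the root's
        must carry a (non-negative) branch length.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self.taxa: list[str] = sorted(t.taxon.label for t in tree.leaf_node_iter())
        if len(self.taxa) != len(set(self.taxa)):
            raise ValueError("duplicate tip labels in tree")
        self._index = {name: i for i, name in enumerate(self.taxa)}
        self._vcv: np.ndarray | None = None

    # ------------------------------------------------------------------ IO
    @classmethod
    def from_newick(cls, source: str) -> "Phylogeny":
        """Read a newick string or file path."""
        if "(" in source:
            tree = dendropy.Tree.get(data=source, schema="newick")
        else:
            tree = dendropy.Tree.get(path=source, schema="newick")
        return cls(tree)

    def to_newick(self) -> str:
        out = io.StringIO()
        self._tree.write(file=out, schema="newick", suppress_rooting=True)
        return out.getvalue().strip()

    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def n_tips(self) -> int:
        return len(self.taxa)

    # -------------------------------------------------------- derived views
    def vcv_matrix(self) -> np.ndarray:
        """Tip variance–covariance matrix V.

        ``V[i, j]`` is the branch-length distance from the root to the
        most recent common ancestor of tips i and j; ``V[i, i]`` is the
        root-to-tip distance. Rows/columns follow :attr:`taxa` order.
        """
        if self._vcv is None:
            n = self.n_tips
            V = np.zeros((n, n))
            # postorder: each node knows the tip indices below it; tips in
            # different child subtrees share this node as their MRCA.
            below: dict[dendropy.Node, list[int]] = {}
            for node in self._tree.postorder_node_iter():
                if node.is_leaf():
                    below[node] = [self._index[node.taxon.label]]
                else:
                    kids = [below[c] for c in node.child_nodes()]
                    depth = self._node_depth(node)
                    for a in range(len(kids)):
                        for b in range(a + 1, len(kids)):
                            ia = np.asarray(kids[a])
                            ib = np.asarray(kids[b])
                            V[np.ix_(ia, ib)] = depth
                            V[np.ix_(ib, ia)] = depth
                    below[node] = [i for k in kids for i in k]
            for leaf in self._tree.leaf_node_iter():
                i = self._index[leaf.taxon.label]
                V[i, i] = self._node_depth(leaf)
            self._vcv = V
        return self._vcv

    def cophenetic_matrix(self) -> np.ndarray:
        """Tip-to-tip patristic distances, in :attr:`taxa` order."""
        V = self.vcv_matrix()
        d = np.diag(V)
        D = d[:, None] + d[None, :] - 2.0 * V
        np.fill_diagonal(D, 0.0)
        return D

    def tip_depths(self) -> np.ndarray:
        return np.diag(self.vcv_matrix()).copy()

    def is_ultrametric(self, rtol: float = 1e-9) -> bool:
        d = self.tip_depths()
        span = d.max() - d.min()
        return bool(span <= rtol * max(d.max(), 1e-300))

    def _node_depth(self, node: dendropy.Node) -> float:
        depth = 0.0
        while node.parent_node is not None:
            depth += node.edge.length if node.edge.length is not None else 0.0
            node = node.parent_node
        return depth


# --------------------------------------------------------------------------
# simulation


def yule_tree(n_tips: int, rng: np.random.Generator, rate: float = 1.0) -> Phylogeny:
    """Simulate a pure-birth (Yule) tree and rescale root depth to 1.

    Lineages split at rate ``rate`` each; after the n-th tip appears the
    clock runs one further exponential waiting time so no terminal branch
    has zero length. Tips are labelled ``sp001 ...`` in a random order.
    """
    if n_tips < 2:
        raise ValueError("a Yule tree needs at least 2 tips")
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    # the root split defines time 0; each active leaf records its birth time
    active = []
    for _ in range(2):
        child = tree.seed_node.new_child()
        child.birth = 0.0
        active.append(child)
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (rate * len(active)))
        node = active.pop(rng.integers(len(active)))
        node.edge.length = t - node.birth
        for _ in range(2):
            child = node.new_child()
            child.birth = t
            active.append(child)
    t += rng.exponential(1.0 / (rate * len(active)))
    labels = [f"sp{i + 1:03d}" for i in range(n_tips)]
    order = rng.permutation(n_tips)
    for node, k in zip(active, order):
        node.edge.length = t - node.birth
        node.taxon = taxa.new_taxon(labels[k])
    # rescale so the root-to-tip depth is exactly 1
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= t
    return Phylogeny(tree)


def brownian_trait(
    phylogeny: Phylogeny, rng: np.random.Generator, sigma2: float = 1.0
) -> dict[str, float]:
    """One Brownian-motion trait realization; variance rate per unit branch."""
    values: dict[dendropy.Node, float] = {}
    out: dict[str, float] = {}
    for node in phylogeny.tree.preorder_node_iter():
        if node.parent_node is None:
            values[node] = 0.0
        else:
            bl = node.edge.length or 0.0
            values[node] = values[node.parent_node] + rng.normal(
                0.0, np.sqrt(sigma2 * bl)
            )
        if node.is_leaf():
            out[node.taxon.label] = values[node]
    return out


# --------------------------------------------------------------------------
# tree surgery


def ultrametricize(phylogeny: Phylogeny, method: str = "mean_path") -> Phylogeny:
    """Force equal root-to-tip depths while keeping the topology.

    ``mean_path`` assigns every internal node the mean of its node-to-tip
    path lengths as its age (tips have age 0), raised where necessary so a
    parent is never younger than a child, then rewrites branch lengths as
    age differences. Idempotent on trees that are already ultrametric.
    """
    if method != "mean_path":
        raise ValueError(f"unknown ultrametricization method: {method!r}")
    tree = dendropy.Tree(phylogeny.tree)  # deep clone
    if tree.seed_node is None or len(tree.seed_node.child_nodes()) == 0:
        raise ValueError("tree has no structure to ultrametricize")
    age: dict[dendropy.Node, float] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            age[node] = 0.0
        else:
            # mean over all descendant tips of the path length to them
            paths: list[float] = []
            stack = [(c, c.edge.length or 0.0) for c in node.child_nodes()]
            while stack:
                n, d = stack.pop()
                if n.is_leaf():
                    paths.append(d)
                else:
                    stack.extend((c, d + (c.edge.length or 0.0)) for c in n.child_nodes())
            a = float(np.mean(paths))
            kid_max = max(age[c] for c in node.child_nodes())
            age[node] = max(a, kid_max)
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = age[node.parent_node] - age[node]
    return Phylogeny(tree)


def taxonomy_tree(taxonomy) -> Phylogeny:
    """Build a taxonomy-backbone ("Phylomatic-style") tree.

    ``taxonomy`` is a DataFrame-like with columns ``species``, ``genus``,
    ``family``. The tree is root → family polytomies → genus polytomies →
    species tips with unit branch lengths at every level, so it is
    ultrametric with depth 3: congeners sit at cophenetic distance 2,
    confamilial non-congeners at 4, everything else at 6.
    """
    import pandas as pd

    df = pd.DataFrame(taxonomy)
    for col in ("species", "genus", "family"):
        if col not in df.columns:
            raise ValueError(f"taxonomy table lacks required column {col!r}")
        if df[col].isna().any() or (df[col].astype(str).str.len() == 0).any():
            raise ValueError(f"taxonomy table has missing values in {col!r}")
    if df["species"].duplicated().any():
        raise ValueError("duplicate species in taxonomy table")
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    for family, fam_df in df.groupby("family", sort=True):
        fam_node = tree.seed_node.new_child(edge_length=1.0)
        for genus, gen_df in fam_df.groupby("genus", sort=True):
            gen_node = fam_node.new_child(edge_length=1.0)
            for sp in sorted(gen_df["species"]):
                leaf = gen_node.new_child(edge_length=1.0)
                leaf.taxon = taxa.new_taxon(sp)
    return Phylogeny(tree)
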