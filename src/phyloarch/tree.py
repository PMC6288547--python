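"""Rooted phylogenies with branch lengths and the Brownian-motion covariance.

The :class:`PhyloTree` is an immutable array-backed structure (parent links,
branch lengths in Myr, children lists) built from a dendropy Newick parse.
It is the shared substrate of every comparative operation in this package:
likelihood traversals walk ``postorder``, and Brownian-motion machinery uses
:func:`vcv` / :func:`lambda_transform`.

Conventions
-----------
* Branch lengths are required on every non-root edge; internal node labels
  are tolerated and preserved; support values are not parsed specially.
* Polytomies are allowed (individual analyses may reject them).
* Ultrametricity is advisory: :meth:`PhyloTree.is_ultrametric` checks all
  root-to-tip path lengths agree to a relative tolerance (default 1e-6), but
  nothing errors on failure because empirical trees are numerically imperfect.
* Species order in :class:`PhyloCovariance` is canonical (sorted tip labels)
  so downstream outputs are bit-stable.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "PhyloCovariance",
    "NewickError",
    "read_newick",
    "write_newick",
    "prune_tips",
    "vcv",
    "lambda_transform",
]


class NewickError(ValueError):
    """Malformed Newick input (parse failure, duplicate labels, missing lengths)."""


@dataclass(frozen=True)
class PhyloTree:
    """A rooted tree: parent links, branch lengths (Myr), per-node labels.

    Node 0 is always the root.  ``lengths[i]`` is the length of the edge above
    node ``i`` (0.0 for the root).  Tips are the nodes with no children; every
    tip carries a unique label.
    """

    parent: np.ndarray            # (n_nodes,) int, -1 for root
    lengths: np.ndarray           # (n_nodes,) float, length of edge above node
    children: tuple               # tuple of tuples of child indices
    labels: tuple                 # per-node label or None

    def __post_init__(self):
        if self.parent[0] != -1:
            raise ValueError("node 0 must be the root")
        if np.sum(self.parent == -1) != 1:
            raise ValueError("exactly one root required")
        if np.any(self.lengths < 0):
            raise ValueError("branch lengths must be >= 0")
        tips = [self.labels[i] for i in self.tip_indices]
        if any(t is None for t in tips):
            raise ValueError("every tip must be labelled")
        if len(set(tips)) != len(tips):
            dup = sorted({t for t in tips if tips.count(t) > 1})
            raise NewickError(f"duplicate tip labels: {dup}")

    # -- basic structure ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return 0

    @functools.cached_property
    def tip_indices(self) -> np.ndarray:
        return np.array([i for i in range(self.n_nodes) if not self.children[i]],
                        dtype=np.int64)

    @property
    def n_tips(self) -> int:
        return len(self.tip_indices)

    @property
    def tip_labels(self) -> list:
        """Tip labels in internal node order (not sorted)."""
        return [self.labels[i] for i in self.tip_indices]

    @functools.cached_property
    def postorder(self) -> np.ndarray:
        """All node indices, children always before parents (cached; do not
        mutate)."""
        order, stack = [], [0]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        return np.array(order[::-1], dtype=np.int64)

    @functools.cached_property
    def _depths(self) -> np.ndarray:
        d = np.zeros(self.n_nodes)
        for v in self.postorder[::-1]:         # preorder
            p = self.parent[v]
            if p >= 0:
                d[v] = d[p] + self.lengths[v]
        return d

    def depths(self) -> np.ndarray:
        """Root-to-node path length for every node (cached; do not mutate)."""
        return self._depths

    def is_ultrametric(self, rtol: float = 1e-6) -> bool:
        td = self.depths()[self.tip_indices]
        scale = max(td.max(), 1e-300)
        return bool((td.max() - td.min()) / scale <= rtol)

    def crown_age(self) -> float:
        return float(self.depths()[self.tip_indices].max())

    def node_times(self) -> np.ndarray:
        """Time before present of every node (tips of an ultrametric tree ~ 0)."""
        d = self.depths()
        return d[self.tip_indices].max() - d

    @functools.cached_property
    def _bifurcating(self) -> bool:
        return all(len(c) in (0, 2) for c in self.children)

    def is_bifurcating(self) -> bool:
        return self._bifurcating

    def rescale(self, crown_age: float) -> "PhyloTree":
        """Return a copy with all branch lengths scaled so the crown age matches."""
        f = crown_age / self.crown_age()
        return PhyloTree(self.parent.copy(), self.lengths * f,
                         self.children, self.labels)

    def tip_index_of(self) -> dict:
        return {self.labels[i]: i for i in self.tip_indices}

    # -- convenience -------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        return read_newick(text)

    def to_newick(self) -> str:
        return write_newick(self)


@dataclass(frozen=True)
class PhyloCovariance:
    """Brownian-motion covariance: entries are shared root-to-MRCA path lengths."""

    matrix: np.ndarray
    species: tuple = field(default=())

    def __post_init__(self):
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("covariance must be square")
        if not np.allclose(m, m.T, rtol=1e-10, atol=1e-12):
            raise ValueError("covariance must be symmetric")
        d = np.diag(m)
        if np.any(m > np.minimum.outer(d, d) + 1e-9 * max(d.max(), 1.0)):
            raise ValueError("off-diagonal entries exceed the smaller diagonal")


# ---------------------------------------------------------------------------
# Newick I/O (dendropy backend)
# ---------------------------------------------------------------------------

def read_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`.

    Branch lengths are required on all non-root edges; polytomies and internal
    node labels are preserved.  Raises :class:`NewickError` on malformed input
    or duplicate tip labels, naming the offending token.
    """
    try:
        dt = dendropy.Tree.get(data=text, schema="newick",
                               preserve_underscores=True,
                               suppress_internal_node_taxa=False)
    except Exception as exc:  # dendropy raises assorted parse errors
        raise NewickError(f"malformed Newick: {exc}") from exc

    nodes = [dt.seed_node]
    index = {id(dt.seed_node): 0}
    for nd in dt.preorder_node_iter():
        if nd is dt.seed_node:
            continue
        index[id(nd)] = len(nodes)
        nodes.append(nd)

    n = len(nodes)
    parent = np.full(n, -1, dtype=np.int64)
    lengths = np.zeros(n)
    children: list = [[] for _ in range(n)]
    labels: list = [None] * n
    for nd in nodes:
        i = index[id(nd)]
        lab = None
        if nd.taxon is not None and nd.taxon.label:
            lab = str(nd.taxon.label)
        elif nd.label:
            lab = str(nd.label)
        labels[i] = lab
        if nd is not dt.seed_node:
            p = index[id(nd.parent_node)]
            parent[i] = p
            children[p].append(i)
            if nd.edge.length is None:
                raise NewickError(
                    f"missing branch length on edge above {lab or 'an internal node'}")
            if nd.edge.length < 0:
                raise NewickError(f"negative branch length above {lab}")
            lengths[i] = float(nd.edge.length)

    tip_labs = [labels[i] for i in range(n) if not children[i]]
    if any(t is None for t in tip_labs):
        raise NewickError("unlabelled tip in Newick input")
    seen: set = set()
    for t in tip_labs:
        if t in seen:
            raise NewickError(f"duplicate tip label: {t!r}")
        seen.add(t)

    return PhyloTree(parent, lengths, tuple(tuple(c) for c in children),
                     tuple(labels))


def write_newick(tree: PhyloTree) -> str:
    """Serialize with full-precision (repr) branch lengths for exact round-trips."""

    def fmt(v: int) -> str:
        kids = tree.children[v]
        lab = tree.labels[v] or ""
        if any(ch in lab for ch in " (),:;'"):
            lab = "'" + lab.replace("'", "''") + "'"
        inner = f"({','.join(fmt(c) for c in kids)})" if kids else ""
        br = "" if tree.parent[v] < 0 else f":{float(tree.lengths[v])!r}"
        return f"{inner}{lab}{br}"

    return fmt(tree.root) + ";"


# ---------------------------------------------------------------------------
# Structure operations
# ---------------------------------------------------------------------------

def prune_tips(tree: PhyloTree, drop) -> PhyloTree:
    """Remove the given tips; suppress resulting degree-2 nodes (lengths summed).

    If all but one child subtree of the root is removed, the root descends to
    the surviving subtree's top node (its stem edge is discarded), as in the
    usual drop-tip convention.  Pairwise MRCA depths of retained tips are
    never altered.
    """
    drop = set(drop)
    labs = set(tree.tip_labels)
    unknown = drop - labs
    if unknown:
        raise KeyError(f"tips not in tree: {sorted(unknown)}")
    if len(labs - drop) < 2:
        raise ValueError("fewer than 2 tips would remain")

    # Rebuild top-down, skipping dropped tips and suppressing unary nodes.
    def build(v, acc_len):
        kids = tree.children[v]
        if not kids:
            if tree.labels[v] in drop:
                return None
            return ("tip", tree.labels[v], acc_len)
        sub = []
        for c in kids:
            r = build(c, tree.lengths[c])
            if r is not None:
                sub.append(r)
        if not sub:
            return None
        if len(sub) == 1:
            kind, payload, l = sub[0]
            return (kind, payload, l + acc_len)
        return ("node", (tree.labels[v], sub), acc_len)

    built = build(tree.root, 0.0)
    if built is None or built[0] == "tip":
        raise ValueError("fewer than 2 tips would remain")

    parent_l, length_l, children_l, labels_l = [], [], [], []

    def emit(node, parent_idx):
        kind, payload, l = node
        idx = len(parent_l)
        parent_l.append(parent_idx)
        length_l.append(l if parent_idx >= 0 else 0.0)
        children_l.append([])
        if parent_idx >= 0:
            children_l[parent_idx].append(idx)
        if kind == "tip":
            labels_l.append(payload)
        else:
            lab, sub = payload
            labels_l.append(lab)
            for s in sub:
                emit(s, idx)

    emit(built, -1)
    return PhyloTree(np.array(parent_l, dtype=np.int64), np.array(length_l),
                     tuple(tuple(c) for c in children_l), tuple(labels_l))


# ---------------------------------------------------------------------------
# Brownian-motion covariance
# ---------------------------------------------------------------------------

def vcv(tree: PhyloTree, order=None) -> PhyloCovariance:
    """Brownian covariance C with C[i,j] = depth of MRCA(i,j), C[i,i] = tip depth.

    Species order defaults to sorted tip labels (canonical, bit-stable).
    """
    if order is None:
        order = sorted(tree.tip_labels)
    pos = {lab: k for k, lab in enumerate(order)}
    missing = set(tree.tip_labels) - set(order)
    if missing or len(order) != tree.n_tips:
        raise ValueError("order must be a permutation of the tip labels")

    depth = tree.depths()
    n = tree.n_tips
    C = np.zeros((n, n))
    tipsets: dict = {}
    for v in tree.postorder:
        kids = tree.children[v]
        if not kids:
            k = pos[tree.labels[v]]
            C[k, k] = depth[v]
            tipsets[v] = [k]
        else:
            groups = [tipsets.pop(c) for c in kids]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    for i in groups[a]:
                        for j in groups[b]:
                            C[i, j] = C[j, i] = depth[v]
            tipsets[v] = [i for g in groups for i in g]
    return PhyloCovariance(C, tuple(order))


def vcv_subset(tree: PhyloTree, species) -> np.ndarray:
    """Brownian covariance restricted (and ordered) to the given tip subset."""
    order = sorted(tree.tip_labels)
    C = vcv(tree, order=order).matrix
    idx = [order.index(s) for s in species]
    return C[np.ix_(idx, idx)]


def lambda_transform(C: PhyloCovariance, lam: float,
                     allow_above_one: bool = False) -> PhyloCovariance:
    """Pagel's lambda rescaling: off-diagonal entries × lam, diagonal unchanged.

    ``lam`` must lie in [0, 1] unless ``allow_above_one`` is set, in which case
    it may extend up to the matrix-feasible maximum (checked via PSD).
    """
    hi = 1.0 if not allow_above_one else np.inf
    if not (0.0 <= lam <= hi):
        raise ValueError(f"lambda must be in [0, {hi}], got {lam}")
    M = C.matrix * lam
    np.fill_diagonal(M, np.diag(C.matrix))
    if allow_above_one and lam > 1.0:
        w = np.linalg.eigvalsh(M)
        if w.min() < -1e-9 * max(abs(w).max(), 1.0):
            raise ValueError(f"lambda={lam} makes the covariance indefinite")
    return PhyloCovariance(M, C.species)
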