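"""Ordination and tree building on a distance matrix.

Two standard visualization inputs for population-structure matrices:

* classical (Torgerson) multidimensional scaling — eigendecomposition of the
  double-centered squared-distance matrix, giving coordinates whose pairwise
  Euclidean distances approximate the input distances;
* the neighbor-joining algorithm of Saitou and Nei — agglomeration on the
  Q criterion, exact on additive matrices.

Distances are used as given (Rst values are plotted raw, not transformed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .amova import DistanceMatrix


# ---------------------------------------------------------------------------
# classical MDS
# ---------------------------------------------------------------------------

@dataclass
class MDSResult:
    """Classical-scaling embedding.

    ``coordinates`` is populations x dims (column-centered, axis signs fixed
    so the largest-magnitude loading on each axis is positive);
    ``eigenvalues`` holds the full descending spectrum of the
    double-centered matrix (negative values diagnose non-Euclidean input);
    ``goodness`` is the fraction of positive-eigenvalue mass captured by the
    retained axes.
    """

    labels: list[str]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    goodness: float


def classical_mds(d: DistanceMatrix, dims: int = 2) -> MDSResult:
    """Torgerson scaling of a symmetric zero-diagonal distance matrix.

    Squares the distances, double-centers (B = -1/2 J D2 J), and keeps the
    top ``dims`` positive-eigenvalue axes scaled by sqrt(eigenvalue). If
    fewer positive eigenvalues exist, the returned dimensionality is reduced
    with a warning.
    """
    if dims < 1:
        raise ValueError("dims must be >= 1")
    m = d.size
    d2 = d.values**2
    j = np.eye(m) - np.ones((m, m)) / m
    b = -0.5 * j @ d2 @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(abs(eigval[0]), 1.0) * 1e-12 if m else 0.0
    n_pos = int((eigval > tol).sum())
    use = min(dims, n_pos)
    if use < dims:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; returning {use} dimension(s)",
            stacklevel=2,
        )
    if use == 0:
        return MDSResult(list(d.labels), np.zeros((m, dims)), eigval, 0.0)
    coords = eigvec[:, :use] * np.sqrt(eigval[:use])
    # reproducible axis orientation
    for ax in range(use):
        col = coords[:, ax]
        if col[np.argmax(np.abs(col))] < 0:
            coords[:, ax] = -col
    pos_mass = eigval[eigval > tol].sum()
    goodness = float(eigval[:use].sum() / pos_mass) if pos_mass > 0 else 0.0
    return MDSResult(list(d.labels), coords, eigval, goodness)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """Node of a rooted representation of an unrooted tree.

    ``length`` is the branch length to the parent (ignored at the root).
    """

    label: str | None = None
    length: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    def walk(self) -> Iterator["TreeNode"]:
        yield self
        for child in self.children:
            yield from child.walk()

    @property
    def is_leaf(self) -> bool:
        return not self.children


_NEWICK_UNSAFE = set(" \t()[]:;,'")


def _newick_label(label: str) -> str:
    if any(c in _NEWICK_UNSAFE for c in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _format_length(x: float) -> str:
    x = float(x)
    if x == int(x):
        return str(int(x))
    return repr(x)  # shortest round-tripping decimal


@dataclass
class Tree:
    """Unrooted tree with labelled leaves, stored rooted at an internal node."""

    root: TreeNode

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.root.walk() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label or "" for n in self.leaves()]

    def to_newick(self) -> str:
        def render(node: TreeNode, top: bool) -> str:
            if node.is_leaf:
                body = _newick_label(node.label or "")
            else:
                inner = ",".join(render(c, False) for c in node.children)
                body = f"({inner})" + (_newick_label(node.label) if node.label else "")
            if top:
                return body
            return f"{body}:{_format_length(node.length)}"

        return render(self.root, True) + ";"

    def path_length_matrix(self) -> DistanceMatrix:
        """Leaf-to-leaf path lengths (the additive distances the tree implies)."""
        leaves = self.leaves()
        labels = [n.label or "" for n in leaves]
        index = {id(n): i for i, n in enumerate(leaves)}
        m = len(leaves)
        dist = np.zeros((m, m))

        def below(node: TreeNode) -> list[tuple[int, float]]:
            if node.is_leaf:
                return [(index[id(node)], 0.0)]
            gathered: list[list[tuple[int, float]]] = []
            for child in node.children:
                sub = [(i, d + child.length) for i, d in below(child)]
                gathered.append(sub)
            for a in range(len(gathered)):
                for b in range(a + 1, len(gathered)):
                    for i, di in gathered[a]:
                        for j, dj in gathered[b]:
                            dist[i, j] = dist[j, i] = di + dj
            return [pair for sub in gathered for pair in sub]

        below(self.root)
        return DistanceMatrix(labels=labels, values=dist)


def neighbor_joining(d: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining on a symmetric distance matrix.

    At each step the pair minimizing
    ``Q(i, j) = (m - 2) d_ij - sum_k d_ik - sum_k d_jk`` is joined, with ties
    broken by the lowest (row, column) index pair; branch lengths follow the
    standard three-point formulas and are clamped to zero when negative
    (without redistributing length). Exact on additive matrices. With two
    taxa, returns the degenerate single-edge tree.
    """
    m = d.size
    if m < 2:
        raise ValueError("neighbor joining needs at least 2 taxa")
    nodes: list[TreeNode] = [TreeNode(label=lab) for lab in d.labels]
    if m == 2:
        # degenerate single-edge tree: the whole length on one branch
        nodes[0].length = 0.0
        nodes[1].length = float(d.values[0, 1])
        return Tree(root=TreeNode(children=[nodes[0], nodes[1]]))

    work = d.values.astype(float).copy()
    active = list(range(m))  # indices into `nodes` via position in `work`

    while len(active) > 3:
        k = len(active)
        sub = work
        r = sub.sum(axis=1)
        best = None
        best_q = np.inf
        for i in range(k):
            for j in range(i + 1, k):
                q = (k - 2) * sub[i, j] - r[i] - r[j]
                if q < best_q - 1e-15:
                    best_q = q
                    best = (i, j)
        i, j = best  # type: ignore[misc]
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (k - 2))
        lj = dij - li
        child_i, child_j = nodes[active[i]], nodes[active[j]]
        child_i.length = max(li, 0.0)
        child_j.length = max(lj, 0.0)
        parent = TreeNode(children=[child_i, child_j])
        # distances from the new node to the remaining taxa
        new_row = 0.5 * (sub[i, :] + sub[j, :] - dij)
        keep = [t for t in range(k) if t not in (i, j)]
        new = np.zeros((k - 1, k - 1))
        new[:-1, :-1] = sub[np.ix_(keep, keep)]
        new[-1, :-1] = new[:-1, -1] = new_row[keep]
        work = new
        nodes.append(parent)
        active = [active[t] for t in keep] + [len(nodes) - 1]

    # close out the final three nodes on a star
    a, b, c = (nodes[t] for t in active)
    dab, dac, dbc = work[0, 1], work[0, 2], work[1, 2]
    a.length = max(0.5 * (dab + dac - dbc), 0.0)
    b.length = max(0.5 * (dab + dbc - dac), 0.0)
    c.length = max(0.5 * (dac + dbc - dab), 0.0)
    return Tree(root=TreeNode(children=[a, b, c]))
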