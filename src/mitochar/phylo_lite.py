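"""Distance-based tree building: neighbor joining with newick output.

Saitou & Nei's neighbor-joining agglomerates the pair minimizing the
Q-criterion ``Q(i,j) = (n-2) d(i,j) - R_i - R_j`` at each step; on an
additive distance matrix it recovers the generating tree and its branch
lengths exactly.  Negative branch-length estimates are clamped to zero and
the clamped deficit recorded.  Used here as the desk-scale tree builder on
K2P matrices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .molevol import DistanceMatrix


@dataclass
class Node:
    label: str | None = None           # leaf label; None for internal nodes
    children: list[tuple["Node", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_labels(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        out = []
        for child, _ in self.children:
            out.extend(child.leaf_labels())
        return out


@dataclass
class Tree:
    root: Node                         # unrooted tree stored with a trifurcating root
    clamped_total: float = 0.0         # summed magnitude of negative lengths clamped

    def leaf_labels(self) -> list[str]:
        return sorted(self.root.leaf_labels())


def neighbor_joining(D: DistanceMatrix) -> Tree:
    """Standard NJ on a complete distance matrix (≥3 labels)."""
    n = len(D.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 labels")
    bad = [(D.labels[i], D.labels[j])
           for i in range(n) for j in range(i + 1, n)
           if not np.isfinite(D.values[i, j])]
    if bad:
        raise ValueError(f"missing distance entries for pairs: {bad}")

    nodes = [Node(label=lab) for lab in D.labels]
    dist = {(i, j): float(D.values[i, j]) for i in range(n) for j in range(n) if i != j}
    active = list(range(n))
    next_id = n
    clamped = 0.0

    def d(i, j):
        return 0.0 if i == j else dist[(i, j)]

    while len(active) > 2:
        m = len(active)
        R = {i: sum(d(i, k) for k in active) for i in active}
        best, best_q = None, math.inf
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d(i, j) - R[i] - R[j]
                if q < best_q - 1e-12:
                    best_q, best = q, (i, j)
        i, j = best
        li = 0.5 * d(i, j) + (R[i] - R[j]) / (2 * (m - 2)) if m > 2 else 0.5 * d(i, j)
        lj = d(i, j) - li
        for length in (li, lj):
            if length < 0:
                clamped += -length
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = Node(children=[(nodes[i], li), (nodes[j], lj)])
        nodes.append(parent)
        u = next_id
        next_id += 1
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (d(i, k) + d(j, k) - d(i, j))
            dist[(u, k)] = dist[(k, u)] = duk
        active = [k for k in active if k not in (i, j)] + [u]

    # join the final two nodes through a shared root edge
    i, j = active
    dij = d(i, j)
    if dij < 0:
        clamped += -dij
        dij = 0.0
    ni, nj = nodes[i], nodes[j]
    if not nj.is_leaf:  # hang the leaf (or smaller node) off the internal node
        ni, nj = nj, ni
    root = ni
    root.children.append((nj, dij))
    return Tree(root=root, clamped_total=clamped)


def _newick(node: Node, length: float | None, ndigits: int = 6) -> str:
    if node.is_leaf:
        body = node.label
    else:
        # deterministic child ordering by smallest descendant label
        kids = sorted(node.children, key=lambda cl: min(cl[0].leaf_labels()))
        body = "(" + ",".join(_newick(c, ln, ndigits) for c, ln in kids) + ")"
    return body if length is None else f"{body}:{length:.{ndigits}f}"


def write_newick(t: Tree, ndigits: int = 6) -> str:
    return _newick(t.root, None, ndigits) + ";"


def read_newick(text: str) -> "dendropy.Tree":
    """Parse newick via dendropy (returned as a dendropy Tree)."""
    import dendropy
    return dendropy.Tree.get(data=text, schema="newick")


def path_lengths(t: Tree) -> dict[tuple[str, str], float]:
    """Leaf-to-leaf path lengths in the tree (for additivity checks)."""
    # collect leaf -> root-path (as list of (node id, cumulative length))
    dists: dict[tuple[str, str], float] = {}

    def walk(node: Node) -> dict[str, float]:
        """leaf label -> distance to this node; records cross-pair paths."""
        if node.is_leaf:
            return {node.label: 0.0}
        below: list[dict[str, float]] = []
        for child, ln in node.children:
            sub = walk(child)
            below.append({lab: dv + ln for lab, dv in sub.items()})
        for a in range(len(below)):
            for b in range(a + 1, len(below)):
                for la, da in below[a].items():
                    for lb, db in below[b].items():
                        key = tuple(sorted((la, lb)))
                        dists[key] = da + db
        merged: dict[str, float] = {}
        for sub in below:
            merged.update(sub)
        return merged

    walk(t.root)
    return dists


def bootstrap_support(aln, model: str = "K2P", replicates: int = 100,
                      seed: int = 0) -> dict[frozenset, float]:
    """Site-resampling bootstrap over an AlignedMatrix: NJ on each resampled
    matrix, returning split frequencies keyed by the smaller leaf set."""
    from .molevol import AlignedMatrix, distance_matrix

    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    all_leaves = frozenset(aln.labels)
    done = 0
    for _ in range(replicates):
        idx = rng.integers(0, aln.length, size=aln.length)
        rows = ["".join(r[i] for i in idx) for r in aln.rows]
        try:
            D = distance_matrix(AlignedMatrix(list(aln.labels), rows), model)
            tree = neighbor_joining(D)
        except ValueError:
            continue
        done += 1
        for split in _splits(tree.root, all_leaves):
            counts[split] = counts.get(split, 0) + 1
    return {s: c / done for s, c in counts.items()} if done else {}


def _splits(root: Node, all_leaves: frozenset) -> set[frozenset]:
    out: set[frozenset] = set()

    def walk(node: Node):
        if node.is_leaf:
            return frozenset([node.label])
        below = frozenset()
        for child, _ in node.children:
            sub = walk(child)
            if 1 < len(sub) < len(all_leaves) - 1:
                out.add(min(sub, all_leaves - sub, key=lambda s: (len(s), sorted(s))))
            below = below | sub
        return below

    walk(root)
    return out
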