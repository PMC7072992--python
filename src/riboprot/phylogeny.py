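"""Distance-based phylogeny: p-distances, neighbor-joining, bootstrap support.

Trees are :class:`skbio.TreeNode` objects. Neighbor-joining is the classic
Saitou–Nei agglomeration with the Studier–Keppler Q criterion; negative
branch-length estimates are clamped to zero with the deficit transferred to
the sibling branch, so total pair path length is preserved. On an exactly
additive distance matrix the reconstructed tree reproduces every input
distance as a leaf-to-leaf path length.

Bootstrap support for an internal edge is the percentage of replicate trees
(alignment columns resampled with replacement, distances recomputed, NJ
rebuilt) that contain the same leaf bipartition.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode

__all__ = [
    "p_distance",
    "p_distance_matrix",
    "nj_tree",
    "bipartitions",
    "bootstrap_support",
]


def p_distance(seq_a: Sequence, seq_b: Sequence) -> float:
    """Proportion of differing positions between two equal-length sequences.

    Percent identity is ``100 * (1 - p)``.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"sequence length mismatch: {len(seq_a)} vs {len(seq_b)}"
        )
    if len(seq_a) == 0:
        raise ValueError("empty sequences")
    diff = sum(a != b for a, b in zip(seq_a, seq_b))
    return diff / len(seq_a)


def p_distance_matrix(sequences: Mapping[str, Sequence]) -> DistanceMatrix:
    """Pairwise p-distance matrix over a set of aligned sequences."""
    ids = list(sequences)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = p_distance(sequences[ids[i]], sequences[ids[j]])
    return DistanceMatrix(d, ids)


def _as_matrix(dm: DistanceMatrix) -> tuple[list[str], np.ndarray]:
    if not isinstance(dm, DistanceMatrix):
        raise TypeError("expected a skbio DistanceMatrix")
    return list(dm.ids), np.asarray(dm.data, dtype=float).copy()


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree from a distance matrix.

    Returns an unrooted tree represented with a basal trifurcation. Requires
    at least three taxa. Ties in the join criterion are broken by the first
    (row-major) minimum, so the result is deterministic for a given input
    ordering, and relabeling invariance holds up to topology.
    """
    labels, d = _as_matrix(dm)
    n = len(labels)
    if n < 3:
        raise ValueError(f"neighbor-joining needs >= 3 taxa, got {n}")

    nodes: list[TreeNode] = [TreeNode(name=lbl) for lbl in labels]

    while n > 3:
        r = d.sum(axis=1)
        # Studier-Keppler criterion Q_ij = (n-2) d_ij - r_i - r_j
        q = (n - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(np.argmin(q), q.shape)
        if i > j:
            i, j = j, i

        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = d[i, j] - li
        # clamp negative estimates, moving the deficit to the sibling branch
        if li < 0:
            lj -= li
            li = 0.0
        if lj < 0:
            li -= lj
            lj = 0.0

        parent = TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        parent.extend([nodes[i], nodes[j]])

        d_new = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        d_new = np.maximum(d_new, 0.0)
        d[i, :] = d_new
        d[:, i] = d_new
        d[i, i] = 0.0
        keep = [k for k in range(n) if k != j]
        d = d[np.ix_(keep, keep)]
        nodes[i] = parent
        del nodes[j]
        n -= 1

    # resolve the final three subtrees around a basal trifurcation
    (a, b, c) = (0, 1, 2)
    la = max(0.0, 0.5 * (d[a, b] + d[a, c] - d[b, c]))
    lb = max(0.0, 0.5 * (d[a, b] + d[b, c] - d[a, c]))
    lc = max(0.0, 0.5 * (d[a, c] + d[b, c] - d[a, b]))
    root = TreeNode()
    for node, length in zip(nodes, (la, lb, lc)):
        node.length = length
        root.append(node)
    return root


def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial leaf bipartitions of an unrooted tree.

    Each bipartition is a frozenset of the two frozensets of tip names on
    either side of an internal edge, so the representation is independent of
    rooting.
    """
    all_tips = frozenset(t.name for t in tree.tips())
    splits: set[frozenset] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = all_tips - side
        if len(side) >= 2 and len(other) >= 2:
            splits.add(frozenset({side, other}))
    return splits


def bootstrap_support(
    characters: Mapping[str, Sequence],
    n_replicates: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> TreeNode:
    """NJ tree from an aligned character matrix, with bootstrap edge supports.

    ``characters`` maps taxon name to its aligned sequence (equal lengths).
    The full-data tree is built from p-distances; each replicate resamples
    alignment columns with replacement and rebuilds the tree. Every internal
    node of the full-data tree gets a ``support`` attribute in [0, 100]: the
    percentage of replicates whose tree contains that node's bipartition.
    With fewer than four taxa there are no internal edges and no supports.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    ids = list(characters)
    seqs = {k: list(characters[k]) for k in ids}
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError("sequences are not aligned (unequal lengths)")
    (n_cols,) = lengths

    tree = nj_tree(p_distance_matrix(seqs))
    if len(ids) < 4:
        return tree

    if rng is None:
        rng = np.random.default_rng(seed)
    arr = np.array([seqs[k] for k in ids])  # taxa x columns
    counts: dict[frozenset, int] = {}
    for _ in range(n_replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        resampled = arr[:, cols]
        n = len(ids)
        d = np.zeros((n, n))
        for i in range(n):
            diff = (resampled[i + 1 :] != resampled[i]).mean(axis=1)
            d[i, i + 1 :] = diff
            d[i + 1 :, i] = diff
        rep_tree = nj_tree(DistanceMatrix(d, ids))
        for split in bipartitions(rep_tree):
            counts[split] = counts.get(split, 0) + 1

    all_tips = frozenset(ids)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        split = frozenset({side, all_tips - side})
        if len(side) >= 2 and len(all_tips - side) >= 2:
            node.support = 100.0 * counts.get(split, 0) / n_replicates
    return tree
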