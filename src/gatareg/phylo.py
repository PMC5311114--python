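"""Pairwise alignment, p-distances and neighbor-joining family trees.

Extracted zinc-finger domain sequences are grouped into families by
building a neighbor-joining tree over p-distances computed from pairwise
global alignments. Alignment uses Needleman-Wunsch with affine gap
penalties (Gotoh's three-state recursion) and a fixed traceback
preference (diagonal, then up, then left) so results are deterministic.

Trees are ``skbio.TreeNode`` objects, so Newick serialisation, tip-to-tip
distances and Robinson-Foulds comparisons come from scikit-bio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode


@dataclass(frozen=True)
class AlignParams:
    """Affine-gap scoring: a gap of length L costs gap_open + (L-1)*gap_extend."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0


DEFAULT_PARAMS = AlignParams()


@dataclass(frozen=True)
class PairwiseAlignment:
    seq_a_id: str
    seq_b_id: str
    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        assert len(self.aligned_a) == len(self.aligned_b)
        assert not any(
            x == "-" and y == "-" for x, y in zip(self.aligned_a, self.aligned_b)
        )


def global_align(
    a: str,
    b: str,
    params: AlignParams = DEFAULT_PARAMS,
    a_id: str = "a",
    b_id: str = "b",
) -> PairwiseAlignment:
    """Optimal global alignment with affine gaps (Gotoh).

    Traceback ties are resolved preferring the diagonal (match/mismatch)
    state, then a gap in ``b`` (consuming ``a``), then a gap in ``a``.
    """
    if not a or not b:
        raise ValueError("global_align requires non-empty sequences")
    la, lb = len(a), len(b)
    go, ge = params.gap_open, params.gap_extend
    NEG = -np.inf
    # M: a[i-1] aligned to b[j-1]; X: gap in b (a consumed); Y: gap in a
    M = np.full((la + 1, lb + 1), NEG)
    X = np.full((la + 1, lb + 1), NEG)
    Y = np.full((la + 1, lb + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = go + (i - 1) * ge
    for j in range(1, lb + 1):
        Y[0, j] = go + (j - 1) * ge
    for i in range(1, la + 1):
        ca = a[i - 1]
        for j in range(1, lb + 1):
            s = params.match if ca == b[j - 1] else params.mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + go, X[i - 1, j] + ge, Y[i - 1, j] + go)
            Y[i, j] = max(M[i, j - 1] + go, Y[i, j - 1] + ge, X[i, j - 1] + go)
    # traceback
    i, j = la, lb
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))  # 0=M,1=X,2=Y
    score = float([M[i, j], X[i, j], Y[i, j]][state])
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        if state == 0:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            prev = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            i, j = i - 1, j - 1
            state = int(np.argmax(prev))
            if i == 0 and j == 0:
                break
        elif state == 1:
            out_a.append(a[i - 1])
            out_b.append("-")
            cands = (M[i - 1, j] + params.gap_open,
                     X[i - 1, j] + params.gap_extend,
                     Y[i - 1, j] + params.gap_open)
            i -= 1
            state = int(np.argmax(cands))
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            cands = (M[i, j - 1] + params.gap_open,
                     Y[i, j - 1] + params.gap_extend,
                     X[i, j - 1] + params.gap_open)
            state = int(np.argmax(cands))
            state = (0, 2, 1)[state]
            j -= 1
    return PairwiseAlignment(
        seq_a_id=a_id,
        seq_b_id=b_id,
        aligned_a="".join(reversed(out_a)),
        aligned_b="".join(reversed(out_b)),
        score=score,
    )


def p_distance(aln: PairwiseAlignment) -> float:
    """Proportion of mismatched residues among gap-free aligned columns."""
    comparable = 0
    mismatches = 0
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if x == "-" or y == "-":
            continue
        comparable += 1
        if x != y:
            mismatches += 1
    if comparable == 0:
        raise ValueError("no comparable (gap-free) columns in alignment")
    return mismatches / comparable


@dataclass
class DistanceMatrix:
    """Symmetric p-distance matrix over ordered sequence ids."""

    ids: list[str]
    d: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("nonzero diagonal in distance matrix")


def distance_matrix_from_seqs(
    seqs: dict[str, str],
    params: AlignParams = DEFAULT_PARAMS,
) -> DistanceMatrix:
    """All-pairs p-distances from pairwise global alignments."""
    ids = list(seqs)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = global_align(seqs[ids[i]], seqs[ids[j]], params)
            d[i, j] = d[j, i] = p_distance(aln)
    return DistanceMatrix(ids=ids, d=d)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree with deterministic tie-breaking.

    Iteratively joins the pair minimising Q(i,j) = (r-2) d(i,j) - R_i - R_j;
    ties go to the lexicographically smallest (id, id) pair. Negative
    branch lengths are clamped to zero with the deficit moved to the
    sibling branch. The result is an unrooted tree represented with a
    trifurcating root.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor-joining needs at least 3 leaves")
    nodes: list[TreeNode] = [TreeNode(name=i) for i in dm.ids]
    # sort key of each working node: smallest leaf id below it
    keys: list[str] = list(dm.ids)
    d = dm.d.copy()

    def join(i: int, j: int, li: float, lj: float) -> TreeNode:
        nonlocal d, nodes, keys
        # clamp negatives, moving the deficit to the sibling
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        nodes[i].length = float(li)
        nodes[j].length = float(lj)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        new_key = min(keys[i], keys[j])
        # distances from the new node to everything else
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(len(nodes)) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep],
                       dnew[keep][None, :]])
        d = np.hstack([d, np.append(dnew[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]
        keys = [keys[k] for k in keep] + [new_key]
        return parent

    while len(nodes) > 3:
        r = len(nodes)
        R = d.sum(axis=1)
        best = None
        for i in range(r):
            for j in range(i + 1, r):
                q = (r - 2) * d[i, j] - R[i] - R[j]
                tie = tuple(sorted((keys[i], keys[j])))
                cand = (q, tie, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        li = 0.5 * d[i, j] + (R[i] - R[j]) / (2 * (r - 2))
        lj = d[i, j] - li
        join(i, j, li, lj)

    # final three nodes: closed-form star resolution
    (a, b, c) = (0, 1, 2)
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    lens = [la, lb, lc]
    # clamp negatives; deficit spread over the other two branches equally
    for k in range(3):
        if lens[k] < 0:
            deficit = lens[k]
            lens[k] = 0.0
            others = [m for m in range(3) if m != k]
            for m in others:
                lens[m] += deficit / 2
    for k, node in enumerate(nodes):
        node.length = float(max(lens[k], 0.0))
    root = TreeNode(children=list(nodes))
    return root


def tip_distances(tree: TreeNode) -> tuple[list[str], np.ndarray]:
    """All-pairs path-length distances between tips."""
    dm = tree.tip_tip_distances()
    return [str(i) for i in dm.ids], dm.data


def assign_families(tree: TreeNode, anchors: dict[str, str]) -> dict[str, str]:
    """Label every leaf with the family of its nearest anchor leaf.

    Distance is path length in the tree; ties go to the smallest anchor id.
    """
    if not anchors:
        raise ValueError("anchors must be non-empty")
    ids, d = tip_distances(tree)
    index = {name: k for k, name in enumerate(ids)}
    missing = set(anchors) - set(index)
    if missing:
        raise ValueError(f"anchor leaves not in tree: {sorted(missing)}")
    anchor_ids = sorted(anchors)
    out: dict[str, str] = {}
    for leaf in ids:
        if leaf in anchors:
            out[leaf] = anchors[leaf]
            continue
        best = min(anchor_ids, key=lambda a: (d[index[leaf], index[a]], a))
        out[leaf] = anchors[best]
    return out


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_newick(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")
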