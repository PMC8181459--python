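"""Neighbor joining and Newick serialization.

Standard Saitou–Nei neighbor joining on a distance matrix: at each step
the pair minimizing Q(i,j) = (r-2) d(i,j) - sum_k d(i,k) - sum_k d(j,k)
is joined, with rate-corrected branch lengths.  On an additive matrix the
generating tree is recovered exactly.  Determinism: Q-ties are broken by
the lowest (i,j) index pair in the current label order, so trees are
bit-stable across runs.  Negative branch lengths are clamped to zero and
the total clamped deficit is recorded on the tree
(``tree.negative_length_deficit``), which is 0 for additive inputs.

The output is an unrooted :class:`skbio.TreeNode` (the root is the final
trifurcation).
"""

from __future__ import annotations

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .errors import InvalidMatrixError, TooFewTaxaError

_NEEDS_QUOTE = set(" ()[]:;,'\t")


def neighbor_joining(d: DistanceMatrix | np.ndarray, labels=None) -> TreeNode:
    """Build an unrooted NJ tree from a distance matrix.

    Accepts a :class:`skbio.DistanceMatrix` or a raw symmetric array plus
    labels.  Raises :class:`TooFewTaxaError` below three taxa and
    :class:`InvalidMatrixError` for asymmetric input.
    """
    if isinstance(d, DistanceMatrix):
        mat = d.data.astype(float).copy()
        labels = list(d.ids)
    else:
        mat = np.asarray(d, dtype=float).copy()
        if labels is None:
            raise InvalidMatrixError("raw matrix input needs labels")
        labels = list(labels)
        if mat.ndim != 2 or mat.shape[0] != mat.shape[1] or len(labels) != mat.shape[0]:
            raise InvalidMatrixError("matrix must be square with one label per row")
        if not np.allclose(mat, mat.T):
            raise InvalidMatrixError("distance matrix must be symmetric")
    n = mat.shape[0]
    if n < 3:
        raise TooFewTaxaError(f"neighbor joining needs >=3 taxa, got {n}")

    nodes: list[TreeNode] = [TreeNode(name=l) for l in labels]
    deficit = 0.0

    def clamp(x: float) -> float:
        nonlocal deficit
        if x < 0:
            deficit += -x
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = mat.sum(axis=1)
        q = (m - 2) * mat - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # argmin scans row-major: ties resolve to the lowest (i, j) pair
        i, j = np.unravel_index(int(np.argmin(q)), q.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * mat[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = mat[i, j] - li
        parent = TreeNode()
        nodes[i].length = clamp(li)
        nodes[j].length = clamp(lj)
        parent.extend([nodes[i], nodes[j]])
        dnew = 0.5 * (mat[i] + mat[j] - mat[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        new_mat = np.zeros((m - 1, m - 1))
        new_mat[:-1, :-1] = mat[np.ix_(keep, keep)]
        new_mat[-1, :-1] = new_mat[:-1, -1] = dnew[keep]
        mat = new_mat
        nodes = [nodes[k] for k in keep] + [parent]

    # closed-form resolution of the final three nodes
    a = 0.5 * (mat[0, 1] + mat[0, 2] - mat[1, 2])
    b = mat[0, 1] - a
    c = mat[0, 2] - a
    root = TreeNode()
    for node, length in zip(nodes, (a, b, c)):
        node.length = clamp(length)
        root.append(node)
    root.negative_length_deficit = deficit
    return root


def _format_label(name: str) -> str:
    if name and any(ch in _NEEDS_QUOTE for ch in name):
        return "'" + name.replace("'", "''") + "'"
    return name


def to_newick(t: TreeNode, precision: int = 10) -> str:
    """Serialize a tree as Newick with branch lengths.

    Labels containing Newick metacharacters (spaces, parentheses, ...) are
    single-quoted; branch lengths are printed to ``precision`` significant
    digits.
    """

    def render(node: TreeNode) -> str:
        if node.is_tip():
            body = _format_label(node.name or "")
        else:
            body = "(" + ",".join(render(ch) for ch in node.children) + ")"
            if node.name:
                body += _format_label(node.name)
        if node.length is not None:
            body += f":{node.length:.{precision}g}"
        return body

    return render(t) + ";"


def from_newick(text: str) -> TreeNode:
    """Parse a Newick string into a :class:`skbio.TreeNode`."""
    import io

    return TreeNode.read(io.StringIO(text))
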