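"""Distance-based phylogeny of miRNA families with Newick output.

For ~18–24-nt mature miRNAs a profile MSA adds nothing over direct
pairwise comparison, so distances are p-distances over a unit-cost global
(Needleman–Wunsch) alignment — edit positions divided by alignment length
— computed with edlib. Trees are built by neighbor joining (scikit-bio);
negative branch-length estimates are clamped to zero with the clamped
amount logged. NJ is consistent on additive matrices: it recovers the
generating topology exactly.
"""

from __future__ import annotations

import io
import logging
import re

import edlib
import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

logger = logging.getLogger("estmir")

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")
_NEWICK_UNSAFE = re.compile(r"[\s()\[\]'\":;,]")


def pairwise_distance(a: str, b: str) -> float:
    """p-distance over a unit-cost global alignment of two sequences:
    (substitutions + indels) / alignment length, in [0, 1]."""
    if not a or not b:
        raise ValueError("sequences must be nonempty")
    if a == b:
        return 0.0
    if b < a:  # canonical order: optimal alignments are not unique and
        a, b = b, a  # their lengths can differ; this keeps d symmetric
    res = edlib.align(a, b, mode="NW", task="path")
    edits = res["editDistance"]
    aln_len = sum(int(n) for n, _ in _CIGAR_RE.findall(res["cigar"]))
    return edits / aln_len


def distance_matrix(seqs: list[str], labels: list[str]) -> DistanceMatrix:
    """Symmetric p-distance matrix over a sequence collection."""
    n = len(seqs)
    if n != len(labels):
        raise ValueError("labels and sequences differ in length")
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = pairwise_distance(seqs[i], seqs[j])
    return DistanceMatrix(mat, labels)


def nj_tree(matrix, labels: list[str] | None = None) -> TreeNode:
    """Neighbor-joining tree from a symmetric distance matrix.

    ``matrix`` may be a skbio DistanceMatrix or a square array (with
    ``labels``). Requires a symmetric, zero-diagonal matrix over n ≥ 3
    taxa. Negative branch-length estimates are clamped to 0 and the total
    clamped amount logged. Deterministic for a given input order.
    """
    if not isinstance(matrix, DistanceMatrix):
        arr = np.asarray(matrix, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(arr, arr.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(arr), 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if labels is None:
            raise ValueError("labels required with a raw matrix")
        matrix = DistanceMatrix(arr, labels)
    if matrix.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    tree = nj(matrix, neg_as_zero=False)
    clamped = 0.0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            clamped += -node.length
            node.length = 0.0
    if clamped:
        logger.info("NJ clamped %.6f of negative branch length to 0", clamped)
    return tree


def write_phylip(dm: DistanceMatrix, path) -> None:
    """Square PHYLIP distance-matrix format (full matrix, 6 decimals)."""
    with open(path, "w") as fh:
        fh.write(f"{dm.shape[0]}\n")
        for label in dm.ids:
            row = " ".join(f"{dm[label, other]:.6f}" for other in dm.ids)
            fh.write(f"{label}  {row}\n")


def _quote_label(label: str) -> str:
    if _NEWICK_UNSAFE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(tree: TreeNode) -> str:
    """Serialize a tree as Newick with 6-decimal branch lengths.

    Labels with Newick-special characters are quoted; the output
    round-trips byte-identically through :func:`read_newick`.
    """
    def fmt(node: TreeNode) -> str:
        if node.children:
            inner = ",".join(fmt(c) for c in node.children)
            s = f"({inner})"
            if node.name:
                s += _quote_label(node.name)
        else:
            s = _quote_label(node.name or "")
        if node.length is not None:
            s += f":{node.length:.6f}"
        return s

    return fmt(tree) + ";"


def read_newick(text: str) -> TreeNode:
    """Parse a Newick string (scikit-bio reader)."""
    return TreeNode.read(io.StringIO(text), format="newick")


def _splits(tree: TreeNode) -> tuple[frozenset, set[frozenset]]:
    """Taxon set and the non-trivial bipartitions of an (un)rooted tree."""
    taxa = frozenset(t.name for t in tree.tips())
    splits: set[frozenset] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(taxa) - 1:
            splits.add(frozenset({side, taxa - side}))
    return taxa, splits


def same_topology(t1: TreeNode, t2: TreeNode) -> bool:
    """True iff two trees on the same taxa induce identical unrooted
    topologies (every non-trivial bipartition shared)."""
    taxa1, s1 = _splits(t1)
    taxa2, s2 = _splits(t2)
    return taxa1 == taxa2 and s1 == s2
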