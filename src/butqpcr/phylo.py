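"""Tree ingestion and clade enumeration for phylogeny-guided primer design.

The design driver descends a rooted tree from the root, attempting a primer
pair on each clade's members and recursing into children on failure, so all
this module needs to supply is newick round-tripping, a root-down clade
enumeration, and a convenience distance/neighbor-joining path for users who
arrive with only an alignment.  Likelihood phylogenetics is deliberately out
of scope: a tree computed elsewhere is consumed as newick.
"""

from __future__ import annotations

import io
from collections import deque
from typing import Sequence

import numpy as np
from Bio import Phylo

from .seqcore import SequenceRecord

__all__ = [
    "CladeTree",
    "parse_newick",
    "write_newick",
    "p_distance_matrix",
    "nj_tree",
    "clades_rootdown",
]


class CladeTree:
    """A rooted tree with uniquely labeled leaves (thin Bio.Phylo wrapper).

    Multifurcations are preserved; branch lengths are optional and may be
    zero.  Every internal node of a parsed tree has at least two children.
    """

    def __init__(self, biopython_tree) -> None:
        self._tree = biopython_tree
        names = self.leaf_names()
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate leaf labels: {dupes}")
        if any(n is None for n in names):
            raise ValueError("every leaf must be labeled")

    @property
    def root(self):
        return self._tree.root

    def leaf_names(self) -> list[str]:
        return [t.name for t in self._tree.get_terminals()]

    def leaf_set(self) -> frozenset[str]:
        return frozenset(self.leaf_names())

    def __len__(self) -> int:
        return len(self._tree.get_terminals())


def parse_newick(text: str) -> CladeTree:
    """Parse a newick string into a :class:`CladeTree`."""
    try:
        tree = Phylo.read(io.StringIO(text), "newick")
    except Exception as e:  # Bio raises several parser error types
        raise ValueError(f"malformed newick: {e}") from e
    return CladeTree(tree)


def write_newick(tree: CladeTree) -> str:
    buf = io.StringIO()
    Phylo.write(tree._tree, buf, "newick", plain=not _has_lengths(tree))
    return buf.getvalue().strip()


def _has_lengths(tree: CladeTree) -> bool:
    return any(
        c.branch_length is not None for c in tree._tree.find_clades() if c != tree.root
    )


def p_distance_matrix(
    msa: Sequence[SequenceRecord],
) -> tuple[list[str], np.ndarray]:
    """Pairwise p-distances on an alignment (gapped columns skipped pairwise).

    d(i, j) is the fraction of compared (both-ungapped) columns at which the
    two sequences differ; a pair with no comparable columns gets distance 0.
    """
    if len({len(r.seq) for r in msa}) > 1:
        raise ValueError("aligned sequences must have equal length")
    ids = [r.id for r in msa]
    arr = np.array([list(r.seq) for r in msa])
    n = len(msa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (arr[i] != "-") & (arr[j] != "-")
            ncmp = int(ok.sum())
            d[i, j] = d[j, i] = (
                float((arr[i][ok] != arr[j][ok]).mean()) if ncmp else 0.0
            )
    return ids, d


def nj_tree(ids: Sequence[str], dist: np.ndarray) -> CladeTree:
    """Neighbor-joining tree from a symmetric distance matrix, midpoint-rooted.

    Additive matrices are recovered exactly (up to rooting).  The descent
    driver needs a root; midpoint rooting is the default because no other
    rooting information is available from a distance matrix.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    if len(ids) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    dist = np.asarray(dist, dtype=float)
    if dist.shape != (len(ids), len(ids)) or not np.allclose(dist, dist.T):
        raise ValueError("distance matrix must be square and symmetric")
    result = nj(DistanceMatrix(dist, list(ids)))
    newick = str(result.write(io.StringIO(), format="newick").getvalue())
    bp = Phylo.read(io.StringIO(newick), "newick")
    # NJ can emit tiny negative branch lengths; clamp for midpoint rooting
    for c in bp.find_clades():
        if c.branch_length is not None and c.branch_length < 0:
            c.branch_length = 0.0
    bp.root_at_midpoint()
    return CladeTree(bp)


def clades_rootdown(tree: CladeTree) -> list[frozenset[str]]:
    """Breadth-first enumeration of every node's leaf set, root first.

    Internal nodes contribute their full leaf sets; each leaf appears as a
    singleton.  This is the attempt order of the design descent.
    """
    out = []
    queue = deque([tree.root])
    while queue:
        node = queue.popleft()
        out.append(frozenset(t.name for t in node.get_terminals()))
        queue.extend(node.clades)
    return out
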