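"""Haplotype assignment of orf138-like sequences against a lettered panel.

The Ogura orf138 gene occurs in a small number of lettered haplotypes that
differ by a handful of substitutions. For such near-identical sequences a
p-distance (substitutions per aligned site) with nearest-neighbour
assignment is method-insensitive, and a neighbour-joining tree on the
p-distance matrix reproduces the grouping a likelihood tree would show.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj

from .align import global_align


@dataclass
class HaplotypeCall:
    best: str
    distances: dict[str, float]
    margin: float
    tree: str  # newick


def pairwise_distance(a: str, b: str) -> float:
    """p-distance: mismatched columns / ungapped columns after global alignment."""
    if not a or not b:
        raise ValueError("empty sequence")
    aln = global_align(a, b)
    counts = aln.counts()
    ungapped = counts.identities + counts.mismatches
    if ungapped == 0:
        raise ValueError("no aligned columns")
    return counts.mismatches / ungapped


def nj_tree(labels: list[str], matrix) -> str:
    """Neighbour-joining tree (newick) from a symmetric distance matrix.

    Negative branch lengths are clamped to zero with the deficit shifted to
    the sister edge (the standard adjustment).
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (len(labels), len(labels)):
        raise ValueError("matrix shape does not match labels")
    if not np.allclose(matrix, matrix.T) or not np.allclose(np.diag(matrix), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if len(labels) < 2:
        raise ValueError("need at least two taxa")
    if len(labels) == 2:
        d = matrix[0, 1] / 2
        return f"({labels[0]}:{d:g},{labels[1]}:{d:g});"
    dm = DistanceMatrix(matrix, ids=list(labels))
    tree = nj(dm, neg_as_zero=True)
    return str(tree).strip()


def assign_haplotype(query: str, panel: list[tuple[str, str]]) -> HaplotypeCall:
    """Assign the query to the nearest panel haplotype by p-distance."""
    if not panel:
        raise ValueError("empty haplotype panel")
    labels = [label for label, _ in panel]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate panel labels")
    distances = {label: pairwise_distance(query, seq) for label, seq in panel}
    ranked = sorted(distances.items(), key=lambda kv: (kv[1], kv[0]))
    best, best_d = ranked[0]
    if len(ranked) > 1 and np.isclose(ranked[1][1], best_d):
        warnings.warn(f"haplotype tie between {best} and {ranked[1][0]}; "
                      "alphabetical winner reported")
    margin = (ranked[1][1] - best_d) if len(ranked) > 1 else 0.0
    all_labels = labels + ["query"]
    n = len(all_labels)
    mat = np.zeros((n, n))
    seqs = [seq for _, seq in panel] + [query]
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = pairwise_distance(seqs[i], seqs[j])
    tree = nj_tree(all_labels, mat)
    return HaplotypeCall(best=best, distances=distances, margin=float(margin),
                         tree=tree)
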