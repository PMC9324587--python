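"""Bipartite network reconstruction by similarity propagation.

A raw 0/1 association matrix wastes the signal carried by entities with no
confirmed association: an isolated miRNA that is highly similar to a
well-annotated one should inherit some of its evidence. Reconstruction
replaces each association cell by the similarity-weighted sum over
neighboring row and column entities,

    A'(a, c) = sum_i sum_j S_row(a, a_i) * S_col(c, c_j) * A(a_i, c_j),

where the sums run over threshold-surviving neighbors (the entity itself is
included with self-similarity 1, so confirmed associations are preserved as
a baseline). Weak neighbors are pruned first: off-diagonal similarities
below the threshold T are removed, except that an entity whose neighbors
would all be pruned keeps its single most similar one. The reconstructed
weights are finally normalized by the global maximum so every layer lives
on a comparable [0, 1] scale.
"""

from __future__ import annotations

import numpy as np

from .matrices import AssociationMatrix, SimilarityMatrix

__all__ = [
    "threshold_neighbors",
    "reconstruct_bipartite",
    "normalize_global_max",
]


def threshold_neighbors(S: SimilarityMatrix, T: float) -> SimilarityMatrix:
    """Prune off-diagonal similarities below *T*, keeping each entity's best.

    If every off-diagonal entry of a row falls below T, the row's largest
    positive off-diagonal entries are retained (all argmax ties). The result
    is re-symmetrized by keeping an edge if either endpoint retained it;
    the diagonal stays 1.
    """
    if not 0.0 <= T <= 1.0:
        raise ValueError("T must lie in [0, 1]")
    v = S.values.copy()
    n = v.shape[0]
    off = ~np.eye(n, dtype=bool)
    kept = v.copy()
    kept[off & (v < T)] = 0.0
    if n > 1:
        for i in range(n):
            row_off = v[i][off[i]]
            if (row_off < T).all():
                best = row_off.max()
                if best > 0.0:
                    ties = off[i] & np.isclose(v[i], best)
                    kept[i, ties] = v[i, ties]
    kept = np.maximum(kept, kept.T)
    np.fill_diagonal(kept, 1.0)
    return SimilarityMatrix(kept, S.index)


def reconstruct_bipartite(
    S_row: SimilarityMatrix,
    S_col: SimilarityMatrix,
    A: AssociationMatrix,
) -> AssociationMatrix:
    """Similarity-propagate a raw association matrix into a weighted one.

    Equivalent to the double sum above: ``A' = S_row_f @ A @ S_col_f.T``
    with both similarity factors already threshold-filtered. Identity
    similarities on both sides reproduce A exactly.
    """
    if A.stage != "raw":
        raise ValueError(f"expected a raw association matrix, got stage {A.stage!r}")
    if A.row_index != S_row.index or A.col_index != S_col.index:
        raise ValueError("association indices do not match the similarity indices")
    values = S_row.values @ A.values @ S_col.values.T
    return AssociationMatrix(values, A.row_index, A.col_index, stage="reconstructed")


def normalize_global_max(A_prime: AssociationMatrix) -> AssociationMatrix:
    """Divide every entry by the single global maximum; all-zero passes through."""
    if A_prime.stage != "reconstructed":
        raise ValueError(
            f"expected a reconstructed association matrix, got stage {A_prime.stage!r}"
        )
    v = A_prime.values
    peak = v.max(initial=0.0)
    out = v / peak if peak > 0 else v.copy()
    return AssociationMatrix(out, A_prime.row_index, A_prime.col_index, stage="normalized")
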