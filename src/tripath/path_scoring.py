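"""Decay-penalized path scoring on the three-layer heterogeneous network.

The six prepared matrices — three threshold-filtered similarity layers and
three normalized bipartite layers — form one heterogeneous network over
miRNA, drug and disease nodes. Each bipartite slice is scored by
enumerating, depth-first, the simple paths of at most L = 2 edges between a
row entity and a column entity:

    W(a, c) = A''(a, c) + sum over length-2 paths p of (prod of edge weights)^fdecay(p)

with the decay exponent ``fdecay(p) = beta * len(p)``. Since every edge
weight lies in (0, 1], raising the path product to a large exponent
penalizes longer (less reliable) evidence chains; at beta = 7 and length 2
the exponent is 14. The two admissible length-2 shapes are
similarity-then-association and association-then-similarity; zero-weight
cells are absent edges and cannot be traversed.

The final score integrates the direct miRNA-disease path weights with the
drug-mediated ones:

    Score(a, c) = W1(a, c) + sum over drugs b of (W2(a, b) * W3(b, c))^fdecay(2)

where W2 (miRNA-drug) and W3 (drug-disease) are first rescaled to [0, 1] by
their global maxima so that the exponent keeps contracting the product.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrices import AssociationMatrix, PathParams, ScoreMatrix, SimilarityMatrix
from .reconstruction import normalize_global_max, reconstruct_bipartite, threshold_neighbors

__all__ = [
    "HeteroNetwork",
    "assemble_three_layer",
    "fdecay",
    "two_layer_path_scores",
    "integrate_scores",
    "predict",
]


@dataclass(frozen=True)
class HeteroNetwork:
    """The assembled three-layer network: filtered similarities + normalized bipartites."""

    S1: SimilarityMatrix  # miRNA
    S2: SimilarityMatrix  # drug
    S3: SimilarityMatrix  # disease
    A1n: AssociationMatrix  # miRNA x disease
    A2n: AssociationMatrix  # miRNA x drug
    A3n: AssociationMatrix  # drug x disease


def assemble_three_layer(
    S1: SimilarityMatrix,
    S2: SimilarityMatrix,
    S3: SimilarityMatrix,
    A1n: AssociationMatrix,
    A2n: AssociationMatrix,
    A3n: AssociationMatrix,
) -> HeteroNetwork:
    """Validate index consistency across the six blocks and bundle them.

    All three layers must be non-empty: the model is specifically about
    injecting drug-mediated evidence, so a degenerate drug layer is refused.
    """
    checks = [
        ("A1n rows vs miRNA similarity", A1n.row_index, S1.index),
        ("A1n columns vs disease similarity", A1n.col_index, S3.index),
        ("A2n rows vs miRNA similarity", A2n.row_index, S1.index),
        ("A2n columns vs drug similarity", A2n.col_index, S2.index),
        ("A3n rows vs drug similarity", A3n.row_index, S2.index),
        ("A3n columns vs disease similarity", A3n.col_index, S3.index),
    ]
    for label, left, right in checks:
        if left != right:
            raise ValueError(f"index mismatch: {label}")
    if len(S1.index) == 0 or len(S2.index) == 0 or len(S3.index) == 0:
        raise ValueError("all three layers must be non-empty")
    return HeteroNetwork(S1, S2, S3, A1n, A2n, A3n)


def fdecay(path_length: int, beta: float) -> float:
    """Decay exponent of a path: ``beta * path_length`` (in edges)."""
    if path_length < 1:
        raise ValueError("path_length must be >= 1")
    if beta <= 0:
        raise ValueError("beta must be positive")
    return beta * path_length


def _adjacency(weights: np.ndarray, *, skip_diagonal: bool) -> list[list[tuple[int, float]]]:
    """Neighbor lists of nonzero entries; zero cells are absent edges."""
    nbrs: list[list[tuple[int, float]]] = []
    for i in range(weights.shape[0]):
        row = weights[i]
        js = np.nonzero(row)[0]
        nbrs.append([(int(j), float(row[j])) for j in js if not (skip_diagonal and j == i)])
    return nbrs


def two_layer_path_scores(
    S_row: SimilarityMatrix,
    S_col: SimilarityMatrix,
    A: AssociationMatrix,
    params: PathParams,
) -> ScoreMatrix:
    """Score one bipartite slice by bounded depth-first path enumeration.

    Starting from each row entity, a depth-first traversal expands along
    nonzero edges (within-layer similarity or cross-layer association) up to
    ``params.L`` edges; every simple path terminating at a column entity
    contributes its weight product raised to the decay exponent. The direct
    association weight enters unpenalized as the length-1 term of the model.
    """
    if params.L != 2:
        raise ValueError("only path length L = 2 is supported")
    if A.row_index != S_row.index or A.col_index != S_col.index:
        raise ValueError("association indices do not match the similarity indices")
    if A.stage != "normalized":
        raise ValueError(f"expected a normalized association matrix, got {A.stage!r}")

    sim_row = _adjacency(S_row.values, skip_diagonal=True)
    sim_col = _adjacency(S_col.values, skip_diagonal=True)
    assoc = _adjacency(A.values, skip_diagonal=False)
    exponent = fdecay(2, params.beta)

    W = A.values.copy()

    # Depth-first expansion from each miRNA-side node. A node is ("row", i)
    # or ("col", j); edges are within-layer similarity or the bipartite
    # association. Paths of exactly 2 edges ending in the column layer score.
    for a in range(len(S_row.index)):
        stack: list[tuple[str, int, float, int, tuple[int, ...]]] = [("row", a, 1.0, 0, (a,))]
        while stack:
            layer, node, product, depth, visited = stack.pop()
            if depth == 2:
                if layer == "col":
                    W[a, node] += product**exponent
                continue
            if layer == "row":
                for j, w in assoc[node]:
                    stack.append(("col", j, product * w, depth + 1, visited))
                for i, w in sim_row[node]:
                    if i not in visited:
                        stack.append(("row", i, product * w, depth + 1, visited + (i,)))
            else:
                for j, w in sim_col[node]:
                    stack.append(("col", j, product * w, depth + 1, visited))
    return ScoreMatrix(W, A.row_index, A.col_index)


def integrate_scores(
    W1: ScoreMatrix,
    W2: ScoreMatrix,
    W3: ScoreMatrix,
    params: PathParams,
) -> ScoreMatrix:
    """Combine direct and drug-mediated path weights into the final scores.

    The mediated term sums, over every drug b, the decayed product of the
    miRNA-drug and drug-disease path weights. With
    ``params.rescale_mediated`` (the default) W2 and W3 are first divided by
    their global maxima so the products stay in [0, 1].
    """
    if W2.row_index != W1.row_index or W3.col_index != W1.col_index:
        raise ValueError("W2/W3 indices do not match W1")
    if W2.col_index != W3.row_index:
        raise ValueError("W2 drug index does not match W3 drug index")
    w2, w3 = W2.values, W3.values
    if params.rescale_mediated:
        if w2.max(initial=0.0) > 0:
            w2 = w2 / w2.max()
        if w3.max(initial=0.0) > 0:
            w3 = w3 / w3.max()
    e = fdecay(2, params.beta)
    # (x*y)^e = x^e * y^e, so the mediator sum is a product of elementwise powers
    mediated = (w2**e) @ (w3**e)
    return ScoreMatrix(W1.values + mediated, W1.row_index, W1.col_index)


def predict(
    S1: SimilarityMatrix,
    S2: SimilarityMatrix,
    S3: SimilarityMatrix,
    A1: AssociationMatrix,
    A2: AssociationMatrix,
    A3: AssociationMatrix,
    params: PathParams | None = None,
    *,
    return_stages: bool = False,
):
    """Run the full pipeline from raw inputs to miRNA-disease scores.

    threshold -> reconstruct -> normalize -> assemble -> per-slice path
    scores -> integration. Deterministic: identical inputs give bit-identical
    scores.

    Returns the final :class:`ScoreMatrix`, or ``(scores, stages)`` with a
    dict of intermediates (filtered similarities, normalized associations,
    W1/W2/W3) when ``return_stages`` is set.
    """
    params = params or PathParams()
    S1f = threshold_neighbors(S1, params.T)
    S2f = threshold_neighbors(S2, params.T)
    S3f = threshold_neighbors(S3, params.T)
    A1n = normalize_global_max(reconstruct_bipartite(S1f, S3f, A1))
    A2n = normalize_global_max(reconstruct_bipartite(S1f, S2f, A2))
    A3n = normalize_global_max(reconstruct_bipartite(S2f, S3f, A3))
    net = assemble_three_layer(S1f, S2f, S3f, A1n, A2n, A3n)
    W1 = two_layer_path_scores(net.S1, net.S3, net.A1n, params)
    W2 = two_layer_path_scores(net.S1, net.S2, net.A2n, params)
    W3 = two_layer_path_scores(net.S2, net.S3, net.A3n, params)
    scores = integrate_scores(W1, W2, W3, params)
    if return_stages:
        stages = {
            "S1f": S1f, "S2f": S2f, "S3f": S3f,
            "A1n": A1n, "A2n": A2n, "A3n": A3n,
            "W1": W1, "W2": W2, "W3": W3,
        }
        return scores, stages
    return scores
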