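"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (explicit loops, no shared code with
the package internals) so that agreement with the vectorized / DFS routes
is meaningful.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# disease semantics (single-code-per-disease universes: the ancestor closure
# of each disease is a simple prefix chain, so term distance is the segment
# difference and no multi-position merging arises)

def _chain_terms(code: str, code_to_disease: dict[str, str]) -> dict[str, int]:
    """term -> hop distance from the disease term, for a single-code disease."""
    parts = code.split(".")
    out: dict[str, int] = {}
    for k in range(len(parts), 0, -1):
        prefix = ".".join(parts[:k])
        term = code_to_disease.get(prefix, prefix)
        dist = len(parts) - k
        out[term] = min(out.get(term, dist), dist)
    return out


def naive_disease_similarities(
    tree_numbers: dict[str, set[str]], phi: float = 0.5
) -> tuple[dict, dict]:
    """Per-pair DDS1/DDS2 for universes with exactly one code per disease."""
    code_to_disease = {next(iter(c)): d for d, c in tree_numbers.items()}
    chains = {
        d: _chain_terms(next(iter(codes)), code_to_disease)
        for d, codes in tree_numbers.items()
    }
    n = len(tree_numbers)
    counts: dict[str, int] = {}
    for chain in chains.values():
        for term in chain:
            counts[term] = counts.get(term, 0) + 1

    def contrib1(d):
        return {t: phi**dist for t, dist in chains[d].items()}

    def contrib2(d):
        return {t: -math.log(counts[t] / n) for t in chains[d]}

    dds1, dds2 = {}, {}
    names = list(tree_numbers)
    for a in names:
        for b in names:
            for dds, contrib in ((dds1, contrib1), (dds2, contrib2)):
                ca, cb = contrib(a), contrib(b)
                shared = set(ca) & set(cb)
                denom = sum(ca.values()) + sum(cb.values())
                num = sum(ca[t] + cb[t] for t in shared)
                dds[a, b] = num / denom if shared and denom > 0 else 0.0
    return dds1, dds2


# ---------------------------------------------------------------------------
# reconstruction

def quadruple_loop_reconstruct(Sr: np.ndarray, Sc: np.ndarray, A: np.ndarray) -> np.ndarray:
    p, r = A.shape
    out = np.zeros((p, r))
    for a in range(p):
        for c in range(r):
            total = 0.0
            for i in range(p):
                for j in range(r):
                    total += Sr[a, i] * Sc[c, j] * A[i, j]
            out[a, c] = total
    return out


# ---------------------------------------------------------------------------
# path scoring

def exhaustive_two_layer(
    Sr: np.ndarray, Sc: np.ndarray, A: np.ndarray, beta: float
) -> np.ndarray:
    """All simple length-2 paths row->row->col and row->col->col, by loops."""
    e = beta * 2
    p, r = A.shape
    W = A.copy()
    for a in range(p):
        for c in range(r):
            for mid in range(p):
                if mid != a and Sr[a, mid] > 0 and A[mid, c] > 0:
                    W[a, c] += (Sr[a, mid] * A[mid, c]) ** e
            for mid in range(r):
                if mid != c and A[a, mid] > 0 and Sc[mid, c] > 0:
                    W[a, c] += (A[a, mid] * Sc[mid, c]) ** e
    return W


def loop_integrate(
    W1: np.ndarray, W2: np.ndarray, W3: np.ndarray, beta: float, rescale: bool = True
) -> np.ndarray:
    if rescale:
        if W2.max() > 0:
            W2 = W2 / W2.max()
        if W3.max() > 0:
            W3 = W3 / W3.max()
    e = beta * 2
    out = W1.copy()
    p, r = W1.shape
    for a in range(p):
        for c in range(r):
            for b in range(W2.shape[1]):
                out[a, c] += (W2[a, b] * W3[b, c]) ** e
    return out


def max_path_products(stages) -> np.ndarray:
    """Per miRNA-disease cell, the largest single path product feeding it.

    Covers the two direct length-2 shapes (filtered similarity then
    association, association then filtered similarity) and the drug-mediated
    product after global-max rescaling. Used to identify cells where the
    large-beta decay limit applies (all products strictly below 1).
    """
    s1 = stages["S1f"].values.copy()
    np.fill_diagonal(s1, 0.0)
    s3 = stages["S3f"].values.copy()
    np.fill_diagonal(s3, 0.0)
    a1 = stages["A1n"].values
    direct1 = (s1[:, :, None] * a1[None, :, :]).max(axis=1)
    direct2 = (a1[:, :, None] * s3[None, :, :]).max(axis=1)
    w2 = stages["W2"].values
    w3 = stages["W3"].values
    if w2.max() > 0:
        w2 = w2 / w2.max()
    if w3.max() > 0:
        w3 = w3 / w3.max()
    mediated = (w2[:, :, None] * w3[None, :, :]).max(axis=1)
    return np.maximum(np.maximum(direct1, direct2), mediated)


# ---------------------------------------------------------------------------
# AUC

def pairwise_auc(pos: list[float], neg: list[float]) -> float:
    wins = 0.0
    for x in pos:
        for y in neg:
            if x > y:
                wins += 1.0
            elif x == y:
                wins += 0.5
    return wins / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# random instances

def random_similarity(rng: np.random.Generator, n: int, zero_frac: float = 0.3) -> np.ndarray:
    m = rng.random((n, n))
    m[rng.random((n, n)) < zero_frac] = 0.0
    m = np.triu(m, 1)
    m = m + m.T
    np.fill_diagonal(m, 1.0)
    return m


def random_normalized_association(
    rng: np.random.Generator, p: int, r: int, zero_frac: float = 0.5
) -> np.ndarray:
    a = rng.random((p, r))
    a[rng.random((p, r)) < zero_frac] = 0.0
    if a.max() > 0:
        a = a / a.max()
    return a
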