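"""Disease semantic similarity from MeSH tree numbers.

Each disease is represented by the directed acyclic graph (DAG) of itself and
all its MeSH ancestors, obtained by truncating its dot-separated tree codes
at the dots (``C04.588.274`` has ancestors ``C04.588`` and ``C04``). Two
per-ancestor weighting models are computed:

* Model 1 (geometric decay): the disease term contributes 1, and each
  ancestor contributes ``phi`` times the best contribution among its
  children inside the DAG, so contributions halve per layer at the default
  ``phi = 0.5``.
* Model 2 (information content): an ancestor term ``a`` contributes
  ``-log(DAG(a) / N)`` where ``DAG(a)`` counts the disease DAGs in the
  universe containing ``a`` and ``N`` is the universe size. Terms shared by
  every disease thus contribute nothing; rare terms contribute most. The
  logarithm base only rescales contributions and cancels in the pairwise
  ratio, so the natural log is used.

The pairwise similarity under either model is the shared-ancestor mass,
``sum over shared terms of (contrib_L + contrib_M)``, divided by the sum of
the two DAGs' total semantic values. The fused disease similarity averages
the two models and is the disease layer (S3) of the heterogeneous network.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Iterable, Mapping
from dataclasses import dataclass

import numpy as np

from .entities import EntityIndex, normalize_name
from .matrices import SimilarityMatrix

__all__ = [
    "DiseaseDAG",
    "SemanticProfile",
    "DAGUniverse",
    "build_disease_dag",
    "build_dag_universe",
    "model1_profile",
    "model2_profile",
    "pair_similarity",
    "fused_disease_similarity",
    "disease_similarity_matrices",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiseaseDAG:
    """A disease term plus all its MeSH ancestors, with parent/child links.

    A term occupying several tree positions is a single node; ``layer`` maps
    each node to its minimum hop distance upward from the disease term
    (0 for the disease itself).
    """

    disease: str
    nodes: frozenset[str]
    children: Mapping[str, frozenset[str]]
    parents: Mapping[str, frozenset[str]]
    layer: Mapping[str, int]


@dataclass(frozen=True)
class SemanticProfile:
    """Per-node semantic contributions of one disease DAG and their sum."""

    contrib: Mapping[str, float]
    total: float


def _prefixes(code: str) -> list[str]:
    """All dot-prefix ancestors of a tree code, nearest first, excluding itself."""
    parts = code.split(".")
    return [".".join(parts[:k]) for k in range(len(parts) - 1, 0, -1)]


def build_disease_dag(
    disease: str,
    codes: Iterable[str],
    mesh: Mapping[str, str] | None = None,
) -> DiseaseDAG:
    """Build the ancestor DAG of *disease* from its tree codes.

    Parameters
    ----------
    disease
        Disease name (normalized internally).
    codes
        The disease's MeSH tree codes; ancestors arise by prefix truncation.
    mesh
        Optional code -> term mapping used to merge multiple tree positions
        of one term into a single node. Codes absent from the mapping are
        treated as terms named by the code itself. The disease's own codes
        always map to the disease.
    """
    disease = normalize_name(disease)
    codes = set(codes)
    if not codes:
        raise ValueError(f"disease {disease!r} has no tree codes")
    mesh = dict(mesh or {})

    def term_of(code: str) -> str:
        if code in codes:
            return disease
        return normalize_name(mesh.get(code, code))

    relevant: set[str] = set()
    for code in codes:
        relevant.add(code)
        relevant.update(_prefixes(code))

    nodes: set[str] = {term_of(c) for c in relevant}
    children: dict[str, set[str]] = {t: set() for t in nodes}
    parents: dict[str, set[str]] = {t: set() for t in nodes}
    for code in relevant:
        if "." not in code:
            continue
        parent_code = code.rsplit(".", 1)[0]
        pt, ct = term_of(parent_code), term_of(code)
        if pt != ct:
            children[pt].add(ct)
            parents[ct].add(pt)

    # layers: BFS upward from the disease term along parent links
    layer = {disease: 0}
    frontier = [disease]
    while frontier:
        nxt: list[str] = []
        for t in frontier:
            for p in parents[t]:
                if p not in layer:
                    layer[p] = layer[t] + 1
                    nxt.append(p)
        frontier = nxt
    if set(layer) != nodes:  # pragma: no cover - defensive; prefix closure reaches all
        unreachable = nodes - set(layer)
        raise ValueError(f"ancestor terms unreachable from {disease!r}: {unreachable}")

    return DiseaseDAG(
        disease=disease,
        nodes=frozenset(nodes),
        children={t: frozenset(c) for t, c in children.items()},
        parents={t: frozenset(p) for t, p in parents.items()},
        layer=dict(layer),
    )


@dataclass(frozen=True)
class DAGUniverse:
    """All disease DAGs of a study, with term occurrence counts.

    ``dag_counts[a]`` is the number of disease DAGs containing term ``a``;
    ``n_diseases`` is the universe size N of the information-content model.
    """

    dags: Mapping[str, DiseaseDAG]
    dag_counts: Mapping[str, int]
    n_diseases: int


def build_dag_universe(tree_numbers: Mapping[str, Iterable[str]]) -> DAGUniverse:
    """Build every disease DAG plus the term occurrence counts.

    The code -> term mapping is derived from the records themselves: a code
    listed for a disease names that disease; unlisted ancestor codes become
    terms named by the code.
    """
    tn = {normalize_name(d): set(codes) for d, codes in tree_numbers.items()}
    mesh: dict[str, str] = {}
    for disease, codes in tn.items():
        for code in codes:
            mesh[code] = disease
    dags = {d: build_disease_dag(d, codes, mesh) for d, codes in tn.items()}
    counts: dict[str, int] = {}
    for dag in dags.values():
        for term in dag.nodes:
            counts[term] = counts.get(term, 0) + 1
    return DAGUniverse(dags=dags, dag_counts=counts, n_diseases=len(dags))


def model1_profile(dag: DiseaseDAG, phi: float = 0.5) -> SemanticProfile:
    """Geometric-decay contributions: 1 at the disease, then best-child * phi."""
    if not 0.0 < phi < 1.0:
        raise ValueError("phi must lie in (0, 1)")
    contrib: dict[str, float] = {}
    in_progress: set[str] = set()

    def value(a: str) -> float:
        if a in contrib:
            return contrib[a]
        if a in in_progress:
            raise ValueError(f"cycle detected at term {a!r}; DAG expected")
        in_progress.add(a)
        if a == dag.disease:
            v = 1.0
        else:
            v = max(phi * value(c) for c in dag.children[a])
        in_progress.discard(a)
        contrib[a] = v
        return v

    for node in dag.nodes:
        value(node)
    return SemanticProfile(contrib=contrib, total=sum(contrib.values()))


def model2_profile(
    dag: DiseaseDAG,
    dag_counts: Mapping[str, int],
    n_diseases: int,
) -> SemanticProfile:
    """Information-content contributions, ``-log(DAG(a)/N)`` with natural log."""
    contrib: dict[str, float] = {}
    for a in dag.nodes:
        count = dag_counts.get(a, 0)
        if count < 1:
            raise ValueError(f"term {a!r} has occurrence count 0; inconsistent universe")
        if count > n_diseases:
            raise ValueError(f"term {a!r} occurs in more DAGs than there are diseases")
        contrib[a] = -math.log(count / n_diseases)
    return SemanticProfile(contrib=contrib, total=sum(contrib.values()))


def pair_similarity(profile_l: SemanticProfile, profile_m: SemanticProfile) -> float:
    """Shared-ancestor similarity of two profiles from the same model.

    Returns 0 when the DAGs share no terms, and 0 when both totals are 0
    (possible under Model 2 when every term is universal).
    """
    shared = set(profile_l.contrib) & set(profile_m.contrib)
    if not shared:
        return 0.0
    denom = profile_l.total + profile_m.total
    if denom == 0.0:
        return 0.0
    num = sum(profile_l.contrib[a] + profile_m.contrib[a] for a in shared)
    return num / denom


def disease_similarity_matrices(
    tree_numbers: Mapping[str, Iterable[str]],
    phi: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, EntityIndex]:
    """Compute (DDS1, DDS2, FDS) matrices over the supplied disease universe.

    Diagonals are 1 by definition (a disease is maximally similar to itself;
    under Model 2 this also covers the degenerate all-universal-terms case
    where the ratio would be 0/0).
    """
    universe = build_dag_universe(tree_numbers)
    names = list(universe.dags)
    index = EntityIndex(names, "disease")
    p1 = {d: model1_profile(dag, phi) for d, dag in universe.dags.items()}
    p2 = {
        d: model2_profile(dag, universe.dag_counts, universe.n_diseases)
        for d, dag in universe.dags.items()
    }
    n = len(names)
    dds1 = np.eye(n)
    dds2 = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = names[i], names[j]
            dds1[i, j] = dds1[j, i] = pair_similarity(p1[a], p1[b])
            dds2[i, j] = dds2[j, i] = pair_similarity(p2[a], p2[b])
    fds = (dds1 + dds2) / 2.0
    np.fill_diagonal(fds, 1.0)
    return dds1, dds2, fds, index


def fused_disease_similarity(
    diseases: Iterable[str],
    tree_numbers: Mapping[str, Iterable[str]],
    phi: float = 0.5,
    *,
    on_missing: str = "exclude",
) -> SimilarityMatrix:
    """Fused (mean of the two models) disease similarity over *diseases*.

    Diseases without tree codes are excluded with a log message by default
    (``on_missing="exclude"``) or raise (``on_missing="error"``).
    """
    if on_missing not in ("exclude", "error"):
        raise ValueError("on_missing must be 'exclude' or 'error'")
    tn = {normalize_name(d): set(c) for d, c in tree_numbers.items()}
    kept: dict[str, set[str]] = {}
    missing: list[str] = []
    for d in diseases:
        nd = normalize_name(d)
        if tn.get(nd):
            kept[nd] = tn[nd]
        else:
            missing.append(nd)
    if missing:
        if on_missing == "error":
            raise KeyError(f"diseases without tree codes: {missing[:5]}")
        logger.warning("excluding %d diseases without tree codes", len(missing))
    if not kept:
        raise ValueError("no disease has tree codes; cannot build a similarity matrix")
    _, _, fds, index = disease_similarity_matrices(kept, phi)
    return SimilarityMatrix(fds, index)
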