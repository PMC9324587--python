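"""Core matrix containers and the shared parameter bundle.

Three container types carry the pipeline's state:

* :class:`SimilarityMatrix` — square, symmetric, unit-diagonal, entries in
  [0, 1]. Holds the miRNA functional similarity, the drug chemical
  similarity, and the fused disease semantic similarity.
* :class:`AssociationMatrix` — rectangular nonnegative matrix between two
  entity sets, with a ``stage`` tag tracking its life cycle: ``raw`` (0/1
  experimentally confirmed edges), ``reconstructed`` (similarity-propagated
  weights), ``normalized`` (divided by the global maximum).
* :class:`ScoreMatrix` — the final (or intermediate) miRNA-disease path
  scores; entrywise at least the normalized direct-association matrix it
  was built from, since path contributions are nonnegative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .entities import EntityIndex

__all__ = [
    "SimilarityMatrix",
    "AssociationMatrix",
    "ScoreMatrix",
    "PathParams",
    "STAGES",
]

STAGES = ("raw", "reconstructed", "normalized")

_SYM_TOL = 1e-9
_RANGE_TOL = 1e-9


@dataclass(frozen=True)
class SimilarityMatrix:
    """Square symmetric similarity matrix in [0, 1] with unit diagonal."""

    values: np.ndarray
    index: EntityIndex

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.index)
        if v.shape != (n, n):
            raise ValueError(f"similarity shape {v.shape} != ({n}, {n})")
        if not np.allclose(v, v.T, atol=_SYM_TOL, rtol=0):
            raise ValueError("similarity matrix is not symmetric (atol 1e-9)")
        if not np.allclose(np.diag(v), 1.0, atol=_RANGE_TOL, rtol=0):
            raise ValueError("similarity diagonal must be 1")
        if v.min() < -_RANGE_TOL or v.max() > 1 + _RANGE_TOL:
            raise ValueError("similarity entries must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.index)


@dataclass(frozen=True)
class AssociationMatrix:
    """Rectangular nonnegative association matrix between two entity sets."""

    values: np.ndarray
    row_index: EntityIndex
    col_index: EntityIndex
    stage: str = "raw"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}, got {self.stage!r}")
        if v.shape != (len(self.row_index), len(self.col_index)):
            raise ValueError(
                f"association shape {v.shape} != "
                f"({len(self.row_index)}, {len(self.col_index)})"
            )
        if v.min() < 0:
            raise ValueError("association entries must be nonnegative")
        if self.stage == "raw" and not np.isin(v, (0.0, 1.0)).all():
            raise ValueError("raw association entries must be 0 or 1")
        if self.stage == "normalized" and v.max() > 0 and not np.isclose(v.max(), 1.0):
            raise ValueError("normalized association must have max entry 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def with_values(self, values: np.ndarray, stage: str | None = None) -> "AssociationMatrix":
        return AssociationMatrix(values, self.row_index, self.col_index, stage or self.stage)


@dataclass(frozen=True)
class ScoreMatrix:
    """miRNA x disease association scores (or an intermediate path-weight matrix)."""

    values: np.ndarray
    row_index: EntityIndex
    col_index: EntityIndex

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.row_index), len(self.col_index)):
            raise ValueError("score matrix shape does not match its indices")
        if not np.isfinite(v).all():
            raise ValueError("score entries must be finite")
        if v.min() < 0:
            raise ValueError("score entries must be nonnegative")


@dataclass(frozen=True)
class PathParams:
    """Tunable parameters of the pipeline.

    Attributes
    ----------
    T
        Similarity threshold in [0, 1]; off-diagonal similarities below T are
        pruned before reconstruction and path search (default 0.7).
    L
        Maximum path length in edges; only 2 is supported (longer paths
        accumulate error and admit closed loops).
    beta
        Attenuation factor of the decay exponent ``beta * len(path)``
        (default 7.0). The literature sometimes calls it alpha.
    phi
        Semantic contribution factor of the ancestor decay in the disease
        DAG model, in (0, 1) (default 0.5).
    rescale_mediated
        Whether the two drug-layer path-weight matrices are rescaled by
        their global maxima before the mediated term is exponentiated, so
        the decay exponent keeps contracting products toward zero.
    """

    T: float = 0.7
    L: int = 2
    beta: float = 7.0
    phi: float = 0.5
    rescale_mediated: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.T <= 1.0:
            raise ValueError("T must lie in [0, 1]")
        if not (isinstance(self.L, int) and self.L >= 1):
            raise ValueError("L must be an integer >= 1")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if not 0.0 < self.phi < 1.0:
            raise ValueError("phi must lie in (0, 1)")
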