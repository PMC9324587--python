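"""Entity indexing: stable name <-> position maps for miRNAs, drugs and diseases.

All inputs (edge lists, similarity matrices, tree-number records) refer to
entities by name. An :class:`EntityIndex` fixes an ordering once so that every
matrix in the pipeline shares the same row/column semantics. Names are
normalized (lowercase, trimmed, internal whitespace collapsed) because the
source databases in this domain disagree on casing and spacing conventions.
"""

from __future__ import annotations

import re
from collections.abc import Iterable, Sequence

__all__ = ["EntityIndex", "build_entity_index", "normalize_name", "KINDS"]

KINDS = ("mirna", "drug", "disease")

_WS = re.compile(r"\s+")


def normalize_name(name: str) -> str:
    """Lowercase, trim, and collapse internal whitespace runs to one space."""
    return _WS.sub(" ", name.strip()).lower()


class EntityIndex:
    """Immutable ordered set of unique (normalized) entity names.

    Parameters
    ----------
    names
        Entity names in the desired order. Duplicates after normalization
        collapse to their first occurrence.
    kind
        One of ``"mirna"``, ``"drug"``, ``"disease"``.
    """

    __slots__ = ("_names", "_pos", "kind")

    def __init__(self, names: Iterable[str], kind: str) -> None:
        if kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {kind!r}")
        ordered: list[str] = []
        pos: dict[str, int] = {}
        for raw in names:
            norm = normalize_name(raw)
            if not norm:
                raise ValueError("entity name is empty after normalization")
            if norm not in pos:
                pos[norm] = len(ordered)
                ordered.append(norm)
        if not ordered:
            raise ValueError("cannot build an EntityIndex from an empty name list")
        self._names = tuple(ordered)
        self._pos = pos
        self.kind = kind

    @property
    def names(self) -> tuple[str, ...]:
        return self._names

    def position(self, name: str) -> int:
        """Return the row/column position of *name* (normalized first)."""
        norm = normalize_name(name)
        try:
            return self._pos[norm]
        except KeyError:
            raise KeyError(f"unknown {self.kind} entity: {name!r}") from None

    def __len__(self) -> int:
        return len(self._names)

    def __contains__(self, name: str) -> bool:
        return normalize_name(name) in self._pos

    def __iter__(self):
        return iter(self._names)

    def __getitem__(self, i: int) -> str:
        return self._names[i]

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, EntityIndex)
            and self.kind == other.kind
            and self._names == other._names
        )

    def __hash__(self) -> int:
        return hash((self.kind, self._names))

    def __repr__(self) -> str:
        return f"EntityIndex(kind={self.kind!r}, n={len(self)})"


def build_entity_index(names: Sequence[str], kind: str) -> EntityIndex:
    """Build an :class:`EntityIndex`, collapsing normalized duplicates.

    Raises
    ------
    ValueError
        If *names* is empty or any name normalizes to the empty string.
    """
    return EntityIndex(names, kind)
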