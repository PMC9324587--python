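"""Readers and writers for the plain-text formats the pipeline consumes.

Formats
-------
* Association edge lists: delimited text, first two columns are row-entity
  and column-entity names (e.g. HMDD-style miRNA/disease pairs). Header
  optional.
* Similarity matrices: dense delimited tables with a header row and a name
  column; row/column order may differ from the target index.
* Disease tree numbers: two columns, disease name and a dot-separated MeSH
  tree code such as ``C04.588.274``; multiple rows per disease accumulate.
* Score tables: miRNA, disease, score, within-disease rank (descending by
  score, ties broken by miRNA index order).

The delimiter is auto-detected between tab and comma unless given.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .entities import EntityIndex, normalize_name
from .matrices import AssociationMatrix, ScoreMatrix, SimilarityMatrix

__all__ = [
    "load_association_edgelist",
    "write_association_edgelist",
    "load_similarity_matrix",
    "write_similarity_matrix",
    "load_tree_numbers",
    "write_tree_numbers",
    "write_score_table",
]

logger = logging.getLogger(__name__)

# Dot-separated alphanumeric segments; empty segments (`C04..588`) are invalid.
_TREE_CODE = re.compile(r"^[A-Za-z0-9]+(\.[A-Za-z0-9]+)*$")

_ASYM_TOL = 1e-6
_RANGE_TOL = 1e-6


def _detect_delimiter(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return "\t" if "\t" in line else ","
    return "\t"


def load_association_edgelist(
    path: str | Path,
    row_index: EntityIndex,
    col_index: EntityIndex,
    *,
    strict: bool = True,
    delimiter: str | None = None,
    header: bool = False,
) -> AssociationMatrix:
    """Load a two-column edge list into a raw 0/1 association matrix.

    Duplicate edges count once. Under ``strict=True`` an edge naming an
    entity absent from either index raises; under ``strict=False`` such
    edges are skipped and their count logged.
    """
    path = Path(path)
    delim = delimiter or _detect_delimiter(path)
    values = np.zeros((len(row_index), len(col_index)))
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if header and lineno == 1:
                continue
            if not line.strip():
                continue
            fields = line.rstrip("\n").split(delim)
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise ValueError(
                    f"{path}:{lineno}: expected at least two delimited columns"
                )
            row_name, col_name = fields[0], fields[1]
            if row_name not in row_index or col_name not in col_index:
                if strict:
                    missing = row_name if row_name not in row_index else col_name
                    raise KeyError(
                        f"{path}:{lineno}: unknown entity {missing!r}"
                    )
                skipped += 1
                continue
            values[row_index.position(row_name), col_index.position(col_name)] = 1.0
    if skipped:
        logger.info("skipped %d edges naming unindexed entities in %s", skipped, path)
    return AssociationMatrix(values, row_index, col_index, stage="raw")


def write_association_edgelist(
    assoc: AssociationMatrix, path: str | Path, *, delimiter: str = "\t"
) -> None:
    """Write the nonzero cells of a raw association matrix as an edge list."""
    with open(path, "w") as fh:
        for i, j in zip(*np.nonzero(assoc.values)):
            fh.write(
                f"{assoc.row_index[i]}{delimiter}{assoc.col_index[j]}\n"
            )


def load_similarity_matrix(
    path: str | Path,
    index: EntityIndex,
    *,
    delimiter: str | None = None,
) -> SimilarityMatrix:
    """Load a dense labelled similarity table, reordered to *index*.

    Rows and columns may appear in any order; both are permuted to the index
    ordering. Mild asymmetry (<= 1e-6) is repaired as ``(M + M.T) / 2``;
    larger asymmetry is an error. The diagonal is forced to 1.
    """
    path = Path(path)
    delim = delimiter or _detect_delimiter(path)
    df = pd.read_csv(path, sep=delim, index_col=0)
    df.index = [normalize_name(str(x)) for x in df.index]
    df.columns = [normalize_name(str(x)) for x in df.columns]
    wanted = list(index.names)
    missing = [n for n in wanted if n not in df.index or n not in df.columns]
    if missing:
        raise KeyError(f"{path}: entities missing from similarity table: {missing[:5]}")
    m = df.loc[wanted, wanted].to_numpy(dtype=float)
    asym = np.abs(m - m.T).max() if m.size else 0.0
    if asym > _ASYM_TOL:
        raise ValueError(f"{path}: similarity matrix asymmetric (max |M-M^T| = {asym:g})")
    m = (m + m.T) / 2.0
    if m.min() < -_RANGE_TOL or m.max() > 1 + _RANGE_TOL:
        raise ValueError(f"{path}: similarity entries outside [0, 1]")
    m = np.clip(m, 0.0, 1.0)
    np.fill_diagonal(m, 1.0)
    return SimilarityMatrix(m, index)


def write_similarity_matrix(
    sim: SimilarityMatrix, path: str | Path, *, delimiter: str = "\t"
) -> None:
    names = list(sim.index.names)
    pd.DataFrame(sim.values, index=names, columns=names).to_csv(path, sep=delimiter)


def load_tree_numbers(
    path: str | Path, *, delimiter: str | None = None
) -> dict[str, set[str]]:
    """Load disease -> MeSH tree-code records; multiple rows per disease merge.

    Codes are validated against the dot-separated alphanumeric grammar;
    a malformed code raises with its line number.
    """
    path = Path(path)
    delim = delimiter or _detect_delimiter(path)
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split(delim)
            if len(fields) < 2 or not fields[0].strip():
                raise ValueError(f"{path}:{lineno}: expected disease and tree code")
            code = fields[1].strip()
            if not _TREE_CODE.match(code):
                raise ValueError(f"{path}:{lineno}: malformed tree code {code!r}")
            mapping.setdefault(normalize_name(fields[0]), set()).add(code)
    return mapping


def write_tree_numbers(
    mapping: dict[str, set[str]], path: str | Path, *, delimiter: str = "\t"
) -> None:
    with open(path, "w") as fh:
        for disease in mapping:
            for code in sorted(mapping[disease]):
                fh.write(f"{disease}{delimiter}{code}\n")


def write_score_table(
    scores: ScoreMatrix,
    path: str | Path,
    *,
    top_k: int | None = None,
    delimiter: str = "\t",
) -> None:
    """Write per-disease descending score rankings.

    Columns: mirna, disease, score, rank (1-based within disease). Ties are
    broken by miRNA index order, so output is deterministic even when all
    scores coincide.
    """
    v = scores.values
    rows = []
    for j, disease in enumerate(scores.col_index.names):
        order = np.argsort(-v[:, j], kind="stable")  # stable: ties keep index order
        if top_k is not None:
            order = order[:top_k]
        for rank, i in enumerate(order, start=1):
            rows.append((scores.row_index[i], disease, v[i, j], rank))
    pd.DataFrame(rows, columns=["mirna", "disease", "score", "rank"]).to_csv(
        path, sep=delimiter, index=False
    )
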