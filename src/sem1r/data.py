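"""Datasets, examples, annotation maps, and semantic covers.

The learner operates on a 2-D binary matrix (rows are genes, columns are
samples).  Every matrix cell is one training example; cells valued 1 are
positive, cells valued 0 negative.  Rows and columns carry direct
ontology-term annotations, which are propagated downward through each
ontology so that a term covers every example annotated by it *or by any
less general term*:

    S(t) = union of M'(t') over all t' with t more-general-or-equal t'

A conjunctive rule R (a set of terms) covers the intersection of its
terms' covers, Theta(R).  These two functions are the semantic core of
the whole package; everything in the search is expressed through them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Literal, Mapping

import numpy as np
import pandas as pd

from .ontology import Ontology, OntologySet

__all__ = [
    "BinaryDataset",
    "ExampleSet",
    "AnnotationMap",
    "SemanticCover",
    "DataError",
    "read_matrix",
    "read_annotation_map",
    "binarize",
    "cells_to_examples",
    "treatment_control_examples",
    "build_semantic_cover",
    "rule_cover",
    "is_more_general_rule",
]

logger = logging.getLogger(__name__)

#: An example is one matrix cell, identified by its (row-id, col-id)
#: pair; toy/abstract problems may use plain hashable identifiers.
ExampleId = Hashable

Axis = Literal["rows", "columns", "examples"]


class DataError(ValueError):
    """Raised for malformed matrices, annotation maps, or id lookups."""


@dataclass(frozen=True)
class BinaryDataset:
    """A 0/1 matrix with named rows and columns."""

    row_ids: tuple[str, ...]
    col_ids: tuple[str, ...]
    cells: np.ndarray  # shape (n_rows, n_cols), values in {0, 1}

    def __post_init__(self):
        if len(set(self.row_ids)) != len(self.row_ids):
            raise DataError("duplicate row ids")
        if len(set(self.col_ids)) != len(self.col_ids):
            raise DataError("duplicate column ids")
        cells = np.asarray(self.cells)
        if cells.shape != (len(self.row_ids), len(self.col_ids)):
            raise DataError(
                f"matrix shape {cells.shape} does not match "
                f"{len(self.row_ids)} rows x {len(self.col_ids)} columns"
            )
        if cells.size and not np.isin(cells, (0, 1)).all():
            raise DataError("matrix cells must be exactly 0 or 1")
        object.__setattr__(self, "cells", cells.astype(np.int8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.cells.shape


@dataclass(frozen=True)
class ExampleSet:
    """Labelled examples: positive (value 1) and negative (value 0) cells."""

    positives: frozenset[ExampleId]
    negatives: frozenset[ExampleId]

    def __post_init__(self):
        object.__setattr__(self, "positives", frozenset(self.positives))
        object.__setattr__(self, "negatives", frozenset(self.negatives))
        if self.positives & self.negatives:
            raise DataError("an example cannot be both positive and negative")

    @property
    def all_examples(self) -> frozenset[ExampleId]:
        return self.positives | self.negatives

    @property
    def n_pos(self) -> int:
        return len(self.positives)

    @property
    def n_neg(self) -> int:
        return len(self.negatives)

    def __len__(self) -> int:
        return len(self.positives) + len(self.negatives)


@dataclass(frozen=True)
class AnnotationMap:
    """Direct entity -> ontology-term annotations for one matrix axis.

    ``axis`` says what the entity ids name: matrix rows, matrix columns,
    or (for abstract problems) the examples themselves.
    """

    direct: Mapping[str, frozenset[str]]
    axis: Axis = "rows"

    def __post_init__(self):
        if self.axis not in ("rows", "columns", "examples"):
            raise DataError(f"unknown annotation axis {self.axis!r}")
        frozen = {e: frozenset(ts) for e, ts in dict(self.direct).items()}
        object.__setattr__(self, "direct", frozen)


@dataclass(frozen=True)
class SemanticCover:
    """Materialized per-term covers S(t) over a fixed example scope.

    Terms absent from every direct annotation map have an empty cover;
    ``get`` returns the empty set for them without raising.
    ``dropped_terms`` reports annotation terms that were not found in
    any loaded ontology (they are ignored, not an error).
    """

    cover: Mapping[str, frozenset[ExampleId]]
    dropped_terms: frozenset[str] = field(default_factory=frozenset)

    def __getitem__(self, term_id: str) -> frozenset[ExampleId]:
        return self.cover[term_id]

    def get(self, term_id: str) -> frozenset[ExampleId]:
        return self.cover.get(term_id, frozenset())

    @property
    def terms(self) -> tuple[str, ...]:
        return tuple(sorted(self.cover))


# ---------------------------------------------------------------------------
# ingestion
# ---------------------------------------------------------------------------

def read_matrix(path) -> pd.DataFrame:
    """Read a TSV/CSV matrix: header row = column ids, first column = row ids."""
    return pd.read_csv(path, sep=None, engine="python", index_col=0)


def read_annotation_map(path, axis: Axis) -> AnnotationMap:
    """Read a two-column (entity-id, term-id) TSV into an :class:`AnnotationMap`.

    Lines starting with ``#`` or ``!`` are skipped.
    """
    direct: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith(("#", "!")):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise DataError(
                    f"{path}:{lineno}: expected two tab-separated columns"
                )
            entity, term = fields[0].strip(), fields[1].strip()
            direct.setdefault(entity, set()).add(term)
    return AnnotationMap(
        direct={e: frozenset(ts) for e, ts in direct.items()}, axis=axis
    )


def binarize(matrix, threshold: float) -> BinaryDataset:
    """Threshold a numeric matrix into a :class:`BinaryDataset`.

    A cell becomes 1 iff its value is strictly greater than
    ``threshold`` (for expression data, e.g. values above 0.5 TPM);
    ties go to 0.
    """
    if not np.isfinite(threshold):
        raise DataError("binarization threshold must be finite")
    if isinstance(matrix, pd.DataFrame):
        row_ids = tuple(str(r) for r in matrix.index)
        col_ids = tuple(str(c) for c in matrix.columns)
        values = matrix.to_numpy()
    else:
        values = np.asarray(matrix)
        if values.ndim != 2:
            raise DataError("matrix must be two-dimensional")
        row_ids = tuple(f"r{i}" for i in range(values.shape[0]))
        col_ids = tuple(f"c{j}" for j in range(values.shape[1]))

    try:
        numeric = values.astype(float)
    except (TypeError, ValueError):
        numeric = None
    if numeric is None or np.isnan(numeric).any():
        coerced = pd.DataFrame(values).apply(pd.to_numeric, errors="coerce")
        bad = np.argwhere(coerced.isna().to_numpy())
        i, j = bad[0]
        raise DataError(
            f"non-numeric or missing value at row {row_ids[i]!r}, "
            f"column {col_ids[j]!r}: {values[i, j]!r}"
        )
    return BinaryDataset(row_ids, col_ids, (numeric > threshold).astype(np.int8))


# ---------------------------------------------------------------------------
# example construction
# ---------------------------------------------------------------------------

def cells_to_examples(dataset: BinaryDataset) -> ExampleSet:
    """Label every matrix cell: value 1 -> positive, value 0 -> negative."""
    ones = np.argwhere(dataset.cells == 1)
    zeros = np.argwhere(dataset.cells == 0)
    positives = frozenset(
        (dataset.row_ids[i], dataset.col_ids[j]) for i, j in ones
    )
    negatives = frozenset(
        (dataset.row_ids[i], dataset.col_ids[j]) for i, j in zeros
    )
    return ExampleSet(positives, negatives)


def treatment_control_examples(
    dataset: BinaryDataset,
    sig_rows: Iterable[str],
    treat_cols: Iterable[str],
    ctrl_cols: Iterable[str],
) -> ExampleSet:
    """Build examples from a treatment/control design.

    Positives are all cells of the selected rows in the treatment
    columns, negatives all cells of those rows in the control columns;
    the matrix values themselves are ignored in this mode.
    """
    sig_rows = set(sig_rows)
    treat_cols = set(treat_cols)
    ctrl_cols = set(ctrl_cols)
    overlap = treat_cols & ctrl_cols
    if overlap:
        raise DataError(
            f"treatment and control columns overlap: {sorted(overlap)}"
        )
    known_rows = set(dataset.row_ids)
    known_cols = set(dataset.col_ids)
    for r in sig_rows - known_rows:
        raise DataError(f"unknown row id {r!r}")
    for c in (treat_cols | ctrl_cols) - known_cols:
        raise DataError(f"unknown column id {c!r}")
    positives = frozenset((r, c) for r in sig_rows for c in treat_cols)
    negatives = frozenset((r, c) for r in sig_rows for c in ctrl_cols)
    return ExampleSet(positives, negatives)


# ---------------------------------------------------------------------------
# semantic covers
# ---------------------------------------------------------------------------

def build_semantic_cover(
    ontologies: OntologySet | Iterable[Ontology],
    maps: Iterable[AnnotationMap],
    examples: ExampleSet,
) -> SemanticCover:
    """Propagate direct annotations into per-term covers S(t).

    For a row-axis term the cover is the set of in-scope cells whose
    row is annotated (directly or through any descendant term); dually
    for columns.  Terms never annotated get an empty cover.  Annotation
    terms missing from every loaded ontology are dropped with a logged
    count and reported in ``dropped_terms``.
    """
    if not isinstance(ontologies, OntologySet):
        ontologies = OntologySet(ontologies)
    scope = examples.all_examples

    # entity -> in-scope examples, per axis
    by_row: dict[str, set[ExampleId]] = {}
    by_col: dict[str, set[ExampleId]] = {}
    for e in scope:
        if isinstance(e, tuple) and len(e) == 2:
            by_row.setdefault(e[0], set()).add(e)
            by_col.setdefault(e[1], set()).add(e)

    # direct example sets M'(t) per term
    direct: dict[str, set[ExampleId]] = {}
    dropped: set[str] = set()
    for amap in maps:
        for entity, terms in amap.direct.items():
            if amap.axis == "rows":
                entity_examples = by_row.get(entity, set())
            elif amap.axis == "columns":
                entity_examples = by_col.get(entity, set())
            else:  # direct example annotation
                entity_examples = {entity} if entity in scope else set()
            if not entity_examples:
                continue
            for t in terms:
                if t not in ontologies:
                    dropped.add(t)
                    continue
                direct.setdefault(t, set()).update(entity_examples)
    if dropped:
        logger.warning(
            "dropped %d annotation term(s) not found in any ontology", len(dropped)
        )

    cover: dict[str, frozenset[ExampleId]] = {}
    for tid in ontologies.term_ids:
        members = set(direct.get(tid, ()))
        for d in ontologies.descendants(tid):
            members.update(direct.get(d, ()))
        cover[tid] = frozenset(members)
    return SemanticCover(cover=cover, dropped_terms=frozenset(dropped))


def rule_cover(
    rule_terms: Iterable[str],
    cover: SemanticCover,
    all_examples: Iterable[ExampleId],
) -> frozenset[ExampleId]:
    """Theta(R): intersection of the member terms' covers.

    The empty rule is the empty conjunction, vacuously true, so it
    covers every example in scope.
    """
    terms = sorted(set(rule_terms))
    if not terms:
        return frozenset(all_examples)
    result = cover.get(terms[0])
    for t in terms[1:]:
        result = result & cover.get(t)
        if not result:
            break
    return frozenset(result)


def is_more_general_rule(
    r1: Iterable[str],
    r2: Iterable[str],
    cover: SemanticCover,
    all_examples: Iterable[ExampleId],
) -> bool:
    """True iff rule ``r1`` covers a superset of rule ``r2``'s cover."""
    all_examples = frozenset(all_examples)
    return rule_cover(r1, cover, all_examples) >= rule_cover(r2, cover, all_examples)
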