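"""Synthetic worlds: the packaged toy fixture and random planted instances.

The toy fixture is a seven-term ontology over three labelled examples,
small enough that every cover, confusion count, and quality value can be
checked by hand; it anchors the unit tests of every other module.  The
exact edge set is a committed reconstruction — what matters, and what
tests assert, are the propagated covers it induces:

    S(t0) = {e1, e2, e3}   S(t1) = {e1}        S(t2) = {e1, e2, e3}
    S(t3) = {e2}           S(t4) = {e1}        S(t5) = {e2}
    S(t6) = {e2}

Random instances plant a conjunctive rule inside a random DAG ontology:
the cells covered by the planted conjunction are set to 1, everything
else to 0, and an optional symmetric noise flips cells independently.
At zero noise the planted rule is a perfect, recoverable description of
the positive class.
"""

from __future__ import annotations

from dataclasses import dataclass

from pathlib import Path

import numpy as np

from .data import (
    AnnotationMap,
    BinaryDataset,
    ExampleSet,
    SemanticCover,
    build_semantic_cover,
    cells_to_examples,
)
from .ontology import Ontology, OntologySet, Term

__all__ = [
    "ToyFixture",
    "PlantedInstance",
    "GenerationError",
    "TOY_EDGES",
    "build_toy_fixture",
    "random_ontology",
    "planted_rule_dataset",
    "ontology_to_obo",
    "export_instance",
]


class GenerationError(RuntimeError):
    """Raised when a random instance cannot be generated."""


# child -> parents; a Hasse-diagram reconstruction consistent with the
# propagated covers documented above
TOY_EDGES: dict[str, tuple[str, ...]] = {
    "t0": (),
    "t1": ("t0",),
    "t2": ("t0",),
    "t3": ("t0",),
    "t4": ("t1", "t2"),
    "t5": ("t2", "t3"),
    "t6": ("t3",),
}

_TOY_DIRECT = {"e1": ("t4",), "e2": ("t5", "t6"), "e3": ("t2",)}
_TOY_POSITIVES = ("e1", "e3")
_TOY_NEGATIVES = ("e2",)


@dataclass(frozen=True)
class ToyFixture:
    """The hand-checkable seven-term, three-example world."""

    ontology: Ontology
    ontologies: OntologySet
    examples: ExampleSet
    annotations: AnnotationMap
    cover: SemanticCover


def build_toy_fixture() -> ToyFixture:
    """Build the toy world: 7 terms t0..t6, examples e1..e3, E+={e1,e3}."""
    terms = [
        Term(id=tid, name=f"toy term {tid}", parent_ids=frozenset(parents),
             ontology_id="toy")
        for tid, parents in TOY_EDGES.items()
    ]
    ontology = Ontology("toy", terms)
    ontologies = OntologySet([ontology])
    examples = ExampleSet(frozenset(_TOY_POSITIVES), frozenset(_TOY_NEGATIVES))
    annotations = AnnotationMap(
        direct={e: frozenset(ts) for e, ts in _TOY_DIRECT.items()},
        axis="examples",
    )
    cover = build_semantic_cover(ontologies, [annotations], examples)
    return ToyFixture(ontology, ontologies, examples, annotations, cover)


# ---------------------------------------------------------------------------
# random generators
# ---------------------------------------------------------------------------

def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def random_ontology(
    n_terms: int,
    max_parents: int = 2,
    seed=None,
    prefix: str = "T",
) -> Ontology:
    """A random single-rooted DAG ontology.

    Term ``i`` (for i >= 1) draws 1..``max_parents`` parents uniformly
    from the earlier terms, which guarantees acyclicity, connectivity,
    and a single root (term 0).  Deterministic for a fixed seed.
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    if max_parents < 1:
        raise ValueError("max_parents must be >= 1")
    rng = _as_rng(seed)
    width = len(str(n_terms - 1))
    ids = [f"{prefix}{i:0{width}d}" for i in range(n_terms)]
    terms = [Term(id=ids[0], name=f"{prefix} root", ontology_id=prefix)]
    for i in range(1, n_terms):
        k = int(rng.integers(1, min(max_parents, i) + 1))
        parents = rng.choice(i, size=k, replace=False)
        terms.append(
            Term(
                id=ids[i],
                name=f"{prefix} term {i}",
                parent_ids=frozenset(ids[int(p)] for p in parents),
                ontology_id=prefix,
            )
        )
    return Ontology(prefix, terms)


@dataclass(frozen=True)
class PlantedInstance:
    """A binary matrix generated from a hidden conjunctive rule."""

    ontology: Ontology
    col_ontology: Ontology | None
    dataset: BinaryDataset
    row_annotations: AnnotationMap
    col_annotations: AnnotationMap | None
    planted_rule: frozenset[str]
    planted_cover: frozenset  # cells covered by the planted conjunction
    noise_rate: float
    seed: int | None

    def problem(self) -> tuple[ExampleSet, SemanticCover, OntologySet]:
        """Materialize the learning problem for this instance."""
        ontos = [self.ontology]
        maps = [self.row_annotations]
        if self.col_ontology is not None:
            ontos.append(self.col_ontology)
            maps.append(self.col_annotations)
        ontologies = OntologySet(ontos)
        examples = cells_to_examples(self.dataset)
        cover = build_semantic_cover(ontologies, maps, examples)
        return examples, cover, ontologies


def _annotate(rng, entity_ids, term_ids, per_entity):
    k = min(per_entity, len(term_ids))
    direct = {}
    for e in entity_ids:
        picks = rng.choice(len(term_ids), size=k, replace=False)
        direct[e] = frozenset(term_ids[int(i)] for i in picks)
    return direct


def _terms_covering(ontology: Ontology, direct_terms) -> set[str]:
    covering = set()
    for t in direct_terms:
        covering.add(t)
        covering.update(ontology.ancestors(t))
    return covering


def planted_rule_dataset(
    ontology: Ontology,
    n_rows: int,
    n_cols: int,
    rule_length: int = 2,
    noise_rate: float = 0.0,
    seed: int | None = None,
    col_ontology: Ontology | None = None,
    annotations_per_entity: int = 2,
    max_tries: int = 200,
) -> PlantedInstance:
    """Generate a matrix whose 1-cells are a planted conjunction's cover.

    Rows (and columns, when ``col_ontology`` is given) receive random
    direct annotations.  A pairwise-incomparable conjunction of
    ``rule_length`` terms with a non-empty, non-universal cover is then
    sampled; covered cells become 1, the rest 0, and each cell is
    flipped independently with probability ``noise_rate``.
    """
    if rule_length < 1:
        raise ValueError("rule_length must be >= 1")
    if not 0.0 <= noise_rate < 0.5:
        raise ValueError("noise_rate must be in [0, 0.5)")
    rng = _as_rng(seed)
    row_ids = [f"r{i:03d}" for i in range(n_rows)]
    col_ids = [f"c{j:03d}" for j in range(n_cols)]

    row_terms = list(ontology.term_ids)
    row_direct = _annotate(rng, row_ids, row_terms, annotations_per_entity)
    col_direct = None
    if col_ontology is not None:
        col_terms = list(col_ontology.term_ids)
        col_direct = _annotate(rng, col_ids, col_terms, annotations_per_entity)

    def rows_under(terms) -> set[str]:
        return {
            r
            for r in row_ids
            if all(t in _terms_covering(ontology, row_direct[r]) for t in terms)
        }

    def cols_under(terms) -> set[str]:
        if col_direct is None:
            return set(col_ids)
        return {
            c
            for c in col_ids
            if all(
                t in _terms_covering(col_ontology, col_direct[c]) for t in terms
            )
        }

    def greedy_incomparable(pool: list[str], onto: Ontology, want: int, rng):
        """Pick up to ``want`` pairwise-incomparable terms from ``pool``."""
        order = rng.permutation(len(pool))
        chosen: list[str] = []
        for i in order:
            t = pool[int(i)]
            if all(
                not (onto.is_more_general(t, c) or onto.is_more_general(c, t))
                for c in chosen
            ):
                chosen.append(t)
                if len(chosen) == want:
                    break
        return chosen

    n_cells = n_rows * n_cols
    for _ in range(max_tries):
        anchor_row = row_ids[int(rng.integers(n_rows))]
        pool_row = sorted(_terms_covering(ontology, row_direct[anchor_row]))
        pools = [(pool_row, ontology)]
        if col_direct is not None:
            anchor_col = col_ids[int(rng.integers(n_cols))]
            pools.append(
                (sorted(_terms_covering(col_ontology, col_direct[anchor_col])),
                 col_ontology)
            )
        # spread the rule's terms over the available axes
        rule_terms: list[str] = []
        per_axis: list[list[str]] = []
        for axis_index, (pool, onto) in enumerate(pools):
            want = rule_length - len(rule_terms) if axis_index == len(pools) - 1 \
                else max(1, rule_length // len(pools))
            if want == 0:
                per_axis.append([])
                continue
            chosen = greedy_incomparable(pool, onto, want, rng)
            rule_terms.extend(chosen)
            per_axis.append(chosen)
        if len(rule_terms) != rule_length:
            continue

        covered_rows = rows_under(per_axis[0])
        covered_cols = cols_under(per_axis[1] if len(per_axis) > 1 else [])
        cover = frozenset((r, c) for r in covered_rows for c in covered_cols)
        if not cover or len(cover) == n_cells:
            continue

        cells = np.zeros((n_rows, n_cols), dtype=np.int8)
        row_index = {r: i for i, r in enumerate(row_ids)}
        col_index = {c: j for j, c in enumerate(col_ids)}
        for r, c in cover:
            cells[row_index[r], col_index[c]] = 1
        if noise_rate > 0.0:
            flips = rng.random((n_rows, n_cols)) < noise_rate
            cells = np.where(flips, 1 - cells, cells).astype(np.int8)

        return PlantedInstance(
            ontology=ontology,
            col_ontology=col_ontology,
            dataset=BinaryDataset(tuple(row_ids), tuple(col_ids), cells),
            row_annotations=AnnotationMap(direct=row_direct, axis="rows"),
            col_annotations=(
                AnnotationMap(direct=col_direct, axis="columns")
                if col_direct is not None
                else None
            ),
            planted_rule=frozenset(rule_terms),
            planted_cover=cover,
            noise_rate=noise_rate,
            seed=seed if isinstance(seed, int) else None,
        )
    raise GenerationError(
        f"no usable planted conjunction found after {max_tries} tries"
    )


# ---------------------------------------------------------------------------
# export (for CLI round trips)
# ---------------------------------------------------------------------------

def ontology_to_obo(ontology: Ontology) -> str:
    """Serialize an ontology as minimal OBO 1.2 text."""
    lines = ["format-version: 1.2", f"ontology: {ontology.id}", ""]
    for tid in ontology.term_ids:
        term = ontology.term(tid)
        lines.append("[Term]")
        lines.append(f"id: {term.id}")
        if term.name:
            lines.append(f"name: {term.name}")
        for parent in sorted(term.parent_ids):
            lines.append(f"is_a: {parent}")
        lines.append("")
    return "\n".join(lines)


def export_instance(instance: PlantedInstance, directory) -> dict[str, Path]:
    """Write a planted instance as OBO + TSV files for end-to-end runs.

    Returns the paths written, keyed by role (``matrix``, ``row_onto``,
    ``row_annot``, and the column-side files when present).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    matrix = directory / "matrix.tsv"
    with open(matrix, "w") as fh:
        fh.write("id\t" + "\t".join(instance.dataset.col_ids) + "\n")
        for i, r in enumerate(instance.dataset.row_ids):
            row = "\t".join(str(int(v)) for v in instance.dataset.cells[i])
            fh.write(f"{r}\t{row}\n")
    paths["matrix"] = matrix

    row_onto = directory / "row_ontology.obo"
    row_onto.write_text(ontology_to_obo(instance.ontology))
    paths["row_onto"] = row_onto

    row_annot = directory / "row_annotations.tsv"
    with open(row_annot, "w") as fh:
        for entity in sorted(instance.row_annotations.direct):
            for t in sorted(instance.row_annotations.direct[entity]):
                fh.write(f"{entity}\t{t}\n")
    paths["row_annot"] = row_annot

    if instance.col_ontology is not None:
        col_onto = directory / "col_ontology.obo"
        col_onto.write_text(ontology_to_obo(instance.col_ontology))
        paths["col_onto"] = col_onto
        col_annot = directory / "col_annotations.tsv"
        with open(col_annot, "w") as fh:
            for entity in sorted(instance.col_annotations.direct):
                for t in sorted(instance.col_annotations.direct[entity]):
                    fh.write(f"{entity}\t{t}\n")
        paths["col_annot"] = col_annot
    return paths
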