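"""Ontology DAGs and the "more general than" partial order.

An ontology is a set of terms related by directed subsumption edges
(child ``is_a`` parent).  The reflexive-transitive closure of those edges
gives the partial order "more general than": ``t1`` is more general than
``t2`` when every entity annotated under ``t2`` is also, semantically,
under ``t1``.  This order is what the rule learner exploits: adding a
generalization of a term already present in a conjunctive rule never
changes the rule's cover, so such candidates can be pruned outright.

Terms from different ontologies are never comparable; rules are free to
mix terms across ontologies (e.g. a gene-function term with an anatomy
term), and :class:`OntologySet` provides the combined view used by the
search.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import networkx as nx
import obonet

__all__ = [
    "Term",
    "Ontology",
    "OntologySet",
    "OntologyError",
    "OboParseError",
    "CycleError",
    "UnknownTermError",
    "parse_obo",
]


class OntologyError(ValueError):
    """Base class for ontology construction and query errors."""


class OboParseError(OntologyError):
    """Raised when an OBO stream cannot be parsed."""


class CycleError(OntologyError):
    """Raised when the subsumption relation is not acyclic."""

    def __init__(self, cycle: list[tuple[str, str]]):
        self.cycle = list(cycle)
        path = " -> ".join(edge[0] for edge in self.cycle)
        super().__init__(f"subsumption edges contain a cycle: {path}")


class UnknownTermError(OntologyError, KeyError):
    """Raised when a term identifier is not present in the ontology."""

    def __init__(self, term_id: str, ontology_id: str = ""):
        where = f" in ontology {ontology_id!r}" if ontology_id else ""
        super().__init__(f"unknown term {term_id!r}{where}")
        self.term_id = term_id


@dataclass(frozen=True)
class Term:
    """A single ontology term.

    Parameters
    ----------
    id
        Opaque identifier, unique within its ontology (e.g. a GO or
        FBbt accession).
    name
        Human-readable label; may be empty.
    parent_ids
        Identifiers of the terms this one is directly subsumed by.
    ontology_id
        Identifier of the owning ontology.
    """

    id: str
    name: str = ""
    parent_ids: frozenset[str] = field(default_factory=frozenset)
    ontology_id: str = ""


class Ontology:
    """A DAG of terms with ancestor/descendant queries.

    Edges run child -> parent, so "ancestors" of a term are all terms
    that are strictly more general than it.  The relation exposed by
    :meth:`is_more_general` is the reflexive-transitive closure of the
    edge set and is validated to be a partial order (acyclicity is
    checked at construction).
    """

    def __init__(self, id: str, terms: Iterable[Term]):
        self.id = id
        self._terms: dict[str, Term] = {}
        for t in terms:
            if t.id in self._terms:
                raise OntologyError(f"duplicate term id {t.id!r} in ontology {id!r}")
            self._terms[t.id] = t

        graph = nx.DiGraph()
        graph.add_nodes_from(self._terms)
        for t in self._terms.values():
            for p in t.parent_ids:
                if p not in self._terms:
                    raise OntologyError(
                        f"term {t.id!r} names unknown parent {p!r} in ontology {id!r}"
                    )
                graph.add_edge(t.id, p)
        if not nx.is_directed_acyclic_graph(graph):
            raise CycleError(nx.find_cycle(graph))
        self._graph = graph
        self._ancestors: dict[str, frozenset[str]] = {}
        self._descendants: dict[str, frozenset[str]] = {}

    # -- container protocol -------------------------------------------------
    def __contains__(self, term_id: str) -> bool:
        return term_id in self._terms

    def __len__(self) -> int:
        return len(self._terms)

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self._terms))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Ontology({self.id!r}, {len(self)} terms)"

    @property
    def term_ids(self) -> tuple[str, ...]:
        """All term identifiers, lexicographically sorted."""
        return tuple(sorted(self._terms))

    @property
    def n_edges(self) -> int:
        return self._graph.number_of_edges()

    def term(self, term_id: str) -> Term:
        try:
            return self._terms[term_id]
        except KeyError:
            raise UnknownTermError(term_id, self.id) from None

    # -- order queries ------------------------------------------------------
    def ancestors(self, term_id: str) -> frozenset[str]:
        """Terms strictly more general than ``term_id``."""
        if term_id not in self._terms:
            raise UnknownTermError(term_id, self.id)
        cached = self._ancestors.get(term_id)
        if cached is None:
            # edges point child -> parent, so reachable nodes are ancestors
            cached = frozenset(nx.descendants(self._graph, term_id))
            self._ancestors[term_id] = cached
        return cached

    def descendants(self, term_id: str) -> frozenset[str]:
        """Terms strictly less general than ``term_id``."""
        if term_id not in self._terms:
            raise UnknownTermError(term_id, self.id)
        cached = self._descendants.get(term_id)
        if cached is None:
            cached = frozenset(nx.ancestors(self._graph, term_id))
            self._descendants[term_id] = cached
        return cached

    def is_more_general(self, t1: str, t2: str) -> bool:
        """True iff ``t1`` is more general than or equal to ``t2``.

        The relation is reflexive: ``is_more_general(t, t)`` is True.
        """
        if t1 not in self._terms:
            raise UnknownTermError(t1, self.id)
        if t2 not in self._terms:
            raise UnknownTermError(t2, self.id)
        return t1 == t2 or t1 in self.ancestors(t2)

    def roots(self) -> frozenset[str]:
        """Terms with no parents."""
        return frozenset(n for n in self._graph if self._graph.out_degree(n) == 0)


class OntologySet:
    """Combined view over several ontologies.

    Terms from different ontologies are mutually incomparable under
    "more general than"; every other query dispatches to the owning
    ontology.  Term identifiers must be globally unique across the set.
    """

    def __init__(self, ontologies: Iterable[Ontology]):
        self.ontologies: list[Ontology] = list(ontologies)
        self._owner: dict[str, Ontology] = {}
        for o in self.ontologies:
            for tid in o.term_ids:
                if tid in self._owner:
                    raise OntologyError(
                        f"term id {tid!r} appears in ontologies "
                        f"{self._owner[tid].id!r} and {o.id!r}"
                    )
                self._owner[tid] = o

    def __contains__(self, term_id: str) -> bool:
        return term_id in self._owner

    def __len__(self) -> int:
        return len(self._owner)

    @property
    def term_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self._owner))

    def ontology_of(self, term_id: str) -> Ontology:
        try:
            return self._owner[term_id]
        except KeyError:
            raise UnknownTermError(term_id) from None

    def term(self, term_id: str) -> Term:
        return self.ontology_of(term_id).term(term_id)

    def ancestors(self, term_id: str) -> frozenset[str]:
        return self.ontology_of(term_id).ancestors(term_id)

    def descendants(self, term_id: str) -> frozenset[str]:
        return self.ontology_of(term_id).descendants(term_id)

    def is_more_general(self, t1: str, t2: str) -> bool:
        """``t1`` more-general-or-equal ``t2``; False across ontologies."""
        o1 = self.ontology_of(t1)
        o2 = self.ontology_of(t2)
        if o1 is not o2:
            return False
        return o1.is_more_general(t1, t2)

    def comparable(self, t1: str, t2: str) -> bool:
        """True iff the two terms are related by the partial order in
        either direction (including equality)."""
        return self.is_more_general(t1, t2) or self.is_more_general(t2, t1)


def parse_obo(
    source,
    *,
    ontology_id: str | None = None,
    include_part_of: bool = False,
) -> Ontology:
    """Parse an OBO flat file into an :class:`Ontology`.

    Parameters
    ----------
    source
        A path, an open text handle, or a string containing OBO text
        (recognised by the presence of a newline).
    ontology_id
        Identifier for the resulting ontology; defaults to the
        ``ontology:`` header of the file, or ``"ontology"``.
    include_part_of
        When True, ``relationship: part_of`` edges contribute to the
        subsumption order in addition to ``is_a``.  Only ``is_a`` is a
        universally safe subsumption relation, hence the default.

    Only ``[Term]`` stanzas are consumed; obsolete terms are dropped.
    A cycle in the selected relations raises :class:`CycleError`.
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    try:
        graph = obonet.read_obo(source, ignore_obsolete=True)
    except Exception as exc:  # obonet raises ValueError on malformed stanzas
        raise OboParseError(f"malformed OBO input: {exc}") from exc

    oid = ontology_id or graph.graph.get("ontology") or "ontology"
    relations = {"is_a"}
    if include_part_of:
        relations.add("part_of")

    terms = []
    for node, data in graph.nodes(data=True):
        parents = frozenset(
            parent
            for _, parent, key in graph.out_edges(node, keys=True)
            if key in relations
        )
        terms.append(
            Term(
                id=node,
                name=data.get("name", ""),
                parent_ids=parents,
                ontology_id=oid,
            )
        )
    return Ontology(oid, terms)
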