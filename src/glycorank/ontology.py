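"""Ontology parsing and DAG queries.

The package works on a subset of the OBO flat-file format: ``[Term]``
stanzas with ``id``, ``name``, ``is_a`` (with optional ``! comment``),
``alt_id`` and ``is_obsolete``. Only ``is_a`` (subclass) edges are
honored — phenotype-profile matching here is purely subclass-based, so
other relationship types are ignored on purpose. Obsolete terms are
excluded entirely; their alternate/own ids never become canonical term
ids downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Set

import networkx as nx
import obonet

from .errors import LookupError_, ValidationError

#: CURIE-style term identifier, e.g. ``"HP:0012345"`` or ``"SYN:0000007"``.
TermId = str


@dataclass
class OntologyGraph:
    """A rooted is_a DAG of phenotype terms.

    Parameters
    ----------
    terms
        Mapping of canonical term id to human-readable label.
    parents
        Mapping of term id to the set of its direct is_a parents. Roots
        map to an empty set.
    alt_ids
        Mapping of alternate (merged) ids to their canonical id. Never
        used as canonical ids; provided only as a lookup convenience.
    """

    terms: Dict[TermId, str]
    parents: Dict[TermId, FrozenSet[TermId]]
    alt_ids: Dict[TermId, TermId] = field(default_factory=dict)
    _anc_cache: Dict[TermId, FrozenSet[TermId]] = field(
        default_factory=dict, repr=False, compare=False
    )

    @property
    def roots(self) -> Set[TermId]:
        """Terms with no is_a parent. Multiple roots are allowed."""
        return {t for t, ps in self.parents.items() if not ps}

    def __contains__(self, term: TermId) -> bool:
        return term in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def validate(self) -> None:
        """Check structural invariants; raise :class:`ValidationError` if broken."""
        for t, ps in self.parents.items():
            for p in ps:
                if p not in self.terms:
                    raise ValidationError(
                        f"term {t!r} has is_a parent {p!r} not defined in the ontology"
                    )
        g = nx.DiGraph((child, parent) for child, ps in self.parents.items() for parent in ps)
        if not nx.is_directed_acyclic_graph(g):
            member = nx.find_cycle(g)[0][0]
            raise ValidationError(f"is_a cycle detected involving term {member!r}")
        if not self.roots:
            raise ValidationError("ontology has no root (every term has a parent)")

    def ancestors(self, term: TermId) -> FrozenSet[TermId]:
        """Reflexive transitive is_a closure of *term* (the term itself included).

        Reflexivity makes the ancestor-Jaccard of a term with itself 1 and
        its self-MICA the term itself, as is standard in semantic-similarity
        work. Results are memoized on the graph.
        """
        if term not in self.terms:
            raise LookupError_(f"unknown term {term!r}")
        cached = self._anc_cache.get(term)
        if cached is not None:
            return cached
        closure: Set[TermId] = set()
        stack = [term]
        while stack:
            t = stack.pop()
            if t in closure:
                continue
            closure.add(t)
            stack.extend(self.parents[t])
        result = frozenset(closure)
        self._anc_cache[term] = result
        return result


def ancestors(graph: OntologyGraph, term: TermId) -> FrozenSet[TermId]:
    """Functional alias for :meth:`OntologyGraph.ancestors`."""
    return graph.ancestors(term)


def parse_obo(path) -> OntologyGraph:
    """Parse an OBO flat file into an :class:`OntologyGraph`.

    Obsolete term stanzas are dropped (including their is_a lines), alt_ids
    are recorded in :attr:`OntologyGraph.alt_ids`, and any relationship
    other than is_a is ignored. An is_a reference to an id that is not a
    defined, non-obsolete term is a validation error, as is a cycle.
    """
    try:
        multigraph = obonet.read_obo(path, ignore_obsolete=True)
    except FileNotFoundError:
        raise
    terms: Dict[TermId, str] = {}
    alt_ids: Dict[TermId, TermId] = {}
    for node, data in multigraph.nodes(data=True):
        if "name" not in data:
            # obonet materializes edge targets as bare nodes; a node with no
            # stanza of its own is an undefined (or obsolete) reference.
            referrers = sorted(
                child for child, parent, key in multigraph.edges(keys=True)
                if parent == node and key == "is_a"
            )
            raise ValidationError(
                f"is_a reference to unknown or obsolete term {node!r}"
                + (f" (referenced by {', '.join(referrers)})" if referrers else "")
            )
        terms[node] = data["name"]
        for alt in data.get("alt_id", []):
            alt_ids[alt] = node
    parents: Dict[TermId, FrozenSet[TermId]] = {
        t: frozenset(
            parent
            for _, parent, key in multigraph.out_edges(t, keys=True)
            if key == "is_a"
        )
        for t in terms
    }
    graph = OntologyGraph(terms=terms, parents=parents, alt_ids=alt_ids)
    graph.validate()
    return graph


def write_obo(graph: OntologyGraph, path) -> None:
    """Serialize *graph* in the same OBO subset :func:`parse_obo` reads."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\nontology: glycorank-synthetic\n")
        for term in sorted(graph.terms):
            fh.write(f"\n[Term]\nid: {term}\nname: {graph.terms[term]}\n")
            for parent in sorted(graph.parents[term]):
                fh.write(f"is_a: {parent} ! {graph.terms[parent]}\n")


def topological_order(graph: OntologyGraph) -> Iterable[TermId]:
    """Terms ordered parents-before-children (roots first)."""
    g = nx.DiGraph()
    g.add_nodes_from(graph.terms)
    g.add_edges_from(
        (parent, child) for child, ps in graph.parents.items() for parent in ps
    )
    return nx.topological_sort(g)
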