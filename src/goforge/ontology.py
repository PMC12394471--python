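"""Gene Ontology graph: OBO parsing, ancestor closure, namespace lookup.

The Gene Ontology is a directed acyclic graph in which specific "child"
terms point at broader "parent" terms along ``is_a`` and ``part_of`` edges;
a term may have several parents. Three namespace roots (biological_process,
molecular_function, cellular_component) have no parents. Annotation
propagation walks parent edges: a gene annotated with a child term is
implicitly annotated with every ancestor.

Only ``[Term]`` stanzas of the OBO 1.2/1.4 flat format are consumed;
``[Typedef]`` and other stanzas are skipped. Obsolete terms are kept in a
side table so annotations citing them can still be reported, but they carry
no edges and never participate in the DAG. Alternate accessions (``alt_id``)
are resolved silently before every lookup, since NCBI gene2go routinely
cites merged ids.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Union

import networkx as nx

from .errors import OboParseError, OntologyLookupError, ValidationError

GO_ID_RE = re.compile(r"GO:\d{7}$")

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")

#: gene2go Category column value for each namespace
NAMESPACE_CATEGORY = {
    "biological_process": "Process",
    "molecular_function": "Function",
    "cellular_component": "Component",
}

_PARENT_RELATIONSHIPS = ("is_a", "part_of")


def is_go_id(token: str) -> bool:
    return bool(GO_ID_RE.match(token))


@dataclass
class GoTerm:
    """One GO term: accession, name, namespace and its parent accessions."""

    id: str
    name: str = ""
    namespace: str = ""
    parents: set[str] = field(default_factory=set)
    obsolete: bool = False
    # edge type per parent ("is_a" or "part_of"), kept so serialization
    # round-trips; propagation treats both identically.
    edge_types: dict[str, str] = field(default_factory=dict)


class OntologyGraph:
    """GO terms plus alt-id aliasing, with memoised ancestor queries."""

    def __init__(self) -> None:
        self.terms: dict[str, GoTerm] = {}
        self.alt_id_map: dict[str, str] = {}
        self.obsolete_terms: dict[str, GoTerm] = {}
        self._ancestor_cache: dict[str, frozenset[str]] = {}

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, go_id: str) -> bool:
        try:
            self.resolve(go_id)
            return True
        except OntologyLookupError:
            return False

    def resolve(self, go_id: str) -> str:
        """Map an accession (possibly an alt_id) to its primary accession."""
        primary = self.alt_id_map.get(go_id, go_id)
        if primary not in self.terms:
            raise OntologyLookupError(go_id)
        return primary

    def term(self, go_id: str) -> GoTerm:
        return self.terms[self.resolve(go_id)]

    def ancestors(self, go_id: str) -> set[str]:
        """Transitive closure over parent edges, excluding the term itself.

        Empty for namespace roots. Memoised; the graph must not be mutated
        after the first query.
        """
        primary = self.resolve(go_id)
        return set(self._ancestors_cached(primary))

    def _ancestors_cached(self, primary: str) -> frozenset[str]:
        cached = self._ancestor_cache.get(primary)
        if cached is not None:
            return cached
        # iterative post-order so deep chains don't hit the recursion limit
        stack = [primary]
        while stack:
            node = stack[-1]
            if node in self._ancestor_cache:
                stack.pop()
                continue
            parents = [self.resolve(p) for p in self.terms[node].parents]
            pending = [p for p in parents if p not in self._ancestor_cache]
            if pending:
                stack.extend(pending)
                continue
            acc: set[str] = set()
            for p in parents:
                acc.add(p)
                acc |= self._ancestor_cache[p]
            self._ancestor_cache[node] = frozenset(acc)
            stack.pop()
        return self._ancestor_cache[primary]

    def namespace_of(self, go_id: str) -> str:
        """Namespace label of a term (alt ids resolve to the primary term)."""
        return self.terms[self.resolve(go_id)].namespace

    def name_of(self, go_id: str) -> str:
        return self.terms[self.resolve(go_id)].name

    def roots(self) -> set[str]:
        return {t.id for t in self.terms.values() if not t.parents}

    def add_term(self, term: GoTerm, alt_ids: Iterable[str] = ()) -> None:
        if term.obsolete:
            term.parents = set()
            term.edge_types = {}
            self.obsolete_terms[term.id] = term
        else:
            self.terms[term.id] = term
        for alt in alt_ids:
            self.alt_id_map[alt] = term.id

    def validate(self) -> None:
        """Check parent references resolve and the non-obsolete DAG is acyclic."""
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for term in self.terms.values():
            for parent in term.parents:
                target = self.alt_id_map.get(parent, parent)
                if target not in self.terms:
                    raise ValidationError(
                        f"term {term.id} references unknown parent {parent}"
                    )
                g.add_edge(term.id, target)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            path = " -> ".join(edge[0] for edge in cycle) + f" -> {cycle[-1][1]}"
            raise ValidationError(f"cycle among non-obsolete terms: {path}")


def parse_obo(stream: Union[str, IO[str]]) -> OntologyGraph:
    """Parse OBO text into an :class:`OntologyGraph`.

    ``is_a:`` and ``relationship: part_of`` lines become parent edges; all
    other relationship types are ignored. ``alt_id:`` lines populate the
    alt-id map. A ``[Term]`` stanza without an ``id:`` raises
    :class:`OboParseError` naming the stanza ordinal; a cycle among
    non-obsolete terms raises :class:`ValidationError` listing one cycle.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    graph = OntologyGraph()

    current: dict | None = None
    in_term = False
    ordinal = 0

    def flush() -> None:
        if not in_term or current is None:
            return
        if current.get("id") is None:
            raise OboParseError("[Term] stanza missing an id", ordinal)
        term = GoTerm(
            id=current["id"],
            name=current.get("name", ""),
            namespace=current.get("namespace", ""),
            parents=set(current["parents"]),
            obsolete=current["obsolete"],
            edge_types=dict(current["edge_types"]),
        )
        graph.add_term(term, alt_ids=current["alt_ids"])

    for raw in stream:
        line = raw.split("!", 1)[0].strip() if raw.lstrip().startswith(("is_a", "relationship")) else raw.strip()
        if line.startswith("["):
            flush()
            ordinal += 1
            in_term = line == "[Term]"
            current = {"id": None, "parents": set(), "alt_ids": [],
                       "obsolete": False, "edge_types": {}} if in_term else None
            continue
        if not in_term or current is None or not line:
            continue
        key, _, value = line.partition(":")
        value = value.strip()
        key = key.strip()
        if key == "id":
            current["id"] = value
        elif key == "name":
            current["name"] = value
        elif key == "namespace":
            current["namespace"] = value
        elif key == "is_a":
            parent = value.split()[0]
            current["parents"].add(parent)
            current["edge_types"][parent] = "is_a"
        elif key == "relationship":
            parts = value.split()
            if len(parts) >= 2 and parts[0] == "part_of":
                current["parents"].add(parts[1])
                current["edge_types"][parts[1]] = "part_of"
        elif key == "alt_id":
            current["alt_ids"].append(value)
        elif key == "is_obsolete":
            current["obsolete"] = value.lower().startswith("true")
    flush()

    graph.validate()
    return graph


def serialize_obo(graph: OntologyGraph, header: str = "format-version: 1.2") -> str:
    """Serialize a graph back to OBO text (inverse of :func:`parse_obo`)."""
    out = [header, ""]
    alt_by_primary: dict[str, list[str]] = {}
    for alt, primary in graph.alt_id_map.items():
        alt_by_primary.setdefault(primary, []).append(alt)
    all_terms = list(graph.terms.values()) + list(graph.obsolete_terms.values())
    for term in sorted(all_terms, key=lambda t: t.id):
        out.append("[Term]")
        out.append(f"id: {term.id}")
        if term.name:
            out.append(f"name: {term.name}")
        if term.namespace:
            out.append(f"namespace: {term.namespace}")
        for alt in sorted(alt_by_primary.get(term.id, [])):
            out.append(f"alt_id: {alt}")
        for parent in sorted(term.parents):
            if term.edge_types.get(parent, "is_a") == "part_of":
                out.append(f"relationship: part_of {parent}")
            else:
                out.append(f"is_a: {parent}")
        if term.obsolete:
            out.append("is_obsolete: true")
        out.append("")
    return "\n".join(out) + "\n"


def load_obo(path) -> OntologyGraph:
    """Parse an OBO file from disk (plain or gzip, detected by magic bytes)."""
    from ._io import open_text

    with open_text(path) as handle:
        return parse_obo(handle)
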