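"""The Gene Ontology DAG with typed hierarchical edges and their reversals.

Terms are vertices; the two hierarchical relations ``is_a`` and ``part_of``
are kept as directed child→parent edges, and every such edge is mirrored by
an automatically generated reversal (``parent_is_a`` / ``parent_part_of``)
so that information can flow in both directions during representation
learning.  All other relation types (``regulates``, ``occurs_in``, ...) are
dropped on load with a logged count.  The subgraph over ``is_a``/``part_of``
must be acyclic.
"""

from __future__ import annotations

import io
import json
import logging
import re
from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import obonet

from .errors import IntegrityError, OboParseError, TermNotFoundError

logger = logging.getLogger(__name__)

HIERARCHY_TYPES = ("is_a", "part_of")
REVERSAL = {"is_a": "parent_is_a", "part_of": "parent_part_of"}
EDGE_TYPES = ("is_a", "part_of", "parent_is_a", "parent_part_of")

_SYNONYM_RE = re.compile(r'"((?:[^"\\]|\\.)*)"')


@dataclass(frozen=True)
class GOTerm:
    """A single ontology term (vertex)."""

    term_id: str
    name: str
    synonyms: tuple[str, ...] = ()
    namespace: str = "synthetic"
    obsolete: bool = False


@dataclass(frozen=True)
class TypedEdge:
    """A directed typed edge; reversals are generated, never supplied."""

    child_id: str
    parent_id: str
    edge_type: str


class GODag:
    """The ontology graph with typed hierarchical edges and reversals.

    Parameters
    ----------
    terms:
        The vertices.  Term ids must be unique and names non-empty.
    edges:
        Forward (child, parent, type) triples with type in ``is_a``/``part_of``.
        Reversal edges are generated automatically; supplying one is an error.
    """

    def __init__(self, terms: Iterable[GOTerm], edges: Iterable[tuple[str, str, str]]):
        self._terms: dict[str, GOTerm] = {}
        for t in terms:
            if not t.name:
                raise IntegrityError(f"term {t.term_id!r} has an empty name")
            if t.term_id in self._terms:
                raise IntegrityError(f"duplicate term id {t.term_id!r}")
            self._terms[t.term_id] = t

        self._parents: dict[str, set[str]] = {tid: set() for tid in self._terms}
        self._children: dict[str, set[str]] = {tid: set() for tid in self._terms}
        forward: list[TypedEdge] = []
        seen: set[tuple[str, str, str]] = set()
        n_obsolete_dropped = 0
        for child, parent, etype in edges:
            if etype not in HIERARCHY_TYPES:
                raise IntegrityError(
                    f"edge ({child}, {parent}) has type {etype!r}; only "
                    f"{HIERARCHY_TYPES} may be supplied (reversals are generated)"
                )
            for endpoint in (child, parent):
                if endpoint not in self._terms:
                    raise IntegrityError(f"edge endpoint {endpoint!r} is not a term")
            if (child, parent, etype) in seen:
                continue
            seen.add((child, parent, etype))
            # Obsolete terms stay as vertices but take no part in the hierarchy.
            if self._terms[child].obsolete or self._terms[parent].obsolete:
                n_obsolete_dropped += 1
                continue
            forward.append(TypedEdge(child, parent, etype))
            self._parents[child].add(parent)
            self._children[parent].add(child)
        if n_obsolete_dropped:
            logger.info("dropped %d hierarchical edges touching obsolete terms", n_obsolete_dropped)

        g = nx.DiGraph()
        g.add_nodes_from(self._terms)
        g.add_edges_from((e.child_id, e.parent_id) for e in forward)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise IntegrityError(f"is_a/part_of subgraph contains a cycle: {cycle}")
        self._nx = g

        self.forward_edges: tuple[TypedEdge, ...] = tuple(forward)
        self.edges: tuple[TypedEdge, ...] = tuple(forward) + tuple(
            TypedEdge(e.parent_id, e.child_id, REVERSAL[e.edge_type]) for e in forward
        )
        self._ancestor_cache: dict[str, frozenset[str]] = {}

        namespaces = {t.namespace for t in self._terms.values() if not t.obsolete}
        if len(namespaces) > 1:
            logger.info("ontology mixes namespaces: %s", sorted(namespaces))

    # -- basic accessors ---------------------------------------------------
    def __contains__(self, term_id: str) -> bool:
        return term_id in self._terms

    def __len__(self) -> int:
        return len(self._terms)

    def __getitem__(self, term_id: str) -> GOTerm:
        try:
            return self._terms[term_id]
        except KeyError:
            raise TermNotFoundError(term_id) from None

    @property
    def terms(self) -> dict[str, GOTerm]:
        return dict(self._terms)

    def term_ids(self) -> list[str]:
        return sorted(self._terms)

    @property
    def roots(self) -> set[str]:
        """Non-obsolete terms with no outgoing is_a/part_of edge."""
        return {
            tid
            for tid, t in self._terms.items()
            if not t.obsolete and not self._parents[tid]
        }

    # -- traversal ---------------------------------------------------------
    def _check(self, term_id: str) -> None:
        if term_id not in self._terms:
            raise TermNotFoundError(term_id)

    def direct_parents(self, term_id: str) -> set[str]:
        self._check(term_id)
        return set(self._parents[term_id])

    def direct_children(self, term_id: str) -> set[str]:
        """Children connected by an is_a or part_of edge; empty for leaves."""
        self._check(term_id)
        return set(self._children[term_id])

    def ancestors(self, term_id: str) -> set[str]:
        """Transitive closure over is_a/part_of, excluding the term itself."""
        self._check(term_id)
        cached = self._ancestor_cache.get(term_id)
        if cached is None:
            # iterative DFS; reuses cached results of parents where available
            out: set[str] = set()
            stack = list(self._parents[term_id])
            while stack:
                p = stack.pop()
                if p in out:
                    continue
                out.add(p)
                hit = self._ancestor_cache.get(p)
                if hit is not None:
                    out |= hit
                else:
                    stack.extend(self._parents[p])
            cached = frozenset(out)
            self._ancestor_cache[term_id] = cached
        return set(cached)

    def descendants(self, term_id: str) -> set[str]:
        self._check(term_id)
        out: set[str] = set()
        stack = list(self._children[term_id])
        while stack:
            c = stack.pop()
            if c not in out:
                out.add(c)
                stack.extend(self._children[c])
        return out

    def is_descendant(self, a: str, b: str) -> bool:
        """True iff ``b`` is a strict ancestor of ``a`` (irreflexive)."""
        self._check(a)
        self._check(b)
        return b in self.ancestors(a)

    def depths(self) -> dict[str, int]:
        """Shortest hierarchical distance from any root, per non-obsolete term."""
        depth: dict[str, int] = {r: 0 for r in self.roots}
        frontier = list(self.roots)
        while frontier:
            nxt = []
            for p in frontier:
                for c in self._children[p]:
                    if c not in depth:
                        depth[c] = depth[p] + 1
                        nxt.append(c)
            frontier = nxt
        return depth

    # -- construction ------------------------------------------------------
    @classmethod
    def from_obo(cls, obo_text: str | io.TextIOBase) -> "GODag":
        """Parse an OBO 1.2/1.4 flat file, keeping only is_a/part_of edges."""
        handle = io.StringIO(obo_text) if isinstance(obo_text, str) else obo_text
        try:
            graph = obonet.read_obo(handle, ignore_obsolete=False)
        except Exception as exc:  # obonet raises bare ValueError on bad stanzas
            raise OboParseError(f"malformed OBO document: {exc}") from exc

        terms: list[GOTerm] = []
        for tid, data in graph.nodes(data=True):
            synonyms = tuple(
                m.group(1) for s in data.get("synonym", ()) if (m := _SYNONYM_RE.search(s))
            )
            terms.append(
                GOTerm(
                    term_id=tid,
                    name=data.get("name") or tid,
                    synonyms=synonyms,
                    namespace=data.get("namespace", "synthetic"),
                    obsolete=str(data.get("is_obsolete", "")).lower() == "true",
                )
            )

        edges: list[tuple[str, str, str]] = []
        dropped = 0
        for child, parent, etype in graph.edges(keys=True):
            if etype in HIERARCHY_TYPES:
                edges.append((child, parent, etype))
            else:
                dropped += 1
        if dropped:
            logger.info("dropped %d non-hierarchical OBO relationships", dropped)
        return cls(terms, edges)

    @classmethod
    def from_json(cls, text: str | dict) -> "GODag":
        """Read the synthetic-DAG JSON dialect.

        ``{"terms": [{"id", "name", "synonyms"?}], "edges": [{"child", "parent", "type"}]}``
        """
        data = json.loads(text) if isinstance(text, str) else text
        terms = [
            GOTerm(
                term_id=t["id"],
                name=t["name"],
                synonyms=tuple(t.get("synonyms", ())),
                namespace=t.get("namespace", "synthetic"),
                obsolete=bool(t.get("obsolete", False)),
            )
            for t in data["terms"]
        ]
        edges = [(e["child"], e["parent"], e["type"]) for e in data["edges"]]
        return cls(terms, edges)

    def to_json(self) -> str:
        return json.dumps(
            {
                "terms": [
                    {
                        "id": t.term_id,
                        "name": t.name,
                        "synonyms": list(t.synonyms),
                        "namespace": t.namespace,
                        "obsolete": t.obsolete,
                    }
                    for t in self._terms.values()
                ],
                "edges": [
                    {"child": e.child_id, "parent": e.parent_id, "type": e.edge_type}
                    for e in self.forward_edges
                ],
            },
            indent=0,
        )
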