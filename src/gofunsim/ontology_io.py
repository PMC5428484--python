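"""OBO ontology parsing and per-namespace DAG queries.

Each Gene Ontology namespace (biological_process, molecular_function,
cellular_component) is represented as a self-contained directed acyclic
graph with a single root — the unique term without any ancestors.
Ancestor sets are *reflexive*: a term is an ancestor of itself. This
convention makes every self-comparison well behaved downstream
(the most informative common ancestor of (t, t) is t itself, and the
common/union ancestor sets of identical terms coincide).

Which edge types define ancestry is configurable; the default
``{is_a, part_of}`` follows GO Consortium practice for annotation
propagation. Cross-namespace edges are dropped so that each namespace
is scored independently.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

#: OBO namespace tags mapped to the short labels used throughout.
NAMESPACE_LABELS = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
}

DEFAULT_RELATIONS = frozenset({"is_a", "part_of"})

GO_ID_RE = re.compile(r"^GO:\d{7}$")


class OntologyError(ValueError):
    """Malformed or internally inconsistent ontology input."""


class UnknownTermError(KeyError):
    """A term identifier that is not (and has no alias) in the DAG."""


@dataclass(frozen=True)
class Term:
    """A single ontology term.

    Parameters
    ----------
    id : str
        Primary accession, ``GO:`` followed by seven digits.
    name : str
        Human-readable label.
    namespace : str
        One of ``BP``, ``MF``, ``CC``.
    parents : frozenset of (str, str)
        ``(parent_id, relation)`` pairs over the retained relations.
    obsolete : bool
        Obsolete terms carry no parents and never enter a DAG.
    """

    id: str
    name: str
    namespace: str
    parents: frozenset = frozenset()
    obsolete: bool = False


@dataclass
class OntologyDAG:
    """One namespace of the ontology as a child-to-parent DAG."""

    namespace: str
    graph: nx.DiGraph
    root: str
    terms: dict
    alt_ids: dict = field(default_factory=dict)
    _ancestor_cache: dict = field(default_factory=dict, repr=False)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms or term_id in self.alt_ids

    def __len__(self) -> int:
        return len(self.terms)

    def resolve(self, term_id: str) -> str:
        """Map an accession (possibly an alt_id alias) to its primary id."""
        if term_id in self.terms:
            return term_id
        if term_id in self.alt_ids:
            return self.alt_ids[term_id]
        raise UnknownTermError(f"term {term_id!r} not in {self.namespace} ontology")

    def ancestors(self, term_id: str) -> frozenset:
        """Reflexive-transitive ancestor closure of a term.

        ``t in ancestors(t)`` and ``root in ancestors(t)`` always hold.
        """
        tid = self.resolve(term_id)
        cached = self._ancestor_cache.get(tid)
        if cached is None:
            # graph edges run child -> parent, so graph-descendants are ancestors
            cached = frozenset(nx.descendants(self.graph, tid)) | {tid}
            self._ancestor_cache[tid] = cached
        return cached

    def descendants(self, term_id: str) -> frozenset:
        """Reflexive-transitive descendant closure (used for IC counting)."""
        tid = self.resolve(term_id)
        return frozenset(nx.ancestors(self.graph, tid)) | {tid}


def _node_namespace(data: dict) -> str | None:
    ns = data.get("namespace")
    return NAMESPACE_LABELS.get(ns)


def parse_obo(path, relations=DEFAULT_RELATIONS) -> dict:
    """Parse an OBO 1.2/1.4 file into per-namespace :class:`OntologyDAG` s.

    Parameters
    ----------
    path : path-like or file-like
        OBO flat file.
    relations : set of str
        Edge types that define ancestry (default ``{is_a, part_of}``).

    Returns
    -------
    dict
        Namespace label (``BP``/``MF``/``CC``) to :class:`OntologyDAG`,
        only for namespaces actually present. Obsolete terms are dropped
        and ``alt_id`` aliases resolved to their primary accession.

    Raises
    ------
    OntologyError
        On malformed stanzas or a cyclic graph.
    """
    relations = frozenset(relations)
    try:
        multigraph = obonet.read_obo(path, ignore_obsolete=True)
    except ValueError as exc:  # obonet names the offending stanza/line
        raise OntologyError(f"malformed OBO input: {exc}") from exc

    dags = {}
    for ns_label in sorted(set(NAMESPACE_LABELS.values())):
        node_ids = [
            n for n, d in multigraph.nodes(data=True) if _node_namespace(d) == ns_label
        ]
        if not node_ids:
            continue
        graph = nx.DiGraph()
        terms = {}
        alt_ids = {}
        node_set = set(node_ids)
        for nid in node_ids:
            data = multigraph.nodes[nid]
            graph.add_node(nid)
            for alias in data.get("alt_id", []):
                alt_ids[alias] = nid
        for child, parent, rel in multigraph.edges(keys=True):
            if rel not in relations:
                continue
            if child in node_set and parent in node_set:  # same namespace only
                graph.add_edge(child, parent, relation=rel)
        for nid in node_ids:
            data = multigraph.nodes[nid]
            parents = frozenset(
                (p, graph.edges[nid, p]["relation"]) for p in graph.successors(nid)
            )
            terms[nid] = Term(
                id=nid,
                name=data.get("name", ""),
                namespace=ns_label,
                parents=parents,
            )
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise OntologyError(
                f"{ns_label} ontology contains a cycle: {cycle}"
            )
        roots = [n for n in graph.nodes if graph.out_degree(n) == 0]
        if len(roots) != 1:
            raise OntologyError(
                f"{ns_label} ontology must have exactly one root "
                f"(term without ancestors); found {sorted(roots)}"
            )
        dags[ns_label] = OntologyDAG(
            namespace=ns_label,
            graph=graph,
            root=roots[0],
            terms=terms,
            alt_ids=alt_ids,
        )
        logger.info(
            "parsed %s: %d terms, root %s", ns_label, len(terms), roots[0]
        )
    if not dags:
        raise OntologyError("no non-obsolete terms with a recognized namespace")
    return dags


_LABEL_TO_OBO_NS = {v: k for k, v in NAMESPACE_LABELS.items()}


def write_obo(dags: dict, path) -> None:
    """Serialize DAGs back to a minimal OBO 1.2 flat file.

    Round-trips everything :func:`parse_obo` retains: term ids, names,
    namespaces, alt_ids, and typed parent edges.
    """
    lines = ["format-version: 1.2", "ontology: go", ""]
    alias_of = {}
    for dag in dags.values():
        for alias, primary in dag.alt_ids.items():
            alias_of.setdefault(primary, []).append(alias)
    for ns_label in sorted(dags):
        dag = dags[ns_label]
        for tid in sorted(dag.terms):
            term = dag.terms[tid]
            lines.append("[Term]")
            lines.append(f"id: {tid}")
            lines.append(f"name: {term.name}")
            lines.append(f"namespace: {_LABEL_TO_OBO_NS[ns_label]}")
            for alias in sorted(alias_of.get(tid, [])):
                lines.append(f"alt_id: {alias}")
            for parent, rel in sorted(term.parents):
                if rel == "is_a":
                    lines.append(f"is_a: {parent}")
                else:
                    lines.append(f"relationship: {rel} {parent}")
            lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))
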