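"""Gene Ontology DAG handling.

Parses OBO flat files into an in-memory DAG restricted to ``is_a`` and
``part_of`` edges, and provides the graph primitives the scoring cascade
needs: ancestor closure, corpus-based information content (IC), Lin
semantic similarity, and most-informative-common-ancestor lookup.

The three GO namespaces (biological_process, molecular_function,
cellular_component) are treated as fully independent sub-ontologies:
each has its own root, its own IC normalisation and its own similarity
space.  Obsolete terms are dropped from the graph but their ids are kept
so that stale references in annotation files can be remapped (via
``replaced_by``) or reported.
"""

from __future__ import annotations

import io
import logging
import math
import os
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Union

import networkx as nx
import obonet

logger = logging.getLogger(__name__)

#: Parent relations retained from the OBO file; everything else is ignored.
RELATIONS = ("is_a", "part_of")

NAMESPACES = ("biological_process", "molecular_function", "cellular_component")


class UnknownTermError(KeyError):
    """Raised when a GO id is not present in the DAG at all."""


class ObsoleteTermError(KeyError):
    """Raised when a GO id refers to an obsolete term."""


@dataclass(frozen=True)
class GoTerm:
    """One non-obsolete ontology term.

    ``parents`` holds ``(parent_id, relation)`` pairs with relation in
    :data:`RELATIONS`; every parent id resolves in the owning DAG.
    """

    id: str
    name: str
    namespace: str
    parents: frozenset[tuple[str, str]]
    alt_ids: frozenset[str] = frozenset()


class GoDag:
    """Directed acyclic graph of GO terms with per-namespace roots.

    Edges point child -> parent.  ``roots`` maps each namespace present
    in the file to its single parentless term.
    """

    def __init__(
        self,
        terms: Mapping[str, GoTerm],
        roots: Mapping[str, str],
        alt_map: Mapping[str, str] | None = None,
        obsolete_ids: Iterable[str] = (),
    ) -> None:
        self.terms: dict[str, GoTerm] = dict(terms)
        self.roots: dict[str, str] = dict(roots)
        self.obsolete_ids: frozenset[str] = frozenset(obsolete_ids)
        # alt or obsolete id -> primary id
        self._alt: dict[str, str] = dict(alt_map or {})
        self._ancestor_cache: dict[str, frozenset[str]] = {}

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def namespace_of(self, term_id: str) -> str:
        return self._get(term_id).namespace

    def root_of(self, term_id: str) -> str:
        return self.roots[self._get(term_id).namespace]

    def is_root(self, term_id: str) -> bool:
        return self.roots.get(self.terms[term_id].namespace) == term_id

    def _get(self, term_id: str) -> GoTerm:
        try:
            return self.terms[term_id]
        except KeyError:
            if term_id in self.obsolete_ids:
                raise ObsoleteTermError(f"GO term {term_id} is obsolete")
            raise UnknownTermError(f"GO term {term_id} is not in the ontology")

    def resolve(self, term_id: str) -> str | None:
        """Map any id (primary, alt_id, or replaced obsolete id) to its
        primary id, or ``None`` when no current term corresponds to it."""
        if term_id in self.terms:
            return term_id
        return self._alt.get(term_id)

    def ancestors(self, term_id: str) -> frozenset[str]:
        """All terms reachable from ``term_id`` via is_a/part_of edges,
        excluding the term itself, restricted to its namespace."""
        cached = self._ancestor_cache.get(term_id)
        if cached is not None:
            return cached
        term = self._get(term_id)
        out: set[str] = set()
        for parent_id, _rel in term.parents:
            if self.terms[parent_id].namespace != term.namespace:
                continue
            out.add(parent_id)
            out |= self.ancestors(parent_id)
        result = frozenset(out)
        self._ancestor_cache[term_id] = result
        return result

    def ancestors_and_self(self, term_id: str) -> frozenset[str]:
        return self.ancestors(term_id) | {term_id}

    def terms_in_namespace(self, namespace: str) -> list[str]:
        return [t for t, term in self.terms.items() if term.namespace == namespace]


def parse_obo(source: Union[str, os.PathLike, IO[str]]) -> GoDag:
    """Parse an OBO 1.2/1.4 file into a :class:`GoDag`.

    ``source`` may be a path or an open text stream.  Only ``is_a`` and
    ``relationship: part_of`` lines become edges; obsolete terms are
    excluded from the graph (their ids are retained for remapping via
    ``replaced_by``); ``alt_id`` lines populate the resolution map.

    Raises ``ValueError`` on a cyclic parent structure (naming one cycle
    member) or on a parent reference to an id not defined in the file.
    """
    if isinstance(source, (str, os.PathLike)) and "\n" in str(source):
        source = io.StringIO(str(source))
    graph = obonet.read_obo(source, ignore_obsolete=False)

    obsolete: set[str] = set()
    alt_map: dict[str, str] = {}
    node_attrs: dict[str, dict] = {}
    for node, data in graph.nodes(data=True):
        if "namespace" not in data and "name" not in data:
            raise ValueError(f"dangling parent reference: {node} is never defined")
        if str(data.get("is_obsolete", "")).lower() == "true":
            obsolete.add(node)
            replaced = data.get("replaced_by") or []
            if replaced:
                alt_map[node] = replaced[0]
        else:
            node_attrs[node] = data

    parents: dict[str, set[tuple[str, str]]] = {t: set() for t in node_attrs}
    for child, parent, relation in graph.edges(keys=True):
        if child in obsolete or relation not in RELATIONS:
            continue
        if parent not in node_attrs:
            if parent in obsolete:
                raise ValueError(f"term {child} has obsolete parent {parent}")
            raise ValueError(f"dangling parent reference: {parent} (from {child})")
        parents[child].add((parent, relation))

    restricted = nx.DiGraph((c, p) for c, ps in parents.items() for p, _ in ps)
    if not nx.is_directed_acyclic_graph(restricted):
        cycle = nx.find_cycle(restricted)
        raise ValueError(f"cyclic parent structure involving {cycle[0][0]}")

    terms: dict[str, GoTerm] = {}
    for node, data in node_attrs.items():
        alt_ids = frozenset(data.get("alt_id", []))
        for alt in alt_ids:
            alt_map[alt] = node
        terms[node] = GoTerm(
            id=node,
            name=data.get("name", node),
            namespace=data["namespace"],
            parents=frozenset(parents[node]),
            alt_ids=alt_ids,
        )

    roots: dict[str, str] = {}
    for term in terms.values():
        in_ns = [p for p, _ in term.parents if terms[p].namespace == term.namespace]
        if in_ns:
            continue
        if term.namespace in roots:
            raise ValueError(
                f"namespace {term.namespace} has multiple roots: "
                f"{roots[term.namespace]}, {term.id}"
            )
        roots[term.namespace] = term.id

    dag = GoDag(terms, roots, alt_map, obsolete)
    for term_id, term in terms.items():
        root = roots[term.namespace]
        if term_id != root and root not in dag.ancestors(term_id):
            raise ValueError(f"term {term_id} does not reach its namespace root {root}")
    return dag


@dataclass
class IcTable:
    """Per-term information content on a log10 scale.

    ``annotated_fraction`` is P(i): the fraction of reference proteins
    annotated (after ancestor closure) with term i, within i's
    namespace; ``ic`` is -log10(P).  Terms never seen in the corpus
    carry the maximum IC observed in their namespace, which keeps every
    downstream score finite.
    """

    ic: dict[str, float]
    annotated_fraction: dict[str, float]
    max_ic: dict[str, float] = field(default_factory=dict)
    _namespace: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, term_id: str) -> float:
        return self.ic[term_id]

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.ic

    def get(self, term_id: str, namespace: str | None = None) -> float:
        """IC of ``term_id``; unknown terms fall back to the namespace
        maximum (logged), matching the treatment of unannotated terms."""
        if term_id in self.ic:
            return self.ic[term_id]
        ns = namespace or self._namespace.get(term_id)
        fallback = self.max_ic.get(ns, max(self.max_ic.values(), default=0.0))
        logger.warning("term %s missing from IC table; using max IC %.4f", term_id, fallback)
        return fallback


def compute_ic(dag: GoDag, annotations) -> IcTable:
    """Information content of every DAG term from a reference corpus.

    For each namespace, P(i) = (#distinct proteins whose ancestor-closed
    annotation set contains i) / (#distinct proteins with at least one
    annotation in that namespace), and IC(i) = -log10 P(i).  Roots get
    IC 0 by construction; terms with no annotated protein get the
    maximum IC observed in their namespace.

    ``annotations`` is a :class:`~gotransfer.reference_data.ReferenceAnnotations`
    (anything with a ``by_protein`` mapping accession -> {(term, evidence)}).
    Raises ``ValueError`` for a DAG namespace with zero annotated proteins.
    """
    term_counts: dict[str, int] = {}
    ns_protein_counts: dict[str, int] = {ns: 0 for ns in dag.roots}
    for protein, pairs in annotations.by_protein.items():
        closed_per_ns: dict[str, set[str]] = {}
        for term_id, _evidence in pairs:
            primary = dag.resolve(term_id)
            if primary is None:
                logger.warning(
                    "annotation %s -> %s does not resolve in the ontology; dropped",
                    protein, term_id,
                )
                continue
            ns = dag.terms[primary].namespace
            closed_per_ns.setdefault(ns, set()).update(dag.ancestors_and_self(primary))
        for ns, closed in closed_per_ns.items():
            ns_protein_counts[ns] += 1
            for t in closed:
                term_counts[t] = term_counts.get(t, 0) + 1

    for ns in dag.roots:
        if ns_protein_counts.get(ns, 0) == 0:
            raise ValueError(f"no annotated proteins in namespace {ns}; cannot compute IC")

    ic: dict[str, float] = {}
    fraction: dict[str, float] = {}
    max_ic: dict[str, float] = {ns: 0.0 for ns in dag.roots}
    namespace_of: dict[str, str] = {}
    unseen: list[str] = []
    for term_id, term in dag.terms.items():
        namespace_of[term_id] = term.namespace
        n = term_counts.get(term_id, 0)
        if n == 0:
            unseen.append(term_id)
            fraction[term_id] = 0.0
            continue
        p = n / ns_protein_counts[term.namespace]
        fraction[term_id] = p
        value = abs(-math.log10(p))  # abs() normalises -0.0 at roots
        ic[term_id] = value
        if value > max_ic[term.namespace]:
            max_ic[term.namespace] = value
    for term_id in unseen:
        ic[term_id] = max_ic[namespace_of[term_id]]

    return IcTable(ic=ic, annotated_fraction=fraction, max_ic=max_ic, _namespace=namespace_of)


def joint_parent(ic: IcTable, dag: GoDag, i: str, j: str) -> str:
    """Most informative common ancestor of ``i`` and ``j``.

    Ancestor sets include the terms themselves, so an ancestor/descendant
    pair returns the ancestor and identical terms return themselves.
    Ties on IC break to the lexicographically smallest GO id.  The
    namespace root is always a common ancestor, so a result exists for
    any same-namespace pair.
    """
    if dag.namespace_of(i) != dag.namespace_of(j):
        raise ValueError(f"{i} and {j} are in different namespaces")
    common = dag.ancestors_and_self(i) & dag.ancestors_and_self(j)
    return max(common, key=lambda t: (ic.get(t), [-ord(c) for c in t]))


def lin_similarity(ic: IcTable, dag: GoDag, i: str, j: str) -> float:
    """Lin semantic similarity Sim(i,j) = 2*IC(k) / (IC(i)+IC(j)),
    where k is the most informative common ancestor.

    Sim(i,i) = 1 by definition; a zero denominator (both terms carry no
    information) yields 0 for distinct terms.
    """
    if dag.namespace_of(i) != dag.namespace_of(j):
        raise ValueError(f"{i} and {j} are in different namespaces")
    if i == j:
        return 1.0
    denom = ic.get(i) + ic.get(j)
    if denom == 0.0:
        return 0.0
    k = joint_parent(ic, dag, i, j)
    return 2.0 * ic.get(k) / denom
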