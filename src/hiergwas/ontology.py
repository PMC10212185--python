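"""Build the unified, filtered hierarchy of biological systems.

A *system* is an ontology term together with the set of genes annotated to it
after propagation (each term inherits all annotations of its descendants).
The hierarchy is built from an OBO file ("is a" and "part of" edges, child ->
parent) and a gene-annotation table (GAF 2.x or a minimal 3-column TSV of
gene / term / evidence code).  Electronic annotations (IEA) are excluded by
default.  The three ontology aspects are joined under a single synthetic
root; systems with fewer than 3 or more than 75 genes are removed, as are
parents whose gene set is nearly identical (>= 90% contained) to a child's.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, TextIO

import networkx as nx
import numpy as np
import obonet

from ._util import DataError

__all__ = [
    "SystemNode",
    "OntologyGraph",
    "OntologyStructureError",
    "ROOT_ID",
    "parse_ontology",
    "unify_roots",
    "propagate_annotations",
    "filter_by_size",
    "collapse_similar",
    "permute_gene_labels",
    "build_hierarchy",
    "write_systems_tsv",
]

#: identifier of the synthetic root joining the ontology aspects
ROOT_ID = "SYS:ROOT"

#: parent-link relationship types kept from the OBO file
_KEPT_RELATIONS = ("is_a", "part_of")


class OntologyStructureError(DataError):
    """Raised when the term graph is not a DAG or otherwise malformed."""


@dataclass
class SystemNode:
    id: str
    name: str = ""
    namespace: str = ""
    parents: set[str] = field(default_factory=set)
    children: set[str] = field(default_factory=set)
    direct_genes: set[str] = field(default_factory=set)
    genes: set[str] = field(default_factory=set)

    def copy(self) -> "SystemNode":
        return SystemNode(
            id=self.id,
            name=self.name,
            namespace=self.namespace,
            parents=set(self.parents),
            children=set(self.children),
            direct_genes=set(self.direct_genes),
            genes=set(self.genes),
        )


@dataclass
class OntologyGraph:
    """DAG of systems keyed by term id; edges run child -> parent."""

    nodes: dict[str, SystemNode] = field(default_factory=dict)
    root: str | None = None

    @property
    def gene_universe(self) -> set[str]:
        out: set[str] = set()
        for node in self.nodes.values():
            out |= node.genes if node.genes else node.direct_genes
        return out

    def copy(self) -> "OntologyGraph":
        return OntologyGraph(
            nodes={nid: n.copy() for nid, n in self.nodes.items()}, root=self.root
        )

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for node in self.nodes.values():
            for p in node.parents:
                g.add_edge(node.id, p)
        return g

    def namespace_roots(self) -> list[str]:
        return sorted(nid for nid, n in self.nodes.items() if not n.parents)

    def check_acyclic(self) -> None:
        if not nx.is_directed_acyclic_graph(self.to_networkx()):
            raise OntologyStructureError("ontology term graph contains a cycle")

    def systems(self) -> list[str]:
        """Testable systems: every node except the synthetic root."""
        return sorted(nid for nid in self.nodes if nid != self.root)


def _as_stream(obj) -> TextIO:
    if isinstance(obj, str):
        return io.StringIO(obj)
    return obj


def parse_ontology(
    obo_stream,
    annotation_stream,
    excluded_evidence: Iterable[str] = ("IEA",),
) -> OntologyGraph:
    """Parse OBO terms plus annotations into an unfiltered, unpropagated graph.

    ``obo_stream``/``annotation_stream`` may be open text streams or strings
    holding the file content.  Annotations with an evidence code in
    ``excluded_evidence`` are dropped; annotations naming unknown terms are
    skipped with a warning.  Obsolete terms are ignored.
    """
    excluded = set(excluded_evidence or ())
    graph = OntologyGraph()

    obo_stream = _as_stream(obo_stream)
    # obonet tolerates empty streams poorly; guard explicitly
    text = obo_stream.read()
    if text.strip():
        multigraph = obonet.read_obo(io.StringIO(text), ignore_obsolete=True)
        for term_id, data in multigraph.nodes(data=True):
            graph.nodes[term_id] = SystemNode(
                id=term_id,
                name=data.get("name", ""),
                namespace=_short_namespace(data.get("namespace", "")),
            )
        for child, parent, rel in multigraph.edges(keys=True):
            if rel not in _KEPT_RELATIONS:
                continue
            if parent not in graph.nodes or child not in graph.nodes:
                continue
            graph.nodes[child].parents.add(parent)
            graph.nodes[parent].children.add(child)
        graph.check_acyclic()

    for gene, term, evidence in _iter_annotations(_as_stream(annotation_stream)):
        if evidence in excluded:
            continue
        node = graph.nodes.get(term)
        if node is None:
            warnings.warn(f"annotation references unknown term {term!r}; skipped")
            continue
        node.direct_genes.add(gene)
    return graph


def _short_namespace(ns: str) -> str:
    return {
        "biological_process": "BP",
        "cellular_component": "CC",
        "molecular_function": "MF",
    }.get(ns, ns)


def _iter_annotations(stream: TextIO):
    """Yield (gene, term, evidence) from GAF 2.x or 3-column TSV rows."""
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("!") or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) >= 7:  # GAF: DB, object id, symbol, qualifier, GO id, ref, evidence
            gene = cols[2] or cols[1]
            term = cols[4]
            evidence = cols[6]
        elif len(cols) == 3:
            gene, term, evidence = cols
        else:
            raise DataError(
                f"annotation line {lineno}: expected GAF (>=7 columns) or "
                f"3-column TSV, got {len(cols)} columns"
            )
        if gene and term:
            yield gene, term, evidence


def unify_roots(graph: OntologyGraph) -> OntologyGraph:
    """Attach all namespace roots to one synthetic root; idempotent."""
    out = graph.copy()
    roots = out.namespace_roots()
    if roots == [ROOT_ID]:
        out.root = ROOT_ID
        return out
    root = SystemNode(id=ROOT_ID, name="root", namespace="root")
    out.nodes[ROOT_ID] = root
    for rid in roots:
        out.nodes[rid].parents.add(ROOT_ID)
        root.children.add(rid)
    out.root = ROOT_ID
    return out


def propagate_annotations(graph: OntologyGraph) -> OntologyGraph:
    """Set each node's gene set to its direct genes plus all descendants'."""
    out = graph.copy()
    out.check_acyclic()
    memo: dict[str, set[str]] = {}

    order = list(nx.topological_sort(out.to_networkx()))  # children before parents
    for nid in order:
        node = out.nodes[nid]
        genes = set(node.direct_genes)
        for child in node.children:
            genes |= memo[child]
        memo[nid] = genes
        node.genes = genes
    return out


def _surviving_parent_map(graph: OntologyGraph, removed: set[str]) -> dict[str, set[str]]:
    """For each removed node, its nearest surviving ancestors."""
    memo: dict[str, set[str]] = {}

    def resolve(nid: str) -> set[str]:
        if nid in memo:
            return memo[nid]
        out: set[str] = set()
        for p in graph.nodes[nid].parents:
            if p in removed:
                out |= resolve(p)
            else:
                out.add(p)
        memo[nid] = out
        return out

    for nid in removed:
        resolve(nid)
    return memo


def _remove_nodes(graph: OntologyGraph, removed: set[str]) -> OntologyGraph:
    """Drop ``removed`` nodes, reconnecting children to nearest surviving ancestors."""
    if not removed:
        return graph
    anc = _surviving_parent_map(graph, removed)
    out = OntologyGraph(root=graph.root)
    for nid, node in graph.nodes.items():
        if nid in removed:
            continue
        new = node.copy()
        parents: set[str] = set()
        for p in node.parents:
            if p in removed:
                parents |= anc[p]
            else:
                parents.add(p)
        new.parents = parents
        new.children = set()
        out.nodes[nid] = new
    for nid, node in out.nodes.items():
        for p in node.parents:
            out.nodes[p].children.add(nid)
    return out


def filter_by_size(graph: OntologyGraph, min_genes: int = 3, max_genes: int = 75) -> OntologyGraph:
    """Remove systems with fewer than ``min_genes`` or more than ``max_genes`` genes.

    Children of removed systems are reconnected to their nearest surviving
    ancestors so reachability from the root is preserved.  The synthetic root
    is exempt (it exists only to keep the DAG single-rooted).
    """
    removed = {
        nid
        for nid, node in graph.nodes.items()
        if nid != graph.root and not (min_genes <= len(node.genes) <= max_genes)
    }
    return _remove_nodes(graph, removed)


def parent_child_similarity(parent: SystemNode, child: SystemNode) -> float:
    """S(P, C) = |A_C| / |A_P| on propagated gene sets."""
    if not parent.genes:
        return 0.0
    return len(child.genes) / len(parent.genes)


def collapse_similar(graph: OntologyGraph, threshold: float = 0.9) -> OntologyGraph:
    """Remove parents nearly identical to a child, to a fixed point.

    A parent is removed when any of its children covers at least ``threshold``
    of its gene set; its children are attached to all of its parents.  Passes
    repeat until no parent qualifies, so reconnection-created parent/child
    pairs are also checked.
    """
    out = graph
    while True:
        removed = set()
        for nid, node in out.nodes.items():
            if nid == out.root:
                continue
            for cid in node.children:
                if parent_child_similarity(node, out.nodes[cid]) >= threshold:
                    removed.add(nid)
                    break
        if not removed:
            return out
        out = _remove_nodes(out, removed)


def permute_gene_labels(graph: OntologyGraph, seed) -> OntologyGraph:
    """Relabel genes by one random bijection over the gene universe.

    Node set, edges and per-system gene counts are unchanged — only which
    gene carries which label.  Used to build 'null' ontologies of identical
    structure for competitive recalibration.
    """
    rng = np.random.default_rng(seed)
    universe = sorted(graph.gene_universe)
    permuted = [universe[i] for i in rng.permutation(len(universe))]
    mapping = dict(zip(universe, permuted))
    out = graph.copy()
    for node in out.nodes.values():
        node.direct_genes = {mapping[g] for g in node.direct_genes}
        node.genes = {mapping[g] for g in node.genes}
    return out


def build_hierarchy(
    obo_stream,
    annotation_stream,
    excluded_evidence: Iterable[str] = ("IEA",),
    min_genes: int = 3,
    max_genes: int = 75,
    similarity_threshold: float = 0.9,
    log=None,
) -> OntologyGraph:
    """Full pipeline: parse, unify roots, propagate, size-filter, collapse."""
    graph = parse_ontology(obo_stream, annotation_stream, excluded_evidence)
    if log:
        log(f"parsed {len(graph.nodes)} terms")
    graph = unify_roots(graph)
    graph = propagate_annotations(graph)
    graph = filter_by_size(graph, min_genes, max_genes)
    if log:
        log(f"{len(graph.systems())} systems after size filter [{min_genes}, {max_genes}]")
    graph = collapse_similar(graph, similarity_threshold)
    if log:
        log(f"{len(graph.systems())} systems after similarity collapse (>= {similarity_threshold})")
    return graph


def write_systems_tsv(graph: OntologyGraph, buf) -> None:
    """Write retained systems as TSV: id, name, namespace, n_genes, genes."""
    close = False
    if isinstance(buf, str):
        buf = open(buf, "w")
        close = True
    try:
        buf.write("system_id\tname\tnamespace\tn_genes\tgenes\n")
        for nid in graph.systems():
            node = graph.nodes[nid]
            genes = ";".join(sorted(node.genes))
            buf.write(f"{nid}\t{node.name}\t{node.namespace}\t{len(node.genes)}\t{genes}\n")
    finally:
        if close:
            buf.close()
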