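"""Gene Ontology DAG handling and annotation propagation.

The ontology is held as a directed acyclic graph with edges pointing from
child terms to their parents.  Annotations follow the true-path rule: a gene
annotated to a term is implicitly annotated to every ancestor of that term,
so per-term gene counts are computed after upward propagation.

Term "level" (minimum number of parent edges to the namespace root) and the
number of descendants of a term are used downstream to flag generic terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet

from .errors import ParseError, StructuralError, ValidationError

#: relations that are followed during upward propagation by default
DEFAULT_RELATIONS = ("is_a",)


class OntologyGraph:
    """A GO-style ontology: terms, typed child->parent edges, namespace roots.

    Parameters
    ----------
    graph :
        Directed graph with child->parent edges; each edge carries a
        ``relation`` attribute and each node may carry ``namespace``,
        ``name`` and ``alt_id`` attributes.
    """

    def __init__(self, graph: nx.DiGraph):
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise StructuralError(f"ontology graph contains a cycle: {cycle}")
        self._graph = graph
        self._alt_ids: dict[str, str] = {}
        for node, data in graph.nodes(data=True):
            for alt in data.get("alt_id", []) or []:
                self._alt_ids[alt] = node
        self._roots = self._find_roots()
        self._ancestor_cache: dict[tuple[str, tuple[str, ...]], frozenset[str]] = {}

    # -- construction -----------------------------------------------------

    def _find_roots(self) -> dict[str, str]:
        roots: dict[str, str] = {}
        for node, data in self._graph.nodes(data=True):
            if self._graph.out_degree(node) == 0:
                ns = data.get("namespace", "default")
                if ns in roots:
                    raise StructuralError(
                        f"namespace {ns!r} has multiple roots: {roots[ns]}, {node}"
                    )
                roots[ns] = node
        return roots

    # -- basic queries -----------------------------------------------------

    @property
    def terms(self) -> set[str]:
        return set(self._graph.nodes)

    @property
    def namespace_roots(self) -> Mapping[str, str]:
        return dict(self._roots)

    def __contains__(self, term: str) -> bool:
        return term in self._graph or term in self._alt_ids

    def __len__(self) -> int:
        return self._graph.number_of_nodes()

    def resolve(self, term: str) -> str:
        """Map an alt_id to its primary id (primary ids map to themselves)."""
        if term in self._graph:
            return term
        if term in self._alt_ids:
            return self._alt_ids[term]
        raise KeyError(f"unknown ontology term: {term}")

    def name(self, term: str) -> str:
        return self._graph.nodes[self.resolve(term)].get("name", "")

    def namespace(self, term: str) -> str:
        return self._graph.nodes[self.resolve(term)].get("namespace", "default")

    def parents(self, term: str, relations: Iterable[str] = DEFAULT_RELATIONS) -> set[str]:
        term = self.resolve(term)
        rels = set(relations)
        return {
            v
            for _, v, data in self._graph.out_edges(term, data=True)
            if data.get("relation", "is_a") in rels
        }

    def ancestors(
        self, term: str, relations: Iterable[str] = DEFAULT_RELATIONS
    ) -> frozenset[str]:
        """All terms reachable from *term* by parent edges (term excluded)."""
        term = self.resolve(term)
        key = (term, tuple(sorted(relations)))
        cached = self._ancestor_cache.get(key)
        if cached is not None:
            return cached
        seen: set[str] = set()
        stack = [term]
        while stack:
            for parent in self.parents(stack.pop(), relations):
                if parent not in seen:
                    seen.add(parent)
                    stack.append(parent)
        result = frozenset(seen)
        self._ancestor_cache[key] = result
        return result

    def term_level(self, term: str, relations: Iterable[str] = DEFAULT_RELATIONS) -> int:
        """Minimum number of parent edges from *term* to its namespace root.

        The namespace root itself has level 0.  Shortest-path depth is the
        conventional meaning of "GO level" and is well defined on a DAG.
        """
        term = self.resolve(term)
        root = self._roots[self.namespace(term)]
        if term == root:
            return 0
        # BFS upward over the selected relations
        frontier = {term}
        level = 0
        seen = {term}
        while frontier:
            level += 1
            nxt: set[str] = set()
            for t in frontier:
                for parent in self.parents(t, relations):
                    if parent == root:
                        return level
                    if parent not in seen:
                        seen.add(parent)
                        nxt.add(parent)
            frontier = nxt
        raise StructuralError(f"term {term} does not reach its namespace root {root}")

    def count_descendants(self, term: str, relations: Iterable[str] = DEFAULT_RELATIONS) -> int:
        """Number of distinct terms having *term* among their ancestors."""
        term = self.resolve(term)
        rels = set(relations)
        seen: set[str] = set()
        stack = [term]
        while stack:
            node = stack.pop()
            for child, _, data in self._graph.in_edges(node, data=True):
                if data.get("relation", "is_a") in rels and child not in seen:
                    seen.add(child)
                    stack.append(child)
        return len(seen)


def parse_obo(path: str | Path) -> OntologyGraph:
    """Parse an OBO 1.2/1.4 file into an :class:`OntologyGraph`.

    Obsolete terms are excluded and alt_ids are mapped to their primary ids.
    A cyclic is_a structure raises :class:`StructuralError`.
    """
    try:
        multigraph = obonet.read_obo(path, ignore_obsolete=True)
    except (ValueError, KeyError) as exc:  # malformed stanza
        raise ParseError(f"malformed OBO file {path}: {exc}") from exc
    # obonet returns a MultiDiGraph with edge keys naming the relation;
    # flatten to a DiGraph with a 'relation' attribute per edge.
    graph = nx.DiGraph()
    for node, data in multigraph.nodes(data=True):
        graph.add_node(node, **data)
    for child, parent, relation in multigraph.edges(keys=True):
        graph.add_edge(child, parent, relation=relation)
    return OntologyGraph(graph)


@dataclass
class AnnotationSet:
    """Per-species gene -> GO-term annotations.

    ``propagated`` records whether the true-path closure has been applied.
    """

    species: str
    annotations: dict[str, set[str]] = field(default_factory=dict)
    propagated: bool = False

    def genes(self) -> set[str]:
        return set(self.annotations)

    def terms(self) -> set[str]:
        out: set[str] = set()
        for ts in self.annotations.values():
            out |= ts
        return out

    def n_pairs(self) -> int:
        """Total number of gene–term annotation pairs."""
        return sum(len(ts) for ts in self.annotations.values())


def propagate_annotations(
    ann: AnnotationSet,
    graph: OntologyGraph,
    relations: Iterable[str] = DEFAULT_RELATIONS,
    on_unknown: str = "warn",
) -> AnnotationSet:
    """Apply the true-path rule: close each gene's term set under ancestry.

    Idempotent and monotone: the output annotation sets contain the input
    sets.  Unknown term ids are skipped with a warning (``on_unknown="warn"``)
    or raise (``on_unknown="error"``).
    """
    if on_unknown not in ("warn", "error"):
        raise ValueError("on_unknown must be 'warn' or 'error'")
    out: dict[str, set[str]] = {}
    unknown: set[str] = set()
    for gene, terms in ann.annotations.items():
        closed: set[str] = set()
        for term in terms:
            if term not in graph:
                if on_unknown == "error":
                    raise ValidationError(
                        f"gene {gene} annotated to unknown term {term}"
                    )
                unknown.add(term)
                continue
            primary = graph.resolve(term)
            closed.add(primary)
            closed |= graph.ancestors(primary, relations)
        out[gene] = closed
    if unknown:
        warnings.warn(
            f"skipped {len(unknown)} unknown term id(s) during propagation: "
            f"{sorted(unknown)[:5]}...",
            stacklevel=2,
        )
    return AnnotationSet(species=ann.species, annotations=out, propagated=True)


# -- annotation readers/writers -------------------------------------------


def read_annotations_tsv(path: str | Path, species: str) -> AnnotationSet:
    """Read a minimal two-column ``gene_id<TAB>term_id`` annotation table."""
    annotations: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 tab-separated columns")
            gene, term = parts[0], parts[1]
            annotations.setdefault(gene, set()).add(term)
    return AnnotationSet(species=species, annotations=annotations)


def read_gaf(
    path: str | Path,
    species: str,
    evidence_include: set[str] | None = None,
) -> AnnotationSet:
    """Read a GAF 2.x association file.

    Uses column 2 (DB object id) as the gene id and column 5 as the GO id.
    Rows whose qualifier contains NOT are skipped; ``evidence_include``
    optionally restricts rows to the listed evidence codes.
    """
    annotations: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("!"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 7:
                raise ParseError(f"{path}:{lineno}: GAF row has fewer than 7 columns")
            gene, qualifier, term, evidence = parts[1], parts[3], parts[4], parts[6]
            if "NOT" in qualifier.split("|"):
                continue
            if evidence_include is not None and evidence not in evidence_include:
                continue
            annotations.setdefault(gene, set()).add(term)
    return AnnotationSet(species=species, annotations=annotations)


def write_annotations_tsv(ann: AnnotationSet, path: str | Path) -> None:
    """Write annotations in the two-column dialect (deterministic order)."""
    with open(path, "w") as fh:
        for gene in sorted(ann.annotations):
            for term in sorted(ann.annotations[gene]):
                fh.write(f"{gene}\t{term}\n")
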