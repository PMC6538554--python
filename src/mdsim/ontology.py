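"""Subsumption DAGs, information content and multi-domain ontology merging.

An :class:`OntologyGraph` is a directed acyclic graph of terms connected by
``is_a`` edges (child -> parent), parsed from OBO flat files.  Each graph
carries a *domain* tag: one ontology describes one area of knowledge
(diseases, symptoms, vaccines, ...).  On top of the graph this module
provides ancestor closures, the most informative common ancestor (MICA),
two information-content estimators (corpus-based and intrinsic), and the
merge operation that joins several domain ontologies under a single root so
that a single-ontology similarity measure can run across domains.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import networkx as nx
import obonet

from .errors import ConfigurationError, LookupError_, ParseError, StructuralError

__all__ = [
    "Term",
    "OntologyGraph",
    "MergedOntology",
    "ICTable",
    "parse_obo",
    "ancestors",
    "descendants",
    "mica",
    "compute_ic_corpus",
    "compute_ic_intrinsic",
    "merge_ontologies",
    "write_obo",
    "write_collision_report",
]

#: sentinel id returned by :func:`mica` when two terms share no ancestor
NO_COMMON_ANCESTOR = None

#: default id of the root created when merged ontologies share no common root
DEFAULT_MERGED_ROOT_ID = "MULTI:0000000"


@dataclass(frozen=True)
class Term:
    """A single ontology concept."""

    id: str
    name: str
    domain: str
    obsolete: bool = False


class OntologyGraph:
    """A rooted subsumption DAG over one (or, after merging, several) domains.

    Edges run child -> parent.  Obsolete terms are kept as nodes for id
    resolution (via ``alt_id`` / ``replaced_by``) but carry no edges and are
    excluded from closure queries.
    """

    def __init__(
        self,
        terms: Mapping[str, Term],
        edges: Iterable[tuple[str, str]],
        alt_ids: Mapping[str, str] | None = None,
        name: str | None = None,
    ) -> None:
        self.terms: dict[str, Term] = dict(terms)
        self.alt_ids: dict[str, str] = dict(alt_ids or {})
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for child, parent in edges:
            if child not in self.terms or parent not in self.terms:
                raise StructuralError(
                    f"edge {child} -> {parent} references a term not in the graph"
                )
            g.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(g):
            cycle = [f"{u} is_a {v}" for u, v, *_ in nx.find_cycle(g)]
            raise StructuralError("subsumption cycle detected: " + "; ".join(cycle))
        self.graph = g
        self.roots: frozenset[str] = frozenset(
            t for t in self.terms
            if g.out_degree(t) == 0 and not self.terms[t].obsolete
        )
        self.name = name or (self.domains()[0] if self.terms else "empty")
        self._anc_cache: dict[str, frozenset[str]] = {}
        self._desc_cache: dict[str, frozenset[str]] = {}

    # -- basic queries ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    @property
    def domain_of(self) -> dict[str, str]:
        return {t: term.domain for t, term in self.terms.items()}

    def domains(self) -> list[str]:
        return sorted({term.domain for term in self.terms.values()})

    def resolve(self, term_id: str) -> str | None:
        """Map an id (primary, alt_id or replaced_by source) to its primary id.

        Returns None if the id is unknown or resolves to an obsolete term
        with no replacement.
        """
        if term_id in self.terms:
            term = self.terms[term_id]
            if term.obsolete:
                repl = self.alt_ids.get(term_id)
                return repl if repl != term_id else None
            return term_id
        return self.alt_ids.get(term_id)

    def ancestors(self, term_id: str) -> frozenset[str]:
        """Reflexive transitive closure over is_a (term itself included)."""
        if term_id not in self.terms:
            raise LookupError_(f"unknown term id: {term_id!r}")
        if self.terms[term_id].obsolete:
            raise LookupError_(f"term {term_id!r} is obsolete")
        cached = self._anc_cache.get(term_id)
        if cached is None:
            cached = frozenset(nx.descendants(self.graph, term_id)) | {term_id}
            self._anc_cache[term_id] = cached
        return cached

    def descendants(self, term_id: str) -> frozenset[str]:
        """Strict descendants of a term (term itself excluded)."""
        if term_id not in self.terms:
            raise LookupError_(f"unknown term id: {term_id!r}")
        cached = self._desc_cache.get(term_id)
        if cached is None:
            cached = frozenset(nx.ancestors(self.graph, term_id))
            self._desc_cache[term_id] = cached
        return cached

    def validate(self) -> None:
        """Check the structural invariants; raise StructuralError on failure."""
        live = [t for t, term in self.terms.items() if not term.obsolete]
        for t in live:
            if t not in self.roots and self.graph.out_degree(t) == 0:
                raise StructuralError(f"non-root term {t} has no parent")
            if not (self.ancestors(t) & self.roots):
                raise StructuralError(f"term {t} is not connected to any root")


@dataclass
class MergedOntology:
    """Result of merging several domain ontologies under a common root."""

    graph: OntologyGraph
    merged_root_id: str
    provenance: dict[str, set[str]]
    collisions: list[str] = field(default_factory=list)


@dataclass
class ICTable:
    """Per-term information content in natural-log units.

    ``source`` records the estimator: "corpus" (negative log of propagated
    relative annotation frequency) or "intrinsic" (descendant-count form).
    """

    ic: dict[str, float]
    ic_max: float
    source: str

    def __getitem__(self, term_id: str) -> float:
        return self.ic[term_id]

    def get(self, term_id: str, default: float = 0.0) -> float:
        return self.ic.get(term_id, default)


# ---------------------------------------------------------------------------
# OBO parsing


_STANZA_RE = re.compile(r"^\[[A-Za-z_]+\]$")
_TAG_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_-]*:")


def _validate_obo_lines(path: str) -> None:
    # obonet is lenient; pre-scan so malformed stanzas fail with a line number
    try:
        fh = open(path, encoding="utf-8")
    except OSError as exc:
        raise ParseError(f"cannot read OBO file {path!r}: {exc}") from exc
    with fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("!", 1)[0].strip()
            if not line:
                continue
            if _STANZA_RE.match(line) or _TAG_RE.match(line):
                continue
            raise ParseError(f"{path}:{lineno}: malformed OBO line: {raw.strip()!r}")


def parse_obo(path: str, domain: str, include_part_of: bool = False) -> OntologyGraph:
    """Parse an OBO 1.2/1.4 file into a subsumption DAG for one domain.

    Only ``is_a`` edges are used by default; ``relationship: part_of`` edges
    are included when *include_part_of* is set.  Obsolete terms are retained
    as isolated nodes so that their ``replaced_by`` targets can be resolved,
    and ``alt_id`` values map to their primary id.

    Raises ParseError for malformed input, StructuralError on cycles.
    """
    _validate_obo_lines(path)
    try:
        raw = obonet.read_obo(path, ignore_obsolete=False)
    except Exception as exc:  # pragma: no cover - obonet failure modes vary
        raise ParseError(f"{path}: could not parse OBO file: {exc}") from exc

    terms: dict[str, Term] = {}
    alt_ids: dict[str, str] = {}
    edges: list[tuple[str, str]] = []
    relations = {"is_a"} | ({"part_of"} if include_part_of else set())

    for node, data in raw.nodes(data=True):
        obsolete = str(data.get("is_obsolete", "false")).lower() == "true"
        terms[node] = Term(
            id=node,
            name=data.get("name", node),
            domain=domain,
            obsolete=obsolete,
        )
        for alt in data.get("alt_id", []):
            alt_ids.setdefault(alt, node)
        if obsolete:
            for repl in data.get("replaced_by", []):
                alt_ids.setdefault(node, repl)

    for child, parent, key in raw.edges(keys=True):
        if key not in relations:
            continue
        if terms[child].obsolete or terms[parent].obsolete:
            continue
        edges.append((child, parent))

    if not any(not t.obsolete for t in terms.values()):
        raise ParseError(f"{path}: no non-obsolete terms found")

    return OntologyGraph(terms, edges, alt_ids=alt_ids, name=domain)


def write_obo(graph: OntologyGraph, path: str) -> None:
    """Serialize a graph back to a deterministic OBO 1.2 flat file."""
    lines = ["format-version: 1.2", f"ontology: {graph.name}", ""]
    for term_id in sorted(graph.terms):
        term = graph.terms[term_id]
        lines.append("[Term]")
        lines.append(f"id: {term.id}")
        lines.append(f"name: {term.name}")
        if term.obsolete:
            lines.append("is_obsolete: true")
        for parent in sorted(graph.graph.successors(term_id)):
            lines.append(f"is_a: {parent} ! {graph.terms[parent].name}")
        lines.append("")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines))


# ---------------------------------------------------------------------------
# Closures and MICA


def ancestors(graph: OntologyGraph, term: str) -> frozenset[str]:
    """Reflexive ancestor closure of *term* (includes the term and all roots above)."""
    return graph.ancestors(term)


def descendants(graph: OntologyGraph, term: str) -> frozenset[str]:
    """Strict descendant set of *term*."""
    return graph.descendants(term)


def mica(
    graph: OntologyGraph, ic: ICTable, t1: str, t2: str
) -> tuple[str | None, float]:
    """Most informative common ancestor of two terms and its IC.

    Ties on IC are broken by the lexicographically smallest term id.  When
    the terms share no ancestor (disjoint graphs queried without merging)
    the sentinel ``(None, 0.0)`` is returned.
    """
    common = graph.ancestors(t1) & graph.ancestors(t2)
    if not common:
        return NO_COMMON_ANCESTOR, 0.0
    best = min(common, key=lambda t: (-ic.get(t, 0.0), t))
    return best, ic.get(best, 0.0)


# ---------------------------------------------------------------------------
# Information content


def compute_ic_corpus(graph: OntologyGraph, corpus) -> ICTable:
    """Corpus-based information content: -ln of propagated annotation frequency.

    freq(t) counts (resource, annotation) pairs whose term is t or one of
    its descendants; the denominator is the total number of resolvable
    pairs, so roots score 0.  Terms never observed (directly or via a
    descendant) receive the maximum IC observed, keeping values finite
    while preserving the rarity ordering.
    """
    counts: dict[str, int] = {t: 0 for t in graph.terms}
    total = 0
    for _resource, term_ids in sorted(corpus.resources.items()):
        for tid in term_ids:
            resolved = graph.resolve(tid)
            if resolved is None:
                continue
            total += 1
            for anc in graph.ancestors(resolved):
                counts[anc] += 1
    if total == 0:
        raise ConfigurationError(
            "corpus contains no annotations resolvable in this ontology"
        )
    ic: dict[str, float] = {}
    observed_max = 0.0
    for t, term in graph.terms.items():
        if term.obsolete:
            continue
        if t in graph.roots:
            ic[t] = 0.0
        elif counts[t] > 0:
            ic[t] = -math.log(counts[t] / total)
            observed_max = max(observed_max, ic[t])
        else:
            ic[t] = math.nan  # placeholder, patched below
    for t, v in ic.items():
        if math.isnan(v):
            ic[t] = observed_max
    return ICTable(ic=ic, ic_max=max(ic.values(), default=0.0), source="corpus")


def compute_ic_intrinsic(graph: OntologyGraph) -> ICTable:
    """Structural information content from descendant counts.

    IC(t) = 1 - ln(1 + |descendants(t)|) / ln(|terms|): leaves get 1, a
    root subsuming everything gets 0.  Used as a fallback for domains
    without an annotation corpus.
    """
    live = [t for t, term in graph.terms.items() if not term.obsolete]
    n = len(live)
    if n == 0:
        raise ConfigurationError("cannot compute intrinsic IC of an empty graph")
    ic: dict[str, float] = {}
    for t in live:
        if n == 1:
            ic[t] = 0.0
            continue
        value = 1.0 - math.log1p(len(graph.descendants(t))) / math.log(n)
        if abs(value) < 1e-12:  # a root subsuming all terms, up to float noise
            value = 0.0
        ic[t] = min(max(value, 0.0), 1.0)
    return ICTable(ic=ic, ic_max=max(ic.values(), default=0.0), source="intrinsic")


# ---------------------------------------------------------------------------
# Merging


def merge_ontologies(
    graphs: list[OntologyGraph],
    root_name: str = "multi-domain root",
    merged_root_id: str = DEFAULT_MERGED_ROOT_ID,
) -> MergedOntology:
    """Merge domain ontologies into one DAG under a common root.

    Terms with identical ids across inputs are unified into a single node
    (children are pooled, the first-seen name and domain win) and recorded
    in ``collisions``; this realizes the shared-concept behaviour where
    subclasses from different domains gain a common non-root ancestor.  A
    fresh root subsuming every former root is created unless all inputs
    already share one single common root id, in which case that root is
    reused.
    """
    if not graphs:
        raise ConfigurationError("merge_ontologies requires at least one input graph")

    terms: dict[str, Term] = {}
    alt_ids: dict[str, str] = {}
    edges: set[tuple[str, str]] = set()
    provenance: dict[str, set[str]] = {}
    collisions: list[str] = []

    for g in graphs:
        for tid, term in g.terms.items():
            provenance.setdefault(tid, set()).add(g.name)
            if tid in terms:
                if tid not in collisions:
                    collisions.append(tid)
            else:
                terms[tid] = term
        for alt, primary in g.alt_ids.items():
            alt_ids.setdefault(alt, primary)
        edges.update(g.graph.edges())

    old_roots = sorted({r for g in graphs for r in g.roots})
    shared_root = (
        len(old_roots) == 1 and all(g.roots == {old_roots[0]} for g in graphs)
    )
    if shared_root:
        root_id = old_roots[0]
    else:
        root_id = merged_root_id
        if root_id in terms:
            raise ConfigurationError(
                f"merged root id {root_id!r} collides with an input term"
            )
        terms[root_id] = Term(id=root_id, name=root_name, domain="merged")
        provenance[root_id] = {"merged"}
        # former roots become children of the new root; a collided term that
        # was a root in one source but a child in another needs no edge
        merged_graph_edges = edges
        for r in old_roots:
            if not any(child == r for child, _ in merged_graph_edges):
                edges.add((r, root_id))

    merged = OntologyGraph(
        terms, sorted(edges), alt_ids=alt_ids, name="+".join(g.name for g in graphs)
    )
    if len(merged.roots) != 1:
        raise StructuralError(
            f"merge produced {len(merged.roots)} roots: {sorted(merged.roots)}"
        )
    collisions.sort()
    return MergedOntology(
        graph=merged,
        merged_root_id=root_id,
        provenance=provenance,
        collisions=collisions,
    )


def write_collision_report(merged: MergedOntology, path: str) -> None:
    """Write the shared-id collision report as a two-column TSV."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("term_id\tsource_ontologies\n")
        for tid in merged.collisions:
            sources = ",".join(sorted(merged.provenance[tid]))
            fh.write(f"{tid}\t{sources}\n")
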