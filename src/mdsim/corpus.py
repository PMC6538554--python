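"""Resource-annotation corpora and their descriptive statistics.

A corpus maps resource ids to sets of ontology term ids drawn from several
orthogonal domains (one ontology per domain).  Real annotation corpora of
this shape are sparse: most resources are annotated in only a few of the
available domains, and not always the same ones, which is what motivates
multi-domain similarity in the first place.  The statistics computed here
summarize that sparseness per domain:

coverage
    fraction of resources with at least one annotation in the domain
volume
    mean annotation count in the domain, over covered resources only
diversity
    number of distinct terms of the domain used anywhere in the corpus
isolation
    fraction of resources annotated *only* in that domain

plus a histogram of how many distinct domains each resource touches.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import pandas as pd

from .errors import InputError
from .ontology import OntologyGraph

logger = logging.getLogger(__name__)

__all__ = ["AnnotationCorpus", "CorpusStats", "load_annotations", "corpus_stats"]


@dataclass
class AnnotationCorpus:
    """Mapping resource id -> set of term ids, partitionable by domain."""

    resources: dict[str, frozenset[str]]
    term_domain: dict[str, str]

    @property
    def m(self) -> int:
        """Number of resources."""
        return len(self.resources)

    @property
    def domain_index(self) -> dict[str, set[str]]:
        """Domain tag -> set of distinct term ids used in that domain."""
        index: dict[str, set[str]] = {}
        for terms in self.resources.values():
            for t in terms:
                index.setdefault(self.term_domain[t], set()).add(t)
        return index

    def domains_of(self, resource_id: str) -> set[str]:
        return {self.term_domain[t] for t in self.resources[resource_id]}

    def annotations_in(self, resource_id: str, domain: str) -> frozenset[str]:
        """The resource's annotations restricted to one domain."""
        return frozenset(
            t for t in self.resources[resource_id] if self.term_domain[t] == domain
        )

    def without_domain(self, domain: str) -> "AnnotationCorpus":
        """A view of the corpus with one domain's annotations removed.

        Resources losing all annotations are kept (with empty sets) so the
        resource universe — and hence any similarity matrix shape — is
        unchanged.
        """
        resources = {
            r: frozenset(t for t in terms if self.term_domain[t] != domain)
            for r, terms in self.resources.items()
        }
        return AnnotationCorpus(resources=resources, term_domain=dict(self.term_domain))

    def to_tsv(self, path: str) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("resource_id\tterm_id\n")
            for r in sorted(self.resources):
                for t in sorted(self.resources[r]):
                    fh.write(f"{r}\t{t}\n")


@dataclass
class CorpusStats:
    """Per-domain summary statistics plus the domain-count histogram."""

    m: int
    coverage: dict[str, float]
    volume: dict[str, float]
    diversity: dict[str, int]
    isolation: dict[str, float]
    histogram: dict[int, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "domain": d,
                "coverage": self.coverage[d],
                "volume": self.volume[d],
                "diversity": self.diversity[d],
                "isolation": self.isolation[d],
            }
            for d in sorted(self.coverage)
        ]
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        payload = {
            "m": self.m,
            "domains": {
                d: {
                    "coverage": self.coverage[d],
                    "volume": self.volume[d],
                    "diversity": self.diversity[d],
                    "isolation": self.isolation[d],
                }
                for d in sorted(self.coverage)
            },
            "histogram": {str(k): v for k, v in sorted(self.histogram.items())},
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _prefix(term_id: str) -> str:
    return term_id.split(":", 1)[0]


def load_annotations(
    path: str,
    ontologies: list[OntologyGraph],
    prefix_map: dict[str, str] | None = None,
) -> AnnotationCorpus:
    """Load a (resource_id, term_id) TSV into an AnnotationCorpus.

    Term ids are resolved against the supplied ontologies (alt_id and
    replaced_by mappings apply); a term's domain is the tag of the ontology
    that resolves it, with the id-prefix convention as arbiter when a term
    resolves in several (an explicit *prefix_map* overrides).  Unresolvable
    annotations are logged and dropped, duplicates are collapsed, and
    resources left without any annotation are dropped with a warning.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", dtype=str, comment=None, header=None,
            names=["resource_id", "term_id"],
        )
    except (OSError, pd.errors.EmptyDataError) as exc:
        raise InputError(f"cannot read annotation file {path!r}: {exc}") from exc
    if len(df) and df.iloc[0, 0] == "resource_id":
        df = df.iloc[1:]
    if df.empty:
        raise InputError(f"annotation file {path!r} contains no rows")

    resources: dict[str, set[str]] = {}
    term_domain: dict[str, str] = {}
    dropped = 0
    for resource_id, term_id in df.itertuples(index=False):
        resolved, domain = _resolve_term(term_id, ontologies, prefix_map)
        if resolved is None:
            dropped += 1
            logger.info("dropping unresolvable annotation %s -> %s", resource_id, term_id)
            continue
        resources.setdefault(resource_id, set()).add(resolved)
        term_domain[resolved] = domain
    for r in [r for r, terms in resources.items() if not terms]:
        logger.warning("resource %s has no resolvable annotations; dropped", r)
        del resources[r]
    if not resources:
        raise InputError(f"annotation file {path!r} yielded zero resolvable annotations")
    if dropped:
        logger.warning("dropped %d unresolvable annotation rows", dropped)
    return AnnotationCorpus(
        resources={r: frozenset(t) for r, t in resources.items()},
        term_domain=term_domain,
    )


def _resolve_term(term_id, ontologies, prefix_map):
    if not isinstance(term_id, str) or not term_id:
        return None, None
    candidates = []
    for g in ontologies:
        resolved = g.resolve(term_id)
        if resolved is not None:
            candidates.append((g, resolved))
    if not candidates:
        return None, None
    if prefix_map and _prefix(term_id) in prefix_map:
        wanted = prefix_map[_prefix(term_id)]
        for g, resolved in candidates:
            if g.terms[resolved].domain == wanted:
                return resolved, wanted
    g, resolved = candidates[0]
    return resolved, g.terms[resolved].domain


def build_corpus(
    resources: dict[str, frozenset[str]], term_domain: dict[str, str]
) -> AnnotationCorpus:
    """Construct a corpus from in-memory mappings (used by the generator)."""
    if any(not terms for terms in resources.values()):
        raise InputError("every resource must carry at least one annotation")
    return AnnotationCorpus(resources=dict(resources), term_domain=dict(term_domain))


def corpus_stats(corpus: AnnotationCorpus) -> CorpusStats:
    """Compute the per-domain coverage/volume/diversity/isolation table.

    Volume is averaged over *covered* resources only: a domain annotating a
    single resource once has volume 1.0 regardless of corpus size, which is
    the only reading under which rarely-used domains keep volume >= 1.
    """
    if corpus.m == 0:
        raise InputError("empty corpus")
    m = corpus.m
    index = corpus.domain_index
    coverage: dict[str, float] = {}
    volume: dict[str, float] = {}
    diversity: dict[str, int] = {}
    isolation: dict[str, float] = {}
    histogram: dict[int, int] = {}

    per_resource_domains = {r: corpus.domains_of(r) for r in corpus.resources}
    for domains in per_resource_domains.values():
        histogram[len(domains)] = histogram.get(len(domains), 0) + 1

    for d in index:
        covered = [r for r, doms in per_resource_domains.items() if d in doms]
        counts = [len(corpus.annotations_in(r, d)) for r in covered]
        coverage[d] = len(covered) / m
        volume[d] = sum(counts) / len(covered)
        diversity[d] = len(index[d])
        isolation[d] = sum(
            1 for r in covered if per_resource_domains[r] == {d}
        ) / m
    return CorpusStats(
        m=m,
        coverage=coverage,
        volume=volume,
        diversity=diversity,
        isolation=isolation,
        histogram=histogram,
    )
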