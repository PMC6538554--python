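"""Single-ontology groupwise similarity measures and their multi-domain liftings.

Term-level measures
    Resnik: IC of the most informative common ancestor (optionally divided
    by the ontology's maximum IC so scores land in [0, 1]).
    Lin: 2 * IC(MICA) / (IC(t1) + IC(t2)).

Groupwise measures over two annotation sets A, B
    resnik_bma / lin_bma: best-match average — the mean of each set's
    best matches into the other, averaged across directions.
    simui: Jaccard overlap of the sets' reflexive ancestor closures.
    simgic: IC-weighted Jaccard of the closures.

Multi-domain liftings of a groupwise measure
    baseline: apply the measure to one designated domain's annotations only.
    aggregative (raw / weighted): score each shared domain independently,
    then average — uniformly, or weighted by how many annotations the two
    resources carry in each domain.
    integrative: merge the domain ontologies under one root and apply the
    measure once to the full annotation sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Literal

import numpy as np
import pandas as pd

from .corpus import AnnotationCorpus
from .errors import ConfigurationError, LookupError_
from .ontology import ICTable, MergedOntology, OntologyGraph, mica

__all__ = [
    "MeasureSpec",
    "SettingSpec",
    "SimilarityMatrix",
    "GROUPWISE_MEASURES",
    "SETTING_MODES",
    "sim_term_resnik",
    "sim_term_lin",
    "sim_group_bma",
    "sim_group_simui",
    "sim_group_simgic",
    "groupwise",
    "sim_resources",
    "similarity_matrix",
]

GROUPWISE_MEASURES = ("resnik_bma", "lin_bma", "simui", "simgic")
SETTING_MODES = ("baseline", "aggregative_raw", "aggregative_weighted", "integrative")

#: sentinel for "similarity undefined" (one of the sets empty)
UNDEFINED = None


@dataclass(frozen=True)
class MeasureSpec:
    """Which groupwise measure to use, and whether Resnik scores are rescaled."""

    groupwise: str = "resnik_bma"
    normalize_resnik: bool = True

    def __post_init__(self) -> None:
        if self.groupwise not in GROUPWISE_MEASURES:
            raise ConfigurationError(
                f"unknown groupwise measure {self.groupwise!r}; "
                f"choose one of {GROUPWISE_MEASURES}"
            )


@dataclass(frozen=True)
class SettingSpec:
    """One of the four multi-domain settings."""

    mode: str
    baseline_domain: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in SETTING_MODES:
            raise ConfigurationError(
                f"unknown setting mode {self.mode!r}; choose one of {SETTING_MODES}"
            )
        if (self.mode == "baseline") != (self.baseline_domain is not None):
            raise ConfigurationError(
                "baseline_domain must be given exactly when mode='baseline'"
            )

    @property
    def label(self) -> str:
        if self.mode == "baseline":
            return f"baseline:{self.baseline_domain}"
        return self.mode

    @property
    def is_multi_domain(self) -> bool:
        return self.mode != "baseline"


@dataclass
class SimilarityMatrix:
    """Symmetric resource-by-resource score table for one (setting, measure)."""

    resource_ids: list[str]
    scores: np.ndarray
    setting: SettingSpec
    measure: MeasureSpec
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = {r: i for i, r in enumerate(self.resource_ids)}

    def value(self, r1: str, r2: str) -> float:
        return float(self.scores[self._index[r1], self._index[r2]])

    def to_tsv(self, path: str) -> None:
        df = pd.DataFrame(self.scores, index=self.resource_ids, columns=self.resource_ids)
        df.to_csv(path, sep="\t", float_format="%.10g")

    def to_long_tsv(self, path: str) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("r1\tr2\tscore\n")
            for i, r1 in enumerate(self.resource_ids):
                for j in range(i + 1, len(self.resource_ids)):
                    fh.write(f"{r1}\t{self.resource_ids[j]}\t{self.scores[i, j]:.10g}\n")

    @classmethod
    def from_tsv(cls, path: str, setting: SettingSpec, measure: MeasureSpec):
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            resource_ids=[str(c) for c in df.columns],
            scores=df.to_numpy(dtype=float),
            setting=setting,
            measure=measure,
        )


# ---------------------------------------------------------------------------
# Term-level measures


def sim_term_resnik(
    graph: OntologyGraph, ic: ICTable, t1: str, t2: str, normalize: bool = False
) -> float:
    """Resnik similarity: IC of the MICA, optionally divided by ic_max."""
    _, value = mica(graph, ic, t1, t2)
    if normalize:
        return value / ic.ic_max if ic.ic_max > 0 else 0.0
    return value


def sim_term_lin(graph: OntologyGraph, ic: ICTable, t1: str, t2: str) -> float:
    """Lin similarity: 2 * IC(MICA) / (IC(t1) + IC(t2)); 0 when the denominator is 0."""
    _, shared = mica(graph, ic, t1, t2)
    denom = ic.get(t1, 0.0) + ic.get(t2, 0.0)
    if denom <= 0.0:
        return 0.0
    return 2.0 * shared / denom


# ---------------------------------------------------------------------------
# Groupwise measures


def sim_group_bma(
    graph: OntologyGraph,
    ic: ICTable,
    termsim: Callable[[OntologyGraph, ICTable, str, str], float],
    a_terms: Iterable[str],
    b_terms: Iterable[str],
) -> float | None:
    """Best-match average of a pairwise term measure over two sets.

    0.5 * (mean over A of the best match in B + mean over B of the best
    match in A); symmetric by construction.  Returns the UNDEFINED sentinel
    (None) when either set is empty.
    """
    a_set, b_set = sorted(set(a_terms)), sorted(set(b_terms))
    if not a_set or not b_set:
        return UNDEFINED
    pair = {
        (a, b): termsim(graph, ic, a, b) for a in a_set for b in b_set
    }
    forward = sum(max(pair[(a, b)] for b in b_set) for a in a_set) / len(a_set)
    backward = sum(max(pair[(a, b)] for a in a_set) for b in b_set) / len(b_set)
    return 0.5 * (forward + backward)


def _closure(graph: OntologyGraph, terms: Iterable[str]) -> frozenset[str]:
    out: set[str] = set()
    for t in terms:
        out |= graph.ancestors(t)
    return frozenset(out)


def sim_group_simui(
    graph: OntologyGraph, a_terms: Iterable[str], b_terms: Iterable[str]
) -> float | None:
    """simUI: Jaccard overlap of the reflexive ancestor closures of two sets."""
    a_set, b_set = set(a_terms), set(b_terms)
    if not a_set or not b_set:
        return UNDEFINED
    anc_a, anc_b = _closure(graph, a_set), _closure(graph, b_set)
    union = anc_a | anc_b
    return len(anc_a & anc_b) / len(union)


def sim_group_simgic(
    graph: OntologyGraph, ic: ICTable, a_terms: Iterable[str], b_terms: Iterable[str]
) -> float | None:
    """simGIC: IC-weighted Jaccard of the ancestor closures.

    When every term in both closures has zero IC the quotient is taken to
    be 1 for identical closures and 0 otherwise.
    """
    a_set, b_set = set(a_terms), set(b_terms)
    if not a_set or not b_set:
        return UNDEFINED
    anc_a, anc_b = _closure(graph, a_set), _closure(graph, b_set)
    inter = sum(ic.get(t, 0.0) for t in anc_a & anc_b)
    union = sum(ic.get(t, 0.0) for t in anc_a | anc_b)
    if union <= 0.0:
        return 1.0 if anc_a == anc_b else 0.0
    return inter / union


def groupwise(
    measure: MeasureSpec,
    graph: OntologyGraph,
    ic: ICTable,
    a_terms: Iterable[str],
    b_terms: Iterable[str],
) -> float | None:
    """Dispatch a MeasureSpec to the corresponding groupwise function."""
    if measure.groupwise == "resnik_bma":
        def term(g, t, x, y):
            return sim_term_resnik(g, t, x, y, normalize=measure.normalize_resnik)
        return sim_group_bma(graph, ic, term, a_terms, b_terms)
    if measure.groupwise == "lin_bma":
        return sim_group_bma(graph, ic, sim_term_lin, a_terms, b_terms)
    if measure.groupwise == "simui":
        return sim_group_simui(graph, a_terms, b_terms)
    return sim_group_simgic(graph, ic, a_terms, b_terms)


# ---------------------------------------------------------------------------
# Multi-domain liftings


def sim_resources(
    setting: SettingSpec,
    measure: MeasureSpec,
    ontologies: dict[str, OntologyGraph],
    ic_tables: dict[str, ICTable],
    corpus: AnnotationCorpus,
    r1: str,
    r2: str,
    merged: MergedOntology | None = None,
    merged_ic: ICTable | None = None,
) -> float:
    """Similarity of two resources under one (setting, measure) pair.

    Domains where either resource lacks annotations are excluded from the
    aggregative averages rather than scored 0: with sparse per-domain
    coverage an absent domain carries no evidence either way.  An undefined
    comparison (no shared domain, or empty baseline subsets) scores 0.
    """
    for r in (r1, r2):
        if r not in corpus.resources:
            raise LookupError_(f"unknown resource id: {r!r}")

    if setting.mode == "baseline":
        d = setting.baseline_domain
        if d not in ontologies:
            raise ConfigurationError(f"no ontology supplied for domain {d!r}")
        value = groupwise(
            measure,
            ontologies[d],
            ic_tables[d],
            corpus.annotations_in(r1, d),
            corpus.annotations_in(r2, d),
        )
        return 0.0 if value is UNDEFINED else value

    if setting.mode == "integrative":
        if merged is None or merged_ic is None:
            raise ConfigurationError("integrative setting requires a merged ontology")
        value = groupwise(
            measure,
            merged.graph,
            merged_ic,
            corpus.resources[r1],
            corpus.resources[r2],
        )
        return 0.0 if value is UNDEFINED else value

    # aggregative (raw or weighted)
    scores: list[float] = []
    weights: list[float] = []
    for d in sorted(ontologies):
        a = corpus.annotations_in(r1, d)
        b = corpus.annotations_in(r2, d)
        if not a or not b:
            continue
        value = groupwise(measure, ontologies[d], ic_tables[d], a, b)
        if value is UNDEFINED:
            continue
        scores.append(value)
        weights.append(float(len(a) + len(b)))
    if not scores:
        return 0.0
    if setting.mode == "aggregative_raw":
        return float(np.mean(scores))
    return float(np.average(scores, weights=weights))


def similarity_matrix(
    setting: SettingSpec,
    measure: MeasureSpec,
    ontologies: dict[str, OntologyGraph],
    ic_tables: dict[str, ICTable],
    corpus: AnnotationCorpus,
    merged: MergedOntology | None = None,
    merged_ic: ICTable | None = None,
) -> SimilarityMatrix:
    """All-pairs similarity over the corpus, computed once per unordered pair."""
    if corpus.m < 2:
        raise ConfigurationError("similarity matrix requires at least 2 resources")
    ids = sorted(corpus.resources)
    n = len(ids)
    scores = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            s = sim_resources(
                setting, measure, ontologies, ic_tables, corpus,
                ids[i], ids[j], merged=merged, merged_ic=merged_ic,
            )
            scores[i, j] = scores[j, i] = s
    return SimilarityMatrix(
        resource_ids=ids, scores=scores, setting=setting, measure=measure
    )
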