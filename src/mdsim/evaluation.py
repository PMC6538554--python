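"""Annotation prediction with ML-KNN and the multi-domain dominance summary.

The validation protocol asks how well a similarity matrix supports
predicting one target domain's annotations from the others: for each
resource, find its k nearest neighbours under the matrix, and estimate a
Bayesian posterior for every candidate label from how often that label
appears in the neighbourhood (the ML-KNN estimator of Zhang & Zhou, with
Laplace-style smoothing s).  Evaluation is leave-one-out: the held-out
resource contributes neither to the priors nor to the neighbourhood count
statistics used to score it.

Five standard multi-label metrics summarize each run (hamming loss,
one-error, coverage, ranking loss, average precision), and H_p counts, over
all (metric, k) runs, how often the p best-performing settings are all
multi-domain settings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .corpus import AnnotationCorpus
from .errors import ConfigurationError
from .ontology import ICTable, OntologyGraph, compute_ic_corpus, merge_ontologies
from .similarity import (
    MeasureSpec,
    SettingSpec,
    SimilarityMatrix,
    similarity_matrix,
)

logger = logging.getLogger(__name__)

__all__ = [
    "MLKNNConfig",
    "LabelPrediction",
    "EvaluationReport",
    "HpSummary",
    "neighborhoods",
    "mlknn_fit_predict",
    "metrics",
    "run_experiment",
    "compute_hp",
]

#: metrics where smaller values indicate better performance
LOWER_IS_BETTER = ("hamming_loss", "one_error", "coverage", "ranking_loss")
HIGHER_IS_BETTER = ("average_precision",)
METRIC_NAMES = LOWER_IS_BETTER + HIGHER_IS_BETTER


@dataclass(frozen=True)
class MLKNNConfig:
    """Parameters of the ML-KNN label predictor."""

    k: int
    target_domain: str
    s: float = 1.0
    label_space: str = "observed"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ConfigurationError("k must be >= 1")
        if self.s <= 0 or not np.isfinite(self.s):
            raise ConfigurationError("smoothing constant s must be finite and > 0")
        if self.label_space not in ("observed", "full_ontology"):
            raise ConfigurationError("label_space must be 'observed' or 'full_ontology'")


@dataclass
class LabelPrediction:
    """Posterior label scores for one resource.

    ``ranking`` orders the label space by descending posterior, ties broken
    by ascending label id; ``predicted`` is the score > 0.5 cut."""

    resource_id: str
    scores: dict[str, float]
    predicted: frozenset[str]
    ranking: list[str]

    def rank_of(self, label: str) -> int:
        """1-based rank of a label in the prediction ordering."""
        return self.ranking.index(label) + 1


@dataclass
class EvaluationReport:
    """Rows of (setting, measure, k, five metrics)."""

    frame: pd.DataFrame

    def to_tsv(self, path: str) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.10g")

    def to_json(self, path: str) -> None:
        self.frame.to_json(path, orient="records", indent=2)

    @classmethod
    def from_rows(cls, rows: list[dict]) -> "EvaluationReport":
        cols = ["setting", "measure", "k", *METRIC_NAMES]
        return cls(frame=pd.DataFrame(rows, columns=cols))


@dataclass
class HpSummary:
    """Counts H_p of runs whose top-p settings are all multi-domain."""

    counts: dict[int, int]
    runs: int

    def to_frame(self) -> pd.DataFrame:
        row = {f"H_{p}": self.counts[p] for p in sorted(self.counts)}
        row["runs"] = self.runs
        return pd.DataFrame([row])


# ---------------------------------------------------------------------------
# Neighbourhoods


def neighborhoods(matrix: SimilarityMatrix, k: int) -> dict[str, list[str]]:
    """The k most similar other resources for each resource.

    Ties are broken by ascending resource id, so equal-similarity
    neighbourhoods are deterministic.
    """
    m = len(matrix.resource_ids)
    if k >= m:
        raise ConfigurationError(f"k={k} must be < number of resources ({m})")
    order = _sorted_neighbor_indices(matrix.scores)
    return {
        rid: [matrix.resource_ids[j] for j in order[i, :k]]
        for i, rid in enumerate(matrix.resource_ids)
    }


def _sorted_neighbor_indices(scores: np.ndarray) -> np.ndarray:
    """Per-row neighbour indices sorted by descending similarity then index.

    Resource ids are stored sorted, so ascending index equals ascending id;
    a stable argsort of the negated scores therefore implements the tie
    rule.  The diagonal (self) is pushed to the end and dropped.
    """
    s = scores.astype(float).copy()
    np.fill_diagonal(s, -np.inf)
    order = np.argsort(-s, axis=1, kind="stable")
    return order[:, :-1]


# ---------------------------------------------------------------------------
# ML-KNN


def _label_matrix(
    corpus: AnnotationCorpus, resource_ids: list[str], config: MLKNNConfig,
    ontology: OntologyGraph | None,
) -> tuple[np.ndarray, list[str]]:
    truth = {r: corpus.annotations_in(r, config.target_domain) for r in resource_ids}
    observed = sorted(set().union(*truth.values()) if truth else set())
    if config.label_space == "full_ontology":
        if ontology is None:
            raise ConfigurationError(
                "label_space='full_ontology' requires the target-domain ontology"
            )
        labels = sorted(
            t for t, term in ontology.terms.items()
            if not term.obsolete and t not in ontology.roots
        )
    else:
        labels = observed
    if not labels:
        raise ConfigurationError("empty label space for the target domain")
    idx = {lab: j for j, lab in enumerate(labels)}
    y = np.zeros((len(resource_ids), len(labels)), dtype=np.int64)
    for i, r in enumerate(resource_ids):
        for t in truth[r]:
            if t in idx:
                y[i, idx[t]] = 1
    return y, labels


def mlknn_fit_predict(
    corpus: AnnotationCorpus,
    matrix: SimilarityMatrix,
    config: MLKNNConfig,
    ontology: OntologyGraph | None = None,
) -> list[LabelPrediction]:
    """Leave-one-out ML-KNN posteriors for every resource.

    For each held-out resource the remaining m-1 resources form the
    training set: label priors P(H_l) = (s + n_l) / (2s + m_train), and the
    neighbourhood-count conditionals P(E_j | H_l) = (s + c_l[j]) /
    (s (k+1) + sum_j c_l[j]) where c_l[j] counts training resources
    carrying l whose k-neighbourhood (within the training set) contains
    exactly j resources carrying l; analogously for the negated event.  The
    held-out resource's posterior combines its own neighbourhood count with
    these estimates by Bayes' rule.
    """
    ids = matrix.resource_ids
    m = len(ids)
    k, s = config.k, config.s
    if k >= m:
        raise ConfigurationError(f"k={k} must be < number of resources ({m})")
    y, labels = _label_matrix(corpus, ids, config, ontology)
    n_labels = len(labels)
    order = _sorted_neighbor_indices(matrix.scores)  # (m, m-1)

    predictions: list[LabelPrediction] = []
    for i in range(m):
        train = np.array([t for t in range(m) if t != i])
        # k-neighbourhoods of training resources within the training set:
        # drop i from each sorted neighbour list, keep the first k (fewer
        # only in the degenerate k = m-1 case, where m-2 others exist)
        y_train = y[train]
        counts = np.empty((m - 1, n_labels), dtype=np.int64)
        for row, t in enumerate(train):
            cand = order[t, : k + 1]
            cand = cand[cand != i][:k]
            counts[row] = y[cand].sum(axis=0)

        # held-out resource's neighbourhood within the training set
        test_nbr = order[i, :k]
        test_counts = y[test_nbr].sum(axis=0)  # (n_labels,)

        n_l = y_train.sum(axis=0)
        m_train = m - 1
        prior = (s + n_l) / (2 * s + m_train)

        scores = np.empty(n_labels)
        for l in range(n_labels):
            c_pos = np.bincount(counts[y_train[:, l] == 1, l], minlength=k + 1)
            c_neg = np.bincount(counts[y_train[:, l] == 0, l], minlength=k + 1)
            j = int(test_counts[l])
            p_e_h = (s + c_pos[j]) / (s * (k + 1) + c_pos.sum())
            p_e_nh = (s + c_neg[j]) / (s * (k + 1) + c_neg.sum())
            num = prior[l] * p_e_h
            scores[l] = num / (num + (1 - prior[l]) * p_e_nh)

        score_map = {labels[l]: float(scores[l]) for l in range(n_labels)}
        ranking = sorted(labels, key=lambda lab: (-score_map[lab], lab))
        predicted = frozenset(lab for lab in labels if score_map[lab] > 0.5)
        predictions.append(
            LabelPrediction(
                resource_id=ids[i],
                scores=score_map,
                predicted=predicted,
                ranking=ranking,
            )
        )
    return predictions


# ---------------------------------------------------------------------------
# Multi-label metrics


def metrics(
    predictions: list[LabelPrediction], truth: dict[str, frozenset[str]]
) -> dict[str, float]:
    """The five ML-KNN evaluation metrics over a set of predictions.

    Resources with an empty truth set are excluded with a warning: one-error,
    coverage, ranking loss and average precision are undefined without at
    least one true label.
    """
    kept = [p for p in predictions if truth.get(p.resource_id)]
    skipped = len(predictions) - len(kept)
    if skipped:
        logger.warning("excluding %d resources with no true target labels", skipped)
    if not kept:
        raise ConfigurationError("no resource has a non-empty truth set")

    hamming = one_error = coverage = rloss = avgprec = 0.0
    for p in kept:
        t = truth[p.resource_id]
        space = set(p.scores)
        true = t & space
        false = space - true
        hamming += len(p.predicted ^ true) / len(space)
        one_error += 0.0 if p.ranking[0] in true else 1.0
        ranks = {lab: p.rank_of(lab) for lab in true}
        coverage += max(ranks.values()) - 1
        if false:
            wrong = sum(
                1 for lt in true for lf in false if p.rank_of(lf) < ranks[lt]
            )
            rloss += wrong / (len(true) * len(false))
        avgprec += (
            sum(
                sum(1 for other in true if ranks[other] <= ranks[lab]) / ranks[lab]
                for lab in true
            )
            / len(true)
        )
    n = len(kept)
    return {
        "hamming_loss": hamming / n,
        "one_error": one_error / n,
        "coverage": coverage / n,
        "ranking_loss": rloss / n,
        "average_precision": avgprec / n,
    }


# ---------------------------------------------------------------------------
# Experiment sweep


def run_experiment(
    corpus: AnnotationCorpus,
    ontologies: dict[str, OntologyGraph],
    settings: list[SettingSpec],
    measures: list[MeasureSpec],
    k_values: list[int],
    target_domain: str,
    s: float = 1.0,
    label_space: str = "observed",
    target_ontology: OntologyGraph | None = None,
) -> EvaluationReport:
    """Sweep (setting, measure, k) and evaluate target-domain prediction.

    Target-domain annotations are removed from all similarity inputs —
    predicting labels from a matrix that already encodes them would be
    circular — but retained as the prediction truth.  The whole sweep is
    deterministic given its inputs.
    """
    for setting in settings:
        if setting.mode == "baseline" and setting.baseline_domain == target_domain:
            raise ConfigurationError(
                "baseline on the target domain would predict labels from themselves"
            )
    truth = {
        r: corpus.annotations_in(r, target_domain) for r in corpus.resources
    }
    n_with_labels = sum(1 for t in truth.values() if t)
    if n_with_labels < max(k_values) + 1:
        raise ConfigurationError(
            f"target domain {target_domain!r} annotated in {n_with_labels} resources; "
            f"need at least k+1 = {max(k_values) + 1}"
        )

    sim_corpus = corpus.without_domain(target_domain)
    source_domains = {d: g for d, g in sorted(ontologies.items()) if d != target_domain}
    ic_tables = {
        d: compute_ic_corpus(g, sim_corpus) for d, g in source_domains.items()
    }
    needs_merge = any(s.mode == "integrative" for s in settings)
    merged = merged_ic = None
    if needs_merge:
        merged = merge_ontologies(list(source_domains.values()))
        merged_ic = compute_ic_corpus(merged.graph, sim_corpus)

    rows: list[dict] = []
    for measure in measures:
        for setting in settings:
            matrix = similarity_matrix(
                setting, measure, source_domains, ic_tables, sim_corpus,
                merged=merged, merged_ic=merged_ic,
            )
            for k in k_values:
                config = MLKNNConfig(
                    k=k, target_domain=target_domain, s=s, label_space=label_space
                )
                predictions = mlknn_fit_predict(
                    corpus, matrix, config, ontology=target_ontology
                )
                row = {
                    "setting": setting.label,
                    "measure": measure.groupwise,
                    "k": k,
                }
                row.update(metrics(predictions, truth))
                rows.append(row)
    return EvaluationReport.from_rows(rows)


def compute_hp(
    report: EvaluationReport,
    multi_domain_settings: set[str] | None = None,
    p_values: tuple[int, ...] = (1, 2, 3),
) -> HpSummary:
    """Count runs where the p best settings are all multi-domain.

    A run is one (measure, metric, k) cell.  H_p is incremented when at
    least p multi-domain settings perform strictly better than the best
    baseline — a baseline tied into the top p blocks the increment, which
    is the conservative reading of multi-domain dominance.
    """
    frame = report.frame
    if multi_domain_settings is None:
        multi_domain_settings = {
            s for s in frame["setting"].unique() if not s.startswith("baseline")
        }
    counts = {p: 0 for p in p_values}
    runs = 0
    for (_measure, k), group in frame.groupby(["measure", "k"], sort=True):
        for metric in METRIC_NAMES:
            values = dict(zip(group["setting"], group[metric]))
            if len(values) < max(p_values):
                raise ConfigurationError(
                    f"run (k={k}, {metric}) has fewer settings than max p"
                )
            sign = 1.0 if metric in HIGHER_IS_BETTER else -1.0
            md = [sign * v for s, v in values.items() if s in multi_domain_settings]
            base = [sign * v for s, v in values.items() if s not in multi_domain_settings]
            best_base = max(base) if base else -np.inf
            dominant = sum(1 for v in md if v > best_base)
            runs += 1
            for p in p_values:
                if dominant >= p:
                    counts[p] += 1
    return HpSummary(counts=counts, runs=runs)
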