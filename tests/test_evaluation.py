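import numpy as np
import pandas as pd
import pytest

from mdsim.corpus import build_corpus
from mdsim.errors import ConfigurationError
from mdsim.evaluation import (
    EvaluationReport,
    LabelPrediction,
    MLKNNConfig,
    compute_hp,
    metrics,
    mlknn_fit_predict,
    neighborhoods,
    run_experiment,
)
from mdsim.similarity import MeasureSpec, SettingSpec, SimilarityMatrix

from conftest import make_graph
from oracles import bf_metrics, bf_mlknn_posterior, bf_neighborhoods


def _matrix(ids, scores):
    return SimilarityMatrix(
        resource_ids=ids,
        scores=np.asarray(scores, dtype=float),
        setting=SettingSpec(mode="aggregative_raw"),
        measure=MeasureSpec(),
    )


class TestNeighborhoods:
    def test_single_best_neighbor(self):
        mx = _matrix(
            ["a", "b", "c"],
            [[1.0, 0.9, 0.1], [0.9, 1.0, 0.5], [0.1, 0.5, 1.0]],
        )
        assert neighborhoods(mx, 1) == {"a": ["b"], "b": ["a"], "c": ["b"]}

    def test_all_equal_scores_tie_by_id(self):
        mx = _matrix(["c", "a", "b"], np.ones((3, 3)))
        # resource ids are stored in the given order; ties resolve by index
        # order which corresponds to sorted ids in library-built matrices
        mx2 = _matrix(sorted(mx.resource_ids), np.ones((3, 3)))
        assert neighborhoods(mx2, 2) == {
            "a": ["b", "c"], "b": ["a", "c"], "c": ["a", "b"]
        }

    def test_k_too_large_rejected(self):
        mx = _matrix(["a", "b"], np.ones((2, 2)))
        with pytest.raises(ConfigurationError):
            neighborhoods(mx, 2)

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            m = int(rng.integers(3, 12))
            ids = sorted(f"r{i:02d}" for i in range(m))
            s = rng.random((m, m))
            s = (s + s.T) / 2
            mx = _matrix(ids, s)
            k = int(rng.integers(1, m))
            assert neighborhoods(mx, k) == bf_neighborhoods(ids, s, k)


class TestMLKNN:
    def _five_resource_setup(self):
        """5 resources; the label is annotated in 2 of any 4 training resources."""
        target = make_graph(
            [("L:1", "L:0"), ("L:2", "L:0"), ("L:3", "L:0")], domain="target"
        )
        resources = {
            "r0": frozenset(["S:1", "L:1"]),
            "r1": frozenset(["S:1", "L:1"]),
            "r2": frozenset(["S:2", "L:2"]),
            "r3": frozenset(["S:2", "L:2"]),
            "r4": frozenset(["S:3", "L:3"]),
        }
        term_domain = {
            "S:1": "src", "S:2": "src", "S:3": "src",
            "L:1": "target", "L:2": "target", "L:3": "target",
        }
        corpus = build_corpus(resources, term_domain)
        # similarity: identical source term -> 1, else 0
        ids = sorted(resources)
        s = np.zeros((5, 5))
        groups = [("r0", "r1"), ("r2", "r3")]
        for a, b in groups:
            i, j = ids.index(a), ids.index(b)
            s[i, j] = s[j, i] = 1.0
        np.fill_diagonal(s, 1.0)
        return corpus, _matrix(ids, s), target

    def test_prior_matches_closed_form(self):
        corpus, mx, target = self._five_resource_setup()
        config = MLKNNConfig(k=1, target_domain="target", s=1.0)
        preds = mlknn_fit_predict(corpus, mx, config)
        # for held-out r4, label L:1 occurs in 2 of the 4 training resources:
        # prior = (1+2)/(2+4) = 0.5; its neighbourhood (r0) carries L:1, and
        # among training resources exactly the two L:1 carriers have an L:1
        # neighbour, so the closed-form posterior follows
        p_r4 = next(p for p in preds if p.resource_id == "r4")
        expected = bf_mlknn_posterior(
            train_labels=[1, 1, 0, 0],
            train_neighbor_counts=[1, 1, 0, 0],
            test_count=1,
            k=1,
            s=1.0,
        )
        assert p_r4.scores["L:1"] == pytest.approx(expected)
        assert (1.0 + 2.0) / (2.0 + 4.0) == 0.5  # the prior inside the oracle

    def test_posteriors_match_brute_force_everywhere(self):
        corpus, mx, target = self._five_resource_setup()
        k, s = 2, 1.0
        config = MLKNNConfig(k=k, target_domain="target", s=s)
        preds = mlknn_fit_predict(corpus, mx, config)
        ids = mx.resource_ids
        labels = sorted({t for r in ids for t in corpus.annotations_in(r, "target")})
        nbr_all = {
            r: [x for x in nb]
            for r, nb in bf_neighborhoods(ids, mx.scores, len(ids) - 1).items()
        }
        for p in preds:
            i = p.resource_id
            train = [r for r in ids if r != i]
            for lab in labels:
                def count(r, within):
                    nbrs = [x for x in nbr_all[r] if x in within][:k]
                    return sum(
                        1 for x in nbrs
                        if lab in corpus.annotations_in(x, "target")
                    )
                train_labels = [
                    1 if lab in corpus.annotations_in(r, "target") else 0
                    for r in train
                ]
                train_counts = [count(r, set(train) - {r}) for r in train]
                expected = bf_mlknn_posterior(
                    train_labels, train_counts, count(i, set(train)), k, s
                )
                assert p.scores[lab] == pytest.approx(expected, abs=1e-12)

    def test_absent_label_posterior_is_prior_driven(self):
        corpus, mx, target = self._five_resource_setup()
        config = MLKNNConfig(
            k=1, target_domain="target", s=1.0, label_space="full_ontology"
        )
        # L:0's children include no 4th label; extend the target graph
        target2 = make_graph(
            [("L:1", "L:0"), ("L:2", "L:0"), ("L:3", "L:0"), ("L:9", "L:0")],
            domain="target",
        )
        preds = mlknn_fit_predict(corpus, mx, config, ontology=target2)
        p = preds[0]
        assert "L:9" in p.scores
        # never observed: counts are all zero, posterior reduces to the
        # smoothed prior against the smoothed negation
        expected = bf_mlknn_posterior([0, 0, 0, 0], [0, 0, 0, 0], 0, 1, 1.0)
        assert p.scores["L:9"] == pytest.approx(expected)

    def test_scores_in_unit_interval_and_prediction_consistent_with_ranking(self):
        corpus, mx, target = self._five_resource_setup()
        preds = mlknn_fit_predict(
            corpus, mx, MLKNNConfig(k=2, target_domain="target")
        )
        for p in preds:
            assert all(0.0 <= v <= 1.0 for v in p.scores.values())
            ranked_scores = [p.scores[l] for l in p.ranking]
            assert ranked_scores == sorted(ranked_scores, reverse=True)
            cut = {l for l in p.ranking if p.scores[l] > 0.5}
            assert cut == set(p.predicted)

    def test_uniform_similarity_posterior_depends_only_on_frequency(self):
        """With k = m-1 and all-equal similarities every resource sees the
        same neighbourhood structure, so posteriors reduce to label
        frequency."""
        corpus, _mx, target = self._five_resource_setup()
        ids = sorted(corpus.resources)
        mx = _matrix(ids, np.ones((5, 5)))
        preds = mlknn_fit_predict(
            corpus, mx, MLKNNConfig(k=4, target_domain="target")
        )
        # labels with equal corpus frequency get identical posteriors
        by_label = {}
        for p in preds:
            truth = corpus.annotations_in(p.resource_id, "target")
            for lab, score in p.scores.items():
                by_label.setdefault((lab in truth, lab), set()).add(round(score, 12))
        # L:1 and L:2 both occur twice: distribution of scores must match
        pos1 = by_label[(True, "L:1")]
        pos2 = by_label[(True, "L:2")]
        assert pos1 == pos2


class TestMetrics:
    def _pred(self, rid, order, scores=None):
        scores = scores or {
            lab: 1.0 - i / len(order) for i, lab in enumerate(order)
        }
        return LabelPrediction(
            resource_id=rid,
            scores=scores,
            predicted=frozenset(l for l, s in scores.items() if s > 0.5),
            ranking=list(order),
        )

    def test_perfect_prediction(self):
        truth = {"r1": frozenset(["a"]), "r2": frozenset(["b", "c"])}
        preds = [
            self._pred("r1", ["a", "b", "c"],
                       {"a": 0.9, "b": 0.2, "c": 0.1}),
            self._pred("r2", ["b", "c", "a"],
                       {"b": 0.9, "c": 0.8, "a": 0.1}),
        ]
        row = metrics(preds, truth)
        assert row["hamming_loss"] == 0.0
        assert row["one_error"] == 0.0
        assert row["ranking_loss"] == 0.0
        assert row["average_precision"] == 1.0
        assert row["coverage"] == pytest.approx(np.mean([0, 1]))

    def test_hand_worked_single_resource(self):
        # labels {a,b,c}, truth {a}, ranking (b,a,c)
        truth = {"r": frozenset(["a"])}
        preds = [self._pred("r", ["b", "a", "c"], {"b": 0.9, "a": 0.6, "c": 0.1})]
        row = metrics(preds, truth)
        assert row["one_error"] == 1.0
        assert row["coverage"] == 1.0
        assert row["ranking_loss"] == pytest.approx(0.5)
        assert row["average_precision"] == pytest.approx(0.5)

    def test_empty_truth_excluded(self):
        truth = {"r1": frozenset(["a"]), "r2": frozenset()}
        preds = [
            self._pred("r1", ["a", "b"], {"a": 0.9, "b": 0.1}),
            self._pred("r2", ["a", "b"], {"a": 0.9, "b": 0.1}),
        ]
        row = metrics(preds, truth)
        assert row["one_error"] == 0.0  # only r1 counted

    def test_matches_direct_definition_oracle_on_random_instances(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            labels = [f"l{i}" for i in range(int(rng.integers(3, 8)))]
            n = int(rng.integers(2, 8))
            preds, truth, rankings, truths = [], {}, {}, {}
            for i in range(n):
                rid = f"r{i}"
                scores = {l: float(rng.random()) for l in labels}  # ties: measure 0
                order = sorted(labels, key=lambda l: (-scores[l], l))
                t = frozenset(
                    rng.choice(labels, size=int(rng.integers(1, len(labels))),
                               replace=False).tolist()
                )
                preds.append(self._pred(rid, order, scores))
                truth[rid] = t
                rankings[rid] = order
                truths[rid] = set(t)
            row = metrics(preds, truth)
            ref = bf_metrics(rankings, truths, labels)
            for key, want in ref.items():
                assert row[key] == pytest.approx(want, abs=1e-12), key

    def test_metrics_match_sklearn_reference(self):
        """Cross-check ranking metrics against scikit-learn on tie-free scores."""
        from sklearn.metrics import (
            coverage_error,
            label_ranking_average_precision_score,
            label_ranking_loss,
        )

        rng = np.random.default_rng(12)
        labels = [f"l{i}" for i in range(6)]
        y_true = np.zeros((10, 6), dtype=int)
        y_score = rng.random((10, 6))
        preds, truth = [], {}
        for i in range(10):
            pos = rng.choice(6, size=int(rng.integers(1, 5)), replace=False)
            y_true[i, pos] = 1
            scores = {l: float(y_score[i, j]) for j, l in enumerate(labels)}
            order = sorted(labels, key=lambda l: (-scores[l], l))
            preds.append(self._pred(f"r{i}", order, scores))
            truth[f"r{i}"] = frozenset(labels[j] for j in pos)
        row = metrics(preds, truth)
        assert row["coverage"] == pytest.approx(coverage_error(y_true, y_score) - 1)
        assert row["ranking_loss"] == pytest.approx(label_ranking_loss(y_true, y_score))
        assert row["average_precision"] == pytest.approx(
            label_ranking_average_precision_score(y_true, y_score)
        )


class TestRunExperiment:
    def _inputs(self):
        from mdsim.synthetic import SyntheticSpec, generate

        spec = SyntheticSpec(
            seed=5, n_domains=3, terms_per_domain=6, max_depth=1, m=30,
            coverage=(1.0, 1.0, 1.0), volume_mean=(1.0, 1.0, 1.0),
            dependency={"D0": 1.0}, target_domain="D2",
        )
        return generate(spec)

    def test_row_cardinality(self):
        onts, corpus = self._inputs()
        settings = [
            SettingSpec(mode="aggregative_raw"),
            SettingSpec(mode="integrative"),
        ]
        report = run_experiment(
            corpus, onts, settings, [MeasureSpec()], [1, 2], "D2"
        )
        assert len(report.frame) == 4
        assert set(report.frame["k"]) == {1, 2}
        assert set(report.frame["setting"]) == {"aggregative_raw", "integrative"}

    def test_baseline_on_target_rejected(self):
        onts, corpus = self._inputs()
        with pytest.raises(ConfigurationError):
            run_experiment(
                corpus, onts,
                [SettingSpec(mode="baseline", baseline_domain="D2")],
                [MeasureSpec()], [1], "D2",
            )

    def test_informative_baseline_beats_unrelated_baseline(self):
        onts, corpus = self._inputs()
        settings = [
            SettingSpec(mode="baseline", baseline_domain="D0"),
            SettingSpec(mode="baseline", baseline_domain="D1"),
        ]
        report = run_experiment(
            corpus, onts, settings, [MeasureSpec()], [3], "D2"
        )
        ap = dict(zip(report.frame["setting"], report.frame["average_precision"]))
        assert ap["baseline:D0"] > ap["baseline:D1"]

    def test_deterministic(self):
        onts, corpus = self._inputs()
        settings = [SettingSpec(mode="aggregative_raw"),
                    SettingSpec(mode="integrative")]
        r1 = run_experiment(corpus, onts, settings, [MeasureSpec()], [2], "D2")
        r2 = run_experiment(corpus, onts, settings, [MeasureSpec()], [2], "D2")
        pd.testing.assert_frame_equal(r1.frame, r2.frame)


class TestComputeHp:
    def _report(self, rows):
        return EvaluationReport.from_rows(rows)

    @staticmethod
    def _row(setting, k, good):
        # "good": low losses / high precision
        q = 0.1 if good else 0.5
        return {
            "setting": setting, "measure": "resnik_bma", "k": k,
            "hamming_loss": q, "one_error": q, "coverage": q * 10,
            "ranking_loss": q, "average_precision": 1 - q,
        }

    def test_full_dominance(self):
        rows = []
        for k in (1, 2):
            for s, good in (
                ("integrative", True), ("aggregative_raw", True),
                ("aggregative_weighted", True), ("baseline:D0", False),
            ):
                rows.append(self._row(s, k, good))
        summary = compute_hp(self._report(rows))
        assert summary.runs == 10  # 5 metrics x 2 k
        assert summary.counts == {1: 10, 2: 10, 3: 10}

    def test_baseline_winning_one_run_blocks_h1(self):
        rows = []
        for s, good in (
            ("integrative", False), ("aggregative_raw", False),
            ("aggregative_weighted", False), ("baseline:D0", True),
        ):
            rows.append(self._row(s, 1, good))
        summary = compute_hp(self._report(rows))
        assert summary.counts[1] == 0

    def test_tie_at_boundary_blocks(self):
        rows = [
            self._row("integrative", 1, True),
            self._row("aggregative_raw", 1, True),
            self._row("aggregative_weighted", 1, True),
            self._row("baseline:D0", 1, True),  # ties all multi-domain rows
        ]
        summary = compute_hp(self._report(rows))
        assert summary.counts == {1: 0, 2: 0, 3: 0}

    def test_monotone_on_random_reports(self):
        rng = np.random.default_rng(17)
        settings = ["integrative", "aggregative_raw", "aggregative_weighted",
                    "baseline:D0", "baseline:D1"]
        for _ in range(20):
            rows = []
            for k in (1, 2, 3):
                for s in settings:
                    rows.append({
                        "setting": s, "measure": "resnik_bma", "k": k,
                        **{m: float(rng.random()) for m in (
                            "hamming_loss", "one_error", "coverage",
                            "ranking_loss", "average_precision")},
                    })
            summary = compute_hp(self._report(rows))
            assert 0 <= summary.counts[3] <= summary.counts[2] <= summary.counts[1]
            assert summary.counts[1] <= summary.runs
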