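"""Tournament CV, ranking AUC, Brier/R2, BBC search."""

import warnings

import numpy as np
import pandas as pd
import pytest

from vmi_radstab.classify import (
    DEFAULT_CONFIGS,
    LearnerSpec,
    bbc_search,
    brier_and_r2,
    evaluate_experiment,
    feature_subsets,
    ranking_auc,
    run_tournament,
    tlpo_splits,
    _mann_whitney_auc,
    _metrics_from_result,
)
from vmi_radstab.stability import StabilityRecord
from vmi_radstab.synthetic import FeatureTableSpec, generate_feature_table


def _records(cccs):
    return [
        StabilityRecord(f"f{i}", "a", "b", c, 1.0, c >= 0.9, c >= 0.9)
        for i, c in enumerate(cccs)
    ]


class TestFeatureSubsets:
    def test_all_perfect_ccc_leaves_non_repeatable_empty(self):
        subs = feature_subsets(_records([1.0, 1.0, 1.0]))
        assert subs["non_repeatable"] == set()
        assert subs["repeatable"] == subs["all"]

    def test_threshold_is_inclusive(self):
        subs = feature_subsets(_records([0.95, 0.9, 0.89]))
        assert subs["repeatable"] == {"f0", "f1"}
        assert subs["non_repeatable"] == {"f2"}

    def test_partition_property(self):
        rng = np.random.default_rng(0)
        subs = feature_subsets(_records(rng.uniform(0, 1, size=40)))
        assert subs["repeatable"] | subs["non_repeatable"] == subs["all"]
        assert subs["repeatable"] & subs["non_repeatable"] == set()

    def test_empty_repeatable_warns_but_proceeds(self):
        with pytest.warns(UserWarning, match="empty"):
            subs = feature_subsets(_records([0.1, 0.2]))
        assert subs["repeatable"] == set()


class TestTlpoSplits:
    @pytest.mark.parametrize("n,expected", [(4, 6), (16, 120)])
    def test_split_count(self, n, expected):
        assert len(tlpo_splits(n)) == expected

    def test_each_index_in_n_minus_1_pairs(self):
        n = 7
        counts = np.zeros(n, dtype=int)
        for train, (i, j) in tlpo_splits(n):
            counts[i] += 1
            counts[j] += 1
            assert len(train) == n - 2
            assert i not in train and j not in train
        assert np.all(counts == n - 1)

    def test_too_few_objects_rejected(self):
        with pytest.raises(ValueError, match="3"):
            tlpo_splits(2)


def _separable_table(n_per_class=4, seed=0):
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for k, cls in enumerate(("neg", "pos")):
        for i in range(n_per_class):
            rows.append([k * 10.0 + rng.normal(scale=0.1), rng.normal()])
            labels.append(cls)
    ids = [f"o{i}" for i in range(len(rows))]
    table = pd.DataFrame(rows, columns=["f_sep", "f_noise"], index=ids)
    return table, pd.Series(labels, index=ids)


class TestRunTournament:
    def test_separable_classes_sweep_all_tournaments(self):
        table, labels = _separable_table()
        res = run_tournament(table, labels)
        pos = (labels == "pos").to_numpy()
        k_pos = res.classes.index("pos")
        assert res.wins[pos, k_pos].min() > res.wins[~pos, k_pos].max()

    def test_constant_features_tie_every_tournament(self):
        n = 8
        ids = [f"o{i}" for i in range(n)]
        table = pd.DataFrame({"f": np.ones(n)}, index=ids)
        labels = pd.Series(["a", "b"] * (n // 2), index=ids)
        res = run_tournament(table, labels)
        assert np.allclose(res.wins, (n - 1) / 2.0)

    def test_wins_conservation(self):
        table, labels = _separable_table(seed=3)
        res = run_tournament(table, labels)
        n = len(table)
        # per pair and class exactly one win is distributed
        assert np.allclose(res.wins.sum(axis=0), n * (n - 1) / 2.0)

    def test_deterministic_given_seeds(self):
        table, labels = _separable_table(seed=4)
        r1 = run_tournament(table, labels, random_state=5)
        r2 = run_tournament(table, labels, random_state=5)
        assert np.array_equal(r1.wins, r2.wins)
        assert np.array_equal(r1.probas, r2.probas)

    def test_unknown_subset_feature_rejected(self):
        table, labels = _separable_table()
        with pytest.raises(ValueError, match="ghost"):
            run_tournament(table, labels, subset={"ghost"})


class TestRankingAuc:
    def test_perfect_ordering(self):
        table, labels = _separable_table()
        res = run_tournament(table, labels)
        per_class, mean = ranking_auc(res, labels)
        assert mean == 1.0

    def test_constant_scores_give_half(self):
        scores = np.ones(10)
        pos = np.array([True] * 4 + [False] * 6)
        assert _mann_whitney_auc(scores, pos) == 0.5

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_concordance(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 6, size=14).astype(float)
        pos = rng.uniform(size=14) < 0.4
        if pos.all() or not pos.any():
            pos[0] = ~pos[0]
        conc = 0.0
        for s_p in scores[pos]:
            for s_n in scores[~pos]:
                conc += 1.0 if s_p > s_n else (0.5 if s_p == s_n else 0.0)
        want = conc / (pos.sum() * (~pos).sum())
        assert _mann_whitney_auc(scores, pos) == pytest.approx(want, abs=1e-12)


class TestBrierR2:
    def test_perfect_predictions(self):
        onehot = np.eye(3)[[0, 1, 2, 1]]
        bs, bs_max, r2 = brier_and_r2(onehot, onehot, np.full(3, 1 / 3))
        assert bs == 0.0
        assert r2 == 1.0

    def test_non_informative_balanced_three_class(self):
        onehot = np.eye(3)[[0, 1, 2]]
        probas = np.full((3, 3), 1 / 3)
        bs, bs_max, r2 = brier_and_r2(probas, onehot, np.full(3, 1 / 3))
        assert bs == pytest.approx(2.0 / 3.0, abs=1e-12)
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_certain_wrong_prediction_maximal(self):
        onehot = np.array([[1.0, 0.0]])
        probas = np.array([[0.0, 1.0]])
        bs, _, _ = brier_and_r2(probas, onehot, np.array([0.5, 0.5]))
        assert bs == 2.0

    def test_unnormalized_probabilities_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            brier_and_r2(np.array([[0.5, 0.6]]), np.array([[1.0, 0.0]]), np.array([0.5, 0.5]))

    def test_r2_identity(self):
        rng = np.random.default_rng(1)
        p = rng.dirichlet(np.ones(3), size=20)
        y = np.eye(3)[rng.integers(0, 3, size=20)]
        bs, bs_max, r2 = brier_and_r2(p, y, np.full(3, 1 / 3))
        assert r2 == pytest.approx(1.0 - bs / bs_max, abs=1e-12)


class TestBBC:
    def _noise_table(self, n=12, p=8, seed=0):
        spec = FeatureTableSpec(
            n_objects=n, n_classes=2, n_features=p, target_ccc=0.9, seed=seed
        )
        test, _, labels = generate_feature_table(spec)
        return test, labels

    def test_single_config_equals_plain_evaluation(self):
        table, labels = self._noise_table()
        spec = LearnerSpec("elastic_net_logistic", n_configs=1, seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = bbc_search(table, labels, spec, B=300, seed=0)
        # with nothing to select, correction only resamples the same predictions
        assert res.corrected.bs == pytest.approx(res.naive.bs, abs=0.05)

    def test_deterministic(self):
        table, labels = self._noise_table(seed=2)
        spec = LearnerSpec("elastic_net_logistic", n_configs=3, seed=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r1 = bbc_search(table, labels, spec, B=100, seed=3)
            r2 = bbc_search(table, labels, spec, B=100, seed=3)
        assert r1.corrected.bs == r2.corrected.bs
        assert r1.corrected.auc_mean == r2.corrected.auc_mean
        assert r1.naive_config == r2.naive_config


class TestEvaluateExperiment:
    def test_grid_shape_and_condition_invariance(self):
        spec = FeatureTableSpec(
            n_objects=8, n_classes=2, n_features=10, target_ccc=0.9,
            class_effect=3.0, seed=5,
        )
        test, _, labels = generate_feature_table(spec)
        cccs = np.linspace(0.5, 1.0, 10)
        records = [
            StabilityRecord(c, "a", "b", v, 1.0, v >= 0.9, v >= 0.9)
            for c, v in zip(test.columns, cccs)
        ]
        tables = {"cond1": test, "cond2": test.copy()}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = evaluate_experiment(
                tables,
                labels,
                {"cond1": records, "cond2": records},
                families=("elastic_net_logistic",),
            )
        assert len(out) == 2 * 3 * 1
        a = out[out.condition == "cond1"].drop(columns="condition").reset_index(drop=True)
        b = out[out.condition == "cond2"].drop(columns="condition").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)
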