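import numpy as np
import pytest

from ipcarf import (ConfusionCounts, FeatureTable, PipelineSpec, RFConfig, accuracy,
                    confusion, cross_validate, f1_score, fpr, grid_search_n_estimators,
                    kfold_split, precision, rank_candidates, recall, roc_and_auc,
                    train_rf)


def concordance_oracle(labels, scores):
    """Brute-force Mann-Whitney concordance: P(score_pos > score_neg) + ties/2."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def _toy_clusters(n=100, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 0.3, (n // 2, 4)), rng.normal(3, 0.3, (n // 2, 4))])
    y = np.repeat([0, 1], n // 2)
    return X, y


class TestTrainRF:
    def test_separable_clusters_training_auc(self):
        X, y = _toy_clusters()
        clf = train_rf(X, y, RFConfig(50, seed=0))
        scores = clf.predict_proba(X)[:, 1]
        assert roc_and_auc(y, scores).auc == 1.0

    def test_same_seed_identical_predictions(self):
        X, y = _toy_clusters(seed=1)
        a = train_rf(X, y, RFConfig(50, seed=3)).predict_proba(X)
        b = train_rf(X, y, RFConfig(50, seed=3)).predict_proba(X)
        assert np.array_equal(a, b)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            train_rf(np.ones((5, 2)), np.ones(5, dtype=int), RFConfig(10))

    def test_shuffled_labels_give_chance_cv_auc(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(200, 6))
        y = np.repeat([0, 1], 100)
        table = FeatureTable(X, y, [("l", f"d{i}") for i in range(200)])
        spec = PipelineSpec(use_ipca=False, rf=RFConfig(50, seed=0))
        auc = cross_validate(spec, table, folds=5, seed=0).mean_auc
        assert 0.35 <= auc <= 0.65


class TestMetrics:
    C = ConfusionCounts(tp=3, tn=2, fp=1, fn=0)

    def test_hand_confusion_values(self):
        assert accuracy(self.C) == pytest.approx(5 / 6)
        assert precision(self.C) == pytest.approx(0.75)
        assert recall(self.C) == 1.0
        assert fpr(self.C) == pytest.approx(1 / 3)

    def test_confusion_counts(self):
        c = confusion([1, 1, 1, 0, 0, 0], [1, 1, 1, 1, 0, 0])
        assert c == self.C

    def test_perfect_predictions(self):
        c = confusion([1, 0, 1], [1, 0, 1])
        assert accuracy(c) == precision(c) == recall(c) == f1_score(c) == 1.0

    def test_all_negative_predictions_zero_recall(self):
        c = confusion([1, 0, 1], [0, 0, 0])
        assert recall(c) == 0.0
        assert np.isnan(precision(c))  # undefined ratio flagged, not raised

    def test_f1_standard_vs_printed_variant(self):
        c = self.C
        p, a, r = precision(c), accuracy(c), recall(c)
        assert f1_score(c) == pytest.approx(2 * p * r / (p + r))
        assert f1_score(c, variant="printed") == pytest.approx(2 * a * r / (a + r))

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            confusion([], [])


class TestRoc:
    def test_scores_equal_labels(self):
        assert roc_and_auc([0, 1, 0, 1], [0, 1, 0, 1]).auc == 1.0

    @pytest.mark.parametrize("seed", range(50))
    def test_auc_equals_concordance_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 40))
        y = rng.integers(0, 2, n)
        if len(np.unique(y)) < 2:
            y[0], y[1] = 0, 1
        s = np.round(rng.random(n), 2)  # rounding forces score ties
        assert roc_and_auc(y, s).auc == pytest.approx(concordance_oracle(y, s), abs=1e-12)

    def test_reversed_scores_complement_auc(self):
        rng = np.random.default_rng(7)
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        s = rng.random(30)
        assert roc_and_auc(y, -s).auc == pytest.approx(1 - roc_and_auc(y, s).auc)

    def test_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(8)
        y = np.repeat([0, 1], 15)
        roc = roc_and_auc(y, rng.random(30))
        assert roc.fpr[0] == 0 and roc.tpr[0] == 0
        assert roc.fpr[-1] == 1 and roc.tpr[-1] == 1
        assert np.all(np.diff(roc.fpr) >= 0) and np.all(np.diff(roc.tpr) >= 0)

    def test_one_class_errors(self):
        with pytest.raises(ValueError):
            roc_and_auc([1, 1], [0.2, 0.4])


class TestKFold:
    def test_fold_sizes(self):
        folds = kfold_split(20, folds=10, stratify_labels=np.repeat([0, 1], 10), seed=0)
        assert all(len(f) == 2 for f in folds)

    def test_folds_partition_indices(self):
        y = np.tile([0, 1], 25)
        folds = kfold_split(50, folds=5, stratify_labels=y, seed=1)
        concat = np.sort(np.concatenate(folds))
        assert np.array_equal(concat, np.arange(50))

    def test_stratification_within_one_sample(self):
        y = np.array([1] * 10 + [0] * 40)
        for f in kfold_split(50, folds=5, stratify_labels=y, seed=2):
            assert abs(y[f].sum() - 2) <= 1

    def test_seed_determinism(self):
        y = np.tile([0, 1], 20)
        a = kfold_split(40, 4, y, seed=3)
        b = kfold_split(40, 4, y, seed=3)
        assert all(np.array_equal(x, z) for x, z in zip(a, b))

    def test_too_many_folds(self):
        with pytest.raises(ValueError):
            kfold_split(3, folds=5)


class TestCrossValidate:
    def test_no_leakage_fit_calls_never_see_test_rows(self, small_dataset, monkeypatch):
        """Instrument the per-fold fit path and verify only training rows reach it."""
        import ipcarf.model_eval as me
        table = small_dataset.features
        marker = np.arange(len(table))  # unique row ids in an extra column
        X = np.column_stack([table.features, marker])
        inst = FeatureTable(X, table.labels, table.pair_ids)
        seen_per_fit = []
        real_train = me.train_rf

        def spy_train(features, labels, config):
            seen_per_fit.append(set(np.asarray(features)[:, -1].astype(int)))
            return real_train(features, labels, config)

        monkeypatch.setattr(me, "train_rf", spy_train)
        folds = me.kfold_split(len(inst), folds=5, stratify_labels=inst.labels, seed=0)
        me.cross_validate(PipelineSpec(use_ipca=False, rf=RFConfig(10, seed=0)),
                          inst, folds=5, seed=0)
        assert len(seen_per_fit) == 5
        for fit_rows, test_idx in zip(seen_per_fit, folds):
            assert not fit_rows & set(test_idx.tolist())

    def test_full_rank_ipca_matches_plain_rf(self, small_dataset):
        """Full-rank orthogonal projection preserves the information the forest sees."""
        table = small_dataset.features
        p = table.features.shape[1]
        with_ipca = cross_validate(PipelineSpec(True, k=p, n_components=p,
                                                rf=RFConfig(100, seed=0)),
                                   table, folds=5, seed=0).mean_auc
        without = cross_validate(PipelineSpec(False, rf=RFConfig(100, seed=0)),
                                 table, folds=5, seed=0).mean_auc
        assert abs(with_ipca - without) < 0.05

    def test_report_structure(self, small_dataset):
        rep = cross_validate(PipelineSpec(rf=RFConfig(30, seed=0)),
                             small_dataset.features, folds=5, seed=0)
        assert len(rep.per_fold) == 5
        assert set(rep.aggregate) == {"accuracy", "precision", "recall", "f1", "auc"}
        d = rep.to_dict()
        assert d["config"]["folds"] == 5


class TestGridSearch:
    def test_single_element_grid(self, small_dataset):
        best, table = grid_search_n_estimators(small_dataset.features, grid=[37],
                                               folds=3, seed=0)
        assert best == 37 and set(table) == {37}

    def test_best_attains_table_max_and_tie_breaks_small(self, small_dataset):
        best, table = grid_search_n_estimators(small_dataset.features,
                                               grid=[20, 40, 60], folds=3, seed=0)
        assert best in table
        assert table[best] == max(table.values())
        assert best == min(n for n, v in table.items() if v == table[best])

    def test_empty_grid_errors(self, small_dataset):
        with pytest.raises(ValueError):
            grid_search_n_estimators(small_dataset.features, grid=[])


class TestRankCandidates:
    def test_ranking_covers_all_zero_cells_and_excludes_positives(self, small_dataset):
        from ipcarf import fit_final_model
        ds = small_dataset
        spec = PipelineSpec(rf=RFConfig(50, seed=0))
        reducer, clf = fit_final_model(spec, ds.features, seed=0)
        disease = ds.associations.dis_labels[0]
        ranking = rank_candidates(clf, disease, ds.associations,
                                  ds.sim_lnc, ds.sim_dis, reducer)
        j = ds.associations.dis_index(disease)
        n_zero = int((ds.associations.values[:, j] == 0).sum())
        assert len(ranking) == n_zero
        positives = {ds.associations.lnc_labels[i]
                     for i in np.flatnonzero(ds.associations.values[:, j])}
        assert not positives & {l for l, _ in ranking}
        scores = [s for _, s in ranking]
        assert scores == sorted(scores, reverse=True)

    def test_unknown_disease_errors(self, small_dataset):
        from ipcarf import fit_final_model
        spec = PipelineSpec(rf=RFConfig(10, seed=0))
        reducer, clf = fit_final_model(spec, small_dataset.features, seed=0)
        with pytest.raises(KeyError):
            rank_candidates(clf, "no such disease", small_dataset.associations,
                            small_dataset.sim_lnc, small_dataset.sim_dis, reducer)
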