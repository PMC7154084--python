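"""Splits, confusion/accuracy, ROC-AUC, chance level, t-tests, pipeline."""

import numpy as np
import pytest
from scipy import stats

from megdecode import evaluate, scalograms, synth


class TestSplitData:
    def _ids_labels(self, n_per_class=100, n_classes=5):
        ids = [f"t{i}" for i in range(n_per_class * n_classes)]
        labels = np.repeat(np.arange(n_classes), n_per_class)
        return ids, labels

    def test_ratio_arithmetic_70_15_15(self):
        ids, labels = self._ids_labels()
        plan = evaluate.split_data(ids, labels, seed=0)
        for rep in range(3):
            sizes = {s: len(plan.ids_in(rep, s)) for s in evaluate.SPLITS}
            assert sizes == {"train": 350, "val": 75, "test": 75}

    def test_stratification_within_one_trial(self):
        ids, labels = self._ids_labels(n_per_class=21, n_classes=3)
        plan = evaluate.split_data(ids, labels, seed=1)
        lab_of = dict(zip(ids, labels))
        for rep in range(3):
            for split, frac in zip(evaluate.SPLITS, (0.7, 0.15, 0.15)):
                got = [lab_of[t] for t in plan.ids_in(rep, split)]
                for c in range(3):
                    assert abs(got.count(c) - frac * 21) <= 1

    def test_deterministic_under_seed(self):
        ids, labels = self._ids_labels(10, 2)
        a = evaluate.split_data(ids, labels, seed=5)
        b = evaluate.split_data(ids, labels, seed=5)
        assert a.assignment == b.assignment

    def test_augmented_children_never_straddle_splits(self):
        ids, labels = self._ids_labels(10, 2)
        parents = {}
        aug_ids, aug_labels = list(ids), list(labels)
        for tid, lab in zip(ids, labels):
            for s in (100, 200):
                cid = f"{tid}_sh{s}"
                aug_ids.append(cid)
                aug_labels.append(lab)
                parents[cid] = tid
        plan = evaluate.split_data(aug_ids, np.asarray(aug_labels), seed=2,
                                   parents=parents)
        for child, parent in parents.items():  # exhaustive audit
            assert plan.assignment[child] == plan.assignment[parent]

    def test_small_class_warns(self):
        with pytest.warns(UserWarning, match="stratify"):
            evaluate.split_data(["a", "b"], np.array([0, 0]), seed=0)


# printed confusion counts from the published study, used as input data
TABLE2 = np.array([
    [1332, 12, 19, 11, 8],
    [10, 1338, 14, 11, 9],
    [21, 8, 1331, 12, 10],
    [12, 15, 12, 1337, 6],
    [7, 12, 14, 7, 1342],
])


class TestConfusionAndAccuracy:
    def test_published_confusion_counts_reproduce_accuracies(self):
        cm = evaluate.ConfusionMatrix(counts=TABLE2, class_labels=list(range(5)))
        per_class = np.round(cm.per_class_accuracy, 2)
        np.testing.assert_array_equal(
            per_class, [96.38, 96.82, 96.31, 96.74, 97.11])
        assert round(cm.average_accuracy, 2) == 96.67

    def test_perfect_predictions_diagonal(self):
        y = np.array([0, 1, 2, 1, 0, 2])
        cm = evaluate.confusion_and_accuracy(y, y, 3)
        assert np.all(cm.counts == np.diag([2, 2, 2]))
        assert cm.average_accuracy == 100.0
        assert cm.overall_accuracy == 100.0

    def test_matches_brute_force_tally(self, rng):
        y_true = rng.integers(0, 4, 200)
        y_pred = rng.integers(0, 4, 200)
        cm = evaluate.confusion_and_accuracy(y_true, y_pred, 4)
        brute = np.zeros((4, 4), dtype=int)
        for t, p in zip(y_true, y_pred):  # tally-loop oracle
            brute[t, p] += 1
        np.testing.assert_array_equal(cm.counts, brute)
        np.testing.assert_array_equal(cm.counts.sum(axis=1),
                                      np.bincount(y_true, minlength=4))

    def test_overall_equals_weighted_mean_of_per_class(self, rng):
        y_true = rng.integers(0, 3, 150)
        y_pred = rng.integers(0, 3, 150)
        cm = evaluate.confusion_and_accuracy(y_true, y_pred, 3)
        w = cm.counts.sum(axis=1) / cm.counts.sum()
        assert cm.overall_accuracy == pytest.approx(
            np.sum(w * cm.per_class_accuracy))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            evaluate.confusion_and_accuracy([], [], 3)


class TestRocAucOvr:
    def test_perfectly_separated_scores(self):
        y = np.array([0, 0, 1, 1, 2, 2])
        scores = np.eye(3)[y] * 0.9 + 0.05
        aucs, macro, undef = evaluate.roc_auc_ovr(scores, y)
        np.testing.assert_allclose(aucs, 1.0)
        assert macro == 1.0 and undef == []

    def test_label_independent_scores_near_half(self, rng):
        y = rng.integers(0, 4, 2000)
        scores = rng.dirichlet(np.ones(4), size=2000)
        _, macro, _ = evaluate.roc_auc_ovr(scores, y)
        assert macro == pytest.approx(0.5, abs=0.03)

    def test_toy_scores_match_concordance_count(self):
        """AUC equals the exhaustive pairwise concordance fraction."""
        y = np.array([1, 0, 1, 0, 1, 0])
        s1 = np.array([0.9, 0.8, 0.7, 0.3, 0.55, 0.2])
        scores = np.column_stack([1 - s1, s1])
        aucs, _, _ = evaluate.roc_auc_ovr(scores, y)
        pos, neg = s1[y == 1], s1[y == 0]
        conc = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert aucs[1] == pytest.approx(conc / (len(pos) * len(neg)))

    def test_absent_class_flagged(self):
        y = np.array([0, 0, 1, 1])
        scores = np.full((4, 3), 1 / 3)
        aucs, _, undef = evaluate.roc_auc_ovr(scores, y)
        assert undef == [2] and np.isnan(aucs[2])


class TestChanceLevel:
    @pytest.mark.parametrize("n,k", [(60, 5), (300, 5), (75, 5)])
    def test_monte_carlo_oracle(self, n, k):
        """Exact binomial inversion agrees with a 1e5-draw simulation."""
        rng = np.random.default_rng(123)
        draws = rng.binomial(n, 1 / k, size=100_000)
        # smallest accuracy whose estimated exceedance prob <= 0.05
        mc = next(100 * c / n for c in range(n + 1)
                  if np.mean(draws >= c) <= 0.05)
        exact = evaluate.chance_level(n, k, alpha=0.05)
        assert abs(exact - mc) <= 0.5

    def test_large_n_approaches_1_over_k(self):
        assert evaluate.chance_level(10**6, 5) == pytest.approx(20.0, abs=0.1)

    def test_single_trial_needs_perfection(self):
        assert evaluate.chance_level(1, 5) == 100.0

    def test_monotone_in_n_and_floor(self):
        vals = [evaluate.chance_level(n, 5) for n in (20, 60, 150, 400, 1000)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))
        assert all(v >= 100 / 5 for v in vals)

    def test_alpha_validated(self):
        with pytest.raises(ValueError):
            evaluate.chance_level(100, 5, alpha=1.5)


class TestCompareMethods:
    def test_identical_arrays_give_p_one(self):
        a = np.array([70.0, 72.0, 68.0])
        res = evaluate.compare_methods(a, a)
        assert res["t"] == 0.0 and res["p"] == 1.0
        assert "flag" in res

    def test_constant_offset_significant(self, rng):
        b = 70 + 0.01 * rng.standard_normal(8)
        a = b + 5.0
        res = evaluate.compare_methods(a, b)
        assert res["p"] < 0.001

    def test_four_element_hand_computation(self):
        a = np.array([80.0, 85.0, 78.0, 90.0])
        b = np.array([75.0, 80.0, 77.0, 84.0])
        d = a - b
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        res = evaluate.compare_methods(a, b)
        assert res["t"] == pytest.approx(t_hand)
        p_hand = 2 * stats.t.sf(abs(t_hand), df=3)
        assert res["p"] == pytest.approx(p_hand)

    def test_one_tail_against_chance(self):
        accs = np.array([55.0, 60.0, 58.0])
        res = evaluate.compare_methods(accs, chance=30.0)
        assert res["test"] == "1sample-1tail" and res["p"] < 0.01

    def test_exactly_one_comparison_mode(self):
        with pytest.raises(ValueError):
            evaluate.compare_methods(np.ones(3))

    def test_holm_correction_monotone(self):
        adj = evaluate.holm_correct([0.01, 0.04, 0.03])
        assert adj[0] == pytest.approx(0.03)
        assert all(0 <= p <= 1 for p in adj)


@pytest.fixture(scope="module")
def tiny_trials():
    cfg = synth.SynthConfig(
        n_channels=6, n_trials_per_class=12, n_classes=5, seed=21,
        stage_snr={"pre": 0.0, "perception": 0.4, "preparation": 0.7,
                   "production": 1.2})
    return synth.generate_dataset(cfg)


class TestRunPipeline:
    def test_unknown_method_and_stage_rejected(self, tiny_trials):
        with pytest.raises(ValueError, match="method"):
            evaluate.run_pipeline(tiny_trials, "production", "svm")
        with pytest.raises(ValueError, match="stage"):
            evaluate.run_pipeline(tiny_trials, "sleep", "ann")

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            evaluate.run_pipeline([], "production", "ann")

    def test_ann_production_above_chance_pre_at_chance(self, tiny_trials):
        rep_prod = evaluate.run_pipeline(tiny_trials, "production", "ann",
                                         seed=3, n_repeats=2, lowpass=False)
        rep_pre = evaluate.run_pipeline(tiny_trials, "pre", "ann",
                                        seed=3, n_repeats=2, lowpass=False)
        assert rep_prod.mean_accuracy > rep_prod.chance_level_pct
        n = rep_pre.n_test_per_repeat * 2
        lo, hi = evaluate.binomial_chance_interval(n, 5, conf=0.99)
        assert lo <= rep_pre.mean_accuracy <= hi
        assert rep_prod.macro_auc > 0.9

    def test_st_cnn_runs_and_aggregates(self, tiny_trials):
        from megdecode import decoders
        cfg = decoders.CnnConfig(input_size=(16, 16, 3), output_classes=5,
                                 seed=0, max_epochs=2)
        rep = evaluate.run_pipeline(tiny_trials[:30], "production", "st_cnn",
                                    seed=1, n_repeats=1, lowpass=False,
                                    img_px=16, n_freqs=16, cnn_cfg=cfg)
        assert rep.confusion.sum() == rep.n_test_per_repeat
        assert 0 <= rep.mean_accuracy <= 100

    def test_sst_pipeline_augments_and_reports(self, tiny_trials):
        from megdecode import decoders
        cfg = decoders.CnnConfig(input_size=(24, 24, 3), output_classes=5,
                                 seed=0, max_epochs=2, first_kernel=5)
        rep = evaluate.run_pipeline(tiny_trials[:30], "production", "sst_cnn",
                                    seed=1, n_repeats=1, lowpass=False,
                                    tile_px=8, n_freqs=16, cnn_cfg=cfg)
        assert rep.params["augment"] is True
        # test rows only count original trials
        assert rep.confusion.sum() == rep.n_test_per_repeat

    def test_report_serialization(self, tiny_trials):
        rep = evaluate.run_pipeline(tiny_trials, "production", "ann",
                                    seed=3, n_repeats=2, lowpass=False)
        js = rep.to_json()
        assert '"mean_accuracy"' in js
        md = rep.to_markdown()
        assert "chance level" in md


def test_label_shuffle_calibration_across_seeds():
    """On label-shuffled data the decoder stays below the chance threshold
    in nearly all seeds (the protocol's false-positive guard)."""
    cfg = synth.SynthConfig(
        n_channels=4, n_trials_per_class=20, n_classes=2, seed=5,
        stage_snr={"pre": 0, "perception": 0, "preparation": 0,
                   "production": 1.0})
    trials = synth.generate_dataset(cfg)
    from megdecode import decoders, wavelets
    X = np.array([wavelets.rms_features(wavelets.dwt_bands(t),
                                        "production").values for t in trials])
    y = np.array([t.label for t in trials])
    below = 0
    n_seeds = 10
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        ys = rng.permutation(y)
        idx = rng.permutation(len(y))
        tr, va, te = idx[:28], idx[28:34], idx[34:]
        cfg_a = decoders.AnnConfig(input_dim=X.shape[1], output_classes=2,
                                   seed=seed, max_epochs=30)
        m = decoders.train_ann(X[tr], ys[tr], X[va], ys[va], cfg_a)
        acc = 100 * np.mean(m.predict(X[te]) == ys[te])
        if acc < evaluate.chance_level(len(te), 2):
            below += 1
    assert below >= 0.8 * n_seeds
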