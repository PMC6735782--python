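"""Training dynamics, grid search, prediction composition, serialization."""

import numpy as np
import pytest

from endjoin.distributions import OutcomeDistribution
from endjoin.model import (DEFAULT_LAMBDA_GRID, ModelConfig, ModelError,
                           RepairOutcomeModel, RepairOutcomeResults,
                           aggregate_baseline, fit_insertion_proportion,
                           grid_search, insertion_proportion_hexamer,
                           predict_full, predict_probs, train_component)
from endjoin.simulator import simulate_dataset, simulate_targets


@pytest.fixture(scope="module")
def tiny_fit():
    """A small fitted model shared by the prediction/serialization tests."""
    ds = simulate_dataset(40, 200, seed=11)
    dists = [OutcomeDistribution.from_counts(
        {e: c for e, c in r.counts.items() if c > 0}) for r in ds.records]
    model = RepairOutcomeModel(ds.targets, dists)
    res = model.fit(l2_grid=[1e-4], val_fraction=0.2, seed=3)
    return ds, model, res


class TestTrainComponent:
    def test_unregularized_fit_converges_to_the_soft_label(self):
        # cross-entropy against a (0.7, 0.3) soft label is minimized when
        # the predicted distribution equals the label
        X = np.ones((1, 1))
        Y = np.array([[0.7, 0.3]])
        cfg = ModelConfig(lam=0.0, learning_rate=0.05, max_epochs=3000)
        W, _ = train_component(X, Y, cfg)
        P = predict_probs(X, W)[0]
        assert P == pytest.approx([0.7, 0.3], abs=1e-3)

    def test_zero_weights_predict_uniform(self):
        W = np.zeros((5, 4))
        P = predict_probs(np.zeros((3, 4)), W)
        assert np.allclose(P, 0.25)

    def test_larger_l2_penalty_shrinks_weights(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 2, size=(30, 10)).astype(float)
        logits = X @ rng.normal(size=(10, 3))
        Y = np.exp(logits) / np.exp(logits).sum(1, keepdims=True)
        small, _ = train_component(X, Y, ModelConfig(penalty="l2", lam=1e-10))
        large, _ = train_component(X, Y, ModelConfig(penalty="l2", lam=1e-1))
        assert np.linalg.norm(large[:-1]) < np.linalg.norm(small[:-1])

    def test_training_loss_decreases_initially(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 2, size=(20, 6)).astype(float)
        Y = rng.dirichlet(np.ones(3), size=20)
        _, hist = train_component(X, Y, ModelConfig(lam=0.0, max_epochs=20,
                                                    batch_size=None))
        losses = [h["train_loss"] for h in hist]
        assert all(b <= a + 1e-12 for a, b in zip(losses, losses[1:]))

    def test_soft_labels_must_sum_to_one(self):
        with pytest.raises(ModelError):
            train_component(np.ones((2, 1)), np.array([[0.5, 0.4]] * 2),
                            ModelConfig())

    def test_empty_training_set_rejected(self):
        with pytest.raises(ModelError):
            train_component(np.zeros((0, 3)), np.zeros((0, 2)), ModelConfig())

    def test_early_stopping_restores_best_epoch(self):
        rng = np.random.default_rng(2)
        X = rng.integers(0, 2, size=(20, 4)).astype(float)
        Y = rng.dirichlet(np.ones(2), size=20)
        Xv = rng.integers(0, 2, size=(8, 4)).astype(float)
        Yv = rng.dirichlet(np.ones(2), size=8)
        W, hist = train_component(X, Y, ModelConfig(lam=0.0, patience=1),
                                  Xv, Yv)
        vals = [h["val_loss"] for h in hist]
        # stopping fires after patience+1 = 2 non-improving epochs
        best = min(vals)
        assert vals.index(best) >= len(vals) - 3


class TestGridSearch:
    def test_single_config_grid_returns_it(self):
        X = np.ones((4, 2))
        Y = np.tile([0.5, 0.5], (4, 1))
        cfg = ModelConfig(penalty="l1", lam=1e-3)
        best, _, log = grid_search(X, Y, X, Y, [cfg])
        assert best == cfg
        assert len(log) == 1

    def test_log_has_one_entry_per_config(self):
        X = np.ones((4, 2))
        Y = np.tile([0.5, 0.5], (4, 1))
        configs = [ModelConfig(lam=l) for l in (1e-8, 1e-5, 1e-2)]
        _, _, log = grid_search(X, Y, X, Y, configs)
        assert len(log) == 3

    def test_ties_resolve_to_the_larger_penalty(self):
        # all-zero features leave only the (unpenalised) bias active, so
        # every lambda yields identical validation MSE
        X = np.zeros((6, 3))
        Y = np.tile([0.3, 0.7], (6, 1))
        configs = [ModelConfig(lam=1e-9), ModelConfig(lam=1e-3)]
        best, _, _ = grid_search(X, Y, X, Y, configs)
        assert best.lam == 1e-3

    def test_default_grid_spans_the_printed_range(self):
        assert DEFAULT_LAMBDA_GRID[0] == 1e-10
        assert DEFAULT_LAMBDA_GRID[-1] == 1e-1

    def test_l1_selects_meaningful_penalty_with_noise_features(self):
        rng = np.random.default_rng(7)
        n = 80
        signal = rng.integers(0, 2, size=(n, 1)).astype(float)
        noise = rng.integers(0, 2, size=(n, 40)).astype(float)
        X = np.hstack([signal, noise])
        p = 0.2 + 0.6 * signal[:, 0]
        Y = np.column_stack([1 - p, p])
        configs = [ModelConfig(penalty="l1", lam=l, max_epochs=100)
                   for l in (1e-10, 1e-4, 1e-2)]
        best, _, _ = grid_search(X[:60], Y[:60], X[60:], Y[60:], configs)
        assert best.lam > 1e-10


class TestPrediction:
    def test_prediction_is_a_distribution(self, tiny_fit):
        ds, _, res = tiny_fit
        d = res.predict(ds.targets[0])
        assert d.is_normalized()
        assert all(p >= 0 for p in d.probs.values())

    def test_insertion_mass_equals_ratio_component(self, tiny_fit):
        ds, _, res = tiny_fit
        t = ds.targets[1]
        p_ins, _, _ = res.predict_components(t)
        d = res.predict(t)
        got = sum(p for e, p in d.probs.items() if e.startswith("I:"))
        assert got == pytest.approx(p_ins, abs=1e-9)

    def test_collapsing_preserves_total_deletion_mass(self, tiny_fit):
        ds, _, res = tiny_fit
        t = ds.targets[2]
        p_ins, p_del, _ = res.predict_components(t)
        d = res.predict(t)
        del_mass = sum(p for e, p in d.probs.items() if e.startswith("D:"))
        assert del_mass == pytest.approx((1 - p_ins) * p_del.sum(), abs=1e-9)

    def test_prediction_is_deterministic(self, tiny_fit):
        ds, _, res = tiny_fit
        a = res.predict(ds.targets[3]).probs
        b = res.predict(ds.targets[3]).probs
        assert a == b

    def test_predict_full_alias(self, tiny_fit):
        ds, _, res = tiny_fit
        assert predict_full(ds.targets[0], res).probs == \
            res.predict(ds.targets[0]).probs


class TestSerialization:
    def test_json_round_trip_is_lossless(self, tiny_fit, tmp_path):
        ds, _, res = tiny_fit
        path = tmp_path / "model.json"
        res.save(path)
        back = RepairOutcomeResults.load(path)
        assert np.array_equal(back.deletion_weights, res.deletion_weights)
        assert back.predict(ds.targets[0]).probs == \
            res.predict(ds.targets[0]).probs

    def test_version_mismatch_refused(self, tiny_fit, tmp_path):
        import json
        _, _, res = tiny_fit
        path = tmp_path / "model.json"
        res.save(path)
        doc = json.loads(path.read_text())
        doc["schema_version"] = "other-schema"
        path.write_text(json.dumps(doc))
        with pytest.raises(ModelError):
            RepairOutcomeResults.load(path)

    def test_summary_mentions_all_components(self, tiny_fit):
        _, _, res = tiny_fit
        text = res.summary()
        for name in ("ratio", "deletion", "insertion"):
            assert name in text


class TestAggregateBaseline:
    def test_pooling_weights_by_support(self):
        a = OutcomeDistribution({"I:A": 1.0}, total_support=300)
        b = OutcomeDistribution({"I:C": 1.0}, total_support=100)
        agg = aggregate_baseline([a, b])
        assert agg.probs["I:A"] == pytest.approx(0.75)
        assert agg.probs["I:C"] == pytest.approx(0.25)


class TestInsertionProportionRegression:
    def test_constant_labels_fit_the_intercept(self):
        hexs = ["ACGTAC", "TTTTTT", "GGGCCC", "ATGCAT"]
        w = fit_insertion_proportion(hexs, np.full(4, 0.3))
        for h in ("CCCGGG", "ACACAC"):
            assert insertion_proportion_hexamer(h, w) == pytest.approx(0.3, abs=1e-6)

    def test_t_at_cut_minus_one_gets_positive_weight(self):
        # simulate targets whose insertion proportion rises when the base
        # 5' of the cut (hexamer position 2) is T
        rng = np.random.default_rng(5)
        targets = simulate_targets(300, 17)
        hexs = [t.hexamer() for t in targets]
        y = np.array([0.45 if h[2] == "T" else 0.25 for h in hexs])
        y = y + rng.normal(0, 0.02, size=len(y))
        w = fit_insertion_proportion(hexs, y)
        from endjoin.features import hexamer_schema
        idx = hexamer_schema().index("hex_mono_2_T")
        assert w[idx] > 0

    def test_predictions_clip_to_unit_interval(self):
        w = np.zeros(105)
        w[-1] = -0.5  # negative intercept
        assert insertion_proportion_hexamer("ACGTAC", w) == 0.0
        w[-1] = 1.5
        assert insertion_proportion_hexamer("ACGTAC", w) == 1.0


class TestFromCounts:
    def test_dataframe_constructor(self):
        import pandas as pd
        targets = simulate_targets(2, 23)
        df = pd.DataFrame({
            "target_id": [targets[0].target_id, targets[0].target_id,
                          targets[1].target_id],
            "event_id": ["I:A", "D:0:2", "I:TG"],
            "umi_count": [30, 70, 10]})
        model = RepairOutcomeModel.from_counts(targets, df)
        assert model.distributions[0].probs["D:0:2"] == pytest.approx(0.7)

    def test_missing_target_rejected(self):
        targets = simulate_targets(2, 29)
        with pytest.raises(ModelError):
            RepairOutcomeModel.from_counts(
                targets, {targets[0].target_id: {"I:A": 5}})
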