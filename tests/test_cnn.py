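"""The histogram regression network: exact gradients, optimization sanity,
corpus construction rules and evaluation metrics."""

import numpy as np
import pytest

from antibunch import (
    CorrelationHistogram,
    G2Regressor,
    HistogramFormat,
    LabeledHistogram,
    ModelSpec,
    TrainConfig,
    build_training_corpus,
    corpus_arrays,
    draw_scenarios,
    evaluate,
    predict_g2,
    split_by_scenario,
)
from antibunch.corpus import (
    DARK_EVENT_THRESHOLD,
    G2_HI,
    G2_LO,
    N1S_HI,
    N1S_LO,
    _n1s_of_label,
    focal_expected_histogram,
    simulate_eval_items,
)
from antibunch.nn.layers import mape_loss


TINY = ModelSpec(input_bins=16, conv_layers=2, filters_per_layer=4, kernel_size=4,
                 pool_size=2, dropout_rate=0.0, fc_sizes=(8, 6, 4))


def _tiny_batch(rng, n=6, bins=16):
    x = rng.poisson(2.0, size=(n, bins)).astype(np.float64)
    return x, x.sum(axis=1), rng.uniform(0.2, 0.9, size=n)


class TestNetworkMechanics:
    def test_default_topology_matches_published_shape(self):
        m = G2Regressor(ModelSpec(), seed=0)
        assert len(m.convs) == 3
        assert all(c.c_out == 260 and c.k == 4 for c in m.convs)
        assert len(m.fcs) == 3
        # flattened features: 107 pooled positions x 260 filters, + N_events
        assert m.fcs[0].W.shape[0] == 107 * 260 + 1

    def test_forward_output_shape_and_clamp(self, rng):
        m = G2Regressor(TINY, seed=1)
        x, ne, _ = _tiny_batch(rng)
        out = m.predict(x, ne)
        assert out.shape == (6,)
        assert np.all((out >= 0.0) & (out <= 1.5))

    def test_wrong_bin_count_rejected(self, rng):
        m = G2Regressor(TINY, seed=1)
        with pytest.raises(ValueError):
            m.forward(np.zeros((2, 10)), np.zeros(2))

    def test_analytic_gradients_match_finite_differences(self, rng):
        """Backpropagation through conv/pool/concat/dense agrees with
        central finite differences to float64 precision."""
        m = G2Regressor(TINY, seed=3, dtype=np.float64)
        x, ne, y = _tiny_batch(rng)
        pred = m.forward(x, ne, train=True)
        _, dpred = mape_loss(pred, y)
        m.backward(dpred)
        grads = [g.copy() for g in m.gradients()]
        eps = 1e-6
        check_rng = np.random.default_rng(0)
        for gi, p in enumerate(m.parameters()):
            flat = p.ravel()
            for i in check_rng.choice(flat.size, size=min(5, flat.size), replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                up, _ = mape_loss(m.forward(x, ne), y)
                flat[i] = orig - eps
                dn, _ = mape_loss(m.forward(x, ne), y)
                flat[i] = orig
                num = (up - dn) / (2 * eps)
                ana = grads[gi].ravel()[i]
                assert ana == pytest.approx(num, rel=1e-4, abs=1e-8)

    def test_training_reduces_loss_and_memorizes_single_sample(self, rng):
        m = G2Regressor(TINY, seed=2)
        x = rng.poisson(3.0, size=(1, 16)).astype(np.float32)
        ne = x.sum(axis=1)
        y = np.array([0.4], dtype=np.float32)
        hist = m.fit(x, ne, y, TrainConfig(epochs=150, batch_size=1, seed=0))
        assert hist.train_loss[-1] < hist.train_loss[0]
        assert hist.train_loss[-1] < 3.0  # single sample is memorized
        assert m.predict(x, ne)[0] == pytest.approx(0.4, abs=0.05)

    def test_save_load_round_trip_is_bit_identical(self, tmp_path, rng):
        m = G2Regressor(TINY, seed=4)
        x, ne, _ = _tiny_batch(rng)
        path = tmp_path / "model.npz"
        m.save(path)
        m2 = G2Regressor.load(path)
        np.testing.assert_array_equal(m.predict(x, ne), m2.predict(x, ne))

    def test_empty_corpus_rejected(self):
        m = G2Regressor(TINY, seed=0)
        with pytest.raises(ValueError):
            m.fit(np.zeros((0, 16)), np.zeros(0), np.zeros(0), TrainConfig())

    def test_mape_requires_positive_targets(self):
        with pytest.raises(ValueError):
            mape_loss(np.array([0.5]), np.array([0.0]))


class TestScenarioBank:
    def test_envelope_is_respected(self):
        bank = draw_scenarios(seed=0)
        emitters = [s for s in bank if not s.is_dark]
        assert len(emitters) == 40
        for s in emitters:
            assert G2_LO <= s.label <= G2_HI
            n1s = float(_n1s_of_label(s.label))
            assert N1S_LO - 1e-9 <= n1s <= N1S_HI + 1e-9
            assert s.signal_rate > 0 and s.background_rate > 0

    def test_scenarios_reproduce_their_label_exactly(self):
        from antibunch import mixed_g2

        for s in draw_scenarios(seed=5):
            if s.is_dark:
                assert s.label == 1.0
            else:
                assert mixed_g2(s.signal_rate, s.background_rate,
                                s.params.g2_zero) == pytest.approx(s.label)

    def test_brightness_anticorrelates_with_label(self):
        bank = [s for s in draw_scenarios(seed=2) if not s.is_dark]
        labels = np.array([s.label for s in bank])
        totals = np.array([s.signal_rate + s.background_rate for s in bank])
        assert np.corrcoef(labels, np.log(totals))[0, 1] < -0.95


@pytest.fixture(scope="module")
def small_corpus():
    bank = draw_scenarios(n_emitters=6, n_dark=1, seed=7)
    items = build_training_corpus(bank, increments_per_scenario=12, seed=7)
    return bank, items


class TestCorpus:

    def test_composite_durations_span_5_to_10s(self, small_corpus):
        _, items = small_corpus
        times = {it.histogram.acquisition_time for it in items}
        assert times == {5.0, 6.0, 7.0, 8.0, 9.0, 10.0}

    def test_dark_items_carry_label_one(self, small_corpus):
        _, items = small_corpus
        for it in items:
            if it.histogram.n_events < DARK_EVENT_THRESHOLD:
                assert it.label == 1.0

    def test_labels_match_scenarios_otherwise(self, small_corpus):
        bank, items = small_corpus
        by_id = {s.scenario_id: s for s in bank}
        for it in items:
            if it.histogram.n_events >= DARK_EVENT_THRESHOLD:
                assert it.label == by_id[it.scenario_id].label

    def test_split_is_emitter_stratified_with_no_leakage(self):
        bank = draw_scenarios(seed=0)
        train, val, test = split_by_scenario(bank)
        ids = lambda part: {s.scenario_id for s in part}
        assert ids(train) & ids(val) == set()
        assert ids(train) & ids(test) == set()
        assert ids(val) & ids(test) == set()
        assert len(train) + len(val) + len(test) == len(bank)
        # held-out parts span the label range rather than clustering
        for part in (val, test):
            labels = sorted(s.label for s in part)
            assert labels[0] < 0.45 and labels[-1] > 0.6

    def test_corpus_determinism_under_seed(self):
        bank = draw_scenarios(n_emitters=3, n_dark=0, seed=9)
        a = build_training_corpus(bank, increments_per_scenario=10, seed=9)
        b = build_training_corpus(bank, increments_per_scenario=10, seed=9)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.histogram.counts, y.histogram.counts)

    def test_focal_expectation_sits_in_event_envelope(self):
        bank = [s for s in draw_scenarios(seed=3) if not s.is_dark]
        for s in bank:
            total = focal_expected_histogram(s, HistogramFormat(), 1.0).sum()
            # expected 1 s totals track the envelope (curve dip lowers the
            # brightest slightly below the flat-rate value)
            assert 0.8 <= total <= 65.0


class TestEvaluation:
    def test_perfect_and_constant_predictors(self, toy_fmt):
        labels = np.array([0.2, 0.4, 0.6, 0.8], dtype=np.float32)

        class Fake:
            def __init__(self, out):
                self.out = np.asarray(out, dtype=np.float32)

            def predict(self, bins, ne):
                return self.out

        items = [
            LabeledHistogram(
                histogram=CorrelationHistogram(counts=[1, 1, 1], format=toy_fmt),
                label=float(l), scenario_id=i)
            for i, l in enumerate(labels)
        ]
        perfect = evaluate(Fake(labels), items)
        assert perfect.mape == pytest.approx(0.0)
        assert perfect.r2 == pytest.approx(100.0)
        assert perfect.rmse == pytest.approx(0.0)
        constant = evaluate(Fake(np.full(4, labels.mean())), items)
        assert constant.r2 == pytest.approx(0.0, abs=1e-6)

    def test_hand_computed_mape(self, toy_fmt):
        # items {(y=0.5, yhat=0.4), (y=0.2, yhat=0.25)} -> (20% + 25%) / 2
        from antibunch.corpus import _report

        rep = _report(np.array([0.4, 0.25]), np.array([0.5, 0.2]))
        assert rep.mape == pytest.approx(22.5)

    def test_order_invariance(self, toy_fmt, rng):
        m = G2Regressor(ModelSpec(input_bins=3, conv_layers=1, filters_per_layer=2,
                                  kernel_size=2, pool_size=1, fc_sizes=(4, 3, 2)), seed=0)
        items = [
            LabeledHistogram(
                histogram=CorrelationHistogram(counts=rng.poisson(2.0, 3), format=toy_fmt),
                label=float(l), scenario_id=i)
            for i, l in enumerate(rng.uniform(0.2, 0.9, size=8))
        ]
        a = evaluate(m, items)
        b = evaluate(m, items[::-1])
        assert a.mape == pytest.approx(b.mape)
        assert a.r2 == pytest.approx(b.r2)

    def test_predict_g2_single_histogram(self, rng):
        m = G2Regressor(TINY, seed=0)
        fmt = HistogramFormat(n_bins=16, span=100.0, zero_bin_index=8)
        h = CorrelationHistogram(counts=rng.poisson(2.0, 16), format=fmt)
        v = predict_g2(m, h)
        assert 0.0 <= v <= 1.5
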