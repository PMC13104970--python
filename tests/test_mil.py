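"""Quantile aggregation, bag-level prediction, loss and training dynamics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import milniche as mn
from milniche.mil import PROB_CLAMP
from tests.conftest import make_crop


def brute_force_quantiles(values, Q):
    """Independent re-statement of the rank-selection rule on a sorted list."""
    values = sorted(values)
    n = len(values)
    out = []
    for q in range(1, Q + 1):
        idx = math.ceil(n * (q - 0.5) / Q)
        idx = min(max(idx, 1), n)
        out.append(values[idx - 1])
    return out


class TestQuantileIndex:
    def test_printed_examples(self):
        assert [mn.quantile_index(10, q, 5) for q in range(1, 6)] == [1, 3, 5, 7, 9]
        assert mn.quantile_index(1, 3, 4) == 1
        assert mn.quantile_index(7, 4, 4) == 7  # ceil(7 * 3.5 / 4) = 7

    def test_bounds_and_monotonicity(self):
        for n in (1, 2, 5, 17):
            for Q in (1, 3, 8):
                idxs = [mn.quantile_index(n, q, Q) for q in range(1, Q + 1)]
                assert all(1 <= i <= n for i in idxs)
                assert idxs == sorted(idxs)

    def test_out_of_range_q(self):
        with pytest.raises(ValueError):
            mn.quantile_index(5, 0, 4)
        with pytest.raises(ValueError):
            mn.quantile_index(5, 5, 4)


class TestQuantileAggregate:
    def test_decile_example(self):
        values = np.round(np.arange(0.1, 1.01, 0.1), 10)
        out = mn.quantile_aggregate(values, 5)
        np.testing.assert_allclose(out, [0.1, 0.3, 0.5, 0.7, 0.9])

    def test_constant_list(self):
        out = mn.quantile_aggregate(np.full(7, 0.4), 3)
        np.testing.assert_allclose(out, [0.4, 0.4, 0.4])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mn.quantile_aggregate(np.array([]), 3)

    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30),
        st.integers(1, 8),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_and_is_subset(self, values, Q):
        values = np.sort(np.asarray(values))
        out = mn.quantile_aggregate(values, Q)
        np.testing.assert_array_equal(out, brute_force_quantiles(values, Q))
        assert all(v in values for v in out)
        assert np.all(np.diff(out) >= 0)


class TestMaskFilter:
    def test_sorts_all_valid_values(self):
        probs = np.zeros((2, 2, 2))
        probs[:, :, 1] = [[0.9, 0.1], [0.5, 0.3]]
        probs[:, :, 0] = 1 - probs[:, :, 1]
        pmap = mn.ProbabilityMap(probs=probs, valid=np.ones((2, 2), bool))
        np.testing.assert_allclose(mn.mask_filter(pmap, 1), [0.1, 0.3, 0.5, 0.9])

    def test_filters_then_sorts(self):
        probs = np.zeros((2, 2, 2))
        probs[:, :, 1] = [[0.9, 0.1], [0.5, 0.3]]
        valid = np.array([[True, True], [False, False]])
        pmap = mn.ProbabilityMap(probs=probs, valid=valid)
        np.testing.assert_allclose(mn.mask_filter(pmap, 1), [0.1, 0.9])

    def test_output_length_equals_valid_count(self):
        rng = np.random.default_rng(0)
        probs = rng.dirichlet(np.ones(3), size=(6, 6)).reshape(6, 6, 3)
        valid = rng.uniform(size=(6, 6)) > 0.5
        pmap = mn.ProbabilityMap(probs=probs, valid=valid)
        assert len(mn.mask_filter(pmap, 2)) == valid.sum()

    def test_empty_valid_falls_back_to_all(self):
        probs = np.full((2, 2, 2), 0.5)
        pmap = mn.ProbabilityMap(probs=probs, valid=np.zeros((2, 2), bool))
        assert len(mn.mask_filter(pmap, 0)) == 4


class TestCrossEntropy:
    def test_perfect_predictions_zero_loss(self):
        preds = [mn.SamplePrediction(np.array([1.0, 0.0])),
                 mn.SamplePrediction(np.array([0.0, 1.0]))]
        assert mn.cross_entropy(preds, [0, 1]) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_predictions_log_k(self):
        preds = [mn.SamplePrediction(np.array([0.5, 0.5]))] * 4
        assert mn.cross_entropy(preds, [0, 1, 0, 1]) == pytest.approx(math.log(2))

    def test_hand_computed_case(self):
        preds = [mn.SamplePrediction(np.array([0.8, 0.2])),
                 mn.SamplePrediction(np.array([0.4, 0.6]))]
        expected = -(math.log(0.8) + math.log(0.6)) / 2
        assert mn.cross_entropy(preds, [0, 1]) == pytest.approx(expected)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        p = rng.dirichlet(np.ones(3), size=6)
        preds = [mn.SamplePrediction(row) for row in p]
        labels = [0, 1, 2, 1, 0, 2]
        base = mn.cross_entropy(preds, labels)
        perm = rng.permutation(6)
        assert mn.cross_entropy(
            [preds[i] for i in perm], [labels[i] for i in perm]
        ) == pytest.approx(base)

    def test_zero_probability_clamped(self):
        preds = [mn.SamplePrediction(np.array([0.0, 1.0]))]
        loss = mn.cross_entropy(preds, [0])
        assert loss == pytest.approx(-math.log(PROB_CLAMP))


@pytest.fixture()
def tiny_model():
    return mn.QuantileMILClassifier(
        n_channels=2, width=8, depth=2, embed_dim=8, instance_size=16,
        n_quantiles=4, seed=0,
    ).init_model()


def random_crop(rng, h=16, n=2):
    patch = rng.uniform(0, 1, (h, h, n))
    mask = rng.uniform(size=(h, h)) > 0.4
    if not mask.any():
        mask[0, 0] = True
    return make_crop(patch, mask)


class TestForwardInstance:
    def test_probabilities_normalised(self, tiny_model):
        crop = random_crop(np.random.default_rng(0))
        pmap = tiny_model.forward_instance(crop)
        np.testing.assert_allclose(pmap.probs.sum(axis=-1), 1.0, atol=1e-6)
        assert pmap.probs.min() >= 0

    def test_zeroed_head_gives_uniform(self, tiny_model):
        tiny_model.model_.head.weight[:] = 0
        tiny_model.model_.head.bias[:] = 0
        pmap = tiny_model.forward_instance(random_crop(np.random.default_rng(1)))
        np.testing.assert_allclose(pmap.probs, 0.5, atol=1e-7)

    def test_deterministic(self, tiny_model):
        crop = random_crop(np.random.default_rng(2))
        p1 = tiny_model.forward_instance(crop).probs
        p2 = tiny_model.forward_instance(crop).probs
        np.testing.assert_array_equal(p1, p2)

    def test_channel_mismatch_rejected(self, tiny_model):
        rng = np.random.default_rng(3)
        bad = make_crop(rng.uniform(size=(16, 16, 3)), np.ones((16, 16)))
        with pytest.raises(ValueError):
            tiny_model.forward_instance(bad)


class TestPredictSample:
    def test_single_location_quantile_vector(self, tiny_model):
        rng = np.random.default_rng(4)
        patch = rng.uniform(0, 1, (16, 16, 2))
        mask = np.zeros((16, 16), bool)
        mask[5, 7] = True
        crop = make_crop(patch, mask)
        bag = mn.InstanceBag("s", 1, [crop])
        pred, qv = tiny_model.predict_sample(bag)
        p = tiny_model.forward_instance(crop).probs[5, 7]
        np.testing.assert_allclose(qv.per_class[0], np.full(4, p[0]), atol=1e-7)
        np.testing.assert_allclose(qv.per_class[1], np.full(4, p[1]), atol=1e-7)
        assert pred.class_probs.sum() == pytest.approx(1.0)

    def test_quantile_vector_shape_and_monotonicity(self, tiny_model):
        rng = np.random.default_rng(5)
        bag = mn.InstanceBag("s", 0, [random_crop(rng) for _ in range(3)])
        pred, qv = tiny_model.predict_sample(bag)
        assert qv.concatenated.shape == (2 * 4,)
        assert np.all(np.diff(qv.per_class, axis=1) >= 0)
        assert pred.class_probs.sum() == pytest.approx(1.0, abs=1e-6)

    def test_uniform_maps_give_uniform_prediction(self, tiny_model):
        tiny_model.model_.head.weight[:] = 0
        tiny_model.model_.head.bias[:] = 0
        rng = np.random.default_rng(6)
        bag = mn.InstanceBag("s", 0, [random_crop(rng) for _ in range(2)])
        pred, _ = tiny_model.predict_sample(bag)
        np.testing.assert_allclose(pred.class_probs, 0.5, atol=1e-6)

    def test_higher_class1_quantiles_predict_class1(self, tiny_model):
        # force spatially constant maps with p1 > p0 by biasing the head
        tiny_model.model_.head.weight[:] = 0
        tiny_model.model_.head.bias[:] = np.array([-1.0, 1.0], dtype=np.float32)
        rng = np.random.default_rng(7)
        bag = mn.InstanceBag("s", 1, [random_crop(rng) for _ in range(2)])
        pred, qv = tiny_model.predict_sample(bag)
        assert np.all(qv.per_class[1] > qv.per_class[0])
        assert pred.predicted_class == 1


class TestEmbedCrop:
    def test_embedding_shape_and_determinism(self, tiny_model):
        crop = random_crop(np.random.default_rng(8))
        e1 = tiny_model.embed_crop(crop)
        e2 = tiny_model.embed_crop(crop)
        assert e1.vector.shape == (8,)
        np.testing.assert_array_equal(e1.vector, e2.vector)
        assert np.all(np.isfinite(e1.vector))


class TestTraining:
    def _toy_bags(self, n_per_class=4, seed=0):
        """Trivially separable bags: class 1 bright in channel 0, class 0 dark."""
        rng = np.random.default_rng(seed)
        bags = []
        for label in (0, 1):
            for i in range(n_per_class):
                crops = []
                for c in range(3):
                    patch = rng.uniform(0, 0.2, (16, 16, 2))
                    if label == 1:
                        patch[:, :, 0] += 0.7
                    crops.append(make_crop(patch, np.ones((16, 16)), f"s{label}{i}", c))
                bags.append(mn.InstanceBag(f"s{label}{i}", label, crops))
        return bags

    def _model(self, epochs, seed=0):
        return mn.QuantileMILClassifier(
            n_channels=2, width=8, depth=2, embed_dim=8, instance_size=16,
            n_quantiles=4, epochs=epochs, lr=3e-3, seed=seed,
        )

    def test_zero_epochs_is_initialisation(self):
        clf = self._model(0)
        clf.fit(self._toy_bags())
        assert clf.loss_history_ == []

    def test_same_seed_reproduces_history(self):
        bags = self._toy_bags()
        h1 = self._model(3).fit(bags).loss_history_
        h2 = self._model(3).fit(bags).loss_history_
        assert h1 == h2

    def test_loss_halves_on_separable_bags(self):
        bags = self._toy_bags(n_per_class=10)
        clf = self._model(10)
        clf.fit(bags)
        assert clf.loss_history_[-1] < 0.5 * clf.loss_history_[0]

    def test_single_class_rejected(self):
        bags = [b for b in self._toy_bags() if b.label == 0]
        with pytest.raises(ValueError):
            self._model(1).fit(bags)

    def test_gradient_flows_through_masked_pixels(self):
        bags = self._toy_bags(n_per_class=1)
        clf = self._model(0)
        clf.fit(self._toy_bags())
        bag = bags[0]
        l0, _ = clf._loss_and_grads(bag, bag.label)
        bag.crops[0].patch[bag.crops[0].mask] += 0.05
        l1, _ = clf._loss_and_grads(bag, bag.label)
        assert abs(l1 - l0) > 1e-8

    def test_embeddings_separate_planted_types(self):
        bags = self._toy_bags(n_per_class=6)
        clf = self._model(8)
        clf.fit(bags)
        embs = {0: [], 1: []}
        for b in bags:
            for c in b.crops:
                embs[b.label].append(clf.embed_crop(c).vector)
        mu0 = np.mean(embs[0], axis=0)
        mu1 = np.mean(embs[1], axis=0)

        def cos(a, b):
            return a @ b / (np.linalg.norm(a) * np.linalg.norm(b) + 1e-12)

        within = cos(embs[0][0], mu0)
        across = cos(embs[0][0], mu1)
        assert within > across
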