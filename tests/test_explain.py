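"""Crop-importance scoring, importance maps, top-crop selection, co-occurrence."""

import numpy as np
import pytest

import milniche as mn
from milniche.explain import crop_source_mask
from tests.conftest import make_crop


def embeddings_from(X, sample_ids=None, sp_ids=None):
    n = len(X)
    return [
        mn.CropEmbedding(
            sample_id=sample_ids[i] if sample_ids else f"s{i % 4}",
            sp_id=sp_ids[i] if sp_ids else i,
            vector=np.asarray(X[i], dtype=float),
        )
        for i in range(n)
    ]


@pytest.fixture()
def separable_embeddings():
    rng = np.random.default_rng(0)
    X0 = rng.normal(loc=-3, size=(40, 6))
    X1 = rng.normal(loc=+3, size=(40, 6))
    emb = embeddings_from(np.vstack([X0, X1]))
    labels = [0] * 40 + [1] * 40
    return emb, labels


class TestCropClassifier:
    def test_separable_training_accuracy(self, separable_embeddings):
        emb, labels = separable_embeddings
        clf = mn.fit_crop_classifier(emb, labels, seed=0, n_estimators=50)
        X = np.stack([e.vector for e in emb])
        assert (clf.predict(X) == labels).mean() == 1.0

    def test_seeded_determinism(self, separable_embeddings):
        emb, labels = separable_embeddings
        X = np.stack([e.vector for e in emb])
        p1 = mn.fit_crop_classifier(emb, labels, seed=3).predict_proba(X)
        p2 = mn.fit_crop_classifier(emb, labels, seed=3).predict_proba(X)
        np.testing.assert_array_equal(p1, p2)

    def test_shuffled_labels_near_chance_on_holdout(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(160, 6))
        labels = list(rng.integers(0, 2, size=160))
        emb = embeddings_from(X)
        clf = mn.fit_crop_classifier(emb[:120], labels[:120], seed=0)
        acc = (clf.predict(X[120:]) == labels[120:]).mean()
        assert 0.35 <= acc <= 0.65

    def test_single_class_rejected(self):
        emb = embeddings_from(np.zeros((10, 3)))
        with pytest.raises(ValueError):
            mn.fit_crop_classifier(emb, [1] * 10)


class TestShapImportance:
    def test_importance_is_absolute_sum(self, separable_embeddings):
        emb, labels = separable_embeddings
        scorer = mn.CropImportanceScorer(n_estimators=30, seed=0).fit(emb, labels)
        for s in scorer.score(emb[:10]):
            assert s.importance == pytest.approx(np.abs(s.shap_values).sum(), abs=1e-12)

    def test_additivity_on_scored_crops(self, separable_embeddings):
        emb, labels = separable_embeddings
        scorer = mn.CropImportanceScorer(n_estimators=30, seed=0).fit(emb, labels)
        scores = scorer.score(emb)
        X = np.stack([e.vector for e in emb])
        margins = scorer.classifier_.predict_proba(X)[:, 1]
        for s, m in zip(scores, margins):
            assert s.shap_values.sum() + scorer.explainer_.expected_value == pytest.approx(
                m, abs=1e-6
            )

    def test_single_embedding_path(self, separable_embeddings):
        emb, labels = separable_embeddings
        clf = mn.fit_crop_classifier(emb, labels, seed=0, n_estimators=20)
        score = mn.shap_importance(clf, emb[0])
        assert score.sample_id == emb[0].sample_id
        assert score.importance >= 0


class TestImportanceMap:
    def _partition(self):
        # two 4x8 superpixels tiling an 8x8 image
        top = np.zeros((8, 8), bool)
        top[:4] = True
        return [
            mn.Superpixel(1, top, (0, 0, 4, 8)),
            mn.Superpixel(2, ~top, (4, 0, 8, 8)),
        ]

    def _score(self, sp_id, imp):
        return mn.ImportanceScore("s", sp_id, np.array([imp]), imp)

    def test_paint_by_region(self):
        m = mn.build_importance_map((8, 8), self._partition(), [self._score(1, 2.5)])
        assert np.all(m.raster[:4] == 2.5)
        assert np.all(m.raster[4:] == 0)

    def test_no_scores_all_zero(self):
        m = mn.build_importance_map((8, 8), self._partition(), [])
        assert np.all(m.raster == 0)

    def test_histogram_matches_area_weighted_scores(self):
        sps = self._partition()
        scores = [self._score(1, 1.5), self._score(2, 0.25)]
        m = mn.build_importance_map((8, 8), sps, scores)
        vals, counts = np.unique(m.raster, return_counts=True)
        assert dict(zip(vals, counts)) == {0.25: 32, 1.5: 32}

    def test_disjoint_score_sets_add(self):
        sps = self._partition()
        m1 = mn.build_importance_map((8, 8), sps, [self._score(1, 1.0)])
        m2 = mn.build_importance_map((8, 8), sps, [self._score(2, 3.0)])
        m12 = mn.build_importance_map(
            (8, 8), sps, [self._score(1, 1.0), self._score(2, 3.0)]
        )
        np.testing.assert_allclose(m1.raster + m2.raster, m12.raster)

    def test_unknown_superpixel_rejected(self):
        with pytest.raises(ValueError):
            mn.build_importance_map((8, 8), self._partition(), [self._score(9, 1.0)])


class TestTopCrops:
    def _scores(self, values, sample="s"):
        return [
            mn.ImportanceScore(sample, i, np.array([v]), float(v))
            for i, v in enumerate(values)
        ]

    def test_selection_order(self):
        out = mn.top_crops(self._scores([5, 3, 9]), 2)
        assert [s.importance for s in out] == [9, 5]

    def test_n_larger_than_list(self):
        out = mn.top_crops(self._scores([1, 2]), 10)
        assert len(out) == 2

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(size=30)
        scores = self._scores(vals)
        out = mn.top_crops(scores, 7)
        expected = sorted(vals, reverse=True)[:7]
        assert [s.importance for s in out] == expected

    def test_complement_dominance(self):
        rng = np.random.default_rng(3)
        scores = self._scores(rng.uniform(size=25))
        chosen = mn.top_crops(scores, 10)
        rest = [s for s in scores if s not in chosen]
        assert min(s.importance for s in chosen) >= max(s.importance for s in rest)


class TestCooccurrence:
    def _crop_at(self, r0, c0, size, sample="s1"):
        patch = np.zeros((size, size, 1), dtype=np.float32)
        mask = np.ones((size, size), bool)
        c = make_crop(patch, mask, sample_id=sample)
        c.origin = (r0, c0)
        c.window = (r0, c0, r0 + size, c0 + size)
        return c

    def test_single_crop_pair_counting(self):
        tmap = np.zeros((16, 16), int)
        tmap[2:4, 2:4] = 1  # type A
        tmap[5:7, 5:7] = 2  # type B
        crop = self._crop_at(0, 0, 8)
        table = mn.cooccurrence_counts([crop], {"s1": tmap}, {1: "A", 2: "B"})
        assert table.loc["A", "B"] == 1
        assert table.loc["A", "A"] == 1
        assert table.loc["B", "B"] == 1

    def test_disjoint_single_types_no_offdiagonal(self):
        tmap = np.zeros((32, 32), int)
        tmap[1:3, 1:3] = 1
        tmap[20:22, 20:22] = 2
        crops = [self._crop_at(0, 0, 8), self._crop_at(18, 18, 8)]
        table = mn.cooccurrence_counts(crops, {"s1": tmap}, {1: "A", 2: "B"})
        assert table.loc["A", "B"] == 0
        assert table.loc["A", "A"] == 1
        assert table.loc["B", "B"] == 1

    def test_symmetry_and_missing_sample_warning(self):
        tmap = np.zeros((16, 16), int)
        tmap[2:6, 2:6] = 1
        tmap[2:6, 8:12] = 3
        crops = [self._crop_at(0, 0, 16), self._crop_at(0, 0, 8, sample="s2")]
        with pytest.warns(UserWarning, match="no type map"):
            table = mn.cooccurrence_counts(crops, {"s1": tmap})
        assert (table.values == table.values.T).all()

    def test_mask_footprint_respected(self):
        # mask covers only the left half of the window: type B on the right
        # must not be counted
        tmap = np.zeros((16, 16), int)
        tmap[4:6, 1:3] = 1
        tmap[4:6, 12:14] = 2
        patch = np.zeros((16, 16, 1), dtype=np.float32)
        mask = np.zeros((16, 16), bool)
        mask[:, :8] = True
        crop = make_crop(patch, mask, sample_id="s1")
        crop.window = (0, 0, 16, 16)
        table = mn.cooccurrence_counts([crop], {"s1": tmap}, {1: "A", 2: "B"})
        assert "A" in table.index
        assert "B" not in table.index


def test_crop_source_mask_roundtrip_identity():
    patch = np.zeros((16, 16, 1), dtype=np.float32)
    mask = np.zeros((16, 16), bool)
    mask[4:8, 2:12] = True
    crop = make_crop(patch, mask)
    crop.window = (10, 20, 26, 36)
    back, (r0, c0) = crop_source_mask(crop)
    assert (r0, c0) == (10, 20)
    np.testing.assert_array_equal(back, mask)
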