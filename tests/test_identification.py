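"""Feature matching, match summarisation, and the identity decision rule."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import finprint as fp
from finprint.identification import (
    WARN_AMBIGUOUS_TIE,
    WARN_LOW_SUPPORT,
    FeatureSet,
    MatchSet,
    ModelScore,
)


def feature_set(descriptors, orientations=None, xy=None):
    d = np.asarray(descriptors, dtype=float)
    n = d.shape[0]
    return FeatureSet(
        xy=np.asarray(xy, float) if xy is not None else np.zeros((n, 2)),
        scales=np.ones(n),
        orientations=np.asarray(orientations, float) if orientations is not None
        else np.zeros(n),
        descriptors=d,
    )


def match_set(orient_pairs, distances=None):
    o = np.asarray(orient_pairs, dtype=float).reshape(-1, 2)
    k = o.shape[0]
    return MatchSet(
        query_xy=np.zeros((k, 2)),
        model_xy=np.zeros((k, 2)),
        distances=np.asarray(distances, float) if distances is not None else np.zeros(k),
        orientations=o,
    )


def brute_force_mutual_nn(d1, d2):
    """Oracle: all-pairs distance matrix, mutual argmin in both directions."""
    D = np.linalg.norm(d1[:, None, :] - d2[None, :, :], axis=2)
    pairs = set()
    for i in range(len(d1)):
        j = int(np.argmin(D[i]))
        if int(np.argmin(D[:, j])) == i:
            pairs.add((i, j))
    return pairs, D


class TestMatchFeatures:
    def test_self_match_is_identity(self):
        rng = np.random.default_rng(0)
        fs = feature_set(rng.normal(size=(12, 8)), orientations=rng.uniform(0, 360, 12))
        ms = fp.match_features(fs, fs)
        assert ms.k == 12
        assert np.all(ms.distances == 0)
        assert np.all(ms.orientations[:, 0] == ms.orientations[:, 1])

    def test_planted_correspondences_recovered(self):
        rng = np.random.default_rng(1)
        planted = rng.normal(size=(20, 16)) * 10
        query = feature_set(np.vstack([planted, rng.normal(size=(10, 16)) * 10 + 100]))
        model = feature_set(
            np.vstack([planted + rng.normal(scale=0.01, size=planted.shape),
                       rng.normal(size=(10, 16)) * 10 - 100])
        )
        ms = fp.match_features(query, model)
        oracle_pairs, _ = brute_force_mutual_nn(query.descriptors, model.descriptors)
        # the 20 planted pairs are mutual NNs and must all be recovered
        assert {(i, i) for i in range(20)} <= oracle_pairs
        assert ms.k == len(oracle_pairs)
        # every planted pair shows up as a near-zero-distance match
        assert (ms.distances < 1).sum() == 20

    def test_one_to_one_cardinality_bound(self):
        rng = np.random.default_rng(2)
        q = feature_set(rng.normal(size=(7, 5)), xy=np.arange(14).reshape(7, 2))
        m = feature_set(rng.normal(size=(4, 5)), xy=np.arange(8).reshape(4, 2))
        ms = fp.match_features(q, m)
        assert ms.k <= 4
        # one-to-one: no duplicated endpoints on either side
        assert len({tuple(p) for p in ms.query_xy}) == ms.k
        assert len({tuple(p) for p in ms.model_xy}) == ms.k

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            q = rng.normal(size=(rng.integers(2, 15), 6))
            m = rng.normal(size=(rng.integers(2, 15), 6))
            ms = fp.match_features(feature_set(q), feature_set(m))
            oracle, D = brute_force_mutual_nn(q, m)
            assert ms.k == len(oracle)
            np.testing.assert_allclose(
                np.sort(ms.distances), np.sort([D[i, j] for i, j in oracle])
            )

    def test_empty_set_rejected(self):
        fs = feature_set(np.ones((3, 4)))
        empty = feature_set(np.empty((0, 4)))
        with pytest.raises(ValueError):
            fp.match_features(fs, empty)


class TestMedianDistanceIqr:
    def test_interquartile_trimmed_median(self):
        assert fp.median_distance_iqr([1, 2, 3, 4, 100]) == 3

    def test_constant_list(self):
        assert fp.median_distance_iqr([7.5] * 4) == 7.5

    def test_singleton(self):
        assert fp.median_distance_iqr([5]) == 5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fp.median_distance_iqr([])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1e6), min_size=1, max_size=40))
    def test_bounded_by_sample_range(self, values):
        d = fp.median_distance_iqr(values)
        assert min(values) <= d <= max(values)


class TestFilterEqualOrientation:
    def test_sub_half_degree_difference_kept_in_degree_mode(self):
        out = fp.filter_equal_orientation(match_set([(30.2, 30.4)]), unit="deg")
        assert out.k == 1

    def test_fifteen_degrees_discarded_in_degree_mode(self):
        out = fp.filter_equal_orientation(match_set([(30.0, 45.0)]), unit="deg")
        assert out.k == 0

    def test_rounding_and_wrapping_convention_degrees(self):
        # differences -0.4, 0.5, 0.6, 180: round-half-to-even keeps -0.4 and 0.5
        pairs = [(10.0 - 0.4, 10.0), (10.5, 10.0), (10.6, 10.0), (190.0, 10.0)]
        out = fp.filter_equal_orientation(match_set(pairs), unit="deg")
        assert out.k == 2

    def test_radian_window_keeps_small_misalignment(self):
        # 15 deg = 0.26 rad rounds to 0; 40 deg = 0.70 rad rounds to 1
        kept = fp.filter_equal_orientation(match_set([(45.0, 30.0)]), unit="rad")
        dropped = fp.filter_equal_orientation(match_set([(70.0, 30.0)]), unit="rad")
        assert kept.k == 1 and dropped.k == 0

    def test_filter_is_subset_operation(self):
        rng = np.random.default_rng(4)
        ms = match_set(rng.uniform(0, 360, (30, 2)), distances=rng.uniform(0, 9, 30))
        out = fp.filter_equal_orientation(ms)
        assert out.k <= ms.k
        assert set(out.distances) <= set(ms.distances)


def score(name, k_star, d_star, k=None):
    fs = feature_set(np.zeros((max(k or k_star, 1), 2)))
    model = fp.FinModel(dolphin_name=name, side="right",
                        image=fp.FinImage(pixels=np.zeros((2, 2, 3), np.uint8)),
                        features=fs)
    return ModelScore(model=model, k=k or max(k_star, 1), k_star=k_star, d_star=d_star)


class TestPredictIdentity:
    def test_highest_k_star_wins(self):
        pred = fp.predict_identity([score("A", 10, 0.2), score("B", 3, 0.1)])
        assert pred.dolphin_name == "A" and not pred.warnings

    def test_distance_tie_break(self):
        pred = fp.predict_identity([score("A", 5, 0.3), score("B", 5, 0.1)])
        assert pred.dolphin_name == "B" and not pred.warnings

    def test_low_support_warning(self):
        pred = fp.predict_identity([score("A", 3, 0.1), score("B", 2, 0.2)])
        assert pred.dolphin_name == "A"
        assert pred.warnings == {WARN_LOW_SUPPORT}

    def test_double_tie_takes_first_with_warning(self):
        pred = fp.predict_identity([score("A", 6, 0.2), score("B", 6, 0.2)])
        assert pred.dolphin_name == "A"
        assert pred.warnings == {WARN_AMBIGUOUS_TIE}

    def test_undefined_distance_loses_tie_break(self):
        pred = fp.predict_identity([score("A", 0, None, k=1), score("B", 0, 0.4, k=1)])
        assert pred.dolphin_name == "B"


class TestCompareToModels:
    def test_self_comparison_perfect_score(self, small_models):
        model = small_models[0]
        scores = fp.compare_to_models(model.features, [model])
        assert scores[0].k_star == len(model.features)
        assert scores[0].d_star == 0.0

    def test_order_and_length_contract(self, small_models):
        query = small_models[0].features
        scores = fp.compare_to_models(query, small_models)
        assert [s.model.dolphin_name for s in scores] == [m.dolphin_name for m in small_models]

    def test_batch_equals_per_model(self, small_models):
        query = small_models[1].features
        batch = fp.compare_to_models(query, small_models)
        singles = [fp.compare_to_models(query, [m])[0] for m in small_models]
        for b, s in zip(batch, singles):
            assert (b.k, b.k_star, b.d_star) == (s.k, s.k_star, s.d_star)

    def test_empty_model_collection_rejected(self, small_models):
        with pytest.raises(ValueError):
            fp.compare_to_models(small_models[0].features, [])


class TestDetectFeatures:
    def test_uniform_region_has_no_keypoints(self):
        img = fp.FinImage(pixels=np.full((120, 120, 3), 128, np.uint8))
        mask = np.zeros((120, 120), bool)
        mask[30:90, 30:90] = True
        fs = fp.detect_features(img, fp.FinMask(mask=mask))
        assert len(fs) == 0

    def test_scarred_fin_has_features(self, small_sim, small_models):
        assert all(len(m.features) >= 5 for m in small_models)

    def test_out_of_fin_deletion(self):
        # noiseless render: the sea is perfectly flat, so every detected
        # keypoint sits on the fin; a mask over the sea corner removes all
        ident = fp.make_identity("flat-sea", seed=21)
        image, _ = fp.generate_fin_image(ident, fp.RenderParams(noise_sd=0.0, seed=1))
        corner = np.zeros((image.height, image.width), bool)
        corner[:40, :40] = True
        fs = fp.detect_features(image, fp.FinMask(mask=corner))
        assert len(fs) == 0

    def test_deterministic(self, small_sim):
        render = small_sim.models[0]
        mask = fp.extract_fin_mask(render.image)
        a = fp.detect_features(render.image, mask)
        b = fp.detect_features(render.image, mask)
        np.testing.assert_array_equal(a.descriptors, b.descriptors)
        np.testing.assert_array_equal(a.xy, b.xy)


class TestIdentify:
    def test_self_identification_zero_distance(self, small_sim, small_models):
        render = small_sim.models[2]
        pred = fp.identify(render.image, small_models)
        assert isinstance(pred, fp.Prediction)
        assert pred.dolphin_name == render.name
        assert pred.winning_score.d_star == 0.0

    def test_rotated_query_same_identity(self, small_sim, small_models):
        ident = small_sim.identities[3]
        image, _ = fp.generate_fin_image(
            ident, fp.RenderParams(rotation_deg=30.0, seed=999)
        )
        pred = fp.identify(image, small_models)
        assert isinstance(pred, fp.Prediction)
        assert pred.dolphin_name == ident.name

    def test_undersized_query_rejected(self, small_models):
        ident = fp.make_identity("tiny", seed=20)
        image, _ = fp.generate_fin_image(
            ident, fp.RenderParams(width=150, height=150, seed=1)
        )
        out = fp.identify(image, small_models)
        assert isinstance(out, fp.Rejection)
        assert {"width", "height"} <= set(out.reasons)

    def test_identify_deterministic(self, small_sim, small_models):
        image = small_sim.queries[0].image
        p1 = fp.identify(image, small_models)
        p2 = fp.identify(image, small_models)
        assert p1.dolphin_name == p2.dolphin_name
        assert p1.winning_score.d_star == p2.winning_score.d_star


class TestGalleryPersistence:
    def test_round_trip(self, small_models, tmp_path):
        fp.save_gallery(small_models, tmp_path / "gallery")
        loaded = fp.load_gallery(tmp_path / "gallery")
        assert [m.dolphin_name for m in loaded] == [m.dolphin_name for m in small_models]
        for a, b in zip(loaded, small_models):
            np.testing.assert_array_equal(a.features.descriptors, b.features.descriptors)
            np.testing.assert_array_equal(a.image.pixels, b.image.pixels)

    def test_missing_gallery_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            fp.load_gallery(tmp_path / "nope")
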