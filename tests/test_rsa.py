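import numpy as np
import pandas as pd
import pytest

from dyadkin import rsa_pipeline as rsa
from dyadkin.rsa_pipeline import RDM, NoiseCeiling

import oracles


def _rdm_from_values(values, name="f"):
    return rsa.feature_rdm(pd.Series(values, index=[f"s{i}" for i in range(len(values))]), name)


class TestRdmInvariants:
    def test_validation(self):
        labels = ("a", "b", "c")
        with pytest.raises(ValueError, match="symmetric"):
            RDM(np.array([[0, 1, 0], [0, 0, 1], [0, 1, 0.0]]), labels)
        with pytest.raises(ValueError, match="diagonal"):
            RDM(np.full((3, 3), 1.0), labels)
        m = np.array([[0, -1, 1], [-1, 0, 1], [1, 1, 0.0]])
        with pytest.raises(ValueError, match="nonnegative"):
            RDM(m, labels)
        with pytest.raises(ValueError, match="finite"):
            RDM(np.array([[0, np.nan], [np.nan, 0.0]]), ("a", "b"))

    def test_vector_length(self):
        r = _rdm_from_values([1.0, 2.0, 4.0, 8.0])
        assert len(r.vector()) == 6


class TestModelRdm:
    def test_block_structure(self):
        cats = {f"s{i}": ("x" if i < 3 else "y") for i in range(6)}
        r = rsa.model_rdm(cats)
        assert r.matrix[:3, :3].sum() == 0
        assert r.matrix[3:, 3:].sum() == 0
        assert (r.matrix[:3, 3:] == 1).all()

    def test_single_category_all_zero(self):
        r = rsa.model_rdm({f"s{i}": "x" for i in range(5)})
        assert r.matrix.sum() == 0

    def test_48_scene_dissimilar_count(self):
        cats = {}
        for e in ("happiness", "affection", "sadness", "anger"):
            for i in range(12):
                cats[f"{e}_{i}"] = e
        r = rsa.model_rdm(cats)
        # derived by counting: 48^2 - 4 * 12^2 off-block entries
        assert int(r.matrix.sum()) == 48**2 - 4 * 12**2 == 1728


class TestBehaviouralRdms:
    @staticmethod
    def _ratings(responses, valences):
        rows = []
        for rater, (resp, val) in enumerate(zip(responses, valences)):
            for i, (r_, v_) in enumerate(zip(resp, val)):
                rows.append((rater, f"s{i}", "anger", r_, v_))
        return pd.DataFrame(rows, columns=["rater", "scene_id", "true_emotion", "response", "valence"])

    def test_constant_rating_zero_rdm(self):
        frame = self._ratings([["anger"] * 4, ["anger"] * 4], [[0] * 4, [1] * 4])
        emo, _, _, _ = rsa.behavioural_rdms(frame)
        assert emo[0].matrix.sum() == 0

    def test_valence_absolute_differences(self):
        frame = self._ratings([["anger"] * 3], [[-5, 0, 5]])
        frame = pd.concat([frame, frame.assign(rater=1)])
        _, val, _, _ = rsa.behavioural_rdms(frame)
        off = val[0].matrix[np.triu_indices(3, 1)]
        assert sorted(off.tolist()) == [5.0, 5.0, 10.0]

    def test_incomplete_ratings_rejected(self):
        frame = self._ratings([["anger"] * 4, ["anger"] * 4], [[0] * 4, [0] * 4])
        frame = frame.drop(frame.index[-1])
        with pytest.raises(ValueError, match="incomplete"):
            rsa.behavioural_rdms(frame)

    def test_noiseless_raters_match_model(self, small_dataset):
        from dyadkin.synthetic_scenes import RaterModel, simulate_ratings

        ident = tuple(tuple(1.0 if i == j else 0.0 for j in range(4)) for i in range(4))
        ratings = simulate_ratings(small_dataset, RaterModel(n_raters=3, confusion=ident, seed=0))
        emo, _, group, _ = rsa.behavioural_rdms(ratings)
        model = rsa.model_rdm({s.scene_id: s.emotion for s in small_dataset})
        for r in emo.values():
            np.testing.assert_array_equal(r.matrix, model.matrix)
        np.testing.assert_array_equal(group.matrix, model.matrix)


class TestFeatureRdm:
    def test_absolute_differences(self):
        r = _rdm_from_values([1.0, 2.0, 4.0])
        off = r.matrix[np.triu_indices(3, 1)]
        assert sorted(off.tolist()) == [1.0, 2.0, 3.0]

    def test_affine_invariance_of_tau(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=12)
        other = _rdm_from_values(rng.normal(size=12))
        t1 = rsa.tau_a(_rdm_from_values(vals), other)
        t2 = rsa.tau_a(_rdm_from_values(3.5 * vals + 2.0), other)
        assert t1 == pytest.approx(t2, abs=1e-12)
        r_scaled = _rdm_from_values(3.5 * vals + 2.0)
        np.testing.assert_allclose(r_scaled.matrix, 3.5 * _rdm_from_values(vals).matrix, rtol=1e-9)

    def test_constant_feature_warns(self):
        with pytest.warns(UserWarning, match="constant"):
            r = _rdm_from_values([2.0, 2.0, 2.0])
        assert r.matrix.sum() == 0

    def test_twenty_rdms(self, features48):
        from dyadkin.pipeline import FEATURE_ORDER

        rdms = rsa.feature_rdms(features48[list(FEATURE_ORDER)])
        assert len(rdms) == 20


class TestTauA:
    def test_identical_untied(self):
        rng = np.random.default_rng(1)
        r = _rdm_from_values(rng.normal(size=10))
        assert rsa.tau_a(r, r) == pytest.approx(1.0, abs=1e-12)

    def test_rank_reversed(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(1, 2, 200)
        y = -x
        assert rsa.tau_a_vectors(x, y) == pytest.approx(-1.0, abs=1e-12)

    def test_tied_toy_matches_enumeration(self):
        x = np.array([1.0, 1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 1.0, 3.0, 3.0])
        assert rsa.tau_a_vectors(x, y) == pytest.approx(oracles.o_tau_a(x, y), abs=1e-12)

    @pytest.mark.parametrize("m", [10, 50, 200])
    def test_random_vectors_match_enumeration(self, m):
        rng = np.random.default_rng(m)
        x = rng.integers(0, 6, m).astype(float)  # plenty of ties
        y = rng.normal(size=m)
        assert rsa.tau_a_vectors(x, y) == pytest.approx(oracles.o_tau_a(x, y), abs=1e-12)

    def test_constant_vector_nan(self):
        with pytest.warns(UserWarning):
            assert np.isnan(rsa.tau_a_vectors(np.ones(5), np.arange(5.0)))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        t1 = rsa.tau_a_vectors(x, y)
        t2 = rsa.tau_a_vectors(np.exp(x), y)
        assert t1 == pytest.approx(t2, abs=1e-12)


class TestRelateModelsToFeatures:
    def test_monotone_feature_tau_one(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=10)
        feature = _rdm_from_values(vals, "feat")
        monotone = RDM(np.exp(feature.matrix) - 1.0, feature.labels, "mono")
        taus, tests, mds = rsa.relate_models_to_features(
            {"mono": monotone}, {"feat": feature}, n_permutations=100, seed=0
        )
        assert taus.loc["mono", "feat"] == pytest.approx(1.0, abs=1e-12)
        d = np.linalg.norm(mds.loc["mono"] - mds.loc["feat"])
        assert d == pytest.approx(0.0, abs=1e-9)
        assert tests.iloc[0]["p"] < 0.05

    def test_independent_rdms_small_tau(self):
        rng = np.random.default_rng(5)
        a = _rdm_from_values(rng.normal(size=48))
        b = _rdm_from_values(rng.normal(size=48))
        taus, tests, _ = rsa.relate_models_to_features({"a": a}, {"b": b}, n_permutations=200, seed=1)
        assert abs(taus.loc["a", "b"]) < 0.15
        assert tests.iloc[0]["p"] > 0.001

    def test_mds_embedding_preserves_distances(self):
        # classical MDS recovers an exactly 2-D configuration
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0], [2.0, 2.0], [3.0, 1.0]])
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
        coords = rsa.classical_mds(d, 2)
        d_hat = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
        np.testing.assert_allclose(d_hat, d, atol=1e-9)

    def test_mds_distance_correlation_on_structured_set(self):
        # feature RDMs spanning a smooth 1-parameter family: embedded
        # distances should track 1 - tau
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=30), rng.normal(size=30)
        rdms = {}
        for k, theta in enumerate(np.linspace(0, np.pi / 2, 6)):
            rdms[f"f{k}"] = _rdm_from_values(np.cos(theta) * x + np.sin(theta) * y, f"f{k}")
        taus, _, mds = rsa.relate_models_to_features(
            {"m": rdms.pop("f0")}, rdms, n_permutations=10, seed=0
        )
        names = list(taus.index)
        emb = mds.loc[names].to_numpy()
        d_emb = np.linalg.norm(emb[:, None] - emb[None, :], axis=2)
        d_tau = 1.0 - taus.to_numpy()
        iu = np.triu_indices(len(names), 1)
        corr = np.corrcoef(d_emb[iu], d_tau[iu])[0, 1]
        assert corr > 0.9


class TestNoiseCeiling:
    def _subject_rdms(self, n_subjects, noise, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.normal(size=(10, 10))
        base = np.abs(base + base.T)
        np.fill_diagonal(base, 0.0)
        labels = tuple(f"s{i}" for i in range(10))
        out = {}
        for s in range(n_subjects):
            pert = rng.normal(0, noise, (10, 10))
            pert = pert + pert.T
            m = np.abs(base + pert)
            np.fill_diagonal(m, 0.0)
            out[s] = RDM(m, labels, f"subj{s}")
        return out

    def test_identical_subjects_bounds_coincide(self):
        subj = self._subject_rdms(4, noise=0.0)
        ceiling = rsa.noise_ceiling(list(subj.values()))
        assert ceiling.lower == pytest.approx(ceiling.upper, abs=1e-12)

    def test_lower_leq_upper(self):
        for seed in range(5):
            subj = self._subject_rdms(6, noise=0.5, seed=seed)
            ceiling = rsa.noise_ceiling(list(subj.values()))
            assert ceiling.lower <= ceiling.upper + 1e-12

    def test_subject_order_invariance(self):
        subj = list(self._subject_rdms(5, noise=0.4, seed=3).values())
        c1 = rsa.noise_ceiling(subj)
        c2 = rsa.noise_ceiling(subj[::-1])
        assert c1.lower == pytest.approx(c2.lower, abs=1e-12)
        assert c1.upper == pytest.approx(c2.upper, abs=1e-12)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            NoiseCeiling(lower=0.5, upper=0.4)


class TestRelateFeaturesToBehaviour:
    def test_identical_subjects_and_feature(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(size=12)
        feat = _rdm_from_values(vals)
        subj = {s: _rdm_from_values(vals) for s in range(4)}
        summary, per_subject, ceiling = rsa.relate_features_to_behaviour({"f": feat}, subj)
        assert summary.loc["f", "mean_corr"] == pytest.approx(1.0, abs=1e-12)
        assert ceiling.upper == pytest.approx(1.0, abs=1e-12)
        assert ceiling.lower == pytest.approx(1.0, abs=1e-12)
        assert per_subject.shape == (1, 4)

    def test_corrections_ordering(self):
        rng = np.random.default_rng(8)
        base = rng.normal(size=20)
        feats = {
            "good": _rdm_from_values(base),
            "bad": _rdm_from_values(rng.normal(size=20)),
        }
        subj = {s: _rdm_from_values(base + rng.normal(0, 0.3, 20)) for s in range(8)}
        summary, _, _ = rsa.relate_features_to_behaviour(feats, subj)
        assert (summary["p_holm"] >= summary["p"] - 1e-15).all()
        assert summary.loc["good", "mean_corr"] > summary.loc["bad", "mean_corr"]


class TestPairwiseFeatureTests:
    def test_identical_features_p_one(self):
        per_subject = pd.DataFrame(
            [[0.3] * 8, [0.3] * 8, [0.1] * 8],
            index=["a", "b", "c"],
            columns=range(8),
        )
        table, mat = rsa.pairwise_feature_tests(per_subject)
        ab = table.query("feature_a == 'a' and feature_b == 'b'").iloc[0]
        assert ab["p"] == 1.0
        assert np.isnan(mat.loc["a", "a"])
        assert mat.loc["a", "c"] == mat.loc["c", "a"]

    def test_uniformly_better_feature_minimal_p(self):
        rng = np.random.default_rng(9)
        better = 0.5 + rng.uniform(0.01, 0.1, 31)
        worse = better - rng.uniform(0.05, 0.1, 31)  # 31 positive differences
        per_subject = pd.DataFrame([better, worse], index=["a", "b"], columns=range(31))
        table, _ = rsa.pairwise_feature_tests(per_subject)
        assert table.iloc[0]["p"] < 1e-5

    def test_too_few_subjects_rejected(self):
        per_subject = pd.DataFrame(np.zeros((2, 4)), index=["a", "b"])
        with pytest.raises(ValueError):
            rsa.pairwise_feature_tests(per_subject)


class TestCombineRdms:
    def test_combine_with_itself(self):
        rng = np.random.default_rng(10)
        r = _rdm_from_values(rng.normal(size=10))
        combo = rsa.combine_rdms([r, r])
        assert rsa.tau_a(combo, r) == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_binary_levels(self):
        cats1 = {f"s{i}": ("x" if i % 2 == 0 else "y") for i in range(8)}
        cats2 = {f"s{i}": ("x" if i < 4 else "y") for i in range(8)}
        combo = rsa.combine_rdms([rsa.model_rdm(cats1), rsa.model_rdm(cats2)])
        levels = sorted(set(np.round(combo.vector(), 12)))
        assert levels == [0.0, 0.5, 1.0]

    def test_constant_excluded(self):
        rng = np.random.default_rng(11)
        good = _rdm_from_values(rng.normal(size=6))
        with pytest.warns(UserWarning, match="excluded"):
            with pytest.raises(ValueError, match="non-constant"):
                rsa.combine_rdms([good, _rdm_from_values([1.0] * 6)])

    def test_label_mismatch_rejected(self):
        a = _rdm_from_values([1.0, 2.0, 3.0])
        b = rsa.feature_rdm(pd.Series([1.0, 2.0, 3.0], index=["x", "y", "z"]))
        with pytest.raises(ValueError, match="labels"):
            rsa.combine_rdms([a, b])
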