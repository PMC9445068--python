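import numpy as np
import pytest

from dyadkin.scene_io import MarkerSet, Scene
from dyadkin.inter_features import (
    INTER_FEATURES,
    distance_correlation,
    interpersonal_distance,
    motion_energy_balance,
    orientation,
    personal_space,
    reduce_interpersonal,
    synchronization,
)

import oracles
from conftest import facing_pair, make_agent, toy_scene

MK = MarkerSet()


def scene_from(c1, c2, fps=100.0):
    return Scene((make_agent(c1), make_agent(c2)), fps=fps, emotion="anger")


class TestInterpersonalDistance:
    def test_static_pair(self):
        c1, c2 = facing_pair(frames=5, separation=1000.0)
        ipd, ipd_std, ipd_t = interpersonal_distance(scene_from(c1, c2))
        assert ipd == pytest.approx(1000.0, abs=1e-9)
        assert ipd_std == pytest.approx(0.0, abs=1e-9)
        assert len(ipd_t) == 5

    def test_linear_approach_mean(self):
        n = 101
        c1, c2 = facing_pair(frames=n, separation=0.0)
        sep = np.linspace(2000.0, 200.0, n)
        c1[:, :, 0] -= sep[:, None] / 2.0
        c2[:, :, 0] += sep[:, None] / 2.0
        ipd, _, _ = interpersonal_distance(scene_from(c1, c2))
        assert ipd == pytest.approx(1100.0, abs=1e-9)

    def test_matches_oracle(self):
        scene = toy_scene(seed=4, frames=6)
        ipd, _, _ = interpersonal_distance(scene)
        oracle = oracles.o_ipd_profile(scene)
        assert ipd == pytest.approx(sum(oracle) / len(oracle), rel=1e-9)


class TestPersonalSpace:
    def test_far_apart_zero(self):
        c1, c2 = facing_pair(frames=4, separation=3000.0)
        assert personal_space(scene_from(c1, c2)) == 0.0

    def test_close_always_hundred(self):
        c1, c2 = facing_pair(frames=4, separation=300.0)
        assert personal_space(scene_from(c1, c2)) == 100.0

    def test_matches_oracle(self):
        scene = toy_scene(seed=6, frames=8, separation=480.0)
        assert personal_space(scene) == pytest.approx(oracles.o_personal_space(scene), rel=1e-9)


class TestOrientation:
    def test_face_to_face(self):
        c1, c2 = facing_pair(frames=5)
        ipo, bal, f1, f2 = orientation(scene_from(c1, c2))
        assert ipo == 100.0
        assert bal == 1.0
        assert f1.all() and f2.all()

    def test_one_sided(self):
        c1, c2 = facing_pair(frames=5)
        # rotate agent 2 by 180 deg about its own centroid: it faces away
        centroid = c2[:, MK.indices(MK.anatomical_13), :2].mean(axis=1, keepdims=True)
        c2r = c2.copy()
        c2r[:, :, :2] = 2 * centroid - c2[:, :, :2]
        for l, r in MK.pairs:
            li, ri = MK.index(l), MK.index(r)
            c2r[:, [li, ri], :] = c2r[:, [ri, li], :]
        ipo, bal, f1, f2 = orientation(scene_from(c1, c2r))
        assert f1.all() and not f2.any()
        assert ipo == 50.0
        assert bal == 0.0

    def test_mutual_only_mode(self):
        c1, c2 = facing_pair(frames=5)
        ipo, _, _, _ = orientation(scene_from(c1, c2), mutual_only=True)
        assert ipo == 100.0

    def test_matches_oracle(self):
        scene = toy_scene(seed=10, frames=7)
        ipo, bal, _, _ = orientation(scene)
        o_ipo, o_bal = oracles.o_orientation(scene)
        assert ipo == pytest.approx(o_ipo, rel=1e-9)
        assert bal == pytest.approx(o_bal, rel=1e-9)

    def test_coincident_shoulders_rejected(self):
        c1, c2 = facing_pair(frames=3)
        c1[:, MK.index("l_shoulder"), :] = c1[:, MK.index("r_shoulder"), :]
        with pytest.raises(ValueError, match="shoulder"):
            orientation(scene_from(c1, c2))


class TestDistanceCorrelation:
    @staticmethod
    def _linear_sep_affine_lc(sep_start, sep_end, n=50):
        # Wrists move radially away from the head (affine LC profile) while a
        # knee displacement cancels the centroid shift, keeping the distance
        # profile exactly linear.
        c1, c2 = facing_pair(frames=n, separation=0.0)
        sep = np.linspace(sep_start, sep_end, n)
        c1[:, :, 0] -= sep[:, None] / 2.0
        c2[:, :, 0] += sep[:, None] / 2.0
        stretch = np.linspace(0.0, 100.0, n)
        for c in (c1, c2):
            head = c[0, MK.index("head")]
            cancel = np.zeros((n, 3))
            for wname in ("l_wrist", "r_wrist"):
                w = MK.index(wname)
                u = c[0, w] - head
                u = u / np.linalg.norm(u)
                c[:, w, :] += stretch[:, None] * u
                cancel += stretch[:, None] * u
            c[:, MK.index("l_knee"), :] -= cancel
        return scene_from(c1, c2)

    def test_affine_profile_perfect_correlation(self):
        scene = self._linear_sep_affine_lc(800.0, 1600.0)
        assert distance_correlation(scene, "LC") == pytest.approx(1.0, abs=1e-9)

    def test_anti_profile(self):
        scene = self._linear_sep_affine_lc(1600.0, 800.0)
        assert distance_correlation(scene, "LC") == pytest.approx(-1.0, abs=1e-9)

    @pytest.mark.parametrize("profile", ["VEL", "ACC", "VOL", "LC"])
    def test_matches_textbook_pearson(self, profile):
        scene = toy_scene(seed=17, frames=9)
        assert distance_correlation(scene, profile) == pytest.approx(
            oracles.o_distance_correlation(scene, profile), rel=1e-9
        )

    def test_zero_variance_profile_missing(self):
        c1, c2 = facing_pair(frames=6)  # static: VEL profile all zero
        with pytest.warns(UserWarning, match="zero-variance"):
            assert np.isnan(distance_correlation(scene_from(c1, c2), "VEL"))

    def test_unknown_profile(self):
        with pytest.raises(ValueError):
            distance_correlation(toy_scene(frames=4), "XXX")


class TestSynchronization:
    def test_mirrored_motion(self):
        n = 20
        c1, c2 = facing_pair(frames=n)
        wave = 10.0 * np.sin(np.linspace(0, 4 * np.pi, n))
        c1[:, :, 2] += wave[:, None]
        c2[:, :, 2] += wave[:, None]  # same vertical motion: identical speeds
        assert synchronization(scene_from(c1, c2), "VEL") == pytest.approx(1.0, abs=1e-9)

    def test_antiphase_speed_profiles(self):
        n = 21
        c1, c2 = facing_pair(frames=n)
        # alternate steps: agent 1 moves on even steps, agent 2 on odd ones
        steps1 = np.array([10.0 if k % 2 == 0 else 0.0 for k in range(n - 1)])
        steps2 = 10.0 - steps1
        c1[:, :, 2] += np.concatenate([[0.0], np.cumsum(steps1)])[:, None]
        c2[:, :, 2] += np.concatenate([[0.0], np.cumsum(steps2)])[:, None]
        assert synchronization(scene_from(c1, c2), "VEL") == pytest.approx(-1.0, abs=1e-9)

    @pytest.mark.parametrize("profile", ["VEL", "ACC"])
    def test_matches_oracle(self, profile):
        scene = toy_scene(seed=23, frames=9)
        assert synchronization(scene, profile) == pytest.approx(
            oracles.o_synchronization(scene, profile), rel=1e-9
        )

    def test_constant_profile_missing(self):
        n = 10
        c1, c2 = facing_pair(frames=n)
        c1[:, :, 2] += 5.0 * np.arange(n)[:, None]  # constant speed
        c2[:, :, 2] += np.random.default_rng(0).normal(0, 5, n)[:, None]
        with pytest.warns(UserWarning):
            assert np.isnan(synchronization(scene_from(c1, c2), "VEL"))


class TestMotionEnergyBalance:
    def test_equal_energy_one(self):
        n = 10
        c1, c2 = facing_pair(frames=n)
        wave = 8.0 * np.sin(np.linspace(0, 2 * np.pi, n))
        c1[:, :, 2] += wave[:, None]
        c2[:, :, 2] += wave[:, None]
        assert motion_energy_balance(scene_from(c1, c2)) == pytest.approx(1.0, abs=1e-12)

    def test_one_static_zero(self):
        n = 10
        c1, c2 = facing_pair(frames=n)
        c1[:, :, 2] += 5.0 * np.arange(n)[:, None]
        assert motion_energy_balance(scene_from(c1, c2)) == 0.0

    def test_both_static_zero(self):
        c1, c2 = facing_pair(frames=5)
        assert motion_energy_balance(scene_from(c1, c2)) == 0.0

    def test_matches_oracle(self):
        scene = toy_scene(seed=29, frames=8)
        assert motion_energy_balance(scene) == pytest.approx(
            oracles.o_motion_energy_balance(scene), rel=1e-9
        )


class TestReduceInterpersonal:
    def test_all_keys_present(self):
        reduced = reduce_interpersonal(toy_scene(seed=2, frames=8))
        assert tuple(reduced) == INTER_FEATURES
        assert all(np.isfinite(v) for v in reduced.values())

    def test_static_scene_degenerate(self):
        c1, c2 = facing_pair(frames=6, separation=900.0)
        with pytest.warns(UserWarning):
            reduced = reduce_interpersonal(scene_from(c1, c2))
        assert np.isfinite(reduced["IPD"])
        assert reduced["PS"] in (0.0, 100.0)
        assert 0.0 <= reduced["IPO"] <= 100.0
        assert reduced["ME_BAL"] == 0.0
        for key in ("DC_VEL", "DC_ACC", "DC_VOL", "DC_LC", "SYNC_VEL", "SYNC_ACC"):
            assert np.isnan(reduced[key])

    def test_counting_table(self, small_dataset):
        rows = [reduce_interpersonal(s) for s in small_dataset]
        assert len(rows) == 8
        assert all(len(r) == 12 for r in rows)
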