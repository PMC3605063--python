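"""Turning-intensity models: geometry, counts, intensities, memory dialects."""

import numpy as np
import pytest

import ringmotion as rm
from ringmotion.models import MemoryState, ZoneSpec, get_model


@pytest.mark.parametrize("a,b,expected", [
    (1.0, 1.0, 0.0),
    (0.0, np.pi, np.pi),
    (0.1, 6.2, abs(((6.2 - 0.1 + np.pi) % (2 * np.pi)) - np.pi)),  # 0.1832
])
def test_angular_separation(a, b, expected):
    assert float(rm.angular_separation(a, b)) == pytest.approx(expected, abs=1e-12)
    assert float(rm.angular_separation(b, a)) == pytest.approx(expected, abs=1e-12)


class TestInZone:
    def test_symmetric_half_width(self):
        z = ZoneSpec("symmetric", 0.2)
        assert rm.in_zone(0.0, rm.ACW, 0.05, z)
        assert not rm.in_zone(0.0, rm.ACW, 0.15, z)
        assert rm.in_zone(0.0, rm.ACW, 0.1, z)  # boundary inclusive

    def test_forward_excludes_behind(self):
        z = ZoneSpec("forward", 0.2)
        assert not rm.in_zone(0.5, rm.ACW, 0.4, z)  # 0.1 behind the heading
        assert rm.in_zone(0.5, rm.ACW, 0.6, z)

    def test_forward_wraps_across_zero(self):
        z = ZoneSpec("forward", 0.2)
        # ACW focal at 6.2; 0.1 is 0.1832 rad ahead through the wrap
        assert rm.in_zone(6.2, rm.ACW, 0.1, z)

    def test_coincident_position(self):
        assert rm.in_zone(1.0, rm.ACW, 1.0, ZoneSpec("symmetric", 0.2))
        assert not rm.in_zone(1.0, rm.ACW, 1.0, ZoneSpec("forward", 0.2))


class TestNeighbourCounts:
    def test_global_counting(self):
        theta = np.zeros(6)
        s = np.array([rm.CW, rm.CW, rm.CW, rm.CW, rm.ACW, rm.ACW])
        assert rm.neighbour_counts(theta, s, 0, ZoneSpec("global")) == (2, 3)

    def test_nearest_k_five_of_six_equals_global(self, rng):
        for _ in range(20):
            theta = rng.random(6) * 2 * np.pi
            s = np.where(rng.random(6) < 0.5, rm.ACW, rm.CW)
            for focal in range(6):
                assert (rm.neighbour_counts(theta, s, focal, ZoneSpec("nearest_k", 5))
                        == rm.neighbour_counts(theta, s, focal, ZoneSpec("global")))

    def test_symmetric_zone_geometry(self):
        theta = np.array([0.0, 0.09, 0.5, 1.0, 2.0, 4.0])
        s = np.array([rm.ACW, rm.CW, rm.ACW, rm.ACW, rm.ACW, rm.ACW])
        assert rm.neighbour_counts(theta, s, 0, ZoneSpec("symmetric", 0.2)) == (1, 0)

    def test_k_must_be_below_n(self):
        theta = np.zeros(3)
        s = np.full(3, rm.ACW)
        with pytest.raises(ValueError):
            rm.neighbour_counts(theta, s, 0, ZoneSpec("nearest_k", 3))


class TestIntensityMarkov:
    def test_mean_field_arithmetic(self):
        lam = rm.intensity_markov(get_model("MF"),
                                  rm.ParamSet(lambda0=-7.5, w_neg=0.76), (5, 0))
        assert lam == pytest.approx(-3.7)

    def test_zero_counts_gives_baseline(self):
        for mid in ("MF", "T", "S1", "S2", "S3", "S4"):
            p = rm.ParamSet(lambda0=-7.5, w_neg=1.0, w_pos=0.5, R=0.2, K=2)
            assert rm.intensity_markov(get_model(mid), p, (0, 0)) == pytest.approx(-7.5)

    def test_positive_neighbours_count_for_s3(self):
        lam = rm.intensity_markov(get_model("S3"),
                                  rm.ParamSet(lambda0=-7.5, w_neg=1.72, w_pos=0.23,
                                              R=0.2), (1, 2))
        assert lam == pytest.approx(-5.32)

    def test_missing_parameter_rejected(self):
        with pytest.raises(ValueError):
            rm.intensity_markov(get_model("MF"), rm.ParamSet(lambda0=-7.5), (1, 0))

    def test_negative_neighbours_never_decrease_probability(self, rng):
        p = rm.ParamSet(lambda0=-7.5, w_neg=0.8)
        model = get_model("MF")
        for n in range(5):
            lo = rm.turn_probability(rm.intensity_markov(model, p, (n, 0)))
            hi = rm.turn_probability(rm.intensity_markov(model, p, (n + 1, 0)))
            assert hi >= lo


class TestIntensityMemory:
    P = rm.ParamSet(lambda0=-7.5, R=0.2, w_neg=1.0, alpha=0.92)

    def test_single_encounter_decays_geometrically(self):
        model = get_model("D1")
        mem = MemoryState()
        lam, mem = rm.intensity_memory_step(model, self.P, mem, {1: True}, False)
        assert lam == pytest.approx(-6.5)
        lam, mem = rm.intensity_memory_step(model, self.P, mem, {}, False)
        assert lam == pytest.approx(-6.58)
        lam, mem = rm.intensity_memory_step(model, self.P, mem, {}, False)
        assert lam == pytest.approx(-7.5 + 0.92 ** 2, abs=1e-12)

    def test_reset_to_baseline_after_own_turn(self):
        model = get_model("D3")
        p = rm.ParamSet(lambda0=-7.5, R=0.2, w_neg=1.0, w_pos=-2.0, alpha=0.9)
        mem = MemoryState()
        _, mem = rm.intensity_memory_step(model, p, mem, {1: True, 2: False}, False)
        lam, mem = rm.intensity_memory_step(model, p, mem, {1: True}, True)
        assert lam == -7.5
        assert mem.traces == {}

    def test_alpha_zero_matches_markov_both_dialects(self, rng):
        for _ in range(50):
            n = 6
            theta = rng.random(n) * 2 * np.pi
            s = np.where(rng.random(n) < 0.5, rm.ACW, rm.CW)
            R = 0.05 + 0.5 * rng.random()
            for sid, did in (("S1", "D1"), ("S3", "D3"), ("S2", "D2"), ("S4", "D4")):
                sm, dm = get_model(sid), get_model(did)
                kw = dict(lambda0=-7.5, R=R, w_neg=1.3)
                if sm.uses_positive:
                    kw["w_pos"] = -0.7
                sp = rm.ParamSet(**kw)
                dp = rm.ParamSet(**kw, alpha=0.0)
                zone = ZoneSpec(sm.zone, R)
                members = {j: bool(s[j] != s[0]) for j in range(1, n)
                           if rm.in_zone(theta[0], s[0], theta[j], zone)}
                lam_s = rm.intensity_markov(sm, sp, rm.neighbour_counts(theta, s, 0, zone))
                for dialect in ("trace", "aggregate"):
                    lam_d, _ = rm.intensity_memory_step(dm, dp, MemoryState(),
                                                        members, False, dialect)
                    assert lam_d == pytest.approx(lam_s, abs=1e-12)

    def test_alpha_bounds_enforced(self):
        with pytest.raises(ValueError):
            rm.ParamSet(lambda0=-7.5, R=0.2, w_neg=1.0, alpha=1.0)


class TestTurnProbability:
    def test_values(self):
        assert rm.turn_probability(0.0) == pytest.approx(0.5)
        assert rm.turn_probability(-7.5) == pytest.approx(1 / (1 + np.exp(7.5)))
        assert rm.turn_probability(-7.5) == pytest.approx(5.5277e-4, rel=1e-4)

    def test_logistic_symmetry(self, rng):
        lam = rng.normal(0, 5, 100)
        np.testing.assert_allclose(rm.turn_probability(lam) + rm.turn_probability(-lam),
                                   1.0, atol=1e-12)


def test_rotation_leaves_counts_invariant(rng):
    theta = rng.random(6) * 2 * np.pi
    s = np.where(rng.random(6) < 0.5, rm.ACW, rm.CW)
    shift = rng.random() * 2 * np.pi
    rotated = (theta + shift) % (2 * np.pi)
    for zone in (ZoneSpec("global"), ZoneSpec("nearest_k", 3),
                 ZoneSpec("symmetric", 0.3), ZoneSpec("forward", 0.3)):
        for focal in range(6):
            assert (rm.neighbour_counts(theta, s, focal, zone)
                    == rm.neighbour_counts(rotated, s, focal, zone))
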