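"""Polarisation, outcome distributions, KL divergence and the G-test."""

import numpy as np
import pytest
from scipy import stats as sps

import ringmotion as rm
from ringmotion.stats import OutcomeDistribution


@pytest.mark.parametrize("c,n,expected", [(6, 6, 1.0), (3, 6, 0.0), (4, 6, 1 / 3)])
def test_polarisation(c, n, expected):
    assert rm.polarisation(c, n) == pytest.approx(expected)


@pytest.mark.parametrize("n,expected", [(1, 1.0), (2, 0.5), (6, 0.3125)])
def test_expected_random_polarisation(n, expected):
    assert rm.expected_random_polarisation(n) == pytest.approx(expected, abs=1e-12)


class TestExcessPolarisation:
    def test_fully_aligned_six(self):
        states = np.full((50, 6), rm.CW, dtype=np.int8)
        recs = [rm.OrientationRecord.from_states(f"t{i}", 0.1, states)
                for i in range(3)]
        series = rm.excess_polarisation_series(recs)
        np.testing.assert_allclose(series, 1 - 0.3125, atol=1e-12)

    def test_single_individual_is_zero(self):
        states = np.full((50, 1), rm.ACW, dtype=np.int8)
        rec = rm.OrientationRecord.from_states("t", 0.1, states)
        np.testing.assert_allclose(rm.excess_polarisation_series([rec]), 0.0)

    def test_iid_fair_orientations_near_zero(self, rng):
        # independent fair coins at every frame: series within CLT bounds
        recs = []
        for i in range(2000):
            states = np.where(rng.random((8, 6)) < 0.5, rm.ACW, rm.CW).astype(np.int8)
            recs.append(rm.OrientationRecord("t%d" % i, 0.1, states,
                                             (np.diff(states, axis=0) != 0).astype(np.uint8)))
        series = rm.excess_polarisation_series(recs)
        assert np.all(np.abs(series) <= 0.03)


class TestFinalOutcome:
    def _rec_from_counts(self, counts, n=6, dt=0.1333):
        # build a state matrix whose clockwise counts follow `counts`
        T = len(counts)
        states = np.full((T, n), rm.ACW, dtype=np.int8)
        for t, c in enumerate(counts):
            states[t, :c] = rm.CW
        return rm.OrientationRecord.from_states("t", dt, states)

    def test_constant_full_alignment(self):
        rec = self._rec_from_counts([6] * 100)
        dist = rm.final_outcome_distribution([rec], window_s=10)
        assert dist.proportions[6] == 1.0

    def test_rounding_half_up(self):
        counts = [5, 6] * 50  # mean 5.5 over any window
        rec = self._rec_from_counts(counts)
        dist = rm.final_outcome_distribution([rec], window_s=10)
        assert dist.proportions[6] == 1.0

    def test_short_trial_rejected(self):
        rec = self._rec_from_counts([3] * 10)
        with pytest.raises(ValueError, match="window"):
            rm.final_outcome_distribution([rec], window_s=10)

    def test_null_ensemble_near_binomial(self):
        s = rm.SimSettings(n_agents=6, model="Null", params=rm.ParamSet(lambda0=-7.5),
                           duration_s=30.0, seed=31)
        ens = rm.run_ensemble(s, 100)
        dist = rm.final_outcome_distribution(ens)
        binom = sps.binom.pmf(np.arange(7), 6, 0.5)
        assert 0.5 * np.abs(dist.proportions - binom).sum() <= 0.15


class TestKlAndGTest:
    def test_identical_distributions(self):
        p = OutcomeDistribution(1, np.array([0.5, 0.5]), 10)
        assert rm.kl_divergence(p, p) == 0.0
        res = rm.g_test(p, p)
        assert res.g_statistic == 0.0 and res.p_value == 1.0

    def test_two_category_value(self):
        p = OutcomeDistribution(1, np.array([0.5, 0.5]), 10)
        q = OutcomeDistribution(1, np.array([0.25, 0.75]), 100)
        kl = rm.kl_divergence(p, q)
        assert kl == pytest.approx(0.5 * np.log(2) + 0.5 * np.log(2 / 3), abs=1e-12)
        assert kl == pytest.approx(0.1438, abs=1e-4)
        res = rm.g_test(p, q)
        assert res.g_statistic == pytest.approx(2 * 10 * kl)
        assert res.df == 1
        assert res.p_value == pytest.approx(0.0899, abs=2e-3)

    def test_non_negative_on_random_pairs(self, rng):
        for _ in range(200):
            p = rng.dirichlet(np.ones(7))
            q = rng.dirichlet(np.ones(7))
            dp = OutcomeDistribution(6, p, 50)
            dq = OutcomeDistribution(6, q, 50)
            assert rm.kl_divergence(dp, dq) >= -1e-12

    def test_zero_simulated_mass_smoothed_to_finite(self):
        p = OutcomeDistribution(2, np.array([0.5, 0.0, 0.5]), 20)
        q = OutcomeDistribution(2, np.array([0.0, 1.0, 0.0]), 100)
        kl = rm.kl_divergence(p, q)
        assert np.isfinite(kl) and kl > 0
        assert np.isfinite(rm.g_test(p, q).p_value)

    def test_mismatched_sizes_rejected(self):
        p = OutcomeDistribution(1, np.array([0.5, 0.5]), 10)
        q = OutcomeDistribution(2, np.array([0.3, 0.3, 0.4]), 10)
        with pytest.raises(ValueError):
            rm.kl_divergence(p, q)


class TestLocalityCurve:
    def test_fully_aligned_trial_gives_empty_curve(self):
        T, n = 20, 4
        theta = np.linspace(0, 2, T)[:, None] + np.linspace(0, 3, n)[None, :]
        times = np.arange(T) / 7.5
        traj = rm.TrialTrajectory("t", 7.5, times, theta % (2 * np.pi))
        rec = rm.OrientationRecord.from_states("t", 1 / 7.5,
                                               np.full((T, n), rm.ACW, dtype=np.int8))
        with pytest.warns(RuntimeWarning, match="no opposite"):
            _, freq, steps, _ = rm.turn_frequency_vs_nearest_opponent([rec], [traj])
        assert steps.sum() == 0
        assert np.all(np.isnan(freq))

    def test_counts_cover_every_opposed_focal_step(self, rng):
        s = rm.SimSettings(n_agents=6, model="Null", params=rm.ParamSet(lambda0=-6.0),
                           duration_s=20.0, seed=41)
        res = rm.simulate_trial(s)
        _, _, steps, _ = rm.turn_frequency_vs_nearest_opponent([res.record],
                                                               [res.trajectory])
        opp_steps = 0
        st = res.record.state[:-1]
        for k in range(st.shape[0]):
            for i in range(6):
                if np.any(st[k] != st[k, i]):
                    opp_steps += 1
        assert steps.sum() == opp_steps


class TestValidateModel:
    TEMPLATE = rm.SimSettings(n_agents=6, model="Null",
                              params=rm.ParamSet(lambda0=-7.5),
                              duration_s=30.0, seed=51)

    def test_single_set_returns_its_p(self):
        obs = OutcomeDistribution(6, sps.binom.pmf(np.arange(7), 6, 0.5), 50)
        res = rm.validate_model(obs, "Null", rm.ParamSet(lambda0=-7.5),
                                self.TEMPLATE, n_sets=1, set_size=40)
        assert len(res.tests) == 1
        assert res.median_p == res.p_values[0]

    def test_matched_generator_is_consistent(self):
        """Observed outcomes drawn from the same model should pass the check."""
        consistent = 0
        for k in range(3):
            obs_settings = rm.SimSettings(n_agents=6, model="Null",
                                          params=rm.ParamSet(lambda0=-7.5),
                                          duration_s=30.0, seed=600 + k)
            obs = rm.final_outcome_distribution(rm.run_ensemble(obs_settings, 50))
            template = rm.SimSettings(n_agents=6, model="Null",
                                      params=rm.ParamSet(lambda0=-7.5),
                                      duration_s=30.0, seed=700 + k)
            res = rm.validate_model(obs, "Null", rm.ParamSet(lambda0=-7.5),
                                    template, n_sets=3, set_size=40)
            consistent += int(res.consistent)
        assert consistent >= 2

    def test_extreme_separation_is_inconsistent(self):
        obs = OutcomeDistribution(6, np.eye(7)[6], 50)  # all trials fully CW
        res = rm.validate_model(obs, "Null", rm.ParamSet(lambda0=-7.5),
                                self.TEMPLATE, n_sets=2, set_size=50)
        assert not res.consistent
        assert res.median_p < 1e-6
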