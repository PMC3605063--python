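"""Likelihood, priors, evidence estimation, MAP extraction."""

import numpy as np
import pytest

import ringmotion as rm
from ringmotion.errors import DegenerateDataError
from ringmotion.experiments import log_evidence_quadrature
from ringmotion.models import MemoryState, ZoneSpec, free_param_names, get_model

DT = 1 / 7.5


def _logsig(x):
    return -np.logaddexp(0.0, -x)


def _make_random_dataset(rng, n_trials=2, T=30, n=4):
    trajs, recs = [], []
    for b in range(n_trials):
        theta = rng.random((T, n)) * 2 * np.pi
        s = np.empty((T, n), dtype=np.int8)
        s[0] = np.where(rng.random(n) < 0.5, rm.ACW, rm.CW)
        flips = rng.random((T - 1, n)) < 0.15
        for t in range(1, T):
            s[t] = np.where(flips[t - 1], -s[t - 1], s[t - 1])
        times = np.arange(T) * DT
        trajs.append(rm.TrialTrajectory(f"r{b}", 7.5, times, theta))
        recs.append(rm.OrientationRecord.from_states(f"r{b}", DT, s))
    return trajs, recs


def _naive_loglik(trajs, recs, model_id, params, snap, dialect="trace"):
    """Independent likelihood route built from the single-step model operations."""
    model = get_model(model_id)
    total = 0.0
    for tr, rec in zip(trajs, recs):
        T, n = tr.n_frames, tr.n_prawns
        mems = [MemoryState() for _ in range(n)]
        for i in range(n):
            for k in range(T - 1):
                theta = tr.theta_rad[k]
                s = rec.state[k]
                turned = bool(rec.events[k - 1, i]) if k > 0 else False
                if model.id == "Null":
                    lam = params.lambda0
                elif not model.memory:
                    if model.zone == "global":
                        zone = ZoneSpec("global")
                    elif model.zone == "nearest_k":
                        zone = ZoneSpec("nearest_k", params.K)
                    else:
                        zone = ZoneSpec(model.zone, snap(params.R))
                    lam = rm.intensity_markov(model, params,
                                              rm.neighbour_counts(theta, s, i, zone))
                else:
                    zone = ZoneSpec(model.zone, snap(params.R))
                    members = {j: bool(s[j] != s[i]) for j in range(n)
                               if j != i and rm.in_zone(theta[i], s[i], theta[j], zone)}
                    lam, mems[i] = rm.intensity_memory_step(model, params, mems[i],
                                                            members, turned, dialect)
                lp = _logsig(lam) if rec.events[k, i] else _logsig(-lam)
                total += lp
    return total


ALL_PARAMS = {
    "Null": rm.ParamSet(lambda0=-3.0),
    "MF": rm.ParamSet(lambda0=-3.0, w_neg=0.7),
    "T": rm.ParamSet(lambda0=-3.0, w_neg=0.7, K=2),
    "S1": rm.ParamSet(lambda0=-3.0, w_neg=0.7, R=0.8),
    "S2": rm.ParamSet(lambda0=-3.0, w_neg=0.7, R=0.8),
    "S3": rm.ParamSet(lambda0=-3.0, w_neg=0.7, w_pos=-0.4, R=0.8),
    "S4": rm.ParamSet(lambda0=-3.0, w_neg=0.7, w_pos=-0.4, R=0.8),
    "D1": rm.ParamSet(lambda0=-3.0, w_neg=0.7, R=0.8, alpha=0.9),
    "D2": rm.ParamSet(lambda0=-3.0, w_neg=0.7, R=0.8, alpha=0.9),
    "D3": rm.ParamSet(lambda0=-3.0, w_neg=0.7, w_pos=-0.4, R=0.8, alpha=0.9),
    "D4": rm.ParamSet(lambda0=-3.0, w_neg=0.7, w_pos=-0.4, R=0.8, alpha=0.9),
}


@pytest.mark.parametrize("model_id", list(ALL_PARAMS))
def test_fast_likelihood_equals_single_step_route(model_id, rng):
    """The vectorised likelihood must agree exactly with the per-step model ops."""
    trajs, recs = _make_random_dataset(rng)
    data = rm.FineScaleData(trajs, recs, r_max=1.0)
    params = ALL_PARAMS[model_id]
    fast = data.loglik(model_id, params)
    slow = _naive_loglik(trajs, recs, model_id, params, data.snap_radius)
    assert fast == pytest.approx(slow, abs=1e-8)


@pytest.mark.parametrize("model_id", ["D1", "D3"])
def test_aggregate_dialect_matches_single_step_route(model_id, rng):
    trajs, recs = _make_random_dataset(rng)
    data = rm.FineScaleData(trajs, recs, r_max=1.0)
    params = ALL_PARAMS[model_id]
    fast = data.loglik(model_id, params, dialect="aggregate")
    slow = _naive_loglik(trajs, recs, model_id, params, data.snap_radius,
                         dialect="aggregate")
    assert fast == pytest.approx(slow, abs=1e-8)


class TestNullClosedForms:
    def test_no_change_two_steps(self):
        theta = np.array([[0.0], [0.1], [0.2]])
        traj = rm.TrialTrajectory("a", 7.5, np.arange(3) * DT, theta)
        rec = rm.OrientationRecord.from_states("a", DT, np.full((3, 1), rm.ACW))
        ll = rm.log_likelihood([rec], [traj], get_model("Null"),
                               rm.ParamSet(lambda0=-7.5))
        p = 1 / (1 + np.exp(7.5))
        assert ll == pytest.approx(2 * np.log(1 - p), abs=1e-12)
        assert ll == pytest.approx(-0.0011058, abs=1e-6)

    def test_single_change(self):
        theta = np.array([[0.0], [0.1]])
        traj = rm.TrialTrajectory("a", 7.5, np.arange(2) * DT, theta)
        rec = rm.OrientationRecord.from_states(
            "a", DT, np.array([[rm.ACW], [rm.CW]], dtype=np.int8))
        ll = rm.log_likelihood([rec], [traj], get_model("Null"),
                               rm.ParamSet(lambda0=-7.5))
        assert ll == pytest.approx(-7.5 - np.log1p(np.exp(-7.5)), abs=1e-12)
        assert ll == pytest.approx(-7.5006, abs=1e-4)

    def test_trial_order_invariance(self, rng):
        trajs, recs = _make_random_dataset(rng, n_trials=4)
        a = rm.FineScaleData(trajs, recs).loglik("Null", rm.ParamSet(lambda0=-2.0))
        b = rm.FineScaleData(trajs[::-1], recs[::-1]).loglik(
            "Null", rm.ParamSet(lambda0=-2.0))
        assert a == pytest.approx(b, abs=1e-9)


class TestBaseline:
    def _rec_with_rate(self, rate, steps=100000):
        n_events = int(round(rate * steps))
        states = np.empty(steps + 1, dtype=np.int8)
        states[0] = rm.ACW
        flips = np.zeros(steps, dtype=bool)
        flips[:n_events] = True
        for t in range(1, steps + 1):
            states[t] = -states[t - 1] if flips[t - 1] else states[t - 1]
        return rm.OrientationRecord.from_states("b", DT, states[:, None])

    def test_inverse_logit_of_rate(self):
        rec = self._rec_with_rate(5.5277e-4, steps=1_000_000)
        lam0 = rm.estimate_baseline([rec])
        r = rec.events.sum() / rec.events.size
        assert lam0 == pytest.approx(np.log(r / (1 - r)), abs=1e-12)
        assert lam0 == pytest.approx(-7.5, abs=0.01)

    def test_half_rate_gives_zero(self):
        rec = self._rec_with_rate(0.5, steps=1000)
        assert rm.estimate_baseline([rec]) == pytest.approx(0.0, abs=1e-12)

    def test_duplication_invariance(self):
        rec = self._rec_with_rate(0.01, steps=10000)
        one = rm.estimate_baseline([rec])
        two = rm.estimate_baseline([rec, rec])
        assert one == pytest.approx(two, abs=1e-12)

    def test_zero_rate_raises(self):
        rec = rm.OrientationRecord.from_states("b", DT, np.full((100, 1), rm.ACW))
        with pytest.raises(DegenerateDataError):
            rm.estimate_baseline([rec])


class TestLogPrior:
    PRIOR = rm.PriorSpec(lambda0=-7.5, w_max=5.0, r_max=0.5, n_agents=6)

    def test_uniform_density(self):
        lp = rm.log_prior(rm.ParamSet(lambda0=-7.5, w_neg=2.5), self.PRIOR, "MF")
        assert lp == pytest.approx(-np.log(5.0))

    def test_out_of_support(self):
        lp = rm.log_prior(rm.ParamSet(lambda0=-7.5, w_neg=1.0, R=0.6),
                          self.PRIOR, "S1")
        assert lp == -np.inf

    def test_discrete_uniform_over_k(self):
        for k in range(1, 6):
            lp = rm.log_prior(rm.ParamSet(lambda0=-7.5, w_neg=1.0, K=k),
                              self.PRIOR, "T")
            assert lp == pytest.approx(np.log(1 / 5) - np.log(5.0))

    def test_lambda0_pinned(self):
        lp = rm.log_prior(rm.ParamSet(lambda0=-7.0, w_neg=1.0), self.PRIOR, "MF")
        assert lp == -np.inf


class TestAis:
    def test_null_evidence_is_exact(self, mf_small_data):
        prior = rm.PriorSpec(lambda0=-7.5, n_agents=6)
        res = rm.ais_log_marginal(mf_small_data, "Null", prior, rm.AisSettings(seed=3))
        assert res.mc_se_nats == 0.0
        assert res.log_ml_nats == pytest.approx(
            mf_small_data.loglik("Null", rm.ParamSet(lambda0=-7.5)))
        assert res.log_ml_bits == pytest.approx(res.log_ml_nats / np.log(2))

    def test_deterministic_for_fixed_seed(self, mf_small_data):
        prior = rm.PriorSpec(lambda0=-7.5, n_agents=6)
        s = rm.AisSettings(n_samples=50, n_temperatures=20, seed=9)
        a = rm.ais_log_marginal(mf_small_data, "MF", prior, s)
        b = rm.ais_log_marginal(mf_small_data, "MF", prior, s)
        assert a.log_ml_nats == b.log_ml_nats
        assert a.map_params == b.map_params

    def test_agrees_with_quadrature(self, mf_small_data):
        prior = rm.PriorSpec(lambda0=-7.5, n_agents=6)
        res = rm.ais_log_marginal(mf_small_data, "MF", prior,
                                  rm.AisSettings(n_samples=400, n_temperatures=60,
                                                 seed=4))
        quad = log_evidence_quadrature(mf_small_data, -7.5, prior.w_max)
        assert abs(res.log_ml_nats - quad) <= 4 * res.mc_se_nats

    def test_evidence_bounded_by_grid_max_likelihood(self, mf_small_data):
        prior = rm.PriorSpec(lambda0=-7.5, n_agents=6)
        res = rm.ais_log_marginal(mf_small_data, "MF", prior,
                                  rm.AisSettings(n_samples=100, n_temperatures=30,
                                                 seed=5))
        grid = mf_small_data.loglik_batch("MF", {"w_neg": np.linspace(0, 5, 200)},
                                          -7.5)
        assert res.log_ml_nats <= grid.max() + 1e-9

    def test_map_is_best_visited_sample(self, mf_small_data):
        prior = rm.PriorSpec(lambda0=-7.5, n_agents=6)
        res = rm.ais_log_marginal(mf_small_data, "MF", prior,
                                  rm.AisSettings(n_samples=60, n_temperatures=20,
                                                 seed=6))
        score = res.samples["log_lik"] + res.samples["log_prior"]
        assert res.map_log_posterior == pytest.approx(score.max())
        assert rm.map_estimate(res) == res.map_params

    def test_compare_models_order_invariant(self, mf_small_data):
        prior = rm.PriorSpec(lambda0=-7.5, n_agents=6)
        s = rm.AisSettings(n_samples=60, n_temperatures=20, seed=7)
        a = rm.compare_models(mf_small_data, ["Null", "MF"], prior, s)
        b = rm.compare_models(mf_small_data, ["MF", "Null"], prior, s)
        assert [r.model_id for r in a] == [r.model_id for r in b]
        assert a[0].log_ml_nats == pytest.approx(b[0].log_ml_nats)


def test_ais_error_shrinks_with_more_samples():
    """Mean |AIS - quadrature| over 10 seeds falls as chains grow 100 -> 1000."""
    s = rm.SimSettings(n_agents=6, model="MF",
                       params=rm.ParamSet(lambda0=-7.5, w_neg=0.76),
                       duration_s=201 / 7.5, seed=101)
    res = rm.run_ensemble(s, 1)[0]
    data = rm.FineScaleData([res.trajectory], [res.record])
    quad = log_evidence_quadrature(data, -7.5, 5.0)
    prior = rm.PriorSpec(lambda0=-7.5, n_agents=6)
    err = {}
    for n in (100, 1000):
        errors = [abs(rm.ais_log_marginal(
            data, "MF", prior,
            rm.AisSettings(n_samples=n, n_temperatures=40, seed=1000 + r)
        ).log_ml_nats - quad) for r in range(10)]
        err[n] = np.mean(errors)
    assert err[1000] < err[100]


def test_no_clamping_on_generator_matched_data(mf_small_data):
    mf_small_data.loglik("MF", rm.ParamSet(lambda0=-7.5, w_neg=0.76))
    assert mf_small_data.last_clamp_events == 0
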