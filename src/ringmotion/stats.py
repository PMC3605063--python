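"""Large-scale observables and quality-of-fit between experiment and simulation.

The group-level order parameter is the polarisation ``|2C - n| / n`` where
``C`` is the number of clockwise-moving individuals out of ``n``.  Randomly
oriented groups have non-zero expected polarisation (larger for smaller
groups, from the binomial distribution of C), so comparisons use the *excess*
polarisation: measured minus the binomial expectation.

The model-vs-data comparison object is the distribution of trial outcomes —
how many individuals travel clockwise at the end of a trial, averaged over the
final ten seconds.  Agreement is scored by the Kullback-Leibler divergence
from the observed outcome distribution to the simulated one, whose statistical
significance comes from the G-test: ``G = 2 m KL`` (natural log, m trials) is
chi-squared with ``n`` degrees of freedom (n+1 outcome categories) under the
null hypothesis that the observed outcomes are draws from the simulated
distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from ._angles import wrap_signed
from .data import CW
from .models import ModelSpec, ParamSet, get_model
from .simulate import SimSettings, SimResult, run_ensemble


@dataclass
class OutcomeDistribution:
    """Distribution of final clockwise counts over trials of one group size."""

    n: int
    proportions: np.ndarray  # length n+1, sums to 1
    n_trials: int

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        if len(self.proportions) != self.n + 1:
            raise ValueError("need n+1 outcome categories")
        if np.any(self.proportions < 0) or abs(self.proportions.sum() - 1.0) > 1e-12:
            raise ValueError("proportions must be a distribution")
        if self.n_trials < 1:
            raise ValueError("need at least one trial")


@dataclass
class FitTestResult:
    """KL divergence with its G-test significance."""

    kl_nats: float
    g_statistic: float
    df: int
    p_value: float


def polarisation(c, n):
    """Order parameter |2c - n| / n in [0, 1]."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0) or np.any(c > n) or n < 1:
        raise ValueError("need 0 <= c <= n, n >= 1")
    return np.abs(2.0 * c - n) / n


def expected_random_polarisation(n: int) -> float:
    """E[|2X - n| / n] for X ~ Binomial(n, 1/2), by exact enumeration."""
    if n < 1:
        raise ValueError("n must be >= 1")
    k = np.arange(n + 1)
    return float(np.sum(sps.binom.pmf(k, n, 0.5) * np.abs(2.0 * k - n) / n))


def excess_polarisation_series(records) -> np.ndarray:
    """Mean-over-trials polarisation time series minus the binomial expectation.

    All records must share group size and duration.
    """
    if not records:
        raise ValueError("no records")
    n = records[0].n_prawns
    T = records[0].n_frames
    if any(r.n_prawns != n or r.n_frames != T for r in records):
        raise ValueError("records must share group size and duration")
    C = np.stack([r.clockwise_counts() for r in records])  # (m, T)
    return polarisation(C, n).mean(axis=0) - expected_random_polarisation(n)


def final_outcome_distribution(results, window_s: float = 10.0) -> OutcomeDistribution:
    """Outcome distribution from the final ``window_s`` of each trial.

    Accepts :class:`OrientationRecord` or :class:`SimResult` items.  Per
    trial the clockwise count is averaged over the last window and rounded
    half-up to an integer category.
    """
    records = [r.record if isinstance(r, SimResult) else r for r in results]
    if not records:
        raise ValueError("no trials")
    n = records[0].n_prawns
    cats = []
    for rec in records:
        if rec.n_prawns != n:
            raise ValueError("trials must share group size")
        k = int(round(window_s / rec.dt_s))
        if rec.n_frames < k:
            raise ValueError(f"trial {rec.trial_id} shorter than the {window_s} s window")
        mean_c = rec.clockwise_counts()[-k:].mean()
        cats.append(int(np.floor(mean_c + 0.5)))  # round half-up
    counts = np.bincount(cats, minlength=n + 1).astype(float)
    return OutcomeDistribution(n, counts / counts.sum(), len(records))


def kl_divergence(p_exp: OutcomeDistribution, q_sim: OutcomeDistribution) -> float:
    """KL(p || q) in nats; categories with p=0 contribute nothing.

    Simulated categories with zero mass but observed support receive a
    pseudo-mass of ``1/(2 * n_simulations)`` before renormalisation, so the
    divergence (and the G statistic built on it) stays finite: an outcome the
    simulation never produced in m runs is treated as having probability below
    one in 2m rather than zero.
    """
    if p_exp.n != q_sim.n:
        raise ValueError("distributions must share group size")
    p = p_exp.proportions
    q = q_sim.proportions.copy()
    zero = (q == 0) & (p > 0)
    if np.any(zero):
        q[zero] = 1.0 / (2.0 * q_sim.n_trials)
        q = q / q.sum()
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def g_test(p_exp: OutcomeDistribution, q_sim: OutcomeDistribution) -> FitTestResult:
    """Likelihood-ratio goodness of fit of observed outcomes to the simulation.

    ``G = 2 m KL`` with m the number of observed trials; the reference
    distribution is chi-squared with ``n`` degrees of freedom (n+1 categories
    minus one).
    """
    kl = kl_divergence(p_exp, q_sim)
    m = p_exp.n_trials
    g = 2.0 * m * kl
    df = p_exp.n
    return FitTestResult(kl, g, df, float(sps.chi2.sf(g, df)))


def turn_frequency_vs_nearest_opponent(records, trajs, bin_width_rad: float = 0.05):
    """Empirical turn frequency binned by distance to the nearest opposite-facing
    neighbour.

    For every decision step and focal individual with at least one
    opposite-facing neighbour, the signed angular separation (positive =
    ahead of the focal) to the nearest one is recorded together with whether
    the focal turned at that step.  Steps with no opposite-facing neighbour
    are excluded.  Returns ``(bin_centres, frequency, n_steps, n_events)``;
    frequency is NaN in empty bins.
    """
    recs = {r.trial_id: r for r in records}
    edges = np.arange(-np.pi, np.pi + bin_width_rad, bin_width_rad)
    centres = 0.5 * (edges[:-1] + edges[1:])
    steps = np.zeros(len(centres))
    events = np.zeros(len(centres))
    for tr in trajs:
        rec = recs[tr.trial_id]
        if tr.n_prawns < 2:
            continue
        th = tr.theta_rad[:-1]
        s = rec.state[:-1]
        E = rec.events
        diff = th[:, None, :] - th[:, :, None]           # [k, i, j] = th_j - th_i
        d_signed = wrap_signed(s[:, :, None] * diff)     # ahead of focal = positive
        opp = s[:, :, None] != s[:, None, :]
        dist = np.where(opp, np.abs(d_signed), np.inf)
        has_opp = opp.any(axis=2)
        j_near = np.argmin(dist, axis=2)
        d_near = np.take_along_axis(d_signed, j_near[:, :, None], axis=2)[:, :, 0]
        d = d_near[has_opp]
        e = E[has_opp].astype(float)
        idx = np.clip(np.digitize(d, edges) - 1, 0, len(centres) - 1)
        steps += np.bincount(idx, minlength=len(centres))
        events += np.bincount(idx, weights=e, minlength=len(centres))
    if steps.sum() == 0:
        warnings.warn("no opposite-facing pairs anywhere; empty curve", RuntimeWarning)
    with np.errstate(invalid="ignore"):
        freq = np.where(steps > 0, events / np.maximum(steps, 1), np.nan)
    return centres, freq, steps.astype(int), events.astype(int)


@dataclass
class ValidationResult:
    """Outcome of the large-scale consistency check for one model."""

    model_id: str
    tests: list
    p_values: np.ndarray
    median_p: float
    consistent: bool  # median p > 0.05


def validate_model(observed, model: ModelSpec | str, params: ParamSet,
                   sim_template: SimSettings, n_sets: int = 10,
                   set_size: int = 100, window_s: float = 10.0) -> ValidationResult:
    """Test observed outcomes against repeated simulation of a fitted model.

    ``observed`` is an :class:`OutcomeDistribution` (or a list of records from
    which one is built).  ``n_sets`` independent sets of ``set_size``
    simulations are run at the template's group size and duration; each set's
    outcome distribution is G-tested against the observed one.  The model is
    flagged consistent when the median p-value exceeds 0.05.
    """
    if not isinstance(observed, OutcomeDistribution):
        observed = final_outcome_distribution(observed, window_s=window_s)
    model = get_model(model) if isinstance(model, str) else model
    from dataclasses import replace
    settings = replace(sim_template, model=model, params=params)
    tests = []
    for k in range(n_sets):
        sims = run_ensemble(settings, set_size, start_index=k * set_size)
        q = final_outcome_distribution(sims, window_s=window_s)
        tests.append(g_test(observed, q))
    p = np.array([t.p_value for t in tests])
    med = float(np.median(p))
    return ValidationResult(model.id, tests, p, med, med > 0.05)
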