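"""Forward simulation of direction-switching agents on the ring.

Agents are self-propelled particles on the annulus midline.  Each carries a
binary orientation (CW / ACW).  Per time step, agents are processed in a fresh
uniformly random order and each moves by a Gaussian step along its heading
(negative draws are permitted — occasional backward drift, as seen in real
animals).  After all agents have moved, every agent decides whether to reverse
direction: the turn probability is the logistic link of the model's turning
intensity evaluated on the synchronous post-move snapshot, with orientations
frozen at their pre-decision values so all agents see the same configuration.
Memory-model traces are propagated across steps and reset on the step after an
agent's own turn.

Simulation output is exact ground truth: noise-free positions, true
orientation states, and the per-step clockwise count ``C(t)`` used by the
large-scale statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._angles import TWO_PI, wrap_angle
from .data import CW, OrientationRecord, TrialTrajectory
from .models import (ModelSpec, ParamSet, get_model, memory_trace_update,
                     require_params, turn_probability)


@dataclass
class SimSettings:
    """One trial's simulation settings.

    ``speed_mean_rad_s``/``speed_sd_rad_s`` parameterise the per-step
    displacement ``N(speed_mean*dt, speed_sd^2*dt)`` along the heading (the
    sqrt(dt) noise scaling keeps variance frame-rate consistent).  Optional
    ``init_theta``/``init_orientation`` pin the initial condition; by default
    positions are uniform on the ring and orientations are fair coin flips.
    """

    n_agents: int
    model: str | ModelSpec = "Null"
    params: ParamSet = field(default_factory=lambda: ParamSet(lambda0=-7.5))
    dt_s: float = 1.0 / 7.5
    duration_s: float = 360.0
    speed_mean_rad_s: float = 0.8
    speed_sd_rad_s: float = 0.4
    seed: int = 0
    dialect: str = "trace"
    init_theta: np.ndarray | None = None
    init_orientation: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_agents < 1:
            raise ValueError("n_agents must be >= 1")
        if self.dt_s <= 0 or self.duration_s < self.dt_s:
            raise ValueError("need dt > 0 and duration >= dt")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s / self.dt_s))


@dataclass
class SimResult:
    """Ground-truth output of one simulated trial."""

    trajectory: TrialTrajectory
    record: OrientationRecord
    clockwise: np.ndarray  # (T,) number of CW agents per frame


@dataclass
class _MemCarry:
    """Mutable quantities the decision rule carries between steps."""

    tau: np.ndarray            # (N, N) per-neighbour traces (trace dialect)
    turned_prev: np.ndarray    # (N,) bool: agent turned at the previous step
    lam_prev: np.ndarray       # (N,) previous intensities (aggregate dialect)
    prev_inz: np.ndarray       # (N, N) previous zone membership (aggregate)


def _snapshot_lambda(model: ModelSpec, params: ParamSet, theta, s,
                     carry: _MemCarry, dialect: str):
    """Turning intensities for all agents from one synchronous snapshot."""
    n = len(theta)
    lam0 = params.lambda0
    if model.id == "Null" or n == 1:
        lam = np.full(n, lam0)
        return lam, carry

    diff = theta[None, :] - theta[:, None]          # [i, j] = theta_j - theta_i
    opp = s[:, None] != s[None, :]
    idx = np.arange(n)
    if model.zone == "global":
        return lam0 + params.w_neg * opp.sum(axis=1), carry  # diagonal is False
    if model.zone == "nearest_k":
        ad = np.abs(diff) % TWO_PI
        sep = np.minimum(ad, TWO_PI - ad)
        sep[idx, idx] = np.inf
        order = np.argsort(sep, axis=1, kind="stable")[:, : params.K]
        nn = np.take_along_axis(opp, order, axis=1).sum(axis=1)
        return lam0 + params.w_neg * nn, carry
    if model.zone == "symmetric":
        ad = np.abs(diff) % TWO_PI
        sep = np.minimum(ad, TWO_PI - ad)
        sep[idx, idx] = np.inf
        inz = sep <= params.R / 2.0
    else:  # forward
        ahead = (s[:, None] * diff) % TWO_PI
        ahead[idx, idx] = np.inf
        inz = (ahead > 0) & (ahead <= params.R)

    W = np.where(opp, params.w_neg, params.w_pos if model.uses_positive else 0.0)
    if not model.memory:
        return lam0 + (W * inz).sum(axis=1), carry
    if dialect == "aggregate":
        new = inz & ~carry.prev_inz
        contrib = (W * new).sum(axis=1)
        lam = lam0 + params.alpha * (carry.lam_prev - lam0) + contrib
        lam = np.where(carry.turned_prev, lam0, lam)
        return lam, _MemCarry(carry.tau, carry.turned_prev, lam, inz)
    lam, tau = memory_trace_update(carry.tau, inz, W, carry.turned_prev,
                                   lam0, params.alpha)
    return lam, _MemCarry(tau, carry.turned_prev, lam, inz)


def simulate_trial(settings: SimSettings) -> SimResult:
    """Simulate one trial; bit-identical output for a fixed seed."""
    model = get_model(settings.model) if isinstance(settings.model, str) else settings.model
    require_params(model, settings.params)
    if model.memory and settings.dialect not in ("trace", "aggregate"):
        raise ValueError("dialect must be 'trace' or 'aggregate'")
    n = settings.n_agents
    T = settings.n_frames
    dt = settings.dt_s
    rng = np.random.default_rng(settings.seed)

    theta = np.empty((T, n))
    s = np.empty((T, n), dtype=np.int8)
    if settings.init_theta is not None:
        theta[0] = wrap_angle(settings.init_theta)
    else:
        theta[0] = rng.random(n) * TWO_PI
    if settings.init_orientation is not None:
        s[0] = np.asarray(settings.init_orientation, dtype=np.int8)
    else:
        s[0] = np.where(rng.random(n) < 0.5, 1, -1)

    step_mu = settings.speed_mean_rad_s * dt
    step_sd = settings.speed_sd_rad_s * np.sqrt(dt)

    lam0 = settings.params.lambda0
    carry = _MemCarry(np.zeros((n, n)), np.zeros(n, dtype=bool),
                      np.full(n, lam0), np.zeros((n, n), dtype=bool))

    for t in range(1, T):
        order = rng.permutation(n)
        draws = rng.normal(step_mu, step_sd, n)
        steps = np.empty(n)
        steps[order] = draws  # agent order[m] takes the m-th draw
        theta[t] = wrap_angle(theta[t - 1] + s[t - 1] * steps)

        lam, carry = _snapshot_lambda(model, settings.params, theta[t], s[t - 1],
                                      carry, settings.dialect)
        u = rng.random(n)
        turn = u < turn_probability(lam)
        s[t] = np.where(turn, -s[t - 1], s[t - 1])
        carry = _MemCarry(carry.tau, turn, carry.lam_prev, carry.prev_inz)

    times = np.arange(T) * dt
    traj = TrialTrajectory(f"sim{settings.seed}", 1.0 / dt, times, theta)
    rec = OrientationRecord.from_states(traj.trial_id, dt, s)
    return SimResult(traj, rec, np.sum(s == CW, axis=1))


def trial_seed(master_seed: int, index: int) -> int:
    """Deterministic per-trial seed derived from a master seed by counter."""
    ss = np.random.SeedSequence((int(master_seed), int(index)))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_ensemble(settings: SimSettings, n_trials: int, start_index: int = 0) -> list[SimResult]:
    """Independent trials with counter-derived seeds.

    Splitting an ensemble (e.g. two runs of 100 with ``start_index`` 0 and
    100) reproduces exactly the trials of a single 200-trial run under the
    same master seed.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    out = []
    for i in range(n_trials):
        idx = start_index + i
        s = replace(settings, seed=trial_seed(settings.seed, idx))
        res = simulate_trial(s)
        res.trajectory.trial_id = f"t{idx:04d}"
        res.record.trial_id = f"t{idx:04d}"
        out.append(res)
    return out
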