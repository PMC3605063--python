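"""Binary orientation classification with a symmetric two-state Gaussian HMM.

An individual travelling around the ring does not move at constant speed: it
stalls and occasionally drifts backwards without physically turning round.
The instantaneous sign of its angular displacement is therefore a noisy proxy
for its true orientation.  The HMM demands sustained evidence before declaring
a direction change: the hidden state is the orientation (CW or ACW), the
observation is the signed per-frame angular displacement, and the emission in
the ACW state is Gaussian with mean ``+mu`` while the CW state is its exact
mirror ``-mu`` (shared standard deviation).  The transition matrix is
symmetric with a single switching probability, and the initial distribution is
uniform — with no side information both orientations are equally likely a
priori.

Parameters are learnt by Baum-Welch (EM) with the symmetry enforced at every
M-step by parameter tying; decoding uses the Viterbi algorithm; remaining
artifactual double-switches (two changes within one second) are removed by a
despiking pass.  All recursions run in log space so that multi-thousand-frame
sequences do not underflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._angles import wrap_signed
from .data import ACW, CW, OrientationRecord, TrialTrajectory
from .errors import DegenerateDataError

_LOG_HALF = np.log(0.5)
_SIGMA_FLOOR = 1e-6

# state index 0 = CW (mean -mu), state index 1 = ACW (mean +mu)
_STATE_OF_INDEX = np.array([CW, ACW], dtype=np.int8)


@dataclass(frozen=True)
class HmmParams:
    """Symmetric two-state HMM parameters.

    ``p_switch`` is the per-frame probability of flipping orientation; ``mu``
    (>0) is the mean signed displacement per frame in the ACW state, the CW
    emission being its mirror (-mu, sigma).
    """

    p_switch: float
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p_switch < 1.0):
            raise ValueError("p_switch must lie in (0, 1)")
        if self.mu < 0:
            raise ValueError("mu must be non-negative (ACW-state mean)")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class HmmFitTrace:
    """Per-iteration log-likelihoods of a Baum-Welch fit."""

    log_likelihoods: np.ndarray
    converged: bool
    n_iter: int


def displacements(traj: TrialTrajectory) -> np.ndarray:
    """Signed per-frame angular steps, shape (T-1, N), wrapped into (-pi, pi].

    Positive means anti-clockwise motion.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least two frames")
    return wrap_signed(np.diff(traj.theta_rad, axis=0))


# ---------------------------------------------------------------------------
# internal batched recursions


def _pack(seqs):
    lengths = np.array([len(s) for s in seqs], dtype=int)
    S, Tmax = len(seqs), int(lengths.max())
    obs = np.zeros((S, Tmax))
    for i, s in enumerate(seqs):
        obs[i, : lengths[i]] = s
    return obs, lengths


def _log_emission(obs: np.ndarray, params: HmmParams) -> np.ndarray:
    """Per-frame emission log densities, shape (S, T, 2)."""
    const = -0.5 * np.log(2 * np.pi) - np.log(params.sigma)
    z_cw = (obs + params.mu) / params.sigma
    z_acw = (obs - params.mu) / params.sigma
    return np.stack([const - 0.5 * z_cw ** 2, const - 0.5 * z_acw ** 2], axis=-1)


def _forward_backward(obs, lengths, params):
    """Batched log-space forward-backward.

    Returns (log_alpha, log_beta, per-sequence log-likelihoods).  Padded
    frames beyond each sequence length are frozen so they do not contribute.
    """
    S, T = obs.shape
    b = _log_emission(obs, params)
    log_stay = np.log1p(-params.p_switch)
    log_switch = np.log(params.p_switch)

    la = np.full((S, T, 2), -np.inf)
    la[:, 0] = _LOG_HALF + b[:, 0]
    for t in range(1, T):
        prev = la[:, t - 1]
        new0 = np.logaddexp(prev[:, 0] + log_stay, prev[:, 1] + log_switch) + b[:, t, 0]
        new1 = np.logaddexp(prev[:, 0] + log_switch, prev[:, 1] + log_stay) + b[:, t, 1]
        active = t < lengths
        la[:, t, 0] = np.where(active, new0, prev[:, 0])
        la[:, t, 1] = np.where(active, new1, prev[:, 1])
    # after freezing, the final slice holds each sequence's terminal alphas
    ll = np.logaddexp(la[:, -1, 0], la[:, -1, 1])

    lb = np.zeros((S, T, 2))
    for t in range(T - 2, -1, -1):
        nxt = lb[:, t + 1]
        term0 = nxt[:, 0] + b[:, t + 1, 0]
        term1 = nxt[:, 1] + b[:, t + 1, 1]
        new0 = np.logaddexp(log_stay + term0, log_switch + term1)
        new1 = np.logaddexp(log_switch + term0, log_stay + term1)
        active = (t + 1) < lengths
        lb[:, t, 0] = np.where(active, new0, 0.0)
        lb[:, t, 1] = np.where(active, new1, 0.0)
    return la, lb, ll, b


def log_likelihood(seqs, params: HmmParams) -> float:
    """Total log-likelihood of displacement sequences under the model."""
    obs, lengths = _pack([np.asarray(s, dtype=float) for s in seqs])
    _, _, ll, _ = _forward_backward(obs, lengths, params)
    return float(ll.sum())


def baum_welch(seqs, init: HmmParams | None = None, max_iter: int = 500,
               tol: float = 1e-8):
    """Fit the symmetric HMM by EM, tying parameters at every M-step.

    ``seqs`` is a list of 1-D displacement sequences.  Returns
    ``(HmmParams, HmmFitTrace)``; the fit trace log-likelihood is
    non-decreasing (EM ascent holds under tying because the constrained
    M-step still maximises the expected complete-data log-likelihood).
    Raises :class:`DegenerateDataError` if the emission scale collapses.
    """
    seqs = [np.asarray(s, dtype=float).ravel() for s in seqs]
    if not seqs or any(len(s) < 2 for s in seqs):
        raise ValueError("need at least one sequence of length >= 2")
    obs, lengths = _pack(seqs)
    S, T = obs.shape
    mask = np.arange(T)[None, :] < lengths[:, None]
    n_total = float(mask.sum())

    if init is None:
        flat = np.concatenate(seqs)
        mu0 = float(np.mean(np.abs(flat)))
        sd0 = float(np.std(flat))
        init = HmmParams(p_switch=0.02, mu=max(mu0, 1e-3), sigma=max(sd0, 1e-3))
    params = init

    lls = []
    converged = False
    for it in range(max_iter):
        la, lb, ll_seq, b = _forward_backward(obs, lengths, params)
        ll = float(ll_seq.sum())
        lls.append(ll)

        # E-step in linear space (values are normalised per frame)
        lgamma = la + lb - ll_seq[:, None, None]
        gamma = np.exp(lgamma)
        gamma[~mask] = 0.0

        log_stay = np.log1p(-params.p_switch)
        log_switch = np.log(params.p_switch)
        # pair posteriors xi(t): valid for frames t with t+1 inside the sequence
        pair_mask = np.arange(T - 1)[None, :] < (lengths[:, None] - 1)
        a_t = la[:, :-1]                      # (S, T-1, 2)
        bb = b[:, 1:] + lb[:, 1:]             # (S, T-1, 2)
        norm = ll_seq[:, None]
        xi_cross = (np.exp(a_t[..., 0] + log_switch + bb[..., 1] - norm)
                    + np.exp(a_t[..., 1] + log_switch + bb[..., 0] - norm))
        xi_same = (np.exp(a_t[..., 0] + log_stay + bb[..., 0] - norm)
                   + np.exp(a_t[..., 1] + log_stay + bb[..., 1] - norm))
        xi_cross[~pair_mask] = 0.0
        xi_same[~pair_mask] = 0.0

        # tied M-step
        p_new = float(xi_cross.sum() / (xi_cross.sum() + xi_same.sum()))
        p_new = min(max(p_new, 1e-12), 1 - 1e-12)
        mu_new = float(np.sum((gamma[..., 1] - gamma[..., 0]) * obs) / n_total)
        if mu_new < 0:  # label swap: the mirror model is identical
            mu_new = -mu_new
        var_new = float(np.sum(gamma[..., 1] * (obs - mu_new) ** 2
                               + gamma[..., 0] * (obs + mu_new) ** 2) / n_total)
        sigma_new = np.sqrt(var_new)
        if sigma_new < _SIGMA_FLOOR:
            raise DegenerateDataError(
                "emission standard deviation collapsed below 1e-6 rad; "
                "provide more (or noisier) training data")
        params = HmmParams(p_switch=p_new, mu=mu_new, sigma=sigma_new)

        if it > 0 and (ll - lls[-2]) < tol * abs(lls[-2]):
            converged = True
            break

    return params, HmmFitTrace(np.array(lls), converged, len(lls))


def viterbi_decode(obs_seq, params: HmmParams) -> np.ndarray:
    """Most probable orientation path for one displacement sequence.

    Returns values in {+1 (ACW), -1 (CW)}.  Ties in the dynamic program are
    broken towards the persisting state (same state as the previous frame).
    """
    return viterbi_decode_batch([np.asarray(obs_seq, dtype=float)], params)[0]


def viterbi_decode_batch(seqs, params: HmmParams) -> list[np.ndarray]:
    """Vectorised Viterbi over a batch of sequences (may differ in length)."""
    seqs = [np.asarray(s, dtype=float).ravel() for s in seqs]
    obs, lengths = _pack(seqs)
    S, T = obs.shape
    b = _log_emission(obs, params)
    log_stay = np.log1p(-params.p_switch)
    log_switch = np.log(params.p_switch)

    delta = _LOG_HALF + b[:, 0]
    psi = np.zeros((S, T, 2), dtype=np.int8)
    for t in range(1, T):
        # predecessor choice per target state; >= prefers staying on ties
        stay0 = delta[:, 0] + log_stay
        cross0 = delta[:, 1] + log_switch
        from0 = np.where(stay0 >= cross0, 0, 1)
        best0 = np.maximum(stay0, cross0) + b[:, t, 0]
        stay1 = delta[:, 1] + log_stay
        cross1 = delta[:, 0] + log_switch
        from1 = np.where(stay1 >= cross1, 1, 0)
        best1 = np.maximum(stay1, cross1) + b[:, t, 1]
        active = t < lengths
        psi[:, t, 0] = from0
        psi[:, t, 1] = from1
        delta = np.where(active[:, None], np.stack([best0, best1], axis=1), delta)

    paths = []
    final = np.argmax(delta, axis=1)
    for i in range(S):
        L = lengths[i]
        idx = np.empty(L, dtype=np.int8)
        idx[-1] = final[i]
        for t in range(L - 1, 0, -1):
            idx[t - 1] = psi[i, t, idx[t]]
        paths.append(_STATE_OF_INDEX[idx])
    return paths


def despike(states, dt_s: float, window_s: float = 1.0) -> np.ndarray:
    """Remove artifactual double direction-changes.

    Scanning forward in time, whenever two consecutive direction changes fall
    within ``window_s`` of each other, the short-lived intervening segment is
    reverted to the preceding state — both changes vanish.  A trailing segment
    shorter than the window (a change the recording ends too soon to confirm)
    is reverted the same way.  The pass repeats until no such instance
    remains, so the output has no two consecutive changes within the window.
    Idempotent.
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    s = np.asarray(states, dtype=np.int8).copy()
    tol = 1e-12
    while True:
        ch = np.flatnonzero(s[1:] != s[:-1]) + 1
        if len(ch) == 0:
            return s
        gaps = np.diff(ch) * dt_s
        bad = np.flatnonzero(gaps <= window_s + tol)
        if len(bad) > 0:
            j = int(bad[0])
            s[ch[j]: ch[j + 1]] = s[ch[j] - 1]
            continue
        if (len(s) - ch[-1]) * dt_s <= window_s + tol:
            s[ch[-1]:] = s[ch[-1] - 1]
            continue
        return s


def classify(trajs, training, window_s: float = 1.0, init: HmmParams | None = None,
             max_iter: int = 500, tol: float = 1e-8):
    """Full orientation pre-processing: fit on single-individual data, decode all.

    ``training`` is a list of single-individual trajectories (the baseline
    treatment); parameters are learnt there only, pooled, then applied to
    every individual of every trajectory in ``trajs``.  Decoded paths are
    despiked and the final frame's state is extended from the last decoded
    frame so records align with the trajectory frame grid.

    Returns ``(HmmParams, list[OrientationRecord], HmmFitTrace)``.
    """
    if not training:
        raise ValueError("training set must be non-empty")
    train_seqs = []
    for tr in training:
        d = displacements(tr)
        train_seqs.extend(d[:, i] for i in range(tr.n_prawns))
    params, trace = baum_welch(train_seqs, init=init, max_iter=max_iter, tol=tol)

    records = []
    for tr in trajs:
        d = displacements(tr)
        paths = viterbi_decode_batch([d[:, i] for i in range(tr.n_prawns)], params)
        T = tr.n_frames
        states = np.empty((T, tr.n_prawns), dtype=np.int8)
        for i, p in enumerate(paths):
            clean = despike(p, tr.dt_s, window_s)
            states[:-1, i] = clean
            states[-1, i] = clean[-1]
        records.append(OrientationRecord.from_states(tr.trial_id, tr.dt_s, states))
    return params, records, trace
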