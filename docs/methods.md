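# Methods

This note documents the models, estimators and numerical choices implemented
in `ringmotion`, the defaults and why they were chosen, and what the synthetic
experiments do and do not demonstrate.

## Geometry and data model

Motion is reduced to an angle on the midline of an annular arena (defaults
200 mm outer / 70 mm inner diameter); radial position is discarded because
every interaction rule considered depends only on angular separations and
orientations.  Increasing angle is anti-clockwise; "CW" means decreasing
angle.  Trials are uniformly sampled at a constant frame rate (default
7.5 Hz, i.e. a 15 Hz recording with every second frame removed — the
`downsample` operation keeps even-indexed frames).  Tracking gaps are
rejected rather than interpolated: a missing (time, individual) cell is a
format error.

## Orientation HMM

The hidden state of each individual is its binary orientation; the
observation is the signed per-frame angular displacement.  The model is
deliberately symmetric: ACW emits N(+μ, σ²), CW emits N(-μ, σ²), a single
switching probability p occupies both off-diagonal transition entries, and
the initial distribution is uniform (0.5, 0.5) — with a symmetric model and
no side information there is no reason to prefer either orientation a priori.
Baum-Welch runs in log space (sequences are thousands of frames; linear-space
recursions underflow) and ties the parameters at every M-step, which
preserves EM's ascent property because the constrained M-step still maximises
the expected complete-data log-likelihood.  Convergence: relative
log-likelihood improvement below 1e-8 or 500 iterations.  An emission scale
collapsing below 1e-6 rad raises an error suggesting more data rather than
returning a degenerate model.

Viterbi decoding breaks dynamic-programming ties towards the persisting
state.  Decoded sequences are despiked: scanning forward, two direction
changes within one second are treated as a tracking artefact and the
intervening segment is reverted; a trailing segment shorter than the window
(a change the recording ends too soon to confirm) is reverted the same way;
the pass repeats to a fixpoint, so no two changes closer than the window
survive and the operation is idempotent.  The HMM is trained on
single-individual trials only and then applied unchanged to all group sizes;
training pools all single-individual sequences.

## Interaction models

All eleven rules produce a turning intensity λ (log-odds of reversing
direction in one step) mapped to probability by the logistic function.
Zones: *symmetric* zones have total width R (half-width R/2 each side,
boundary inclusive; a neighbour at the focal's exact position counts);
*forward* zones cover (0, R] ahead along the heading (a coincident neighbour
does not count); *nearest-K* selects the K smallest angular separations with
ties broken by ascending individual index; the focal individual is never its
own neighbour.  w⁻ (opposite-moving neighbours) is constrained non-negative;
w⁺ (same-moving) enters additively with free sign — fitted values of w⁺ can
be strongly negative, i.e. aligned company suppresses turning.

The memory models (D1–D4) are auto-regressive.  The implemented default
("trace" dialect) keeps one trace per neighbour: while a neighbour is inside
the zone it contributes its full weight, re-evaluated each step from its
current relative direction; once it leaves, its trace decays geometrically by
α per step; when the focal individual itself turns, all traces are cleared
and the intensity is exactly λ₀ on the following step.  This reading gives
separate meaning to "still in the zone" and "new arrivals" and starts the
fade when the interaction ends.  An alternative "aggregate" dialect
(λ_t = λ₀ + α(λ_{t-1} - λ₀) + Σ weights of new arrivals, same reset) is
selectable in configuration for sensitivity analysis.  With α = 0 both
dialects coincide exactly with the matching Markovian spatial model on any
configuration without a pending reset; on the step immediately after a turn
they give λ₀ by construction while a Markovian model would count current
neighbours — this is the intended semantics of the reset, not a defect.

## Likelihood

The data enter as a Bernoulli point process: for each trial, individual and
decision step, the event indicator (turn between frames t and t+1) has
probability logistic(λ) with λ computed from the synchronous frame-t snapshot
of all positions and orientations; memory traces are propagated from the
trial start and reset only by the focal's own turns.  Probabilities are
clamped at 1e-12 before logging; clamping events are counted and warn, and
are zero on generator-matched data.

Two numerical organisations, verified against each other and against a naive
per-step reference in the tests:

* Memoryless models depend on the data only through the joint histogram of
  (n⁻, n⁺) over decision steps split by outcome.  These sufficient statistics
  are memoised per zone, making one likelihood evaluation O(N²) regardless of
  dataset size.
* The zone radius is snapped to a 256-point grid on (0, r_max].  The
  likelihood is piecewise constant in R between observed separations, so a
  ~0.002 rad grid loses nothing material while letting spatial zones be
  memoised; the posterior uncertainty on R is two orders of magnitude larger.
* Memory models admit no sufficient statistics and are evaluated by a
  recursion over time, vectorised across trials, individuals and — inside the
  evidence estimator — across all parameter samples simultaneously.

The baseline λ₀ is not fitted: it is the logit of the pooled turn rate of the
single-individual trials, and enters every model as a point mass (Dirac
prior), exactly as shared parameters must for a fair evidence comparison.

## Priors and evidence

Priors are independent and shared across models: w⁻ ~ U[0, w_max],
w⁺ ~ U[-w_max, w_max], R ~ U(0, r_max], K ~ discrete uniform on {1..N-1},
α ~ U[0, 1).  Defaults w_max = 5 and r_max = 0.5 rad: the interaction radius
of this system is empirically confined to a few tenths of a radian (the
locality diagnostic peaks well inside ±0.25 rad), and fitted coupling
magnitudes stay well below 5.  Both are configuration knobs and are recorded
in every report.

Evidence is estimated by annealed importance sampling: each of n_samples
(default 1000) independent chains starts at a prior draw and is annealed
through tempered targets prior × likelihood^β along the ladder
β_k = (k/(K-1))³, K = 100 temperatures — cubic spacing is denser near β = 0
where the annealing integrand changes fastest.  One Metropolis sweep per
rung: a joint Gaussian proposal per continuous parameter with base scale 5%
of the prior range, reflected at the bounds (reflection preserves proposal
symmetry), and ±1 steps for K (out-of-range proposals stay put, keeping the
kernel symmetric).  The base scale is shrunk deterministically as
1/√(1 + β·E/10), E the number of observed events, so chains keep mixing once
the tempered posterior concentrates (posterior scale shrinks like
1/√(β·information)).  The log evidence is the log-mean-exp of the per-chain
log weights; its Monte-Carlo standard error comes from the weight variance.
Evidence is computed in nats and reported in bits.  A model with no free
parameters (the baseline) has exact evidence and zero standard error.  Every
visited sample's prior × likelihood is recorded and the MAP estimate is the
best-scoring visited sample (ties: first occurrence).  Per-model seeds are
derived by stable hashing, so a comparison is invariant to evaluation order.

## Simulator

Agents are initialised with i.i.d. uniform positions and fair-coin
orientations.  Per step: agents move in a fresh uniformly random order, each
by a Gaussian step N(v·dt, s²·dt) along its heading (negative draws allowed —
backward drift); after all moves, every agent draws its turn decision from
the post-move positions with orientations frozen at their pre-decision
values.  Freezing orientations within a step keeps the simulator's decision
rule aligned with the likelihood's synchronous-snapshot convention; the
movement stage remains sequential in a random order as a tie-breaker for the
random-number stream.  The √dt noise scaling keeps step variance frame-rate
consistent.  Default free speed v = 0.8 rad/s, s = 0.4 rad/s, chosen so that
with the ~1 s memory half-life an opposite-moving pair separated by half the
arena still influence each other, as observed in this system.  Ensemble
seeds are derived from the master seed by counter, so splitting an ensemble
into batches reproduces the identical trials.

## Synthetic data

The generator's defaults are the study conditions: 360 s trials at 7.5 Hz,
group sizes 1/3/6/12 (size 1 is mandatory — it is the HMM training set and
the source of the baseline rate), generating rule D3 with λ₀ = -7.5,
R = 0.19 rad, w⁻ = 0.99, w⁺ = -3.59, α = 0.92.  Observation noise enters at
the displacement level: the generator's per-frame step is N(±0.1, 0.05²) rad
signed by the true orientation, so stalls and backward drift occur with the
Gaussian-tail probability and the HMM's emission model is exactly the
generator at matched parameters.  Deliberately, the noisy displacements *are*
the motion — the positions written out are the positions at which decisions
were made.  Re-drawing displacements after the fact would make the observed
positions a random walk around the true ones (relative error growing like
σ√(2k), radians by trial end), destroying the spatial signal that the
inference is supposed to recover; real tracking error is bounded and small
compared to the zone sizes, so omitting it is the more faithful emulation.
What the generator does not emulate: positional jitter from the tracker,
identity swaps, detection dropouts, speed variation between individuals, and
any radial structure.  Passing tests therefore demonstrate correctness of the
estimators under the model class, not robustness to tracking pathologies.

## Large-scale statistics

Polarisation is |2C - n|/n for C clockwise individuals out of n; the excess
polarisation subtracts the exact binomial expectation E|2X - n|/n,
X ~ Bin(n, ½) (0.3125 for n = 6).  A trial's outcome is the clockwise count
averaged over its final 10 s, rounded half-up.  Model-vs-data agreement is
KL(observed ‖ simulated) in nats; simulated categories with zero mass but
observed support receive pseudo-mass 1/(2·number of simulations) before
renormalisation, so a never-simulated outcome is treated as rarer than one in
2m rather than impossible and the G statistic stays finite.  G = 2·m·KL is
referred to χ² with n degrees of freedom (n+1 categories minus one).  The
consistency protocol simulates 10 independent sets of 100 trials at the MAP
parameters, G-tests each set against the observed distribution, reports all
ten p-values and flags the model consistent when their median exceeds 0.05.
The turning-frequency diagnostic bins, per decision step and focal with at
least one opposite-facing neighbour, the signed separation to the nearest
such neighbour (positive = ahead) against whether the focal turned next
step; steps with no opposite-facing neighbour are excluded entirely.

## Problem sizes of the shipped experiments

The self-consistency experiments in `ringmotion.experiments` use: 10 seeds of
200-step datasets for the AIS-quadrature comparison; 50 six-agent 360-s
trials for coupling recovery; 20 replicates of 10-trial datasets for
model-selection recovery; 1000 random configurations for the memoryless
limit; 100 instances of length ≤ 12 for exhaustive Viterbi checks; 2000
multinomial replicates for G-test calibration; 2000 non-interacting trials
for the binomial large-scale check; 500 trials per group size for the
alignment ordering; 20 replicates of 16 trials for the locality diagnostic;
and 40 six-agent trials (plus 8 single-agent training trials) with a reduced
evidence run (48 chains × 20 temperatures) for the end-to-end recovery.
These sizes give comfortable statistical margins for every check while
keeping a full run to minutes on one CPU.

## Known limitations

* Evidence estimates for the memory models at full default AIS settings are
  computationally heavy on large datasets; the chain-batched likelihood makes
  reduced settings (tens of chains, tens of temperatures) practical and the
  end-to-end experiment shows they suffice for model identification, but
  publication-grade evidence for D-models warrants larger runs.
* The exact auto-regressive aggregation of the memory intensity admits two
  readings; both are implemented, the per-neighbour-trace dialect is the
  default, and conclusions should be checked under the aggregate dialect.
* The simulator has no excluded volume: agents pass through each other, as in
  the model class, which real animals cannot.
* Despiking removes unconfirmable trailing direction changes; per-trial event
  rates are thus biased very slightly downward near the recording end.
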