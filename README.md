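# ringmotion

Multi-scale Bayesian inference of interaction rules for direction-switching
animal groups on a ring arena.

## The scientific problem

Small groups of glass prawns (*Paratya australiensis*) confined to an annular
arena show a density-dependent transition to collective motion: as group size
grows, trials increasingly end with every individual circling the same way.
The interesting question is not *that* they align but *which individual-level
interaction rule produces the alignment* — and whether a rule inferred from
fine-scale movements also reproduces the group-scale behaviour.

On the annulus, motion reduces to one angular coordinate and a binary
orientation: clockwise (CW) or anti-clockwise (ACW).  Each model assigns every
individual, at every time step, a latent *turning intensity* λ — the log-odds
of reversing direction in the next step — mapped to a probability by the
logistic link `p = 1/(1+e^{-λ})`.  Eleven candidate rules are compared:

| family | id | zone | intensity |
|---|---|---|---|
| non-interacting | Null | — | `λ = λ₀` |
| mean field | MF | all others | `λ = λ₀ + w⁻ n⁻` |
| topological | T | K nearest | `λ = λ₀ + w⁻ n⁻(K)` |
| spatial (Markovian) | S1–S4 | width R, symmetric or forward | `λ = λ₀ + w⁻ n⁻(R) [+ w⁺ n⁺(R)]` |
| spatial + memory | D1–D4 | as S1–S4 | auto-regressive: departed neighbours keep contributing, decaying by α per step; reset to λ₀ after an own turn |

`n⁻`/`n⁺` count neighbours moving opposite to / with the focal individual.
The likelihood of a dataset is the Bernoulli product over trials, individuals
and steps of turn/no-turn probabilities computed from the previous-frame
snapshot.  Models are ranked by their **marginal likelihood** (evidence),
estimated by annealed importance sampling over the parameter priors, which
penalises superfluous parameters automatically; MAP parameters are the
best-scoring visited samples.  A selected model must also pass a group-scale
consistency check: simulate it forward and compare the distribution of final
clockwise counts with the observed one via the Kullback-Leibler divergence and
its G-test (`G = 2·m·KL ~ χ²`).

Raw tracking data are noisy — a prawn stalls or drifts backwards without
turning round — so observed trajectories are first reduced to orientation
sequences with a symmetric two-state Gaussian HMM (Baum-Welch fitting on
single-animal trials, Viterbi decoding, one-second despiking).

The original experimental recordings are not publicly deposited; the package
therefore ships a first-class synthetic-data generator that emulates the study
conditions (360 s trials at 7.5 Hz, group sizes 1/3/6/12, annulus of 200/70 mm
diameters) with any of the eleven rules as ground truth, so the entire
pipeline is exercised end to end with known answers.

## Worked example

```python
import ringmotion as rm

# generate a small study-like dataset: memory model D3 as ground truth
params = rm.ParamSet(**rm.DEFAULT_GENERATOR_PARAMS)   # λ₀=-7.5, R=0.19, w⁻=0.99, w⁺=-3.59, α=0.92
ds = rm.generate_dataset("D3", params, group_sizes=[1, 6], n_trials_per_size=10,
                         noise=rm.NoiseSpec(), seed=1)

# HMM pre-processing: train on the single-animal trials, decode everything
training = [t for t in ds.trajectories if t.n_prawns == 1]
hmm, records, _ = rm.classify(ds.trajectories, training)
print(f"p_switch={hmm.p_switch:.4f}  mu={hmm.mu:.3f}  sigma={hmm.sigma:.3f}")

# baseline turning intensity from the single-animal records
lam0 = rm.estimate_baseline([r for r in records if r.n_prawns == 1])
print(f"lambda0 = {lam0:.2f}")

# compare the generating model against the non-interacting baseline
six = [t for t in ds.trajectories if t.n_prawns == 6]
recs = {r.trial_id: r for r in records}
data = rm.FineScaleData(six, [recs[t.trial_id] for t in six])
results = rm.compare_models(data, ["Null", "D3"],
                            rm.PriorSpec(lambda0=lam0, n_agents=6),
                            rm.AisSettings(n_samples=48, n_temperatures=20, seed=1))
for r in results:
    print(f"{r.model_id:4s} log-evidence {r.log_ml_bits:9.1f} bits")
```

prints (exactly, for these seeds):

```
p_switch=0.0007  mu=0.100  sigma=0.050
lambda0 = -7.31
D3   log-evidence   -1480.3 bits
Null log-evidence   -1527.3 bits
```

The HMM recovers the generator's displacement statistics (mean 0.1 rad/frame,
sd 0.05); the baseline is the logit of the observed single-animal turn rate
(close to the generating λ₀ = -7.5); and the memory model beats the
non-interacting baseline by ~47 bits of evidence on only ten six-animal
trials.  `rm.map_estimate(results[0])` then
returns the fitted parameters, and `rm.validate_model(...)` runs the
group-scale G-test against forward simulations.

The same pipeline is available from the shell (`synth`, `preprocess`, `fit`,
`simulate`, `validate`, `report`, `run-all`); a YAML configuration controls
trial counts, models and evidence settings:

```sh
ringmotion run-all --config my_run.yaml --outdir runs/demo --seed 1 --models Null,MF,D3
```

Without `--config` the study-scale preset is used (25 trials per group size,
full 360 s trials), which takes correspondingly longer.

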