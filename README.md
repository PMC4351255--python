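# augment-rl

Attention-Gated MEmory Tagging (AuGMEnT): a biologically plausible
implementation of SARSA(λ) in a three-layer neural network that *learns
its own working memory*, together with the four classic monkey
behavioural tasks used to study learned persistent activity in
association cortex, the training protocols, and the post-hoc neural
analyses.

## Who this is for

Computational neuroscientists who want to simulate trial-and-error
learning of sequential decision tasks with a learning rule that uses
only synapse-local quantities — Hebbian coincidence, attentional
feedback from the selected action, eligibility *tags* and memory
*traces* — modulated by a single globally broadcast reward-prediction
error, and to compare the emergent association-layer representations
with neurophysiological recordings.

## The model

Time is discrete. A stimulus vector *x(t)* feeds three sensory channel
types: instantaneous units *x*, and on/off transient units
*x⁺ = [x(t) − x(t−1)]₊*, *x⁻ = [x(t−1) − x(t)]₊*.

The association layer holds **regular units** (sigmoidal, driven by
instantaneous input)

    y_j^R = σ(Σ_i v_ij^R x_i + v_0j),    σ(a) = 1 / (1 + exp(θ − a)),

and **memory units**, which integrate transient input over the trial
and therefore exhibit persistent activity:

    inp_m^M(t) = inp_m^M(t−1) + Σ_l v_lm^M x'_l(t),    y_m^M = σ(inp_m^M).

Action values are a linear readout, `q_k = Σ_j w_jk y_j^R + w_0k +
Σ_m w_mk y_m^M`. A Max-Boltzmann controller takes the greedy action
with probability 1 − ε and a softmax sample otherwise. After selecting
action *a* the SARSA temporal-difference error

    δ(t) = r(t) + γ q_a(t) − q_{a'}(t−1)

scales the plasticity of every tagged synapse, `Δw = β δ Tag`. Tags
decay by λγ per step and are created by the attentional feedback from
the winning action: output synapses tag with presynaptic activity;
synapses onto regular units tag with `x_i σ'(inp_j) w'_aj`; synapses
onto memory units first accumulate a non-decaying presynaptic trace
`sTrace_lm = Σ_t x'_l(t)` which feedback converts into a tag. For λ = 0
every update equals `−β ∂E/∂w` for the squared prediction error of the
sampled transition — verified in this package against central finite
differences (`augment_rl.gradient_check`).

Default parameters: β = 0.15, λ = 0.20, γ = 0.90, ε = 0.025, θ = 2.5;
3 regular + 4 memory association units, 3 Q-units, weights initialized
uniformly on [−0.25, 0.25]. A single parameter set is used for all
tasks.

## Tasks

| task | inputs | requirement |
| --- | --- | --- |
| saccade/antisaccade | mark shade (black/white) + cue side | saccade toward (pro) or away from (anti) a remembered cue after a delay |
| match-to-category | 20 direction-tuned units | left if the two motion cues share a category, right otherwise |
| probabilistic classification | targets + 10 shapes × 4 locations | pick the side whose color is more likely baited given the shape evidence |
| vibrotactile comparison | 20 frequency-tuned units + skin contact | left if F2 < F1, right if F2 > F1 |

All tasks share fixation/hold shaping (reward 0.2) and a final reward
of 1.5 units, abort rules, and an identical `reset/step` interface
(`augment_rl.tasks`).

## Worked example

```python
from augment_rl.training import run_experiment

result = run_experiment("saccade", n_networks=10, seed=7)
print(result.summary)
```

prints (exact numbers for this seed):

```
{'task': 'saccade', 'n_networks': 10, 'n_converged': 10,
 'convergence_fraction': 1.0,
 'convergence_ci': (np.float64(0.7224598312333834), 1.0),
 'median_trials': 4080.0, 'median_fix_trial': 252.0,
 'median_go_trial': 1378.5}
```

All ten networks mastered the full task (90% windowed accuracy on every
trial type plus a frozen verification battery) after a median of 4,080
trials; fixation was acquired (attained in 90 of 100 consecutive
trials) after a median of 252 trials, and fixation was maintained up to
the go signal after roughly 1,400 trials. The convergence interval is a
Wilson 95% band for the convergence fraction. Analyses of the trained networks —
PCA of association activity, representational-similarity matrices,
category-boundary tuning, logLR quintile curves, and the F1/F2
regression — live in `augment_rl.analysis`.

A command-line interface wraps the same machinery:

```bash
augment train --task saccade --n-networks 10 --seed 7 --out results/
augment sweep --task saccade --betas 0.05,0.15,0.25 --lams 0.0,0.2 --n-networks 5
augment analyze --task vibrotactile --n-networks 5 --seed 3 --out results/
```

Runs are configured by an INI file (`--config run.ini`):

```ini
[learning]
beta = 0.15
lambda = 0.20

[architecture]
n_memory = 4

[run]
task = saccade
n_networks = 100
seed = 1
```

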