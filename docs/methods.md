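# Methods

This note documents the modelling choices behind `augment_rl`: the
learning scheme, the task simulators, the convergence bookkeeping, and
the numerical decisions that were genuinely open.

## Learning scheme

The agent is a three-layer feedforward network trained by SARSA(λ)
realized entirely through synapse-local machinery. Each time step runs
in a fixed canonical order:

1. encode on/off transients of the stimulus against the previous step;
2. add the transient activity to the presynaptic traces of the
   memory-unit synapses (traces never decay within a trial);
3. feedforward pass (regular units from instantaneous input; memory
   units from their within-trial accumulator; linear Q readout);
4. on a terminal observation: a last update with target value zero,
   then a full trial reset (accumulators, traces, tags, stored value);
5. Max-Boltzmann action selection (greedy with probability 1 − ε,
   softmax sample otherwise; argmax ties broken uniformly);
6. SARSA error δ from the stored previous chosen value and the *current
   tags*, which were laid down after the previous action — this is the
   unique ordering under which the tag contents equal the gradient of
   the previously chosen Q-value;
7. tag decay by λγ, then tag formation gated by the newly selected
   action (output synapses: presynaptic activity; association synapses:
   presynaptic activity — or trace — × postsynaptic sigmoid slope ×
   feedback weight from the winner);
8. store the chosen (pre-update) Q-value for the next step.

Feedback weights are stored separately from their feedforward partners,
initialized from the same uniform distribution, and updated by the same
tag rule; learning makes the two proportional rather than identical, so
no storage is shared. Bias inputs (constant 1) reach regular and Q
units and are ordinary plastic synapses; memory units receive no bias
and no instantaneous input — integrating a constant would turn any
weak input into a ramp.

The per-step update is compiled with numba; the Python `Network` class
owns the arrays and the random streams. One master seed per network
spawns independent child streams for weight initialization and action
selection, so freezing exploration never perturbs task randomness.

### Gradient oracle

For λ = 0 the update of every weight on a sampled transition equals a
step of size β along `δ ∂q_a(t−1)/∂w`. `gradient_check` verifies this
by replaying a forced-action episode with frozen weights and comparing
each tag against central finite differences (step 1e−5) of the chosen
Q-value. For synapses onto memory units the accumulator factorizes as
(weight) × (summed transient input) only if weights are constant within
the episode; the frozen replay makes this exact, and the observed
discrepancies are at numerical precision (~1e−12). The comparison
requires feedback weights set equal to feedforward ones; the package
exposes `Network.symmetrize_feedback()` for that purpose.

### Numerical hygiene

Sigmoid and softmax exponents are clipped at ±500 (saturation without
overflow; no behavioural effect at this scale). The Boltzmann sample is
computed max-subtracted. All state is float64.

## Parameters

| parameter | default | meaning |
| --- | --- | --- |
| β | 0.15 | learning rate for all synapses |
| λ | 0.20 | trace decay; tags retain λγ per step |
| γ | 0.90 | reward discount per time step |
| ε | 0.025 | exploration probability per step |
| θ | 2.5 | sigmoid offset |
| init | U[−0.25, 0.25] | all weights, feedback included |
| layers | 3 regular, 4 memory, 3 Q | one set for every task |

θ deserves a note: the activation's offset is not independently
identifiable because bias weights can compensate for it. We default to
θ = 2.5, which keeps naive-network activities near 0.08 and initial
Q-values small — in calibration runs this reproduced the published
convergence medians better than θ ∈ {0, 1.5}, which made early
learning unrealistically fast.

## Task environments

All four tasks share one discrete-time interface (`reset`/`step`
returning stimulus vector, reward, terminal flag) and one reward
scheme: shaping reward r_i = 0.2 with the event that confirms fixation
or key-hold, final reward r_f = 1.5 for a correct (or, in the
probabilistic task, lucky-baited) choice; everything else ends with
nothing. Fixation/hold must be attained within 10 observations (two
consecutive center/hold actions), responses within 8; breaking fixation
before the go signal aborts. Environments are pure functions of their
random stream, replayable bit-exactly from a seed.

Decisions the task descriptions left open:

* **Saccade input layout.** Two mutually exclusive fixation-mark units
  (black / white) plus two cue units; the task is unsolvable without
  mark-shade information. The canonical correct trial spans exactly
  8 steps (empty, mark, mark, cue, delay, delay, go, outcome), which is
  also the time base of the activity analyses.
* **Trump symbols.** The decisive shapes of the classification task are
  given finite log-evidence weights ±5 (odds 10⁵). The evidence sum
  then always exists, a lone trump fixes the bait side to numerical
  certainty, and two opposing trumps cancel exactly.
* **Classification "correct".** Learning curves score a choice correct
  when it picks the side with the higher bait probability (either side
  at W = 0); the *reward* still follows the realized bait.
* **Vibrotactile rest state.** The frequency-tuned units are silent
  when no vibration is applied, and rate noise (s.d. 0.075, truncated
  to [0, 1]) enters only while a stimulus drives them. The alternative
  reading — evaluating the tuning curves at 0 Hz between stimuli, which
  pins the ten decreasing units near saturation — was tested and
  degrades variable-F1 learning far below the published speed, so the
  silent-rest convention is used.
* **Direction noise** (s.d. 5°) perturbs the stimulus angle before
  tuning-curve evaluation, for both cues alike; categories are defined
  by the true direction label.

## Training and convergence bookkeeping

Accuracy is tracked in per-stratum rolling windows over the last trials
*of that stratum* (50 trials per trial type / cue-1 direction / 5-Hz F1
bin), and the criterion requires every stratum to clear its threshold
simultaneously (90% saccade, 80% category and variable-F1, a single
overall 90% window for fixed-F1). Aborted trials count as errors in
their stratum. Where the protocol includes a frozen verification
(saccade: 20 trials per type at ≥ 90%; variable-F1: the 3 × 10 × 20
psychometric battery with ≥ 50% at ±2 Hz and > 75% beyond), learning
and exploration are zeroed for the battery and training resumes on
failure, with at least 50 trials between attempts. Milestones (fixation
acquired; fixation held to the go signal) are the first trial at which
the event occurred in 90 of the preceding 100 trials.

The classification curriculum ladders eight levels — symbol pairs added
from the trumps outward, then sequence length 1→4 — advancing at 85%
success over level-specific windows (1,000 up to 20,000 trials) within
a 500,000-trial total budget. Convergence medians are computed over
converged networks; convergence fractions over all networks, with
Wilson confidence intervals.

## Analyses

All analyses freeze the network (β = ε = 0) and force fixation up to
the go signal so probe trials have canonical timing. PCA operates on
the 32 × 7 matrix of association activities (8 steps × 4 trial types);
similarity analysis marks, per time step and unit group, the pair of
trial types with the smallest Euclidean distance (ties split the unit
of mass). Category tuning is read at the last delay step and summarized
by the adjacent 30° direction pair with the largest activity change
(units below a 10⁻³ floor are excluded as untuned). The logLR quintile
analysis enumerates all 10⁴ length-4 symbol sequences exactly —
enumeration is also the oracle for its prefix-marginalization law in
the tests. The two-frequency regression evaluates the full 46 × 46
(F1, F2) grid with noise-free tuning, so the least-squares fit is
deterministic; psychometric curves are two-parameter logistic fits of
the choice fraction against F2.

## What the simulations do and do not show

The task generators emulate the *protocols* of the original animal
experiments (trial phases, randomization, shaping, reward schedules),
not the animals' sensory physiology: tuning curves are idealized,
noise is additive and independent per step, and time is a coarse
discrete grid. Passing the reproduction suite therefore shows that the
learning scheme — not a tuned architecture — constructs the required
working-memory representations under these abstracted conditions; it
does not certify behaviour on real neural or behavioural data.

Known limitations, found while reproducing the published statistics at
desk scale (15–100 networks; the published experiments used 100 to
10,000):

* The fixation-acquisition milestone of the saccade task is reached
  earlier here (median ≈ 100–180 trials across seeds vs. 224): roughly
  half of our networks already fixate in ≥ 90 of their first 100
  trials. Full-task, go-milestone and convergence statistics match.
* The fixed-F1 vibrotactile variant converges in a median of ≈ 650
  trials against the published 1,390 under the plain 50-trial
  90%-running-accuracy reading of that criterion; and after block
  training only a minority of our networks lose their F1 sensitivity
  completely, so the averaged psychometric collapse onto 30 Hz is
  weaker than published. Both suggest the original fixed-F1 protocol
  contained additional structure the text does not state.
* Variable-F1 convergence medians land ~10–15% above the published
  value; the gap is dominated by how often the frozen verification
  battery is retried, a protocol detail the text leaves open.

No empirical number in this note is asserted anywhere except where the
test suite or `scripts/acceptance.py` computes it at run time.
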