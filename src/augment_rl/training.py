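"""Training loops, convergence criteria and multi-network experiments.

Conventions shared by all tasks:

* accuracy is tracked per stratum (trial type, cue-1 direction, F1 bin,
  or curriculum level) in rolling windows over the last trials *of that
  stratum*; the criterion requires every stratum to clear its threshold
  simultaneously;
* when the windowed criterion is met, learning and exploration are
  frozen (beta = epsilon = 0) and a task-specific verification battery
  is run; if it fails, training resumes;
* aborted trials (broken fixation, timeouts) count as incorrect in the
  stratum of the trial.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .network import Network
from .params import ArchitectureSpec, LearningParams
from .tasks import (
    CategoryEnv,
    ClassificationEnv,
    SaccadeEnv,
    VibrotactileEnv,
)
from .tasks.category import N_DIRECTIONS

MAX_TRIAL_STEPS = 64


@dataclass
class TrialSummary:
    trial_type: object
    outcome: str
    correct: Optional[bool]
    reward: float
    length: int
    fixated: bool
    reached_go: bool
    chose: Optional[int]


def run_trial(net: Network, env, record=False):
    """Run one trial to the terminal step; optionally keep per-step logs."""
    logs = [] if record else None
    x, r, terminal = env.reset()
    total_reward = 0.0
    steps = 0
    while True:
        steps += 1
        if steps > MAX_TRIAL_STEPS:
            raise RuntimeError("trial exceeded the hard step cap; "
                               "environment failed to terminate")
        total_reward += r
        if record:
            a, _, log = net.step_logged(x, r, terminal)
            logs.append(log)
        else:
            a, _ = net.step(x, r, terminal)
        if terminal:
            break
        x, r, terminal = env.step(a)
    summary = TrialSummary(
        trial_type=env.trial_type, outcome=env.outcome, correct=env.correct,
        reward=total_reward, length=steps, fixated=env.fixated,
        reached_go=env.reached_go, chose=env.chose,
    )
    return (summary, logs) if record else summary


class RollingWindow:
    """Boolean rolling window with an O(1) running sum."""

    def __init__(self, size):
        self.size = size
        self._d = deque(maxlen=size)
        self._sum = 0

    def add(self, value: bool):
        if len(self._d) == self.size:
            self._sum -= self._d[0]
        v = 1 if value else 0
        self._d.append(v)
        self._sum += v

    @property
    def full(self):
        return len(self._d) == self.size

    @property
    def fraction(self):
        return self._sum / len(self._d) if self._d else 0.0

    def at_least(self, threshold):
        return self.full and self._sum >= threshold * self.size - 1e-9


@dataclass
class ConvergenceCriterion:
    """All strata must reach `threshold` accuracy over `window` trials."""

    strata: tuple
    threshold: float = 0.9
    window: int = 50
    verify: Optional[Callable[[Network], bool]] = None
    #: minimum trials between verification attempts while criterion holds
    verify_interval: int = 50


@dataclass
class TrainResult:
    converged: bool
    trials: Optional[int]          # trial index at criterion (1-based)
    fix_trial: Optional[int]       # milestone: fixation acquired (90/100)
    go_trial: Optional[int]        # milestone: held until go (90/100)
    total_trials: int


def train_to_criterion(net: Network, env, criterion: ConvergenceCriterion,
                       max_trials: int) -> TrainResult:
    """Train until every stratum clears the windowed criterion (plus the
    optional frozen verification battery) or the trial budget runs out.

    Also records the fixation and go milestones: the first trial at which
    the milestone was attained in 90 of the preceding 100 trials.
    """
    windows = {s: RollingWindow(criterion.window) for s in criterion.strata}
    fix_window = RollingWindow(100)
    go_window = RollingWindow(100)
    fix_trial = go_trial = None
    last_verify = -10**9

    for trial in range(1, max_trials + 1):
        summary = run_trial(net, env)
        windows[summary.trial_type].add(summary.outcome == "correct")
        fix_window.add(summary.fixated)
        go_window.add(summary.reached_go)
        if fix_trial is None and fix_window.at_least(0.9):
            fix_trial = trial
        if go_trial is None and go_window.at_least(0.9):
            go_trial = trial

        if all(w.at_least(criterion.threshold) for w in windows.values()):
            if criterion.verify is None:
                return TrainResult(True, trial, fix_trial, go_trial, trial)
            if trial - last_verify >= criterion.verify_interval:
                last_verify = trial
                with net.frozen_mode():
                    ok = criterion.verify(net)
                if ok:
                    return TrainResult(True, trial, fix_trial, go_trial, trial)
    return TrainResult(False, None, fix_trial, go_trial, max_trials)


# -- task-specific criteria ------------------------------------------


def verify_saccade(net, env_seed=None, trials_per_type=20, threshold=0.9,
                   pro_only=False, rng=None):
    """Frozen check: >= 90% correct on each trial type."""
    if rng is None:
        rng = np.random.default_rng(env_seed)
    types = ("PL", "PR") if pro_only else ("PL", "PR", "AL", "AR")
    env = SaccadeEnv(rng=rng, shaping=True, pro_only=pro_only)
    for ttype in types:
        n_ok = 0
        for _ in range(trials_per_type):
            env.reset(trial_type=ttype)
            if _play_frozen(net, env) == "correct":
                n_ok += 1
        if n_ok < threshold * trials_per_type:
            return False
    return True


def _play_frozen(net, env, max_steps=MAX_TRIAL_STEPS):
    """Continue a trial already reset on `env`; return the outcome."""
    x, r, terminal = env._x, 0.0, False
    for _ in range(max_steps):
        a, _ = net.step(x, r, terminal)
        if terminal:
            return env.outcome
        x, r, terminal = env.step(a)
    raise RuntimeError("frozen trial did not terminate")


def psychometric_battery(net, rng=None, f1_values=(20.0, 30.0, 40.0),
                         offsets=(2.0, 4.0, 6.0, 8.0, 10.0), repeats=20,
                         noise_sd=None):
    """Frozen F1 x F2-offset battery.

    Returns a DataFrame with columns f1, f2, offset, n, n_right,
    n_correct where 'right' means the agent judged F2 > F1.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    env = VibrotactileEnv(rng=rng, shaping=True, mode="variable")
    if noise_sd is not None:
        env.noise_sd = noise_sd
    rows = []
    for f1 in f1_values:
        for off in list(offsets) + [-o for o in offsets]:
            f2 = f1 + off
            n_right = n_correct = n_resp = 0
            for _ in range(repeats):
                env.reset(f1=f1, f2=f2)
                outcome = _play_frozen(net, env)
                if outcome in ("correct", "wrong"):
                    n_resp += 1
                    if env.chose == 2:  # RIGHT: judged F2 > F1
                        n_right += 1
                    if outcome == "correct":
                        n_correct += 1
            rows.append(dict(f1=f1, f2=f2, offset=off, n=repeats,
                             n_responded=n_resp, n_right=n_right,
                             n_correct=n_correct))
    return pd.DataFrame(rows)


def verify_vibrotactile(net, rng=None, repeats=20):
    """Frozen battery: >= 50% correct at the 2 Hz offsets and > 75%
    beyond, for each tested F1."""
    df = psychometric_battery(net, rng=rng, repeats=repeats)
    for _, row in df.iterrows():
        acc = row.n_correct / row.n
        if abs(row.offset) <= 2.0 + 1e-9:
            if acc < 0.5:
                return False
        elif acc <= 0.75:
            return False
    return True


def saccade_criterion(pro_only=False, verify_rng=None):
    types = ("PL", "PR") if pro_only else ("PL", "PR", "AL", "AR")
    return ConvergenceCriterion(
        strata=types, threshold=0.9, window=50,
        verify=lambda net: verify_saccade(net, rng=verify_rng,
                                          pro_only=pro_only),
    )


def category_criterion():
    return ConvergenceCriterion(
        strata=tuple(range(N_DIRECTIONS)), threshold=0.8, window=50,
        verify=None,
    )


def vibrotactile_criterion(mode="variable", verify_rng=None):
    if mode == "variable":
        return ConvergenceCriterion(
            strata=tuple(range(9)), threshold=0.8, window=50,
            verify=lambda net: verify_vibrotactile(net, rng=verify_rng),
        )
    # fixed mode: a single 90% running-accuracy window over all trials
    return ConvergenceCriterion(strata=(FIXED_STRATUM,), threshold=0.9,
                                window=50, verify=None)


FIXED_STRATUM = "all"


class _SingleStratumEnv:
    """Wrapper mapping every trial onto one stratum (fixed-F1 variant)."""

    def __init__(self, env):
        self.env = env

    def reset(self, **kw):
        return self.env.reset(**kw)

    def step(self, a):
        return self.env.step(a)

    def __getattr__(self, name):
        return getattr(self.env, name)

    @property
    def trial_type(self):
        return FIXED_STRATUM


# -- curriculum for the probabilistic classification task ------------

#: (number of symbols, sequence length, success window) per level
CURRICULUM_LEVELS = (
    (2, 1, 1000), (4, 1, 1500), (6, 1, 2000), (8, 1, 2500), (10, 1, 3000),
    (10, 2, 10000), (10, 3, 10000), (10, 4, 20000),
)


@dataclass
class CurriculumResult:
    converged: bool
    total_trials: int
    level_trials: list = field(default_factory=list)


def run_curriculum(net: Network, env: ClassificationEnv,
                   levels=CURRICULUM_LEVELS,
                   max_total_trials=500_000) -> CurriculumResult:
    """Train through the difficulty ladder; advance at 85% windowed
    success. Weights persist across levels; a single total trial budget
    covers the whole ladder."""
    total = 0
    level_trials = []
    for (n_sym, seq_len, window) in levels:
        env.configure(n_sym, seq_len)
        w = RollingWindow(window)
        t_level = 0
        while True:
            if total >= max_total_trials:
                return CurriculumResult(False, total, level_trials)
            summary = run_trial(net, env)
            total += 1
            t_level += 1
            w.add(summary.outcome == "correct")
            if w.at_least(0.85):
                level_trials.append(t_level)
                break
    return CurriculumResult(True, total, level_trials)


# -- block training for the fixed-F1 vibrotactile variant ------------


def block_training(net: Network, rng, f1_blocks=(20.0, 40.0, 30.0),
                   offsets=(2.0, 4.0, 6.0, 8.0, 10.0), repeats=150):
    """Sequential-block exposure after fixed-F1 training.

    Each block fixes F1 and presents the ten F2 offsets `repeats` times
    in shuffled order (learning on). Block order is pseudorandom except
    that the 30 Hz block always comes last. Returns per-block accuracy.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    others = [f for f in f1_blocks if f != 30.0]
    rng.shuffle(others)
    order = others + [30.0]
    env = VibrotactileEnv(rng=rng, shaping=True, mode="variable")
    all_offsets = list(offsets) + [-o for o in offsets]
    block_acc = {}
    for f1 in order:
        pairs = np.array(all_offsets * repeats)
        rng.shuffle(pairs)
        n_ok = 0
        for off in pairs:
            env.reset(f1=f1, f2=f1 + off)
            x, r, terminal = env._x, 0.0, False
            while True:
                a, _ = net.step(x, r, terminal)
                if terminal:
                    break
                x, r, terminal = env.step(a)
            if env.outcome == "correct":
                n_ok += 1
        block_acc[f1] = n_ok / len(pairs)
    return block_acc


# -- multi-network experiments ---------------------------------------


def _spawn(seed_seq, n):
    if not isinstance(seed_seq, np.random.SeedSequence):
        seed_seq = np.random.SeedSequence(seed_seq)
    return seed_seq.spawn(n)


def make_env(task, rng, shaping=True, mode="variable", pro_only=False):
    if task == "saccade":
        return SaccadeEnv(rng=rng, shaping=shaping, pro_only=pro_only)
    if task == "category":
        return CategoryEnv(rng=rng, shaping=shaping)
    if task == "classification":
        return ClassificationEnv(rng=rng, shaping=shaping, n_symbols=2,
                                 seq_len=1)
    if task == "vibrotactile":
        env = VibrotactileEnv(rng=rng, shaping=shaping, mode=mode)
        return env if mode == "variable" else _SingleStratumEnv(env)
    raise ValueError(f"unknown task {task!r}")


def default_max_trials(task):
    return {"saccade": 25_000, "category": 50_000,
            "classification": 500_000, "vibrotactile": 50_000}[task]


@dataclass
class ExperimentResult:
    task: str
    table: pd.DataFrame       # one row per network
    summary: dict

    def converged_median(self, column="trials"):
        sub = self.table[self.table.converged]
        return float(sub[column].median()) if len(sub) else float("nan")


def train_one(task, seed_seq, params=None, arch_overrides=None,
              shaping=True, mode="variable", pro_only=False,
              max_trials=None):
    """Train a single network on `task`; returns (net, row dict)."""
    ss_net, ss_env, ss_verify = _spawn(seed_seq, 3)
    env = make_env(task, np.random.default_rng(ss_env), shaping=shaping,
                   mode=mode, pro_only=pro_only)
    n_inst = env.n_inputs
    arch_kw = dict(arch_overrides or {})
    arch = ArchitectureSpec(n_inst=n_inst, **arch_kw)
    net = Network(n_inst, params=params, arch=arch, seed=ss_net)
    if max_trials is None:
        max_trials = default_max_trials(task)

    verify_rng = np.random.default_rng(ss_verify)
    if task == "saccade":
        crit = saccade_criterion(pro_only=pro_only, verify_rng=verify_rng)
        res = train_to_criterion(net, env, crit, max_trials)
        row = dict(converged=res.converged, trials=res.trials,
                   fix_trial=res.fix_trial, go_trial=res.go_trial)
    elif task == "category":
        res = train_to_criterion(net, env, category_criterion(), max_trials)
        row = dict(converged=res.converged, trials=res.trials,
                   fix_trial=res.fix_trial, go_trial=res.go_trial)
    elif task == "classification":
        res = run_curriculum(net, env, max_total_trials=max_trials)
        row = dict(converged=res.converged, trials=res.total_trials,
                   level_trials=res.level_trials)
    elif task == "vibrotactile":
        crit = vibrotactile_criterion(mode, verify_rng=verify_rng)
        res = train_to_criterion(net, env, crit, max_trials)
        row = dict(converged=res.converged, trials=res.trials)
    else:
        raise ValueError(f"unknown task {task!r}")
    return net, row


def run_experiment(task, n_networks=100, seed=0, params=None,
                   arch_overrides=None, shaping=True, mode="variable",
                   pro_only=False, max_trials=None, keep_networks=False,
                   progress=False):
    """Train `n_networks` independent networks; aggregate convergence.

    Per-network seeds are spawned from the master seed by a counter
    scheme, so increasing `n_networks` extends rather than reshuffles the
    set of networks.
    """
    seqs = _spawn(seed, n_networks)
    rows, nets = [], []
    iterator = enumerate(seqs)
    if progress:
        from tqdm import tqdm
        iterator = tqdm(list(iterator), desc=task)
    for i, ss in iterator:
        net, row = train_one(task, ss, params=params,
                             arch_overrides=arch_overrides, shaping=shaping,
                             mode=mode, pro_only=pro_only,
                             max_trials=max_trials)
        row["network"] = i
        rows.append(row)
        if keep_networks:
            nets.append(net)
    table = pd.DataFrame(rows)
    n_conv = int(table.converged.sum())
    conv = table[table.converged]
    summary = dict(
        task=task, n_networks=n_networks, n_converged=n_conv,
        convergence_fraction=n_conv / n_networks,
        convergence_ci=_binomial_ci(n_conv, n_networks),
        median_trials=(float(conv.trials.median()) if n_conv else None),
    )
    if "fix_trial" in table.columns:
        fixes = table.fix_trial.dropna()
        summary["median_fix_trial"] = float(fixes.median()) if len(fixes) else None
        goes = table.go_trial.dropna()
        summary["median_go_trial"] = float(goes.median()) if len(goes) else None
    result = ExperimentResult(task=task, table=table, summary=summary)
    return (result, nets) if keep_networks else result


def _binomial_ci(k, n, z=1.96):
    """Wilson score interval for a convergence fraction."""
    if n == 0:
        return (0.0, 1.0)
    p = k / n
    denom = 1 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return (max(0.0, center - half), min(1.0, center + half))


# -- parameter / size sweeps -----------------------------------------


def sweep_learning_parameters(task, betas, lams, n_networks=10, seed=0,
                              max_trials=None, **task_kw):
    """Grid over (beta, lambda); returns a tidy DataFrame of convergence
    fraction and median trials per cell."""
    rows = []
    for beta in betas:
        for lam in lams:
            params = LearningParams(beta=beta, lam=lam)
            res = run_experiment(task, n_networks=n_networks, seed=seed,
                                 params=params, max_trials=max_trials,
                                 **task_kw)
            rows.append(dict(beta=beta, lam=lam,
                             convergence=res.summary["convergence_fraction"],
                             median_trials=res.summary["median_trials"]))
    return pd.DataFrame(rows)


def sweep_network_size(task="saccade", factors=(1, 2, 4), n_networks=10,
                       seed=0, param_scale=1.0, max_trials=None, **task_kw):
    """Scale the association layer by integer factors (regular and memory
    counts alike), optionally scaling (beta, lambda) jointly."""
    base = LearningParams()
    rows = []
    for f in factors:
        params = LearningParams(beta=base.beta * param_scale,
                                lam=base.lam * param_scale)
        res = run_experiment(task, n_networks=n_networks, seed=seed,
                             params=params,
                             arch_overrides=dict(n_regular=3 * f,
                                                 n_memory=4 * f),
                             max_trials=max_trials, **task_kw)
        rows.append(dict(factor=f, param_scale=param_scale,
                         convergence=res.summary["convergence_fraction"],
                         median_trials=res.summary["median_trials"]))
    return pd.DataFrame(rows)
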