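"""Post-hoc analyses of trained networks.

Everything here operates on *frozen* networks (learning rate and
exploration set to zero): dimensionality reduction and representational
similarity for the saccade task, boundary tuning for the category task,
log-likelihood-ratio quintile activity and symbol-weight recovery for
the probabilistic classification task, and the two-frequency regression
and psychometric fits for the vibrotactile task.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.decomposition import PCA

from .network import Network
from .tasks import CategoryEnv, ClassificationEnv, SaccadeEnv, VibrotactileEnv
from .tasks.base import CENTER
from .tasks.category import N_DIRECTIONS
from .tasks.classification import (
    N_SYMBOLS,
    SYMBOL_WEIGHTS,
    p_red,
    symbol_input_index,
)

SACCADE_PHASES = ("start", "fix1", "fix2", "cue", "delay1", "delay2",
                  "go", "terminal")


def probe_trial(net: Network, env, reset_output):
    """Play one frozen trial, forcing fixation/hold until the go phase.

    The center action is forced while the environment has not yet issued
    its go signal, so every probe trial has the canonical pre-go timing;
    from the go observation on, the network acts greedily. Returns the
    list of per-step logs.
    """
    x, r, terminal = reset_output
    logs = []
    while True:
        force = CENTER if (not terminal and env._phase != "go") else -1
        a, _, log = net.step_logged(x, r, terminal, force_action=force)
        logs.append(log)
        if terminal:
            return logs
        x, r, terminal = env.step(a)


# -- saccade task ----------------------------------------------------


def saccade_activations(net: Network, n_steps=8):
    """Association-layer activity for the four trial types.

    Returns (matrix, unit_labels): the matrix stacks, per trial type in
    the order PL, PR, AL, AR, one row per time step, with the regular
    units followed by the memory units as columns (shape
    ``(n_steps * 4, n_regular + n_memory)``).
    """
    env = SaccadeEnv(rng=0, shaping=True)
    rows = []
    with net.frozen_mode():
        for ttype in ("PL", "PR", "AL", "AR"):
            net.reset_trial()
            logs = probe_trial(net, env, env.reset(trial_type=ttype))
            if len(logs) < n_steps:
                raise RuntimeError(f"trial shorter than {n_steps} steps")
            for log in logs[:n_steps]:
                rows.append(np.concatenate([log.y_reg, log.y_mem]))
    labels = ([f"reg{j}" for j in range(net.arch.n_regular)]
              + [f"mem{m}" for m in range(net.arch.n_memory)])
    return np.asarray(rows), labels


def pca_association(mat):
    """PCA of the (time x trial type) by unit observation matrix.

    Returns (components, variance_fractions, projection2d).
    """
    mat = np.asarray(mat, dtype=float)
    if np.allclose(mat, mat.mean(axis=0), atol=1e-12):
        raise ValueError("constant activation matrix: variance undefined")
    n_comp = min(mat.shape)
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(mat)
    return pca.components_, pca.explained_variance_ratio_, scores[:, :2]


def similarity_matrices(net: Network, n_steps=8):
    """Smallest-distance incidence matrices per phase and unit group.

    For each time step and unit group (memory / regular / Q), the four
    trial-type activity vectors are compared pairwise by Euclidean
    distance; the minimal off-diagonal pair(s) receive the unit of mass
    (split equally on ties). Returns ``{group: array (n_steps, 4, 4)}``.
    """
    env = SaccadeEnv(rng=0, shaping=True)
    groups = {"regular": [], "memory": [], "q": []}
    with net.frozen_mode():
        for ttype in ("PL", "PR", "AL", "AR"):
            net.reset_trial()
            logs = probe_trial(net, env, env.reset(trial_type=ttype))
            groups["regular"].append([lg.y_reg for lg in logs[:n_steps]])
            groups["memory"].append([lg.y_mem for lg in logs[:n_steps]])
            groups["q"].append([lg.q for lg in logs[:n_steps]])
    out = {}
    for name, acts in groups.items():
        acts = np.asarray(acts)  # (4 types, n_steps, units)
        mats = np.zeros((n_steps, 4, 4))
        for t in range(n_steps):
            d = np.full((4, 4), np.inf)
            for i in range(4):
                for j in range(i + 1, 4):
                    d[i, j] = np.linalg.norm(acts[i, t] - acts[j, t])
            dmin = d.min()
            winners = np.argwhere(np.isclose(d, dmin, rtol=1e-12, atol=1e-12))
            for (i, j) in winners:
                mats[t, i, j] += 1.0 / len(winners)
                mats[t, j, i] += 1.0 / len(winners)
        out[name] = mats
    return out


# -- category task ---------------------------------------------------


def category_delay_tuning(net: Network, n_repeats=10, rng=None):
    """Mean memory-unit activity at the last delay step per cue-1
    direction, averaged over noisy repeats. Shape (12, n_memory)."""
    env = CategoryEnv(rng=np.random.default_rng(rng), shaping=True)
    acts = np.zeros((N_DIRECTIONS, net.arch.n_memory))
    with net.frozen_mode():
        for d in range(N_DIRECTIONS):
            for _ in range(n_repeats):
                net.reset_trial()
                logs = probe_trial(net, env, env.reset(cue1=d))
                # canonical timing: empty, fix, fix, cue-1, delay, delay, ...
                acts[d] += logs[5].y_mem
    return acts / n_repeats


def category_change_preference(tuning, floor=1e-3):
    """Adjacent-pair direction change with the largest activity jump.

    For each memory unit, scans the 12 wrapped adjacent 30-degree pairs
    and records the index of the pair with the maximal absolute activity
    difference plus whether that pair straddles a category boundary
    (pairs 5-6 and 11-0). Units whose maximal jump is below `floor` are
    reported with pair index -1 (untuned).

    Returns a DataFrame with columns unit, pair, crosses_boundary.
    """
    tuning = np.asarray(tuning)
    boundary_pairs = {5, 11}
    rows = []
    for m in range(tuning.shape[1]):
        diffs = np.abs(np.roll(tuning[:, m], -1) - tuning[:, m])
        best = int(np.argmax(diffs))
        if diffs[best] < floor:
            rows.append(dict(unit=m, pair=-1, crosses_boundary=False))
        else:
            rows.append(dict(unit=m, pair=best,
                             crosses_boundary=best in boundary_pairs))
    return pd.DataFrame(rows)


# -- probabilistic classification task -------------------------------


def enumerate_reward_probabilities():
    """P(red baited) for all 10**4 length-4 symbol sequences.

    Returns (sequences (10000, 4), weight_sums (10000,), p (10000,)).
    """
    grid = np.array(np.meshgrid(*[np.arange(N_SYMBOLS)] * 4,
                                indexing="ij")).reshape(4, -1).T
    sums = SYMBOL_WEIGHTS[grid].sum(axis=1)
    return grid, sums, p_red(sums)


def prefix_log_likelihood_ratio(prefix):
    """log10 P(red)/P(green) after observing `prefix`, marginalizing
    uniformly over the unobserved remainder of the length-4 sequence."""
    prefix = np.atleast_1d(np.asarray(prefix, dtype=int))
    n_rest = 4 - len(prefix)
    w0 = SYMBOL_WEIGHTS[prefix].sum()
    if n_rest == 0:
        p = p_red(w0)
    else:
        rest = np.array(np.meshgrid(*[np.arange(N_SYMBOLS)] * n_rest,
                                    indexing="ij")).reshape(n_rest, -1).T
        p = p_red(w0 + SYMBOL_WEIGHTS[rest].sum(axis=1)).mean()
    p = min(max(p, 1e-12), 1 - 1e-12)
    return float(np.log10(p / (1.0 - p)))


def loglr_quintile_edges():
    """Quintile edges of the logLR distribution per prefix length."""
    edges = {}
    for l in range(1, 5):
        grid = np.array(np.meshgrid(*[np.arange(N_SYMBOLS)] * l,
                                    indexing="ij")).reshape(l, -1).T
        vals = np.array([prefix_log_likelihood_ratio(s) for s in grid])
        edges[l] = np.quantile(vals, [0.2, 0.4, 0.6, 0.8])
    return edges


def loglr_quintile_activity(net: Network, n_trials=2000, rng=None):
    """Mean memory activity per logLR quintile and prefix length.

    Frozen trials of the full task (10 symbols, length 4) are played
    with forced fixation; after the l-th symbol the memory activities
    are binned by the quintile of the logLR of the observed prefix.
    Each unit's quintile axis is oriented so activity increases, then
    units are averaged. Returns an array (4 lengths, 5 quintiles).
    """
    rng = np.random.default_rng(rng)
    env = ClassificationEnv(rng=rng, shaping=True, n_symbols=N_SYMBOLS,
                            seq_len=4)
    edges = loglr_quintile_edges()
    M = net.arch.n_memory
    sums = np.zeros((M, 4, 5))
    counts = np.zeros((4, 5))
    with net.frozen_mode():
        for _ in range(n_trials):
            net.reset_trial()
            logs = probe_trial(net, env, env.reset())
            seq = env.symbols
            # symbol l (1-based) is on screen from step 3 + l
            for l in range(1, 5):
                q = int(np.searchsorted(
                    edges[l], prefix_log_likelihood_ratio(seq[:l])))
                y = logs[2 + l].y_mem
                sums[:, l - 1, q] += y
                counts[l - 1, q] += 1
    with np.errstate(invalid="ignore"):
        mean = sums / counts[None, :, :]
    oriented = np.empty_like(mean)
    for m in range(M):
        flip = False
        final = mean[m, 3]
        if np.isfinite(final[[0, 4]]).all() and final[4] < final[0]:
            flip = True
        oriented[m] = mean[m, :, ::-1] if flip else mean[m]
    return np.nanmean(oriented, axis=0)


def symbol_weight_correlation(net: Network):
    """Spearman correlation, per memory unit, between the learned
    symbol weights and the true evidence weights.

    The learned weight of symbol s for a memory unit is the mean of the
    on-channel synaptic weights from the four retinotopic copies of s.
    Constant weight vectors yield rho = 0.
    """
    rhos = np.zeros(net.arch.n_memory)
    for m in range(net.arch.n_memory):
        w = np.zeros(N_SYMBOLS)
        for s in range(N_SYMBOLS):
            idx = [symbol_input_index(loc, s) for loc in range(4)]
            w[s] = net.V_mem[idx, m].mean()
        if np.allclose(w, w[0]):
            rhos[m] = 0.0
        else:
            rho = stats.spearmanr(w, SYMBOL_WEIGHTS).statistic
            rhos[m] = 0.0 if np.isnan(rho) else rho
    return rhos


# -- vibrotactile task -----------------------------------------------


def frequency_regression(freqs, activities):
    """OLS of unit activities on (F1, F2, 1).

    `freqs` is (n, 2) with the F1/F2 pairs; `activities` is (n, units).
    Returns a DataFrame with columns a1, a2, b (one row per unit).
    """
    freqs = np.asarray(freqs, dtype=float)
    X = np.column_stack([freqs, np.ones(len(freqs))])
    coef, *_ = np.linalg.lstsq(X, np.asarray(activities, dtype=float),
                               rcond=None)
    return pd.DataFrame(coef.T, columns=["a1", "a2", "b"])


def f1f2_regression(net: Network, f_min=5, f_max=50, step=1):
    """Least-squares frequency coefficients at the comparison step.

    Every (F1, F2) pair on the grid is played once with noise-free
    tuning and forced holding; unit activities are read at the step
    where F2 comes on. Activities are regressed on (F1, F2, 1).

    Returns {'memory' | 'regular' | 'q': DataFrame(a1, a2, b)} plus key
    'memory_corr' with the Pearson correlation between a1 and a2 across
    memory units.
    """
    env = VibrotactileEnv(rng=0, shaping=True, mode="variable", noise_sd=0.0)
    grid = [(f1, f2)
            for f1 in np.arange(f_min, f_max + 1e-9, step)
            for f2 in np.arange(f_min, f_max + 1e-9, step)]
    act = {"regular": [], "memory": [], "q": []}
    with net.frozen_mode():
        for (f1, f2) in grid:
            net.reset_trial()
            logs = probe_trial(net, env, env.reset(f1=f1, f2=f2))
            # canonical timing: contact, contact, F1, delay, delay, F2, ...
            comp = logs[5]
            act["regular"].append(comp.y_reg)
            act["memory"].append(comp.y_mem)
            act["q"].append(comp.q)
    out = {name: frequency_regression(grid, ys) for name, ys in act.items()}
    a1 = out["memory"].a1.to_numpy()
    a2 = out["memory"].a2.to_numpy()
    out["memory_corr"] = float(np.corrcoef(a1, a2)[0, 1])
    return out


def _logistic(f2, loc, slope):
    return 1.0 / (1.0 + np.exp(-(f2 - loc) / slope))


def psychometric_fit(battery: pd.DataFrame):
    """Two-parameter logistic fits of P(judged F2 > F1) against F2.

    `battery` is the output of
    :func:`augment_rl.training.psychometric_battery`. Returns a
    DataFrame with one row per F1: location, slope and a degenerate
    flag (all-or-nothing response patterns get a penalized fit).
    """
    rows = []
    for f1, sub in battery.groupby("f1"):
        f2 = sub.f2.to_numpy(dtype=float)
        p = sub.n_right.to_numpy(dtype=float) / sub.n.to_numpy(dtype=float)
        degenerate = p.min() > 0.99 or p.max() < 0.01
        try:
            popt, _ = optimize.curve_fit(
                _logistic, f2, p, p0=(float(f1), 2.0),
                bounds=([0.0, 0.1], [55.0, 50.0]), maxfev=5000)
            loc, slope = popt
        except RuntimeError:
            order = np.argsort(f2)
            loc = float(np.interp(0.5, p[order], f2[order]))
            slope, degenerate = np.nan, True
        rows.append(dict(f1=f1, location=float(loc), slope=float(slope),
                         degenerate=bool(degenerate)))
    return pd.DataFrame(rows)
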