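"""Finite-difference oracle for the gradient-descent equivalence.

With lambda = 0 (full tag decay each step) and the feedback weights set
equal to their feedforward partners, the tag-based update of every weight
on a sampled SARSA transition equals ``beta * delta`` times the gradient
of the previously chosen Q-value with respect to that weight. This module
verifies the claim numerically: it replays a fixed episode (forced
actions, frozen weights) and compares each tag against a central
finite-difference estimate of ``d q_a(t-1) / d w``.

For the synapses onto memory units the equivalence relies on the input
accumulator factorizing as (weight) x (summed transient input), which is
exact when the weights do not change within the episode - guaranteed here
because the replays run with the learning rate set to zero.
"""

from __future__ import annotations

import numpy as np

from .network import Network
from .params import ArchitectureSpec, LearningParams

_FAMILIES = ("V_reg", "V_mem", "W_reg", "W_mem")


def _replay_q(net_weights, arch, theta, episode_x, actions, upto):
    """Frozen replay of steps 0..upto; return q of the action chosen at upto."""
    net = Network(
        arch.n_inst,
        params=LearningParams(beta=1e-12, lam=0.0, gamma=0.9,
                              epsilon=0.0, theta=theta),
        arch=arch, seed=0,
    )
    net.beta = 0.0
    net.set_weights(net_weights)
    for t in range(upto + 1):
        net.step(episode_x[t], 0.0, False, force_action=int(actions[t]))
    return net.q[actions[upto]]


def gradient_discrepancy(net: Network, episode_x, actions, transition=None,
                         fd_step: float = 1e-5):
    """Max |tag - finite-difference gradient| per weight family.

    Parameters
    ----------
    net : Network
        Must have ``lam == 0``. Its feedback weights are symmetrized to
        the feedforward ones before the comparison.
    episode_x : array (T, n_inst)
        Observation sequence of the episode.
    actions : sequence of int, length T
        Forced action at every step.
    transition : int, optional
        Index t of the scrutinized transition; the update at step t uses
        the tags formed after the action at t-1. Defaults to the last
        step, ``T - 1``.
    fd_step : float
        Central-difference step size.

    Returns
    -------
    dict mapping family name ('V_reg', 'V_mem', 'W_reg', 'W_mem') to the
    maximum absolute elementwise discrepancy.
    """
    if net.params.lam != 0.0:
        raise ValueError("gradient equivalence requires lambda = 0 (alpha = 1)")
    episode_x = np.asarray(episode_x, dtype=float)
    T = episode_x.shape[0]
    actions = np.asarray(actions, dtype=int)
    if transition is None:
        transition = T - 1
    if transition < 1:
        raise ValueError("need at least one prior action before the transition")

    net.symmetrize_feedback()
    w0 = net.copy_weights()
    arch, theta = net.arch, net.params.theta

    # run frozen up to the step before the transition to capture the tags
    probe = Network(arch.n_inst, params=net.params, arch=arch, seed=0)
    probe.beta = 0.0
    probe.set_weights(w0)
    for t in range(transition):
        probe.step(episode_x[t], 0.0, False, force_action=int(actions[t]))
    tags = {k: probe.tags[k].copy() for k in _FAMILIES}

    out = {}
    for fam in _FAMILIES:
        base = w0[fam]
        grad = np.zeros_like(base)
        it = np.nditer(base, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            wp = {k: v.copy() for k, v in w0.items()}
            wp[fam][idx] = base[idx] + fd_step
            qp = _replay_q(wp, arch, theta, episode_x, actions, transition - 1)
            wm = {k: v.copy() for k, v in w0.items()}
            wm[fam][idx] = base[idx] - fd_step
            qm = _replay_q(wm, arch, theta, episode_x, actions, transition - 1)
            grad[idx] = (qp - qm) / (2.0 * fd_step)
        out[fam] = float(np.max(np.abs(tags[fam] - grad)))
    return out


def random_instance(rng, n_inst=3, n_steps=3):
    """Draw a random small network + episode for the oracle.

    Returns ``(net, episode_x, actions)`` with lambda = 0, nonnegative
    random stimuli and random forced actions.
    """
    arch = ArchitectureSpec(n_inst=n_inst)
    params = LearningParams(beta=0.15, lam=0.0, gamma=0.9,
                            epsilon=0.0, theta=2.5)
    net = Network(n_inst, params=params, arch=arch,
                  seed=int(rng.integers(2**31)))
    episode_x = rng.uniform(0.0, 1.0, size=(n_steps, n_inst))
    # sprinkle zeros so on/off transients both occur
    episode_x[rng.random(size=episode_x.shape) < 0.3] = 0.0
    actions = rng.integers(0, arch.n_q, size=n_steps)
    return net, episode_x, actions
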