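"""The attention-gated memory-tagging agent.

A three-layer network learns action values by SARSA(lambda), implemented
with local synaptic machinery only: eligibility *tags* on every plastic
synapse, non-decaying presynaptic *traces* on the synapses onto memory
units, an attentional feedback signal from the selected action that
converts activity (or traces) into tags, and a globally broadcast
reward-prediction error that scales all tagged synapses.

Layer structure
---------------
* sensory: ``n_inst`` instantaneous units plus on/off transient channels
  that fire at positive/negative stimulus changes;
* association: ``n_regular`` sigmoidal units driven by the instantaneous
  input, and ``n_memory`` units that integrate *transient* input over the
  trial (hence show persistent, working-memory-like activity);
* Q-layer: one unit per action, linear in the association activities.

Action selection is Max-Boltzmann: greedy with probability 1 - epsilon,
otherwise a softmax sample of the Q-values.
"""

from __future__ import annotations

from contextlib import contextmanager
from dataclasses import dataclass

import numpy as np

from . import _kernel
from .params import ArchitectureSpec, LearningParams

__all__ = [
    "Network",
    "StepLog",
    "encode_sensory",
    "sigma",
    "sigma_prime",
    "boltzmann_probabilities",
]


def encode_sensory(x_now: np.ndarray, x_prev: np.ndarray):
    """Split a stimulus change into on (rise) and off (fall) transients.

    Returns ``(x_on, x_off)`` with ``x_on = [x_now - x_prev]_+`` and
    ``x_off = [x_prev - x_now]_+``; at most one of the two is nonzero per
    component. At trial start ``x_prev`` is the all-zero vector.
    """
    x_now = np.asarray(x_now, dtype=float)
    x_prev = np.asarray(x_prev, dtype=float)
    if x_now.shape != x_prev.shape:
        raise ValueError(
            f"shape mismatch: x_now {x_now.shape} vs x_prev {x_prev.shape}"
        )
    d = x_now - x_prev
    return np.maximum(d, 0.0), np.maximum(-d, 0.0)


def sigma(inp, theta: float = 2.5):
    """Sigmoidal activation ``1 / (1 + exp(theta - inp))``."""
    z = np.clip(theta - np.asarray(inp, dtype=float), -500.0, 500.0)
    return 1.0 / (1.0 + np.exp(z))


def sigma_prime(y):
    """Derivative of the sigmoid expressed through the activity: y(1-y)."""
    y = np.asarray(y, dtype=float)
    return y * (1.0 - y)


def boltzmann_probabilities(q: np.ndarray) -> np.ndarray:
    """Softmax of the Q-values used by the exploratory branch."""
    q = np.asarray(q, dtype=float)
    z = np.exp(q - q.max())
    return z / z.sum()


@dataclass
class StepLog:
    """Per-step record for analysis: activities, values, choice, RPE."""

    t: int
    action: int
    reward: float
    delta: float
    q: np.ndarray
    y_reg: np.ndarray
    y_mem: np.ndarray


class Network:
    """One agent: weights, tags, traces and the per-step update rule.

    Parameters
    ----------
    n_inst : int
        Number of instantaneous sensory inputs (task dependent).
    params : LearningParams, optional
    arch : ArchitectureSpec, optional
        If given, its ``n_inst`` must match the first argument.
    seed : int or numpy.random.SeedSequence, optional
        Master seed; independent child streams are derived for weight
        initialization and action selection, so disabling exploration does
        not perturb any other randomness.
    """

    def __init__(self, n_inst, params=None, arch=None, seed=None):
        self.params = params if params is not None else LearningParams()
        if arch is None:
            arch = ArchitectureSpec(n_inst=n_inst)
        elif arch.n_inst != n_inst:
            raise ValueError("arch.n_inst does not match n_inst")
        self.arch = arch

        if isinstance(seed, np.random.SeedSequence):
            ss = seed
        else:
            ss = np.random.SeedSequence(seed)
        ss_weights, ss_action = ss.spawn(2)
        self._rng_action = np.random.default_rng(ss_action)
        rng_w = np.random.default_rng(ss_weights)

        I, J = arch.n_inst, arch.n_regular
        M, K = arch.n_memory, arch.n_q
        lo, hi = arch.init_low, arch.init_high
        u = rng_w.uniform
        self.V_reg = u(lo, hi, size=(I + 1, J))
        self.V_mem = u(lo, hi, size=(2 * I, M))
        self.W_reg = u(lo, hi, size=(J + 1, K))
        self.W_mem = u(lo, hi, size=(M, K))
        # feedback weights are stored separately (the rule makes them
        # proportional to their feedforward partners, not identical)
        self.FB_reg = u(lo, hi, size=(K, J))
        self.FB_mem = u(lo, hi, size=(K, M))

        self.T_V_reg = np.zeros_like(self.V_reg)
        self.T_V_mem = np.zeros_like(self.V_mem)
        self.T_W_reg = np.zeros_like(self.W_reg)
        self.T_W_mem = np.zeros_like(self.W_mem)
        self.T_FB_reg = np.zeros_like(self.FB_reg)
        self.T_FB_mem = np.zeros_like(self.FB_mem)
        self.trace = np.zeros(2 * I)

        self.x_prev = np.zeros(I)
        self.inp_mem = np.zeros(M)
        self._q_state = np.zeros(2)  # [stored chosen q, valid flag]
        self.y_reg = np.zeros(J)
        self.y_mem = np.zeros(M)
        self.q = np.zeros(K)
        self.t = 0

        # mutable copies of the learning constants so that freezing
        # (beta = epsilon = 0) is a cheap, reversible state change
        self.beta = self.params.beta
        self.epsilon = self.params.epsilon
        self._lam_gamma = self.params.lam * self.params.gamma
        self._gamma = self.params.gamma
        self._theta = self.params.theta

    # -- stepping -----------------------------------------------------

    def step(self, x, reward=0.0, terminal=False, force_action=-1):
        """Advance one time step; return ``(action, delta)``.

        ``action`` is -1 on terminal steps (the trial resets internally,
        after a final update against a zero terminal value). ``delta`` is
        NaN when no transition was available to evaluate.
        """
        u = self._rng_action.random(2)
        self.t += 1
        a, delta = _kernel.agent_step(
            np.ascontiguousarray(x, dtype=np.float64),
            float(reward), bool(terminal),
            u[0], u[1], int(force_action),
            self.beta, self._lam_gamma, self._gamma, self.epsilon,
            self._theta,
            self.V_reg, self.V_mem, self.W_reg, self.W_mem,
            self.FB_reg, self.FB_mem,
            self.x_prev, self.inp_mem, self._q_state, self.trace,
            self.T_V_reg, self.T_V_mem, self.T_W_reg, self.T_W_mem,
            self.T_FB_reg, self.T_FB_mem,
            self.y_reg, self.y_mem, self.q,
        )
        if terminal:
            self.t = 0
        return a, delta

    def step_logged(self, x, reward=0.0, terminal=False, force_action=-1):
        """Like :meth:`step` but also return a :class:`StepLog` snapshot."""
        t = self.t + 1
        a, delta = self.step(x, reward, terminal, force_action)
        log = StepLog(
            t=t, action=a, reward=float(reward), delta=delta,
            q=self.q.copy(), y_reg=self.y_reg.copy(),
            y_mem=self.y_mem.copy(),
        )
        return a, delta, log

    def reset_trial(self):
        """Clear all within-trial state; weights persist."""
        self.x_prev[:] = 0.0
        self.inp_mem[:] = 0.0
        self.trace[:] = 0.0
        for tag in self.tags.values():
            tag[:] = 0.0
        self._q_state[:] = 0.0
        self.y_reg[:] = 0.0
        self.y_mem[:] = 0.0
        self.q[:] = 0.0
        self.t = 0

    # -- freezing -----------------------------------------------------

    @property
    def frozen(self) -> bool:
        return self.beta == 0.0 and self.epsilon == 0.0

    def freeze(self):
        """Disable learning and exploration (beta = epsilon = 0)."""
        self.beta = 0.0
        self.epsilon = 0.0

    def thaw(self):
        """Restore the configured learning rate and exploration."""
        self.beta = self.params.beta
        self.epsilon = self.params.epsilon

    @contextmanager
    def frozen_mode(self):
        beta, eps = self.beta, self.epsilon
        self.freeze()
        try:
            yield self
        finally:
            self.beta, self.epsilon = beta, eps

    # -- views --------------------------------------------------------

    @property
    def weights(self):
        return {
            "V_reg": self.V_reg, "V_mem": self.V_mem,
            "W_reg": self.W_reg, "W_mem": self.W_mem,
            "FB_reg": self.FB_reg, "FB_mem": self.FB_mem,
        }

    @property
    def tags(self):
        return {
            "V_reg": self.T_V_reg, "V_mem": self.T_V_mem,
            "W_reg": self.T_W_reg, "W_mem": self.T_W_mem,
            "FB_reg": self.T_FB_reg, "FB_mem": self.T_FB_mem,
        }

    @property
    def q_stored(self):
        """Previously chosen Q-value, or None before the first action."""
        return self._q_state[0] if self._q_state[1] != 0.0 else None

    def copy_weights(self):
        return {k: v.copy() for k, v in self.weights.items()}

    def set_weights(self, weights):
        for k, v in weights.items():
            getattr(self, k)[...] = v

    def symmetrize_feedback(self):
        """Set each feedback weight equal to its feedforward partner.

        Useful for exact gradient comparisons; during normal learning the
        tag rule only makes the two *proportional*.
        """
        self.FB_reg[...] = self.W_reg[1:, :].T
        self.FB_mem[...] = self.W_mem.T
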