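"""Shared trial-environment machinery.

Every task uses three actions. Action 1 doubles as "fixate" (visual
tasks) or "hold the key" (vibrotactile); actions 0 and 2 are the left and
right responses. Rewards: a small shaping reward ``r_i`` (0.2 units) for
attaining fixation/hold, and the full task reward ``r_f`` (1.5 units) for
a correct choice. Wrong choices, fixation breaks and timeouts abort the
trial without further reward.
"""

from __future__ import annotations

import numpy as np

LEFT, CENTER, RIGHT = 0, 1, 2

R_FINAL = 1.5
R_SHAPE = 0.2


class TrialEnv:
    """Base class: phase bookkeeping common to all four tasks.

    Subclasses implement :meth:`_draw_trial` (sample a trial spec into
    attributes) and :meth:`_observe` (fill ``self._x`` for the current
    phase), and drive the phase machine from :meth:`step`.

    Attributes set per trial
    ------------------------
    trial_type : hashable
        Stratum key for windowed-accuracy bookkeeping.
    correct_action : int or None
        Ground-truth response; None if both responses count as correct.
    outcome : str or None
        'correct', 'wrong', 'broke_fix', 'timeout_fix', 'timeout_go';
        None while the trial is running.
    fixated, reached_go : bool
        Milestone flags (shaping reward attained; held until go signal).
    chose : int or None
        The response action actually emitted, if any.
    """

    n_actions = 3
    n_inputs: int  # set by subclass

    #: observations allowed in the fixation/hold acquisition window
    acquire_limit = 10
    #: observations allowed in the response window
    respond_limit = 8

    def __init__(self, rng=None, shaping=True):
        if rng is None or isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(rng)
        elif isinstance(rng, np.random.SeedSequence):
            rng = np.random.default_rng(rng)
        self.rng = rng
        self.r_shape = R_SHAPE if shaping else 0.0
        self.r_final = R_FINAL
        self._x = np.zeros(self.n_inputs)

    # -- public API: subclasses implement _reset / _step ---------------

    def reset(self, **trial_options):
        """Start a fresh trial; returns ``(x, reward, terminal)``.

        The observation is a copy, safe to hold across steps.
        """
        x, reward, terminal = self._reset(**trial_options)
        return x.copy(), reward, terminal

    def step(self, action):
        """Consume the agent's action; returns ``(x, reward, terminal)``."""
        x, reward, terminal = self._step(action)
        return x.copy(), reward, terminal

    # -- per-trial state ----------------------------------------------

    def _new_trial_state(self):
        self.trial_type = None
        self.correct_action = None
        self.outcome = None
        self.fixated = False
        self.reached_go = False
        self.chose = None
        self._fix_streak = 0
        self._acquire_steps = 0
        self._respond_steps = 0
        self.t = 0

    def _terminal(self, outcome, reward=0.0):
        self.outcome = outcome
        self._x[:] = 0.0
        return self._x, reward, True

    def _abort(self, outcome):
        return self._terminal(outcome, 0.0)

    def _finish(self, action):
        self.chose = action
        correct = (self.correct_action is None) or (action == self.correct_action)
        if self._rewarded(action, correct):
            return self._terminal("correct" if correct else "wrong", self.r_final)
        return self._terminal("correct" if correct else "wrong", 0.0)

    def _rewarded(self, action, correct):
        """Whether the final reward is delivered; tasks with probabilistic
        payoffs override this."""
        return correct

    @property
    def correct(self):
        """True/False once the trial ended with a choice; None otherwise."""
        if self.outcome in ("correct", "wrong"):
            return self.outcome == "correct"
        return None
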