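"""Delayed pro-/anti-saccade task.

A trial: one step of empty screen; a fixation mark appears whose shade
(black vs white) instructs a pro- or anti-saccade. The agent must fixate
(select the center action) within 10 steps; after two consecutive
fixation steps a cue flashes left or right for one step together with
the shaping reward. Two delay steps follow with only the mark visible,
then the mark switches off (the go signal). Responding toward the
remembered cue (pro) or away from it (anti) earns the full reward; any
non-center action before the go signal, or running out the windows,
aborts the trial. In the pro-only variant the mark shade still varies
but a pro-saccade is always required, making the shade task-irrelevant.
"""

from __future__ import annotations

from .base import CENTER, LEFT, RIGHT, TrialEnv

# input layout
FIX_BLACK, FIX_WHITE, CUE_LEFT, CUE_RIGHT = 0, 1, 2, 3

TRIAL_TYPES = ("PL", "PR", "AL", "AR")


class SaccadeEnv(TrialEnv):
    n_inputs = 4

    def __init__(self, rng=None, shaping=True, pro_only=False):
        super().__init__(rng=rng, shaping=shaping)
        self.pro_only = pro_only
        self.trial_types = ("PL", "PR") if pro_only else TRIAL_TYPES

    def _reset(self, trial_type=None):
        self._new_trial_state()
        if trial_type is None:
            trial_type = self.trial_types[
                self.rng.integers(len(self.trial_types))]
        elif trial_type not in TRIAL_TYPES:
            raise ValueError(f"unknown trial type {trial_type!r}")
        self.trial_type = trial_type
        self._pro = self.trial_type[0] == "P"
        self._cue_left = self.trial_type[1] == "L"
        if self._pro:
            self.correct_action = LEFT if self._cue_left else RIGHT
        else:
            self.correct_action = RIGHT if self._cue_left else LEFT
        self._fix_unit = FIX_BLACK if self._pro else FIX_WHITE
        self._phase = "start"
        self._x[:] = 0.0  # empty screen
        self.t = 1
        return self._x, 0.0, False

    def _step(self, action):
        self.t += 1
        phase = self._phase
        x = self._x

        if phase == "start":
            # mark comes on; acquisition window opens
            self._phase = "acquire"
            x[:] = 0.0
            x[self._fix_unit] = 1.0
            return x, 0.0, False

        if phase == "acquire":
            self._acquire_steps += 1
            self._fix_streak = self._fix_streak + 1 if action == CENTER else 0
            if self._fix_streak == 2:
                self.fixated = True
                self._phase = "cue"
                x[:] = 0.0
                x[self._fix_unit] = 1.0
                x[CUE_LEFT if self._cue_left else CUE_RIGHT] = 1.0
                return x, self.r_shape, False
            if self._acquire_steps >= self.acquire_limit:
                return self._abort("timeout_fix")
            x[:] = 0.0
            x[self._fix_unit] = 1.0
            return x, 0.0, False

        if phase in ("cue", "delay1"):
            if action != CENTER:
                return self._abort("broke_fix")
            self._phase = "delay1" if phase == "cue" else "delay2"
            x[:] = 0.0
            x[self._fix_unit] = 1.0
            return x, 0.0, False

        if phase == "delay2":
            if action != CENTER:
                return self._abort("broke_fix")
            self._phase = "go"
            self.reached_go = True
            x[:] = 0.0  # mark off = go signal
            return x, 0.0, False

        # go phase: center is a legal wait action
        if action == CENTER:
            self._respond_steps += 1
            if self._respond_steps >= self.respond_limit:
                return self._abort("timeout_go")
            x[:] = 0.0
            return x, 0.0, False
        return self._finish(action)
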