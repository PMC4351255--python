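"""Delayed match-to-category task.

Twelve motion directions, 30 degrees apart, are split by a boundary into
two categories of six. After fixation is acquired, a first motion cue is
flashed for one step (with the shaping reward), followed by a two-step
memory delay and then a second motion cue, which doubles as the go
signal - the fixation mark stays on in this task. A saccade to the left
is required when both cues belong to the same category, to the right
otherwise. Motion direction is read through a bank of 20 units with
circular Gaussian tuning (s.d. 12 deg, preferred directions evenly
spaced on the circle), and each presented direction is jittered by
Gaussian noise (s.d. 5 deg) before tuning-curve evaluation.
"""

from __future__ import annotations

import numpy as np

from .base import CENTER, LEFT, RIGHT, TrialEnv

N_DIRECTIONS = 12
DIRECTIONS = 15.0 + 30.0 * np.arange(N_DIRECTIONS)  # degrees
#: category of each direction index: 0 for (0, 180), 1 for (180, 360)
CATEGORY = (DIRECTIONS > 180.0).astype(int)

N_TUNED = 20
PREFERRED = 360.0 * np.arange(N_TUNED) / N_TUNED
TUNING_SD = 12.0
DIRECTION_NOISE_SD = 5.0

FIX = 0  # index of the fixation-mark input


def direction_tuning(direction_deg):
    """Circular-Gaussian population response to a motion direction."""
    d = (np.asarray(direction_deg, dtype=float) - PREFERRED + 180.0) % 360.0 - 180.0
    return np.exp(-(d ** 2) / (2.0 * TUNING_SD ** 2))


class CategoryEnv(TrialEnv):
    n_inputs = 1 + N_TUNED

    def __init__(self, rng=None, shaping=True, noise_sd=DIRECTION_NOISE_SD):
        super().__init__(rng=rng, shaping=shaping)
        self.noise_sd = noise_sd

    def _reset(self, cue1=None, cue2=None):
        """Start a trial; cue direction indices may be forced for probing."""
        self._new_trial_state()
        self._cue1 = int(self.rng.integers(N_DIRECTIONS)) if cue1 is None else int(cue1)
        self._cue2 = int(self.rng.integers(N_DIRECTIONS)) if cue2 is None else int(cue2)
        self.match = CATEGORY[self._cue1] == CATEGORY[self._cue2]
        self.correct_action = LEFT if self.match else RIGHT
        self.trial_type = self._cue1  # strata = cue-1 direction
        self._phase = "start"
        self._x[:] = 0.0
        self.t = 1
        return self._x, 0.0, False

    def _cue_obs(self, idx):
        self._x[:] = 0.0
        self._x[FIX] = 1.0
        direction = DIRECTIONS[idx]
        if self.noise_sd > 0.0:
            direction = direction + self.rng.normal(0.0, self.noise_sd)
        self._x[1:] = direction_tuning(direction)
        return self._x

    def _fix_obs(self):
        self._x[:] = 0.0
        self._x[FIX] = 1.0
        return self._x

    def _step(self, action):
        self.t += 1
        phase = self._phase

        if phase == "start":
            self._phase = "acquire"
            return self._fix_obs(), 0.0, False

        if phase == "acquire":
            self._acquire_steps += 1
            self._fix_streak = self._fix_streak + 1 if action == CENTER else 0
            if self._fix_streak == 2:
                self.fixated = True
                self._phase = "cue"
                return self._cue_obs(self._cue1), self.r_shape, False
            if self._acquire_steps >= self.acquire_limit:
                return self._abort("timeout_fix")
            return self._fix_obs(), 0.0, False

        if phase in ("cue", "delay1", "delay2"):
            if action != CENTER:
                return self._abort("broke_fix")
            if phase == "cue":
                self._phase = "delay1"
                return self._fix_obs(), 0.0, False
            if phase == "delay1":
                self._phase = "delay2"
                return self._fix_obs(), 0.0, False
            self._phase = "go"
            self.reached_go = True
            return self._cue_obs(self._cue2), 0.0, False

        # go phase: cue-2 stays visible; center waits
        if action == CENTER:
            self._respond_steps += 1
            if self._respond_steps >= self.respond_limit:
                return self._abort("timeout_go")
            return self._x, 0.0, False
        return self._finish(action)
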