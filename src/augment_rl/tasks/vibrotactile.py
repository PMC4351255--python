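"""Vibrotactile two-frequency comparison task.

A trial opens with a binary skin-contact unit switching on. The agent
must press the hold key (center action) within 10 steps; after two
consecutive hold steps the first flutter stimulus F1 is applied for one
step together with the shaping reward. A two-step delay follows, then
the second stimulus F2 stays on while the agent responds: left if
F2 < F1, right if F2 > F1, within 8 steps.

Frequencies are read through 20 sigmoidal tuning curves
``1 / (1 + exp(w * (c - f)))`` - ten centers evenly spaced between 5.5
and 49.5 Hz, each represented by an increasing (w = +5) and a
decreasing (w = -5) unit - with independent zero-mean Gaussian noise
(s.d. 0.075) added to the rates while a stimulus is on, truncated to
[0, 1]. Tuned units are silent when no vibration is applied.

Modes
-----
variable : F1 uniform on [5, 50] Hz; F2 uniform with |F2 - F1| >= 2 Hz.
fixed    : F1 = 30 Hz; F2 on a 2.5 Hz grid in [5, 50] with
           |F2 - 30| >= 10 Hz.
Forced pairs (for batteries and block training) via ``reset(f1=, f2=)``.
"""

from __future__ import annotations

import numpy as np

from .base import CENTER, LEFT, RIGHT, TrialEnv

N_TUNED = 20
CENTERS = np.repeat(np.linspace(5.5, 49.5, 10), 2)
STEEPNESS = np.tile([5.0, -5.0], 10)
RATE_NOISE_SD = 0.075
F_MIN, F_MAX = 5.0, 50.0
MIN_SEPARATION = 2.0

CONTACT = N_TUNED  # index of the skin-contact unit

_FIXED_GRID = np.arange(F_MIN, F_MAX + 1e-9, 2.5)
FIXED_F1 = 30.0
FIXED_F2_CHOICES = _FIXED_GRID[np.abs(_FIXED_GRID - FIXED_F1) >= 10.0]


def frequency_tuning(freq_hz):
    """Noise-free population response of the 20 tuned units."""
    z = np.clip(STEEPNESS * (CENTERS - float(freq_hz)), -500.0, 500.0)
    return 1.0 / (1.0 + np.exp(z))


class VibrotactileEnv(TrialEnv):
    n_inputs = N_TUNED + 1

    def __init__(self, rng=None, shaping=True, mode="variable",
                 noise_sd=RATE_NOISE_SD):
        if mode not in ("variable", "fixed"):
            raise ValueError(f"unknown mode {mode!r}")
        super().__init__(rng=rng, shaping=shaping)
        self.mode = mode
        self.noise_sd = noise_sd

    def _draw_pair(self):
        rng = self.rng
        if self.mode == "fixed":
            return FIXED_F1, float(FIXED_F2_CHOICES[rng.integers(len(FIXED_F2_CHOICES))])
        f1 = rng.uniform(F_MIN, F_MAX)
        while True:
            f2 = rng.uniform(F_MIN, F_MAX)
            if abs(f2 - f1) >= MIN_SEPARATION:
                return f1, f2

    def _reset(self, f1=None, f2=None):
        self._new_trial_state()
        if f1 is None or f2 is None:
            self.f1, self.f2 = self._draw_pair()
        else:
            self.f1, self.f2 = float(f1), float(f2)
        self.correct_action = LEFT if self.f2 < self.f1 else RIGHT
        self.trial_type = min(int((self.f1 - F_MIN) // 5.0), 8)  # 5 Hz F1 bin
        self._phase = "acquire"
        self._x[:] = 0.0
        self._x[CONTACT] = 1.0
        self.t = 1
        return self._x, 0.0, False

    def _stim_obs(self, freq):
        x = self._x
        x[:N_TUNED] = frequency_tuning(freq)
        if self.noise_sd > 0.0:
            x[:N_TUNED] += self.rng.normal(0.0, self.noise_sd, N_TUNED)
            np.clip(x[:N_TUNED], 0.0, 1.0, out=x[:N_TUNED])
        x[CONTACT] = 1.0
        return x

    def _contact_obs(self):
        self._x[:] = 0.0
        self._x[CONTACT] = 1.0
        return self._x

    def _step(self, action):
        self.t += 1
        phase = self._phase

        if phase == "acquire":
            self._acquire_steps += 1
            self._fix_streak = self._fix_streak + 1 if action == CENTER else 0
            if self._fix_streak == 2:
                self.fixated = True
                self._phase = "f1"
                return self._stim_obs(self.f1), self.r_shape, False
            if self._acquire_steps >= self.acquire_limit:
                return self._abort("timeout_fix")
            return self._contact_obs(), 0.0, False

        if phase in ("f1", "delay1", "delay2"):
            if action != CENTER:
                return self._abort("broke_fix")
            if phase == "f1":
                self._phase = "delay1"
                return self._contact_obs(), 0.0, False
            if phase == "delay1":
                self._phase = "delay2"
                return self._contact_obs(), 0.0, False
            self._phase = "go"
            self.reached_go = True
            return self._stim_obs(self.f2), 0.0, False

        # comparison phase: F2 stays on (re-noised each step); hold waits
        if action == CENTER:
            self._respond_steps += 1
            if self._respond_steps >= self.respond_limit:
                return self._abort("timeout_go")
            return self._stim_obs(self.f2), 0.0, False
        return self._finish(action)
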