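"""Probabilistic weighted-symbol classification task.

After fixation is acquired the screen shows a red and a green saccade
target (their sides randomized per trial) and a sequence of one to four
shapes, appearing cumulatively, one per step, at randomized distinct
locations around fixation. Each shape carries a log10 evidence weight
for the red target; reward is assigned to the red target with
probability ``P(red) = 10**W / (1 + 10**W)`` where ``W`` sums the
weights of the presented shapes, and to the green target otherwise.
After a two-step delay the fixation mark turns off (go) and the agent
saccades to one side; the full reward is delivered only if the baited
target sat on the chosen side. For learning-curve bookkeeping a choice
is "correct" when it selects the side with the higher reward
probability (either side if equal).

The two "trump" shapes are decisive: they guarantee reward on their
side. They are represented with finite weights of +/-5 (odds 10**5) so
that the evidence sum stays defined and two opposing trumps cancel.
"""

from __future__ import annotations

import numpy as np

from .base import CENTER, LEFT, RIGHT, TrialEnv

TRUMP_WEIGHT = 5.0
#: evidence weights, in the pairwise order the curriculum introduces them
SYMBOL_WEIGHTS = np.array(
    [TRUMP_WEIGHT, -TRUMP_WEIGHT, 0.9, -0.9, 0.7, -0.7, 0.5, -0.5, 0.3, -0.3]
)
N_SYMBOLS = 10
N_LOCATIONS = 4

FIX = 0
# target-color units: (side, color) -> input index
TGT_LEFT_RED, TGT_LEFT_GREEN, TGT_RIGHT_RED, TGT_RIGHT_GREEN = 1, 2, 3, 4
SYMBOL_OFFSET = 5  # then 4 locations x 10 symbols


def p_red(weight_sum):
    """Probability that the red target is baited given evidence sum W."""
    return 10.0 ** weight_sum / (1.0 + 10.0 ** weight_sum)


def symbol_input_index(location, symbol):
    return SYMBOL_OFFSET + location * N_SYMBOLS + symbol


class ClassificationEnv(TrialEnv):
    n_inputs = 1 + 4 + N_LOCATIONS * N_SYMBOLS

    def __init__(self, rng=None, shaping=True, n_symbols=N_SYMBOLS,
                 seq_len=4):
        super().__init__(rng=rng, shaping=shaping)
        self.configure(n_symbols, seq_len)

    def configure(self, n_symbols, seq_len):
        """Set the curriculum level (available symbols, sequence length)."""
        if not 2 <= n_symbols <= N_SYMBOLS or n_symbols % 2:
            raise ValueError("n_symbols must be an even count in [2, 10]")
        if not 1 <= seq_len <= N_LOCATIONS:
            raise ValueError("seq_len must be in [1, 4]")
        self.n_symbols = int(n_symbols)
        self.seq_len = int(seq_len)

    def _reset(self, symbols=None, red_side=None):
        self._new_trial_state()
        rng = self.rng
        if symbols is None:
            symbols = rng.integers(self.n_symbols, size=self.seq_len)
        self.symbols = np.asarray(symbols, dtype=int)
        self.locations = rng.permutation(N_LOCATIONS)[: len(self.symbols)]
        if red_side is None:
            red_side = LEFT if rng.random() < 0.5 else RIGHT
        self.red_side = red_side
        self.green_side = RIGHT if red_side == LEFT else LEFT

        self.weight_sum = float(SYMBOL_WEIGHTS[self.symbols].sum())
        self.p_red = p_red(self.weight_sum)
        red_baited = rng.random() < self.p_red
        self.baited_side = self.red_side if red_baited else self.green_side
        if self.p_red > 0.5:
            self.correct_action = self.red_side
        elif self.p_red < 0.5:
            self.correct_action = self.green_side
        else:
            self.correct_action = None  # either side counts as correct
        self.trial_type = len(self.symbols)  # stratum: sequence length
        self._shown = 0
        self._phase = "start"
        self._x[:] = 0.0
        self.t = 1
        return self._x, 0.0, False

    def _rewarded(self, action, correct):
        return action == self.baited_side

    def _scene(self, fix_on):
        """Targets + all symbols shown so far; fixation mark optional."""
        x = self._x
        x[:] = 0.0
        if fix_on:
            x[FIX] = 1.0
        if self.red_side == LEFT:
            x[TGT_LEFT_RED] = 1.0
            x[TGT_RIGHT_GREEN] = 1.0
        else:
            x[TGT_RIGHT_RED] = 1.0
            x[TGT_LEFT_GREEN] = 1.0
        for i in range(self._shown):
            x[symbol_input_index(self.locations[i], self.symbols[i])] = 1.0
        return x

    def _step(self, action):
        self.t += 1
        phase = self._phase

        if phase == "start":
            self._phase = "acquire"
            self._x[:] = 0.0
            self._x[FIX] = 1.0
            return self._x, 0.0, False

        if phase == "acquire":
            self._acquire_steps += 1
            self._fix_streak = self._fix_streak + 1 if action == CENTER else 0
            if self._fix_streak == 2:
                self.fixated = True
                self._shown = 1
                self._phase = "symbols" if self._shown < len(self.symbols) else "delay1"
                return self._scene(True), self.r_shape, False
            if self._acquire_steps >= self.acquire_limit:
                return self._abort("timeout_fix")
            self._x[:] = 0.0
            self._x[FIX] = 1.0
            return self._x, 0.0, False

        if phase in ("symbols", "delay1", "delay2", "go_signal"):
            if action != CENTER:
                return self._abort("broke_fix")
            if phase == "symbols":
                self._shown += 1
                if self._shown >= len(self.symbols):
                    self._phase = "delay1"
                return self._scene(True), 0.0, False
            if phase == "delay1":
                self._phase = "delay2"
                return self._scene(True), 0.0, False
            if phase == "delay2":
                self._phase = "go_signal"
                return self._scene(True), 0.0, False
            self._phase = "go"
            self.reached_go = True
            return self._scene(False), 0.0, False  # mark off = go

        if action == CENTER:
            self._respond_steps += 1
            if self._respond_steps >= self.respond_limit:
                return self._abort("timeout_go")
            return self._x, 0.0, False
        return self._finish(action)
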