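"""Learning and architecture parameters.

The defaults are the single parameter set used for every task: a small
sigmoidal network (3 regular + 4 memory association units, 3 action-value
units) trained with SARSA(lambda) realized through synaptic tags and traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class LearningParams:
    """Scalar learning constants.

    Parameters
    ----------
    beta : float
        Learning rate (> 0).
    lam : float
        SARSA trace-decay lambda in [0, 1]. Tags decay by a factor
        ``lam * gamma`` per time step.
    gamma : float
        Discount factor in [0, 1].
    epsilon : float
        Exploration probability of the Max-Boltzmann controller.
    theta : float
        Offset of the sigmoidal activation ``1 / (1 + exp(theta - inp))``.
        A positive offset keeps naive-network activities low; bias weights
        can compensate for any particular choice.
    """

    beta: float = 0.15
    lam: float = 0.20
    gamma: float = 0.90
    epsilon: float = 0.025
    theta: float = 2.5

    def __post_init__(self) -> None:
        if not self.beta > 0:
            raise ValueError(f"beta must be positive, got {self.beta}")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"lambda must be in [0, 1], got {self.lam}")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must be in [0, 1], got {self.gamma}")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError(f"epsilon must be in [0, 1], got {self.epsilon}")

    @property
    def alpha(self) -> float:
        """Tag persistence, always derived as ``1 - lam * gamma``."""
        return 1.0 - self.lam * self.gamma


@dataclass(frozen=True)
class ArchitectureSpec:
    """Layer sizes and the initial-weight range.

    ``n_inst`` is the number of instantaneous sensory inputs; each input is
    additionally represented by an on- and an off-transient channel, so the
    memory units see ``2 * n_inst`` transient inputs.
    """

    n_inst: int
    n_regular: int = 3
    n_memory: int = 4
    n_q: int = 3
    init_low: float = -0.25
    init_high: float = 0.25

    def __post_init__(self) -> None:
        for name in ("n_inst", "n_regular", "n_memory", "n_q"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not self.init_low < self.init_high:
            raise ValueError("init_low must be < init_high")

    @property
    def n_transient(self) -> int:
        return 2 * self.n_inst
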