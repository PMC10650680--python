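"""Progress-driven learning-rate decay and adversarial ramp.

Both schedules are pure functions of the training progress p = t / T in
[0, 1]:

* learning rate:  eta_p = eta_0 * (1 + a p)^(-b), the inverse-decay rule of
  standard fine-tuning protocols (defaults a = 10, b = 0.75);
* adversarial ramp: lambda(p) = 2 / (1 + exp(-eps p)) - 1 with eps = 10,
  which rises from 0 to ~1 and suppresses the adversarial gradient early in
  training while the classifier is still noisy.

Parameter groups follow the usual convention of training freshly added
layers 10x faster than the feature backbone (backbone eta_0 = 0.001, new
task layers eta_0 = 0.01 at full scale).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ScheduleState", "lr_at", "adv_ramp"]


@dataclass(frozen=True)
class ScheduleState:
    """Training progress plus the schedule constants.

    p is clamped to [0, 1]; eta0 is the initial learning rate of the group
    the schedule is evaluated for.
    """

    p: float
    eta0: float = 0.001
    a: float = 10.0
    b: float = 0.75
    epsilon: float = 10.0

    def __post_init__(self):
        if self.eta0 <= 0 or self.a <= 0 or self.b <= 0 or self.epsilon <= 0:
            raise ValueError("schedule constants must be positive")
        object.__setattr__(self, "p", float(min(1.0, max(0.0, self.p))))


def lr_at(state: ScheduleState) -> float:
    """Inverse-decay learning rate eta_0 (1 + a p)^(-b); eta_0 at p=0."""
    return state.eta0 * (1.0 + state.a * state.p) ** (-state.b)


def adv_ramp(state: ScheduleState) -> float:
    """lambda(p) = 2/(1+exp(-eps p)) - 1: zero at p=0, saturating below 1."""
    return 2.0 / (1.0 + np.exp(-state.epsilon * state.p)) - 1.0
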