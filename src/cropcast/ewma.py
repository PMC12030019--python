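"""Exponentially weighted moving average smoothing.

S_1 = Y_1 and S_t = alpha * Y_t + (1 - alpha) * S_{t-1}. A fixed smoothing
parameter is used (default alpha = 0.3); alpha = 1 is permitted as a
passthrough edge case.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EwmaState", "ewma_smooth"]

DEFAULT_ALPHA = 0.3


@dataclass
class EwmaState:
    """Streaming EWMA: feed observations one at a time via :meth:`update`."""

    alpha: float = DEFAULT_ALPHA
    S: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must be in (0, 1]")

    def update(self, y: float) -> float:
        self.S = y if self.S is None else self.alpha * y + (1 - self.alpha) * self.S
        return self.S


def ewma_smooth(Y: np.ndarray, alpha: float = DEFAULT_ALPHA) -> np.ndarray:
    """Smooth a vector with the EWMA recursion, initialised at S_1 = Y_1."""
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must be in (0, 1]")
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 1 or len(Y) == 0:
        raise ValueError("Y must be a non-empty 1-D vector")
    S = np.empty_like(Y)
    S[0] = Y[0]
    for t in range(1, len(Y)):
        S[t] = alpha * Y[t] + (1 - alpha) * S[t - 1]
    return S
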