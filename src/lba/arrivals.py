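"""Non-homogeneous Poisson arrival generation by thinning.

Rate functions are piecewise constant: a list of ``(start_time, rate)``
breakpoints with rates in events per minute, valid from the breakpoint up
to the next one (the last segment extends to the horizon).
"""

from __future__ import annotations

import numpy as np

__all__ = ["PiecewiseRate", "sample_nhpp"]


class PiecewiseRate:
    """Piecewise-constant intensity λ(t), t in minutes."""

    def __init__(self, breakpoints: list[tuple[float, float]]):
        if not breakpoints:
            raise ValueError("rate function needs at least one segment")
        self.times = np.array([b[0] for b in breakpoints], dtype=float)
        self.rates = np.array([b[1] for b in breakpoints], dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        if np.any(self.rates < 0):
            raise ValueError("arrival rate is negative on some segment")

    def __call__(self, t: float) -> float:
        idx = int(np.searchsorted(self.times, t, side="right")) - 1
        if idx < 0:
            return 0.0
        return float(self.rates[idx])

    @property
    def max_rate(self) -> float:
        return float(self.rates.max())

    def scaled(self, factor: float) -> "PiecewiseRate":
        return PiecewiseRate(
            [(float(t), float(r) * factor) for t, r in zip(self.times, self.rates)]
        )


def sample_nhpp(
    rate: PiecewiseRate, horizon: float, rng: np.random.Generator
) -> np.ndarray:
    """Arrival times on [0, horizon) from λ(t) via Lewis–Shedler thinning."""
    lam_max = rate.max_rate
    if lam_max == 0.0:
        return np.array([])
    out = []
    t = 0.0
    while True:
        t += rng.exponential(1.0 / lam_max)
        if t >= horizon:
            break
        if rng.uniform() * lam_max <= rate(t):
            out.append(t)
    return np.array(out)
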