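"""Exponential lateness loss and the five-bin lateness distribution.

Lateness is signed (completion minus deadline, in hours; negative =
early).  The per-study loss L = exp(2 * lateness) satisfies the three
institutional axioms: additivity across studies, non-negativity (an
early study cannot offset a tardy one), and super-linearity in the
tardy regime (L(a*l) >= a*L(l) for a >= 1, l >= 0) — two studies one
hour late are preferable to one study two hours late.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LATENESS_BINS",
    "study_loss",
    "total_loss",
    "bin_lateness",
    "LatenessReport",
]

#: bin edges in minutes past the deadline
LATENESS_BINS = (
    ("before the deadline", -np.inf, 0.0),
    ("slightly after the deadline", 0.0, 15.0),
    ("late", 15.0, 45.0),
    ("very late", 45.0, 60.0),
    ("extremely late", 60.0, np.inf),
)


def study_loss(lateness_hours: float) -> float:
    """L = exp(2 * lateness), lateness in hours (signed)."""
    return float(np.exp(2.0 * lateness_hours))


@dataclass
class LatenessReport:
    lateness_hours: dict[str, float] = field(default_factory=dict)
    pool_size_samples: list[float] = field(default_factory=list)

    @property
    def losses(self) -> dict[str, float]:
        return {sid: study_loss(l) for sid, l in self.lateness_hours.items()}

    @property
    def total_loss(self) -> float:
        return total_loss(self)

    @property
    def pool_size_mean(self) -> float:
        return float(np.mean(self.pool_size_samples)) if self.pool_size_samples else 0.0

    @property
    def pool_size_std(self) -> float:
        return float(np.std(self.pool_size_samples)) if self.pool_size_samples else 0.0


def total_loss(report: LatenessReport) -> float:
    """Additive total: sum of exp(2 * lateness_i)."""
    return float(sum(report.losses.values()))


def bin_lateness(report: LatenessReport) -> dict[str, float]:
    """Fractions of studies per lateness bin (sums to 1 when nonempty)."""
    n = len(report.lateness_hours)
    out = {name: 0.0 for name, _, _ in LATENESS_BINS}
    if n == 0:
        return out
    for lat_h in report.lateness_hours.values():
        lat_min = lat_h * 60.0
        for name, lo, hi in LATENESS_BINS:
            if lo < lat_min <= hi or (lo == -np.inf and lat_min <= hi):
                out[name] += 1.0
                break
    return {name: v / n for name, v in out.items()}
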