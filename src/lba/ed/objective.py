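"""The five-part ED objective and the metric container it prices.

score = a1 * risk + a2 * excess-wait penalty + a3 * LOS + a4 * crowding
      + a5 * preemption penalty  (+ terminal penalty for patients still
      in the ED at end of horizon)

Component totals are pre-priced by the weight tables (risk table, excess
slope, preemption penalty) but not by the alphas, so the objective is
exactly linear in the alphas.  In the offline model the crowding integral
``int kappa(t) dt`` equals the summed length of stay (every patient is
present from arrival to discharge), an identity that is tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from lba.ed.scenario import EDObjectiveWeights

__all__ = ["ShiftMetrics", "ed_objective"]


@dataclass
class ShiftMetrics:
    """Accumulated quantities of one shift (simulated or scheduled)."""

    risk_sum: float = 0.0              # priced by the risk table
    excess_sum: float = 0.0            # priced by the excess-wait slopes
    los_sum: float = 0.0               # minutes
    crowding_integral: float = 0.0     # patient-minutes
    preempt_penalty_sum: float = 0.0   # priced per interruption
    terminal_sum: float = 0.0          # penalty for patients not discharged
    wait_times: dict = field(default_factory=dict)      # (pid, e) -> minutes
    excess_minutes: dict = field(default_factory=dict)  # (pid, e) -> minutes
    los: dict = field(default_factory=dict)             # pid -> minutes
    preempt_counts: dict = field(default_factory=dict)  # (pid, e) -> int
    n_patients: int = 0
    n_completed: int = 0

    @property
    def preemption_total(self) -> int:
        return sum(self.preempt_counts.values())


def ed_objective(metrics: ShiftMetrics, weights: EDObjectiveWeights) -> float:
    """Weighted five-part score (lower is better)."""
    a1, a2, a3, a4, a5 = weights.alphas
    return (
        a1 * metrics.risk_sum
        + a2 * metrics.excess_sum
        + a3 * metrics.los_sum
        + a4 * metrics.crowding_integral
        + a5 * metrics.preempt_penalty_sum
        + metrics.terminal_sum
    )
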