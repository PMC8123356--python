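"""Offline schedules on the slot grid: derivation, audit and pricing.

A schedule is a binary grid ``y[i, j, e, t]``: patient ``i`` is treated by
physician ``j`` for her exam ``e`` (0-based index, exam 1 or 2) in slot
``t``.  Everything else — start/end slots, wait times, length of stay,
preemption counts, which physician performed which exam — is derived from
the grid combinatorially here, independently of how a solver represented
those quantities internally.  This makes the module usable both as the
pricing routine for schedules and as an independent constraint checker
for solver output.

Offline accounting is slot-granular: arrivals are rounded up to the slot
grid and all durations are in whole slots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np

from lba.ed.objective import ShiftMetrics, ed_objective
from lba.ed.scenario import EDObjectiveWeights, EDScenario

__all__ = [
    "SlotProblem",
    "ScheduleSolution",
    "derive_solution",
    "check_constraints",
    "schedule_metrics",
]


@dataclass(frozen=True)
class SlotProblem:
    """Slot-rounded view of a scenario (shared by solver, oracle, audit)."""

    arr1: tuple[int, ...]          # arrival slot of exam 1, per patient
    tt_slots: tuple[tuple[int, ...], ...]   # per patient, per exam index
    lt_slots: tuple[int, ...]
    n_exams: tuple[int, ...]       # 1 or 2
    work_unit: int                 # scale making slot-work integral for all CE

    @classmethod
    def from_scenario(cls, scenario: EDScenario) -> "SlotProblem":
        slot = scenario.slot_minutes
        arr1, tts, lts, nex = [], [], [], []
        for p in scenario.patients:
            arr1.append(int(ceil(p.arrival1 / slot - 1e-9)))
            e1 = max(1, int(ceil(p.tt1 / slot - 1e-9)))
            if p.needs_second_exam:
                e2 = max(1, int(ceil(p.tt2 / slot - 1e-9)))
                tts.append((e1, e2))
                lts.append(int(ceil(p.lt / slot - 1e-9)))
                nex.append(2)
            else:
                tts.append((e1, 0))
                lts.append(0)
                nex.append(1)
        # smallest U such that U / CE_j is integral for every physician
        unit = 1
        while unit <= 64:
            if all(
                abs(unit / c.ce - round(unit / c.ce)) < 1e-9
                for c in scenario.physicians
            ):
                break
            unit += 1
        else:
            raise ValueError(
                "physician efficiency factors do not admit a common slot-work "
                "unit; use CE values on a small rational grid"
            )
        return cls(tuple(arr1), tuple(tts), tuple(lts), tuple(nex), unit)


@dataclass
class ScheduleSolution:
    """A priced offline schedule with all derived quantities."""

    y: np.ndarray                      # bool (n_patients, n_phys, 2, T)
    st: dict = field(default_factory=dict)       # (i, e) -> first slot
    et: dict = field(default_factory=dict)       # (i, e) -> end slot (exclusive)
    wt_min: dict = field(default_factory=dict)   # (i, e) -> minutes
    los_min: dict = field(default_factory=dict)  # i -> minutes
    pc: dict = field(default_factory=dict)       # (i, e) -> preemption count
    ac: set = field(default_factory=set)         # {(i, j, e)}
    objective: float = 0.0
    optimal: bool = True
    solver_status: str = "derived"

    @property
    def total_preemptions(self) -> int:
        return sum(self.pc.values())


def _segments(row: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a boolean time row, as (start, end_excl)."""
    idx = np.flatnonzero(row)
    if len(idx) == 0:
        return []
    cuts = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[cuts + 1]])
    ends = np.concatenate([idx[cuts] + 1, [idx[-1] + 1]])
    return list(zip(starts.tolist(), ends.tolist()))


def derive_solution(
    y: np.ndarray, scenario: EDScenario, weights: EDObjectiveWeights
) -> ScheduleSolution:
    """Derive start/end/WT/LOS/PC/AC and the objective from a raw grid."""
    sol = ScheduleSolution(y=np.asarray(y, bool))
    prob = SlotProblem.from_scenario(scenario)
    slot = scenario.slot_minutes
    for i, p in enumerate(scenario.patients):
        arrival = {1: prob.arr1[i]}
        for e in p.exams:
            occ = sol.y[i, :, e - 1, :].any(axis=0)
            slots = np.flatnonzero(occ)
            if len(slots) == 0:
                continue
            sol.st[(i, e)] = int(slots[0])
            sol.et[(i, e)] = int(slots[-1]) + 1
            if e == 1:
                arrival[2] = sol.et[(i, 1)] + prob.lt_slots[i]
            sol.wt_min[(i, e)] = (sol.st[(i, e)] - arrival[e]) * slot
            starts = 0
            for j in range(sol.y.shape[1]):
                segs = _segments(sol.y[i, j, e - 1, :])
                if segs:
                    sol.ac.add((i, j, e))
                starts += len(segs)
            sol.pc[(i, e)] = starts - 1
        last = p.exams[-1]
        if (i, last) in sol.et:
            sol.los_min[i] = (sol.et[(i, last)] - prob.arr1[i]) * slot
    metrics = schedule_metrics(sol, scenario, weights)
    sol.objective = ed_objective(metrics, weights)
    return sol


def schedule_metrics(
    sol: ScheduleSolution, scenario: EDScenario, weights: EDObjectiveWeights
) -> ShiftMetrics:
    """Price a derived schedule into shift metrics (offline accounting)."""
    m = ShiftMetrics(n_patients=len(scenario.patients))
    for i, p in enumerate(scenario.patients):
        for e in p.exams:
            if (i, e) not in sol.st:
                continue
            wt = sol.wt_min[(i, e)]
            m.wait_times[(p.id, e)] = wt
            exc_min = max(0.0, wt - p.tbar(e))
            m.excess_minutes[(p.id, e)] = exc_min
            m.excess_sum += weights.exc(p, e, exc_min)
            m.preempt_counts[(p.id, e)] = sol.pc[(i, e)]
            m.preempt_penalty_sum += sol.pc[(i, e)] * weights.pre(p, e)
        for (ii, j, e) in sol.ac:
            if ii == i:
                m.risk_sum += weights.risk(p, scenario.physicians[j], e)
        if i in sol.los_min:
            m.los_sum += sol.los_min[i]
            m.los[p.id] = sol.los_min[i]
            m.n_completed += 1
        else:
            m.terminal_sum += weights.terminal_penalty
    # every patient is in the ED from arrival to discharge
    m.crowding_integral = m.los_sum
    return m


def check_constraints(y: np.ndarray, scenario: EDScenario) -> list[str]:
    """Independent feasibility audit of a schedule grid.

    Verifies physician and patient slot capacities, work conservation
    scaled by CE, arrival/lab ordering between exams, and that no patient
    is treated before arrival.  Returns a list of human-readable
    violations (empty = feasible).
    """
    y = np.asarray(y, bool)
    prob = SlotProblem.from_scenario(scenario)
    n, mphys, _, T = y.shape
    out = []
    # one patient per physician per slot
    per_phys = y.sum(axis=(0, 2))
    for j, t in zip(*np.nonzero(per_phys > 1)):
        out.append(f"physician {j} treats {per_phys[j, t]} patients in slot {t}")
    # one physician per patient per slot (both exams)
    per_pat = y.sum(axis=(1, 2))
    for i, t in zip(*np.nonzero(per_pat > 1)):
        out.append(f"patient {i} is treated by {per_pat[i, t]} physicians in slot {t}")
    for i, p in enumerate(scenario.patients):
        if y[i, :, :, : prob.arr1[i]].any():
            out.append(f"patient {i} treated before arrival slot {prob.arr1[i]}")
        for e in p.exams:
            work = sum(
                y[i, j, e - 1, :].sum() / scenario.physicians[j].ce
                for j in range(mphys)
            )
            if abs(work - prob.tt_slots[i][e - 1]) > 1e-9:
                out.append(
                    f"patient {i} exam {e}: scheduled work {work} != "
                    f"required {prob.tt_slots[i][e - 1]} slots"
                )
        if p.needs_second_exam:
            occ1 = np.flatnonzero(y[i, :, 0, :].any(axis=0))
            occ2 = np.flatnonzero(y[i, :, 1, :].any(axis=0))
            if len(occ1) and len(occ2):
                et1 = occ1[-1] + 1
                if occ2[0] < et1 + prob.lt_slots[i]:
                    out.append(
                        f"patient {i} exam 2 starts at {occ2[0]} before lab "
                        f"completes at {et1 + prob.lt_slots[i]}"
                    )
    return out
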