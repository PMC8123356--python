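"""Event-driven simulation of one ED shift under an online policy.

Continuous-time (minutes) discrete-event simulation of the standard ED
work-flow: arrival -> triage -> first examination -> optional lab ->
second examination -> discharge.  The policy is invoked at every arrival,
lab completion and treatment completion and may seat waiting patients
with idle physicians, keep them waiting, or preempt a busy physician
(the interrupted patient returns to the queue with her remaining nominal
treatment time preserved; the interruption is penalized).

Accounting mirrors the offline objective: wait time is measured to the
first treatment start of each exam, risk is charged once per distinct
(patient, physician, exam), the crowding integral is the summed in-ED
time, and patients still present at end of shift incur their partial LOS
plus a terminal penalty.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

from lba.ed.objective import ShiftMetrics, ed_objective
from lba.ed.scenario import (
    EDObjectiveWeights,
    EDScenario,
    Patient,
    WAIT_ROOM,
)

__all__ = ["EDState", "simulate_shift"]


@dataclass
class _PatRT:
    patient: Patient
    index: int
    stage: str = "pre"          # pre | wait | treat | lab | done
    exam: int = 1
    ready_time: float = 0.0     # when the current exam became startable
    remaining_tt: float = 0.0   # nominal minutes left on the current exam
    started: bool = False       # current exam ever started
    used: frozenset = frozenset()


@dataclass
class _PhysRT:
    busy: tuple | None = None   # (patient_index, exam, end_time)
    idle_since: float = 0.0
    token: int = 0              # invalidates stale completion events


class EDState:
    """Live simulation state exposed to online policies."""

    def __init__(self, scenario: EDScenario, weights: EDObjectiveWeights):
        self.scenario = scenario
        self.weights = weights
        self.time = 0.0
        self.pats = [
            _PatRT(patient=p, index=i, ready_time=p.arrival1)
            for i, p in enumerate(scenario.patients)
        ]
        self.phys = [_PhysRT() for _ in scenario.physicians]
        self.metrics = ShiftMetrics(n_patients=len(scenario.patients))

    def waiting(self) -> list[_PatRT]:
        return [
            rt
            for rt in self.pats
            if rt.stage == "wait" and rt.ready_time <= self.time + 1e-9
        ]

    def idle_minutes(self, j: int) -> float:
        return 0.0 if self.phys[j].busy else self.time - self.phys[j].idle_since

    def busy_severity(self, j: int) -> int:
        b = self.phys[j].busy
        return self.pats[b[0]].patient.severity if b else 0


def simulate_shift(
    policy,
    scenario: EDScenario,
    weights: EDObjectiveWeights,
    rng: np.random.Generator,
) -> ShiftMetrics:
    """Run one shift; returns the accumulated metrics.

    ``policy`` is called repeatedly at each event with
    ``policy.decide(state, rng)`` and must return ``(patient_index,
    physician_id_or_WAIT_ROOM)`` or ``None`` to stop deciding at this
    instant; patients already decided at the instant are excluded by the
    caller via ``state.decided``.
    """
    state = EDState(scenario, weights)
    m = state.metrics
    horizon = scenario.horizon_minutes
    heap: list = []
    seq = 0
    for i, p in enumerate(scenario.patients):
        heapq.heappush(heap, (p.arrival1, seq, "arrival", i))
        seq += 1

    def start_treatment(i: int, j: int):
        nonlocal seq
        rt = state.pats[i]
        ph = state.phys[j]
        now = state.time
        if ph.busy is not None:                       # preemption
            i2, e2, end2 = ph.busy
            rt2 = state.pats[i2]
            rt2.remaining_tt = max(0.0, (end2 - now) / scenario.physicians[j].ce)
            rt2.stage = "wait"
            key = (rt2.patient.id, e2)
            m.preempt_counts[key] = m.preempt_counts.get(key, 0) + 1
            m.preempt_penalty_sum += weights.pre(rt2.patient, e2)
            decided.add(i2)
        if not rt.started:
            wt = now - rt.ready_time
            m.wait_times[(rt.patient.id, rt.exam)] = wt
            exc_min = max(0.0, wt - rt.patient.tbar(rt.exam))
            m.excess_minutes[(rt.patient.id, rt.exam)] = exc_min
            m.excess_sum += weights.exc(rt.patient, rt.exam, exc_min)
            m.preempt_counts.setdefault((rt.patient.id, rt.exam), 0)
            rt.started = True
        if j not in rt.used:
            m.risk_sum += weights.risk(
                rt.patient, scenario.physicians[j], rt.exam
            )
            rt.used = rt.used | {j}
        rt.stage = "treat"
        end = now + rt.remaining_tt * scenario.physicians[j].ce
        ph.token += 1
        ph.busy = (i, rt.exam, end)
        heapq.heappush(heap, (end, seq, "treat_end", (j, ph.token)))
        seq += 1

    def finish_patient(rt: _PatRT, now: float):
        los = now - rt.patient.arrival1
        m.los[rt.patient.id] = los
        m.los_sum += los
        m.crowding_integral += los
        m.n_completed += 1
        rt.stage = "done"

    decided: set[int] = set()

    while heap:
        t, _, kind, payload = heapq.heappop(heap)
        if t > horizon + 1e-9:
            break
        state.time = t
        decided = set()
        if kind == "arrival":
            rt = state.pats[payload]
            rt.stage = "wait"
            rt.exam = 1
            rt.ready_time = rt.patient.arrival1
            rt.remaining_tt = rt.patient.tt1
        elif kind == "treat_end":
            j, token = payload
            ph = state.phys[j]
            if ph.token != token or ph.busy is None:
                continue                               # stale (preempted)
            i, e, _ = ph.busy
            ph.busy = None
            ph.idle_since = t
            rt = state.pats[i]
            rt.remaining_tt = 0.0
            if e == 1 and rt.patient.needs_second_exam:
                rt.stage = "lab"
                heapq.heappush(heap, (t + rt.patient.lt, seq, "lab_end", i))
                seq += 1
            else:
                finish_patient(rt, t)
        elif kind == "lab_end":
            rt = state.pats[payload]
            rt.stage = "wait"
            rt.exam = 2
            rt.ready_time = t
            rt.remaining_tt = rt.patient.tt2
        # policy round
        guard = 0
        while guard < 10 * len(state.pats) + 10:
            guard += 1
            if not [rt for rt in state.waiting() if rt.index not in decided]:
                break
            choice = policy.decide(state, rng, exclude=decided)
            if choice is None:
                break
            i, target = choice
            decided.add(i)
            if target == WAIT_ROOM:
                continue
            j = next(
                jj
                for jj, c in enumerate(scenario.physicians)
                if c.id == target
            )
            start_treatment(i, j)

    # end of horizon: patients still in the ED
    for rt in state.pats:
        if rt.stage in ("wait", "treat", "lab") or (
            rt.stage == "pre" and rt.patient.arrival1 < horizon
        ):
            in_ed = max(0.0, horizon - rt.patient.arrival1)
            m.los_sum += in_ed
            m.crowding_integral += in_ed
            m.terminal_sum += weights.terminal_penalty
    return m
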