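"""Distilling offline-optimal schedules into ranking decision events.

Decision instants are the times a new patient arrives (either exam, a
lab completion makes a patient available for exam 2) or a treatment
completes.  At each instant the option the optimal schedule takes —
seat patient p with physician c, or leave p in the wait room — becomes
the chosen option, paired against the options not taken: the same
patient with every other physician and the WaitRoom, and (for a seating)
every other assignable patient with the chosen physician.
"""

from __future__ import annotations

import numpy as np

from lba.ranking import DecisionEvent
from lba.ed.features import EDPairContext, featurize_ed_pair
from lba.ed.schedule import ScheduleSolution, SlotProblem
from lba.ed.scenario import EDScenario

__all__ = ["extract_decision_events"]


def _pending_exam(i, t, arrivals, sol):
    """The exam patient i is waiting for at slot t, or None."""
    for e in (1, 2):
        if (i, e) not in arrivals:
            continue
        if arrivals[(i, e)] <= t and sol.st.get((i, e), -1) >= t:
            return e
    return None


def _phys_context(j, t, sol, scenario):
    """Busy-severity and idle-time of physician j just before deciding at t."""
    busy_sev = 0
    occupied = np.flatnonzero(sol.y[:, j, :, :].any(axis=(0, 1)))
    # treating someone at t whose treatment did not just start as part of
    # this same decision round
    for i2 in range(sol.y.shape[0]):
        for e2 in (1, 2):
            if sol.y[i2, j, e2 - 1, t] and sol.st.get((i2, e2)) != t:
                busy_sev = scenario.patients[i2].severity
    before = occupied[occupied < t]
    idle_since = (before[-1] + 1) if len(before) else 0
    idle_min = (t - idle_since) * scenario.slot_minutes if busy_sev == 0 else 0.0
    return busy_sev, idle_min


def extract_decision_events(
    sol: ScheduleSolution, scenario: EDScenario
) -> list[DecisionEvent]:
    prob = SlotProblem.from_scenario(scenario)
    slot = scenario.slot_minutes
    injuries = scenario.injury_types or _injury_types(scenario)

    arrivals: dict[tuple[int, int], int] = {}
    for i, p in enumerate(scenario.patients):
        arrivals[(i, 1)] = prob.arr1[i]
        if p.needs_second_exam and (i, 1) in sol.et:
            arrivals[(i, 2)] = sol.et[(i, 1)] + prob.lt_slots[i]

    # (slot, kind, payload); kind 0 = arrival (payload patient, exam),
    # kind 1 = completion (payload physician)
    raw: list[tuple[int, int, tuple]] = []
    for (i, e), t in arrivals.items():
        raw.append((t, 0, (i, e)))
    for (i, e), t_end in sol.et.items():
        js = np.flatnonzero(sol.y[i, :, e - 1, t_end - 1])
        raw.append((t_end, 1, (int(js[0]) if len(js) else 0,)))
    raw.sort(key=lambda r: (r[0], r[1], r[2]))

    events: list[DecisionEvent] = []

    def pair_vec(i, e, j, t):
        p = scenario.patients[i]
        wait = (t - arrivals[(i, e)]) * slot
        ctx = EDPairContext(
            exam=e,
            wait_minutes=wait,
            remaining_tt=p.tt(e),
        )
        if j is not None:
            busy_sev, idle_min = _phys_context(j, t, sol, scenario)
            ctx.busy_severity = busy_sev
            ctx.idle_minutes = idle_min
        phys = scenario.physicians[j] if j is not None else None
        return featurize_ed_pair(p, phys, ctx, injuries)

    for t, kind, payload in raw:
        assignable = [
            (i, _pending_exam(i, t, arrivals, sol))
            for i in range(len(scenario.patients))
        ]
        assignable = [(i, e) for i, e in assignable if e is not None]
        if not assignable:
            continue
        nphys = len(scenario.physicians)
        if kind == 0:
            i0, e0 = payload
            if _pending_exam(i0, t, arrivals, sol) != e0:
                continue
        else:
            # decision subject: the patient the schedule seats now, if any
            seated = [
                (i, e) for (i, e) in assignable if sol.st.get((i, e)) == t
            ]
            if seated:
                i0, e0 = seated[0]
            else:
                # schedule keeps everyone waiting; subject = longest waiting
                i0, e0 = max(assignable, key=lambda ie: t - arrivals[ie])
        if sol.st.get((i0, e0)) == t:
            j0 = int(np.flatnonzero(sol.y[i0, :, e0 - 1, t])[0])
            chosen = pair_vec(i0, e0, j0, t)
            alts = [pair_vec(i0, e0, j, t) for j in range(nphys) if j != j0]
            alts.append(pair_vec(i0, e0, None, t))
            alts.extend(
                pair_vec(i2, e2, j0, t)
                for (i2, e2) in assignable
                if i2 != i0
            )
        else:
            chosen = pair_vec(i0, e0, None, t)
            alts = [pair_vec(i0, e0, j, t) for j in range(nphys)]
        events.append(
            DecisionEvent(
                time=t * slot,
                chosen=chosen,
                alternatives=tuple(alts),
                event_id=f"s{scenario.seed}-t{t}-k{kind}-p{i0}e{e0}",
            )
        )
    return events


def _injury_types(scenario: EDScenario) -> tuple[str, ...]:
    seen = []
    for p in scenario.patients:
        if p.injury not in seen:
            seen.append(p.injury)
    for c in scenario.physicians:
        if c.specialty and c.specialty not in seen:
            seen.append(c.specialty)
    return tuple(sorted(seen))
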