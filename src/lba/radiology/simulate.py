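"""Event-driven reading-room simulation under an exposure policy.

Arrivals update the exposure pools (policy hook); whenever a reader is
idle with a nonempty pool they draw one study by quantal response, read
it for the skill-dependent reading time, and on completion the policy
may refill their pool.  A study being read leaves every pool.  The run
continues past the arrival window until every study is read; per-study
signed lateness, the exponential loss and pool-size statistics are
recorded.
"""

from __future__ import annotations

import heapq

import numpy as np

from lba.radiology.loss import LatenessReport
from lba.radiology.scenario import RadScenario, choice_probabilities, reading_time
from lba.radiology.state import ExposureState

__all__ = ["simulate_reading_room"]


def simulate_reading_room(
    policy,
    scenario: RadScenario,
    rng: np.random.Generator,
    k: int | None = None,
) -> LatenessReport:
    k = scenario.k if k is None else k
    state = ExposureState(scenario=scenario, k=k)
    report = LatenessReport()

    heap: list = []
    seq = 0
    for s in scenario.studies:
        heapq.heappush(heap, (s.arrival, seq, "arrival", s.id))
        seq += 1

    def assign_idle_readers():
        nonlocal seq
        for r in scenario.readers:
            if r.id in state.reading:
                continue
            pool = state.pools[r.id]
            if not pool:
                continue
            studies = [state.study(sid) for sid in pool]
            probs = choice_probabilities(r, studies)
            pick = studies[int(rng.choice(len(studies), p=probs))]
            state.remove_everywhere(pick.id)
            state.pending.discard(pick.id)
            end = state.time + reading_time(r, pick, scenario.read_time)
            state.reading[r.id] = (pick.id, end)
            heapq.heappush(heap, (end, seq, "read_end", r.id))
            seq += 1

    while heap or state.pending:
        if heap:
            t, _, kind, payload = heapq.heappop(heap)
            state.time = t
            arrived_sid = None
            if kind == "arrival":
                state.pending.add(payload)
                arrived_sid = payload
            else:
                rid = payload
                sid, end = state.reading.pop(rid)
                state.completed[sid] = t
                report.lateness_hours[sid] = state.lateness_hours(sid, at=t)
            policy.refresh(state)
            if kind == "arrival":
                policy.on_arrival(state, arrived_sid)
            else:
                policy.on_completion(state, rid)
        else:
            # stall guard: pending studies, no events in flight — refill
            # every idle reader, then force-expose if still orphaned
            policy.refresh(state)
            for r in scenario.readers:
                if r.id not in state.reading:
                    policy.on_completion(state, r.id)
            if all(not p for p in state.pools.values()) and state.pending:
                sid = min(state.pending, key=lambda s: state.study(s).due_time)
                rid = next(
                    r.id for r in scenario.readers if r.id not in state.reading
                )
                state.pools[rid].append(sid)
        assign_idle_readers()
        report.pool_size_samples.extend(
            len(state.pools[r.id]) for r in scenario.readers
        )

    return report
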