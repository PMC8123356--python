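"""Online assignment policies for the ED shift simulator.

``FCFSwUPolicy`` is the conventional heuristic baseline: severities 3–5
form one non-urgent class admitted first-come-first-served to an idle
physician whose specialty matches the injury or who has none (never to a
mismatched specialist); severities 1–2 form one urgent class for which
the most senior eligible physician — preferring a matching specialist,
and excluding anyone already treating another urgent patient — is called
immediately, interrupting a non-urgent treatment if necessary.

``LBAPolicy`` builds every candidate option — each waiting patient paired
with each physician (busy physicians imply preemption) and with the
WaitRoom — and selects by an all-pairs majority vote of the trained
comparator.
"""

from __future__ import annotations

import numpy as np

from lba.ranking import ComparatorModel, FeatureVector, majority_vote_select
from lba.ed.features import EDPairContext, featurize_ed_pair
from lba.ed.scenario import WAIT_ROOM
from lba.ed.simulate import EDState

__all__ = ["FCFSwUPolicy", "LBAPolicy"]


class FCFSwUPolicy:
    """First-Come-First-Served with Urgencies."""

    name = "fcfswu"

    def decide(self, state: EDState, rng, exclude: set[int] = frozenset()):
        waiting = [rt for rt in state.waiting() if rt.index not in exclude]
        if not waiting:
            return None
        scen = state.scenario

        urgent = sorted(
            (rt for rt in waiting if rt.patient.urgent),
            key=lambda rt: (rt.patient.severity, rt.ready_time),
        )
        for rt in urgent:
            eligible = []
            for j, c in enumerate(scen.physicians):
                b = state.phys[j].busy
                if b is not None and state.pats[b[0]].patient.urgent:
                    continue                      # never interrupt an urgent case
                if b is not None and b[0] == rt.index:
                    continue
                eligible.append((j, c))
            if not eligible:
                continue
            eligible.sort(
                key=lambda jc: (
                    jc[1].specialty == rt.patient.injury,
                    jc[1].seniority_rank,
                    state.phys[jc[0]].busy is None,
                ),
                reverse=True,
            )
            return rt.index, eligible[0][1].id

        nonurgent = sorted(
            (rt for rt in waiting if not rt.patient.urgent),
            key=lambda rt: rt.ready_time,
        )
        for rt in nonurgent:
            idle_ok = [
                (j, c)
                for j, c in enumerate(scen.physicians)
                if state.phys[j].busy is None
                and (c.specialty is None or c.specialty == rt.patient.injury)
            ]
            if not idle_ok:
                continue
            idle_ok.sort(
                key=lambda jc: (
                    jc[1].specialty == rt.patient.injury,
                    jc[1].seniority_rank,
                ),
                reverse=True,
            )
            return rt.index, idle_ok[0][1].id
        return None


class LBAPolicy:
    """Majority-vote selection with a trained pairwise comparator."""

    name = "lba"

    def __init__(self, model: ComparatorModel, injury_types: tuple[str, ...]):
        self.model = model
        self.injury_types = tuple(injury_types)

    def candidate_options(
        self, state: EDState, exclude: set[int] = frozenset()
    ) -> list[tuple[int, str, FeatureVector]]:
        opts = []
        for rt in state.waiting():
            if rt.index in exclude:
                continue
            base = EDPairContext(
                exam=rt.exam,
                wait_minutes=state.time - rt.ready_time,
                remaining_tt=rt.remaining_tt,
            )
            for j, c in enumerate(state.scenario.physicians):
                b = state.phys[j].busy
                if b is not None and b[0] == rt.index:
                    continue
                ctx = EDPairContext(
                    exam=base.exam,
                    wait_minutes=base.wait_minutes,
                    remaining_tt=base.remaining_tt,
                    busy_severity=state.busy_severity(j),
                    idle_minutes=state.idle_minutes(j),
                )
                opts.append(
                    (rt.index, c.id,
                     featurize_ed_pair(rt.patient, c, ctx, self.injury_types))
                )
            opts.append(
                (rt.index, WAIT_ROOM,
                 featurize_ed_pair(rt.patient, None, base, self.injury_types))
            )
        return opts

    def decide(self, state: EDState, rng, exclude: set[int] = frozenset()):
        opts = self.candidate_options(state, exclude)
        if not opts:
            return None
        win = majority_vote_select(self.model, [o[2] for o in opts], rng)
        i, target, _ = opts[win]
        return i, target
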