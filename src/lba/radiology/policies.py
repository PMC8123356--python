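"""Exposure policies: Naive, interval heuristic H, and the learned policy.

* ``NaivePolicy`` exposes every pending study to every reader (no cap).
* ``HPolicy`` splits each study's arrival-to-deadline interval into three
  equal parts: subspecialty readers only, then a wider group (readers
  sharing the study's modality), then — and past the deadline — all
  readers, until the study is read.
* ``DNNExposurePolicy`` maintains per-reader ordered pools of size at
  most k using a trained comparator: a new arrival either fills spare
  pool capacity (ordered insertion) or challenges the lowest-ranking
  pending study; on a completion the highest-ranking unexposed study is
  added to the free reader's pool.  A zero-exposure guard ensures no
  study is orphaned.
"""

from __future__ import annotations

import numpy as np

from lba.ranking import ComparatorModel, compare
from lba.radiology.features import featurize_rad_pair
from lba.radiology.state import ExposureState

__all__ = ["NaivePolicy", "HPolicy", "DNNExposurePolicy", "h_exposure_group"]


class NaivePolicy:
    name = "naive"

    def refresh(self, state: ExposureState) -> None:
        order = sorted(state.pending, key=lambda sid: state.study(sid).arrival)
        for rid in state.pools:
            state.pools[rid] = list(order)

    def on_arrival(self, state, sid):
        pass

    def on_completion(self, state, rid):
        pass


def h_exposure_group(state: ExposureState, sid: str, now: float) -> list[str]:
    """Reader ids the interval heuristic exposes ``sid`` to at ``now``."""
    s = state.study(sid)
    age = now - s.arrival
    third = s.deadline / 3.0
    if age < third:
        return [r.id for r in state.scenario.readers if s.mb in r.subspecialty]
    if age < 2 * third:
        return [
            r.id
            for r in state.scenario.readers
            if any(mb[0] == s.modality for mb in r.subspecialty)
        ]
    return [r.id for r in state.scenario.readers]


class HPolicy:
    name = "h"

    def refresh(self, state: ExposureState) -> None:
        order = sorted(state.pending, key=lambda sid: state.study(sid).arrival)
        pools: dict[str, list[str]] = {rid: [] for rid in state.pools}
        for sid in order:
            for rid in h_exposure_group(state, sid, state.time):
                pools[rid].append(sid)
        state.pools = pools

    def on_arrival(self, state, sid):
        pass

    def on_completion(self, state, rid):
        pass


class DNNExposurePolicy:
    name = "dnn"

    def __init__(self, model: ComparatorModel, k: int):
        if k < 1:
            raise ValueError("pool cap k must be >= 1")
        self.model = model
        self.k = k

    # -- helpers --------------------------------------------------------
    def _pref(self, state, sid_a, sid_b, rid) -> float:
        return compare(
            self.model,
            featurize_rad_pair(sid_a, rid, state),
            featurize_rad_pair(sid_b, rid, state),
        )

    def _insert_ordered(self, state, rid, sid) -> None:
        pool = state.pools[rid]
        pos = len(pool)
        for i, inc in enumerate(pool):
            if self._pref(state, sid, inc, rid) >= 0.5:
                pos = i
                break
        pool.insert(pos, sid)

    def _top_of(self, state, candidates, rid) -> str:
        top = candidates[0]
        for c in candidates[1:]:
            if self._pref(state, c, top, rid) >= 0.5:
                top = c
        return top

    def _offer(self, state, rid, sid) -> bool:
        """Insert if there is room, else challenge the lowest-ranking study."""
        pool = state.pools[rid]
        if sid in pool:
            return True
        if len(pool) < self.k:
            self._insert_ordered(state, rid, sid)
            return True
        worst = pool[-1]
        if self._pref(state, sid, worst, rid) >= 0.5:
            pool.pop()
            self._insert_ordered(state, rid, sid)
            return True
        return False

    # -- policy hooks ---------------------------------------------------
    def refresh(self, state: ExposureState) -> None:
        pass

    def on_arrival(self, state: ExposureState, sid: str) -> None:
        placed = False
        for rid in state.pools:
            placed |= self._offer(state, rid, sid)
        if not placed and state.pools:
            # zero-exposure guard: evict the weakest incumbent of the
            # best-scoring reader
            scores = {
                rid: self._pref(state, sid, state.pools[rid][-1], rid)
                for rid in state.pools
                if state.pools[rid]
            }
            rid = max(scores, key=scores.get)
            state.pools[rid].pop()
            self._insert_ordered(state, rid, sid)

    def on_completion(self, state: ExposureState, rid: str) -> None:
        unexposed = state.unexposed_pending()
        if not unexposed:
            return
        top = self._top_of(state, unexposed, rid)
        self._offer(state, rid, top)
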