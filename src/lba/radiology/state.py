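"""Shared exposure state for the reading-room simulator and MCTS."""

from __future__ import annotations

from dataclasses import dataclass, field

from lba.radiology.scenario import RadScenario, Reader, Study

__all__ = ["ExposureState"]


@dataclass
class ExposureState:
    """Clock, per-reader ordered pools, and study bookkeeping."""

    scenario: RadScenario
    k: int
    time: float = 0.0
    pools: dict[str, list[str]] = field(default_factory=dict)       # ordered
    pending: set[str] = field(default_factory=set)                  # arrived, unread
    reading: dict[str, tuple[str, float]] = field(default_factory=dict)
    completed: dict[str, float] = field(default_factory=dict)       # sid -> time

    def __post_init__(self):
        if not self.pools:
            self.pools = {r.id: [] for r in self.scenario.readers}
        self._studies = {s.id: s for s in self.scenario.studies}
        self._readers = {r.id: r for r in self.scenario.readers}

    def study(self, sid: str) -> Study:
        return self._studies[sid]

    def reader(self, rid: str) -> Reader:
        return self._readers[rid]

    def exposure_count(self, sid: str) -> int:
        return sum(sid in pool for pool in self.pools.values())

    def unexposed_pending(self) -> list[str]:
        exposed = set()
        for pool in self.pools.values():
            exposed.update(pool)
        return sorted(self.pending - exposed)

    def lateness_hours(self, sid: str, at: float | None = None) -> float:
        s = self.study(sid)
        t = self.time if at is None else at
        return (t - s.due_time) / 60.0

    def remove_everywhere(self, sid: str) -> None:
        for pool in self.pools.values():
            if sid in pool:
                pool.remove(sid)
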