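"""Monte-Carlo tree search over exposure decisions.

The stochastic reader choices make the offline exposure problem
unsuitable for a deterministic solver, so the (near-)optimal policy is
approximated by UCT: decision nodes are arrival/completion events where
one pending study may be added to one reader's pool (or no exposure
made); chance is the readers' quantal-response draws, re-sampled on
every simulation (open-loop averaging); rollouts expose
earliest-deadline-first; the return is the negated total exponential
lateness loss.  Each committed decision is paired with its rejected
alternatives to form comparator training events.

``exhaustive_best_order`` is an independent oracle for single-reader
instances: it enumerates all reading orders and minimizes the loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np

from lba.ranking import DecisionEvent
from lba.radiology.features import featurize_rad_pair
from lba.radiology.loss import study_loss
from lba.radiology.scenario import (
    RadScenario,
    choice_probabilities,
    reading_time,
)
from lba.radiology.state import ExposureState

__all__ = ["MCTSConfig", "mcts_plan", "mcts_search", "exhaustive_best_order"]


@dataclass
class MCTSConfig:
    exploration: float = np.sqrt(2.0)
    max_exposures_per_event: int = 1


# -- lightweight simulation state -------------------------------------------

@dataclass
class _SimState:
    time: float
    pending: frozenset          # arrived, unread, unassigned
    pools: tuple                # tuple of frozensets, per reader index
    reading: tuple              # per reader: (sid, end) or None
    next_arrival: int           # index into the arrival-sorted study list
    loss: float


def _initial(scenario: RadScenario) -> _SimState:
    return _SimState(
        time=0.0,
        pending=frozenset(),
        pools=tuple(frozenset() for _ in scenario.readers),
        reading=tuple(None for _ in scenario.readers),
        next_arrival=0,
        loss=0.0,
    )


def _smap(scenario: RadScenario) -> dict:
    m = getattr(scenario, "_sid_map", None)
    if m is None:
        m = {s.id: s for s in scenario.studies}
        scenario._sid_map = m
    return m


def _arrival_order(scenario: RadScenario) -> list:
    """Studies sorted by arrival time (the event order of the search)."""
    m = getattr(scenario, "_arrival_order", None)
    if m is None:
        m = sorted(scenario.studies, key=lambda s: (s.arrival, s.id))
        scenario._arrival_order = m
    return m


def _actions(state: _SimState, scenario: RadScenario, k: int):
    """(study, reader-index) exposure actions, plus None (no exposure).

    The no-exposure action is only offered when time can still advance
    without it (a reading in flight, a future arrival, or an idle reader
    about to draw from a nonempty pool); otherwise committing to it
    would stall the trajectory.
    """
    progress = (
        any(r is not None for r in state.reading)
        or state.next_arrival < len(scenario.studies)
        or any(
            state.reading[j] is None and state.pools[j]
            for j in range(len(scenario.readers))
        )
    )
    acts = [None] if progress else []
    for sid in sorted(state.pending):
        for j in range(len(scenario.readers)):
            if state.reading[j] is None and sid not in state.pools[j] and len(state.pools[j]) < k:
                acts.append((sid, j))
    return acts


def _advance(
    state: _SimState, scenario: RadScenario, rng: np.random.Generator
) -> _SimState:
    """Start idle readers on quantal draws, then move to the next event."""
    studies = _smap(scenario)
    order = _arrival_order(scenario)
    pools = [set(p) for p in state.pools]
    reading = list(state.reading)
    pending = set(state.pending)
    loss = state.loss
    t = state.time

    for j, r in enumerate(scenario.readers):
        if reading[j] is None and pools[j]:
            cand = [studies[sid] for sid in sorted(pools[j])]
            probs = choice_probabilities(r, cand)
            pick = cand[int(rng.choice(len(cand), p=probs))]
            for pp in pools:
                pp.discard(pick.id)
            pending.discard(pick.id)
            reading[j] = (pick.id, t + reading_time(r, pick, scenario.read_time))

    # next event: earliest of arrivals and read completions
    t_arr = (
        order[state.next_arrival].arrival
        if state.next_arrival < len(order)
        else np.inf
    )
    t_done = min((rd[1] for rd in reading if rd), default=np.inf)
    nxt = min(t_arr, t_done)
    if nxt == np.inf:
        return _SimState(t, frozenset(pending), tuple(map(frozenset, pools)),
                         tuple(reading), state.next_arrival, loss)
    t = nxt
    next_arrival = state.next_arrival
    if t_arr <= t_done:
        pending.add(order[next_arrival].id)
        next_arrival += 1
    else:
        j = int(np.argmin([rd[1] if rd else np.inf for rd in reading]))
        sid, end = reading[j]
        reading[j] = None
        loss += study_loss((end - studies[sid].due_time) / 60.0)
    return _SimState(t, frozenset(pending), tuple(map(frozenset, pools)),
                     tuple(reading), next_arrival, loss)


def _terminal(state: _SimState, scenario: RadScenario) -> bool:
    return (
        state.next_arrival >= len(scenario.studies)
        and not state.pending
        and all(r is None for r in state.reading)
    )


def _rollout(state: _SimState, scenario: RadScenario, k: int, rng) -> float:
    """Earliest-deadline-first exposure to completion; returns total loss."""
    studies = _smap(scenario)
    guard = 0
    while not _terminal(state, scenario) and guard < 10000:
        guard += 1
        if state.pending:
            by_deadline = sorted(state.pending, key=lambda sid: studies[sid].due_time)
            pools = [set(p) for p in state.pools]
            placed = False
            for sid in by_deadline:
                for j in range(len(scenario.readers)):
                    if (
                        state.reading[j] is None
                        and len(pools[j]) < k
                        and sid not in pools[j]
                    ):
                        pools[j].add(sid)
                        placed = True
                        break
                if placed:
                    break
            if placed:
                state = _SimState(
                    state.time, state.pending, tuple(map(frozenset, pools)),
                    state.reading, state.next_arrival, state.loss,
                )
        state = _advance(state, scenario, rng)
    return state.loss


@dataclass
class _Node:
    visits: int = 0
    value: float = 0.0           # running mean of negative loss
    children: dict = field(default_factory=dict)


def _uct_pick(node: _Node, actions, c: float, spread: float, rng):
    unvisited = [a for a in actions if a not in node.children]
    if unvisited:
        return unvisited[int(rng.integers(len(unvisited)))]
    logn = np.log(max(node.visits, 1))
    best, best_v = None, -np.inf
    for a in actions:
        ch = node.children[a]
        v = ch.value + c * spread * np.sqrt(logn / ch.visits)
        if v > best_v:
            best, best_v = a, v
    return best


def mcts_plan(
    scenario: RadScenario,
    budget: int,
    cfg: MCTSConfig,
    rng: np.random.Generator,
    k: int | None = None,
    collect_events: bool = True,
) -> tuple[list[DecisionEvent], float]:
    """Plan one scenario with per-decision UCT; returns (events, loss)."""
    if budget < 1:
        raise ValueError("MCTS budget must be positive")
    k = scenario.k if k is None else k
    state = _initial(scenario)
    state = _advance(state, scenario, rng)   # move to the first arrival
    events: list[DecisionEvent] = []
    c = cfg.exploration
    nstep = 0

    while not _terminal(state, scenario):
        actions = _actions(state, scenario, k)
        if not actions:
            break
        if len(actions) == 1:
            state = _apply(state, actions[0], scenario)
        else:
            root = _Node()
            losses = []
            for _ in range(budget):
                a = _uct_pick(
                    root, actions, c,
                    (np.ptp(losses) if len(losses) > 1 and np.ptp(losses) > 0 else 1.0),
                    rng,
                )
                st = _apply(state, a, scenario)
                st = _advance(st, scenario, rng)
                total = _rollout(st, scenario, k, rng)
                losses.append(total)
                ch = root.children.setdefault(a, _Node())
                ch.visits += 1
                ch.value += ((-total) - ch.value) / ch.visits
                root.visits += 1
            best = max(
                root.children,
                key=lambda a: (root.children[a].value, root.children[a].visits),
            )
            if collect_events and best is not None:
                alt_actions = [
                    a for a in actions if a is not None and a != best
                ]
                if alt_actions:
                    est = _exposure_view(state, scenario, k)
                    chosen = featurize_rad_pair(
                        best[0], scenario.readers[best[1]].id, est
                    )
                    alts = tuple(
                        featurize_rad_pair(a[0], scenario.readers[a[1]].id, est)
                        for a in alt_actions
                    )
                    events.append(
                        DecisionEvent(
                            time=state.time,
                            chosen=chosen,
                            alternatives=alts,
                            event_id=f"mcts-{scenario.seed}-{nstep}",
                        )
                    )
            state = _apply(state, best, scenario)
        state = _advance(state, scenario, rng)
        nstep += 1
        if nstep > 10 * len(scenario.studies) + 100:
            break
    return events, state.loss


def _apply(state: _SimState, action, scenario) -> _SimState:
    if action is None:
        return state
    sid, j = action
    pools = [set(p) for p in state.pools]
    pools[j].add(sid)
    return _SimState(
        state.time, state.pending, tuple(map(frozenset, pools)),
        state.reading, state.next_arrival, state.loss,
    )


def _exposure_view(state: _SimState, scenario: RadScenario, k: int) -> ExposureState:
    """Bridge the compact search state to the feature encoder."""
    est = ExposureState(scenario=scenario, k=k)
    est.time = state.time
    est.pending = set(state.pending)
    est.pools = {
        scenario.readers[j].id: sorted(state.pools[j])
        for j in range(len(scenario.readers))
    }
    est.reading = {
        scenario.readers[j].id: state.reading[j]
        for j in range(len(scenario.readers))
        if state.reading[j] is not None
    }
    return est


def mcts_search(
    scenario_sampler,
    budget: int,
    cfg: MCTSConfig,
    rng: np.random.Generator,
) -> list[DecisionEvent]:
    """Run MCTS over sampled scenarios; pool all decision events."""
    events: list[DecisionEvent] = []
    for scenario in scenario_sampler:
        ev, _ = mcts_plan(scenario, budget, cfg, rng)
        events.extend(ev)
    return events


def exhaustive_best_order(scenario: RadScenario) -> tuple[tuple[str, ...], float]:
    """Single-reader oracle: best reading order by full enumeration."""
    if len(scenario.readers) != 1:
        raise ValueError("the order oracle handles single-reader scenarios only")
    reader = scenario.readers[0]
    studies = scenario.studies
    if len(studies) > 7:
        raise ValueError("too many studies for exhaustive enumeration")
    best_order, best_loss = None, np.inf
    for perm in permutations(studies):
        t, loss = 0.0, 0.0
        for s in perm:
            t = max(t, s.arrival) + reading_time(reader, s, scenario.read_time)
            loss += study_loss((t - s.due_time) / 60.0)
        if loss < best_loss - 1e-12:
            best_loss, best_order = loss, tuple(s.id for s in perm)
    return best_order, best_loss
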