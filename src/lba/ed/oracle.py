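"""Exhaustive slot-grid schedule optimizer for tiny ED instances.

An independent oracle for the MILP: depth-first search over per-slot
physician actions with memoization on the residual state.  It shares only
the slot-rounding conventions and the pricing tables with the solver —
the search itself knows nothing about the MILP encoding — so agreement of
the two objective values on a battery of instances is a meaningful check.

Intended for instances of at most a few patients, physicians and slots;
larger instances are refused with a size report.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from lba.ed.schedule import ScheduleSolution, SlotProblem, derive_solution
from lba.ed.scenario import EDObjectiveWeights, EDScenario

__all__ = ["InstanceTooLargeError", "brute_force_schedule"]

_INF = float("inf")


class InstanceTooLargeError(ValueError):
    pass


@dataclass(frozen=True)
class _PatState:
    # exam: 1 or 2 while pending, 0 when done
    exam: int
    rem: int            # remaining work units for the current exam
    ready: int          # earliest slot the current exam may run
    used: int           # bitmask of physicians already on this exam
    started: bool


def brute_force_schedule(
    scenario: EDScenario, weights: EDObjectiveWeights
) -> ScheduleSolution:
    """Exact optimum by exhaustive search; matches the MILP's accounting."""
    n = len(scenario.patients)
    m = len(scenario.physicians)
    T = scenario.horizon_slots
    if n > 4 or m > 3 or T > 20:
        raise InstanceTooLargeError(
            f"instance with {n} patients, {m} physicians, {T} slots exceeds "
            "the enumeration budget (max 4 patients, 3 physicians, 20 slots)"
        )
    prob = SlotProblem.from_scenario(scenario)
    slot = scenario.slot_minutes
    U = prob.work_unit
    a1, a2, a3, a4, a5 = weights.alphas
    dec = [int(round(U / c.ce)) for c in scenario.physicians]
    pats = scenario.patients

    init = tuple(
        _PatState(1, U * prob.tt_slots[i][0], prob.arr1[i], 0, False)
        for i in range(n)
    )
    memo: dict = {}

    def actions_for(state, t):
        """Per-physician feasible actions: None or (i,)."""
        avail = [
            i
            for i, ps in enumerate(state)
            if ps.exam and ps.ready <= t and ps.rem > 0
        ]
        opts = []
        for j in range(m):
            opts.append([None] + [i for i in avail if dec[j] <= state[i].rem])
        combos = []
        for combo in product(*opts):
            picked = [i for i in combo if i is not None]
            if len(picked) == len(set(picked)):
                combos.append(combo)
        return combos

    def step_cost_and_state(state, last, combo, t):
        cost = 0.0
        new = list(state)
        for j, i in enumerate(combo):
            if i is None:
                continue
            ps = new[i]
            p = pats[i]
            e = ps.exam
            if last[j] != (i, e):                      # a start indicator fires
                if ps.started:
                    cost += a5 * weights.pre(p, e)
                else:
                    excess = max(0.0, (t - ps.ready) * slot - p.tbar(e))
                    cost += a2 * weights.exc(p, e, excess)
                if not (ps.used >> j) & 1:
                    cost += a1 * weights.risk(p, scenario.physicians[j], e)
            used = ps.used | (1 << j)
            rem = ps.rem - dec[j]
            started = True
            if rem == 0:
                if e == 1 and pats[i].needs_second_exam:
                    new[i] = _PatState(
                        2,
                        U * prob.tt_slots[i][1],
                        t + 1 + prob.lt_slots[i],
                        0,
                        False,
                    )
                else:
                    cost += (a3 + a4) * slot * (t + 1 - prob.arr1[i])
                    new[i] = _PatState(0, 0, 0, 0, False)
            else:
                new[i] = _PatState(e, rem, ps.ready, used, started)
        newlast = tuple(
            (combo[j], state[combo[j]].exam) if combo[j] is not None else None
            for j in range(m)
        )
        return cost, tuple(new), newlast

    def best(t, state, last):
        if all(ps.exam == 0 for ps in state):
            return 0.0, None
        if t >= T:
            return _INF, None
        key = (t, state, last)
        if key in memo:
            return memo[key]
        combos = actions_for(state, t)
        if all(all(x is None for x in cb) for cb in combos):
            # nothing assignable: jump to the next readiness time
            nxt = min(
                (ps.ready for ps in state if ps.exam and ps.ready > t),
                default=T,
            )
            sub, _ = best(max(nxt, t + 1), state, (None,) * m)
            memo[key] = (sub, ("jump", max(nxt, t + 1)))
            return memo[key]
        bc, barg = _INF, None
        for combo in combos:
            c0, nstate, nlast = step_cost_and_state(state, last, combo, t)
            sub, _ = best(t + 1, nstate, nlast)
            total = c0 + sub
            if total < bc:
                bc, barg = total, combo
        memo[key] = (bc, barg)
        return memo[key]

    obj, _ = best(0, init, (None,) * m)
    if obj == _INF:
        raise ValueError("no feasible schedule within the horizon")

    # reconstruct the optimal grid by replay
    grid = np.zeros((n, m, 2, T), bool)
    t, state, last = 0, init, (None,) * m
    while not all(ps.exam == 0 for ps in state):
        _, arg = memo[(t, state, last)]
        if arg is None:
            break
        if isinstance(arg, tuple) and len(arg) == 2 and arg[0] == "jump":
            t, last = arg[1], (None,) * m
            continue
        for j, i in enumerate(arg):
            if i is not None:
                grid[i, j, state[i].exam - 1, t] = True
        _, state, last = step_cost_and_state(state, last, arg, t)
        t += 1

    sol = derive_solution(grid, scenario, weights)
    if abs(sol.objective - obj) > 1e-6 * max(1.0, abs(obj)):
        raise AssertionError(
            f"oracle replay objective {sol.objective} != search value {obj}"
        )
    sol.solver_status = "exhaustive"
    return sol
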