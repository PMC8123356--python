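"""The offline patient–physician assignment MILP.

Builds and solves, over a discrete slot horizon, the assignment problem
with binary indicators ``y[i, j, e, t]`` (patient i treated by physician j
for exam e in slot t), minimizing the five-part ED objective.  Modeling
choices:

* start indicators ``rho`` are the standard binary linearization of
  y_t AND NOT y_{t-1};
* first/last occupied slots are pinned by cumulative indicators
  (``u_t`` = "started by t", ``w_t`` = "occupied at or after t"), whose
  chained bounds force them to match the occupancy pattern exactly,
  independent of objective direction;
* work conservation: sum_j sum_t y / CE_j equals the required slots per
  exam (equality, so every patient is fully treated within the horizon or
  the model is infeasible);
* the excess-wait penalty must be linear in the excess for the MILP
  (the default table is); the crowding integral equals summed LOS.

The backend is HiGHS via ``scipy.optimize.milp``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from lba.ed.schedule import (
    ScheduleSolution,
    SlotProblem,
    check_constraints,
    derive_solution,
)
from lba.ed.scenario import EDObjectiveWeights, EDScenario

__all__ = [
    "EDMilpModel",
    "SolverConfig",
    "InfeasibleScheduleError",
    "SolutionAuditError",
    "build_offline_milp",
    "solve_offline",
]

_INF = np.inf


class InfeasibleScheduleError(RuntimeError):
    """The offline instance admits no feasible schedule."""


class SolutionAuditError(RuntimeError):
    """Solver output failed the independent constraint audit."""


@dataclass
class SolverConfig:
    time_limit: float = 60.0      # seconds
    mip_gap: float = 0.0          # relative optimality gap


@dataclass
class EDMilpModel:
    scenario: EDScenario
    weights: EDObjectiveWeights
    prob: SlotProblem
    c: np.ndarray = field(default_factory=lambda: np.array([]))
    constant: float = 0.0
    constraints: list = field(default_factory=list)
    integrality: np.ndarray = field(default_factory=lambda: np.array([]))
    bounds: Bounds | None = None
    y_index: dict = field(default_factory=dict)
    n_vars: int = 0


class _RowBuilder:
    def __init__(self):
        self.rows, self.cols, self.vals = [], [], []
        self.lb, self.ub = [], []
        self.n = 0

    def add(self, coeffs: dict[int, float], lb: float, ub: float):
        for col, v in coeffs.items():
            self.rows.append(self.n)
            self.cols.append(col)
            self.vals.append(v)
        self.lb.append(lb)
        self.ub.append(ub)
        self.n += 1

    def to_constraint(self, n_vars: int) -> LinearConstraint:
        A = sparse.coo_matrix(
            (self.vals, (self.rows, self.cols)), shape=(self.n, n_vars)
        ).tocsr()
        return LinearConstraint(A, np.array(self.lb), np.array(self.ub))


def _capacity_report(scenario: EDScenario, prob: SlotProblem) -> str:
    T = scenario.horizon_slots
    need = sum(
        sum(prob.tt_slots[i][e - 1] for e in p.exams)
        for i, p in enumerate(scenario.patients)
    )
    have = sum(T / c.ce for c in scenario.physicians)
    lines = [f"required work {need} slots vs capacity {have:.1f} CE-adjusted slots"]
    for i, p in enumerate(scenario.patients):
        tmin2 = prob.arr1[i] + prob.tt_slots[i][0] + prob.lt_slots[i]
        last_need = prob.tt_slots[i][prob.n_exams[i] - 1]
        tail = tmin2 if p.needs_second_exam else prob.arr1[i]
        if tail + last_need > T:
            lines.append(
                f"patient {p.id}: earliest completion slot {tail + last_need} "
                f"exceeds horizon {T}"
            )
    return "; ".join(lines)


def build_offline_milp(
    scenario: EDScenario, weights: EDObjectiveWeights
) -> EDMilpModel:
    """Assemble the MILP for one realized scenario."""
    prob = SlotProblem.from_scenario(scenario)
    model = EDMilpModel(scenario=scenario, weights=weights, prob=prob)
    n = len(scenario.patients)
    mphys = len(scenario.physicians)
    T = scenario.horizon_slots
    if n == 0:
        return model
    a3a4 = (weights.alphas[2] + weights.alphas[3]) * scenario.slot_minutes

    tmin: dict[tuple[int, int], int] = {}
    for i, p in enumerate(scenario.patients):
        tmin[(i, 1)] = prob.arr1[i]
        if p.needs_second_exam:
            tmin[(i, 2)] = prob.arr1[i] + prob.tt_slots[i][0] + prob.lt_slots[i]
        for e in p.exams:
            if tmin[(i, e)] + prob.tt_slots[i][e - 1] > T:
                raise InfeasibleScheduleError(
                    "instance infeasible before solving: "
                    + _capacity_report(scenario, prob)
                )

    # --- variable indexing -------------------------------------------
    idx = 0
    y, rho, u, w, a, delta = {}, {}, {}, {}, {}, {}
    for i, p in enumerate(scenario.patients):
        for e in p.exams:
            for t in range(tmin[(i, e)], T):
                for j in range(mphys):
                    y[(i, j, e, t)] = idx; idx += 1
                    rho[(i, j, e, t)] = idx; idx += 1
                u[(i, e, t)] = idx; idx += 1
                w[(i, e, t)] = idx; idx += 1
            for j in range(mphys):
                a[(i, j, e)] = idx; idx += 1
            delta[(i, e)] = idx; idx += 1
    n_vars = idx
    c = np.zeros(n_vars)
    integrality = np.ones(n_vars)
    lb = np.zeros(n_vars)
    ub = np.ones(n_vars)
    for key, col in delta.items():
        integrality[col] = 0
        ub[col] = _INF

    rowsb = _RowBuilder()
    slot = scenario.slot_minutes
    a1, a2, a3, a4, a5 = weights.alphas
    constant = 0.0

    # physician capacity (Eq. 3)
    for j in range(mphys):
        for t in range(T):
            coeffs = {
                y[(i, j, e, t)]: 1.0
                for i, p in enumerate(scenario.patients)
                for e in p.exams
                if (i, j, e, t) in y
            }
            if coeffs:
                rowsb.add(coeffs, -_INF, 1.0)
    # patient capacity (Eq. 4, across exams and physicians)
    for i, p in enumerate(scenario.patients):
        for t in range(T):
            coeffs = {
                y[(i, j, e, t)]: 1.0
                for e in p.exams
                for j in range(mphys)
                if (i, j, e, t) in y
            }
            if coeffs:
                rowsb.add(coeffs, -_INF, 1.0)

    for i, p in enumerate(scenario.patients):
        for e in p.exams:
            t0 = tmin[(i, e)]
            trange = range(t0, T)
            L = T - t0
            # start indicators rho (Eq. 5, linearized)
            for t in trange:
                for j in range(mphys):
                    ycur = y[(i, j, e, t)]
                    r = rho[(i, j, e, t)]
                    if t == t0:
                        rowsb.add({r: 1.0, ycur: -1.0}, 0.0, 0.0)
                    else:
                        yprev = y[(i, j, e, t - 1)]
                        rowsb.add({ycur: 1.0, yprev: -1.0, r: -1.0}, -_INF, 0.0)
                        rowsb.add({r: 1.0, ycur: -1.0}, -_INF, 0.0)
                        rowsb.add({r: 1.0, yprev: 1.0}, -_INF, 1.0)
            # cumulative "started by t" u and "occupied at/after t" w
            for t in trange:
                occ = {y[(i, j, e, t)]: 1.0 for j in range(mphys)}
                cu = u[(i, e, t)]
                cw = w[(i, e, t)]
                row = dict(occ); row[cu] = -1.0
                rowsb.add(row, -_INF, 0.0)                      # u_t >= occ_t
                row = dict(occ); row[cw] = -1.0
                rowsb.add(row, -_INF, 0.0)                      # w_t >= occ_t
                if t > t0:
                    rowsb.add({u[(i, e, t)]: 1.0, u[(i, e, t - 1)]: -1.0}, 0.0, _INF)
                if t + 1 < T:
                    rowsb.add({w[(i, e, t + 1)]: 1.0, w[(i, e, t)]: -1.0}, -_INF, 0.0)
                # u_t <= cumulative occupancy up to t
                row = {y[(i, j, e, tt)]: 1.0 for tt in range(t0, t + 1) for j in range(mphys)}
                row[cu] = row.get(cu, 0.0) - 1.0
                rowsb.add(row, 0.0, _INF)
                # w_t <= occupancy from t onward
                row = {y[(i, j, e, tt)]: 1.0 for tt in range(t, T) for j in range(mphys)}
                row[cw] = row.get(cw, 0.0) - 1.0
                rowsb.add(row, 0.0, _INF)
            # work conservation (Eq. 15)
            row = {
                y[(i, j, e, t)]: 1.0 / scenario.physicians[j].ce
                for t in trange
                for j in range(mphys)
            }
            req = float(prob.tt_slots[i][e - 1])
            rowsb.add(row, req, req)
            # examination indicators AC (Eq. 17)
            for j in range(mphys):
                col_a = a[(i, j, e)]
                row = {y[(i, j, e, t)]: 1.0 for t in trange}
                row[col_a] = -float(L)
                rowsb.add(row, -_INF, 0.0)                      # sum y <= L * a
                row = {y[(i, j, e, t)]: 1.0 for t in trange}
                row[col_a] = row.get(col_a, 0.0) - 1.0
                rowsb.add(row, 0.0, _INF)                       # a <= sum y
                c[col_a] += a1 * weights.risk(p, scenario.physicians[j], e)
            # preemption pricing (Eq. 16): PC = sum rho - 1
            pre = weights.pre(p, e)
            for t in trange:
                for j in range(mphys):
                    c[rho[(i, j, e, t)]] += a5 * pre
            constant -= a5 * pre
            # excess wait (Eq. 14 + penalty)
            slope = weights.exc(p, e, 1.0)   # linear excess penalty required
            col_d = delta[(i, e)]
            c[col_d] += a2 * slope
            if e == 1:
                row = {u[(i, e, t)]: slot for t in trange}
                row[col_d] = 1.0
                rowsb.add(row, slot * L - p.tbar1, _INF)
            else:
                row = {col_d: 1.0}
                for t in trange:
                    row[u[(i, 2, t)]] = slot
                for t in range(tmin[(i, 1)], T):
                    row[w[(i, 1, t)]] = slot
                lbv = slot * (T - tmin[(i, 1)] - prob.lt_slots[i]) - p.tbar2
                rowsb.add(row, lbv, _INF)
        # ordering between exams: st2 >= et1 + LT (Eqs. 10–12)
        if p.needs_second_exam:
            row = {u[(i, 2, t)]: -1.0 for t in range(tmin[(i, 2)], T)}
            for t in range(tmin[(i, 1)], T):
                row[w[(i, 1, t)]] = row.get(w[(i, 1, t)], 0.0) - 1.0
            rowsb.add(row, prob.lt_slots[i] + tmin[(i, 1)] - T, _INF)
        # LOS pricing (Eqs. 13 + crowding identity)
        e_last = p.exams[-1]
        for t in range(tmin[(i, e_last)], T):
            c[w[(i, e_last, t)]] += a3a4
        constant += a3a4 * (tmin[(i, e_last)] - prob.arr1[i])

    model.c = c
    model.constant = constant
    model.constraints = [rowsb.to_constraint(n_vars)]
    model.integrality = integrality
    model.bounds = Bounds(lb, ub)
    model.y_index = y
    model.n_vars = n_vars
    return model


def solve_offline(
    model: EDMilpModel, solver_cfg: SolverConfig | None = None
) -> ScheduleSolution:
    """Solve the MILP and return an audited :class:`ScheduleSolution`."""
    cfg = solver_cfg or SolverConfig()
    scenario, weights = model.scenario, model.weights
    n = len(scenario.patients)
    mphys = len(scenario.physicians)
    T = scenario.horizon_slots
    if n == 0:
        return derive_solution(np.zeros((0, mphys, 2, T), bool), scenario, weights)

    options = {"time_limit": cfg.time_limit}
    if cfg.mip_gap:
        options["mip_rel_gap"] = cfg.mip_gap
    res = milp(
        c=model.c,
        constraints=model.constraints,
        integrality=model.integrality,
        bounds=model.bounds,
        options=options,
    )
    if res.status == 2 or res.x is None:
        raise InfeasibleScheduleError(
            f"solver reports infeasibility ({res.message}); "
            + _capacity_report(scenario, model.prob)
        )

    grid = np.zeros((n, mphys, 2, T), bool)
    for (i, j, e, t), col in model.y_index.items():
        grid[i, j, e - 1, t] = res.x[col] > 0.5
    violations = check_constraints(grid, scenario)
    if violations:
        raise SolutionAuditError(
            "solver output violates constraints: " + "; ".join(violations)
        )
    sol = derive_solution(grid, scenario, weights)
    solver_obj = float(res.fun) + model.constant
    if abs(solver_obj - sol.objective) > 1e-6 * max(1.0, abs(sol.objective)):
        raise SolutionAuditError(
            f"solver objective {solver_obj:.6f} disagrees with independently "
            f"derived objective {sol.objective:.6f}"
        )
    sol.optimal = res.status == 0
    sol.solver_status = res.message
    return sol
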