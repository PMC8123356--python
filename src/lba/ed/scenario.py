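"""ED actors, objective weights and night-shift scenario generation.

Patients carry a triage severity (ESI 1–5, 1 most acute), an injury type,
per-exam wait-time bounds and nominal treatment times; physicians carry
seniority, an optional injury-type specialty and a time-efficiency factor
CE >= 1 (treating a patient occupies CE * TT physician-minutes).  Arrivals
follow a configurable non-homogeneous Poisson process; a flow multiplier
of 2 models heavy nights with twice the expected patient count.

All constants here are configuration defaults: hospital-specific risk
tables, wait-penalty slopes and objective weights differ between
institutions and are meant to be overridden.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from lba.arrivals import PiecewiseRate, sample_nhpp

__all__ = [
    "SENIORITY_LEVELS",
    "WAIT_ROOM",
    "Patient",
    "Physician",
    "EDObjectiveWeights",
    "EDScenarioConfig",
    "EDScenario",
    "generate_ed_scenario",
]

SENIORITY_LEVELS = ("assistant", "intern", "resident", "attending")

#: sentinel id for the dummy infinite-capacity "physician" that models the
#: decision to let a patient keep waiting.
WAIT_ROOM = "WaitRoom"


@dataclass(frozen=True)
class Patient:
    id: str
    severity: int
    injury: str
    arrival1: float               # minutes from shift start
    tbar1: float                  # triage wait bound, exam 1 (min)
    tbar2: float                  # triage wait bound, exam 2 (min)
    tt1: float                    # nominal treatment time, exam 1 (min)
    tt2: float                    # nominal treatment time, exam 2 (min; 0 if single exam)
    lt: float                     # lab time between exams (min; 0 if single exam)
    needs_second_exam: bool

    def __post_init__(self):
        if self.severity not in (1, 2, 3, 4, 5):
            raise ValueError(f"severity must be 1..5, got {self.severity}")
        if self.tbar1 <= 0 or self.tbar2 <= 0 or self.tt1 <= 0 or self.lt < 0:
            raise ValueError("invalid patient timing parameters")

    @property
    def exams(self) -> tuple[int, ...]:
        return (1, 2) if self.needs_second_exam else (1,)

    def tt(self, e: int) -> float:
        return self.tt1 if e == 1 else self.tt2

    def tbar(self, e: int) -> float:
        return self.tbar1 if e == 1 else self.tbar2

    @property
    def urgent(self) -> bool:
        return self.severity <= 2


@dataclass(frozen=True)
class Physician:
    id: str
    seniority: str                # one of SENIORITY_LEVELS
    specialty: str | None         # injury type or None
    ce: float = 1.0               # time-efficiency factor, >= 1

    def __post_init__(self):
        if self.seniority not in SENIORITY_LEVELS:
            raise ValueError(f"unknown seniority {self.seniority!r}")
        if self.ce < 1.0:
            raise ValueError("efficiency factor CE must be >= 1")

    @property
    def seniority_rank(self) -> int:
        """1 (assistant) .. 4 (attending)."""
        return SENIORITY_LEVELS.index(self.seniority) + 1


@dataclass
class EDObjectiveWeights:
    """Weights and penalty tables of the five-part ED objective.

    score = a1 * total risk + a2 * total excess-wait penalty
          + a3 * total LOS (min) + a4 * crowding integral (patient-min)
          + a5 * total preemption penalty
    """

    alphas: tuple[float, float, float, float, float] = (1.0, 1.0, 0.05, 0.02, 1.0)
    base_risk: dict[int, float] = field(
        default_factory=lambda: {1: 10.0, 2: 6.0, 3: 3.0, 4: 2.0, 5: 1.0}
    )
    seniority_risk_factor: dict[str, float] = field(
        default_factory=lambda: {
            "attending": 1.0, "resident": 1.2, "intern": 1.5, "assistant": 1.8,
        }
    )
    specialty_mismatch_factor: float = 1.5
    specialty_match_factor: float = 0.8
    # excess-wait slope per minute past the triage bound, by severity;
    # steeper for more acute patients
    exc_slope: dict[int, float] = field(
        default_factory=lambda: {1: 5.0, 2: 3.0, 3: 1.5, 4: 1.0, 5: 0.5}
    )
    # flat penalty per interruption, by severity
    pre_penalty: dict[int, float] = field(
        default_factory=lambda: {1: 30.0, 2: 25.0, 3: 20.0, 4: 15.0, 5: 10.0}
    )
    # charged per patient not discharged by end of horizon
    terminal_penalty: float = 100.0

    def risk(self, patient: Patient, physician: Physician, e: int) -> float:
        r = self.base_risk[patient.severity]
        r *= self.seniority_risk_factor[physician.seniority]
        if physician.specialty is None:
            pass
        elif physician.specialty == patient.injury:
            r *= self.specialty_match_factor
        else:
            r *= self.specialty_mismatch_factor
        return r

    def exc(self, patient: Patient, e: int, excess_minutes: float) -> float:
        return self.exc_slope[patient.severity] * max(0.0, excess_minutes)

    def pre(self, patient: Patient, e: int) -> float:
        return self.pre_penalty[patient.severity]


@dataclass
class EDScenarioConfig:
    shift_minutes: float = 480.0
    slot_minutes: float = 5.0
    # night-shift arrival intensity, events/min (declining through the night)
    rate_breakpoints: list[tuple[float, float]] = field(
        default_factory=lambda: [(0.0, 4 / 60), (120.0, 3 / 60), (300.0, 2 / 60)]
    )
    flow_multiplier: float = 1.0          # 1 = normal, 2 = heavy
    severity_probs: dict[int, float] = field(
        default_factory=lambda: {1: 0.03, 2: 0.07, 3: 0.35, 4: 0.35, 5: 0.20}
    )
    injury_types: tuple[str, ...] = ("internal", "orthopedic", "cardiac")
    injury_probs: tuple[float, ...] = (0.5, 0.3, 0.2)
    tt1_range: tuple[float, float] = (10.0, 30.0)     # uniform, minutes
    tt2_range: tuple[float, float] = (10.0, 20.0)
    lt_range: tuple[float, float] = (20.0, 60.0)
    second_exam_prob: float = 0.4
    tbar1: dict[int, float] = field(
        default_factory=lambda: {1: 5.0, 2: 10.0, 3: 30.0, 4: 60.0, 5: 120.0}
    )
    tbar2: dict[int, float] = field(
        default_factory=lambda: {1: 5.0, 2: 10.0, 3: 30.0, 4: 60.0, 5: 120.0}
    )
    n_physicians: int = 3
    specialty_prob: float = 0.5
    # CE by seniority; the defaults stay on the half-slot grid so the
    # offline work-conservation constraint is attainable exactly
    ce_by_seniority: dict[str, float] = field(
        default_factory=lambda: {
            "attending": 1.0, "resident": 1.0, "intern": 2.0, "assistant": 2.0,
        }
    )
    max_patients: int | None = None       # truncate (earliest kept) if set

    def heavy(self) -> "EDScenarioConfig":
        """The same configuration under heavy flow (rates doubled)."""
        return replace(self, flow_multiplier=2.0)


@dataclass
class EDScenario:
    patients: list[Patient]
    physicians: list[Physician]
    horizon_slots: int
    slot_minutes: float
    injury_types: tuple[str, ...] = ("internal", "orthopedic", "cardiac")
    seed: int | None = None

    @property
    def horizon_minutes(self) -> float:
        return self.horizon_slots * self.slot_minutes

    def to_json(self, path) -> None:
        doc = {
            "horizon_slots": self.horizon_slots,
            "slot_minutes": self.slot_minutes,
            "injury_types": list(self.injury_types),
            "seed": self.seed,
            "patients": [vars(p).copy() for p in self.patients],
            "physicians": [vars(c).copy() for c in self.physicians],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "EDScenario":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            patients=[Patient(**p) for p in doc["patients"]],
            physicians=[Physician(**c) for c in doc["physicians"]],
            horizon_slots=doc["horizon_slots"],
            slot_minutes=doc["slot_minutes"],
            injury_types=tuple(doc.get("injury_types", ())),
            seed=doc.get("seed"),
        )


def generate_ed_scenario(cfg: EDScenarioConfig, seed: int) -> EDScenario:
    """Draw one shift scenario: staffed physicians plus realized arrivals."""
    rng = np.random.default_rng(seed)
    rate = PiecewiseRate(cfg.rate_breakpoints).scaled(cfg.flow_multiplier)
    arrivals = sample_nhpp(rate, cfg.shift_minutes, rng)

    severities = list(cfg.severity_probs)
    sev_p = np.array([cfg.severity_probs[s] for s in severities], float)
    sev_p /= sev_p.sum()
    inj_p = np.array(cfg.injury_probs, float)
    inj_p /= inj_p.sum()

    patients = []
    for i, arr in enumerate(arrivals):
        sev = int(rng.choice(severities, p=sev_p))
        injury = str(rng.choice(cfg.injury_types, p=inj_p))
        second = bool(rng.uniform() < cfg.second_exam_prob)
        tt1 = float(rng.uniform(*cfg.tt1_range))
        tt2 = float(rng.uniform(*cfg.tt2_range)) if second else 0.0
        lt = float(rng.uniform(*cfg.lt_range)) if second else 0.0
        patients.append(
            Patient(
                id=f"p{i}",
                severity=sev,
                injury=injury,
                arrival1=float(arr),
                tbar1=cfg.tbar1[sev],
                tbar2=cfg.tbar2[sev],
                tt1=tt1,
                tt2=tt2,
                lt=lt,
                needs_second_exam=second,
            )
        )
    if cfg.max_patients is not None:
        patients = patients[: cfg.max_patients]

    if cfg.n_physicians < 1:
        raise ValueError("a scenario needs at least one physician")
    physicians = []
    for j in range(cfg.n_physicians):
        seniority = str(rng.choice(SENIORITY_LEVELS))
        specialty = (
            str(rng.choice(cfg.injury_types))
            if rng.uniform() < cfg.specialty_prob
            else None
        )
        physicians.append(
            Physician(
                id=f"c{j}",
                seniority=seniority,
                specialty=specialty,
                ce=cfg.ce_by_seniority[seniority],
            )
        )

    horizon_slots = int(round(cfg.shift_minutes / cfg.slot_minutes))
    return EDScenario(
        patients=patients,
        physicians=physicians,
        horizon_slots=horizon_slots,
        slot_minutes=cfg.slot_minutes,
        injury_types=tuple(cfg.injury_types),
        seed=seed,
    )
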