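"""Studies, readers, quantal-response choice and scenario generation.

A study is a (modality, body part, deadline) tuple; a reader is defined
by a subspecialty list of (modality, body part) pairs and a nonnegative
utility over study types.  Any reader may read any study, but reading
outside the subspecialty takes ``rho`` times the nominal time (defaults:
3 min nominal, rho = 3, hence 9 min out-of-subspecialty).

Readers pick from their exposure pool by quantal response: the selection
probability of a study is proportional to exp(utility).  Utilities are
not observed directly; following revealed preference, the normalized
frequency of the study types a reader historically selected serves as
the utility proxy.  The generator emulates that estimation pipeline with
a synthetic selection history drawn from a latent Dirichlet preference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from lba.arrivals import PiecewiseRate, sample_nhpp

__all__ = [
    "Study",
    "Reader",
    "ReadTimeModel",
    "RadScenarioConfig",
    "RadScenario",
    "generate_radiology_scenario",
    "reading_time",
    "choice_probabilities",
    "estimate_utilities",
]

MB = tuple[str, str]


@dataclass(frozen=True)
class Study:
    id: str
    modality: str
    body_part: str
    deadline: float          # minutes after arrival
    arrival: float           # minutes from scenario start

    @property
    def mb(self) -> MB:
        return (self.modality, self.body_part)

    @property
    def due_time(self) -> float:
        return self.arrival + self.deadline


@dataclass(frozen=True)
class Reader:
    id: str
    subspecialty: frozenset          # of (modality, body part) pairs
    utility: dict                    # (modality, body part) -> float >= 0

    def u(self, study: Study) -> float:
        return float(self.utility.get(study.mb, 0.0))


@dataclass
class ReadTimeModel:
    nominal: dict = field(default_factory=dict)   # (M, B) -> minutes
    default_nominal: float = 3.0
    rho: float = 3.0                               # out-of-subspecialty factor

    def __post_init__(self):
        if self.rho <= 1.0:
            raise ValueError("skill-efficiency factor rho must exceed 1")
        if any(v <= 0 for v in self.nominal.values()) or self.default_nominal <= 0:
            raise ValueError("nominal reading times must be positive")

    def t(self, mb: MB) -> float:
        return float(self.nominal.get(mb, self.default_nominal))


def reading_time(reader: Reader, study: Study, model: ReadTimeModel) -> float:
    """Minutes for ``reader`` to read ``study``."""
    t = model.t(study.mb)
    return t if study.mb in reader.subspecialty else model.rho * t


def choice_probabilities(reader: Reader, pool: list[Study]) -> np.ndarray:
    """Quantal-response (softmax-of-utility) selection over the pool."""
    if len(pool) == 0:
        raise ValueError("cannot choose from an empty pool")
    u = np.array([reader.u(s) for s in pool])
    e = np.exp(u - u.max())
    return e / e.sum()


def estimate_utilities(
    history: dict[str, list[MB]], warn=None
) -> dict[str, dict[MB, float]]:
    """Revealed-preference utility proxies from selection histories.

    ``history`` maps reader id to the list of study types they selected;
    the utility of a type is its normalized selection frequency (unseen
    types implicitly 0).  Readers with empty histories get an empty
    (uniform-zero) utility and a warning.
    """
    out: dict[str, dict[MB, float]] = {}
    for rid, picks in history.items():
        if not picks:
            if warn is not None:
                warn(f"reader {rid}: empty history, uniform utility")
            out[rid] = {}
            continue
        u: dict[MB, float] = {}
        for mb in picks:
            u[mb] = u.get(mb, 0.0) + 1.0
        total = sum(u.values())
        out[rid] = {mb: v / total for mb, v in u.items()}
    return out


def _default_read_time() -> ReadTimeModel:
    """Per-modality nominal reading minutes (in-subspecialty); rho = 3."""
    per_modality = {"XR": 3.0, "US": 5.0, "CT": 10.0, "MRI": 15.0}
    nominal = {
        (m, b): t
        for m, t in per_modality.items()
        for b in ("head", "chest", "abdomen", "spine", "limb")
    }
    return ReadTimeModel(nominal=nominal, default_nominal=3.0, rho=3.0)


@dataclass
class RadScenarioConfig:
    """Default study conditions: a 10-reader panel facing a 45-minute
    burst of 60 studies — an overloaded morning worklist in which routing
    and prioritization decisions matter.  Deadlines mix stat studies
    (30–120 min) with routine ones (log-uniform up to one week)."""

    modalities: tuple[str, ...] = ("XR", "US", "CT", "MRI")
    body_parts: tuple[str, ...] = ("head", "chest", "abdomen", "spine", "limb")
    n_readers: int = 10
    n_studies: int = 60
    k: int = 10
    # arrivals: constant-rate window sized to yield n_studies in expectation
    arrival_window: float = 30.0             # minutes
    deadline_range: tuple[float, float] = (30.0, 10080.0)   # 30 min .. 1 week
    stat_fraction: float = 0.7               # share with short (stat) deadlines
    stat_deadline_max: float = 120.0         # stat: uniform [range lo, this]
    subspecialty_size: int = 5
    history_length: int = 200                # synthetic selections per reader
    history_concentration: float = 0.3       # Dirichlet alpha of latent taste
    read_time: ReadTimeModel = field(default_factory=_default_read_time)

    @property
    def types(self) -> list[MB]:
        return [(m, b) for m in self.modalities for b in self.body_parts]


@dataclass
class RadScenario:
    studies: list[Study]
    readers: list[Reader]
    read_time: ReadTimeModel
    k: int
    seed: int | None = None


def generate_radiology_scenario(cfg: RadScenarioConfig, seed: int) -> RadScenario:
    """Seed-reproducible study stream plus reader panel."""
    if not cfg.modalities or not cfg.body_parts:
        raise ValueError("modality and body-part sets must be nonempty")
    rng = np.random.default_rng(seed)
    types = cfg.types

    rate = cfg.n_studies / cfg.arrival_window
    arrivals = sample_nhpp(
        PiecewiseRate([(0.0, rate)]), cfg.arrival_window, rng
    )
    # fix the count at n_studies (the stream length is part of the design)
    while len(arrivals) < cfg.n_studies:
        arrivals = np.append(arrivals, rng.uniform(0, cfg.arrival_window))
    arrivals = np.sort(arrivals[: cfg.n_studies])

    lo, hi = cfg.deadline_range
    stat = rng.uniform(size=len(arrivals)) < cfg.stat_fraction
    deadlines = np.where(
        stat,
        rng.uniform(lo, cfg.stat_deadline_max, size=len(arrivals)),
        np.exp(
            rng.uniform(
                np.log(cfg.stat_deadline_max), np.log(hi), size=len(arrivals)
            )
        ),
    )

    studies = []
    for i, (arr, dl) in enumerate(zip(arrivals, deadlines)):
        mi = int(rng.integers(len(types)))
        m, b = types[mi]
        studies.append(
            Study(id=f"s{i}", modality=m, body_part=b,
                  deadline=float(dl), arrival=float(arr))
        )

    history: dict[str, list[MB]] = {}
    subs: dict[str, frozenset] = {}
    for j in range(cfg.n_readers):
        rid = f"r{j}"
        picks_idx = rng.choice(
            len(types), size=min(cfg.subspecialty_size, len(types)), replace=False
        )
        subs[rid] = frozenset(types[i] for i in picks_idx)
        taste = rng.dirichlet(
            np.full(len(types), cfg.history_concentration)
        )
        sel = rng.choice(len(types), size=cfg.history_length, p=taste)
        history[rid] = [types[i] for i in sel]

    utilities = estimate_utilities(history)
    readers = [
        Reader(id=rid, subspecialty=subs[rid], utility=utilities[rid])
        for rid in subs
    ]
    return RadScenario(
        studies=studies, readers=readers, read_time=cfg.read_time,
        k=cfg.k, seed=seed,
    )
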