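"""The combined patient–physician feature vector for the ED comparator.

One vector describes one candidate assignment option — a (waiting patient,
physician) pair, or (patient, WaitRoom) for the option of keeping the
patient waiting.  Fields, in fixed order:

patient:  severity/5; injury one-hot; remaining nominal treatment time
          (min); wait time so far (min); time remaining to the triage wait
          bound, tbar - WT (min)
physician: seniority/4; specialization one-hot; status (0 if idle, else
          severity/5 of the patient under treatment); idle time (min)

The WaitRoom option zeroes the entire physician sub-vector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from lba.ranking import FeatureVector
from lba.ed.scenario import Patient, Physician

__all__ = ["ed_schema_id", "ed_feature_dim", "featurize_ed_pair", "EDPairContext"]


def ed_schema_id(injury_types: tuple[str, ...]) -> str:
    return "ed/" + ",".join(injury_types)


def ed_feature_dim(injury_types: tuple[str, ...]) -> int:
    return 2 * len(injury_types) + 7


@dataclass
class EDPairContext:
    """Decision-time state of one candidate pair."""

    exam: int                     # 1 or 2
    wait_minutes: float           # time waited for this exam so far
    remaining_tt: float           # nominal treatment minutes still needed
    busy_severity: int = 0        # 0 if the physician is idle
    idle_minutes: float = 0.0


def featurize_ed_pair(
    patient: Patient,
    physician: Physician | None,
    ctx: EDPairContext,
    injury_types: tuple[str, ...],
) -> FeatureVector:
    """Encode one assignment option; ``physician=None`` means WaitRoom."""
    if patient.injury not in injury_types:
        raise ValueError(f"unknown injury type {patient.injury!r}")
    k = len(injury_types)
    v = np.zeros(2 * k + 7)
    v[0] = patient.severity / 5.0
    v[1 + injury_types.index(patient.injury)] = 1.0
    v[k + 1] = ctx.remaining_tt
    v[k + 2] = ctx.wait_minutes
    v[k + 3] = patient.tbar(ctx.exam) - ctx.wait_minutes
    if physician is not None:
        v[k + 4] = physician.seniority_rank / 4.0
        if physician.specialty is not None:
            v[k + 5 + injury_types.index(physician.specialty)] = 1.0
        v[2 * k + 5] = ctx.busy_severity / 5.0
        v[2 * k + 6] = ctx.idle_minutes
    return FeatureVector(v, ed_schema_id(injury_types))
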