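"""The seven-feature encoding of one (study, reader) exposure option.

Reader-side features describe the reader's current pool; study-side
features describe the study's urgency and visibility:

1. subspecialty match — 1 if the study's (modality, body part) is in the
   reader's subspecialty;
2. fraction of the reader's pool within their subspecialty;
3. number of past-deadline studies in the reader's pool;
4. the study's signed lateness (hours);
5. the study's associated subspecialty scarcity — fraction of all
   readers holding it as a subspecialty;
6. time left until the deadline (hours, clipped at 0);
7. number of readers the study is currently exposed to.
"""

from __future__ import annotations

from lba.ranking import FeatureVector
from lba.radiology.state import ExposureState

__all__ = ["RAD_SCHEMA", "RAD_DIM", "featurize_rad_pair"]

RAD_SCHEMA = "radiology/v1"
RAD_DIM = 7


def featurize_rad_pair(sid: str, rid: str, state: ExposureState) -> FeatureVector:
    s = state.study(sid)
    r = state.reader(rid)
    pool = state.pools[rid]
    v = [0.0] * RAD_DIM
    v[0] = 1.0 if s.mb in r.subspecialty else 0.0
    if pool:
        v[1] = sum(state.study(p).mb in r.subspecialty for p in pool) / len(pool)
        v[2] = float(sum(state.lateness_hours(p) > 0 for p in pool))
    lat = state.lateness_hours(sid)
    v[3] = lat
    nread = len(state.scenario.readers)
    v[4] = sum(s.mb in rr.subspecialty for rr in state.scenario.readers) / nread
    v[5] = max(0.0, -lat)
    v[6] = float(state.exposure_count(sid))
    return FeatureVector(v, RAD_SCHEMA)
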