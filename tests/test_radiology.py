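"""Radiology domain: reading times, quantal choice, utilities, the
exponential lateness loss, bins, exposure policies and the simulator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lba.radiology.scenario import (
    RadScenario,
    RadScenarioConfig,
    Reader,
    ReadTimeModel,
    Study,
    choice_probabilities,
    estimate_utilities,
    generate_radiology_scenario,
    reading_time,
)
from lba.radiology.loss import LatenessReport, bin_lateness, study_loss, total_loss
from lba.radiology.features import RAD_DIM, RAD_SCHEMA, featurize_rad_pair
from lba.radiology.policies import DNNExposurePolicy, HPolicy, NaivePolicy, h_exposure_group
from lba.radiology.simulate import simulate_reading_room
from lba.radiology.state import ExposureState
from lba.ranking import random_comparator


def study(i=0, m="CT", b="head", deadline=60.0, arrival=0.0):
    return Study(id=f"s{i}", modality=m, body_part=b, deadline=deadline, arrival=arrival)


def reader(j=0, subs=(("CT", "head"),), util=None):
    return Reader(id=f"r{j}", subspecialty=frozenset(subs), utility=util or {})


def tiny_scenario(studies, readers, k=10, rt=None):
    return RadScenario(studies=studies, readers=readers,
                       read_time=rt or ReadTimeModel(), k=k, seed=0)


class TestReadingTime:
    def test_in_subspecialty_nominal(self):
        assert reading_time(reader(), study(), ReadTimeModel()) == 3.0

    def test_out_of_subspecialty_scaled(self):
        assert reading_time(reader(subs=(("MRI", "spine"),)), study(),
                            ReadTimeModel()) == 9.0

    def test_rho_near_one_limit(self):
        rt = ReadTimeModel(rho=1.0 + 1e-9)
        t_in = reading_time(reader(), study(), rt)
        t_out = reading_time(reader(subs=(("MRI", "spine"),)), study(), rt)
        assert t_out == pytest.approx(t_in, rel=1e-8)

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError):
            ReadTimeModel(rho=0.9)


class TestQuantalResponse:
    def test_equal_utilities_uniform(self):
        r = reader(util={("CT", "head"): 0.2})
        pool = [study(i) for i in range(4)]
        assert np.allclose(choice_probabilities(r, pool), 0.25)

    def test_singleton_pool(self):
        assert choice_probabilities(reader(), [study()])[0] == 1.0

    def test_softmax_value(self):
        r = reader(util={("CT", "head"): 1.0, ("MRI", "spine"): 0.0})
        pool = [study(0, "CT", "head"), study(1, "MRI", "spine")]
        p = choice_probabilities(r, pool)
        assert p[0] == pytest.approx(np.e / (np.e + 1), abs=1e-12)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            choice_probabilities(reader(), [])

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 1000))
    def test_normalization_and_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        types = [("CT", "head"), ("MRI", "spine"), ("US", "limb")]
        util = {t: float(rng.uniform(0, 1)) for t in types}
        r = reader(util=util)
        pool = [study(i, *types[i % 3]) for i in range(5)]
        p = choice_probabilities(r, pool)
        assert p.sum() == pytest.approx(1.0)
        # increasing the utility of study 0's type raises its probability
        util2 = dict(util)
        util2[pool[0].mb] = util[pool[0].mb] + 0.5
        p2 = choice_probabilities(reader(util=util2), pool)
        assert p2[0] > p[0]


class TestUtilityEstimation:
    def test_frequency_proxy(self):
        hist = {"r0": [("CT", "head")] * 6 + [("MRI", "spine")] * 4}
        u = estimate_utilities(hist)["r0"]
        assert u[("CT", "head")] == pytest.approx(0.6)
        assert sum(u.values()) == pytest.approx(1.0)

    def test_empty_history_warns(self):
        warnings = []
        u = estimate_utilities({"r0": []}, warn=warnings.append)
        assert u["r0"] == {} and warnings

    def test_recovers_generating_rates(self):
        """Histories sampled from a known softmax produce frequency
        estimates within 3 s.e. of the generating selection rates."""
        rng = np.random.default_rng(7)
        types = [("CT", "head"), ("MRI", "spine"), ("US", "limb")]
        logits = np.array([1.0, 0.0, -1.0])
        probs = np.exp(logits) / np.exp(logits).sum()
        n = 2000
        picks = rng.choice(3, size=n, p=probs)
        hist = {"r0": [types[i] for i in picks]}
        u = estimate_utilities(hist)["r0"]
        for t, p in zip(types, probs):
            se = np.sqrt(p * (1 - p) / n)
            assert abs(u.get(t, 0.0) - p) < 3 * se


class TestLoss:
    @pytest.mark.parametrize(
        "lateness,expected",
        [(0.0, 1.0), (-1.0, np.exp(-2)), (1.0, np.exp(2))],
    )
    def test_closed_form(self, lateness, expected):
        assert study_loss(lateness) == pytest.approx(expected, rel=1e-12)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(l=st.floats(0.5, 5), alpha=st.floats(1, 4))
    def test_superlinearity_nonnegativity(self, l, alpha):
        """exp(2l) grows super-linearly: L(a*l) >= a*L(l) wherever
        l >= ln(a)/(2(a-1)), which the tardy regime l >= 1/2 h covers for
        every a >= 1; non-negativity holds everywhere."""
        assert study_loss(alpha * l) >= alpha * study_loss(l) - 1e-9
        assert study_loss(l) >= 0 and study_loss(-l) >= 0

    def test_two_studies_one_hour_beat_one_study_two_hours(self):
        assert study_loss(1.0) + study_loss(1.0) <= study_loss(2.0)

    def test_additivity(self):
        rep = LatenessReport(lateness_hours={"a": 0.5, "b": -0.25, "c": 1.0})
        assert total_loss(rep) == pytest.approx(
            sum(study_loss(x) for x in rep.lateness_hours.values())
        )


class TestBins:
    @pytest.mark.parametrize(
        "lateness_min,expected",
        [(-5.0, "before the deadline"), (10.0, "slightly after the deadline"),
         (30.0, "late"), (50.0, "very late"), (70.0, "extremely late")],
    )
    def test_bin_assignment(self, lateness_min, expected):
        rep = LatenessReport(lateness_hours={"s": lateness_min / 60.0})
        bins = bin_lateness(rep)
        assert bins[expected] == 1.0

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(0)
        rep = LatenessReport(
            lateness_hours={f"s{i}": float(rng.normal(0, 1)) for i in range(40)}
        )
        assert sum(bin_lateness(rep).values()) == pytest.approx(1.0)


class TestGenerator:
    def test_default_counts(self):
        sc = generate_radiology_scenario(RadScenarioConfig(), 1)
        assert len(sc.readers) == 10 and len(sc.studies) == 60 and sc.k == 10

    def test_deadlines_within_range(self):
        sc = generate_radiology_scenario(RadScenarioConfig(), 2)
        lo, hi = RadScenarioConfig().deadline_range
        assert all(lo <= s.deadline <= hi for s in sc.studies)

    def test_seed_reproducible(self):
        a = generate_radiology_scenario(RadScenarioConfig(), 3)
        b = generate_radiology_scenario(RadScenarioConfig(), 3)
        assert [vars(s) for s in a.studies] == [vars(s) for s in b.studies]

    def test_empty_modalities_rejected(self):
        with pytest.raises(ValueError):
            generate_radiology_scenario(RadScenarioConfig(modalities=()), 0)


class TestExposurePolicies:
    def state_with(self, studies, readers, k=10, now=0.0):
        sc = tiny_scenario(studies, readers, k=k)
        st_ = ExposureState(scenario=sc, k=k)
        st_.time = now
        st_.pending = {s.id for s in studies if s.arrival <= now}
        return st_

    def test_naive_exposes_all_to_all(self):
        studies = [study(i) for i in range(5)]
        readers = [reader(0), reader(1, subs=(("MRI", "spine"),))]
        st_ = self.state_with(studies, readers)
        NaivePolicy().refresh(st_)
        assert all(len(st_.pools[r.id]) == 5 for r in readers)

    def test_h_interval_boundaries(self):
        """D = 3 h: subspecialists before 60 min, modality group before
        120 min, everyone afterwards."""
        s = study(deadline=180.0)
        subspec = reader(0, subs=(("CT", "head"),))
        same_modality = reader(1, subs=(("CT", "chest"),))
        other = reader(2, subs=(("MRI", "spine"),))
        st_ = self.state_with([s], [subspec, same_modality, other])
        assert h_exposure_group(st_, "s0", 30.0) == ["r0"]
        assert set(h_exposure_group(st_, "s0", 90.0)) == {"r0", "r1"}
        assert set(h_exposure_group(st_, "s0", 150.0)) == {"r0", "r1", "r2"}
        assert set(h_exposure_group(st_, "s0", 500.0)) == {"r0", "r1", "r2"}

    def test_dnn_insert_under_cap_and_replace_at_cap(self):
        model = random_comparator(RAD_SCHEMA, RAD_DIM, seed=0)
        pol = DNNExposurePolicy(model, k=2)
        studies = [study(i, deadline=60.0 + i) for i in range(4)]
        st_ = self.state_with(studies, [reader(0)], k=2)
        for s in studies[:3]:
            pol.on_arrival(st_, s.id)
        assert len(st_.pools["r0"]) == 2        # cap respected

    def test_dnn_pool_never_exceeds_k_full_simulation(self):
        model = random_comparator(RAD_SCHEMA, RAD_DIM, seed=1)
        sc = generate_radiology_scenario(RadScenarioConfig(n_studies=40), 5)

        class AuditedPolicy(DNNExposurePolicy):
            max_seen = 0

            def on_arrival(self, state, sid):
                super().on_arrival(state, sid)
                AuditedPolicy.max_seen = max(
                    AuditedPolicy.max_seen,
                    max(len(p) for p in state.pools.values()),
                )

        pol = AuditedPolicy(model, k=5)
        simulate_reading_room(pol, sc, np.random.default_rng(2), k=5)
        assert 0 < AuditedPolicy.max_seen <= 5

    def test_featurize_values(self):
        s = study(deadline=120.0)
        r = reader(0, subs=(("CT", "head"),))
        st_ = self.state_with([s], [r])
        v = featurize_rad_pair("s0", "r0", st_)
        assert len(v) == RAD_DIM
        assert v.values[0] == 1.0               # subspecialty match
        assert v.values[1] == 0.0 and v.values[2] == 0.0  # empty pool
        assert v.values[3] == pytest.approx(-2.0)         # 2 h early
        assert v.values[6] == 0.0               # not exposed yet


class TestSimulation:
    def test_single_reader_single_study_deterministic(self):
        s = study(deadline=30.0)
        sc = tiny_scenario([s], [reader(0)], k=1)
        rep = simulate_reading_room(NaivePolicy(), sc, np.random.default_rng(0), k=1)
        # read immediately for 3 minutes: lateness = (3 - 30) min
        assert rep.lateness_hours["s0"] == pytest.approx((3 - 30) / 60.0)

    def test_total_loss_matches_recomputation(self):
        sc = generate_radiology_scenario(RadScenarioConfig(n_studies=30), 9)
        rep = simulate_reading_room(HPolicy(), sc, np.random.default_rng(1))
        assert rep.total_loss == pytest.approx(
            sum(study_loss(l) for l in rep.lateness_hours.values())
        )
        assert len(rep.lateness_hours) == 30    # every study eventually read

    def test_naive_pool_exceeds_dnn_pool(self):
        model = random_comparator(RAD_SCHEMA, RAD_DIM, seed=3)
        sc = generate_radiology_scenario(RadScenarioConfig(), 11)
        rn = simulate_reading_room(NaivePolicy(), sc, np.random.default_rng(4))
        rd = simulate_reading_room(DNNExposurePolicy(model, 10), sc,
                                   np.random.default_rng(4), k=10)
        assert rn.pool_size_mean > rd.pool_size_mean
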