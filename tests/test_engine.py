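"""Event engine: ordering, determinism, accounting, and agreement with a
deterministic cohort-expectation oracle."""

import copy

import numpy as np
import pytest

from afsim import SimulationConfig, run_replication, simulate_year
from afsim.engine import effective_probability, event_stream

from conftest import make_cohort, make_risks


class TestSimulateYear:
    def test_no_probabilities_no_events_age_incremented(self):
        p = make_cohort(1, score=2, age=60.0)[0]
        rng = np.random.default_rng(0)
        event = simulate_year(p, make_risks(), year=1, rng_stream=rng)
        assert event == {}
        assert p.alive and p.age == 61.0 and p.strokes == []

    def test_certain_other_death_preempts_stroke_draw(self):
        # other-cause death is drawn first; a certain stroke never happens
        p = make_cohort(1, age=60.0)[0]
        risks = make_risks(p_isch_by_score=[1.0] * 7, q=1.0)
        event = simulate_year(p, risks, year=1,
                              rng_stream=np.random.default_rng(0))
        assert event == {"death": "other"}
        assert p.death == (1, "other") and p.strokes == []

    def test_dead_patient_rejected(self):
        p = make_cohort(1)[0]
        p.alive = False
        with pytest.raises(ValueError):
            simulate_year(p, make_risks(), 1, np.random.default_rng(0))

    def test_treatment_scales_ischaemic_risk(self):
        # rr x p closed form, with clipping above one
        assert effective_probability(np.array([0.1]), np.array([0.5]))[0] \
            == pytest.approx(0.05)
        with pytest.warns(RuntimeWarning):
            clipped = effective_probability(np.array([0.6]), np.array([2.0]))
        assert clipped[0] == 1.0

    def test_incident_stroke_raises_dynamic_score(self):
        p = make_cohort(1, score=0, age=60.0)[0]
        risks = make_risks(p_isch_by_score=[1.0] * 7)
        event = simulate_year(p, risks, 1, np.random.default_rng(0))
        assert event["stroke"] == "ischaemic"
        assert p.prior_stroke_tia and p.chads2 == 2


class TestRunReplication:
    def test_certain_other_death_ends_in_one_year(self, sim_config):
        cohort = make_cohort(50)
        res = run_replication(cohort, make_risks(q=1.0), sim_config, 0)
        assert res.final_year == 1
        end = res.snapshots["end"]
        assert end["other_deaths"] == 50 and end["strokes"] == 0

    def test_expected_strokes_binomial(self):
        # no mortality until the max-age guard; snapshot after one year
        cohort = make_cohort(2000, score=3, age=60.0)
        risks = make_risks(p_isch_by_score=[0, 0, 0, 0.1, 0, 0, 0])
        config = SimulationConfig(snapshot_years=(1,), max_age=70.0,
                                  base_seed=5)
        res = run_replication(cohort, risks, config, 0)
        observed = res.snapshots[1]["ischaemic_strokes"]
        assert abs(observed - 200) < 4 * np.sqrt(2000 * 0.1 * 0.9)

    def test_same_seed_identical_result(self, sim_config):
        cohort = make_cohort(100, score=2, age=70.0)
        risks = make_risks(p_isch_by_score=[0.05] * 7, p_haem=0.01,
                           cf_isch=0.2, cf_haem=0.4, q=0.08)
        a = run_replication(cohort, risks, sim_config, 3)
        b = run_replication(cohort, risks, sim_config, 3)
        assert a.snapshots == b.snapshots
        c = run_replication(cohort, risks, sim_config, 4)
        assert c.snapshots != a.snapshots

    def test_input_cohort_not_mutated(self, sim_config):
        cohort = make_cohort(20, age=80.0)
        before = copy.deepcopy([(p.age, p.alive) for p in cohort])
        run_replication(cohort, make_risks(q=0.5), sim_config, 0)
        assert [(p.age, p.alive) for p in cohort] == before

    def test_accounting_identity_and_monotonicity(self, sim_config):
        cohort = make_cohort(300, score=2, age=72.0, treatment="warfarin")
        risks = make_risks(p_isch_by_score=[0.04] * 7, p_haem=0.005,
                           rr_isch={"none": 1, "warfarin": 0.36, "noac": 0.31},
                           cf_isch=0.2, cf_haem=0.45, q=0.06)
        res = run_replication(cohort, risks, sim_config, 1)
        end = res.snapshots["end"]
        assert end["stroke_deaths"] + end["other_deaths"] == 300
        order = [1, 5, 10, "end"]
        for out in ("ischaemic_strokes", "haemorrhagic_strokes",
                    "stroke_deaths", "other_deaths", "strokes", "deaths"):
            vals = [res.snapshots[s][out] for s in order]
            assert vals == sorted(vals)

    def test_empty_cohort_rejected(self, sim_config):
        with pytest.raises(ValueError):
            run_replication([], make_risks(), sim_config, 0)


class TestScalarVectorEquivalence:
    def test_vectorised_engine_matches_scalar_reference(self):
        """The array engine and the per-patient reference path consume the
        same stream and must produce identical event histories."""
        cohort = make_cohort(25, score=2, age=72.0, treatment="warfarin") \
            + make_cohort(15, score=4, age=80.0, treatment="none")
        for i, p in enumerate(cohort):
            p.id = i
        risks = make_risks(p_isch_by_score=[0.02 * s for s in range(7)],
                           p_haem=0.01,
                           rr_isch={"none": 1, "warfarin": 0.4, "noac": 0.3},
                           rr_haem={"none": 1, "warfarin": 2.0, "noac": 1.2},
                           cf_isch=0.25, cf_haem=0.5, q=0.10)
        config = SimulationConfig(snapshot_years=(2, 5), max_age=95.0,
                                  base_seed=17)
        vec = run_replication(cohort, risks, config, 0)

        scalar = copy.deepcopy(cohort)
        rng = event_stream(config.base_seed, 0)
        year = 0
        while any(p.alive for p in scalar):
            year += 1
            for p in scalar:
                if p.alive:
                    simulate_year(p, risks, year, rng,
                                  dynamic_score=config.dynamic_score,
                                  max_age=config.max_age)
                else:
                    rng.random(4)  # stream protocol: 4 draws per patient-year
        assert year == vec.final_year
        end = vec.snapshots["end"]
        assert end["ischaemic_strokes"] == sum(
            t == "ischaemic" for p in scalar for (_, t) in p.strokes)
        assert end["haemorrhagic_strokes"] == sum(
            t == "haemorrhagic" for p in scalar for (_, t) in p.strokes)
        assert end["stroke_deaths"] == sum(
            p.death[1] == "stroke" for p in scalar)
        assert end["other_deaths"] == sum(
            p.death[1] == "other" for p in scalar)


def cohort_expectation(p0, p1, ph, cf_i, cf_h, q, years):
    """Deterministic Markov cohort oracle for a homogeneous cohort of mass 1:
    state a = alive without in-simulation stroke (ischaemic prob p0),
    state b = alive after a stroke (prob p1 via the raised score).
    Returns expected cumulative (ischaemic, haemorrhagic, stroke deaths,
    other deaths) per person after ``years`` years, mirroring the engine's
    draw order: other-cause death, then one stroke, then case fatality."""
    a, b = 1.0, 0.0
    e = {"isch": 0.0, "haem": 0.0, "stroke_death": 0.0, "other_death": 0.0}
    for _ in range(years):
        e["other_death"] += (a + b) * q
        isch = (a * p0 + b * p1) * (1 - q)
        haem = (a * (1 - p0) + b * (1 - p1)) * ph * (1 - q)
        e["isch"] += isch
        e["haem"] += haem
        e["stroke_death"] += isch * cf_i + haem * cf_h
        survivors_to_b = isch * (1 - cf_i) + haem * (1 - cf_h)
        a = a * (1 - q) * (1 - p0) * (1 - ph)
        b = b * (1 - q) * (1 - p1) * (1 - ph) + survivors_to_b
    return e


class TestCohortExpectationOracle:
    def test_engine_mean_matches_markov_oracle(self):
        """Monte-Carlo mean of the stochastic engine equals the deterministic
        cohort-expectation calculation within sampling error."""
        n, years, reps = 400, 8, 120
        p_by_score = [0.08, 0.0, 0.15, 0.0, 0.0, 0.0, 0.0]
        ph, cf_i, cf_h, q = 0.02, 0.3, 0.5, 0.07
        # all flags false, age 60: score 0 before a stroke, 2 after
        cohort = make_cohort(n, score=0, age=60.0)
        risks = make_risks(p_isch_by_score=p_by_score, p_haem=ph,
                           cf_isch=cf_i, cf_haem=cf_h, q=q)
        config = SimulationConfig(snapshot_years=(years,), max_age=75.0,
                                  base_seed=2024)
        samples = {k: [] for k in ("isch", "haem", "stroke_death",
                                   "other_death")}
        for r in range(reps):
            res = run_replication(cohort, risks, config, r)
            snap = res.snapshots[years]
            samples["isch"].append(snap["ischaemic_strokes"])
            samples["haem"].append(snap["haemorrhagic_strokes"])
            samples["stroke_death"].append(snap["stroke_deaths"])
            samples["other_death"].append(snap["other_deaths"])
        expected = cohort_expectation(p_by_score[0], p_by_score[2], ph,
                                      cf_i, cf_h, q, years)
        for key, vals in samples.items():
            vals = np.array(vals, dtype=float)
            se = vals.std(ddof=1) / np.sqrt(reps)
            assert abs(vals.mean() - n * expected[key]) < 4.5 * se, key
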