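"""Shared fixtures: toy risk/cost/DALY models and small cohorts."""

import numpy as np
import pandas as pd
import pytest

from afsim import (AllocationTable, CostModel, DalyModel, Patient, PointCost,
                   PopulationSpec, RiskModel, SimulationConfig, TriangularCost)


def flat_life_table(q: float) -> pd.DataFrame:
    """Constant annual other-cause death probability at all ages below 110."""
    rows = []
    for sex in ("male", "female"):
        rows.append({"age_band": "0-109", "sex": sex, "q": q})
        rows.append({"age_band": "110+", "sex": sex, "q": 1.0})
    return pd.DataFrame(rows)


def make_risks(p_isch_by_score=None, p_haem=0.0, rr_isch=None, rr_haem=None,
               cf_isch=0.0, cf_haem=0.0, q=0.0) -> RiskModel:
    return RiskModel(
        p_ischaemic_by_score=np.array(
            p_isch_by_score if p_isch_by_score is not None else [0.0] * 7),
        p_haemorrhagic_base=p_haem,
        rr_ischaemic=rr_isch or {"none": 1.0, "warfarin": 1.0, "noac": 1.0},
        rr_haemorrhagic=rr_haem or {"none": 1.0, "warfarin": 1.0, "noac": 1.0},
        case_fatality={"ischaemic": cf_isch, "haemorrhagic": cf_haem},
        life_table=flat_life_table(q))


def make_cohort(n: int, score: int = 0, treatment: str = "none",
                age: float = 60.0, sex: str = "male") -> list:
    """Homogeneous cohort with flags chosen to be consistent with the score
    (prior-stroke point only used for scores >= 2 when needed)."""
    flags = {"chf": False, "hypertension": False, "diabetes": False,
             "prior_stroke_tia": False}
    residual = score - (1 if age >= 75 else 0)
    order = ["chf", "hypertension", "diabetes"]
    if residual >= 2 and residual > len(order):
        flags["prior_stroke_tia"] = True
        residual -= 2
    for name in order[:residual]:
        flags[name] = True
    return [Patient(id=i, age=age, sex=sex, chads2=score, treatment=treatment,
                    **flags) for i in range(n)]


def make_costs(none=0.0, warfarin=100.0, noac=200.0, acute_isch=1000.0,
               acute_haem=2000.0, death=50.0, **kw) -> CostModel:
    def dist(v):
        return v if isinstance(v, (PointCost, TriangularCost)) else PointCost(v)
    return CostModel(annual_treatment_cost={"none": dist(none),
                                            "warfarin": dist(warfarin),
                                            "noac": dist(noac)},
                     acute_cost={"ischaemic": acute_isch,
                                 "haemorrhagic": acute_haem},
                     stroke_death_cost=death, **kw)


def make_dalys(w_isch=0.3, w_haem=0.5, max_age=120, slope=0.5,
               yll_all_cause=False) -> DalyModel:
    ages = np.arange(0, max_age + 1)
    residual = (max_age - ages) * slope + 0.5
    return DalyModel(disability_weight={"ischaemic": w_isch,
                                        "haemorrhagic": w_haem},
                     reference_life_expectancy=pd.DataFrame(
                         {"age": ages, "residual_years": residual}),
                     yll_all_cause=yll_all_cause)


@pytest.fixture
def sim_config():
    return SimulationConfig(snapshot_years=(1, 5, 10), max_age=110.0,
                            n_replications=3, base_seed=99)


@pytest.fixture
def small_table():
    return AllocationTable(np.array([[3, 2, 1], [4, 0, 2], [5, 3, 3],
                                     [2, 2, 2], [1, 1, 0], [0, 1, 1],
                                     [0, 0, 1]]))


@pytest.fixture
def pop_spec():
    return PopulationSpec(size=0, male_fraction=0.6, age_mean=75.6,
                          age_sd=11.89, age_min=0, age_max=103,
                          mode="table_exact")
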