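"""Annual-cycle stochastic event engine.

Each replication simulates every patient year by year until the whole cohort
has died. Within a year the draw order is fixed: other-cause death first
(from the life table), then at most one stroke (ischaemic risk graded by
CHADS2 score and scaled by the treatment's relative risk; haemorrhagic risk
treatment-dependent), then case fatality given a stroke. An incident stroke
sets the prior-stroke flag, which raises the CHADS2 score in subsequent years
when dynamic scoring is on (as does crossing age 75).

Random-number protocol: the event stream consumes exactly four uniforms per
patient per simulated year, in patient order, whether or not the patient is
alive and whatever their treatment. Streams are derived from
(base_seed, replication index, purpose), so two scenarios run under common
random numbers see identical draws and differ only through treatment effects.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .outcomes import CostModel, DalyModel
from .population import Patient, TREATMENTS, compute_chads2

log = logging.getLogger(__name__)

_STREAM_EVENTS = 0
_STREAM_COSTS = 1

COUNT_OUTPUTS = ("ischaemic_strokes", "haemorrhagic_strokes", "strokes",
                 "stroke_deaths", "other_deaths", "deaths")
COST_OUTPUTS = ("cost_treatment", "cost_acute", "cost_stroke_death", "cost_total")
DALY_OUTPUTS = ("yll", "yld", "dalys")
OUTPUTS = COUNT_OUTPUTS + COST_OUTPUTS + DALY_OUTPUTS


def event_stream(base_seed: int, rep_index: int, purpose: int = _STREAM_EVENTS,
                 extra: Sequence[int] = ()) -> np.random.Generator:
    """Named random stream for one (replication, purpose) pair."""
    return np.random.default_rng(
        np.random.SeedSequence([int(base_seed), int(rep_index), int(purpose),
                                *[int(e) for e in extra]]))


def _parse_age_band(band: str) -> tuple:
    band = str(band).strip()
    if band.endswith("+"):
        lo = int(band[:-1])
        return lo, None
    lo, hi = band.split("-")
    return int(lo), int(hi)


@dataclass
class RiskModel:
    """Annual event probabilities and treatment relative risks.

    ``p_ischaemic_by_score`` gives the untreated annual ischaemic stroke
    probability per CHADS2 score 0-6; treatment scales it by ``rr_ischaemic``.
    Haemorrhagic risk is treatment- but not score-dependent unless a per-score
    override is supplied. The life table gives annual other-cause death
    probability by age band and sex (bands like ``"70-74"``, top band
    ``"110+"``). The major-bleed hook is structural only and disabled unless
    both its fields are supplied.
    """

    p_ischaemic_by_score: np.ndarray
    p_haemorrhagic_base: float
    rr_ischaemic: dict
    rr_haemorrhagic: dict
    case_fatality: dict  # {"ischaemic": p, "haemorrhagic": p}
    life_table: pd.DataFrame  # columns: age_band, sex, q
    p_haemorrhagic_by_score: Optional[np.ndarray] = None
    p_major_bleed: Optional[float] = None
    rr_major_bleed: Optional[dict] = None

    def validate(self) -> None:
        p = np.asarray(self.p_ischaemic_by_score, dtype=float)
        if p.shape != (7,):
            raise ValueError("risk.ischaemic_by_score: need 7 values (scores 0-6)")
        if ((p < 0) | (p > 1)).any():
            raise ValueError("risk.ischaemic_by_score: probabilities must be in [0, 1]")
        if not 0.0 <= self.p_haemorrhagic_base <= 1.0:
            raise ValueError("risk.haemorrhagic_base: must be in [0, 1]")
        if self.p_haemorrhagic_by_score is not None:
            ph = np.asarray(self.p_haemorrhagic_by_score, dtype=float)
            if ph.shape != (7,) or ((ph < 0) | (ph > 1)).any():
                raise ValueError("risk.haemorrhagic_by_score: need 7 probabilities in [0, 1]")
        for name, rr in (("rr_ischaemic", self.rr_ischaemic),
                         ("rr_haemorrhagic", self.rr_haemorrhagic)):
            for t in TREATMENTS:
                if t not in rr:
                    raise ValueError(f"risk.{name}.{t}: missing")
                if rr[t] <= 0:
                    raise ValueError(f"risk.{name}.{t}: relative risk must be > 0")
        for typ in ("ischaemic", "haemorrhagic"):
            cf = self.case_fatality.get(typ)
            if cf is None or not 0.0 <= cf <= 1.0:
                raise ValueError(f"risk.case_fatality.{typ}: must be in [0, 1]")
        for col in ("age_band", "sex", "q"):
            if col not in self.life_table.columns:
                raise ValueError(f"risk.life_table: missing column {col!r}")
        if ((self.life_table["q"] < 0) | (self.life_table["q"] > 1)).any():
            raise ValueError("risk.life_table.q: probabilities must be in [0, 1]")

    def haemorrhagic_by_score(self) -> np.ndarray:
        if self.p_haemorrhagic_by_score is not None:
            return np.asarray(self.p_haemorrhagic_by_score, dtype=float)
        return np.full(7, float(self.p_haemorrhagic_base))

    def q_arrays(self, max_age: int) -> np.ndarray:
        """Other-cause annual death probability by (sex, integer age).

        Returns shape (2, max_age+1): row 0 male, row 1 female. Ages beyond
        the top band inherit its q.
        """
        q = np.full((2, max_age + 1), np.nan)
        for _, row in self.life_table.iterrows():
            lo, hi = _parse_age_band(row["age_band"])
            hi = max_age if hi is None else min(int(hi), max_age)
            sex_idx = 0 if str(row["sex"]).lower().startswith("m") else 1
            if lo <= max_age:
                q[sex_idx, lo:hi + 1] = float(row["q"])
        if np.isnan(q).any():
            missing = int(np.argwhere(np.isnan(q))[0][1])
            raise ValueError(f"risk.life_table: no q for age {missing}")
        return q

    def other_cause_q(self, age: float, sex: str) -> float:
        a = int(age)
        for _, row in self.life_table.iterrows():
            lo, hi = _parse_age_band(row["age_band"])
            sex_match = str(row["sex"]).lower()[0] == sex.lower()[0]
            if sex_match and a >= lo and (hi is None or a <= hi):
                return float(row["q"])
        raise ValueError(f"risk.life_table: no q for age {a}, sex {sex}")


def effective_probability(base: np.ndarray, rr: np.ndarray,
                          context: str = "") -> np.ndarray:
    """rr x base, clipped to [0, 1] with a warning when clipping occurs."""
    p = np.asarray(base, dtype=float) * np.asarray(rr, dtype=float)
    if (p > 1.0).any():
        warnings.warn(f"effective {context} probability exceeds 1 and was clipped",
                      RuntimeWarning, stacklevel=2)
    return np.clip(p, 0.0, 1.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Run control: 1-year cycle, snapshots, replication and stream settings."""

    snapshot_years: tuple = (1, 5, 10)
    max_age: float = 110.0
    n_replications: int = 50
    base_seed: int = 12345
    crn: bool = True           # common random numbers across scenarios
    dynamic_score: bool = True  # recompute CHADS2 as age/strokes accumulate
    recurrent_strokes: bool = True
    record_histories: bool = False

    def validate(self) -> None:
        if any(int(y) <= 0 for y in self.snapshot_years):
            raise ValueError("simulation.snapshot_years: must be positive")
        if self.n_replications < 1:
            raise ValueError("simulation.n_replications: must be >= 1")
        if self.base_seed < 0:
            raise ValueError("simulation.base_seed: must be >= 0")
        if self.max_age <= 0:
            raise ValueError("simulation.max_age: must be > 0")


@dataclass
class ReplicationResult:
    """Cumulative outputs of one replication, per snapshot year and at the end."""

    snapshots: dict            # {year or "end": {output: value}}
    final_year: int
    seed_key: tuple
    guard_activated: bool = False
    histories: Optional[list] = None

    def value(self, output: str, snapshot) -> float:
        return self.snapshots[snapshot][output]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"snapshot": str(snap), "output": k, "value": v}
                for snap, rec in self.snapshots.items() for k, v in rec.items()]
        return pd.DataFrame(rows)


def simulate_year(patient: Patient, risks: RiskModel, year: int,
                  rng_stream: np.random.Generator, *,
                  dynamic_score: bool = True, recurrent_strokes: bool = True,
                  max_age: Optional[float] = None) -> dict:
    """Advance one patient one year; scalar reference path of the engine.

    Consumes exactly four uniforms (other-cause death, ischaemic stroke,
    haemorrhagic stroke, case fatality) and mutates the patient in place.
    Returns an event record, empty when nothing happened.
    """
    if not patient.alive:
        raise ValueError("simulate_year called on a dead patient")
    u = rng_stream.random(4)

    q = 1.0 if (max_age is not None and patient.age >= max_age) \
        else risks.other_cause_q(patient.age, patient.sex)
    if u[0] < q:
        patient.alive = False
        patient.death = (year, "other")
        return {"death": "other"}

    score = patient.chads2 if not dynamic_score else compute_chads2(
        patient.chf, patient.hypertension, patient.diabetes,
        patient.prior_stroke_tia, patient.age)
    treat = patient.treatment
    event: dict = {}
    eligible = recurrent_strokes or not patient.strokes
    p_isch = float(effective_probability(
        np.array([risks.p_ischaemic_by_score[score]]),
        np.array([risks.rr_ischaemic[treat]]), "ischaemic")[0])
    p_haem = float(effective_probability(
        np.array([risks.haemorrhagic_by_score()[score]]),
        np.array([risks.rr_haemorrhagic[treat]]), "haemorrhagic")[0])

    stroke_type = None
    if eligible and u[1] < p_isch:
        stroke_type = "ischaemic"
    elif eligible and u[2] < p_haem:
        stroke_type = "haemorrhagic"

    if stroke_type is not None:
        patient.strokes.append((year, stroke_type))
        patient.prior_stroke_tia = True
        event["stroke"] = stroke_type
        if u[3] < risks.case_fatality[stroke_type]:
            patient.alive = False
            patient.death = (year, "stroke")
            event["death"] = "stroke"
            return event

    patient.age += 1.0
    if dynamic_score:
        patient.refresh_chads2()
    return event


def run_replication(cohort: Sequence[Patient], risks: RiskModel,
                    config: SimulationConfig, rep_index: int,
                    cost_model: Optional[CostModel] = None,
                    daly_model: Optional[DalyModel] = None, *,
                    stream_key: Sequence[int] = ()) -> ReplicationResult:
    """Run one replication to extinction of the cohort (vectorised).

    The input cohort is not mutated. Deterministic given
    (config.base_seed, rep_index, stream_key).
    """
    n = len(cohort)
    if n == 0:
        raise ValueError("run_replication needs a nonempty cohort")
    if any(not p.alive for p in cohort):
        raise ValueError("run_replication needs an all-alive cohort")
    config.validate()
    risks.validate()

    rng_events = event_stream(config.base_seed, rep_index, _STREAM_EVENTS, stream_key)
    rng_costs = event_stream(config.base_seed, rep_index, _STREAM_COSTS, stream_key)

    age = np.array([p.age for p in cohort], dtype=float)
    entry_age = age.copy()
    sex_code = np.array([0 if p.sex == "male" else 1 for p in cohort], dtype=np.int64)
    chf = np.array([p.chf for p in cohort], dtype=bool)
    htn = np.array([p.hypertension for p in cohort], dtype=bool)
    dm = np.array([p.diabetes for p in cohort], dtype=bool)
    pstk = np.array([p.prior_stroke_tia for p in cohort], dtype=bool)
    score_static = np.array([p.chads2 for p in cohort], dtype=np.int64)
    treat_code = np.array([TREATMENTS.index(p.treatment) for p in cohort],
                          dtype=np.int64)
    alive = np.ones(n, dtype=bool)

    max_age_int = int(np.ceil(config.max_age)) + 1
    q_by_sex_age = risks.q_arrays(max_age_int)
    p_isch_by_score = np.asarray(risks.p_ischaemic_by_score, dtype=float)
    p_haem_by_score = risks.haemorrhagic_by_score()
    rr_isch = np.array([risks.rr_ischaemic[t] for t in TREATMENTS])
    rr_haem = np.array([risks.rr_haemorrhagic[t] for t in TREATMENTS])
    cf_isch = float(risks.case_fatality["ischaemic"])
    cf_haem = float(risks.case_fatality["haemorrhagic"])

    price = None
    if cost_model is not None:
        cost_model.validate()
        dists = [cost_model.annual_treatment_cost[t] for t in TREATMENTS]
        if cost_model.sample_once_per_patient:
            # one uniform per patient, transformed through that patient's
            # treatment price distribution -- aligned across scenarios
            u_price = rng_costs.random(n)
            price = np.empty(n)
            for j, dist in enumerate(dists):
                mask = treat_code == j
                price[mask] = dist.ppf(u_price[mask])
        acute_isch = float(cost_model.acute_cost["ischaemic"])
        acute_haem = float(cost_model.acute_cost["haemorrhagic"])
    if daly_model is not None:
        daly_model.validate()
        w_isch = float(daly_model.disability_weight["ischaemic"])
        w_haem = float(daly_model.disability_weight["haemorrhagic"])

    had_isch = np.zeros(n, dtype=bool)
    had_haem = np.zeros(n, dtype=bool)

    cums = {k: 0.0 for k in OUTPUTS}
    snapshots: dict = {}
    histories = None
    if config.record_histories:
        histories = [{"treatment": TREATMENTS[treat_code[i]],
                      "entry_age": float(entry_age[i]), "strokes": [],
                      "death": None,
                      "price": None if price is None else float(price[i])}
                     for i in range(n)]

    guard = False
    year = 0
    snapshot_years = sorted(int(y) for y in config.snapshot_years)

    def record():
        rec = dict(cums)
        rec["strokes"] = rec["ischaemic_strokes"] + rec["haemorrhagic_strokes"]
        rec["deaths"] = rec["stroke_deaths"] + rec["other_deaths"]
        rec["cost_total"] = (rec["cost_treatment"] + rec["cost_acute"]
                             + rec["cost_stroke_death"])
        rec["dalys"] = rec["yll"] + rec["yld"]
        return rec

    while alive.any():
        year += 1
        u = rng_events.random((n, 4))

        if cost_model is not None:
            if not cost_model.sample_once_per_patient:
                u_price = rng_costs.random(n)
                price = np.empty(n)
                for j, dist in enumerate(dists):
                    mask = treat_code == j
                    price[mask] = dist.ppf(u_price[mask])
            cums["cost_treatment"] += float(price[alive].sum())

        ages_int = np.clip(age.astype(np.int64), 0, max_age_int)
        q = q_by_sex_age[sex_code, ages_int]
        over = age >= config.max_age
        if (over & alive).any() and not guard:
            guard = True
            log.info("max-age guard activated in year %d", year)
        q = np.where(over, 1.0, q)
        die_other = alive & (u[:, 0] < q)

        at_risk = alive & ~die_other
        if config.dynamic_score:
            score = (chf.astype(np.int64) + htn.astype(np.int64)
                     + dm.astype(np.int64) + 2 * pstk.astype(np.int64)
                     + (age >= 75).astype(np.int64))
        else:
            score = score_static
        p_i = effective_probability(p_isch_by_score[score], rr_isch[treat_code],
                                    "ischaemic")
        p_h = effective_probability(p_haem_by_score[score], rr_haem[treat_code],
                                    "haemorrhagic")
        eligible = at_risk if config.recurrent_strokes \
            else (at_risk & ~(had_isch | had_haem))
        isch = eligible & (u[:, 1] < p_i)
        haem = eligible & ~isch & (u[:, 2] < p_h)
        stroke = isch | haem
        cf = np.where(isch, cf_isch, cf_haem)
        die_stroke = stroke & (u[:, 3] < cf)

        cums["ischaemic_strokes"] += int(isch.sum())
        cums["haemorrhagic_strokes"] += int(haem.sum())
        cums["stroke_deaths"] += int(die_stroke.sum())
        cums["other_deaths"] += int(die_other.sum())
        if cost_model is not None:
            cums["cost_acute"] += float(isch.sum() * acute_isch
                                        + haem.sum() * acute_haem)
            cums["cost_stroke_death"] += float(die_stroke.sum()
                                               * cost_model.stroke_death_cost)
        if daly_model is not None:
            dead_yll = die_stroke | (die_other if daly_model.yll_all_cause
                                     else np.zeros(n, dtype=bool))
            if dead_yll.any():
                cums["yll"] += float(daly_model.residual(age[dead_yll]).sum())

        if histories is not None:
            for i in np.nonzero(isch)[0]:
                histories[i]["strokes"].append((year, "ischaemic"))
            for i in np.nonzero(haem)[0]:
                histories[i]["strokes"].append((year, "haemorrhagic"))
            for i in np.nonzero(die_other)[0]:
                histories[i]["death"] = (year, "other")
            for i in np.nonzero(die_stroke)[0]:
                histories[i]["death"] = (year, "stroke")

        # disability accrues at the end of each year lived after a stroke,
        # at the maximum weight among stroke types suffered in earlier years
        if daly_model is not None:
            w_pre = np.maximum(np.where(had_isch, w_isch, 0.0),
                               np.where(had_haem, w_haem, 0.0))
        had_stroke_pre = had_isch | had_haem

        had_isch |= isch
        had_haem |= haem
        pstk |= stroke
        alive = alive & ~die_other & ~die_stroke

        if daly_model is not None:
            mask = alive & had_stroke_pre
            if mask.any():
                cums["yld"] += float(w_pre[mask].sum())
        age[alive] += 1.0

        if year in snapshot_years:
            snapshots[year] = record()

    final = record()
    for y in snapshot_years:
        if y not in snapshots:
            snapshots[y] = dict(final)
    snapshots["end"] = final

    return ReplicationResult(snapshots=snapshots, final_year=year,
                             seed_key=(int(config.base_seed), int(rep_index),
                                       *[int(e) for e in stream_key]),
                             guard_activated=guard, histories=histories)
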