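"""Configuration loading and validation, packaged fixtures, run manifests.

A full model configuration is a directory holding ``config.yaml`` plus CSV
side tables (allocation table, per-score ischaemic risk, life table,
reference life expectancy). Everything a run needs is user-supplied config;
the packaged defaults are a clearly-labelled literature-derived fixture, not
built-in truth.
"""

from __future__ import annotations

import copy
import datetime
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .engine import RiskModel, SimulationConfig
from .outcomes import CostModel, DalyModel, PointCost, TriangularCost
from .population import AllocationTable, N_SCORES, PopulationSpec, TREATMENTS
from .scenarios import DEFAULT_RETAINED_UNTREATED, ScenarioSpec


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending field path."""


class MissingTableError(ConfigError):
    """A referenced CSV side table is absent."""


class ProbabilityRangeError(ConfigError):
    """A probability lies outside [0, 1]."""


class MalformedTriangleError(ConfigError):
    """A triangular cost violates min <= mode <= max."""


# ---------------------------------------------------------------------------
# Reference experiment tables (printed scenario allocations, kept verbatim)
# ---------------------------------------------------------------------------
# Columns: none (NT), warfarin, noac; one row per CHADS2 score 0-6.
REFERENCE_ALLOCATIONS = {
    "S0": ((904, 322, 360), (747, 912, 726), (693, 1174, 894), (402, 760, 582),
           (233, 503, 437), (107, 190, 178), (17, 29, 25)),
    "S1": ((904, 322, 360), (747, 912, 726), (64, 1803, 894), (37, 1125, 582),
           (21, 715, 437), (10, 287, 178), (1, 45, 25)),
    "S2": ((904, 322, 360), (747, 912, 726), (64, 1174, 1523), (37, 760, 947),
           (21, 503, 649), (10, 190, 275), (1, 29, 41)),
    "S3": ((904, 322, 360), (747, 912, 726), (64, 1531, 1166), (37, 967, 740),
           (21, 616, 535), (10, 240, 225), (1, 38, 32)),
}

FIXTURE_NAMES = ("table2_baseline", "table2_s1", "table2_s2", "table2_s3",
                 "toy_smoke")


def reference_allocation(name: str = "S0") -> AllocationTable:
    return AllocationTable(np.array(REFERENCE_ALLOCATIONS[name]))


# ---------------------------------------------------------------------------
# Literature-derived default parameter fixture
# ---------------------------------------------------------------------------

# Annual ischaemic stroke probability (untreated) by CHADS2 score: the
# classic registry-derived gradient 1.9% ... 18.2% per year for scores 0-6.
DEFAULT_P_ISCHAEMIC = (0.019, 0.028, 0.040, 0.059, 0.085, 0.125, 0.182)
DEFAULT_P_HAEMORRHAGIC = 0.002
# Relative risks versus no treatment (meta-analytic stroke-prevention
# effects: warfarin ~64% relative risk reduction; NOACs modestly better).
DEFAULT_RR_ISCHAEMIC = {"none": 1.0, "warfarin": 0.36, "noac": 0.31}
# Intracranial bleeding is commoner on anticoagulation, more so on warfarin.
DEFAULT_RR_HAEMORRHAGIC = {"none": 1.0, "warfarin": 2.5, "noac": 1.25}
DEFAULT_CASE_FATALITY = {"ischaemic": 0.20, "haemorrhagic": 0.45}

DEFAULT_TREATMENT_COST = {
    "none": PointCost(0.0),
    "warfarin": PointCost(290.0),  # drug plus INR monitoring, GBP/year
    "noac": TriangularCost(603.0, 670.0, 737.0),  # peak GBP 670 +/- 10%
}
DEFAULT_ACUTE_COST = {"ischaemic": 11600.0, "haemorrhagic": 13800.0}
DEFAULT_STROKE_DEATH_COST = 150.0  # in-hospital death following stroke (negligible)

DEFAULT_DISABILITY_WEIGHT = {"ischaemic": 0.27, "haemorrhagic": 0.52}

_GOMPERTZ_B = 0.095
_Q75 = {"male": 0.030, "female": 0.020}


def default_life_table() -> pd.DataFrame:
    """Gompertz-style life table in 5-year bands, calibrated to UK-like
    annual other-cause death probabilities at age 75; top band 110+ has q=1."""
    rows = []
    for sex, q75 in _Q75.items():
        a = q75 / math.exp(_GOMPERTZ_B * 75)
        for lo in range(0, 110, 5):
            mid = lo + 2.5
            q = min(0.7, a * math.exp(_GOMPERTZ_B * mid))
            rows.append({"age_band": f"{lo}-{lo + 4}", "sex": sex, "q": round(q, 6)})
        rows.append({"age_band": "110+", "sex": sex, "q": 1.0})
    return pd.DataFrame(rows)


def default_life_expectancy(life_table: Optional[pd.DataFrame] = None,
                            max_age: int = 110) -> pd.DataFrame:
    """Residual life expectancy by age, computed from the (sex-averaged)
    life table: e(a) = 0.5 + sum of survival probabilities to later ages."""
    if life_table is None:
        life_table = default_life_table()
    rm = RiskModel(np.zeros(7), 0.0, {t: 1.0 for t in TREATMENTS},
                   {t: 1.0 for t in TREATMENTS},
                   {"ischaemic": 0.0, "haemorrhagic": 0.0}, life_table)
    q = rm.q_arrays(max_age).mean(axis=0)
    ages = np.arange(0, max_age + 1)
    e = np.empty_like(ages, dtype=float)
    for a in ages:
        surv = np.cumprod(1.0 - q[a:])
        e[a] = 0.5 + surv.sum()
    return pd.DataFrame({"age": ages, "residual_years": e})


# ---------------------------------------------------------------------------
# Full configuration
# ---------------------------------------------------------------------------

@dataclass
class FullConfig:
    """Everything one experiment needs, validated as a unit."""

    population: PopulationSpec
    baseline_allocation: AllocationTable
    scenarios: dict  # name -> ScenarioSpec (baseline is implicit)
    risks: RiskModel
    costs: CostModel
    dalys: DalyModel
    sim: SimulationConfig

    def validate(self) -> "FullConfig":
        try:
            self.population.validate()
            self.risks.validate()
            self.costs.validate()
            self.dalys.validate()
            self.sim.validate()
            for name, spec in self.scenarios.items():
                spec.resolve_retained(self.baseline_allocation)
        except ConfigError:
            raise
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc
        return self

    def deepcopy(self) -> "FullConfig":
        return copy.deepcopy(self)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        def dist(d):
            if isinstance(d, TriangularCost):
                return {"triangular": [d.low, d.mode, d.high]}
            return float(d.value)

        return {
            "population": {
                "size": self.population.size,
                "male_fraction": self.population.male_fraction,
                "age_mean": self.population.age_mean,
                "age_sd": self.population.age_sd,
                "age_min": self.population.age_min,
                "age_max": self.population.age_max,
                "mode": self.population.mode,
            },
            "allocation": [list(map(int, row)) for row in
                           self.baseline_allocation.counts],
            "scenarios": {
                name: {"kind": s.kind,
                       "eligibility_min_score": s.eligibility_min_score,
                       "retained_untreated":
                           None if s.retained_untreated is None
                           else list(s.retained_untreated)}
                for name, s in self.scenarios.items()},
            "risk": {
                "ischaemic_by_score":
                    [float(p) for p in self.risks.p_ischaemic_by_score],
                "haemorrhagic_base": float(self.risks.p_haemorrhagic_base),
                "haemorrhagic_by_score":
                    None if self.risks.p_haemorrhagic_by_score is None
                    else [float(p) for p in self.risks.p_haemorrhagic_by_score],
                "rr_ischaemic": {k: float(v)
                                 for k, v in self.risks.rr_ischaemic.items()},
                "rr_haemorrhagic": {k: float(v)
                                    for k, v in self.risks.rr_haemorrhagic.items()},
                "case_fatality": {k: float(v)
                                  for k, v in self.risks.case_fatality.items()},
                "life_table": self.risks.life_table.to_dict("records"),
            },
            "costs": {
                "annual_treatment": {t: dist(d) for t, d in
                                     self.costs.annual_treatment_cost.items()},
                "acute": {k: float(v) for k, v in self.costs.acute_cost.items()},
                "stroke_death": float(self.costs.stroke_death_cost),
                "sample_once_per_patient": self.costs.sample_once_per_patient,
            },
            "dalys": {
                "disability_weight": {k: float(v) for k, v in
                                      self.dalys.disability_weight.items()},
                "life_expectancy":
                    self.dalys.reference_life_expectancy.to_dict("records"),
                "yll_all_cause": self.dalys.yll_all_cause,
            },
            "simulation": {
                "snapshot_years": list(self.sim.snapshot_years),
                "max_age": self.sim.max_age,
                "n_replications": self.sim.n_replications,
                "base_seed": self.sim.base_seed,
                "crn": self.sim.crn,
                "dynamic_score": self.sim.dynamic_score,
                "recurrent_strokes": self.sim.recurrent_strokes,
            },
        }


def config_digest(config: FullConfig) -> str:
    """SHA-256 of the canonical JSON form; stable under key reordering."""
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _parse_cost_dist(raw, path: str):
    if isinstance(raw, dict):
        if set(raw) != {"triangular"}:
            raise ConfigError(f"{path}: expected a number or "
                              f"{{triangular: [min, mode, max]}}")
        tri = raw["triangular"]
        if not (isinstance(tri, (list, tuple)) and len(tri) == 3):
            raise MalformedTriangleError(f"{path}.triangular: need [min, mode, max]")
        lo, mode, hi = (float(v) for v in tri)
        try:
            return TriangularCost(lo, mode, hi)
        except ValueError as exc:
            raise MalformedTriangleError(f"{path}.triangular: {exc}") from exc
    return PointCost(float(raw))


def _check_prob(value, path: str) -> float:
    v = float(value)
    if not 0.0 <= v <= 1.0:
        raise ProbabilityRangeError(f"{path}: probability {v} outside [0, 1]")
    return v


def config_from_dict(raw: dict) -> FullConfig:
    """Build and validate a FullConfig from its plain-dict form."""
    try:
        pop = raw["population"]
        population = PopulationSpec(
            size=int(pop["size"]), male_fraction=float(pop["male_fraction"]),
            age_mean=float(pop["age_mean"]), age_sd=float(pop["age_sd"]),
            age_min=float(pop.get("age_min", 0.0)),
            age_max=float(pop.get("age_max", 103.0)),
            mode=pop.get("mode", "table_exact"))
        allocation = AllocationTable(np.array(raw["allocation"]))
        scenarios = {}
        for name, s in (raw.get("scenarios") or {}).items():
            scenarios[name] = ScenarioSpec(
                kind=s["kind"],
                eligibility_min_score=int(s.get("eligibility_min_score", 2)),
                retained_untreated=s.get("retained_untreated"))
        risk = raw["risk"]
        p_isch = [_check_prob(v, f"risk.ischaemic_by_score[{i}]")
                  for i, v in enumerate(risk["ischaemic_by_score"])]
        haem_score = risk.get("haemorrhagic_by_score")
        risks = RiskModel(
            p_ischaemic_by_score=np.array(p_isch),
            p_haemorrhagic_base=_check_prob(risk["haemorrhagic_base"],
                                            "risk.haemorrhagic_base"),
            rr_ischaemic={k: float(v) for k, v in risk["rr_ischaemic"].items()},
            rr_haemorrhagic={k: float(v) for k, v in risk["rr_haemorrhagic"].items()},
            case_fatality={k: _check_prob(v, f"risk.case_fatality.{k}")
                           for k, v in risk["case_fatality"].items()},
            life_table=pd.DataFrame(risk["life_table"]),
            p_haemorrhagic_by_score=None if haem_score is None
            else np.array([_check_prob(v, f"risk.haemorrhagic_by_score[{i}]")
                           for i, v in enumerate(haem_score)]))
        costs_raw = raw["costs"]
        costs = CostModel(
            annual_treatment_cost={
                t: _parse_cost_dist(d, f"costs.annual_treatment.{t}")
                for t, d in costs_raw["annual_treatment"].items()},
            acute_cost={k: float(v) for k, v in costs_raw["acute"].items()},
            stroke_death_cost=float(costs_raw.get("stroke_death", 0.0)),
            sample_once_per_patient=bool(
                costs_raw.get("sample_once_per_patient", True)))
        dalys_raw = raw["dalys"]
        dalys = DalyModel(
            disability_weight={k: float(v) for k, v in
                               dalys_raw["disability_weight"].items()},
            reference_life_expectancy=pd.DataFrame(dalys_raw["life_expectancy"]),
            yll_all_cause=bool(dalys_raw.get("yll_all_cause", False)))
        sim_raw = raw.get("simulation", {})
        sim = SimulationConfig(
            snapshot_years=tuple(sim_raw.get("snapshot_years", (1, 5, 10))),
            max_age=float(sim_raw.get("max_age", 110.0)),
            n_replications=int(sim_raw.get("n_replications", 50)),
            base_seed=int(sim_raw.get("base_seed", 12345)),
            crn=bool(sim_raw.get("crn", True)),
            dynamic_score=bool(sim_raw.get("dynamic_score", True)),
            recurrent_strokes=bool(sim_raw.get("recurrent_strokes", True)))
    except KeyError as exc:
        raise ConfigError(f"missing configuration key: {exc.args[0]}") from exc
    return FullConfig(population, allocation, scenarios, risks, costs,
                      dalys, sim).validate()


def default_config(allocation: str = "S0", mode: str = "table_exact",
                   size: int = 10300, base_seed: int = 12345,
                   n_replications: int = 50) -> FullConfig:
    """The packaged reference configuration (baseline allocation + default
    literature-derived risk, cost and DALY parameters)."""
    life = default_life_table()
    cfg = FullConfig(
        population=PopulationSpec(size=size, male_fraction=0.5768,
                                  age_mean=75.60, age_sd=11.89,
                                  age_min=0.0, age_max=103.0, mode=mode),
        baseline_allocation=reference_allocation(allocation),
        scenarios={
            "all_warfarin": ScenarioSpec("all_warfarin",
                                         retained_untreated=DEFAULT_RETAINED_UNTREATED),
            "all_noac": ScenarioSpec("all_noac",
                                     retained_untreated=DEFAULT_RETAINED_UNTREATED),
            "nice_mix": ScenarioSpec("nice_mix",
                                     retained_untreated=DEFAULT_RETAINED_UNTREATED),
        },
        risks=RiskModel(
            p_ischaemic_by_score=np.array(DEFAULT_P_ISCHAEMIC),
            p_haemorrhagic_base=DEFAULT_P_HAEMORRHAGIC,
            rr_ischaemic=dict(DEFAULT_RR_ISCHAEMIC),
            rr_haemorrhagic=dict(DEFAULT_RR_HAEMORRHAGIC),
            case_fatality=dict(DEFAULT_CASE_FATALITY),
            life_table=life),
        costs=CostModel(
            annual_treatment_cost=dict(DEFAULT_TREATMENT_COST),
            acute_cost=dict(DEFAULT_ACUTE_COST),
            stroke_death_cost=DEFAULT_STROKE_DEATH_COST),
        dalys=DalyModel(
            disability_weight=dict(DEFAULT_DISABILITY_WEIGHT),
            reference_life_expectancy=default_life_expectancy(life)),
        sim=SimulationConfig(base_seed=base_seed, n_replications=n_replications),
    )
    return cfg.validate()


def toy_config(base_seed: int = 12345) -> FullConfig:
    """~100-patient smoke configuration that completes a full experiment in
    seconds; allocation is the baseline table scaled down ~1:100."""
    cfg = default_config(base_seed=base_seed, n_replications=3)
    counts = np.maximum(1, np.round(cfg.baseline_allocation.counts / 100)
                        ).astype(np.int64)
    cfg.baseline_allocation = AllocationTable(counts)
    # packaged retained-untreated defaults refer to the full-size table; use a
    # uniform retained fraction instead
    cfg.scenarios = {
        kind: ScenarioSpec.from_retained_fraction(kind, cfg.baseline_allocation, 0.1)
        for kind in ("all_warfarin", "all_noac", "nice_mix")}
    return cfg.validate()


# ---------------------------------------------------------------------------
# Disk round trip
# ---------------------------------------------------------------------------

_SIDE_TABLES = {
    "allocation": "allocation_baseline.csv",
    "ischaemic": "ischaemic_risk.csv",
    "life_table": "life_table.csv",
    "life_expectancy": "life_expectancy.csv",
}


def save_config(config: FullConfig, outdir) -> Path:
    """Write config.yaml plus CSV side tables into ``outdir``; returns the
    path to config.yaml."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    d = config.to_dict()

    config.baseline_allocation.to_csv(outdir / _SIDE_TABLES["allocation"])
    pd.DataFrame({"chads2": range(N_SCORES),
                  "p": d["risk"]["ischaemic_by_score"]}
                 ).to_csv(outdir / _SIDE_TABLES["ischaemic"], index=False)
    config.risks.life_table.to_csv(outdir / _SIDE_TABLES["life_table"], index=False)
    config.dalys.reference_life_expectancy.to_csv(
        outdir / _SIDE_TABLES["life_expectancy"], index=False)

    yaml_doc = {k: v for k, v in d.items()}
    yaml_doc["allocation"] = _SIDE_TABLES["allocation"]
    yaml_doc["risk"] = dict(d["risk"])
    yaml_doc["risk"]["ischaemic_by_score"] = _SIDE_TABLES["ischaemic"]
    yaml_doc["risk"]["life_table"] = _SIDE_TABLES["life_table"]
    yaml_doc["dalys"] = dict(d["dalys"])
    yaml_doc["dalys"]["life_expectancy"] = _SIDE_TABLES["life_expectancy"]

    path = outdir / "config.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(yaml_doc, fh, sort_keys=False)
    return path


def load_config(path) -> FullConfig:
    """Load and validate a configuration from config.yaml (CSV side-table
    references resolved relative to the YAML file)."""
    path = Path(path)
    if path.is_dir():
        path = path / "config.yaml"
    if not path.exists():
        raise MissingTableError(f"configuration file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    base = path.parent

    def read_table(ref, field_path):
        if isinstance(ref, str):
            p = base / ref
            if not p.exists():
                raise MissingTableError(f"{field_path}: table file not found: {p}")
            # round-trip parsing keeps float cells bit-identical, so a saved
            # configuration reloads with the same digest
            return pd.read_csv(p, float_precision="round_trip")
        return ref

    if isinstance(raw.get("allocation"), str):
        raw["allocation"] = AllocationTable.from_frame(
            read_table(raw["allocation"], "allocation")).counts.tolist()
    risk = raw.get("risk", {})
    if isinstance(risk.get("ischaemic_by_score"), str):
        tab = read_table(risk["ischaemic_by_score"], "risk.ischaemic_by_score")
        risk["ischaemic_by_score"] = tab.sort_values("chads2")["p"].tolist()
    if isinstance(risk.get("life_table"), str):
        risk["life_table"] = read_table(risk["life_table"],
                                        "risk.life_table").to_dict("records")
    dalys = raw.get("dalys", {})
    if isinstance(dalys.get("life_expectancy"), str):
        dalys["life_expectancy"] = read_table(
            dalys["life_expectancy"], "dalys.life_expectancy").to_dict("records")
    return config_from_dict(raw)


def make_fixture(name: str, outdir) -> Path:
    """Write a named configuration bundle to disk.

    ``table2_baseline`` and ``table2_s1``/``s2``/``s3`` carry the reference
    scenario allocation tables verbatim; ``toy_smoke`` is a ~100-patient
    configuration for fast end-to-end runs.
    """
    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    if name == "toy_smoke":
        cfg = toy_config()
    else:
        key = {"table2_baseline": "S0", "table2_s1": "S1",
               "table2_s2": "S2", "table2_s3": "S3"}[name]
        cfg = default_config(allocation=key)
        if key != "S0":
            # a scenario table is itself the baseline here; no further shifts
            cfg.scenarios = {}
    return save_config(cfg, outdir)


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Everything needed to reproduce a run bit-for-bit."""

    config_digest: str
    base_seed: int
    n_replications: int
    created: str = field(default_factory=lambda: datetime.datetime.now(
        datetime.timezone.utc).isoformat(timespec="seconds"))
    version: str = __version__

    @classmethod
    def for_run(cls, config: FullConfig, n_replications: Optional[int] = None
                ) -> "RunManifest":
        return cls(config_digest=config_digest(config),
                   base_seed=int(config.sim.base_seed),
                   n_replications=int(n_replications if n_replications is not None
                                      else config.sim.n_replications))

    def to_json(self, path=None) -> str:
        blob = json.dumps(self.__dict__, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(blob + "\n")
        return blob

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        return cls(**json.loads(text))
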