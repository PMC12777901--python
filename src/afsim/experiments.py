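"""Experiment orchestration: replication sizing, scenario comparison and
one-way sensitivity analysis.

Replication sizing follows the confidence-interval precision rule: keep
adding replications while the upper confidence bound of the running mean
differs from the previous running mean by more than a stated fraction
(default 1%). Scenario comparisons are paired under common random numbers
(the default) or use the unequal-variance two-sample interval otherwise;
confidence intervals are t-based on replication means, 95% by default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace as dc_replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .engine import (OUTPUTS, ReplicationResult, RiskModel, SimulationConfig,
                     run_replication)
from .outcomes import CostModel, DalyModel, PointCost, TriangularCost
from .population import (AllocationTable, PopulationSpec, generate_population,
                         reallocate_treatments)
from .scenarios import ScenarioSpec, apply_scenario

log = logging.getLogger(__name__)

_STREAM_POPULATION = 2

DEFAULT_INCREMENTS = tuple(round(x, 2) for x in np.arange(-0.20, 0.2001, 0.05))


class ZeroMeanError(ValueError):
    """Relative precision is undefined when the running mean is zero."""


class NotConvergedError(RuntimeError):
    """The precision rule was not met within the supplied stream."""


def min_replications(output_stream: Iterable[float], precision: float = 0.01,
                     confidence: float = 0.95, min_reps: int = 3,
                     fallback_absolute: bool = False) -> int:
    """First replication count at which the CI precision rule is met.

    Returns the smallest n >= ``min_reps`` with
    ``|upper CI bound of mean(x[:n]) - mean(x[:n-1])| / mean(x[:n-1]) < precision``.
    With ``fallback_absolute`` the comparison switches to the absolute
    difference when the previous running mean is zero; otherwise a zero mean
    raises :class:`ZeroMeanError`. Deterministic given the stream.
    """
    x = np.asarray(list(output_stream), dtype=float)
    if min_reps < 2:
        raise ValueError("min_reps must be >= 2")
    if x.size < min_reps:
        raise ValueError(f"stream yields {x.size} values; need at least {min_reps}")
    for n in range(min_reps, x.size + 1):
        m_prev = float(x[: n - 1].mean())
        m_n = float(x[:n].mean())
        s = float(x[:n].std(ddof=1))
        half = stats.t.ppf(1 - (1 - confidence) / 2, n - 1) * s / math.sqrt(n)
        diff = abs((m_n + half) - m_prev)
        if m_prev == 0.0:
            if not fallback_absolute:
                raise ZeroMeanError("running mean is zero at n="
                                    f"{n - 1}; relative precision undefined")
            if diff < precision:
                return n
        elif diff / abs(m_prev) < precision:
            return n
    raise NotConvergedError(f"precision rule not met within {x.size} replications")


def min_replications_trace(output_stream: Iterable[float],
                           confidence: float = 0.95,
                           min_reps: int = 3) -> pd.DataFrame:
    """Per-n diagnostics of the precision rule (for plotting/inspection)."""
    x = np.asarray(list(output_stream), dtype=float)
    rows = []
    for n in range(min_reps, x.size + 1):
        m_prev = float(x[: n - 1].mean())
        m_n = float(x[:n].mean())
        s = float(x[:n].std(ddof=1))
        half = stats.t.ppf(1 - (1 - confidence) / 2, n - 1) * s / math.sqrt(n)
        diff = abs((m_n + half) - m_prev)
        rows.append({"n": n, "running_mean": m_n, "ci_half_width": half,
                     "abs_diff": diff,
                     "rel_diff": diff / abs(m_prev) if m_prev else math.nan})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Experiment runner
# ---------------------------------------------------------------------------

@dataclass
class ExperimentResult:
    """Replication sets and tidy summaries for a set of scenarios."""

    scenario_tables: dict               # name -> AllocationTable
    results: dict                       # name -> [ReplicationResult]
    replications: pd.DataFrame          # scenario, output, snapshot, replication, value
    summary: pd.DataFrame               # scenario, output, snapshot, mean, sd, ci_*
    base_seed: int
    n_replications: int
    crn: bool

    def replication_values(self, scenario: str, output: str,
                           snapshot) -> np.ndarray:
        return np.array([r.value(output, snapshot)
                         for r in self.results[scenario]], dtype=float)


def replications_frame(results: Sequence[ReplicationResult],
                       scenario: str = "") -> pd.DataFrame:
    rows = []
    for i, r in enumerate(results):
        for snap, rec in r.snapshots.items():
            for out, val in rec.items():
                rows.append({"scenario": scenario, "output": out,
                             "snapshot": str(snap), "replication": i,
                             "value": float(val)})
    return pd.DataFrame(rows)


def _summarize(reps: pd.DataFrame, confidence: float = 0.95) -> pd.DataFrame:
    def agg(g: pd.DataFrame) -> pd.Series:
        v = g["value"].to_numpy(dtype=float)
        n = v.size
        mean = float(v.mean())
        if n > 1:
            sd = float(v.std(ddof=1))
            half = stats.t.ppf(1 - (1 - confidence) / 2, n - 1) * sd / math.sqrt(n)
        else:
            sd, half = math.nan, math.nan  # CI undefined with one replication
        return pd.Series({"mean": mean, "sd": sd, "n": n,
                          "ci_lower": mean - half, "ci_upper": mean + half,
                          "ci_defined": n > 1})
    out = (reps.groupby(["scenario", "output", "snapshot"], sort=False)
               .apply(agg, include_groups=False).reset_index())
    return out


def run_experiment(config, scenario_specs: Optional[dict] = None,
                   n_replications: Optional[int] = None,
                   confidence: float = 0.95) -> ExperimentResult:
    """Run the baseline and each scenario over replications.

    ``config`` is a :class:`afsim.io.FullConfig`. Every replication
    regenerates the cohort from the baseline allocation table and reallocates
    treatments per scenario, so that under common random numbers each
    scenario sees the same patients and the same event draws.
    """
    sim: SimulationConfig = config.sim
    sim.validate()
    reps = int(n_replications if n_replications is not None else sim.n_replications)
    if reps < 1:
        raise ValueError("n_replications must be >= 1")
    if scenario_specs is None:
        scenario_specs = {"baseline": ScenarioSpec("baseline"), **config.scenarios}
    elif "baseline" not in scenario_specs:
        scenario_specs = {"baseline": ScenarioSpec("baseline"), **scenario_specs}

    tables = {name: apply_scenario(config.baseline_allocation, spec)
              for name, spec in scenario_specs.items()}
    results: dict = {name: [] for name in tables}

    for r in range(reps):
        pop_rng_seed = np.random.SeedSequence(
            [int(sim.base_seed), r, _STREAM_POPULATION])
        cohort = generate_population(config.population, config.baseline_allocation,
                                     pop_rng_seed)
        for s_idx, (name, table) in enumerate(tables.items()):
            scen_cohort = reallocate_treatments(cohort, table)
            key = () if sim.crn else (s_idx + 1,)
            results[name].append(run_replication(
                scen_cohort, config.risks, sim, r,
                cost_model=config.costs, daly_model=config.dalys,
                stream_key=key))
        if (r + 1) % 10 == 0:
            log.info("completed replication %d/%d", r + 1, reps)

    frames = [replications_frame(results[name], name) for name in tables]
    rep_frame = pd.concat(frames, ignore_index=True)
    summary = _summarize(rep_frame, confidence)
    return ExperimentResult(scenario_tables=tables, results=results,
                            replications=rep_frame, summary=summary,
                            base_seed=int(sim.base_seed), n_replications=reps,
                            crn=bool(sim.crn))


# ---------------------------------------------------------------------------
# Scenario comparison
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    """Mean differences (alternative - baseline) with t-based CIs."""

    table: pd.DataFrame  # output, snapshot, mean_diff, ci_half_width, ...
    confidence: float
    paired: bool

    def row(self, output: str, snapshot) -> pd.Series:
        t = self.table
        m = t[(t["output"] == output) & (t["snapshot"] == str(snapshot))]
        return m.iloc[0]


def compare_scenarios(base: Sequence[ReplicationResult],
                      alt: Sequence[ReplicationResult],
                      confidence: float = 0.95,
                      paired: bool = True) -> ComparisonResult:
    """Compare two replication sets per output and snapshot.

    Paired mode (requires equal replication counts, appropriate under common
    random numbers) builds the CI on per-replication differences; unpaired
    mode uses the Welch unequal-variance interval.
    """
    if not base or not alt:
        raise ValueError("both replication sets must be nonempty")
    if paired and len(base) != len(alt):
        raise ValueError("paired comparison needs equal replication counts")
    snapshots = list(base[0].snapshots.keys())
    rows = []
    for out in OUTPUTS:
        for snap in snapshots:
            xb = np.array([r.value(out, snap) for r in base], dtype=float)
            xa = np.array([r.value(out, snap) for r in alt], dtype=float)
            if paired:
                d = xa - xb
                n = d.size
                mean = float(d.mean())
                if n > 1:
                    sd = float(d.std(ddof=1))
                    half = stats.t.ppf(1 - (1 - confidence) / 2, n - 1) \
                        * sd / math.sqrt(n)
                else:
                    half = math.nan
            else:
                mean = float(xa.mean() - xb.mean())
                na, nb = xa.size, xb.size
                if na > 1 and nb > 1:
                    va, vb = xa.var(ddof=1), xb.var(ddof=1)
                    se2 = va / na + vb / nb
                    if se2 == 0:
                        half = 0.0
                    else:
                        df = se2 ** 2 / ((va / na) ** 2 / (na - 1)
                                         + (vb / nb) ** 2 / (nb - 1))
                        half = stats.t.ppf(1 - (1 - confidence) / 2, df) \
                            * math.sqrt(se2)
                else:
                    half = math.nan
            rows.append({"output": out, "snapshot": str(snap),
                         "mean_diff": mean, "ci_half_width": half,
                         "n_base": len(base), "n_alt": len(alt),
                         "ci_defined": not math.isnan(half)})
    return ComparisonResult(table=pd.DataFrame(rows), confidence=confidence,
                            paired=paired)


# ---------------------------------------------------------------------------
# One-way sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SensitivityGrid:
    """Relative increments for a one-way sweep (must include 0, kept sorted)."""

    parameter: str
    increments: tuple = DEFAULT_INCREMENTS

    def __post_init__(self):
        inc = tuple(sorted(float(i) for i in self.increments))
        if 0.0 not in inc:
            raise ValueError("sensitivity increments must include 0")
        object.__setattr__(self, "increments", inc)


@dataclass
class SensitivityResult:
    grid: SensitivityGrid
    summaries: pd.DataFrame  # summary frame with an extra `increment` column

    def series(self, output: str, snapshot, scenario: str = "baseline") -> pd.Series:
        t = self.summaries
        m = t[(t["output"] == output) & (t["snapshot"] == str(snapshot))
              & (t["scenario"] == scenario)].sort_values("increment")
        return m.set_index("increment")["mean"]


def _resolve_parent(config, path: str):
    parts = path.split(".")
    obj = config
    for key in parts[:-1]:
        if isinstance(obj, dict):
            if key not in obj:
                raise KeyError(f"unknown parameter path segment {key!r} in {path!r}")
            obj = obj[key]
        else:
            if not hasattr(obj, key):
                raise KeyError(f"unknown parameter path segment {key!r} in {path!r}")
            obj = getattr(obj, key)
    return obj, parts[-1]


def scale_parameter(config, path: str, factor: float):
    """Return a copy of ``config`` with the addressed value scaled by ``factor``.

    The path addresses attributes and dict keys, e.g.
    ``"costs.annual_treatment_cost.noac"``. Triangular distributions scale all
    three of (min, mode, max); point distributions and bare floats scale the
    value.
    """
    cfg = config.deepcopy()
    parent, leaf = _resolve_parent(cfg, path)
    if isinstance(parent, dict):
        if leaf not in parent:
            raise KeyError(f"unknown parameter path leaf {leaf!r} in {path!r}")
        value = parent[leaf]
    else:
        if not hasattr(parent, leaf):
            raise KeyError(f"unknown parameter path leaf {leaf!r} in {path!r}")
        value = getattr(parent, leaf)

    if isinstance(value, (PointCost, TriangularCost)):
        new = value.scaled(factor)
    elif isinstance(value, (int, float)) and not isinstance(value, bool):
        new = type(value)(value * factor) if isinstance(value, float) \
            else float(value) * factor
    else:
        raise KeyError(f"parameter path {path!r} does not address a scalar or "
                       f"cost distribution (got {type(value).__name__})")

    if isinstance(parent, dict):
        parent[leaf] = new
    else:
        setattr(parent, leaf, new)
    return cfg


def sensitivity_oneway(config, parameter_path: str,
                       grid: Optional[SensitivityGrid] = None,
                       scenario_specs: Optional[dict] = None,
                       n_replications: Optional[int] = None) -> SensitivityResult:
    """Rerun the full experiment at each relative increment of one parameter.

    Common random numbers (same base seed) apply across increments, so the 0%
    increment reproduces the unperturbed run exactly.
    """
    if grid is None:
        grid = SensitivityGrid(parameter_path)
    frames = []
    for inc in grid.increments:
        cfg = scale_parameter(config, parameter_path, 1.0 + inc)
        res = run_experiment(cfg, scenario_specs, n_replications)
        s = res.summary.copy()
        s["increment"] = inc
        frames.append(s)
        log.info("sensitivity %s at %+.0f%% done", parameter_path, 100 * inc)
    return SensitivityResult(grid=grid,
                             summaries=pd.concat(frames, ignore_index=True))
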