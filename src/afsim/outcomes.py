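"""Cost and DALY accounting.

Costs accrue in three categories: annual treatment cost (per year alive on
treatment; NOAC prices follow a triangular distribution representing price
heterogeneity, sampled once per patient by default), acute care cost per
stroke event, and a per-event cost of death in hospital following a stroke.

DALYs are the undiscounted GBD-style sum YLL + YLD: years of life lost equal
the residual reference life expectancy at the age of (stroke) death, and
years lived with disability accrue the maximum disability weight among the
stroke types suffered, for every completed year lived after the first stroke.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# Cost distributions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PointCost:
    """Degenerate cost distribution: always ``value`` (GBP/year)."""

    value: float

    def __post_init__(self):
        if self.value < 0:
            raise ValueError("cost must be >= 0")

    @property
    def mean(self) -> float:
        return self.value

    def ppf(self, u):
        return np.full_like(np.asarray(u, dtype=float), self.value)

    def sample(self, rng: np.random.Generator, size=None):
        return self.ppf(rng.random(size if size is not None else ()))

    def scaled(self, factor: float) -> "PointCost":
        return PointCost(self.value * factor)


@dataclass(frozen=True)
class TriangularCost:
    """Triangular(min, mode, max) annual cost in GBP."""

    low: float
    mode: float
    high: float

    def __post_init__(self):
        if not (self.low <= self.mode <= self.high):
            raise ValueError(f"malformed triangle: need min <= mode <= max, "
                             f"got ({self.low}, {self.mode}, {self.high})")
        if self.low < 0:
            raise ValueError("cost must be >= 0")

    @property
    def mean(self) -> float:
        return (self.low + self.mode + self.high) / 3.0

    def ppf(self, u):
        """Closed-form triangular quantile function (degenerate-safe)."""
        u = np.asarray(u, dtype=float)
        a, c, b = self.low, self.mode, self.high
        if b == a:
            return np.full_like(u, a)
        fc = (c - a) / (b - a)
        left = a + np.sqrt(np.clip(u, 0, 1) * (b - a) * (c - a))
        right = b - np.sqrt((1 - np.clip(u, 0, 1)) * (b - a) * (b - c))
        return np.where(u < fc, left, right)

    def sample(self, rng: np.random.Generator, size=None):
        return self.ppf(rng.random(size if size is not None else ()))

    def scaled(self, factor: float) -> "TriangularCost":
        return TriangularCost(self.low * factor, self.mode * factor,
                              self.high * factor)


CostDistribution = Union[PointCost, TriangularCost]


def sample_annual_cost(dist: CostDistribution, rng_stream: np.random.Generator):
    """Draw one annual cost from a point or triangular distribution."""
    return float(dist.sample(rng_stream))


@dataclass
class CostModel:
    """Unit costs by category (GBP)."""

    annual_treatment_cost: dict  # treatment -> CostDistribution
    acute_cost: dict             # stroke type -> GBP per event
    stroke_death_cost: float = 0.0
    sample_once_per_patient: bool = True  # one price draw per patient vs per year

    def validate(self) -> None:
        for t, dist in self.annual_treatment_cost.items():
            if not isinstance(dist, (PointCost, TriangularCost)):
                raise ValueError(f"costs.annual_treatment.{t}: not a cost distribution")
        for k, v in self.acute_cost.items():
            if v < 0:
                raise ValueError(f"costs.acute.{k}: must be >= 0")
        if self.stroke_death_cost < 0:
            raise ValueError("costs.stroke_death: must be >= 0")


@dataclass
class DalyModel:
    """Disability weights and the reference life-expectancy table.

    ``reference_life_expectancy`` maps age to residual years (strictly
    decreasing); lookups interpolate linearly and clamp at the table ends.
    No discounting or age-weighting is applied.
    """

    disability_weight: dict  # stroke type -> weight in [0, 1]
    reference_life_expectancy: pd.DataFrame  # columns: age, residual_years
    yll_all_cause: bool = False  # count YLL for other-cause deaths too

    def validate(self) -> None:
        for k, w in self.disability_weight.items():
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"dalys.disability_weight.{k}: must be in [0, 1]")
        tab = self.reference_life_expectancy
        for col in ("age", "residual_years"):
            if col not in tab.columns:
                raise ValueError(f"dalys.life_expectancy: missing column {col!r}")
        res = tab.sort_values("age")["residual_years"].to_numpy()
        if not (np.diff(res) < 0).all():
            raise ValueError("dalys.life_expectancy: residual_years must be "
                             "strictly decreasing in age")

    def residual(self, ages) -> np.ndarray:
        tab = self.reference_life_expectancy.sort_values("age")
        return np.interp(np.asarray(ages, dtype=float),
                         tab["age"].to_numpy(dtype=float),
                         tab["residual_years"].to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# Per-patient accrual from an event history
# ---------------------------------------------------------------------------
#
# A history is a mapping with keys:
#   treatment: str; entry_age: float; strokes: [(year, type)];
#   death: (year, cause) or None; price: optional pre-sampled annual cost.
# Years are 1-based simulation years. A patient alive at the start of year y
# accrues that year's treatment cost; disability accrues at the end of each
# year lived after the first stroke.

def _death_year(history) -> Optional[int]:
    d = history.get("death")
    return None if d is None else int(d[0])


def accrue_costs(history, costs: CostModel,
                 rng_stream: Optional[np.random.Generator] = None,
                 snapshot_years: Sequence[int] = (1, 5, 10)) -> dict:
    """Per-category cost totals at each snapshot year (plus ``"end"``).

    The annual price is taken from ``history["price"]`` when present,
    otherwise sampled once from the treatment's cost distribution.
    """
    dist = costs.annual_treatment_cost[history["treatment"]]
    price = history.get("price")
    if price is None:
        if rng_stream is None:
            price = dist.mean
        else:
            price = sample_annual_cost(dist, rng_stream)
    d = _death_year(history)
    strokes = history.get("strokes", [])
    stroke_death = history.get("death") is not None and history["death"][1] == "stroke"

    def at(year_cap: Optional[int]) -> dict:
        # years alive on treatment: patient accrues at the start of every year
        # they begin alive, including the year of death
        if year_cap is None:
            years_on = d if d is not None else 0
        else:
            years_on = min(d, year_cap) if d is not None else year_cap
        treatment = years_on * price
        acute = sum(costs.acute_cost[typ] for (y, typ) in strokes
                    if year_cap is None or y <= year_cap)
        death_cost = costs.stroke_death_cost if (
            stroke_death and (year_cap is None or d <= year_cap)) else 0.0
        return {"treatment": treatment, "acute": acute,
                "stroke_death": death_cost,
                "total": treatment + acute + death_cost}

    out = {y: at(y) for y in snapshot_years}
    out["end"] = at(None)
    return out


def compute_dalys(history, dalys: DalyModel,
                  snapshot_years: Sequence[int] = (1, 5, 10)) -> dict:
    """DALY (= YLL + YLD) totals at each snapshot year (plus ``"end"``)."""
    d = _death_year(history)
    cause = None if history.get("death") is None else history["death"][1]
    strokes = sorted(history.get("strokes", []))
    entry_age = float(history["entry_age"])

    yll_total = 0.0
    if d is not None and (cause == "stroke" or dalys.yll_all_cause):
        yll_total = float(dalys.residual(entry_age + d - 1))

    horizon = d if d is not None else (max(snapshot_years) if snapshot_years else 0)

    def at(year_cap: Optional[int]) -> dict:
        cap = horizon if year_cap is None else min(horizon, year_cap)
        yld = 0.0
        for y in range(1, cap + 1):
            alive_at_end = d is None or y < d
            if not alive_at_end:
                continue
            prior = [typ for (sy, typ) in strokes if sy < y]
            if prior:
                yld += max(dalys.disability_weight[t] for t in prior)
        yll = yll_total if (d is not None and (year_cap is None or d <= year_cap)) else 0.0
        return {"yll": yll, "yld": yld, "dalys": yll + yld}

    out = {y: at(y) for y in snapshot_years}
    out["end"] = at(None)
    return out
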