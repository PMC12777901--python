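"""Synthetic AF cohort generation.

Builds the simulated atrial-fibrillation population from demographic summary
statistics (sex split, age mean/SD/range) and a CHADS2 x treatment allocation
table, and computes CHADS2 scores from their clinical components.

The CHADS2 score awards 1 point each for congestive heart failure,
hypertension, diabetes and age >= 75, and 2 points for a prior stroke or TIA
(range 0-6). Cohorts carry the score both as an attribute and as the set of
component flags, so the score can be recomputed as patients age or suffer
strokes during simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

TREATMENTS = ("none", "warfarin", "noac")
N_SCORES = 7  # CHADS2 scores 0..6

# Order in which treatment blocks are laid out inside each CHADS2 stratum of a
# generated cohort. Scenario reallocation relies on this: warfarin grows from
# the left of the untreated block and NOAC from its right, so patients already
# on treatment keep their treatment when untreated patients are shifted.
_LAYOUT_ORDER = ("warfarin", "none", "noac")


def compute_chads2(chf: bool, hypertension: bool, diabetes: bool,
                   prior_stroke_tia: bool, age: float) -> int:
    """CHADS2 score from its five components.

    1 point each for CHF, hypertension, diabetes and age >= 75; 2 points for
    prior stroke/TIA. Raises ``ValueError`` for a negative age.
    """
    if age < 0:
        raise ValueError(f"age must be >= 0, got {age}")
    return (int(bool(chf)) + int(bool(hypertension)) + int(bool(diabetes))
            + 2 * int(bool(prior_stroke_tia)) + (1 if age >= 75 else 0))


@dataclass
class Patient:
    """One simulated individual with AF."""

    id: int
    age: float
    sex: str  # "male" | "female"
    chf: bool
    hypertension: bool
    diabetes: bool
    prior_stroke_tia: bool
    chads2: int
    treatment: str = "none"  # "none" | "warfarin" | "noac"
    hasbled: Optional[int] = None  # bleeding-risk hook; unused by default
    alive: bool = True
    strokes: list = field(default_factory=list)  # [(year, "ischaemic"|"haemorrhagic")]
    death: Optional[tuple] = None  # (year, "stroke"|"other")

    def refresh_chads2(self) -> int:
        self.chads2 = compute_chads2(self.chf, self.hypertension, self.diabetes,
                                     self.prior_stroke_tia, self.age)
        return self.chads2


@dataclass(frozen=True)
class PopulationSpec:
    """Demographic summary the cohort is sampled from.

    ``mode="table_exact"`` reproduces the allocation table cell-for-cell (the
    cohort size is the table's grand total and ``size`` is ignored);
    ``mode="sampled"`` draws ``size`` patients with (score, treatment)
    multinomially from the table's proportions.
    """

    size: int
    male_fraction: float
    age_mean: float
    age_sd: float
    age_min: float = 0.0
    age_max: float = 103.0
    mode: str = "table_exact"

    def validate(self) -> None:
        if self.size < 0:
            raise ValueError("population.size: must be >= 0")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValueError("population.male_fraction: must be in [0, 1]")
        if self.age_min > self.age_max:
            raise ValueError("population.age_min: must be <= age_max")
        if self.age_sd <= 0:
            raise ValueError("population.age_sd: must be > 0")
        if self.mode not in ("table_exact", "sampled"):
            raise ValueError(f"population.mode: unknown mode {self.mode!r}")


class AllocationTable:
    """Counts of patients by CHADS2 score (0-6) x treatment (none/warfarin/noac).

    The unit of scenario algebra. Serializes losslessly to CSV with header
    ``chads2,none,warfarin,noac`` and seven data rows.
    """

    def __init__(self, counts):
        arr = np.asarray(counts)
        if arr.shape != (N_SCORES, len(TREATMENTS)):
            raise ValueError(f"allocation table must be {N_SCORES}x{len(TREATMENTS)}, "
                             f"got {arr.shape}")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("allocation table cells must be integers")
            arr = np.round(arr).astype(np.int64)
        if (arr < 0).any():
            bad = int(np.argwhere(arr < 0)[0][0])
            raise ValueError(f"allocation table has negative cell(s), first at score {bad}")
        self.counts = arr.astype(np.int64)

    # -- accessors ---------------------------------------------------------
    def column(self, treatment: str) -> np.ndarray:
        return self.counts[:, TREATMENTS.index(treatment)].copy()

    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def treatment_totals(self) -> dict:
        return {t: int(self.counts[:, j].sum()) for j, t in enumerate(TREATMENTS)}

    def grand_total(self) -> int:
        return int(self.counts.sum())

    def copy(self) -> "AllocationTable":
        return AllocationTable(self.counts.copy())

    def __eq__(self, other) -> bool:
        return isinstance(other, AllocationTable) and np.array_equal(self.counts, other.counts)

    def __repr__(self) -> str:
        return f"AllocationTable(grand_total={self.grand_total()})"

    # -- CSV round trip ----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"chads2": np.arange(N_SCORES),
                             **{t: self.counts[:, j] for j, t in enumerate(TREATMENTS)}})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AllocationTable":
        missing = {"chads2", *TREATMENTS} - set(df.columns)
        if missing:
            raise ValueError(f"allocation table missing column(s): {sorted(missing)}")
        df = df.sort_values("chads2")
        if list(df["chads2"]) != list(range(N_SCORES)):
            raise ValueError("allocation table must have one row per CHADS2 score 0-6")
        return cls(df[list(TREATMENTS)].to_numpy())

    @classmethod
    def from_csv(cls, path) -> "AllocationTable":
        return cls.from_frame(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Age model: normal(location, sd) truncated to [age_min, age_max] by rejection,
# with the location calibrated so the *truncated* mean hits the target mean
# (the upper truncation alone would otherwise drag the mean down ~0.3 y).
# ---------------------------------------------------------------------------

@lru_cache(maxsize=64)
def truncated_normal_location(target_mean: float, sd: float,
                              lo: float, hi: float) -> float:
    """Location mu such that a normal(mu, sd) truncated to [lo, hi] has the target mean."""

    def gap(mu):
        a, b = (lo - mu) / sd, (hi - mu) / sd
        return stats.truncnorm.mean(a, b, loc=mu, scale=sd) - target_mean

    return float(optimize.brentq(gap, target_mean - 2 * sd, target_mean + 2 * sd,
                                 xtol=1e-9))


def _sample_ages(rng: np.random.Generator, n: int, mu: float, sd: float,
                 lo: float, hi: float, require: Optional[str] = None) -> np.ndarray:
    """Rejection-sample n ages from truncated normal, optionally conditioned on
    the age-75 CHADS2 component (``require`` in {None, "lt75", "ge75"})."""
    out = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        draw = rng.normal(mu, sd, todo.size)
        ok = (draw >= lo) & (draw <= hi)
        if require == "lt75":
            ok &= draw < 75.0
        elif require == "ge75":
            ok &= draw >= 75.0
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return out


# Valid (chf, hypertension, diabetes, prior_stroke_tia) combinations for each
# residual score (target CHADS2 minus the age>=75 point). Prior stroke counts 2.
_FLAG_COMBOS = {
    r: [(c, h, d, s)
        for c in (0, 1) for h in (0, 1) for d in (0, 1) for s in (0, 1)
        if c + h + d + 2 * s == r]
    for r in range(6)
}


def generate_population(spec: PopulationSpec, table: AllocationTable,
                        rng_seed: int) -> list:
    """Generate the synthetic cohort.

    In ``table_exact`` mode the returned cohort's (chads2, treatment)
    cross-tabulation equals the input table cell-for-cell. Ages and sexes are
    sampled from the spec; comorbidity flags are back-filled uniformly at
    random among combinations consistent with the assigned score (the age
    component being fixed by the sampled age). Deterministic given the seed.
    """
    spec.validate()
    rng = np.random.default_rng(rng_seed)

    if spec.mode == "sampled":
        total = table.grand_total()
        if spec.size == 0:
            return []
        if total == 0:
            raise ValueError("sampled mode needs a nonempty allocation table")
        probs = table.counts.flatten() / total
        counts = rng.multinomial(spec.size, probs).reshape(N_SCORES, len(TREATMENTS))
    else:
        counts = table.counts
        if counts.sum() == 0:
            return []

    # Feasibility of score/age combinations: a score-0 patient cannot be >= 75
    # (the age point alone would make the score 1) and a score-6 patient must
    # be >= 75 (flags contribute at most 5 points).
    if counts[0].sum() > 0 and spec.age_min >= 75:
        raise ValueError("score-0 patients need age < 75 but age_min >= 75")
    if counts[6].sum() > 0 and spec.age_max < 75:
        raise ValueError("score-6 patients need age >= 75 but age_max < 75")

    mu = truncated_normal_location(spec.age_mean, spec.age_sd,
                                   spec.age_min, spec.age_max)

    # Sample the full age marginal first, then assign ages to patients through
    # feasibility pools: score-0 patients must be < 75 (else the age point
    # alone makes the score 1) and score-6 patients must be >= 75. This keeps
    # the cohort's age distribution equal to the calibrated truncated normal
    # while honouring the score/age coupling.
    n_total = int(counts.sum())
    ages_all = _sample_ages(rng, n_total, mu, spec.age_sd,
                            spec.age_min, spec.age_max)
    need_lt = int(counts[0].sum())
    need_ge = int(counts[6].sum())
    lt_pool = list(ages_all[ages_all < 75.0])
    ge_pool = list(ages_all[ages_all >= 75.0])
    # top up a pool by conditional rejection sampling in the (rare) case the
    # marginal draw under-fills it
    if len(lt_pool) < need_lt:
        lt_pool += list(_sample_ages(rng, need_lt - len(lt_pool), mu, spec.age_sd,
                                     spec.age_min, spec.age_max, "lt75"))
    if len(ge_pool) < need_ge:
        ge_pool += list(_sample_ages(rng, need_ge - len(ge_pool), mu, spec.age_sd,
                                     spec.age_min, spec.age_max, "ge75"))
    rest_pool = lt_pool[need_lt:] + ge_pool[need_ge:]
    rng.shuffle(rest_pool)
    lt_pool, ge_pool = lt_pool[:need_lt], ge_pool[:need_ge]

    patients: list = []
    pid = 0
    for s in range(N_SCORES):
        pool = lt_pool if s == 0 else (ge_pool if s == 6 else rest_pool)
        for treat in _LAYOUT_ORDER:
            k = int(counts[s, TREATMENTS.index(treat)])
            if k == 0:
                continue
            ages, pool[:] = pool[:k], pool[k:]
            males = rng.random(k) < spec.male_fraction
            for i in range(k):
                age = float(ages[i])
                residual = s - (1 if age >= 75 else 0)
                combos = _FLAG_COMBOS[residual]
                c, h, d, st = combos[int(rng.integers(len(combos)))]
                patients.append(Patient(
                    id=pid, age=age,
                    sex="male" if males[i] else "female",
                    chf=bool(c), hypertension=bool(h), diabetes=bool(d),
                    prior_stroke_tia=bool(st), chads2=s, treatment=treat))
                pid += 1
    return patients


def crosstab(cohort: Iterable[Patient]) -> AllocationTable:
    """(chads2, treatment) cross-tabulation of a cohort as an AllocationTable."""
    counts = np.zeros((N_SCORES, len(TREATMENTS)), dtype=np.int64)
    for p in cohort:
        counts[p.chads2, TREATMENTS.index(p.treatment)] += 1
    return AllocationTable(counts)


def _fit_row(row: np.ndarray, n: int) -> np.ndarray:
    """Apportion n patients to treatments in the proportions of ``row``
    (largest-remainder; exact pass-through when the totals already agree)."""
    row = np.asarray(row, dtype=np.int64)
    if row.sum() == n:
        return row.copy()
    if row.sum() == 0:
        raise ValueError("cannot apportion patients to an all-zero allocation row")
    quota = row / row.sum() * n
    base = np.floor(quota).astype(np.int64)
    rem = n - base.sum()
    order = np.argsort(-(quota - base), kind="stable")
    base[order[:rem]] += 1
    return base


def reallocate_treatments(cohort: Sequence[Patient],
                          table: AllocationTable) -> list:
    """Return a copy of the cohort with treatments reassigned to match ``table``.

    Within each CHADS2 stratum patients are relabelled in the fixed
    warfarin|none|noac layout, so under a scenario shift only previously
    untreated patients change treatment — the basis for common-random-number
    comparisons. Patient identity (id, age, sex, flags) is preserved.
    """
    by_score: list = [[] for _ in range(N_SCORES)]
    for p in cohort:
        by_score[p.chads2].append(p)
    out = []
    for s in range(N_SCORES):
        group = by_score[s]
        if not group:
            if table.row_totals()[s] != 0:
                raise ValueError(f"score {s}: table expects patients but cohort has none")
            continue
        target = _fit_row(table.counts[s], len(group))
        labels = []
        for treat in _LAYOUT_ORDER:
            labels.extend([treat] * int(target[TREATMENTS.index(treat)]))
        for p, t in zip(group, labels):
            out.append(replace(p, treatment=t, strokes=list(p.strokes)))
    out.sort(key=lambda p: p.id)
    return out


@dataclass
class PopulationSummary:
    """Descriptive summary mirroring the source dataset's published table."""

    n: int
    male_pct: float
    age_mean: float
    age_sd: float
    age_median: float
    chads2_hist: np.ndarray
    treatment_hist: dict
    moments_defined: bool


def summarize_population(cohort: Sequence[Patient]) -> PopulationSummary:
    n = len(cohort)
    chads2_hist = np.zeros(N_SCORES, dtype=np.int64)
    treatment_hist = {t: 0 for t in TREATMENTS}
    for p in cohort:
        chads2_hist[p.chads2] += 1
        treatment_hist[p.treatment] += 1
    if n == 0:
        return PopulationSummary(0, math.nan, math.nan, math.nan, math.nan,
                                 chads2_hist, treatment_hist, moments_defined=False)
    ages = np.array([p.age for p in cohort])
    male_pct = 100.0 * sum(p.sex == "male" for p in cohort) / n
    sd = float(ages.std(ddof=1)) if n > 1 else math.nan
    return PopulationSummary(n, male_pct, float(ages.mean()), sd,
                             float(np.median(ages)), chads2_hist, treatment_hist,
                             moments_defined=True)
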