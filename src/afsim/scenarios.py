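"""Treatment-allocation scenarios.

Transforms a baseline CHADS2 x treatment allocation table under
"treat all those who can be treated" policies: shift untreated patients with
CHADS2 >= 2 (the guideline treatment threshold) onto warfarin only, NOACs
only, or a mix proportional to each score's existing warfarin:NOAC ratio.
A per-score count of patients who remain untreated (presumed contraindicated)
is an explicit input, not a derived rule.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .population import AllocationTable, N_SCORES, TREATMENTS

log = logging.getLogger(__name__)

SCENARIO_KINDS = ("baseline", "all_warfarin", "all_noac", "nice_mix")

# Untreated patients retained (contraindicated) per CHADS2 score in the
# packaged reference experiment; scores 0-1 are below the treatment threshold
# and keep their full untreated counts.
DEFAULT_RETAINED_UNTREATED = (904, 747, 64, 37, 21, 10, 1)

_NONE = TREATMENTS.index("none")
_WAR = TREATMENTS.index("warfarin")
_NOAC = TREATMENTS.index("noac")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class ScenarioSpec:
    """How to reallocate untreated patients.

    ``retained_untreated`` gives, per score, how many untreated patients stay
    untreated after the shift; ``None`` selects the packaged defaults for
    eligible scores and the baseline untreated counts below the eligibility
    threshold.
    """

    kind: str
    eligibility_min_score: int = 2
    retained_untreated: Optional[Sequence[int]] = None

    def __post_init__(self):
        if self.kind not in SCENARIO_KINDS:
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.retained_untreated is not None:
            object.__setattr__(self, "retained_untreated",
                               tuple(int(v) for v in self.retained_untreated))
            if len(self.retained_untreated) != N_SCORES:
                raise ValueError("retained_untreated needs one entry per score 0-6")

    @classmethod
    def from_retained_fraction(cls, kind: str, baseline: AllocationTable,
                               fraction: float,
                               eligibility_min_score: int = 2) -> "ScenarioSpec":
        """Convenience: retain a uniform fraction of each eligible score's
        untreated patients (round half-up)."""
        if not 0.0 <= fraction <= 1.0:
            raise ValueError("retained fraction must be in [0, 1]")
        nt = baseline.column("none")
        retained = [int(nt[s]) if s < eligibility_min_score
                    else _round_half_up(fraction * nt[s])
                    for s in range(N_SCORES)]
        return cls(kind, eligibility_min_score, tuple(retained))

    def resolve_retained(self, baseline: AllocationTable) -> np.ndarray:
        nt = baseline.column("none")
        if self.retained_untreated is None:
            retained = np.array([int(nt[s]) if s < self.eligibility_min_score
                                 else DEFAULT_RETAINED_UNTREATED[s]
                                 for s in range(N_SCORES)], dtype=np.int64)
        else:
            retained = np.array(self.retained_untreated, dtype=np.int64)
        for s in range(N_SCORES):
            if retained[s] > nt[s]:
                raise ValueError(f"retained_untreated[{s}]={retained[s]} exceeds "
                                 f"baseline untreated count {nt[s]}")
            if s < self.eligibility_min_score and retained[s] != nt[s]:
                raise ValueError(f"score {s} is below the eligibility threshold; "
                                 f"retained count must equal the baseline untreated "
                                 f"count {nt[s]}")
            if retained[s] < 0:
                raise ValueError(f"retained_untreated[{s}] must be >= 0")
        return retained


def apply_scenario(baseline: AllocationTable, spec: ScenarioSpec) -> AllocationTable:
    """Reallocate untreated patients per the scenario rule.

    Grand total is conserved exactly: warfarin shares under ``nice_mix`` are
    rounded half-up and the remainder of each score's shifted patients goes to
    NOAC. A score with no treated patients falls back to a 50:50 split.
    """
    if spec.kind == "baseline":
        return baseline.copy()
    retained = spec.resolve_retained(baseline)
    counts = baseline.counts.copy()
    for s in range(spec.eligibility_min_score, N_SCORES):
        shifted = int(counts[s, _NONE] - retained[s])
        if shifted == 0:
            continue
        counts[s, _NONE] = retained[s]
        if spec.kind == "all_warfarin":
            counts[s, _WAR] += shifted
        elif spec.kind == "all_noac":
            counts[s, _NOAC] += shifted
        else:  # nice_mix
            war, noac = int(baseline.counts[s, _WAR]), int(baseline.counts[s, _NOAC])
            if war + noac == 0:
                log.warning("nice_mix: score %d has no treated patients; "
                            "falling back to a 50:50 split of %d shifted", s, shifted)
                w_share = _round_half_up(shifted / 2)
            else:
                w_share = _round_half_up(shifted * war / (war + noac))
            counts[s, _WAR] += w_share
            counts[s, _NOAC] += shifted - w_share
    return AllocationTable(counts)


@dataclass
class ConservationReport:
    """Per-score row-total discrepancy between two allocation tables."""

    ok: bool
    row_discrepancy: np.ndarray  # b row totals minus a row totals
    offending_scores: list
    tolerance: int

    def __bool__(self) -> bool:
        return self.ok


def conservation_check(a: AllocationTable, b: AllocationTable,
                       tolerance: int = 1) -> ConservationReport:
    """Check that per-score row totals agree within ``tolerance`` patients.

    The default tolerance of 1 accommodates rounding in proportional splits.
    """
    disc = b.row_totals() - a.row_totals()
    offending = [int(s) for s in range(N_SCORES) if abs(int(disc[s])) > tolerance]
    return ConservationReport(ok=not offending, row_discrepancy=disc,
                              offending_scores=offending, tolerance=tolerance)
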