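"""RECIST v1.1 best-response classification and cohort benefit/feasibility stats.

Best response is computed from target-lesion diameter sums only (no
non-target or new-lesion rules, no confirmation scans): CR when the sum
reaches zero, PR when the best baseline-referenced change reaches -30%,
PD when - before any PR/CR - a timepoint rises at least 20% above the
nadir so far with at least a 5 mm absolute increase, SD otherwise, and
NED for subjects rendered free of measurable disease by surgery. Note the
two reference conventions: PD is nadir-referenced per RECIST, while the
waterfall percent change is baseline-referenced.

The clinical benefit rate is (CR + PR + SD + NED) / (CR + PR + SD + NED + PD).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from mtbkit.io import LesionSeries, Milestones, MILESTONE_ORDER

__all__ = [
    "RESPONSE_CLASSES",
    "BestResponse",
    "percent_change",
    "classify_best_response",
    "clinical_benefit_rate",
    "feasibility_summary",
    "cycle_start_summary",
    "waterfall_table",
    "round_half_up",
]

RESPONSE_CLASSES = ("CR", "PR", "SD", "PD", "NED")
BENEFIT_CLASSES = ("CR", "PR", "SD", "NED")

CYCLE_CATEGORIES = ("c1", "c2", "c3", "c5", "never")


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round half away from zero at the printed precision (5 rounds up)."""
    q = Decimal(1).scaleb(-ndigits)
    out = float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
    return out


@dataclass(frozen=True)
class BestResponse:
    """A subject's best overall response and baseline-referenced best change."""

    subject_id: str
    response: str
    best_percent_change: float | None

    def __post_init__(self) -> None:
        if self.response not in RESPONSE_CLASSES:
            raise ValueError(f"unknown response class {self.response!r}")
        if self.response == "NED" and self.best_percent_change is not None:
            raise ValueError("percent change is undefined for NED")


def percent_change(baseline_sum: float, timepoint_sum: float) -> float:
    """Percent change of the target-lesion sum from baseline."""
    if baseline_sum <= 0:
        raise ValueError("baseline sum must be positive")
    return 100.0 * (timepoint_sum - baseline_sum) / baseline_sum


def classify_best_response(
    series: LesionSeries,
    pr_boundary_inclusive: bool = True,
) -> BestResponse:
    """Classify a lesion series into CR/PR/SD/PD/NED.

    ``pr_boundary_inclusive`` controls whether a change of exactly -30%
    counts as PR (the RECIST "at least 30% decrease" reading, the default)
    or falls to SD.
    """
    if series.ned_flag:
        return BestResponse(series.subject_id, "NED", None)
    if not series.timepoint_sums:
        raise ValueError(f"{series.subject_id}: no post-baseline timepoints")
    baseline = series.baseline_sum
    sums = series.timepoint_sums
    best_sum = min(sums)
    if baseline == 0:
        raise ValueError(f"{series.subject_id}: zero baseline with measurable disease")
    best_change = percent_change(baseline, best_sum)

    if best_sum == 0:
        return BestResponse(series.subject_id, "CR", best_change)
    pr = best_change <= -30.0 if pr_boundary_inclusive else best_change < -30.0
    if pr:
        return BestResponse(series.subject_id, "PR", best_change)

    # PD: >= +20% over the nadir so far AND >= 5 mm absolute increase
    nadir = baseline
    progressed = False
    for s in sums:
        if s >= 1.2 * nadir and s - nadir >= 5.0:
            progressed = True
            break
        nadir = min(nadir, s)
    klass = "PD" if progressed else "SD"
    return BestResponse(series.subject_id, klass, best_change)


def clinical_benefit_rate(
    responses: Sequence[BestResponse | str],
) -> tuple[float, float]:
    """Proportion and rounded percent of subjects with clinical benefit.

    Benefit counts CR, PR, SD and NED; the denominator adds PD. Returns
    ``(proportion, percent)`` with the percent rounded half-up to the
    nearest integer.
    """
    if not responses:
        raise ValueError("response list is empty")
    classes = [
        r if isinstance(r, str) else r.response for r in responses
    ]
    unknown = set(classes) - set(RESPONSE_CLASSES)
    if unknown:
        raise ValueError(f"unknown response classes: {sorted(unknown)}")
    benefit = sum(1 for c in classes if c in BENEFIT_CLASSES)
    total = len(classes)
    proportion = benefit / total
    return proportion, round_half_up(100.0 * proportion, 0)


def feasibility_summary(
    milestones: Iterable[Milestones],
) -> pd.DataFrame:
    """Mean, median and (min, max) days per milestone across the cohort.

    Subjects missing a milestone are excluded from that milestone's
    statistics only.
    """
    milestones = list(milestones)
    if not milestones:
        raise ValueError("milestone list is empty")
    rows = []
    for name in MILESTONE_ORDER:
        values = np.array(
            [getattr(m, name) for m in milestones if getattr(m, name) is not None],
            dtype=float,
        )
        if values.size == 0:
            rows.append(
                {"milestone": name, "n": 0, "mean": np.nan, "median": np.nan,
                 "min": np.nan, "max": np.nan}
            )
        else:
            rows.append(
                {
                    "milestone": name,
                    "n": int(values.size),
                    "mean": float(values.mean()),
                    "median": float(np.median(values)),
                    "min": float(values.min()),
                    "max": float(values.max()),
                }
            )
    return pd.DataFrame(rows).set_index("milestone")


def cycle_start_summary(
    counts: Mapping[str, int], n: int
) -> dict[str, float]:
    """Percent of subjects first starting the full regimen at each cycle.

    ``counts`` maps cycle categories (``c1``, ``c2``, ``c3``, ``c5``,
    ``never``) to subject counts out of ``n``. Percentages are reported to
    two decimals (half-up); ``ever_started`` is the percent of subjects
    who started all recommended agents at any cycle.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    unknown = set(counts) - set(CYCLE_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown cycle categories: {sorted(unknown)}")
    total = sum(counts.values())
    if total > n:
        raise ValueError(f"counts sum to {total} > n={n}")
    out = {
        cat: round_half_up(100.0 * counts.get(cat, 0) / n, 2)
        for cat in CYCLE_CATEGORIES
    }
    out["ever_started"] = round_half_up(
        100.0 * (n - counts.get("never", 0)) / n, 2
    )
    return out


def waterfall_table(
    responses: Sequence[BestResponse],
) -> dict:
    """Waterfall summary over subjects with measurable disease.

    Returns the per-subject best percent changes sorted descending plus
    counts of decrease (< 0), no change (exactly 0) and increase (> 0),
    and the percent with a decrease to two decimals.
    """
    changes = []
    for r in responses:
        if r.best_percent_change is None:
            raise ValueError(
                f"{r.subject_id}: no measurable-disease percent change"
            )
        changes.append((r.subject_id, r.best_percent_change))
    changes.sort(key=lambda t: (-t[1], t[0]))
    values = [c for _, c in changes]
    n = len(values)
    n_decrease = sum(1 for v in values if v < 0)
    n_no_change = sum(1 for v in values if v == 0)
    n_increase = sum(1 for v in values if v > 0)
    return {
        "subjects": [s for s, _ in changes],
        "best_percent_change": values,
        "n": n,
        "n_decrease": n_decrease,
        "n_no_change": n_no_change,
        "n_increase": n_increase,
        "percent_decrease": round_half_up(100.0 * n_decrease / n, 2) if n else 0.0,
        "percent_increase": round_half_up(100.0 * n_increase / n, 2) if n else 0.0,
    }
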