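"""Cohort aggregation: type proportions, migration ages, region statistics.

Percentages are integers rounded half away from zero — the convention that
reproduces every printed cohort percentage from whole-fish counts.
Undetermined calls are excluded from denominators and reported separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import LifeHistoryCall
from .reduction import ValidationError

TYPE_IDS = (1, 2, 3, 4, 5, 6)
ANADROMOUS = (1, 2, 3)
NONANADROMOUS = (5, 6)
ENTRY_AGE_COLUMNS = ("0", "1", "2", "3", "4", "5+")


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def percent(count: int, total: int) -> int:
    return round_half_away(100.0 * count / total)


@dataclass(frozen=True)
class CohortSummary:
    """Counts, percentages and tables for a classified cohort."""

    n_total: int
    n_undetermined: int
    counts: dict
    percents: dict
    pct_anadromous: int
    pct_nonanadromous: int
    migration_table: pd.DataFrame
    region_table: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_total:
            raise ValidationError("type counts must sum to n_total")
        if abs(sum(self.percents.values()) - 100) > 2:
            raise ValidationError("percents must sum to 100 within rounding")


# ---------------------------------------------------------------------------
# proportions
# ---------------------------------------------------------------------------

def proportions_from_counts(counts: dict[int, int],
                            ) -> tuple[dict[int, int], int, int]:
    """Per-type integer percentages plus combined anadromous/nonanadromous.

    ``counts`` maps type id (1–6) to fish count. Returns (per-type percents,
    anadromous percent, nonanadromous percent).
    """
    n = sum(counts.values())
    if n == 0:
        raise ValidationError("no classified fish to summarize")
    percents = {t: percent(counts.get(t, 0), n) for t in TYPE_IDS}
    pct_ana = percent(sum(counts.get(t, 0) for t in ANADROMOUS), n)
    pct_non = percent(sum(counts.get(t, 0) for t in NONANADROMOUS), n)
    return percents, pct_ana, pct_non


def type_proportions(calls: list[LifeHistoryCall],
                     ) -> tuple[dict[int, int], dict[int, int]]:
    """Counts and rounded percentages per life-history type.

    Undetermined calls are excluded from the denominator.
    """
    ok = [c for c in calls if c.status == "ok"]
    if not ok:
        raise ValidationError("no classified calls")
    counts = {t: sum(1 for c in ok if c.type_id == t) for t in TYPE_IDS}
    percents, _, _ = proportions_from_counts(counts)
    return counts, percents


# ---------------------------------------------------------------------------
# migration ages
# ---------------------------------------------------------------------------

def migration_counts_to_row(age_counts: dict[int, int]) -> list[int]:
    """Entry-age counts → integer percent row for ages 0–4 and 5+."""
    n = sum(age_counts.values())
    pooled = [age_counts.get(a, 0) for a in range(5)]
    pooled.append(sum(v for a, v in age_counts.items() if a >= 5))
    if n == 0:
        return [0] * 6
    return [percent(c, n) for c in pooled]


def migration_age_table(calls: list[LifeHistoryCall]) -> pd.DataFrame:
    """Percent of each anadromous type entering the sea at ages 0–4, 5+.

    Rows are types 1–3; empty rows are all-zero with N = 0. Entry ages of
    five and beyond share the last column.
    """
    rows = {}
    for t in ANADROMOUS:
        ages = [c.entry_age for c in calls
                if c.status == "ok" and c.type_id == t
                and c.entry_age is not None]
        age_counts: dict[int, int] = {}
        for a in ages:
            age_counts[a] = age_counts.get(a, 0) + 1
        rows[t] = migration_counts_to_row(age_counts) + [len(ages)]
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=list(ENTRY_AGE_COLUMNS) + ["N"])


# ---------------------------------------------------------------------------
# region statistics
# ---------------------------------------------------------------------------

def region_stats_table(calls: list[LifeHistoryCall]) -> pd.DataFrame:
    """Mean/median/min/max/SE of region mean ratios, per type × region kind.

    The N here counts otoliths with a detectable region of that kind, which
    can differ from the classification N (a region is occasionally
    undetectable); types with no members appear with N = 0.
    """
    records = []
    for kind in ("natal", "juvenile"):
        for t in TYPE_IDS:
            vals = []
            for c in calls:
                if c.status != "ok" or c.type_id != t:
                    continue
                region = c.natal if kind == "natal" else c.juvenile
                if region is not None:
                    vals.append(region.mean_ratio)
            v = np.asarray(vals, float)
            n = len(v)
            rec = {"kind": kind, "type_id": t, "N": n}
            if n:
                rec.update(mean=float(v.mean()), median=float(np.median(v)),
                           min=float(v.min()), max=float(v.max()),
                           se=float(v.std(ddof=1) / math.sqrt(n)) if n > 1
                           else 0.0)
            else:
                rec.update(mean=np.nan, median=np.nan, min=np.nan,
                           max=np.nan, se=np.nan)
            records.append(rec)
    return pd.DataFrame.from_records(
        records, columns=["kind", "type_id", "mean", "median", "min", "max",
                          "se", "N"])


# ---------------------------------------------------------------------------
# full summary
# ---------------------------------------------------------------------------

def summarize_cohort(calls: list[LifeHistoryCall]) -> CohortSummary:
    """Aggregate classified calls into the cohort report."""
    counts, percents = type_proportions(calls)
    _, pct_ana, pct_non = proportions_from_counts(counts)
    n_und = sum(1 for c in calls if c.status != "ok")
    return CohortSummary(
        n_total=sum(counts.values()), n_undetermined=n_und,
        counts=counts, percents=percents,
        pct_anadromous=pct_ana, pct_nonanadromous=pct_non,
        migration_table=migration_age_table(calls),
        region_table=region_stats_table(calls))
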