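"""Cohort characteristics of a deduplicated report set.

Counts and percentages by sex, age bin, country (top-ranked), serious
outcome and reporter type, plus the annual reporting trend. Serious-outcome
categories are not mutually exclusive (a report hospitalized *and*
life-threatening increments both rows), so their percentages need not sum
to 100; every exclusive category does, with "unspecified" absorbing missing
values. Percentages are exact-rational half-up roundings to 2 decimals.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import pandas as pd

from .ingest import AGE_BIN_LABELS, SpontaneousReport
from .synthetic import (
    OUTCOME_CODES,
    REFERENCE_YEAR_SPAN,
    REPORTER_LEVELS,
    SEX_LEVELS,
)

AGE_LEVELS = AGE_BIN_LABELS + ("unspecified",)


def pct(count: int, total: int, decimals: int = 2) -> float:
    """100*count/total, rounded half-up at ``decimals`` using exact rational
    arithmetic (float rounding artefacts cannot flip a printed digit)."""
    if total <= 0:
        raise ValueError("total must be positive")
    scale = 10**decimals
    x = Fraction(100 * count * scale, total)
    # half-up integer rounding of the exact fraction
    q = (2 * x.numerator + x.denominator) // (2 * x.denominator)
    return q / scale


@dataclass(frozen=True)
class CohortSummary:
    n_events: int
    sex: Mapping[str, int]
    age: Mapping[str, int]
    country: Mapping[str, int]  # all countries, descending count
    outcomes: Mapping[str, int]  # not mutually exclusive
    reporter: Mapping[str, int]
    annual: Mapping[int, int]

    def percentages(self, category: str) -> dict:
        table = getattr(self, category)
        return {k: pct(v, self.n_events) for k, v in table.items()}

    def top_countries(self, k: int = 5) -> list[tuple[str, int]]:
        return list(self.country.items())[:k]

    def to_frame(self) -> pd.DataFrame:
        rows = [("total", "n_events", self.n_events, 100.0)]
        for section in ("sex", "age", "country", "outcomes", "reporter"):
            for level, count in getattr(self, section).items():
                rows.append((section, str(level), count, pct(count, self.n_events)))
        for year, count in self.annual.items():
            rows.append(("year", str(year), count, pct(count, self.n_events)))
        return pd.DataFrame(rows, columns=["section", "category", "count", "pct"])


def _ordered_counts(counter: Counter, levels: Sequence[str]) -> dict:
    out = {level: counter.get(level, 0) for level in levels}
    for level in sorted(set(counter) - set(levels)):
        out[level] = counter[level]
    return out


def summarize_cohort(reports: Sequence[SpontaneousReport]) -> CohortSummary:
    """Category counts over a deduplicated (typically PS-filtered) cohort."""
    if not reports:
        raise ValueError("empty report set")
    n = len(reports)
    sex: Counter = Counter(r.sex for r in reports)
    age: Counter = Counter(r.age_group for r in reports)
    country: Counter = Counter(r.country for r in reports)
    reporter: Counter = Counter(r.reporter for r in reports)
    outcomes: Counter = Counter()
    for r in reports:
        outcomes.update(set(r.serious_outcomes))
    country_sorted = dict(
        sorted(country.items(), key=lambda kv: (-kv[1], kv[0]))
    )
    return CohortSummary(
        n_events=n,
        sex=_ordered_counts(sex, SEX_LEVELS),
        age=_ordered_counts(age, AGE_LEVELS),
        country=country_sorted,
        outcomes={code: outcomes.get(code, 0) for code in ("LT", "HO", "DS", "DE")},
        reporter=_ordered_counts(reporter, REPORTER_LEVELS),
        annual=annual_trend(reports).counts,
    )


@dataclass(frozen=True)
class AnnualTrend:
    counts: Mapping[int, int]  # zero-filled over the span
    peak_year: int
    peak_count: int
    peak_share_pct: float


def annual_trend(reports: Sequence[SpontaneousReport]) -> AnnualTrend:
    """Report counts per receipt year, zero-filled over the union of the
    2004-2023 reference span and the observed years; ties at the peak go to
    the earliest year."""
    if not reports:
        raise ValueError("empty report set")
    counts: Counter = Counter(r.receipt_year for r in reports)
    lo = min(REFERENCE_YEAR_SPAN[0], min(counts))
    hi = max(REFERENCE_YEAR_SPAN[1], max(counts))
    filled = {year: counts.get(year, 0) for year in range(lo, hi + 1)}
    peak_year = max(filled, key=lambda y: (filled[y], -y))
    return AnnualTrend(
        counts=filled,
        peak_year=peak_year,
        peak_count=filled[peak_year],
        peak_share_pct=pct(filled[peak_year], len(reports)),
    )
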