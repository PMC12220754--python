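"""Per-(drug, event) 2x2 contingency tables from a cleaned report universe.

The universe convention: the "drug of interest" rows (a, b) count reports
naming the target drug as primary suspect; everything else — including
reports where the drug appears only in a secondary role — falls in the
comparator rows (c, d). The counting unit is the deduplicated report: a
report contributes at most 1 to any one cell, and at SOC level a report with
several PTs of the same SOC still counts once.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .ingest import SpontaneousReport
from .synthetic import ROLE_PS

LEVEL_PT = "PT"
LEVEL_SOC = "SOC"


@dataclass(frozen=True)
class ContingencyTable:
    """Cell counts for one drug-event pair.

    a: reports with the target drug (PS) and the target event;
    b: with the drug, without the event; c: without the drug, with the event;
    d: neither. ``event_observed`` is False when the event never co-occurs
    with the drug (a = 0 tables are allowed but flagged).
    """

    drug: str
    event: str
    level: str
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.level not in (LEVEL_PT, LEVEL_SOC):
            raise ValueError(f"level must be {LEVEL_PT!r} or {LEVEL_SOC!r}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def event_observed(self) -> bool:
        return (self.a + self.c) > 0

    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


def _event_sets(report: SpontaneousReport, level: str) -> frozenset:
    if level == LEVEL_PT:
        return report.pts
    return report.socs


def build_table(
    reports: Sequence[SpontaneousReport], drug: str, event: str, level: str = LEVEL_PT
) -> ContingencyTable:
    """2x2 table of one (drug, event) pair over the whole universe."""
    a = b = c = d = 0
    for r in reports:
        is_ps = r.has_drug(drug, ROLE_PS)
        has_event = event in _event_sets(r, level)
        if is_ps and has_event:
            a += 1
        elif is_ps:
            b += 1
        elif has_event:
            c += 1
        else:
            d += 1
    return ContingencyTable(drug=drug, event=event, level=level, a=a, b=b, c=c, d=d)


def build_all_tables(
    reports: Sequence[SpontaneousReport], drug: str
) -> list[ContingencyTable]:
    """One PT-level table per PT observed with the drug (as PS) and one
    SOC-level table per SOC observed with it, in a single pass.

    Requires SOCs attached (:func:`pvsignal.ingest.attach_soc`). Order is
    deterministic: level, then descending a, then event name.
    """
    n = len(reports)
    n_ps = 0
    pt_total: Counter = Counter()
    soc_total: Counter = Counter()
    pt_with_drug: Counter = Counter()
    soc_with_drug: Counter = Counter()
    for r in reports:
        if any(soc is None for _, soc in r.events):
            raise ValueError("SOCs must be attached before building SOC tables")
        pts = r.pts
        socs = r.socs
        pt_total.update(pts)
        soc_total.update(socs)
        if r.has_drug(drug, ROLE_PS):
            n_ps += 1
            pt_with_drug.update(pts)
            soc_with_drug.update(socs)

    tables = []
    for level, with_drug, totals in (
        (LEVEL_PT, pt_with_drug, pt_total),
        (LEVEL_SOC, soc_with_drug, soc_total),
    ):
        for event, a in with_drug.items():
            c = totals[event] - a
            tables.append(
                ContingencyTable(
                    drug=drug,
                    event=event,
                    level=level,
                    a=a,
                    b=n_ps - a,
                    c=c,
                    d=n - n_ps - c,
                )
            )
    tables.sort(key=lambda t: (t.level, -t.a, t.event))
    return tables


def tables_to_frame(tables: Iterable[ContingencyTable]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "drug": t.drug,
                "event": t.event,
                "level": t.level,
                "a": t.a,
                "b": t.b,
                "c": t.c,
                "d": t.d,
                "N": t.n,
            }
            for t in tables
        ]
    )
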