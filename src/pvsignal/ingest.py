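"""Reading and cleaning FAERS-style quarterly report tables.

The cleaning chain mirrors standard spontaneous-report practice: join the
four quarterly tables on the primary id, keep the latest version of every
case, normalize verbatim drug names to canonical ingredients, restrict the
query to reports naming the target drug as primary suspect (PS), and attach
each preferred term's primary System Organ Class.

All operations are deterministic and order-insensitive; every row or case
dropped along the way is tallied in a :class:`CleaningLog`.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .synthetic import (
    CODE_TO_REPORTER,
    CODE_TO_SEX,
    QUARTER_FILES,
    ROLE_PS,
    RawCaseRecord,
)

UNMAPPED_SOC = "UNMAPPED"

#: Age bins, in years: [0,18), [18,45), [45,65), [65,75), [75,inf).
#: Missing or implausible ages (<0 or >120) fall in "unspecified".
AGE_BIN_EDGES = (18, 45, 65, 75)
AGE_BIN_LABELS = ("<18", "18-44", "45-64", "65-74", ">=75")

SERIOUS_OUTCOME_CODES = frozenset({"DE", "DS", "HO", "LT"})


@dataclass
class CleaningLog:
    """Running counters for rows/cases affected by cleaning steps."""

    counters: dict[str, int] = field(default_factory=dict)

    def bump(self, name: str, k: int = 1) -> None:
        self.counters[name] = self.counters.get(name, 0) + k

    def get(self, name: str) -> int:
        return self.counters.get(name, 0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.counters.items()), columns=["counter", "count"]
        )


@dataclass(frozen=True)
class SpontaneousReport:
    """One deduplicated case: the unit of counting for every 2x2 cell."""

    case_id: str
    case_version: int
    receipt_year: int
    sex: str
    age_group: str
    country: str
    reporter: str
    drugs: tuple[tuple[str, str], ...]  # (normalized name, role code)
    events: tuple[tuple[str, Optional[str]], ...]  # (PT, SOC or None)
    serious_outcomes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.events:
            raise ValueError("a spontaneous report must carry at least one event")
        bad = set(self.serious_outcomes) - SERIOUS_OUTCOME_CODES
        if bad:
            raise ValueError(f"unknown serious-outcome codes: {sorted(bad)}")

    def has_drug(self, drug: str, role: Optional[str] = None) -> bool:
        return any(
            name == drug and (role is None or r == role) for name, r in self.drugs
        )

    @property
    def pts(self) -> frozenset:
        return frozenset(pt for pt, _ in self.events)

    @property
    def socs(self) -> frozenset:
        return frozenset(soc for _, soc in self.events if soc is not None)


@dataclass(frozen=True)
class PtSocMap:
    """PT -> (PT code, SOC name, SOC code); every PT has one primary SOC."""

    entries: Mapping[str, tuple[str, str, str]]

    @classmethod
    def from_tsv(cls, path) -> "PtSocMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"pt", "pt_code", "soc_name", "soc_code"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"PT->SOC map missing columns: {sorted(missing)}")
        entries = {
            row.pt: (row.pt_code, row.soc_name, row.soc_code)
            for row in df.itertuples()
        }
        if len(entries) != len(df):
            raise ValueError("duplicate PT entries in PT->SOC map")
        return cls(entries=entries)

    def soc_of(self, pt: str) -> Optional[str]:
        hit = self.entries.get(pt)
        return hit[1] if hit else None


def _packaged(name: str) -> Path:
    return Path(resources.files("pvsignal").joinpath("data", name))


def load_toy_pt_soc_map() -> PtSocMap:
    """Small synthetic PT->SOC vocabulary shipped with the package (invented
    codes; stands in for the licensed MedDRA dictionary)."""
    return PtSocMap.from_tsv(_packaged("toy_pt_soc_map.tsv"))


def load_drug_dictionary(path=None) -> dict[str, str]:
    """Load a verbatim->canonical drug-name dictionary (two-column TSV).

    Keys are whitespace-collapsed and casefolded; the shipped toy dictionary
    is used when ``path`` is None.
    """
    path = _packaged("toy_drug_dictionary.tsv") if path is None else path
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"verbatim", "canonical"} <= set(df.columns):
        raise ValueError("drug dictionary needs 'verbatim' and 'canonical' columns")
    return {_name_key(row.verbatim): row.canonical for row in df.itertuples()}


def _name_key(name: str) -> str:
    return " ".join(name.split()).casefold()


def read_faers_quarter(
    directory, log: Optional[CleaningLog] = None
) -> list[RawCaseRecord]:
    """Join one quarter's DEMO/DRUG/REAC/OUTC tables into raw case records.

    One record per (case_id, case_version); DRUG/REAC/OUTC rows whose
    primaryid has no DEMO row are dropped with a warning and counted as
    ``orphan_rows``. Records with no REAC rows survive here (they are
    rejected at deduplication, where the events-non-empty invariant bites).
    """
    directory = Path(directory)
    log = log if log is not None else CleaningLog()
    tables: dict[str, pd.DataFrame] = {}
    for name, columns in QUARTER_FILES.items():
        path = directory / f"{name}.txt"
        if not path.exists():
            raise FileNotFoundError(f"missing quarter table: {path}")
        df = pd.read_csv(path, sep="$", dtype=str, keep_default_na=False)
        missing = set(columns) - set(df.columns)
        if missing:
            raise ValueError(f"{name} table missing columns: {sorted(missing)}")
        tables[name] = df

    demo = tables["DEMO"]
    known = set(demo["primaryid"])
    grouped: dict[str, dict[str, list]] = {
        pid: {"drugs": [], "events": [], "outcomes": []} for pid in known
    }
    for name, key in (("DRUG", "drugs"), ("REAC", "events"), ("OUTC", "outcomes")):
        df = tables[name]
        orphan = ~df["primaryid"].isin(known)
        n_orphan = int(orphan.sum())
        if n_orphan:
            warnings.warn(
                f"{name}: dropped {n_orphan} row(s) with no matching DEMO record"
            )
            log.bump("orphan_rows", n_orphan)
            df = df[~orphan]
        for row in df.itertuples():
            if name == "DRUG":
                grouped[row.primaryid][key].append((row.drugname, row.role_cod))
            elif name == "REAC":
                grouped[row.primaryid][key].append(row.pt)
            else:
                grouped[row.primaryid][key].append(row.outc_cod)

    records: list[RawCaseRecord] = []
    for row in demo.itertuples():
        parts = grouped[row.primaryid]
        try:
            date = dt.datetime.strptime(row.fda_dt, "%Y%m%d").date()
            version = int(row.caseversion)
        except ValueError:
            log.bump("malformed_demo_rows")
            continue
        age: Optional[int]
        try:
            age = int(row.age) if row.age != "" else None
        except ValueError:
            age = None
            log.bump("malformed_age_values")
        if not parts["drugs"] or not parts["events"]:
            # deferred: represented with a placeholder so dedup can reject it
            log.bump("cases_missing_drug_or_event")
            continue
        records.append(
            RawCaseRecord(
                case_id=row.caseid,
                case_version=version,
                receipt_date=date,
                sex=CODE_TO_SEX.get(row.sex, "unspecified"),
                age=age,
                country=row.occr_country,
                reporter=CODE_TO_REPORTER.get(row.occp_cod, "unspecified"),
                drug_entries=tuple(parts["drugs"]),
                event_entries=tuple(parts["events"]),
                outcome_codes=tuple(parts["outcomes"]),
            )
        )
    return records


def bin_age(age: Optional[int]) -> str:
    if age is None or age < 0 or age > 120:
        return "unspecified"
    for edge, label in zip(AGE_BIN_EDGES, AGE_BIN_LABELS):
        if age < edge:
            return label
    return AGE_BIN_LABELS[-1]


def _dedup_rank(record: RawCaseRecord) -> tuple:
    return (record.case_version, record.receipt_date, record.primaryid)


def deduplicate(
    records: Sequence[RawCaseRecord], log: Optional[CleaningLog] = None
) -> list[SpontaneousReport]:
    """Keep exactly one record per case_id: highest case version, ties broken
    by latest receipt date, then lexicographically largest primary id.

    The winners are converted to :class:`SpontaneousReport` (ages binned,
    serious-outcome codes filtered to DE/DS/HO/LT). Output sorted by case_id,
    so shuffled input yields an identical list.
    """
    log = log if log is not None else CleaningLog()
    best: dict[str, RawCaseRecord] = {}
    for rec in records:
        cur = best.get(rec.case_id)
        if cur is None or _dedup_rank(rec) > _dedup_rank(cur):
            best[rec.case_id] = rec
    n_dropped = len(records) - len(best)
    if n_dropped:
        log.bump("duplicate_versions_removed", n_dropped)
    out = []
    for case_id in sorted(best):
        rec = best[case_id]
        out.append(
            SpontaneousReport(
                case_id=rec.case_id,
                case_version=rec.case_version,
                receipt_year=rec.receipt_date.year,
                sex=rec.sex,
                age_group=bin_age(rec.age),
                country=rec.country,
                reporter=rec.reporter,
                drugs=rec.drug_entries,
                events=tuple((pt, None) for pt in rec.event_entries),
                serious_outcomes=tuple(
                    code for code in rec.outcome_codes if code in SERIOUS_OUTCOME_CODES
                ),
            )
        )
    return out


def normalize_drug_names(
    reports: Sequence[SpontaneousReport],
    dictionary: Mapping[str, str],
    log: Optional[CleaningLog] = None,
) -> list[SpontaneousReport]:
    """Replace verbatim drug names by canonical ingredient names.

    Lookup is case- and whitespace-insensitive; unmapped names pass through
    verbatim and are counted (one count per drug entry). Idempotent whenever
    the dictionary maps canonical names to themselves.
    """
    from dataclasses import replace

    log = log if log is not None else CleaningLog()
    out = []
    for r in reports:
        entries = []
        for name, role in r.drugs:
            canonical = dictionary.get(_name_key(name))
            if canonical is None:
                log.bump("unmapped_drug_names")
                canonical = name
            entries.append((canonical, role))
        out.append(replace(r, drugs=tuple(entries)))
    return out


def filter_primary_suspect(
    reports: Sequence[SpontaneousReport], drug: str
) -> list[SpontaneousReport]:
    """Reports naming ``drug`` with the primary-suspect role on any entry."""
    return [r for r in reports if r.has_drug(drug, ROLE_PS)]


def attach_soc(
    reports: Sequence[SpontaneousReport],
    pt_soc: PtSocMap,
    log: Optional[CleaningLog] = None,
) -> list[SpontaneousReport]:
    """Attach each PT's primary SOC; PTs absent from the map get the sentinel
    ``UNMAPPED`` SOC (kept, so marginal totals are preserved) and counted."""
    from dataclasses import replace

    if not pt_soc.entries:
        raise ValueError("empty PT->SOC map")
    log = log if log is not None else CleaningLog()
    out = []
    for r in reports:
        events = []
        for pt, _ in r.events:
            soc = pt_soc.soc_of(pt)
            if soc is None:
                log.bump("unmapped_pts")
                soc = UNMAPPED_SOC
            events.append((pt, soc))
        out.append(replace(r, events=tuple(events)))
    return out


def clean_universe(
    records: Sequence[RawCaseRecord],
    dictionary: Mapping[str, str],
    pt_soc: PtSocMap,
    log: Optional[CleaningLog] = None,
) -> list[SpontaneousReport]:
    """Deduplicate, normalize drug names and attach SOCs in one call. The
    result is the full analysis universe (not PS-filtered): 2x2 tables need
    the comparator reports too."""
    log = log if log is not None else CleaningLog()
    reports = deduplicate(records, log)
    reports = normalize_drug_names(reports, dictionary, log)
    return attach_soc(reports, pt_soc, log)
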