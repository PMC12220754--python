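"""Synthetic spontaneous-report generator with known ground truth.

Emulates the statistical structure of a spontaneous adverse-event reporting
stream (FAERS-like): each case carries one or more drugs with role codes, one
or more MedDRA-style preferred terms (PTs), demographics, serious-outcome
codes, a receipt date, and possibly several case versions (duplicates).

The event model is deliberately simple so that ground truth is available in
closed form: every PT is an independent Bernoulli draw per report with
probability ``baseline_event_prob``, multiplied by the relative rate of any
planted (drug, PT) signal whenever the report carries that drug (capped at 1).
Under this model the population odds ratio of a planted pair, in the
primary-suspect 2x2 universe used downstream, is a known function of the
configuration (see :func:`planted_odds_ratio`).
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

ROLE_PS = "PS"
ROLE_SS = "SS"
ROLE_C = "C"
ROLE_I = "I"
SECONDARY_ROLES = (ROLE_SS, ROLE_C, ROLE_I)

OUTCOME_CODES = ("DE", "DS", "HO", "LT")

SEX_LEVELS = ("male", "female", "unspecified")
AGE_GROUPS = ("<18", "18-44", "45-64", "65-74", ">=75", "unspecified")
REPORTER_LEVELS = (
    "consumer",
    "lawyer",
    "physician",
    "other health-professional",
    "pharmacist",
    "unspecified",
)

# Reference cohort profile: montelukast primary-suspect reports with
# demographics, FAERS 2004Q1-2023Q3 (19,630 events). Used both as the default
# demographic mix of the generator and as a fixed fixture for descriptive
# statistics.
REFERENCE_COHORT_SIZE = 19630
REFERENCE_SEX_COUNTS = {"male": 10405, "female": 7327, "unspecified": 1898}
REFERENCE_AGE_COUNTS = {
    "<18": 6088,
    "18-44": 3104,
    "45-64": 3180,
    "65-74": 1259,
    ">=75": 699,
    "unspecified": 5300,
}
REFERENCE_COUNTRY_COUNTS = {
    "US": 10228,
    "GB": 3560,
    "CA": 1707,
    "FR": 486,
    "JP": 384,
    "OTHER": 3265,
}
REFERENCE_OUTCOME_COUNTS = {"LT": 1378, "HO": 3987, "DS": 2207, "DE": 497}
REFERENCE_REPORTER_COUNTS = {
    "consumer": 7702,
    "lawyer": 286,
    "physician": 4565,
    "other health-professional": 3540,
    "pharmacist": 2316,
    "unspecified": 1221,
}
REFERENCE_PEAK_YEAR = 2013
REFERENCE_PEAK_YEAR_COUNT = 2132
REFERENCE_YEAR_SPAN = (2004, 2023)

_AGE_BOUNDS = {
    "<18": (1, 17),
    "18-44": (18, 44),
    "45-64": (45, 64),
    "65-74": (65, 74),
    ">=75": (75, 100),
}


def reference_year_counts() -> dict[int, int]:
    """Annual report counts of the reference cohort: the 2013 peak carries its
    exact share (2,132 of 19,630); the remainder is spread evenly over the
    other years of the 2004-2023 span."""
    lo, hi = REFERENCE_YEAR_SPAN
    other_years = [y for y in range(lo, hi + 1) if y != REFERENCE_PEAK_YEAR]
    rest = REFERENCE_COHORT_SIZE - REFERENCE_PEAK_YEAR_COUNT
    base, extra = divmod(rest, len(other_years))
    counts = {y: base + (1 if i < extra else 0) for i, y in enumerate(other_years)}
    counts[REFERENCE_PEAK_YEAR] = REFERENCE_PEAK_YEAR_COUNT
    return dict(sorted(counts.items()))


@dataclass(frozen=True)
class DemographicMix:
    """Categorical distributions for the demographic fields of a report.

    ``sex``, ``age_group``, ``country``, ``reporter`` and ``year`` are
    probability tables (values sum to 1); ``outcome_probs`` are *independent*
    per-code probabilities, because a report may carry several serious-outcome
    codes at once.
    """

    sex: Mapping[str, float]
    age_group: Mapping[str, float]
    country: Mapping[str, float]
    reporter: Mapping[str, float]
    outcome_probs: Mapping[str, float]
    year: Mapping[int, float]

    def validate(self) -> None:
        for name in ("sex", "age_group", "country", "reporter", "year"):
            table = getattr(self, name)
            if not table:
                raise ValueError(f"empty demographic table: {name}")
            probs = np.asarray(list(table.values()), dtype=float)
            if (probs < 0).any() or (probs > 1).any():
                raise ValueError(f"{name} probabilities outside [0, 1]")
            if not math.isclose(probs.sum(), 1.0, abs_tol=1e-6):
                raise ValueError(f"{name} probabilities must sum to 1")
        for code, p in self.outcome_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"outcome probability for {code} outside [0, 1]")


def default_demographic_mix() -> DemographicMix:
    """Demographic mix matching the reference cohort profile."""
    n = REFERENCE_COHORT_SIZE
    return DemographicMix(
        sex={k: v / n for k, v in REFERENCE_SEX_COUNTS.items()},
        age_group={k: v / n for k, v in REFERENCE_AGE_COUNTS.items()},
        country={k: v / n for k, v in REFERENCE_COUNTRY_COUNTS.items()},
        reporter={k: v / n for k, v in REFERENCE_REPORTER_COUNTS.items()},
        outcome_probs={k: v / n for k, v in REFERENCE_OUTCOME_COUNTS.items()},
        year={k: v / n for k, v in reference_year_counts().items()},
    )


@dataclass(frozen=True)
class RawCaseRecord:
    """One case version, as it would appear in a quarterly extract.

    ``is_latest_version`` is generator ground truth for deduplication tests
    and is excluded from equality so that write/read round-trips compare
    record-equal.
    """

    case_id: str
    case_version: int
    receipt_date: dt.date
    sex: str
    age: Optional[int]
    country: str
    reporter: str
    drug_entries: tuple[tuple[str, str], ...]
    event_entries: tuple[str, ...]
    outcome_codes: tuple[str, ...]
    is_latest_version: bool = field(default=True, compare=False)

    def __post_init__(self) -> None:
        if not self.drug_entries:
            raise ValueError("a case record needs at least one drug entry")
        if not self.event_entries:
            raise ValueError("a case record needs at least one event entry")
        if self.case_version < 1:
            raise ValueError("case_version must be a positive integer")

    @property
    def primaryid(self) -> str:
        return f"{self.case_id}{self.case_version}"


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic report stream.

    planted_signals are (drug, PT, relative-rate multiplier) triples: reports
    carrying the drug draw the PT with probability
    min(1, baseline_event_prob * multiplier). A multiplier of 1 is the null.
    """

    n_reports: int
    drug_vocab: tuple[str, ...]
    event_vocab: tuple[tuple[str, str], ...]  # (PT, SOC) pairs
    baseline_event_prob: float = 0.02
    planted_signals: tuple[tuple[str, str, float], ...] = ()
    drug_exposure_prob: float = 0.15
    duplicate_rate: float = 0.0
    demographic_mix: DemographicMix = field(default_factory=default_demographic_mix)
    background_pt: Optional[str] = "Drug ineffective"
    background_pt_soc: str = "General disorders and administration site conditions"
    background_drug: str = "UNSPECIFIED CO-MEDICATION"
    seed: int = 0

    def validate(self) -> None:
        if self.n_reports <= 0:
            raise ValueError("n_reports must be positive")
        if not self.drug_vocab:
            raise ValueError("drug_vocab is empty")
        if not self.event_vocab:
            raise ValueError("event_vocab is empty")
        if len(set(self.drug_vocab)) != len(self.drug_vocab):
            raise ValueError("drug_vocab entries must be unique")
        pts = [pt for pt, _ in self.event_vocab]
        if len(set(pts)) != len(pts):
            raise ValueError("event_vocab PTs must be unique")
        for p, name in (
            (self.baseline_event_prob, "baseline_event_prob"),
            (self.drug_exposure_prob, "drug_exposure_prob"),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} outside [0, 1]")
        if not 0.0 <= self.duplicate_rate < 1.0:
            raise ValueError("duplicate_rate outside [0, 1)")
        known_pts = set(pts) | ({self.background_pt} if self.background_pt else set())
        for drug, pt, mult in self.planted_signals:
            if drug not in self.drug_vocab:
                raise ValueError(f"planted drug {drug!r} not in drug_vocab")
            if pt not in known_pts:
                raise ValueError(f"planted PT {pt!r} not in event_vocab")
            if mult < 0:
                raise ValueError("planted multiplier must be >= 0")
        self.demographic_mix.validate()

    @property
    def effective_event_vocab(self) -> tuple[tuple[str, str], ...]:
        """Event vocabulary with the background PT appended when configured
        and not already present."""
        if self.background_pt is None:
            return self.event_vocab
        if any(pt == self.background_pt for pt, _ in self.event_vocab):
            return self.event_vocab
        return self.event_vocab + ((self.background_pt, self.background_pt_soc),)


def _sample_categorical(
    rng: np.random.Generator, table: Mapping, size: int
) -> np.ndarray:
    levels = list(table.keys())
    probs = np.asarray(list(table.values()), dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(len(levels), size=size, p=probs)
    return np.asarray(levels, dtype=object)[idx]


def generate_reports(config: GeneratorConfig) -> list[RawCaseRecord]:
    """Draw ``config.n_reports`` case records (all version 1, distinct ids).

    Fully reproducible from ``config.seed``: the draw order is fixed
    (exposures, events, roles, demographics) regardless of parameter values.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    drugs = config.drug_vocab
    vocab = config.effective_event_vocab
    pts = [pt for pt, _ in vocab]
    d_index = {name: j for j, name in enumerate(drugs)}
    p_index = {pt: k for k, pt in enumerate(pts)}

    exposed = rng.random((n, len(drugs))) < config.drug_exposure_prob

    prob = np.full((n, len(pts)), config.baseline_event_prob)
    for drug, pt, mult in config.planted_signals:
        mask = exposed[:, d_index[drug]]
        prob[mask, p_index[pt]] *= mult
    np.clip(prob, 0.0, 1.0, out=prob)
    events = rng.random((n, len(pts))) < prob

    no_event = ~events.any(axis=1)
    if no_event.any():
        if config.background_pt is None:
            raise ValueError(
                "a report drew zero events and no background PT is configured"
            )
        events[no_event, p_index[config.background_pt]] = True

    # role draws are made up-front so the stream is identical however many
    # drugs a given report carries
    ps_pick = rng.random(n)
    secondary = rng.integers(0, len(SECONDARY_ROLES), size=(n, len(drugs)))

    sex = _sample_categorical(rng, config.demographic_mix.sex, n)
    age_group = _sample_categorical(rng, config.demographic_mix.age_group, n)
    age_frac = rng.random(n)
    country = _sample_categorical(rng, config.demographic_mix.country, n)
    reporter = _sample_categorical(rng, config.demographic_mix.reporter, n)
    out_codes = list(config.demographic_mix.outcome_probs.keys())
    out_probs = np.asarray(list(config.demographic_mix.outcome_probs.values()))
    outcomes = rng.random((n, len(out_codes))) < out_probs
    year = _sample_categorical(rng, config.demographic_mix.year, n)
    month = rng.integers(1, 13, size=n)
    day = rng.integers(1, 29, size=n)

    reports: list[RawCaseRecord] = []
    for i in range(n):
        exp_idx = np.flatnonzero(exposed[i])
        if exp_idx.size:
            ps_j = exp_idx[int(ps_pick[i] * exp_idx.size)]
            entries = tuple(
                (drugs[j], ROLE_PS if j == ps_j else SECONDARY_ROLES[secondary[i, j]])
                for j in exp_idx
            )
        else:
            entries = ((config.background_drug, ROLE_C),)
        grp = age_group[i]
        if grp == "unspecified":
            age = None
        else:
            lo, hi = _AGE_BOUNDS[grp]
            age = lo + int(age_frac[i] * (hi - lo + 1))
        reports.append(
            RawCaseRecord(
                case_id=str(10_000_000 + i),
                case_version=1,
                receipt_date=dt.date(int(year[i]), int(month[i]), int(day[i])),
                sex=str(sex[i]),
                age=age,
                country=str(country[i]),
                reporter=str(reporter[i]),
                drug_entries=entries,
                event_entries=tuple(pts[k] for k in np.flatnonzero(events[i])),
                outcome_codes=tuple(
                    c for c, hit in zip(out_codes, outcomes[i]) if hit
                ),
            )
        )
    return reports


def inject_duplicates(
    reports: Sequence[RawCaseRecord], duplicate_rate: float, seed: int
) -> list[RawCaseRecord]:
    """Re-emit floor(rate * n) seeded-selected cases with an incremented case
    version and a later receipt date; the superseded originals are flagged
    ``is_latest_version=False`` (ground truth for deduplication)."""
    if not 0.0 <= duplicate_rate < 1.0:
        raise ValueError("duplicate_rate outside [0, 1)")
    n_dup = int(duplicate_rate * len(reports))
    if n_dup == 0:
        return list(reports)
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(len(reports), size=n_dup, replace=False).tolist())
    out = list(reports)
    for i in chosen:
        src = out[i]
        out[i] = replace(src, is_latest_version=False)
        out.append(
            replace(
                src,
                case_version=src.case_version + 1,
                receipt_date=src.receipt_date + dt.timedelta(days=int(rng.integers(1, 91))),
                is_latest_version=True,
            )
        )
    return out


# --- FAERS quarterly ASCII dialect -----------------------------------------
#
# One "$"-delimited text file per table, first row = column names, no quoting
# and no escape mechanism: a field containing "$" cannot be represented and is
# rejected at write time.

DEMO_COLUMNS = (
    "primaryid", "caseid", "caseversion", "fda_dt",
    "sex", "age", "occr_country", "occp_cod",
)
DRUG_COLUMNS = ("primaryid", "drugname", "role_cod")
REAC_COLUMNS = ("primaryid", "pt")
OUTC_COLUMNS = ("primaryid", "outc_cod")
QUARTER_FILES = {
    "DEMO": DEMO_COLUMNS,
    "DRUG": DRUG_COLUMNS,
    "REAC": REAC_COLUMNS,
    "OUTC": OUTC_COLUMNS,
}

SEX_TO_CODE = {"male": "M", "female": "F", "unspecified": ""}
CODE_TO_SEX = {"M": "male", "F": "female"}
REPORTER_TO_CODE = {
    "consumer": "CN",
    "lawyer": "LW",
    "physician": "MD",
    "other health-professional": "OT",
    "pharmacist": "PH",
    "unspecified": "",
}
CODE_TO_REPORTER = {v: k for k, v in REPORTER_TO_CODE.items() if v}


def _emit_row(fields: Sequence[str]) -> str:
    for f in fields:
        if "$" in f:
            raise ValueError(f"field contains the '$' delimiter: {f!r}")
    return "$".join(fields)


def write_faers_quarter(reports: Sequence[RawCaseRecord], directory) -> dict[str, str]:
    """Write DEMO/DRUG/REAC/OUTC files for one quarter; returns table->path.

    Round-trips losslessly through :func:`pvsignal.ingest.read_faers_quarter`.
    """
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows: dict[str, list[str]] = {name: [_emit_row(cols)] for name, cols in QUARTER_FILES.items()}
    for r in reports:
        pid = r.primaryid
        rows["DEMO"].append(
            _emit_row(
                (
                    pid,
                    r.case_id,
                    str(r.case_version),
                    r.receipt_date.strftime("%Y%m%d"),
                    SEX_TO_CODE.get(r.sex, ""),
                    "" if r.age is None else str(r.age),
                    r.country,
                    REPORTER_TO_CODE.get(r.reporter, ""),
                )
            )
        )
        for name, role in r.drug_entries:
            rows["DRUG"].append(_emit_row((pid, name, role)))
        for pt in r.event_entries:
            rows["REAC"].append(_emit_row((pid, pt)))
        for code in r.outcome_codes:
            rows["OUTC"].append(_emit_row((pid, code)))
    paths = {}
    for name, lines in rows.items():
        path = directory / f"{name}.txt"
        path.write_text("\n".join(lines) + "\n")
        paths[name] = str(path)
    return paths


# --- ground truth ----------------------------------------------------------

def expected_cell_probabilities(
    config: GeneratorConfig, drug: str, pt: str
) -> tuple[float, float, float, float]:
    """Population (a, b, c, d) cell probabilities of the primary-suspect 2x2
    for one (drug, PT) pair under the generative model.

    Derivation: each of the D vocabulary drugs is exposed independently with
    probability p and the primary-suspect role is assigned uniformly among the
    exposed drugs, so P(drug is PS) = (1 - (1-p)^D) / D by symmetry. The PT is
    drawn with probability min(1, baseline * multiplier) when the drug is
    carried (PS or not) and baseline otherwise. Only valid when the PT carries
    at most one planted signal and is not the background PT.
    """
    config.validate()
    signals = [(dg, m) for dg, p, m in config.planted_signals if p == pt]
    if len(signals) > 1:
        raise ValueError("closed form requires at most one planted signal per PT")
    if pt == config.background_pt:
        raise ValueError("background PT probability is inflated by the fill-in rule")
    mult = 1.0
    if signals:
        sig_drug, m = signals[0]
        if sig_drug != drug:
            raise ValueError("PT is planted on a different drug")
        mult = m
    p = config.drug_exposure_prob
    d_count = len(config.drug_vocab)
    q_ps = (1.0 - (1.0 - p) ** d_count) / d_count
    p_event_carried = min(1.0, config.baseline_event_prob * mult)
    p_event_other = config.baseline_event_prob
    pi_a = q_ps * p_event_carried
    pi_b = q_ps * (1.0 - p_event_carried)
    pi_c = (p - q_ps) * p_event_carried + (1.0 - p) * p_event_other
    pi_d = 1.0 - pi_a - pi_b - pi_c
    return pi_a, pi_b, pi_c, pi_d


def planted_odds_ratio(config: GeneratorConfig, drug: str, pt: str) -> float:
    """True odds ratio of the primary-suspect 2x2 for a planted pair."""
    pi_a, pi_b, pi_c, pi_d = expected_cell_probabilities(config, drug, pt)
    return (pi_a * pi_d) / (pi_b * pi_c)


def multiplier_for_target_odds_ratio(
    config: GeneratorConfig, drug: str, pt: str, target_or: float
) -> float:
    """Relative-rate multiplier whose planted pair attains ``target_or`` as
    the true primary-suspect 2x2 odds ratio.

    The multiplier acts on carriage of the drug while the 2x2 conditions on
    the primary-suspect role, so the attained odds ratio is diluted below the
    multiplier; this inverts :func:`planted_odds_ratio` numerically.
    """
    from scipy.optimize import brentq

    if target_or <= 0:
        raise ValueError("target odds ratio must be positive")
    base = replace(config, planted_signals=())

    def gap(m: float) -> float:
        probed = replace(base, planted_signals=((drug, pt, m),))
        return planted_odds_ratio(probed, drug, pt) - target_or

    hi = 2.0
    while gap(hi) < 0:
        hi *= 2.0
        if min(1.0, config.baseline_event_prob * hi) >= 1.0:
            raise ValueError("target odds ratio unattainable (probability capped at 1)")
    return float(brentq(gap, 1e-9, hi, xtol=1e-12))


def build_reference_cohort():
    """Deterministically construct the 19,630-report reference cohort whose
    category counts equal the reference profile exactly (each categorical
    field is assigned independently by slicing, serious outcomes by prefix).

    Returns a list of :class:`pvsignal.ingest.SpontaneousReport`.
    """
    from .ingest import SpontaneousReport

    n = REFERENCE_COHORT_SIZE

    def expand(counts):
        out = []
        for level, k in counts.items():
            out.extend([level] * k)
        return out

    sex = expand(REFERENCE_SEX_COUNTS)
    age = expand(REFERENCE_AGE_COUNTS)
    country = expand(REFERENCE_COUNTRY_COUNTS)
    reporter = expand(REFERENCE_REPORTER_COUNTS)
    years = expand(reference_year_counts())
    outcome_sets = []
    for i in range(n):
        codes = tuple(
            code
            for code in OUTCOME_CODES
            if i < REFERENCE_OUTCOME_COUNTS.get(code, 0)
        )
        outcome_sets.append(codes)
    return [
        SpontaneousReport(
            case_id=str(20_000_000 + i),
            case_version=1,
            receipt_year=years[i],
            sex=sex[i],
            age_group=age[i],
            country=country[i],
            reporter=reporter[i],
            drugs=(("MONTELUKAST", ROLE_PS),),
            events=(("Nightmare", "Psychiatric disorders"),),
            serious_outcomes=outcome_sets[i],
        )
        for i in range(n)
    ]
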