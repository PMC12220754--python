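"""Disproportionality statistics and the four-way signal rule.

Four classical measures of a drug-event pair's over-reporting on the 2x2
table (a, b, c, d; N = a+b+c+d):

* ROR  — reporting odds ratio ad/bc, Wald 95% CI on the log scale.
* PRR  — proportional reporting ratio [a/(a+b)] / [c/(c+d)] with the
  uncorrected chi-square statistic (ad-bc)^2 N / ((a+b)(a+c)(c+d)(b+d)).
* BCPNN — information component IC = log2(aN/((a+b)(a+c))) with Bayesian
  shrinkage: posterior mean E(IC) and variance V(IC) under Dirichlet priors
  (alpha1 = beta1 = 1, alpha = beta = 2, gamma11 = 1, gamma scaled so the
  prior IC is centred at 0); the signal bound is IC-2SD = E(IC) - 2*sqrt(V).
* EBGM — the relative reporting ratio aN/((a+c)(a+b)) with log-scale 95%
  bounds. Note this unshrunk ratio equals 2^IC identically; a true
  gamma-Poisson shrinkage backend is a hook for the future.

A pair is a signal only when all four criteria hold simultaneously:
a >= 3 with ROR CI lower bound > 1; the same plus PRR >= 2 and chi2 >= 4;
IC-2SD > 0; EBGM05 > 2. Statistics undefined on zero cells fail their
criterion (an optional Haldane-Anscombe +0.5 correction is available but
off by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .contingency import ContingencyTable, build_all_tables
from .ingest import SpontaneousReport

Z95 = 1.96

# BCPNN prior hyperparameters
ALPHA1 = 1.0
BETA1 = 1.0
ALPHA = 2.0
BETA = 2.0
GAMMA11 = 1.0

TIER_NONE = "none"
TIER_WEAK = "weak"
TIER_MEDIUM = "medium"
TIER_STRONG = "strong"


@dataclass(frozen=True)
class SignalThresholds:
    """Signal criteria; defaults are the classical published thresholds."""

    min_cases: int = 3
    ror_ci_low: float = 1.0
    prr_ci_low: float = 1.0
    prr_min: float = 2.0
    chi2_min: float = 4.0
    ic_2sd_min: float = 0.0
    ebgm05_min: float = 2.0

    def validate(self) -> None:
        if self.min_cases < 0:
            raise ValueError("min_cases must be >= 0")
        for name in ("ror_ci_low", "prr_ci_low", "prr_min", "chi2_min", "ebgm05_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class RORResult:
    ror: float
    ci_low: float
    ci_high: float
    defined: bool


@dataclass(frozen=True)
class PRRResult:
    prr: float
    ci_low: float
    ci_high: float
    chi2: float
    defined: bool


@dataclass(frozen=True)
class BCPNNResult:
    ic: float  # naive information component (no shrinkage); -inf when a = 0
    e_ic: float
    v_ic: float
    ic_minus_2sd: float
    tier: str
    defined: bool


@dataclass(frozen=True)
class EBGMResult:
    ebgm: float
    ebgm05: float
    ebgm95: float
    defined: bool  # point estimate defined; CI additionally needs all cells > 0


@dataclass(frozen=True)
class SignalVerdict:
    ror_pass: bool
    prr_pass: bool
    bcpnn_pass: bool
    ebgm_pass: bool

    @property
    def overall(self) -> bool:
        return self.ror_pass and self.prr_pass and self.bcpnn_pass and self.ebgm_pass


def _corrected(t: ContingencyTable, correction: bool) -> tuple[float, float, float, float]:
    a, b, c, d = t.cells()
    if correction and min(a, b, c, d) == 0:
        return (a + 0.5, b + 0.5, c + 0.5, d + 0.5)
    return (float(a), float(b), float(c), float(d))


def compute_ror(t: ContingencyTable, correction: bool = False) -> RORResult:
    """Reporting odds ratio with Wald 95% CI; undefined on any zero cell
    unless the Haldane-Anscombe correction is requested."""
    a, b, c, d = _corrected(t, correction)
    if min(a, b, c, d) <= 0:
        return RORResult(math.nan, math.nan, math.nan, defined=False)
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return RORResult(
        ror=ror,
        ci_low=math.exp(math.log(ror) - Z95 * se),
        ci_high=math.exp(math.log(ror) + Z95 * se),
        defined=True,
    )


def compute_prr(t: ContingencyTable, correction: bool = False) -> PRRResult:
    """Proportional reporting ratio, its Wald CI (SE on the log scale is
    sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d))) and the uncorrected chi-square.

    Defined for a > 0 and c > 0 (b may be 0: the 1/a - 1/(a+b) term simply
    vanishes). chi2 is NaN when any table margin is empty.
    """
    a, b, c, d = _corrected(t, correction)
    n = a + b + c + d
    if a <= 0 or c <= 0 or (a + b) <= 0 or (c + d) <= 0:
        return PRRResult(math.nan, math.nan, math.nan, math.nan, defined=False)
    prr = (a / (a + b)) / (c / (c + d))
    se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    margins = (a + b) * (a + c) * (c + d) * (b + d)
    chi2 = ((a * d - b * c) ** 2 * n / margins) if margins > 0 else math.nan
    return PRRResult(
        prr=prr,
        ci_low=math.exp(math.log(prr) - Z95 * se),
        ci_high=math.exp(math.log(prr) + Z95 * se),
        chi2=chi2,
        defined=True,
    )


def ic_tier(ic_minus_2sd: float) -> str:
    """Signal tier from the IC-2SD bound: none (<=0), weak (0,1.5],
    medium (1.5,3], strong (>3)."""
    if not (ic_minus_2sd > 0):  # NaN also lands here
        return TIER_NONE
    if ic_minus_2sd <= 1.5:
        return TIER_WEAK
    if ic_minus_2sd <= 3.0:
        return TIER_MEDIUM
    return TIER_STRONG


def compute_bcpnn(t: ContingencyTable) -> BCPNNResult:
    """Information component with Bayesian shrinkage.

    gamma = gamma11 (N+alpha)(N+beta) / ((a+b+alpha1)(a+c+beta1)), which
    centres the prior IC at zero;

    E(IC) = log2 [ (a+gamma11)(N+alpha)(N+beta)
                   / ((N+gamma)(a+b+alpha1)(a+c+beta1)) ]

    V(IC) = (ln 2)^-2 [ (N-a+gamma-gamma11) / ((a+gamma11)(1+N+gamma))
                      + (N-(a+b)+alpha-alpha1) / ((a+b+alpha1)(1+N+alpha))
                      + (N-(a+c)+beta-beta1) / ((a+c+beta1)(1+N+beta)) ]

    Finite for zero cells (the priors regularize); requires N > 0.
    """
    a, b, c, d = (float(x) for x in t.cells())
    n = a + b + c + d
    if n <= 0:
        raise ValueError("empty table: N must be positive")
    margin_x = a + b
    margin_y = a + c
    if a > 0 and margin_x > 0 and margin_y > 0:
        ic = math.log2(a * n / (margin_x * margin_y))
    else:
        ic = -math.inf
    gamma = GAMMA11 * (n + ALPHA) * (n + BETA) / ((margin_x + ALPHA1) * (margin_y + BETA1))
    e_ic = math.log2(
        (a + GAMMA11)
        * (n + ALPHA)
        * (n + BETA)
        / ((n + gamma) * (margin_x + ALPHA1) * (margin_y + BETA1))
    )
    v_ic = (
        (n - a + gamma - GAMMA11) / ((a + GAMMA11) * (1 + n + gamma))
        + (n - margin_x + ALPHA - ALPHA1) / ((margin_x + ALPHA1) * (1 + n + ALPHA))
        + (n - margin_y + BETA - BETA1) / ((margin_y + BETA1) * (1 + n + BETA))
    ) / math.log(2) ** 2
    ic_minus_2sd = e_ic - 2.0 * math.sqrt(v_ic)
    return BCPNNResult(
        ic=ic,
        e_ic=e_ic,
        v_ic=v_ic,
        ic_minus_2sd=ic_minus_2sd,
        tier=ic_tier(ic_minus_2sd),
        defined=True,
    )


def compute_ebgm(t: ContingencyTable, correction: bool = False) -> EBGMResult:
    """Relative reporting ratio aN/((a+c)(a+b)) with log-scale 95% bounds
    (SE sqrt(1/a+1/b+1/c+1/d), so the CI needs all cells > 0)."""
    a, b, c, d = _corrected(t, correction)
    n = a + b + c + d
    if (a + b) <= 0 or (a + c) <= 0:
        return EBGMResult(math.nan, math.nan, math.nan, defined=False)
    ebgm = a * n / ((a + c) * (a + b))
    if min(a, b, c, d) > 0:
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        lo = math.exp(math.log(ebgm) - Z95 * se)
        hi = math.exp(math.log(ebgm) + Z95 * se)
    else:
        lo = hi = math.nan
    return EBGMResult(ebgm=ebgm, ebgm05=lo, ebgm95=hi, defined=True)


def evaluate_criteria(
    ror: RORResult,
    prr: PRRResult,
    bcpnn: BCPNNResult,
    ebgm: EBGMResult,
    a: int,
    thresholds: SignalThresholds = SignalThresholds(),
) -> SignalVerdict:
    """Per-method pass/fail and the four-way conjunction; undefined
    statistics fail their criterion."""
    thresholds.validate()
    enough = a >= thresholds.min_cases
    ror_pass = bool(ror.defined and enough and ror.ci_low > thresholds.ror_ci_low)
    prr_pass = bool(
        prr.defined
        and enough
        and prr.ci_low > thresholds.prr_ci_low
        and prr.prr >= thresholds.prr_min
        and not math.isnan(prr.chi2)
        and prr.chi2 >= thresholds.chi2_min
    )
    bcpnn_pass = bool(bcpnn.defined and bcpnn.ic_minus_2sd > thresholds.ic_2sd_min)
    ebgm_pass = bool(
        ebgm.defined
        and not math.isnan(ebgm.ebgm05)
        and ebgm.ebgm05 > thresholds.ebgm05_min
    )
    return SignalVerdict(
        ror_pass=ror_pass,
        prr_pass=prr_pass,
        bcpnn_pass=bcpnn_pass,
        ebgm_pass=ebgm_pass,
    )


@dataclass(frozen=True)
class ScreenResult:
    table: ContingencyTable
    ror: RORResult
    prr: PRRResult
    bcpnn: BCPNNResult
    ebgm: EBGMResult
    verdict: SignalVerdict


def compute_all(
    t: ContingencyTable,
    thresholds: SignalThresholds = SignalThresholds(),
    correction: bool = False,
) -> ScreenResult:
    ror = compute_ror(t, correction)
    prr = compute_prr(t, correction)
    bcpnn = compute_bcpnn(t)
    ebgm = compute_ebgm(t, correction)
    verdict = evaluate_criteria(ror, prr, bcpnn, ebgm, t.a, thresholds)
    return ScreenResult(table=t, ror=ror, prr=prr, bcpnn=bcpnn, ebgm=ebgm, verdict=verdict)


def _rank_key(res: ScreenResult, rank_by: str):
    if rank_by == "ror":
        primary = res.ror.ror if res.ror.defined else -math.inf
    elif rank_by == "cases":
        primary = res.table.a
    else:
        raise ValueError(f"unknown ranking key: {rank_by!r}")
    return (-primary, -res.table.a, res.table.event)


def screen(
    reports: Sequence[SpontaneousReport],
    drug: str,
    rank_by: str = "ror",
    thresholds: SignalThresholds = SignalThresholds(),
    correction: bool = False,
) -> list[ScreenResult]:
    """Evaluate every PT- and SOC-level pair for one drug over the cleaned
    universe, ranked by ROR (default) or by case count, descending."""
    tables = build_all_tables(reports, drug)
    results = [compute_all(t, thresholds, correction) for t in tables]
    results.sort(key=lambda r: _rank_key(r, rank_by))
    return results


def screen_frame(results: Sequence[ScreenResult]) -> pd.DataFrame:
    """Full-precision tabular view of a screen; one row per pair."""
    rows = []
    for r in results:
        t = r.table
        rows.append(
            {
                "drug": t.drug,
                "level": t.level,
                "event": t.event,
                "a": t.a,
                "b": t.b,
                "c": t.c,
                "d": t.d,
                "N": t.n,
                "ror": r.ror.ror,
                "ror_ci_low": r.ror.ci_low,
                "ror_ci_high": r.ror.ci_high,
                "prr": r.prr.prr,
                "prr_ci_low": r.prr.ci_low,
                "prr_ci_high": r.prr.ci_high,
                "chi2": r.prr.chi2,
                "ic": r.bcpnn.ic,
                "e_ic": r.bcpnn.e_ic,
                "ic_minus_2sd": r.bcpnn.ic_minus_2sd,
                "ic_tier": r.bcpnn.tier,
                "ebgm": r.ebgm.ebgm,
                "ebgm05": r.ebgm.ebgm05,
                "ebgm95": r.ebgm.ebgm95,
                "ror_pass": r.verdict.ror_pass,
                "prr_pass": r.verdict.prr_pass,
                "bcpnn_pass": r.verdict.bcpnn_pass,
                "ebgm_pass": r.verdict.ebgm_pass,
                "signal": r.verdict.overall,
            }
        )
    return pd.DataFrame(rows)


def _fmt(x: float, nd: int = 2) -> str:
    # half-up rounding, matching the descriptives convention
    from decimal import ROUND_HALF_UP, Decimal

    if x is None or (isinstance(x, float) and (math.isnan(x) or math.isinf(x))):
        return "NA"
    return str(Decimal(x).quantize(Decimal(1).scaleb(-nd), rounding=ROUND_HALF_UP))


def format_signal_table(
    results: Sequence[ScreenResult],
    level: Optional[str] = None,
    top_n: Optional[int] = None,
) -> pd.DataFrame:
    """Report-style view: case counts plus "estimate(bound)" strings rounded
    to 2 decimals — ROR(95% CI), PRR(chi2), E(IC)(IC-2SD), EBGM(EBGM05)."""
    rows = []
    for r in results:
        if level is not None and r.table.level != level:
            continue
        rows.append(
            {
                "level": r.table.level,
                "event": r.table.event,
                "case_reports": r.table.a,
                "ROR(95% CI)": f"{_fmt(r.ror.ror)}({_fmt(r.ror.ci_low)}-{_fmt(r.ror.ci_high)})",
                "PRR(chi2)": f"{_fmt(r.prr.prr)}({_fmt(r.prr.chi2)})",
                "IC(IC-2SD)": f"{_fmt(r.bcpnn.e_ic)}({_fmt(r.bcpnn.ic_minus_2sd)})",
                "EBGM(EBGM05)": f"{_fmt(r.ebgm.ebgm)}({_fmt(r.ebgm.ebgm05)})",
                "signal": r.verdict.overall,
            }
        )
        if top_n is not None and len(rows) >= top_n:
            break
    return pd.DataFrame(rows)
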