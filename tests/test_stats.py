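"""Signal statistics: worked examples frozen from a high-precision symbolic
oracle, published criteria, and algebraic invariants of the formulas."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import pvsignal as pv
from pvsignal.contingency import ContingencyTable
from pvsignal.stats import TIER_MEDIUM, TIER_NONE, TIER_STRONG, TIER_WEAK, ic_tier

from .oracles import oracle_stats


def table(a, b, c, d, level="PT"):
    return ContingencyTable(drug="X", event="Y", level=level, a=a, b=b, c=c, d=d)


cells_pos = st.integers(min_value=1, max_value=10_000)


class TestWorkedExamples:
    """Frozen values computed with the exact-rational sympy oracle."""

    def test_balanced_table_is_null(self):
        r = pv.compute_all(table(5, 5, 5, 5))
        assert r.ror.ror == pytest.approx(1.0)
        assert r.prr.prr == pytest.approx(1.0)
        assert r.ebgm.ebgm == pytest.approx(1.0)
        assert r.prr.chi2 == 0.0
        assert r.ror.ci_low < 1.0 < r.ror.ci_high
        assert not r.verdict.overall

    def test_10_20_30_40(self):
        r = pv.compute_all(table(10, 20, 30, 40))
        assert r.ror.ror == pytest.approx(2 / 3, rel=1e-12)
        assert r.ror.ci_low == pytest.approx(0.272510367781, rel=1e-9)
        assert r.ror.ci_high == pytest.approx(1.630926735241, rel=1e-9)
        assert r.prr.prr == pytest.approx(7 / 9, rel=1e-12)
        assert r.prr.chi2 == pytest.approx(0.793650793651, rel=1e-9)
        assert r.bcpnn.ic == pytest.approx(-0.263034405834, rel=1e-9)
        assert r.bcpnn.e_ic == pytest.approx(-0.264831759194, rel=1e-9)
        assert r.bcpnn.v_ic == pytest.approx(0.244766119601, rel=1e-9)
        assert r.ebgm.ebgm == pytest.approx(5 / 6, rel=1e-12)
        assert r.ebgm.ebgm05 == pytest.approx(0.340637959726, rel=1e-9)

    def test_exact_rational_ror(self):
        assert pv.compute_ror(table(3, 1, 1, 3)).ror == pytest.approx(9.0, rel=1e-14)

    def test_prr_with_empty_b_cell(self):
        # a/(a+b) = 1; the 1/a - 1/(a+b) variance term vanishes
        r = pv.compute_prr(table(3, 0, 10, 100))
        assert r.defined
        assert r.prr == pytest.approx(11.0, rel=1e-12)
        assert r.ci_low == pytest.approx(6.091735627515, rel=1e-9)
        assert r.ci_high == pytest.approx(19.862976235126, rel=1e-9)


class TestZeroCells:
    def test_ror_undefined_without_correction(self):
        r = pv.compute_ror(table(0, 10, 10, 10))
        assert not r.defined and math.isnan(r.ror)

    def test_haldane_correction_restores_estimate(self):
        r = pv.compute_ror(table(0, 10, 10, 10), correction=True)
        assert r.defined
        assert r.ror == pytest.approx((0.5 * 10.5) / (10.5 * 10.5))

    def test_bcpnn_finite_on_empty_a_and_never_signals(self):
        r = pv.compute_bcpnn(table(0, 50, 50, 500))
        assert math.isfinite(r.e_ic) and math.isfinite(r.v_ic)
        assert r.ic == -math.inf
        assert r.ic_minus_2sd <= 0
        assert r.tier == TIER_NONE

    def test_ebgm_point_without_ci(self):
        r = pv.compute_ebgm(table(5, 0, 5, 90))
        assert r.defined and math.isnan(r.ebgm05)

    def test_undefined_statistics_fail_their_criterion(self):
        t = table(0, 10, 10, 10)
        v = pv.compute_all(t).verdict
        assert not any([v.ror_pass, v.prr_pass, v.bcpnn_pass, v.ebgm_pass])


class TestOracleEquivalence:
    def test_random_tables_match_symbolic_oracle(self):
        rng = np.random.default_rng(7)
        cells = rng.integers(1, 10_001, size=(200, 4))
        for a, b, c, d in cells:
            r = pv.compute_all(table(int(a), int(b), int(c), int(d)))
            o = oracle_stats(int(a), int(b), int(c), int(d))
            got = {
                "ror": r.ror.ror,
                "ror_ci_low": r.ror.ci_low,
                "ror_ci_high": r.ror.ci_high,
                "prr": r.prr.prr,
                "prr_ci_low": r.prr.ci_low,
                "prr_ci_high": r.prr.ci_high,
                "chi2": r.prr.chi2,
                "ic": r.bcpnn.ic,
                "e_ic": r.bcpnn.e_ic,
                "v_ic": r.bcpnn.v_ic,
                "ic_minus_2sd": r.bcpnn.ic_minus_2sd,
                "ebgm": r.ebgm.ebgm,
                "ebgm05": r.ebgm.ebgm05,
                "ebgm95": r.ebgm.ebgm95,
            }
            for key, expected in o.items():
                err = abs(got[key] - expected) / max(abs(expected), 1e-300)
                assert err < 1e-10, (key, (a, b, c, d), got[key], expected)

    def test_ror_ci_against_statsmodels(self):
        sm_ct = pytest.importorskip("statsmodels.stats.contingency_tables")
        t = table(12, 34, 56, 789)
        r = pv.compute_ror(t)
        ref = sm_ct.Table2x2(np.array([[12, 34], [56, 789]]))
        assert r.ror == pytest.approx(ref.oddsratio, rel=1e-12)
        lo, hi = ref.oddsratio_confint(0.05)
        # statsmodels uses z from the normal quantile, not the rounded 1.96
        assert r.ci_low == pytest.approx(lo, rel=1e-3)
        assert r.ci_high == pytest.approx(hi, rel=1e-3)

    def test_chi2_against_scipy(self):
        from scipy.stats import chi2_contingency

        t = table(12, 34, 56, 789)
        ref = chi2_contingency(np.array([[12, 34], [56, 789]]), correction=False)
        assert pv.compute_prr(t).chi2 == pytest.approx(ref.statistic, rel=1e-12)


class TestInvariants:
    @given(cells_pos, cells_pos, cells_pos, cells_pos)
    def test_ebgm_equals_two_to_the_ic(self, a, b, c, d):
        r = pv.compute_all(table(a, b, c, d))
        assert 2 ** r.bcpnn.ic == pytest.approx(r.ebgm.ebgm, rel=1e-12)

    @given(cells_pos, cells_pos, cells_pos, cells_pos)
    def test_chi2_zero_iff_independent(self, a, b, c, d):
        r = pv.compute_prr(table(a, b, c, d))
        if a * d == b * c:
            assert r.chi2 == pytest.approx(0.0, abs=1e-9)
        else:
            assert r.chi2 > 0

    @given(cells_pos, cells_pos, cells_pos)
    def test_ror_monotone_in_a(self, b, c, d):
        rors = [pv.compute_ror(table(a, b, c, d)).ror for a in (1, 5, 25, 125)]
        assert all(x < y for x, y in zip(rors, rors[1:]))

    @given(cells_pos, cells_pos, cells_pos, cells_pos)
    def test_ci_brackets_point_estimates(self, a, b, c, d):
        r = pv.compute_all(table(a, b, c, d))
        assert r.ror.ci_low <= r.ror.ror <= r.ror.ci_high
        assert r.prr.ci_low <= r.prr.prr <= r.prr.ci_high
        assert r.ebgm.ebgm05 <= r.ebgm.ebgm <= r.ebgm.ebgm95
        assert r.bcpnn.ic_minus_2sd < r.bcpnn.e_ic

    @pytest.mark.parametrize("k", [1, 10, 100, 1000])
    def test_shrinkage_vanishes_for_large_counts(self, k):
        base = (10, 20, 30, 40)
        r = pv.compute_bcpnn(table(*(k * x for x in base)))
        o = oracle_stats(*(k * x for x in base))
        gap = abs(r.e_ic - r.ic)
        assert r.e_ic == pytest.approx(o["e_ic"], rel=1e-10)
        if k > 1:
            prev = pv.compute_bcpnn(table(*((k // 10 or 1) * x for x in base)))
            assert gap < abs(prev.e_ic - prev.ic)
            assert r.v_ic < prev.v_ic
        if k == 1000:
            assert gap < 1e-3 and r.v_ic < 1e-3


class TestCriteria:
    def test_fewer_than_three_cases_never_signals(self):
        # an extreme table: huge disproportionality but a = 2
        r = pv.compute_all(table(2, 1, 1, 100_000))
        assert not r.verdict.ror_pass
        assert not r.verdict.prr_pass
        assert not r.verdict.overall

    @pytest.mark.parametrize(
        "value,tier",
        [
            (-0.5, TIER_NONE),
            (0.0, TIER_NONE),
            (0.1, TIER_WEAK),
            (1.5, TIER_WEAK),
            (2.0, TIER_MEDIUM),
            (3.0, TIER_MEDIUM),
            (3.01, TIER_STRONG),
        ],
    )
    def test_ic_tiers(self, value, tier):
        assert ic_tier(value) == tier

    def test_all_thresholds_crossed_gives_overall_signal(self):
        ror = pv.RORResult(ror=3.0, ci_low=1.2, ci_high=7.0, defined=True)
        prr = pv.PRRResult(prr=2.5, ci_low=1.1, ci_high=5.0, chi2=5.0, defined=True)
        bcpnn = pv.BCPNNResult(
            ic=1.0, e_ic=0.9, v_ic=0.16, ic_minus_2sd=0.1, tier=TIER_WEAK, defined=True
        )
        ebgm = pv.EBGMResult(ebgm=3.0, ebgm05=2.1, ebgm95=4.5, defined=True)
        v = pv.evaluate_criteria(ror, prr, bcpnn, ebgm, a=3)
        assert v.overall and all([v.ror_pass, v.prr_pass, v.bcpnn_pass, v.ebgm_pass])

    @given(cells_pos, cells_pos, cells_pos, cells_pos)
    def test_conjunction_never_more_permissive_than_any_method(self, a, b, c, d):
        v = pv.compute_all(table(a, b, c, d)).verdict
        if v.overall:
            assert v.ror_pass and v.prr_pass and v.bcpnn_pass and v.ebgm_pass


class TestScreen:
    def test_planted_signal_ranks_first_and_schema(self, small_reports):
        universe = pv.clean_universe(
            small_reports, pv.load_drug_dictionary(), pv.load_toy_pt_soc_map()
        )
        results = pv.screen(universe, "MONTELUKAST")
        pt_results = [r for r in results if r.table.level == "PT"]
        assert pt_results[0].table.event == "Nightmare"
        df = pv.screen_frame(results)
        required = {
            "a", "ror", "ror_ci_low", "ror_ci_high", "prr", "chi2",
            "e_ic", "ic_minus_2sd", "ebgm", "ebgm05", "signal",
        }
        assert required <= set(df.columns)
        formatted = pv.format_signal_table(results, level="PT", top_n=5)
        assert {
            "case_reports", "ROR(95% CI)", "PRR(chi2)", "IC(IC-2SD)", "EBGM(EBGM05)"
        } <= set(formatted.columns)
        assert len(formatted) == 5

    def test_rank_by_cases(self, small_reports):
        universe = pv.clean_universe(
            small_reports, pv.load_drug_dictionary(), pv.load_toy_pt_soc_map()
        )
        results = pv.screen(universe, "MONTELUKAST", rank_by="cases")
        counts = [r.table.a for r in results]
        assert counts == sorted(counts, reverse=True)
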