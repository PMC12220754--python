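"""Independent high-precision evaluation of the four signal statistics.

Everything here is computed symbolically with sympy (exact rationals, logs
and square roots evaluated at 50 digits) straight from the published
formulas, sharing no code with :mod:`pvsignal.stats`. Used to freeze
expected values and for the formula-equivalence sweeps.
"""

from __future__ import annotations

import sympy as sp

Z = sp.Rational(196, 100)
ALPHA1 = sp.Integer(1)
BETA1 = sp.Integer(1)
ALPHA = sp.Integer(2)
BETA = sp.Integer(2)
GAMMA11 = sp.Integer(1)

PREC = 50


def _f(expr) -> float:
    return float(sp.N(expr, PREC))


def oracle_stats(a: int, b: int, c: int, d: int) -> dict[str, float]:
    """All four statistics (point estimates, bounds, chi-square, shrinkage
    moments) for one table with strictly positive cells."""
    a, b, c, d = (sp.Integer(x) for x in (a, b, c, d))
    n = a + b + c + d

    ror = a * d / (b * c)
    se_or = sp.sqrt(sp.Rational(1, 1) / a + 1 / b + 1 / c + 1 / d)
    prr = (a / (a + b)) / (c / (c + d))
    se_prr = sp.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    chi2 = (a * d - b * c) ** 2 * n / ((a + b) * (a + c) * (c + d) * (b + d))

    ic = sp.log(a * n / ((a + b) * (a + c)), 2)
    gamma = GAMMA11 * (n + ALPHA) * (n + BETA) / ((a + b + ALPHA1) * (a + c + BETA1))
    e_ic = sp.log(
        (a + GAMMA11) * (n + ALPHA) * (n + BETA)
        / ((n + gamma) * (a + b + ALPHA1) * (a + c + BETA1)),
        2,
    )
    v_ic = (
        (n - a + gamma - GAMMA11) / ((a + GAMMA11) * (1 + n + gamma))
        + (n - (a + b) + ALPHA - ALPHA1) / ((a + b + ALPHA1) * (1 + n + ALPHA))
        + (n - (a + c) + BETA - BETA1) / ((a + c + BETA1) * (1 + n + BETA))
    ) / sp.log(2) ** 2
    ic_minus_2sd = e_ic - 2 * sp.sqrt(v_ic)

    ebgm = a * n / ((a + c) * (a + b))
    se_eb = se_or

    return {
        "ror": _f(ror),
        "ror_ci_low": _f(sp.exp(sp.log(ror) - Z * se_or)),
        "ror_ci_high": _f(sp.exp(sp.log(ror) + Z * se_or)),
        "prr": _f(prr),
        "prr_ci_low": _f(sp.exp(sp.log(prr) - Z * se_prr)),
        "prr_ci_high": _f(sp.exp(sp.log(prr) + Z * se_prr)),
        "chi2": _f(chi2),
        "ic": _f(ic),
        "e_ic": _f(e_ic),
        "v_ic": _f(v_ic),
        "ic_minus_2sd": _f(ic_minus_2sd),
        "ebgm": _f(ebgm),
        "ebgm05": _f(sp.exp(sp.log(ebgm) - Z * se_eb)),
        "ebgm95": _f(sp.exp(sp.log(ebgm) + Z * se_eb)),
    }
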