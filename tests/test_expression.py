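"""RPKM, the two-library exact test, BH FDR and DEG calling.

The two-library statistic is checked against three independent routes:
an exact rational-arithmetic oracle, scipy's negative-binomial pmf
(the same distribution in closed form), and brute-force tail summation.
"""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from twolib import (
    SimulationConfig,
    ac_probability,
    ac_test,
    bh_fdr,
    call_degs,
    expression_table,
    log2_ratio,
    rpkm,
    simulate_all,
)

# ---------------------------------------------------------------- RPKM


def test_rpkm_values_and_errors():
    assert rpkm(0, 1e6, 1000) == 0.0
    assert rpkm(1000, 1e6, 1000) == pytest.approx(1000.0)
    with pytest.raises(ValueError):
        rpkm(1, 0, 100)
    with pytest.raises(ValueError):
        rpkm(1, 100, 0)


@given(st.integers(0, 10_000), st.integers(1, 10**7), st.integers(1, 10**5))
@settings(max_examples=50, deadline=None)
def test_rpkm_scales_inversely_with_depth(c, n, l):
    assert rpkm(c, 2 * n, l) == pytest.approx(rpkm(c, n, l) / 2)


# ------------------------------------------------------- log2 ratio

TABLE1_ROWS = [
    # (control RPKM, infected RPKM, printed |log2| ratio)
    (0.001, 27.68816, 14.75698),
    (5.548758, 867.0767, 7.287851),
    (7.672419, 1009.571, 7.039846),
    (3.794324, 390.9363, 6.686947),
    (28.3137, 0.366668, -6.27088),
]


@pytest.mark.parametrize("control,infected,expected", TABLE1_ROWS)
def test_log2_ratio_reproduces_printed_rows(control, infected, expected):
    assert log2_ratio(infected, control) == pytest.approx(expected, abs=5e-6)


def test_log2_ratio_floor_and_identity():
    # zero expression is clamped to the 0.001 pseudo-floor
    assert log2_ratio(27.68816, 0.0) == pytest.approx(14.75698, abs=5e-6)
    assert log2_ratio(3.0, 3.0) == 0.0
    with pytest.raises(ValueError):
        log2_ratio(1.0, 1.0, floor=0.0)


# ---------------------------------------------- two-library statistic


def exact_ac_probability(y, x, n1, n2):
    """Rational-arithmetic oracle for p(y | x)."""
    r = Fraction(n2) / Fraction(n1)
    return r**y * comb(x + y, y) / (1 + r) ** (x + y + 1)


def test_ac_probability_closed_forms():
    assert ac_probability(0, 0, 10, 10) == pytest.approx(0.5)
    assert ac_probability(1, 0, 10, 10) == pytest.approx(0.25)
    with pytest.raises(ValueError):
        ac_probability(-1, 0, 10, 10)
    with pytest.raises(ValueError):
        ac_probability(0, 0, 0, 10)


@pytest.mark.parametrize("n1,n2", [(10**6, 10**6), (2 * 10**6, 10**6), (10**6, 2 * 10**6)])
def test_ac_probability_matches_rational_oracle(n1, n2):
    for x in range(0, 51, 10):
        for y in range(0, 51, 7):
            exact = float(exact_ac_probability(y, x, n1, n2))
            assert ac_probability(y, x, n1, n2) == pytest.approx(exact, rel=1e-12)


def test_ac_probability_is_negative_binomial():
    # p(.|x) is NB(x+1 successes, p = N1/(N1+N2)) — closed-form cross-check
    n1, n2 = 3.0e6, 1.5e6
    for x, y in [(0, 0), (5, 12), (40, 3), (17, 17)]:
        nb = stats.nbinom.pmf(y, x + 1, n1 / (n1 + n2))
        assert ac_probability(y, x, n1, n2) == pytest.approx(float(nb), rel=1e-10)


@pytest.mark.parametrize("ratio", [0.5, 1.0, 2.0])
@pytest.mark.parametrize("x", [0, 1, 10, 100])
def test_ac_probability_sums_to_one(ratio, x):
    n1 = 1e6
    n2 = ratio * n1
    kmax = int(ratio * (x + 1) + 40 * np.sqrt(ratio * (1 + ratio) * (x + 1)) + 200)
    total = sum(ac_probability(k, x, n1, n2) for k in range(kmax))
    assert total == pytest.approx(1.0, abs=1e-10)


def test_ac_test_symmetric_cases():
    assert ac_test(0, 0, 1e6, 1e6) == 1.0
    assert ac_test(7, 7, 1e6, 1e6) == 1.0


def test_ac_test_matches_direct_summation():
    x, y, n = 3, 30, 10**6
    lower = sum(float(exact_ac_probability(k, x, n, n)) for k in range(y + 1))
    upper = sum(float(exact_ac_probability(k, x, n, n)) for k in range(y, 10_000))
    expected = min(1.0, 2.0 * min(lower, upper))
    assert ac_test(x, y, n, n) == pytest.approx(expected, rel=1e-9)


def test_ac_test_one_sided_options():
    p_less = ac_test(10, 2, 1e6, 1e6, alternative="less")
    p_greater = ac_test(10, 2, 1e6, 1e6, alternative="greater")
    assert p_less < 0.05 < p_greater
    with pytest.raises(ValueError):
        ac_test(1, 1, 1e6, 1e6, alternative="bogus")


@given(st.integers(0, 200), st.integers(0, 200),
       st.sampled_from([(1e6, 1e6), (5e5, 1e6), (1e6, 2e6), (2e6, 5e5)]))
@settings(max_examples=100, deadline=None)
def test_ac_test_swap_discrepancy_bounded(x, y, sizes):
    """Swapping (x, N1) with (y, N2) is only approximately neutral.

    The test conditions on the library-1 count, so exchanging the
    libraries changes the tail index sets; at small counts the two
    p-values can differ, but never by more than a factor of
    1 + max(N1/N2, N2/N1), and the decision at any practical threshold
    is unaffected for non-degenerate counts.
    """
    n1, n2 = sizes
    a = ac_test(x, y, n1, n2)
    b = ac_test(y, x, n2, n1)
    bound = 1.0 + max(n1 / n2, n2 / n1) + 1e-9
    if min(a, b) > 0:
        assert max(a, b) / min(a, b) <= bound


# -------------------------------------------------------------- FDR


def test_bh_fdr_hand_computed_cases():
    assert bh_fdr([0.03]) == pytest.approx([0.03])      # m=1: q = p
    np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                               [0.04, 0.04, 0.04, 0.04])
    # input order is preserved
    q = bh_fdr([0.04, 0.01, 0.02, 0.03])
    np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.2])


@given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
@settings(max_examples=60, deadline=None)
def test_bh_fdr_matches_statsmodels(p):
    from statsmodels.stats.multitest import multipletests
    expected = multipletests(p, method="fdr_bh")[1]
    np.testing.assert_allclose(bh_fdr(p), expected, atol=1e-12)


@given(st.lists(st.floats(0, 1), min_size=2, max_size=30))
@settings(max_examples=40, deadline=None)
def test_bh_fdr_monotone_in_sorted_p(p):
    p = np.asarray(p)
    q = bh_fdr(p)
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-12)


# -------------------------------------------------------- DEG calls


def _frame(q, log2):
    return pd.DataFrame({"gene_id": [f"g{i}" for i in range(len(q))],
                         "q_value": q, "log2_ratio": log2})


def test_call_degs_inclusive_boundaries():
    df, summary = call_degs(_frame([0.001, 0.002, 0.001], [1.0, 5.0, -1.0]))
    assert list(df["deg_call"]) == ["up", "none", "down"]
    assert summary == {"n_genes": 3, "n_up": 1, "n_down": 1, "n_deg": 2}


def test_expression_table_and_power(default_study):
    """A seeded default run recovers nearly every planted DE gene."""
    study = default_study
    table = expression_table(study.control, study.infected, study.reference.lengths)
    table, summary = call_degs(table)
    called = set(table.loc[table["deg_call"] != "none", "gene_id"])
    truth = study.truth.de_gene_ids
    assert len(called & truth) / len(truth) >= 0.95
    # direction agrees with the planted fold change
    for g in called & truth:
        fc = study.truth.true_fold_change[g]
        call = table.set_index("gene_id").loc[g, "deg_call"]
        assert (call == "up") == (fc > 1)
    assert summary["n_deg"] == len(called)


def test_global_null_is_calibrated():
    """Under de_fraction=0, p <= 0.05 at most at the nominal rate (+3 sigma)."""
    cfg = SimulationConfig(n_genes=400, de_fraction=0.0, seed=21,
                           library_sizes=(200_000, 200_000))
    study = simulate_all(cfg)
    table = expression_table(study.control, study.infected, study.reference.lengths)
    for alpha in (0.05, 0.01):
        frac = float((table["p_value"] <= alpha).mean())
        assert frac <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / len(table))
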