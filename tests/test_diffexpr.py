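"""TPM normalisation, fold changes, and the exact conditional count test."""

import math

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

from mirpipe.diffexpr import (
    MiRNAExpressionRecord,
    build_records,
    call_differential,
    exact_count_test,
    log2_fold_change,
    low_expression_filter,
    normalize_tpm,
)
from oracles import exact_test_rational


@pytest.mark.parametrize("count, total, tpm", [
    (100, 1_000_000, 100.0),
    (0, 10**6, 0.0),
    (123, 20_328_011, 6.0508),
])
def test_normalize_tpm(count, total, tpm):
    assert normalize_tpm(count, total) == pytest.approx(tpm, abs=5e-5)


def test_normalize_tpm_zero_total_errors():
    with pytest.raises(ValueError):
        normalize_tpm(1, 0)


@pytest.mark.parametrize("tpms, kept", [
    ((5.0, 8.0), False),    # below threshold in both libraries
    ((12.0, 3.0), True),    # reaches threshold in one
    ((0.0, 0.0), False),
])
def test_low_expression_filter(tpms, kept):
    rec = MiRNAExpressionRecord("m", 0, 0, 1, 1, tpm_ctl=tpms[0], tpm_def=tpms[1])
    assert (len(low_expression_filter([rec])) == 1) is kept


@pytest.mark.parametrize("tpm_def, tpm_ctl, expected", [
    (7.5, 7.5, 0.0),
    (20.0, 5.0, 2.0),
    (2000.0, 0.0, math.log2(200_000)),  # zero replaced by 0.01 pseudo-TPM
])
def test_log2_fold_change(tpm_def, tpm_ctl, expected):
    assert log2_fold_change(tpm_def, tpm_ctl) == pytest.approx(expected)


def test_exact_test_trivial_cases():
    res = exact_count_test(0, 0, 10**6, 10**6)
    assert res.p_point == pytest.approx(0.5)
    assert exact_count_test(7, 0, 10**6, 10**6).tail_upper == pytest.approx(1.0)


def test_exact_test_input_validation():
    with pytest.raises(ValueError):
        exact_count_test(-1, 0, 10, 10)
    with pytest.raises(ValueError):
        exact_count_test(0, 0, 0, 10)


def test_exact_test_matches_rational_oracle():
    """Log-space tails agree with exact rational arithmetic to 1e-9."""
    for ratio_n2, ratio_n1 in ((1, 2), (1, 1), (2, 1)):
        N1, N2 = 10**6 * ratio_n1, 10**6 * ratio_n2
        for x in (0, 1, 3, 5, 10, 25, 50):
            for y in (0, 1, 2, 5, 15, 30, 50):
                got = exact_count_test(x, y, N1, N2)
                point, lower, upper = exact_test_rational(x, y, N1, N2)
                assert got.p_point == pytest.approx(point, abs=1e-9)
                assert got.tail_lower == pytest.approx(lower, abs=1e-9)
                assert got.tail_upper == pytest.approx(upper, abs=1e-9)


def test_exact_test_agrees_with_negative_binomial():
    """Cross-check: p(y|x) is NB(x+1, N1/(N1+N2)) — independent scipy route."""
    N1, N2 = 10**6, 2 * 10**6
    p = N1 / (N1 + N2)
    for x, y in ((0, 3), (4, 9), (12, 2)):
        res = exact_count_test(x, y, N1, N2)
        assert res.p_point == pytest.approx(scipy.stats.nbinom.pmf(y, x + 1, p))
        assert res.tail_lower == pytest.approx(scipy.stats.nbinom.cdf(y, x + 1, p))


def test_pmf_normalizes():
    """Sum_y p(y|x) = 1 within 1e-12 (truncated summation) for x <= 20."""
    N1, N2 = 10**6, 10**6
    for x in range(0, 21):
        res = exact_count_test(x, 0, N1, N2)
        # lower tail at y -> infinity approaches 1; use the identity
        # tail_lower(y) + tail_upper(y) - p_point(y) = 1 at a far-out y
        far = exact_count_test(x, 500, N1, N2)
        assert far.tail_lower == pytest.approx(1.0, abs=1e-12)
        assert res.tail_lower + res.tail_upper - res.p_point == pytest.approx(1.0, abs=1e-9)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.integers(0, 60), st.integers(0, 60))
def test_exact_test_symmetric_at_equal_depths(x, y):
    a = exact_count_test(x, y, 10**6, 10**6)
    b = exact_count_test(y, x, 10**6, 10**6)
    assert a.p_point == pytest.approx(b.p_point, rel=1e-9)


@pytest.mark.parametrize("p, lfc, significant", [
    (0.5, 3.0, False),
    (1e-6, 1.4, False),   # fails the fold-change gate
    (1e-3, 2.0, True),
])
def test_call_differential_gates(p, lfc, significant, monkeypatch):
    rec = MiRNAExpressionRecord("m", 10, 40, 10**6, 10**6)
    rec.tpm_ctl, rec.tpm_def, rec.log2fc = 10.0, 40.0, lfc
    import mirpipe.diffexpr as de
    monkeypatch.setattr(de, "exact_count_test",
                        lambda *a: de.DifferentialTestResult(p, p, p, p))
    out = de.call_differential([rec])
    assert out[0].significant is significant
    if significant:
        assert out[0].direction == "up"


def test_call_differential_sorting_and_direction():
    counts = {"a": (100, 800), "b": (800, 100), "c": (50, 52)}
    recs = build_records(counts, 10**6, 10**6)
    out = call_differential(recs)
    assert [r.id for r in out[:2]] == ["a", "b"]  # |lfc| = 3 both, tie by id
    assert out[0].direction == "up" and out[1].direction == "down"
    assert out[-1].id == "c" and not out[-1].significant


def test_null_calibration_and_power():
    """<= 3% of 1000 null features reach p < 0.01; features at |lfc|=3 and
    TPM >= 50 at depth 5e5 are recovered >= 90% of the time."""
    from mirpipe.synth import simulate_count_pairs

    depth = 500_000
    n = 1000
    for seed in (11, 12, 13):
        rng = np.random.default_rng(seed)
        tpms = rng.uniform(20, 2000, size=n)
        x, y = simulate_count_pairs(tpms, np.zeros(n), depth, depth, seed)
        fp = sum(exact_count_test(int(a), int(b), depth, depth).p_reported < 0.01
                 for a, b in zip(x, y))
        assert fp / n <= 0.03

    rng = np.random.default_rng(99)
    n_de = 200
    tpms = np.concatenate([rng.uniform(50, 2000, size=n_de),
                           rng.uniform(20, 2000, size=800)])
    lfcs = np.concatenate([np.where(np.arange(n_de) % 2 == 0, 3.0, -3.0),
                           np.zeros(800)])
    x, y = simulate_count_pairs(tpms, lfcs, depth, depth, 99)
    hits = 0
    for i in range(n_de):
        res = exact_count_test(int(x[i]), int(y[i]), depth, depth)
        lfc = np.log2(max(y[i], 0.005) / max(x[i], 0.005))
        if res.p_reported < 0.01 and abs(lfc) > 1.5 and np.sign(lfc) == np.sign(lfcs[i]):
            hits += 1
    assert hits / n_de >= 0.90
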