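"""Overlap indices and randomization null models."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from frogdiet import null_model_overlap, pairwise_overlap
from frogdiet.composition import DietMatrix
from frogdiet.errors import UndefinedOverlapError, VocabularyError
from frogdiet.overlap import enumerate_ra3_tails

vectors = st.lists(st.floats(0.0, 100.0), min_size=2, max_size=12).filter(
    lambda v: sum(v) > 1e-6
)


def test_identical_vectors_overlap_one():
    u = np.array([3.0, 1.0, 0.0, 2.0])
    for form in ("symmetric", "asymmetric_jk", "asymmetric_kj"):
        assert pairwise_overlap(u, 2.5 * u, form=form) == pytest.approx(1.0)


def test_disjoint_supports_overlap_zero():
    assert pairwise_overlap([1.0, 2.0, 0.0, 0.0], [0.0, 0.0, 3.0, 1.0]) == 0.0


def test_zero_sum_and_mismatch_rejected():
    with pytest.raises(UndefinedOverlapError):
        pairwise_overlap([0.0, 0.0], [1.0, 1.0])
    with pytest.raises(UndefinedOverlapError):
        pairwise_overlap([1.0, 1.0], [1.0, 1.0, 1.0])
    with pytest.raises(VocabularyError):
        pairwise_overlap([1.0], [1.0], form="schoener")


@given(u=vectors, v=vectors, c=st.floats(0.01, 100.0))
@settings(max_examples=200, derandomize=True)
def test_symmetric_overlap_invariances(u, v, c):
    """Rescaling either vector and permuting categories leave Pianka fixed."""
    m = min(len(u), len(v))
    u, v = np.array(u[:m]), np.array(v[:m])
    if u.sum() <= 1e-6 or v.sum() <= 1e-6:
        return
    base = pairwise_overlap(u, v)
    assert 0.0 <= base <= 1.0 + 1e-12
    assert pairwise_overlap(c * u, v) == pytest.approx(base, abs=1e-9)
    rng = np.random.default_rng(0)
    perm = rng.permutation(m)
    assert pairwise_overlap(u[perm], v[perm]) == pytest.approx(base, abs=1e-9)


@given(u=vectors, v=vectors)
@settings(max_examples=200, derandomize=True)
def test_symmetric_squared_equals_product_of_asymmetric(u, v):
    m = min(len(u), len(v))
    u, v = np.array(u[:m]), np.array(v[:m])
    if u.sum() <= 1e-6 or v.sum() <= 1e-6:
        return
    sym = pairwise_overlap(u, v, form="symmetric")
    jk = pairwise_overlap(u, v, form="asymmetric_jk")
    kj = pairwise_overlap(u, v, form="asymmetric_kj")
    assert sym ** 2 == pytest.approx(jk * kj, abs=1e-9)


def _matrix(rows: dict) -> DietMatrix:
    return DietMatrix(data=pd.DataFrame(rows).T.astype(float), basis="count")


def test_uniform_rows_make_reshuffling_null_degenerate():
    m = _matrix({"j": [1, 1, 1, 1], "k": [2, 2, 2, 2]})
    res = null_model_overlap(m, ("j", "k"), algorithm="RA3", iterations=200, seed=0)
    assert res.observed == pytest.approx(1.0)
    assert res.p_upper == pytest.approx(1.0)
    assert res.p_lower == pytest.approx(1.0)
    assert res.null_sd == pytest.approx(0.0, abs=1e-12)


def test_seed_determinism():
    m = _matrix({"j": [5, 1, 0, 2], "k": [0, 3, 3, 1]})
    a = null_model_overlap(m, ("j", "k"), iterations=500, seed=11)
    b = null_model_overlap(m, ("j", "k"), iterations=500, seed=11)
    assert a == b
    c = null_model_overlap(m, ("j", "k"), iterations=500, seed=12)
    assert (a.p_upper, a.null_mean) != (c.p_upper, c.null_mean)


def test_unknown_algorithm_rejected():
    m = _matrix({"j": [1, 2], "k": [2, 1]})
    with pytest.raises(VocabularyError):
        null_model_overlap(m, ("j", "k"), algorithm="RA9")


def test_monte_carlo_tails_match_exhaustive_enumeration():
    """On a 2x3 matrix the 36 equally likely reshuffle pairs are exhaustible;
    Monte-Carlo tail fractions must agree within 3 binomial SEs."""
    u, v = np.array([2.0, 1.0, 0.0]), np.array([0.0, 1.0, 2.0])
    exact_ge, exact_le = enumerate_ra3_tails(u, v)
    m = _matrix({"j": u, "k": v})
    B = 40000
    res = null_model_overlap(m, ("j", "k"), iterations=B, seed=3)
    mc_ge = res.p_upper * (B + 1) / B - 1 / B  # undo add-one convention
    mc_le = res.p_lower * (B + 1) / B - 1 / B
    for exact, mc in ((exact_ge, mc_ge), (exact_le, mc_le)):
        se = np.sqrt(exact * (1 - exact) / B)
        assert abs(mc - exact) <= 3 * se + 1e-12
    # ties counted in both tails
    assert res.p_lower + res.p_upper >= 1.0


def test_null_p_values_uniform_under_the_null():
    """When the observed data are themselves an RA3 draw, the upper-tail
    Monte-Carlo p-value is uniform; KS must not reject at alpha = 0.01."""
    rng = np.random.default_rng(2024)
    base = rng.gamma(1.0, 1.0, size=(2, 12))
    pvals = []
    for rep in range(500):
        obs = rng.permuted(base, axis=1)
        m = _matrix({"j": obs[0], "k": obs[1]})
        res = null_model_overlap(m, ("j", "k"), iterations=99,
                                 seed=int(rng.integers(2**31)))
        pvals.append(res.p_upper)
    stat = stats.kstest(pvals, "uniform").statistic
    # asymptotic two-sided 1% critical value, plus the <=1/100 offset the
    # discrete support {1/100, ..., 1} contributes
    crit = 1.628 / np.sqrt(500) + 0.01
    assert stat <= crit


@pytest.mark.parametrize("algorithm", ["RA1", "RA2", "RA4"])
def test_alternative_null_algorithms_run_and_respect_structure(algorithm):
    m = _matrix({"j": [4, 2, 0, 1], "k": [0, 3, 2, 2]})
    res = null_model_overlap(m, ("j", "k"), algorithm=algorithm,
                             iterations=300, seed=5)
    assert 0.0 < res.p_upper <= 1.0
    assert 0.0 < res.p_lower <= 1.0
    assert res.algorithm == algorithm


def test_ra4_preserves_zero_structure_exactly():
    """RA4 reshuffles only non-zero cells, so disjoint supports stay
    disjoint and every null overlap equals the observed zero."""
    m = _matrix({"j": [1, 2, 0, 0], "k": [0, 0, 3, 4]})
    res = null_model_overlap(m, ("j", "k"), algorithm="RA4",
                             iterations=200, seed=1)
    assert res.observed == 0.0
    assert res.null_mean == 0.0
    assert res.p_upper == pytest.approx(1.0)
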