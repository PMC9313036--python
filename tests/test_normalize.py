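"""Normalization schemes: worked examples, dilution invariance, and
equivalence of the vectorized transforms with literal step-by-step loops."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from urinorm import (
    NormalizationSpec,
    ValidationError,
    apply_scheme,
    deseq2_reference,
    normalize_abs,
    normalize_all,
    normalize_cs,
    normalize_deseq2,
    normalize_is,
    normalize_pqn,
    pqn_reference,
    standard_schemes,
)
from urinorm.tables import ConfigurationError


def frame(rows, columns=None):
    columns = columns or [f"m{j}" for j in range(len(rows[0]))]
    return pd.DataFrame(np.asarray(rows, dtype=float), columns=columns)


# ---------------------------------------------------------------- oracles

def pqn_loop_oracle(X: np.ndarray, pre_cs: bool) -> tuple[np.ndarray, np.ndarray]:
    """Literal per-step loop implementation of PQN, kept independent of the
    vectorized code path."""
    X = X.astype(float).copy()
    n, p = X.shape
    if pre_cs:
        for i in range(n):
            X[i] = X[i] / sum(X[i])
    reference = np.array([float(np.median(X[:, j])) for j in range(p)])
    s = np.empty(n)
    out = np.empty_like(X)
    for i in range(n):
        quotients = [X[i, j] / reference[j] for j in range(p)]
        s[i] = float(np.median(quotients))
        out[i] = X[i] / s[i]
    return out, s


def deseq2_loop_oracle(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = X.astype(float)
    n, p = X.shape
    reference = np.array([
        float(np.exp(np.mean([np.log(X[i, j]) for i in range(n)]))) for j in range(p)
    ])
    s = np.empty(n)
    out = np.empty_like(X)
    for i in range(n):
        s[i] = float(np.median([X[i, j] / reference[j] for j in range(p)]))
        out[i] = X[i] / s[i]
    return out, s


# ------------------------------------------------------------------- ABS

def test_abs_is_identity(small_table):
    result = normalize_abs(small_table)
    pd.testing.assert_frame_equal(result.values, small_table)
    assert (result.scale_factors == 1.0).all()
    assert result.reference_profile.empty
    again = normalize_abs(result.values)
    pd.testing.assert_frame_equal(again.values, small_table)


def test_abs_rejects_empty_and_nonpositive():
    with pytest.raises(ValidationError):
        normalize_abs(pd.DataFrame())
    with pytest.raises(ValidationError, match="non-positive"):
        normalize_abs(frame([[1.0, 0.0], [2.0, 3.0]]))


# -------------------------------------------------------------------- IS

def test_is_divides_and_excludes_reference():
    table = frame([[4.0, 8.0, 2.0]], columns=["met1", "met2", "crea"])
    result = normalize_is(table, "crea")
    assert result.values.columns.tolist() == ["met1", "met2"]
    assert result.values.iloc[0].tolist() == [2.0, 4.0]
    assert result.excluded == ("crea",)
    assert result.scale_factors.iloc[0] == 2.0
    assert result.label == "IS-CREA" or result.scheme.method == "IS"


def test_is_missing_reference_errors(small_table):
    with pytest.raises(ValidationError, match="not in table"):
        normalize_is(small_table, "nonexistent")


def test_is_labels(small_table):
    for ref, label in [("creatinine", "IS-CREA"), ("glucose", "IS-GLUC"),
                       ("urea", "IS-UREA"), ("pseudouridine", "IS-PSEURID")]:
        assert normalize_is(small_table, ref).label == label


# -------------------------------------------------------------------- CS

def test_cs_worked_example():
    result = normalize_cs(frame([[2.0, 3.0, 5.0]]))
    assert result.values.iloc[0].tolist() == [0.2, 0.3, 0.5]
    assert result.scale_factors.iloc[0] == 10.0


def test_cs_full_subset_rows_sum_to_one(small_table):
    result = normalize_cs(small_table)
    assert np.allclose(result.values.sum(axis=1), 1.0, atol=1e-12)


def test_cs_empty_subset_errors(small_table):
    with pytest.raises((ValidationError, ConfigurationError)):
        normalize_cs(small_table, subset=[])


# ------------------------------------------------------------------- PQN

def test_pqn_worked_example_raw_reference():
    """Hand-executed four-step oracle: X=[[1,2,4],[2,4,8],[1,2,100]],
    r=[1,2,8], s=[1,2,1]."""
    result = normalize_pqn(frame([[1, 2, 4], [2, 4, 8], [1, 2, 100]]), pre_cs=False)
    assert result.reference_profile.tolist() == [1.0, 2.0, 8.0]
    assert result.scale_factors.tolist() == [1.0, 2.0, 1.0]
    expected = np.array([[1, 2, 4], [1, 2, 4], [1, 2, 100]], dtype=float)
    assert np.array_equal(result.values.to_numpy(), expected)


def test_pqn_pure_dilution_rows_collapse():
    base = np.array([1.0, 3.0, 7.0, 2.0])
    X = np.outer([0.5, 1.0, 4.0], base)
    result = normalize_pqn(frame(X), pre_cs=False)
    out = result.values.to_numpy()
    assert np.allclose(out, out[0], atol=1e-12)


def test_pqn_single_sample_scale_is_one():
    result = normalize_pqn(frame([[3.0, 6.0, 9.0]]), pre_cs=False)
    assert result.scale_factors.iloc[0] == 1.0


def test_pqn_scale_factors_are_total_divisor(small_table):
    for pre_cs in (True, False):
        result = normalize_pqn(small_table, pre_cs=pre_cs)
        reconstructed = result.values.mul(result.scale_factors, axis=0)
        assert np.allclose(reconstructed.to_numpy(), small_table.to_numpy(), rtol=1e-12)


# ---------------------------------------------------------------- DESEQ2

def test_deseq2_worked_example():
    result = normalize_deseq2(frame([[1, 2, 4], [4, 8, 16]]))
    assert np.allclose(result.reference_profile, [2.0, 4.0, 8.0], rtol=1e-12)
    assert np.allclose(result.scale_factors, [0.5, 2.0], rtol=1e-12)
    assert np.allclose(result.values.to_numpy(),
                       [[2, 4, 8], [2, 4, 8]], rtol=1e-12)


def test_deseq2_rejects_nonpositive():
    with pytest.raises(ValidationError):
        normalize_deseq2(frame([[1.0, 2.0], [0.0, 3.0]]))


# ------------------------------------------------------------ invariance

@pytest.mark.parametrize("c", [0.1, 3.0, 50.0])
def test_recomputed_dilution_invariance(small_table, c):
    """IS, CS and prescaled PQN are invariant to scaling one sample's row
    even when the scheme is refit on the perturbed table."""
    scaled = small_table.copy()
    scaled.iloc[3] *= c
    for norm, renorm in [
        (normalize_is(small_table, "creatinine"), normalize_is(scaled, "creatinine")),
        (normalize_cs(small_table), normalize_cs(scaled)),
        (normalize_pqn(small_table, pre_cs=True), normalize_pqn(scaled, pre_cs=True)),
    ]:
        assert np.allclose(norm.values.to_numpy(), renorm.values.to_numpy(), atol=1e-10)


@pytest.mark.parametrize("c", [0.1, 3.0, 50.0])
def test_fixed_reference_scale_factor_scales_by_c(small_table, c):
    """Against a fixed reference profile, the quotient schemes' scale factor
    for a diluted sample changes by exactly c, leaving its output unchanged."""
    scaled = small_table.copy()
    scaled.iloc[3] *= c
    ref_pqn = pqn_reference(small_table, pre_cs=False)
    ref_gm = deseq2_reference(small_table)
    for base, perturbed in [
        (normalize_pqn(small_table, pre_cs=False, reference=ref_pqn),
         normalize_pqn(scaled, pre_cs=False, reference=ref_pqn)),
        (normalize_deseq2(small_table, reference=ref_gm),
         normalize_deseq2(scaled, reference=ref_gm)),
    ]:
        ratio = perturbed.scale_factors / base.scale_factors
        expected = np.ones(len(small_table))
        expected[3] = c
        assert np.allclose(ratio, expected, rtol=1e-12)
        assert np.allclose(base.values.to_numpy(), perturbed.values.to_numpy(),
                           atol=1e-10)


def test_pure_dilution_scale_factors_match_truth_exactly():
    rng = np.random.default_rng(0)
    base = rng.lognormal(size=10)
    d = rng.lognormal(sigma=0.7, size=30)
    X = frame(np.outer(d, base))
    for result in (normalize_pqn(X), normalize_deseq2(X)):
        r = np.corrcoef(np.log(result.scale_factors), np.log(d))[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)


# --------------------------------------------------- vectorized vs loops

@settings(max_examples=200, derandomize=True, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_pqn_deseq2_match_literal_loop(seed):
    rng = np.random.default_rng(seed)
    X = rng.lognormal(mean=0.0, sigma=1.5, size=(5, 5))
    table = frame(X)
    for pre_cs in (True, False):
        expected_out, expected_s = pqn_loop_oracle(X, pre_cs)
        result = normalize_pqn(table, pre_cs=pre_cs)
        assert np.allclose(result.values.to_numpy(), expected_out, atol=1e-12, rtol=0)
        total = expected_s * X.sum(axis=1) if pre_cs else expected_s
        assert np.allclose(result.scale_factors, total, rtol=1e-12)
    expected_out, expected_s = deseq2_loop_oracle(X)
    result = normalize_deseq2(table)
    assert np.allclose(result.values.to_numpy(), expected_out, atol=1e-12, rtol=0)
    assert np.allclose(result.scale_factors, expected_s, rtol=1e-12)


def test_deseq2_matches_reference_implementation():
    """Cross-check the geometric-mean quotient scheme against pydeseq2's
    median-of-ratios size factors. pydeseq2 medians the log ratios; with an
    odd metabolite count the median is a single order statistic, so the two
    conventions coincide exactly."""
    from pydeseq2.preprocessing import deseq2_norm

    rng = np.random.default_rng(5)
    X = pd.DataFrame(rng.lognormal(sigma=1.0, size=(20, 9)),
                     columns=[f"m{j}" for j in range(9)])
    normed, size_factors = deseq2_norm(X)
    ours = normalize_deseq2(X)
    assert np.allclose(np.asarray(size_factors).ravel(),
                       ours.scale_factors.to_numpy(), rtol=1e-12)
    assert np.allclose(np.asarray(normed), ours.values.to_numpy(), rtol=1e-12)


# --------------------------------------------------------------- dispatch

def test_apply_scheme_dispatches(small_table):
    spec = NormalizationSpec("IS", reference_metabolite="creatinine")
    direct = normalize_is(small_table, "creatinine")
    routed = apply_scheme(small_table, spec)
    pd.testing.assert_frame_equal(direct.values, routed.values)
    pd.testing.assert_frame_equal(
        apply_scheme(small_table, NormalizationSpec("ABS")).values, small_table
    )


def test_eight_standard_schemes(small_table):
    specs = standard_schemes()
    assert [s.label for s in specs] == [
        "ABS", "IS-CREA", "IS-GLUC", "IS-UREA", "IS-PSEURID", "CS", "PQN", "DESEQ2"
    ]
    tables = normalize_all(small_table)
    assert len(tables) == 8
    for norm in tables:
        assert (norm.values.to_numpy() > 0).all()
        assert (norm.scale_factors > 0).all()


def test_unknown_method_rejected():
    with pytest.raises(ConfigurationError):
        NormalizationSpec("quantile")
    with pytest.raises(ConfigurationError):
        NormalizationSpec("IS")  # no reference metabolite
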