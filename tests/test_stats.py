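"""AUC engine, logistic ORs, linear differences, correlations, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from dgf_kinetics.errors import DerivationError, SeparationError
from dgf_kinetics.stats import (
    bootstrap_ci,
    complete_case,
    default_complete_case_fields,
    delong_ci,
    group_summary,
    linear_diff,
    logistic_or,
    mann_whitney_auc,
    pearson,
    roc_auc,
)


# ---------------------------------------------------------------------------
# AUC: brute-force oracle and invariances
# ---------------------------------------------------------------------------

def brute_force_auc(pos, neg):
    """Exhaustive pairwise concordance with half-credit for ties."""
    total = 0.0
    for x in pos:
        for y in neg:
            total += 1.0 if x > y else (0.5 if x == y else 0.0)
    return total / (len(pos) * len(neg))


def test_auc_equals_exhaustive_concordance_with_ties():
    rng = np.random.default_rng(17)
    for _ in range(100):
        n_pos = int(rng.integers(1, 31))
        n_neg = int(rng.integers(1, 31))
        # integer support forces ties
        pos = rng.integers(0, 8, size=n_pos).astype(float)
        neg = rng.integers(0, 8, size=n_neg).astype(float)
        assert mann_whitney_auc(pos, neg) == pytest.approx(
            brute_force_auc(pos, neg), abs=1e-12)


def test_auc_agrees_with_sklearn():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(3)
    pos, neg = rng.normal(1, 1, 40), rng.normal(0, 1, 35)
    ours = mann_whitney_auc(pos, neg)
    ref = roc_auc_score([1] * 40 + [0] * 35, np.concatenate([pos, neg]))
    assert ours == pytest.approx(ref, abs=1e-12)


@given(st.floats(0.1, 50.0), st.floats(-5.0, 5.0))
def test_auc_invariant_under_monotone_transform(scale, shift):
    rng = np.random.default_rng(8)
    pos, neg = rng.normal(1, 1, 20), rng.normal(0, 1, 25)
    base = mann_whitney_auc(pos, neg)
    assert mann_whitney_auc(scale * pos + shift, scale * neg + shift) == \
        pytest.approx(base, abs=1e-12)
    assert mann_whitney_auc(np.exp(pos), np.exp(neg)) == pytest.approx(base, abs=1e-12)


def test_auc_extremes_and_null():
    assert mann_whitney_auc([3, 4, 5], [0, 1, 2]) == 1.0
    rng = np.random.default_rng(12)
    vals = rng.normal(size=200)
    aucs = []
    for _ in range(200):
        lab = rng.permutation(np.repeat([0, 1], 100)).astype(bool)
        aucs.append(mann_whitney_auc(vals[lab], vals[~lab]))
    assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)


def test_delong_and_bootstrap_cover_true_auc():
    """Both CI methods cover a binormal true AUC near the nominal 95% rate
    (200 replicates, n=89), and DeLong's CI contains the point estimate
    the bootstrap resamples around."""
    rng = np.random.default_rng(100)
    mu = 1.0
    true_auc = sps.norm.cdf(mu / np.sqrt(2))
    cover_d = cover_b = 0
    for _ in range(200):
        pos = rng.normal(mu, 1, 45)
        neg = rng.normal(0, 1, 44)
        auc_d, (lo_d, hi_d) = delong_ci(pos, neg)
        auc_b, (lo_b, hi_b) = bootstrap_ci(pos, neg, n_boot=400, rng=rng)
        assert auc_d == auc_b  # same Mann-Whitney point estimate
        assert lo_d <= auc_b <= hi_d
        cover_d += lo_d <= true_auc <= hi_d
        cover_b += lo_b <= true_auc <= hi_b
    # 3 binomial SEs around 0.95 with 200 replicates is about +/- 0.046
    assert 0.90 <= cover_d / 200 <= 0.995
    assert 0.89 <= cover_b / 200 <= 0.995


# ---------------------------------------------------------------------------
# logistic odds ratios
# ---------------------------------------------------------------------------

def _table_from_counts(a, b, c, d):
    """exposed: a events / b non-events; reference: c events / d non-events."""
    return pd.DataFrame({
        "outcome": [1] * a + [0] * b + [1] * c + [0] * d,
        "exposure": ["exposed"] * (a + b) + ["ref"] * (c + d),
    })


def test_logistic_or_matches_cross_product_closed_form():
    a, b, c, d = 15, 7, 2, 14
    est = logistic_or(_table_from_counts(a, b, c, d), "outcome", "exposure",
                      reference="ref", levels=["exposed"])
    target = (a * d) / (b * c)  # = 15.0
    assert target == 15.0
    assert est[1].odds_ratio == pytest.approx(target, abs=1e-6)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    assert est[1].ci95[0] == pytest.approx(np.exp(np.log(target) - 1.96 * se), rel=1e-6)
    assert est[1].ci95[1] == pytest.approx(np.exp(np.log(target) + 1.96 * se), rel=1e-6)
    assert est[0].odds_ratio == 1.0 and est[0].level == "ref"
    assert est[1].n_used == a + b + c + d


def test_logistic_or_detects_separation_and_firth_opts_in():
    df = pd.DataFrame({"outcome": [1] * 10 + [0] * 10,
                       "exposure": ["hi"] * 10 + ["ref"] * 10})
    with pytest.raises(SeparationError):
        logistic_or(df, "outcome", "exposure", reference="ref")
    est = logistic_or(df, "outcome", "exposure", reference="ref", firth=True)
    assert np.isfinite(est[1].odds_ratio) and est[1].odds_ratio > 1


def test_firth_close_to_mle_when_separation_absent():
    df = _table_from_counts(15, 7, 2, 14)
    mle = logistic_or(df, "outcome", "exposure", reference="ref")[1]
    fir = logistic_or(df, "outcome", "exposure", reference="ref", firth=True)[1]
    # Firth shrinks toward the null but stays in the same ballpark
    assert 0.3 * mle.odds_ratio < fir.odds_ratio < mle.odds_ratio


def test_logistic_or_listwise_deletion():
    df = _table_from_counts(15, 7, 2, 14)
    df.loc[0, "outcome"] = np.nan
    est = logistic_or(df, "outcome", "exposure", reference="ref")
    assert est[1].n_used == 37


# ---------------------------------------------------------------------------
# linear differences
# ---------------------------------------------------------------------------

def test_linear_diff_zero_variance_groups():
    df = pd.DataFrame({"y": [10.0] * 4 + [4.0] * 4,
                       "g": ["a"] * 4 + ["b"] * 4})
    out = linear_diff(df, "y", "g", reference="a")
    assert out.loc["b", "difference"] == pytest.approx(-6.0)
    assert out.loc["b", "ci_high"] - out.loc["b", "ci_low"] == pytest.approx(0.0, abs=1e-9)


def test_linear_diff_equals_two_sample_t_test():
    rng = np.random.default_rng(4)
    ya, yb = rng.normal(5, 2, 14), rng.normal(7, 2, 11)
    df = pd.DataFrame({"y": np.concatenate([ya, yb]),
                       "g": ["a"] * 14 + ["b"] * 11})
    out = linear_diff(df, "y", "g", reference="a")
    assert out.loc["b", "difference"] == pytest.approx(yb.mean() - ya.mean(), rel=1e-9)
    res = sps.ttest_ind(yb, ya, equal_var=True)
    lo, hi = res.confidence_interval(0.95)
    assert out.loc["b", "ci_low"] == pytest.approx(lo, rel=1e-9)
    assert out.loc["b", "ci_high"] == pytest.approx(hi, rel=1e-9)


def test_linear_diff_shift_invariance_and_small_groups():
    df = pd.DataFrame({"y": [1.0, 2.0, 5.0, 6.0], "g": ["a", "a", "b", "b"]})
    base = linear_diff(df, "y", "g", reference="a")
    shifted = linear_diff(df.assign(y=df["y"] + 100.0), "y", "g", reference="a")
    assert shifted.loc["b", "difference"] == pytest.approx(base.loc["b", "difference"])
    with pytest.raises(DerivationError):
        linear_diff(pd.DataFrame({"y": [1.0, 2.0, 3.0], "g": ["a", "a", "b"]}),
                    "y", "g", reference="a")


# ---------------------------------------------------------------------------
# Pearson
# ---------------------------------------------------------------------------

def test_pearson_oracle_cases():
    r, p = pearson([1, 2, 3, 4], [2, 4, 6, 8])
    assert r == pytest.approx(1.0)
    r, _ = pearson([0, 1, 2], [0, 1, 0])
    assert r == pytest.approx(0.0, abs=1e-12)
    r1, _ = pearson([1, 2, 3, 5], [4, 1, 3, 2])
    r2, _ = pearson([1, 2, 3, 5], [-4, -1, -3, -2])
    assert r2 == pytest.approx(-r1)
    # pairwise-complete deletion
    r3, _ = pearson([1, 2, np.nan, 3, 5], [4, 1, 9, 3, 2])
    assert r3 == pytest.approx(r1)
    with pytest.raises(DerivationError):
        pearson([1, 1, 1], [1, 2, 3])
    with pytest.raises(DerivationError):
        pearson([1, 2], [1, 2])


# ---------------------------------------------------------------------------
# group summaries and complete case
# ---------------------------------------------------------------------------

def _mini_table():
    return pd.DataFrame({
        "group": ["no", "no", "no", "no", "mild", "mild", "severe"],
        "x_pod4": [1.0, 2.0, 3.0, 4.0, 7.0, 7.0, np.nan],
    })


def test_group_summary_linear_interpolation_quantiles():
    gs = group_summary(_mini_table(), "x", 4)
    assert gs.loc["no", "median"] == pytest.approx(2.5)
    assert gs.loc["no", "q1"] == pytest.approx(1.75)
    assert gs.loc["no", "q3"] == pytest.approx(3.25)
    assert gs.loc["mild", "q3"] - gs.loc["mild", "q1"] == 0.0  # constant group
    assert np.isnan(gs.loc["severe", "median"])  # empty after NaN removal
    assert gs.loc["all", "n"] == 6


def test_complete_case_drops_exactly_incomplete_rows():
    fields = ["a_pod4", "b_pod10"]
    df = pd.DataFrame({"a_pod4": [1.0, np.nan, 2.0], "b_pod10": [1.0, 1.0, 1.0]})
    out = complete_case(df, fields)
    assert list(out.index) == [0, 2]
    assert complete_case(df.dropna(), fields).equals(df.dropna())
    with pytest.raises(DerivationError):
        complete_case(df.assign(b_pod10=np.nan), fields)


def test_complete_case_mcar_retention_matches_binomial_expectation():
    """With 20% MCAR on 10 fields, retention ~ 0.8^10 within 3 binomial SEs."""
    rng = np.random.default_rng(31)
    n, k, p = 2000, 10, 0.2
    data = {f"f{i}_pod4": np.where(rng.random(n) < p, np.nan, 1.0) for i in range(k)}
    df = pd.DataFrame(data)
    kept = len(complete_case(df, list(data))) / n
    expect = (1 - p) ** k
    se = np.sqrt(expect * (1 - expect) / n)
    assert abs(kept - expect) < 3 * se


# ---------------------------------------------------------------------------
# table-level ROC
# ---------------------------------------------------------------------------

def _roc_table():
    rng = np.random.default_rng(6)
    groups = ["no"] * 20 + ["mild"] * 20 + ["moderate"] * 25 + ["severe"] * 24
    n = len(groups)
    marker = np.where(np.array(groups) == "no", rng.normal(0, 1, n),
                      rng.normal(2, 1, n))
    tfs = np.where(np.array(groups) == "no", rng.normal(2.5, 0.5, n),
                   rng.normal(1.0, 0.5, n))
    return pd.DataFrame({"group": groups, "m_pod4": marker, "tfs_pod4": tfs})


def test_roc_auc_orientation_and_contrasts():
    table = _roc_table()
    est = roc_auc(table, "m", 4, "fdgf_yes_vs_no")
    assert est.auc > 0.85
    assert est.n_neg == 20 and est.n_pos == 69
    # lower TFS means fDGF: auto-negation must land on the same side
    est_tfs = roc_auc(table, "tfs", 4, "fdgf_yes_vs_no")
    assert est_tfs.auc > 0.85
    sev = roc_auc(table, "m", 4, "severe_vs_mild_moderate")
    assert sev.n_pos == 24 and sev.n_neg == 45  # the "no" group is excluded
    with pytest.raises(DerivationError):
        roc_auc(table[table["group"] == "no"], "m", 4, "fdgf_yes_vs_no")


def test_roc_auc_invariant_under_sd_standardization():
    from dgf_kinetics.biomarkers import standardize

    table = _roc_table()
    base = roc_auc(table, "m", 4, "fdgf_yes_vs_no").auc
    std = table.assign(m_pod4=standardize(table["m_pod4"]))
    assert roc_auc(std, "m", 4, "fdgf_yes_vs_no").auc == pytest.approx(base, abs=1e-12)


def test_roc_auc_ci_methods_are_seeded():
    table = _roc_table()
    a = roc_auc(table, "m", 4, "fdgf_yes_vs_no", ci_method="bootstrap",
                n_boot=300, rng=np.random.default_rng(5))
    b = roc_auc(table, "m", 4, "fdgf_yes_vs_no", ci_method="bootstrap",
                n_boot=300, rng=np.random.default_rng(5))
    assert a.ci95 == b.ci95


def test_default_complete_case_fields_cover_pods_4_and_10():
    fields = default_complete_case_fields()
    assert "tfs_pod4" in fields and "tfs_pod10" in fields
    assert "ngal_cr_pod4" in fields and "fe_b2m_pod10" in fields
    assert not any(f.endswith("_pod1") for f in fields)
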