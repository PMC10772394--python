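"""Association screens: logistic LR, BH control, differential tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

import rppasig as rs
from rppasig.core import ValidationError

from .oracles import bh_step_up, logistic_group_lr


def test_constant_biomarker_is_a_precondition_error():
    y = np.array([0, 1, 0, 1])
    with pytest.raises(ValidationError):
        rs.fit_logistic_lr(y, np.ones(4))
    with pytest.raises(ValidationError):
        rs.fit_logistic_lr(np.zeros(4), np.arange(4.0))


def test_logistic_lr_matches_group_mle_oracle():
    """Binary biomarker, no covariates: the LR statistic equals the
    closed-form two-group Bernoulli enumeration."""
    y = np.array([1] * 8 + [0] * 2 + [1] * 2 + [0] * 8)
    x = np.array([1.0] * 10 + [0.0] * 10)
    fit = rs.fit_logistic_lr(y, x)
    expected = logistic_group_lr(k1=8, n1=10, k0=2, n0=10)
    assert fit.lr_stat == pytest.approx(expected, abs=1e-6)
    assert fit.coef > 0


def test_logistic_lr_affine_invariance(rng):
    y = (rng.random(200) < 0.4).astype(int)
    x = rng.standard_normal(200)
    a = rs.fit_logistic_lr(y, x)
    b = rs.fit_logistic_lr(y, 3.5 * x - 2.0)
    assert a.lr_stat == pytest.approx(b.lr_stat, rel=1e-6)
    assert b.coef == pytest.approx(a.coef / 3.5, rel=1e-5)


def test_logistic_type_one_error_in_binomial_band(rng):
    """Null biomarkers at n=500: LR p < 0.05 rejection rate within the
    binomial 95% band over 500 simulations."""
    hits = 0
    n_sim = 500
    for _ in range(n_sim):
        y = (rng.random(500) < 0.35).astype(int)
        if y.min() == y.max():
            continue
        x = rng.standard_normal(500)
        hits += rs.fit_logistic_lr(y, x).lr_p < 0.05
    lo, hi = 0.05 - 1.96 * np.sqrt(0.05 * 0.95 / n_sim), \
        0.05 + 1.96 * np.sqrt(0.05 * 0.95 / n_sim)
    assert lo <= hits / n_sim <= hi


def test_bh_trivial_and_worked_example():
    assert rs.bh_adjust([0.03]).tolist() == [0.03]
    np.testing.assert_allclose(rs.bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])
    np.testing.assert_allclose(rs.bh_adjust([0.005, 0.01, 0.03, 0.05]),
                               [0.02, 0.02, 0.04, 0.05])


def test_bh_matches_step_up_oracle(rng):
    for _ in range(100):
        p = rng.random(rng.integers(1, 40))
        np.testing.assert_allclose(rs.bh_adjust(p), bh_step_up(p), rtol=1e-12)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=30))
def test_bh_is_monotone_and_bounded(p):
    q = rs.bh_adjust(p)
    assert (q >= np.asarray(p) - 1e-12).all() and (q <= 1.0 + 1e-12).all()
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()


def test_bh_handles_missing_and_rejects_out_of_range():
    q = rs.bh_adjust([0.01, np.nan, 0.04])
    assert np.isnan(q[1])
    np.testing.assert_allclose(q[[0, 2]], bh_step_up(np.array([0.01, 0.04])))
    with pytest.raises(ValidationError):
        rs.bh_adjust([-0.1, 0.5])


def test_screen_recovers_planted_analytes(small_cohort):
    """Every planted analyte is detected and signed correctly at the small
    cohort's effect size; null-analyte BH discoveries stay rare."""
    truth = small_cohort["truth"]
    rec = rs.association_screen(small_cohort["harmonized"],
                                small_cohort["clinical"], "population")
    planted = list(truth.beta[truth.beta != 0].index)
    by_analyte = rec.set_index("analyte")
    # power is limited at n=150, so require most planted effects nominal and
    # every detected one correctly signed (the full-recovery claim is tested
    # at the trial scale)
    nominal_planted = [a for a in planted if by_analyte.loc[a, "nominal"]]
    assert len(nominal_planted) >= len(planted) // 2 + 1
    for analyte in nominal_planted:
        assert by_analyte.loc[analyte, "direction"] == np.sign(truth.beta[analyte])
    assert (rec["bh_p"] >= rec["lr_p"] - 1e-12).all()
    assert (~rec["significant"] | rec["nominal"]).all()


def test_screen_is_column_order_independent(small_cohort):
    z = small_cohort["harmonized"]
    rec_fwd = rs.association_screen(z, small_cohort["clinical"], "population")
    rec_rev = rs.association_screen(z[z.columns[::-1]],
                                    small_cohort["clinical"], "population")
    merged = rec_fwd.set_index("analyte").join(
        rec_rev.set_index("analyte"), rsuffix="_rev")
    np.testing.assert_allclose(merged["lr_p"], merged["lr_p_rev"], rtol=1e-9)
    np.testing.assert_allclose(merged["bh_p"], merged["bh_p_rev"], rtol=1e-9)


def test_single_class_scope_is_skipped(small_cohort):
    clinical = small_cohort["clinical"].copy()
    clinical.loc[clinical["arm"] == "Ctr", "pcr"] = 0
    rec = rs.association_screen(small_cohort["harmonized"], clinical, "arm:Ctr")
    assert len(rec) == 0


def test_differential_screen_null_and_planted(rng):
    n, k = 200, 30
    X = pd.DataFrame(rng.standard_normal((n, k)),
                     index=[f"p{i}" for i in range(n)],
                     columns=[f"A{i}" for i in range(k)])
    labels = np.array(["g1"] * 100 + ["g2"] * 100)
    X.iloc[100:, 0] += 1.0     # planted 1-SD shift in the first analyte
    rec = rs.differential_screen(X, labels)
    by = rec.set_index("analyte")
    assert by.loc["A0", "significant"]
    null_sig = by.drop("A0")["significant"].sum()
    assert null_sig <= 3       # BH keeps null discoveries rare
    with pytest.raises(ValidationError):
        rs.differential_screen(X, np.array(["g1"] * n))


def test_differential_null_rejection_rate_in_alpha_band(rng):
    """Permuted labels: per-analyte nominal rejections stay in the binomial
    band over 200 replicated null analytes."""
    n = 400
    labels = np.array(["a"] * 200 + ["b"] * 200)
    X = pd.DataFrame(rng.standard_normal((n, 200)),
                     index=[f"p{i}" for i in range(n)],
                     columns=[f"N{i}" for i in range(200)])
    rec = rs.differential_screen(X, labels)
    frac = (rec["lr_p"] < 0.05).mean()
    half = 1.96 * np.sqrt(0.05 * 0.95 / 200)
    assert 0.05 - half <= frac <= 0.05 + half


def test_count_significant_and_response_rates(small_cohort):
    assert rs.count_significant(pd.DataFrame(columns=["significant"])) == 0
    rec = pd.DataFrame({"significant": [True, False, True]})
    assert rs.count_significant(rec) == 2
    clinical = small_cohort["clinical"]
    rates = rs.group_response_rates(clinical["subtype"].to_numpy(), clinical)
    for _, row in rates.iterrows():
        sub = clinical[clinical["subtype"] == row["group"]]
        assert row["n"] == len(sub)
        assert row["rate"] == pytest.approx(sub["pcr"].mean())
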