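"""Balanced-subsampling batch standardization."""

import numpy as np
import pandas as pd
import pytest

import rppasig as rs
from rppasig.core import PipelineConfig, ValidationError
from rppasig.harmonize import HarmonizationError, _largest_remainder


def _clin(subtypes):
    hr = ["pos" if s in ("HR+HER2-", "HR+HER2+") else "neg" for s in subtypes]
    her2 = ["pos" if s.endswith("HER2+") else "neg" for s in subtypes]
    return pd.DataFrame({
        "patient_id": [f"p{i}" for i in range(len(subtypes))],
        "hr": hr, "her2": her2, "subtype": subtypes,
        "arm": "Ctr", "pcr": 0, "array_id": "a1",
    })


def test_stratified_split_is_exact_for_round_proportions(rng):
    clin = _clin(["HR+HER2-"] * 3 + ["TN"] * 3)
    idx = rs.stratified_subsample(clin, (0.5, 0.5, 0.0, 0.0), 4, rng)
    sub = clin.iloc[idx]["subtype"].value_counts()
    assert sub["HR+HER2-"] == 2 and sub["TN"] == 2


def test_empty_required_stratum_raises(rng):
    clin = _clin(["TN"] * 4)
    with pytest.raises(HarmonizationError):
        rs.stratified_subsample(clin, (1.0, 0.0, 0.0, 0.0), 2, rng)


def test_full_fraction_empirical_proportions_recover_whole_array(rng):
    subtypes = ["HR+HER2-"] * 7 + ["TN"] * 9 + ["HR+HER2+"] * 3 + ["HR-HER2+"] * 1
    clin = _clin(subtypes)
    props = tuple(np.array([7, 9, 3, 1]) / 20)
    idx = rs.stratified_subsample(clin, props, 20, rng)
    assert sorted(idx) == list(range(20))


def test_largest_remainder_totals_and_order():
    # quotas (5.5, 2.5, 1.5, 0.5): all remainders tie at .5, broken by order
    assert _largest_remainder(10, (0.55, 0.25, 0.15, 0.05)).tolist() == [6, 3, 1, 0]
    assert _largest_remainder(7, (0.5, 0.5, 0.0, 0.0)).sum() == 7
    assert _largest_remainder(20, (0.35, 0.45, 0.15, 0.05)).tolist() == [7, 9, 3, 1]


def test_single_full_subsample_reduces_to_plain_moments():
    """B=1 with fraction 1 and empirical proportions forces mu/sigma to the
    plain column mean and (n-1) SD exactly."""
    rng = np.random.default_rng(2)
    subtypes = ["HR+HER2-"] * 6 + ["TN"] * 4
    clin = _clin(subtypes)
    m = pd.DataFrame(rng.standard_normal((10, 3)), index=clin["patient_id"],
                     columns=["A", "B", "C"])
    cfg = PipelineConfig(n_subsamples=1, subsample_fraction=1.0,
                         subtype_proportions=(0.6, 0.4, 0.0, 0.0), seed=0)
    mu, sigma = rs.resample_moments(m, clin, cfg)
    # equality forced by sampling the full set; row order may differ, so
    # allow summation-order rounding only
    np.testing.assert_allclose(mu, m.mean(), rtol=1e-12)
    np.testing.assert_allclose(sigma, m.std(ddof=1), rtol=1e-12)


def test_constant_analyte_hits_sd_floor():
    clin = _clin(["HR+HER2-"] * 4 + ["TN"] * 4)
    m = pd.DataFrame({"flat": np.ones(8), "ok": np.arange(8.0)},
                     index=clin["patient_id"])
    cfg = PipelineConfig(n_subsamples=3, subtype_proportions=(0.5, 0.5, 0, 0), seed=1)
    _, sigma = rs.resample_moments(m, clin, cfg)
    assert sigma["flat"] == cfg.sd_floor
    assert sigma["ok"] > cfg.sd_floor


def test_balanced_mean_matches_closed_form():
    """Two subtypes with means 0 and 1 at proportions (1/2, 1/2): the balanced
    subsample mean converges to 1/2 regardless of the array's own mix."""
    rng = np.random.default_rng(7)
    subtypes = ["HR+HER2-"] * 120 + ["TN"] * 40   # unbalanced 3:1 array
    clin = _clin(subtypes)
    values = np.where(np.array(subtypes) == "TN", 1.0, 0.0) + \
        0.05 * rng.standard_normal(160)
    m = pd.DataFrame({"A": values}, index=clin["patient_id"])
    cfg = PipelineConfig(n_subsamples=2000, subsample_fraction=0.5,
                         subtype_proportions=(0.5, 0.5, 0.0, 0.0), seed=3)
    mu, _ = rs.resample_moments(m, clin, cfg)
    mc_se = values.std() / np.sqrt(cfg.n_subsamples * 40)
    assert abs(mu["A"] - 0.5) < max(3 * mc_se, 0.01)


def test_zscore_trivial_points():
    m = pd.DataFrame({"A": [3.0, 5.0]}, index=["p", "q"])
    mu = pd.Series({"A": 3.0})
    sigma = pd.Series({"A": 2.0})
    z = rs.zscore_array(m, mu, sigma)
    assert z.loc["p", "A"] == 0.0
    assert z.loc["q", "A"] == 1.0
    with pytest.raises(HarmonizationError):
        rs.zscore_array(pd.DataFrame({"B": [1.0]}, index=["p"]), mu, sigma)


def test_combine_arrays_union_and_duplicates():
    a = pd.DataFrame({"A": [1.0], "B": [2.0]}, index=["p1"])
    b = pd.DataFrame({"B": [3.0], "C": [4.0]}, index=["p2"])
    combined = rs.combine_arrays([a, b])
    assert list(combined.columns) == ["A", "B", "C"]
    assert np.isnan(combined.loc["p2", "A"]) and np.isnan(combined.loc["p1", "C"])
    with pytest.raises(ValidationError):
        rs.combine_arrays([a, a])
    pd.testing.assert_frame_equal(rs.combine_arrays([a]), a)


def test_affine_batch_transform_is_removed(small_cohort):
    """Applying a per-(array, analyte) affine map a*x + c to the raw endpoints
    leaves the harmonized values unchanged (same seed, same subsamples)."""
    matrices = small_cohort["matrices"]
    clinical = small_cohort["clinical"]
    cfg = PipelineConfig(n_subsamples=40, seed=5)
    z0, _ = rs.harmonize(matrices, clinical, cfg)
    rng = np.random.default_rng(0)
    warped = {}
    for arr, m in matrices.items():
        a = np.exp(rng.normal(0, 0.3, m.shape[1]))
        c = rng.normal(0, 2, m.shape[1])
        warped[arr] = m * a + c
    z1, _ = rs.harmonize(warped, clinical, cfg)
    np.testing.assert_allclose(z0.to_numpy(), z1.to_numpy(), rtol=1e-9, atol=1e-9)


def test_fixed_seed_gives_identical_model(small_cohort):
    cfg = PipelineConfig(n_subsamples=25, seed=11)
    _, m1 = rs.harmonize(small_cohort["matrices"], small_cohort["clinical"], cfg)
    _, m2 = rs.harmonize(small_cohort["matrices"], small_cohort["clinical"], cfg)
    pd.testing.assert_frame_equal(m1.mu, m2.mu)
    pd.testing.assert_frame_equal(m1.sigma, m2.sigma)


def test_model_json_round_trip(tmp_path, small_cohort):
    model = small_cohort["model"]
    path = tmp_path / "model.json"
    model.to_json(path)
    back = rs.HarmonizationModel.from_json(path)
    np.testing.assert_allclose(back.mu.to_numpy(), model.mu.to_numpy(), rtol=1e-12)
    assert back.metadata["n_subsamples"] == model.metadata["n_subsamples"]


def test_harmonizer_is_sklearn_compatible(small_cohort):
    est = rs.BatchHarmonizer(n_subsamples=5, seed=1)
    params = est.get_params()
    assert params["n_subsamples"] == 5
    est.set_params(n_subsamples=7)
    assert est.n_subsamples == 7
    with pytest.raises(ValidationError):
        rs.BatchHarmonizer().transform(small_cohort["matrices"]["array1"])
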