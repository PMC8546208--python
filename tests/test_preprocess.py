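import numpy as np
import pandas as pd
import pytest

from adproteo import (
    DataModelError,
    ImputationParams,
    classify_on_off,
    compute_validity,
    filter_quantitative,
    impute_downshifted_normal,
    log2_median_normalize,
    merge_technical_replicates,
    preprocess_region,
)
from conftest import make_matrix, make_sample_table


class TestReplicateMerging:
    def test_median_over_present_values(self):
        samples = make_sample_table(n_ad=1, n_control=1, reps=2)
        m = make_matrix(
            [[4.0, 6.0, 1.0, np.nan], [4.0, np.nan, np.nan, np.nan]],
            samples.sample_ids,
        )
        merged = merge_technical_replicates(m, samples)
        assert merged.sample_ids == ["AD01_HP", "CT01_HP"]
        assert merged.values.loc["F0"].tolist() == [5.0, 1.0]  # median{4,6}; present-only
        assert merged.values.loc["F1", "AD01_HP"] == 4.0
        assert np.isnan(merged.values.loc["F1", "CT01_HP"])  # all-missing stays missing

    def test_single_replicate_is_identity(self):
        samples = make_sample_table(n_ad=2, n_control=2, reps=1)
        m = make_matrix(np.arange(1, 9, dtype=float).reshape(2, 4), samples.sample_ids)
        assert merge_technical_replicates(m, samples) == m


class TestNormalization:
    def test_log2_then_median_centring(self):
        m = make_matrix([[2.0], [8.0]], ["S1"])
        out = log2_median_normalize(m)
        assert out.scale == "log2"
        assert out.values["S1"].tolist() == [-1.0, 1.0]

    def test_identical_column_becomes_zero(self):
        m = make_matrix([[7.0], [7.0], [7.0]], ["S1"])
        assert (log2_median_normalize(m).values["S1"] == 0).all()

    def test_column_medians_are_zero_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            vals = np.power(2.0, rng.normal(20, 2, size=(30, 5)))
            vals[rng.random(vals.shape) < 0.2] = np.nan
            if np.isnan(vals).all(axis=0).any():
                continue
            out = log2_median_normalize(make_matrix(vals, [f"S{j}" for j in range(5)]))
            med = out.values.median(axis=0, skipna=True)
            assert np.allclose(med, 0.0, atol=1e-12)

    def test_empty_column_rejected(self):
        m = make_matrix([[np.nan], [np.nan]], ["S1"])
        with pytest.raises(DataModelError, match="no present values"):
            log2_median_normalize(m)


class TestValidity:
    def test_exact_fractions(self):
        samples = make_sample_table(n_ad=11, n_control=12)
        vals = np.ones((3, 23))
        vals[0, :3] = np.nan          # 8/11 AD valid, 12/12 control
        vals[2, :] = np.nan           # fully missing
        m = make_matrix(vals, samples.sample_ids, scale="log2")
        m.scale = "log2"
        prof = compute_validity(m, samples)
        assert prof.loc[0, "frac_valid_ad"] == 8 / 11
        assert prof.loc[0, "frac_valid_control"] == 1.0
        assert prof.loc[1, "frac_valid_ad"] == 1.0 and prof.loc[1, "frac_valid_control"] == 1.0
        assert prof.loc[2, "frac_valid_ad"] == 0.0 and prof.loc[2, "frac_valid_control"] == 0.0


def _profiles(rows):
    frame = pd.DataFrame(rows, columns=["feature_id", "n_valid_ad", "n_ad", "n_valid_control", "n_control"])
    frame["frac_valid_ad"] = frame["n_valid_ad"] / frame["n_ad"]
    frame["frac_valid_control"] = frame["n_valid_control"] / frame["n_control"]
    return frame


# 30 validity profiles covering every boundary of the 70/10 and 66/33 rules,
# with hand-computed qualitative and quantitative decisions.
BOUNDARY_PROFILES = [
    # (id, valid_ad, n_ad, valid_ctl, n_ctl, qualitative, quantitative)
    ("q01", 9, 11, 1, 12, "qualitative_on_AD", "on_off_like"),    # 0.818 vs 0.083
    ("q02", 0, 11, 12, 12, "qualitative_off_AD", "on_off_like"),
    ("q03", 8, 11, 2, 12, "none", "on_off_like"),                 # 0.167 >= 0.10
    ("q04", 7, 10, 0, 10, "qualitative_on_AD", "on_off_like"),    # exactly 0.70 counts
    ("q05", 69, 100, 9, 100, "none", "on_off_like"),              # 0.69 < 0.70
    ("q06", 70, 100, 10, 100, "none", "on_off_like"),             # exactly 0.10 fails <
    ("q07", 70, 100, 9, 100, "qualitative_on_AD", "on_off_like"),
    ("q08", 1, 10, 7, 10, "none", "on_off_like"),                 # ad exactly 0.10 fails <0.10
    ("q09", 0, 10, 7, 10, "qualitative_off_AD", "on_off_like"),
    ("q10", 11, 11, 12, 12, "none", "quantitative"),
    ("t01", 8, 11, 9, 12, "none", "quantitative"),                # 0.727, 0.75
    ("t02", 66, 100, 66, 100, "none", "quantitative"),            # exactly 0.66 both
    ("t03", 65, 100, 66, 100, "none", "excluded"),                # 0.65 < 0.66, 0.66 not < 0.33
    ("t04", 33, 100, 66, 100, "none", "excluded"),                # exactly 0.33 fails < 0.33
    ("t05", 32, 100, 66, 100, "none", "on_off_like"),             # 0.32 < 0.33
    ("t06", 66, 100, 32, 100, "none", "on_off_like"),
    ("t07", 27, 100, 75, 100, "none", "on_off_like"),
    ("t08", 45, 100, 41, 100, "none", "excluded"),
    ("t09", 0, 11, 0, 12, "none", "excluded"),
    ("t10", 33, 50, 33, 50, "none", "quantitative"),              # 33/50 = 0.66 exactly
    ("t11", 16, 50, 33, 50, "none", "on_off_like"),               # 16/50 = 0.32 < 0.33
    ("t12", 17, 50, 33, 50, "none", "excluded"),                  # 17/50 = 0.34
    ("t13", 3, 11, 8, 12, "none", "on_off_like"),                 # 0.273 < 0.33, 0.667 >= 0.66
    ("t14", 4, 11, 8, 12, "none", "excluded"),                    # 0.364
    ("t15", 8, 12, 3, 11, "none", "on_off_like"),                 # mirrored
    ("b01", 11, 11, 0, 12, "qualitative_on_AD", "on_off_like"),
    ("b02", 10, 11, 1, 12, "qualitative_on_AD", "on_off_like"),   # 0.909, 0.083
    ("b03", 1, 12, 11, 11, "qualitative_off_AD", "on_off_like"),
    ("b04", 2, 12, 11, 11, "none", "on_off_like"),                # 0.167 >= 0.10
    ("b05", 50, 100, 50, 100, "none", "excluded"),
]


@pytest.fixture()
def profiles():
    return _profiles([(fid, a, na, c, nc) for fid, a, na, c, nc, _, _ in BOUNDARY_PROFILES])


class TestFilterRules:
    def test_qualitative_rule_on_boundary_fixture(self, profiles):
        out = classify_on_off(profiles).set_index("feature_id")["status"]
        for fid, *_rest in BOUNDARY_PROFILES:
            expected = next(q for f, _, _, _, _, q, _ in BOUNDARY_PROFILES if f == fid)
            assert out[fid] == expected, fid

    def test_quantitative_rule_on_boundary_fixture(self, profiles):
        out = filter_quantitative(profiles).set_index("feature_id")["status"]
        for fid, _, _, _, _, _, expected in BOUNDARY_PROFILES:
            assert out[fid] == expected, fid

    def test_rules_are_pure_functions_of_the_profile(self, profiles):
        a = filter_quantitative(profiles)
        b = filter_quantitative(profiles.sample(frac=1.0, random_state=1).reset_index(drop=True))
        merged = a.merge(b, on="feature_id", suffixes=("_a", "_b"))
        assert (merged["status_a"] == merged["status_b"]).all()


class TestImputation:
    def test_no_missing_is_identity(self):
        m = make_matrix([[1.0, 2.0], [3.0, 4.0]], ["S1", "S2"], scale="log2")
        out = impute_downshifted_normal(m, ImputationParams(seed=0))
        assert out == m

    def test_same_seed_same_output_and_column_order_invariance(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(0, 1, size=(50, 4))
        vals[rng.random(vals.shape) < 0.3] = np.nan
        cols = ["S1", "S2", "S3", "S4"]
        m = make_matrix(vals, cols, scale="log2")
        a = impute_downshifted_normal(m, ImputationParams(seed=7))
        b = impute_downshifted_normal(m, ImputationParams(seed=7))
        assert a == b
        # permuting columns must not change any sample's draws
        m_perm = make_matrix(vals[:, ::-1], cols[::-1], scale="log2")
        c = impute_downshifted_normal(m_perm, ImputationParams(seed=7))
        pd.testing.assert_frame_equal(a.values[cols], c.values[cols])
        d = impute_downshifted_normal(m, ImputationParams(seed=8))
        assert not a == d

    def test_imputed_distribution_matches_downshifted_normal(self):
        # present values engineered to mean 20, SD exactly 1 -> imputed cells
        # should be ~N(20 - 1.8, 0.3^2)
        n_missing = 100_000
        pattern = np.tile([-1.0, 1.0], 1000)
        present = 20.0 + pattern / pattern.std(ddof=1)
        col = np.concatenate([present, np.full(n_missing, np.nan)])
        m = make_matrix(col[:, None], ["S1"], scale="log2")
        out = impute_downshifted_normal(m, ImputationParams(seed=3))
        imputed = out.values["S1"].to_numpy()[len(present):]
        se_mean = 0.3 / np.sqrt(n_missing)
        se_sd = 0.3 / np.sqrt(2 * n_missing)
        assert abs(imputed.mean() - 18.2) < 4 * se_mean
        assert abs(imputed.std(ddof=1) - 0.3) < 4 * se_sd

    def test_imputation_is_per_column(self):
        # two columns with very different centres: draws must track their own column
        col1 = np.concatenate([np.random.default_rng(0).normal(0, 1, 200), [np.nan] * 50])
        col2 = np.concatenate([np.random.default_rng(1).normal(30, 1, 200), [np.nan] * 50])
        m = make_matrix(np.column_stack([col1, col2]), ["low", "high"], scale="log2")
        out = impute_downshifted_normal(m, ImputationParams(seed=0))
        imp1 = out.values["low"].to_numpy()[200:]
        imp2 = out.values["high"].to_numpy()[200:]
        assert imp1.mean() < 5 and imp2.mean() > 25

    def test_too_few_present_values_rejected(self):
        m = make_matrix([[1.0], [np.nan], [np.nan]], ["S1"], scale="log2")
        with pytest.raises(DataModelError, match="fewer than 2"):
            impute_downshifted_normal(m, ImputationParams(seed=0))

    def test_raw_scale_rejected(self):
        m = make_matrix([[1.0], [2.0]], ["S1"], scale="raw")
        with pytest.raises(DataModelError):
            impute_downshifted_normal(m, ImputationParams(seed=0))


class TestRegionChain:
    def test_preprocess_region_filters_and_completes(self, small_study):
        res = preprocess_region(small_study["protein"], small_study["cohort"], "HP")
        assert res.imputed.n_missing() == 0
        retained = set(res.quantitative.loc[res.quantitative["status"] != "excluded", "feature_id"])
        assert set(res.imputed.feature_ids) == retained
        # normalization holds on the full (pre-imputation) matrix
        assert np.allclose(res.normalized.values.median(axis=0, skipna=True), 0.0, atol=1e-12)
        assert len(res.samples) == 23
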