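"""Trait-database loading, harmonisation, filtering and statistics."""

from io import StringIO

import numpy as np
import pandas as pd
import pytest

from respcrit import (
    assign_climate_zone,
    control_subset,
    generate_database,
    harmonize_units,
    load_database,
    make_fwsw_dataset,
    make_zone_dataset,
    method_comparisons,
    pcrit_regression,
    salinity_comparison,
    zone_anova,
)


def roundtrip(df: pd.DataFrame):
    buf = StringIO()
    df.to_csv(buf, index=False)
    buf.seek(0)
    return load_database(buf)


class TestLoad:
    def test_empty_file(self):
        buf = StringIO("species,pcrit_value,pcrit_unit,trial_temperature\n")
        rec, rep = load_database(buf)
        assert len(rec) == 0 and len(rep) == 0

    def test_synthetic_fixture_round_trips_without_rejection(self):
        df, _ = generate_database(331, seed=1)
        rec, rep = roundtrip(df)
        assert len(rec) == 331
        assert len(rep) == 0

    def test_mmhg_rows_kept_not_rejected(self):
        buf = StringIO(
            "species,pcrit_value,pcrit_unit,trial_temperature\n"
            "Cyprinus carpio,38.6,mmHg,15\n"
        )
        rec, rep = load_database(buf)
        assert len(rec) == 1 and rec.loc[0, "pcrit_unit"] == "mmHg"

    def test_rows_missing_mandatory_fields_logged(self):
        buf = StringIO(
            "species,pcrit_value,pcrit_unit,trial_temperature\n"
            ",5.0,kPa,15\n"
            "Danio rerio,,kPa,15\n"
            "Danio rerio,5.0,kPa,\n"
            "Danio rerio,-2.0,kPa,15\n"
        )
        rec, rep = load_database(buf)
        assert len(rec) == 0
        assert sorted(rep["reason"]) == [
            "missing_pcrit_value",
            "missing_species",
            "missing_trial_temperature",
            "nonpositive_pcrit",
        ]

    def test_column_map_renames_headers(self):
        buf = StringIO("Species,Critical PO2,Critical PO2 units,Temperature\nX y,5,kPa,15\n")
        rec, rep = load_database(
            buf,
            column_map={
                "Species": "species",
                "Critical PO2": "pcrit_value",
                "Critical PO2 units": "pcrit_unit",
                "Temperature": "trial_temperature",
            },
        )
        assert len(rec) == 1


class TestHarmonize:
    def test_pressure_conversion_needs_no_conditions(self):
        df = pd.DataFrame(
            {
                "species": ["x"],
                "pcrit_value": [38.6],
                "pcrit_unit": ["mmHg"],
                "trial_temperature": [15.0],
            }
        )
        out = harmonize_units(df)
        assert out.loc[0, "pcrit_kpa"] == pytest.approx(38.6 * 101.325 / 760, rel=1e-9)

    def test_same_kpa_different_salinity_gives_different_mg_per_l(self):
        df = pd.DataFrame(
            {
                "species": ["fw", "sw"],
                "pcrit_value": [6.0, 6.0],
                "pcrit_unit": ["kPa", "kPa"],
                "trial_temperature": [15.0, 15.0],
                "salinity": [0.0, 35.0],
            }
        )
        out = harmonize_units(df)
        assert out.loc[0, "pcrit_mg_per_l"] > out.loc[1, "pcrit_mg_per_l"]

    def test_missing_salinity_flagged_not_dropped(self):
        df = pd.DataFrame(
            {
                "species": ["x"],
                "pcrit_value": [5.0],
                "pcrit_unit": ["kPa"],
                "trial_temperature": [15.0],
            }
        )
        out = harmonize_units(df)
        assert np.isnan(out.loc[0, "pcrit_mg_per_l"])
        assert out.loc[0, "conversion_flag"] == "no_salinity"
        assert out.loc[0, "pcrit_kpa"] == 5.0

    def test_idempotent(self):
        df, _ = generate_database(120, seed=4)
        once = harmonize_units(df)
        twice = harmonize_units(once)
        pd.testing.assert_series_equal(once["pcrit_kpa"], twice["pcrit_kpa"])
        pd.testing.assert_series_equal(once["pcrit_mg_per_l"], twice["pcrit_mg_per_l"])

    def test_generator_truth_recovered_across_units(self):
        df, sidecar = generate_database(200, seed=9)
        out = harmonize_units(df)
        assert np.allclose(out["pcrit_kpa"], sidecar["true_pcrit_kpa"], rtol=1e-9)


class TestControlSubset:
    def test_fixture_built_to_published_counts(self):
        df, _ = generate_database(331, seed=1)
        cs = control_subset(df)
        assert len(cs.records) == 297
        assert len(cs.records) + len(cs.exclusion_log) == 331

    @pytest.mark.parametrize(
        "row,reason",
        [
            ({"fed_state": "fed", "additional_stressor": False, "acclimation_days": 10}, "fed"),
            (
                {"fed_state": "unfed", "additional_stressor": True, "acclimation_days": 10},
                "stressor",
            ),
            (
                {"fed_state": "unfed", "additional_stressor": False, "acclimation_days": 2},
                "short_acclimation",
            ),
            (
                {"fed_state": None, "additional_stressor": False, "acclimation_days": 10},
                "missing_field",
            ),
        ],
    )
    def test_exclusion_reasons(self, row, reason):
        df = pd.DataFrame([{"species": "x", **row}])
        cs = control_subset(df)
        assert len(cs.records) == 0
        assert cs.exclusion_log.loc[0, "reason"] == reason

    def test_acclimation_exactly_two_days_excluded(self):
        df = pd.DataFrame(
            [
                {"species": "x", "fed_state": "unfed", "additional_stressor": False,
                 "acclimation_days": 2.0},
                {"species": "x", "fed_state": "unfed", "additional_stressor": False,
                 "acclimation_days": 2.5},
            ]
        )
        cs = control_subset(df)
        assert len(cs.records) == 1


class TestClimateZone:
    @pytest.mark.parametrize(
        "lat,zone",
        [
            (-14.67, "tropical"),
            (0.0, "tropical"),
            (23.44, "tropical"),
            (30.0, "subtropical"),
            (50.0, "temperate"),
            (66.56, "temperate"),
            (70.0, "polar"),
            (-80.0, "polar"),
        ],
    )
    def test_default_cutoffs(self, lat, zone):
        assert assign_climate_zone(lat) == zone

    def test_configurable_cutoffs(self):
        assert assign_climate_zone(30.0, cutoffs=(25.0, 28.0, 60.0)) == "temperate"

    def test_invalid_latitude(self):
        with pytest.raises(ValueError):
            assign_climate_zone(95.0)
        with pytest.raises(ValueError):
            assign_climate_zone(float("nan"))


class TestZoneAnova:
    def test_identical_groups_give_f_zero(self):
        df = pd.DataFrame(
            {
                "climate_zone": ["tropical"] * 5 + ["temperate"] * 5,
                "pcrit_kpa": [5.0] * 10,
            }
        )
        res = zone_anova(df)
        assert res["F"] == pytest.approx(0.0, abs=1e-12)

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "climate_zone": ["tropical"] * 20 + ["temperate"] * 20,
                "pcrit_kpa": np.concatenate(
                    [rng.normal(5, 0.5, 20), rng.normal(10, 0.5, 20)]
                ),
            }
        )
        res = zone_anova(df)
        assert res["p"] < 1e-6
        assert bool(res["pairwise"].loc[0, "significant"])

    def test_polar_excluded_and_f_in_published_vicinity(self):
        df = make_zone_dataset(seed=3)
        res = zone_anova(df, zone_column="climate_zone")
        assert "polar" not in res["group_sizes"]
        # construction mirrors the published zone contrast, F(2,297)=4.05
        assert 1.0 < res["F"] < 9.0
        means = res["group_means"]
        assert means["tropical"] < means["temperate"]

    def test_degenerate_groups_raise_with_sizes(self):
        df = pd.DataFrame({"climate_zone": ["tropical"], "pcrit_kpa": [5.0]})
        with pytest.raises(ValueError, match="group sizes"):
            zone_anova(df)


class TestMethodComparisons:
    def test_equal_groups_give_t_zero(self):
        df = pd.DataFrame(
            {
                "species": ["c"] * 8,
                "respirometry_type": ["closed_static_individual"] * 4
                + ["closed_flow_through"] * 4,
                "pcrit_kpa": [4.0, 5.0, 6.0, 7.0] * 2,
            }
        )
        res = method_comparisons(df)
        assert len(res) == 1
        assert res.loc[0, "t"] == pytest.approx(0.0, abs=1e-12)
        assert res.loc[0, "p"] == pytest.approx(1.0)

    def test_null_effect_rarely_significant_over_seeds(self):
        # no method effect, n=4 per method: the false-positive rate stays
        # at the nominal level
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame(
                {
                    "species": ["carp"] * 8,
                    "respirometry_type": ["closed_static_individual"] * 4
                    + ["closed_flow_through"] * 4,
                    "pcrit_kpa": rng.normal(5.0, 1.0, 8),
                }
            )
            res = method_comparisons(df)
            if res.loc[0, "p"] > 0.05:
                hits += 1
        assert hits >= 90

    def test_shifted_group_detected(self):
        df = pd.DataFrame(
            {
                "species": ["c"] * 10,
                "respirometry_type": ["closed_static_individual"] * 5
                + ["intermittent_flow"] * 5,
                "pcrit_kpa": [5.0, 5.1, 4.9, 5.05, 4.95, 9.0, 9.1, 8.9, 9.05, 8.95],
            }
        )
        res = method_comparisons(df)
        assert res.loc[0, "p"] < 1e-6

    def test_no_eligible_species_warns_and_returns_empty(self):
        df = pd.DataFrame(
            {
                "species": ["a", "b"],
                "respirometry_type": ["closed_static_individual"] * 2,
                "pcrit_kpa": [5.0, 6.0],
            }
        )
        with pytest.warns(UserWarning):
            res = method_comparisons(df)
        assert len(res) == 0


class TestSalinityComparison:
    @pytest.fixture
    def harmonized_fwsw(self):
        df = make_fwsw_dataset(seed=2)
        df = df.rename(columns={"pcrit_kpa": "pcrit_value"}).assign(pcrit_unit="kPa")
        return harmonize_units(df)

    def test_kpa_contrast_significant(self, harmonized_fwsw):
        res = salinity_comparison(harmonized_fwsw)
        assert res["pcrit_kpa"]["p"] < 0.001
        assert res["pcrit_kpa"]["mean_freshwater"] < res["pcrit_kpa"]["mean_seawater"]
        assert res["pcrit_kpa"]["percent_difference_of_means"] == pytest.approx(23.0, abs=8.0)

    def test_mg_per_l_contrast_null(self, harmonized_fwsw):
        res = salinity_comparison(harmonized_fwsw)
        assert res["pcrit_mg_per_l"]["p"] > 0.05

    def test_identical_distributions_not_significant(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(5, 1, 60)
        df = pd.DataFrame(
            {
                "water_type": ["freshwater"] * 30 + ["seawater"] * 30,
                "pcrit_kpa": np.concatenate([vals[:30], vals[30:]]),
                "pcrit_mg_per_l": np.concatenate([vals[:30], vals[30:]]),
            }
        )
        res = salinity_comparison(df)
        assert res["pcrit_kpa"]["p"] > 0.3

    def test_empty_group_raises(self):
        df = pd.DataFrame({"water_type": ["seawater"] * 5, "pcrit_kpa": [5.0] * 5,
                           "pcrit_mg_per_l": [2.0] * 5})
        with pytest.raises(ValueError, match="non-empty"):
            salinity_comparison(df)


class TestRegression:
    def test_noise_free_recovery_exact(self):
        from respcrit import DatabaseTargets

        df, _ = generate_database(400, seed=6, targets=DatabaseTargets(r_squared=None))
        out = harmonize_units(df)
        res = pcrit_regression(out)
        b = res["coefficients"].set_index("predictor")["b"]
        assert b["salinity"] == pytest.approx(0.047, abs=1e-8)
        assert b["trial_temperature"] == pytest.approx(-0.083, abs=1e-8)
        assert b["body_mass"] == pytest.approx(1.931, abs=1e-8)
        assert b["rmr"] == pytest.approx(0.001, abs=1e-8)
        assert res["intercept"] == pytest.approx(5.689, abs=1e-8)

    def test_adjusted_r2_near_target_at_published_n(self):
        df, _ = generate_database(1159, seed=2)
        res = pcrit_regression(harmonize_units(df))
        assert res["adjusted_r_squared"] == pytest.approx(0.195, abs=0.05)

    def test_constant_predictor_excluded_by_stepwise(self):
        df, _ = generate_database(300, seed=8)
        out = harmonize_units(df)
        out["rmr"] = 1.0
        res = pcrit_regression(out, selection="stepwise")
        assert "rmr" in set(res["excluded"]["predictor"])
        assert "rmr" not in set(res["coefficients"]["predictor"])

    def test_stepwise_keeps_strong_predictors(self):
        df, _ = generate_database(1159, seed=3)
        res = pcrit_regression(harmonize_units(df), selection="stepwise")
        kept = set(res["coefficients"]["predictor"])
        assert {"salinity", "trial_temperature", "body_mass"} <= kept

    def test_collinear_design_raises(self):
        df, _ = generate_database(200, seed=5)
        out = harmonize_units(df)
        out["rmr"] = out["salinity"] * 2.0  # exact collinearity
        with pytest.raises(ValueError, match="ollinear"):
            pcrit_regression(out)

    def test_ci_coverage_of_generating_coefficients(self):
        # 95% CIs from correctly specified OLS should cover the truth
        import statsmodels.api as sm

        cover = np.zeros(4)
        n_rep = 100
        truth = np.array([0.047, -0.083, 1.931, 0.001])
        for seed in range(n_rep):
            df, _ = generate_database(400, seed=seed)
            out = harmonize_units(df)
            X = sm.add_constant(
                out[["salinity", "trial_temperature", "body_mass", "rmr"]].to_numpy()
            )
            fit = sm.OLS(out["pcrit_kpa"].to_numpy(), X).fit()
            ci = fit.conf_int(alpha=0.05)[1:]
            cover += (ci[:, 0] <= truth) & (truth <= ci[:, 1])
        assert np.all(cover >= 90)
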