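"""Data model, fixture integrity, effort accounting, and removal design."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import occumix as ox


class TestFixture:
    def test_nineteen_site_years(self, fixture_design):
        assert fixture_design.n_sites == 19
        assert sorted(set(fixture_design.table["habitat"])) == sorted(ox.HABITATS)

    def test_site_m_2014_row(self, fixture_design):
        t = fixture_design.table
        row = t[(t["site"] == "M") & (t["year"] == 2014)].iloc[0]
        assert row["transect_km"] == pytest.approx(0.28)
        assert row["acos"] == 6

    def test_visit_correction_recorded(self, fixture_estimates):
        j15 = fixture_estimates.query("site == 'J' and year == 2015").iloc[0]
        assert j15["n_visits"] == 6
        assert j15["n_visits_printed"] == 8
        assert fixture_estimates["n_visits"].sum() == 132

    def test_eleven_detected(self, fixture_design):
        assert int(fixture_design.detected.sum()) == 11


class TestLoadSurveyTable:
    def test_empty_file_is_schema_error(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(ox.SchemaError):
            ox.load_survey_table(path)

    def test_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("site,year,habitat\nA,2014,scrub\n")
        with pytest.raises(ox.SchemaError):
            ox.load_survey_table(path)

    def test_unknown_habitat_rejected(self, tmp_path):
        path = tmp_path / "hab.csv"
        path.write_text(
            "site,year,habitat,area_ha,n_visits,acos,transect_km\n"
            "A,2014,wetland,1.0,4,10,1.0\n")
        with pytest.raises(ox.ValidationError):
            ox.load_survey_table(path)

    def test_nonpositive_length_rejected(self, tmp_path):
        path = tmp_path / "len.csv"
        path.write_text(
            "site,year,habitat,area_ha,n_visits,acos,transect_km\n"
            "A,2014,scrub,1.0,4,10,0.0\n")
        with pytest.raises(ox.ValidationError):
            ox.load_survey_table(path)

    def test_round_trip(self, fixture_design, tmp_path):
        path = tmp_path / "rt.csv"
        ox.write_survey_table(fixture_design, path)
        reread, _ = ox.load_survey_table(path)
        pd.testing.assert_frame_equal(
            reread.table[fixture_design.table.columns], fixture_design.table)


class TestDetectionHistory:
    @pytest.mark.parametrize("counts, expected", [
        ([[0, 2], [0, 0]], [[0, 1], [0, 0]]),
        ([[12, 12], [12, 12]], [[1, 1], [1, 1]]),
        ([[np.nan, np.nan]], [[np.nan, np.nan]]),
    ])
    def test_thresholding(self, counts, expected):
        hist = ox.build_detection_history(ox.CountMatrix(counts))
        assert np.array_equal(hist.values, np.asarray(expected, float), equal_nan=True)

    def test_negative_count_rejected(self):
        with pytest.raises(ox.ValidationError):
            ox.CountMatrix([[-1, 0]])

    def test_non_binary_history_rejected(self):
        with pytest.raises(ox.ValidationError):
            ox.DetectionHistory([[0, 2]])

    def test_matrix_round_trip(self, tmp_path):
        counts = ox.CountMatrix([[0, 2, np.nan], [1, np.nan, np.nan]])
        path = tmp_path / "counts.csv"
        counts.to_csv(path)
        assert ox.CountMatrix.from_csv(path) == counts

    @given(st.lists(st.lists(st.integers(0, 30), min_size=3, max_size=3),
                    min_size=1, max_size=6))
    def test_threshold_matches_naive_rule(self, rows):
        hist = ox.build_detection_history(ox.CountMatrix(rows))
        assert np.array_equal(hist.values, (np.asarray(rows) >= 1).astype(float))


class TestScaling:
    def test_scaled_mean_zero_sd_one(self, fixture_covariates):
        scaled = ox.scale_covariates(fixture_covariates, names=["acos"])
        col = scaled.site["acos"].to_numpy()
        assert abs(col.mean()) < 1e-10
        assert abs(col.std(ddof=1) - 1.0) < 1e-10

    def test_value_at_mean_projects_to_zero(self, fixture_covariates):
        scaled = ox.scale_covariates(fixture_covariates, names=["acos"])
        mean, _ = scaled.scaling["acos"]
        assert scaled.project("acos", mean) == pytest.approx(0.0)
        # the study-wide mean survey effort, back on raw scale
        assert round(mean) == 95

    def test_quadratic_is_square_of_scaled_linear(self, fixture_covariates):
        scaled = ox.scale_covariates(fixture_covariates, names=["acos^2"])
        np.testing.assert_allclose(
            scaled.site["acos2"], scaled.site["acos"] ** 2, atol=1e-12)

    def test_zero_variance_rejected(self):
        covs = ox.CovariateSet(site=pd.DataFrame({"x": [3.0, 3.0, 3.0]}))
        with pytest.raises(ox.ValidationError):
            ox.scale_covariates(covs, names=["x"])


class TestEffortSummary:
    def test_fixture_totals(self, fixture_design):
        s = ox.summarize_effort(fixture_design)
        assert s.total_surveys == 132
        assert s.total_aco_checks == 12335
        assert round(s.total_km) == 613
        assert s.naive_occupancy == pytest.approx(11 / 19)

    def test_observation_means(self, fixture_design):
        rng = np.random.default_rng(0)
        mask = fixture_design.visit_mask()
        counts = ox.CountMatrix(np.where(mask, rng.poisson(0.4, mask.shape), np.nan))
        s = ox.summarize_effort(fixture_design, counts)
        total = np.nansum(counts.values)
        assert s.mean_obs_per_survey == pytest.approx(total / 132)
        assert s.mean_obs_per_transect == pytest.approx(total / 19)

    @given(st.integers(1, 200))
    def test_totals_match_row_wise_summation(self, seed):
        design, _ = ox.generate_design(ox.GeneratorConfig(seed=seed, n_sites=8))
        s = ox.summarize_effort(design)
        t = design.table
        assert s.total_aco_checks == sum(
            int(k) * int(a) for k, a in zip(t["n_visits"], t["acos"]))
        assert s.total_km == pytest.approx(sum(
            float(k) * float(l) for k, l in zip(t["n_visits"], t["transect_km"])))


class TestRemovalDesign:
    def test_truncates_after_first_detection(self, fixture_design):
        hist = ox.DetectionHistory([[0, 1, 1, 0]])
        design = ox.SurveyDesign(fixture_design.table.iloc[[0]].assign(n_visits=4))
        truncated, _ = ox.apply_removal_design(hist, design)
        assert np.array_equal(truncated.values, [[0, 1, np.nan, np.nan]],
                              equal_nan=True)

    def test_all_zero_history_unchanged(self, fixture_design):
        mask = fixture_design.visit_mask()
        hist = ox.DetectionHistory(np.where(mask, 0.0, np.nan))
        truncated, summary = ox.apply_removal_design(hist, fixture_design)
        assert truncated == hist
        assert summary.total_surveys == 132

    def test_reduced_effort_matches_per_row_scan(self, fixture_design):
        hist = ox.simulate_occupancy_data(
            fixture_design, beta0=float(np.log(0.44 / 0.56)), p=0.33, seed=1)
        _, summary = ox.apply_removal_design(hist, fixture_design)
        # independent per-row scan of the same history
        surveys = km = checks = 0.0
        t = fixture_design.table
        for i in range(hist.n_sites):
            row = hist.values[i]
            used = int(t["n_visits"].iloc[i])
            for j, v in enumerate(row):
                if v == 1.0:
                    used = j + 1
                    break
            surveys += used
            km += used * t["transect_km"].iloc[i]
            checks += used * t["acos"].iloc[i]
        assert summary.total_surveys == surveys
        assert summary.total_aco_checks == checks
        assert summary.total_km == pytest.approx(km)

    def test_never_increases_effort_and_idempotent(self, fixture_design):
        hist = ox.simulate_occupancy_data(
            fixture_design, beta0=0.0, p=0.5, seed=9)
        full = ox.summarize_effort(fixture_design)
        once, s1 = ox.apply_removal_design(hist, fixture_design)
        twice, s2 = ox.apply_removal_design(once, fixture_design)
        assert s1.total_surveys <= full.total_surveys
        assert s1.total_aco_checks <= full.total_aco_checks
        assert s1.total_km <= full.total_km
        assert once == twice
        assert s1 == s2
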