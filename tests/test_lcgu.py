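"""Calibration, whole-brain denominators, uptake ratios and regional t-tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dgconnect import (
    SyntheticConfig,
    all_region_ttests,
    fit_calibration,
    generate_uptake,
    region_group_ttest,
    uptake_ratio,
    uptake_table_from_sections,
    whole_brain_average,
)
from dgconnect.exceptions import (
    CalibrationError,
    CalibrationRangeError,
    ConfigurationError,
    DegenerateDataError,
    MissingDataError,
    QuantificationError,
)


class TestCalibration:
    def test_linear_standards_inverted_exactly(self):
        """OD = a*activity + b: the fitted mapping inverts the line."""
        act = np.array([39.0, 200.0, 500.0, 1069.0])
        od = 0.001 * act + 0.05
        curve = fit_calibration(list(zip(act, od)))
        q = 0.001 * 350.0 + 0.05
        assert curve(q) == pytest.approx(350.0, rel=1e-10)

    def test_interpolation_nodes_exact(self):
        act = np.array([39.0, 120.0, 420.0, 700.0, 1069.0])
        od = np.log1p(act / 100.0)
        curve = fit_calibration(pd.DataFrame({"activity": act, "optical_density": od}))
        for a, o in zip(act, od):
            assert curve(o) == pytest.approx(a, rel=1e-12)

    def test_saturating_exponential_recovered_within_1pct(self):
        """Film saturation model OD = M(1 - exp(-k A)); invert analytically."""
        M, k = 2.5, 1.0 / 400.0
        act = np.linspace(39.0, 1069.0, 9)
        od = M * (1.0 - np.exp(-k * act))
        curve = fit_calibration(list(zip(act, od)))
        q_act = 555.0
        q_od = M * (1.0 - np.exp(-k * q_act))
        assert curve(q_od) == pytest.approx(q_act, rel=0.01)

    def test_non_monotone_standards_rejected(self):
        with pytest.raises(CalibrationError, match="monotone"):
            fit_calibration([(39.0, 0.1), (200.0, 0.4), (500.0, 0.3), (1069.0, 0.8)])

    def test_out_of_range_query_refused(self):
        act = [39.0, 200.0, 500.0, 1069.0]
        od = [0.1, 0.3, 0.6, 0.9]
        curve = fit_calibration(list(zip(act, od)))
        with pytest.raises(CalibrationRangeError):
            curve(0.95)
        assert curve(0.95, extrapolate=True) > 1069.0 * 0.9  # explicit override works

    def test_too_few_standards(self):
        with pytest.raises(CalibrationError, match="4 standards"):
            fit_calibration([(39.0, 0.1), (200.0, 0.3), (500.0, 0.6)])

    def test_decreasing_od_supported(self):
        """Film conventions vary; a strictly decreasing OD-activity relation is fine."""
        act = [39.0, 200.0, 500.0, 1069.0]
        od = [0.9, 0.6, 0.3, 0.1]
        curve = fit_calibration(list(zip(act, od)))
        assert curve(0.6) == pytest.approx(200.0, rel=1e-12)


class TestWholeBrain:
    def test_constant_field_returns_constant(self):
        rows = [
            {"animal_id": "a", "region": r, "section_index": s, "value": 7.5}
            for r in ("X", "Y") for s in (1, 2)
        ]
        assert whole_brain_average(pd.DataFrame(rows), "a", "X") == 7.5

    def test_restricted_section_set_enumeration(self, toy_sections):
        """Y appears in sections 2-3 only: denominator averages those sections' rows."""
        # sections 2, 3 contain X:12, X:14, Y:20, Y:22 -> mean 17
        assert whole_brain_average(toy_sections, "a1", "Y") == pytest.approx(17.0)
        # X appears in all three sections -> mean of all five measurements
        assert whole_brain_average(toy_sections, "a1", "X") == pytest.approx(
            (10 + 12 + 14 + 20 + 22) / 5
        )

    def test_disjoint_regions_have_different_denominators(self):
        rows = [
            {"animal_id": "a", "region": "X", "section_index": 1, "value": 10.0},
            {"animal_id": "a", "region": "Y", "section_index": 2, "value": 30.0},
        ]
        df = pd.DataFrame(rows)
        assert whole_brain_average(df, "a", "X") != whole_brain_average(df, "a", "Y")

    def test_per_animal_switch(self, toy_sections):
        assert whole_brain_average(toy_sections, "a1", "Y", per_animal=True) == pytest.approx(
            (10 + 12 + 14 + 20 + 22) / 5
        )

    def test_missing_region_raises(self, toy_sections):
        with pytest.raises(MissingDataError):
            whole_brain_average(toy_sections, "a1", "Z")


class TestUptakeRatio:
    def test_identity_when_equal(self):
        assert uptake_ratio(5.0, 5.0) == 1.0

    def test_zero_denominator(self):
        with pytest.raises(QuantificationError):
            uptake_ratio(1.0, 0.0)

    def test_toy_table_hand_enumeration(self, toy_sections):
        table = uptake_table_from_sections(toy_sections)
        # X: conc 12, denominator 15.6 (all five values); Y: conc 21, denominator 17
        assert table.loc[0, "X"] == pytest.approx(12.0 / 15.6)
        assert table.loc[0, "Y"] == pytest.approx(21.0 / 17.0)

    def test_scale_invariance_per_animal(self, toy_sections):
        """Multiplying one animal's entire section set by k leaves URs unchanged."""
        scaled = toy_sections.copy()
        scaled["value"] *= 3.7
        a = uptake_table_from_sections(toy_sections)
        b = uptake_table_from_sections(scaled)
        pd.testing.assert_frame_equal(a, b)

    def test_optical_density_rows_need_calibration(self, toy_sections):
        od = toy_sections.assign(value_kind="optical_density")
        with pytest.raises(ConfigurationError, match="calibration"):
            uptake_table_from_sections(od)

    def test_calibrated_od_path_matches_direct_activity(self, toy_sections):
        """OD values passed through an exactly linear calibration reproduce activities."""
        act = np.array([5.0, 10.0, 15.0, 20.0, 25.0])
        od = 0.01 * act
        curve = fit_calibration(list(zip(act, od)))
        as_od = toy_sections.assign(
            value=toy_sections["value"] * 0.01, value_kind="optical_density"
        )
        direct = uptake_table_from_sections(toy_sections)
        via_od = uptake_table_from_sections(as_od, calibration=curve)
        pd.testing.assert_frame_equal(direct, via_od)


class TestRegionTTest:
    def _table(self, ctrl, trt, region="R"):
        n = len(ctrl) + len(trt)
        return pd.DataFrame(
            {
                "animal_id": [f"a{i}" for i in range(n)],
                "group": ["control"] * len(ctrl) + ["treated"] * len(trt),
                region: list(ctrl) + list(trt),
            }
        )

    def test_identical_groups_null(self):
        r = region_group_ttest(self._table([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]), "R")
        assert r.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)
        assert not r.significant

    def test_hand_computed_pooled_t(self):
        """{1,2,3} vs {4,5,6}: t = -3.674 on 4 df."""
        r = region_group_ttest(self._table([1.0, 2.0, 3.0], [4.0, 5.0, 6.0]), "R")
        assert r.t_statistic == pytest.approx(-3.674, abs=5e-4)
        assert r.df == 4
        assert r.significant

    def test_shifted_region_flagged_null_regions_calibrated(self):
        """A 5-SD shift is flagged; untouched regions flag at ~5% across replicates."""
        study_rates = []
        for s in range(40):
            study = generate_uptake(SyntheticConfig(n_per_group=10, rng_seed=900 + s))
            table = study.uptake.copy()
            shift_region = table.columns[2]
            sd = table[shift_region].std(ddof=1)
            table.loc[table["group"] == "treated", shift_region] += 5 * sd
            res = all_region_ttests(table)
            assert res.loc[res["region"] == shift_region, "significant"].iloc[0]
            study_rates.append(res.loc[res["region"] != shift_region, "significant"].mean())
        # regions within a study share latent factors, so flags cluster:
        # compare the mean study-level rate against its empirical SEM
        rate = np.mean(study_rates)
        sem = np.std(study_rates, ddof=1) / np.sqrt(len(study_rates))
        assert abs(rate - 0.05) < 3 * sem

    def test_degenerate_variance(self):
        with pytest.raises(DegenerateDataError):
            region_group_ttest(self._table([1.0, 1.0, 1.0], [2.0, 2.0]), "R")

    def test_welch_option(self):
        t_pooled = region_group_ttest(self._table([1.0, 2.0, 3.0], [4.0, 6.0, 8.0]), "R")
        t_welch = region_group_ttest(
            self._table([1.0, 2.0, 3.0], [4.0, 6.0, 8.0]), "R", equal_var=False
        )
        assert t_welch.df < t_pooled.df

    def test_permuted_labels_give_uniform_pvalues(self):
        """Label permutation yields p ~ Uniform(0,1) (KS check over 600 shuffles)."""
        study = generate_uptake(SyntheticConfig(n_per_group=10, rng_seed=77))
        table = study.uptake
        region = table.columns[5]
        rng = np.random.default_rng(0)
        labels = table["group"].to_numpy().copy()
        pvals = []
        for _ in range(600):
            rng.shuffle(labels)
            shuffled = table.assign(group=labels)
            pvals.append(region_group_ttest(shuffled, region).p_value)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 1e-3
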