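"""Jackknife machinery, connection calls, group comparison and label rules."""

import numpy as np
import pandas as pd
import pytest

from dgconnect import (
    SeedConnectivity,
    SyntheticConfig,
    build_connectivity_report,
    call_connection,
    compare_groups,
    generate_uptake,
    jackknife,
    jackknife_vip,
)
from dgconnect.connectivity import swap_label
from dgconnect.exceptions import ConfigurationError, DegenerateDataError


class TestJackknife:
    def test_mean_statistic_closed_form(self, rng):
        """For the sample mean the jackknife SE equals s/sqrt(n) exactly."""
        x = rng.standard_normal(17)
        _, sd, _ = jackknife(x.reshape(-1, 1), lambda d: d.mean())
        assert sd[0] == pytest.approx(x.std(ddof=1) / np.sqrt(17), rel=1e-12)

    def test_three_animal_brute_force(self):
        """n = 3 hand table: SD matches explicit enumeration of the 3 refits."""
        rows = np.array([[1.0, 2.0], [2.0, 5.0], [4.0, 3.0]])
        stat = lambda d: np.array([d[:, 0].mean() * d[:, 1].mean()])  # noqa: E731
        theta, sd, loo = jackknife(rows, stat)
        by_hand = np.array(
            [stat(rows[[1, 2]])[0], stat(rows[[0, 2]])[0], stat(rows[[0, 1]])[0]]
        )
        expected = np.sqrt(2.0 / 3.0 * ((by_hand - by_hand.mean()) ** 2).sum())
        assert sd[0] == pytest.approx(expected, rel=1e-12)
        assert loo.ravel() == pytest.approx(by_hand)

    def test_duplicated_rows_shrink_sd(self, small_table):
        """Doubling every animal (identical pairs) reduces the jackknife SD."""
        region = small_table.columns[2]
        base = jackknife_vip(small_table, region, "control", n_components=1)
        doubled = pd.concat([small_table, small_table.assign(animal_id=small_table.animal_id + "b")],
                            ignore_index=True)
        dup = jackknife_vip(doubled, region, "control", n_components=1)
        assert (dup["sd_jack"].to_numpy() < base["sd_jack"].to_numpy()).all()

    def test_needs_three_observations(self):
        with pytest.raises(ConfigurationError, match="at least 3"):
            jackknife(np.ones((2, 1)), lambda d: d.mean())

    def test_vip_ci_brackets_estimate(self, small_table):
        est = jackknife_vip(small_table, small_table.columns[2], "treated")
        assert (est["ci_low"] <= est["vip"]).all()
        assert (est["vip"] <= est["ci_high"]).all()
        assert (est["sd_jack"] >= 0).all()


class TestConnectionCall:
    @pytest.mark.parametrize(
        "ci_low, ci_high, expected",
        [(0.85, 1.40, True), (0.60, 1.10, False)],
    )
    def test_default_lower_bound_rule(self, ci_low, ci_high, expected):
        assert call_connection(ci_low, vip=(ci_low + ci_high) / 2) is expected

    def test_zero_threshold_connects_positive_vip(self):
        assert call_connection(ci_low=0.01, vip=0.5, threshold=0.0) is True

    def test_point_criterion(self):
        assert call_connection(ci_low=0.5, vip=1.2, criterion="point") is True
        assert call_connection(ci_low=0.9, vip=0.7, criterion="point") is False

    def test_unknown_criterion(self):
        with pytest.raises(ConfigurationError):
            call_connection(1.0, criterion="bogus")


class TestCompareGroups:
    def _est(self, vip, sd, seed="S", target="T"):
        tmult = 2.262  # t_{0.975, 9}
        return {"seed": seed, "target": target, "vip": vip, "sd_jack": sd,
                "ci_low": vip - tmult * sd, "ci_high": vip + tmult * sd}

    def test_identical_estimates_unchanged(self):
        e = self._est(1.2, 0.1)
        out = compare_groups(e, dict(e), family_size=48, n_control=10, n_treated=10)
        assert out.t_statistic == 0.0
        assert out.label == "unchanged"

    def test_lost_connection(self):
        """Significant drop, connected in control only -> lost."""
        out = compare_groups(
            self._est(1.5, 0.05), self._est(0.4, 0.05),
            family_size=48, n_control=10, n_treated=10,
        )
        assert out.p_bonferroni < 0.05
        assert out.label == "lost"

    def test_increased_connection(self):
        """Significant rise, connected in both groups -> increased."""
        out = compare_groups(
            self._est(1.2, 0.03), self._est(1.8, 0.03),
            family_size=48, n_control=10, n_treated=10,
        )
        assert out.label == "increased"

    def test_gained_connection(self):
        out = compare_groups(
            self._est(0.3, 0.05), self._est(1.4, 0.05),
            family_size=48, n_control=10, n_treated=10,
        )
        assert out.label == "gained"

    def test_significant_but_disconnected_stays_unchanged(self):
        """Both CIs below threshold: no category applies even if p is small."""
        out = compare_groups(
            self._est(0.1, 0.02), self._est(0.5, 0.02),
            family_size=48, n_control=10, n_treated=10,
        )
        assert out.p_bonferroni < 0.05
        assert out.label == "unchanged"

    def test_bonferroni_capped_at_one(self):
        out = compare_groups(
            self._est(1.00, 0.3), self._est(1.01, 0.3),
            family_size=48, n_control=10, n_treated=10,
        )
        assert out.p_bonferroni == 1.0

    def test_degenerate_sds_raise(self):
        with pytest.raises(DegenerateDataError):
            compare_groups(self._est(1.0, 0.0), self._est(1.2, 0.0),
                           family_size=48, n_control=10, n_treated=10)

    def test_mismatched_edges_rejected(self):
        with pytest.raises(ConfigurationError):
            compare_groups(self._est(1.0, 0.1, target="A"), self._est(1.0, 0.1, target="B"),
                           family_size=48, n_control=10, n_treated=10)


class TestSeedConnectivity:
    def test_comparison_count(self, null_study):
        """4 seeds x 49 regions -> exactly 4 x 48 comparisons."""
        model = SeedConnectivity().fit(null_study.uptake)
        assert len(model.comparisons_) == 4 * 48
        assert len(model.edges_) == 2 * 4 * 48
        assert model.labels_.shape == (4, 49)

    def test_seed_excluded_from_own_predictors(self, null_study):
        model = SeedConnectivity().fit(null_study.uptake)
        for seed in model.labels_.index:
            targets = set(model.comparisons_.loc[model.comparisons_["seed"] == seed, "target"])
            assert seed not in targets
            assert model.labels_.loc[seed, seed] == ""

    def test_deterministic_refit(self, null_study):
        a = SeedConnectivity().fit(null_study.uptake)
        b = SeedConnectivity().fit(null_study.uptake)
        pd.testing.assert_frame_equal(a.edges_, b.edges_)
        pd.testing.assert_frame_equal(a.comparisons_, b.comparisons_)

    def test_group_relabel_swaps_directional_labels(self):
        """Swapping group labels maps gained<->lost and increased<->decreased."""
        study = generate_uptake(
            SyntheticConfig(rng_seed=5, edge_effects=[("DSub", "AV", "treated", 0.4)])
        )
        fwd = SeedConnectivity(control_label="control").fit(study.uptake)
        rev = SeedConnectivity(control_label="treated").fit(study.uptake)
        exp = fwd.comparisons_["label"].map(swap_label)
        assert (rev.comparisons_["label"] == exp).all()
        assert np.allclose(rev.comparisons_["t"], -fwd.comparisons_["t"])

    def test_unknown_seed_rejected(self, null_study):
        with pytest.raises(ConfigurationError, match="unknown seed"):
            SeedConnectivity(seeds=("Nope",)).fit(null_study.uptake)

    def test_single_group_rejected(self, null_study):
        table = null_study.uptake[null_study.uptake["group"] == "control"]
        with pytest.raises(ConfigurationError, match="two group levels"):
            SeedConnectivity().fit(table)

    def test_global_family_scales_pvalues(self, small_table):
        region = small_table.columns[2]
        per_seed = SeedConnectivity(seeds=(region,), family="per_seed").fit(small_table)
        glob = SeedConnectivity(seeds=(region,), family="global").fit(small_table)
        # one seed: global family equals per-seed family, p identical
        assert np.allclose(per_seed.comparisons_["p_bonferroni"],
                           glob.comparisons_["p_bonferroni"])
        assert per_seed.family_size_ == glob.family_size_ == small_table.shape[1] - 3

    def test_report_wrapper_matches_estimator(self, small_table):
        region = small_table.columns[2]
        rep = build_connectivity_report(small_table, seeds=(region,), n_components=1)
        est = SeedConnectivity(seeds=(region,), n_components=1).fit(small_table)
        pd.testing.assert_frame_equal(rep["comparisons"], est.comparisons_)
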