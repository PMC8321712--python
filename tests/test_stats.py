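import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from petloop import phantom, stats


def raw_sample_with(mean, sd, n, rng):
    """A concrete sample with exactly the requested mean and SD (ddof=1)."""
    z = rng.normal(size=n)
    z = (z - z.mean()) / z.std(ddof=1)
    return mean + sd * z


@pytest.fixture(scope="module")
def targets():
    return stats.load_group_targets()


@pytest.fixture(scope="module")
def printed_comparison(targets):
    return stats.compare_from_summaries(targets)


def simulated_cohorts(n, seed):
    targets = stats.load_group_targets()
    out = []
    for group, s in (("healthy", seed), ("gad", seed + 1)):
        spec = phantom.CohortSpec(
            targets=stats.targets_to_cohort_targets(targets, group),
            n_subjects=n, seed=s,
        )
        with pytest.warns(UserWarning):  # printed rates imply clipped endpoints
            out.append(phantom.sample_cohort(spec).metrics)
    return out


class TestTwoSampleT:
    def test_left_prefrontal_peak_matches_printed_value(self):
        t, df, p = stats.two_sample_t(
            stats.GroupSummary(2.41, 0.21, 20), stats.GroupSummary(2.04, 0.20, 20)
        )
        assert round(abs(t), 2) == 5.71
        assert df == 38
        assert p < 0.05

    def test_identical_summaries_give_zero(self):
        g = stats.GroupSummary(1.97, 0.2, 20)
        t, _, p = stats.two_sample_t(g, g)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_matches_raw_cohort_computation(self, rng):
        """Summary-based t equals scipy's t on raw samples with those summaries."""
        for m1, s1, n1, m2, s2, n2 in [
            (2.41, 0.21, 20, 2.04, 0.20, 20),
            (0.10, 0.01, 12, 0.09, 0.02, 31),
        ]:
            x = raw_sample_with(m1, s1, n1, rng)
            y = raw_sample_with(m2, s2, n2, rng)
            want = sps.ttest_ind(x, y)
            t, df, p = stats.two_sample_t(
                stats.GroupSummary(m1, s1, n1), stats.GroupSummary(m2, s2, n2)
            )
            assert t == pytest.approx(want.statistic, rel=1e-9)
            assert p == pytest.approx(want.pvalue, rel=1e-9)

    def test_antisymmetry(self):
        g1 = stats.GroupSummary(1.5, 0.2, 10)
        g2 = stats.GroupSummary(1.8, 0.3, 14)
        t12, _, p12 = stats.two_sample_t(g1, g2)
        t21, _, p21 = stats.two_sample_t(g2, g1)
        assert t12 == -t21 and p12 == p21

    def test_zero_variance_unequal_means_is_infinite(self):
        t, _, p = stats.two_sample_t(
            stats.GroupSummary(1.0, 0.0, 5), stats.GroupSummary(2.0, 0.0, 5)
        )
        assert np.isinf(t) and p == 0.0

    def test_welch_differs_under_unequal_variances(self):
        g1 = stats.GroupSummary(1.0, 0.1, 10)
        g2 = stats.GroupSummary(1.2, 0.9, 40)
        _, df_pooled, _ = stats.two_sample_t(g1, g2)
        _, df_welch, _ = stats.two_sample_t(g1, g2, welch=True)
        assert df_pooled == 48 and df_welch < 48

    def test_significance_threshold_at_df38(self):
        crit = sps.t.ppf(0.975, 38)
        for t_val, expect in [(crit * 0.99, False), (crit * 1.01, True)]:
            p = 2 * sps.t.sf(t_val, 38)
            assert bool(p < 0.05) is expect


class TestPrintedTables:
    def test_reproduces_printed_t_in_22_of_24_cells(self, targets, printed_comparison):
        """Pooled t from printed mean+/-SD matches the printed |t| to 2 dp
        everywhere except the two documented t=2.1 cells (which compute 2.0)."""
        match = printed_comparison["t_abs"] == targets["t_printed"]
        assert match.sum() == 22
        mismatched = targets[~match.to_numpy()]
        assert set(mismatched["t_printed"]) == {2.1}
        assert set(mismatched["side"]) == {"right"}
        assert set(printed_comparison.loc[~match.to_numpy(), "t_abs"]) == {2.0}

    def test_significance_calls_match_printed_p_row(self, targets, printed_comparison):
        assert (
            printed_comparison["significant"]
            == targets["significant_printed"].astype(bool)
        ).all()


class TestCompareGroups:
    def test_row_count_and_determinism(self):
        h, g = simulated_cohorts(12, seed=5)
        a = stats.compare_groups(h, g)
        b = stats.compare_groups(h, g)
        assert len(a) == 24
        pd.testing.assert_frame_equal(a, b)

    def test_missing_cell_rejected(self):
        h, g = simulated_cohorts(4, seed=1)
        with pytest.raises(ValueError, match="missing cell"):
            stats.compare_groups(h[h.roi != "thalamus"], g)

    def test_summaries_recover_sample_moments(self, rng):
        df = pd.DataFrame(
            dict(subject=range(8), roi="r", side="left", metric="peak",
                 value=rng.normal(2, 0.3, 8))
        )
        out = stats.summarize_metrics(df)
        assert out.loc[0, "mean"] == pytest.approx(df["value"].mean())
        assert out.loc[0, "sd"] == pytest.approx(df["value"].std(ddof=1))
        assert out.loc[0, "n"] == 8

    def test_bonferroni_is_more_conservative(self):
        h, g = simulated_cohorts(30, seed=9)
        plain = stats.compare_groups(h, g)
        corrected = stats.compare_groups(h, g, correction="bonferroni")
        assert corrected["significant"].sum() <= plain["significant"].sum()
        assert (corrected["p_adjusted"] >= plain["p_adjusted"] - 1e-15).all()


class TestClassifyDynamics:
    def test_left_prefrontal_pattern(self, printed_comparison):
        """Lower peak and pre-peak rate, higher post-peak rate, all significant:
        slow advance, fast washout, decreased total."""
        rows = printed_comparison.query("roi == 'prefrontal' and side == 'left'")
        label = stats.classify_dynamics(rows)
        assert (label.in_label, label.out_label, label.total_label) == (
            "slow-in", "fast-out", "decreased"
        )

    def test_left_thalamus_pattern(self, printed_comparison):
        rows = printed_comparison.query("roi == 'thalamus' and side == 'left'")
        label = stats.classify_dynamics(rows)
        assert (label.in_label, label.out_label, label.total_label) == (
            "fast-in", "fast-out", "increased"
        )

    def test_nonsignificant_roi_is_all_none(self, printed_comparison):
        rows = printed_comparison.query("roi == 'striatum' and side == 'right'")
        label = stats.classify_dynamics(rows)
        assert (label.in_label, label.out_label, label.total_label) == (
            "none", "none", "none"
        )

    def test_wrong_metric_set_rejected(self, printed_comparison):
        rows = printed_comparison.query("metric == 'peak'").head(3)
        with pytest.raises(ValueError, match="peak, pre_rate"):
            stats.classify_dynamics(rows)

    def test_dynamics_table_covers_all_rois(self, printed_comparison):
        table = stats.dynamics_table(printed_comparison)
        assert len(table) == 8
        assert set(zip(table.roi, table.side)) == {
            (r, s) for r in phantom.LOOP_ROIS for s in phantom.SIDES
        }


class TestRoiPattern:
    def test_majority_rule_on_printed_tables(self, printed_comparison):
        pattern = stats.roi_alteration_pattern(printed_comparison)
        altered = pattern.set_index(["roi", "side"])["altered"]
        assert altered[("striatum", "right")] == False  # noqa: E712
        assert altered[("hippocampus", "right")] == False  # noqa: E712
        assert altered.drop([("striatum", "right"), ("hippocampus", "right")]).all()


class TestPlotTac:
    def test_figure_written_and_means_match_columns(self, tmp_path, rng):
        curves = []
        for group_offset in (0.0, 0.4):
            rows = []
            for subject in range(3):
                values = np.linspace(1, 2, 11) + group_offset + 0.01 * subject
                for t, v in zip(np.arange(0, 151, 15), values):
                    rows.append(
                        dict(subject=subject, roi="prefrontal", side="left",
                             time=t, value=v)
                    )
            curves.append(pd.DataFrame(rows))
        path = tmp_path / "tac.png"
        plotted = stats.plot_tac(curves[0], curves[1], path)
        assert path.exists() and path.stat().st_size > 0
        healthy_t0 = plotted.query("group == 'healthy' and time == 0")["mean"]
        direct = curves[0].query("time == 0")["value"].mean()
        assert healthy_t0.iloc[0] == pytest.approx(direct)

    def test_empty_group_rejected(self, tmp_path):
        df = pd.DataFrame(columns=["subject", "roi", "side", "time", "value"])
        with pytest.raises(ValueError):
            stats.plot_tac(df, df, tmp_path / "x.png")
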