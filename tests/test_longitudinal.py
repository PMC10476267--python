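"""t statistics, BH adjustment and the MR rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

import tmtbridge as tb
from tmtbridge.errors import ValidationError
from tmtbridge.stats import pooled_ttest_rows

from conftest import bh_brute_force, noiseless_config, planted_nonflat


class TestPooledTTest:
    def test_identical_groups_give_null_result(self):
        res = pooled_ttest_rows(np.array([[1.0, 2.0, 3.0]]), np.array([[1.0, 2.0, 3.0]]))
        assert res.loc[0, "log2fc"] == 0.0
        assert res.loc[0, "t"] == 0.0
        assert res.loc[0, "p_value"] == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # mean diff 2, pooled SD 1, se = sqrt(2/3): t = 2.449, df = 4, p = 0.0705
        res = pooled_ttest_rows(np.array([[3.0, 4.0, 5.0]]), np.array([[1.0, 2.0, 3.0]]))
        assert res.loc[0, "log2fc"] == pytest.approx(2.0)
        assert res.loc[0, "t"] == pytest.approx(2.449, abs=1e-3)
        assert res.loc[0, "df"] == 4
        assert res.loc[0, "p_value"] == pytest.approx(0.0705, abs=2e-4)

    def test_agrees_with_scipy_on_random_rows(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, size=(50, 3))
        b = rng.normal(0.5, 1, size=(50, 3))
        res = pooled_ttest_rows(a, b)
        ref = sps.ttest_ind(a, b, axis=1, equal_var=True)
        np.testing.assert_allclose(res["t"], ref.statistic, rtol=1e-10)
        np.testing.assert_allclose(res["p_value"], ref.pvalue, rtol=1e-10)

    def test_welch_flag_agrees_with_scipy(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, size=(40, 4))
        b = rng.normal(0.3, 2, size=(40, 3))
        res = pooled_ttest_rows(a, b, equal_var=False)
        ref = sps.ttest_ind(a, b, axis=1, equal_var=False)
        np.testing.assert_allclose(res["t"], ref.statistic, rtol=1e-10)
        np.testing.assert_allclose(res["p_value"], ref.pvalue, rtol=1e-10)

    def test_degenerate_zero_variance_policy(self):
        a = np.array([[2.0, 2.0, 2.0], [2.0, 2.0, 2.0]])
        b = np.array([[2.0, 2.0, 2.0], [1.0, 1.0, 1.0]])
        res = pooled_ttest_rows(a, b)
        assert res["degenerate"].all()
        assert res.loc[0, "p_value"] == 1.0  # equal means: no evidence
        assert res.loc[1, "p_value"] == 0.0  # unequal means, zero noise
        assert res.loc[1, "log2fc"] == 1.0

    def test_insufficient_replicates_excluded(self):
        a = np.array([[1.0, np.nan, np.nan]])
        b = np.array([[1.0, 2.0, 3.0]])
        assert pooled_ttest_rows(a, b)["p_value"].isna().all()


class TestBHAdjust:
    def test_textbook_example(self):
        np.testing.assert_allclose(
            tb.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(tb.bh_adjust([0.05]), [0.05])

    def test_capped_at_one(self):
        np.testing.assert_allclose(tb.bh_adjust([1.0, 1.0]), [1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            tb.bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=200))
    def test_matches_brute_force_step_up(self, p):
        np.testing.assert_allclose(tb.bh_adjust(p), bh_brute_force(p), rtol=1e-12)

    @given(
        st.lists(st.floats(min_value=0.001, max_value=0.999), min_size=2, max_size=30),
        st.integers(min_value=0, max_value=29),
    )
    def test_raising_one_p_never_lowers_any_adjusted_p(self, p, idx):
        idx = idx % len(p)
        before = tb.bh_adjust(p)
        bumped = list(p)
        bumped[idx] = min(1.0, bumped[idx] * 1.5 + 1e-4)
        after = tb.bh_adjust(bumped)
        assert (after >= before - 1e-12).all()


class TestMRRule:
    @pytest.mark.parametrize(
        "adj, fc, expected",
        [
            ((0.01, 0.04), (1.2, 0.3), True),   # both significant, one large FC
            ((0.06, 0.01), (2.0, 2.0), False),  # significance fails at one stage
            ((0.01, 0.01), (0.8, -0.9), False),  # magnitude fails at both
        ],
    )
    def test_rule_truth_table(self, adj, fc, expected):
        ratios = pd.DataFrame(
            {
                "comparison": ["EM_vs_M", "LM_vs_M"],
                "log2fc": fc,
                "adj_p": adj,
            },
            index=["P0", "P0"],
        )
        calls = tb.call_mr(ratios)
        assert bool(calls.loc["P0", "is_mr"]) is expected

    def test_missing_comparison_excludes_protein(self):
        ratios = pd.DataFrame(
            {"comparison": ["EM_vs_M"], "log2fc": [2.0], "adj_p": [0.01]}, index=["P0"]
        )
        assert tb.call_mr(ratios).empty

    def test_noiseless_early_jump_fold_change_is_exact(self):
        cfg = tb.SimulationConfig(
            n_proteins=30, seed=1, noise_sd_log2=0.0,
            fraction_per_archetype={"C5_early_jump": 1.0},
            channel_loading_log2=np.zeros((3, 10)), effect_grid=(),
        )
        _, matrices, design = tb.simulate(cfg)
        bridged = tb.bridge_correct(matrices, design)
        res = tb.stage_ratio(bridged, "untreated", "EM_vs_M")
        np.testing.assert_allclose(res["log2fc"], 2.0, atol=1e-12)

    def test_noiseless_recovery_of_planted_mr_set(self, noiseless_run):
        _, truth, _, _, bridged = noiseless_run
        calls = tb.mr_analysis(bridged, "untreated")
        assert tb.mr_set(calls) == planted_nonflat(truth)


class TestMarkerReport:
    def test_planted_markers_flagged_significant_at_both_stages(self):
        cfg = tb.SimulationConfig(
            n_proteins=400, seed=13, noise_sd_log2=0.05,
            fraction_per_archetype={"C5_early_jump": 0.05},
            effect_grid=(),
        )
        truth, matrices, design = tb.simulate(cfg)
        bridged = tb.normalize(matrices, design)
        markers = sorted(truth.index[truth["archetype"] == "C5_early_jump"])[:6]
        report, absent = tb.marker_report(bridged, markers)
        assert absent == []
        assert report["significant_both_stages"].all()
        # standardization convention: median 0 per component column
        for cond, grp in report.groupby("condition"):
            assert np.median(grp["log2fc_em_std"]) == pytest.approx(0.0, abs=1e-9)

    def test_absent_marker_reported_not_fatal(self, noiseless_run):
        _, _, _, _, bridged = noiseless_run
        present = bridged.protein_ids[0]
        report, absent = tb.marker_report(bridged, [present, "GHOST"])
        assert absent == ["GHOST"]
        assert set(report.index) == {present}

    def test_flat_markers_rarely_significant(self, noisy_run):
        # Unregulated proteins must not look like markers: the rate of
        # double-stage significance among nulls stays within the FDR level.
        # (EM and LM tests share the myoblast replicates, so their false
        # positives correlate; individual flukes are possible, a high rate is
        # not.)
        _, truth, _, _, bridged = noisy_run
        effect_cols = [c for c in truth.columns if c.startswith(("vehicle_", "tmx_"))]
        untouched = (truth["archetype"] == "flat") & (truth[effect_cols] == 0).all(axis=1)
        flats = sorted(truth.index[untouched])[:40]
        report, _ = tb.marker_report(bridged, flats)
        assert report["significant_both_stages"].mean() <= 0.05
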