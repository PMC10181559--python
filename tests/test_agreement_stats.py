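import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ppgprv.agreement_stats import (
    bland_altman,
    build_agreement_report,
    cohort_table,
    df_percent,
    linreg_r2,
    p_bias,
    paired_compare,
    posthoc_dunn,
    posthoc_tukey,
    rmse,
    scheirer_ray_hare,
    variance_gate,
)

# Printed cohort-table cells that are exact arithmetic functions of the
# printed device means: (ecg_mean, ppg_mean, expected, decimals).
DF_CELLS = [
    (81.44, 81.23, 0.26, 2),
    (757.16, 758.69, 0.2, 1),
    (47.94, 52.21, 8.91, 2),
    (733.66, 728.62, 0.69, 2),
    (63.15, 61.57, 2.5, 1),
    (24.39, 33.37, 36.82, 2),
    (46.55, 51.58, 10.8, 1),
    (72.71, 72.38, 0.45, 2),
    (851.51, 855.18, 0.43, 2),
    (48.0, 55.72, 16.1, 1),
    (49.52, 46.69, 5.7, 1),
]
PBIAS_CELLS = [
    (81.44, 81.23, 0.3, 1),
    (757.16, 758.69, -0.2, 1),
    (47.94, 52.21, -8.2, 1),
    (38.33, 42.58, -10.0, 0),
    (88.58, 88.29, 0.3, 1),
    (733.66, 728.62, 0.7, 1),
    (63.15, 61.57, 2.6, 1),
    (83.28, 83.81, -0.6, 1),
    (72.71, 72.38, 0.5, 1),
    (851.51, 855.18, -0.4, 1),
    (48.0, 55.72, -13.9, 1),
    (49.52, 46.69, 6.0, 0),
]


class TestDfPercent:
    @pytest.mark.parametrize("ecg,ppg,expected,nd", DF_CELLS)
    def test_reproduces_printed_cells(self, ecg, ppg, expected, nd):
        assert round(df_percent(ecg, ppg), nd) == pytest.approx(expected)

    def test_equal_means_zero(self):
        assert df_percent(50.0, 50.0) == 0.0

    def test_zero_ecg_errors(self):
        with pytest.raises(ValueError):
            df_percent(0.0, 50.0)


class TestPBias:
    @pytest.mark.parametrize("ecg,ppg,expected,nd", PBIAS_CELLS)
    def test_reproduces_printed_cells(self, ecg, ppg, expected, nd):
        assert round(p_bias(ecg, ppg), nd) == pytest.approx(expected)

    def test_equal_means_zero(self):
        assert p_bias(50.0, 50.0) == 0.0

    def test_zero_ppg_errors(self):
        with pytest.raises(ValueError):
            p_bias(50.0, 0.0)


class TestRmse:
    def test_identical_pairs_zero(self):
        assert rmse([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_unit_cross(self):
        assert rmse([1.0, 0.0], [0.0, 1.0]) == pytest.approx(1.0)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(size=40), rng.normal(size=40)
        expected = (sum((x - y) ** 2 for x, y in zip(a, b)) / 40.0) ** 0.5
        assert rmse(a, b) == pytest.approx(expected, rel=1e-12)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            rmse([], [])


class TestBlandAltman:
    def test_identical_pairs(self):
        res = bland_altman([3.0, 4.0, 5.0], [3.0, 4.0, 5.0])
        assert res.bias == 0.0
        assert res.loa_low == res.loa_high == 0.0

    def test_two_unit_diffs(self):
        # diffs {-1, +1}: bias 0, sd = sqrt(2), LoA = +/- 1.96*sqrt(2)
        res = bland_altman([1.0, 2.0], [2.0, 1.0])
        assert res.bias == pytest.approx(0.0)
        assert res.loa_high == pytest.approx(1.96 * np.sqrt(2.0))
        assert res.loa_low == pytest.approx(-1.96 * np.sqrt(2.0))

    def test_construction_invariants(self):
        rng = np.random.default_rng(11)
        a, b = rng.normal(10, 2, 50), rng.normal(10, 2, 50)
        res = bland_altman(a, b)
        sd = np.std(a - b, ddof=1)
        assert res.loa_low == pytest.approx(res.bias - 1.96 * sd)
        assert res.loa_high == pytest.approx(res.bias + 1.96 * sd)
        assert res.loa_low <= res.bias <= res.loa_high

    def test_gaussian_coverage(self):
        rng = np.random.default_rng(13)
        a = rng.normal(0, 1, 10000)
        b = np.zeros(10000)
        res = bland_altman(a, b)
        inside = np.mean((res.pair_diffs >= res.loa_low) & (res.pair_diffs <= res.loa_high))
        assert inside == pytest.approx(0.95, abs=0.01)

    def test_label_swap_mirrors(self):
        rng = np.random.default_rng(17)
        a, b = rng.normal(5, 1, 30), rng.normal(5, 1, 30)
        fwd, rev = bland_altman(a, b), bland_altman(b, a)
        assert rev.bias == pytest.approx(-fwd.bias)
        assert rev.loa_low == pytest.approx(-fwd.loa_high)
        assert rev.loa_high == pytest.approx(-fwd.loa_low)


class TestLinreg:
    def test_exact_line(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = linreg_r2(x, 2.0 * x + 1.0)
        assert res["slope"] == pytest.approx(2.0)
        assert res["intercept"] == pytest.approx(1.0)
        assert res["r2"] == pytest.approx(1.0)

    def test_constant_response(self):
        res = linreg_r2([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        assert res["r2"] == 0.0

    def test_closed_form_oracle(self):
        rng = np.random.default_rng(19)
        x = rng.normal(size=25)
        y = 1.5 * x + rng.normal(size=25)
        res = linreg_r2(x, y)
        # Normal equations solved directly.
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert res["intercept"] == pytest.approx(beta[0], rel=1e-9)
        assert res["slope"] == pytest.approx(beta[1], rel=1e-9)
        resid = y - X @ beta
        r2 = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
        assert res["r2"] == pytest.approx(r2, rel=1e-9)

    def test_degenerate_x_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            linreg_r2([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestPairedCompare:
    def test_gaussian_differences_take_t_branch(self):
        hits = 0
        n_seeds = 1000
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            ecg = rng.normal(60, 5, 30)
            ppg = ecg + rng.normal(0, 1, 30)
            if paired_compare(ecg, ppg)["test_used"] == "paired_t":
                hits += 1
        # Shapiro-Wilk at level 0.05 should pass ~95% of Gaussian draws.
        assert 0.92 <= hits / n_seeds <= 0.98

    def test_heavy_tails_take_wilcoxon_branch(self):
        hits = 0
        n_seeds = 400
        for seed in range(n_seeds):
            rng = np.random.default_rng(10_000 + seed)
            ecg = rng.normal(60, 5, 30)
            ppg = ecg + rng.standard_cauchy(30)
            if paired_compare(ecg, ppg)["test_used"] == "wilcoxon":
                hits += 1
        assert hits / n_seeds > 0.5

    def test_mirrored_pairs_degenerate(self):
        x = np.arange(10.0)
        res = paired_compare(x, x)
        assert res["test_used"] == "degenerate"
        assert np.isnan(res["p_value"])

    def test_matches_scipy_t(self):
        rng = np.random.default_rng(3)
        ecg = rng.normal(60, 5, 20)
        ppg = ecg + rng.normal(0.5, 0.5, 20)
        res = paired_compare(ecg, ppg)
        if res["test_used"] == "paired_t":
            expected = stats.ttest_rel(ecg, ppg)
            assert res["p_value"] == pytest.approx(expected.pvalue)


class TestVarianceGate:
    def test_identical_groups_homogeneous(self):
        g = [1.0, 2.0, 3.0, 4.0]
        assert variance_gate([g, list(g)])["homogeneous"]

    def test_equal_variance_level(self):
        passes = 0
        n_seeds = 500
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            if variance_gate([rng.normal(0, 1, 30), rng.normal(0, 1, 30)])["homogeneous"]:
                passes += 1
        assert 0.92 <= passes / n_seeds <= 0.985

    def test_hundredfold_variance_detected(self):
        rejects = 0
        n_seeds = 300
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            gate = variance_gate([rng.normal(0, 1, 30), rng.normal(0, 10, 30)])
            rejects += not gate["homogeneous"]
        assert rejects / n_seeds > 0.99

    def test_degenerate_errors(self):
        with pytest.raises(ValueError):
            variance_gate([[1.0, 2.0]])


class TestScheirerRayHare:
    def test_reduces_to_kruskal_wallis(self):
        # Oracle: independent tie-corrected Kruskal-Wallis implementation
        # (scipy) when factor B is constant.
        rng = np.random.default_rng(23)
        values = rng.normal(size=60)
        factor_a = np.repeat(["x", "y", "z"], 20)
        factor_b = np.repeat(["only"], 60)
        res = scheirer_ray_hare(values, factor_a, factor_b)
        kw = stats.kruskal(values[:20], values[20:40], values[40:])
        assert res["H_A"] == pytest.approx(kw.statistic, abs=1e-9)
        assert res["p_values"]["A"] == pytest.approx(kw.pvalue, abs=1e-9)
        assert res["H_B"] == 0.0

    def test_reduction_with_ties(self):
        rng = np.random.default_rng(29)
        values = rng.integers(0, 5, size=45).astype(float)  # heavy ties
        factor_a = np.repeat(["x", "y", "z"], 15)
        factor_b = np.repeat(["only"], 45)
        res = scheirer_ray_hare(values, factor_a, factor_b)
        kw = stats.kruskal(values[:15], values[15:30], values[30:])
        assert res["H_A"] == pytest.approx(kw.statistic, abs=1e-9)

    def test_all_equal_values(self):
        values = np.ones(24)
        a = np.tile(["p", "q"], 12)
        b = np.repeat(["u", "v", "w"], 8)
        res = scheirer_ray_hare(values, a, b)
        assert res["H_A"] == res["H_B"] == res["H_interaction"] == 0.0

    def test_permutation_type_i_error(self):
        # Empirical level of H_A at nominal 0.05 under a permutation null
        # (3x4 layout, 3 per cell).
        rng = np.random.default_rng(31)
        base = rng.normal(size=36)
        factor_a = np.repeat(["a1", "a2", "a3"], 12)
        factor_b = np.tile(np.repeat(["b1", "b2", "b3", "b4"], 3), 3)
        rejections = 0
        n_perm = 2000
        for _ in range(n_perm):
            values = rng.permutation(base)
            res = scheirer_ray_hare(values, factor_a, factor_b)
            rejections += res["p_values"]["A"] < 0.05
        assert rejections / n_perm == pytest.approx(0.05, abs=0.02)

    def test_both_factors_constant_errors(self):
        with pytest.raises(ValueError):
            scheirer_ray_hare([1.0, 2.0], ["a", "a"], ["b", "b"])


class TestPosthocDunn:
    def test_two_groups_match_ranksum_z(self):
        # Oracle: direct normal-approximation rank-sum z statistic.
        rng = np.random.default_rng(37)
        x, y = rng.normal(0, 1, 12), rng.normal(1, 1, 15)
        values = np.concatenate([x, y])
        groups = np.array(["x"] * 12 + ["y"] * 15)
        p = posthoc_dunn(values, groups, adjust="none").loc["x", "y"]
        n = values.size
        ranks = stats.rankdata(values)
        z = (ranks[:12].mean() - ranks[12:].mean()) / np.sqrt(
            (n * (n + 1) / 12.0) * (1 / 12 + 1 / 15)
        )
        assert p == pytest.approx(2 * stats.norm.sf(abs(z)), rel=1e-9)

    def test_identical_groups_p_near_one(self):
        values = np.tile(np.arange(10.0), 2)
        groups = np.repeat(["a", "b"], 10)
        p = posthoc_dunn(values, groups, adjust="none").loc["a", "b"]
        assert p > 0.99

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(41)
        g1 = rng.normal(0, 1, 30)
        g2 = rng.normal(0, 1, 30)
        g3 = rng.normal(5, 1, 30)  # 5 SD shift
        values = np.concatenate([g1, g2, g3])
        groups = np.repeat(["a", "b", "c"], 30)
        mat = posthoc_dunn(values, groups)  # holm-adjusted
        assert mat.loc["a", "c"] < 0.001
        assert mat.loc["b", "c"] < 0.001

    def test_holm_never_below_raw(self):
        rng = np.random.default_rng(43)
        values = rng.normal(size=40)
        groups = np.repeat(["a", "b", "c", "d"], 10)
        raw = posthoc_dunn(values, groups, adjust="none")
        holm = posthoc_dunn(values, groups, adjust="holm")
        off_diag = ~np.eye(4, dtype=bool)
        assert (holm.values[off_diag] >= raw.values[off_diag] - 1e-12).all()


def make_cohort(n_subjects=12, bias=0.0, noise=1.0, seed=0, indicators=("HR", "SDNN")):
    rng = np.random.default_rng(seed)
    rows = []
    means = {"HR": 80.0, "IBI": 750.0, "SDNN": 50.0, "RMSSD": 40.0}
    for s in range(n_subjects):
        for scen in ("sitting", "standing"):
            for ind in indicators:
                ecg = rng.normal(means[ind], means[ind] * 0.15)
                ppg = ecg + bias + rng.normal(0.0, noise)
                rows.append(
                    {"subject_id": f"s{s}", "scenario": scen, "indicator": ind,
                     "ecg_value": ecg, "ppg_value": ppg}
                )
    return pd.DataFrame(rows)


class TestBuildAgreementReport:
    def test_perfect_agreement(self):
        cohort = make_cohort(noise=0.0)
        cohort["ppg_value"] = cohort["ecg_value"]
        report = build_agreement_report(cohort)
        for scen, inds in report["rows"].items():
            for ind, row in inds.items():
                assert row["df_pct"] == 0.0
                assert row["p_bias"] == 0.0
                assert row["rmse"] == 0.0
                assert report["regression"][scen][ind]["r2"] == pytest.approx(1.0)
                assert report["paired_tests"][scen][ind]["test_used"] == "degenerate"

    def test_known_bias_recovered(self):
        bias = 3.0
        report = build_agreement_report(make_cohort(n_subjects=40, bias=bias, seed=5))
        ba = report["bland_altman"]["sitting"]["HR"]
        # ECG - PPG diffs center on -bias; CI half-width ~ 1.96*sd/sqrt(n)
        assert ba["bias"] == pytest.approx(-bias, abs=1.96 / np.sqrt(40) * 1.5)

    def test_single_indicator_restricted(self):
        report = build_agreement_report(make_cohort(indicators=("RMSSD",)))
        for inds in report["rows"].values():
            assert list(inds) == ["RMSSD"]

    def test_two_way_branch_present(self):
        report = build_agreement_report(make_cohort(n_subjects=15, seed=9))
        two_way = report["two_way"]
        assert two_way["branch"] in ("anova", "scheirer_ray_hare")
        assert "levene" in two_way
        assert "posthoc" in two_way

    def test_duplicate_rows_rejected(self):
        cohort = make_cohort()
        with pytest.raises(ValueError, match="duplicate"):
            build_agreement_report(pd.concat([cohort, cohort.iloc[:1]]))

    def test_cohort_table_layout(self):
        report = build_agreement_report(make_cohort())
        frame = cohort_table(report, "sitting")
        assert list(frame.columns) == [
            "indicator", "ecg_mean", "ecg_sd", "ppg_mean", "ppg_sd",
            "diff_mean", "diff_sd", "rmse", "p_bias", "df_pct",
        ]
        assert set(frame["indicator"]) == {"HR", "SDNN"}


class TestPosthocTukey:
    def test_runs_and_reports_pairs(self):
        rng = np.random.default_rng(47)
        values = np.concatenate([rng.normal(0, 1, 20), rng.normal(3, 1, 20)])
        groups = np.repeat(["a", "b"], 20)
        frame = posthoc_tukey(values, groups)
        assert len(frame) == 1
        assert bool(frame.iloc[0]["reject"]) is True
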