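"""Device-agreement workflow for paired ECG/PPG indicator cohorts.

Given per-subject paired indicator values (one row per subject x
scenario x indicator), this module produces descriptive agreement rows
(means, difference, RMSE, percentage bias, difference factor),
normality-gated paired tests, a Levene-gated two-way analysis (ANOVA on
homogeneous variances, Scheirer-Ray-Hare on ranks otherwise) with post
hoc tests, Bland-Altman limits of agreement, and ordinary least squares
regression.

Conventions (both reconstructed from table consistency and documented
as such):

* difference factor  DF% = 100 * |ecg_mean - ppg_mean| / ecg_mean
* percentage bias  P bias = 100 * (ecg_mean - ppg_mean) / ppg_mean
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SCENARIOS",
    "INDICATORS",
    "AgreementRow",
    "BlandAltmanResult",
    "df_percent",
    "p_bias",
    "rmse",
    "bland_altman",
    "linreg_r2",
    "paired_compare",
    "variance_gate",
    "scheirer_ray_hare",
    "posthoc_dunn",
    "posthoc_tukey",
    "agreement_row",
    "build_agreement_report",
    "cohort_table",
]

SCENARIOS = ("sitting", "sitting_deep_breathing", "standing", "supine")
INDICATORS = ("HR", "IBI", "SDNN", "RMSSD")


# ---------------------------------------------------------------------------
# Descriptive agreement measures
# ---------------------------------------------------------------------------

def df_percent(ecg_mean: float, ppg_mean: float) -> float:
    """Difference factor: relative absolute difference of the device means, %."""
    if ecg_mean == 0:
        raise ValueError("DF%% undefined for zero ECG mean")
    return 100.0 * abs(ecg_mean - ppg_mean) / ecg_mean


def p_bias(ecg_mean: float, ppg_mean: float) -> float:
    """Percentage bias: signed relative difference of the device means, %."""
    if ppg_mean == 0:
        raise ValueError("P bias undefined for zero PPG mean")
    return 100.0 * (ecg_mean - ppg_mean) / ppg_mean


def rmse(ecg: np.ndarray, ppg: np.ndarray) -> float:
    """Root mean square of the paired differences."""
    ecg = np.asarray(ecg, dtype=float)
    ppg = np.asarray(ppg, dtype=float)
    if ecg.size == 0 or ecg.shape != ppg.shape:
        raise ValueError("need equal-length, non-empty paired arrays")
    return float(np.sqrt(np.mean((ecg - ppg) ** 2)))


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bias and 1.96-SD limits of agreement, plus the raw pairs."""

    bias: float
    loa_low: float
    loa_high: float
    pair_means: np.ndarray
    pair_diffs: np.ndarray

    def to_dict(self) -> dict:
        return {
            "bias": self.bias,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "pair_means": list(self.pair_means),
            "pair_diffs": list(self.pair_diffs),
        }


def bland_altman(ecg: np.ndarray, ppg: np.ndarray) -> BlandAltmanResult:
    """Bland-Altman agreement: diffs are ECG minus PPG, SD uses N-1."""
    ecg = np.asarray(ecg, dtype=float)
    ppg = np.asarray(ppg, dtype=float)
    if ecg.size < 2 or ecg.shape != ppg.shape:
        raise ValueError("need at least two pairs")
    diffs = ecg - ppg
    bias = float(np.mean(diffs))
    spread = 1.96 * float(np.std(diffs, ddof=1))
    return BlandAltmanResult(
        bias=bias,
        loa_low=bias - spread,
        loa_high=bias + spread,
        pair_means=(ecg + ppg) / 2.0,
        pair_diffs=diffs,
    )


def linreg_r2(ecg: np.ndarray, ppg: np.ndarray) -> dict:
    """OLS of the PPG values on the ECG values, with R^2."""
    ecg = np.asarray(ecg, dtype=float)
    ppg = np.asarray(ppg, dtype=float)
    if ecg.size < 3 or ecg.shape != ppg.shape:
        raise ValueError("need at least three pairs")
    if np.ptp(ecg) == 0:
        raise ValueError("degenerate regressor: ECG values have zero variance")
    result = stats.linregress(ecg, ppg)
    fitted = result.intercept + result.slope * ecg
    ss_res = float(np.sum((ppg - fitted) ** 2))
    ss_tot = float(np.sum((ppg - np.mean(ppg)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return {"slope": float(result.slope), "intercept": float(result.intercept), "r2": r2}


# ---------------------------------------------------------------------------
# Gated inferential tests
# ---------------------------------------------------------------------------

def paired_compare(ecg: np.ndarray, ppg: np.ndarray, alpha: float = 0.05) -> dict:
    """Normality-gated paired comparison.

    Shapiro-Wilk on the paired differences decides the branch: p > alpha
    selects the paired t-test, otherwise the Wilcoxon signed-rank test
    (Pratt handling of zero differences; exact null for n < 25, normal
    approximation with continuity correction otherwise).
    """
    ecg = np.asarray(ecg, dtype=float)
    ppg = np.asarray(ppg, dtype=float)
    if ecg.size < 3 or ecg.shape != ppg.shape:
        raise ValueError("need at least three pairs")
    diffs = ecg - ppg
    if np.all(diffs == 0):
        return {
            "normality_p": float("nan"),
            "test_used": "degenerate",
            "statistic": float("nan"),
            "p_value": float("nan"),
        }
    normality_p = float(stats.shapiro(diffs).pvalue)
    if normality_p > alpha:
        res = stats.ttest_rel(ecg, ppg)
        return {
            "normality_p": normality_p,
            "test_used": "paired_t",
            "statistic": float(res.statistic),
            "p_value": float(res.pvalue),
        }
    n_nonzero = int(np.count_nonzero(diffs))
    # Exact null when small and tie/zero-free; otherwise normal
    # approximation with continuity correction.
    method = "exact" if (n_nonzero < 25 and n_nonzero == diffs.size) else "approx"
    try:
        res = stats.wilcoxon(diffs, zero_method="pratt", correction=True, method=method)
    except ValueError:
        res = stats.wilcoxon(diffs, zero_method="pratt", correction=True, method="approx")
    return {
        "normality_p": normality_p,
        "test_used": "wilcoxon",
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
    }


def variance_gate(groups, alpha: float = 0.05, center: str = "mean") -> dict:
    """Levene's homogeneity-of-variance gate (mean-centered by default)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need at least two groups with at least two values each")
    stat, pvalue = stats.levene(*groups, center=center)
    return {
        "levene_stat": float(stat),
        "levene_p": float(pvalue),
        "homogeneous": bool(pvalue > alpha),
    }


def scheirer_ray_hare(values, factor_a, factor_b) -> dict:
    """Rank-based two-way analysis (factors plus interaction).

    All values are ranked jointly with midranks for ties; a fixed-effects
    sum-of-squares decomposition runs on the ranks; each H statistic is
    SS_effect / MS_total with MS_total = SS_total/(n-1), which on
    midranks carries the usual tie correction automatically.  P-values
    come from the chi-square distribution on the effect's df.

    A constant factor degenerates gracefully (H = 0, df = 0, p = 1) so
    the decomposition collapses to the Kruskal-Wallis statistic for the
    remaining factor; it is an error for both factors to be constant.
    """
    values = np.asarray(values, dtype=float)
    factor_a = np.asarray(factor_a)
    factor_b = np.asarray(factor_b)
    if not (values.size == factor_a.size == factor_b.size):
        raise ValueError("values and factors must have the same length")
    levels_a = np.unique(factor_a)
    levels_b = np.unique(factor_b)
    if levels_a.size < 2 and levels_b.size < 2:
        raise ValueError("at least one factor needs two or more levels")

    n = values.size
    ranks = stats.rankdata(values)
    grand = ranks.mean()
    ss_total = float(np.sum((ranks - grand) ** 2))
    ms_total = ss_total / (n - 1)

    def _ss(labels) -> float:
        ss = 0.0
        for level in np.unique(labels):
            sel = ranks[labels == level]
            ss += sel.size * (sel.mean() - grand) ** 2
        return float(ss)

    ss_a = _ss(factor_a)
    ss_b = _ss(factor_b)
    cells = np.char.add(np.char.add(factor_a.astype(str), "\x1f"), factor_b.astype(str))
    ss_cells = _ss(cells)
    ss_ab = max(ss_cells - ss_a - ss_b, 0.0)

    df_a = levels_a.size - 1
    df_b = levels_b.size - 1
    df_ab = df_a * df_b

    if ms_total == 0:  # all values identical
        h_a = h_b = h_ab = 0.0
    else:
        h_a, h_b, h_ab = ss_a / ms_total, ss_b / ms_total, ss_ab / ms_total

    def _p(h: float, df: int) -> float:
        return float(stats.chi2.sf(h, df)) if df > 0 else 1.0

    return {
        "H_A": h_a,
        "H_B": h_b,
        "H_interaction": h_ab,
        "df": {"A": df_a, "B": df_b, "interaction": df_ab},
        "p_values": {
            "A": _p(h_a, df_a),
            "B": _p(h_b, df_b),
            "interaction": _p(h_ab, df_ab),
        },
    }


def _holm(pvals: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment."""
    order = np.argsort(pvals)
    m = pvals.size
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals[idx])
        adjusted[idx] = min(running, 1.0)
    return adjusted


def posthoc_dunn(values, groups, adjust: str = "holm") -> pd.DataFrame:
    """Dunn's pairwise z tests on joint ranks with tie correction.

    Returns a symmetric DataFrame of two-sided p-values (diagonal 1.0),
    Holm-adjusted by default (``adjust='none'`` for raw p-values).
    """
    if adjust not in ("none", "holm"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = list(pd.unique(groups))
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    n = values.size
    ranks = stats.rankdata(values)
    _, counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n - 1))
    variance_unit = n * (n + 1) / 12.0 - tie_term

    mean_rank = {lv: ranks[groups == lv].mean() for lv in levels}
    size = {lv: int((groups == lv).sum()) for lv in levels}

    pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1 :]]
    raw = np.empty(len(pairs))
    for i, (a, b) in enumerate(pairs):
        se = np.sqrt(variance_unit * (1.0 / size[a] + 1.0 / size[b]))
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        raw[i] = 2.0 * stats.norm.sf(abs(z))
    pvals = _holm(raw) if adjust == "holm" else raw

    mat = pd.DataFrame(np.ones((len(levels), len(levels))), index=levels, columns=levels)
    for (a, b), p in zip(pairs, pvals):
        mat.loc[a, b] = mat.loc[b, a] = p
    return mat


def posthoc_tukey(values, groups) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons (post-ANOVA branch)."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    res = pairwise_tukeyhsd(np.asarray(values, dtype=float), np.asarray(groups))
    frame = pd.DataFrame(
        res.summary().data[1:], columns=[str(c) for c in res.summary().data[0]]
    )
    return frame


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgreementRow:
    """One scenario x indicator row of the agreement table."""

    ecg_mean: float
    ecg_sd: float
    ppg_mean: float
    ppg_sd: float
    diff_mean: float
    diff_sd: float
    rmse: float
    p_bias: float
    df_pct: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


_COHORT_COLUMNS = ["subject_id", "scenario", "indicator", "ecg_value", "ppg_value"]


def _validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    table = cohort[_COHORT_COLUMNS].copy()
    if table[["ecg_value", "ppg_value"]].isna().any().any():
        raise ValueError("cohort contains non-finite indicator values")
    dup = table.duplicated(["subject_id", "scenario", "indicator"])
    if dup.any():
        raise ValueError("duplicate subject x scenario x indicator rows")
    return table


def agreement_row(ecg: np.ndarray, ppg: np.ndarray) -> AgreementRow:
    """Descriptive agreement statistics for one scenario x indicator cell."""
    ecg = np.asarray(ecg, dtype=float)
    ppg = np.asarray(ppg, dtype=float)
    diffs = ecg - ppg
    sd = float(np.std(diffs, ddof=1)) if diffs.size > 1 else 0.0
    return AgreementRow(
        ecg_mean=float(np.mean(ecg)),
        ecg_sd=float(np.std(ecg, ddof=1)) if ecg.size > 1 else 0.0,
        ppg_mean=float(np.mean(ppg)),
        ppg_sd=float(np.std(ppg, ddof=1)) if ppg.size > 1 else 0.0,
        diff_mean=float(np.mean(diffs)),
        diff_sd=sd,
        rmse=rmse(ecg, ppg),
        p_bias=p_bias(float(np.mean(ecg)), float(np.mean(ppg))),
        df_pct=df_percent(float(np.mean(ecg)), float(np.mean(ppg))),
        n=int(ecg.size),
    )


def build_agreement_report(cohort: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Full agreement workflow on a paired cohort table.

    Per scenario x indicator cell: descriptive row, normality-gated
    paired test, Bland-Altman, and regression.  Across cells: Levene
    gate on the relative differences, then either two-way ANOVA with
    Tukey post hoc or the rank-based two-way analysis with Dunn post
    hoc (factors: scenario, indicator, interaction).  Degenerate cells
    are skipped and logged in ``report['skipped']``.
    """
    table = _validate_cohort(cohort)
    report: dict = {"schema_version": 1, "rows": {}, "paired_tests": {},
                    "bland_altman": {}, "regression": {}, "skipped": []}

    rel_values, rel_scenario, rel_indicator = [], [], []
    for (scenario, indicator), cell in table.groupby(["scenario", "indicator"]):
        ecg = cell["ecg_value"].to_numpy(dtype=float)
        ppg = cell["ppg_value"].to_numpy(dtype=float)
        key = (str(scenario), str(indicator))
        report["rows"].setdefault(key[0], {})[key[1]] = agreement_row(ecg, ppg).to_dict()
        rel = 100.0 * (ecg - ppg) / np.where(ecg == 0, np.nan, ecg)
        rel_values.extend(rel[np.isfinite(rel)])
        rel_scenario.extend([key[0]] * int(np.isfinite(rel).sum()))
        rel_indicator.extend([key[1]] * int(np.isfinite(rel).sum()))

        for name, fn, minimum in (
            ("paired_tests", lambda: paired_compare(ecg, ppg, alpha=alpha), 3),
            ("bland_altman", lambda: bland_altman(ecg, ppg).to_dict(), 2),
            ("regression", lambda: linreg_r2(ecg, ppg), 3),
        ):
            if ecg.size < minimum or (name == "regression" and np.ptp(ecg) == 0):
                report["skipped"].append(
                    {"cell": list(key), "analysis": name, "reason": "degenerate cell"}
                )
                continue
            report[name].setdefault(key[0], {})[key[1]] = fn()

    report["two_way"] = _two_way_analysis(
        np.asarray(rel_values), np.asarray(rel_scenario), np.asarray(rel_indicator),
        alpha=alpha,
    )
    return report


def _two_way_analysis(values, scenario, indicator, alpha: float) -> dict:
    """Levene-gated two-way analysis of the relative differences."""
    out: dict = {}
    cells = np.char.add(np.char.add(scenario.astype(str), "\x1f"), indicator.astype(str))
    groups = [values[cells == c] for c in np.unique(cells)]
    usable = [g for g in groups if g.size >= 2]
    if len(usable) < 2 or np.unique(scenario).size < 2 or np.unique(indicator).size < 2:
        out["skipped"] = "insufficient groups for the two-way analysis"
        return out
    if np.ptp(values) == 0:
        out["skipped"] = "relative differences are constant"
        return out
    gate = variance_gate(usable, alpha=alpha)
    out["levene"] = gate
    if gate["homogeneous"]:
        out["branch"] = "anova"
        out["anova"] = _two_way_anova(values, scenario, indicator)
        out["posthoc"] = {
            "method": "tukey",
            "scenario": posthoc_tukey(values, scenario).to_dict(orient="records"),
            "indicator": posthoc_tukey(values, indicator).to_dict(orient="records"),
        }
    else:
        out["branch"] = "scheirer_ray_hare"
        out["scheirer_ray_hare"] = scheirer_ray_hare(values, scenario, indicator)
        out["posthoc"] = {
            "method": "dunn",
            "scenario": posthoc_dunn(values, scenario).to_dict(),
            "indicator": posthoc_dunn(values, indicator).to_dict(),
        }
    return out


def _two_way_anova(values, factor_a, factor_b) -> dict:
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    frame = pd.DataFrame({"value": values, "A": factor_a, "B": factor_b})
    model = ols("value ~ C(A) * C(B)", data=frame).fit()
    table = sm.stats.anova_lm(model, typ=2)
    return {
        str(idx): {"F": float(row["F"]), "p": float(row["PR(>F)"])}
        for idx, row in table.iterrows()
        if idx != "Residual"
    }


def cohort_table(report: dict, scenario: str) -> pd.DataFrame:
    """One scenario's agreement rows in the printed column order."""
    rows = report["rows"].get(scenario, {})
    records = []
    for indicator in INDICATORS:
        if indicator not in rows:
            continue
        r = rows[indicator]
        records.append({
            "indicator": indicator,
            "ecg_mean": round(r["ecg_mean"], 2),
            "ecg_sd": round(r["ecg_sd"], 2),
            "ppg_mean": round(r["ppg_mean"], 2),
            "ppg_sd": round(r["ppg_sd"], 2),
            "diff_mean": round(r["diff_mean"], 2),
            "diff_sd": round(r["diff_sd"], 2),
            "rmse": round(r["rmse"], 2),
            "p_bias": round(r["p_bias"], 1),
            "df_pct": round(r["df_pct"], 2),
        })
    return pd.DataFrame.from_records(records)
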