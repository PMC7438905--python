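"""Group-level statistics for the cohort result table.

Covers the battery applied to the emulated study design: two-sample tests
from summary statistics (pooled t and the Cochran & Cox approximate t'),
one-way ANOVA (raw or summary path), mixed-design repeated-measures ANOVA
with the Greenhouse-Geisser sphericity correction, Bonferroni-adjusted
post-hocs, Pearson chi-squared, Kruskal-Wallis, and Spearman correlations.

Summary-statistics entry points are first class because published tables
report (n, mean, SD) rather than raw data; every summary-path statistic is
algebraically identical to its raw-data counterpart.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as ss

from .datatypes import BAND_ORDER, CohortResultTable, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "GroupSummary",
    "TestResult",
    "pooled_t",
    "cochran_cox_t",
    "one_way_anova",
    "rm_anova_gg",
    "gg_epsilon",
    "bonferroni_adjust",
    "chi_squared",
    "kruskal_wallis",
    "spearman",
    "run_group_analysis",
]


@dataclass(frozen=True)
class GroupSummary:
    """(n, mean, SD) of one variable in one group."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValidationError("variance-based tests need n >= 2 per group")
        if self.sd < 0:
            raise ValidationError("sd must be non-negative")

    @classmethod
    def from_sample(cls, label: str, x: Sequence[float]) -> "GroupSummary":
        x = np.asarray(x, dtype=float)
        return cls(label=label, n=len(x), mean=float(x.mean()), sd=float(x.std(ddof=1)))


@dataclass(frozen=True)
class TestResult:
    """One test's outcome: statistic, degrees of freedom, p, correction."""

    name: str
    value: float
    df: Union[float, tuple, None]
    p: float
    correction: str = "none"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.isfinite(self.p) and not 0.0 <= self.p <= 1.0:
            raise ValidationError(f"p-value out of range: {self.p}")


def pooled_t(a: GroupSummary, b: GroupSummary) -> TestResult:
    """Classic pooled-variance two-sample t from summary statistics."""
    df = a.n + b.n - 2
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    if sp2 == 0:
        if a.mean == b.mean:
            return TestResult("t", 0.0, df, 1.0)
        raise ValidationError("zero pooled variance with unequal means")
    t = (a.mean - b.mean) / np.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
    p = 2.0 * ss.t.sf(abs(t), df)
    return TestResult("t", float(t), df, float(p))


def cochran_cox_t(
    a: GroupSummary, b: GroupSummary, alpha: float = 0.05, welch_df: bool = False
) -> TestResult:
    """Cochran & Cox approximate t-test for unequal variances.

    t' = (m_a - m_b) / sqrt(s_a^2/n_a + s_b^2/n_b). Significance is judged
    against the weighted critical value t*(alpha) = (w_a t_a + w_b t_b) /
    (w_a + w_b) with weights w_i = s_i^2/n_i and component critical values
    at n_i - 1 df; the reported p is the alpha at which |t'| equals that
    weighted critical value (found by bisection). ``welch_df=True`` reports
    the Welch-Satterthwaite approximation instead.
    """
    wa, wb = a.sd**2 / a.n, b.sd**2 / b.n
    if wa + wb == 0:
        raise ValidationError("both variances are zero")
    t_prime = (a.mean - b.mean) / np.sqrt(wa + wb)
    if welch_df:
        df = (wa + wb) ** 2 / (wa**2 / (a.n - 1) + wb**2 / (b.n - 1))
        p = 2.0 * ss.t.sf(abs(t_prime), df)
        return TestResult("t'", float(t_prime), float(df), float(p), correction="welch")

    def crit(al: float) -> float:
        ta = ss.t.ppf(1.0 - al / 2.0, a.n - 1)
        tb = ss.t.ppf(1.0 - al / 2.0, b.n - 1)
        return (wa * ta + wb * tb) / (wa + wb)

    # p solves |t'| = crit(p); crit is decreasing in alpha
    lo, hi = 1e-12, 1.0
    if abs(t_prime) >= crit(lo):
        p = lo
    elif abs(t_prime) <= crit(hi):
        p = 1.0
    else:
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if crit(mid) > abs(t_prime):
                lo = mid
            else:
                hi = mid
        p = 0.5 * (lo + hi)
    significant = abs(t_prime) >= crit(alpha)
    return TestResult(
        "t'",
        float(t_prime),
        (a.n - 1, b.n - 1),
        float(p),
        extra={"significant_at_alpha": bool(significant), "alpha": alpha,
               "critical_value": float(crit(alpha))},
    )


def _as_summaries(groups) -> list[GroupSummary]:
    out = []
    for i, g in enumerate(groups):
        if isinstance(g, GroupSummary):
            out.append(g)
        else:
            out.append(GroupSummary.from_sample(f"group{i}", np.asarray(g, dtype=float)))
    return out


def one_way_anova(groups: Sequence) -> TestResult:
    """One-way fixed-effects ANOVA from raw samples or GroupSummary objects.

    The summary path reconstructs the between/within sums of squares from
    (n, mean, SD) exactly, so both paths give identical F on the same data.
    """
    summaries = _as_summaries(groups)
    if len(summaries) < 2:
        raise ValidationError("need at least 2 groups")
    n_tot = sum(s.n for s in summaries)
    grand = sum(s.n * s.mean for s in summaries) / n_tot
    ss_between = sum(s.n * (s.mean - grand) ** 2 for s in summaries)
    ss_within = sum((s.n - 1) * s.sd**2 for s in summaries)
    df_b = len(summaries) - 1
    df_w = n_tot - len(summaries)
    if ss_within == 0:
        if ss_between == 0:
            return TestResult("F", 0.0, (df_b, df_w), 1.0, extra={"degenerate": True})
        raise ValidationError("zero within-group variance with unequal means")
    F = (ss_between / df_b) / (ss_within / df_w)
    p = ss.f.sf(F, df_b, df_w)
    return TestResult("F", float(F), (df_b, df_w), float(p))


def gg_epsilon(cov: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from a k x k within-subject covariance.

    Computed from the double-centered covariance S*: eps = (tr S*)^2 /
    ((k-1) sum S*_ij^2), bounded in [1/(k-1), 1].
    """
    S = np.asarray(cov, dtype=float)
    k = S.shape[0]
    row = S.mean(axis=0, keepdims=True)
    col = S.mean(axis=1, keepdims=True)
    Sdc = S - row - col + S.mean()
    denom = (k - 1) * (Sdc**2).sum()
    if denom <= 0:
        return 1.0
    eps = np.trace(Sdc) ** 2 / denom
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def rm_anova_gg(
    values: np.ndarray,
    groups: Sequence[str],
    level_names: Optional[Sequence[str]] = None,
) -> Dict[str, TestResult]:
    """Mixed-design (split-plot) ANOVA with Greenhouse-Geisser correction.

    Parameters
    ----------
    values
        Array ``(n_subjects, k)`` of the within-subject measurements, one
        column per within level (e.g. frequency band), balanced.
    groups
        Between-subject group label per row.

    Returns the ``group`` (between), ``within`` (level main effect) and
    ``interaction`` tests; the two within-subject effects carry
    GG-corrected p-values with epsilon estimated from the pooled
    within-group covariance of the level scores.
    """
    X = np.asarray(values, dtype=float)
    if X.ndim != 2:
        raise ValidationError("values must be subjects x levels")
    if np.isnan(X).any():
        raise ValidationError("missing cells in the repeated-measures layout")
    groups = np.asarray(groups)
    n, k = X.shape
    labels = np.unique(groups)
    g = len(labels)
    if g < 2:
        raise ValidationError("need at least 2 groups")
    counts = {lab: int((groups == lab).sum()) for lab in labels}
    if min(counts.values()) < 2:
        raise ValidationError("need >= 2 subjects per group")

    grand = X.mean()
    subj_mean = X.mean(axis=1)
    lvl_mean = X.mean(axis=0)
    grp_mean = {lab: X[groups == lab].mean() for lab in labels}
    cell_mean = {lab: X[groups == lab].mean(axis=0) for lab in labels}

    ss_group = k * sum(counts[lab] * (grp_mean[lab] - grand) ** 2 for lab in labels)
    ss_subj = k * ((subj_mean - grand) ** 2).sum()
    ss_err_between = ss_subj - ss_group
    ss_level = n * ((lvl_mean - grand) ** 2).sum()
    ss_inter = sum(
        counts[lab]
        * ((cell_mean[lab] - grp_mean[lab] - lvl_mean + grand) ** 2).sum()
        for lab in labels
    )
    ss_within_total = ((X - subj_mean[:, None]) ** 2).sum()
    ss_err_within = ss_within_total - ss_level - ss_inter

    df_group, df_eb = g - 1, n - g
    df_level, df_inter = k - 1, (g - 1) * (k - 1)
    df_ew = (n - g) * (k - 1)

    # pooled within-group covariance of the k level scores
    pooled = np.zeros((k, k))
    for lab in labels:
        Xi = X[groups == lab]
        pooled += (len(Xi) - 1) * np.cov(Xi, rowvar=False)
    pooled /= n - g
    eps = gg_epsilon(pooled) if k > 1 else 1.0

    def f_test(ss_num, df_num, ss_den, df_den, name, gg=False):
        if ss_den <= 0:
            return TestResult(name, np.nan, (df_num, df_den), np.nan,
                              extra={"degenerate": True})
        F = (ss_num / df_num) / (ss_den / df_den)
        if gg:
            p = float(ss.f.sf(F, eps * df_num, eps * df_den))
            return TestResult(
                name, float(F), (eps * df_num, eps * df_den), p,
                correction="greenhouse-geisser",
                extra={"epsilon": eps, "uncorrected_df": (df_num, df_den),
                       "uncorrected_p": float(ss.f.sf(F, df_num, df_den))},
            )
        return TestResult(name, float(F), (df_num, df_den), float(ss.f.sf(F, df_num, df_den)))

    return {
        "group": f_test(ss_group, df_group, ss_err_between, df_eb, "F"),
        "within": f_test(ss_level, df_level, ss_err_within, df_ew, "F", gg=True),
        "interaction": f_test(ss_inter, df_inter, ss_err_within, df_ew, "F", gg=True),
    }


def bonferroni_adjust(p_values: Sequence[float], m: Optional[int] = None) -> np.ndarray:
    """p_adj = min(1, m * p), order preserved; m defaults to len(p_values)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = len(p) if m is None else int(m)
    if m < len(p):
        raise ValidationError("family size m must be >= the number of p-values")
    return np.minimum(1.0, m * p)


def chi_squared(counts: np.ndarray) -> TestResult:
    """Pearson chi-squared test of independence on an r x c count table."""
    obs = np.asarray(counts, dtype=float)
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValidationError("contingency table has a zero marginal")
    stat, p, df, expected = ss.chi2_contingency(obs, correction=False)
    if (expected <= 0).any():
        raise ValidationError("expected counts must be positive")
    return TestResult("X^2", float(stat), int(df), float(p))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis rank H with tie correction."""
    if len(groups) < 2:
        raise ValidationError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) == 0 for a in arrays):
        raise ValidationError("every group needs at least one observation")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return TestResult("H", 0.0, len(groups) - 1, 1.0, extra={"all_tied": True})
    stat, p = ss.kruskal(*arrays)
    return TestResult("H", float(stat), len(groups) - 1, float(p))


def spearman(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Spearman rho (average ranks for ties) with the t-approximation p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValidationError("need equal-length samples with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValidationError("zero variance in ranks")
    rho, p = ss.spearmanr(x, y)
    return TestResult("rho", float(rho), len(x) - 2, float(p))


def run_group_analysis(
    table: CohortResultTable,
    alpha: float = 0.05,
    posthoc_m: int = 3,
    out_dir: Optional[Union[str, Path]] = None,
) -> dict:
    """The full analysis plan on one cohort table.

    Mixed-design RM-ANOVA (group x band, GG-corrected) for C and for L;
    one-way ANOVA across groups for MMN latency and amplitude with
    Bonferroni pairwise post-hocs; Spearman correlations of MMN amplitude
    with C and with L per band within the AVH group. Writes a tidy CSV and
    a JSON report when ``out_dir`` is given.
    """
    df = table.frame
    group_labels = sorted(df["group"].unique())
    if len(group_labels) < 2:
        raise ValidationError("need at least 2 groups")
    report: dict = {"alpha": alpha, "tests": {}}

    # --- RM-ANOVA on network metrics (band within, group between)
    wide = {}
    for metric in ("C", "L"):
        pivot = df.pivot(index="subject_id", columns="band", values=metric)
        pivot = pivot.loc[:, [b for b in BAND_ORDER if b in pivot.columns]]
        n_bad = int(pivot.isna().any(axis=1).sum())
        if n_bad:
            # undefined metrics (e.g. path length of an edgeless graph):
            # listwise-drop those subjects from the repeated-measures model
            logger.warning(
                "%s: dropping %d subject(s) with undefined values from the "
                "repeated-measures ANOVA", metric, n_bad,
            )
            pivot = pivot.dropna()
        subj_group = df.drop_duplicates("subject_id").set_index("subject_id")["group"]
        grp = subj_group.loc[pivot.index].to_numpy()
        wide[metric] = (pivot, grp)
        if pivot.shape[1] >= 2:
            res = rm_anova_gg(pivot.to_numpy(), grp, level_names=list(pivot.columns))
        else:
            res = {"group": one_way_anova(
                [pivot.to_numpy()[grp == lab, 0] for lab in group_labels]
            )}
        report["tests"][f"rm_anova_{metric}"] = {k: _result_dict(v) for k, v in res.items()}

    # --- one-way ANOVA on the per-subject MMN measurements
    per_subj = df.drop_duplicates("subject_id")
    for var in ("mmn_latency_ms", "mmn_amplitude_uv"):
        samples = [per_subj.loc[per_subj["group"] == lab, var].to_numpy() for lab in group_labels]
        report["tests"][f"anova_{var}"] = _result_dict(one_way_anova(samples))
        pair_res = {}
        raw_p = []
        pairs = [
            (group_labels[i], group_labels[j])
            for i in range(len(group_labels))
            for j in range(i + 1, len(group_labels))
        ]
        for la, lb in pairs:
            res = pooled_t(
                GroupSummary.from_sample(la, per_subj.loc[per_subj["group"] == la, var]),
                GroupSummary.from_sample(lb, per_subj.loc[per_subj["group"] == lb, var]),
            )
            pair_res[f"{la}_vs_{lb}"] = res
            raw_p.append(res.p)
        adj = bonferroni_adjust(raw_p, m=max(posthoc_m, len(raw_p)))
        report["tests"][f"posthoc_{var}"] = {
            key: {**_result_dict(res), "p_bonferroni": float(pa)}
            for (key, res), pa in zip(pair_res.items(), adj)
        }

    # --- Spearman correlations within the AVH group
    if "AVH" in group_labels:
        avh = df[df["group"] == "AVH"]
        corr = {}
        for metric in ("C", "L"):
            for band in BAND_ORDER:
                sub = avh[avh["band"] == band]
                if len(sub) >= 3:
                    res = spearman(sub["mmn_amplitude_uv"], sub[metric])
                    corr[f"{metric}_{band}"] = _result_dict(res)
        report["tests"]["spearman_avh"] = corr

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "stats_report.json").write_text(json.dumps(report, indent=1) + "\n")
        _report_to_frame(report).to_csv(out / "stats_report.csv", index=False)
    return report


def _result_dict(res: TestResult) -> dict:
    df = res.df
    if isinstance(df, tuple):
        df = [float(v) for v in df]
    return {
        "statistic": res.name,
        "value": res.value,
        "df": df,
        "p": res.p,
        "correction": res.correction,
        **({"extra": res.extra} if res.extra else {}),
    }


def _flatten(prefix: str, node, rows: list) -> None:
    if isinstance(node, dict) and "statistic" in node:
        rows.append(
            {
                "test": prefix,
                "statistic": node["statistic"],
                "value": node["value"],
                "df": str(node["df"]),
                "p": node["p"],
                "correction": node.get("correction", "none"),
            }
        )
    elif isinstance(node, dict):
        for key, sub in node.items():
            _flatten(f"{prefix}.{key}" if prefix else key, sub, rows)


def _report_to_frame(report: dict) -> pd.DataFrame:
    rows: list = []
    _flatten("", report["tests"], rows)
    return pd.DataFrame(rows)
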