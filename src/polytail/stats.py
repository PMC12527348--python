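"""Adaptive differential poly(A) tail-length statistics.

The engine mirrors the decision tree used throughout the package:

* two groups — Student's t (normal, homogeneous variances), Welch's t
  (normal, heterogeneous) or the Wilcoxon rank-sum test (anything else,
  including any group with fewer than three observations);
* three or more groups — one-way ANOVA with Tukey HSD, Welch's ANOVA with
  Games–Howell, or Kruskal–Wallis with Dunn/Bonferroni post-hocs, under the
  same assumption gates.

Normality is assessed with Shapiro–Wilk up to n = 5000 and the Lilliefors
test above (Kolmogorov–Smirnov with estimated moments, Dallal–Wilkinson
p-approximation); variance homogeneity with the Brown–Forsythe variant of
Levene's test (absolute deviations from group medians). Groups that are
constant or smaller than three are treated as not assessable and routed to
the non-parametric branch rather than erroring.

Per-feature runners apply the tree gene-by-gene (or transcript-by-
transcript), adjust p-values across features, attach Cohen's d and the
log2 fold change of mean tail length (treated over control), and call
differential polyadenylation: ``collapsed`` (shorter tails, log2FC < 0) or
``expansion`` (longer tails) at adjusted p below alpha.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats._lilliefors import lilliefors

from .errors import UndefinedStatisticError, ValidationError

logger = logging.getLogger(__name__)

TWO_GROUP_TESTS = ("student_t", "welch_t", "wilcoxon")
K_GROUP_TESTS = ("anova", "welch_anova", "kruskal_wallis")

ADJUST_METHODS = ("holm", "hochberg", "hommel", "bonferroni", "BH", "BY", "fdr", "none")

#: Shapiro–Wilk is used up to this sample size, Lilliefors above.
SHAPIRO_MAX_N = 5000

#: Exact Wilcoxon null is enumerated when both groups are at most this size
#: and there are no ties; otherwise the normal approximation with tie and
#: continuity corrections is used.
WILCOXON_EXACT_MAX_N = 25


# ---------------------------------------------------------------------------
# assumption checks


@dataclass
class NormalityResult:
    method: str  # shapiro | lilliefors | not_assessable
    statistic: float
    p: float

    @property
    def assessable(self) -> bool:
        return self.method != "not_assessable"


@dataclass
class HomogeneityResult:
    statistic: float
    p: float
    method: str = "levene_median"
    assessable: bool = True


@dataclass
class AssumptionReport:
    """Per-group normality plus a variance-homogeneity check."""

    normality: list[NormalityResult]
    homogeneity: HomogeneityResult
    min_n: int


def assess_normality(values) -> NormalityResult:
    """Normality check with a deterministic size-based method switch.

    n < 3 or constant input -> not assessable (non-normal downstream);
    3 <= n <= 5000 -> Shapiro–Wilk; n > 5000 -> Lilliefors.
    """
    x = np.asarray(values, dtype=float)
    if x.size and not np.all(np.isfinite(x)):
        raise ValidationError("non-finite values in normality check")
    if x.size < 3 or np.ptp(x) == 0:
        return NormalityResult("not_assessable", float("nan"), float("nan"))
    if x.size <= SHAPIRO_MAX_N:
        stat, p = sps.shapiro(x)
        return NormalityResult("shapiro", float(stat), float(p))
    stat, p = lilliefors(x, dist="norm", pvalmethod="approx")
    return NormalityResult("lilliefors", float(stat), float(p))


def assess_variance_homogeneity(groups: list) -> HomogeneityResult:
    """Brown–Forsythe test: one-way F on absolute deviations from group medians."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValidationError("need at least two groups for a variance check")
    if any(a.size < 2 for a in arrays):
        return HomogeneityResult(float("nan"), float("nan"), assessable=False)
    with np.errstate(invalid="ignore"):
        stat, p = sps.levene(*arrays, center="median")
    if not math.isfinite(stat):
        # all deviations zero (constant groups): homogeneity is undefined
        return HomogeneityResult(float("nan"), float("nan"), assessable=False)
    return HomogeneityResult(float(stat), float(p))


def assess_groups(groups: list) -> AssumptionReport:
    norms = [assess_normality(g) for g in groups]
    homog = assess_variance_homogeneity(groups)
    min_n = min(len(g) for g in groups)
    return AssumptionReport(norms, homog, min_n)


def select_test(report: AssumptionReport, k: int, alpha_assumption: float = 0.05) -> str:
    """Route to a test id given assumption checks and the number of groups.

    All groups normal and homogeneous variances -> student_t / anova;
    all normal but heterogeneous -> welch_t / welch_anova; otherwise
    (non-normality, not-assessable checks, or any group below n = 3) ->
    wilcoxon / kruskal_wallis.
    """
    if k < 2:
        raise ValidationError("test selection requires at least two groups")
    all_normal = all(r.assessable and r.p > alpha_assumption for r in report.normality)
    if not all_normal or report.min_n < 3:
        return "wilcoxon" if k == 2 else "kruskal_wallis"
    if report.homogeneity.assessable and report.homogeneity.p > alpha_assumption:
        return "student_t" if k == 2 else "anova"
    return "welch_t" if k == 2 else "welch_anova"


# ---------------------------------------------------------------------------
# two-group tests


@dataclass
class TestResult:
    test_id: str
    statistic: float
    p_value: float
    posthoc: pd.DataFrame | None = None


def _wilcoxon_rank_sum(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        # every observation identical: no evidence of a shift by definition
        return float(a.size * b.size / 2.0), 1.0
    ties = len(np.unique(pooled)) < pooled.size
    exact = (not ties) and a.size <= WILCOXON_EXACT_MAX_N and b.size <= WILCOXON_EXACT_MAX_N
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return float(res.statistic), float(res.pvalue)


def run_two_group_test(a, b, test_id: str) -> TestResult:
    """Two-sided two-sample test; see module docstring for the three branches."""
    if test_id not in TWO_GROUP_TESTS:
        raise ValidationError(f"unknown two-group test {test_id!r}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValidationError("both groups must be non-empty")
    if test_id == "wilcoxon":
        stat, p = _wilcoxon_rank_sum(a, b)
        return TestResult("wilcoxon", stat, p)
    if a.size < 2 or b.size < 2:
        raise ValidationError("t-tests require at least two observations per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise UndefinedStatisticError("zero variance in both groups; t statistic undefined")
    res = sps.ttest_ind(a, b, equal_var=(test_id == "student_t"))
    return TestResult(test_id, float(res.statistic), float(res.pvalue))


# ---------------------------------------------------------------------------
# k-group tests and post-hocs


def _welch_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """Welch's heteroscedastic one-way F (the oneway.test(var.equal=FALSE) statistic)."""
    k = len(groups)
    n = np.array([g.size for g in groups], dtype=float)
    m = np.array([g.mean() for g in groups])
    v = np.array([g.var(ddof=1) for g in groups])
    w = n / v
    sw = w.sum()
    mw = (w * m).sum() / sw
    a = (w * (m - mw) ** 2).sum() / (k - 1)
    lam = ((1 - w / sw) ** 2 / (n - 1)).sum() / (k**2 - 1)
    f = a / (1 + 2 * lam * (k - 2))
    df1 = k - 1
    df2 = 1.0 / (3.0 * lam)
    p = sps.f.sf(f, df1, df2)
    return float(f), float(p)


def _tukey_posthoc(groups: list[np.ndarray], labels: list[str]) -> pd.DataFrame:
    res = sps.tukey_hsd(*groups)
    rows = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        rows.append({
            "pair": f"{labels[i]}-{labels[j]}",
            "statistic": float(res.statistic[i, j]),
            "p_adjusted": float(res.pvalue[i, j]),
            "method": "tukey_hsd",
        })
    return pd.DataFrame(rows)


def _games_howell_posthoc(groups: list[np.ndarray], labels: list[str]) -> pd.DataFrame:
    """Pairwise Games–Howell: Welch t, Welch df, studentized-range p."""
    k = len(groups)
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        gi, gj = groups[i], groups[j]
        vi, vj = gi.var(ddof=1) / gi.size, gj.var(ddof=1) / gj.size
        se = math.sqrt(vi + vj)
        t = (gi.mean() - gj.mean()) / se
        df = (vi + vj) ** 2 / (vi**2 / (gi.size - 1) + vj**2 / (gj.size - 1))
        p = float(sps.studentized_range.sf(abs(t) * math.sqrt(2.0), k, df))
        rows.append({
            "pair": f"{labels[i]}-{labels[j]}",
            "statistic": float(t),
            "p_adjusted": min(1.0, p),
            "method": "games_howell",
        })
    return pd.DataFrame(rows)


def _dunn_posthoc(groups: list[np.ndarray], labels: list[str]) -> pd.DataFrame:
    """Dunn's rank z-tests with tie correction and Bonferroni adjustment."""
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes, start = [], [], 0
    for g in groups:
        mean_ranks.append(ranks[start:start + g.size].mean())
        sizes.append(g.size)
        start += g.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    n_pairs = len(groups) * (len(groups) - 1) // 2
    rows = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        se = math.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({
            "pair": f"{labels[i]}-{labels[j]}",
            "statistic": float(z),
            "p_adjusted": min(1.0, p * n_pairs),
            "method": "dunn_bonferroni",
        })
    return pd.DataFrame(rows)


def run_k_group_test(groups: list, test_id: str, labels: list[str] | None = None) -> TestResult:
    """Omnibus k-group test (k >= 3) with all pairwise post-hoc comparisons."""
    if test_id not in K_GROUP_TESTS:
        raise ValidationError(f"unknown k-group test {test_id!r}")
    if len(groups) < 3:
        raise ValidationError("k-group tests require at least three groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if labels is None:
        labels = [f"group{i + 1}" for i in range(len(arrays))]
    if test_id == "anova":
        stat, p = sps.f_oneway(*arrays)
        posthoc = _tukey_posthoc(arrays, labels)
    elif test_id == "welch_anova":
        stat, p = _welch_anova(arrays)
        posthoc = _games_howell_posthoc(arrays, labels)
    else:
        try:
            stat, p = sps.kruskal(*arrays)
        except ValueError:
            # all values identical across every group: H = 0 by definition
            stat, p = 0.0, 1.0
        posthoc = _dunn_posthoc(arrays, labels)
    return TestResult(test_id, float(stat), float(p), posthoc)


# ---------------------------------------------------------------------------
# effect sizes and adjustment


def cohens_d(a, b) -> float:
    """Standardized mean difference (a - b) over the pooled standard deviation.

    By convention in the per-feature runners ``a`` is the treated group and
    ``b`` the control. Returns NaN when the pooled variance is zero.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("Cohen's d requires at least two observations per group")
    n1, n2 = a.size, b.size
    pooled_var = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    if pooled_var == 0:
        return float("nan")
    return float((a.mean() - b.mean()) / math.sqrt(pooled_var))


def log2_fold_change(mean_control: float, mean_treated: float) -> float:
    if mean_control <= 0 or mean_treated <= 0:
        raise ValidationError("log2 fold change requires strictly positive means")
    return float(np.log2(mean_treated / mean_control))


_SM_METHOD = {
    "holm": "holm",
    "hochberg": "simes-hochberg",
    "hommel": "hommel",
    "bonferroni": "bonferroni",
    "bh": "fdr_bh",
    "by": "fdr_by",
    "fdr": "fdr_bh",
}


def adjust_pvalues(p, method: str = "BH") -> np.ndarray:
    """Multiple-testing adjustment preserving order and missing values.

    Missing entries stay missing and are excluded from the number of tests m.
    ``fdr`` is an alias of Benjamini–Hochberg; ``none`` returns the input.
    """
    arr = np.asarray(p, dtype=float)
    if method not in ADJUST_METHODS and method.lower() not in _SM_METHOD:
        raise ValidationError(f"unknown adjustment method {method!r}")
    valid = ~np.isnan(arr)
    if np.any((arr[valid] < 0) | (arr[valid] > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    out = np.full(arr.shape, np.nan)
    if method.lower() == "none":
        out[valid] = arr[valid]
        return out
    if valid.sum():
        from statsmodels.stats.multitest import multipletests

        _, adj, _, _ = multipletests(arr[valid], method=_SM_METHOD[method.lower()])
        out[valid] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# per-feature runners


FEATURE_STATS_COLUMNS = [
    "feature_id", "n_control", "n_treated", "mean_control", "mean_treated",
    "test_id", "p_value", "padj", "cohens_d", "log2fc", "dpg_call",
]


def _feature_groups(polya: pd.DataFrame, level: str):
    if level not in polya.columns:
        raise ValidationError(f"level column {level!r} not present")
    usable = polya[polya[level].notna()]
    n_excluded = len(polya) - len(usable)
    if n_excluded:
        logger.info("excluding %d records with missing %s from testing", n_excluded, level)
    return usable.groupby(level, sort=True)


def _two_group_feature_test(a: np.ndarray, b: np.ndarray, mode: str,
                            alpha_assumption: float) -> TestResult:
    if mode == "wilcoxon_only":
        return run_two_group_test(a, b, "wilcoxon")
    report = assess_groups([a, b])
    test_id = select_test(report, k=2, alpha_assumption=alpha_assumption)
    try:
        return run_two_group_test(a, b, test_id)
    except UndefinedStatisticError:
        return run_two_group_test(a, b, "wilcoxon")


def per_feature_two_group(
    polya: pd.DataFrame,
    level: str = "gene_id",
    control_group: str = "CTR",
    treated_group: str = "HIGH",
    mode: str = "adaptive",
    adjust_method: str = "BH",
    min_n: int = 3,
    alpha: float = 0.05,
    alpha_assumption: float = 0.05,
) -> pd.DataFrame:
    """Feature-by-feature two-group testing with adjustment and DPG calls.

    mode="wilcoxon_only" forces the rank-sum test everywhere; mode="adaptive"
    runs the assumption checks per feature and selects Student/Welch/Wilcoxon.
    Features where either group has fewer than ``min_n`` tails are reported
    as ``not_tested`` with missing p. log2fc is treated over control, so
    negative values mean tail shortening ("collapsed").
    """
    if mode not in ("wilcoxon_only", "adaptive"):
        raise ValidationError(f"unknown mode {mode!r}")
    present = set(polya["group"].unique())
    for label in (control_group, treated_group):
        if label not in present:
            raise ValidationError(f"group label {label!r} not present in the table")
    rows = []
    for feature_id, sub in _feature_groups(polya, level):
        a = sub.loc[sub["group"] == treated_group, "polyA_length"].to_numpy(float)
        b = sub.loc[sub["group"] == control_group, "polyA_length"].to_numpy(float)
        row = {
            "feature_id": feature_id,
            "n_control": b.size, "n_treated": a.size,
            "mean_control": b.mean() if b.size else np.nan,
            "mean_treated": a.mean() if a.size else np.nan,
            "test_id": None, "p_value": np.nan, "padj": np.nan,
            "cohens_d": np.nan, "log2fc": np.nan, "dpg_call": "not_tested",
        }
        if a.size >= min_n and b.size >= min_n:
            result = _two_group_feature_test(a, b, mode, alpha_assumption)
            row["test_id"] = result.test_id
            row["p_value"] = result.p_value
            if a.size >= 2 and b.size >= 2:
                row["cohens_d"] = cohens_d(a, b)
            row["log2fc"] = log2_fold_change(row["mean_control"], row["mean_treated"])
            row["dpg_call"] = "ns"
        rows.append(row)
    stats = pd.DataFrame(rows, columns=FEATURE_STATS_COLUMNS)
    stats["padj"] = adjust_pvalues(stats["p_value"].to_numpy(), adjust_method)
    stats = call_dpgs(stats, alpha=alpha)
    stats.attrs.update({
        "mode": mode, "adjust_method": adjust_method, "alpha": alpha,
        "control_group": control_group, "treated_group": treated_group,
        "level": level,
    })
    return stats


def per_feature_k_group(
    polya: pd.DataFrame,
    level: str = "gene_id",
    grouping: str = "group",
    mode: str = "adaptive",
    adjust_method: str = "BH",
    min_n: int = 3,
    alpha: float = 0.05,
    alpha_assumption: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Omnibus k-group testing per feature (k >= 3 grouping values).

    mode="kruskal_only" always runs Kruskal–Wallis; mode="adaptive" applies
    the ANOVA / Welch ANOVA / Kruskal–Wallis tree per feature. Effect sizes
    and fold changes are not reported (no control/treated designation).
    Returns the per-feature stats table and a post-hoc table with one row per
    (feature, pair).
    """
    if mode not in ("kruskal_only", "adaptive"):
        raise ValidationError(f"unknown mode {mode!r}")
    labels = sorted(polya[grouping].dropna().unique().tolist())
    if len(labels) < 3:
        raise ValidationError(
            "fewer than three grouping values; use per_feature_two_group instead"
        )
    rows, posthoc_frames = [], []
    for feature_id, sub in _feature_groups(polya, level):
        groups = [sub.loc[sub[grouping] == lab, "polyA_length"].to_numpy(float)
                  for lab in labels]
        ns = {f"n_{lab}": g.size for lab, g in zip(labels, groups)}
        row = {"feature_id": feature_id, **ns,
               "test_id": None, "p_value": np.nan, "padj": np.nan,
               "dpg_call": "not_tested"}
        if all(g.size >= min_n for g in groups):
            if mode == "kruskal_only":
                test_id = "kruskal_wallis"
            else:
                report = assess_groups(groups)
                test_id = select_test(report, k=len(groups),
                                      alpha_assumption=alpha_assumption)
            result = run_k_group_test(groups, test_id, labels=labels)
            row["test_id"] = result.test_id
            row["p_value"] = result.p_value
            row["dpg_call"] = "ns"
            ph = result.posthoc.copy()
            ph.insert(0, "feature_id", feature_id)
            posthoc_frames.append(ph)
        rows.append(row)
    stats = pd.DataFrame(rows)
    stats["padj"] = adjust_pvalues(stats["p_value"].to_numpy(), adjust_method)
    stats = call_dpgs(stats, alpha=alpha)
    posthoc = (pd.concat(posthoc_frames, ignore_index=True) if posthoc_frames
               else pd.DataFrame(columns=["feature_id", "pair", "statistic",
                                          "p_adjusted", "method"]))
    stats.attrs.update({"mode": mode, "adjust_method": adjust_method,
                        "alpha": alpha, "grouping": grouping, "level": level})
    return stats, posthoc


def call_dpgs(stats: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Label differentially polyadenylated features at adjusted p < alpha.

    With a fold-change column: ``collapsed`` (log2fc < 0, shorter tails) or
    ``expansion`` (log2fc > 0). Without one (k-group tables) significant
    features get the direction-free label ``dpg``. The alpha comparison is
    strict; untested rows stay ``not_tested``.
    """
    out = stats.copy()
    tested = out["padj"].notna()
    sig = tested & (out["padj"] < alpha)
    out.loc[tested, "dpg_call"] = "ns"
    if "log2fc" in out.columns:
        out.loc[sig & (out["log2fc"] < 0), "dpg_call"] = "collapsed"
        out.loc[sig & (out["log2fc"] > 0), "dpg_call"] = "expansion"
    else:
        out.loc[sig, "dpg_call"] = "dpg"
    out.loc[~tested, "dpg_call"] = "not_tested"
    return out


def global_group_test(
    polya: pd.DataFrame,
    grouping_factor: str = "group",
    alpha_assumption: float = 0.05,
) -> TestResult:
    """Pooled comparison of whole tail-length distributions between groups.

    All tail lengths are pooled per grouping value and the adaptive decision
    tree is applied once — this is the omnibus statistic reported alongside a
    density plot, with the selected test's own post-hoc pairs when k > 2.
    """
    labels = sorted(polya[grouping_factor].dropna().unique().tolist())
    if len(labels) < 2:
        raise ValidationError("global test requires at least two grouping values")
    groups = [polya.loc[polya[grouping_factor] == lab, "polyA_length"].to_numpy(float)
              for lab in labels]
    report = assess_groups(groups)
    test_id = select_test(report, k=len(labels), alpha_assumption=alpha_assumption)
    if len(labels) == 2:
        try:
            return run_two_group_test(groups[0], groups[1], test_id)
        except UndefinedStatisticError:
            return run_two_group_test(groups[0], groups[1], "wilcoxon")
    return run_k_group_test(groups, test_id, labels=labels)
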