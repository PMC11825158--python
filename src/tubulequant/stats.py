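"""Group comparisons and method-agreement correlation analysis.

Group tests reproduce a normality-gated workflow common in histology
papers: per-group Shapiro–Wilk; if every group is consistent with
normality, an additive two-factor (randomized-block) ANOVA with
condition and subject as crossed factors, followed by Tukey HSD on
condition using the blocked model's residual mean square; otherwise
Kruskal–Wallis on condition followed by Dunn's pairwise test with
Bonferroni adjustment.  Subjects contribute every condition, which is
what justifies the block structure.

Method agreement uses Pearson's r between the all-shape tubular density
(Method 1) and each round-tubule metric (Methods 2–4), computed on
sample-level values (one point per subject x condition) and additionally
stratified by whether the sample reached the conventional floor of 25
round tubular cross-sections.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import QuantConfig
from .metrics import METHOD_FIELDS, SampleMetrics
from .model import AnalysisError

log = logging.getLogger(__name__)

STRATA = ("all", "below_threshold", "at_or_above_threshold")


@dataclass
class GroupSummary:
    condition: str
    n: int
    mean: float
    sd: float


@dataclass
class PairwiseComparison:
    group_a: str
    group_b: str
    p_adjusted: float
    significant: bool
    mean_diff: float  # mean(b) - mean(a)


@dataclass
class ComparisonResult:
    metric: str
    test_used: str  # "anova_tukey" or "kruskal_dunn"
    groups: list[GroupSummary]
    omnibus_p: float
    pairwise: list[PairwiseComparison]
    n_dropped_missing: int = 0
    notes: str = (
        "two-factor additive model: condition + subject (randomized block); "
        "normality gate: per-group Shapiro-Wilk at alpha"
    )


@dataclass
class CorrelationResult:
    method: str  # compared against method1
    stratum: str  # all | below_threshold | at_or_above_threshold
    n: int
    r: float | None
    p: float | None
    slope: float | None = None
    intercept: float | None = None


def pearson_correlation(x, y) -> tuple[float, float, float, float]:
    """Pearson's r with two-sided p (t transform, n-2 df) and the
    least-squares best-fit line.

    Returns ``(r, p, slope, intercept)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise AnalysisError("pearson_correlation: x and y must be equal-length 1-D")
    if len(x) < 3:
        raise AnalysisError("pearson_correlation: need at least 3 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise AnalysisError("pearson_correlation: non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise AnalysisError("pearson_correlation: zero variance in an input")
    fit = sps.linregress(x, y)
    return float(fit.rvalue), float(fit.pvalue), float(fit.slope), float(fit.intercept)


def _shapiro_gate(groups: dict[str, np.ndarray], alpha: float) -> bool:
    """True when every group is consistent with normality.

    Groups with fewer than 3 observations cannot be assessed and fail the
    gate (nonparametric branch); constant groups pass it (a zero-range
    sample cannot reject normality).
    """
    for label, vals in groups.items():
        if len(vals) < 3:
            log.info("group %s has n=%d < 3; normality not assessable", label, len(vals))
            return False
        if np.ptp(vals) == 0:
            continue
        p = sps.shapiro(vals).pvalue
        if p < alpha:
            return False
    return True


def _tukey_pairs(
    df: pd.DataFrame, mse: float, df_resid: float, alpha: float
) -> list[PairwiseComparison]:
    """Tukey–Kramer pairwise tests on condition means using the blocked
    model's residual mean square."""
    stats_ = df.groupby("condition")["value"].agg(["mean", "count"])
    k = len(stats_)
    out = []
    for a, b in itertools.combinations(sorted(stats_.index), 2):
        ma, na = stats_.loc[a, "mean"], stats_.loc[a, "count"]
        mb, nb = stats_.loc[b, "mean"], stats_.loc[b, "count"]
        se = math.sqrt(mse / 2.0 * (1.0 / na + 1.0 / nb))
        if se == 0:
            p = 0.0 if mb != ma else 1.0
        else:
            q = abs(mb - ma) / se
            p = float(sps.studentized_range.sf(q, k, df_resid))
        out.append(PairwiseComparison(a, b, min(1.0, p), p < alpha, float(mb - ma)))
    return out


def _dunn_pairs(groups: dict[str, np.ndarray], alpha: float) -> list[PairwiseComparison]:
    """Dunn's rank-based pairwise test with Bonferroni adjustment."""
    labels = sorted(groups)
    values = np.concatenate([groups[g] for g in labels])
    n_per = {g: len(groups[g]) for g in labels}
    ranks = sps.rankdata(values)
    n_total = len(values)
    mean_rank = {}
    start = 0
    for g in labels:
        mean_rank[g] = ranks[start : start + n_per[g]].mean()
        start += n_per[g]
    # tie correction
    _, counts = np.unique(values, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (12.0 * (n_total - 1)) if n_total > 1 else 0.0
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    m = len(labels) * (len(labels) - 1) // 2
    out = []
    for a, b in itertools.combinations(labels, 2):
        se = math.sqrt(var_base * (1.0 / n_per[a] + 1.0 / n_per[b]))
        if se == 0:
            p_adj = 1.0
        else:
            z = (mean_rank[b] - mean_rank[a]) / se
            p_adj = min(1.0, 2.0 * sps.norm.sf(abs(z)) * m)
        diff = float(groups[b].mean() - groups[a].mean())
        out.append(PairwiseComparison(a, b, p_adj, p_adj < alpha, diff))
    return out


def compare_groups(
    samples: list[SampleMetrics],
    metric: str,
    config: QuantConfig | None = None,
) -> ComparisonResult:
    """Compare a metric across experimental conditions.

    Requires at least two conditions with at least two usable samples
    each; samples where the metric is missing are dropped with a logged
    count.
    """
    config = config or QuantConfig()
    if metric not in METHOD_FIELDS:
        raise AnalysisError(f"unknown metric {metric!r}; expected one of {METHOD_FIELDS}")
    rows = [
        {"value": getattr(s, metric), "condition": s.condition, "subject": s.subject_id}
        for s in samples
    ]
    df = pd.DataFrame(rows)
    n_missing = int(df["value"].isna().sum())
    if n_missing:
        log.info("compare_groups(%s): dropped %d sample(s) with missing metric", metric, n_missing)
    df = df.dropna(subset=["value"]).reset_index(drop=True)
    usable = df.groupby("condition").size()
    usable = usable[usable >= 2]
    if len(usable) < 2:
        raise AnalysisError(
            f"compare_groups({metric}): need >=2 conditions with >=2 samples, got {len(usable)}"
        )
    df = df[df["condition"].isin(usable.index)]
    groups = {g: sub["value"].to_numpy(float) for g, sub in df.groupby("condition")}
    summaries = [
        GroupSummary(g, len(v), float(v.mean()), float(v.std(ddof=1))) for g, v in sorted(groups.items())
    ]

    if _shapiro_gate(groups, config.alpha):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        model = smf.ols("value ~ C(condition) + C(subject)", data=df).fit()
        table = sm.stats.anova_lm(model, typ=2)
        omnibus_p = float(table.loc["C(condition)", "PR(>F)"])
        if math.isnan(omnibus_p):  # zero residual variance: perfect separation
            omnibus_p = 0.0 if table.loc["C(condition)", "sum_sq"] > 0 else 1.0
        pairwise = _tukey_pairs(df, float(model.mse_resid), float(model.df_resid), config.alpha)
        test_used = "anova_tukey"
    else:
        if all(np.ptp(v) == 0 for v in groups.values()) and len({v[0] for v in groups.values()}) == 1:
            raise AnalysisError("compare_groups: all observations identical")
        omnibus_p = float(sps.kruskal(*groups.values()).pvalue)
        pairwise = _dunn_pairs(groups, config.alpha)
        test_used = "kruskal_dunn"
    return ComparisonResult(
        metric=metric,
        test_used=test_used,
        groups=summaries,
        omnibus_p=omnibus_p,
        pairwise=pairwise,
        n_dropped_missing=n_missing,
    )


def correlate_methods(
    samples: list[SampleMetrics],
    threshold: int | None = None,
    config: QuantConfig | None = None,
) -> list[CorrelationResult]:
    """Correlate Methods 2–4 against Method 1 across samples, overall and
    stratified by round-tubule availability (< threshold vs >= threshold).

    Strata with fewer than 3 complete pairs yield a result with r and p
    undefined (``None``).
    """
    config = config or QuantConfig()
    if threshold is None:
        threshold = config.min_round_tubules
    out: list[CorrelationResult] = []
    for method in METHOD_FIELDS[1:]:
        pairs = [
            (s.method1, getattr(s, method), s.n_round_total)
            for s in samples
            if s.method1 is not None and getattr(s, method) is not None
        ]
        n_dropped = len(samples) - len(pairs)
        if n_dropped:
            log.info("correlate_methods(%s): dropped %d incomplete pair(s)", method, n_dropped)
        strata = {
            "all": pairs,
            "below_threshold": [p for p in pairs if p[2] < threshold],
            "at_or_above_threshold": [p for p in pairs if p[2] >= threshold],
        }
        for name in STRATA:
            sel = strata[name]
            if len(sel) < 3:
                out.append(CorrelationResult(method, name, len(sel), None, None))
                continue
            x = [p[0] for p in sel]
            y = [p[1] for p in sel]
            try:
                r, p, slope, intercept = pearson_correlation(x, y)
            except AnalysisError:
                out.append(CorrelationResult(method, name, len(sel), None, None))
                continue
            out.append(CorrelationResult(method, name, len(sel), r, p, slope, intercept))
    return out
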