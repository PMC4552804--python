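"""Longitudinal and reproducibility statistics.

Implements the statistical toolbox of the stiffness pipeline: Bland-Altman
95 % limits of agreement, per-timepoint Wilcoxon rank-sum tests (exact
enumeration at small n) with Benjamini-Hochberg step-up correction, the
rank-based ANOVA-type statistic (ATS) for the two-group repeated-measures
layout (one whole-plot group factor, one repeated time factor), tie-corrected
Kruskal-Wallis, quadratic trajectory fitting with R-squared, and a plain
one-way ANOVA used for the fibre-directionality group comparisons.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

LOA_FACTOR = 1.96          # large-sample 95 % limits of agreement
EXACT_RANKSUM_MAX_N = 12   # exact enumeration up to this combined sample size


# ---------------------------------------------------------------------------
# Bland-Altman agreement


@dataclass(frozen=True)
class AgreementSummary:
    """Bland-Altman bias and 95 % limits of agreement (kPa)."""

    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    coverage: float
    n: int


def bland_altman(values_a, values_b) -> tuple[AgreementSummary, pd.DataFrame]:
    """Agreement between two matched measurement series.

    Returns the summary (bias = mean difference, limits of agreement =
    bias +/- 1.96 SD of the differences, achieved coverage) together with the
    plot-ready ``(mean, diff)`` table.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired series must be 1-D and of equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    diff = a - b
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    lo, hi = bias - LOA_FACTOR * sd, bias + LOA_FACTOR * sd
    coverage = float(np.mean((diff >= lo) & (diff <= hi)))
    table = pd.DataFrame({"mean": (a + b) / 2.0, "diff": diff})
    return AgreementSummary(bias, sd, lo, hi, coverage, a.size), table


# ---------------------------------------------------------------------------
# rank-sum tests


def ranksum_exact(x, y) -> float:
    """Two-sided exact Wilcoxon rank-sum p by full enumeration with mid-ranks.

    Enumerates every assignment of the pooled mid-ranks to the first group;
    the two-sided p doubles the smaller tail (point included), capped at 1.
    Valid with ties, intended for combined n <= 12.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n, nx = pooled.size, x.size
    observed = ranks[:nx].sum()
    sums = np.array([sum(c) for c in itertools.combinations(ranks, nx)])
    eps = 1e-9
    lower = np.mean(sums <= observed + eps)
    upper = np.mean(sums >= observed - eps)
    return float(min(1.0, 2.0 * min(lower, upper)))


def ranksum(x, y) -> float:
    """Two-sided rank-sum p: exact enumeration for combined n <= 12,
    tie-corrected normal approximation otherwise."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if x.size + y.size <= EXACT_RANKSUM_MAX_N:
        return ranksum_exact(x, y)
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def adjust_pvalues(pvalues, method: str = "bh") -> np.ndarray:
    """Multiplicity adjustment: Benjamini-Hochberg step-up (default) or
    plain Bonferroni."""
    pvalues = np.asarray(pvalues, dtype=float)
    key = {"bh": "fdr_bh", "bonferroni": "bonferroni"}[method]
    return multipletests(pvalues, method=key)[1]


def ranksum_by_time(table: pd.DataFrame, value: str = "median_kpa",
                    method: str = "bh") -> pd.DataFrame:
    """Per-hour two-group rank-sum tests with step-up adjustment.

    ``table`` is a tidy frame with columns ``group``, ``hour`` and the value
    column; hours where either group is absent are skipped. Returns one row
    per tested hour with raw and adjusted p.
    """
    rows = []
    for hour, sub in table.dropna(subset=[value]).groupby("hour"):
        groups = {g: s[value].to_numpy() for g, s in sub.groupby("group")}
        if len(groups) < 2:
            continue
        (ga, xa), (gb, xb) = sorted(groups.items())[:2]
        rows.append({"hour": hour, "n_" + ga: xa.size, "n_" + gb: xb.size,
                     "p_raw": ranksum(xa, xb)})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_adj"] = adjust_pvalues(out["p_raw"].to_numpy(), method=method)
    return out


# ---------------------------------------------------------------------------
# ANOVA-type statistic for the two-factor (group x time) repeated design


@dataclass(frozen=True)
class ATSResult:
    """ANOVA-type statistic for one effect."""

    statistic: float
    df_num: float
    df_den: float   # inf for within-subject effects
    p_value: float


def _contrast_projection(c: np.ndarray) -> np.ndarray:
    return c.T @ np.linalg.pinv(c @ c.T) @ c


def anova_type_statistic(table: pd.DataFrame, value: str = "median_kpa"
                         ) -> dict[str, ATSResult]:
    """Rank-based ANOVA-type statistics for group, time and interaction.

    The design has one whole-plot factor (group, one level per subject) and
    one repeated factor (time). All observations are jointly mid-ranked;
    relative treatment effects per group x time cell are contrasted with
    Box-approximation degrees of freedom. The group (whole-plot) effect uses
    an F reference with estimated denominator df; time and interaction use
    F(df, inf). Missing cells are handled by available-case estimates.
    Replicated observations per subject x time (e.g. two operators) are
    averaged on the rank scale.
    """
    df = table.dropna(subset=[value]).copy()
    groups = sorted(df["group"].unique())
    hours = sorted(df["hour"].unique())
    a, t = len(groups), len(hours)
    if a < 2 or t < 2:
        raise ValueError("need >= 2 groups and >= 2 time points")
    for g in groups:
        if df.loc[df["group"] == g, "animal"].nunique() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")

    n_obs = len(df)
    df["_rank"] = sps.rankdata(df[value].to_numpy()) / n_obs
    # subject x time matrix of mean normalised ranks, NaN where missing
    prof = df.pivot_table(index=["group", "animal"], columns="hour",
                          values="_rank", aggfunc="mean")
    prof = prof.reindex(columns=hours)

    p_hat = np.zeros(a * t)
    v_blocks = []
    n_subjects = []
    for gi, g in enumerate(groups):
        block = prof.loc[g].to_numpy()          # n_g x t, may contain NaN
        n_g = block.shape[0]
        n_subjects.append(n_g)
        cell_means = np.nanmean(block, axis=0)
        p_hat[gi * t:(gi + 1) * t] = cell_means
        # available-case covariance of subject rank profiles
        centred = block - cell_means
        cov = np.zeros((t, t))
        for s1 in range(t):
            for s2 in range(s1, t):
                pair = centred[:, s1] * centred[:, s2]
                ok = ~np.isnan(pair)
                m = int(ok.sum())
                cov[s1, s2] = cov[s2, s1] = (pair[ok].sum() / (m - 1)
                                             if m > 1 else 0.0)
        v_blocks.append(cov / n_g)
    n_total_subjects = sum(n_subjects)
    v_hat = n_total_subjects * _block_diag(v_blocks)

    one_t = np.ones((1, t))
    one_a = np.ones((1, a))
    p_a = np.eye(a) - np.ones((a, a)) / a
    p_t = np.eye(t) - np.ones((t, t)) / t
    contrasts = {
        "group": np.kron(p_a, one_t / t),
        "time": np.kron(one_a / a, p_t),
        "interaction": np.kron(p_a, p_t),
    }

    results: dict[str, ATSResult] = {}
    for effect, c in contrasts.items():
        m = _contrast_projection(c)
        mv = m @ v_hat
        trace_mv = float(np.trace(mv))
        if trace_mv <= 0:
            results[effect] = ATSResult(0.0, 1.0, math.inf, 1.0)
            continue
        stat = n_total_subjects * float(p_hat @ m @ p_hat) / trace_mv
        df_num = trace_mv**2 / float(np.trace(mv @ mv))
        if effect == "group":
            # Box-type denominator df for the whole-plot factor
            denom = 0.0
            for gi, n_g in enumerate(n_subjects):
                block_trace = float(np.trace(
                    mv[gi * t:(gi + 1) * t, gi * t:(gi + 1) * t]))
                denom += block_trace**2 / (n_g - 1)
            df_den = trace_mv**2 / denom if denom > 0 else math.inf
            p = float(sps.f.sf(stat, df_num, df_den))
        else:
            df_den = math.inf
            p = float(sps.chi2.sf(stat * df_num, df_num))
        results[effect] = ATSResult(stat, df_num, df_den, p)
    return results


def _block_diag(blocks: list[np.ndarray]) -> np.ndarray:
    size = sum(b.shape[0] for b in blocks)
    out = np.zeros((size, size))
    pos = 0
    for b in blocks:
        k = b.shape[0]
        out[pos:pos + k, pos:pos + k] = b
        pos += k
    return out


# ---------------------------------------------------------------------------
# simple group tests


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and chi-square p-value.

    Degenerate all-identical data returns (0, 1) instead of raising.
    """
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def one_way_anova(*groups) -> tuple[float, float]:
    """Plain one-way ANOVA F and p (used for the R / intensity comparisons)."""
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    f, p = sps.f_oneway(*groups)
    return float(f), float(p)


# ---------------------------------------------------------------------------
# trajectory fitting


@dataclass(frozen=True)
class TrajectoryFit:
    """Quadratic stiffness-vs-time fit E(t) = a t^2 + b t + c."""

    a: float
    b: float
    c: float
    r_squared: float


def fit_quadratic(hours, stiffness) -> TrajectoryFit:
    """Ordinary least squares fit of stiffness on {1, t, t^2} with R^2.

    Requires at least 3 distinct hours. When the response is constant
    (SS_tot = 0) R^2 is defined as 0, with a warning.
    """
    t = np.asarray(hours, dtype=float)
    y = np.asarray(stiffness, dtype=float)
    ok = ~(np.isnan(t) | np.isnan(y))
    t, y = t[ok], y[ok]
    if np.unique(t).size < 3:
        raise ValueError("need >= 3 distinct hours for a quadratic fit")
    design = np.column_stack([np.ones_like(t), t, t**2])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        warnings.warn("constant response: R^2 defined as 0", RuntimeWarning)
        r2 = 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    return TrajectoryFit(a=float(coef[2]), b=float(coef[1]), c=float(coef[0]),
                         r_squared=r2)


def fit_group_trajectories(table: pd.DataFrame, value: str = "median_kpa",
                           on_medians: bool = True) -> dict[str, TrajectoryFit]:
    """Per-group quadratic fits of stiffness versus hours.

    By default fits the per-hour medians across animals/operators (one point
    per examination time); set ``on_medians=False`` to fit all raw points.
    """
    fits = {}
    for group, sub in table.dropna(subset=[value]).groupby("group"):
        if on_medians:
            agg = sub.groupby("hour")[value].median()
            fits[group] = fit_quadratic(agg.index.to_numpy(), agg.to_numpy())
        else:
            fits[group] = fit_quadratic(sub["hour"].to_numpy(),
                                        sub[value].to_numpy())
    return fits
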