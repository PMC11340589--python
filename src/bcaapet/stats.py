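"""Cohort-level statistics for the depot comparisons.

Routing follows the conventions of the imaging analysis it supports:
paired depot measurements go through repeated-measures ANOVA with Tukey
correction when every depot passes Shapiro-Wilk normality (alpha = 0.05),
and otherwise through the Friedman test with Dunn correction; independent
groups go through one-way ANOVA + Tukey (>= 3 normal groups), the
Mann-Whitney U test (2 groups, rank route), or Kruskal-Wallis + Dunn
(>= 3 groups, rank route); correlations use Spearman's rho.  All tests are
two-sided at the 95% confidence level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientGroupError, UndefinedCorrelationError

__all__ = [
    "ComparisonResult",
    "compare_depots_paired",
    "compare_groups",
    "spearman_corr",
    "relative_expression",
    "clearance_estimate",
    "bmi_category",
    "bat_group",
    "friedman_test",
    "HBAT_VOLUME_THRESHOLD_ML",
]

#: FDG-PET-detectable BAT volume (mL) at or above which a participant is
#: classed HBAT (high BAT volume); below it, LBAT.
HBAT_VOLUME_THRESHOLD_ML = 20.0

SHAPIRO_ALPHA = 0.05


@dataclass(frozen=True)
class ComparisonResult:
    test: str
    statistic: float
    pvalue: float
    pairwise: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)
    group_summary: dict[str, dict[str, float]] = field(default_factory=dict)
    route: str = ""


def _is_normal(x: np.ndarray) -> bool:
    x = np.asarray(x, dtype=float)
    if x.size < 3 or np.ptp(x) == 0.0:
        return False
    return sps.shapiro(x).pvalue > SHAPIRO_ALPHA


def _summaries(columns: dict[str, np.ndarray], normal: bool) -> dict[str, dict[str, float]]:
    out = {}
    for name, x in columns.items():
        if normal:
            out[name] = {"mean": float(np.mean(x)), "sd": float(np.std(x, ddof=1))}
        else:
            q1, med, q3 = np.percentile(x, [25, 50, 75])
            out[name] = {"median": float(med), "iqr_low": float(q1), "iqr_high": float(q3)}
    return out


def friedman_test(data: np.ndarray) -> tuple[float, float]:
    """Friedman chi-square statistic and p for an (n subjects x k) table.

    Within-row midranks; tie-corrected.  Degenerate tables in which every
    row is constant (no rank variation at all) return statistic 0, p = 1.
    """
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, data)
    if np.ptp(ranks, axis=1).max() == 0.0:
        return 0.0, 1.0
    stat, p = sps.friedmanchisquare(*[data[:, j] for j in range(k)])
    return float(stat), float(p)


def _dunn_pairwise(
    ranks_mean: dict[str, float], n: int, k: int, scale: float
) -> dict[tuple[str, str], dict[str, float]]:
    """Dunn z-tests on mean ranks with Bonferroni family correction."""
    names = list(ranks_mean)
    ncomp = k * (k - 1) // 2
    out = {}
    for a, b in combinations(names, 2):
        z = (ranks_mean[a] - ranks_mean[b]) / scale
        p_raw = float(2.0 * sps.norm.sf(abs(z)))
        out[(a, b)] = {
            "statistic": float(z),
            "p_raw": p_raw,
            "p_adj": float(min(1.0, p_raw * ncomp)),
        }
    return out


def _tukey_pairwise_rm(
    columns: dict[str, np.ndarray], ms_error: float, df_error: int, n: int
) -> dict[tuple[str, str], dict[str, float]]:
    k = len(columns)
    out = {}
    for a, b in combinations(columns, 2):
        diff = float(np.mean(columns[a]) - np.mean(columns[b]))
        q = abs(diff) / np.sqrt(ms_error / n)
        p_adj = float(sps.studentized_range.sf(q, k, df_error))
        out[(a, b)] = {"statistic": float(q), "estimate": diff, "p_adj": min(1.0, p_adj)}
    return out


def compare_depots_paired(
    values: pd.DataFrame, force_route: str | None = None
) -> ComparisonResult:
    """Paired comparison of one measurement across >= 3 depots.

    ``values``: wide DataFrame, one row per subject, one column per depot.
    Incomplete rows are dropped listwise with a warning.  The parametric
    route (all depots Shapiro-normal) is repeated-measures ANOVA with Tukey
    correction on the subject-by-depot error term; the rank route is the
    Friedman test with Dunn correction.
    """
    df = pd.DataFrame(values)
    if df.shape[1] < 3:
        raise InsufficientGroupError("need >= 3 depots for a paired depot comparison")
    complete = df.dropna()
    if len(complete) < len(df):
        warnings.warn(
            f"dropping {len(df) - len(complete)} incomplete subjects (listwise)",
            UserWarning,
        )
    if len(complete) < 3:
        raise InsufficientGroupError("need >= 3 complete subjects")
    data = complete.to_numpy(dtype=float)
    n, k = data.shape
    columns = {c: data[:, j] for j, c in enumerate(complete.columns)}

    if force_route is None:
        route = "parametric" if all(_is_normal(x) for x in columns.values()) else "rank"
    else:
        route = force_route

    if route == "parametric":
        grand = data.mean()
        ss_subject = k * np.sum((data.mean(axis=1) - grand) ** 2)
        ss_treat = n * np.sum((data.mean(axis=0) - grand) ** 2)
        ss_total = np.sum((data - grand) ** 2)
        ss_error = ss_total - ss_subject - ss_treat
        df_treat, df_error = k - 1, (n - 1) * (k - 1)
        ms_treat = ss_treat / df_treat
        ms_error = ss_error / df_error
        if ms_error <= 0:
            f_stat, p = np.inf if ms_treat > 0 else 0.0, 0.0 if ms_treat > 0 else 1.0
            pairwise = {}
        else:
            f_stat = ms_treat / ms_error
            p = float(sps.f.sf(f_stat, df_treat, df_error))
            pairwise = _tukey_pairwise_rm(columns, ms_error, df_error, n)
        return ComparisonResult(
            test="rm_anova_tukey",
            statistic=float(f_stat),
            pvalue=float(p),
            pairwise=pairwise,
            group_summary=_summaries(columns, normal=True),
            route="parametric",
        )

    stat, p = friedman_test(data)
    ranks = np.apply_along_axis(sps.rankdata, 1, data)
    mean_ranks = {c: float(ranks[:, j].mean()) for j, c in enumerate(complete.columns)}
    scale = np.sqrt(k * (k + 1) / (6.0 * n))
    pairwise = _dunn_pairwise(mean_ranks, n, k, scale)
    return ComparisonResult(
        test="friedman_dunn",
        statistic=stat,
        pvalue=p,
        pairwise=pairwise,
        group_summary=_summaries(columns, normal=False),
        route="rank",
    )


def _mannwhitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: exact for combined n <= 20 without ties,
    tie-corrected normal approximation otherwise."""
    combined = np.concatenate([x, y])
    exact = combined.size <= 20 and np.unique(combined).size == combined.size
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    values, labels, force_route: str | None = None
) -> ComparisonResult:
    """Compare a measurement between independent groups.

    Two groups: Mann-Whitney U on the rank route, Welch-free pooled t on the
    parametric route is deliberately not offered — two-group contrasts in
    this pipeline are rank-based.  Three or more groups: one-way ANOVA with
    Tukey correction when every group is Shapiro-normal, otherwise
    Kruskal-Wallis with Dunn correction.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    names = [str(g) for g in pd.unique(labels)]
    groups = {g: values[labels == g] for g in pd.unique(labels)}
    if len(groups) < 2:
        raise InsufficientGroupError("need >= 2 groups")
    for g, x in groups.items():
        if x.size < 2:
            raise InsufficientGroupError(f"group {g!r} has n < 2")
    columns = {str(g): x for g, x in groups.items()}

    if len(groups) == 2:
        (na, xa), (nb, xb) = list(columns.items())
        stat, p = _mannwhitney(xa, xb)
        return ComparisonResult(
            test="mann_whitney_u",
            statistic=stat,
            pvalue=p,
            pairwise={(na, nb): {"statistic": stat, "p_raw": p, "p_adj": p}},
            group_summary=_summaries(columns, normal=False),
            route="rank",
        )

    if force_route is None:
        route = "parametric" if all(_is_normal(x) for x in columns.values()) else "rank"
    else:
        route = force_route

    if route == "parametric":
        f_stat, p = sps.f_oneway(*columns.values())
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        flat = np.concatenate(list(columns.values()))
        labs = np.concatenate([[g] * x.size for g, x in columns.items()])
        tk = pairwise_tukeyhsd(flat, labs, alpha=0.05)
        pairwise = {}
        for row in tk.summary().data[1:]:
            a, b, diff, p_adj = str(row[0]), str(row[1]), float(row[2]), float(row[3])
            pairwise[(a, b)] = {"estimate": diff, "p_adj": p_adj}
        return ComparisonResult(
            test="anova_tukey",
            statistic=float(f_stat),
            pvalue=float(p),
            pairwise=pairwise,
            group_summary=_summaries(columns, normal=True),
            route="parametric",
        )

    stat, p = sps.kruskal(*columns.values())
    all_vals = np.concatenate(list(columns.values()))
    all_ranks = sps.rankdata(all_vals)
    sizes = {g: x.size for g, x in columns.items()}
    offsets = np.cumsum([0] + [x.size for x in columns.values()])
    mean_ranks = {
        g: float(all_ranks[offsets[j] : offsets[j + 1]].mean())
        for j, g in enumerate(columns)
    }
    ntot = all_vals.size
    ncomp = len(columns) * (len(columns) - 1) // 2
    pairwise = {}
    for a, b in combinations(columns, 2):
        se = np.sqrt(ntot * (ntot + 1) / 12.0 * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p_raw = float(2.0 * sps.norm.sf(abs(z)))
        pairwise[(a, b)] = {
            "statistic": float(z),
            "p_raw": p_raw,
            "p_adj": float(min(1.0, p_raw * ncomp)),
        }
    return ComparisonResult(
        test="kruskal_dunn",
        statistic=float(stat),
        pvalue=float(p),
        pairwise=pairwise,
        group_summary=_summaries(columns, normal=False),
        route="rank",
    )


def spearman_corr(x, y) -> tuple[float, float]:
    """Spearman's rho with midrank ties, two-sided p.

    Raises UndefinedCorrelationError for constant vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired vectors with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def relative_expression(ct_target, ct_reference):
    """Relative gene expression 2^(-(ct_target - ct_reference)).

    Quantification against a housekeeping reference (RPLP0) without a
    calibrator sample: one extra target cycle halves the expression.
    """
    ct_target = np.asarray(ct_target, dtype=float)
    ct_reference = np.asarray(ct_reference, dtype=float)
    if np.any(~np.isfinite(ct_target)) or np.any(~np.isfinite(ct_reference)):
        raise ValueError("Ct values must be finite")
    if np.any(ct_target <= 0) or np.any(ct_reference <= 0):
        raise ValueError("Ct values must be positive")
    out = np.power(2.0, ct_reference - ct_target)
    return float(out) if out.ndim == 0 else out


def clearance_estimate(tissue_volume_cm3: float, ki_mL_per_min_per_cm3: float) -> float:
    """Whole-tissue plasma clearance, mL/min = volume x net uptake rate.

    E.g. ~100 cm^3 of supraclavicular BAT at Ki = 0.012 mL/min/cm^3 clears
    about 1.2 mL of plasma per minute.
    """
    if tissue_volume_cm3 < 0 or ki_mL_per_min_per_cm3 < 0:
        raise ValueError("inputs must be nonnegative")
    return tissue_volume_cm3 * ki_mL_per_min_per_cm3


def bmi_category(bmi: float) -> str:
    """WHO adult categories: NW (<25), OW (25-<30), OB (>=30)."""
    if bmi <= 0:
        raise ValueError("bmi must be positive")
    if bmi < 25.0:
        return "NW"
    if bmi < 30.0:
        return "OW"
    return "OB"


def bat_group(bat_volume_ml: float) -> str:
    """HBAT if FDG-detectable BAT volume >= 20 mL, else LBAT."""
    if bat_volume_ml < 0:
        raise ValueError("volume must be >= 0")
    return "HBAT" if bat_volume_ml >= HBAT_VOLUME_THRESHOLD_ML else "LBAT"
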