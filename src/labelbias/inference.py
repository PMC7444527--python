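"""Uncertainty quantification and hypothesis tests for the survey analysis.

Covers the inferential toolkit the pipeline reports: volunteer-level
bootstrap confidence intervals (volunteers are the exchangeable unit — all
of a volunteer's responses move together when resampling), two-sample rank
tests for per-item rating distributions, the across-item mean-shift t test,
Pearson chi-squared homogeneity tests for count tables, and one-way /
split-plot (mixed) analyses of variance on per-volunteer rates.

The rank test is implemented in the Mann-Whitney two-sample form: within a
sourced survey variant each volunteer saw a given face pair under exactly
one label (version counterbalancing), so the told-same and told-different
rating samples for an item come from disjoint volunteer groups.  A
signed-rank variant is provided for genuinely paired inputs.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestResult",
    "BootstrapConfig",
    "BootstrapResult",
    "bootstrap_statistic",
    "rank_sum_item_test",
    "signed_rank_test",
    "item_shift_summary",
    "chi_squared_test",
    "oneway_anova",
    "mixed_anova",
    "repeated_measures_anova",
]


@dataclasses.dataclass(frozen=True)
class TestResult:
    statistic: float
    df: tuple[float, ...]
    p_value: float
    method: str
    effect: dict = dataclasses.field(default_factory=dict)
    degenerate: bool = False


# ---------------------------------------------------------------------------
# bootstrap


@dataclasses.dataclass
class BootstrapConfig:
    """Volunteer-level percentile bootstrap.

    ``stratify`` names a column (default the survey variant) within which
    volunteers are resampled independently, preserving per-condition sample
    sizes; set to None to resample the pooled volunteer list.
    """

    n_boot: int = 2000
    seed: int | np.random.SeedSequence = 0
    unit: str = "volunteer"
    interval: str = "percentile"
    level: float = 0.95
    stratify: str | None = "variant"

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if not 0.0 < self.level < 1.0:
            raise ValueError("level must lie in (0, 1)")
        if self.unit != "volunteer":
            raise ValueError("only volunteer-level resampling is supported")
        if self.interval != "percentile":
            raise ValueError("only percentile intervals are supported")


@dataclasses.dataclass
class BootstrapResult:
    estimate: float
    ci_low: float
    ci_high: float
    level: float
    n_boot: int
    n_failed: int
    replicates: np.ndarray


def bootstrap_statistic(
    records: pd.DataFrame,
    statistic: Callable[[pd.DataFrame], float],
    config: BootstrapConfig | None = None,
) -> BootstrapResult:
    """Percentile bootstrap CI of ``statistic`` over resampled volunteers.

    Volunteers are drawn with replacement (within strata when configured);
    every record of a drawn volunteer enters the replicate, preserving the
    within-volunteer response structure.  Replicates on which the statistic
    is undefined (raises ValueError / ZeroDivisionError or returns NaN) are
    dropped; more than 50% failures is an error.  Identical seeds give
    bit-identical intervals.
    """
    cfg = config or BootstrapConfig()
    if records["volunteer_id"].nunique() < 2:
        raise ValueError("bootstrap needs >= 2 distinct volunteers")
    estimate = float(statistic(records))

    df = records.reset_index(drop=True)
    if cfg.stratify is not None and cfg.stratify in df.columns:
        strata_labels = df[cfg.stratify].astype(str)
    else:
        strata_labels = pd.Series("_all", index=df.index)

    # positional row indices per volunteer, grouped by stratum, in sorted
    # order so that the resampling stream is reproducible
    strata: list[list[np.ndarray]] = []
    for _, sub in df.groupby(strata_labels, sort=True):
        idx = sub.groupby("volunteer_id", sort=True).indices
        rows = [np.asarray(sub.index)[v] for _, v in sorted(idx.items())]
        strata.append(rows)

    rng = np.random.default_rng(cfg.seed)
    reps = np.full(cfg.n_boot, np.nan)
    for b in range(cfg.n_boot):
        parts = []
        for rows in strata:
            draw = rng.integers(0, len(rows), size=len(rows))
            parts.extend(rows[j] for j in draw)
        sample = df.take(np.concatenate(parts))
        try:
            val = float(statistic(sample))
        except (ValueError, ZeroDivisionError, FloatingPointError):
            continue
        reps[b] = val

    finite = reps[np.isfinite(reps)]
    n_failed = cfg.n_boot - finite.size
    if n_failed > 0.5 * cfg.n_boot:
        raise ValueError(
            f"statistic undefined on {n_failed}/{cfg.n_boot} bootstrap replicates"
        )
    alpha = (1.0 - cfg.level) / 2.0
    lo, hi = np.quantile(finite, [alpha, 1.0 - alpha])
    return BootstrapResult(
        estimate=estimate,
        ci_low=float(lo),
        ci_high=float(hi),
        level=cfg.level,
        n_boot=cfg.n_boot,
        n_failed=int(n_failed),
        replicates=reps,
    )


# ---------------------------------------------------------------------------
# rank tests


def _u_statistic(ranks: np.ndarray, n1: int) -> float:
    return float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)


def rank_sum_item_test(
    ratings_a: Sequence[float], ratings_b: Sequence[float]
) -> TestResult:
    """Two-sample Mann-Whitney rank test with ties handled by mid-ranks.

    Uses exact permutation enumeration when both samples have at most 8
    observations (exact even under ties), otherwise the tie-corrected normal
    approximation without continuity correction.  Two-sided p-value; the
    reported statistic is U for the first sample.
    """
    a = np.asarray(ratings_a, dtype=float)
    b = np.asarray(ratings_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both rating lists must be non-empty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u1 = _u_statistic(ranks, n1)
    mu = n1 * n2 / 2.0

    if n1 <= 8 and n2 <= 8:
        obs = abs(u1 - mu)
        total = 0
        extreme = 0
        idx = np.arange(n1 + n2)
        for combo in itertools.combinations(idx, n1):
            u = float(ranks[list(combo)].sum() - n1 * (n1 + 1) / 2.0)
            total += 1
            if abs(u - mu) >= obs - 1e-9:
                extreme += 1
        p = extreme / total
        method = "mann-whitney (exact permutation)"
    else:
        _, counts = np.unique(pooled, return_counts=True)
        n = n1 + n2
        tie_term = float(np.sum(counts**3 - counts))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var <= 0:
            p = 1.0
        else:
            z = (u1 - mu) / math.sqrt(var)
            p = float(2.0 * stats.norm.sf(abs(z)))
        method = "mann-whitney (normal approximation, tie-corrected)"

    return TestResult(
        statistic=u1,
        df=(float(n1), float(n2)),
        p_value=min(1.0, p),
        method=method,
        effect={"u1": u1, "n1": n1, "n2": n2},
    )


def signed_rank_test(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Wilcoxon signed-rank test for genuinely paired samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if np.allclose(x, y):
        return TestResult(0.0, (float(x.size),), 1.0, "wilcoxon signed-rank",
                          degenerate=True)
    res = stats.wilcoxon(x, y)
    return TestResult(
        statistic=float(res.statistic),
        df=(float(x.size),),
        p_value=float(res.pvalue),
        method="wilcoxon signed-rank",
    )


# ---------------------------------------------------------------------------
# item-shift summary


def item_shift_summary(
    per_item_pairs: Sequence[tuple[float, float]]
) -> TestResult:
    """Across-item mean rating shift between told-same and told-different.

    Each element is (mean rating under "same" label, mean rating under
    "different" label) for one face pair.  Reports the average of the
    per-item differences and a one-sample two-sided t test of the
    differences against 0 with items - 1 degrees of freedom.
    """
    pairs = np.asarray(per_item_pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 2:
        raise ValueError("need >= 2 (mean_same, mean_different) pairs")
    diffs = pairs[:, 0] - pairs[:, 1]
    k = diffs.size
    shift = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    effect = {"mean_shift": shift, "per_item_differences": diffs.tolist()}
    if sd == 0.0:
        if shift == 0.0:
            return TestResult(0.0, (float(k - 1),), 1.0,
                              "one-sample t on per-item shifts", effect)
        return TestResult(
            math.copysign(math.inf, shift), (float(k - 1),), 0.0,
            "one-sample t on per-item shifts", effect, degenerate=True,
        )
    t = shift / (sd / math.sqrt(k))
    p = float(2.0 * stats.t.sf(abs(t), df=k - 1))
    return TestResult(float(t), (float(k - 1),), p,
                      "one-sample t on per-item shifts", effect)


# ---------------------------------------------------------------------------
# chi-squared and ANOVA


def chi_squared_test(counts: Sequence[Sequence[float]]) -> TestResult:
    """Pearson chi-squared test of homogeneity on an r x c count table.

    No continuity correction; expected counts from the row/column margins;
    df = (r - 1)(c - 1).
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2:
        raise ValueError("counts must be a 2-D table")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    row_tot = table.sum(axis=1)
    col_tot = table.sum(axis=0)
    if (row_tot == 0).any():
        raise ValueError(f"row {int(np.argmax(row_tot == 0))} has zero total")
    if (col_tot == 0).any():
        raise ValueError(f"column {int(np.argmax(col_tot == 0))} has zero total")
    res = stats.chi2_contingency(table, correction=False)
    return TestResult(
        statistic=float(res.statistic),
        df=(float(res.dof),),
        p_value=float(res.pvalue),
        method="pearson chi-squared",
    )


def oneway_anova(groups: Sequence[Sequence[float]]) -> TestResult:
    """One-way fixed-effects ANOVA: F = MS_between / MS_within.

    With zero within-group variance everywhere, F is defined as 0 when the
    group means are also equal, and as +inf (degenerate flag) otherwise.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs >= 2 values")
    k = len(arrays)
    n_total = sum(a.size for a in arrays)
    grand = np.concatenate(arrays).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df1, df2 = k - 1, n_total - k
    if ss_within == 0.0:
        if np.isclose(ss_between, 0.0):
            return TestResult(0.0, (float(df1), float(df2)), 1.0, "one-way ANOVA")
        return TestResult(math.inf, (float(df1), float(df2)), 0.0,
                          "one-way ANOVA", degenerate=True)
    f = (ss_between / df1) / (ss_within / df2)
    p = float(stats.f.sf(f, df1, df2))
    return TestResult(float(f), (float(df1), float(df2)), p, "one-way ANOVA")


def _check_complete(data: pd.DataFrame, subject: str, within: str) -> list:
    levels = sorted(data[within].unique())
    counts = data.groupby([subject, within]).size().unstack(fill_value=0)
    bad = counts.index[(counts != 1).any(axis=1)].tolist()
    return bad


def mixed_anova(
    data: pd.DataFrame,
    dv: str,
    within: str,
    subject: str,
    between: str | None = None,
) -> dict[str, TestResult]:
    """Split-plot ANOVA with one within-subject and one between-subject factor.

    Expects long-format data with exactly one observation per subject x
    within level.  The between main effect is tested against
    subjects-within-groups; the within main effect and the interaction
    against the within x subjects residual.  Group sizes may differ between
    groups (weighted-means sums of squares, which are exactly orthogonal
    here because every subject contributes all within levels).  With
    ``between=None`` this reduces to a one-way repeated-measures ANOVA.
    """
    cols = [subject, within, dv] + ([between] if between else [])
    df = data.loc[:, cols].copy()
    bad = _check_complete(df, subject, within)
    if bad:
        raise ValueError(
            "subjects missing a within level or observed more than once: "
            + ", ".join(map(str, bad[:10]))
        )
    if between is None:
        between = "_group"
        df[between] = "all"
    groups_per_subject = df.groupby(subject)[between].nunique()
    if (groups_per_subject > 1).any():
        raise ValueError("each subject must belong to exactly one between group")

    w = df[within].nunique()
    n_subj = df[subject].nunique()
    k = df[between].nunique()
    grand = df[dv].mean()

    subj_means = df.groupby(subject)[dv].mean()
    subj_group = df.groupby(subject)[between].first()
    group_means = df.groupby(between)[dv].mean()
    level_means = df.groupby(within)[dv].mean()
    cell_means = df.groupby([between, within])[dv].mean()
    n_g = subj_group.value_counts()

    ss_total = float(((df[dv] - grand) ** 2).sum())
    ss_between = float(w * (n_g * (group_means - grand) ** 2).sum())
    ss_subj = float(
        w * ((subj_means - group_means.reindex(subj_group).set_axis(subj_means.index)) ** 2).sum()
    )
    ss_within = float(n_subj * ((level_means - grand) ** 2).sum())
    ss_inter = 0.0
    for (g, j), cm in cell_means.items():
        ss_inter += n_g[g] * (cm - group_means[g] - level_means[j] + grand) ** 2
    ss_inter = float(ss_inter)
    ss_err = max(ss_total - ss_between - ss_subj - ss_within - ss_inter, 0.0)

    df_b, df_s = k - 1, n_subj - k
    df_w = w - 1
    df_i = (k - 1) * (w - 1)
    df_e = (n_subj - k) * (w - 1)

    def _f(ss_num: float, df_num: int, ss_den: float, df_den: int, label: str) -> TestResult:
        if df_num == 0:
            return TestResult(math.nan, (0.0, float(df_den)), math.nan, label,
                              degenerate=True)
        ms_num = ss_num / df_num
        ms_den = ss_den / df_den if df_den > 0 else math.nan
        if not math.isfinite(ms_den) or ms_den == 0.0:
            if np.isclose(ms_num, 0.0):
                return TestResult(0.0, (float(df_num), float(df_den)), 1.0, label)
            return TestResult(math.inf, (float(df_num), float(df_den)), 0.0,
                              label, degenerate=True)
        f = ms_num / ms_den
        p = float(stats.f.sf(f, df_num, df_den))
        return TestResult(float(f), (float(df_num), float(df_den)), p, label)

    out = {
        "within": _f(ss_within, df_w, ss_err, df_e, "within main effect (split-plot)"),
    }
    if k > 1:
        out["between"] = _f(ss_between, df_b, ss_subj, df_s,
                            "between main effect (split-plot)")
        out["interaction"] = _f(ss_inter, df_i, ss_err, df_e,
                                "between x within interaction (split-plot)")
    out["_ss"] = {  # type: ignore[assignment]
        "between": ss_between, "subjects": ss_subj, "within": ss_within,
        "interaction": ss_inter, "error": ss_err, "total": ss_total,
    }
    return out


def repeated_measures_anova(
    data: pd.DataFrame, dv: str, within: str, subject: str
) -> TestResult:
    """One-way repeated-measures ANOVA (no between factor).

    With a two-level within factor over N subjects this is the F(1, N-1)
    layout; F equals the square of the paired t statistic.
    """
    return mixed_anova(data, dv=dv, within=within, subject=subject)["within"]
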