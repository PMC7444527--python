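"""End-to-end analysis: screen -> rates -> SDT -> inference -> report.

``run_full_analysis`` reproduces the study's reporting layout on any
canonical response table: accuracy/TPR/FPR by information source and by
prior label with volunteer-level bootstrap CIs, pooled d'/criterion per
label condition, per-item rating-shift tests, z-space ROC fits with Az per
condition and overall, and (when volunteer profiles are supplied) the trust
proportions and demographic blocking chi-squared tables.

All headline estimates are computed at the decision threshold theta = 0.5,
which separates responses expressing any confidence in "same person" from
the rest; the full threshold grid is always also emitted.  Pooled-rate SDT
is the default because individual volunteers routinely produce rates of 0
or 1 on 6+6 items, where d' is undefined; per-volunteer SDT with a
log-linear rate correction is available behind a flag.

Logs are structured and count-only: response contents never appear in logs,
since in real deployments these are human-subjects data.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from decimal import ROUND_HALF_EVEN, Decimal
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .inference import (
    BootstrapConfig,
    bootstrap_statistic,
    chi_squared_test,
    item_shift_summary,
    mixed_anova,
    oneway_anova,
    rank_sum_item_test,
    repeated_measures_anova,
)
from .sdt import (
    DEFAULT_THRESHOLDS,
    corrected_rate,
    dprime_criterion,
    fit_roc_zspace,
    rates_at_threshold,
    threshold_sweep,
    validate_grid,
)
from .survey_io import (
    CatchRule,
    read_response_table,
    read_volunteer_table,
    screen_catch_trials,
    summarize_design,
)

__all__ = ["AnalysisConfig", "AnalysisReport", "run_full_analysis", "render_report"]

logger = logging.getLogger("labelbias")

_SOURCE_NAMES = {"control": "none", "human_source": "human", "computer_source": "computer"}


@dataclasses.dataclass
class AnalysisConfig:
    """Configuration of the full pipeline run."""

    threshold_grid: tuple[float, ...] = DEFAULT_THRESHOLDS
    headline_threshold: float = 0.5
    n_boot: int = 2000
    level: float = 0.95
    seed: int = 0
    catch_rule: CatchRule = dataclasses.field(default_factory=CatchRule)
    include_control_in_overall_roc: bool = True
    per_subject_sdt: bool = False
    rate_correction: str = "log_linear"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        self.threshold_grid = validate_grid(self.threshold_grid)
        if self.headline_threshold not in self.threshold_grid:
            raise ValueError(
                f"headline threshold {self.headline_threshold} not in grid "
                f"{self.threshold_grid}"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["threshold_grid"] = list(d["threshold_grid"])
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        d = dict(d)
        if "threshold_grid" in d:
            d["threshold_grid"] = tuple(d["threshold_grid"])
        if isinstance(d.get("catch_rule"), Mapping):
            d["catch_rule"] = CatchRule(**d["catch_rule"])
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclasses.dataclass
class AnalysisReport:
    tables: dict[str, pd.DataFrame]
    metadata: dict
    warnings: list[str]


# ---------------------------------------------------------------------------
# helpers


def _per_volunteer_rates(records: pd.DataFrame, theta: float) -> pd.DataFrame:
    """Per-volunteer ACC/TPR/FPR at one threshold (raw proportions)."""
    df = records.copy()
    df["decide_same"] = df["rating"] > theta
    df["hit"] = (df["truth"] == "same") & df["decide_same"]
    df["fa"] = (df["truth"] == "different") & df["decide_same"]
    df["is_same"] = df["truth"] == "same"
    g = df.groupby("volunteer_id", sort=True)
    out = pd.DataFrame(
        {
            "n_same": g["is_same"].sum(),
            "n_diff": g["is_same"].count() - g["is_same"].sum(),
            "hits": g["hit"].sum(),
            "fas": g["fa"].sum(),
        }
    )
    out["tpr"] = out["hits"] / out["n_same"]
    out["fpr"] = out["fas"] / out["n_diff"]
    correct = (out["hits"] + (out["n_diff"] - out["fas"]))
    out["acc"] = correct / (out["n_same"] + out["n_diff"])
    return out.reset_index()


def _pooled_metric(metric: str, theta: float) -> Callable[[pd.DataFrame], float]:
    def stat(df: pd.DataFrame) -> float:
        point = rates_at_threshold(df, theta)
        return getattr(point, metric)

    return stat


def _sdt_metric(metric: str, theta: float) -> Callable[[pd.DataFrame], float]:
    def stat(df: pd.DataFrame) -> float:
        point = rates_at_threshold(df, theta)
        summary = dprime_criterion(point.tpr, point.fpr)
        return getattr(summary, metric)

    return stat


def _prior_subsets(kept: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Label conditions: none (control), told-same, told-different."""
    return {
        "none": kept[kept["variant"] == "control"],
        "same": kept[kept["prior_label"] == "same"],
        "different": kept[kept["prior_label"] == "different"],
    }


def _holm(pvals: Sequence[float]) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    if len(pvals) == 0:
        return np.array([])
    return multipletests(pvals, method="holm")[1]


# ---------------------------------------------------------------------------
# main entry point


def run_full_analysis(
    responses: pd.DataFrame | str | Path,
    volunteers: pd.DataFrame | str | Path | None = None,
    config: AnalysisConfig | None = None,
) -> AnalysisReport:
    """Execute the complete analysis and return all report tables.

    Deterministic for fixed (input, config): every bootstrap draws its seed
    from a spawn of ``config.seed`` in a fixed order.
    """
    cfg = config or AnalysisConfig()
    if not isinstance(responses, pd.DataFrame):
        responses = read_response_table(responses)
    if volunteers is not None and not isinstance(volunteers, pd.DataFrame):
        volunteers = read_volunteer_table(volunteers)

    logger.info("stage=read records=%d volunteers=%d", len(responses),
                responses["volunteer_id"].nunique())

    screening = screen_catch_trials(responses, cfg.catch_rule)
    kept = screening.kept
    logger.info("stage=screen kept_volunteers=%d excluded=%d",
                kept["volunteer_id"].nunique(), len(screening.excluded_volunteers))
    if kept.empty:
        raise ValueError("screening removed every volunteer; nothing to analyse")

    design = summarize_design(responses)
    theta = cfg.headline_threshold
    seed_stream = iter(np.random.SeedSequence(cfg.seed).spawn(512))

    def boot(df: pd.DataFrame, stat: Callable[[pd.DataFrame], float]):
        bc = BootstrapConfig(n_boot=cfg.n_boot, seed=next(seed_stream),
                             level=cfg.level)
        return bootstrap_statistic(df, stat, bc)

    tables: dict[str, pd.DataFrame] = {}
    warnings_out = list(screening.warnings)

    tables["exclusions"] = screening.report()
    tables["design_summary"] = design.as_frame()

    # -- rates by information source (variant) -----------------------------
    rows = []
    source_groups: dict[str, pd.DataFrame] = {}
    for variant in ("control", "human_source", "computer_source"):
        sub = kept[kept["variant"] == variant]
        if sub.empty:
            continue
        source_groups[variant] = sub
        row = {"source": _SOURCE_NAMES[variant],
               "n": sub["volunteer_id"].nunique()}
        for metric in ("acc", "fpr", "tpr"):
            res = boot(sub, _pooled_metric(metric, theta))
            row[metric] = res.estimate
            row[f"{metric}_lo"] = res.ci_low
            row[f"{metric}_hi"] = res.ci_high
        rows.append(row)
    tables["table4_rates_by_source"] = pd.DataFrame(rows)
    logger.info("stage=rates_by_source groups=%d", len(rows))

    # -- rates by prior label ----------------------------------------------
    priors = _prior_subsets(kept)
    rows = []
    for label, sub in priors.items():
        if sub.empty:
            continue
        row = {"prior": label, "n": sub["volunteer_id"].nunique()}
        for metric in ("acc", "fpr", "tpr"):
            res = boot(sub, _pooled_metric(metric, theta))
            row[metric] = res.estimate
            row[f"{metric}_lo"] = res.ci_low
            row[f"{metric}_hi"] = res.ci_high
        rows.append(row)
    tables["table5_rates_by_prior"] = pd.DataFrame(rows)

    # -- pooled SDT per prior condition ------------------------------------
    rows = []
    for label, sub in priors.items():
        if sub.empty:
            continue
        point = rates_at_threshold(sub, theta)
        summary = dprime_criterion(point.tpr, point.fpr, condition=label)
        row = {"prior": label, "n": sub["volunteer_id"].nunique(),
               "tpr": point.tpr, "fpr": point.fpr}
        for metric in ("dprime", "criterion"):
            res = boot(sub, _sdt_metric(metric, theta))
            row[metric] = getattr(summary, metric)
            row[f"{metric}_lo"] = res.ci_low
            row[f"{metric}_hi"] = res.ci_high
        rows.append(row)
    tables["table6_sdt"] = pd.DataFrame(rows)
    logger.info("stage=sdt conditions=%d", len(rows))

    # -- ANOVA layer ---------------------------------------------------------
    anova_rows = []
    pv_by_variant = {
        v: _per_volunteer_rates(sub, theta) for v, sub in source_groups.items()
    }
    for metric in ("acc", "fpr", "tpr"):
        groups = [t[metric].to_numpy() for t in pv_by_variant.values()
                  if len(t) >= 2]
        if len(groups) >= 2:
            res = oneway_anova(groups)
            anova_rows.append(
                {"effect": "source", "metric": metric, "F": res.statistic,
                 "df1": res.df[0], "df2": res.df[1], "p": res.p_value,
                 "layout": "one-way between volunteers"}
            )

    sourced = kept[(kept["variant"] != "control") & (kept["prior_label"] != "none")]
    if not sourced.empty:
        per_label = []
        for label in ("same", "different"):
            t = _per_volunteer_rates(sourced[sourced["prior_label"] == label], theta)
            t["prior_label"] = label
            per_label.append(t)
        long = pd.concat(per_label, ignore_index=True)
        variant_of = sourced.groupby("volunteer_id")["variant"].first()
        long["variant"] = long["volunteer_id"].map(variant_of)
        complete = long.groupby("volunteer_id")["prior_label"].nunique()
        keep_ids = complete[complete == 2].index
        long = long[long["volunteer_id"].isin(keep_ids)]
        for metric in ("acc", "fpr", "tpr"):
            rm = repeated_measures_anova(long, dv=metric, within="prior_label",
                                         subject="volunteer_id")
            anova_rows.append(
                {"effect": "prior_label", "metric": metric, "F": rm.statistic,
                 "df1": rm.df[0], "df2": rm.df[1], "p": rm.p_value,
                 "layout": "repeated measures, subjects pooled across sources"}
            )
            mixed = mixed_anova(long, dv=metric, within="prior_label",
                                subject="volunteer_id", between="variant")
            for eff in ("between", "within", "interaction"):
                if eff not in mixed:
                    continue
                r = mixed[eff]
                anova_rows.append(
                    {"effect": {"between": "source", "within": "prior_label",
                                "interaction": "source x prior_label"}[eff],
                     "metric": metric, "F": r.statistic, "df1": r.df[0],
                     "df2": r.df[1], "p": r.p_value,
                     "layout": "split-plot (source between, label within)"}
                )
    tables["anova"] = pd.DataFrame(anova_rows)

    # -- per-item shift tests ------------------------------------------------
    item_rows = []
    if not sourced.empty:
        for item_id, sub in sourced.groupby("item_id", sort=True):
            a = sub.loc[sub["prior_label"] == "same", "rating"].to_numpy()
            b = sub.loc[sub["prior_label"] == "different", "rating"].to_numpy()
            if a.size == 0 or b.size == 0:
                continue
            res = rank_sum_item_test(a, b)
            item_rows.append(
                {"item_id": item_id, "truth": sub["truth"].iloc[0],
                 "n_same_label": a.size, "n_diff_label": b.size,
                 "mean_same_label": a.mean(), "mean_diff_label": b.mean(),
                 "shift": a.mean() - b.mean(),
                 "statistic": res.statistic, "p": res.p_value}
            )
    items_df = pd.DataFrame(item_rows)
    if not items_df.empty:
        items_df["significant"] = items_df["p"] < cfg.alpha
        items_df["p_holm"] = _holm(items_df["p"].tolist())
        shift = item_shift_summary(
            list(zip(items_df["mean_same_label"], items_df["mean_diff_label"]))
        )
        tables["fig4_shift_summary"] = pd.DataFrame(
            [{"mean_shift": shift.effect["mean_shift"], "t": shift.statistic,
              "df": shift.df[0], "p": shift.p_value,
              "n_items": len(items_df),
              "n_significant": int(items_df["significant"].sum())}]
        )
    tables["fig4_item_tests"] = items_df
    logger.info("stage=item_tests items=%d", len(items_df))

    # -- ROC sweeps and z-space fits ------------------------------------------
    roc_rows, fit_rows = [], []
    roc_conditions = dict(priors)
    overall = kept if cfg.include_control_in_overall_roc else sourced
    roc_conditions["overall"] = overall
    for label, sub in roc_conditions.items():
        if sub.empty:
            continue
        points = threshold_sweep(sub, cfg.threshold_grid)
        for p in points:
            roc_rows.append(
                {"condition": label, "theta": p.theta, "fpr": p.fpr,
                 "tpr": p.tpr, "acc": p.acc, "n": p.n, "m": p.m}
            )
        try:
            fit = fit_roc_zspace(points)
        except ValueError as exc:
            warnings_out.append(f"ROC fit skipped for condition {label!r}: {exc}")
            continue
        fit_rows.append(
            {"condition": label, "intercept": fit.intercept, "slope": fit.slope,
             "az": fit.az, "n_points": len(fit.points),
             "improper": fit.improper}
        )
    tables["fig5_roc"] = pd.DataFrame(roc_rows)
    tables["fig5_roc_fit"] = pd.DataFrame(fit_rows)

    # -- optional per-subject SDT ---------------------------------------------
    if cfg.per_subject_sdt:
        pv = _per_volunteer_rates(kept, theta)
        rows = []
        for _, r in pv.iterrows():
            tpr = corrected_rate(int(r["hits"]), int(r["n_same"]), cfg.rate_correction)
            fpr = corrected_rate(int(r["fas"]), int(r["n_diff"]), cfg.rate_correction)
            s = dprime_criterion(tpr, fpr)
            rows.append({"volunteer_id": r["volunteer_id"], "tpr": tpr,
                         "fpr": fpr, "dprime": s.dprime, "criterion": s.criterion})
        tables["per_subject_sdt"] = pd.DataFrame(rows)

    # -- trust and blocking (require profiles) --------------------------------
    if volunteers is not None:
        prof = volunteers[volunteers["volunteer_id"].isin(kept["volunteer_id"])]
        variant_of = kept.groupby("volunteer_id")["variant"].first()
        prof = prof.assign(variant=prof["volunteer_id"].map(variant_of))

        trust_rows, yes_counts, no_counts, totals = [], [], [], []
        for variant in ("control", "human_source", "computer_source"):
            sub = prof[(prof["variant"] == variant)
                       & (prof["trust_response"] != "missing")]
            if sub.empty:
                continue
            n = len(sub)
            n_yes = int((sub["trust_response"] == "yes").sum())
            n_no = int((sub["trust_response"] == "no").sum())
            trust_rows.append(
                {"source": _SOURCE_NAMES[variant], "n": n,
                 "p_yes": n_yes / n, "p_no": n_no / n,
                 "p_not_sure": (n - n_yes - n_no) / n}
            )
            yes_counts.append(n_yes)
            no_counts.append(n_no)
            totals.append(n)
        tables["trust"] = pd.DataFrame(trust_rows)
        test_rows = []
        if len(totals) >= 2:
            for name, counts in (("yes", yes_counts), ("no", no_counts)):
                table = [counts, [t - c for t, c in zip(totals, counts)]]
                res = chi_squared_test(table)
                test_rows.append({"response": name, "chi2": res.statistic,
                                  "df": res.df[0], "p": res.p_value})
        tables["trust_tests"] = pd.DataFrame(test_rows)

        block_rows = []
        demo = prof[prof["variant"].notna()]
        for field in ("gender", "age_bin", "race"):
            sub = demo[demo[field] != "missing"]
            counts = pd.crosstab(sub[field], sub["variant"])
            if counts.shape[0] < 2 or counts.shape[1] < 2:
                continue
            res = chi_squared_test(counts.to_numpy())
            block_rows.append({"demographic": field, "chi2": res.statistic,
                               "df": res.df[0], "p": res.p_value,
                               "balanced": res.p_value >= cfg.alpha})
        tables["table2_blocking"] = pd.DataFrame(block_rows)

    metadata = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "counts": {
            "records_read": int(len(responses)),
            "volunteers_read": int(responses["volunteer_id"].nunique()),
            "volunteers_excluded": len(screening.excluded_volunteers),
            "volunteers_analyzed": int(kept["volunteer_id"].nunique()),
            "records_analyzed": int(len(kept)),
        },
    }
    logger.info("stage=done tables=%d", len(tables))
    return AnalysisReport(tables=tables, metadata=metadata,
                          warnings=warnings_out)


# ---------------------------------------------------------------------------
# rendering


def _present(value) -> str:
    """Round-half-even presentation at 2 decimals (e.g. 0.0458 -> '0.05')."""
    if isinstance(value, (bool, np.bool_)):
        return str(bool(value))
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    if isinstance(value, (float, np.floating)):
        if not np.isfinite(value):
            return str(value)
        return str(Decimal(repr(float(value))).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_EVEN))
    return str(value)


def render_report(
    report: AnalysisReport,
    outdir: str | Path,
    formats: Sequence[str] = ("csv", "json"),
) -> list[Path]:
    """Write one file per report section plus metadata.

    Full-precision CSVs are canonical; a ``*_presentation.csv`` copy rounds
    numbers to two decimals (round-half-even) in the style of the published
    tables.  The output directory is verified writable before any file is
    created, so partial reports are never left behind silently.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    probe = outdir / ".write_probe"
    try:
        probe.write_text("")
        probe.unlink()
    except OSError as exc:  # pragma: no cover - environment dependent
        raise OSError(f"output directory {outdir} is not writable: {exc}") from exc

    written: list[Path] = []
    sections = dict(sorted(report.tables.items()))
    if "csv" in formats:
        for name, table in sections.items():
            path = outdir / f"{name}.csv"
            table.to_csv(path, index=False, lineterminator="\n",
                         float_format="%.17g")
            written.append(path)
            pres = table.copy()
            for col in pres.columns:
                pres[col] = [_present(v) for v in pres[col]]
            ppath = outdir / f"{name}_presentation.csv"
            pres.to_csv(ppath, index=False, lineterminator="\n")
            written.append(ppath)
    if "json" in formats:
        payload = {
            name: json.loads(table.to_json(orient="records", double_precision=15))
            for name, table in sections.items()
        }
        path = outdir / "report.json"
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
        written.append(path)
    meta_path = outdir / "metadata.json"
    meta_path.write_text(json.dumps(report.metadata, indent=1, sort_keys=True))
    written.append(meta_path)
    if report.warnings:
        wpath = outdir / "warnings.txt"
        wpath.write_text("\n".join(report.warnings) + "\n")
        written.append(wpath)
    return written
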