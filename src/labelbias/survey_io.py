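"""Reading, validation, and screening of face-matching survey response tables.

The canonical interchange format is a long-format, UTF-8, comma-separated
CSV with a header row and one row per volunteer x face pair:

``volunteer_id,variant,version,item_id,truth,prior_label,rating,is_catch``

* ``variant`` is the survey condition a volunteer was assigned to:
  ``control`` (no prior identity information), ``human_source`` or
  ``computer_source`` (a prior "same person" / "different people" decision
  attributed to a human or an algorithm).
* ``version`` counterbalances which label each face pair carries within a
  sourced variant (``1`` or ``2``; ``none`` for the control variant).
* ``truth`` is the ground-truth mated status of the pair (``same`` /
  ``different``), ``prior_label`` is the label shown to the volunteer
  (``none`` in the control variant and on catch trials).
* ``rating`` is the 7-point graded certainty response, an integer in
  [-3, +3] where +3 means "absolutely certain this is the same person" and
  -3 "absolutely certain these are different people".
* ``is_catch`` marks celebrity screening pairs, which are used only to
  screen out non-compliant volunteers and are never analysed further.

In memory the collection of responses is a :class:`pandas.DataFrame` with
exactly these columns; all functions in this package accept and return that
frame.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RESPONSE_COLUMNS",
    "VOLUNTEER_COLUMNS",
    "VARIANTS",
    "TRUTHS",
    "PRIOR_LABELS",
    "VERSIONS",
    "AGE_BINS",
    "TRUST_RESPONSES",
    "SchemaError",
    "ValidationError",
    "CatchRule",
    "ScreeningResult",
    "DesignSummary",
    "read_response_table",
    "write_response_table",
    "read_volunteer_table",
    "write_volunteer_table",
    "validate_responses",
    "screen_catch_trials",
    "summarize_design",
    "write_exclusion_report",
]

RESPONSE_COLUMNS = (
    "volunteer_id",
    "variant",
    "version",
    "item_id",
    "truth",
    "prior_label",
    "rating",
    "is_catch",
)
VOLUNTEER_COLUMNS = ("volunteer_id", "gender", "age_bin", "race", "trust_response")

VARIANTS = ("control", "human_source", "computer_source")
TRUTHS = ("same", "different")
PRIOR_LABELS = ("none", "same", "different")
VERSIONS = ("1", "2", "none")
AGE_BINS = ("18-25", "26-35", "36-45", "46-55", "56-65", "65+")
TRUST_RESPONSES = ("yes", "no", "not_sure", "missing")

_BOOL_MAP = {
    "true": True,
    "false": False,
    "1": True,
    "0": False,
    "True": True,
    "False": False,
}


class SchemaError(ValueError):
    """A required column is missing or the file cannot be interpreted."""


class ValidationError(ValueError):
    """One or more rows violate the response-table contract."""


def _fail(messages: list[str], limit: int = 25) -> None:
    if messages:
        shown = messages[:limit]
        if len(messages) > limit:
            shown.append(f"... and {len(messages) - limit} more")
        raise ValidationError("\n".join(shown))


def validate_responses(records: pd.DataFrame) -> pd.DataFrame:
    """Validate a typed response frame and return it with canonical dtypes.

    Checks column presence, enum membership, the rating range, the
    variant/label consistency rules, and uniqueness of volunteer x item
    within a (variant, version) cell.  Raises :class:`SchemaError` or
    :class:`ValidationError`; error messages carry 0-based row positions.
    """
    missing = [c for c in RESPONSE_COLUMNS if c not in records.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    df = records.loc[:, list(RESPONSE_COLUMNS)].copy()
    df = df.reset_index(drop=True)
    errors: list[str] = []

    rating = pd.to_numeric(df["rating"], errors="coerce")
    bad = rating.isna() | (rating != np.floor(rating)) | (rating < -3) | (rating > 3)
    for pos in df.index[bad]:
        errors.append(
            f"row {pos}: rating {df.at[pos, 'rating']!r} is not an integer in [-3, 3]"
        )

    for col, allowed in (
        ("variant", VARIANTS),
        ("truth", TRUTHS),
        ("prior_label", PRIOR_LABELS),
    ):
        vals = df[col].astype(str)
        bad = ~vals.isin(allowed)
        for pos in df.index[bad]:
            errors.append(
                f"row {pos}: unknown {col} value {df.at[pos, col]!r} "
                f"(allowed: {', '.join(allowed)})"
            )
        df[col] = vals

    version = df["version"].astype(str)
    bad = ~version.isin(VERSIONS)
    for pos in df.index[bad]:
        errors.append(f"row {pos}: unknown version value {df.at[pos, 'version']!r}")
    df["version"] = version

    if df["is_catch"].dtype != bool:
        catch = df["is_catch"].astype(str).map(_BOOL_MAP)
        for pos in df.index[catch.isna()]:
            errors.append(
                f"row {pos}: is_catch value {df.at[pos, 'is_catch']!r} is not boolean"
            )
        df["is_catch"] = catch.fillna(False).astype(bool)

    _fail(errors)

    df["rating"] = rating.astype(np.int64)
    df["volunteer_id"] = df["volunteer_id"].astype(str)
    df["item_id"] = df["item_id"].astype(str)

    # variant/label consistency: the control variant and all catch trials
    # carry no prior label; experimental items in sourced variants carry one.
    is_control = df["variant"] == "control"
    bad = is_control & (df["prior_label"] != "none")
    for pos in df.index[bad]:
        errors.append(f"row {pos}: control-variant response must have prior_label 'none'")
    bad = df["is_catch"] & (df["prior_label"] != "none")
    for pos in df.index[bad]:
        errors.append(f"row {pos}: catch trial must have prior_label 'none'")
    bad = ~is_control & ~df["is_catch"] & (df["prior_label"] == "none")
    for pos in df.index[bad]:
        errors.append(
            f"row {pos}: sourced-variant experimental response must carry a prior label"
        )
    bad = is_control & (df["version"] != "none")
    for pos in df.index[bad]:
        errors.append(f"row {pos}: control-variant response must have version 'none'")

    dup = df.duplicated(subset=["volunteer_id", "variant", "version", "item_id"], keep=False)
    if dup.any():
        pairs = df.loc[dup, ["volunteer_id", "item_id"]].drop_duplicates()
        for _, row in pairs.iterrows():
            errors.append(
                f"duplicate response for volunteer {row.volunteer_id!r} "
                f"item {row.item_id!r}"
            )

    _fail(errors)
    return df


def read_response_table(path: str | Path, *, delimiter: str = ",") -> pd.DataFrame:
    """Read and validate a long-format response CSV.

    Row order is preserved.  Unparseable or invalid rows are reported with
    their position (0-based data-row index; add 2 for the physical file line
    given the header).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    return validate_responses(raw)


def write_response_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write the canonical CSV form (fixed column order, 'true'/'false' flags)."""
    df = validate_responses(records).copy()
    df["is_catch"] = np.where(df["is_catch"], "true", "false")
    df.to_csv(path, index=False, lineterminator="\n")


def read_volunteer_table(path: str | Path) -> pd.DataFrame:
    """Read a volunteer profile CSV (demographics + trust response).

    Missing demographic fields are permitted and normalised to ``missing``;
    such volunteers are retained for detection-theory analyses and dropped
    only from demographic tables.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in VOLUNTEER_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    df = raw.loc[:, list(VOLUNTEER_COLUMNS)].copy().reset_index(drop=True)
    for col in ("gender", "age_bin", "race", "trust_response"):
        df[col] = df[col].astype(str).str.strip().replace("", "missing")
    errors: list[str] = []
    bad = ~df["trust_response"].isin(TRUST_RESPONSES)
    for pos in df.index[bad]:
        errors.append(
            f"row {pos}: unknown trust_response {df.at[pos, 'trust_response']!r}"
        )
    bad = ~df["age_bin"].isin(AGE_BINS + ("missing",))
    for pos in df.index[bad]:
        errors.append(f"row {pos}: unknown age_bin {df.at[pos, 'age_bin']!r}")
    if df["volunteer_id"].duplicated().any():
        dups = df.loc[df["volunteer_id"].duplicated(), "volunteer_id"].unique()
        errors.append(f"duplicate volunteer_id(s): {', '.join(map(str, dups))}")
    _fail(errors)
    return df


def write_volunteer_table(profiles: pd.DataFrame, path: str | Path) -> None:
    profiles.loc[:, list(VOLUNTEER_COLUMNS)].to_csv(path, index=False, lineterminator="\n")


@dataclasses.dataclass(frozen=True)
class CatchRule:
    """Correctness rule for celebrity screening (catch) trials.

    A catch response is correct when the sign of the rating matches the
    ground truth and the volunteer expressed at least ``min_confidence``
    certainty.  With the default of 1, a "not sure" (0) response counts as a
    failure: catch pairs are chosen to be easy, so an unsure answer signals
    non-compliance or a perception problem.  Set ``min_confidence`` to 0 and
    ``fail_on_unsure`` to False to accept any response whose sign does not
    contradict the truth.
    """

    min_confidence: int = 1
    fail_on_unsure: bool = True

    def is_correct(self, truth: str, rating: int) -> bool:
        if rating == 0:
            return not self.fail_on_unsure
        if truth == "same":
            return rating >= self.min_confidence
        return rating <= -self.min_confidence


@dataclasses.dataclass
class ScreeningResult:
    """Outcome of catch-trial screening.

    ``kept`` contains only experimental (non-catch) responses from retained
    volunteers; exclusion is volunteer-level, so no volunteer appears both in
    ``kept`` and in ``excluded_volunteers``.
    """

    kept: pd.DataFrame
    excluded_volunteers: list[str]
    reasons: dict[str, str]
    warnings: list[str]

    def report(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "volunteer_id": list(self.excluded_volunteers),
                "reason": [self.reasons[v] for v in self.excluded_volunteers],
            }
        )


def screen_catch_trials(
    records: pd.DataFrame, rule: CatchRule | None = None
) -> ScreeningResult:
    """Exclude volunteers who failed any celebrity catch trial.

    A volunteer is excluded iff at least one of their catch-trial responses
    violates ``rule``.  Catch trials themselves are dropped from the kept
    set (they are screening devices, not stimuli under analysis).  Volunteers
    with no catch trials cannot be screened; they are retained and reported
    in ``warnings``.  Screening is idempotent: re-screening an
    already-screened set excludes no one further.
    """
    if records.empty:
        raise ValidationError("cannot screen an empty response table")
    rule = rule or CatchRule()
    df = validate_responses(records)

    catch = df[df["is_catch"]]
    all_volunteers = df["volunteer_id"].unique()
    warnings = [
        f"volunteer {v!r} has no catch trials and cannot be screened; retained"
        for v in sorted(set(all_volunteers) - set(catch["volunteer_id"]))
    ]

    reasons: dict[str, str] = {}
    if not catch.empty:
        ok = np.array(
            [rule.is_correct(t, r) for t, r in zip(catch["truth"], catch["rating"])]
        )
        for _, row in catch[~ok].iterrows():
            vid = row["volunteer_id"]
            reason = (
                f"catch trial {row['item_id']} (truth={row['truth']}) "
                f"rated {row['rating']:+d}"
            )
            reasons.setdefault(vid, reason)

    excluded = sorted(reasons)
    kept = df[~df["is_catch"] & ~df["volunteer_id"].isin(excluded)].reset_index(drop=True)
    return ScreeningResult(kept, excluded, reasons, warnings)


def write_exclusion_report(result: ScreeningResult, path: str | Path) -> None:
    result.report().to_csv(path, index=False, lineterminator="\n")


@dataclasses.dataclass
class DesignSummary:
    """Structural summary of a response table against the intended design:
    three survey variants, experimental pairs balanced same/different, and
    each pair shown under both labels across the two survey versions within
    each sourced variant."""

    volunteers_per_variant: dict[str, int]
    n_same_items: int
    n_diff_items: int
    truth_balanced: bool
    item_label_coverage: pd.DataFrame
    counterbalanced: bool
    n_catch_items: int

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"field": f"volunteers[{k}]", "value": v}
            for k, v in sorted(self.volunteers_per_variant.items())
        ]
        rows += [
            {"field": "n_same_items", "value": self.n_same_items},
            {"field": "n_diff_items", "value": self.n_diff_items},
            {"field": "n_catch_items", "value": self.n_catch_items},
            {"field": "truth_balanced", "value": self.truth_balanced},
            {"field": "counterbalanced", "value": self.counterbalanced},
        ]
        return pd.DataFrame(rows)


def summarize_design(records: pd.DataFrame) -> DesignSummary:
    """Report volunteer counts, item balance, and label counterbalancing.

    Imbalances are reported as flags, never raised as errors: the summary is
    a diagnostic, and real screening losses (unequal variant sizes) are
    expected.
    """
    df = validate_responses(records)
    per_variant = (
        df.groupby("variant")["volunteer_id"].nunique().to_dict()
    )
    exp = df[~df["is_catch"]]
    items_same = exp.loc[exp["truth"] == "same", "item_id"].nunique()
    items_diff = exp.loc[exp["truth"] == "different", "item_id"].nunique()

    sourced = exp[exp["variant"] != "control"]
    if sourced.empty:
        coverage = pd.DataFrame(
            columns=["item_id", "n_same_label", "n_diff_label", "counterbalanced"]
        )
    else:
        counts = (
            sourced.groupby(["item_id", "prior_label"]).size().unstack(fill_value=0)
        )
        coverage = pd.DataFrame(
            {
                "item_id": counts.index,
                "n_same_label": counts.get("same", pd.Series(0, index=counts.index)),
                "n_diff_label": counts.get(
                    "different", pd.Series(0, index=counts.index)
                ),
            }
        ).reset_index(drop=True)
        coverage["counterbalanced"] = (coverage["n_same_label"] > 0) & (
            coverage["n_diff_label"] > 0
        )

    return DesignSummary(
        volunteers_per_variant=per_variant,
        n_same_items=items_same,
        n_diff_items=items_diff,
        truth_balanced=items_same == items_diff,
        item_label_coverage=coverage,
        counterbalanced=bool(coverage["counterbalanced"].all())
        if len(coverage)
        else False,
        n_catch_items=df.loc[df["is_catch"], "item_id"].nunique(),
    )
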