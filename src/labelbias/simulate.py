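"""Synthetic survey generator: equal-variance Gaussian raters on a 7-point scale.

The generative model mirrors the structure the analysis assumes.  Each
volunteer v has a sensitivity d'_v drawn from a Normal(mu_dprime,
sigma_dprime^2) truncated at zero (a screened population does not contain
systematically anti-correlated raters).  Viewing a face pair produces latent
similarity evidence e ~ Normal(d'_v, 1) for mated pairs and Normal(0, 1)
for non-mated pairs.  Six strictly increasing category boundaries map the
evidence to the 7-point certainty rating: the rating is -3 plus the number
of boundaries strictly below e.

A prior identity label shifts all six boundaries rigidly: -delta/2 when the
volunteer is told "same person" (making "same" responses easier) and
+delta/2 when told "different people".  Because the shift acts on the
boundaries and never on the evidence, sensitivity is untouched by
construction — the generator realises the hypothesis that labels move the
decision criterion only.

The survey design is the three-variant, two-version layout: a control
variant with no labels plus human-source and computer-source variants in
which each experimental pair appears under the "same" label in one version
and the "different" label in the other.  Celebrity catch pairs use a large
latent separation so that compliant simulated volunteers nearly always pass
screening; a configurable fraction of volunteers is planted with a catch
failure to exercise the screening stage.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .survey_io import RESPONSE_COLUMNS, validate_responses

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_raters",
    "simulate_survey",
    "simulate_profiles",
    "fixture_small",
    "boundaries_for_criterion",
]

_BOUNDARY_OFFSETS = np.array([-2.5, -1.5, -0.5, 0.5, 1.5, 2.5])

#: Trust-question response probabilities per variant (yes, no, not_sure),
#: matching the reported study proportions: most people trust themselves,
#: fewer trust computers, and humans are the most distrusted source.
_TRUST_PROBS: Mapping[str, tuple[float, float, float]] = {
    "control": (0.73, 0.09, 0.18),
    "computer_source": (0.56, 0.08, 0.36),
    "human_source": (0.53, 0.18, 0.29),
}
_GENDER = (("female", 0.5), ("male", 0.5))
_AGE = (("18-25", 0.06), ("26-35", 0.33), ("36-45", 0.20), ("46-55", 0.20),
        ("56-65", 0.16), ("65+", 0.05))
_RACE = (("black", 0.47), ("white", 0.38), ("other", 0.15))


@dataclasses.dataclass
class SimConfig:
    """Generative parameters of the synthetic survey.

    Defaults emulate the study conditions: ~120 volunteers per variant, 12
    experimental pairs balanced 6 mated / 6 non-mated, 2 celebrity catch
    pairs, population sensitivity around 1.4 with moderate between-rater
    spread, and a label-induced criterion shift delta of 0.22 latent units
    (the criterion gap the pooled analysis is designed to detect).

    ``boundaries`` overrides the rating-category boundaries explicitly;
    otherwise they are placed symmetrically around the midpoint
    mu_dprime / 2 with ``boundary_spacing`` latent units between adjacent
    boundaries.
    """

    n_volunteers_per_variant: int = 120
    n_same_items: int = 6
    n_diff_items: int = 6
    n_catch: int = 2
    mu_dprime: float = 1.4
    sigma_dprime: float = 0.3
    boundary_spacing: float = 0.5
    boundaries: tuple[float, ...] | None = None
    delta: float = 0.22
    catch_separation: float = 6.0
    catch_fail_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_volunteers_per_variant, self.n_same_items, self.n_diff_items) < 1:
            raise ValueError("volunteer and item counts must be positive")
        if self.n_catch < 0:
            raise ValueError("n_catch must be >= 0")
        if self.sigma_dprime < 0:
            raise ValueError("sigma_dprime must be >= 0")
        if self.sigma_dprime == 0 and self.mu_dprime <= 0:
            raise ValueError("mu_dprime must be positive when sigma_dprime is 0")
        if not 0.0 <= self.catch_fail_rate <= 1.0:
            raise ValueError("catch_fail_rate must lie in [0, 1]")
        if self.boundary_spacing <= 0:
            raise ValueError("boundary_spacing must be positive")
        b = self.resolved_boundaries()
        if len(b) != 6 or np.any(np.diff(b) <= 0):
            raise ValueError("boundaries must be 6 strictly increasing values")

    def resolved_boundaries(self) -> np.ndarray:
        if self.boundaries is not None:
            return np.asarray(self.boundaries, dtype=float)
        return self.mu_dprime / 2.0 + self.boundary_spacing * _BOUNDARY_OFFSETS

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["boundaries"] is not None:
            d["boundaries"] = list(d["boundaries"])
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if d.get("boundaries") is not None:
            d["boundaries"] = tuple(d["boundaries"])
        return cls(**d)


def boundaries_for_criterion(
    dprime: float, criterion: float, spacing: float = 0.5
) -> tuple[float, ...]:
    """Category boundaries that place the headline criterion exactly.

    The decision threshold theta = 0.5 corresponds to the boundary between
    ratings 0 and +1 (the fourth of six).  For unit-variance evidence with
    separation d', a latent cut at t yields criterion c = t - d'/2, so the
    fourth boundary is placed at d'/2 + criterion and the rest extend with
    the given spacing.
    """
    b4 = dprime / 2.0 + criterion
    return tuple(b4 + spacing * np.array([-3.0, -2.0, -1.0, 0.0, 1.0, 2.0]))


@dataclasses.dataclass
class GroundTruth:
    """Generating parameters realised for one simulated survey.

    ``volunteers`` holds one row per volunteer (id, variant, version,
    dprime, catch_fail).  Responses are regenerable bit-identically from the
    stored config, whose seed drives both the rater draw and the response
    draw through independent child streams.
    """

    volunteers: pd.DataFrame
    config: SimConfig

    def effective_criteria(self) -> dict[str, float]:
        """Headline (theta = 0.5) criterion implied per label condition."""
        b4 = float(self.config.resolved_boundaries()[3])
        base = b4 - self.config.mu_dprime / 2.0
        d = self.config.delta
        return {"none": base, "same": base - d / 2.0, "different": base + d / 2.0}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": self.config.to_dict(),
            "effective_criteria": self.effective_criteria(),
            "volunteers": self.volunteers.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _streams(seed: int) -> list[np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(3)
    return [np.random.default_rng(c) for c in children]


def simulate_raters(config: SimConfig) -> GroundTruth:
    """Draw the volunteer population: sensitivities, variants, versions."""
    rng = _streams(config.seed)[0]
    n = config.n_volunteers_per_variant
    total = 3 * n

    if config.sigma_dprime == 0:
        dprime = np.full(total, config.mu_dprime)
    else:
        a = (0.0 - config.mu_dprime) / config.sigma_dprime
        dprime = truncnorm.rvs(
            a, np.inf, loc=config.mu_dprime, scale=config.sigma_dprime,
            size=total, random_state=rng,
        )

    variants = np.repeat(["control", "human_source", "computer_source"], n)
    within = np.tile(np.arange(n), 3)
    versions = np.where(variants == "control", "none",
                        np.where(within % 2 == 0, "1", "2"))
    catch_fail = rng.random(total) < config.catch_fail_rate

    volunteers = pd.DataFrame(
        {
            "volunteer_id": [f"v{i + 1:04d}" for i in range(total)],
            "variant": variants,
            "version": versions,
            "dprime": dprime,
            "catch_fail": catch_fail,
        }
    )
    return GroundTruth(volunteers=volunteers, config=config)


def _item_table(config: SimConfig) -> pd.DataFrame:
    rows = []
    for i in range(config.n_same_items):
        rows.append(("s%02d" % (i + 1), "same", False, i))
    for i in range(config.n_diff_items):
        rows.append(("d%02d" % (i + 1), "different", False, i))
    for i in range(config.n_catch):
        rows.append(("c%02d" % (i + 1), "same" if i % 2 == 0 else "different",
                     True, i))
    return pd.DataFrame(rows, columns=["item_id", "truth", "is_catch", "rank"])


def _labels_for(variant: str, version: str, items: pd.DataFrame) -> np.ndarray:
    """Prior label per item: counterbalanced across versions, none on catch."""
    labels = np.full(len(items), "none", dtype=object)
    if variant == "control":
        return labels
    flip = version == "2"
    told_same = ((items["rank"] % 2 == 0) ^ flip) & ~items["is_catch"]
    told_diff = ((items["rank"] % 2 == 1) ^ flip) & ~items["is_catch"]
    labels[told_same.to_numpy()] = "same"
    labels[told_diff.to_numpy()] = "different"
    return labels


def simulate_survey(truth: GroundTruth) -> pd.DataFrame:
    """Generate the full long-format response table for a rater population.

    Deterministic given the config seed.  Volunteers appear in id order;
    each volunteer's items appear in presentation order with the catch pairs
    last, matching the administered survey.
    """
    config = truth.config
    rng = _streams(config.seed)[1]
    items = _item_table(config)
    vols = truth.volunteers
    n_items = len(items)
    n_vols = len(vols)
    boundaries = config.resolved_boundaries()
    center = float(boundaries.mean())

    # per-(volunteer, item) latent evidence means
    dprime = vols["dprime"].to_numpy()[:, None]
    is_same = (items["truth"] == "same").to_numpy()[None, :]
    is_catch = items["is_catch"].to_numpy()[None, :]
    mean = np.where(is_same, dprime, 0.0)
    catch_mean = np.where(is_same, center + config.catch_separation / 2.0,
                          center - config.catch_separation / 2.0)
    mean = np.where(is_catch, catch_mean, mean)
    evidence = mean + rng.standard_normal((n_vols, n_items))

    # label-induced rigid boundary shift
    label_rows = [
        _labels_for(v, ver, items)
        for v, ver in zip(vols["variant"], vols["version"])
    ]
    labels = np.array(label_rows, dtype=object)
    shift = np.where(labels == "same", -config.delta / 2.0,
                     np.where(labels == "different", config.delta / 2.0, 0.0))

    adjusted = (evidence - shift).ravel()
    rating = np.searchsorted(boundaries, adjusted, side="left") - 3
    rating = rating.reshape(n_vols, n_items)

    # planted catch failures: force one wrong-direction catch response
    if config.n_catch > 0:
        catch_pos = int(np.flatnonzero(items["is_catch"].to_numpy())[0])
        wrong = -2 if items.at[items.index[catch_pos], "truth"] == "same" else 2
        for vi in np.flatnonzero(vols["catch_fail"].to_numpy()):
            rating[vi, catch_pos] = wrong

    df = pd.DataFrame(
        {
            "volunteer_id": np.repeat(vols["volunteer_id"].to_numpy(), n_items),
            "variant": np.repeat(vols["variant"].to_numpy(), n_items),
            "version": np.repeat(vols["version"].to_numpy(), n_items),
            "item_id": np.tile(items["item_id"].to_numpy(), n_vols),
            "truth": np.tile(items["truth"].to_numpy(), n_vols),
            "prior_label": labels.ravel(),
            "rating": rating.ravel().astype(np.int64),
            "is_catch": np.tile(items["is_catch"].to_numpy(), n_vols),
        },
        columns=list(RESPONSE_COLUMNS),
    )
    return validate_responses(df)


def simulate_profiles(truth: GroundTruth) -> pd.DataFrame:
    """Volunteer demographics and trust responses.

    Demographics are drawn exchangeably across variants (the design blocks
    on them, so no variant effect is generated); trust-question proportions
    differ by variant as configured in ``_TRUST_PROBS``.
    """
    rng = _streams(truth.config.seed)[2]
    vols = truth.volunteers

    def _draw(pairs) -> np.ndarray:
        values = [v for v, _ in pairs]
        probs = np.array([p for _, p in pairs])
        return rng.choice(values, size=len(vols), p=probs / probs.sum())

    trust = np.empty(len(vols), dtype=object)
    for variant, (py, pn, pu) in _TRUST_PROBS.items():
        mask = (vols["variant"] == variant).to_numpy()
        trust[mask] = rng.choice(
            ["yes", "no", "not_sure"], size=int(mask.sum()), p=[py, pn, pu]
        )
    return pd.DataFrame(
        {
            "volunteer_id": vols["volunteer_id"],
            "gender": _draw(_GENDER),
            "age_bin": _draw(_AGE),
            "race": _draw(_RACE),
            "trust_response": trust,
        }
    )


def fixture_small(return_truth: bool = False):
    """Deterministic 168-row table for documentation examples and fast tests.

    Four volunteers per variant under the default generative parameters
    (seed 7), exercising every variant, version, truth, and label value,
    with exactly one planted catch failure (volunteer ``v0001`` rates the
    mated celebrity pair -2).
    """
    config = SimConfig(n_volunteers_per_variant=4, seed=7)
    truth = simulate_raters(config)
    truth.volunteers.loc[0, "catch_fail"] = True
    df = simulate_survey(truth)
    return (df, truth) if return_truth else df
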