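"""Simulation experiments built on the generator and the analysis pipeline.

These are the package's own validation studies: they simulate rating data
under known generative parameters, push it through the same code path a
real dataset would take, and summarise how well the analysis recovers the
truth.  Two questions matter most:

* **Sensitivity neutrality.** If three conditions share a common d' and
  differ only in their decision criterion, the fitted Az values must agree
  — a criterion shift moves operating points *along* the ROC, not off it.
* **Parameter recovery.** Pooled d' and the told-same/told-different
  criterion gap estimated by the pipeline should track the generating
  values (the criterion gap recovers the boundary shift delta up to the
  mild attenuation induced by between-rater d' spread).
"""

from __future__ import annotations

import itertools
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .sdt import dprime_criterion, fit_roc_zspace, rates_at_threshold, threshold_sweep
from .simulate import SimConfig, boundaries_for_criterion, simulate_raters, simulate_survey
from .survey_io import screen_catch_trials

__all__ = ["az_neutrality_trial", "az_neutrality_study", "recover_sdt_parameters"]

#: Condition-specific headline criteria and rater counts used by default in
#: the neutrality study: a no-label condition and two label conditions whose
#: criteria straddle it, at the study's per-condition sample sizes.
DEFAULT_CRITERIA: Mapping[str, float] = {"none": 0.16, "same": 0.05, "different": 0.27}
DEFAULT_N_RATERS: Mapping[str, int] = {"none": 120, "same": 223, "different": 223}


def _simulate_condition(
    n_raters: int,
    dprime: float,
    criterion: float,
    seed: int,
    n_same_items: int = 6,
    n_diff_items: int = 6,
    spacing: float = 0.5,
) -> pd.DataFrame:
    """Rating table for one homogeneous condition (no labels, fixed d')."""
    config = SimConfig(
        n_volunteers_per_variant=n_raters,
        n_same_items=n_same_items,
        n_diff_items=n_diff_items,
        n_catch=0,
        mu_dprime=dprime,
        sigma_dprime=0.0,
        boundaries=boundaries_for_criterion(dprime, criterion, spacing),
        delta=0.0,
        seed=seed,
    )
    records = simulate_survey(simulate_raters(config))
    return records[records["variant"] == "control"].reset_index(drop=True)


def az_neutrality_trial(
    seed: int,
    dprime: float = 1.39,
    criteria: Mapping[str, float] = DEFAULT_CRITERIA,
    n_raters: Mapping[str, int] = DEFAULT_N_RATERS,
    grid: Sequence[float] | None = None,
) -> dict:
    """Fit Az per condition under a common d' and return the pairwise gaps.

    Each condition gets its own category boundaries placing the headline
    criterion, the full threshold sweep, and an unweighted z-space ROC fit.
    Returns the per-condition Az values and the maximum pairwise absolute
    difference.
    """
    children = np.random.SeedSequence(seed).spawn(len(criteria))
    az: dict[str, float] = {}
    for child, (label, crit) in zip(children, sorted(criteria.items())):
        records = _simulate_condition(
            n_raters[label], dprime, crit, seed=int(child.generate_state(1)[0] % (2**31))
        )
        points = (threshold_sweep(records, grid) if grid is not None
                  else threshold_sweep(records))
        az[label] = fit_roc_zspace(points).az
    gaps = [abs(az[a] - az[b]) for a, b in itertools.combinations(sorted(az), 2)]
    return {"az": az, "max_pairwise_gap": max(gaps)}


def az_neutrality_study(seed: int, n_reps: int = 20, **kwargs) -> dict:
    """Repeat the neutrality trial over independent seeds.

    Returns all per-replicate maximum pairwise Az gaps together with their
    median and the fraction of replicates below 0.02 (the agreement margin
    used when reading fitted Az values off a common ROC).
    """
    children = np.random.SeedSequence(seed).spawn(n_reps)
    gaps = [
        az_neutrality_trial(int(c.generate_state(1)[0] % (2**31)), **kwargs)[
            "max_pairwise_gap"
        ]
        for c in children
    ]
    gaps_arr = np.asarray(gaps)
    return {
        "gaps": gaps,
        "median_gap": float(np.median(gaps_arr)),
        "frac_below_0.02": float(np.mean(gaps_arr < 0.02)),
        "n_reps": n_reps,
    }


def recover_sdt_parameters(
    seed: int, config: SimConfig | None = None, theta: float = 0.5
) -> dict:
    """One full generate -> screen -> pool -> estimate cycle.

    Simulates a survey (default: the study-sized design), screens catch
    trials, and returns pooled d' and criterion for the none / told-same /
    told-different conditions alongside the generating values.
    """
    base = config or SimConfig()
    cfg = SimConfig.from_dict({**base.to_dict(), "seed": seed})
    truth = simulate_raters(cfg)
    records = simulate_survey(truth)
    kept = screen_catch_trials(records).kept

    out: dict[str, dict] = {"estimated": {}, "generating": truth.effective_criteria()}
    subsets = {
        "none": kept[kept["variant"] == "control"],
        "same": kept[kept["prior_label"] == "same"],
        "different": kept[kept["prior_label"] == "different"],
    }
    for label, sub in subsets.items():
        point = rates_at_threshold(sub, theta)
        s = dprime_criterion(point.tpr, point.fpr, condition=label)
        out["estimated"][label] = {"dprime": s.dprime, "criterion": s.criterion}
    est = out["estimated"]
    out["criterion_gap"] = est["different"]["criterion"] - est["same"]["criterion"]
    out["dprime_gap"] = est["different"]["dprime"] - est["same"]["dprime"]
    out["delta"] = cfg.delta
    out["mu_dprime"] = cfg.mu_dprime
    return out
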