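"""Equal-variance signal detection theory for 7-point rating data.

A graded certainty response R in [-3, +3] is converted to a binary
same/different decision by a sliding non-integer threshold theta: the
decision is "same" iff R > theta.  Sweeping theta over the six mid-points of
the scale yields one (FPR, TPR) operating point per threshold, from which we
compute

* pooled accuracy via the exact identity
  ``ACC = (n*TPR + m*(1 - FPR)) / (n + m)`` with n same-truth and m
  different-truth responses,
* sensitivity ``d' = z(TPR) - z(FPR)`` and decision criterion
  ``c = -(z(TPR) + z(FPR)) / 2`` at a single threshold (z is the standard
  normal quantile), and
* a threshold-free area ``Az = Phi(I / sqrt(1 + S^2))`` from the ordinary
  least-squares fit ``z(TPR) = I + S * z(FPR)`` over the operating points
  (the Gaussian-model ROC area).

Rates exactly 0 or 1 leave d', c and the z-transform undefined; callers can
pool responses across volunteers (the default throughout this package) or
apply :func:`corrected_rate`.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "DEFAULT_THRESHOLDS",
    "RatePoint",
    "SDTSummary",
    "ROCFit",
    "ImproperROCWarning",
    "validate_grid",
    "binarize_rating",
    "rates_at_threshold",
    "threshold_sweep",
    "dprime_criterion",
    "corrected_rate",
    "fit_roc_zspace",
]

#: Mid-points of the 7-point certainty scale, from "very permissive" (-2.5)
#: to "very strict" (+2.5).
DEFAULT_THRESHOLDS: tuple[float, ...] = (-2.5, -1.5, -0.5, 0.5, 1.5, 2.5)


class ImproperROCWarning(UserWarning):
    """Fitted z-space slope is non-positive (improper ROC)."""


@dataclasses.dataclass(frozen=True)
class RatePoint:
    """Operating point of the rating task at one decision threshold."""

    theta: float
    tpr: float
    fpr: float
    acc: float
    n: int  # same-truth responses
    m: int  # different-truth responses


@dataclasses.dataclass(frozen=True)
class SDTSummary:
    """Pooled sensitivity and criterion at a single threshold."""

    dprime: float
    criterion: float
    tpr: float
    fpr: float
    condition: str = ""


@dataclasses.dataclass(frozen=True)
class ROCFit:
    """z-space linear ROC fit: intercept I, slope S, Az = Phi(I/sqrt(1+S^2))."""

    intercept: float
    slope: float
    az: float
    points: tuple[tuple[float, float], ...]  # retained (z_fpr, z_tpr) pairs
    improper: bool = False


def validate_grid(grid: Sequence[float]) -> tuple[float, ...]:
    """Check that a threshold grid is strictly increasing and tie-free.

    Each threshold must be non-integral so that integer ratings can never tie
    with it.
    """
    grid = tuple(float(t) for t in grid)
    if len(grid) == 0:
        raise ValueError("threshold grid is empty")
    if any(float(t).is_integer() for t in grid):
        raise ValueError("thresholds must be non-integral (integer ratings would tie)")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("threshold grid must be strictly increasing")
    return grid


def binarize_rating(rating: int, theta: float) -> int:
    """Map a graded rating to a binary decision: 1 ("same") iff rating > theta."""
    if float(theta).is_integer():
        raise ValueError(f"theta={theta} is integral; decisions would be ambiguous")
    return int(rating > theta)


def _split_ratings(records: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    if records.empty:
        raise ValueError("no responses supplied")
    same = records.loc[records["truth"] == "same", "rating"].to_numpy()
    diff = records.loc[records["truth"] == "different", "rating"].to_numpy()
    if same.size == 0:
        raise ValueError("no same-truth responses: TPR is undefined")
    if diff.size == 0:
        raise ValueError("no different-truth responses: FPR is undefined")
    return same, diff


def rates_at_threshold(records: pd.DataFrame, theta: float) -> RatePoint:
    """Pooled TPR, FPR, and accuracy of the binarized responses at ``theta``.

    TPR is the fraction of same-truth responses with rating > theta, FPR the
    fraction of different-truth responses with rating > theta; accuracy
    follows from the pooling identity (weights n and m are the class counts).
    """
    if float(theta).is_integer():
        raise ValueError(f"theta={theta} is integral; decisions would be ambiguous")
    same, diff = _split_ratings(records)
    n, m = same.size, diff.size
    tpr = float(np.mean(same > theta))
    fpr = float(np.mean(diff > theta))
    acc = (n * tpr + m * (1.0 - fpr)) / (n + m)
    return RatePoint(theta=float(theta), tpr=tpr, fpr=fpr, acc=acc, n=n, m=m)


def threshold_sweep(
    records: pd.DataFrame, grid: Sequence[float] = DEFAULT_THRESHOLDS
) -> list[RatePoint]:
    """One :class:`RatePoint` per grid threshold, in grid order.

    Because the decision rule is a step function of theta, TPR and FPR are
    non-increasing along the (increasing) grid.
    """
    grid = validate_grid(grid)
    return [rates_at_threshold(records, t) for t in grid]


def dprime_criterion(tpr: float, fpr: float, condition: str = "") -> SDTSummary:
    """Equal-variance sensitivity d' and criterion c from one rate pair.

    Requires both rates strictly inside (0, 1); at the boundary the normal
    quantile diverges.  Pool responses across volunteers or use
    :func:`corrected_rate` before calling.
    """
    if not (0.0 < tpr < 1.0 and 0.0 < fpr < 1.0):
        raise ValueError(
            f"rates must lie strictly in (0, 1), got tpr={tpr}, fpr={fpr}; "
            "pool responses or apply corrected_rate()"
        )
    zt, zf = norm.ppf(tpr), norm.ppf(fpr)
    return SDTSummary(
        dprime=float(zt - zf),
        criterion=float(-(zt + zf) / 2.0),
        tpr=float(tpr),
        fpr=float(fpr),
        condition=condition,
    )


def corrected_rate(successes: int, trials: int, mode: str = "log_linear") -> float:
    """Boundary-safe proportion estimate.

    ``log_linear`` returns (successes + 0.5) / (trials + 1), which keeps
    per-volunteer rates away from 0 and 1 so that individual-level d' can be
    computed; ``none`` returns the raw proportion.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not 0 <= successes <= trials:
        raise ValueError(f"successes={successes} outside [0, trials={trials}]")
    if mode == "log_linear":
        return (successes + 0.5) / (trials + 1.0)
    if mode == "none":
        return successes / trials
    raise ValueError(f"unknown correction mode {mode!r}")


def fit_roc_zspace(points: Iterable[RatePoint]) -> ROCFit:
    """Gaussian-model ROC fit in z-space.

    Transforms each operating point to (z(FPR), z(TPR)), drops degenerate
    points (either rate at 0 or 1), and fits z(TPR) = I + S * z(FPR) by
    unweighted ordinary least squares.  The area under the fitted ROC is
    Az = Phi(I / sqrt(1 + S^2)).  A non-positive slope yields an improper
    ROC: the fit is returned with ``improper=True`` and a warning.
    """
    retained = [
        p for p in points if 0.0 < p.tpr < 1.0 and 0.0 < p.fpr < 1.0
    ]
    if len(retained) < 2:
        raise ValueError(
            f"need >= 2 non-degenerate operating points, got {len(retained)}"
        )
    zf = norm.ppf([p.fpr for p in retained])
    zt = norm.ppf([p.tpr for p in retained])
    slope, intercept = np.polyfit(zf, zt, 1)
    az = float(norm.cdf(intercept / np.sqrt(1.0 + slope**2)))
    improper = bool(slope <= 0)
    if improper:
        warnings.warn(
            f"fitted z-space slope {slope:.3f} <= 0: improper ROC",
            ImproperROCWarning,
            stacklevel=2,
        )
    return ROCFit(
        intercept=float(intercept),
        slope=float(slope),
        az=az,
        points=tuple(zip(zf.tolist(), zt.tolist())),
        improper=improper,
    )
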