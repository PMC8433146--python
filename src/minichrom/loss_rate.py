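"""Estimators for the per-division mini-chromosome loss rate.

Both estimators invert the retention model ``f_n = f0 (1 - r)^n``, where n is
the number of cell divisions (3 per day for DT40), r the per-division loss
rate, and f_n the fraction of cells retaining the chromosome:

* clone-median: from a limiting-dilution assay, the median per-clone
  GFP-negative fraction m (after excluding clones at 100%, which plausibly
  lost the chromosome at day 0) gives ``r = 1 - (1 - m)^(1/n)`` with f0 = 1;
* time-course: log-linear least squares of ``ln f = ln f0 + n ln(1 - r)``
  over a bulk culture sampled at several days.

GFP-negative is used as "not retaining", so epigenetically silenced carriers
bias r upward; an optional background-subtraction mode corrects a fixed
day-0 negative fraction (off by default).  Double-GFP cells count as
retaining; re-loss from two-copy cells is ignored.  Confidence intervals are
seeded percentile bootstraps (over clones, or over residuals).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "LossRateEstimate",
    "EstimationError",
    "CloneLossRateEstimator",
    "TimecourseLossRateEstimator",
    "num_divisions",
    "invert_retention",
    "bootstrap_ci",
    "estimate_from_clone_assay",
    "fit_timecourse",
    "read_clone_assay_tsv",
    "write_clone_assay_tsv",
    "read_timecourse_tsv",
    "write_timecourse_tsv",
]


class EstimationError(ValueError):
    """No usable data for rate estimation."""


@dataclass(frozen=True)
class LossRateEstimate:
    """A per-division loss-rate estimate with its bootstrap interval."""

    r_per_division: float
    ci_lower: float
    ci_upper: float
    ci_level: float
    n_divisions: int
    f0: float
    method: str
    n_obs: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_per_division <= 1.0:
            raise ValueError(f"rate must be in [0, 1], got {self.r_per_division}")
        if not self.ci_lower <= self.r_per_division <= self.ci_upper:
            raise ValueError("confidence interval must contain the point estimate")

    @property
    def percent_per_division(self) -> float:
        return 100.0 * self.r_per_division


def num_divisions(days: float, divisions_per_day: int = 3) -> int:
    """Number of cell divisions in ``days`` (DT40: three per day)."""
    if days < 0:
        raise ValueError(f"days must be >= 0, got {days}")
    if divisions_per_day < 1:
        raise ValueError("divisions_per_day must be >= 1")
    return int(round(days * divisions_per_day))


def invert_retention(f0: float, f_n: float, n: int) -> float:
    """Solve ``f_n = f0 (1 - r)^n`` for r: ``r = 1 - (f_n / f0)^(1/n)``.

    Complete loss (``f_n = 0``) returns 1.0 with a warning — the rate is only
    bounded below by the observation.
    """
    if not 0.0 < f0 <= 1.0:
        raise ValueError(f"f0 must be in (0, 1], got {f0}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if f_n < 0.0:
        raise ValueError(f"f_n must be >= 0, got {f_n}")
    if f_n > f0:
        raise ValueError(f"retained fraction f_n={f_n} exceeds f0={f0}")
    if f_n == 0.0:
        warnings.warn("complete loss observed; per-division rate censored at 1.0")
        return 1.0
    return 1.0 - (f_n / f0) ** (1.0 / n)


def bootstrap_ci(
    statistic: Callable[[np.ndarray], float],
    data: Sequence[float] | np.ndarray,
    n_resamples: int = 2000,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[float, float]:
    """Seeded nonparametric percentile bootstrap interval of a statistic."""
    if n_resamples < 100:
        raise ValueError("n_resamples must be >= 100")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    data = np.asarray(data, dtype=float)
    if data.size < 2:
        warnings.warn("bootstrap over fewer than two observations; degenerate interval")
        value = float(statistic(data))
        return value, value
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, data.size, size=(n_resamples, data.size))
    stats = np.asarray([statistic(data[row]) for row in idx], dtype=float)
    lower, upper = np.quantile(stats, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lower), float(upper)


# ---------------------------------------------------------------------------
# Clone-median estimator

class CloneLossRateEstimator(BaseEstimator):
    """Median-based loss-rate estimator for limiting-dilution clone assays.

    ``fit(X)`` takes per-clone GFP-negative fractions.  The median (robust to
    the heavy right tail produced by losses in the first divisions) of the
    clones, after excluding complete-loss clones, is inverted through the
    retention model with f0 = 1.

    Parameters
    ----------
    duration_days, divisions_per_day :
        Clonal growth time; n = round(duration_days * divisions_per_day).
    exclude_complete_loss : bool
        Drop clones with a GFP-negative fraction of exactly 1.0, attributed to
        chromosome loss at day 0 (on by default).
    background_negative_fraction : float
        Optional fixed GFP-negative background (e.g. silenced carriers at day
        0) subtracted from every clone before inversion; 0 disables.
    """

    def __init__(
        self,
        duration_days: float = 7.0,
        divisions_per_day: int = 3,
        exclude_complete_loss: bool = True,
        background_negative_fraction: float = 0.0,
        n_bootstrap: int = 2000,
        ci_level: float = 0.95,
        random_state: int | None = None,
    ):
        self.duration_days = duration_days
        self.divisions_per_day = divisions_per_day
        self.exclude_complete_loss = exclude_complete_loss
        self.background_negative_fraction = background_negative_fraction
        self.n_bootstrap = n_bootstrap
        self.ci_level = ci_level
        self.random_state = random_state

    def fit(self, X, y=None):
        fractions = np.asarray(
            getattr(X, "gfp_negative_fraction", X), dtype=float
        ).ravel()
        if fractions.size < 1:
            raise EstimationError("need at least one clone")
        if fractions.min() < 0 or fractions.max() > 1:
            raise EstimationError("clone fractions must lie in [0, 1]")
        kept = fractions[fractions < 1.0] if self.exclude_complete_loss else fractions
        if kept.size == 0:
            raise EstimationError("all clones excluded as complete loss")
        bg = self.background_negative_fraction
        if bg > 0.0:
            kept = np.clip((kept - bg) / (1.0 - bg), 0.0, 1.0)
        n = num_divisions(self.duration_days, self.divisions_per_day)

        def stat(values: np.ndarray) -> float:
            m = float(np.median(values))
            if m >= 1.0:
                return 1.0
            return invert_retention(1.0, 1.0 - m, n)

        rate = stat(kept)
        if kept.size >= 2:
            lower, upper = bootstrap_ci(
                stat, kept, self.n_bootstrap, self.ci_level, seed=self.random_state
            )
        else:
            lower = upper = rate
        self.n_divisions_ = n
        self.median_negative_fraction_ = float(np.median(kept))
        self.n_clones_used_ = int(kept.size)
        self.rate_per_division_ = rate
        self.ci_ = (min(lower, rate), max(upper, rate))
        self.estimate_ = LossRateEstimate(
            r_per_division=rate,
            ci_lower=self.ci_[0],
            ci_upper=self.ci_[1],
            ci_level=self.ci_level,
            n_divisions=n,
            f0=1.0,
            method="clone_median",
            n_obs=self.n_clones_used_,
        )
        return self

    def predict(self, X):
        """Expected GFP-negative fraction after X days of clonal growth."""
        if not hasattr(self, "rate_per_division_"):
            raise EstimationError("estimator is not fitted")
        days = np.asarray(X, dtype=float)
        return 1.0 - (1.0 - self.rate_per_division_) ** (days * self.divisions_per_day)


# ---------------------------------------------------------------------------
# Time-course estimator

def _fit_loglinear(
    n: np.ndarray, log_f: np.ndarray, f0_mode: str
) -> tuple[float, float]:
    """Least-squares fit of ``log f = log f0 + n * slope``; returns
    (slope, log_f0)."""
    if f0_mode == "fixed":
        at_zero = n == 0
        if not at_zero.any():
            raise EstimationError("f0_mode='fixed' requires a day-0 measurement")
        log_f0 = float(log_f[at_zero].mean())
        denom = float((n * n).sum())
        if denom == 0:
            raise EstimationError("need at least one timepoint after day 0")
        slope = float((n * (log_f - log_f0)).sum() / denom)
    elif f0_mode == "free":
        slope, log_f0 = (float(v) for v in np.polyfit(n, log_f, 1))
    else:
        raise ValueError(f"unknown f0_mode {f0_mode!r}")
    return slope, log_f0


class TimecourseLossRateEstimator(BaseEstimator):
    """Log-linear loss-rate estimator for bulk GFP time-courses.

    ``fit(X, y)`` takes sampling days and the retained (GFP-positive)
    fractions, and fits ``ln f = ln f0 + n ln(1 - r)`` with n = 3 divisions
    per day by default.  ``f0_mode="fixed"`` pins f0 at the day-0 measurement;
    ``"free"`` fits it as an intercept.  The CI is a seeded residual bootstrap.
    """

    def __init__(
        self,
        divisions_per_day: int = 3,
        f0_mode: str = "fixed",
        n_bootstrap: int = 2000,
        ci_level: float = 0.95,
        random_state: int | None = None,
    ):
        self.divisions_per_day = divisions_per_day
        self.f0_mode = f0_mode
        self.n_bootstrap = n_bootstrap
        self.ci_level = ci_level
        self.random_state = random_state

    def fit(self, X, y):
        days = np.asarray(X, dtype=float).ravel()
        retained = np.asarray(y, dtype=float).ravel()
        if days.size != retained.size:
            raise EstimationError("days and fractions must have equal length")
        if days.size < 2:
            raise EstimationError("need at least two timepoints")
        if retained.min() <= 0 or retained.max() > 1:
            raise EstimationError("retained fractions must lie in (0, 1]")
        n = np.rint(days * self.divisions_per_day)
        log_f = np.log(retained)
        slope, log_f0 = _fit_loglinear(n, log_f, self.f0_mode)
        rate = float(np.clip(1.0 - np.exp(slope), 0.0, 1.0))
        fitted = log_f0 + slope * n
        residuals = log_f - fitted

        rng = np.random.default_rng(self.random_state)
        rates = np.empty(self.n_bootstrap)
        for b in range(self.n_bootstrap):
            resampled = fitted + rng.choice(residuals, size=residuals.size, replace=True)
            slope_b, _ = _fit_loglinear(n, resampled, self.f0_mode)
            rates[b] = np.clip(1.0 - np.exp(slope_b), 0.0, 1.0)
        alpha = 1.0 - self.ci_level
        lower, upper = np.quantile(rates, [alpha / 2, 1 - alpha / 2])

        self.rate_per_division_ = rate
        self.f0_ = float(np.exp(log_f0))
        self.ci_ = (min(float(lower), rate), max(float(upper), rate))
        self.n_timepoints_ = int(days.size)
        self.estimate_ = LossRateEstimate(
            r_per_division=rate,
            ci_lower=self.ci_[0],
            ci_upper=self.ci_[1],
            ci_level=self.ci_level,
            n_divisions=int(n.max()),
            f0=self.f0_,
            method="timecourse",
            n_obs=self.n_timepoints_,
        )
        return self

    def predict(self, X):
        """Expected retained fraction at the given days."""
        if not hasattr(self, "rate_per_division_"):
            raise EstimationError("estimator is not fitted")
        days = np.asarray(X, dtype=float)
        return self.f0_ * (1.0 - self.rate_per_division_) ** (
            days * self.divisions_per_day
        )


# ---------------------------------------------------------------------------
# Functional wrappers

def estimate_from_clone_assay(
    assay,
    duration_days: float | None = None,
    divisions_per_day: int = 3,
    exclude_complete_loss: bool = True,
    background_negative_fraction: float = 0.0,
    n_bootstrap: int = 2000,
    ci_level: float = 0.95,
    seed: int | None = None,
) -> LossRateEstimate:
    """Clone-median loss-rate estimate from a clone assay (or a fraction
    array, or a DataFrame with a ``gfp_negative_fraction`` column)."""
    if duration_days is None:
        duration_days = getattr(assay, "duration_days", None)
        if duration_days is None:
            raise EstimationError("duration_days is required when the assay does not carry it")
    if isinstance(assay, pd.DataFrame):
        assay = assay["gfp_negative_fraction"].to_numpy()
    est = CloneLossRateEstimator(
        duration_days=duration_days,
        divisions_per_day=divisions_per_day,
        exclude_complete_loss=exclude_complete_loss,
        background_negative_fraction=background_negative_fraction,
        n_bootstrap=n_bootstrap,
        ci_level=ci_level,
        random_state=seed,
    ).fit(assay)
    return est.estimate_


def _timecourse_arrays(samples) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(samples, pd.DataFrame):
        days = samples["day"].to_numpy(dtype=float)
        retained = 1.0 - samples["fraction_negative"].to_numpy(dtype=float)
        return days, retained
    first = samples[0]
    if hasattr(first, "fraction_gfp_negative"):
        days = np.asarray([s.day for s in samples], dtype=float)
        retained = np.asarray(
            [1.0 - s.fraction_gfp_negative for s in samples], dtype=float
        )
        return days, retained
    pairs = np.asarray(samples, dtype=float)
    return pairs[:, 0], pairs[:, 1]


def fit_timecourse(
    samples,
    divisions_per_day: int = 3,
    f0_mode: str = "fixed",
    n_bootstrap: int = 2000,
    ci_level: float = 0.95,
    seed: int | None = None,
) -> LossRateEstimate:
    """Time-course loss-rate estimate from ``(day, retained_fraction)`` pairs,
    a list of flow samples, or a time-course DataFrame."""
    days, retained = _timecourse_arrays(samples)
    est = TimecourseLossRateEstimator(
        divisions_per_day=divisions_per_day,
        f0_mode=f0_mode,
        n_bootstrap=n_bootstrap,
        ci_level=ci_level,
        random_state=seed,
    ).fit(days, retained)
    return est.estimate_


# ---------------------------------------------------------------------------
# TSV interfaces

def write_clone_assay_tsv(assay, path) -> None:
    """Write per-clone fractions: clone_id, gfp_negative_fraction[, double]."""
    negative = np.asarray(getattr(assay, "gfp_negative_fraction", assay), dtype=float)
    data = {
        "clone_id": [f"clone{i + 1:04d}" for i in range(negative.size)],
        "gfp_negative_fraction": negative,
    }
    double = getattr(assay, "gfp_double_fraction", None)
    if double is not None:
        data["gfp_double_fraction"] = np.asarray(double, dtype=float)
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_clone_assay_tsv(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    if "gfp_negative_fraction" not in frame.columns:
        raise EstimationError(f"{path}: missing column 'gfp_negative_fraction'")
    values = frame["gfp_negative_fraction"]
    if values.min() < 0 or values.max() > 1:
        raise EstimationError(f"{path}: fractions must lie in [0, 1]")
    return frame


def write_timecourse_tsv(samples, path) -> None:
    """Write flow samples as TSV: day, fraction_negative, fraction_single,
    fraction_double."""
    pd.DataFrame(
        {
            "day": [s.day for s in samples],
            "fraction_negative": [s.fraction_gfp_negative for s in samples],
            "fraction_single": [s.fraction_gfp_single for s in samples],
            "fraction_double": [s.fraction_gfp_double for s in samples],
        }
    ).to_csv(path, sep="\t", index=False)


def read_timecourse_tsv(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    missing = {"day", "fraction_negative"} - set(frame.columns)
    if missing:
        raise EstimationError(f"{path}: missing columns {sorted(missing)}")
    return frame
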