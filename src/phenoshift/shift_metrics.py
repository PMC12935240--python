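"""Convert fitted circular slopes into days-per-decade shift estimates.

The fitted regression gives, per posterior draw, a mean direction
mu(year) on the link scale.  The total shift over a species' collection
span is the link-scale difference mu(last year) - mu(first year) — which
cannot wrap, since the tan-half link confines mu to one open turn around
the intercept — converted to days via 365/(2*pi).  Dividing by the span
in decades gives the headline days-per-decade rate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .circular_glm import CircularGLMFit

logger = logging.getLogger(__name__)

RAD_TO_DAYS = 365.0 / (2.0 * math.pi)


@dataclass(frozen=True)
class ShiftEstimate:
    """Per-species phenological shift summary."""

    species: str
    days_per_decade: float
    abs_days_per_decade: float
    days_per_decade_sd: float
    total_shift_days: float
    span_years: int
    direction: str  # "later" | "earlier"
    slope_mean: float
    slope_sd: float
    n_specimens: int


@dataclass(frozen=True)
class DatasetSummary:
    dataset_id: str
    mean_abs_slope: float
    mean_slope_sd: float
    n_positive: int
    n_negative: int
    mean_abs_days_per_decade: float
    n_species: int


def shift_from_fit(fit: CircularGLMFit, species: str = "") -> ShiftEstimate:
    """Shift estimate from one fitted regression.

    Per posterior draw the link-scale change over the observed span is
    delta = 2*atan(beta1*(x_max - c)) - 2*atan(beta1*(x_min - c)); the
    reported total is the posterior mean of delta in days, and the rate
    divides by span/10.  Posterior slope uncertainty therefore propagates
    into the rate's posterior SD.
    """
    x_min, x_max = fit.x_range
    span = x_max - x_min
    if span <= 0:
        raise ValueError("zero collection-year span")
    delta = 2.0 * np.arctan(fit.beta1_samples * (x_max - fit.x_center)) - 2.0 * np.arctan(
        fit.beta1_samples * (x_min - fit.x_center)
    )
    total_days = delta * RAD_TO_DAYS
    dpd_draws = total_days / (span / 10.0)
    total = float(total_days.mean())
    dpd = float(dpd_draws.mean())
    return ShiftEstimate(
        species=species,
        days_per_decade=dpd,
        abs_days_per_decade=abs(dpd),
        days_per_decade_sd=float(dpd_draws.std(ddof=1)),
        total_shift_days=total,
        span_years=int(span),
        direction="later" if dpd > 0 else "earlier",
        slope_mean=fit.beta1_mean,
        slope_sd=fit.beta1_sd,
        n_specimens=fit.n_obs,
    )


def rate_from_total(total_days: float, span_years: float) -> float:
    """days-per-decade rate from a total shift over a span of years."""
    if span_years <= 0:
        raise ValueError("span_years must be > 0")
    return total_days / (span_years / 10.0)


def round_sigfigs(value: float, sigfigs: int = 3) -> float:
    """Display rounding to significant figures (0 stays 0)."""
    if value == 0:
        return 0.0
    magnitude = math.floor(math.log10(abs(value)))
    return round(value, sigfigs - 1 - magnitude)


def direction_counts(estimates: Sequence[ShiftEstimate]) -> tuple[int, int]:
    """(n_positive, n_negative) by sign of days_per_decade.

    Exact zeros (not expected from continuous posteriors) are excluded
    from both tallies and logged.
    """
    if not estimates:
        raise ValueError("need at least one estimate")
    n_pos = sum(1 for e in estimates if e.days_per_decade > 0)
    n_neg = sum(1 for e in estimates if e.days_per_decade < 0)
    n_zero = len(estimates) - n_pos - n_neg
    if n_zero:
        logger.warning("%d exact-zero shifts excluded from direction counts", n_zero)
    return n_pos, n_neg


def summarize_dataset(
    estimates: Sequence[ShiftEstimate], dataset_id: str
) -> DatasetSummary:
    """Dataset-level averages: mean |slope|, mean slope SD, direction
    counts, mean |days/decade|, species count."""
    if not estimates:
        raise ValueError("need at least one estimate")
    n_pos, n_neg = direction_counts(estimates)
    return DatasetSummary(
        dataset_id=dataset_id,
        mean_abs_slope=float(np.mean([abs(e.slope_mean) for e in estimates])),
        mean_slope_sd=float(np.mean([e.slope_sd for e in estimates])),
        n_positive=n_pos,
        n_negative=n_neg,
        mean_abs_days_per_decade=float(np.mean([e.abs_days_per_decade for e in estimates])),
        n_species=len(estimates),
    )


def estimates_to_frame(estimates: Sequence[ShiftEstimate]) -> pd.DataFrame:
    """Per-species estimates table (full precision)."""
    return pd.DataFrame(
        [
            {
                "species": e.species,
                "slope_mean": e.slope_mean,
                "slope_sd": e.slope_sd,
                "days_per_decade": e.days_per_decade,
                "days_per_decade_sd": e.days_per_decade_sd,
                "total_shift_days": e.total_shift_days,
                "direction": e.direction,
                "span_years": e.span_years,
                "n_specimens": e.n_specimens,
            }
            for e in estimates
        ]
    )


def summary_to_frame(summaries: Sequence[DatasetSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "dataset": s.dataset_id,
                "mean_abs_slope": s.mean_abs_slope,
                "mean_slope_sd": s.mean_slope_sd,
                "n_positive": s.n_positive,
                "n_negative": s.n_negative,
                "mean_abs_days_per_decade": s.mean_abs_days_per_decade,
                "n_species": s.n_species,
            }
            for s in summaries
        ]
    )
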