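"""Species inclusion criteria and dataset construction.

Four rules decide whether a species enters an analysis dataset: a cap on
the number of calendar months with flowering records (optionally required
to form one contiguous circular block, December adjacent to January), a
minimum specimen count, a minimum collection-year span OR a calendar-year
window, and an optional cap on specimens per collection day.  Six named
presets combine these rules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .records_io import SpecimenRecord, species_in

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DatasetCriteria:
    """One row of inclusion rules.

    ``year_window`` is (earliest allowed, latest allowed); either bound
    may be None.  When a window is set, specimen counts, month counts and
    year spans are all recomputed on the windowed records.
    """

    max_months_flowering: int = 4
    min_specimens: int = 20
    min_year_span: int | None = 29
    year_window: tuple[int | None, int | None] | None = None
    max_per_day: int | None = None
    require_consecutive_months: bool = True

    def __post_init__(self):
        if self.max_months_flowering < 1 or self.min_specimens < 1:
            raise ValueError("thresholds must be positive")
        if self.max_per_day is not None and self.max_per_day < 1:
            raise ValueError("max_per_day must be >= 1")


#: The six standard criteria rows: months cap / specimen floor / span or
#: window / per-day cap.
STANDARD_DATASETS: dict[str, DatasetCriteria] = {
    "dataset1": DatasetCriteria(4, 20, 29),
    "dataset2": DatasetCriteria(3, 20, 29),
    "dataset3": DatasetCriteria(4, 51, 29),
    "dataset4": DatasetCriteria(4, 20, None, year_window=(1960, None)),
    "dataset5": DatasetCriteria(4, 20, None, year_window=(None, 1959)),
    "dataset6": DatasetCriteria(4, 20, 29, max_per_day=1),
}


@dataclass(frozen=True)
class SpeciesEligibility:
    species: str
    months_flowering: int
    months_consecutive: bool
    n_specimens: int
    year_span: int
    passes_months: bool
    passes_count: bool
    passes_span: bool

    @property
    def eligible(self) -> bool:
        return self.passes_months and self.passes_count and self.passes_span


def months_flowering(records: Sequence[SpecimenRecord]) -> tuple[int, bool]:
    """Distinct flowering months pooled over all years, plus contiguity.

    Returns (count, consecutive) where consecutive is True iff the
    months occupy one contiguous arc of the 12-month circle (so Dec-Jan
    counts as adjacent).
    """
    months = sorted({r.event_month for r in records})
    if not months:
        raise ValueError("empty record list")
    k = len(months)
    if k in (1, 12):
        return k, True
    # contiguous on the circle <=> exactly one gap > 1 in the cyclic
    # sequence of sorted months
    gaps = [months[i + 1] - months[i] for i in range(k - 1)]
    gaps.append(months[0] + 12 - months[-1])
    n_breaks = sum(1 for g in gaps if g > 1)
    return k, n_breaks <= 1


def dedupe_per_day(
    records: Sequence[SpecimenRecord], max_per_day: int
) -> list[SpecimenRecord]:
    """Cap records per (species, date), keeping the lexicographically
    smallest occurrence ids so the result is deterministic."""
    if max_per_day < 1:
        raise ValueError("max_per_day must be >= 1")
    by_day: dict[tuple, list[SpecimenRecord]] = {}
    for r in records:
        key = (r.species, r.event_year, r.event_month, r.event_day)
        by_day.setdefault(key, []).append(r)
    kept = []
    for group in by_day.values():
        group.sort(key=lambda r: r.occurrence_id)
        kept.extend(group[:max_per_day])
    # restore input order for determinism of downstream tables
    order = {id(r): i for i, r in enumerate(records)}
    kept.sort(key=lambda r: order[id(r)])
    return kept


def _window_filter(
    records: Sequence[SpecimenRecord],
    window: tuple[int | None, int | None] | None,
) -> list[SpecimenRecord]:
    if window is None:
        return list(records)
    lo, hi = window
    return [
        r
        for r in records
        if (lo is None or r.event_year >= lo) and (hi is None or r.event_year <= hi)
    ]


def apply_criteria(
    records: Sequence[SpecimenRecord], criteria: DatasetCriteria
) -> tuple[list[str], list[SpecimenRecord]]:
    """Apply one criteria row; return (eligible species, surviving records).

    Per species: the year window is applied first, then the per-day cap;
    month counts, specimen counts and year spans are all evaluated on the
    surviving records.
    """
    eligible: list[str] = []
    surviving: list[SpecimenRecord] = []
    for sp, elig, recs in iter_eligibility(records, criteria):
        if elig is not None and elig.eligible:
            eligible.append(sp)
            surviving.extend(recs)
    if not eligible:
        logger.warning("no species satisfies the criteria %s", criteria)
    return eligible, surviving


def iter_eligibility(records, criteria):
    """Yield (species, SpeciesEligibility | None, surviving records)."""
    for sp in species_in(records):
        recs = [r for r in records if r.species == sp]
        recs = _window_filter(recs, criteria.year_window)
        if criteria.max_per_day is not None:
            recs = dedupe_per_day(recs, criteria.max_per_day)
        if not recs:
            yield sp, None, []
            continue
        n_months, consecutive = months_flowering(recs)
        years = [r.event_year for r in recs]
        span = max(years) - min(years)
        passes_months = n_months <= criteria.max_months_flowering and (
            consecutive or not criteria.require_consecutive_months
        )
        passes_count = len(recs) >= criteria.min_specimens
        passes_span = criteria.min_year_span is None or span >= criteria.min_year_span
        yield sp, SpeciesEligibility(
            species=sp,
            months_flowering=n_months,
            months_consecutive=consecutive,
            n_specimens=len(recs),
            year_span=span,
            passes_months=passes_months,
            passes_count=passes_count,
            passes_span=passes_span,
        ), recs


def eligibility_report(records, criteria) -> pd.DataFrame:
    """Per-species eligibility table (CSV-exportable)."""
    rows = []
    for sp, elig, _ in iter_eligibility(records, criteria):
        if elig is None:
            rows.append({"species": sp, "n_specimens": 0, "eligible": False})
        else:
            rows.append(
                {
                    "species": sp,
                    "months_flowering": elig.months_flowering,
                    "months_consecutive": elig.months_consecutive,
                    "n_specimens": elig.n_specimens,
                    "year_span": elig.year_span,
                    "passes_months": elig.passes_months,
                    "passes_count": elig.passes_count,
                    "passes_span": elig.passes_span,
                    "eligible": elig.eligible,
                }
            )
    return pd.DataFrame(rows)
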