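"""Reading Darwin Core-style occurrence tables and circular date handling.

Herbarium occurrence records carry a collection date and a species name.
For circular regression the collection date is reduced to an ordinal
day-of-year (Jan 1 = 1), rescaled in leap years so that every year maps
onto a common 365-day circle, and then mapped to an angle in (-pi, pi].
"""

from __future__ import annotations

import calendar
import datetime as _dt
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: basisOfRecord values treated as physical museum/herbarium specimens.
PRESERVED_SPECIMEN_VALUES = frozenset({"PRESERVED_SPECIMEN", "PreservedSpecimen"})

_SPECIES_COLUMNS = ("scientificName", "species")


class SchemaError(ValueError):
    """An occurrence table is missing a mandatory column."""


@dataclass(frozen=True)
class SpecimenRecord:
    """One dated, flowering herbarium occurrence of one species."""

    species: str
    occurrence_id: str
    event_year: int
    event_month: int
    event_day: int
    basis_of_record: str
    latitude: float | None = None
    longitude: float | None = None


@dataclass(frozen=True)
class CircularObservation:
    """A (year, angle) pair fed to the circular regression.

    ``doy`` is the leap-scaled day-of-year in (0, 365]; ``theta`` is its
    image under the radian map, in (-pi, pi].
    """

    year: int
    doy: float
    theta: float


def day_of_year(year: int, month: int, day: int) -> float:
    """Leap-scaled ordinal day of the year, in (0, 365].

    The ordinal day (Jan 1 = 1) is computed on the actual calendar; in
    leap years it is multiplied by 365/366 so Dec 31 maps to 365 in every
    year and all dates share one 365-day circle.

    Raises ``ValueError`` for an invalid Gregorian date.
    """
    ordinal = _dt.date(year, month, day).timetuple().tm_yday
    if calendar.isleap(year):
        return ordinal * 365.0 / 366.0
    return float(ordinal)


def day_to_radians(doy: float | np.ndarray) -> float | np.ndarray:
    """Map day-of-year in (0, 365] to an angle in (-pi, pi].

    theta = 2*pi*doy/365 - pi; strictly increasing, with doy = 365 -> pi.
    """
    doy = np.asarray(doy, dtype=float)
    if np.any(doy <= 0) or np.any(doy > 365):
        raise ValueError("day-of-year must lie in (0, 365]")
    # divide first so doy = 365 lands exactly on pi (not one ulp above)
    theta = np.minimum(2.0 * np.pi * (doy / 365.0) - np.pi, np.pi)
    return float(theta) if theta.ndim == 0 else theta


def radians_to_day(theta: float | np.ndarray) -> float | np.ndarray:
    """Inverse of :func:`day_to_radians`; wraps inputs outside (-pi, pi]."""
    theta = np.asarray(theta, dtype=float)
    # wrap into (-pi, pi]
    wrapped = -(np.mod(-theta + np.pi, 2.0 * np.pi) - np.pi)
    doy = (wrapped + np.pi) * 365.0 / (2.0 * np.pi)
    doy = np.where(doy <= 0.0, doy + 365.0, doy)
    return float(doy) if doy.ndim == 0 else doy


def _parse_event_date(value) -> tuple[int, int, int] | None:
    """Parse an ISO eventDate into (year, month, day); None if unusable.

    Records without a full day (bare years, year-month, ranges) cannot be
    placed on the circle and are rejected rather than imputed.
    """
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    text = str(value).strip()
    if not text:
        return None
    # take the start of an ISO interval "a/b"
    text = text.split("/")[0].split("T")[0]
    parts = text.split("-")
    if len(parts) != 3:
        return None
    try:
        y, m, d = (int(p) for p in parts)
        _dt.date(y, m, d)
    except ValueError:
        return None
    return y, m, d


def _coerce_int(value) -> int | None:
    try:
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return None
        return int(float(value))
    except (TypeError, ValueError):
        return None


def _coerce_float(value) -> float | None:
    try:
        out = float(value)
    except (TypeError, ValueError):
        return None
    return None if math.isnan(out) else out


def records_from_frame(
    frame: pd.DataFrame,
    preserved_values: Iterable[str] = PRESERVED_SPECIMEN_VALUES,
) -> list[SpecimenRecord]:
    """Convert a raw occurrence DataFrame into validated SpecimenRecords.

    Rows are dropped (and counted in the log) when the species is missing,
    the date is absent/invalid, or the basis of record is not a preserved
    specimen.  Split year/month/day columns win over eventDate when both
    are present; if the two disagree the row is dropped.
    """
    species_col = next((c for c in _SPECIES_COLUMNS if c in frame.columns), None)
    if species_col is None:
        raise SchemaError("missing mandatory column: scientificName (or species)")
    if "basisOfRecord" not in frame.columns:
        raise SchemaError("missing mandatory column: basisOfRecord")
    if "occurrenceID" not in frame.columns:
        raise SchemaError("missing mandatory column: occurrenceID")
    has_split = all(c in frame.columns for c in ("year", "month", "day"))
    if not has_split and "eventDate" not in frame.columns:
        raise SchemaError("missing mandatory column: eventDate (or year/month/day)")

    preserved = frozenset(preserved_values)
    records: list[SpecimenRecord] = []
    n_bad_date = n_bad_species = n_not_specimen = n_conflict = 0
    for row in frame.itertuples(index=False):
        row_d = row._asdict() if hasattr(row, "_asdict") else dict(zip(frame.columns, row))
        species = row_d.get(species_col)
        if species is None or (isinstance(species, float) and math.isnan(species)) or not str(species).strip():
            n_bad_species += 1
            continue
        basis = str(row_d.get("basisOfRecord", "")).strip()
        if basis not in preserved:
            n_not_specimen += 1
            continue

        split_date = None
        if has_split:
            y = _coerce_int(row_d.get("year"))
            m = _coerce_int(row_d.get("month"))
            d = _coerce_int(row_d.get("day"))
            if y is not None and m is not None and d is not None:
                try:
                    _dt.date(y, m, d)
                    split_date = (y, m, d)
                except ValueError:
                    n_bad_date += 1
                    continue
        iso_date = _parse_event_date(row_d.get("eventDate"))
        if split_date is not None and iso_date is not None and split_date != iso_date:
            n_conflict += 1
            continue
        date = split_date or iso_date
        if date is None:
            n_bad_date += 1
            continue

        records.append(
            SpecimenRecord(
                species=str(species).strip(),
                occurrence_id=str(row_d.get("occurrenceID", "")),
                event_year=date[0],
                event_month=date[1],
                event_day=date[2],
                basis_of_record=basis,
                latitude=_coerce_float(row_d.get("decimalLatitude")),
                longitude=_coerce_float(row_d.get("decimalLongitude")),
            )
        )
    logger.info(
        "parsed %d records (dropped: %d bad date, %d missing species, "
        "%d non-specimen basis, %d date conflicts)",
        len(records), n_bad_date, n_bad_species, n_not_specimen, n_conflict,
    )
    return records


def read_occurrences(
    path,
    preserved_values: Iterable[str] = PRESERVED_SPECIMEN_VALUES,
) -> list[SpecimenRecord]:
    """Read a tab- or comma-separated Darwin Core-style occurrence file."""
    frame = pd.read_csv(path, sep=None, engine="python", dtype=str)
    return records_from_frame(frame, preserved_values)


def records_to_frame(records: Sequence[SpecimenRecord]) -> pd.DataFrame:
    """Normalized Darwin Core-style DataFrame for export."""
    return pd.DataFrame(
        {
            "scientificName": [r.species for r in records],
            "occurrenceID": [r.occurrence_id for r in records],
            "eventDate": [
                f"{r.event_year:04d}-{r.event_month:02d}-{r.event_day:02d}" for r in records
            ],
            "year": [r.event_year for r in records],
            "month": [r.event_month for r in records],
            "day": [r.event_day for r in records],
            "basisOfRecord": [r.basis_of_record for r in records],
            "decimalLatitude": [r.latitude for r in records],
            "decimalLongitude": [r.longitude for r in records],
        }
    )


def build_series(
    records: Sequence[SpecimenRecord], species: str
) -> list[CircularObservation]:
    """Observation series (year, doy, theta) for one species.

    Raises ``ValueError`` if the species has no records.
    """
    obs = []
    for r in records:
        if r.species != species:
            continue
        doy = day_of_year(r.event_year, r.event_month, r.event_day)
        obs.append(CircularObservation(year=r.event_year, doy=doy, theta=float(day_to_radians(doy))))
    if not obs:
        raise ValueError(f"no records for species {species!r}")
    return obs


def species_in(records: Sequence[SpecimenRecord]) -> list[str]:
    """Distinct species names in first-appearance order."""
    seen: dict[str, None] = {}
    for r in records:
        seen.setdefault(r.species, None)
    return list(seen)
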