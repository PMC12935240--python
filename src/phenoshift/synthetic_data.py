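"""Synthetic herbarium occurrence generator.

Emulates the statistical structure the downstream analysis assumes:
per-species flowering dates on the calendar circle following a Von Mises
distribution whose mean day drifts linearly in time, collection effort
uneven across years (including an optional early-20th-century dip in
collecting), and occasional multiple specimens on one day.  The point is
to make every pipeline stage testable offline, with known ground truth.
"""

from __future__ import annotations

import calendar
import datetime as _dt
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .records_io import day_to_radians, radians_to_day

__all__ = ["SimSpeciesSpec", "SimConfig", "simulate_records", "simulate_bm_trait"]


@dataclass(frozen=True)
class SimSpeciesSpec:
    """Generative parameters for one simulated species.

    Parameters
    ----------
    species_id:
        Label used as scientificName in the output table.
    mean_doy_at_ref:
        Mean flowering day-of-year at the reference year (midpoint of
        ``year_range``), in [1, 365].
    drift_days_per_decade:
        Signed true shift of the mean flowering day, days per decade.
    kappa:
        Von Mises concentration of flowering dates about the mean
        (kappa = 15 keeps ~95% of dates within about +/-30 days).
    records_per_year_rate:
        Expected number of collections per calendar year.
    year_range:
        (first_year, last_year), inclusive.
    effort_dip:
        Optional (start_year, end_year, multiplier): within the window the
        collection rate is multiplied by ``multiplier`` in [0, 1],
        emulating depressed collecting (e.g. the 1914-1945 war decades).
    """

    species_id: str
    mean_doy_at_ref: float
    drift_days_per_decade: float
    kappa: float
    records_per_year_rate: float
    year_range: tuple[int, int]
    effort_dip: tuple[int, int, float] | None = None

    def __post_init__(self):
        if not self.kappa > 0:
            raise ValueError(f"kappa must be > 0, got {self.kappa}")
        if not (1 <= self.mean_doy_at_ref <= 365):
            raise ValueError("mean_doy_at_ref must lie in [1, 365]")
        if self.records_per_year_rate < 0:
            raise ValueError("records_per_year_rate must be >= 0")
        first, last = self.year_range
        if not first < last:
            raise ValueError("year_range must satisfy first_year < last_year")
        if self.effort_dip is not None:
            _, _, mult = self.effort_dip
            if not 0.0 <= mult <= 1.0:
                raise ValueError("effort dip multiplier must lie in [0, 1]")

    @property
    def ref_year(self) -> float:
        first, last = self.year_range
        return (first + last) / 2.0


@dataclass
class SimConfig:
    species: list[SimSpeciesSpec] = field(default_factory=list)
    seed: int = 0
    max_per_day: int | None = None


def _species_rng(master_seed: int, species_id: str) -> np.random.Generator:
    # stable per-species stream: adding a species never perturbs the others
    tag = zlib.crc32(species_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([master_seed, tag]))


def _effort_weights(spec: SimSpeciesSpec) -> tuple[np.ndarray, np.ndarray]:
    first, last = spec.year_range
    years = np.arange(first, last + 1)
    weights = np.full(years.shape, spec.records_per_year_rate, dtype=float)
    if spec.effort_dip is not None:
        d0, d1, mult = spec.effort_dip
        weights[(years >= d0) & (years <= d1)] *= mult
    return years, weights


def _doy_to_date(year: int, doy: float) -> tuple[int, int]:
    """Leap-scaled day-of-year -> (month, day) in the given calendar year."""
    days_in_year = 366 if calendar.isleap(year) else 365
    ordinal = doy * days_in_year / 365.0
    ordinal_int = int(np.clip(round(ordinal), 1, days_in_year))
    date = _dt.date(year, 1, 1) + _dt.timedelta(days=ordinal_int - 1)
    return date.month, date.day


def simulate_records(config: SimConfig) -> pd.DataFrame:
    """Generate an occurrence table in the Darwin Core-style schema.

    For each species, per-year record counts are Poisson with the
    effort-weighted rate; each record's day-of-year is a Von Mises draw
    centered on the drifting mean (mean_doy_at_ref + drift * elapsed
    decades from the midpoint reference year), wrapped across Dec 31, and
    realized as a valid Gregorian calendar date.  Deterministic under
    ``config.seed``.
    """
    rows = []
    for spec in config.species:
        rng = _species_rng(config.seed, spec.species_id)
        years, weights = _effort_weights(spec)
        counts = rng.poisson(weights)
        mu_ref = float(day_to_radians(spec.mean_doy_at_ref))
        idx = 0
        per_day: dict[tuple[int, int, int], int] = {}
        for year, count in zip(years, counts):
            if count == 0:
                continue
            drift_rad = (
                2.0 * np.pi / 365.0
                * spec.drift_days_per_decade
                * (year - spec.ref_year) / 10.0
            )
            thetas = rng.vonmises(mu_ref + drift_rad, spec.kappa, size=count)
            for theta in thetas:
                doy = float(radians_to_day(theta))
                month, day = _doy_to_date(int(year), doy)
                if config.max_per_day is not None:
                    key = (int(year), month, day)
                    per_day[key] = per_day.get(key, 0) + 1
                    if per_day[key] > config.max_per_day:
                        continue
                rows.append(
                    {
                        "scientificName": spec.species_id,
                        "occurrenceID": f"{spec.species_id}:{idx:05d}",
                        "eventDate": f"{year:04d}-{month:02d}-{day:02d}",
                        "year": int(year),
                        "month": month,
                        "day": day,
                        "basisOfRecord": "PRESERVED_SPECIMEN",
                        "decimalLatitude": None,
                        "decimalLongitude": None,
                    }
                )
                idx += 1
    return pd.DataFrame(
        rows,
        columns=[
            "scientificName", "occurrenceID", "eventDate", "year", "month",
            "day", "basisOfRecord", "decimalLatitude", "decimalLongitude",
        ],
    )


def write_records(frame: pd.DataFrame, path) -> None:
    """Write the occurrence table as tab-separated Darwin Core-style text."""
    frame.to_csv(path, sep="\t", index=False)


def load_sim_config(path) -> SimConfig:
    """Read a simulation config from YAML (keys mirror SimSpeciesSpec)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    species = [
        SimSpeciesSpec(
            species_id=str(s["species_id"]),
            mean_doy_at_ref=float(s["mean_doy_at_ref"]),
            drift_days_per_decade=float(s.get("drift_days_per_decade", 0.0)),
            kappa=float(s["kappa"]),
            records_per_year_rate=float(s["records_per_year_rate"]),
            year_range=tuple(int(v) for v in s["year_range"]),
            effort_dip=(
                tuple(s["effort_dip"][:2]) + (float(s["effort_dip"][2]),)
                if s.get("effort_dip")
                else None
            ),
        )
        for s in raw.get("species", [])
    ]
    return SimConfig(
        species=species,
        seed=int(raw.get("seed", 0)),
        max_per_day=raw.get("max_per_day"),
    )


def simulate_bm_trait(tree, sigma2: float, seed: int) -> dict[str, float]:
    """Simulate one Brownian-motion trait vector on a phylogeny.

    Draws from a multivariate normal with covariance ``sigma2`` times the
    phylogenetic covariance matrix (shared root-to-MRCA path lengths).
    Returns a tip-label -> value mapping; deterministic under ``seed``.

    Raises ``ValueError`` when any branch length is missing or
    non-positive (assign lengths first, e.g. with
    :func:`phenoshift.phylo_signal.grafen_branch_lengths`).
    """
    from .phylo_signal import phylo_vcv

    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        if edge.length is None or edge.length <= 0:
            raise ValueError(
                "tree has missing or non-positive branch lengths; "
                "assign them first (see grafen_branch_lengths)"
            )
    labels, vcv = phylo_vcv(tree)
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(vcv + 1e-12 * np.eye(len(labels)))
    values = np.sqrt(sigma2) * chol @ rng.standard_normal(len(labels))
    return dict(zip(labels, values.tolist()))
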