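"""Shared fixtures: hand-built occurrence records and a fixed test tree."""

from __future__ import annotations

import numpy as np
import pytest

from phenoshift.records_io import SpecimenRecord


def make_record(species, year, month, day, occ=None):
    return SpecimenRecord(
        species=species,
        occurrence_id=occ or f"{species}:{year:04d}-{month:02d}-{day:02d}",
        event_year=year,
        event_month=month,
        event_day=day,
        basis_of_record="PRESERVED_SPECIMEN",
    )


def _spread(species, years, months, per_year=1, day_step=3):
    """Deterministic records for one species: ``per_year`` records in each
    (year, month) combination, on distinct days."""
    out = []
    for y in years:
        for m in months:
            for k in range(per_year):
                out.append(make_record(species, y, m, 1 + k * day_step, occ=f"{species}:{y}:{m}:{k}"))
    return out


@pytest.fixture(scope="session")
def six_species_records():
    """Six species exercising each inclusion rule.

    Hand-tallied facts (records are one per (year, month) unless noted):

    - alpha: months Mar-Jun (4, consecutive); 15 years x 4 months = 60
      records over 1900-2000; 28 records in 1900-1955, 32 in 1960-2000.
    - bravo: months Dec-Feb (3, consecutive ACROSS the year wrap);
      years 1950-2000; 55 records of which 10 are same-day duplicates;
      45 distinct days; 18 records before 1960, 37 from 1960 on.
    - charlie: months Jan-Jun (6) -> always fails the month cap.
    - delta: months Jan + Jun (2, NOT consecutive) -> fails contiguity.
    - echo: compliant months but only 12 records -> fails the count floor.
    - foxtrot: 4 consecutive months, 25 records, years 1990-2010 only
      (span 20) -> fails span rows, passes the post-1960 window row.
    """
    records = []
    # alpha: 1900..1955 (7 years x 4 = 28), 1960..2000 (8 years x 4 = 32)
    alpha_years = [1900, 1910, 1920, 1930, 1940, 1950, 1955, 1960, 1965, 1970, 1975, 1980, 1985, 1990, 2000]
    records += _spread("alpha", alpha_years, [3, 4, 5, 6])
    # bravo: 11 years x 3 months = 33 base records + 12 extra distinct-day
    # records + 10 same-day duplicates of the first December record
    bravo_years = [1950, 1955, 1960, 1965, 1970, 1975, 1980, 1985, 1990, 1995, 2000]
    records += _spread("bravo", bravo_years, [12, 1, 2])
    records += [make_record("bravo", y, 1, 20, occ=f"bravo:x:{y}") for y in bravo_years + [1962]]
    records += [make_record("bravo", 1950, 12, 1, occ=f"bravo:dup{k:02d}") for k in range(10)]
    # charlie: 6 months
    records += _spread("charlie", [1950, 1960, 1970, 1980, 1990, 2000, 2010], [1, 2, 3, 4, 5, 6])
    # delta: non-contiguous months
    records += _spread("delta", [1950, 1955, 1960, 1965, 1970, 1975, 1980, 1985, 1990, 1995, 2000, 2005], [1, 6])
    # echo: too few records
    records += _spread("echo", [1950, 1970, 1990], [3, 4, 5, 6])
    # foxtrot: short, recent span
    records += _spread("foxtrot", [1990, 1995, 2000, 2005, 2010], [3, 4, 5, 6], per_year=1)
    records += [make_record("foxtrot", 1992, 3, 15 + k, occ=f"foxtrot:y{k}") for k in range(5)]
    return records


def random_topology_newick(n_tips: int, seed: int) -> str:
    """Deterministic random binary topology (no branch lengths)."""
    rng = np.random.default_rng(seed)
    nodes = [f"t{i:02d}" for i in range(1, n_tips + 1)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b})")
    return nodes[0] + ";"


@pytest.fixture(scope="session")
def tree33():
    """Fixed 33-tip tree with Grafen branch lengths."""
    import dendropy

    from phenoshift.phylo_signal import grafen_branch_lengths

    topo = dendropy.Tree.get(data=random_topology_newick(33, seed=20240901), schema="newick")
    return grafen_branch_lengths(topo)
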