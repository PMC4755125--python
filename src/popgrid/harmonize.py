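"""Census harmonization: reallocate counts onto a fixed target zone set.

All census years are fitted and redistributed over one time-invariant target
tessellation (a GAUL level-3 analog).  A source unit falling (effectively)
wholly inside one target contributes its whole count there; a unit straddling
several targets contributes ``count * intersection_area / source_area`` to
each.  Totals are conserved exactly up to mass falling outside every target,
which is tracked and reported rather than silently dropped.

The average spatial resolution (ASR) summary — the side length of the mean
square unit, ``sqrt(total_area / n_units)`` — quantifies the granularity of a
census tessellation in km.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from shapely.geometry.base import BaseGeometry
from shapely.strtree import STRtree
from shapely.validation import make_valid

from .zones import PolygonSet

logger = logging.getLogger(__name__)

#: A source is "contained" in a target when at least this share of its area
#: falls inside — absorbs sliver mismatches between digitized boundary sets.
CONTAINMENT_SHARE = 0.999


class HarmonizeError(Exception):
    pass


@dataclass
class CensusUnit:
    """One source census polygon with its population count."""

    unit_id: int
    polygon: BaseGeometry
    count: float
    year: str = ""

    def __post_init__(self) -> None:
        if self.count < 0:
            raise HarmonizeError(f"unit {self.unit_id}: count must be >= 0")
        if self.polygon.area <= 0:
            raise HarmonizeError(f"unit {self.unit_id}: polygon area must be > 0")


@dataclass
class HarmonizedCensus:
    """Counts on the fixed target zones; every target id is present."""

    counts: dict[int, float]
    year: str = ""
    source_total: float = 0.0
    unallocated: float = 0.0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise HarmonizeError("harmonized counts must be non-negative")

    @property
    def total(self) -> float:
        return float(sum(self.counts.values()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"target_zone_id": list(self.counts), "count": list(self.counts.values()),
             "year": self.year}
        ).sort_values("target_zone_id", ignore_index=True)

    def report(self) -> dict:
        return {
            "year": self.year,
            "source_total": self.source_total,
            "harmonized_total": self.total,
            "unallocated": self.unallocated,
        }


def reallocate_counts(
    sources: Iterable[CensusUnit],
    targets: PolygonSet,
    containment_share: float = CONTAINMENT_SHARE,
    repair: bool = True,
    year: str = "",
) -> HarmonizedCensus:
    """Area-weighted reallocation of source counts onto the target zones.

    Parameters
    ----------
    sources
        Census units of one year in the working CRS.
    targets
        The fixed target tessellation (same CRS).
    containment_share
        Minimum share of a source's area inside a single target for the
        count to be assigned completely to that target.
    repair
        Repair invalid geometries with ``make_valid`` before intersecting;
        if False, invalid geometry raises.

    Notes
    -----
    A source intersecting no target is logged and its count accumulated in
    ``unallocated``; partial overlaps likewise leave the uncovered share
    unallocated, so ``harmonized_total + unallocated == source_total``.
    """
    sources = list(sources)
    target_geoms = []
    target_ids = []
    for u in targets:
        geom = u.polygon
        if not geom.is_valid:
            if not repair:
                raise HarmonizeError(f"target {u.unit_id}: invalid geometry")
            geom = make_valid(geom)
        target_geoms.append(geom)
        target_ids.append(u.unit_id)
    tree = STRtree(target_geoms)

    counts: dict[int, float] = {tid: 0.0 for tid in target_ids}
    source_total = 0.0
    unallocated = 0.0
    for src in sources:
        source_total += src.count
        geom = src.polygon
        if not geom.is_valid:
            if not repair:
                raise HarmonizeError(f"source {src.unit_id}: invalid geometry")
            geom = make_valid(geom)
        src_area = geom.area
        cand = tree.query(geom)
        shares: list[tuple[int, float]] = []
        for j in cand:
            inter = geom.intersection(target_geoms[j])
            if not inter.is_empty and inter.area > 0:
                shares.append((target_ids[j], inter.area / src_area))
        if not shares:
            logger.warning(
                "source %s (count %s) intersects no target; count unallocated",
                src.unit_id, src.count,
            )
            unallocated += src.count
            continue
        best_id, best_share = max(shares, key=lambda t: t[1])
        if best_share >= containment_share:
            counts[best_id] += src.count
            continue
        covered = 0.0
        for tid, share in shares:
            counts[tid] += src.count * share
            covered += share
        if covered < 1.0 - 1e-12:
            unallocated += src.count * (1.0 - covered)

    return HarmonizedCensus(
        counts=counts, year=year, source_total=source_total, unallocated=unallocated
    )


def compute_asr(total_area_km2: float, n_units: int) -> float:
    """Average spatial resolution in km: side of the mean square unit.

    ``ASR = sqrt(total_area / n_units)`` — the edge length the units would
    have if the study area were tiled by equal squares.
    """
    if n_units < 1:
        raise HarmonizeError("n_units must be >= 1")
    if total_area_km2 <= 0:
        raise HarmonizeError("total_area must be > 0")
    return math.sqrt(total_area_km2 / n_units)


def write_harmonized(path: str | Path, census: HarmonizedCensus) -> Path:
    """Serialize as CSV (target_zone_id, count, year)."""
    path = Path(path)
    census.to_frame().to_csv(path, index=False)
    return path


def read_census_table(path: str | Path) -> pd.DataFrame:
    """Read a census CSV with columns unit_id, population, year."""
    df = pd.read_csv(path)
    required = {"unit_id", "population", "year"}
    if not required.issubset(df.columns):
        raise HarmonizeError(f"census CSV must have columns {sorted(required)}")
    return df
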