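"""Reading, validation and aggregation of mountain-road occurrence surveys.

The surveys follow the MIREN road-survey layout: within each region a few
roads are stratified by elevation into ~20 transects, each transect holding
up to three plots (0, 50 and 100 m from the road verge). Species records
from the plots of one transect are collapsed to presence-absence per
transect, which is the unit every downstream analysis works on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

VALID_DISTANCE_CLASSES = (0, 50, 100)

#: canonical column names of the long-format occurrence layout
OCCURRENCE_COLUMNS = (
    "region",
    "road",
    "transect",
    "elevation",
    "distance_class",
    "year",
    "species",
)


class SchemaError(ValueError):
    """A required column is missing or the schema mapping is invalid."""


class InputError(ValueError):
    """The input table exists but cannot be used (empty, unparseable rows)."""


@dataclass(frozen=True)
class OccurrenceRecord:
    """One species observation in one plot of one transect in one survey year."""

    region: str
    road: str
    transect: str
    elevation: float
    distance_class: int
    year: int
    species: str
    abundance_class: int | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.elevation):
            raise InputError(f"non-finite elevation for {self.species!r} in {self.region!r}")
        if self.distance_class not in VALID_DISTANCE_CLASSES:
            raise InputError(
                f"distance_class {self.distance_class!r} not in {VALID_DISTANCE_CLASSES}"
            )


@dataclass(frozen=True)
class RegionDesign:
    """Sampling frame of one region: gradient bounds, roads and survey years."""

    bounds: tuple[float, float]
    years: tuple[int, ...]
    roads: Mapping[str, tuple[float, ...]]  # road -> transect elevations

    def __post_init__(self) -> None:
        lo, hi = self.bounds
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError(f"invalid gradient bounds {self.bounds}")
        if len(self.years) < 2:
            raise ValueError("a region needs at least two survey years")
        for road, elevs in self.roads.items():
            arr = np.asarray(elevs, dtype=float)
            if arr.size and (arr.min() < lo or arr.max() > hi):
                raise ValueError(f"road {road!r} has transects outside bounds {self.bounds}")

    @property
    def elevations(self) -> np.ndarray:
        """Sorted unique transect elevations across all roads."""
        vals = np.concatenate([np.asarray(e, dtype=float) for e in self.roads.values()])
        return np.unique(vals)

    @property
    def interval_years(self) -> int:
        return max(self.years) - min(self.years)


@dataclass(frozen=True)
class SurveyDesign:
    """Sampling frames for a set of regions."""

    regions: Mapping[str, RegionDesign]

    def __getitem__(self, region: str) -> RegionDesign:
        try:
            return self.regions[region]
        except KeyError:
            raise KeyError(f"unknown region {region!r}") from None


@dataclass
class PresenceTable:
    """Per-transect presence-absence of one region in one survey year.

    ``occupancy`` has one row per occupied (species, transect) pair with the
    transect elevation attached; a species' occurrence frequency is its number
    of occupied transects.
    """

    region: str
    year: int
    occupancy: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"species", "transect", "elevation"}
        missing = required - set(self.occupancy.columns)
        if missing:
            raise SchemaError(f"presence table missing columns {sorted(missing)}")
        if self.occupancy.duplicated(["species", "transect"]).any():
            raise InputError("duplicate (species, transect) rows in presence table")

    @property
    def species(self) -> list[str]:
        return sorted(self.occupancy["species"].unique())

    def frequency(self, species: str | None = None):
        """Occupied-transect count per species (or for one species)."""
        counts = self.occupancy.groupby("species")["transect"].nunique()
        if species is None:
            return counts
        return int(counts.get(species, 0))

    def occupied_elevations(self, species: str) -> np.ndarray:
        sub = self.occupancy.loc[self.occupancy["species"] == species, "elevation"]
        return np.sort(sub.to_numpy(dtype=float))

    def drop_species(self, species: Iterable[str]) -> "PresenceTable":
        drop = set(species)
        keep = ~self.occupancy["species"].isin(drop)
        return PresenceTable(self.region, self.year, self.occupancy.loc[keep].reset_index(drop=True))

    def to_records(self) -> list[OccurrenceRecord]:
        """Expand back to one roadside (0 m) record per occupied transect."""
        return [
            OccurrenceRecord(
                region=self.region,
                road=str(row.get("road", "NA")),
                transect=str(row["transect"]),
                elevation=float(row["elevation"]),
                distance_class=0,
                year=self.year,
                species=str(row["species"]),
            )
            for _, row in self.occupancy.iterrows()
        ]


#: mapping (region, year) -> PresenceTable
PresenceTables = dict


def read_occurrences(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> list[OccurrenceRecord]:
    """Read a long-format occurrence CSV into validated records.

    Parameters
    ----------
    path:
        CSV with one row per species x plot x survey year.
    schema:
        Optional mapping from canonical column names (``region``, ``road``,
        ``transect``, ``elevation``, ``distance_class``, ``year``,
        ``species``, ``abundance_class``) to the file's column names.
        Unmapped canonical names are looked up verbatim; extra file columns
        are ignored.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    df = pd.read_csv(path)
    if df.empty:
        raise InputError(f"empty occurrence table: {path}")

    schema = dict(schema or {})
    colmap = {name: schema.get(name, name) for name in OCCURRENCE_COLUMNS}
    missing = [src for src in colmap.values() if src not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns {missing} in {path}")
    abundance_col = schema.get("abundance_class", "abundance_class")
    has_abundance = abundance_col in df.columns

    records: list[OccurrenceRecord] = []
    bad_rows: list[tuple[int, str]] = []
    for idx, row in df.iterrows():
        try:
            elevation = float(row[colmap["elevation"]])
            year = int(row[colmap["year"]])
            distance = int(row[colmap["distance_class"]])
            abundance = None
            if has_abundance and not pd.isna(row[abundance_col]):
                abundance = int(row[abundance_col])
            records.append(
                OccurrenceRecord(
                    region=str(row[colmap["region"]]),
                    road=str(row[colmap["road"]]),
                    transect=str(row[colmap["transect"]]),
                    elevation=elevation,
                    distance_class=distance,
                    year=year,
                    species=str(row[colmap["species"]]),
                    abundance_class=abundance,
                )
            )
        except (ValueError, TypeError, InputError) as exc:
            bad_rows.append((int(idx), str(exc)))
    if bad_rows:
        shown = "; ".join(f"row {i}: {msg}" for i, msg in bad_rows[:10])
        raise InputError(f"{len(bad_rows)} unparseable rows in {path}: {shown}")
    return records


def collapse_to_presence(
    records: Sequence[OccurrenceRecord],
    distance_classes: Iterable[int] | None = None,
) -> PresenceTables:
    """Collapse plot-level records to per-transect presence-absence.

    Records from the plots of one transect (0/50/100 m) count as a single
    presence; ``distance_classes`` restricts which plots contribute (default:
    all three, the main-analysis setting).
    """
    if distance_classes is not None:
        keep = set(int(d) for d in distance_classes)
        unknown = keep - set(VALID_DISTANCE_CLASSES)
        if unknown:
            raise ValueError(f"unknown distance classes {sorted(unknown)}")
        records = [r for r in records if r.distance_class in keep]
    if not records:
        raise InputError("no records left after distance-class filtering")

    df = pd.DataFrame(
        {
            "region": [r.region for r in records],
            "year": [r.year for r in records],
            "species": [r.species for r in records],
            "transect": [r.transect for r in records],
            "elevation": [r.elevation for r in records],
        }
    )
    # one transect must sit at one elevation
    n_elev = df.groupby(["region", "transect"])["elevation"].nunique()
    conflicts = n_elev[n_elev > 1]
    if len(conflicts):
        raise InputError(
            f"transects with conflicting elevations: {list(conflicts.index[:5])}"
        )

    tables: PresenceTables = {}
    for (region, year), sub in df.groupby(["region", "year"]):
        occ = (
            sub.drop_duplicates(["species", "transect"])[["species", "transect", "elevation"]]
            .sort_values(["species", "transect"])
            .reset_index(drop=True)
        )
        tables[(region, int(year))] = PresenceTable(str(region), int(year), occ)
    return tables


_FILTER_MIN_FREQ = {"singleton": 2, "f1": 6, "f2": 11, "f3": 11}


def apply_filters(
    tables: PresenceTables,
    filter_id: str = "singleton",
    min_species_per_region: int = 5,
) -> tuple[PresenceTables, pd.DataFrame]:
    """Filter species by occurrence frequency; drop under-populated regions.

    ``singleton`` removes species recorded once in a region over all years;
    ``f1``/``f2`` keep species with >5 / >10 occurrences per region over all
    years; ``f3`` keeps species with >10 occurrences per region in both the
    first and last survey year (strict inequalities throughout). Regions left
    with fewer than ``min_species_per_region`` species are excluded.

    Returns the filtered tables plus an exclusion report with columns
    (region, species, reason).
    """
    if filter_id not in _FILTER_MIN_FREQ:
        raise ValueError(f"unknown filter_id {filter_id!r}; use one of {sorted(_FILTER_MIN_FREQ)}")
    min_freq = _FILTER_MIN_FREQ[filter_id]

    regions = sorted({region for region, _ in tables})
    report_rows: list[dict] = []
    out: PresenceTables = {}
    for region in regions:
        years = sorted(year for reg, year in tables if reg == region)
        region_tables = {year: tables[(region, year)] for year in years}

        freq_total: dict[str, int] = {}
        for table in region_tables.values():
            for sp, n in table.frequency().items():
                freq_total[sp] = freq_total.get(sp, 0) + int(n)

        excluded: set[str] = set()
        if filter_id == "f3":
            first, last = region_tables[years[0]], region_tables[years[-1]]
            for sp in freq_total:
                if first.frequency(sp) < min_freq or last.frequency(sp) < min_freq:
                    excluded.add(sp)
            reason = f"frequency <= 10 in first or last year ({filter_id})"
        else:
            for sp, n in freq_total.items():
                if n < min_freq:
                    excluded.add(sp)
            reason = (
                "recorded once in region (singleton)"
                if filter_id == "singleton"
                else f"total frequency <= {min_freq - 1} ({filter_id})"
            )
        for sp in sorted(excluded):
            report_rows.append({"region": region, "species": sp, "reason": reason})

        kept_species = set(freq_total) - excluded
        if len(kept_species) < min_species_per_region:
            report_rows.append(
                {
                    "region": region,
                    "species": "*",
                    "reason": f"fewer than {min_species_per_region} species after {filter_id}",
                }
            )
            continue
        for year, table in region_tables.items():
            out[(region, year)] = table.drop_species(excluded)

    report = pd.DataFrame(report_rows, columns=["region", "species", "reason"])
    return out, report


def surveyed_elevations(
    design: SurveyDesign,
    region: str,
    scope: str = "region",
):
    """Transect elevations of a region, pooled or per road.

    ``scope='region'`` returns the sorted unique elevations across roads (the
    candidate vector of the null model's default variant); ``scope='per_road'``
    returns a mapping road -> sorted unique elevations.
    """
    rd = design[region]
    if scope == "region":
        return rd.elevations
    if scope == "per_road":
        return {road: np.unique(np.asarray(e, dtype=float)) for road, e in rd.roads.items()}
    raise ValueError(f"unknown scope {scope!r}; use 'region' or 'per_road'")


def design_from_records(records: Sequence[OccurrenceRecord]) -> SurveyDesign:
    """Infer the sampling frame from occurrence records.

    Gradient bounds are the min/max transect elevation seen per region, roads
    and transects come from the record labels, years from the survey years
    observed. Adequate when the occurrence table covers every surveyed
    transect; otherwise declare the design explicitly.
    """
    per_region: dict[str, dict] = {}
    for r in records:
        info = per_region.setdefault(r.region, {"roads": {}, "years": set()})
        info["roads"].setdefault(r.road, {})[r.transect] = r.elevation
        info["years"].add(r.year)
    regions = {}
    for region, info in per_region.items():
        roads = {
            road: tuple(sorted(transects.values())) for road, transects in info["roads"].items()
        }
        elevs = [e for t in info["roads"].values() for e in t.values()]
        regions[region] = RegionDesign(
            bounds=(min(elevs), max(elevs)),
            years=tuple(sorted(info["years"])),
            roads=roads,
        )
    return SurveyDesign(regions=regions)


def write_presence_tables(tables: PresenceTables, path: str | Path) -> None:
    """Serialize presence tables to one long CSV (region, year, species, transect, elevation)."""
    frames = []
    for (region, year), table in sorted(tables.items()):
        df = table.occupancy.copy()
        df.insert(0, "year", year)
        df.insert(0, "region", region)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_presence_tables(path: str | Path) -> PresenceTables:
    """Inverse of :func:`write_presence_tables`."""
    df = pd.read_csv(path)
    tables: PresenceTables = {}
    for (region, year), sub in df.groupby(["region", "year"]):
        occ = (
            sub[["species", "transect", "elevation"]]
            .astype({"species": str, "transect": str, "elevation": float})
            .sort_values(["species", "transect"])
            .reset_index(drop=True)
        )
        tables[(str(region), int(year))] = PresenceTable(str(region), int(year), occ)
    return tables
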