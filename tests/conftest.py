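import numpy as np
import pandas as pd
import pytest

from upslope import (
    OccurrenceRecord,
    RegionDesign,
    SurveyDesign,
    SyntheticParams,
    collapse_to_presence,
    generate_design,
    generate_spread_dataset,
)


@pytest.fixture
def toy_records():
    """Two regions, two waves; species with controlled frequencies."""
    rows = []

    def add(region, road, transect, elev, dist, year, species):
        rows.append(
            OccurrenceRecord(
                region=region, road=road, transect=transect, elevation=elev,
                distance_class=dist, year=year, species=species,
            )
        )

    # region A: speciesX in 2 transects both years; speciesY in 1 transect once
    for year in (2008, 2018):
        add("A", "r1", "t1", 600.0, 0, year, "speciesX")
        add("A", "r1", "t1", 600.0, 50, year, "speciesX")  # duplicate plot, same transect
        add("A", "r1", "t2", 800.0, 0, year, "speciesX")
    add("A", "r1", "t3", 1000.0, 0, 2008, "speciesY")
    # region B: three species in both years
    for year in (2008, 2018):
        for sp, elevs in [("a", [500, 700]), ("b", [900]), ("c", [500, 900, 1100])]:
            for e in elevs:
                add("B", "r1", f"t{e}", float(e), 0, year, sp)
    return rows


@pytest.fixture
def toy_tables(toy_records):
    return collapse_to_presence(toy_records)


@pytest.fixture
def toy_design():
    roads = {
        "r1": tuple(np.linspace(500, 2000, 20)),
        "r2": tuple(np.linspace(500, 2000, 20)),
        "r3": tuple(np.linspace(510, 1990, 20)),
    }
    region = RegionDesign(bounds=(500.0, 2000.0), years=(2008, 2013, 2018), roads=roads)
    return SurveyDesign(regions={"R01": region})


@pytest.fixture(scope="session")
def spread_dataset():
    """One deterministic 3-region spread dataset shared across tests."""
    params = SyntheticParams(n_regions=3, n_species=30, seed=42)
    design = generate_design(params)
    tables, truth = generate_spread_dataset(design, params)
    return params, design, tables, truth
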