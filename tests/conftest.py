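"""Shared fixtures: small synthetic study components, all seeded."""

import numpy as np
import pandas as pd
import pytest

from aquamicrobe import synthetic as syn
from aquamicrobe.io_formats import ReadRecord


@pytest.fixture(scope="session")
def ref_db():
    return syn.default_reference_db(seed=1)


@pytest.fixture(scope="session")
def design():
    return syn.StudyDesign()


@pytest.fixture(scope="session")
def profiles(design, ref_db):
    return syn.simulate_communities(design, ref_db, seed=1)


@pytest.fixture(scope="session")
def root_day61_profile(profiles):
    return next(p for p in profiles if p.tank == 5 and p.compartment == "root" and p.day == 61)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_read(read_id="r1", sequence="ACGT", q=30):
    return ReadRecord(read_id, sequence, np.full(len(sequence), q, dtype=np.int64))


@pytest.fixture(scope="session")
def small_count_table():
    """Tiny 6-sample x 4-taxon table with tank/compartment/inoculum metadata."""
    counts = pd.DataFrame(
        {
            "Pseudomonas": [500, 450, 100, 120, 600, 90],
            "Rahnella": [50, 80, 400, 350, 30, 420],
            "Serratia": [200, 180, 210, 190, 220, 205],
            "Aeromonas": [250, 290, 290, 340, 150, 285],
        },
        index=[f"S{i}" for i in range(6)],
    )
    meta = pd.DataFrame(
        {
            "tank": [1, 2, 3, 4, 5, 6],
            "compartment": ["root"] * 6,
            "inoculum": ["EIT", "EIT", "CIT", "CIT", "EIT", "CIT"],
            "day": [61] * 6,
        },
        index=counts.index,
    )
    from aquamicrobe.io_formats import CountTable

    return CountTable(counts, meta)
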