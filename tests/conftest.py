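import numpy as np
import pytest

from uvbdemog import CohortCensus, FounderRecord, census_from_founders, study_scenario


def make_census(n_x, b_x, **meta):
    """Small helper: census with default metadata and contiguous days."""
    defaults = dict(
        cohort_id="c1",
        generation="F1",
        treatment="control",
        feeding="fed",
        replicate_id="r1",
    )
    defaults.update(meta)
    return CohortCensus(
        days=np.arange(len(n_x)), n_x=np.array(n_x), b_x=np.array(b_x), **defaults
    )


@pytest.fixture(scope="session")
def scenario():
    """The calibrated study scenario (session-scoped; calibration is pure)."""
    return study_scenario(seed=2025)


@pytest.fixture()
def toy_founders():
    """Five founders with distinct lifespans and birth schedules."""
    return [
        FounderRecord(death_day=3, births=[0, 2, 1]),
        FounderRecord(death_day=5, births=[0, 1, 3, 2, 0]),
        FounderRecord(death_day=2, births=[0, 4]),
        FounderRecord(death_day=6, births=[0, 0, 2, 2, 1, 0]),
        FounderRecord(death_day=4, births=[0, 3, 0, 1]),
    ]


@pytest.fixture()
def toy_cohort(toy_founders):
    return census_from_founders(toy_founders)
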