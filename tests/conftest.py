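import numpy as np
import pandas as pd
import pytest

import homeclass as hc


def build_population(persons, claims=None, dmh=None, amb=None, rx=None, deaths=None, shelters=None):
    """Hand-roll a LinkedPopulation from partial tables (tests only)."""
    empty = {
        "claims": pd.DataFrame(columns=["person_id", "source", "icd_codes"]),
        "dmh_records": pd.DataFrame(columns=["person_id", "month", "housing_status"]),
        "ambulance_records": pd.DataFrame(columns=["person_id", "narrative"]),
        "prescription_records": pd.DataFrame(columns=["person_id", "patient_address"]),
        "death_records": pd.DataFrame(columns=["person_id", "underlying_cause", "multiple_causes", "literal_text"]),
    }
    return hc.LinkedPopulation(
        persons=persons,
        claims=claims if claims is not None else empty["claims"],
        dmh_records=dmh if dmh is not None else empty["dmh_records"],
        ambulance_records=amb if amb is not None else empty["ambulance_records"],
        prescription_records=rx if rx is not None else empty["prescription_records"],
        death_records=deaths if deaths is not None else empty["death_records"],
        shelter_addresses=shelters if shelters is not None else ["123 MAIN ST BOSTON MA"],
    )


@pytest.fixture
def tiny_population():
    """Six persons exercising each known-case criterion exactly once.

    0: APCD Z590 claim + keyword narrative (two sources)
    1: CaseMix V60-family claim only
    2: DMH housing-loss month only
    3: shelter-matching prescription only
    4: background records, no signals
    5: no records at all
    """
    persons = pd.DataFrame(
        {
            "person_id": range(6),
            "age": [30, 45, 52, 28, 61, 19],
            "sex": ["M", "F", "M", "F", "F", "M"],
            "true_homeless": [True, True, True, True, False, False],
            "died_opioid_overdose": False,
        }
    )
    claims = pd.DataFrame(
        {
            "person_id": [0, 1, 4, 4],
            "source": ["APCD", "CaseMix", "APCD", "CaseMix"],
            "icd_codes": ["Z59.0;F1120", "v60.0", "I10", "J069"],
        }
    )
    dmh = pd.DataFrame(
        {
            "person_id": [2, 2, 4],
            "month": [0, 1, 0],
            "housing_status": ["housed", "housing_loss", "housed"],
        }
    )
    amb = pd.DataFrame(
        {
            "person_id": [0, 4],
            "narrative": ["pt found outside HOMELESS encampment", "chest pain at residence"],
        }
    )
    rx = pd.DataFrame(
        {
            "person_id": [3, 4],
            "patient_address": ["123  Main st., Boston MA", "45 OAK ST SALEM MA"],
        }
    )
    return build_population(persons, claims=claims, dmh=dmh, amb=amb, rx=rx)


@pytest.fixture(scope="session")
def small_population():
    """A seeded 30k-person default-config population, shared across tests."""
    return hc.generate_population(hc.SimulationConfig(n_persons=30_000, seed=42))


@pytest.fixture(scope="session")
def small_report():
    """A full pipeline run at n=60k, shared across tests."""
    cfg = hc.PipelineConfig(sim=hc.SimulationConfig(n_persons=60_000, seed=5), split_seed=6, downsample_seed=7)
    return hc.run_pipeline(cfg)
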