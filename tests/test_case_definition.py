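"""Composite known-case definition: code, keyword, address and DMH criteria."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from homeclass.case_definition import (
    address_matches_shelter,
    dmh_housing_loss,
    has_homeless_icd,
    identify_known_homeless,
    narrative_indicates_homeless,
    normalize_address,
    normalize_icd,
)


@pytest.mark.parametrize(
    "raw, expected",
    [
        ("V.60", "V60"),
        ("z59.0", "Z590"),
        (" t40.1 ", "T401"),
        ("X42", "X42"),
    ],
)
def test_normalize_icd(raw, expected):
    assert normalize_icd(raw) == expected


@pytest.mark.parametrize("bad", ["", "   ", None])
def test_normalize_icd_rejects_malformed(bad):
    with pytest.raises(ValueError):
        normalize_icd(bad)


@pytest.mark.parametrize(
    "codes, expected",
    [
        (["Z590"], True),
        (["z59.0"], True),
        (["V600", "I219"], True),
        (["V.60"], True),
        (["I219"], False),
        ([], False),
        (["Z5900"], False),  # only the exact Z590 code qualifies
    ],
)
def test_has_homeless_icd(codes, expected):
    assert has_homeless_icd(codes) is expected


def test_v60_prefix_flag_narrows_to_exact_code():
    assert has_homeless_icd(["V6041"], v60_prefix=True)
    assert not has_homeless_icd(["V6041"], v60_prefix=False)
    assert has_homeless_icd(["V60"], v60_prefix=False)


@pytest.mark.parametrize(
    "text, expected",
    [
        ("Pt is homeless, lives under bridge", True),
        ("picked up at Pine Street SHELTER", True),
        ("resides at home with spouse", False),
        ("", False),
        ("pt was sheltered in place", True),  # substring semantics by default
    ],
)
def test_narrative_keywords(text, expected):
    assert narrative_indicates_homeless(text) is expected


def test_narrative_word_boundary_mode():
    assert not narrative_indicates_homeless("pt was sheltered in place", word_boundary=True)
    assert narrative_indicates_homeless("staying at a shelter downtown", word_boundary=True)


@pytest.mark.parametrize(
    "address, shelters, expected",
    [
        ("123 Main St.", ["123  MAIN ST"], True),
        ("124 Main St", ["123 MAIN ST"], False),
        ("", ["123 MAIN ST"], False),
        ("123 main st", ["456 OAK AVE", "123 MAIN ST"], True),
    ],
)
def test_address_matching(address, shelters, expected):
    assert address_matches_shelter(address, shelters) is expected


def test_address_matching_requires_shelter_list():
    with pytest.raises(ValueError):
        address_matches_shelter("1 Elm St", [])


@given(st.text(max_size=60))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_address_normalization_idempotent(raw):
    once = normalize_address(raw)
    assert normalize_address(once) == once


@pytest.mark.parametrize(
    "statuses, expected",
    [
        (["housed", "housing_loss", "housed"], True),
        (["housed", "housed"], False),
        ([], False),
    ],
)
def test_dmh_housing_loss(statuses, expected):
    assert dmh_housing_loss(statuses) is expected


def test_identify_known_homeless_tiny(tiny_population):
    ind = identify_known_homeless(tiny_population).set_index("person_id")
    assert ind.loc[0, ["via_apcd", "via_matris"]].all() and ind.loc[0, "n_sources"] == 2
    assert ind.loc[1, "via_casemix"] and ind.loc[1, "n_sources"] == 1
    assert ind.loc[2, "via_dmh"] and ind.loc[2, "n_sources"] == 1
    assert ind.loc[3, "via_pmp"] and ind.loc[3, "n_sources"] == 1
    assert not ind.loc[4, "known_homeless"]
    assert not ind.loc[5, "known_homeless"]
    # type invariants: union and count
    src = ind[["via_apcd", "via_casemix", "via_dmh", "via_matris", "via_pmp"]]
    assert (ind["known_homeless"] == src.any(axis=1)).all()
    assert (ind["n_sources"] == src.sum(axis=1)).all()


def test_identify_is_idempotent_and_monotone(tiny_population):
    first = identify_known_homeless(tiny_population)
    second = identify_known_homeless(tiny_population)
    pd.testing.assert_frame_equal(first, second)

    # adding a record can flag a person but never unflag anyone
    extra = tiny_population.claims.copy()
    extra = pd.concat(
        [extra, pd.DataFrame({"person_id": [5], "source": ["APCD"], "icd_codes": ["Z590"]})],
        ignore_index=True,
    )
    tiny_population.claims = extra
    after = identify_known_homeless(tiny_population)
    assert (after["known_homeless"] | ~first["known_homeless"]).all()
    assert after.set_index("person_id").loc[5, "known_homeless"]


def test_unknown_person_id_rejected(tiny_population):
    tiny_population.claims.loc[len(tiny_population.claims)] = [99, "APCD", "Z590"]
    with pytest.raises(ValueError, match="unknown person_id"):
        identify_known_homeless(tiny_population)


def test_zero_false_capture_means_perfect_specificity(small_population):
    """With no planted false signals, every known case is truly homeless."""
    ind = identify_known_homeless(small_population)
    merged = ind.merge(small_population.persons[["person_id", "true_homeless"]], on="person_id")
    assert merged.loc[merged["known_homeless"], "true_homeless"].all()
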