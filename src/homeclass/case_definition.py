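"""Composite "known case of homelessness" definition over linked record tables.

A person is a known case if any of four administrative indicators fires at any
point in the observation window:

1. an insurance claim (APCD) or acute-care hospital discharge (Case Mix) carrying
   an ICD-9 V60-family or ICD-10 Z590 housing-circumstances code;
2. a state mental-health (DMH) monthly housing-status record of housing loss;
3. an ambulance-trip (MATRIS) narrative containing "homeless" or "shelter";
4. a prescription-monitoring (PMP) patient address matching an emergency shelter.

All matching is deliberately simple — substring and exact-after-normalization —
because these indicators act as definitive flags, not probabilistic evidence.
"""

from __future__ import annotations

import re
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "normalize_icd",
    "has_homeless_icd",
    "narrative_indicates_homeless",
    "normalize_address",
    "address_matches_shelter",
    "dmh_housing_loss",
    "identify_known_homeless",
]

#: Statuses a DMH monthly housing record may carry.
HOUSING_LOSS = "housing_loss"

_KEYWORD_SUBSTRING = re.compile(r"homeless|shelter", re.IGNORECASE)
_KEYWORD_WORD = re.compile(r"\b(?:homeless|shelter)\b", re.IGNORECASE)
_ADDRESS_PUNCT = re.compile(r"[^A-Z0-9 ]")
_WS = re.compile(r"\s+")


def normalize_icd(code: str) -> str:
    """Canonicalize an ICD code: uppercase, strip periods and whitespace.

    Raises
    ------
    ValueError
        If the code is empty or whitespace-only (malformed record).
    """
    if code is None or not str(code).strip():
        raise ValueError("empty ICD code in record")
    return str(code).strip().upper().replace(".", "")


def has_homeless_icd(codes: Iterable[str], *, v60_prefix: bool = True) -> bool:
    """True if any code indicates homelessness (ICD-9 V60 family or ICD-10 Z590).

    ``v60_prefix`` controls whether the whole V60 category matches (default) or
    only the bare "V60" code; the source criterion cites the category.
    """
    for code in codes:
        c = normalize_icd(code)
        if c == "Z590":
            return True
        if v60_prefix:
            if c.startswith("V60"):
                return True
        elif c == "V60":
            return True
    return False


def narrative_indicates_homeless(narrative: str, *, word_boundary: bool = False) -> bool:
    """Keyword screen of a free-text ambulance narrative.

    Case-insensitive substring search for "homeless" or "shelter" (so
    "sheltered" matches by default); ``word_boundary=True`` requires whole
    words.
    """
    if narrative is None:
        return False
    pattern = _KEYWORD_WORD if word_boundary else _KEYWORD_SUBSTRING
    return bool(pattern.search(str(narrative)))


def normalize_address(address: str) -> str:
    """Uppercase, drop punctuation, collapse whitespace runs."""
    if address is None:
        return ""
    a = _ADDRESS_PUNCT.sub("", str(address).upper().replace("\t", " "))
    return _WS.sub(" ", a).strip()


def address_matches_shelter(address: str, shelters: Sequence[str]) -> bool:
    """Exact match of normalized patient address against normalized shelter list."""
    if not shelters:
        raise ValueError("shelter list must be non-empty")
    a = normalize_address(address)
    if not a:
        return False
    return a in {normalize_address(s) for s in shelters}


def dmh_housing_loss(monthly_statuses: Iterable[str]) -> bool:
    """True if any monthly DMH housing-status record shows a loss of housing."""
    return any(s == HOUSING_LOSS for s in monthly_statuses)


def _claims_code_flag(claims: pd.DataFrame, source: str, v60_prefix: bool) -> pd.Series:
    """person_ids with >=1 claim in `source` carrying a homelessness code."""
    sub = claims.loc[claims["source"] == source, ["person_id", "icd_codes"]]
    if sub.empty:
        return pd.Series(dtype=np.int64)
    codes = (
        sub["icd_codes"].astype(str).str.upper().str.replace(".", "", regex=False).str.replace(" ", "", regex=False)
    )
    if v60_prefix:
        pat = r"(?:^|;)V60|(?:^|;)Z590(?:;|$)"
    else:
        pat = r"(?:^|;)V60(?:;|$)|(?:^|;)Z590(?:;|$)"
    hit = codes.str.contains(pat, regex=True, na=False)
    return sub.loc[hit, "person_id"].drop_duplicates()


def _check_ids(table: pd.DataFrame, known_ids: pd.Index, name: str) -> None:
    if table is None or table.empty:
        return
    if not table["person_id"].isin(known_ids).all():
        bad = table.loc[~table["person_id"].isin(known_ids), "person_id"].iloc[0]
        raise ValueError(f"{name} references unknown person_id {bad!r}")


def identify_known_homeless(
    population,
    *,
    v60_prefix: bool = True,
    word_boundary: bool = False,
) -> pd.DataFrame:
    """Apply all four known-case criteria to a :class:`~homeclass.simulate.LinkedPopulation`.

    Returns one row per person with per-source boolean flags (``via_apcd``,
    ``via_casemix``, ``via_dmh``, ``via_matris``, ``via_pmp``), their union
    ``known_homeless`` and the number of firing sources ``n_sources``.
    """
    persons = population.persons
    ids = pd.Index(persons["person_id"])
    if ids.has_duplicates:
        raise ValueError("persons table contains duplicate person_id")
    for name in ("claims", "dmh_records", "ambulance_records", "prescription_records"):
        _check_ids(getattr(population, name), ids, name)

    out = pd.DataFrame({"person_id": persons["person_id"].to_numpy()})

    claims = population.claims
    apcd_ids = _claims_code_flag(claims, "APCD", v60_prefix)
    casemix_ids = _claims_code_flag(claims, "CaseMix", v60_prefix)

    dmh = population.dmh_records
    if dmh is not None and not dmh.empty:
        dmh_ids = dmh.loc[dmh["housing_status"] == HOUSING_LOSS, "person_id"].drop_duplicates()
    else:
        dmh_ids = pd.Series(dtype=np.int64)

    amb = population.ambulance_records
    if amb is not None and not amb.empty:
        pattern = _KEYWORD_WORD if word_boundary else _KEYWORD_SUBSTRING
        hit = amb["narrative"].astype(str).str.contains(pattern, na=False)
        matris_ids = amb.loc[hit, "person_id"].drop_duplicates()
    else:
        matris_ids = pd.Series(dtype=np.int64)

    rx = population.prescription_records
    if rx is not None and not rx.empty:
        shelter_set = {normalize_address(s) for s in population.shelter_addresses}
        shelter_set.discard("")
        norm = (
            rx["patient_address"]
            .astype(str)
            .str.upper()
            .str.replace(_ADDRESS_PUNCT.pattern, "", regex=True)
            .str.replace(r"\s+", " ", regex=True)
            .str.strip()
        )
        pmp_ids = rx.loc[norm.isin(shelter_set), "person_id"].drop_duplicates()
    else:
        pmp_ids = pd.Series(dtype=np.int64)

    for col, flagged in (
        ("via_apcd", apcd_ids),
        ("via_casemix", casemix_ids),
        ("via_dmh", dmh_ids),
        ("via_matris", matris_ids),
        ("via_pmp", pmp_ids),
    ):
        out[col] = out["person_id"].isin(flagged).to_numpy()

    src = out[["via_apcd", "via_casemix", "via_dmh", "via_matris", "via_pmp"]].to_numpy()
    out["known_homeless"] = src.any(axis=1)
    out["n_sources"] = src.sum(axis=1).astype(np.int64)
    return out
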