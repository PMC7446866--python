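"""Fatal opioid-overdose classification from death records.

A death is an opioid-related overdose when the underlying cause of death is a
poisoning/overdose category (X40-X49, X60-X69, X85-X90, Y10-Y19, or Y35.2) and
at least one multiple-cause field carries an opioid T-code
(T40.0-T40.4 or T40.6; T40.5, cocaine, is deliberately absent). Records with no
ICD code assigned yet fall back to a keyword search of the literal
cause-of-death text.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .case_definition import normalize_icd

__all__ = [
    "OPIOID_T_CODES",
    "DEFAULT_LITERAL_KEYWORDS",
    "DeathClassification",
    "is_poisoning_underlying",
    "classify_opioid_death",
    "classify_deaths",
    "count_overdose_deaths",
]

#: Multiple-cause ICD-10 codes identifying opioid involvement.
OPIOID_T_CODES = frozenset({"T400", "T401", "T402", "T403", "T404", "T406"})

#: Fallback terms for death certificates without an assigned ICD-10 code.
DEFAULT_LITERAL_KEYWORDS = (
    "heroin",
    "fentanyl",
    "opioid",
    "opiate",
    "morphine",
    "oxycodone",
    "methadone",
)

# (letter, low category, high category) prefix ranges for poisoning/overdose.
_POISONING_RANGES = (("X", 40, 49), ("X", 60, 69), ("X", 85, 90), ("Y", 10, 19))


@dataclass
class DeathClassification:
    person_id: object
    is_poisoning: bool
    is_opioid_overdose: bool
    matched_underlying: str = ""
    matched_multiple: list = field(default_factory=list)
    via_literal_text: bool = False


def is_poisoning_underlying(code: str) -> bool:
    """Whether an underlying-cause ICD-10 code is a poisoning/overdose category.

    Matching is at the 3-character category level (any fourth character), plus
    the single subcategory Y35.2 (legal-intervention poisoning).
    """
    if code is None or not str(code).strip():
        return False
    c = normalize_icd(code)
    if c.startswith("Y352"):
        return True
    if len(c) < 3 or not c[1:3].isdigit():
        return False
    letter, num = c[0], int(c[1:3])
    return any(letter == lo_letter and lo <= num <= hi for lo_letter, lo, hi in _POISONING_RANGES)


def _split_codes(codes) -> list:
    if codes is None:
        return []
    if isinstance(codes, str):
        return [c for c in codes.split(";") if c.strip()]
    return [c for c in codes if c is not None and str(c).strip()]


def classify_opioid_death(
    record,
    *,
    literal_keywords: Sequence[str] = DEFAULT_LITERAL_KEYWORDS,
) -> DeathClassification:
    """Classify one death record (mapping or namedtuple-like row).

    Expects fields ``person_id``, ``underlying_cause``, ``multiple_causes``
    (list or ";"-joined string) and ``literal_text``. The literal-text fallback
    applies only when the record carries no ICD code at all.
    """
    get = record.get if hasattr(record, "get") else lambda k, d=None: getattr(record, k, d)
    person_id = get("person_id")
    underlying = get("underlying_cause") or ""
    multiple = _split_codes(get("multiple_causes"))
    literal = str(get("literal_text") or "")

    has_codes = bool(str(underlying).strip()) or bool(multiple)
    if not has_codes and not literal.strip():
        raise ValueError(f"death record for person {person_id!r} has neither ICD codes nor literal text")

    if has_codes:
        poisoning = is_poisoning_underlying(underlying)
        opioid_multiple = [c for c in multiple if normalize_icd(c) in OPIOID_T_CODES]
        is_od = poisoning and bool(opioid_multiple)
        return DeathClassification(
            person_id=person_id,
            is_poisoning=poisoning,
            is_opioid_overdose=is_od,
            matched_underlying=normalize_icd(underlying) if poisoning and str(underlying).strip() else "",
            matched_multiple=[normalize_icd(c) for c in opioid_multiple] if is_od else [],
        )

    text = literal.lower()
    hit = any(k.lower() in text for k in literal_keywords)
    return DeathClassification(
        person_id=person_id,
        is_poisoning=hit,
        is_opioid_overdose=hit,
        via_literal_text=hit,
    )


def classify_deaths(
    death_records: pd.DataFrame,
    *,
    literal_keywords: Sequence[str] = DEFAULT_LITERAL_KEYWORDS,
) -> pd.DataFrame:
    """Classify a death-record table; one output row per input record."""
    rows = []
    for rec in death_records.to_dict("records"):
        c = classify_opioid_death(rec, literal_keywords=literal_keywords)
        rows.append(
            {
                "person_id": c.person_id,
                "is_poisoning": c.is_poisoning,
                "is_opioid_overdose": c.is_opioid_overdose,
                "matched_underlying": c.matched_underlying,
                "matched_multiple": ";".join(c.matched_multiple),
                "via_literal_text": c.via_literal_text,
            }
        )
    cols = [
        "person_id",
        "is_poisoning",
        "is_opioid_overdose",
        "matched_underlying",
        "matched_multiple",
        "via_literal_text",
    ]
    return pd.DataFrame(rows, columns=cols)


def count_overdose_deaths(classifications: pd.DataFrame, person_set: Iterable) -> int:
    """Number of persons in ``person_set`` classified as fatal opioid overdoses."""
    person_set = set(person_set)
    if not person_set:
        return 0
    sub = classifications[
        classifications["is_opioid_overdose"] & classifications["person_id"].isin(person_set)
    ]
    return int(sub["person_id"].nunique())
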