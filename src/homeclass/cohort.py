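"""Analytic-cohort restriction and master-demographics reconciliation.

The analytic cohort keeps unique persons who (a) appear in the all-payer
claims database, (b) appear in at least one other linked source, and
(c) are at least 11 years old — the restriction that screens out
non-residents and unresolved duplicates in the real warehouse.
"""

from __future__ import annotations

from typing import Dict, Sequence

import numpy as np
import pandas as pd

__all__ = ["restrict_cohort", "reconcile_demographics", "DEFAULT_PRECEDENCE"]

#: "best available" source order for demographic reconciliation
DEFAULT_PRECEDENCE = ("claims", "mental_health", "vital_records", "ambulance", "prescriptions")

MIN_AGE = 11


def restrict_cohort(population, min_age: int = MIN_AGE) -> pd.DataFrame:
    """One row per person with the inclusion flag and the reason for exclusion.

    Presence in a source means >=1 record in that source's table; the
    "other" sources counted against the APCD are Case Mix, DMH, ambulance,
    prescription-monitoring, and death records.
    """
    persons = population.persons
    ids = persons["person_id"]

    apcd_ids = set(population.claims.loc[population.claims["source"] == "APCD", "person_id"])
    other_tables = [
        population.claims.loc[population.claims["source"] == "CaseMix", "person_id"],
        population.dmh_records["person_id"] if not population.dmh_records.empty else pd.Series(dtype=np.int64),
        population.ambulance_records["person_id"] if not population.ambulance_records.empty else pd.Series(dtype=np.int64),
        population.prescription_records["person_id"] if not population.prescription_records.empty else pd.Series(dtype=np.int64),
        population.death_records["person_id"] if not population.death_records.empty else pd.Series(dtype=np.int64),
    ]

    in_apcd = ids.isin(apcd_ids).to_numpy()
    n_other = np.zeros(len(ids), dtype=np.int64)
    for tab in other_tables:
        n_other += ids.isin(set(tab)).to_numpy()
    age_ok = persons["age"].to_numpy() >= min_age
    included = in_apcd & (n_other >= 1) & age_ok

    reason = np.full(len(ids), "", dtype=object)
    reason[~age_ok] = "under_min_age"
    reason[~in_apcd & (reason == "")] = "no_apcd_record"
    reason[(n_other == 0) & (reason == "")] = "no_other_source"
    reason[included] = ""

    return pd.DataFrame(
        {
            "person_id": ids.to_numpy(),
            "in_apcd": in_apcd,
            "n_other_sources": n_other,
            "age": persons["age"].to_numpy(),
            "included": included,
            "exclusion_reason": reason,
        }
    )


def reconcile_demographics(
    per_source: Dict[str, pd.DataFrame],
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
) -> pd.DataFrame:
    """Collapse per-source demographic tables to one row per person.

    Each source table must carry a ``person_id`` column. The highest-
    precedence source that contains a person supplies that person's entire
    row (row-level precedence, deterministic). Sources absent from
    ``precedence`` are appended after it in sorted-name order.

    Raises
    ------
    ValueError
        If a source table has no ``person_id`` column, or no source has any
        rows at all.
    """
    order = [s for s in precedence if s in per_source]
    order += sorted(s for s in per_source if s not in order)
    if not order:
        raise ValueError("no demographic sources supplied")
    frames = []
    for rank, source in enumerate(order):
        df = per_source[source]
        if "person_id" not in df.columns:
            raise ValueError(f"source {source!r} lacks a person_id column")
        f = df.copy()
        f["_rank"] = rank
        f["_source"] = source
        frames.append(f)
    merged = pd.concat(frames, ignore_index=True)
    if merged.empty:
        raise ValueError("no demographic rows supplied for any person")
    merged = merged.sort_values(["person_id", "_rank"], kind="stable")
    best = merged.drop_duplicates("person_id", keep="first").reset_index(drop=True)
    return best.drop(columns="_rank").rename(columns={"_source": "source"})
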