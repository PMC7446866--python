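"""Seeded generator of synthetic linked administrative records.

The generator emulates the statistical structure of a state-level linked
data warehouse built around an all-payer claims database (APCD): a latent
true-homelessness status with ~4.6% five-year prevalence, five
administrative sources that each capture only a small fraction of true
cases (so observed "known-case" prevalence lands near 0.82%), binary
predictor features whose rates differ by true status, and a fatal
opioid-overdose outcome with a strongly elevated rate in the homeless
group.

Per-source capture is mediated by a latent "service engagement" factor:
a true homeless person is engaged with probability ``engagement_prob``,
and only engaged persons can be captured, independently per source with
probability ``sensitivity / engagement_prob``. Marginal per-source capture
rates therefore equal the configured sensitivities, while the shared factor
induces the positive inter-source overlap seen in real linked data (about a
third of known cases carry multiple indicators). ``engagement_prob = 1``
recovers fully independent capture.

Everything is drawn from one ``numpy`` Generator in a fixed order, so equal
configs (including seed) produce byte-identical populations.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "PredictorSpec",
    "SimulationConfig",
    "LinkedPopulation",
    "default_predictor_spec",
    "generate_shelter_addresses",
    "generate_narrative",
    "generate_population",
    "expected_observed_prevalence",
    "expected_inclusion_fraction",
    "write_population",
    "read_population",
]

SOURCES = ("apcd_icd", "casemix_icd", "dmh", "matris", "pmp")
PREDICTOR_GROUPS = (
    "sociodemographic",
    "drug_alcohol",
    "mental_health",
    "physical_health",
    "other_service",
)

# --- text pools -------------------------------------------------------------

# Ambulance narratives with no "homeless"/"shelter" substring anywhere.
_NEGATIVE_NARRATIVES = (
    "67 yo male with chest pain at residence, transported to ED",
    "pt fell from ladder at home, laceration to scalp",
    "MVC on route 9, driver ambulatory on scene, refused transport",
    "called for syncope at workplace, vitals stable",
    "pt with SOB, hx COPD, nebulizer en route",
    "diabetic emergency, glucose 42, responded to D50",
    "elderly female lift assist at private home, no injury",
    "seizure activity reported by spouse, postictal on arrival",
    "abd pain x2 days, transported from apartment",
    "pt found at bus stop intoxicated, GCS 14",
    "allergic reaction to bee sting at park",
    "overdose suspected, naloxone administered, pt roused",
    "psychiatric evaluation requested by family at home",
    "laceration to hand from kitchen knife, bleeding controlled",
    "back pain after lifting boxes at work site",
    "pt ambulatory, c/o dizziness outside grocery store",
)

# Templates with a {kw} slot for a planted keyword.
_KEYWORD_NARRATIVES = (
    "pt is {kw}, found sleeping under overpass, c/o cough",
    "picked up outside {kw} on main st, intoxicated",
    "{kw} male found unresponsive in doorway, naloxone given",
    "crew dispatched to {kw} for fall victim",
    "pt reports being {kw} for 2 years, requests detox",
    "staff at the {kw} called for seizure, pt postictal",
    "{kw} female, frostbite to fingers, cold exposure",
)

_KEYWORDS = ("homeless", "HOMELESS", "Homeless", "shelter", "SHELTER", "Shelter")

_SHELTER_STREETS = (
    "HARRISON AVE",
    "PINE ST",
    "ALBANY ST",
    "SHAWMUT AVE",
    "FRIEND ST",
    "PARADISE RD",
    "WINTER ST",
    "GREEN ST",
)
_SHELTER_NAMES = ("BOSTON", "WORCESTER", "SPRINGFIELD", "LOWELL", "BROCKTON", "LYNN", "QUINCY")

_RESIDENTIAL_STREETS = (
    "MAPLE AVE",
    "OAK ST",
    "ELM ST",
    "MAIN ST",
    "WASHINGTON ST",
    "PLEASANT ST",
    "HIGHLAND AVE",
    "BEACON ST",
    "CHESTNUT ST",
    "SCHOOL ST",
)
_TOWNS = ("AMHERST", "SALEM", "NEWTON", "CAMBRIDGE", "FALL RIVER", "PITTSFIELD", "TAUNTON")

# Background (non-signal) ICD code strings for claims, ";"-joined per claim.
_BACKGROUND_CODES = (
    "I10",
    "E119",
    "J069",
    "M545",
    "K219",
    "F329",
    "J449",
    "N390",
    "E785",
    "Z0000",
    "I10;E785",
    "J069;R05",
    "M545;G8929",
    "F419;F329",
)

# Claims planted for ICD-based capture: a homelessness code, sometimes with a
# co-occurring background diagnosis.
_SIGNAL_CODES = (
    "Z590",
    "Z59.0",
    "V60.0",
    "V600",
    "V6041",
    "Z590;F1120",
    "V600;J449",
    "Z59.0;F1010",
)

_POISONING_UNDERLYING = ("X42", "X44", "X41", "X64", "Y12", "X85", "Y352")
_OPIOID_MULTIPLE = (
    "T401",
    "T402",
    "T404",
    "T401;T426",
    "T402;T509",
    "T406",
    "T400;T404",
    "T403",
)
_NATURAL_UNDERLYING = ("I219", "I251", "C349", "J449", "G309", "I639", "C509")
_NATURAL_MULTIPLE = ("I10", "E119", "J969", "I509", "N179", "F03")
_NONOPIOID_POISONING_MULTIPLE = ("T509", "T405", "T426;T509", "T510", "T405;T509")
_OPIOID_LITERALS = (
    "acute fentanyl intoxication",
    "heroin and cocaine toxicity",
    "acute opioid intoxication",
    "mixed drug toxicity including oxycodone",
    "acute morphine and alcohol intoxication",
)


@dataclass(frozen=True)
class PredictorSpec:
    """One binary predictor: population base rate and its log-odds shift
    among the true homeless."""

    name: str
    group: str
    baseline_prob: float
    log_odds_given_true_homeless: float

    def __post_init__(self):
        if self.group not in PREDICTOR_GROUPS:
            raise ValueError(f"unknown predictor group {self.group!r}")
        if not 0 < self.baseline_prob < 1:
            raise ValueError("baseline_prob must be in (0, 1)")


def default_predictor_spec() -> list:
    """Twenty indicator predictors, four per group.

    Base rates and effects emulate administrative indicator variables that
    are individually uncommon in the general insured population but strongly
    enriched among people experiencing homelessness (substance-use,
    mental-health, and service-contact flags); a few weaker, more prevalent
    proxies are included for realism. Effects are on the log-odds scale and
    are deliberately large: in this synthetic world, excess overdose risk
    flows only through the latent status, so recovering the embedded rate
    ratio through a thresholded classifier requires near-perfect specificity
    against the latent truth.
    """
    spec = [
        # sociodemographic
        ("medicaid_member", "sociodemographic", 0.12, 2.4),
        ("public_assistance", "sociodemographic", 0.012, 4.0),
        ("veteran_benefits", "sociodemographic", 0.020, 1.0),
        ("unstable_employment_proxy", "sociodemographic", 0.025, 2.8),
        # drug / alcohol
        ("substance_use_disorder_dx", "drug_alcohol", 0.028, 4.2),
        ("opioid_use_disorder_dx", "drug_alcohol", 0.007, 4.4),
        ("alcohol_use_disorder_dx", "drug_alcohol", 0.015, 3.8),
        ("detox_treatment_episode", "drug_alcohol", 0.003, 5.0),
        # mental health
        ("psychosis_dx", "mental_health", 0.0045, 4.4),
        ("bipolar_dx", "mental_health", 0.009, 3.6),
        ("anxiety_dx", "mental_health", 0.09, 1.2),
        ("psychiatric_hospitalization", "mental_health", 0.0022, 5.0),
        # physical health
        ("skin_soft_tissue_infection", "physical_health", 0.010, 3.6),
        ("injection_drug_use_dx", "physical_health", 0.0018, 5.2),
        ("hepatitis_c_dx", "physical_health", 0.0045, 4.2),
        ("chronic_pain_dx", "physical_health", 0.05, 1.4),
        # other service use
        ("frequent_ed_visits", "other_service", 0.022, 4.0),
        ("incarceration_history", "other_service", 0.003, 4.8),
        ("ambulance_trip_any", "other_service", 0.07, 2.2),
        ("case_management_service", "other_service", 0.0035, 4.6),
    ]
    return [PredictorSpec(n, g, p, b) for n, g, p, b in spec]


def _default_capture() -> dict:
    return {"apcd_icd": 0.10, "casemix_icd": 0.094, "dmh": 0.0013, "matris": 0.014, "pmp": 0.029}


def _default_membership() -> dict:
    return {"apcd": 1.0, "casemix": 0.55, "dmh": 0.004, "matris": 0.12, "pmp": 0.75}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic linked-record study population.

    Capture sensitivities default to values calibrated so that, with a 4.6%
    true five-year prevalence, per-source known-case counts mirror the
    relative magnitudes seen in state linked data and the overall known-case
    prevalence lands near 0.82%.
    """

    n_persons: int = 100_000
    true_prevalence: float = 0.046
    capture_sensitivity: dict = field(default_factory=_default_capture)
    engagement_prob: float = 0.26
    predictor_spec: list = field(default_factory=default_predictor_spec)
    baseline_overdose_prob: float = 4.5e-4
    true_rate_ratio: float = 20.0
    n_shelters: int = 25
    membership_prob: dict = field(default_factory=_default_membership)
    background_death_prob: float = 0.012
    nonopioid_poisoning_frac: float = 0.01
    pending_literal_frac: float = 0.03
    false_capture_prob: float = 0.0
    age_range: tuple = (11, 90)
    seed: int = 0

    def __post_init__(self):
        if self.n_persons <= 0:
            raise ValueError("n_persons must be positive")
        if not 0 <= self.true_prevalence <= 1:
            raise ValueError("true_prevalence must be a probability")
        if set(self.capture_sensitivity) != set(SOURCES):
            raise ValueError(f"capture_sensitivity must have exactly the sources {SOURCES}")
        for s, v in self.capture_sensitivity.items():
            if not 0 <= v <= 1:
                raise ValueError(f"capture sensitivity for {s} must be a probability")
        if not 0 < self.engagement_prob <= 1:
            raise ValueError("engagement_prob must be in (0, 1]")
        for s, v in self.capture_sensitivity.items():
            if v > self.engagement_prob:
                raise ValueError(
                    f"capture sensitivity for {s} ({v}) exceeds engagement_prob "
                    f"({self.engagement_prob}); the marginal rate is unattainable"
                )
        if expected_observed_prevalence(self) > self.true_prevalence + 1e-12 and self.false_capture_prob == 0:
            raise ValueError("capture configuration implies observed prevalence above true prevalence")
        names = [p.name for p in self.predictor_spec]
        if len(set(names)) != len(names):
            raise ValueError("predictor names must be unique")
        for key in ("baseline_overdose_prob", "false_capture_prob", "pending_literal_frac", "nonopioid_poisoning_frac", "background_death_prob"):
            v = getattr(self, key)
            if not 0 <= v <= 1:
                raise ValueError(f"{key} must be a probability")
        if self.true_rate_ratio <= 0:
            raise ValueError("true_rate_ratio must be positive")
        if self.n_shelters < 1:
            raise ValueError("n_shelters must be at least 1")
        for s, v in self.membership_prob.items():
            if not 0 <= v <= 1:
                raise ValueError(f"membership probability for {s} must be a probability")


@dataclass
class LinkedPopulation:
    """Per-person ground truth plus per-source record tables.

    ``icd_codes`` / ``multiple_causes`` columns hold ";"-joined code strings
    (one cell per record) so every table round-trips through plain CSV.
    """

    persons: pd.DataFrame
    claims: pd.DataFrame
    dmh_records: pd.DataFrame
    ambulance_records: pd.DataFrame
    prescription_records: pd.DataFrame
    death_records: pd.DataFrame
    shelter_addresses: list
    config: Optional[SimulationConfig] = None

    @property
    def predictor_names(self) -> list:
        if self.config is not None:
            return [p.name for p in self.config.predictor_spec]
        fixed = {"person_id", "age", "sex", "true_homeless", "died_opioid_overdose"}
        return [c for c in self.persons.columns if c not in fixed]


def expected_observed_prevalence(config: SimulationConfig) -> float:
    """Analytic known-case fraction implied by the capture model (signals only)."""
    phi = config.engagement_prob
    miss = 1.0
    for s in SOURCES:
        miss *= 1.0 - config.capture_sensitivity[s] / phi
    p_union_true = phi * (1.0 - miss)
    fp_union = 1.0 - (1.0 - config.false_capture_prob) ** len(SOURCES)
    return config.true_prevalence * p_union_true + (1.0 - config.true_prevalence) * fp_union


def expected_multisource_share(config: SimulationConfig) -> float:
    """Analytic share of known cases flagged by two or more sources
    (true cases only; exact under the engagement-capture model)."""
    phi = config.engagement_prob
    a = [config.capture_sensitivity[s] / phi for s in SOURCES]
    p0 = math.prod(1.0 - x for x in a)
    p1 = p0 * sum(x / (1.0 - x) for x in a)
    p_ge1 = 1.0 - p0
    return (p_ge1 - p1) / p_ge1


def expected_inclusion_fraction(config: SimulationConfig) -> float:
    """Analytic cohort-inclusion fraction for a non-homeless, non-decedent
    person of eligible age (APCD membership and >=1 other source)."""
    m = config.membership_prob
    others = 1.0
    for s in ("casemix", "dmh", "matris", "pmp"):
        others *= 1.0 - m[s]
    return m["apcd"] * (1.0 - others)


def generate_shelter_addresses(n_shelters: int, seed: int = 0) -> list:
    """``n_shelters`` pairwise-distinct normalized shelter address strings."""
    if n_shelters < 1:
        raise ValueError("n_shelters must be at least 1")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_shelters):
        street = _SHELTER_STREETS[rng.integers(len(_SHELTER_STREETS))]
        city = _SHELTER_NAMES[rng.integers(len(_SHELTER_NAMES))]
        number = 10 + 3 * i + int(rng.integers(0, 3))  # disjoint ranges => distinct
        out.append(f"{number} {street} {city} MA")
    return out


def generate_narrative(plant_keyword: bool, rng) -> str:
    """One ambulance narrative; contains "homeless"/"shelter" iff planted."""
    if plant_keyword:
        template = _KEYWORD_NARRATIVES[rng.integers(len(_KEYWORD_NARRATIVES))]
        return template.format(kw=_KEYWORDS[rng.integers(len(_KEYWORDS))])
    return _NEGATIVE_NARRATIVES[rng.integers(len(_NEGATIVE_NARRATIVES))]


def _messy_address(address: str, rng) -> str:
    """Formatting noise that survives normalization (case, punctuation, spaces)."""
    style = int(rng.integers(0, 4))
    if style == 0:
        return address.lower()
    if style == 1:
        return address.replace(" ", "  ").title()
    if style == 2:
        head, _, tail = address.rpartition(" ")
        return f"{head}, {tail}."
    return address


def _pick(pool, size, rng) -> np.ndarray:
    return np.asarray(pool, dtype=object)[rng.integers(0, len(pool), size=size)]


def generate_population(config: SimulationConfig) -> LinkedPopulation:
    """Draw a full synthetic linked population from one seeded generator.

    True status, engagement, per-source capture, predictors, deaths,
    memberships and all record rows are drawn in a fixed order, so equal
    configs yield byte-identical populations.
    """
    n = config.n_persons
    rng = np.random.default_rng(config.seed)

    person_id = np.arange(n, dtype=np.int64)
    lo, hi = config.age_range
    age = rng.integers(lo, hi + 1, size=n)
    sex = np.where(rng.random(n) < 0.485, "M", "F")
    true_h = rng.random(n) < config.true_prevalence
    engaged = true_h & (rng.random(n) < config.engagement_prob)

    captures = {}
    for s in SOURCES:
        p_cond = config.capture_sensitivity[s] / config.engagement_prob
        cap = engaged & (rng.random(n) < p_cond)
        if config.false_capture_prob > 0:
            cap |= ~true_h & (rng.random(n) < config.false_capture_prob)
        captures[s] = cap

    persons = pd.DataFrame({"person_id": person_id, "age": age, "sex": sex, "true_homeless": true_h})
    for spec in config.predictor_spec:
        p = np.where(
            true_h,
            expit(logit(spec.baseline_prob) + spec.log_odds_given_true_homeless),
            spec.baseline_prob,
        )
        persons[spec.name] = (rng.random(n) < p).astype(np.int8)

    p_od = np.minimum(1.0, config.baseline_overdose_prob * np.where(true_h, config.true_rate_ratio, 1.0))
    died_od = rng.random(n) < p_od
    persons["died_opioid_overdose"] = died_od
    died_other = ~died_od & (rng.random(n) < config.background_death_prob)

    membership = {s: rng.random(n) < config.membership_prob[s] for s in ("apcd", "casemix", "dmh", "matris", "pmp")}
    # a captured signal implies a record in that source
    membership["apcd"] |= captures["apcd_icd"]
    membership["casemix"] |= captures["casemix_icd"]
    membership["dmh"] |= captures["dmh"]
    membership["matris"] |= captures["matris"]
    membership["pmp"] |= captures["pmp"]

    shelters = generate_shelter_addresses(config.n_shelters, seed=int(rng.integers(0, 2**31 - 1)))

    # --- claims (APCD + CaseMix) -------------------------------------------
    claim_parts = []
    for source, member_key, cap_key in (("APCD", "apcd", "apcd_icd"), ("CaseMix", "casemix", "casemix_icd")):
        ids = person_id[membership[member_key]]
        claim_parts.append(
            pd.DataFrame({"person_id": ids, "source": source, "icd_codes": _pick(_BACKGROUND_CODES, ids.size, rng)})
        )
        sig_ids = person_id[captures[cap_key]]
        claim_parts.append(
            pd.DataFrame({"person_id": sig_ids, "source": source, "icd_codes": _pick(_SIGNAL_CODES, sig_ids.size, rng)})
        )
    claims = pd.concat(claim_parts, ignore_index=True)

    # --- DMH monthly housing status ----------------------------------------
    dmh_ids = person_id[membership["dmh"]]
    dmh_parts = [
        pd.DataFrame({"person_id": np.repeat(dmh_ids, 2), "month": np.tile([0, 1], dmh_ids.size), "housing_status": "housed"})
    ]
    loss_ids = person_id[captures["dmh"]]
    dmh_parts.append(pd.DataFrame({"person_id": loss_ids, "month": 2, "housing_status": "housing_loss"}))
    dmh_records = pd.concat(dmh_parts, ignore_index=True)

    # --- ambulance narratives ----------------------------------------------
    amb_ids = person_id[membership["matris"] & ~captures["matris"]]
    neg = _pick(_NEGATIVE_NARRATIVES, amb_ids.size, rng)
    kw_ids = person_id[captures["matris"]]
    templates = _pick(_KEYWORD_NARRATIVES, kw_ids.size, rng)
    kws = _pick(_KEYWORDS, kw_ids.size, rng)
    pos = np.array([t.format(kw=k) for t, k in zip(templates, kws)], dtype=object)
    ambulance_records = pd.DataFrame(
        {
            "person_id": np.concatenate([amb_ids, kw_ids]),
            "narrative": np.concatenate([neg, pos]) if (amb_ids.size + kw_ids.size) else np.array([], dtype=object),
        }
    )

    # --- prescriptions -------------------------------------------------------
    rx_ids = person_id[membership["pmp"] & ~captures["pmp"]]
    number = rng.integers(1, 999, size=rx_ids.size).astype(str)
    street = _pick(_RESIDENTIAL_STREETS, rx_ids.size, rng)
    town = _pick(_TOWNS, rx_ids.size, rng)
    res_addr = pd.Series(number).str.cat(pd.Series(street, dtype=object).str.cat(pd.Series(town, dtype=object), sep=" "), sep=" ") + " MA"
    shel_ids = person_id[captures["pmp"]]
    shel_pick = _pick(shelters, shel_ids.size, rng)
    shel_addr = np.array([_messy_address(a, rng) for a in shel_pick], dtype=object)
    prescription_records = pd.DataFrame(
        {
            "person_id": np.concatenate([rx_ids, shel_ids]),
            "patient_address": np.concatenate([res_addr.to_numpy(dtype=object), shel_addr])
            if (rx_ids.size + shel_ids.size)
            else np.array([], dtype=object),
        }
    )

    # --- death records -------------------------------------------------------
    od_ids = person_id[died_od]
    pending = rng.random(od_ids.size) < config.pending_literal_frac
    od_underlying = _pick(_POISONING_UNDERLYING, od_ids.size, rng)
    od_multiple = _pick(_OPIOID_MULTIPLE, od_ids.size, rng)
    od_literal = np.where(pending, _pick(_OPIOID_LITERALS, od_ids.size, rng), "")
    od_underlying = np.where(pending, "", od_underlying)
    od_multiple = np.where(pending, "", od_multiple)

    other_ids = person_id[died_other]
    nonop_poison = rng.random(other_ids.size) < config.nonopioid_poisoning_frac
    other_underlying = np.where(
        nonop_poison,
        _pick(("X44", "X41", "Y11"), other_ids.size, rng),
        _pick(_NATURAL_UNDERLYING, other_ids.size, rng),
    )
    other_multiple = np.where(
        nonop_poison,
        _pick(_NONOPIOID_POISONING_MULTIPLE, other_ids.size, rng),
        _pick(_NATURAL_MULTIPLE, other_ids.size, rng),
    )
    death_records = pd.DataFrame(
        {
            "person_id": np.concatenate([od_ids, other_ids]),
            "underlying_cause": np.concatenate([od_underlying, other_underlying]),
            "multiple_causes": np.concatenate([od_multiple, other_multiple]),
            "literal_text": np.concatenate([od_literal, np.repeat("", other_ids.size)]),
        }
    )

    return LinkedPopulation(
        persons=persons,
        claims=claims,
        dmh_records=dmh_records,
        ambulance_records=ambulance_records,
        prescription_records=prescription_records,
        death_records=death_records,
        shelter_addresses=shelters,
        config=config,
    )


# --- disk round-trip ---------------------------------------------------------

_TABLES = ("persons", "claims", "dmh_records", "ambulance_records", "prescription_records", "death_records")


def write_population(population: LinkedPopulation, outdir) -> None:
    """Write every record table as UTF-8 CSV plus truth and config-echo JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in _TABLES:
        getattr(population, name).to_csv(outdir / f"{name}.csv", index=False)
    (outdir / "shelter_addresses.json").write_text(json.dumps(population.shelter_addresses, indent=2))
    truth = population.persons[["person_id", "true_homeless", "died_opioid_overdose"]]
    (outdir / "truth.json").write_text(
        json.dumps(
            {
                str(r.person_id): {"true_homeless": bool(r.true_homeless), "died_opioid_overdose": bool(r.died_opioid_overdose)}
                for r in truth.itertuples()
            }
        )
    )
    if population.config is not None:
        cfg = asdict(population.config)
        cfg["predictor_spec"] = [asdict(p) for p in population.config.predictor_spec]
        cfg["age_range"] = list(cfg["age_range"])
        (outdir / "config.json").write_text(json.dumps(cfg, indent=2))


def read_population(indir) -> LinkedPopulation:
    """Re-load a population previously written by :func:`write_population`."""
    indir = Path(indir)
    tables = {}
    for name in _TABLES:
        df = pd.read_csv(indir / f"{name}.csv", keep_default_na=False)
        tables[name] = df
    shelters = json.loads((indir / "shelter_addresses.json").read_text())
    config = None
    cfg_path = indir / "config.json"
    if cfg_path.exists():
        raw = json.loads(cfg_path.read_text())
        raw["predictor_spec"] = [PredictorSpec(**p) for p in raw["predictor_spec"]]
        raw["age_range"] = tuple(raw["age_range"])
        config = SimulationConfig(**raw)
    return LinkedPopulation(shelter_addresses=shelters, config=config, **tables)
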