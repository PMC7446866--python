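"""End-to-end orchestration: simulate -> define cases -> restrict cohort ->
split / downsample / fit / score -> evaluate -> weighted rate comparison.

Every stage is deterministic given the three seeds (data, split, downsample),
and each emitted table is re-validated against its module invariants before
being written.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .case_definition import identify_known_homeless
from .cohort import restrict_cohort
from .evaluation import PerformanceReport, compute_auc, compute_performance, confusion_at_threshold
from .model import ClassifierResults, HomelessnessClassifier, downsample_majority, stratified_split
from .overdose import classify_deaths
from .rates import SCHEMES, assign_risk_scores, rate_ratio_ci, weighted_group_counts
from .simulate import LinkedPopulation, PredictorSpec, SimulationConfig, generate_population, write_population

__all__ = [
    "PipelineConfig",
    "RunReport",
    "run_pipeline",
    "summarize_known_sources",
    "estimate_rr_coverage",
    "null_signal_auc",
]

log = logging.getLogger("homeclass")


@dataclass
class PipelineConfig:
    """Configuration of a full synthetic study run."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    dev_fraction: float = 0.75
    threshold: float = 0.5
    schemes: tuple = SCHEMES
    convention: str = "full_sum"
    split_seed: int = 1
    downsample_seed: int = 2
    min_age: int = 11
    out_dir: Optional[str] = None

    def __post_init__(self):
        if not 0 < self.dev_fraction < 1:
            raise ValueError("dev_fraction must be in (0, 1)")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        unknown = set(self.schemes) - set(SCHEMES)
        if unknown:
            raise ValueError(f"unknown scheme(s): {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("sim", {})
        if "predictor_spec" in sim_raw:
            sim_raw["predictor_spec"] = [PredictorSpec(**p) for p in sim_raw["predictor_spec"]]
        if "age_range" in sim_raw:
            sim_raw["age_range"] = tuple(sim_raw["age_range"])
        if "schemes" in raw:
            raw["schemes"] = tuple(raw["schemes"])
        return cls(sim=SimulationConfig(**sim_raw), **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"]["predictor_spec"] = [asdict(p) for p in self.sim.predictor_spec]
        d["sim"]["age_range"] = list(self.sim.age_range)
        d["schemes"] = list(self.schemes)
        return d


@dataclass
class RunReport:
    """Everything a run produces, in memory."""

    config: PipelineConfig
    population: LinkedPopulation
    indicators: pd.DataFrame
    source_summary: dict
    cohort: pd.DataFrame
    split: pd.DataFrame
    model: ClassifierResults
    performance: PerformanceReport
    rates: dict
    death_classifications: pd.DataFrame
    manifest: dict

    def summary(self) -> str:
        lines = [
            f"homeclass run (n={self.config.sim.n_persons:,}, data seed {self.config.sim.seed})",
            f"  known cases: {self.source_summary['total_known']:,} "
            f"({100 * self.source_summary['known_prevalence']:.2f}% of cohort universe); "
            f"multi-source share {100 * self.source_summary['multi_source_share']:.1f}%",
            "",
            self.performance.summary(),
            "",
            "Fatal opioid overdose rate comparison (validation sample)",
            "-" * 42,
        ]
        for scheme, rc in self.rates.items():
            lines.append(f"{scheme:<22}{rc.summary()}")
        return "\n".join(lines)


def summarize_known_sources(indicators: pd.DataFrame) -> dict:
    """Per-source known-case counts, total, and the multi-indicator share."""
    if indicators.empty:
        raise ValueError("indicator table is empty")
    total = int(indicators["known_homeless"].sum())
    multi = int((indicators["n_sources"] >= 2).sum())
    return {
        "by_source": {
            c.removeprefix("via_"): int(indicators[c].sum())
            for c in ("via_apcd", "via_casemix", "via_dmh", "via_matris", "via_pmp")
        },
        "total_known": total,
        "multi_source_count": multi,
        "multi_source_share": multi / total if total else 0.0,
        "known_prevalence": total / len(indicators),
    }


def _stage(name, t0):
    log.info("stage %-18s %.2fs", name, time.perf_counter() - t0)
    return time.perf_counter()


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run the full study workflow; see the module docstring for the stages."""
    t = time.perf_counter()
    try:
        population = generate_population(config.sim)
    except Exception as e:
        raise RuntimeError(f"stage 'simulate' failed: {e}") from e
    t = _stage("simulate", t)

    try:
        indicators = identify_known_homeless(population)
        source_summary = summarize_known_sources(indicators)
    except Exception as e:
        raise RuntimeError(f"stage 'define-cases' failed: {e}") from e
    t = _stage("define-cases", t)

    try:
        cohort = restrict_cohort(population, min_age=config.min_age)
    except Exception as e:
        raise RuntimeError(f"stage 'cohort' failed: {e}") from e
    t = _stage("cohort", t)

    try:
        features = population.predictor_names
        frame = population.persons[["person_id"] + features].merge(
            indicators[["person_id", "known_homeless"]], on="person_id", validate="one_to_one"
        )
        frame = frame.merge(cohort[["person_id", "included"]], on="person_id", validate="one_to_one")
        frame = frame[frame["included"]].drop(columns="included")
        split = stratified_split(
            frame["person_id"].to_numpy(),
            frame["known_homeless"].to_numpy(),
            dev_fraction=config.dev_fraction,
            seed=config.split_seed,
        )
        frame = frame.merge(split[["person_id", "partition"]], on="person_id", validate="one_to_one")
        dev = frame[frame["partition"] == "development"]
        val = frame[frame["partition"] == "validation"]
        balanced_ids = downsample_majority(
            dev["person_id"].to_numpy(), dev["known_homeless"].to_numpy(), seed=config.downsample_seed
        )
        balanced = dev[dev["person_id"].isin(balanced_ids)]
        model = HomelessnessClassifier.from_dataframe(balanced, "known_homeless", features).fit()
    except Exception as e:
        raise RuntimeError(f"stage 'fit' failed: {e}") from e
    t = _stage("fit", t)

    try:
        probs = model.predict(val[features])
        labels_val = val["known_homeless"].to_numpy()
        auc = compute_auc(probs, labels_val)
        conf = confusion_at_threshold(probs, labels_val, config.threshold)
        performance = compute_performance(conf, auc=auc, prevalence=float(labels_val.mean()))
    except Exception as e:
        raise RuntimeError(f"stage 'evaluate' failed: {e}") from e
    t = _stage("evaluate", t)

    try:
        deaths = classify_deaths(population.death_records)
        od_ids = set(deaths.loc[deaths["is_opioid_overdose"], "person_id"])
        death_flags = val["person_id"].isin(od_ids).to_numpy()
        rates = {}
        for scheme in config.schemes:
            scores = assign_risk_scores(probs, labels_val, scheme, threshold=config.threshold)
            counts = weighted_group_counts(scores, death_flags, convention=config.convention, threshold=config.threshold)
            rc = rate_ratio_ci(counts.deaths_homeless, counts.n_homeless, counts.deaths_nonhomeless, counts.n_nonhomeless)
            rc.counts = counts
            rc.scheme = scheme
            rates[scheme] = rc
    except Exception as e:
        raise RuntimeError(f"stage 'rates' failed: {e}") from e
    t = _stage("rates", t)

    manifest = {
        "homeclass_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": config.to_dict(),
        "seeds": {
            "data": config.sim.seed,
            "split": config.split_seed,
            "downsample": config.downsample_seed,
        },
        "n_validation": int(len(val)),
        "n_development_balanced": int(len(balanced)),
    }

    report = RunReport(
        config=config,
        population=population,
        indicators=indicators,
        source_summary=source_summary,
        cohort=cohort,
        split=split,
        model=model,
        performance=performance,
        rates=rates,
        death_classifications=deaths,
        manifest=manifest,
    )
    _validate_report(report)
    if config.out_dir:
        write_outputs(report, config.out_dir)
    return report


def _validate_report(report: RunReport) -> None:
    """Re-check cross-module invariants before anything is written."""
    ind = report.indicators
    src = ind[["via_apcd", "via_casemix", "via_dmh", "via_matris", "via_pmp"]].to_numpy()
    assert (ind["known_homeless"].to_numpy() == src.any(axis=1)).all()
    assert (ind["n_sources"].to_numpy() == src.sum(axis=1)).all()
    parts = report.split["partition"]
    assert set(parts.unique()) <= {"development", "validation"}
    for rc in report.rates.values():
        c = rc.counts
        if c.convention == "full_sum":
            n_val = report.manifest["n_validation"]
            assert abs((c.n_homeless + c.n_nonhomeless) - n_val) < 1e-6


def write_outputs(report: RunReport, out_dir) -> None:
    """Write all run artifacts (CSV + JSON) to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_population(report.population, out / "population")
    report.indicators.to_csv(out / "indicators.csv", index=False)
    report.cohort.to_csv(out / "cohort.csv", index=False)
    report.split.to_csv(out / "split.csv", index=False)
    report.death_classifications.to_csv(out / "death_classifications.csv", index=False)
    (out / "model.json").write_text(report.model.to_json())
    perf = report.performance
    (out / "performance.json").write_text(json.dumps(perf.as_percent_table(), indent=2))
    rows = []
    for scheme, rc in report.rates.items():
        c = rc.counts
        rows.append(
            {
                "scheme": scheme,
                "n_homeless": c.n_homeless,
                "deaths_homeless": c.deaths_homeless,
                "rate_homeless_per_100k": round(rc.rate_homeless, 1),
                "n_nonhomeless": c.n_nonhomeless,
                "deaths_nonhomeless": c.deaths_nonhomeless,
                "rate_nonhomeless_per_100k": round(rc.rate_nonhomeless, 1),
                "rate_ratio": round(rc.rate_ratio, 1),
                "ci_low": None if rc.ci_low is None else round(rc.ci_low, 1),
                "ci_high": None if rc.ci_high is None else round(rc.ci_high, 1),
            }
        )
    pd.DataFrame(rows).to_csv(out / "rate_comparison.csv", index=False)
    (out / "source_summary.json").write_text(json.dumps(report.source_summary, indent=2))
    (out / "manifest.json").write_text(json.dumps(report.manifest, indent=2))


def _spawn_seeds(master_seed: int, k: int) -> np.ndarray:
    """k reproducible sub-seeds (< 2**31) from one master seed."""
    return np.random.SeedSequence(master_seed).generate_state(k, dtype=np.uint32) % (2**31 - 1)


def estimate_rr_coverage(
    master_seed: int = 1,
    n_replicates: int = 200,
    n_persons: int = 500_000,
    true_rate_ratio: float = 20.0,
    scheme: str = "threshold_binary",
) -> dict:
    """Monte-Carlo recovery study for the embedded overdose rate ratio.

    Runs the complete workflow (generate, define cases, restrict, split,
    downsample, fit, score, weight) on independent replicates and records how
    often the 95% CI of the chosen scheme's estimated rate ratio covers the
    configured true value.
    """
    seeds = _spawn_seeds(master_seed, 3 * n_replicates)
    rrs, covered = [], 0
    for i in range(n_replicates):
        s = seeds[3 * i : 3 * i + 3]
        cfg = PipelineConfig(
            sim=SimulationConfig(n_persons=n_persons, seed=int(s[0]), true_rate_ratio=true_rate_ratio),
            split_seed=int(s[1]),
            downsample_seed=int(s[2]),
        )
        rc = run_pipeline(cfg).rates[scheme]
        rrs.append(rc.rate_ratio)
        if rc.ci_low is not None and rc.ci_low <= true_rate_ratio <= rc.ci_high:
            covered += 1
    return {
        "coverage": covered / n_replicates,
        "n_replicates": n_replicates,
        "n_persons": n_persons,
        "rate_ratios": rrs,
        "true_rate_ratio": true_rate_ratio,
    }


def null_signal_auc(master_seed: int = 1, n_persons: int = 200_000) -> float:
    """Validation AUC when every predictor effect is zero (uninformative
    features); sits at 0.5 up to Monte-Carlo noise."""
    from dataclasses import replace

    from .simulate import default_predictor_spec

    null_spec = [replace(p, log_odds_given_true_homeless=0.0) for p in default_predictor_spec()]
    seeds = _spawn_seeds(master_seed + 104_729, 3)
    cfg = PipelineConfig(
        sim=SimulationConfig(n_persons=n_persons, seed=int(seeds[0]), predictor_spec=null_spec),
        split_seed=int(seeds[1]),
        downsample_seed=int(seeds[2]),
    )
    return float(run_pipeline(cfg).performance.auc)
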