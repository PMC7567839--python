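"""End-to-end orchestration: simulate -> ingest -> importance -> metrics -> compare.

``run_all`` executes the stages in order from one :class:`PipelineConfig`,
persisting each stage's table as CSV in the output directory together
with a reproducibility manifest (config hash, seed, package versions,
SHA-256 checksums of every written file) and a plain-text summary report
(species counts per life-history group and per strongest predictor, and
the pairwise comparison tables). Seasons are analyzed independently
throughout.

Every stage is also callable on its own; rerunning a downstream stage on
the persisted upstream CSVs reproduces the end-to-end result.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import compare, importance, ingest, rangemetrics, simulate

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """One configuration for the whole analysis.

    Exactly one of ``simulation`` (generate a synthetic survey) or
    ``survey_path`` (read an existing survey CSV) must be set. With
    ``survey_path``, ``metadata_path`` must point at the species ->
    life_history table; ``substrate_path`` optionally triggers a
    nearest-neighbour grain-size join.
    """
    simulation: simulate.SimulationConfig | None = None
    survey_path: str | None = None
    metadata_path: str | None = None
    substrate_path: str | None = None
    rules: ingest.FilterRules = field(default_factory=ingest.FilterRules)
    fit_spec: importance.SmoothFitSpec = field(default_factory=importance.SmoothFitSpec)
    periods: rangemetrics.PeriodSpec = field(default_factory=rangemetrics.PeriodSpec)
    kde: rangemetrics.KdeOptions = field(default_factory=rangemetrics.KdeOptions)
    adjust: str | None = None

    def validate(self) -> None:
        problems = []
        if (self.simulation is None) == (self.survey_path is None):
            problems.append("exactly one of simulation / survey_path must be set")
        if self.survey_path is not None and self.metadata_path is None:
            problems.append("survey_path requires metadata_path")
        if problems:
            raise ValueError("invalid pipeline config: " + "; ".join(problems))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return {"__type__": type(o).__name__, **dataclasses.asdict(o)}
        if isinstance(o, (np.floating, np.integer)):
            return float(o)
        if isinstance(o, (tuple, set)):
            return list(o)
        return str(o)
    blob = json.dumps(dataclasses.asdict(config), default=default, sort_keys=True)
    return hashlib.sha256(blob.encode("utf8")).hexdigest()


def _summary_report(meta: pd.DataFrame, strongest: pd.DataFrame,
                    comparisons: pd.DataFrame) -> str:
    lines = ["# Pipeline summary", ""]
    lh = dict(zip(meta["species"], meta["life_history"]))
    for season, g in strongest.groupby("season"):
        lines.append(f"## Season: {season}")
        counts = g["species"].map(lh).value_counts()
        lines.append("species per life-history group: "
                     + ", ".join(f"{k}={v}" for k, v in counts.items()))
        by_pred = g.dropna(subset=["strongest_predictor"]) \
                   .groupby("strongest_predictor")["species"].count()
        lines.append("species per strongest predictor: "
                     + ", ".join(f"{k}={v}" for k, v in by_pred.items()))
        cross = (g.assign(life_history=g["species"].map(lh))
                  .dropna(subset=["strongest_predictor"])
                  .groupby(["life_history", "strongest_predictor"])["species"].count())
        lines.append("life-history x strongest predictor:")
        for (a, b), n in cross.items():
            lines.append(f"  {a:9s} {b:10s} {n}")
        lines.append("")
    lines.append("## Pairwise rank-sum comparisons")
    lines.append(comparisons.to_string(index=False) if len(comparisons)
                 else "(no comparisons computed)")
    lines.append("")
    return "\n".join(lines)


def run_all(config: PipelineConfig, out_dir) -> dict:
    """Run every stage; returns the result tables plus the manifest.

    Writes survey.csv (and truth.csv when simulating), filtered.csv,
    filter_log.csv, deviance.csv, strongest.csv, range_metrics.csv,
    comparisons.csv, summary.txt, and manifest.json under ``out_dir``.
    A stage failure aborts with that stage named, leaving prior outputs
    in place.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save(df: pd.DataFrame, name: str) -> None:
        p = out / name
        df.to_csv(p, index=False)
        written.append(p)

    stage = "simulate"
    try:
        if config.simulation is not None:
            survey, truth = simulate.build_survey(config.simulation)
            meta = simulate.species_metadata(config.simulation)
            save(survey, "survey.csv")
            save(truth, "truth.csv")
            save(meta, "species_metadata.csv")
        else:
            survey = ingest.read_survey(config.survey_path)
            meta = pd.read_csv(config.metadata_path)
            if config.substrate_path is not None:
                substrate = pd.read_csv(config.substrate_path)
                survey = ingest.join_substrate(survey, substrate)[ingest.REQUIRED_COLUMNS]

        stage = "ingest"
        filtered, retained, log = ingest.apply_filters(survey, config.rules)
        save(filtered, "filtered.csv")
        save(log, "filter_log.csv")

        stage = "importance"
        table, strongest = importance.deviance_table(filtered, config.fit_spec)
        save(table, "deviance.csv")
        save(strongest, "strongest.csv")

        stage = "rangemetrics"
        metrics = rangemetrics.range_metrics_table(filtered, config.periods, config.kde)
        save(metrics, "range_metrics.csv")

        stage = "compare"
        life_history = dict(zip(meta["species"], meta["life_history"]))
        comparisons = compare.compare_all(metrics, life_history, strongest,
                                          adjust=config.adjust)
        save(comparisons, "comparisons.csv")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    report = _summary_report(meta, strongest, comparisons)
    (out / "summary.txt").write_text(report)
    written.append(out / "summary.txt")

    import scipy
    import statsmodels

    from . import __version__
    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.simulation.seed if config.simulation else None,
        "versions": {"rangeshift": __version__, "numpy": np.__version__,
                     "scipy": scipy.__version__, "pandas": pd.__version__,
                     "statsmodels": statsmodels.__version__},
        "files": {p.name: _sha256(p) for p in written},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"survey": survey, "filtered": filtered, "retained": retained,
            "deviance": table, "strongest": strongest, "metrics": metrics,
            "comparisons": comparisons, "manifest": manifest, "summary": report}


def make_fixtures(out_dir, seed: int = 0) -> dict[str, Path]:
    """Write miniature survey / substrate / metadata CSVs (< 500 rows).

    One stratum, two stations per pass, three species (one per
    life-history group) over the full 33-year window: small enough for
    unit tests and docs, yet passes every inclusion filter and yields a
    complete range-metrics row per species.
    """
    strata = (simulate.StratumSpec("T1", (38.0, 41.0), (-72.0, -69.0),
                                   mean_depth=100.0, area=2.0e4),)
    # broad, high-baseline niches: with only 2 stations per pass the
    # fixture species must still clear the presence and edge-CPUE filters
    species = (
        simulate.SpeciesProfile(
            name="pelagic_1", life_history="pelagic",
            niche={"btemp": simulate.NicheTerm(12.0, 2.5, 2.0)},
            baseline_log_cpue=1.2, true_shift_km_per_decade=70.0),
        simulate.SpeciesProfile(
            name="benthic_1", life_history="benthic",
            niche={"grainsize": simulate.NicheTerm(0.5, 0.4, 2.0)},
            baseline_log_cpue=1.2),
        simulate.SpeciesProfile(
            name="demersal_1", life_history="demersal",
            niche={"btemp": simulate.NicheTerm(11.5, 2.5, 1.2),
                   "grainsize": simulate.NicheTerm(0.6, 0.4, 1.2)},
            baseline_log_cpue=1.2, true_shift_km_per_decade=35.0),
    )
    cfg = simulate.SimulationConfig(
        seed=seed, strata=strata, species=species,
        stations_per_unit_area=1e-4, grid_resolution=0.2)
    env = simulate.generate_environment(cfg)
    survey, truth = simulate.build_survey(cfg, env)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "survey": out / "survey.csv",
        "truth": out / "truth.csv",
        "substrate": out / "substrate.csv",
        "metadata": out / "species_metadata.csv",
    }
    survey.to_csv(paths["survey"], index=False)
    truth.to_csv(paths["truth"], index=False)
    simulate.substrate_table(env, thin=2).to_csv(paths["substrate"], index=False)
    simulate.species_metadata(cfg).to_csv(paths["metadata"], index=False)
    return paths
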