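"""End-to-end runs: simulate/load -> episodes -> prevalence -> ITS -> reports.

A run is described by a :class:`RunConfig`; ``run_analysis`` executes every
stage, writes all tables, model cards and plots into the output directory
and returns a manifest (input hashes, config echo, file list with hashes).
Two runs on identical inputs produce identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from . import __version__
from .claims import (
    DEFAULT_DRUG_REGISTRY,
    StudyCalendar,
    filter_cohort,
    read_dispensations,
    read_population,
    registry_by_atc,
    write_dispensations,
    write_population,
)
from .episodes import EpisodeConfig, episodes_for_cohort, write_episodes
from .its import ArimaSpec, plot_counterfactual, run_its, write_model_card, write_result
from .prevalence import (
    class_and_drug_profile,
    overall_prevalence,
    weekly_prevalence,
    write_profile,
    write_series,
)
from .simulate import SimulationConfig, simulate_registry, write_truth

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    output_dir: Path
    claims_path: Path | None = None       # None => simulate
    population_path: Path | None = None
    calendar: StudyCalendar = field(default_factory=StudyCalendar)
    episode_config: EpisodeConfig = field(default_factory=EpisodeConfig)
    arima_spec: ArimaSpec = field(default_factory=ArimaSpec)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    groups: tuple[str, ...] = ("N06A", "N06AA", "N06AB", "N06AX")
    sex_strata_for: tuple[str, ...] = ("N06A",)
    age_min: int = 18
    age_max: int = 22
    alpha: float = 0.05
    seed: int = 0
    make_plots: bool = True


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def study_preset(output_dir: str | Path, seed: int = 0) -> RunConfig:
    """Preset encoding the published study design: 2018-01-01 to 2021-11-01,
    interruption 2020-03-09, ages 18-22, grace factor 1.5, 12 burn-in weeks,
    weekly seasonal period 52."""
    return RunConfig(output_dir=Path(output_dir), seed=seed,
                     simulation=SimulationConfig(seed=seed))


def run_analysis(config: RunConfig) -> dict:
    """Execute the full pipeline and return the run manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "config": _config_echo(config),
                      "inputs": {}, "outputs": {}}

    if config.claims_path is None:
        logger.info("simulating registry (seed %d)", config.simulation.seed)
        records, population, truth = simulate_registry(config.simulation)
        claims_path = out / "claims.csv"
        pop_path = out / "population.csv"
        write_dispensations(records, claims_path)
        write_population(population, pop_path)
        write_truth(truth, out / "truth.csv")
    else:
        claims_path = Path(config.claims_path)
        if config.population_path is None or not Path(config.population_path).exists():
            raise FileNotFoundError(
                f"population file not found: {config.population_path}")
        if not claims_path.exists():
            raise FileNotFoundError(f"claims file not found: {claims_path}")
        pop_path = Path(config.population_path)
        records = read_dispensations(claims_path, DEFAULT_DRUG_REGISTRY)
        population = read_population(pop_path)
    manifest["inputs"] = {str(claims_path): _sha256(claims_path),
                          str(pop_path): _sha256(pop_path)}

    cal = config.calendar
    cohort = filter_cohort(records, cal, config.age_min, config.age_max)
    sex_of = {r.subject_id: r.sex for r in cohort}
    registry = registry_by_atc(DEFAULT_DRUG_REGISTRY)

    episodes_by_grouping = {
        "umbrella": episodes_for_cohort(
            cohort, registry, dataclasses.replace(config.episode_config,
                                                  grouping="umbrella")),
        "per_atc_class": episodes_for_cohort(
            cohort, registry, dataclasses.replace(config.episode_config,
                                                  grouping="per_atc_class")),
    }
    write_episodes(episodes_by_grouping["umbrella"], out / "episodes_umbrella.csv")
    write_episodes(episodes_by_grouping["per_atc_class"], out / "episodes_by_class.csv")

    overall = overall_prevalence(sex_of, population, cal, alpha=config.alpha)
    profile = class_and_drug_profile(
        cohort, population, cal, config.alpha,
        drug_names={s.atc_code: s.drug_name for s in DEFAULT_DRUG_REGISTRY})
    write_profile(profile, out / "profile.csv")

    its_summaries = {}
    for group in config.groups:
        grouping = "umbrella" if group == "N06A" else "per_atc_class"
        episodes = episodes_by_grouping[grouping]
        strata = ("all",) + (("F", "M") if group in config.sex_strata_for else ())
        for stratum in strata:
            tag = f"{group}_{stratum}"
            series = weekly_prevalence(episodes, group, cal, population,
                                       stratum, sex_of, config.alpha)
            write_series(series, out / f"series_{tag}.csv")
            try:
                fitted, result = run_its(series, config.arima_spec, config.alpha)
            except Exception as exc:  # degenerate series (e.g. empty group)
                logger.warning("ITS skipped for %s: %s", tag, exc)
                continue
            write_result(result, cal, out / f"counterfactual_{tag}.csv")
            write_model_card(fitted, out / f"model_{tag}.txt")
            if config.make_plots:
                plot_counterfactual(series, result, out / f"plot_{tag}.png")
            i = result.weeks.index(result.max_diff_week)
            its_summaries[tag] = {
                "order": list(fitted.order),
                "max_diff_week": result.max_diff_week,
                "max_diff_per_10k": round(float(result.diff_per_10k[i]), 1),
                "first_persistent_week": result.first_persistent_week,
            }

    lo, hi = overall.ci_per_10k
    manifest["summary"] = {
        "n_subjects": overall.numerator,
        "overall_rate_per_10k": round(overall.rate_per_10k, 1),
        "overall_ci_per_10k": [round(lo, 1), round(hi, 1)],
        "multi_class_share": round(profile.multi_class_share, 3),
        "its": its_summaries,
    }
    for p in sorted(out.iterdir()):
        if p.name != "manifest.json" and p.is_file():
            manifest["outputs"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str) + "\n", encoding="utf-8")
    return manifest


def _config_echo(config: RunConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        if isinstance(obj, Mapping):
            return {str(k): enc(v) for k, v in obj.items()}
        return str(obj) if not isinstance(obj, (int, float, bool, str, type(None))) else obj
    return enc(config)
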