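"""End-to-end orchestration: simulate -> describe -> screen -> enumerate ->
fit -> average -> report, writing publication-shaped CSV outputs and a run
manifest sufficient for exact re-execution."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .bma import BayesianModelAveraging
from .datamodel import StudyDataset, load_dataset
from .descriptive import descriptive_table, round_half_away
from .mcmc import McmcSettings, derive_seed
from .screening import (
    build_exclusions,
    indicator_correlations,
    screen_table,
    univariate_screen,
)
from .simulate import SimulationConfig, generate_study

logger = logging.getLogger(__name__)

#: Task groups taken through the full averaging stage; QC and flavoring stop
#: after univariate screening (too few samples for multiple regression).
BMA_TASK_GROUPS = ("overall", "roasting", "grinding", "packaging")
SCREEN_ONLY_TASK_GROUPS = ("qc", "flavoring")


@dataclass
class RunConfig:
    """Everything one pipeline run needs."""

    samples_path: str | None = None
    determinants_path: str | None = None
    facilities_path: str | None = None
    simulation: SimulationConfig | None = None
    analytes: tuple = ("diacetyl",)
    task_groups: tuple = BMA_TASK_GROUPS + SCREEN_ONLY_TASK_GROUPS
    screening_level: float = 0.80
    collinearity_threshold: float = 0.5
    settings: McmcSettings = field(default_factory=McmcSettings)
    descriptive_settings: McmcSettings | None = None
    out_dir: str = "expodet_run"
    seed: int = 0
    force_bma_groups: tuple = ()  # override the screen-only rule

    def __post_init__(self):
        if not (0 < self.screening_level < 1):
            raise ValueError("screening_level must be in (0, 1)")
        if not (0 < self.collinearity_threshold <= 1):
            raise ValueError("collinearity_threshold must be in (0, 1]")


@dataclass
class ReportBundle:
    """All artefacts of one pipeline run."""

    descriptive: dict = field(default_factory=dict)  # analyte -> DataFrame
    screening: dict = field(default_factory=dict)  # (analyte, group) -> results
    heatmap: pd.DataFrame | None = None
    bma: dict = field(default_factory=dict)  # (analyte, group) -> BMAResults
    manifest: dict = field(default_factory=dict)


def _load_or_simulate(config: RunConfig, analyte: str) -> StudyDataset:
    if config.samples_path is not None:
        return load_dataset(
            config.samples_path, config.determinants_path, analyte, config.facilities_path
        )
    sim = config.simulation or SimulationConfig.default(analyte)
    if sim.analyte != analyte:
        sim = dataclasses.replace(sim, analyte=analyte)
    analyte_key = sum(ord(c) for c in analyte)  # stable across processes
    sim = dataclasses.replace(sim, seed=derive_seed(config.seed, analyte_key))
    dataset, _ = generate_study(sim)
    return dataset


def write_heatmap_data(screen_results: dict) -> pd.DataFrame:
    """Long-format heatmap data: one row per (task model, determinant) with
    its direction and strongest notable level (none/80/90/95)."""
    rows = []
    for (analyte, group), results in screen_results.items():
        for res in results:
            level = res.strongest_level
            rows.append(
                {
                    "analyte": analyte,
                    "task_model": str(group),
                    "determinant": res.determinant,
                    "direction": res.direction,
                    "level": level if level else "none",
                }
            )
    return pd.DataFrame(
        rows, columns=["analyte", "task_model", "determinant", "direction", "level"]
    )


def write_bma_table(result, dataset: StudyDataset | None = None) -> pd.DataFrame:
    """Publication-shaped averaged-coefficient table, grouped by the
    determinant dictionary's editorial groupings, percentages to one decimal
    (half away from zero)."""
    res = getattr(result, "result", result)
    tab = res.to_table()
    if dataset is not None:
        tab.insert(
            0, "group", [dataset.spec(d).group for d in tab["determinant"]]
        )
    tab["pct_models"] = [round_half_away(x, 1) for x in tab["pct_models"]]
    return tab


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Run the full analysis per analyte x task group and write artefacts."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle()
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "screening_level": config.screening_level,
        "collinearity_threshold": config.collinearity_threshold,
        "stages": [],
        "warnings": [],
    }

    desc_settings = config.descriptive_settings or dataclasses.replace(
        config.settings, thin=1, kept_iterations=2 * config.settings.kept_iterations
    )

    for analyte in config.analytes:
        dataset = _load_or_simulate(config, analyte)
        manifest["stages"].append({"stage": "load", "analyte": analyte, "n": len(dataset.records)})

        desc = descriptive_table(dataset, settings=desc_settings.with_seed(
            derive_seed(config.seed, 1)
        ))
        desc.to_csv(out / f"descriptive_table_{analyte}.csv", index=False)
        bundle.descriptive[analyte] = desc

        det_names = [d.name for d in dataset.determinants]
        for group in config.task_groups:
            try:
                results = univariate_screen(
                    dataset,
                    det_names,
                    task_filter=group,
                    settings=config.settings.with_seed(derive_seed(config.seed, 2)),
                )
            except (ValueError, KeyError) as exc:
                logger.warning("screening failed for %s/%s: %s", analyte, group, exc)
                manifest["warnings"].append(f"screen {analyte}/{group}: {exc}")
                continue
            bundle.screening[(analyte, group)] = results
            screen_table(results).to_csv(
                out / f"univariate_screen_{analyte}_{group}.csv", index=False
            )
            manifest["stages"].append(
                {"stage": "screen", "analyte": analyte, "group": group,
                 "n_determinants": len(results)}
            )

            do_bma = group in BMA_TASK_GROUPS or group in config.force_bma_groups
            if not do_bma:
                continue
            notable = [r.determinant for r in results if r.notable_80]
            if not notable:
                manifest["warnings"].append(f"bma {analyte}/{group}: nothing notable at 80%")
                continue
            if len(notable) >= 2:
                corr = indicator_correlations(dataset, notable, group)
                corr.stack().rename("r").reset_index().to_csv(
                    out / f"correlations_{analyte}_{group}.csv", index=False
                )
                exclusions = build_exclusions(
                    corr,
                    [dataset.spec(n) for n in notable],
                    threshold=config.collinearity_threshold,
                )
            else:
                exclusions = None
            with open(out / f"exclusions_{analyte}_{group}.json", "w", encoding="utf-8") as fh:
                json.dump(exclusions.to_json_dict() if exclusions else {}, fh, indent=1)

            bma = BayesianModelAveraging(
                dataset, notable, exclusions, task_filter=group
            )
            fitted = bma.fit(
                config.settings.with_seed(derive_seed(config.seed, 3)),
                cache_dir=out / "cache",
            )
            bundle.bma[(analyte, group)] = fitted
            write_bma_table(fitted, dataset).to_csv(
                out / f"bma_table_{analyte}_{group}.csv", index=False
            )
            with open(out / f"model_space_{analyte}_{group}.json", "w", encoding="utf-8") as fh:
                json.dump(bma.space.to_json_dict(), fh, indent=1)
            manifest["stages"].append(
                {
                    "stage": "bma",
                    "analyte": analyte,
                    "group": group,
                    "n_models": len(bma.space.models),
                    "intercept_reference_gm_ppb": fitted.intercept_reference_gm_ppb,
                }
            )

    heat = write_heatmap_data(bundle.screening)
    heat.to_csv(out / "heatmap_data.csv", index=False)
    bundle.heatmap = heat
    manifest["elapsed_s"] = round(time.time() - t0, 2)
    bundle.manifest = manifest
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)
    return bundle
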