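"""End-to-end experiment driver: data -> features -> (selection) ->
training -> temporal hold-out validation -> habitat maps.

One :class:`ExperimentConfig` and one master seed drive the whole run; all
stage seeds (simulation, subsampling, selection, calibration folds) are
derived deterministically from the master seed, so re-running a recorded
config reproduces every report number bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import __version__
from .classifier import (TrainingConfig, build_training_set, save_model,
                         train)
from .evaluation import (contrast_table, evaluate_labels,
                         probability_summary, round_half_up)
from .geodata_io import (INVASIVE, NATIVE, FeatureTable, attach_features,
                         concat_tables, read_occurrences,
                         write_feature_table)
from .grids import ClimateStack, read_stacks, write_ascii_grid, write_stacks
from .mapping import predict_average_map, predict_raster
from .selection import GAConfig, ga_select
from .synthetic_world import (WorldConfig, generate_climate_stack,
                              generate_occurrences, make_paperlike_scenario)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class ExperimentConfig:
    target_species: str
    native_species: tuple[str, ...]
    train_years: tuple[int, ...]
    test_year: int
    data_source: str = "synthetic"  # "synthetic" | "files"
    variables: tuple[str, ...] | None = None  # None -> all available
    training: TrainingConfig = field(default_factory=TrainingConfig)
    ga: GAConfig | None = None
    world: WorldConfig | None = None  # synthetic source
    separation: float = 1.0  # synthetic niche separation scale
    occurrence_paths: Mapping[str, str] | None = None  # files source
    raster_manifest: str | None = None
    output_dir: str | None = None
    master_seed: int = 0

    def validate(self) -> None:
        if self.test_year in self.train_years:
            raise ConfigError("train years and test year must be disjoint")
        if not self.native_species:
            raise ConfigError("need at least one native species")
        if self.data_source not in ("synthetic", "files"):
            raise ConfigError(f"unknown data source {self.data_source!r}")
        if self.data_source == "files":
            if not self.occurrence_paths or not self.raster_manifest:
                raise ConfigError("files source needs occurrence_paths and "
                                  "raster_manifest")

    @property
    def role_map(self) -> dict[str, str]:
        roles = {self.target_species: INVASIVE}
        roles.update({s: NATIVE for s in self.native_species})
        return roles


@dataclass
class ExperimentReport:
    config: dict
    seeds: dict
    version: str
    species_counts_before: dict
    species_counts_after: dict
    selected_variables: list[str]
    selection_trace: list[float] | None
    confusion: dict
    metrics: dict
    probability_summary: dict
    contrasts: list[dict]
    artifacts: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    return str(obj)


def _stage_seeds(master_seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(master_seed)
    names = ("simulate", "occurrences", "subsample", "selection")
    state = ss.generate_state(len(names)) % (2 ** 31)
    return dict(zip(names, (int(s) for s in state)))


def _load_synthetic(config: ExperimentConfig, seeds: dict
                    ) -> tuple[dict[int, ClimateStack], FeatureTable]:
    world, niches, _truth = make_paperlike_scenario(
        seeds["simulate"], separation=config.separation)
    if config.world is not None:
        world = dataclasses.replace(config.world, seed=seeds["simulate"])
    years = sorted({*config.train_years, config.test_year})
    missing = [y for y in years if y not in world.years]
    if missing:
        raise ConfigError(f"world config lacks years {missing}")
    stacks = {yr: generate_climate_stack(world, yr) for yr in years}
    wanted = {config.target_species, *config.native_species}
    niche_by_id = {n.species_id: n for n in niches}
    absent = wanted - set(niche_by_id)
    if absent:
        raise ConfigError(f"species {sorted(absent)} not in scenario")
    records = []
    for species in sorted(wanted):
        for yr in years:
            records.extend(generate_occurrences(
                world, niche_by_id[species], stacks[yr],
                seed=seeds["occurrences"]))
    variables = tuple(config.variables or world.variables)
    table = attach_features(records, stacks, variables, config.role_map)
    return stacks, table


def _load_files(config: ExperimentConfig) -> tuple[dict[int, ClimateStack],
                                                   FeatureTable]:
    stacks_by_label = read_stacks(config.raster_manifest)
    stacks = {int(lbl): s for lbl, s in stacks_by_label.items()}
    records = []
    for species, path in config.occurrence_paths.items():
        records.extend(read_occurrences(path, config.role_map,
                                        species_id=species))
    years = {*config.train_years, config.test_year}
    records = [r for r in records if r.year in years]
    first = next(iter(stacks.values()))
    variables = tuple(config.variables or first.variables)
    table = attach_features(records, stacks, variables, config.role_map)
    return stacks, table


def run_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Execute the full study: train on the training years, validate on the
    hold-out year, map the hold-out year and the multi-year average."""
    config.validate()
    seeds = _stage_seeds(config.master_seed)

    try:
        if config.data_source == "synthetic":
            stacks, table = _load_synthetic(config, seeds)
        else:
            stacks, table = _load_files(config)
    except Exception as exc:
        raise RuntimeError(f"stage 'data': {exc}; check paths/world config "
                           "and species ids") from exc

    in_train = table.data["year"].isin(config.train_years).to_numpy()
    in_test = (table.data["year"] == config.test_year).to_numpy()
    train_table = table.subset(in_train)
    test_table = table.subset(in_test)
    if len(train_table) == 0 or len(test_table) == 0:
        raise ConfigError("no records in training or test years")

    selected = list(table.variables)
    trace = None
    if config.ga is not None:
        ga_conf = dataclasses.replace(config.ga, seed=seeds["selection"])
        selected, trace = ga_select(train_table, config.training, ga_conf)
        train_table = FeatureTable(train_table.data, selected)
        test_table = FeatureTable(test_table.data, selected)

    counts_before = train_table.species_counts()
    capped = build_training_set(train_table, seed=seeds["subsample"],
                                config=config.training)
    counts_after = capped.species_counts()
    model = train(capped, config.training)

    predicted = model.predict_class(test_table)
    observed = test_table.data["label"].to_numpy()
    evald = evaluate_labels(observed, predicted)
    cm = evald["confusion"]
    invasive_test = test_table.subset(
        (test_table.data["label"] == INVASIVE).to_numpy())
    psummary = probability_summary(model, invasive_test)
    contrasts = contrast_table(capped)

    test_raster = predict_raster(model, stacks[config.test_year])
    period_raster = predict_average_map(
        model, [stacks[y] for y in sorted(stacks)])

    artifacts: dict[str, str] = {}
    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_feature_table(table, out / "features.csv")
        save_model(model, out / "model.joblib")
        write_stacks(stacks.values(), out / "grids")
        for name, raster in (("probability_%s" % config.test_year,
                              test_raster),
                             ("colonisation_potential", period_raster)):
            write_ascii_grid(out / f"{name}.asc", raster.values,
                             raster.geometry)
            artifacts[name] = str(out / f"{name}.asc")
        artifacts.update({"features": str(out / "features.csv"),
                          "model": str(out / "model.joblib")})

    def _metrics_row(m) -> dict:
        row = {"precision": round_half_up(m.precision),
               "recall": round_half_up(m.recall),
               "f1": round_half_up(m.f1)}
        row["n"] = m.n if hasattr(m, "n") else m.n_invasive + m.n_native
        return row

    report = ExperimentReport(
        config=dataclasses.asdict(config),
        seeds=seeds,
        version=__version__,
        species_counts_before=counts_before,
        species_counts_after=counts_after,
        selected_variables=selected,
        selection_trace=trace,
        confusion={
            "invasive_positive": dataclasses.asdict(cm),
            "native_positive": dataclasses.asdict(cm.swapped()),
        },
        metrics={
            "invasive": _metrics_row(evald["invasive"]),
            "native": _metrics_row(evald["native"]),
            "weighted": _metrics_row(evald["weighted"]),
            "weighted_raw": dataclasses.asdict(evald["weighted"]),
        },
        probability_summary=dataclasses.asdict(psummary),
        contrasts=contrasts,
        artifacts=artifacts,
    )
    if config.output_dir is not None:
        report.write(Path(config.output_dir) / "report.json")
    return report
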