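"""Pipeline orchestration: simulate -> velocity -> transitions -> enrich -> spatial.

Each stage reads its inputs from the run directory, writes TSV/MatrixMarket/
JSON outputs plus a manifest (config echo, seed, output checksums), and is
individually invocable.  Velocity and transition models are fitted per
condition, since fate dynamics are condition-specific; the transition stage
then compares the per-cell transition masses between conditions.  Reruns
with identical config and seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import io as spio

from . import io as dio
from . import popstats, spatial as spatial_mod, transitions as trans_mod
from .synthetic import (
    CONTROL,
    TBI,
    LineageSpec,
    NoiseConfig,
    SpatialLayoutConfig,
    default_gene_programs,
    simulate_dataset,
    simulate_spatial,
)
from .velocity import VelocityConfig, estimate_velocity

logger = logging.getLogger("dgfate")

STAGES = ("simulate", "velocity", "transitions", "enrich", "spatial")


class PipelineDependencyError(RuntimeError):
    """An enabled stage is missing the outputs of an upstream stage."""


def setup_logging(outdir: str | Path | None = None, verbosity: int = logging.INFO) -> None:
    """Console + optional run-log-file logging (timestamp-free formatter,
    so log files do not break rerun byte-identity)."""
    root = logging.getLogger("dgfate")
    root.setLevel(verbosity)
    root.handlers.clear()
    fmt = logging.Formatter("%(levelname)s %(name)s: %(message)s")
    sh = logging.StreamHandler()
    sh.setFormatter(fmt)
    root.addHandler(sh)
    if outdir is not None:
        Path(outdir).mkdir(parents=True, exist_ok=True)
        fh = logging.FileHandler(Path(outdir) / "run.log", mode="w")
        fh.setFormatter(fmt)
        root.addHandler(fh)


@dataclass(frozen=True)
class SimulateConfig:
    n_genes: int = 100
    cells_per_condition: dict[str, int] = field(
        default_factory=lambda: {CONTROL: 6000, TBI: 6000}
    )
    fate_bias: dict[str, float] = field(
        default_factory=lambda: {CONTROL: 0.5, TBI: 0.75}
    )
    animals_per_condition: dict[str, int] = field(
        default_factory=lambda: {CONTROL: 5, TBI: 6}
    )
    noise_model: str = "poisson"
    capture_sigma: float = 0.3
    target_counts_per_cell: float | None = 3000.0
    segment_duration: float = 3.0
    include_malat1: bool = True


@dataclass(frozen=True)
class TransitionsStageConfig:
    sigma: float = 0.05
    min_neighborhood: int = 300
    scale: str = "sqrt"
    exclude_populations: tuple[str, ...] = ()
    per_neighbor_mean: bool = False
    min_cells: int = 2
    write_matrices: bool = True


@dataclass(frozen=True)
class EnrichConfig:
    p0: str | float = "auto"  # "auto": TBI share of the analysed cells
    cluster_col: str = "population"


@dataclass(frozen=True)
class SpatialStageConfig:
    enabled: bool = True
    cells_per_population_per_animal: int = 40
    animals_per_condition: dict[str, int] = field(
        default_factory=lambda: {CONTROL: 4, TBI: 5}
    )


@dataclass(frozen=True)
class RunConfig:
    outdir: str = "dgfate_run"
    seed: int = 1
    stages: tuple[str, ...] = STAGES
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    velocity: VelocityConfig = field(default_factory=VelocityConfig)
    transitions: TransitionsStageConfig = field(default_factory=TransitionsStageConfig)
    enrich: EnrichConfig = field(default_factory=EnrichConfig)
    spatial: SpatialStageConfig = field(default_factory=SpatialStageConfig)

    def __post_init__(self) -> None:
        for s in self.stages:
            if s not in STAGES:
                raise ValueError(f"unknown stage {s!r}")
        if "simulate" in self.stages and self.seed is None:
            raise ValueError("a seed is required when simulation is enabled")

    @staticmethod
    def from_dict(raw: dict) -> "RunConfig":
        def build(cls, key):
            sub = dict(raw.get(key) or {})
            for f_ in dataclasses.fields(cls):
                if f_.name in sub and isinstance(sub[f_.name], list):
                    sub[f_.name] = tuple(sub[f_.name])
            return cls(**sub)

        kwargs: dict = {}
        for key in ("outdir", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        if "stages" in raw:
            kwargs["stages"] = tuple(raw["stages"])
        kwargs["simulate"] = build(SimulateConfig, "simulate")
        kwargs["velocity"] = build(VelocityConfig, "velocity")
        kwargs["transitions"] = build(TransitionsStageConfig, "transitions")
        kwargs["enrich"] = build(EnrichConfig, "enrich")
        kwargs["spatial"] = build(SpatialStageConfig, "spatial")
        return RunConfig(**kwargs)

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return RunConfig.from_dict(yaml.safe_load(fh) or {})


def _config_echo(config: RunConfig) -> dict:
    return json.loads(json.dumps(dataclasses.asdict(config), default=list))


def _require(path: Path, stage: str, needed_by: str) -> None:
    if not path.exists():
        raise PipelineDependencyError(
            f"stage '{needed_by}' needs {path}, which stage '{stage}' produces; "
            f"run '{stage}' first"
        )


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(config: RunConfig) -> None:
    out = Path(config.outdir) / "data"
    sc = config.simulate
    lineage = LineageSpec(
        fate_bias_by_condition=sc.fate_bias,
        cells_per_condition=sc.cells_per_condition,
        animals_per_condition=sc.animals_per_condition,
        segment_duration=sc.segment_duration,
    )
    programs = default_gene_programs(
        lineage, n_genes=sc.n_genes, seed=config.seed, include_malat1=sc.include_malat1
    )
    noise = NoiseConfig(
        model=sc.noise_model,
        capture_sigma=sc.capture_sigma,
        target_counts_per_cell=sc.target_counts_per_cell,
    )
    ds = simulate_dataset(lineage, programs, noise=noise, seed=config.seed)
    dio.write_dataset(ds, out)
    if config.spatial.enabled:
        layout = SpatialLayoutConfig(
            animals_per_condition=config.spatial.animals_per_condition,
            cells_per_population_per_animal=config.spatial.cells_per_population_per_animal,
        )
        dio.write_spatial(
            simulate_spatial(layout, seed=config.seed + 1), out / "spatial.tsv"
        )
    dio.write_manifest(
        out / "manifest.json",
        {"stage": "simulate", "seed": config.seed, "config": _config_echo(config),
         "checksums": dio.checksum_dir(out)},
    )
    logger.info("simulate: %d genes x %d cells written to %s", ds.n_genes, ds.n_cells, out)


def stage_velocity(config: RunConfig) -> None:
    base = Path(config.outdir)
    _require(base / "data" / "spliced.mtx", "simulate", "velocity")
    ds = dio.read_dataset(base / "data")
    for cond in sorted(ds.cell_meta["condition"].unique()):
        sub = ds.subset_condition(cond)
        res = estimate_velocity(sub, config.velocity)
        out = base / "velocity" / cond
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({"gene_id": res.kept_genes, "gamma_hat": res.gamma_hat}).to_csv(
            out / "gamma.tsv", sep="\t", index=False
        )
        spio.mmwrite(str(out / "current.mtx"), _sparse(res.current))
        spio.mmwrite(str(out / "deltae.mtx"), _sparse(res.delta_e))
        spio.mmwrite(str(out / "velocity.mtx"), _sparse(res.velocity))
        dio.write_manifest(
            out / "manifest.json",
            {"stage": "velocity", "condition": cond, "seed": config.seed,
             "config": _config_echo(config),
             "n_kept_genes": int(res.kept_genes.size),
             "dropped_degenerate": list(map(str, res.dropped_degenerate)),
             "checksums": dio.checksum_dir(out)},
        )
        logger.info("velocity[%s]: kept %d genes", cond, res.kept_genes.size)


def _sparse(mat: np.ndarray):
    from scipy import sparse

    return sparse.coo_matrix(mat)


def stage_transitions(config: RunConfig) -> None:
    base = Path(config.outdir)
    _require(base / "data" / "cells.tsv", "simulate", "transitions")
    ds = dio.read_dataset(base / "data")
    tcfg = config.transitions
    model_cfg = trans_mod.TransitionConfig(
        sigma=tcfg.sigma,
        min_neighborhood=tcfg.min_neighborhood,
        scale=tcfg.scale,
        exclude_populations=tuple(tcfg.exclude_populations),
        per_neighbor_mean=tcfg.per_neighbor_mean,
    )
    out = base / "transitions"
    out.mkdir(parents=True, exist_ok=True)
    summaries = []
    for cond in sorted(ds.cell_meta["condition"].unique()):
        vdir = base / "velocity" / cond
        _require(vdir / "current.mtx", "velocity", "transitions")
        current = np.asarray(spio.mmread(vdir / "current.mtx").todense())
        delta_e = np.asarray(spio.mmread(vdir / "deltae.mtx").todense())
        sub = ds.subset_condition(cond)
        labels = sub.cell_meta["population"].to_numpy()
        keep = ~np.isin(labels, model_cfg.exclude_populations)
        inner_cfg = trans_mod.TransitionConfig(
            **{**model_cfg.__dict__, "exclude_populations": ()}
        )
        model = trans_mod.fit_transition_model(
            sub.embedding[keep], labels[keep], current[:, keep], delta_e[:, keep],
            inner_cfg,
        )
        cell_ids = sub.cell_meta["cell_id"].to_numpy()[keep]
        if tcfg.write_matrices:
            for kind in ("cc", "tp"):
                frames = []
                blocks = getattr(model, f"{kind}_by_population")
                for p, rows in model.rows_by_population.items():
                    n_p = model.n_by_population[p]
                    src = np.repeat(cell_ids[rows], n_p)
                    tgt = cell_ids[model.neighbor_idx[rows, :n_p].ravel()]
                    frames.append(
                        pd.DataFrame(
                            {"source_population": p, "source_cell": src,
                             "target_cell": tgt, "value": blocks[p].ravel()}
                        )
                    )
                pd.concat(frames, ignore_index=True).to_csv(
                    out / f"{kind}_{cond}.tsv", sep="\t", index=False
                )
        summary = trans_mod.population_transition_summary(
            sub.embedding[keep], labels[keep], current[:, keep], delta_e[:, keep],
            condition=cond, cell_ids=cell_ids, config=inner_cfg,
        )
        summaries.append(summary)
        logger.info(
            "transitions[%s]: %d populations, neighbourhoods %s",
            cond, len(model.n_by_population), model.n_by_population,
        )
    summary = pd.concat(summaries, ignore_index=True)
    stats = (
        summary.groupby(["source", "target", "condition"])["mass"]
        .agg(n_cells="count", mean="mean", median="median",
             q1=lambda v: v.quantile(0.25), q3=lambda v: v.quantile(0.75))
        .reset_index()
    )
    stats.to_csv(out / "summary.tsv", sep="\t", index=False)
    summary.to_csv(out / "per_cell_mass.tsv", sep="\t", index=False)
    conds = tuple(sorted(ds.cell_meta["condition"].unique()))
    comparisons = trans_mod.compare_conditions(
        summary, conditions=conds[:2], min_cells=tcfg.min_cells
    )
    with open(out / "comparisons.json", "w") as fh:
        json.dump(
            json.loads(comparisons.to_json(orient="records")), fh,
            indent=2, sort_keys=True,
        )
        fh.write("\n")
    dio.write_manifest(
        out / "manifest.json",
        {"stage": "transitions", "seed": config.seed, "config": _config_echo(config),
         "checksums": dio.checksum_dir(out)},
    )


def stage_enrich(config: RunConfig) -> None:
    base = Path(config.outdir)
    _require(base / "data" / "cells.tsv", "simulate", "enrich")
    cells = pd.read_csv(base / "data" / "cells.tsv", sep="\t")
    table = popstats.composition_table(cells, cluster_col=config.enrich.cluster_col)
    p0 = (
        popstats.expected_fraction(cells)
        if config.enrich.p0 == "auto"
        else float(config.enrich.p0)
    )
    result = popstats.binomial_enrichment(table, p0)
    result.insert(1, "p0", p0)
    out = base / "enrichment"
    out.mkdir(parents=True, exist_ok=True)
    result.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    dio.write_manifest(
        out / "manifest.json",
        {"stage": "enrich", "seed": config.seed, "p0": p0,
         "config": _config_echo(config), "checksums": dio.checksum_dir(out)},
    )
    logger.info("enrich: %d clusters tested against p0=%.4f", len(result), p0)


def stage_spatial(config: RunConfig) -> None:
    base = Path(config.outdir)
    spath = base / "data" / "spatial.tsv"
    _require(spath, "simulate", "spatial")
    cells = dio.read_spatial(spath)
    assignment = spatial_mod.assign_zone(cells)
    composition = spatial_mod.zone_composition(assignment)
    tests = spatial_mod.compare_locations(composition)
    out = base / "spatial"
    out.mkdir(parents=True, exist_ok=True)
    assignment.to_csv(out / "zones.tsv", sep="\t", index=False)
    composition.to_csv(out / "composition.tsv", sep="\t", index=False)
    with open(out / "location_tests.json", "w") as fh:
        json.dump(json.loads(tests.to_json(orient="records")), fh, indent=2, sort_keys=True)
        fh.write("\n")
    dio.write_manifest(
        out / "manifest.json",
        {"stage": "spatial", "seed": config.seed, "config": _config_echo(config),
         "checksums": dio.checksum_dir(out)},
    )
    logger.info("spatial: %d location comparisons", len(tests))


_STAGE_FN = {
    "simulate": stage_simulate,
    "velocity": stage_velocity,
    "transitions": stage_transitions,
    "enrich": stage_enrich,
    "spatial": stage_spatial,
}


def run_pipeline(config: RunConfig, dry_run: bool = False) -> dict:
    """Execute the enabled stages in dependency order and write a run manifest.

    With ``dry_run`` the planned stages are returned and nothing is written.
    """
    planned = [s for s in STAGES if s in config.stages]
    if dry_run:
        logger.info("dry run: would execute %s", planned)
        return {"planned_stages": planned, "dry_run": True}
    base = Path(config.outdir)
    base.mkdir(parents=True, exist_ok=True)
    for s in planned:
        if s == "spatial" and not config.spatial.enabled:
            logger.info("spatial stage disabled; skipping")
            continue
        _STAGE_FN[s](config)
    manifest = {
        "stages": planned,
        "seed": config.seed,
        "config": _config_echo(config),
        "checksums": dio.checksum_dir(base),
    }
    dio.write_manifest(base / "manifest.json", manifest)
    return manifest
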