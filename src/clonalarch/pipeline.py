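"""End-to-end orchestration: config in, tables/trees/report out.

A single YAML config drives the run: either paths to an observed
genotype matrix (plus optional catalog and colony table) or an embedded
simulation config.  The pipeline executes

    read/simulate -> conflict scan -> repair -> clone calling ->
    mutation ordering -> clone tree -> temporal tables ->
    ADO validation (when colonies are present)

and writes every artifact with a content hash into a JSON manifest, so
identical config + seed reproduce identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ado as ado_mod
from .clone_calling import ClonePartition, call_clones, clone_entropy
from .genotype_io import (
    ColonyTable,
    GenotypeMatrix,
    GenotypeState,
    genotype_counts,
    read_colony_table,
    read_genotype_matrix,
    read_mutation_catalog,
    write_colony_table,
    write_genotype_matrix,
)
from .phylogeny import build_clone_tree, export_newick, find_conflicts, order_mutations, repair_min_flips
from .synthetic import SimulationConfig, simulate_dataset
from .temporal import frequency_trajectories, timescape_records, track_clones, zygosity_evolution

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Everything a run needs; exactly one of (input paths, simulation)."""

    outdir: str = "clonalarch_out"
    seed: int = 0
    log_level: str = "INFO"
    # input mode A: observed data
    matrix_path: str | None = None
    catalog_path: str | None = None
    colonies_path: str | None = None
    colony_mutation: str | None = None
    timepoint_order: list[str] = field(default_factory=list)
    # input mode B: simulation
    simulation: SimulationConfig | None = None
    # analysis parameters
    resolution: str = "zygosity"
    min_cells: int = 1
    repair_budget: int | None = None

    def __post_init__(self) -> None:
        has_paths = self.matrix_path is not None
        has_sim = self.simulation is not None
        if has_paths == has_sim:
            raise ValueError("config needs exactly one of matrix_path or simulation")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if raw.get("simulation") is not None and not isinstance(raw["simulation"], SimulationConfig):
            raw["simulation"] = SimulationConfig.from_dict(raw["simulation"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full analysis; returns the artifact manifest."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    report: dict = {"seed": cfg.seed, "stages": []}

    def stage(name: str):
        report["stages"].append(name)
        logger.info("stage: %s", name)

    def run_stage(name, fn, *args, **kwargs):
        stage(name)
        try:
            return fn(*args, **kwargs)
        except Exception as e:  # noqa: BLE001 - re-raised with stage context
            raise PipelineError(name, e) from e

    # -- inputs ------------------------------------------------------------
    colonies: ColonyTable | None = None
    if cfg.simulation is not None:
        def _simulate():
            sim = cfg.simulation
            ds = simulate_dataset(sim, seed=cfg.seed)
            write_genotype_matrix(ds.observed, outdir / "observed_matrix.tsv")
            artifacts["observed_matrix"] = outdir / "observed_matrix.tsv"
            _write_csv(ds.truth, outdir / "truth_clones.tsv")
            artifacts["truth_clones"] = outdir / "truth_clones.tsv"
            if ds.colonies is not None:
                write_colony_table(ds.colonies, outdir / "colonies.tsv")
                artifacts["colonies"] = outdir / "colonies.tsv"
            return ds.observed, ds.colonies

        matrix, colonies = run_stage("simulate", _simulate)
    else:
        def _read():
            catalog = read_mutation_catalog(cfg.catalog_path) if cfg.catalog_path else None
            m = read_genotype_matrix(
                cfg.matrix_path,
                catalog=catalog,
                timepoint_order=cfg.timepoint_order or None,
            )
            col = None
            if cfg.colonies_path:
                col = read_colony_table(cfg.colonies_path, cfg.colony_mutation or m.mutation_ids[0])
            return m, col

        matrix, colonies = run_stage("read", _read)

    # -- conflicts and repair -----------------------------------------------
    conflicts = run_stage("conflict_scan", find_conflicts, matrix)
    _write_csv(conflicts.to_frame(), outdir / "conflicts.tsv")
    artifacts["conflicts"] = outdir / "conflicts.tsv"

    flips: list = []
    if not conflicts.is_conflict_free:
        def _repair():
            repaired, fl = repair_min_flips(matrix, cfg.repair_budget)
            return repaired, fl

        matrix, flips = run_stage("repair", _repair)
    _write_csv(
        pd.DataFrame(flips, columns=["cell_id", "mutation", "old", "new"]),
        outdir / "repair_flips.tsv",
    )
    artifacts["repair_flips"] = outdir / "repair_flips.tsv"

    # -- clones, order, tree --------------------------------------------------
    partition = run_stage("clone_calling", call_clones, matrix, cfg.resolution, cfg.min_cells)
    _write_csv(partition.to_frame(), outdir / "clones.tsv")
    artifacts["clones"] = outdir / "clones.tsv"

    order = run_stage("mutation_order", order_mutations, matrix)

    major = partition.major_only() if cfg.min_cells > 1 else partition
    tree = run_stage("clone_tree", build_clone_tree, major, order)
    (outdir / "clone_tree.nwk").write_text(export_newick(tree) + "\n")
    artifacts["clone_tree_newick"] = outdir / "clone_tree.nwk"
    (outdir / "clone_tree.json").write_text(
        json.dumps(tree.to_json_dict(), indent=2, sort_keys=True) + "\n"
    )
    artifacts["clone_tree_json"] = outdir / "clone_tree.json"

    # -- temporal dynamics -----------------------------------------------------
    trajectories = run_stage("trajectories", frequency_trajectories, matrix, order)
    _write_csv(trajectories.frame, outdir / "mutation_trajectories.tsv")
    artifacts["mutation_trajectories"] = outdir / "mutation_trajectories.tsv"

    prevalence = run_stage("prevalence", track_clones, major, tree)
    _write_csv(prevalence.frame, outdir / "clone_prevalence.tsv")
    artifacts["clone_prevalence"] = outdir / "clone_prevalence.tsv"
    (outdir / "timescape.json").write_text(
        json.dumps(timescape_records(prevalence, tree), indent=2, sort_keys=True) + "\n"
    )
    artifacts["timescape"] = outdir / "timescape.json"

    def _zygosity():
        rows = []
        for mid in matrix.mutation_ids:
            for rec in zygosity_evolution(matrix, mid):
                rows.append(
                    {
                        "mutation": mid,
                        "timepoint": rec.timepoint,
                        **{f"p_{k}": v for k, v in rec.proportions.items()},
                        "mutated_fraction": rec.mutated_fraction,
                    }
                )
        return pd.DataFrame(rows)

    zyg = run_stage("zygosity_evolution", _zygosity)
    _write_csv(zyg, outdir / "zygosity_evolution.tsv")
    artifacts["zygosity_evolution"] = outdir / "zygosity_evolution.tsv"

    entropy = {
        tp: clone_entropy(partition, tp) for tp in matrix.timepoint_order
    }

    # -- ADO validation ---------------------------------------------------------
    ado_result = None
    if colonies is not None:
        def _ado():
            mut = colonies.mutation_id
            out = {}
            for tp in matrix.timepoint_order:
                col_counts = colonies.counts(tp)
                if col_counts.sum() == 0:
                    continue
                counts = genotype_counts(matrix, mut, tp)
                cells3 = [counts[GenotypeState.WT], counts[GenotypeState.HET], counts[GenotypeState.HOM]]
                est = ado_mod.estimate_ado_rate(
                    cells3, col_counts, cell_missing=counts[GenotypeState.MISSING],
                    seed=cfg.seed, n_boot=200,
                )
                test = ado_mod.genotype_distribution_test(cells3, col_counts, seed=cfg.seed)
                out[tp] = {
                    "mutation": mut,
                    "cell_counts": cells3,
                    "cell_missing": counts[GenotypeState.MISSING],
                    "colony_counts": [int(x) for x in col_counts],
                    "d_hat": est.d_hat,
                    "ci": list(est.ci),
                    "estimator": est.method,
                    "identifiable": est.identifiable,
                    "distribution_test_p": test.p_value,
                    "distribution_test_method": test.method,
                }
            return out

        ado_result = run_stage("ado_validation", _ado)
        (outdir / "ado_validation.json").write_text(
            json.dumps(ado_result, indent=2, sort_keys=True) + "\n"
        )
        artifacts["ado_validation"] = outdir / "ado_validation.json"

    # -- manifest ----------------------------------------------------------------
    manifest = {
        "seed": cfg.seed,
        "resolution": cfg.resolution,
        "stages": report["stages"],
        "n_cells": matrix.n_cells,
        "n_clones": len(partition.clones),
        "n_unassigned": len(partition.unassigned),
        "n_flips": len(flips),
        "clone_entropy": {k: (None if v != v else round(v, 10)) for k, v in entropy.items()},
        "artifacts": {
            name: {"path": str(p.name), "sha256": _sha256(p)} for name, p in sorted(artifacts.items())
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
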