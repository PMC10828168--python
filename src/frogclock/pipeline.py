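"""End-to-end orchestration: simulate -> qc -> clocks -> ewas -> enrichment.

Each stage writes the delimited tables its module defines; a JSON manifest
records versions, seeds, the config echo and per-stage row counts, so a run
is reproducible from its output directory alone.  Identical config + seeds
give byte-identical tables.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clocks import CLOCK_SPECS, clock_spec, cross_validate, fit_clock, write_clock
from .cluster import average_linkage, correlation_dissimilarity, cut_height, to_newick
from .enrichment import TOP_K, enrichment_report
from .ewas import GENOMEWIDE_P, SUGGESTIVE_P, correlation_screen, stouffer_combine, threshold_report
from .io import (
    _shortest_repr,
    assemble_cohort,
    default_registry,
    read_annotation_sets,
    read_beta_matrix,
    read_sample_sheet,
    write_annotation_sets,
    write_beta_matrix,
    write_sample_sheet,
)
from .simulate import SimulationConfig, SpeciesPlan, default_study_plan, generate_cohort

__all__ = ["RunConfig", "StageError", "run_pipeline", "load_run_config"]

class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything a reproducible run needs.

    Either ``simulate`` is set (a SimulationConfig) or the three input paths
    are; thresholds default to the study's fixed values.
    """

    simulate: SimulationConfig | None = None
    beta_path: str | None = None
    sheet_path: str | None = None
    annotation_sets_path: str | None = None
    annotation_background_path: str | None = None
    clocks: tuple = tuple(CLOCK_SPECS)
    seed: int = 1
    genomewide_p: float = GENOMEWIDE_P
    suggestive_p: float = SUGGESTIVE_P
    top_k: int = TOP_K
    cut_height: float = 0.29
    run_qc: bool = True
    run_ewas: bool = True
    run_enrichment: bool = True

    def validate(self) -> None:
        if self.simulate is None:
            for p in (self.beta_path, self.sheet_path):
                if not p:
                    raise ValueError("need either a simulate config or input paths")
                if not Path(p).exists():
                    raise ValueError(f"input path does not exist: {p}")
            if self.run_enrichment and not (
                self.annotation_sets_path and self.annotation_background_path
            ):
                raise ValueError("enrichment stage needs annotation paths")
        for name in self.clocks:
            try:
                clock_spec(name)
            except KeyError as exc:
                raise ValueError(str(exc)) from exc
        if not (0 < self.genomewide_p <= self.suggestive_p < 1):
            raise ValueError("bad significance thresholds")


def load_run_config(path) -> RunConfig:
    """Load a RunConfig from YAML (keys mirror the dataclass fields)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sim = raw.pop("simulate", None)
    if sim is not None:
        plans = tuple(
            SpeciesPlan(
                species=p["species"], age_lo=float(p["age_lo"]),
                age_hi=float(p["age_hi"]), tissues=dict(p["tissues"]),
            )
            for p in sim.pop("plans", [])
        )
        if sim.pop("default_study_plan", False) or not plans:
            cfg = default_study_plan(seed=int(sim.pop("seed", 0)))
            sim = SimulationConfig(**{**asdict_shallow(cfg), **sim, "plans": cfg.plans})
        else:
            sim = SimulationConfig(plans=plans, **sim)
    clocks = raw.pop("clocks", None)
    config = RunConfig(simulate=sim, **raw)
    if clocks is not None:
        config.clocks = tuple(clocks)
    return config


def asdict_shallow(cfg: SimulationConfig) -> dict:
    d = {k: v for k, v in cfg.__dict__.items() if k != "plans"}
    return d


def _write_table(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, sep="\t", index=False, float_format=_shortest_repr)
    return len(df)


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run the configured stages, writing tables and a manifest under
    *out_dir*.  Returns the manifest dict."""
    try:
        config.validate()
    except ValueError as exc:
        raise StageError("config", exc) from exc

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    registry = default_registry()
    manifest: dict = {
        "frogclock_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "stages": {},
        "config": {
            "clocks": list(config.clocks),
            "genomewide_p": config.genomewide_p,
            "suggestive_p": config.suggestive_p,
            "top_k": config.top_k,
            "cut_height": config.cut_height,
            "simulated": config.simulate is not None,
        },
    }

    # -- inputs -----------------------------------------------------------
    truth = None
    try:
        if config.simulate is not None:
            cohort, sets, truth = generate_cohort(config.simulate, registry)
            write_beta_matrix(cohort.beta, out / "beta.tsv")
            write_sample_sheet(cohort.samples, out / "samples.tsv")
            write_annotation_sets(sets, out / "annotation_sets.tsv",
                                  out / "annotation_background.tsv")
            _write_table(truth.cpgs, out / "truth_cpgs.tsv")
            manifest["stages"]["simulate"] = {
                "n_cpgs": cohort.n_cpgs,
                "n_samples": cohort.n_samples,
                "clip_rate": truth.clip_rate,
                "sim_seed": config.simulate.seed,
            }
        else:
            beta = read_beta_matrix(config.beta_path)
            samples = read_sample_sheet(config.sheet_path)
            cohort = assemble_cohort(beta, samples)
            sets = None
            if config.annotation_sets_path:
                sets = read_annotation_sets(
                    config.annotation_sets_path, config.annotation_background_path
                )
            manifest["stages"]["load"] = {
                "n_cpgs": cohort.n_cpgs, "n_samples": cohort.n_samples,
            }
    except StageError:
        raise
    except Exception as exc:
        raise StageError("input", exc) from exc

    # -- qc clustering -----------------------------------------------------
    if config.run_qc:
        try:
            dist = correlation_dissimilarity(cohort)
            dend = average_linkage(dist)
            branches = cut_height(dend, config.cut_height)
            merge_table = pd.DataFrame(
                {
                    "merge": np.arange(len(dend.heights)),
                    "left": dend.merges[:, 0],
                    "right": dend.merges[:, 1],
                    "height": dend.heights,
                }
            )
            _write_table(merge_table, out / "qc_merges.tsv")
            _write_table(
                branches.rename_axis("sample_id").reset_index(),
                out / "qc_branches.tsv",
            )
            (out / "qc_dendrogram.nwk").write_text(to_newick(dend) + "\n")
            manifest["stages"]["qc"] = {
                "n_branches": int(branches.max()),
                "cut_height": config.cut_height,
            }
        except Exception as exc:
            raise StageError("qc", exc) from exc

    # -- clocks ------------------------------------------------------------
    if config.clocks:
        try:
            rows = []
            for name in config.clocks:
                spec = clock_spec(name)
                model = fit_clock(cohort, spec, registry, config.seed)
                write_clock(model, out / f"clock_{name}.tsv")
                cv = cross_validate(cohort, spec, registry, config.seed)
                cv_table = pd.DataFrame(
                    {
                        "sample_id": cv.predictions.index,
                        "fold": cv.folds.to_numpy(),
                        "predicted": cv.predictions.to_numpy(),
                        "observed": cv.observed.to_numpy(),
                    }
                )
                _write_table(cv_table, out / f"cv_{name}.tsv")
                rows.append(
                    {
                        "clock": name,
                        "n": len(cv.predictions),
                        "n_selected_cpgs": model.n_selected,
                        "pearson_r": cv.pearson_r,
                        "median_abs_error": cv.median_abs_error,
                    }
                )
            metrics = pd.DataFrame(rows)
            _write_table(metrics, out / "clock_metrics.tsv")
            manifest["stages"]["clocks"] = {
                "fitted": list(config.clocks),
                "n_clocks": len(config.clocks),
            }
        except Exception as exc:
            raise StageError("clocks", exc) from exc

    # -- ewas --------------------------------------------------------------
    ewas_tables = {}
    if config.run_ewas:
        try:
            frogs = cohort.select_samples(cohort.cohorts == "frog")
            for sp in sorted(set(frogs.species)):
                sub = frogs.select_samples(frogs.species == sp)
                ewas_tables[sp] = correlation_screen(sub)
            if len(ewas_tables) >= 2:
                ewas_tables["meta"] = stouffer_combine(
                    [ewas_tables[sp] for sp in sorted(ewas_tables)]
                )
            merged = None
            for name, table in ewas_tables.items():
                t = table.set_index("cpg_id")
                if "z_meta" not in t.columns:
                    t = t[["n", "r", "z", "p"]].add_suffix(f"_{name}")
                else:
                    t = t[["z_meta", "p_meta"]]
                merged = t if merged is None else merged.join(t, how="outer")
            _write_table(merged.reset_index(), out / "ewas.tsv")
            report = threshold_report(
                ewas_tables.get("meta", next(iter(ewas_tables.values()))),
                config.genomewide_p, config.suggestive_p,
            )
            (out / "ewas_thresholds.json").write_text(
                json.dumps(report, indent=2, sort_keys=True) + "\n"
            )
            manifest["stages"]["ewas"] = {
                "tables": sorted(ewas_tables),
                "n_cpgs": int(len(merged)),
                "n_genomewide": report["genomewide"]["n_total"],
                "n_suggestive": report["suggestive"]["n_total"],
            }
        except Exception as exc:
            raise StageError("ewas", exc) from exc

    # -- enrichment --------------------------------------------------------
    if config.run_enrichment and ewas_tables and sets is not None:
        try:
            table = enrichment_report(ewas_tables, sets, config.top_k)
            _write_table(table, out / "enrichment.tsv")
            manifest["stages"]["enrichment"] = {
                "n_rows": len(table),
                "sources": sorted(ewas_tables),
                "sets": sorted(sets.named_sets),
                "top_k": config.top_k,
            }
        except Exception as exc:
            raise StageError("enrichment", exc) from exc

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
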