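"""End-to-end analysis pipeline.

Stages: load or simulate the trial -> augmented-design adjustment and
ANOVA per trait (traits whose adjusted-genotype F test is not significant
at alpha are dropped, unless configured otherwise) -> genetic-parameter
panel -> CVg-weighted rank-sum selection -> gains for the selected set ->
multivariate characterization of the selected genotypes -> tables,
figures and a machine-readable manifest.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import augmented_design, genetic_parameters, multivariate
from . import selection_index, synthetic_data, traits_io

logger = logging.getLogger(__name__)

STAGES = ("load", "adjust", "genetic_parameters", "selection",
          "multivariate", "report")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    outdir: str | Path = "augbreed_run"
    # input: either a plot-table CSV (+ optional trait config) ...
    trial_path: str | Path | None = None
    trait_config_path: str | Path | None = None
    # ... or a simulation (preset name or SimulationConfig)
    simulate: str | synthetic_data.SimulationConfig | None = "table1"
    seed: int | None = None

    intensity: float = 0.05
    alpha: float = 0.01
    weights: str = "cvg"            # cvg | unit
    tie_policy: str = "average"
    xo_reference: str = "tests"     # tests | checks
    keep_nonsignificant: bool = False
    n_clusters: int = 2
    make_figures: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class PipelineResult:
    """Artifacts of a run; ``manifest`` is also written as JSON."""

    table: traits_io.TrialTable
    panel: pd.DataFrame
    selection: selection_index.SelectionResult
    clusters: pd.Series | None
    manifest: dict
    outdir: Path


def _json_safe(obj):
    if isinstance(obj, dict):
        return {str(k): _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute all stages and write every artifact under ``outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run_log.txt"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s "
                                           "%(levelname)s %(message)s"))
    root = logging.getLogger("augbreed")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    manifest: dict = {
        "package": "augbreed",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config": _json_safe(dataclasses.asdict(config)
                             | {"simulate": str(config.simulate)}),
        "stages": [],
        "summary": {},
    }
    stage_start = time.perf_counter()

    def finish_stage(name: str) -> None:
        nonlocal stage_start
        now = time.perf_counter()
        manifest["stages"].append(
            {"name": name, "status": "completed",
             "seconds": round(now - stage_start, 3)})
        stage_start = now

    try:
        # ---- load -------------------------------------------------------
        truth = None
        if config.trial_path is not None:
            table = traits_io.read_trial(
                config.trial_path, config.trait_config_path)
            sim_config = None
        else:
            sim_config = (config.simulate
                          if isinstance(config.simulate,
                                        synthetic_data.SimulationConfig)
                          else _preset(config.simulate))
            if config.seed is not None:
                sim_config = dataclasses.replace(sim_config, seed=config.seed)
            manifest["seed"] = sim_config.seed
            table, truth = synthetic_data.simulate_trial(sim_config)
            traits_io.write_table(table, outdir / "trial.csv")
            truth.genotype_effects.to_csv(outdir / "truth_genotypes.csv")
            truth.block_effects.to_csv(outdir / "truth_blocks.csv")
        summary = manifest["summary"]
        design = table.design_summary()
        summary["n_blocks"] = design.n_blocks
        summary["n_checks"] = design.n_checks
        summary["n_tests"] = design.n_tests
        finish_stage("load")

        # ---- adjust + ANOVA + significance filter -----------------------
        anova = genetic_parameters.anova_panel(table, alpha=config.alpha)
        anova.to_csv(outdir / "anova.csv", index=False)
        adjusted: dict[str, augmented_design.AdjustedValues] = {}
        kept, dropped = [], []
        for trait in table.trait_names:
            at = augmented_design.anova_augmented(
                table, trait, alpha=config.alpha)
            adjusted[trait] = augmented_design.adjust(table, trait)
            if at.is_significant("genotypes_adj") or config.keep_nonsignificant:
                kept.append(trait)
            else:
                dropped.append(trait)
                logger.info(
                    "trait %s: adjusted-genotype F test not significant at "
                    "alpha=%g (p=%.4g); excluded from index and "
                    "multivariate stages", trait, config.alpha,
                    at.p_value("genotypes_adj"))
        if not kept:
            raise RuntimeError("no trait passed the F-test filter")
        values = pd.DataFrame(
            {t: adjusted[t].adjusted for t in kept})
        pd.DataFrame({t: adjusted[t].adjusted for t in table.trait_names}
                     ).to_csv(outdir / "adjusted_values.csv")
        summary["traits_analyzed"] = kept
        summary["traits_excluded"] = dropped
        finish_stage("adjust")

        # ---- genetic parameters (pre-selection) -------------------------
        params = {t: genetic_parameters.trait_params(
            adjusted[t], xo_reference=config.xo_reference) for t in kept}
        finish_stage("genetic_parameters")

        # ---- selection ---------------------------------------------------
        weights = None
        if config.weights == "cvg":
            weights = selection_index.weights_from_cvg(
                {t: params[t].CVg_pct for t in kept})
        elif config.weights != "unit":
            raise ValueError(f"unknown weights mode {config.weights!r}")
        result = selection_index.run_selection(
            values, table.traits, intensity=config.intensity,
            weights=weights, tie_policy=config.tie_policy)
        selected = set(result.selected_ids)

        panel, params = genetic_parameters.parameter_panel(
            table, selection=selected, traits=kept,
            xo_reference=config.xo_reference)
        panel.to_csv(outdir / "genetic_parameters.csv")

        report = result.table.copy()
        report.insert(0, "population_id", table.tests.drop_duplicates(
            "genotype_id").set_index("genotype_id")["population_id"]
            .reindex(report.index))
        report.to_csv(outdir / "selection.csv")

        summary["n_selected"] = result.n_selected
        summary["intensity"] = config.intensity
        summary["top_genotype"] = result.table["overall_rank"].idxmin()
        summary["h2_pct"] = {t: 100.0 * params[t].h2 for t in kept}
        summary["GS_pct"] = {t: params[t].GS_pct for t in kept}
        summary["CVg_pct"] = {t: params[t].CVg_pct for t in kept}
        finish_stage("selection")

        # ---- multivariate on the selected set ---------------------------
        clusters = None
        sel_values = values.loc[sorted(selected)].dropna()
        if len(sel_values) >= 3:
            z = multivariate.zscore(sel_values)
            z.z.to_csv(outdir / "zscores.csv")
            layout = multivariate.heatmap_layout(z)
            clusters = multivariate.cut_clusters(
                layout.row_tree, min(config.n_clusters, len(sel_values)))
            clusters.to_csv(outdir / "cluster_labels.csv")
            pca_result = multivariate.pca(z)
            pca_result.scores.to_csv(outdir / "pc_scores.csv")
            pca_result.loadings.to_csv(outdir / "pc_loadings.csv")
            pca_result.contributions.to_csv(outdir / "pc_contributions.csv")
            network = multivariate.correlation_network(sel_values)
            network.corr.to_csv(outdir / "correlation_matrix.csv")
            if config.make_figures:
                multivariate.plot_heatmap(z, outdir / "heatmap.png")
                multivariate.plot_biplot(
                    pca_result, outdir / "pca_biplot.png", clusters=clusters)
                multivariate.plot_network(
                    network, outdir / "correlation_network.png")
            summary["pc_explained_pct"] = {
                pc: float(v)
                for pc, v in pca_result.explained_pct.head(2).items()}
            summary["cluster_sizes"] = clusters.value_counts().to_dict()
            off = network.corr.where(
                ~np.eye(len(network.corr), dtype=bool)).stack()
            summary["corr_min"] = float(off.min())
            summary["corr_max"] = float(off.max())
        else:
            logger.warning("fewer than 3 selected genotypes with complete "
                           "data; multivariate stage skipped")
        finish_stage("multivariate")

        # ---- report ------------------------------------------------------
        with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(_json_safe(manifest), fh, indent=2)
        finish_stage("report")
        # rewrite with the final stage recorded
        with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(_json_safe(manifest), fh, indent=2)
    except Exception as exc:
        stage = STAGES[min(len(manifest["stages"]), len(STAGES) - 1)]
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()

    return PipelineResult(table=table, panel=panel, selection=result,
                          clusters=clusters, manifest=manifest,
                          outdir=outdir)


def _preset(name: str | None) -> synthetic_data.SimulationConfig:
    if name in (None, "table1"):
        return synthetic_data.table1_preset()
    raise ValueError(f"unknown simulation preset {name!r}")


def verify(outdir: str | Path, rtol: float = 1e-9) -> dict:
    """Re-run a finished analysis from its manifest and diff the summary.

    Only simulated runs can be verified this way (the archived seed and
    configuration regenerate the inputs).  Returns a dict with
    ``identical`` and any differing summary keys.
    """
    outdir = Path(outdir)
    with open(outdir / "manifest.json", "r", encoding="utf-8") as fh:
        manifest = json.load(fh)
    cfg_raw = dict(manifest["config"])
    cfg_raw["outdir"] = str(outdir / "_verify")
    if cfg_raw.get("trial_path") is None:
        cfg_raw["simulate"] = ("table1" if "table1" in str(
            cfg_raw.get("simulate")) else cfg_raw.get("simulate"))
        cfg_raw["seed"] = manifest["seed"]
    config = RunConfig(**cfg_raw)
    rerun = run_pipeline(config)

    diffs = {}
    for key, old in manifest["summary"].items():
        new = _json_safe(rerun.manifest["summary"].get(key))
        if not _close(old, new, rtol):
            diffs[key] = {"archived": old, "recomputed": new}
    return {"identical": not diffs, "differences": diffs}


def _close(a, b, rtol: float) -> bool:
    if isinstance(a, dict) and isinstance(b, dict):
        return a.keys() == b.keys() and all(
            _close(a[k], b[k], rtol) for k in a)
    if isinstance(a, (int, float)) and isinstance(b, (int, float)):
        return bool(np.isclose(a, b, rtol=rtol, equal_nan=True))
    return a == b
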