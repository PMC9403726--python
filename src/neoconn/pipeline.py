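"""Config-driven orchestration of the full analysis.

Stages, in order: load or simulate a cohort -> age-adjust behavioural
outcomes -> cost-corrected graph metrics per subject -> group-level
core-periphery partition and edge typing -> covariate-adjusted partial
Spearman associations (global and nodal features, BH-FDR within explicit
families) -> network-based statistics with the primary-threshold
sensitivity sweep.  Every stage writes its tables under the output
directory; a failure in one outcome's analysis is recorded and does not
abort the others.  A single master seed deterministically derives
per-stage seeds, so a rerun with the same config reproduces every numeric
output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import (
    Connectome,
    ValidationError,
    read_cohort,
    read_connectome,
    read_node_table,
    write_connectome,
    write_node_table,
)
from .behavior import age_adjust, fdr_adjust, partial_spearman
from .coreperiphery import (
    classification_table,
    consensus_partition,
    core_periphery_partition,
)
from .io import edge_list
from .metrics import (
    cost_corrected_features,
    density,
    features_long_table,
)
from .nbs import (
    DesignSpec,
    component_table,
    default_sweep_thresholds,
    edge_t_table,
    nbs_test,
)
from .simulate import SimulationConfig, derive_seeds, simulate_cohort

logger = logging.getLogger("neoconn")

__all__ = ["PipelineConfig", "RunReport", "validate_config", "run_pipeline"]

_TOP_KEYS = {
    "seed", "out_dir", "simulation", "inputs", "density_grid",
    "core_periphery", "outcomes", "covariates", "graph_covariates_extra",
    "nbs", "verbosity",
}
_NBS_KEYS = {
    "t_threshold", "n_permutations", "alpha", "direction", "sweep",
    "edge_presence_fraction",
}
_CP_KEYS = {"n_restarts", "mode"}
_GRID_KEYS = {"start", "stop", "step"}
_INPUT_KEYS = {"connectome_dir", "cohort", "node_table"}


@dataclass
class PipelineConfig:
    seed: int
    out_dir: str
    simulation: SimulationConfig | None = None
    inputs: dict | None = None
    density_grid: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(5, 51) / 100.0, 2)
    )
    core_periphery: dict = field(
        default_factory=lambda: {"n_restarts": 100, "mode": "group_mean"}
    )
    outcomes: tuple = ("internalizing_raw", "externalizing_raw")
    covariates: tuple = (
        "ga_birth", "sex", "injury_rating", "cognitive_composite", "imd",
    )
    graph_covariates_extra: tuple = ("pma_scan",)
    nbs: dict = field(
        default_factory=lambda: {
            "t_threshold": 3.1,
            "n_permutations": 10_000,
            "alpha": 0.025,
            "direction": "negative",
            "sweep": True,
            "edge_presence_fraction": 0.9,
        }
    )
    verbosity: str = "info"


def _reject_unknown(d: dict, allowed: set, where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValidationError(f"unknown key(s) in {where}: {sorted(unknown)}")


def validate_config(path: str) -> PipelineConfig:
    """Parse and validate a YAML pipeline config, filling all defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    if not isinstance(raw, dict):
        raise ValidationError("config root must be a mapping")
    _reject_unknown(raw, _TOP_KEYS, "config")
    if "seed" not in raw:
        raise ValidationError("config field 'seed' is mandatory")
    has_sim = "simulation" in raw and raw["simulation"] is not None
    has_inp = "inputs" in raw and raw["inputs"] is not None
    if has_sim == has_inp:
        raise ValidationError(
            "config must name exactly one of 'simulation' or 'inputs'"
        )
    cfg = PipelineConfig(seed=int(raw["seed"]), out_dir=str(raw.get("out_dir", "out")))
    if has_sim:
        sim = dict(raw["simulation"])
        sim_fields = {f.name for f in dataclasses.fields(SimulationConfig)}
        _reject_unknown(sim, sim_fields, "config.simulation")
        if "effect_edges" in sim:
            sim["effect_edges"] = tuple(tuple(e) for e in sim["effect_edges"])
        sim.setdefault("seed", int(raw["seed"]))
        try:
            cfg.simulation = SimulationConfig(**sim)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"config.simulation: {exc}") from exc
    else:
        inp = dict(raw["inputs"])
        _reject_unknown(inp, _INPUT_KEYS, "config.inputs")
        missing = _INPUT_KEYS - set(inp)
        if missing:
            raise ValidationError(f"config.inputs missing: {sorted(missing)}")
        cfg.inputs = inp
    if "density_grid" in raw:
        g = dict(raw["density_grid"])
        _reject_unknown(g, _GRID_KEYS, "config.density_grid")
        start, stop, step = g.get("start", 0.05), g.get("stop", 0.50), g.get("step", 0.01)
        if not (0 < start <= stop <= 1 and step > 0):
            raise ValidationError("config.density_grid bounds invalid")
        n = int(round((stop - start) / step)) + 1
        cfg.density_grid = np.round(start + step * np.arange(n), 10)
    if "core_periphery" in raw:
        cp = dict(raw["core_periphery"])
        _reject_unknown(cp, _CP_KEYS, "config.core_periphery")
        if cp.get("mode", "group_mean") not in ("group_mean", "consensus"):
            raise ValidationError("core_periphery.mode must be group_mean|consensus")
        cfg.core_periphery.update(cp)
    if "outcomes" in raw:
        cfg.outcomes = tuple(raw["outcomes"])
    if "covariates" in raw:
        cfg.covariates = tuple(raw["covariates"])
    if "graph_covariates_extra" in raw:
        cfg.graph_covariates_extra = tuple(raw["graph_covariates_extra"])
    if "nbs" in raw:
        nb = dict(raw["nbs"])
        _reject_unknown(nb, _NBS_KEYS, "config.nbs")
        cfg.nbs.update(nb)
    if not 0 < cfg.nbs["alpha"] < 1:
        raise ValidationError("nbs.alpha must be in (0, 1)")
    if not 0 <= cfg.nbs["edge_presence_fraction"] <= 1:
        raise ValidationError("nbs.edge_presence_fraction must be in [0, 1]")
    cfg.verbosity = str(raw.get("verbosity", "info"))
    return cfg


@dataclass
class RunReport:
    config: dict
    version: str
    stages: dict = field(default_factory=dict)
    tables: dict = field(default_factory=dict)
    errors: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.errors

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "version": self.version,
                    "config": self.config,
                    "stages": self.stages,
                    "tables": self.tables,
                    "errors": self.errors,
                },
                fh,
                indent=2,
                sort_keys=True,
                default=str,
            )
            fh.write("\n")


def _config_echo(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["density_grid"] = [float(x) for x in cfg.density_grid]
    return d


def _encode_numeric(col: pd.Series) -> np.ndarray:
    if col.dtype == object:
        levels = sorted(col.dropna().unique())
        return col.map({lev: i for i, lev in enumerate(levels)}).to_numpy(float)
    return col.to_numpy(float)


def _write_csv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, index=False, float_format="%.12g")


def load_inputs(cfg: PipelineConfig):
    """Materialize (connectomes, cohort, node_table) from files or simulation."""
    if cfg.simulation is not None:
        sc = simulate_cohort(cfg.simulation)
        return sc.connectomes, sc.cohort, sc.node_table, sc.truth
    node_table = read_node_table(cfg.inputs["node_table"])
    cohort = read_cohort(cfg.inputs["cohort"])
    cdir = cfg.inputs["connectome_dir"]
    connectomes = []
    for sid in cohort["subject_id"]:
        for ext in (".csv", ".tsv"):
            p = os.path.join(cdir, f"{sid}{ext}")
            if os.path.exists(p):
                connectomes.append(read_connectome(p, node_table, subject_id=sid))
                break
        else:
            raise ValidationError(f"no connectome file for subject {sid!r} in {cdir}")
    return connectomes, cohort, node_table, None


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Execute all stages, writing every table under ``cfg.out_dir``."""
    os.makedirs(cfg.out_dir, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.verbosity.upper(), logging.INFO))
    report = RunReport(config=_config_echo(cfg), version=__version__)
    stage_seeds = derive_seeds(cfg.seed, 4)

    def out(name: str) -> str:
        return os.path.join(cfg.out_dir, name)

    def register(key: str, name: str) -> None:
        report.tables[key] = name

    def stage(name):
        t0 = time.perf_counter()
        logger.info("stage %s: start", name)
        return t0

    def done(name, t0, **summary):
        logger.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
        report.stages[name] = summary

    # ---- stage 1: load or simulate -------------------------------------
    t0 = stage("load")
    connectomes, cohort, node_table, truth = load_inputs(cfg)
    if cfg.simulation is not None:
        sim_dir = out("simulated")
        os.makedirs(sim_dir, exist_ok=True)
        for c in connectomes:
            write_connectome(c, os.path.join(sim_dir, f"{c.subject_id}.csv"))
        _write_csv(cohort, os.path.join(sim_dir, "cohort.csv"))
        write_node_table(node_table, os.path.join(sim_dir, "node_table.csv"))
        truth_df = pd.DataFrame(
            truth["effect_edges"], columns=["node_a", "node_b"]
        )
        truth_df["effect_beta"] = truth["effect_beta"]
        truth_df["effect_outcome"] = truth["effect_outcome"]
        _write_csv(truth_df, os.path.join(sim_dir, "truth.csv"))
        register("simulated", "simulated")
    done("load", t0, n_subjects=len(connectomes), n_nodes=connectomes[0].n_nodes)

    # ---- stage 2: age-adjusted outcomes --------------------------------
    t0 = stage("age_adjust")
    adjusted_cols = []
    for outcome in cfg.outcomes:
        adj = age_adjust(cohort[outcome], cohort["corrected_age_followup"])
        col = f"{outcome}_adj"
        cohort[col] = np.nan
        cohort.loc[adj.index, col] = adj["age_adjusted"]
        adjusted_cols.append(col)
    _write_csv(
        cohort[["subject_id", "corrected_age_followup", *cfg.outcomes, *adjusted_cols]],
        out("adjusted_scores.csv"),
    )
    register("adjusted_scores", "adjusted_scores.csv")
    done("age_adjust", t0, outcomes=list(cfg.outcomes))

    # ---- stage 3: graph metrics ----------------------------------------
    t0 = stage("metrics")
    long_tables = []
    global_rows = []
    for c in connectomes:
        cc = cost_corrected_features(c, cfg.density_grid)
        long_tables.append(features_long_table(cc))
        agg = cc.cost_corrected
        global_rows.append(
            (
                c.subject_id,
                density(c),
                agg["mean_strength"],
                agg["global_efficiency"],
                agg["local_efficiency"],
            )
        )
    features = pd.concat(long_tables, ignore_index=True)
    _write_csv(features, out("features.csv"))
    globals_df = pd.DataFrame(
        global_rows,
        columns=[
            "subject_id", "density", "cc_mean_strength",
            "cc_global_efficiency", "cc_local_efficiency",
        ],
    )
    _write_csv(globals_df, out("global_features.csv"))
    register("features", "features.csv")
    register("global_features", "global_features.csv")
    done("metrics", t0, n_rows=len(features))

    # ---- stage 4: core-periphery ---------------------------------------
    t0 = stage("core_periphery")
    cp_seed = int(stage_seeds[0])
    n_restarts = int(cfg.core_periphery["n_restarts"])
    if cfg.core_periphery["mode"] == "consensus":
        part = consensus_partition(connectomes, seed=cp_seed, n_restarts=n_restarts)
    else:
        mean_w = np.mean([c.weights for c in connectomes], axis=0)
        mean_conn = Connectome("group_mean", mean_w, connectomes[0].node_ids)
        part = core_periphery_partition(mean_conn, seed=cp_seed, n_restarts=n_restarts)
        write_connectome(mean_conn, out("group_mean_connectome.csv"))
    labelled = part.to_node_table(node_table)
    write_node_table(labelled, out("node_partition.csv"))
    mean_w = np.mean([c.weights for c in connectomes], axis=0)
    mean_conn = Connectome("group_mean", mean_w, connectomes[0].node_ids)
    cls = classification_table(edge_list(mean_conn), part.labels)
    _write_csv(cls, out("edge_classification.csv"))
    register("node_partition", "node_partition.csv")
    register("edge_classification", "edge_classification.csv")
    done(
        "core_periphery", t0,
        n_core=part.n_core, n_periphery=part.n_periphery,
        quality=part.quality,
        edge_type_counts=cls["type"].value_counts().to_dict(),
    )

    # ---- stage 5: associations -----------------------------------------
    t0 = stage("associations")
    assoc_rows = []
    cov_base = [
        _encode_numeric(cohort[c]) for c in cfg.covariates
    ]
    cov_graph = cov_base + [
        _encode_numeric(cohort[c]) for c in cfg.graph_covariates_extra
    ]
    nodal = features[features["node_id"] != "global"]
    for outcome, col in zip(cfg.outcomes, adjusted_cols):
        y = cohort[col].to_numpy(float)
        try:
            for feat_col in (
                "density", "cc_mean_strength", "cc_global_efficiency",
                "cc_local_efficiency",
            ):
                try:
                    r = partial_spearman(
                        globals_df[feat_col].to_numpy(), y, cov_graph,
                        x_name=feat_col, y_name=col,
                    )
                except ValueError:
                    continue  # e.g. zero-variance feature (constant density)
                assoc_rows.append(
                    (outcome, "global", feat_col, "global",
                     r.partial_rho, r.p_value, r.n_used)
                )
            wide = {
                feat: nodal[nodal["feature"] == feat]
                .pivot(index="subject_id", columns="node_id", values="value")
                .loc[cohort["subject_id"]]
                for feat in ("nodal_degree", "nodal_strength", "nodal_efficiency")
            }
            for feat, table in wide.items():
                for node in table.columns:
                    try:
                        r = partial_spearman(
                            table[node].to_numpy(), y, cov_graph,
                            x_name=feat, y_name=col,
                        )
                    except ValueError:
                        continue  # e.g. zero-variance node at low density
                    assoc_rows.append(
                        (outcome, "nodal", feat, node,
                         r.partial_rho, r.p_value, r.n_used)
                    )
        except Exception as exc:  # noqa: BLE001 - stage errors are collected
            report.errors[f"associations:{outcome}"] = str(exc)
    assoc = pd.DataFrame(
        assoc_rows,
        columns=["outcome", "family", "feature", "node_id", "partial_rho", "p", "n"],
    )
    if len(assoc):
        # FDR families: global features pooled per outcome; nodal features
        # pooled across all nodes x metrics per outcome
        fam = assoc["outcome"] + ":" + assoc["family"]
        assoc["p_fdr"] = fdr_adjust(assoc["p"].to_numpy(), family=fam.to_numpy())
    _write_csv(assoc, out("associations.csv"))
    register("associations", "associations.csv")
    done("associations", t0, n_tests=len(assoc))

    # ---- stage 6: network-based statistics -----------------------------
    t0 = stage("nbs")
    nbs_summaries = {}
    for k, (outcome, col) in enumerate(zip(cfg.outcomes, adjusted_cols)):
        try:
            design = DesignSpec(
                predictor=col,
                covariates=tuple(cfg.covariates) + tuple(cfg.graph_covariates_extra),
                direction=cfg.nbs["direction"],
                t_threshold=float(cfg.nbs["t_threshold"]),
                n_permutations=int(cfg.nbs["n_permutations"]),
                alpha=float(cfg.nbs["alpha"]),
                seed=int(stage_seeds[1]) + k,
                edge_presence_fraction=float(cfg.nbs["edge_presence_fraction"]),
            )
            if cfg.nbs["sweep"]:
                sweep = nbs_test(
                    cohort, connectomes, design,
                    thresholds=default_sweep_thresholds(),
                )
                summary = sweep.summary()
                _write_csv(summary, out(f"nbs_sweep_{outcome}.csv"))
                register(f"nbs_sweep_{outcome}", f"nbs_sweep_{outcome}.csv")
                primary_idx = int(
                    np.argmin(np.abs(sweep.thresholds - design.t_threshold))
                )
                result = sweep.results[primary_idx]
            else:
                result = nbs_test(cohort, connectomes, design)
            _write_csv(edge_t_table(result.glm), out(f"nbs_edge_t_{outcome}.csv"))
            _write_csv(component_table(result), out(f"nbs_components_{outcome}.csv"))
            register(f"nbs_edge_t_{outcome}", f"nbs_edge_t_{outcome}.csv")
            register(f"nbs_components_{outcome}", f"nbs_components_{outcome}.csv")
            sig = result.significant
            nbs_summaries[outcome] = {
                "threshold": result.threshold,
                "n_components": len(result.components),
                "n_significant": len(sig),
                "max_extent": result.components[0].extent if result.components else 0,
                "min_p_fwe": min(
                    (c.p_fwe for c in result.components), default=None
                ),
            }
        except Exception as exc:  # noqa: BLE001
            report.errors[f"nbs:{outcome}"] = str(exc)
    done("nbs", t0, **nbs_summaries)

    report.write(out("report.json"))
    return report
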