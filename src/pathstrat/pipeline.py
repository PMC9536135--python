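"""End-to-end orchestration: simulate -> enrich -> signatures -> cluster ->
survival -> single-cell -> modules -> annotate, from one YAML/dict config,
with provenance capture.

Every stage writes plain TSV/GMT/JSON outputs into the run directory so each
stage is independently re-runnable and diffable.  A global seed is set in the
config; each stage derives a deterministic sub-seed from the stage name, so
stages can be reordered or disabled without seed collisions.  The manifest
records the config snapshot, per-stage seeds, package version, SHA-256
digests of every stage output, and timestamps; re-running the same config
reproduces byte-identical stage outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._version import __version__
from .io import ExpressionMatrix, GeneSetCollection, SurvivalTable, write_gmt, write_matrix
from .simulate import SimulationConfig, simulate_bulk, simulate_single_cell
from .enrichment import normalize_es
from .signatures import pca_decompose, synthesize_signature, score_signature_matrix
from .clustering import consensus_cluster, nmf_cluster, rf_robustness
from .survival import km_curve, pairwise_logrank_adjusted
from .single_cell import cell_scores, correlation_map
from .coexpression import detect_modules, module_cluster_association, hub_genes
from .annotation import differential_expression, ora

logger = logging.getLogger("pathstrat")

STAGES = (
    "simulate",
    "enrich",
    "signatures",
    "cluster",
    "survival",
    "single_cell",
    "modules",
    "annotate",
)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "pathstrat_run",
    "stages": list(STAGES),
    "simulate": {},           # SimulationConfig overrides
    "enrich": {"n_perm": 500, "weight": 1.0},
    "signatures": {"dataset_code": "S", "top_n": 20, "min_overlap": 5, "n_components": 2},
    "cluster": {"k_range": [2, 3, 4, 5], "n_resamples": 100, "subsample": 0.8},
    "single_cell": {"n_cells": 400, "effect": 2.0, "noise_sd": 1.0, "dropout": 0.3},
    "modules": {"n_de_genes": 300, "min_module_size": 10, "power": 6},
    "annotate": {"de_p_adj": 0.05},
}


@dataclass
class RunManifest:
    config: dict
    seeds: dict[str, int]
    version: str
    digests: dict[str, dict[str, str]] = field(default_factory=dict)
    timestamps: dict[str, str] = field(default_factory=dict)
    stages_run: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True, default=str)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed derived from the stage name."""
    return (int(global_seed) * 2654435761 + zlib.crc32(stage.encode())) % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _merge(base: dict, override: dict | None) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(config: str | Path | dict | None) -> dict:
    if config is None:
        cfg = {}
    elif isinstance(config, dict):
        cfg = config
    else:
        with open(config) as fh:
            cfg = yaml.safe_load(fh) or {}
    merged = _merge(DEFAULT_CONFIG, cfg)
    unknown = set(merged["stages"]) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s) in config: {sorted(unknown)}")
    if not isinstance(merged["seed"], int):
        raise ValueError("config 'seed' must be an integer")
    return merged


def run_pipeline(config: str | Path | dict | None = None) -> RunManifest:
    """Run the enabled stages in dependency order and write a manifest.

    Any stage failure halts the run with the stage name and cause; the
    manifest is written last, to ``<outdir>/manifest.json``.
    """
    cfg = load_config(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    enabled = [s for s in STAGES if s in cfg["stages"]]
    seeds = {s: stage_seed(cfg["seed"], s) for s in enabled}
    manifest = RunManifest(config=cfg, seeds=seeds, version=__version__)

    state: dict = {}
    for stage in enabled:
        logger.info("stage %s starting", stage)
        manifest.timestamps[stage] = datetime.now(timezone.utc).isoformat()
        try:
            outputs = _STAGE_FUNCS[stage](cfg, seeds[stage], outdir, state)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest.digests[stage] = {p.name: _sha256(p) for p in outputs}
        manifest.stages_run.append(stage)
    (outdir / "manifest.json").write_text(manifest.to_json() + "\n")
    return manifest


# ---------------------------------------------------------------------------
# stage implementations (cfg, seed, outdir, shared state) -> list of outputs
# ---------------------------------------------------------------------------

def _stage_simulate(cfg, seed, outdir, state):
    sim_cfg = SimulationConfig(**{**cfg["simulate"], "seed": seed})
    matrix, clinical, collection, truth = simulate_bulk(sim_cfg)
    state.update(matrix=matrix, clinical=clinical, collection=collection, truth=truth)
    paths = [outdir / "expression.tsv", outdir / "clinical.tsv", outdir / "genesets.gmt",
             outdir / "truth.json"]
    write_matrix(matrix, paths[0])
    write_matrix(clinical, paths[1])
    write_gmt(collection, paths[2])
    paths[3].write_text(json.dumps(
        {
            "labels": truth.labels,
            "program_genes": truth.program_genes,
            "hazards": truth.survival_params,
            "directions": truth.directions,
        }, indent=2, sort_keys=True) + "\n")
    return paths


def _stage_enrich(cfg, seed, outdir, state):
    profile = normalize_es(
        state["matrix"], state["collection"],
        n_perm=cfg["enrich"]["n_perm"], seed=seed, weight=cfg["enrich"]["weight"],
    )
    state["profile"] = profile
    paths = [outdir / "profile_nes.tsv", outdir / "profile_meta.json"]
    profile.nes.to_csv(paths[0], sep="\t", float_format="%.10g")
    paths[1].write_text(json.dumps(
        {"n_perm": profile.n_perm, "seed": profile.seed, "weight": profile.weight},
        indent=2, sort_keys=True) + "\n")
    return paths


def _stage_signatures(cfg, seed, outdir, state):
    sc = cfg["signatures"]
    pca = pca_decompose(state["profile"], n_components=sc["n_components"])
    sigs = []
    for comp in range(1, sc["n_components"] + 1):
        for direction in ("positive", "negative"):
            try:
                sigs.append(
                    synthesize_signature(
                        pca, state["collection"], comp, direction,
                        dataset_code=sc["dataset_code"],
                        top_n=sc["top_n"], min_overlap=sc["min_overlap"],
                    )
                )
            except ValueError as exc:
                logger.warning("signature PC%d %s skipped: %s", comp, direction, exc)
    if not sigs:
        raise ValueError("no signature could be synthesized")
    state["pca"] = pca
    state["signatures"] = sigs
    sig_collection = GeneSetCollection(sets=[s.as_gene_set() for s in sigs], label="signatures")
    paths = [outdir / "signatures.gmt", outdir / "contributions.tsv", outdir / "signature_nes.tsv"]
    write_gmt(sig_collection, paths[0])
    pca.contributions.to_csv(paths[1], sep="\t", float_format="%.10g")
    sig_profile = score_signature_matrix(
        state["matrix"], sigs, n_perm=cfg["enrich"]["n_perm"], seed=seed,
        weight=cfg["enrich"]["weight"],
    )
    state["signature_profile"] = sig_profile
    sig_profile.nes.to_csv(paths[2], sep="\t", float_format="%.10g")
    return paths


def _stage_cluster(cfg, seed, outdir, state):
    cc = cfg["cluster"]
    result = consensus_cluster(
        state["profile"], k_range=tuple(cc["k_range"]),
        n_resamples=cc["n_resamples"], subsample=cc["subsample"], seed=seed,
    )
    nmf_labels = nmf_cluster(state["profile"], k=result.chosen_k, seed=seed)
    robustness = rf_robustness(state["profile"], result.labels, seed=seed)
    state["consensus"] = result
    paths = [outdir / "labels.tsv", outdir / "pac.tsv", outdir / "robustness.json"]
    pd.DataFrame({"consensus": result.labels, "nmf": nmf_labels}).rename_axis("sample").to_csv(
        paths[0], sep="\t")
    pd.Series(result.pac, name="pac").rename_axis("k").to_csv(paths[1], sep="\t")
    paths[2].write_text(json.dumps(
        {
            "chosen_k": result.chosen_k,
            "oob_accuracy": robustness.oob_accuracy,
            "per_cluster_accuracy": robustness.per_cluster_accuracy,
        }, indent=2, sort_keys=True) + "\n")
    return paths


def _stage_survival(cfg, seed, outdir, state):
    clinical: SurvivalTable = state["clinical"]
    labels = state["consensus"].labels
    table = SurvivalTable(
        data=clinical.data.assign(group=labels.loc[clinical.data["sample"]].to_numpy()),
        time_unit=clinical.time_unit,
    )
    pairwise = pairwise_logrank_adjusted(table)
    medians = {
        str(g): km_curve(table, g).median for g in sorted(pd.unique(table.data["group"]))
    }
    paths = [outdir / "survdiff.tsv", outdir / "medians.json"]
    pairwise.to_csv(paths[0], sep="\t", index=False, float_format="%.10g")
    paths[1].write_text(json.dumps(medians, indent=2, sort_keys=True) + "\n")
    return paths


def _stage_single_cell(cfg, seed, outdir, state):
    sc = cfg["single_cell"]
    truth = state["truth"]
    states = [
        (f"STATE_C{c + 1}", truth.planted_sets[c][0], sc["effect"])
        for c in sorted(truth.program_genes)
    ]
    cells, sc_truth = simulate_single_cell(
        n_cells=sc["n_cells"], states=states, noise_sd=sc["noise_sd"],
        dropout=sc["dropout"], seed=seed,
    )
    sets = [s.as_gene_set() for s in state["signatures"]]
    sets += [gs for _, gs, _ in states]
    scores = cell_scores(cells, sets)
    cmap = correlation_map(scores)
    state["cell_scores"] = scores
    state["sc_truth"] = sc_truth
    paths = [outdir / "cell_scores.tsv", outdir / "corr_r.tsv", outdir / "corr_p_raw.tsv",
             outdir / "corr_p_adj.tsv", outdir / "corr_groups.tsv"]
    scores.scores.rename_axis("cell").to_csv(paths[0], sep="\t", float_format="%.10g")
    cmap.r.to_csv(paths[1], sep="\t", float_format="%.10g")
    cmap.p_raw.to_csv(paths[2], sep="\t", float_format="%.10g")
    cmap.p_adj.to_csv(paths[3], sep="\t", float_format="%.10g")
    cmap.clusters.rename("group").rename_axis("signature").to_csv(paths[4], sep="\t")
    return paths


def _stage_modules(cfg, seed, outdir, state):
    mc = cfg["modules"]
    labels = state["consensus"].labels
    de = differential_expression(state["matrix"], labels, cluster=labels.iloc[0])
    top = de.sort_values("p").head(mc["n_de_genes"]).index
    sub = ExpressionMatrix(values=state["matrix"].values.loc[top])
    modules = detect_modules(sub, power=mc["power"], min_module_size=mc["min_module_size"])
    if not modules.module_ids():
        raise ValueError("no coexpression module passed the size threshold")
    assoc = module_cluster_association(modules, labels)
    hubs = hub_genes(modules)
    state["modules"] = modules
    paths = [outdir / "module_assignments.tsv", outdir / "module_eigengenes.tsv",
             outdir / "module_cluster.tsv", outdir / "hub_genes.tsv"]
    modules.assignments.rename("module").rename_axis("gene").to_csv(paths[0], sep="\t")
    modules.eigengenes.rename_axis("sample").to_csv(paths[1], sep="\t", float_format="%.10g")
    assoc.to_csv(paths[2], sep="\t", float_format="%.10g")
    rows = [
        {"module": mod, "gene": g, "kme": v}
        for mod, series in hubs.hubs.items() for g, v in series.items()
    ]
    pd.DataFrame(rows, columns=["module", "gene", "kme"]).to_csv(
        paths[3], sep="\t", index=False, float_format="%.10g")
    return paths


def _stage_annotate(cfg, seed, outdir, state):
    labels = state["consensus"].labels
    matrix = state["matrix"]
    universe = matrix.genes
    paths = []
    for cluster in sorted(pd.unique(labels)):
        de = differential_expression(matrix, labels, cluster=cluster)
        up = de[(de["p_adj"] < cfg["annotate"]["de_p_adj"]) & (de["log_fc"] > 0)].index
        enr = ora(list(up), state["collection"], universe)
        p_de = outdir / f"de_cluster{cluster}.tsv"
        p_ora = outdir / f"ora_cluster{cluster}.tsv"
        de.rename_axis("gene").to_csv(p_de, sep="\t", float_format="%.10g")
        enr.to_csv(p_ora, sep="\t", float_format="%.10g")
        paths += [p_de, p_ora]
    return paths


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "enrich": _stage_enrich,
    "signatures": _stage_signatures,
    "cluster": _stage_cluster,
    "survival": _stage_survival,
    "single_cell": _stage_single_cell,
    "modules": _stage_modules,
    "annotate": _stage_annotate,
}
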