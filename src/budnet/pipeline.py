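"""End-to-end orchestration: simulate -> env -> deg -> bias -> modules -> graph -> grn.

A single :class:`PipelineConfig` (loadable from YAML) drives every stage
with one global seed; per-stage sub-seeds are derived from it through
``numpy.random.SeedSequence.spawn`` so each stage is independently
reproducible. Every output file is listed in a manifest JSON with a
SHA-256 content hash; identical config + seed yields identical hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    coexpression_graph,
    coexpression_modules,
    expression_prep,
    grn_inference,
    organ_bias,
    synthetic_data,
)
from .containers import ExpressionMatrix

log = logging.getLogger("budnet")

STAGES = ("simulate", "env", "deg", "bias", "modules", "graph", "grn")


@dataclass
class PipelineConfig:
    """Resolved pipeline configuration; unknown keys are rejected on load."""

    outdir: str = "budnet_out"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    # input paths; when absent, the simulate stage provides the data
    counts_path: str | None = None
    sample_meta_path: str | None = None
    traits_path: str | None = None
    annotation_path: str | None = None
    # stage parameters
    simulate: dict = field(default_factory=dict)
    deg: dict = field(default_factory=lambda: {"fc_min": 1.4, "fdr_max": 0.05})
    network_filter: dict = field(default_factory=lambda: {"fc_min": 1.5, "fdr_max": 0.01})
    modules: dict = field(
        default_factory=lambda: {"cut_height": 0.99, "min_module_size": 30, "merge_height": 0.25}
    )
    graph: dict = field(default_factory=lambda: {"k": 5, "r_min": 0.75})
    grn: dict = field(default_factory=lambda: {"ntrees": 500})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(payload)

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in payload:
            payload = dict(payload)
            payload["stages"] = tuple(payload["stages"])
            bad = set(payload["stages"]) - set(STAGES)
            if bad:
                raise ValueError(f"unknown stages: {sorted(bad)}")
        return cls(**payload)

    def resolved(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def validate_inputs(
    counts_path: str | Path | None = None,
    sample_meta_path: str | Path | None = None,
    traits_path: str | Path | None = None,
) -> dict:
    """Structural checks on input files; returns a report, never raises."""
    failures: list[str] = []
    counts = meta = None
    if counts_path is not None:
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        if counts.index.duplicated().any():
            failures.append("duplicated gene ids in the counts matrix")
        if (counts.to_numpy() < 0).any():
            failures.append("negative counts")
    if sample_meta_path is not None:
        meta = pd.read_csv(sample_meta_path, sep="\t", index_col=0)
        if counts is not None and set(counts.columns) != set(meta.index):
            failures.append("counts samples and metadata samples are misaligned")
        for col in ("organ", "timepoint"):
            if col not in meta.columns:
                failures.append(f"metadata lacks column {col!r}")
    if traits_path is not None and meta is not None:
        traits = pd.read_csv(traits_path, sep="\t")
        if "sample_id" in traits.columns and not set(meta.index) <= set(traits["sample_id"]):
            failures.append("trait table does not cover every sample")
    return {"ok": not failures, "failures": failures}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in order; returns the manifest dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).spawn(len(STAGES))
    stage_seed = {s: int(seeds[i].generate_state(1)[0] % (2**31 - 1)) for i, s in enumerate(STAGES)}

    outputs: dict[str, Path] = {}
    state: dict = {}
    current = None
    try:
        for stage in STAGES:
            if stage not in config.stages:
                continue
            current = stage
            log.info("stage %s", stage)
            _STAGE_FUNCS[stage](config, stage_seed[stage], outdir, outputs, state)
    except Exception as exc:  # noqa: BLE001 - named-stage abort contract
        for p in outputs.values():
            marker = p.with_suffix(p.suffix + ".partial")
            marker.write_text("")
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    (outdir / "config_resolved.yaml").write_text(yaml.safe_dump(config.resolved()))
    outputs["config_resolved"] = outdir / "config_resolved.yaml"
    manifest = {
        "seed": config.seed,
        "stages": list(config.stages),
        "outputs": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in sorted(outputs.items())},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


# ------------------------------------------------------------------ stages
def _stage_simulate(config, seed, outdir, outputs, state):
    if config.counts_path is not None:
        matrix = ExpressionMatrix.from_tsv(
            config.counts_path, layer="counts", meta_path=config.sample_meta_path
        )
        state["matrix_counts"] = matrix
        state["truth"] = None
        return
    sim_kwargs = dict(config.simulate)
    sim_kwargs.setdefault("seed", seed)
    sim_cfg = synthetic_data.SimulationConfig(**sim_kwargs)
    matrix, truth = synthetic_data.simulate_expression(sim_cfg)
    state["matrix_counts"], state["truth"] = matrix, truth
    matrix.to_tsv(outdir / "counts.tsv")
    matrix.sample_meta.to_csv(outdir / "sample_meta.tsv", sep="\t")
    truth.to_json(outdir / "ground_truth.json")
    outputs["counts"] = outdir / "counts.tsv"
    outputs["sample_meta"] = outdir / "sample_meta.tsv"
    outputs["ground_truth"] = outdir / "ground_truth.json"


def _stage_env(config, seed, outdir, outputs, state):
    matrix = state["matrix_counts"]
    if config.traits_path is not None:
        traits = pd.read_csv(config.traits_path, sep="\t")
    else:
        truth = state.get("truth")
        if truth is not None and truth.trait_curves is not None:
            curves = truth.trait_curves
        else:
            curves = synthetic_data.simulate_traits()
        meta = matrix.sample_meta.reset_index()
        traits = meta.merge(curves, on="timepoint")[["sample_id", "CHILLING", "LOD"]]
    state["traits"] = traits
    traits.to_csv(outdir / "traits_per_sample.tsv", sep="\t", index=False)
    outputs["traits"] = outdir / "traits_per_sample.tsv"


def _stage_deg(config, seed, outdir, outputs, state):
    matrix = state["matrix_counts"]
    factors = expression_prep.tmm_factors(matrix.values)
    logm = expression_prep.normalize_log_cpm(matrix, factors)
    n_batches = (
        matrix.sample_meta["batch"].nunique() if "batch" in matrix.sample_meta else 1
    )
    corrected = expression_prep.correct_batch(logm) if n_batches > 1 else logm
    state["matrix_log"] = corrected

    meta = matrix.sample_meta
    records = []
    deg_sets, net_sets = {}, {}
    for organ in meta["organ"].unique():
        cols = meta.index[meta["organ"] == organ]
        sub = corrected.values[cols]
        recs = expression_prep.test_de(sub, meta.loc[cols, "timepoint"])
        recs.insert(0, "organ", organ)
        records.append(recs)
        deg_sets[organ] = expression_prep.filter_deg(recs, **config.deg)
        net_sets[organ] = expression_prep.filter_deg(recs, **config.network_filter)
    table = pd.concat(records, ignore_index=True)
    table.to_csv(outdir / "deg_table.tsv", sep="\t", index=False)
    outputs["deg_table"] = outdir / "deg_table.tsv"
    state["deg_sets"], state["net_sets"] = deg_sets, net_sets
    organs = sorted(deg_sets)
    if len(organs) == 2:
        venn = expression_prep.venn_partition(deg_sets[organs[0]], deg_sets[organs[1]])
        venn["set_a"], venn["set_b"] = organs
        (outdir / "deg_venn.json").write_text(json.dumps(venn, indent=1, sort_keys=True))
        outputs["deg_venn"] = outdir / "deg_venn.json"


def _stage_bias(config, seed, outdir, outputs, state):
    corrected = state["matrix_log"]
    table = organ_bias.bias_table(corrected)
    table.to_csv(outdir / "bias_table.tsv", sep="\t", index_label="gene_id")
    outputs["bias_table"] = outdir / "bias_table.tsv"
    state["bias_table"] = table

    shared = table.index[table["specificity"] == "shared"]
    feats = organ_bias.group_mean_features(corrected)
    if len(shared) >= 3:
        model = organ_bias.pca_shared(feats.loc[shared])
        scores = model.scores_.copy()
        specific = table.index[table["specificity"].isin(["flower_specific", "vegetative_specific"])]
        if len(specific):
            scores = pd.concat([scores, model.project(feats.loc[specific])])
        scores.to_csv(outdir / "pca_scores.tsv", sep="\t", index_label="gene_id")
        outputs["pca_scores"] = outdir / "pca_scores.tsv"
        r, p = organ_bias.pc_bias_correlation(
            scores.loc[table.index.intersection(scores.index), "PC1"],
            table.loc[table.index.intersection(scores.index), "coef_condition"],
        )
        summary = {
            "pc1_variance_pct": float(model.variance_explained_[0]),
            "pc1_coef_condition_r": r,
            "pc1_coef_condition_p": p,
        }
        (outdir / "bias_pca_summary.json").write_text(json.dumps(summary, indent=1))
        outputs["bias_pca_summary"] = outdir / "bias_pca_summary.json"
        state["pca_scores"] = scores


def _stage_modules(config, seed, outdir, outputs, state):
    corrected = state["matrix_log"]
    meta = corrected.sample_meta
    traits = state["traits"].set_index("sample_id")
    all_assign, all_corr = [], []
    state["modules"] = {}
    for organ in meta["organ"].unique():
        cols = meta.index[meta["organ"] == organ]
        genes = sorted(state["net_sets"].get(organ, set(corrected.values.index)))
        expr = corrected.values.loc[genes, cols]
        expr = expr[expr.std(axis=1) > 0]
        if expr.shape[0] < 20:
            log.warning("too few network genes for organ %s; skipped", organ)
            continue
        mod_kwargs = dict(config.modules)
        adjacency_type = mod_kwargs.pop("adjacency_type", "unsigned")
        power, _ = coexpression_modules.soft_threshold_power(expr)
        model = coexpression_modules.adjacency_tom(expr, power, adjacency_type)
        prefix = organ[0].upper()
        mods = coexpression_modules.detect_modules(
            model, expr, label_prefix=prefix, **mod_kwargs
        )
        state["modules"][organ] = (mods, expr)
        assign = pd.DataFrame(
            {"gene_id": list(mods.module_of_gene), "module": list(mods.module_of_gene.values())}
        )
        assign.insert(0, "organ", organ)
        all_assign.append(assign)
        if mods.labels:
            mtc = coexpression_modules.module_trait_correlation(
                mods.eigengenes, traits.loc[cols]
            )
            mtc.insert(0, "organ", organ)
            all_corr.append(mtc)
            mods.trait_correlations = mtc
    if all_assign:
        pd.concat(all_assign, ignore_index=True).to_csv(
            outdir / "module_assignment.tsv", sep="\t", index=False
        )
        outputs["module_assignment"] = outdir / "module_assignment.tsv"
    if all_corr:
        pd.concat(all_corr, ignore_index=True).to_csv(
            outdir / "module_trait_correlation.tsv", sep="\t", index=False
        )
        outputs["module_trait_correlation"] = outdir / "module_trait_correlation.tsv"


def _stage_graph(config, seed, outdir, outputs, state):
    corrected = state["matrix_log"]
    meta = corrected.sample_meta
    frames = []
    for organ, (mods, expr) in state.get("modules", {}).items():
        assigned = [g for g, m in mods.module_of_gene.items() if m != "unassigned"]
        if len(assigned) < 2:
            continue
        corr = coexpression_graph.pairwise_correlation(expr.loc[assigned])
        graph = coexpression_graph.build_topk_graph(corr, **config.graph)
        edges = coexpression_graph.edge_list(graph)
        edges.insert(0, "organ", organ)
        bins = coexpression_graph.degree_bins(graph)
        edges["degree_bin_a"] = edges["gene_a"].map(bins)
        frames.append(edges)
    if frames:
        pd.concat(frames, ignore_index=True).to_csv(
            outdir / "coexpression_graph_edges.tsv", sep="\t", index=False
        )
        outputs["graph_edges"] = outdir / "coexpression_graph_edges.tsv"


def _stage_grn(config, seed, outdir, outputs, state):
    corrected = state["matrix_log"]
    meta = corrected.sample_meta
    regset = grn_inference.RegulatorSet.with_default_bifc()
    regs = [r for r in regset.regulators if r in corrected.values.index]
    if len(regs) < 2:
        log.warning("fewer than 2 regulators present; GRN stage skipped")
        return
    regset = dataclasses.replace(regset, regulators=tuple(regs))
    organs = list(meta["organ"].unique())
    cpm = 2.0**corrected.values - 1.0
    if len(organs) == 2:
        f_cols = meta.index[meta["organ"] == "flower"]
        v_cols = meta.index[meta["organ"] == "vegetative"]
        parts = grn_inference.partition_genes(cpm[f_cols], cpm[v_cols])
        partitions = {
            "shared": parts["shared"],
            "flower": parts["flower_specific"],
            "vegetative": parts["vegetative_specific"],
        }
    else:
        partitions = {"shared": set(corrected.values.index)}
    grn_kwargs = dict(config.grn)
    grn_kwargs.setdefault("seed", seed)
    params = grn_inference.GRNParams(**grn_kwargs)
    annotation = (
        pd.read_csv(config.annotation_path, sep="\t")
        if config.annotation_path
        else None
    )
    nets = grn_inference.infer_grn(corrected.values, regset, partitions, params, annotation)
    for context, edges in nets.items():
        name = f"grn_edges_{context.lstrip('_')}.tsv"
        edges.to_csv(outdir / name, sep="\t", index=False)
        outputs[f"grn_{context.lstrip('_')}"] = outdir / name


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "env": _stage_env,
    "deg": _stage_deg,
    "bias": _stage_bias,
    "modules": _stage_modules,
    "graph": _stage_graph,
    "grn": _stage_grn,
}
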