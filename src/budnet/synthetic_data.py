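"""Synthetic winter bud expression datasets with known ground truth.

Emulates the design of a two-organ (flower / vegetative bud), six-timepoint,
three-to-four-replicate RNA-seq time course sampled along a chilling-unit
accumulation window, with a two-year batch structure. Counts are negative
binomial around a log-linear mean:

    mu[g, s] = library_factor[s] * exp(
        baseline[g]
        + loading[g] * trait_driver(timepoint, organ)
        + organ_bias[g, organ]
        + regulator_effect contribution (for planted GRN targets)
        + batch_offset[g, batch]
    )

Ground truth (module membership, organ bias, planted regulator->target
edges, trait curves) is returned alongside the matrix so every downstream
stage — DEG filtering, organ-bias classification, module detection,
module-trait correlation and GRN inference — can be scored against known
answers.

Everything is a pure function of (configuration, seed): the same seed
produces a byte-identical dataset.
"""

from __future__ import annotations

import datetime as _dt
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

ORGANS = ("flower", "vegetative")
DEFAULT_REGULATORS = ("DAM1", "DAM2", "DAM3", "DAM4", "DAM5", "DAM6", "SVP1", "SVP2")
TRAIT_PROFILES = ("chilling_up", "chilling_down", "lod_up", "lod_down", "none")

# Table-level defaults for the sampled winter window: chilling accumulates
# from 0 to 930 CU while day length falls from 12.85 h to 8.72 h.
DEFAULT_CU_MAX = 930.0
DEFAULT_LOD_START = 12.85
DEFAULT_LOD_END = 8.72


@dataclass
class SimulationConfig:
    """Parameters of the synthetic bud time-course generator.

    Attributes
    ----------
    n_genes
        Total genes, including module members, planted regulators and
        decoys.
    n_timepoints, n_replicates
        Time course design; replicates default to 3 (the study design used
        three or four trees per timepoint).
    module_sizes / trait_profiles
        Planted co-expression modules and the environmental driver of each
        (``chilling_up`` rises with CHILLING, ``lod_down`` falls with LOD,
        ...; ``none`` is an internally correlated module with no
        environmental trend).
    module_loading
        Log-scale amplitude of the module driver (natural-log units).
    bias_fraction / bias_effect
        Fraction of genes given an organ-biased offset and its magnitude in
        log2 units (flower-up and vegetative-up in equal numbers).
    regulators / n_targets_per_regulator / regulator_effect
        Planted regulator genes with distinctive noise-free profiles; each
        target's log-mean receives ``regulator_effect`` times its
        regulator's standardised profile.
    noise_dispersion
        Negative-binomial dispersion phi (var = mu + phi mu^2); 0 gives
        Poisson noise.
    batch_effect_sd
        SD (natural-log scale) of gene-wise per-batch offsets; replicates
        are split across two batches within every organ x timepoint group,
        mirroring a two-year sampling structure.
    library_size_range
        Uniform range of per-sample library sizes (total counts scale).
    """

    n_genes: int = 500
    n_timepoints: int = 6
    n_replicates: int = 3
    organs: tuple[str, ...] = ORGANS
    module_sizes: tuple[int, ...] = ()
    trait_profiles: tuple[str, ...] = ()
    module_loading: float = 1.0
    bias_fraction: float = 0.0
    bias_effect: float = 1.5
    regulators: tuple[str, ...] = ()
    n_targets_per_regulator: int = 0
    regulator_effect: float = 1.0
    noise_dispersion: float = 0.05
    batch_effect_sd: float = 0.0
    library_size_range: tuple[float, float] = (8e5, 1.2e6)
    baseline_log_mean: float = math.log(200.0)
    baseline_log_sd: float = 0.8
    cu_max: float = DEFAULT_CU_MAX
    lod_start: float = DEFAULT_LOD_START
    lod_end: float = DEFAULT_LOD_END
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_timepoints < 2 or self.n_replicates < 1:
            raise ValueError("n_genes >= 1, n_timepoints >= 2, n_replicates >= 1 required")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("module_sizes sum exceeds n_genes")
        if len(self.module_sizes) != len(self.trait_profiles):
            raise ValueError("module_sizes and trait_profiles must have equal length")
        for p in self.trait_profiles:
            if p not in TRAIT_PROFILES:
                raise ValueError(f"unknown trait profile {p!r}")
        if not 0.0 <= self.bias_fraction <= 1.0:
            raise ValueError("bias_fraction must be in [0, 1]")
        if self.noise_dispersion < 0:
            raise ValueError("noise_dispersion must be >= 0")
        if len(self.regulators) != len(set(self.regulators)):
            raise ValueError("duplicate regulator names")
        n_planted = sum(self.module_sizes) + len(self.regulators) * (1 + self.n_targets_per_regulator)
        if n_planted > self.n_genes:
            raise ValueError("modules + regulators + targets exceed n_genes")

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)


@dataclass
class GroundTruth:
    """Planted structure of a simulated dataset."""

    module_of_gene: dict[str, str] = field(default_factory=dict)
    bias_of_gene: dict[str, str] = field(default_factory=dict)
    grn_edges: list[tuple[str, str]] = field(default_factory=list)
    trait_curves: pd.DataFrame | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "module_of_gene": self.module_of_gene,
            "bias_of_gene": self.bias_of_gene,
            "grn_edges": [list(e) for e in self.grn_edges],
            "trait_curves": None
            if self.trait_curves is None
            else self.trait_curves.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        curves = payload.get("trait_curves")
        return cls(
            module_of_gene=payload["module_of_gene"],
            bias_of_gene=payload["bias_of_gene"],
            grn_edges=[tuple(e) for e in payload["grn_edges"]],
            trait_curves=None if curves is None else pd.DataFrame(curves),
        )


def simulate_traits(
    n_timepoints: int = 6,
    cu_max: float = DEFAULT_CU_MAX,
    lod_start: float = DEFAULT_LOD_START,
    lod_end: float = DEFAULT_LOD_END,
) -> pd.DataFrame:
    """Monotone environmental trait curves over the sampling window.

    CHILLING rises linearly from 0 to ``cu_max``; LOD falls linearly from
    ``lod_start`` to ``lod_end`` — the two cues are anti-correlated by
    construction, as they are over a real autumn-winter window.
    """
    if n_timepoints < 2:
        raise ValueError("n_timepoints must be >= 2")
    if cu_max <= 0:
        raise ValueError("cu_max must be positive")
    if lod_start <= lod_end:
        raise ValueError("lod_start must exceed lod_end")
    t = np.arange(n_timepoints)
    return pd.DataFrame(
        {
            "timepoint": t,
            "CHILLING": np.linspace(0.0, cu_max, n_timepoints),
            "LOD": np.linspace(lod_start, lod_end, n_timepoints),
        }
    )


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def _driver_value(profile: str, z_chill: np.ndarray, z_lod: np.ndarray) -> np.ndarray:
    if profile == "chilling_up":
        return z_chill
    if profile == "chilling_down":
        return -z_chill
    if profile == "lod_up":
        return z_lod
    if profile == "lod_down":
        return -z_lod
    return np.zeros_like(z_chill)


def simulate_expression(config: SimulationConfig):
    """Generate a counts matrix, sample metadata and ground truth.

    Returns
    -------
    (ExpressionMatrix, GroundTruth)
        The matrix carries counts plus sample metadata (organ,
        timepoint, timepoint_cu, batch, replicate).
    """
    from .containers import ExpressionMatrix

    rng = np.random.default_rng(config.seed)
    traits = simulate_traits(
        config.n_timepoints, config.cu_max, config.lod_start, config.lod_end
    )
    z_chill = _zscore(traits["CHILLING"].to_numpy())
    z_lod = _zscore(traits["LOD"].to_numpy())

    # ---- gene bookkeeping -------------------------------------------------
    n_reg = len(config.regulators)
    n_tgt = n_reg * config.n_targets_per_regulator
    n_module = sum(config.module_sizes)
    gene_ids: list[str] = []
    module_of: dict[str, str] = {}
    for m, size in enumerate(config.module_sizes):
        label = f"M{m + 1}"
        for i in range(size):
            gid = f"G{len(gene_ids):05d}"
            gene_ids.append(gid)
            module_of[gid] = label
    reg_ids = list(config.regulators)
    gene_ids.extend(reg_ids)
    target_of: dict[str, str] = {}
    for r in reg_ids:
        for _ in range(config.n_targets_per_regulator):
            gid = f"G{len(gene_ids) - n_reg:05d}"
            gene_ids.append(gid)
            target_of[gid] = r
    while len(gene_ids) < config.n_genes:
        gene_ids.append(f"G{len(gene_ids) - n_reg:05d}")
    assert len(gene_ids) == config.n_genes

    # ---- sample bookkeeping ----------------------------------------------
    sample_ids, organ_l, tp_l, cu_l, batch_l, rep_l = [], [], [], [], [], []
    for organ in config.organs:
        for t in range(config.n_timepoints):
            for r in range(config.n_replicates):
                sample_ids.append(f"{organ[0].upper()}_t{t}_r{r + 1}")
                organ_l.append(organ)
                tp_l.append(t)
                cu_l.append(float(traits["CHILLING"].iloc[t]))
                batch_l.append("A" if r < (config.n_replicates + 1) // 2 else "B")
                rep_l.append(r + 1)
    n_samples = len(sample_ids)
    tp = np.array(tp_l)
    organ_is_flower = np.array([o == "flower" for o in organ_l], dtype=float)
    batch_is_b = np.array([b == "B" for b in batch_l], dtype=float)

    # ---- log-mean assembly ------------------------------------------------
    baseline = rng.normal(config.baseline_log_mean, config.baseline_log_sd, config.n_genes)
    log_mu = np.tile(baseline[:, None], (1, n_samples))

    for m, (size, profile) in enumerate(zip(config.module_sizes, config.trait_profiles)):
        driver = _driver_value(profile, z_chill, z_lod)[tp]
        start = sum(config.module_sizes[:m])
        log_mu[start : start + size, :] += config.module_loading * driver[None, :]

    # organ bias: half flower-up, half vegetative-up, drawn from module and
    # decoy genes (regulators and planted GRN targets excluded so bias does
    # not confound the regulator signal)
    bias_of: dict[str, str] = {g: "balanced" for g in gene_ids}
    eligible = [i for i, g in enumerate(gene_ids) if g not in reg_ids and g not in target_of]
    n_biased = int(round(config.bias_fraction * config.n_genes))
    n_biased = min(n_biased, len(eligible))
    if n_biased and config.bias_effect != 0:
        chosen = rng.choice(len(eligible), size=n_biased, replace=False)
        half = n_biased // 2
        delta = config.bias_effect * math.log(2.0)  # log2 -> natural log
        for j, pos in enumerate(chosen):
            i = eligible[pos]
            g = gene_ids[i]
            if j < half:
                bias_of[g] = "flower"
                log_mu[i, :] += delta * organ_is_flower
            else:
                bias_of[g] = "vegetative"
                log_mu[i, :] += delta * (1.0 - organ_is_flower)

    # regulators: distinctive noise-free profiles from a small basis so a
    # tree ensemble can tell them apart
    grn_edges: list[tuple[str, str]] = []
    if reg_ids:
        z_t = _zscore(tp.astype(float))
        basis = np.stack(
            [
                z_t,
                _zscore(z_t**2),
                _zscore(np.cos(math.pi * tp / max(tp.max(), 1))),
                organ_is_flower - organ_is_flower.mean(),
                _zscore(z_t * organ_is_flower),
            ]
        )
        reg_profiles = {}
        for r in reg_ids:
            w = rng.normal(0.0, 1.0, basis.shape[0])
            prof = w @ basis
            reg_profiles[r] = _zscore(prof)
            i = gene_ids.index(r)
            log_mu[i, :] += reg_profiles[r]
        for gid, r in target_of.items():
            i = gene_ids.index(gid)
            log_mu[i, :] += config.regulator_effect * reg_profiles[r]
            grn_edges.append((r, gid))

    if config.batch_effect_sd > 0:
        offsets = rng.normal(0.0, config.batch_effect_sd, (config.n_genes, 2))
        log_mu += offsets[:, [0]] * (1.0 - batch_is_b)[None, :]
        log_mu += offsets[:, [1]] * batch_is_b[None, :]

    lib_sizes = rng.uniform(*config.library_size_range, n_samples)
    lib_factor = lib_sizes / lib_sizes.mean()
    mu = np.exp(log_mu) * lib_factor[None, :]

    if config.noise_dispersion > 0:
        shape = 1.0 / config.noise_dispersion
        lam = rng.gamma(shape, mu / shape)
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(mu)

    values = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids)
    meta = pd.DataFrame(
        {
            "organ": organ_l,
            "timepoint": tp_l,
            "timepoint_cu": cu_l,
            "batch": batch_l,
            "replicate": rep_l,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    matrix = ExpressionMatrix(values=values, layer="counts", sample_meta=meta)
    truth = GroundTruth(
        module_of_gene=module_of, bias_of_gene=bias_of, grn_edges=grn_edges, trait_curves=traits
    )
    return matrix, truth


def simulate_temperatures(
    start_date: str | _dt.date,
    n_days: int,
    seed: int = 0,
    mean_start: float = 16.0,
    mean_end: float = 3.0,
    diurnal_amplitude: float = 5.0,
    noise_sd: float = 1.5,
) -> pd.DataFrame:
    """Hourly synthetic temperature record over an autumn-winter window.

    Seasonal linear cooling from ``mean_start`` to ``mean_end`` deg C plus a
    diurnal sinusoid (coolest ~05:00, warmest ~17:00) and Gaussian noise.
    Returns a DataFrame (timestamp, temp_c) of length ``24 * n_days``.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    rng = np.random.default_rng(seed)
    start = pd.Timestamp(start_date)
    hours = np.arange(24 * n_days)
    timestamps = start + pd.to_timedelta(hours, unit="h")
    season = mean_start + (mean_end - mean_start) * hours / max(hours[-1], 1)
    diurnal = diurnal_amplitude * np.sin(2 * math.pi * (hours % 24 - 11) / 24.0)
    noise = rng.normal(0.0, noise_sd, hours.size) if noise_sd > 0 else 0.0
    return pd.DataFrame({"timestamp": timestamps, "temp_c": season + diurnal + noise})


def write_dataset(outdir: str | Path, config: SimulationConfig) -> dict[str, Path]:
    """Simulate and write a full dataset (TSV/CSV/JSON) to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix, truth = simulate_expression(config)
    paths = {
        "counts": outdir / "counts.tsv",
        "sample_meta": outdir / "sample_meta.tsv",
        "ground_truth": outdir / "ground_truth.json",
        "traits": outdir / "traits.tsv",
        "config": outdir / "sim_config.json",
    }
    matrix.to_tsv(paths["counts"])
    matrix.sample_meta.to_csv(paths["sample_meta"], sep="\t")
    truth.to_json(paths["ground_truth"])
    truth.trait_curves.to_csv(paths["traits"], sep="\t", index=False)
    paths["config"].write_text(json.dumps(asdict(config), indent=1, sort_keys=True))
    return paths
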