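"""Weighted co-expression modules and module-trait correlation.

The classic weighted-correlation workflow: a soft-thresholded adjacency
(|Pearson r|^beta), topological overlap similarity (TOM), average-linkage
hierarchical clustering on 1 - TOM with a static cut, small-cluster
pruning, eigengene-based module merging, module labels ordered by size,
eigengene-trait Pearson correlations with t-distribution p-values, and
hypergeometric GO-term enrichment per module.

Defaults (unsigned adjacency, unsigned TOM, average linkage, static cut at
0.99, minimum module size 30, merge threshold 0.25 on eigengene
dissimilarity) approximate the reference tool's default behaviour; every
knob is exposed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .expression_prep import bh_adjust


@dataclass
class CoexpressionModel:
    """Soft-thresholded adjacency and its topological overlap matrix."""

    soft_power: int
    adjacency_type: str  # "unsigned" | "signed"
    adjacency: pd.DataFrame
    tom: pd.DataFrame
    linkage_: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = self.tom.to_numpy()
        if not np.allclose(t, t.T, atol=1e-10):
            raise ValueError("TOM must be symmetric")
        if t.min() < -1e-10 or t.max() > 1 + 1e-10:
            raise ValueError("TOM values must lie in [0, 1]")
        if not np.allclose(np.diag(t), 1.0):
            raise ValueError("TOM diagonal must be 1")


@dataclass
class ModuleSet:
    """Gene-to-module assignment with eigengenes and trait correlations."""

    module_of_gene: dict[str, str]
    labels: list[str]  # ordered by descending size
    eigengenes: pd.DataFrame | None = None  # modules x samples
    trait_correlations: pd.DataFrame | None = None
    unassigned_label: str = "unassigned"

    def genes_of(self, label: str) -> list[str]:
        return [g for g, m in self.module_of_gene.items() if m == label]

    def sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for m in self.module_of_gene.values():
            out[m] = out.get(m, 0) + 1
        return out


def _correlation(expr: pd.DataFrame) -> np.ndarray:
    x = expr.to_numpy(dtype=float)
    sd = x.std(axis=1)
    if (sd == 0).any():
        bad = expr.index[np.where(sd == 0)[0][0]]
        raise ValueError(f"constant gene {bad!r} has undefined correlations")
    c = np.corrcoef(x)
    if np.isnan(c).any():
        i, j = np.argwhere(np.isnan(c))[0]
        raise ValueError(f"NaN correlation between {expr.index[i]!r} and {expr.index[j]!r}")
    return c


def soft_threshold_power(
    expr: pd.DataFrame,
    candidate_powers=range(1, 21),
    target_r2: float = 0.8,
    n_bins: int = 10,
    fallback: int = 6,
) -> tuple[int, pd.DataFrame]:
    """Smallest power giving an approximately scale-free topology.

    For each candidate beta, connectivity k_i = sum_j |r_ij|^beta (j != i)
    is binned, and the fit R^2 of log10 p(k) on log10 mean-k over occupied
    bins is recorded (counted as 0 when the slope is positive, since
    scale-free topology requires a decreasing degree distribution). Returns
    the smallest power whose R^2 >= ``target_r2`` plus the fit table; falls
    back to ``fallback`` with a warning when none qualifies.
    """
    if expr.shape[0] < 20:
        raise ValueError("need >= 20 genes to assess scale-free fit")
    corr = np.abs(_correlation(expr))
    np.fill_diagonal(corr, 0.0)
    rows = []
    chosen = None
    for beta in candidate_powers:
        k = (corr**beta).sum(axis=1)
        r2, slope = _scale_free_fit(k, n_bins)
        rows.append((beta, r2, slope, float(k.mean())))
        if chosen is None and slope < 0 and r2 >= target_r2:
            chosen = int(beta)
    table = pd.DataFrame(rows, columns=["power", "fit_r2", "slope", "mean_k"])
    if chosen is None:
        warnings.warn(
            f"no candidate power reached scale-free fit R^2 >= {target_r2}; "
            f"falling back to {fallback}"
        )
        chosen = fallback
    return chosen, table


def _scale_free_fit(k: np.ndarray, n_bins: int) -> tuple[float, float]:
    k = k[k > 0]
    if k.size < 3 or np.allclose(k, k[0]):
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    idx = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        members = k[idx == b]
        if members.size == 0:
            continue
        xs.append(np.log10(members.mean()))
        ys.append(np.log10(members.size / k.size))
    if len(xs) < 3:
        return 0.0, 0.0
    slope, _, r, _, _ = stats.linregress(xs, ys)
    return float(r**2), float(slope)


def adjacency_tom(
    expr: pd.DataFrame, soft_power: int, adjacency_type: str = "unsigned"
) -> CoexpressionModel:
    """Soft-thresholded adjacency and unsigned topological overlap.

    unsigned: a_ij = |r_ij|^beta; signed: a_ij = ((1 + r_ij)/2)^beta.
    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    a_ii = 0 in the sums and TOM diagonal set to 1.
    """
    if soft_power < 1:
        raise ValueError("soft_power must be >= 1")
    corr = _correlation(expr)
    if adjacency_type == "unsigned":
        a = np.abs(corr) ** soft_power
    elif adjacency_type == "signed":
        a = ((1.0 + corr) / 2.0) ** soft_power
    else:
        raise ValueError("adjacency_type must be 'unsigned' or 'signed'")
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    l = a @ a
    k_min = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (l + a) / (k_min + 1.0 - a)
    tom = np.where(np.isfinite(tom), tom, 0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    idx = expr.index
    return CoexpressionModel(
        soft_power=int(soft_power),
        adjacency_type=adjacency_type,
        adjacency=pd.DataFrame(a, index=idx, columns=idx),
        tom=pd.DataFrame(tom, index=idx, columns=idx),
    )


def detect_modules(
    model: CoexpressionModel,
    expr: pd.DataFrame,
    cut_height: float = 0.99,
    min_module_size: int = 30,
    merge_height: float = 0.25,
    label_prefix: str = "M",
) -> ModuleSet:
    """Average-linkage clustering of 1 - TOM with static cut and merging.

    Clusters smaller than ``min_module_size`` go to the unassigned pool.
    Modules whose eigengenes correlate above ``1 - merge_height`` are merged
    iteratively. Final labels are ``{prefix}1..{prefix}n`` in descending
    size order.
    """
    genes = list(model.tom.index)
    diss = 1.0 - model.tom.to_numpy()
    np.fill_diagonal(diss, 0.0)
    z = linkage(squareform(diss, checks=False), method="average")
    raw = fcluster(z, t=cut_height, criterion="distance")

    clusters: dict[int, list[str]] = {}
    for g, c in zip(genes, raw):
        clusters.setdefault(int(c), []).append(g)
    kept = {c: gs for c, gs in clusters.items() if len(gs) >= min_module_size}
    if not kept:
        warnings.warn("all genes unassigned: no cluster reached min_module_size")
        return ModuleSet(
            module_of_gene={g: "unassigned" for g in genes}, labels=[], eigengenes=None
        )

    groups = list(kept.values())
    groups = _merge_by_eigengene(groups, expr, merge_height)
    groups.sort(key=lambda gs: (-len(gs), gs[0]))
    module_of = {g: "unassigned" for g in genes}
    labels = []
    for i, gs in enumerate(groups):
        label = f"{label_prefix}{i + 1}"
        labels.append(label)
        for g in gs:
            module_of[g] = label
    mset = ModuleSet(module_of_gene=module_of, labels=labels)
    mset.eigengenes = module_eigengenes(expr, mset)
    model.linkage_ = z
    return mset


def _merge_by_eigengene(groups: list[list[str]], expr: pd.DataFrame, merge_height: float):
    while len(groups) > 1:
        eig = np.stack([_first_pc(expr.loc[gs]) for gs in groups])
        c = np.corrcoef(eig)
        np.fill_diagonal(c, -np.inf)
        i, j = np.unravel_index(np.argmax(c), c.shape)
        if c[i, j] <= 1.0 - merge_height:
            break
        merged = groups[i] + groups[j]
        groups = [gs for k, gs in enumerate(groups) if k not in (i, j)] + [merged]
    return groups


def _first_pc(expr_block: pd.DataFrame) -> np.ndarray:
    """First PC across samples of gene-standardised expression, sign-oriented
    to correlate positively with the module mean profile."""
    x = expr_block.to_numpy(dtype=float)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=1, keepdims=True)) / sd
    if z.shape[0] == 1:
        return z[0]
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    pc = vt[0]
    mean_profile = z.mean(axis=0)
    if np.dot(pc, mean_profile) < 0:
        pc = -pc
    return pc


def module_eigengenes(expr: pd.DataFrame, module_set: ModuleSet) -> pd.DataFrame:
    """Modules x samples eigengene matrix (first PC per module)."""
    if not module_set.labels:
        raise ValueError("empty module set")
    rows = {}
    for label in module_set.labels:
        gs = module_set.genes_of(label)
        rows[label] = _first_pc(expr.loc[gs])
    return pd.DataFrame(rows, index=expr.columns).T


def module_trait_correlation(
    eigengenes: pd.DataFrame, trait_table: pd.DataFrame
) -> pd.DataFrame:
    """Pearson r and p (t distribution, n-2 dof) per module x trait.

    ``trait_table`` columns are traits (e.g. CHILLING, LOD), rows are
    samples aligned with the eigengene columns.
    """
    traits = trait_table
    if "sample_id" in traits.columns:
        traits = traits.set_index("sample_id")
    traits = traits.loc[list(eigengenes.columns)]
    rows = []
    for module in eigengenes.index:
        e = eigengenes.loc[module].to_numpy(dtype=float)
        for trait in traits.columns:
            t = traits[trait].to_numpy(dtype=float)
            if t.std() == 0:
                raise ValueError(f"trait {trait!r} is constant")
            r, p = stats.pearsonr(e, t)
            rows.append((module, trait, float(r), float(p)))
    return pd.DataFrame(rows, columns=["module", "trait", "r", "p"])


def hypergeom_enrichment(
    module_genes,
    annotation: pd.DataFrame,
    background,
) -> pd.DataFrame:
    """One-sided hypergeometric GO-term enrichment with BH across terms.

    ``annotation`` maps gene -> term (columns ``gene_id``, ``term``);
    ``background`` is the gene universe (must contain the module). For each
    term with K annotated genes in the background and k in the module of
    size n, p = P(X >= k) under sampling n genes from the background
    without replacement.
    """
    module = set(module_genes)
    bg = set(background)
    if not module <= bg:
        raise ValueError("background must contain every module gene")
    if not module:
        return pd.DataFrame(
            columns=["module_size", "term", "k_in_module", "K_in_background", "p_hypergeom", "fdr"]
        )
    ann = annotation[annotation["gene_id"].isin(bg)]
    skipped = set(annotation["term"]) - set(ann["term"])
    if skipped:
        warnings.warn(f"terms absent from background skipped: {sorted(skipped)[:5]}")
    n_bg, n_mod = len(bg), len(module)
    rows = []
    for term, genes in ann.groupby("term")["gene_id"]:
        term_genes = set(genes)
        k = len(term_genes & module)
        big_k = len(term_genes)
        p = float(stats.hypergeom.sf(k - 1, n_bg, big_k, n_mod))
        rows.append((n_mod, term, k, big_k, p))
    out = pd.DataFrame(
        rows, columns=["module_size", "term", "k_in_module", "K_in_background", "p_hypergeom"]
    )
    if len(out):
        out["fdr"] = bh_adjust(out["p_hypergeom"]).to_numpy()
    else:
        out["fdr"] = []
    return out
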