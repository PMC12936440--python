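"""Count normalisation, batch correction, differential expression and DEG sets.

The stage mirrors a standard bulk RNA-seq preparation: TMM between-sample
normalisation, log2-CPM transform, removal of batch structure from combined
multi-year datasets, a per-gene across-timepoint test with BH correction,
and fold-change/FDR gates producing the global DEG set (FC >= 1.4,
FDR < 0.05) and the stricter network input set (FC >= 1.5, FDR < 0.01).

The differential-expression statistic is a per-gene one-way ANOVA F-test
across timepoints on log2 data — a transparent surrogate for
noise-distribution-based DE engines; the fold-change and FDR gates are
applied exactly as stated above.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix


# --------------------------------------------------------------------- TMM
def tmm_factors(
    counts: pd.DataFrame,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalisation factors, one per sample.

    The reference sample is the one whose upper-quartile (of counts scaled
    by library size) is closest to the mean upper-quartile. For every other
    sample, M (log2 expression ratio vs the reference) and A (average log2
    abundance) values are computed over genes expressed in both; the upper
    and lower ``trim_m`` fraction by M and ``trim_a`` fraction by A are
    discarded and the factor is 2 to the precision-weighted mean of the
    remaining M values. Factors are rescaled to geometric mean 1.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    zero = np.where(lib == 0)[0]
    if zero.size:
        raise ValueError(f"sample {counts.columns[zero[0]]!r} has zero total counts")
    x = counts.to_numpy(dtype=float)
    f75 = np.array([np.quantile(x[:, j][x[:, j] > 0] / lib[j], 0.75) if (x[:, j] > 0).any()
                    else 0.0 for j in range(x.shape[1])])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    log_factors = np.zeros(x.shape[1])
    for j in range(x.shape[1]):
        if j == ref:
            continue
        log_factors[j] = _tmm_pair(x[:, j], lib[j], x[:, ref], lib[ref], trim_m, trim_a)
    # rescale so the geometric mean of the factors is 1
    log_factors -= log_factors.mean()
    return pd.Series(2.0**log_factors, index=counts.columns, name="tmm_factor")


def _tmm_pair(obs, lib_obs, ref, lib_ref, trim_m, trim_a) -> float:
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        return 0.0
    o, r = obs[keep], ref[keep]
    m = np.log2((o / lib_obs) / (r / lib_ref))
    a = 0.5 * np.log2((o / lib_obs) * (r / lib_ref))
    # delta-method precision weights (asymptotic variance of M)
    w = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    finite = np.isfinite(m) & np.isfinite(a) & (np.abs(m) < 1e10)
    m, a, w = m[finite], a[finite], w[finite]
    if m.size == 0:
        return 0.0
    n = m.size
    lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
    rank_m = stats.rankdata(m, method="average")
    rank_a = stats.rankdata(a, method="average")
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any():
        return 0.0
    inv_w = 1.0 / w[keep2]
    return float(np.sum(inv_w * m[keep2]) / np.sum(inv_w))


def normalize_log_cpm(
    counts: ExpressionMatrix | pd.DataFrame,
    factors: pd.Series | None = None,
    pseudocount: float = 1.0,
) -> ExpressionMatrix:
    """log2 counts-per-million with TMM-adjusted library sizes.

    value = log2( count / (lib_size * factor) * 1e6 + pseudocount ).
    Doubling every count and library size leaves the result unchanged.
    """
    if isinstance(counts, ExpressionMatrix):
        if counts.layer != "counts":
            raise ValueError(f"expected a counts layer, got {counts.layer!r}")
        frame, meta = counts.values, counts.sample_meta
    else:
        frame, meta = counts, None
    if factors is None:
        factors = tmm_factors(frame)
    if set(factors.index) != set(frame.columns):
        raise ValueError("normalisation factors do not match the sample set")
    factors = factors.loc[frame.columns]
    eff_lib = frame.sum(axis=0) * factors
    cpm = frame.div(eff_lib, axis=1) * 1e6
    logv = np.log2(cpm + pseudocount)
    return ExpressionMatrix(values=logv, layer="log2", sample_meta=meta)


# ------------------------------------------------------------ batch removal
def correct_batch(
    matrix_log: ExpressionMatrix | pd.DataFrame,
    batch_labels: pd.Series | np.ndarray | None = None,
    group_labels: pd.Series | np.ndarray | None = None,
    n_components: int = 1,
    confound_r: float = 0.7,
) -> ExpressionMatrix:
    """Remove batch-associated principal components from within-group residuals.

    ANOVA-decomposition + PCA-denoising: per-gene group (organ x timepoint)
    means are fitted and removed; principal components of the residual
    matrix whose sample scores correlate with a batch indicator above
    ``confound_r`` in absolute value are subtracted (after re-centring
    within groups, so group means are preserved exactly); the corrected
    matrix is means + cleaned residuals.

    With a single batch the matrix is returned unchanged. A batch perfectly
    confounded with the grouping cannot be separated: a warning is issued
    and the component is left alone.
    """
    if isinstance(matrix_log, ExpressionMatrix):
        frame, meta = matrix_log.values, matrix_log.sample_meta
        if batch_labels is None and meta is not None and "batch" in meta:
            batch_labels = meta["batch"]
        if group_labels is None and meta is not None:
            group_labels = meta["organ"].astype(str) + ":" + meta["timepoint"].astype(str)
    else:
        frame, meta = matrix_log, None
    if batch_labels is None or group_labels is None:
        raise ValueError("batch and group labels are required")
    batch = np.asarray(batch_labels).astype(str)
    group = np.asarray(group_labels).astype(str)
    uniq_batches = np.unique(batch)
    if uniq_batches.size < 2:
        return ExpressionMatrix(values=frame.copy(), layer="batch_corrected", sample_meta=meta)

    x = frame.to_numpy(dtype=float)
    group_codes, group_idx = np.unique(group, return_inverse=True)
    means = np.zeros((x.shape[0], group_codes.size))
    for g in range(group_codes.size):
        means[:, g] = x[:, group_idx == g].mean(axis=1)
    fitted = means[:, group_idx]
    resid = x - fitted

    # batches fully nested in single groups carry no separable signal
    for b in uniq_batches:
        if np.unique(group[batch == b]).size == 1 and np.unique(batch[np.isin(group, group[batch == b])]).size == 1:
            warnings.warn(f"batch {b!r} is confounded with a group; left uncorrected")

    u, s, vt = np.linalg.svd(resid, full_matrices=False)
    removed = np.zeros_like(resid)
    dummies = np.stack([(batch == b).astype(float) for b in uniq_batches])
    for c in range(min(n_components, s.size)):
        scores = vt[c]
        if scores.std() == 0:
            continue
        r_max = max(
            abs(np.corrcoef(scores, d)[0, 1]) for d in dummies if d.std() > 0
        )
        if r_max > confound_r:
            removed += s[c] * np.outer(u[:, c], vt[c])
    # re-centre the removed piece within groups so group means survive intact
    for g in range(group_codes.size):
        cols = group_idx == g
        removed[:, cols] -= removed[:, cols].mean(axis=1, keepdims=True)
    corrected = fitted + resid - removed
    out = pd.DataFrame(corrected, index=frame.index, columns=frame.columns)
    return ExpressionMatrix(values=out, layer="batch_corrected", sample_meta=meta)


# ------------------------------------------------------- differential tests
@dataclass
class DEGRecord:
    gene_id: str
    contrast: str
    log2fc: float
    p_value: float
    fdr: float


def test_de(
    matrix: ExpressionMatrix | pd.DataFrame,
    timepoints: pd.Series | np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-gene one-way F-test across timepoints on log2 expression.

    Returns a long DataFrame (gene_id, contrast, log2fc, p_value, fdr) with
    one row per gene per non-reference timepoint: log2fc is the mean
    difference vs the first timepoint; the p-value is the gene's across-
    timepoint F-test, BH-adjusted across genes. Timepoints with a single
    replicate are excluded with a warning.
    """
    if isinstance(matrix, ExpressionMatrix):
        frame = matrix.values
        if timepoints is None and matrix.sample_meta is not None:
            timepoints = matrix.sample_meta["timepoint"]
    else:
        frame = matrix
    if timepoints is None:
        raise ValueError("timepoint labels are required")
    tp = np.asarray(timepoints)
    levels = [t for t in pd.unique(tp)]
    counts = {t: int((tp == t).sum()) for t in levels}
    usable = [t for t in levels if counts[t] >= 2]
    dropped = [t for t in levels if counts[t] < 2]
    if dropped:
        warnings.warn(f"timepoints with a single replicate excluded: {dropped}")
    if len(usable) < 2:
        raise ValueError("need at least two timepoints with >= 2 replicates")

    x = frame.to_numpy(dtype=float)
    groups = [x[:, tp == t] for t in usable]
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat, p = stats.f_oneway(*groups, axis=1)
    # genes constant across all samples: no evidence of change
    p = np.where(np.isnan(p), 1.0, p)
    fdr = bh_adjust(pd.Series(p, index=frame.index))

    ref = usable[0]
    ref_mean = x[:, tp == ref].mean(axis=1)
    records = []
    for t in usable[1:]:
        lfc = x[:, tp == t].mean(axis=1) - ref_mean
        records.append(
            pd.DataFrame(
                {
                    "gene_id": frame.index,
                    "contrast": f"{t}_vs_{ref}",
                    "log2fc": lfc,
                    "p_value": p,
                    "fdr": fdr.to_numpy(),
                }
            )
        )
    return pd.concat(records, ignore_index=True)


def bh_adjust(p_values: pd.Series | np.ndarray) -> pd.Series:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    arr = np.asarray(p_values, dtype=float)
    if np.isnan(arr).any():
        raise ValueError("NaN p-values are not allowed")
    if ((arr < 0) | (arr > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    adj = multipletests(arr, method="fdr_bh")[1]
    index = p_values.index if isinstance(p_values, pd.Series) else None
    return pd.Series(adj, index=index, name="fdr")


def filter_deg(records: pd.DataFrame, fc_min: float = 1.4, fdr_max: float = 0.05) -> set[str]:
    """Genes passing the fold-change and FDR gates.

    A gene survives if its maximum absolute log2 fold change across
    contrasts is >= log2(fc_min) (boundary inclusive) AND its minimum FDR
    is <= fdr_max. The global DEG set uses (1.4, 0.05); the network input
    set uses (1.5, 0.01).
    """
    if fc_min < 1:
        raise ValueError("fc_min must be >= 1")
    by_gene = records.groupby("gene_id").agg(
        max_abs_lfc=("log2fc", lambda s: s.abs().max()),
        min_fdr=("fdr", "min"),
    )
    thr = np.log2(fc_min)
    keep = by_gene[(by_gene["max_abs_lfc"] >= thr - 1e-12) & (by_gene["min_fdr"] <= fdr_max)]
    return set(keep.index)


def venn_partition(set_a: set, set_b: set) -> dict[str, int]:
    """Shared / unique partition of two DEG sets."""
    a, b = set(set_a), set(set_b)
    return {
        "shared": len(a & b),
        "unique_a": len(a - b),
        "unique_b": len(b - a),
    }
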