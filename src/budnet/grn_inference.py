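"""DAM/SVP gene-regulatory-network inference and annotation.

Tree-ensemble network inference in the GENIE3 style: for every target
gene, a Random Forest regression of its standardised expression profile on
the candidate regulator profiles (DAM1-6, SVP1, SVP2 by default); the
importance of a regulator for a target is its share of the total impurity
(variance) reduction, normalised to sum to 1 per target. Edges are then
thresholded per network context (flower 0.30, vegetative 0.36, shared
0.27; strict ">"), classified by strength (<0.3 weak, 0.3-0.5 moderate,
>0.5 strong), combined into homodimer/heterodimer regulatory units guided
by a BiFC protein-interaction table, and optionally filtered to targets
carrying significantly enriched GO terms.

The dimer rule makes the narrative logic explicit: within one network, if
two retained regulators of a target form a BiFC-positive pair they are
merged into a single heterodimer edge (validated); regulators left
unpaired act as homodimers; a BiFC-negative pair is never merged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .coexpression_modules import hypergeom_enrichment
from .containers import ExpressionMatrix

DEFAULT_REGULATORS = ("DAM1", "DAM2", "DAM3", "DAM4", "DAM5", "DAM6", "SVP1", "SVP2")

#: BiFC outcomes reported for the DAM/SVP set: SVP1 interacts with DAM3,
#: DAM5 and DAM6; DAM5-DAM6 is a positive pair; DAM6-DAM3 does not interact.
DEFAULT_BIFC_POSITIVE = (
    ("SVP1", "DAM3"),
    ("SVP1", "DAM5"),
    ("SVP1", "DAM6"),
    ("DAM5", "DAM6"),
)
DEFAULT_BIFC_NEGATIVE = (("DAM6", "DAM3"),)

DEFAULT_THRESHOLDS = {"flower": 0.30, "vegetative": 0.36, "shared": 0.27}


@dataclass
class RegulatorSet:
    """Candidate regulators plus their pairwise BiFC interaction table."""

    regulators: tuple[str, ...] = DEFAULT_REGULATORS
    bifc: dict[frozenset, str] = field(default_factory=dict)

    @classmethod
    def with_default_bifc(cls, regulators=DEFAULT_REGULATORS) -> "RegulatorSet":
        table = {frozenset(p): "positive" for p in DEFAULT_BIFC_POSITIVE}
        table.update({frozenset(p): "negative" for p in DEFAULT_BIFC_NEGATIVE})
        return cls(regulators=tuple(regulators), bifc=table)

    @classmethod
    def from_table(cls, table: pd.DataFrame, regulators=DEFAULT_REGULATORS) -> "RegulatorSet":
        """Build from a (reg_a, reg_b, outcome) table; outcome in
        {positive, negative, untested}."""
        bifc = {}
        for _, row in table.iterrows():
            out = str(row["outcome"]).lower()
            if out not in {"positive", "negative", "untested"}:
                raise ValueError(f"unknown BiFC outcome {row['outcome']!r}")
            if out != "untested":
                bifc[frozenset((row["reg_a"], row["reg_b"]))] = out
        return cls(regulators=tuple(regulators), bifc=bifc)

    def status(self, a: str, b: str) -> str:
        return self.bifc.get(frozenset((a, b)), "untested")


@dataclass
class GRNParams:
    """Tree-ensemble and thresholding parameters."""

    ntrees: int = 500
    seed: int = 0
    thresholds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))

    def __post_init__(self) -> None:
        if self.ntrees < 1:
            raise ValueError("ntrees must be >= 1")
        if any(t <= 0 for t in self.thresholds.values()):
            raise ValueError("thresholds must be positive")


def partition_genes(
    expr_flower: pd.DataFrame,
    expr_vegetative: pd.DataFrame,
    min_expr: float = 1.0,
    min_samples: int = 2,
) -> dict[str, set[str]]:
    """Shared / flower-specific / vegetative-specific gene partition.

    Presence in an organ = normalised expression >= ``min_expr`` in at
    least ``min_samples`` samples of that organ's matrix. The two matrices
    share a gene-id namespace; genes absent from both are dropped.
    """
    common = expr_flower.index.union(expr_vegetative.index)
    if expr_flower.index.intersection(expr_vegetative.index).empty:
        raise ValueError("no overlap between the flower and vegetative gene namespaces")

    def present(expr: pd.DataFrame) -> set[str]:
        mask = (expr >= min_expr).sum(axis=1) >= min_samples
        return set(expr.index[mask])

    in_f, in_v = present(expr_flower), present(expr_vegetative)
    return {
        "shared": in_f & in_v,
        "flower_specific": in_f - in_v,
        "vegetative_specific": in_v - in_f,
    }


def genie3_importances(
    expr: pd.DataFrame,
    regulator_ids,
    params: GRNParams | None = None,
    targets=None,
) -> pd.DataFrame:
    """Random-Forest importance matrix (regulators x targets).

    Each target's standardised profile is regressed on the regulator
    profiles with ``ntrees`` trees and sqrt(#regulators) candidate features
    per split; importances are impurity reductions normalised to sum to 1
    per target. A regulator is never a predictor of itself but may appear
    as a target of the others. Fully seeded: per-target seeds are derived
    from ``params.seed``.
    """
    params = params or GRNParams()
    regulator_ids = [r for r in regulator_ids]
    if len(regulator_ids) < 2:
        raise ValueError("need at least 2 regulators")
    missing = [r for r in regulator_ids if r not in expr.index]
    if missing:
        raise ValueError(f"regulators missing from the matrix: {missing}")
    if targets is None:
        targets = [g for g in expr.index if g not in set(regulator_ids)]
    reg_x = expr.loc[regulator_ids].to_numpy(dtype=float).T  # samples x regulators
    seed_seq = np.random.SeedSequence(params.seed)
    child_seeds = seed_seq.generate_state(len(targets))
    weights = np.zeros((len(regulator_ids), len(targets)))
    max_feat = max(1, int(np.sqrt(len(regulator_ids))))
    for t_idx, target in enumerate(targets):
        y = expr.loc[target].to_numpy(dtype=float)
        sd = y.std()
        y = (y - y.mean()) / sd if sd > 0 else y - y.mean()
        rf = RandomForestRegressor(
            n_estimators=params.ntrees,
            max_features=max_feat,
            random_state=int(child_seeds[t_idx] % (2**31 - 1)),
            n_jobs=1,
        )
        rf.fit(reg_x, y)
        imp = rf.feature_importances_
        total = imp.sum()
        weights[:, t_idx] = imp / total if total > 0 else np.full_like(imp, 1.0 / imp.size)
    return pd.DataFrame(weights, index=regulator_ids, columns=list(targets))


def threshold_edges(
    weights: pd.DataFrame,
    network_context: str,
    params: GRNParams | None = None,
) -> pd.DataFrame:
    """Edges above the context threshold (strict ``>``).

    Context thresholds default to flower 0.30, vegetative 0.36, shared
    0.27. Returns (regulator, target, weight, network, strength) sorted by
    descending weight.
    """
    params = params or GRNParams()
    if network_context not in params.thresholds:
        raise ValueError(
            f"unknown network context {network_context!r}; "
            f"expected one of {sorted(params.thresholds)}"
        )
    tau = params.thresholds[network_context]
    rows = []
    for reg in weights.index:
        for tgt in weights.columns:
            w = float(weights.loc[reg, tgt])
            if w > tau:
                rows.append((reg, tgt, w, network_context, classify_edge_strength(w)))
    out = pd.DataFrame(rows, columns=["regulator", "target", "weight", "network", "strength"])
    return out.sort_values(["weight", "regulator", "target"], ascending=[False, True, True]).reset_index(drop=True)


def classify_edge_strength(weight: float) -> str:
    """Weight bands for display: <0.3 weak, 0.3-0.5 moderate, >0.5 strong.

    Band boundaries 0.3 and 0.5 are inclusive in the moderate band.
    """
    if weight <= 0:
        raise ValueError("weight must be positive")
    if weight < 0.3:
        return "weak"
    if weight <= 0.5:
        return "moderate"
    return "strong"


def annotate_dimers(edges: pd.DataFrame, regulator_set: RegulatorSet) -> pd.DataFrame:
    """Merge retained regulators of a target into dimer regulatory units.

    Within each (target, network): BiFC-positive pairs among the retained
    regulators are merged greedily by descending combined weight into
    heterodimer edges (``bifc_validated`` True, weight = mean of the two);
    unpaired regulators become homodimer edges. BiFC-negative pairs are
    never merged (asserted).
    """
    rows = []
    for (target, network), grp in edges.groupby(["target", "network"], sort=True):
        regs = dict(zip(grp["regulator"], grp["weight"]))
        pairs = [
            (a, b)
            for i, a in enumerate(sorted(regs))
            for b in sorted(regs)[i + 1 :]
            if regulator_set.status(a, b) == "positive"
        ]
        pairs.sort(key=lambda p: -(regs[p[0]] + regs[p[1]]))
        used: set[str] = set()
        for a, b in pairs:
            if a in used or b in used:
                continue
            used.update((a, b))
            rows.append(
                {
                    "regulators": f"{min(a, b)}+{max(a, b)}",
                    "target": target,
                    "weight": (regs[a] + regs[b]) / 2.0,
                    "network": network,
                    "dimer": "heterodimer",
                    "bifc_validated": True,
                }
            )
        for r in sorted(set(regs) - used):
            rows.append(
                {
                    "regulators": r,
                    "target": target,
                    "weight": regs[r],
                    "network": network,
                    "dimer": "homodimer",
                    "bifc_validated": regulator_set.status(r, r) == "positive",
                }
            )
    out = pd.DataFrame(
        rows,
        columns=["regulators", "target", "weight", "network", "dimer", "bifc_validated"],
    )
    if len(out):
        out["strength"] = [classify_edge_strength(w) for w in out["weight"]]
        for unit in out.loc[out["dimer"] == "heterodimer", "regulators"]:
            a, b = unit.split("+")
            assert regulator_set.status(a, b) != "negative", (
                f"BiFC-negative pair {unit} merged into a heterodimer"
            )
    else:
        out["strength"] = []
    return out.sort_values(["network", "target", "regulators"]).reset_index(drop=True)


def go_filter_targets(
    edges: pd.DataFrame,
    annotation: pd.DataFrame,
    background=None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Restrict the visual network to targets with enriched GO terms.

    Per network, the target set is tested for GO-term enrichment
    (hypergeometric, BH-adjusted) against ``background`` (default: all
    annotated genes plus the targets); edges whose target carries at least
    one retained term (adjusted p < alpha) survive. Unannotated targets are
    dropped here but remain in the full edge table the caller holds.
    """
    if annotation is None or annotation.empty:
        warnings.warn("empty annotation: GO filter passes all edges through")
        return edges.copy()
    gene_terms = annotation.groupby("gene_id")["term"].agg(set)
    keep_rows = []
    for network, grp in edges.groupby("network"):
        targets = set(grp["target"])
        bg = set(background) if background is not None else set(gene_terms.index) | targets
        enr = hypergeom_enrichment(targets & bg, annotation, bg)
        retained_terms = set(enr.loc[enr["fdr"] < alpha, "term"])
        for idx, row in grp.iterrows():
            terms = gene_terms.get(row["target"], set())
            if terms & retained_terms:
                keep_rows.append(idx)
    return edges.loc[sorted(keep_rows)].reset_index(drop=True)


def infer_grn(
    expr: ExpressionMatrix | pd.DataFrame,
    regulator_set: RegulatorSet,
    partitions: dict[str, set[str]],
    params: GRNParams | None = None,
    annotation: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Full GRN stage: importances, thresholds, dimers, optional GO filter.

    ``partitions`` maps network context (shared / flower / vegetative) to
    its target gene set. Returns per-context annotated edge tables plus the
    raw thresholded edges under key ``"_raw"``.
    """
    params = params or GRNParams()
    frame = expr.values if isinstance(expr, ExpressionMatrix) else expr
    out: dict[str, pd.DataFrame] = {}
    raw_all = []
    for context, targets in partitions.items():
        targets = sorted(set(targets) & set(frame.index) - set(regulator_set.regulators))
        if not targets:
            out[context] = pd.DataFrame(
                columns=["regulators", "target", "weight", "network", "dimer",
                         "bifc_validated", "strength"]
            )
            continue
        weights = genie3_importances(frame, regulator_set.regulators, params, targets=targets)
        edges = threshold_edges(weights, context, params)
        raw_all.append(edges)
        annotated = annotate_dimers(edges, regulator_set)
        if annotation is not None:
            annotated = go_filter_targets(annotated, annotation)
        out[context] = annotated
    out["_raw"] = (
        pd.concat(raw_all, ignore_index=True) if raw_all else pd.DataFrame()
    )
    return out
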