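# budnet

Analysis pipeline for winter transcriptional programs in temperate fruit-tree
buds. Peach (*Prunus persica*) flower and vegetative buds experience identical
winters yet run different developmental programs; `budnet` provides the
computational stages used to dissect that divergence from bulk RNA-seq time
courses sampled along chilling-unit accumulation:

1. **Environmental traits** — Utah-model chilling units (CU) from hourly (or
   daily min/max) temperature records, and day length (LOD) from the sunrise
   equation, assembled into a per-sample trait table.
2. **Expression preparation** — TMM normalisation, log2-CPM transform,
   removal of multi-year batch structure, per-gene across-timepoint tests
   with BH correction, and the FC/FDR gates producing the global DEG set
   (FC ≥ 1.4, FDR < 0.05) and the stricter network set (FC ≥ 1.5, FDR < 0.01).
3. **Organ bias** — per-gene linear model `expression ~ Condition +
   Timepoint` (coefficient = flower − vegetative), flower/vegetative/balanced
   classification, and a genes-as-points PCA of shared genes with
   organ-specific genes projected into the same space; PC1 is correlated with
   the condition coefficient.
4. **Co-expression modules** — soft-thresholded correlation network,
   topological overlap, average-linkage clustering with eigengene merging,
   and module–trait (CHILLING/LOD) Pearson correlations with hypergeometric
   GO enrichment per module.
5. **Reduced co-expression graph** — per-gene top-5 partners by Pearson r,
   union, r ≥ 0.75 floor, isolated nodes dropped, node degree binned
   ({1}, {2–4}, {5–6}, {7–9}, {≥10}).
6. **Gene regulatory networks** — tree-ensemble (GENIE3-style) importances of
   DAM1–6/SVP1–2 regulators per target (500 trees, √p candidate features,
   importances normalised to sum to 1 per target), strict thresholding at
   0.30 (flower) / 0.36 (vegetative) / 0.27 (shared), edge-strength bands
   (<0.3 weak, 0.3–0.5 moderate, >0.5 strong), and homodimer/heterodimer
   annotation guided by a BiFC protein-interaction table.

A synthetic-data module generates negative-binomial count time courses with
planted co-expression modules, organ-biased genes, batch structure and a
regulator→target network, so every stage is testable against known ground
truth without downloading data.

## Worked example

Day length at the sampling site (Legnaro, Italy) for the first sampling
date of the time course:

```python
>>> from budnet.environment import day_length
>>> round(day_length("2021-09-08", 45.35, 11.96), 2)
12.91
```

Planted-module recovery with anti-correlated environmental drivers — two
60-gene modules, one rising and one falling with chilling accumulation:

```python
from budnet.synthetic_data import SimulationConfig, simulate_expression
from budnet.expression_prep import normalize_log_cpm
from budnet import coexpression_modules as cm

cfg = SimulationConfig(n_genes=120, module_sizes=(60, 60),
                       trait_profiles=("chilling_up", "chilling_down"),
                       noise_dispersion=0.05, seed=1)
matrix, truth = simulate_expression(cfg)
logm = normalize_log_cpm(matrix).values
model = cm.adjacency_tom(logm, soft_power=6, adjacency_type="signed")
mods = cm.detect_modules(model, logm, min_module_size=30)
traits = (matrix.sample_meta.reset_index()
          .merge(truth.trait_curves, on="timepoint")
          .set_index("sample_id")[["CHILLING", "LOD"]])
print(cm.module_trait_correlation(mods.eigengenes, traits))
```

prints (r rounded, p in scientific notation):

```
module    trait      r       p
    M1 CHILLING  0.978 1.0e-24
    M1      LOD -0.978 1.0e-24
    M2 CHILLING -0.979 3.2e-25
    M2      LOD  0.979 3.2e-25
```

Both planted modules are recovered exactly (60 + 60 genes) and carry the
planted signed trait pattern: M1 rises with chilling and falls with day
length, M2 the reverse — the signature the module–trait heatmap of a real
bud time course displays.

The full pipeline runs end-to-end on a synthetic demo with

```bash
budnet run --outdir demo_out --seed 7
```

writing counts, the DEG table and Venn partition, the organ-bias table and
PCA scores, module assignments and trait correlations, the reduced
co-expression graph and the per-context GRN edge tables, plus a manifest
with a SHA-256 hash per artifact (identical seed ⇒ identical hashes).

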