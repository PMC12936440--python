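# Methods

This note documents the models and procedures implemented in `budnet`, the
assumptions behind them, the defaults that matter, and what the synthetic
data generator does and does not emulate.

## Environmental covariates

**Chilling units.** Hourly temperatures are weighted with the Utah model's
piecewise-constant bands (Richardson 1974): 0 for T ≤ 1.4 °C; 0.5 for
1.5–2.4; 1.0 for 2.5–9.1; 0.5 for 9.2–12.4; 0 for 12.5–15.9; −0.5 for
16.0–18.0; −1.0 above 18 °C. Band edges are kept at the published
one-decimal resolution; a temperature between edges falls in the band whose
upper edge it does not exceed. Accumulation is the cumulative sum of hourly
contributions from a configured start date. Negative daily totals are
**not** clamped by default — warm spells subtract chill — because no single
convention is standard; `clamp_daily_negative=True` switches to clamping.
Daily min/max records are first reconstructed to hourly values with a
two-segment half-cosine (minimum near sunrise, maximum at 14:00 local),
standard practice when only daily extremes are archived. Gaps longer than
24 h abort with an error naming the gap: silently bridging a missing week
of winter would bias the accumulated total.

**Day length (LOD).** Sunset minus sunrise from the standard sunrise
equation, with a zenith of 90.833° (34′ refraction + 16′ solar radius) and
the NOAA solar-position declination (true solar longitude and obliquity of
date). The simpler textbook declination approximations disagree with
published sunrise tables by up to 0.13 h at mid-latitudes on some autumn
dates, which exceeds the 0.1 h agreement we target; the NOAA form tracks
the sampling-calendar values to within 0.06 h across the whole window.
Latitudes at or beyond 66.5° are rejected rather than special-cased — polar
day/night handling is out of scope. The default site is Legnaro, Italy
(45.35 N, 11.96 E), configurable everywhere.

## Synthetic data generator

Counts are negative binomial around a log-linear mean:

    mu[g,s] = lib_factor[s] · exp( baseline[g] + loading·driver(t, organ)
                                   + organ_bias + regulator_effect·x_R
                                   + batch_offset[g, batch] )

with gene-wise baseline ~ N(log 200, 0.8²), NB dispersion φ (variance
μ + φμ², φ = 0 giving Poisson), and per-sample library sizes uniform in
0.8–1.2 M. The design mirrors a two-organ × six-timepoint ×
three-replicate winter time course: CHILLING rises linearly 0 → 930 CU and
LOD falls 12.85 → 8.72 h over the window (the anchor values of the real
sampling calendar), so the two cues are exactly anti-correlated, as their
real counterparts nearly are. Module genes load on the z-scored trait
curves; organ-biased genes (half flower-up, half vegetative-up) receive a
log2-scale offset in one organ; planted regulators get distinctive
noise-free profiles from a small temporal/organ basis and each target's
log-mean adds `regulator_effect` times its regulator's standardized
profile, which makes importance-based recovery well-posed. Batch offsets
are gene-wise Gaussian per batch, shared across organs, with replicates
split across two batches inside every organ × timepoint group — the
simplest structure an ANOVA-decomposition correction can remove and a
deliberate simplification of the real design, where batches align with
sampling years.

What the generator does **not** emulate: read-level artifacts, isoforms and
mapping bias, gene–gene correlation beyond the planted modules, GC/length
effects, outlier samples, or batches confounded with timepoints. Passing
recovery tests therefore demonstrate that each stage extracts the signal it
claims to extract under its stated noise model — not that the stages are
robust to every pathology of real RNA-seq.

Everything is a pure function of (configuration, seed); the same seed gives
a byte-identical dataset.

## Normalisation and differential expression

TMM factors follow the trimmed-mean-of-M-values definition: reference =
sample whose upper-quartile (counts/library) is closest to the mean
upper-quartile; per-sample M and A values over genes positive in both;
double trim (30 % by M, 5 % by A, rank-based with the floor(n·trim)+1 …
n−floor(n·trim) retention window); precision-weighted mean of retained M
values via delta-method weights; factors rescaled to geometric mean 1.
log2-CPM uses effective library sizes (library × factor) and a pseudocount
of 1 on the CPM scale, so a zero count maps to 0 and doubling all counts
and libraries changes nothing.

Batch correction is an ANOVA-decomposition + PCA-denoising core: per-gene
organ × timepoint means are removed, principal components of the residual
matrix whose sample scores correlate with a batch indicator at |r| > 0.7
are subtracted, and the removed piece is re-centred within groups so group
means are preserved exactly (to 1e−8 in tests). A batch nested inside a
single group is uncorrectable and is left alone with a warning. The
component count (default 1, more if requested) and the 0.7 confounding
threshold are exposed.

The differential-expression statistic is a per-gene one-way ANOVA F-test
across timepoints on log2 data, with BH adjustment across genes and
per-contrast log2 fold changes against the first timepoint. This is a
transparent surrogate for noise-distribution-based DE engines; the
downstream gates are what the pipeline actually consumes and they are
applied verbatim: global DEG set at max |log2FC| ≥ log2 1.4 (boundary
inclusive) and min FDR ≤ 0.05, network input set at 1.5 / 0.01. "Overall
fold change" is read as the maximum absolute contrast against the first
timepoint; a union-over-contrasts reading of the DEG definition.

## Organ-bias classification and projection PCA

Each gene's log2 profile is fitted with least squares on
`intercept + Condition + Timepoint(categorical)`; the Condition coefficient
is flower minus vegetative (the sign convention used everywhere), and its
two-sided t-test p-value is BH-adjusted across genes. Classification:
flower-biased if coef ≥ +log2 1.5 with adjusted p < 0.05, vegetative-biased
if ≤ −log2 1.5, balanced otherwise; both thresholds are explicit,
configurable defaults. Organ specificity is a separate presence call
(expression ≥ 1 CPM in ≥ 2 samples of an organ; specific = present in
exactly one organ) and is deliberately independent of the bias category.

The PCA treats genes as observations and organ × timepoint mean expression
as features. Each gene's feature vector is z-scored across features before
the centered PCA (`scale_genes=True`): without this, ~86 % of gene-to-gene
variance is overall abundance and PC1 carries no organ information; with
it, PC1 aligns with the flower–vegetative axis and correlates strongly
(|r| ≈ 0.9 on planted data) with the condition coefficient. Organ-specific
genes are projected into the shared-gene space by the same transformation;
because the row scaling uses only the projected gene's own values,
projecting a training gene reproduces its stored score to 1e−10.
Per-sample features instead of group means are supported.

## Co-expression modules

Unsigned adjacency a = |r|^β (signed a = ((1+r)/2)^β available), soft
power chosen as the smallest β whose scale-free fit R² ≥ 0.8 (log-log
regression of binned degree frequency on mean degree, slope required
negative; fallback 6 with a warning). Topological overlap
TOM = (Σ_u a_iu·a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij), diagonal 1.
Modules: average-linkage clustering of 1 − TOM, static cut at 0.99,
clusters below 30 genes unassigned, iterative merging of modules whose
eigengenes correlate above 0.75, labels ordered by descending size.
Eigengenes are the first principal component of gene-standardized module
expression, sign-oriented to correlate positively with the module mean
profile. Module–trait association is Pearson r with the t-distribution
p-value on n − 2 degrees of freedom. GO enrichment per module is the
one-sided hypergeometric tail with BH across terms.

Two structural caveats, established during design and reflected in the
tests: (i) an *unsigned* network cannot separate two modules driven by
perfectly anti-correlated covariates — between-module |r| equals
within-module |r| — so recovery analyses of oppositely-driven modules use
the signed adjacency; (ii) under a static cut, unassigned background genes
can chain otherwise well-separated clusters through the TOM inflation that
low-connectivity nodes experience, so recovery is assessed on the planted
blocks themselves. Dynamic tree cutting is not implemented.

## Reduced co-expression graph

The literal three-step rule: per gene keep the 5 most highly correlated
partners by **signed** r (descending, ties broken by lexicographic partner
id), take the union of candidate edges over genes, discard edges below
r = 0.75 (boundary inclusive), drop isolated nodes. The union rule — rather
than mutual top-k — is what allows hubs of degree ≥ 10 under k = 5, the
degree class the display bins single out ({1}, {2–4}, {5–6}, {7–9}, {≥10};
the {1} bin is an extension below the smallest published display bin).
Ranking by |r| is available behind a flag but with the 0.75 floor the
signed reading already excludes every negative edge. Graph invariants
(floor, top-k membership, no isolates) are asserted on every build.

## Regulatory network inference

For each target, a Random Forest regression of its standardized profile on
the 8 candidate regulators (DAM1–6, SVP1, SVP2): 500 trees, ⌊√p⌋ candidate
features per split, importance = impurity reduction share normalised to
sum to 1 per target, fully seeded (per-target seeds derived from one
SeedSequence). A regulator never predicts itself but may be a target of
the others. With only 8 candidate features, √p sampling lets deep splits on
noise features claim part of the impurity, so even a target that is an
exact copy of its regulator yields an importance near 0.4 — dominant
(2.5–4× the best decoy across seeds) rather than near 1; ranking quality is
the meaningful property, and on the planted network (40 true edges among
3 840 candidates) the ranked list attains AUPR ≈ 80× the random baseline.

Edges survive a strict `weight > τ` test with per-context τ: flower 0.30,
vegetative 0.36, shared 0.27 (taken as given parameters; their derivation
from the weight distributions is not modelled). Strength bands: <0.3 weak,
0.3–0.5 moderate (both boundaries inclusive), >0.5 strong. Dimer
annotation makes the narrative regulatory logic explicit and algorithmic:
within a (target, network), BiFC-positive pairs among the retained
regulators are merged greedily by descending combined weight into
heterodimer edges (validated, weight = pair mean); leftover regulators are
homodimer edges; BiFC-negative pairs are never merged (asserted on every
run). The default interaction table records the positive pairs SVP1–DAM3,
SVP1–DAM5, SVP1–DAM6 and DAM5–DAM6 and the negative pair DAM6–DAM3;
everything else is untested, and the table is fully user-overridable. The
optional GO filter keeps edges whose target carries at least one term
enriched (hypergeometric + BH, adjusted p < 0.05) in that network's target
set; unannotated targets drop out of the visual set only.

## Pipeline and reproducibility

One global seed is fanned out to per-stage sub-seeds through
`numpy.random.SeedSequence.spawn`, so stages are independently
reproducible. Every artifact is a TSV/CSV/JSON file listed in a manifest
with its SHA-256 hash; identical configuration + seed reproduces identical
hashes. A failing stage aborts with the stage named and `.partial` markers
next to the outputs already written. Unknown configuration keys are
rejected, and the fully resolved configuration is written next to the
outputs.

## Problem sizes used in the test suite

Recovery analyses run at the scale their claims refer to: organ bias on
500 genes (30 % biased, log2 effect 1.5, dispersion 0.05), module recovery
on 2 × 60 planted genes, and the regulatory network at 8 regulators ×
(40 planted targets + 400 decoys) × 500 trees. Unit tests use smaller
designs (tens of genes, ≤ 200 trees) chosen so each property is already
decidable there.

## Known limitations

* The DE statistic is a surrogate; absolute DEG counts from the real study
  design are not reproducible here and are not targeted.
* Static tree cut only; dynamic hybrid cutting and blockwise decomposition
  for >20 k genes are not implemented.
* The dimer-assignment rule is an explicit interpretation of regulatory
  logic that the source analyses state only as outcomes.
* Chill accumulation supports the Utah model only (no dynamic/chill-portion
  or growing-degree-hour models).
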