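# Methods

## Scientific setting

Soil is spatially structured down to the millimetre scale: aggregates a
few milligrams in mass behave as partially isolated microbial
communities. Sampling the same soil at decreasing mass therefore trades
averaging for resolution — a 250 mg sample homogenises hundreds of
microhabitats and looks the same every time, while a 1 mg sample or a
single ~5 mg aggregate captures a handful of microhabitats and differs
from its neighbours. The package implements the analysis chain that
quantifies this: contaminant filtering against no-soil controls,
community structure in Aitchison geometry, and co-occurrence network
inference at aggregate resolution, together with a generative model that
reproduces these phenomena with known ground truth.

## The synthetic generator

### Microhabitat-mixture model

A pool of `n_microhabitats` community profiles is drawn once per
experiment. Profile weights are i.i.d. lognormal per taxon
(`lognormal_sigma`), closed to sum 1. A sample of mass *m* mg mixes
`round(m * microhabitats_per_mg)` profiles drawn with replacement
(minimum 1); an aggregate instead draws a single contiguous block of
`aggregate_fraction` as many profiles from the ring of microhabitats —
a spatially coherent unit that holds fewer, more correlated
microhabitats than equal-mass bulk soil. Expected 16S copies are the
mass-weighted mixture times `carrying_density`, with Poisson noise.
Homogenate aliquots are binomial thinnings of a pooled two-extract copy
vector, so all aliquots share one expected composition. Every extract
(including the no-soil controls) receives Poisson reagent contamination
from a disjoint contaminant taxon pool at a fixed absolute load, and is
sequenced multinomially at a lognormally varying depth.

### Planted associations

Taxa named in a `PlantedAssociation` carry an enrichment indicator over
the microhabitat ring: `enrich_segments` contiguous arcs covering a
fraction `enrich_prob` of the ring. Spatial contiguity matters — soil
properties vary smoothly at this scale, and it is what lets a contiguous
aggregate block be coherently "on" or "off" for a taxon rather than
averaging the state away. A strength-1 positive association copies the
partner's arcs exactly; a negative one complements them; strength < 1
mixes in an independent arc set per microhabitat. Enriched association
taxa take relative weight `enrich_abundance` (default 0.6, i.e. ~2% of
a 30-taxon community — minor members, like real co-occurrence network
hubs), non-enriched `enrich_abundance / enrich_boost` (~25-fold lower,
effectively absent).

Two failure modes shaped these choices, and both are worth knowing about
when interpreting benchmark results on other generators:

1. **Closure leakage.** If association taxa swing between, say, 30% and
   0.1% of the composition, their on/off state drags every other taxon's
   relative abundance along through the sum constraint, creating strong
   apparent correlations among *all* taxa pairs. The ReBoot null cannot
   absorb third-party closure effects (its renormalisation only involves
   the two focal taxa), so the planted signal must be kept a minor part
   of the composition.
2. **Arc overlap.** Independent associations whose arcs happen to
   overlap produce genuine (not spurious) cross-pair correlations.
   Splitting the covered fraction into many short segments
   (`enrich_segments = 12`) shrinks the realised overlap variance; the
   residual overlap is the main source of false-positive edges in the
   recovery benchmark.

### Defaults and what they emulate

| parameter | default | rationale |
|---|---|---|
| `n_taxa` | 150 | abundant fraction of a soil community after a 0.1–0.2% filter |
| `n_microhabitats` | 1024 | large enough that 37 aggregate blocks rarely overlap |
| `lognormal_sigma` | 1.0 | inter-microhabitat dispersion; drives the mass–heterogeneity gradient without generating heavy-tailed chance correlations |
| `microhabitats_per_mg` | 4.0 | spatial grain: a 1 mg sample holds ~4 microhabitats, 250 mg ~1000 |
| `aggregate_fraction` | 0.5 | an aggregate holds about half the microhabitats of equal-mass loose soil, contiguously |
| `carrying_density` | 1e5 copies/mg | scaled-down prokaryotic load; only ratios to the contaminant load matter downstream |
| `contaminant_copies_per_extract` | 7.5e5 | fixed kit-derived load: ~3% contaminant reads in a 250 mg extract, ~100% in controls, majority in ≤5 mg extracts |
| `depth_mean`, `depth_dispersion` | 20 000, 0.2 | per-sample lognormal depth variation around a typical amplicon run |
| `enrich_prob`, `enrich_segments` | 0.3, 12 | ~40% of aggregates intersect an association's arcs; short segments limit chance arc overlap |
| `enrich_abundance`, `enrich_boost` | 0.6, 25 | conditional presence at ~2% vs ~0.08% relative weight |

The generator reproduces the *qualitative* study phenomena — the
within-group Aitchison distance ordering 1 > 5 > 25 ≥ 250 mg, flat
homogenate aliquots with a small 1 mg-equivalent elevation,
contaminant-dominated controls, and association recovery from aggregates
but not from bulk — not any real dataset's SV counts, richness, or
coverage values. It contains no chimeras, no sequencing error model, no
phylogenetic structure, and its microhabitats are an abstract ring, not
a 3-D pore geometry. Passing tests therefore demonstrate correctness of
the analysis chain under the model's assumptions, not performance on
real amplicon data.

## Filtering rules

Thresholds are compared inclusively (≥). The contaminant rule is scoped
per experiment (each table carries its own controls); control relative
abundances are computed on the unfiltered table. Abundance filters
recompute relative abundances on the sample set actually being compared,
after any prior subsetting. Order of operations is fixed: contaminant
removal → abundance filter → (CZM → CLR → distances/PCA, or network).

## Compositional stage

CZM zero replacement imputes, per sample with total *N*, each zero as
`0.65 / (N + 1)` and multiplicatively rescales the nonzero proportions —
the published default of the count-zero-multiplicative scheme; the
constant is exposed (`czm_replace(table, f=...)`) for sensitivity
checks. CLR uses the natural log and per-sample geometric means; PCA is
a centred SVD of the CLR matrix with no unit-variance scaling, the
standard choice in Aitchison geometry. Aitchison distance is the
Euclidean distance of CLR columns (`scipy.spatial.distance.pdist`).

## Ensemble network inference

### Scores and preselection

Pearson and Spearman act on relative abundances across samples; mutual
information uses equal-frequency binning with `floor(sqrt(n_samples))`
bins (natural log), with rank ties broken by stable sample order so the
discretisation is deterministic; Bray–Curtis is Σ|x−y| / Σ(x+y);
Kullback–Leibler is the symmetrised (Jeffreys) divergence of the two
SVs' sample profiles, each closed to sum 1 after adding the 1e-8
pseudocount. Per metric, the `k_preselect` highest and lowest scoring
pairs are kept (ties broken lexicographically by pair position);
the candidate set is the union. Pairs with undefined scores (constant
SV under a correlation) are excluded from that metric's ranking with a
warning.

### ReBoot null and bootstrap

For each candidate edge one set of `n_perm` permutations is drawn and
**all** of the edge's metrics are evaluated on the same permuted data —
this preserves the inter-metric dependence that Brown's method later
estimates. Each permutation shuffles the two focal SVs independently
across samples and re-closes every sample's full composition to sum 1;
the re-closure keeps the two-taxon compositional coupling in the null.
Bootstrap draws resample samples with replacement, again shared across
metrics. An edge metric is *stable* if its observed score lies inside
the inclusive [2.5th, 97.5th] percentile interval (linear interpolation)
of its bootstrap distribution; if more than half the bootstrap
replicates are degenerate the metric is unstable.

Mutual information is exempted from the stability veto: duplicated
samples in a bootstrap draw concentrate the binned joint histogram, so
bootstrap MI is systematically *higher* than the observed value and the
percentile test would reject exactly the strongest MI edges. Its
stability flag is still computed and reported.

### p-values: why empirical counting

The per-metric p-value is the add-one two-sided empirical tail about the
null mean, `p = (1 + #extreme) / (n_perm + 1)`. Two alternatives were
evaluated and rejected for the default:

- a **Gaussian fit** to the null (the classical ReBoot construction,
  available as `p_method="gaussian"`) extrapolates far into a tail the
  permutation distribution does not have — count data make per-pair
  nulls heavy-tailed and pair-specifically shaped, and under the global
  null the Gaussian tail produced spurious networks in the large
  majority of runs;
- **pooling standardised null scores across edges** to refine the tail
  resolution breaks the conditional (per-pair) calibration that makes a
  permutation test exact, for the same reason: the null's tail shape is
  pair-specific.

Empirical counting floors p at `1/(n_perm + 1)`; evidence beyond the
floor is recovered at the ensemble level, because Brown's method merges
the five metrics' floored p-values with an empirically estimated
dependence — three nearly independent metrics at the floor merge to a
much smaller value than three redundant ones. The fold-about-the-mean
two-sided construction is only approximately uniform for skewed nulls
(mild liberality at small α for a single fixed pair, KS-indistinguishable
from uniform at n = 200); the downstream BH stage over the full candidate
family more than absorbs it, as the global-null calibration shows.

### Sign, support, merging, correction

Edge sign per metric is +1 (co-presence) when the observed score is
above the null mean for similarity metrics or below it for dissimilarity
metrics. Mutual information cannot orient an association — exclusion
raises MI just as co-presence does — so in ensemble assembly MI is
sign-agnostic and supports the consensus sign of the signed metrics;
the consensus is the majority sign among eligible signed metrics, ties
resolved toward the smallest p. Strict-mode support counts preselecting,
stable (MI exempt), sign-consistent metrics.

Brown's method: with m supporting p-values, `X = −2 Σ ln p_i` is
referred to a scaled χ² with `c = Var/(2E)`, `df = 2E²/Var`, `E = 2m`,
`Var = 4m + 2 Σ_{i<j} cov(−2 ln p_i, −2 ln p_j)`, covariances estimated
from the per-permutation p-values of the shared null. Independence
recovers Fisher's method; perfect dependence recovers the single p.

BH correction spans **every tested candidate edge** (any candidate with
at least one supporting metric), not only those surviving the stability
and support filters. Preselection is a computational shortcut, not a
hypothesis reduction: restricting the BH family to the few edges that
survive all filters re-tests only the selected extremes and destroys
error control under the global null, which is exactly the regime the
lenient/strict contrast in sparse data probes. The stability, ≥3-metric
support, and q ≤ 0.05 filters then prune the final strict edge set;
lenient mode skips stability, support, and BH, keeping merged p ≤ 0.05.

### Determinism and degenerate inputs

A root seed spawns one `SeedSequence` child per candidate edge in sorted
pair order, so results are bit-reproducible and individual edges can be
re-evaluated in isolation. Fewer than three samples, fewer than two SVs
after the 0.2% filter, or an empty candidate set yield an explicit empty
network rather than an error. Degenerate (NaN) null or bootstrap scores
are dropped; a metric whose entire null is degenerate contributes no
evidence.

## Topology

Degree, connected components and unnormalised Brandes betweenness come
from networkx; signs are ignored for topology (a `positive_only` flag
restricts to co-presence edges). Betweenness is reported as a ranked
list — no numeric "keystone" cutoff is imposed. GraphML export carries
node abundance/degree/betweenness and edge sign/support/p/q attributes
and round-trips losslessly.

## Problem sizes used by the test suite

The packaged checks run at desk scale: 200 permutations and 200
bootstraps per edge, k = 50 preselection for the 30-taxon global-null
calibration (100 tables of 40 samples), and k = 35 for the 30-taxon /
37-aggregate recovery benchmark (20 seeds; k scaled so that preselection
retains a comparable fraction of all pairs as a k = 1000 run on a
~270-SV table). Production analyses should use the 1000/1000/1000
defaults of `NetworkConfig`.

## Known limitations

- The generator's microhabitat ring has no 3-D structure, no distance
  decay within bulk samples, and its association mechanism (shared
  enrichment arcs) is one of many conceivable ones.
- The stability filter's percentile construction assumes the bootstrap
  distribution of a score is roughly centred on the observed value;
  beyond the MI exemption above, strongly biased statistics would need
  the same treatment.
- Brown's covariance is estimated from `n_perm` shared permutations per
  edge; at very small `n_perm` the estimate is noisy and merged p-values
  for borderline edges fluctuate between runs with different seeds.
- The empirical p floor ties achievable q-values to
  `n_perm × (BH family size)`; very sparse true-edge structures need
  larger `n_perm` to be detectable at q ≤ 0.05.
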