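# aggregatomics

Aggregate-scale analysis of soil prokaryotic communities: how small can a
soil sample get before its 16S amplicon profile stops representing the
bulk soil — and what do single soil aggregates (~2 mm, ~5 mg) reveal that
a homogenised 250 mg sample averages away?

The package is aimed at microbial ecologists working with sequence-variant
(SV/ASV) count tables from soil sampled at multiple masses, and at method
developers who need a ground-truthed benchmark for co-occurrence network
inference on compositional count data. It provides:

- **Contaminant filtering** against no-soil extraction controls: any SV
  with relative abundance ≥ 0.1% in at least one control of an experiment
  is a potential reagent contaminant and is removed, with per-sample
  read-fraction diagnostics.
- **Compositional community structure**: count-zero-multiplicative (CZM)
  zero replacement, centred log-ratio (CLR) transform, Aitchison
  distances (Euclidean distance of CLR columns), within-group distance
  summaries and PCA — the standard Aitchison-geometry workflow for
  relative-abundance data.
- **Ensemble co-occurrence networks**: five association metrics (Pearson,
  Spearman, mutual information, Bray–Curtis, symmetrised
  Kullback–Leibler), preselection of the *k* highest- and lowest-scoring
  pairs per metric, ReBoot significance (permutation nulls with
  per-sample renormalisation to absorb compositional artifacts, plus
  bootstrap stability intervals), Brown's dependent-p-value merging,
  Benjamini–Hochberg correction, and strict/lenient assembly modes.
- **A synthetic generator** of aggregate-scale communities built on a
  microhabitat-mixture model, with planted pairwise associations as
  ground truth, reagent contamination, homogenate controls, and the
  sample layouts of three in-silico experiments.

## The model in brief

A sample of mass $m$ mixes $round(m \cdot \rho)$ microhabitats from a
fixed pool of lognormal community profiles ($\rho$ = microhabitats per
mg); single aggregates draw one contiguous block of fewer microhabitats.
Reads are multinomial draws from the Poisson-noised copy-number mixture
plus a fixed reagent-contaminant load. For a candidate edge between SVs
$x$ and $y$, the ReBoot null score distribution is obtained by permuting
$x$ and $y$ independently across samples, re-closing every sample's
composition to sum 1, and rescoring; the edge p-value is the two-sided
empirical tail probability about the null mean with add-one correction,

$$p = \frac{1 + \#\{|s^{null} - \bar s^{null}| \ge |s^{obs} - \bar s^{null}|\}}{n_{perm} + 1}.$$

Per-edge p-values from the supporting metrics are merged with Brown's
scaled-$\chi^2$ method, with the covariance of $-2\ln p_i$ estimated
empirically from the shared permutation null, and BH-corrected across
all tested candidate edges.

## Worked example

Simulate 37 single aggregates with two planted associations — SV1–SV2
co-presence and SV3–SV4 exclusion — filter contaminants, and infer the
strict-mode network:

```python
import aggregatomics as ag
from aggregatomics.network import NetworkConfig, build_network
from aggregatomics.simulate import SimConfig, generate_experiment
from aggregatomics.topology import topology_summary

config = SimConfig(
    n_taxa=30,
    associations=[
        ag.PlantedAssociation("SV1", "SV2", sign=1),
        ag.PlantedAssociation("SV3", "SV4", sign=-1),
    ],
    seed=2,
)
design = [("aggregate", 5.3, 37), ("control", 0.0, 6)]
table, metadata, truth = generate_experiment(design, config)

flagged = ag.flag_contaminants(table, metadata)
filtered, removed = ag.remove_svs(table, flagged)

net_config = NetworkConfig(n_perm=200, n_boot=200, k_preselect=35, seed=2)
result = build_network(filtered, metadata, net_config, group="aggregate_5.3mg")
```

Output:

```
simulated table: 60 SVs x 43 samples
contaminants flagged: 30; median read fraction removed from aggregates: 0.582
strict network: 5 nodes, 3 edges (from 203 candidate pairs)
  SV1 -- SV2: sign +1, support 3/5, merged p 4.13e-05, q 0.008
  SV1 -- SV20: sign -1, support 4/5, merged p 4.77e-04, q 0.026
  SV3 -- SV4: sign -1, support 4/5, merged p 5.08e-04, q 0.026
components: [3, 2]; top degree: SV1
```

Both planted associations are recovered with their planted signs at
q ≤ 0.05 (one extra edge, SV1–SV20, is a false discovery — at q ≤ 0.05
occasional false edges are expected). A 5.3 mg aggregate extract carries
more reagent-contaminant reads than a 250 mg extract, hence the large
removed fraction; the filter takes them out before any analysis.

The three experiment layouts (mass series 250→1 mg; homogenate aliquot
controls; 250 mg vs single aggregates) run end-to-end from the command
line:

```bash
aggregatomics run-experiment --preset experiment3 --seed 1 --out out/e3 \
    --n-perm 1000 --n-boot 1000
aggregatomics simulate --preset experiment1 --seed 1 --out out/sim
aggregatomics filter --table out/sim/sv_table.tsv --metadata out/sim/metadata.tsv --out out/filt
```

Each run writes tab-delimited tables (SV matrix, metadata, distance
matrices, edge lists), GraphML networks, topology summaries, and a YAML
snapshot of the fully resolved configuration.

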