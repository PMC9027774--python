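# comethyl

Co-methylation network analysis for methylation-array cohort studies.

`comethyl` takes a probes × samples methylation matrix (β values, or paired
methylated/unmethylated signal intensities) for a two-group cohort — e.g.
drug-hypersensitive cases versus drug-tolerant controls — and carries it
through the full weighted-network workflow used in array-based epigenomics:

1. **Normalization and value scales.** β = M/(M + U + α) with the array
   offset α (default 100); M values are the logit, M = log₂(β/(1 − β)).
   Tests and correlations run on the M scale; effect sizes are reported as
   Δβ. Between-sample quantile normalization stands in for raw-data
   normalization.
2. **Differential positions and regions (DMPs/DMRs).** Per feature: a
   two-sample t-test on M values, Benjamini–Hochberg FDR, and a *combined
   rank* — each feature ranked by |Δβ|, by p, and by q, keeping the worst of
   the three. Regions (promoter, gene, tiling window, CpG island) are
   per-sample means of member-probe M values; promoter screening uses only
   annotated protein-coding promoters.
3. **Weighted co-methylation network** on promoter M profiles: unsigned
   adjacency a_ij = |cor(x_i, x_j)|^β′ with a soft-thresholding power β′
   chosen for scale-free topology (or fixed, e.g. 14); topological overlap
   TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij)/(min(k_i, k_j) + 1 − a_ij);
   average-linkage clustering of 1 − TOM with eigengene merging at height
   0.15. Modules are named by size-ordered colors (turquoise = largest,
   grey = unassigned).
4. **Eigengenes, hubs, enrichment.** Module eigengene ME = first principal
   direction of the standardized member profiles; gene significance
   GS = −log₂(p); module membership MM = cor(x_i, ME); hubs are the top-20
   features by MM per module; module gene lists are scored against GMT gene
   sets with the upper-tail hypergeometric (one-sided Fisher) test.

Because real cohort array data is rarely shareable, the package ships a
synthetic-data generator that plants co-methylation modules (latent
per-sample factors), group mean shifts on the M scale, and an intensity
model — so every stage can be validated against known ground truth.

## Worked example

```python
from comethyl import (SimulationConfig, simulate_dataset, compute_beta,
                      beta_to_m, CoMethylationNetwork)
from comethyl.differential import summarize_regions, test_features, combined_rank
from comethyl.conetwork import gene_significance, select_hubs
import pandas as pd

config = SimulationConfig(seed=7, n_promoters=300, n_modules=3,
                          loading_range=(0.7, 0.9), noise_sd=0.2,
                          n_differential=20)
sheet, intensities, annotation, truth = simulate_dataset(config)

m = beta_to_m(compute_beta(intensities))
promoters = summarize_regions(m, annotation, "promoter")
stats = combined_rank(test_features(promoters.as_methylation_matrix(), sheet))
net = CoMethylationNetwork(power=14).fit(promoters.values.T)

print("module sizes:", dict(net.assignment_.sizes()))
gs = pd.Series(gene_significance(stats["p_value"].reindex(promoters.values.index)),
               index=promoters.values.index)
print(select_hubs(net.module_membership_, gs, net.assignment_, "turquoise",
                  top_n=5).round(3))
```

prints

```
module sizes: {'turquoise': 60, 'blue': 60, 'brown': 60, 'grey': 120}
               module     MM     GS  gs_significant  hub_rank
feature_id
PROM_0057   turquoise  0.980  2.779           False         1
PROM_0025   turquoise  0.978  4.607            True         2
PROM_0008   turquoise  0.978  3.402           False         3
PROM_0049   turquoise  0.978  3.599           False         4
PROM_0028   turquoise  0.978  4.593            True         5
```

The three planted 60-promoter modules are recovered exactly (the 120
unstructured promoters fall into grey); the hub table ranks the turquoise
module's promoters by their correlation with its eigengene (MM), and
`gs_significant` marks those whose case/control difference clears
GS ≥ −log₂(0.05). With `n_differential=20` planted shifts, the top combined-
rank DMR in this run is `PROM_0237` (Δβ = 0.172, q = 7.6e-15).

The same analysis runs from the shell:

```sh
comethyl run --config config.yaml --out results/
```

with subcommands (`simulate`, `normalize`, `dmp`, `dmr`, `network`,
`modules`, `hubs`, `edges`, `enrich`) for individual stages. Every output is
a TSV under the run directory with a JSON manifest; a fixed seed reproduces
the directory byte for byte.

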