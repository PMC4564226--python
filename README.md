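# genegravity

A gene gravity model for the somatic evolution of cancer genomes.

Cancer cohorts show that a mutated gene can shape the subsequent mutational
landscape of a tumor: carriers of nonsynonymous mutations in certain genes
accumulate more mutations genome-wide, and interacting, co-expressed gene
pairs tend to be co-mutated. `genegravity` implements a quantitative model
of this effect for people analysing cohort-level mutation and expression
data (MAF-like mutation tables, gene × sample expression matrices) on a
protein interaction network (PIN).

## The model

Per-gene cumulative nonsynonymous mutation counts **M₀** are smoothed over
the PIN by random walk with restart,

```
M(t+1) = α Pᵀ M(t) + (1 − α) M₀,        P_ij = 1/k_i  for j ~ i,
```

with restart weight 1 − α back to the raw counts (α = 0.7 by default,
convergence when ‖ΔM‖₂ < 10⁻⁶; for α < 1 the fixed point is
(1 − α)(I − αPᵀ)⁻¹M₀). Separately, each PIN edge is annotated with the
Pearson correlation (PCC) of its endpoints' expression across the cohort
after a two-stage expressed-gene filter — the co-expressed PIN (CePIN).
Treating the propagated mass as gravitational mass and r = 1/PCC as
distance, each interacting pair gets a gravitation score

```
G_ij = k · M_i · M_j / r_ij² = M_i · M_j · PCC_ij²,      k = 1,
```

signed attractive/repulsive by the correlation's sign. The per-gene
summary **aveG** (mean G over a gene's scored partners) ranks genes by
their inferred pressure on genome evolution; set-level machinery compares
aveG and pair-level G between gene catalogues (drivers, CGC, chromatin
regulation factors, DNA-repair, essential, oncogenes, TSGs) using Wilcoxon
rank-sum tests with Benjamini–Hochberg control, Fisher's exact enrichment,
X-vs-autosome contrasts and mutation-density comparisons.

A fully seeded synthetic-data module generates network, expression,
mutation and metadata bundles with planted hot/co-expressed gene sets, so
the whole pipeline is testable without any cohort download.

## Worked example

```python
import genegravity as gg
from genegravity import synthdata, setstats

study = synthdata.synth_study("small", seed=11)        # 200 genes, 50 samples
filtered, kept = gg.filter_expression(study.expression)
cepin = gg.build_cepin(study.network, filtered)
m0 = gg.build_m0(study.mutations, study.network)
prop = gg.propagate(study.network, m0)                 # alpha = 0.7
table = gg.pairwise_gravity(cepin, prop)
scores = gg.aveg_scores(table, metadata=study.metadata,
                        degrees=study.network.degrees)

hot = study.ground_truth["hot_genes"]
planted = scores[scores.gene.isin(hot)].aveg
background = scores[~scores.gene.isin(hot)].aveg
print(f"median aveG planted {planted.median():.1f} "
      f"vs background {background.median():.2f}")
print(f"rank-sum p = {setstats.wilcoxon_rank_sum(planted, background).p:.3g}")
```

prints

```
median aveG planted 188.0 vs background 4.13
rank-sum p = 1.22e-11
```

— the twenty genes planted with a 10× mutation rate and 0.8 co-expression
with their partners dominate the aveG ranking, which is exactly the
high-gravity signature the score is designed to expose.

The same pipeline is available from the shell: `genegravity synth`,
`build-cepin`, `propagate`, `gravity`, `compare-sets`, `enrich-top`,
`x-chrom`, `density`, and `run` (YAML config, one output bundle with a
manifest); stages exchange plain TSVs.

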