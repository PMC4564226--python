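# Methods

## Model and assumptions

The package scores the pressure a gene exerts on cancer genome evolution
by combining two cohort-level signals on a protein interaction network
(PIN): how mutated a gene's network neighbourhood is, and how strongly
co-expressed a gene is with its interaction partners.

**Mutation propagation.** The initial mass M₀ᵢ is the cohort-cumulative
count of nonsynonymous mutation events in gene *i* (an option counts
distinct mutated samples instead; another divides by cDNA length, giving
mutations per bp). The mass is smoothed by random walk with restart,
M(t+1) = αPᵀM(t) + (1−α)M₀ from M(0) = M₀, with P the row-normalized
adjacency. Because P is row-stochastic, Pᵀ preserves the total mass, so
ΣM = ΣM₀ throughout (observed drift ≤ 10⁻⁹ relative). At α = 0 the output
is the raw counts; at α = 1 mass forgets M₀ and converges to the
degree-proportional state kᵢ/2N_L on connected non-bipartite graphs (on
bipartite graphs the pure walk oscillates; any α < 1 damps this). The model
assumes mutation influence travels along undirected physical interactions
and treats the cohort as a single aggregate — there is no per-sample
propagation.

**Co-expression distance.** A gene is *expressed* in a sample when its
value is at or above the sample's 20th expression percentile, and retained
when expressed in at least 20% of samples; both cutoffs are parameters.
Each surviving edge carries the Pearson correlation of its endpoints over
all cohort samples. The correlation is turned into a gravitational
distance r = 1/PCC, so G_ij = MᵢMⱼPCC²ᵢⱼ with the gravitation constant
fixed at k = 1 (not configurable — changing k rescales every score and
silently breaks cross-run comparability). G is kept as a non-negative
magnitude plus a sign class (attractive PCC > 0 / repulsive PCC < 0 /
null PCC = 0): cumulative-distribution analyses consume the magnitude,
attractive/repulsive analyses the class.

**Gene-level summary.** aveGᵢ = Σⱼ G_ij / nᵢ, where nᵢ is by default the
number of *scored* partners — edges that survived the expression filter
and have a defined correlation — rather than the raw PIN degree. G is
undefined on dropped edges, and dividing by the full degree would conflate
"weakly coupled" with "not measured"; a flag restores the PIN-degree
denominator for sensitivity analysis. avePCC uses |PCC| over the same
partners.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| α (restart tuning) | 0.7 | diffusion strength; 0 = no propagation, 1 = network-only. Results change little above ~0.7; `alpha_sweep` quantifies this via Spearman rank correlations between consecutive α values. |
| tol | 10⁻⁶ | L2 norm of the update at which the power iteration stops. |
| max_iter | 10,000 | iteration cap; exceeding it raises with the last residual. |
| sample_quantile | 0.20 | per-sample expression percentile below which a gene is unexpressed in that sample (ties at the threshold count as expressed). |
| sample_fraction | 0.20 | minimum fraction of samples a gene must be expressed in. |
| universe | 20,462 | protein-coding gene count behind catalogue enrichment tests. |
| significance | q < 0.1 | conventional reporting threshold; reported, never enforced. |

## Statistical machinery

Distribution contrasts use the Wilcoxon rank-sum test: full enumeration
over group assignments (with midranks for ties) when the combined sample
size is ≤ 20, otherwise the tie-corrected normal approximation; two-sided
p doubles the smaller tail and caps at 1. Benjamini–Hochberg families are
explicit inputs — the package never guesses which tests belong together —
and q-values are attached per declared family. Reported "±" values are
standard errors of the mean.

Catalogue enrichment (one set inside another against the genome) uses
Fisher's exact test on [[overlap, |A|−overlap], [|B|, N−|B|]], i.e. the
overlap rate within set A against set B's prevalence in the whole
universe; this is the construction that reproduces the published reference
examples (driver∩CRF p ≈ 3.1 × 10⁻²¹, driver∩DNA-repair
p ≈ 1.1 × 10⁻⁶ at the printed counts). Set-versus-set contrasts use a
plain two-sided 2×2 exact test. Top-n (default 100) aveG enrichment is
one-sided within the scored-gene universe, with ties at the boundary
broken by stable gene-identifier order. The interaction-pair benchmark
compares M₀ᵢ + M₀ⱼ on true edges against uniformly sampled non-adjacent
pairs (with replacement, seeded); the pair statistic is this package's
documented choice, as the original pair-density statistic is defined only
in earlier work.

## Numerical and degenerate-input choices

- Isolated nodes have no outgoing transition; they are given a unit
  self-transition, so mass placed on them stays put (fixed point
  Mᵢ = M₀ᵢ) and global conservation is retained.
- The closed-form solve (I − αPᵀ)M = (1−α)M₀ is refused at α = 1, where
  the resolvent is singular; the power iteration covers that limit.
- The operator is applied as a sparse matrix; a dense n × n array is never
  built, keeping >10⁴-gene networks tractable.
- Correlations are clipped into [−1, 1] to absorb floating-point spill;
  constant expression vectors make the correlation undefined and drop the
  edge (counted, never imputed).
- An exact PCC of 0 keeps its edge with sign class "null" and G = 0.
- Edge lists are cleaned on load (self-loops dropped, duplicates in either
  orientation collapsed); loading is idempotent and order-independent, and
  a cleaned network with no edges at all is rejected.
- All TSV writers serialize floats with 17 significant digits so that
  file-mediated pipelines reproduce in-process results exactly; the cost
  is marginally larger files.
- Nonsynonymous variant classes default to the standard MAF set (missense,
  nonsense, nonstop, splice site, translation start site, frame-shift and
  in-frame indels) and are configurable, since upstream callers differ.

## The synthetic-data generator

`synth_study` emulates the cohort inputs at desk scale with known ground
truth: a preferential-attachment network (largest component kept), an
expression matrix with planted co-expression, a Poisson mutation table
with planted hot genes and hypermutated carrier samples, chromosome labels
(X for ~5% of genes) and log-normal cDNA lengths (median ~2 kb,
exercising the length-normalized path).

Planted co-expression uses a latent factor per star: a hub gene and its
partners all load √|ρ| on a shared standard-normal factor (partners signed
by the target), giving population correlation exactly ρ on each planted
edge — the simplest construction with a closed-form target. A consequence
is that planted edge sets must form stars; a gene that would need two
factors raises an error rather than silently missing its target.

Preset conditions: `small` (200 genes / 50 samples) for unit tests and
`paper_shaped` (5,000 genes / 300 samples) for integration tests, both
with 10%-of-genes hot sets at 10× the base rate of 5 expected mutations
per gene per cohort, planted co-expression 0.8, a 10% carrier fraction at
5× genome-wide rate, and an X-linked planted subset at a further 3× mass;
`null` (600 genes / 100 samples) plants nothing and serves as the negative
control. The cohort-scale preset is deliberately smaller than a real
pan-cancer cohort — large enough for the planted contrasts to be decisive,
small enough to keep the whole suite interactive.

What passing these tests shows — and does not. Recovery of planted
structure demonstrates that the pipeline's plumbing, scoring and tests
behave as specified under a model where the signal is real and the noise
is Poisson/Gaussian. Real tumor data are over-dispersed, batch-affected
and copy-number contaminated, expression is not normal, and mutational
signatures are not uniform across genes; none of that is emulated, so
synthetic recovery does not certify biological findings on real cohorts.

## Known limitations

- Cohort-aggregate propagation only; no per-sample smoothing and no
  insulated diffusion variant that would decouple scores from hub degree
  (aveG correlates with connectivity by construction).
- Gene identity is exact string match; symbol aliasing is upstream.
- The published network's exact edge/gene counts (113,473 / 13,579) can
  only be checked against a locally supplied copy of that supplementary
  table; the file is too large to redistribute here.
- Exact rank-sum enumeration is O(C(n, m)) and capped at combined n = 20.
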