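"""Set-level statistics: rank tests, FDR control, enrichment, and the
chromosome / mutation-density contrasts.

Distribution comparisons use the Wilcoxon rank-sum test — exact by full
enumeration for small groups (combined n <= 20, midranks for ties), a
normal approximation with tie-corrected variance otherwise — with
Benjamini-Hochberg control within explicitly declared families; q < 0.1 is
the conventional significance level and is reported, never enforced.

Enrichment of one gene set inside another is scored with Fisher's exact
test on the 2x2 table that contrasts the set's overlap rate against the
second set's prevalence in the whole gene universe,

    [[overlap, |A| - overlap], [|B|, N - |B|]],

which reproduces the printed reference examples (chromatin-regulation
factors and DNA-repair genes inside the 614-gene driver catalogue against
the 20,462 protein-coding universe). Set-versus-set contrasts use a plain
two-sided 2x2 exact test. Reported "±" values are standard errors of the
mean.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .netio import AUTOSOMES, InteractionNetwork

SIGNIFICANCE_Q = 0.1


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: float
    sem: float


def summarize(label: str, values) -> GroupSummary:
    arr = np.asarray(list(values), dtype=float)
    sem = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else float("nan")
    return GroupSummary(label, int(arr.size), float(arr.mean()), sem)


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    p: float
    q: float | None = None
    groups: tuple[GroupSummary, ...] = ()
    family: str | None = None

    @property
    def significant(self) -> bool | None:
        return None if self.q is None else bool(self.q < SIGNIFICANCE_Q)


@dataclass
class GeneSetCatalog:
    """Named gene sets plus the universe size used for enrichment tests.

    The default universe of 20,462 is the protein-coding gene count of the
    reference annotation the model's driver/CRF/DNA-repair catalogues were
    drawn from.
    """

    sets: dict[str, frozenset[str]] = field(default_factory=dict)
    universe: int = 20_462

    def __post_init__(self) -> None:
        self.sets = {name: frozenset(genes) for name, genes in self.sets.items()}
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if len(genes) > self.universe:
                raise ValueError(f"gene set {name!r} larger than the declared universe")

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return sorted(self.sets)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum

EXACT_MAX_N = 20


def _exact_rank_sum_p(a: np.ndarray, b: np.ndarray, alternative: str) -> tuple[float, float]:
    """Exact rank-sum p by full enumeration over group assignments.

    Uses midranks (doubled to stay in integers), so ties are handled by the
    same convention as the asymptotic branch.
    """
    pooled = np.concatenate([a, b])
    ranks2 = np.rint(2 * stats.rankdata(pooled)).astype(np.int64)
    m = a.size
    observed = int(ranks2[:m].sum())
    total = math.comb(pooled.size, m)
    n_le = 0
    n_ge = 0
    for combo in itertools.combinations(range(pooled.size), m):
        w = int(ranks2[list(combo)].sum())
        if w <= observed:
            n_le += 1
        if w >= observed:
            n_ge += 1
    p_less = n_le / total
    p_greater = n_ge / total
    if alternative == "less":
        p = p_less
    elif alternative == "greater":
        p = p_greater
    else:
        p = min(1.0, 2.0 * min(p_less, p_greater))
    return observed / 2.0, p


def wilcoxon_rank_sum(a, b, alternative: str = "two-sided", name: str = "wilcoxon") -> TestResult:
    """Wilcoxon rank-sum test of two value lists.

    Exact enumeration when the combined sample size is <= 20, otherwise the
    tie-corrected normal approximation. The statistic reported is the rank
    sum of the first group.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if a.size + b.size <= EXACT_MAX_N:
        statistic, p = _exact_rank_sum_p(a, b, alternative)
    else:
        result = stats.mannwhitneyu(a, b, alternative=alternative, method="asymptotic")
        statistic = float(result.statistic + a.size * (a.size + 1) / 2)  # U -> rank sum
        p = float(result.pvalue)
    return TestResult(
        name=name,
        statistic=float(statistic),
        p=float(min(p, 1.0)),
        groups=(summarize("a", a), summarize("b", b)),
    )


# ---------------------------------------------------------------------------
# Multiple testing


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order restored, capped at 1."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def adjust_family(results, family: str | None = None) -> list[TestResult]:
    """Attach BH q-values to a family of test results (one shared family)."""
    results = list(results)
    qs = bh_adjust([r.p for r in results])
    return [replace(r, q=float(q), family=family if family is not None else r.family) for r, q in zip(results, qs)]


# ---------------------------------------------------------------------------
# Fisher tests


def fisher_enrichment(
    overlap: int,
    set_a_size: int,
    set_b_size: int,
    universe: int = 20_462,
    alternative: str = "greater",
    name: str = "fisher_enrichment",
) -> TestResult:
    """Enrichment of set B membership inside set A against B's prevalence
    in the universe: exact test on [[k, |A|-k], [|B|, N-|B|]]."""
    if min(overlap, set_a_size, set_b_size, universe) < 0:
        raise ValueError("counts must be non-negative")
    if overlap > min(set_a_size, set_b_size):
        raise ValueError("overlap exceeds a set size")
    if max(set_a_size, set_b_size) > universe:
        raise ValueError("set sizes exceed the universe")
    if set_a_size == 0:
        return TestResult(name=name, statistic=float("nan"), p=1.0)
    table = [[overlap, set_a_size - overlap], [set_b_size, universe - set_b_size]]
    odds, p = stats.fisher_exact(table, alternative=alternative)
    return TestResult(name=name, statistic=float(odds), p=float(p))


def fisher_2x2(table, alternative: str = "two-sided", name: str = "fisher_2x2") -> TestResult:
    """Exact conditional test of an arbitrary 2x2 count table."""
    arr = np.asarray(table, dtype=np.int64)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ValueError("table must be 2x2 with non-negative counts")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("2x2 table has an all-zero margin")
    odds, p = stats.fisher_exact(arr, alternative=alternative)
    return TestResult(name=name, statistic=float(odds), p=float(p))


def topn_enrichment(
    scores: pd.DataFrame,
    geneset,
    n: int = 100,
    name: str = "topn_enrichment",
) -> TestResult:
    """Enrichment of ``geneset`` among the top-n aveG genes.

    Ties at the aveG boundary are broken by stable gene-identifier order;
    the universe is the scored gene list itself and the alternative is
    one-sided enrichment.
    """
    if n > len(scores):
        raise ValueError("n exceeds the number of scored genes")
    geneset = set(geneset)
    ordered = scores.sort_values(["aveg", "gene"], ascending=[False, True], kind="stable")
    top = set(ordered["gene"].head(n))
    scored = set(scores["gene"])
    in_set = scored & geneset
    k = len(top & in_set)
    table = [[k, n - k], [len(in_set) - k, len(scored) - n - (len(in_set) - k)]]
    odds, p = stats.fisher_exact(table, alternative="greater")
    return TestResult(name=name, statistic=float(odds), p=float(p))


# ---------------------------------------------------------------------------
# Chromosome and density contrasts


def x_vs_autosomes(scores: pd.DataFrame, geneset=None, name: str = "x_vs_autosomes") -> TestResult:
    """Rank-sum contrast of aveG on the X chromosome versus the 22
    autosomes, within ``geneset`` if given (Y-linked genes are excluded)."""
    if "chromosome" not in scores.columns:
        raise ValueError("scores table lacks chromosome labels")
    subset = scores if geneset is None else scores[scores["gene"].isin(set(geneset))]
    x_vals = subset.loc[subset["chromosome"] == "X", "aveg"]
    auto_vals = subset.loc[subset["chromosome"].isin(AUTOSOMES), "aveg"]
    if len(x_vals) < 2:
        raise ValueError(f"insufficient X-linked genes: {len(x_vals)}")
    if len(auto_vals) < 2:
        raise ValueError(f"insufficient autosomal genes: {len(auto_vals)}")
    result = wilcoxon_rank_sum(x_vals, auto_vals, name=name)
    return replace(
        result,
        groups=(summarize("X", x_vals), summarize("autosomes", auto_vals)),
    )


def mutation_density_compare(
    per_sample_density: pd.Series,
    mutated_samples,
    name: str = "mutation_density",
) -> TestResult:
    """Compare genome-wide mutations/Mb between carriers of a candidate
    gene's mutations and wild-type samples."""
    mutated = set(mutated_samples)
    unknown = mutated - set(per_sample_density.index)
    if unknown:
        raise ValueError(f"mutated samples missing from density table: {sorted(unknown)}")
    mut_vals = per_sample_density.loc[per_sample_density.index.isin(mutated)]
    wt_vals = per_sample_density.loc[~per_sample_density.index.isin(mutated)]
    if len(mut_vals) == 0 or len(wt_vals) == 0:
        raise ValueError("both mutated and wild-type groups must be non-empty")
    if len(mut_vals) < 2 or len(wt_vals) < 2:
        raise ValueError("each group needs at least 2 samples")
    result = wilcoxon_rank_sum(mut_vals, wt_vals, name=name)
    return replace(
        result,
        groups=(summarize("mutated", mut_vals), summarize("wild_type", wt_vals)),
    )


def score_covariate_correlation(
    scores: pd.DataFrame,
    covariate: str,
    exclusions=(),
) -> tuple[float, float]:
    """Pearson correlation (with t-test p) of aveG against a per-gene
    covariate (cdna_length, degree or avepcc), after dropping excluded
    genes (the length analysis conventionally drops TTN and MUC16)."""
    if covariate not in scores.columns:
        raise ValueError(f"unknown covariate {covariate!r}")
    subset = scores[~scores["gene"].isin(set(exclusions))].dropna(subset=["aveg", covariate])
    if len(subset) < 10:
        raise ValueError("need at least 10 genes after exclusions")
    x = subset["aveg"].to_numpy(dtype=float)
    y = subset[covariate].to_numpy(dtype=float)
    if np.all(y == y[0]):
        raise ValueError("constant covariate")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Interaction-pair mutation enrichment benchmark


def ppi_pair_mutation_enrichment(
    network: InteractionNetwork,
    m0,
    n_draws: int,
    seed: int,
    alternative: str = "greater",
    name: str = "ppi_pair_enrichment",
) -> TestResult:
    """Are interacting pairs more mutation-loaded than random pairs?

    The per-pair statistic is M0_i + M0_j; true edges are compared against
    ``n_draws`` uniformly sampled non-adjacent, non-self pairs (with
    replacement across draws) by rank-sum test. Fully seeded.
    """
    if isinstance(m0, pd.Series):
        mass = m0
    elif hasattr(m0, "mass"):
        mass = m0.mass
    else:
        mass = pd.Series(m0)
    nodes = network.sorted_nodes()
    n = len(nodes)
    if network.n_edges >= n * (n - 1) // 2:
        raise ValueError("complete graph: no non-adjacent pairs to sample")
    values = mass.reindex(nodes).to_numpy(dtype=float)
    index = {g: i for i, g in enumerate(nodes)}
    edge_stats = np.array([values[index[a]] + values[index[b]] for a, b in network.edges()])

    rng = np.random.default_rng(seed)
    drawn = np.empty(n_draws, dtype=float)
    filled = 0
    while filled < n_draws:
        batch = max(n_draws - filled, 1000)
        ii = rng.integers(0, n, size=batch)
        jj = rng.integers(0, n, size=batch)
        for i, j in zip(ii, jj):
            if i == j or network.graph.has_edge(nodes[i], nodes[j]):
                continue
            drawn[filled] = values[i] + values[j]
            filled += 1
            if filled == n_draws:
                break
    result = wilcoxon_rank_sum(edge_stats, drawn, alternative=alternative, name=name)
    return replace(
        result,
        groups=(summarize("ppi_pairs", edge_stats), summarize("random_pairs", drawn)),
    )


def exclude_samples(
    mutations: pd.DataFrame,
    exclusion_list,
    sample_col: str = "Tumor_Sample_Barcode",
) -> tuple[pd.DataFrame, int]:
    """Drop all records of the listed samples (e.g. ultra-mutated tumors);
    returns the filtered table and the number of removed rows."""
    excluded = set(exclusion_list)
    keep = ~mutations[sample_col].isin(excluded)
    return mutations.loc[keep].reset_index(drop=True), int((~keep).sum())


# ---------------------------------------------------------------------------
# File interfaces


def read_gene_set(path) -> frozenset[str]:
    """One gene symbol per line; blank lines ignored."""
    with open(path) as fh:
        return frozenset(line.strip() for line in fh if line.strip())


def load_catalog(paths: dict[str, str], universe: int = 20_462) -> GeneSetCatalog:
    return GeneSetCatalog({name: read_gene_set(p) for name, p in paths.items()}, universe=universe)


def read_sample_list(path) -> frozenset[str]:
    with open(path) as fh:
        return frozenset(line.strip() for line in fh if line.strip())


def results_to_frame(results) -> pd.DataFrame:
    """Flatten TestResults into the results TSV layout."""
    rows = []
    for r in results:
        row = {
            "test": r.name,
            "family": r.family,
            "statistic": r.statistic,
            "p": r.p,
            "q": r.q,
        }
        for g in r.groups:
            row[f"n_{g.label}"] = g.n
            row[f"mean_{g.label}"] = g.mean
            row[f"sem_{g.label}"] = g.sem
        rows.append(row)
    return pd.DataFrame(rows)


def write_results_tsv(results, path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False, float_format="%.17g")
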