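"""Seeded synthetic studies with planted, recoverable structure.

Every generator is deterministic under its seed and emulates one input of
the cohort pipeline:

* a sparse scale-free-like interaction network (preferential attachment or
  a Poisson configuration model), cleaned and reduced to its largest
  component;
* an expression matrix in which chosen network edges carry a planted
  co-expression: both genes of a planted edge load sqrt(|rho|) on a shared
  latent factor (partners signed by the target), giving population
  correlation exactly rho between an edge's genes while unplanted genes
  stay independent;
* a MAF-like mutation table with per-(gene, sample) Poisson counts whose
  rate is inflated for planted hot genes and for mutator-carrier samples.

The bundled presets mirror the cohort conditions at desk scale: a planted
driver set that is simultaneously highly mutated and co-expressed with its
interaction partners (the high-gravitation signature), an X-linked planted
subset with additionally inflated mass, and a subset of hypermutated
carrier samples. Mutation counts are Poisson rather than over-dispersed:
enough for planted-signal recovery with closed-form expectations, though
real tumor cohorts are burstier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .netio import GeneMetadata, InteractionNetwork, load_interactions
from .setstats import GeneSetCatalog

MAF_CLASSES = (
    "Missense_Mutation",
    "Nonsense_Mutation",
    "Frame_Shift_Del",
    "Frame_Shift_Ins",
    "Splice_Site",
)


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(n)]


def _sample_names(n: int) -> list[str]:
    return [f"S{i:04d}" for i in range(n)]


def synth_network(
    n_genes: int,
    mean_degree: float = 6.0,
    model: str = "preferential_attachment",
    seed: int = 0,
) -> InteractionNetwork:
    """Scale-free-like undirected network; largest component retained."""
    if n_genes < 10:
        raise ValueError("need at least 10 genes")
    if mean_degree < 2 or mean_degree >= n_genes:
        raise ValueError(f"infeasible mean degree {mean_degree} for {n_genes} genes")
    names = _gene_names(n_genes)
    if model == "preferential_attachment":
        m = max(1, round(mean_degree / 2))
        graph = nx.barabasi_albert_graph(n_genes, m, seed=seed)
    elif model == "configuration":
        rng = np.random.default_rng(seed)
        degrees = rng.poisson(mean_degree, size=n_genes)
        if degrees.sum() % 2:
            degrees[0] += 1
        graph = nx.Graph(nx.configuration_model(degrees.tolist(), seed=seed))
        graph.remove_edges_from(nx.selfloop_edges(graph))
    else:
        raise ValueError(f"unknown network model {model!r}")
    component = max(nx.connected_components(graph), key=len)
    graph = graph.subgraph(component)
    edges = sorted(
        (names[a], names[b]) if names[a] <= names[b] else (names[b], names[a])
        for a, b in graph.edges
    )
    return load_interactions(edges)


def synth_expression(
    network: InteractionNetwork,
    n_samples: int,
    coexpressed_edges=(),
    target_pcc: float = 0.8,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Expression matrix with planted co-expression on chosen edges.

    Planted edges must form stars (each connected component of the planted
    edge set needs a hub touching all its edges): the hub and its partners
    share one latent factor, so each planted edge's population correlation
    is exactly ``target_pcc``. A gene required to serve two different
    factors raises an error. Values are shifted to be non-negative, which
    leaves all correlations untouched.
    """
    if not abs(target_pcc) < 1:
        raise ValueError("|target_pcc| must be < 1")
    coexpressed_edges = [tuple(sorted(e)) for e in coexpressed_edges]
    network_edges = set(network.edges())
    for edge in coexpressed_edges:
        if edge not in network_edges:
            raise ValueError(f"planted edge {edge} is not a network edge")

    planted = nx.Graph(coexpressed_edges)
    loading: dict[str, tuple[int, float]] = {}  # gene -> (factor id, signed loading)
    root = np.sqrt(abs(target_pcc))
    sign = 1.0 if target_pcc >= 0 else -1.0
    for factor_id, component in enumerate(nx.connected_components(planted)):
        comp = planted.subgraph(component)
        hubs = [g for g in comp if comp.degree[g] == comp.number_of_edges()]
        if not hubs:
            raise ValueError(
                "planted edges must form stars: a gene would need two latent factors"
            )
        hub = sorted(hubs)[0]
        loading[hub] = (factor_id, root)
        for partner in sorted(set(comp) - {hub}):
            loading[partner] = (factor_id, sign * root)

    rng = np.random.default_rng(seed)
    genes = network.sorted_nodes()
    n_factors = max((fid for fid, _ in loading.values()), default=-1) + 1
    factors = rng.standard_normal((n_factors, n_samples))
    private = rng.standard_normal((len(genes), n_samples))
    values = np.empty((len(genes), n_samples))
    resid = np.sqrt(1 - abs(target_pcc))
    for i, gene in enumerate(genes):
        if gene in loading:
            fid, load = loading[gene]
            values[i] = load * factors[fid] + resid * private[i]
        else:
            values[i] = private[i]
    values *= noise_sd
    values -= values.min()  # non-negative expression levels
    return pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=_sample_names(n_samples))


def synth_mutations(
    network: InteractionNetwork,
    n_samples: int,
    base_rate: float = 5.0,
    hot_genes=(),
    hot_multiplier=10.0,
    mutator_carriers=(),
    mutator_multiplier: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """MAF-like mutation table from a per-(gene, sample) Poisson model.

    ``base_rate`` is the expected nonsynonymous mutation count per gene
    over the whole cohort; the per-cell rate is base_rate / n_samples,
    multiplied by the hot-gene factor (scalar, or mapping gene -> factor)
    and by the mutator factor for carrier samples. All multipliers must be
    >= 1.
    """
    samples = _sample_names(n_samples)
    genes = network.sorted_nodes()
    if np.isscalar(hot_multiplier):
        if hot_multiplier < 1:
            raise ValueError("multipliers must be >= 1")
        hot_map = {g: float(hot_multiplier) for g in hot_genes}
    else:
        hot_map = {g: float(v) for g, v in dict(hot_multiplier).items()}
        if any(v < 1 for v in hot_map.values()):
            raise ValueError("multipliers must be >= 1")
    if mutator_multiplier < 1:
        raise ValueError("multipliers must be >= 1")
    unknown = set(hot_map) - set(genes)
    if unknown:
        raise ValueError(f"hot genes absent from network: {sorted(unknown)}")

    gene_factor = np.array([hot_map.get(g, 1.0) for g in genes])
    carriers = set(mutator_carriers)
    sample_factor = np.array([mutator_multiplier if s in carriers else 1.0 for s in samples])
    rates = (base_rate / n_samples) * np.outer(gene_factor, sample_factor)
    rng = np.random.default_rng(seed)
    counts = rng.poisson(rates)

    gi, si = np.nonzero(counts)
    reps = counts[gi, si]
    gene_col = np.repeat(np.asarray(genes, dtype=object)[gi], reps)
    sample_col = np.repeat(np.asarray(samples, dtype=object)[si], reps)
    classes = rng.choice(MAF_CLASSES, size=gene_col.size)
    return pd.DataFrame(
        {
            "Hugo_Symbol": gene_col,
            "Tumor_Sample_Barcode": sample_col,
            "Variant_Classification": classes,
        }
    )


def synth_metadata(
    genes,
    x_fraction: float = 0.05,
    force_x=(),
    force_autosome=(),
    seed: int = 0,
) -> GeneMetadata:
    """Chromosome labels (X for ~5% of genes) and log-normal cDNA lengths
    (median ~2 kb), with optional forced X / autosome assignments."""
    rng = np.random.default_rng(seed)
    genes = sorted(genes)
    force_x = set(force_x)
    force_autosome = set(force_autosome)
    meta = GeneMetadata()
    autosome_labels = [str(i) for i in range(1, 23)]
    for gene in genes:
        if gene in force_x:
            chrom = "X"
        elif gene in force_autosome:
            chrom = str(rng.choice(autosome_labels))
        elif rng.random() < x_fraction:
            chrom = "X"
        else:
            chrom = str(rng.choice(autosome_labels))
        length = max(100, int(rng.lognormal(mean=np.log(2000.0), sigma=0.6)))
        meta.chromosome[gene] = chrom
        meta.cdna_length[gene] = length
    return meta


@dataclass
class SyntheticStudy:
    network: InteractionNetwork
    expression: pd.DataFrame
    mutations: pd.DataFrame
    metadata: GeneMetadata
    catalog: GeneSetCatalog
    ground_truth: dict = field(default_factory=dict)
    seed: int = 0


PRESETS = {
    # n_genes, n_samples, n_hot, base_rate, hot_mult, target_pcc, planted
    "small": dict(n_genes=200, n_samples=50, n_hot=20, base_rate=5.0, hot_multiplier=10.0, target_pcc=0.8, planted=True),
    "paper_shaped": dict(n_genes=5000, n_samples=300, n_hot=100, base_rate=5.0, hot_multiplier=10.0, target_pcc=0.8, planted=True),
    "null": dict(n_genes=600, n_samples=100, n_hot=30, base_rate=5.0, hot_multiplier=1.0, target_pcc=0.8, planted=False),
}


def synth_study(preset: str = "small", seed: int = 0) -> SyntheticStudy:
    """Generate a complete seeded study bundle for one preset.

    ``small`` (200 genes / 50 samples) is sized for unit tests,
    ``paper_shaped`` (5,000 genes / 300 samples) for integration tests.
    ``null`` plants nothing: the "driver" set is a random gene set with no
    mutation or co-expression signal, the negative control for enrichment.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}")
    cfg = PRESETS[preset]
    rng = np.random.default_rng(seed)
    network = synth_network(cfg["n_genes"], mean_degree=6.0, seed=seed)
    genes = network.sorted_nodes()

    # planted driver set: prefer genes with >= 2 partners so stars exist
    eligible = [g for g in genes if network.degree(g) >= 2]
    hot_genes = sorted(rng.choice(eligible, size=cfg["n_hot"], replace=False))
    hot_set = set(hot_genes)

    # star partners: unshared non-hot neighbours of each hot gene
    taken: set[str] = set()
    planted_edges: list[tuple[str, str]] = []
    for hub in hot_genes:
        partners = [
            nb for nb in sorted(network.graph.neighbors(hub))
            if nb not in hot_set and nb not in taken
        ][:4]
        taken.update(partners)
        planted_edges.extend(tuple(sorted((hub, nb))) for nb in partners)

    # X-linked planted subset (about a tenth of the hot set, at least 3)
    n_x = max(3, cfg["n_hot"] // 10)
    x_hot = sorted(rng.choice(hot_genes, size=n_x, replace=False))
    metadata = synth_metadata(
        genes, force_x=x_hot, force_autosome=set(hot_genes) - set(x_hot), seed=seed + 1
    )

    carriers = sorted(
        rng.choice(_sample_names(cfg["n_samples"]), size=max(2, cfg["n_samples"] // 10), replace=False)
    )

    if cfg["planted"]:
        hot_map = {g: cfg["hot_multiplier"] for g in hot_genes}
        for g in x_hot:
            hot_map[g] = cfg["hot_multiplier"] * 3.0  # extra X-linked mass
        coexpressed = planted_edges
        mutator_multiplier = 5.0
    else:
        hot_map = {}
        coexpressed = []
        mutator_multiplier = 1.0

    expression = synth_expression(
        network,
        cfg["n_samples"],
        coexpressed_edges=coexpressed,
        target_pcc=cfg["target_pcc"],
        seed=seed + 2,
    )
    mutations = synth_mutations(
        network,
        cfg["n_samples"],
        base_rate=cfg["base_rate"],
        hot_genes=hot_genes,
        hot_multiplier=hot_map if hot_map else 1.0,
        mutator_carriers=carriers if cfg["planted"] else (),
        mutator_multiplier=mutator_multiplier,
        seed=seed + 3,
    )

    random_set = sorted(rng.choice([g for g in genes if g not in hot_set], size=cfg["n_hot"], replace=False))
    catalog = GeneSetCatalog(
        {"driver": frozenset(hot_genes), "random": frozenset(random_set)},
        universe=len(genes),
    )
    ground_truth = {
        "hot_genes": frozenset(hot_genes),
        "hot_multiplier": cfg["hot_multiplier"] if cfg["planted"] else 1.0,
        "coexpressed_edges": frozenset(coexpressed),
        "target_pcc": cfg["target_pcc"] if cfg["planted"] else 0.0,
        "mutator_carriers": frozenset(carriers if cfg["planted"] else ()),
        "mutator_multiplier": mutator_multiplier,
        "x_linked_hot": frozenset(x_hot),
    }
    return SyntheticStudy(network, expression, mutations, metadata, catalog, ground_truth, seed)


def write_study(study: SyntheticStudy, outdir) -> dict[str, str]:
    """Write a study through the public TSV dialects (round-trippable)."""
    import os

    from . import coexpr, netio, propagation as propagate

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "network": os.path.join(outdir, "network.tsv"),
        "expression": os.path.join(outdir, "expression.tsv"),
        "mutations": os.path.join(outdir, "mutations.tsv"),
        "metadata": os.path.join(outdir, "metadata.tsv"),
    }
    netio.write_edge_tsv(study.network, paths["network"])
    coexpr.write_expression_tsv(study.expression, paths["expression"])
    propagate.write_mutations_tsv(study.mutations, paths["mutations"])
    netio.write_metadata_tsv(study.metadata, paths["metadata"])
    for name, genes in study.catalog.sets.items():
        path = os.path.join(outdir, f"geneset_{name}.txt")
        with open(path, "w") as fh:
            fh.write("\n".join(sorted(genes)) + "\n")
        paths[f"geneset_{name}"] = path
    return paths
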