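"""Protein interaction network construction and gene metadata handling.

The propagation substrate is an undirected protein interaction network
(PIN): gene identifiers as nodes, experimentally supported interactions as
edges. Input edge lists are cleaned on load — self-loops are dropped and
duplicate records (in either orientation) are collapsed — so that the
degree-sum identity ``sum_i k_i = 2 * N_L`` holds by construction.

Gene identity is a case-sensitive exact string match; symbol aliasing is
treated as an upstream curation step and never attempted here.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx

VALID_CHROMOSOMES = frozenset(str(i) for i in range(1, 23)) | {"X", "Y"}
AUTOSOMES = frozenset(str(i) for i in range(1, 23))


@dataclass
class InteractionNetwork:
    """Undirected gene interaction graph.

    Wraps a :class:`networkx.Graph` and records how many raw input records
    were discarded during cleaning. Disconnected graphs and isolated nodes
    are accepted; downstream propagation simply leaves zero-mass components
    at zero.
    """

    graph: nx.Graph
    n_self_loops_dropped: int = 0
    n_duplicates_dropped: int = 0

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        """Total edge count N_L."""
        return self.graph.number_of_edges()

    def degree(self, gene: str) -> int:
        return self.graph.degree[gene]

    @property
    def degrees(self) -> dict[str, int]:
        return dict(self.graph.degree())

    def edges(self) -> Iterator[tuple[str, str]]:
        """Edges as canonically ordered (sorted) pairs."""
        for a, b in self.graph.edges:
            yield (a, b) if a <= b else (b, a)

    def has_edge(self, a: str, b: str) -> bool:
        return self.graph.has_edge(a, b)

    def sorted_nodes(self) -> list[str]:
        return sorted(self.graph.nodes)


def load_interactions(edge_records: Iterable[Sequence[str]]) -> InteractionNetwork:
    """Build a cleaned undirected network from raw gene-pair records.

    Self-loops are removed and duplicate edges (including reversed order)
    are collapsed; the counts of dropped records are stored on the returned
    network. The result is independent of record order and idempotent under
    reloading.

    Raises
    ------
    ValueError
        If the input is empty ("empty network") or a record is malformed
        (the error names the offending record number, 1-based).
    """
    graph = nx.Graph()
    n_self = 0
    n_dup = 0
    n_records = 0
    for lineno, record in enumerate(edge_records, start=1):
        if len(record) < 2:
            raise ValueError(f"malformed edge record at line {lineno}: {record!r}")
        a, b = str(record[0]).strip(), str(record[1]).strip()
        if not a or not b:
            raise ValueError(f"malformed edge record at line {lineno}: empty gene identifier")
        n_records += 1
        if a == b:
            n_self += 1
            continue
        if graph.has_edge(a, b):
            n_dup += 1
            continue
        graph.add_edge(a, b)
    if n_records == 0 or graph.number_of_edges() == 0:
        raise ValueError("empty network")
    return InteractionNetwork(graph, n_self_loops_dropped=n_self, n_duplicates_dropped=n_dup)


def restrict_to_genes(network: InteractionNetwork, keep: Iterable[str]) -> InteractionNetwork:
    """Induced subgraph on ``keep ∩ nodes`` with degrees and N_L recomputed.

    Nodes in ``keep`` that lose all their edges remain as isolated nodes of
    the restricted network.
    """
    keep = set(keep)
    retained = keep & set(network.graph.nodes)
    if not retained:
        raise ValueError("no genes retained")
    sub = nx.Graph(network.graph.subgraph(retained))
    return InteractionNetwork(sub)


@dataclass
class GeneMetadata:
    """Validated per-gene annotation: chromosome label and cDNA length (bp)."""

    chromosome: dict[str, str] = field(default_factory=dict)
    cdna_length: dict[str, int] = field(default_factory=dict)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.chromosome)

    def __len__(self) -> int:
        return len(self.chromosome)


def load_gene_metadata(records: Iterable[Sequence]) -> GeneMetadata:
    """Validate (gene, chromosome, cdna_length) rows into a GeneMetadata table.

    Chromosome labels must be in 1..22, X or Y; lengths must be positive;
    duplicate genes are rejected.
    """
    meta = GeneMetadata()
    for record in records:
        if len(record) < 3:
            raise ValueError(f"malformed metadata record: {record!r}")
        gene, chrom, length = str(record[0]), str(record[1]), record[2]
        if gene in meta.chromosome:
            raise ValueError(f"duplicate gene in metadata: {gene}")
        if chrom not in VALID_CHROMOSOMES:
            raise ValueError(f"unknown chromosome {chrom!r} for gene {gene}")
        length = int(length)
        if length <= 0:
            raise ValueError(f"non-positive cDNA length for gene {gene}: {length}")
        meta.chromosome[gene] = chrom
        meta.cdna_length[gene] = length
    return meta


# ---------------------------------------------------------------------------
# TSV interfaces


def read_edge_tsv(path, header: bool = False) -> InteractionNetwork:
    """Read a two-column gene_a/gene_b TSV edge list and clean it."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        rows = list(reader)
    if header and rows:
        rows = rows[1:]
    return load_interactions(rows)


def write_edge_tsv(network: InteractionNetwork, path, header: bool = True) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        if header:
            writer.writerow(["gene_a", "gene_b"])
        for a, b in sorted(network.edges()):
            writer.writerow([a, b])


def read_metadata_tsv(path) -> GeneMetadata:
    """Read gene metadata TSV with columns gene, chromosome, cdna_length_bp."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        records = [(r["gene"], r["chromosome"], r["cdna_length_bp"]) for r in reader]
    return load_gene_metadata(records)


def write_metadata_tsv(metadata: GeneMetadata, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene", "chromosome", "cdna_length_bp"])
        for gene in sorted(metadata.chromosome):
            writer.writerow([gene, metadata.chromosome[gene], metadata.cdna_length[gene]])
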