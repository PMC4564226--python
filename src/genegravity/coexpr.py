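"""Expression filtering and the co-expressed protein interaction network.

A gene counts as *expressed* in a sample if its value is at or above the
sample's 20th expression percentile; genes expressed in fewer than 20% of
samples are discarded. The interaction network restricted to the surviving
genes, with every edge annotated by the cohort-wide Pearson correlation of
its endpoints, is the co-expressed PIN (CePIN). The correlation doubles as
an inverse "biological distance" (r = 1/PCC), so its sign splits edges into
attractive (PCC > 0), repulsive (PCC < 0) and null (PCC = 0) classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .netio import InteractionNetwork, restrict_to_genes

SIGN_ATTRACTIVE = "attractive"
SIGN_REPULSIVE = "repulsive"
SIGN_NULL = "null"


def validate_expression(matrix: pd.DataFrame) -> None:
    if matrix.index.has_duplicates:
        raise ValueError("duplicate gene identifiers in expression matrix")
    if matrix.columns.has_duplicates:
        raise ValueError("duplicate sample identifiers in expression matrix")


def filter_expression(
    matrix: pd.DataFrame,
    sample_quantile: float = 0.20,
    sample_fraction: float = 0.20,
) -> tuple[pd.DataFrame, frozenset[str]]:
    """Apply the two-stage expression filter.

    Stage one flags a gene as expressed in a sample iff its value is >= the
    ``sample_quantile`` empirical quantile of that sample's values (linear
    interpolation; ties at the threshold count as expressed). Stage two
    removes genes whose expressed-sample fraction is below
    ``sample_fraction``. All samples are kept.

    Returns the filtered matrix and the surviving gene set.
    """
    validate_expression(matrix)
    if not 0 < sample_quantile < 1:
        raise ValueError("sample_quantile must be in (0, 1)")
    if not 0 < sample_fraction <= 1:
        raise ValueError("sample_fraction must be in (0, 1]")
    if matrix.shape[1] < 3:
        raise ValueError("too few samples")
    values = matrix.to_numpy(dtype=float)
    thresholds = np.quantile(values, sample_quantile, axis=0)
    expressed = values >= thresholds[np.newaxis, :]
    frac = expressed.mean(axis=1)
    keep = frac >= sample_fraction
    filtered = matrix.loc[keep]
    return filtered, frozenset(filtered.index)


def pearson_cc(x, y) -> float:
    """Product-moment correlation of two equal-length vectors (n >= 3).

    Raises ValueError for constant input, where the correlation is
    undefined; callers drop the corresponding edge.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("vectors must be one-dimensional and of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations for correlation")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.dot(xc, xc))
    sy = np.sqrt(np.dot(yc, yc))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("undefined correlation: constant vector")
    r = float(np.dot(xc, yc) / (sx * sy))
    return max(-1.0, min(1.0, r))


def sign_class(pcc: float) -> str:
    if pcc > 0:
        return SIGN_ATTRACTIVE
    if pcc < 0:
        return SIGN_REPULSIVE
    return SIGN_NULL


@dataclass
class CoexpressionNetwork:
    """CePIN: the interaction network restricted to expressed genes, with
    per-edge Pearson correlation and sign class.

    ``edges`` has columns gene_a, gene_b (canonically ordered), pcc and
    sign_class. ``n_undefined_dropped`` counts edges removed because one
    endpoint had constant expression.
    """

    network: InteractionNetwork
    edges: pd.DataFrame
    n_undefined_dropped: int = 0

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def pcc_map(self) -> dict[tuple[str, str], float]:
        return {
            (a, b): p
            for a, b, p in zip(self.edges["gene_a"], self.edges["gene_b"], self.edges["pcc"])
        }


def build_cepin(
    network: InteractionNetwork,
    filtered: pd.DataFrame,
    transform: str = "none",
) -> CoexpressionNetwork:
    """Annotate the network's edges with expression correlations.

    The network is restricted to genes present in ``filtered`` (the output
    of :func:`filter_expression`); each surviving edge gets the Pearson
    correlation of its endpoints computed over *all* cohort samples. Edges
    with undefined correlation (constant expression) are dropped and
    counted. ``transform="log2"`` applies log2(x + 1) before correlating.
    """
    if transform not in ("none", "log2"):
        raise ValueError(f"unknown transform {transform!r}")
    restricted = restrict_to_genes(network, set(filtered.index))
    values = filtered.to_numpy(dtype=float)
    if transform == "log2":
        values = np.log2(values + 1.0)
    # row-standardize once so each edge PCC is a dot product
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    gene_index = {g: i for i, g in enumerate(filtered.index)}

    rows = []
    n_undef = 0
    for a, b in restricted.edges():
        ia, ib = gene_index[a], gene_index[b]
        if norms[ia] == 0.0 or norms[ib] == 0.0:
            n_undef += 1
            continue
        r = float(np.dot(centered[ia], centered[ib]) / (norms[ia] * norms[ib]))
        r = max(-1.0, min(1.0, r))
        rows.append((a, b, r, sign_class(r)))
    if not rows:
        raise ValueError("no surviving edges in CePIN")
    edges = pd.DataFrame(rows, columns=["gene_a", "gene_b", "pcc", "sign_class"])
    edges = edges.sort_values(["gene_a", "gene_b"], ignore_index=True)
    kept_edges = [(a, b) for a, b in zip(edges["gene_a"], edges["gene_b"])]
    import networkx as nx

    graph = nx.Graph(kept_edges)
    return CoexpressionNetwork(InteractionNetwork(graph), edges, n_undefined_dropped=n_undef)


# ---------------------------------------------------------------------------
# TSV interfaces


def read_expression_tsv(path) -> pd.DataFrame:
    """Expression TSV: first column gene, remaining columns one per sample."""
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    validate_expression(matrix)
    return matrix


def write_expression_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene", float_format="%.17g")


def read_cepin_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})


def write_cepin_tsv(cepin: CoexpressionNetwork, path) -> None:
    cepin.edges.to_csv(path, sep="\t", index=False, float_format="%.17g")
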