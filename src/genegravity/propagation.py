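"""Random-walk-with-restart smoothing of per-gene mutation counts.

The cohort-cumulative nonsynonymous mutation count of each gene (M0) is
spread over the interaction network by iterating

    M(t+1) = alpha * P^T M(t) + (1 - alpha) * M0,       M(0) = M0,

where P is the row-normalized adjacency (P_ij = 1/k_i for neighbours j of
i) and alpha in [0, 1] tunes how far mass diffuses: alpha = 0 keeps M = M0,
alpha = 1 forgets M0 entirely and converges to the degree-proportional
stationary state k_i / 2 N_L on connected (non-bipartite) graphs. For
alpha < 1 the fixed point has the closed form
(1 - alpha) (I - alpha P^T)^{-1} M0.

Because P is row-stochastic, P^T preserves the total mass, so
sum(M) = sum(M0) throughout the iteration. Isolated nodes, where the
paper-style transition row is undefined, are given a unit self-transition:
mass placed on them stays put (fixed point M_i = M0_i) and conservation is
retained.

The operator is applied in sparse form; a dense n x n matrix is never
materialized, which keeps cohort-scale networks (>10,000 genes) tractable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.stats import spearmanr

from .netio import GeneMetadata, InteractionNetwork

#: MAF variant classifications counted as nonsynonymous by default.
NONSYNONYMOUS_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Splice_Site",
        "Translation_Start_Site",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
    }
)

GENE_COL = "Hugo_Symbol"
SAMPLE_COL = "Tumor_Sample_Barcode"
CLASS_COL = "Variant_Classification"


@dataclass
class MutationVector:
    """Per-gene initial mutation mass M0, indexed exactly by network nodes."""

    mass: pd.Series
    n_samples: int = 0
    n_records_used: int = 0
    n_records_nonsyn_dropped: int = 0  # records failing the classification filter
    n_genes_dropped: int = 0  # mutated genes absent from the network

    @property
    def total(self) -> float:
        return float(self.mass.sum())


@dataclass
class PropagationConfig:
    alpha: float = 0.7
    tol: float = 1e-6
    max_iter: int = 10_000

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class PropagatedVector:
    """Smoothed mutation mass with solver diagnostics."""

    mass: pd.Series
    iterations: int = 0
    residual: float = 0.0
    alpha: float = 0.7

    @property
    def total(self) -> float:
        return float(self.mass.sum())


class ConvergenceError(RuntimeError):
    """Power iteration failed to reach tolerance; carries the last residual."""

    def __init__(self, iterations: int, residual: float):
        self.iterations = iterations
        self.residual = residual
        super().__init__(
            f"propagation did not converge in {iterations} iterations "
            f"(last residual {residual:.3e})"
        )


def build_m0(
    mutations: pd.DataFrame,
    network: InteractionNetwork,
    normalize_by_length: bool = False,
    metadata: GeneMetadata | None = None,
    classes: frozenset[str] = NONSYNONYMOUS_CLASSES,
    gene_col: str = GENE_COL,
    sample_col: str = SAMPLE_COL,
    class_col: str = CLASS_COL,
    count_samples: bool = False,
) -> MutationVector:
    """Aggregate a MAF-like mutation table into the initial mass vector M0.

    Only records whose variant classification is in ``classes`` count.
    ``count_samples=True`` counts distinct mutated samples per gene instead
    of mutation events. With ``normalize_by_length`` each count is divided
    by the gene's cDNA length in bp (mutation density M/L), which requires
    ``metadata`` covering every mutated network gene.
    """
    nodes = network.sorted_nodes()
    mass = pd.Series(0.0, index=pd.Index(nodes, name="gene"))
    if len(mutations) == 0:
        return MutationVector(mass, n_samples=0)

    is_nonsyn = mutations[class_col].isin(classes)
    nonsyn = mutations.loc[is_nonsyn]
    n_class_dropped = int((~is_nonsyn).sum())
    in_net = nonsyn[gene_col].isin(mass.index)
    used = nonsyn.loc[in_net]
    n_genes_dropped = nonsyn.loc[~in_net, gene_col].nunique()

    if count_samples:
        counts = used.groupby(gene_col)[sample_col].nunique()
    else:
        counts = used.groupby(gene_col).size()
    mass.loc[counts.index] = counts.astype(float)

    if normalize_by_length:
        if metadata is None:
            raise ValueError("length normalization requires gene metadata")
        mutated = [g for g in counts.index if g not in metadata.cdna_length]
        if mutated:
            raise ValueError(f"missing cDNA length for genes: {sorted(mutated)}")
        lengths = pd.Series({g: metadata.cdna_length[g] for g in counts.index}, dtype=float)
        mass.loc[counts.index] = counts.astype(float) / lengths

    return MutationVector(
        mass,
        n_samples=int(mutations[sample_col].nunique()),
        n_records_used=int(len(used)),
        n_records_nonsyn_dropped=n_class_dropped,
        n_genes_dropped=int(n_genes_dropped),
    )


def _transition_transpose(network: InteractionNetwork, nodes: list[str]) -> sp.csr_array:
    """Sparse P^T = A D^{-1} for symmetric adjacency A; isolated nodes get a
    unit self-transition so the operator stays mass-conserving."""
    adj = nx_to_sparse(network, nodes)
    degrees = np.asarray(adj.sum(axis=1)).ravel()
    inv_k = np.zeros_like(degrees, dtype=float)
    nz = degrees > 0
    inv_k[nz] = 1.0 / degrees[nz]
    pt = adj @ sp.diags_array(inv_k)
    if (~nz).any():
        idx = np.flatnonzero(~nz)
        loop = sp.csr_array(
            (np.ones(idx.size), (idx, idx)), shape=pt.shape
        )
        pt = pt + loop
    return sp.csr_array(pt)


def nx_to_sparse(network: InteractionNetwork, nodes: list[str]) -> sp.csr_array:
    import networkx as nx

    return sp.csr_array(nx.to_scipy_sparse_array(network.graph, nodelist=nodes, format="csr", dtype=float))


def _as_vector(m0, nodes: list[str]) -> np.ndarray:
    if isinstance(m0, MutationVector):
        series = m0.mass
    elif isinstance(m0, pd.Series):
        series = m0
    else:
        series = pd.Series(m0)
    if set(series.index) != set(nodes):
        raise ValueError("M0 must be indexed exactly by the network nodes")
    vec = series.reindex(nodes).to_numpy(dtype=float)
    if (vec < 0).any():
        raise ValueError("M0 entries must be non-negative")
    return vec


def propagate(
    network: InteractionNetwork,
    m0,
    config: PropagationConfig | None = None,
) -> PropagatedVector:
    """Fixed-point iteration of the restart recurrence until the L2 update
    norm drops below ``config.tol`` (default 1e-6)."""
    config = config or PropagationConfig()
    nodes = network.sorted_nodes()
    v0 = _as_vector(m0, nodes)
    alpha = config.alpha
    if alpha == 0.0:
        return PropagatedVector(pd.Series(v0, index=nodes), iterations=1, residual=0.0, alpha=alpha)
    pt = _transition_transpose(network, nodes)
    current = v0.copy()
    restart = (1.0 - alpha) * v0
    for iteration in range(1, config.max_iter + 1):
        nxt = alpha * (pt @ current) + restart
        residual = float(np.linalg.norm(nxt - current))
        current = nxt
        if residual < config.tol:
            return PropagatedVector(
                pd.Series(current, index=nodes), iterations=iteration, residual=residual, alpha=alpha
            )
    raise ConvergenceError(config.max_iter, residual)


def propagate_closed_form(
    network: InteractionNetwork,
    m0,
    alpha: float = 0.7,
) -> PropagatedVector:
    """Direct sparse solve of (I - alpha P^T) M = (1 - alpha) M0.

    Only defined for alpha < 1; at alpha = 1 the resolvent is singular and
    the power iteration must be used instead.
    """
    if not 0.0 <= alpha < 1.0:
        raise ValueError("closed form undefined; use power iteration")
    nodes = network.sorted_nodes()
    v0 = _as_vector(m0, nodes)
    if alpha == 0.0:
        return PropagatedVector(pd.Series(v0, index=nodes), iterations=0, residual=0.0, alpha=alpha)
    pt = _transition_transpose(network, nodes)
    system = sp.eye_array(len(nodes), format="csc") - alpha * sp.csc_array(pt)
    solution = spla.spsolve(system, (1.0 - alpha) * v0)
    return PropagatedVector(pd.Series(solution, index=nodes), iterations=0, residual=0.0, alpha=alpha)


def alpha_sweep(
    network: InteractionNetwork,
    m0,
    alphas,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Propagate at each alpha and summarize stability across the sweep.

    Returns the per-alpha mass table (genes x alphas) and a table of
    Spearman rank correlations between consecutive alphas.
    """
    alphas = list(alphas)
    if any(not 0.0 <= a < 1.0 for a in alphas):
        raise ValueError("alphas must lie in [0, 1)")
    columns = {}
    for alpha in alphas:
        result = propagate(network, m0, PropagationConfig(alpha=alpha, tol=tol, max_iter=max_iter))
        columns[alpha] = result.mass
    table = pd.DataFrame(columns)
    rows = []
    for lo, hi in zip(alphas, alphas[1:]):
        rho = spearmanr(table[lo], table[hi]).statistic
        rows.append((lo, hi, float(rho)))
    corrs = pd.DataFrame(rows, columns=["alpha_lo", "alpha_hi", "spearman_rho"])
    return table, corrs


# ---------------------------------------------------------------------------
# TSV interfaces


def read_mutations_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def write_mutations_tsv(mutations: pd.DataFrame, path) -> None:
    mutations.to_csv(path, sep="\t", index=False)


def write_propagated_tsv(m0: MutationVector, result: PropagatedVector, path) -> None:
    frame = pd.DataFrame(
        {"gene": result.mass.index, "m0": m0.mass.reindex(result.mass.index), "m_propagated": result.mass.values}
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_propagated_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"gene": str})
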