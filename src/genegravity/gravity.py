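"""Pairwise gravitation scores and per-gene summaries.

By analogy with Newton's law, two interacting genes attract in proportion
to the product of their (propagated) mutation masses and inversely to the
square of their biological distance r_ij = 1/PCC_ij:

    G_ij = k * M_i * M_j / r_ij^2 = M_i * M_j * PCC_ij^2,   k = 1.

G is stored as a non-negative magnitude together with a sign class taken
from the correlation (attractive for PCC > 0, repulsive for PCC < 0, null
for PCC = 0): cumulative-distribution analyses use the magnitude, AG/RG
analyses use the class. The per-gene summary aveG is the mean G over a
gene's scored partners, and avePCC the mean |PCC| over the same partners.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coexpr import CoexpressionNetwork, sign_class
from .netio import GeneMetadata

GRAVITATION_CONSTANT = 1.0  # the model's k; fixed to avoid silent unit drift


def gravity_score(m_i: float, m_j: float, pcc: float) -> tuple[float, str]:
    """Single-pair gravitation magnitude and sign class."""
    if m_i < 0 or m_j < 0:
        raise ValueError("masses must be non-negative")
    if abs(pcc) > 1:
        raise ValueError("|PCC| must be <= 1")
    return GRAVITATION_CONSTANT * m_i * m_j * pcc * pcc, sign_class(pcc)


def pairwise_gravity(cepin: CoexpressionNetwork, masses) -> pd.DataFrame:
    """One gravity record per CePIN edge.

    ``masses`` maps every CePIN gene to its propagated mutation mass
    (a mapping or pandas Series); missing genes raise with their names.
    Returns columns gene_a, gene_b, pcc, g_score, sign_class.
    """
    if isinstance(masses, pd.Series):
        masses = masses.to_dict()
    elif hasattr(masses, "mass"):  # PropagatedVector / MutationVector
        masses = masses.mass.to_dict()
    edges = cepin.edges
    genes = set(edges["gene_a"]) | set(edges["gene_b"])
    missing = sorted(g for g in genes if g not in masses)
    if missing:
        raise ValueError(f"missing propagated mass for genes: {missing}")
    ma = edges["gene_a"].map(masses).to_numpy(dtype=float)
    mb = edges["gene_b"].map(masses).to_numpy(dtype=float)
    pcc = edges["pcc"].to_numpy(dtype=float)
    table = edges[["gene_a", "gene_b", "pcc", "sign_class"]].copy()
    table["g_score"] = GRAVITATION_CONSTANT * ma * mb * pcc**2
    return table[["gene_a", "gene_b", "pcc", "g_score", "sign_class"]]


def aveg_scores(
    gravity: pd.DataFrame,
    metadata: GeneMetadata | None = None,
    degrees: dict[str, int] | None = None,
    denominator: str = "partners",
) -> pd.DataFrame:
    """Per-gene aveG and avePCC over scored partners.

    aveG_i = sum_j G_ij / n_i where n_i is by default the number of scored
    partners (edges with a defined G); ``denominator="degree"`` divides by
    the full PIN degree instead (requires ``degrees``). avePCC uses |PCC|.
    Genes without any scored edge do not appear.
    """
    if gravity.empty:
        raise ValueError("empty gravity table")
    if denominator not in ("partners", "degree"):
        raise ValueError("denominator must be 'partners' or 'degree'")
    long = pd.concat(
        [
            gravity[["gene_a", "g_score", "pcc"]].rename(columns={"gene_a": "gene"}),
            gravity[["gene_b", "g_score", "pcc"]].rename(columns={"gene_b": "gene"}),
        ],
        ignore_index=True,
    )
    long["abs_pcc"] = long["pcc"].abs()
    grouped = long.groupby("gene").agg(
        g_sum=("g_score", "sum"),
        n_partners=("g_score", "size"),
        avepcc=("abs_pcc", "mean"),
    )
    if denominator == "partners":
        grouped["aveg"] = grouped["g_sum"] / grouped["n_partners"]
    else:
        if degrees is None:
            raise ValueError("degree denominator requires a degree mapping")
        deg = pd.Series(degrees).reindex(grouped.index)
        grouped["aveg"] = grouped["g_sum"] / deg
    scores = grouped.reset_index()[["gene", "aveg", "n_partners", "avepcc"]]
    if degrees is not None:
        scores["degree"] = scores["gene"].map(degrees)
    if metadata is not None:
        scores["chromosome"] = scores["gene"].map(metadata.chromosome)
        scores["cdna_length"] = scores["gene"].map(metadata.cdna_length)
    return scores.sort_values("gene", ignore_index=True)


def split_ag_rg(gravity: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition edges into attractive (PCC > 0) and repulsive (PCC < 0)
    gravitation; null edges belong to neither table."""
    attractive = gravity[gravity["sign_class"] == "attractive"].reset_index(drop=True)
    repulsive = gravity[gravity["sign_class"] == "repulsive"].reset_index(drop=True)
    return attractive, repulsive


def classify_pairs(gravity: pd.DataFrame, geneset) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split edges into set-pairs (>= 1 endpoint in ``geneset``) and
    non-set-pairs (no endpoint in the set)."""
    geneset = set(geneset)
    in_set = gravity["gene_a"].isin(geneset) | gravity["gene_b"].isin(geneset)
    return (
        gravity[in_set].reset_index(drop=True),
        gravity[~in_set].reset_index(drop=True),
    )


@dataclass
class CumulativeCurve:
    """Complementary cumulative distribution C(g) = fraction of scores >= g."""

    thresholds: np.ndarray
    fraction: np.ndarray

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.fraction = np.asarray(self.fraction, dtype=float)


def default_grid(scores: np.ndarray, n_points: int = 200) -> np.ndarray:
    """0 plus ``n_points`` log-spaced thresholds spanning the positive scores."""
    positive = scores[scores > 0]
    if positive.size == 0:
        return np.array([0.0])
    lo, hi = positive.min(), positive.max()
    if lo == hi:
        grid = np.array([lo])
    else:
        grid = np.geomspace(lo, hi, n_points)
    return np.concatenate([[0.0], grid])


def complementary_cumulative(scores, grid=None) -> CumulativeCurve:
    """Survival curve of a score list on a threshold grid."""
    scores = np.asarray(list(scores), dtype=float)
    if scores.size == 0:
        raise ValueError("empty score list")
    if grid is None:
        grid = default_grid(scores)
    grid = np.asarray(grid, dtype=float)
    sorted_scores = np.sort(scores)
    # count of scores >= g via searchsorted on the ascending sort
    counts = scores.size - np.searchsorted(sorted_scores, grid, side="left")
    return CumulativeCurve(grid, counts / scores.size)


# ---------------------------------------------------------------------------
# TSV interfaces


def write_gravity_tsv(gravity: pd.DataFrame, path) -> None:
    gravity.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_gravity_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str, "sign_class": str})


def write_scores_tsv(scores: pd.DataFrame, path) -> None:
    scores.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_scores_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"gene": str, "chromosome": str})
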