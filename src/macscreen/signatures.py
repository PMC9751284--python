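"""Gene-set signature scoring and compound-level transcriptome analysis.

Wells are scored against named gene lists (ASC signature, pro-apoptotic
signature) by a rank-based recovery-curve AUC over all expressed genes:
genes are ranked by decreasing expression, the cumulative count of set genes
is traced over the top fraction of ranks, and the area under that step curve
is normalized by its maximum.  Being rank-based, the score is invariant to
any monotone normalization of expression.

The module also provides compound embedding/clustering (PCA -> shared-
nearest-neighbour graph -> seeded community detection at a chosen
resolution) and the multi-parameter selection that flags compounds raising
ASC differentiation with or without a concurrent loss of cell number.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "GeneSet",
    "auc_signature_score",
    "score_wells",
    "correlate_scores",
    "embed_compounds",
    "select_multiparameter",
]


@dataclass(frozen=True)
class GeneSet:
    """A named, non-empty list of unique gene ids."""

    name: str
    genes: tuple

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValueError("gene set must be non-empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene ids must be unique")

    @classmethod
    def from_iterable(cls, name: str, genes) -> "GeneSet":
        return cls(name, tuple(genes))


def auc_signature_score(
    expression: pd.Series, gene_set: GeneSet, top_fraction: float = 0.05
) -> float:
    """Recovery-curve AUC of a gene set in one well's expression profile.

    Genes are ranked by decreasing expression with stable ties broken by
    gene id; the recovery curve is the cumulative number of set genes at
    ranks ``1..ceil(top_fraction * G)``; the score is the area under that
    step curve divided by the maximal achievable area.  Lies in [0, 1]:
    1 when all set genes occupy the very top ranks, 0 when none reach the
    cutoff.
    """
    if not 0 < top_fraction < 1:
        raise ValueError("top_fraction must be in (0, 1)")
    universe = expression.index
    in_set = universe.isin(gene_set.genes)
    if not in_set.any():
        raise ValueError(f"gene set {gene_set.name!r} disjoint from universe")
    # stable sort on gene id first, then descending expression
    ordered = expression.sort_index(kind="stable")
    ordered = ordered.sort_values(ascending=False, kind="stable")
    cutoff = int(np.ceil(top_fraction * len(universe)))
    hits = ordered.index[:cutoff].isin(gene_set.genes)
    cum = np.cumsum(hits)
    m = min(len(gene_set.genes), int(in_set.sum()))
    max_cum = np.minimum(np.arange(1, cutoff + 1), m)
    return float(cum.sum() / max_cum.sum())


def score_wells(
    matrix: pd.DataFrame,
    gene_sets: dict[str, GeneSet],
    top_fraction: float = 0.05,
) -> pd.DataFrame:
    """AUC score of every well (column) against every gene set."""
    rows = {
        well: {
            name: auc_signature_score(matrix[well], gs, top_fraction)
            for name, gs in gene_sets.items()
        }
        for well in matrix.columns
    }
    return pd.DataFrame.from_dict(rows, orient="index")


def correlate_scores(x, y) -> tuple[float, float]:
    """Pearson correlation and two-sided p (exact t transform)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size != x.size:
        raise ValueError("need >= 3 paired wells")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("scores must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("undefined correlation: zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def _snn_graph(pcs: np.ndarray, n_neighbors: int) -> ig.Graph:
    """Shared-nearest-neighbour graph with Jaccard edge weights."""
    n = pcs.shape[0]
    nn = NearestNeighbors(n_neighbors=min(n_neighbors, n)).fit(pcs)
    _, idx = nn.kneighbors(pcs)
    neighbor_sets = [set(row) for row in idx]
    edges, weights = [], []
    for i in range(n):
        for j in idx[i]:
            if j <= i:
                continue
            shared = len(neighbor_sets[i] & neighbor_sets[int(j)])
            union = len(neighbor_sets[i] | neighbor_sets[int(j)])
            w = shared / union
            if w > 0:
                edges.append((i, int(j)))
                weights.append(w)
    g = ig.Graph(n=n, edges=edges)
    g.es["weight"] = weights
    return g


def embed_compounds(
    normalized: pd.DataFrame,
    n_pcs: int = 10,
    resolution: float = 2.0,
    n_neighbors: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Embed and cluster wells from a normalized genes x wells matrix.

    Standardizes genes, projects onto the top ``n_pcs`` principal
    components, builds a shared-nearest-neighbour graph and partitions it
    with seeded resolution-parameterized community detection.  Returns one
    row per well with columns dim1, dim2 (first two PCs, for plotting only)
    and cluster; the partition is the contract, the layout is decorative.
    """
    wells = normalized.columns
    if len(wells) < n_pcs + 1:
        raise ValueError("need at least n_pcs + 1 wells")
    X = normalized.to_numpy(dtype=float).T  # wells x genes
    sd = X.std(axis=0)
    keep = sd > 0
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    pcs = PCA(n_components=min(n_pcs, min(X.shape) - 1), random_state=seed).fit_transform(X)
    graph = _snn_graph(pcs, n_neighbors=n_neighbors)
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
    )
    return pd.DataFrame(
        {
            "dim1": pcs[:, 0],
            "dim2": pcs[:, 1] if pcs.shape[1] > 1 else 0.0,
            "cluster": part.membership,
        },
        index=wells,
    )


_CATEGORIES = (
    "diff-up, number-preserved",
    "diff-up, number-down",
    "number-down only",
    "none",
)


def select_multiparameter(
    scores: pd.DataFrame,
    control_wells,
    z_hi: float = 2.0,
    z_lo: float = -2.0,
) -> pd.DataFrame:
    """Multi-parameter compound selection from per-well summary scores.

    ``scores`` has one row per well with columns ``cd138_expression`` and
    ``cell_number`` (plus anything else, carried through).  z-scores are
    computed against the mean/SD of the control wells; categories:

    * ``diff-up, number-preserved`` — CD138 z >= z_hi, |cell-number z| < z_hi
      (differentiation boosted, numbers intact);
    * ``diff-up, number-down`` — CD138 z >= z_hi and cell-number z <= z_lo
      (differentiation boosted at the cost of survival);
    * ``number-down only`` — cell-number z <= z_lo alone;
    * ``none`` otherwise.
    """
    control_wells = list(control_wells)
    if len(control_wells) < 3:
        raise ValueError("need >= 3 control wells")
    ctrl = scores.loc[control_wells]
    out = scores.copy()
    for col in ("cd138_expression", "cell_number"):
        mu = ctrl[col].mean()
        sd = ctrl[col].std(ddof=1)
        if sd == 0:
            raise ValueError(f"degenerate control distribution for {col}")
        out[f"z_{col}"] = (scores[col] - mu) / sd
    zc = out["z_cd138_expression"]
    zn = out["z_cell_number"]
    cat = np.select(
        [
            (zc >= z_hi) & (np.abs(zn) < z_hi),
            (zc >= z_hi) & (zn <= z_lo),
            zn <= z_lo,
        ],
        _CATEGORIES[:3],
        default=_CATEGORIES[3],
    )
    out["category"] = cat
    return out
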