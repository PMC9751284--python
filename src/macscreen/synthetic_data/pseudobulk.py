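"""Per-well pseudo-bulk count generation carrying signature structure.

Each well's transcriptome is sampled for a fixed aliquot of cells (5000 by
convention) as negative-binomial counts whose means are baseline expression
levels modulated by the well's phenotypic state: genes in the ASC signature
scale with the differentiated (CD138+) fraction of live cells, genes in the
pro-apoptotic signature with the dead fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cyton import PopulationState

__all__ = ["GeneModel", "sample_pseudobulk", "default_gene_model"]


@dataclass
class GeneModel:
    """Generative expression model for a toy transcriptome.

    ``baseline`` maps gene id -> mean expression (arbitrary units, > 0).
    Genes in ``asc_set`` have their means multiplied by ``1 + k_asc * f_ASC``
    where ``f_ASC`` is the differentiated fraction of live cells; genes in
    ``apoptotic_set`` by ``1 + k_apop * f_dead``.  Counts are negative
    binomial with a common dispersion (variance = mu + dispersion * mu^2).
    """

    baseline: pd.Series
    asc_set: frozenset = frozenset()
    apoptotic_set: frozenset = frozenset()
    k_asc: float = 10.0
    k_apop: float = 10.0
    dispersion: float = 0.1

    def __post_init__(self) -> None:
        if (self.baseline <= 0).any():
            raise ValueError("baseline means must be > 0")
        genes = set(self.baseline.index)
        if not set(self.asc_set) <= genes or not set(self.apoptotic_set) <= genes:
            raise ValueError("signature sets must be subsets of the gene universe")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")

    @property
    def genes(self) -> pd.Index:
        return self.baseline.index


def default_gene_model(
    n_genes: int = 200,
    n_asc: int = 20,
    n_apop: int = 20,
    k_asc: float = 10.0,
    k_apop: float = 10.0,
    dispersion: float = 0.1,
    seed: int | np.random.Generator = 0,
) -> GeneModel:
    """A toy transcriptome with disjoint ASC and pro-apoptotic signatures.

    Baseline means are lognormal (a heavy-tailed abundance distribution, as in
    real libraries); the first ``n_asc`` genes form the ASC set and the next
    ``n_apop`` the pro-apoptotic set.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ids = [f"gene{i:04d}" for i in range(n_genes)]
    means = rng.lognormal(mean=2.0, sigma=1.0, size=n_genes) + 0.5
    return GeneModel(
        baseline=pd.Series(means, index=ids),
        asc_set=frozenset(ids[:n_asc]),
        apoptotic_set=frozenset(ids[n_asc : n_asc + n_apop]),
        k_asc=k_asc,
        k_apop=k_apop,
        dispersion=dispersion,
    )


def sample_pseudobulk(
    state: PopulationState,
    model: GeneModel,
    depth: int = 100_000,
    seed: int | np.random.Generator = 0,
) -> pd.Series:
    """Sample one well's UMI counts from the population state.

    Means are ``baseline * (1 + k_asc * f_ASC)`` for ASC-signature genes and
    ``baseline * (1 + k_apop * f_dead)`` for pro-apoptotic genes, rescaled so
    the expected library size equals ``depth``; counts are negative binomial.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    n_live = state.live.sum() + state.asc.sum()
    if n_live <= 0:
        raise ValueError("zero live cells: nothing to sequence")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    f_asc = state.asc.sum() / n_live
    f_dead = state.dead_cum / (n_live + state.dead_cum)
    mu = model.baseline.to_numpy(dtype=float).copy()
    is_asc = model.baseline.index.isin(model.asc_set)
    is_apop = model.baseline.index.isin(model.apoptotic_set)
    mu[is_asc] *= 1.0 + model.k_asc * f_asc
    mu[is_apop] *= 1.0 + model.k_apop * f_dead
    mu *= depth / mu.sum()

    if model.dispersion == 0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / model.dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    return pd.Series(counts, index=model.genes, name="counts")
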