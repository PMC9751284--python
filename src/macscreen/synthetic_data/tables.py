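"""Synthetic per-gene differential tables (promoter H3K27me3 and RNA logFC).

Emulates the style of output of an upstream differential pipeline: one row
per gene with a log2 fold-change and an adjusted p-value, with an optional
negative coupling between the methylation change and the expression change
(loss of the repressive mark derepresses the gene).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["simulate_methylation_rna_tables"]


def simulate_methylation_rna_tables(
    n_genes: int = 2000,
    coupling: float = -0.5,
    meth_sd: float = 1.2,
    rna_noise_sd: float = 0.3,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired methylation and RNA logFC tables with linear coupling.

    Methylation logFC ~ Normal(0, meth_sd); RNA logFC =
    ``coupling * meth_logFC + Normal(0, rna_noise_sd)``.  Adjusted p-values
    are generated monotone in |logFC| (purely decorative ranking noise).

    Returns ``(meth_table, rna_table)``, each with columns gene, logFC,
    adj_p indexed by gene.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    genes = [f"gene{i:05d}" for i in range(n_genes)]
    meth = rng.normal(0.0, meth_sd, n_genes)
    rna = coupling * meth + rng.normal(0.0, rna_noise_sd, n_genes)

    def table(lfc: np.ndarray) -> pd.DataFrame:
        adj_p = np.exp(-np.abs(lfc) * 2.0) * rng.uniform(0.5, 1.0, n_genes)
        return pd.DataFrame(
            {"gene": genes, "logFC": lfc, "adj_p": np.clip(adj_p, 0.0, 1.0)}
        ).set_index("gene")

    return table(meth), table(rna)
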