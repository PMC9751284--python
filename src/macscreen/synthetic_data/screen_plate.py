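"""Synthetic arrayed CRISPR screen plates.

One guide per well, read out as the percentage of CD138+ cells by flow
cytometry, with an untreated arm and a drug-treated arm (the drug adds a
constant differentiation boost unless a gene's knockout abolishes it), plus
uninfected control wells in each arm.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["synthesize_crispr_plate"]


def synthesize_crispr_plate(
    gene_effects: pd.DataFrame,
    base_cd138: float = 20.0,
    drug_boost: float = 15.0,
    noise_sd: float = 2.0,
    replicates: int = 2,
    guides_per_gene: int = 1,
    n_uninfected: int = 4,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Build a two-arm arrayed screen plate.

    ``gene_effects`` is indexed by gene with columns ``effect_untreated`` and
    ``effect_treated`` (percentage-point shifts of CD138+ relative to the
    uninfected baseline of each arm).  Untreated wells read
    ``base + effect_untreated + noise``; treated wells read
    ``base + drug_boost + effect_treated + noise``; uninfected wells carry no
    gene effect.  Readouts are clamped to [0, 100].

    Returns a tidy plate table with columns well, gene, guide, replicate,
    treated, cd138_pct (gene is ``"uninfected"`` for control wells).
    """
    if not 0 <= base_cd138 <= 100:
        raise ValueError("base_cd138 must lie in [0, 100]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    rows = []
    for treated in (False, True):
        arm_base = base_cd138 + (drug_boost if treated else 0.0)
        for gene, eff in gene_effects.iterrows():
            shift = eff["effect_treated"] if treated else eff["effect_untreated"]
            for g in range(1, guides_per_gene + 1):
                for rep in range(1, replicates + 1):
                    rows.append((gene, f"{gene}_g{g}", rep, treated, arm_base + shift))
        for rep in range(1, n_uninfected + 1):
            rows.append(("uninfected", "none", rep, treated, arm_base))
    plate = pd.DataFrame(
        rows, columns=["gene", "guide", "replicate", "treated", "cd138_pct"]
    )
    plate["cd138_pct"] = np.clip(
        plate["cd138_pct"] + rng.normal(0.0, noise_sd, len(plate)), 0.0, 100.0
    )
    plate.insert(0, "well", [f"W{i:03d}" for i in range(len(plate))])
    return plate
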