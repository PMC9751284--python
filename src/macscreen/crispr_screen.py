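"""Arrayed CRISPR screen metrics.

Two readouts from one-guide-per-well plates scored by the percentage of
CD138+ cells:

* the untreated differentiation effect of each knockout — the mean shift in
  CD138+ relative to uninfected wells, ranked so that knockouts that boost
  differentiation (e.g. PRC2 components) rank first and knockouts of core
  differentiation factors rank last;
* the drug-dependence score — the treated-minus-untreated CD138 difference
  per gene, standardized across the plate's genes, where genes whose
  knockout abolishes the drug response fall far below the plate mean and are
  called hits at a z cutoff (default -1).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["untreated_ranking", "dependence_zscores", "UNINFECTED"]

UNINFECTED = "uninfected"


def _gene_means(plate: pd.DataFrame, treated: bool) -> pd.Series:
    """Replicates averaged per guide, then guides averaged per gene."""
    arm = plate[plate["treated"] == treated]
    per_guide = arm.groupby(["gene", "guide"])["cd138_pct"].mean()
    return per_guide.groupby("gene").mean()


def untreated_ranking(plate: pd.DataFrame) -> pd.DataFrame:
    """Per-gene CD138 shift vs uninfected wells in the untreated arm.

    ``delta_untreated`` is in percentage points; the table is sorted
    descending (ties broken by gene id) so differentiation-boosting
    knockouts come first.
    """
    means = _gene_means(plate, treated=False)
    if UNINFECTED not in means.index:
        raise ValueError("no uninfected wells in the untreated arm")
    baseline = means[UNINFECTED]
    delta = (means.drop(UNINFECTED) - baseline).rename("delta_untreated")
    out = delta.reset_index().sort_values(
        ["delta_untreated", "gene"], ascending=[False, True], kind="stable"
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out.set_index("gene")


def dependence_zscores(
    plate: pd.DataFrame, z_cutoff: float = -1.0, robust: bool = False
) -> pd.DataFrame:
    """Drug-dependence score per gene with hit calls at ``z <= z_cutoff``.

    For each gene, ``delta_dependence`` = mean treated CD138 - mean
    untreated CD138 (replicates averaged per guide, guides per gene);
    z-scores standardize these deltas over the plate's genes (uninfected
    wells are excluded from the reference distribution).  ``robust`` swaps
    mean/SD for median/1.4826*MAD.  Genes are ranked descending in z, so
    dependence-abolishing hits occupy the bottom ranks.
    """
    treated = _gene_means(plate, treated=True).drop(UNINFECTED, errors="ignore")
    untreated = _gene_means(plate, treated=False).drop(UNINFECTED, errors="ignore")
    missing = treated.index.symmetric_difference(untreated.index)
    if len(missing):
        raise ValueError(f"genes missing one arm: {sorted(missing)}")
    if len(treated) < 3:
        raise ValueError("need >= 3 genes for a z-score reference")
    d = (treated - untreated).rename("delta_dependence")
    if robust:
        center = d.median()
        scale = 1.4826 * (d - center).abs().median()
    else:
        center = d.mean()
        scale = d.std(ddof=1)
    if scale == 0 or not np.isfinite(scale):
        warnings.warn("degenerate delta distribution: all z set to 0, no hits")
        z = pd.Series(0.0, index=d.index)
    else:
        z = (d - center) / scale
    out = pd.DataFrame({"delta_dependence": d, "z": z})
    out["hit"] = (out["z"] <= z_cutoff) & (scale > 0)
    # descending: strongest positive dependence first, hits at the bottom
    out = out.sort_index(kind="stable").sort_values(
        "z", ascending=False, kind="stable"
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out
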