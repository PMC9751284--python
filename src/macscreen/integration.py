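"""Integration of promoter H3K27me3 changes with expression changes.

Consumes per-gene log2 fold-change / adjusted-p tables produced by an
upstream differential pipeline (or the synthetic generator), applies the
standard DEG threshold filter, bins genes by the magnitude and direction of
their promoter methylation change, and compares the RNA logFC distribution
across bins — the readout that reveals the inverse correlation between the
repressive mark and expression.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BINS",
    "filter_degs",
    "bin_methylation_changes",
    "expression_by_bin",
]

# ordered from strongest loss to strongest gain of the mark
BINS = ("High down", "Mid down", "Low down", "Low up", "Mid up", "High up")
_LOW_BINS = ("Low down", "Low up")


def _validate(table: pd.DataFrame, need_p: bool = True) -> None:
    if "logFC" not in table.columns:
        raise ValueError("table must have a logFC column")
    if not np.isfinite(table["logFC"]).all():
        raise ValueError("logFC must be finite")
    if need_p:
        p = table["adj_p"]
        if ((p < 0) | (p > 1)).any():
            raise ValueError("adjusted p-values must lie in [0, 1]")


def filter_degs(
    table: pd.DataFrame, fc_thr: float = 1.0, adjp_thr: float = 0.05
) -> pd.DataFrame:
    """Differentially expressed genes at |logFC| >= fc_thr and adj p <= thr.

    Both boundaries are inclusive.  Returns the retained rows with an added
    ``direction`` column ("up"/"down" by the sign of logFC).
    """
    if fc_thr <= 0 or adjp_thr <= 0:
        raise ValueError("thresholds must be > 0")
    _validate(table)
    keep = (table["logFC"].abs() >= fc_thr) & (table["adj_p"] <= adjp_thr)
    out = table[keep].copy()
    out["direction"] = np.where(out["logFC"] > 0, "up", "down")
    return out


def bin_methylation_changes(meth: pd.DataFrame) -> pd.Series:
    """Bin genes by promoter methylation logFC.

    High down: logFC < -2; Mid down: [-2, -1); Low down: [-1, 0);
    Low up: (0, 1]; Mid up: (1, 2]; High up: > 2.  A logFC of exactly 0
    belongs to no bin and is labelled ``"excluded"``.
    """
    _validate(meth, need_p=False)
    lfc = meth["logFC"]
    label = np.select(
        [
            lfc < -2,
            (lfc >= -2) & (lfc < -1),
            (lfc >= -1) & (lfc < 0),
            (lfc > 0) & (lfc <= 1),
            (lfc > 1) & (lfc <= 2),
            lfc > 2,
        ],
        BINS,
        default="excluded",
    )
    return pd.Series(label, index=meth.index, name="bin")


def expression_by_bin(
    rna: pd.DataFrame,
    bins: pd.Series,
    baseline_bins: tuple = _LOW_BINS,
    all_pairs: bool = False,
) -> pd.DataFrame:
    """RNA logFC distribution per methylation-change bin.

    For each non-empty bin reports n, median and IQR of the RNA logFC, plus
    a two-sided Wilcoxon rank-sum p-value against the pooled baseline bins
    (the minimal-methylation-change genes) — or, with ``all_pairs``, the
    smallest Bonferroni-adjusted p over all pairwise comparisons.
    """
    _validate(rna, need_p=False)
    shared = rna.index.intersection(bins.index)
    lfc = rna.loc[shared, "logFC"]
    lab = bins.loc[shared]
    groups = {
        b: lfc[lab == b].to_numpy() for b in BINS if (lab == b).sum() > 0
    }
    if len(groups) < 2:
        raise ValueError("need >= 2 non-empty bins")
    baseline = np.concatenate(
        [groups.get(b, np.empty(0)) for b in baseline_bins]
    )
    if baseline.size == 0 and not all_pairs:
        raise ValueError("empty baseline: no genes in the Low bins")
    rows = []
    names = list(groups)
    for b, vals in groups.items():
        if all_pairs:
            ps = [
                stats.mannwhitneyu(vals, groups[o], alternative="two-sided").pvalue
                for o in names
                if o != b
            ]
            p = min(1.0, min(ps) * len(ps)) if ps else np.nan
        else:
            p = float(
                stats.mannwhitneyu(vals, baseline, alternative="two-sided").pvalue
            )
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows.append(
            {
                "bin": b,
                "n": vals.size,
                "median": med,
                "iqr": q3 - q1,
                "p_vs_baseline": p,
            }
        )
    out = pd.DataFrame(rows).set_index("bin")
    return out.loc[[b for b in BINS if b in out.index]]
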