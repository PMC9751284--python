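"""Quantitative flow-cytometry framework for the B-cell response.

Implements bead-calibrated absolute counting, dye-dilution division
assignment, precursor-cohort statistics and the two-timepoint compound
classification:

* absolute live-cell number from the live-cell : calibration-bead event
  ratio (a known number of beads is spiked into each sample);
* generation assignment from CTV-like intensity (the dye halves at each
  division);
* cohort numbers ``C_i = N_i / 2**i``, which remove the effect of division
  so founder-cohort survival can be followed, and the cohort-weighted mean
  division number (MDN) summarizing proliferation kinetics;
* per-compound classification of the three response axes — survival from
  24 hr absolute counts (before cells enter division), proliferation from
  72 hr MDN, differentiation from 72 hr CD138+ percentage — by ANOVA with
  Bonferroni-corrected contrasts against control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DivisionCensus",
    "CompoundClassification",
    "absolute_count",
    "assign_divisions",
    "build_census",
    "cohort_numbers",
    "mean_division_number",
    "differentiation_fraction",
    "classify_compound",
    "classify_plate",
]


@dataclass
class DivisionCensus:
    """Bead-calibrated per-generation counts.

    ``counts[i]`` is the absolute number of live cells assigned to
    generation ``i``; ``cd138_counts[i]`` the CD138+ subset thereof.
    """

    counts: np.ndarray
    cd138_counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.cd138_counts = np.asarray(self.cd138_counts, dtype=float)
        if self.counts.shape != self.cd138_counts.shape:
            raise ValueError("counts and cd138_counts must align")
        if (self.counts < 0).any() or (self.cd138_counts < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.cd138_counts > self.counts + 1e-9).any():
            raise ValueError("cd138_counts cannot exceed counts")


@dataclass
class CompoundClassification:
    """Direction call per response axis with the supporting p-values."""

    compound_id: str
    survival: str
    proliferation: str
    differentiation: str
    p_survival: float
    p_proliferation: float
    p_differentiation: float


def absolute_count(
    n_live_events: float, n_bead_events: float, beads_added: float = 10_000
) -> float:
    """Absolute live-cell number from the live : bead event ratio."""
    if n_bead_events <= 0:
        raise ValueError("calibration failure: no bead events acquired")
    return n_live_events / n_bead_events * beads_added


def assign_divisions(intensities, i0: float, max_gen: int = 8) -> np.ndarray:
    """Generation per event: ``round(log2(i0 / intensity))`` clamped to range.

    Bin edges sit at half-integer log2 distances from the undivided
    reference intensity ``i0``.
    """
    x = np.asarray(intensities, dtype=float)
    if i0 <= 0:
        raise ValueError("i0 must be > 0")
    if (x <= 0).any():
        raise ValueError("intensities must be > 0")
    gen = np.rint(np.log2(i0 / x))
    return np.clip(gen, 0, max_gen).astype(int)


def build_census(
    events: pd.DataFrame,
    i0: float,
    max_gen: int = 8,
    beads_added: float | None = None,
) -> DivisionCensus:
    """Bead-calibrated division census from a flow event table.

    Expects boolean columns ``is_bead``, ``viable``, ``cd138`` and a float
    column ``ctv``.  Live cells are viable non-bead events; each per-
    generation event count is scaled to absolute numbers by the bead ratio.
    """
    if beads_added is None:
        beads_added = events.attrs.get("beads_added", 10_000)
    n_beads = int(events["is_bead"].sum())
    if n_beads == 0:
        raise ValueError("calibration failure: no bead events in table")
    live = events[~events["is_bead"] & events["viable"]]
    gen = assign_divisions(live["ctv"].to_numpy(), i0, max_gen)
    counts = np.bincount(gen, minlength=max_gen + 1).astype(float)
    cd138 = np.bincount(
        gen, weights=live["cd138"].to_numpy(dtype=float), minlength=max_gen + 1
    )
    scale = beads_added / n_beads
    return DivisionCensus(counts * scale, cd138 * scale)


def cohort_numbers(census: DivisionCensus) -> np.ndarray:
    """Cohort numbers ``C_i = N_i / 2**i`` (division-corrected counts)."""
    i = np.arange(census.counts.size)
    return census.counts / 2.0**i


def mean_division_number(
    census: DivisionCensus, exclude_undivided: bool = False
) -> float:
    """Cohort-weighted mean division number of responding cells.

    ``MDN = Σ i·C_i / Σ C_i``.  With ``exclude_undivided`` the generation-0
    cohort is dropped before averaging (an optional activation gate).
    """
    c = cohort_numbers(census)
    i = np.arange(c.size, dtype=float)
    if exclude_undivided:
        c = c[1:]
        i = i[1:]
    total = c.sum()
    if total <= 0:
        raise ValueError("undefined MDN: empty cohort")
    return float((i * c).sum() / total)


def differentiation_fraction(census: DivisionCensus) -> float:
    """Percentage of live cells that are CD138+."""
    total = census.counts.sum()
    if total <= 0:
        raise ValueError("empty census")
    return float(100.0 * census.cd138_counts.sum() / total)


_AXES = ("survival", "proliferation", "differentiation")

# Minimum relative change vs control for a direction call.  A statistically
# significant but small shift stays "none": with thousands of events per well
# the contrasts resolve shifts far below biological relevance, and the CD138%
# readout is division-linked (a proliferation change drags differentiation
# along at roughly its own relative magnitude), so the differentiation axis
# carries a wider band than the kinetic axes.
DEFAULT_MIN_EFFECT = {
    "survival": 0.15,
    "proliferation": 0.10,
    "differentiation": 0.40,
}


def _axis_call(
    treated: np.ndarray,
    control: np.ndarray,
    alpha: float,
    n_comparisons: int,
    min_rel_effect: float,
) -> tuple[str, float]:
    """Welch t contrast vs control, Bonferroni-corrected, effect-gated."""
    t, p = stats.ttest_ind(treated, control, equal_var=False)
    p_adj = min(1.0, float(p) * n_comparisons)
    if not np.isfinite(p_adj):
        return "none", 1.0
    mc = np.mean(control)
    rel = np.abs(np.mean(treated) - mc) / max(np.abs(mc), 1e-12)
    if p_adj > alpha or rel < min_rel_effect:
        return "none", p_adj
    return ("up" if np.mean(treated) > mc else "down"), p_adj


def classify_compound(
    treated: pd.DataFrame,
    control: pd.DataFrame,
    alpha: float = 0.05,
    n_comparisons: int = 1,
    compound_id: str = "compound",
    min_effect: dict | None = None,
) -> CompoundClassification:
    """Classify one compound's effect on the three response axes.

    ``treated`` and ``control`` carry one row per replicate with columns
    ``count_24h`` (absolute live number at 24 hr), ``mdn_72h`` and
    ``cd138_pct_72h``.  Each axis is labelled by a Bonferroni-corrected
    contrast against control (``n_comparisons`` is the number of compounds
    sharing the correction); an axis is "none" unless the corrected p is
    <= alpha AND the relative change exceeds the axis' minimum effect size;
    direction follows the sign of the mean difference.
    """
    min_effect = {**DEFAULT_MIN_EFFECT, **(min_effect or {})}
    for df, name in ((treated, "treated"), (control, "control")):
        if len(df) < 2:
            raise ValueError(f"need >= 2 {name} replicates per timepoint")
        missing = {"count_24h", "mdn_72h", "cd138_pct_72h"} - set(df.columns)
        if missing:
            raise ValueError(f"missing replicate columns: {sorted(missing)}")
    calls = {}
    for axis, col in zip(_AXES, ("count_24h", "mdn_72h", "cd138_pct_72h")):
        calls[axis] = _axis_call(
            treated[col].to_numpy(),
            control[col].to_numpy(),
            alpha,
            n_comparisons,
            min_effect[axis],
        )
    return CompoundClassification(
        compound_id=compound_id,
        survival=calls["survival"][0],
        proliferation=calls["proliferation"][0],
        differentiation=calls["differentiation"][0],
        p_survival=calls["survival"][1],
        p_proliferation=calls["proliferation"][1],
        p_differentiation=calls["differentiation"][1],
    )


def classify_plate(
    replicates: pd.DataFrame,
    control_id: str = "control",
    alpha: float = 0.05,
    min_effect: dict | None = None,
) -> pd.DataFrame:
    """Classify every compound on a plate against the control wells.

    ``replicates`` has one row per well with columns compound_id, count_24h,
    mdn_72h, cd138_pct_72h.  For each axis a one-way ANOVA across all groups
    gates the per-compound contrasts: if the ANOVA is not significant at
    ``alpha`` every compound is labelled "none" on that axis; otherwise each
    compound is contrasted against control with Bonferroni correction over
    the number of compounds.
    """
    groups = {cid: g for cid, g in replicates.groupby("compound_id")}
    if control_id not in groups:
        raise ValueError(f"no control wells labelled {control_id!r}")
    control = groups.pop(control_id)
    n_comp = len(groups)
    anova_ok = {}
    for axis, col in zip(_AXES, ("count_24h", "mdn_72h", "cd138_pct_72h")):
        samples = [g[col].to_numpy() for g in groups.values()] + [
            control[col].to_numpy()
        ]
        _, p = stats.f_oneway(*samples)
        anova_ok[axis] = bool(np.isfinite(p) and p <= alpha)
    rows = []
    for cid, g in sorted(groups.items()):
        cls = classify_compound(
            g, control, alpha=alpha, n_comparisons=n_comp, compound_id=cid,
            min_effect=min_effect,
        )
        row = {
            "compound_id": cid,
            "survival": cls.survival if anova_ok["survival"] else "none",
            "proliferation": cls.proliferation if anova_ok["proliferation"] else "none",
            "differentiation": (
                cls.differentiation if anova_ok["differentiation"] else "none"
            ),
            "p_survival": cls.p_survival,
            "p_proliferation": cls.p_proliferation,
            "p_differentiation": cls.p_differentiation,
        }
        rows.append(row)
    return pd.DataFrame(rows).set_index("compound_id")
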