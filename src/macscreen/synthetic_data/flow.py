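"""Flow-cytometry event sampling from a simulated population census.

Emulates acquisition of a dye-dilution (CTV-like) stained culture to which a
known number of calibration beads and a viability dye have been added: live
generation-``i`` cells appear at intensity ``i0 / 2**i`` with lognormal
staining noise, differentiated cells carry a CD138 flag, dead cells appear as
non-viable events, and beads are acquired at the same fraction as cells so
that the live-cell : bead ratio is an unbiased estimator of absolute number.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cyton import PopulationState

__all__ = ["sample_flow_events", "DEFAULT_I0", "DEFAULT_BEADS"]

DEFAULT_I0 = 1.0e4  # undivided-cell CTV intensity, arbitrary units
DEFAULT_BEADS = 10_000  # calibration beads added per sample


def sample_flow_events(
    state: PopulationState,
    beads_added: int = DEFAULT_BEADS,
    ctv_cv: float = 0.10,
    acquisition_fraction: float = 0.3,
    i0: float = DEFAULT_I0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Sample an event table from a population census.

    Each live cell (and each bead) is acquired independently with probability
    ``acquisition_fraction``.  Live generation-``i`` events get intensity
    ``i0 / 2**i`` times multiplicative lognormal noise with coefficient of
    variation ``ctv_cv``; dead cells are emitted as non-viable events at
    undivided intensity.

    Returns a DataFrame with columns ``ctv`` (float), ``cd138``, ``viable``,
    ``is_bead`` (bool) and attrs ``beads_added``.
    """
    if beads_added <= 0:
        raise ValueError("beads_added must be > 0")
    if ctv_cv < 0:
        raise ValueError("ctv_cv must be >= 0")
    if not 0 < acquisition_fraction <= 1:
        raise ValueError("acquisition_fraction must be in (0, 1]")
    total = state.live.sum() + state.asc.sum() + state.dead_cum
    if total <= 0:
        raise ValueError("cannot sample events from an empty population state")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    gens, intensities, cd138, viable = [], [], [], []
    for i in range(state.max_gen + 1):
        for count, is_asc in ((state.live[i], False), (state.asc[i], True)):
            k = rng.binomial(int(round(count)), acquisition_fraction)
            if k == 0:
                continue
            gens.append(np.full(k, i))
            intensities.append(np.full(k, i0 / 2.0**i))
            cd138.append(np.full(k, is_asc))
            viable.append(np.ones(k, dtype=bool))
    # dead cells: PI-positive, excluded from live gating downstream
    k_dead = rng.binomial(int(round(state.dead_cum)), acquisition_fraction)
    if k_dead:
        gens.append(np.zeros(k_dead))
        intensities.append(np.full(k_dead, i0))
        cd138.append(np.zeros(k_dead, dtype=bool))
        viable.append(np.zeros(k_dead, dtype=bool))
    k_beads = rng.binomial(beads_added, acquisition_fraction)

    n_cells = sum(arr.size for arr in gens)
    ctv = np.concatenate(intensities) if n_cells else np.empty(0)
    if ctv_cv > 0 and n_cells:
        sdlog = np.sqrt(np.log1p(ctv_cv**2))
        ctv = ctv * rng.lognormal(-0.5 * sdlog**2, sdlog, n_cells)
    events = pd.DataFrame(
        {
            "ctv": np.concatenate([ctv, np.full(k_beads, np.nan)]),
            "cd138": np.concatenate(
                [np.concatenate(cd138) if n_cells else np.empty(0, bool),
                 np.zeros(k_beads, dtype=bool)]
            ),
            "viable": np.concatenate(
                [np.concatenate(viable) if n_cells else np.empty(0, bool),
                 np.ones(k_beads, dtype=bool)]
            ),
            "is_bead": np.concatenate(
                [np.zeros(n_cells, dtype=bool), np.ones(k_beads, dtype=bool)]
            ),
            "true_generation": np.concatenate(
                [np.concatenate(gens) if n_cells else np.empty(0),
                 np.full(k_beads, -1)]
            ).astype(int),
        }
    )
    events.attrs["beads_added"] = beads_added
    events.attrs["acquisition_fraction"] = acquisition_fraction
    events.attrs["i0"] = i0
    return events
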