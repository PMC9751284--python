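"""Synthetic ELISpot well-image stacks with known spot ground truth.

Each well image is a light membrane (constant background) on which every
antibody-secreting cell has left a dark, slightly smoothed disk; Gaussian
camera noise is added on top.  Spot positions are resampled per well with a
minimum separation so connected-component counting is well defined.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = ["synthesize_elispot_stack"]


def synthesize_elispot_stack(
    n_spots,
    spot_radius_px: int = 5,
    spot_depth: float = 25.0,
    bg_level: float = 200.0,
    noise_sd: float = 2.0,
    stack_size: int = 12,
    shape: tuple[int, int] = (128, 128),
    smooth_sigma: float = 0.8,
    margin: int | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Generate a stack of well images plus a per-well truth table.

    ``n_spots`` is either one count for every well or a sequence of length
    ``stack_size``.  Spot centres are drawn uniformly with pairwise
    separation >= 3 * radius (rejection sampling; raises if the packing is
    infeasible).  Truth ``total_area`` is the summed pixel area of the hard
    disks before smoothing.

    The stack stands in for a plate's worth of wells: the downstream median
    projection is only spot-free where fewer than half the wells carry a
    spot at a given pixel, so very small stacks with dense spots would leak
    spots into the background (as they would on a real plate).

    Returns ``(stack, truth)`` where ``stack`` has shape
    ``(stack_size, *shape)`` and ``truth`` has one row per well with columns
    well_index, n_spots, total_area, centroids (list of (row, col)).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = np.broadcast_to(np.asarray(n_spots, dtype=int), (stack_size,))
    if margin is None:
        margin = 3 * spot_radius_px
    h, w = shape
    min_sep = 3.0 * spot_radius_px

    yy, xx = np.mgrid[0:h, 0:w]
    stack = np.empty((stack_size, h, w), dtype=float)
    records = []
    for k in range(stack_size):
        centers: list[tuple[float, float]] = []
        attempts = 0
        while len(centers) < counts[k]:
            cy = rng.uniform(margin, h - margin)
            cx = rng.uniform(margin, w - margin)
            if all(np.hypot(cy - y, cx - x) >= min_sep for y, x in centers):
                centers.append((cy, cx))
            attempts += 1
            if attempts > 10_000:
                raise ValueError("infeasible spot packing for this well geometry")
        disks = np.zeros((h, w))
        area = 0
        for cy, cx in centers:
            disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= spot_radius_px**2
            disks[disk] = 1.0
            area += int(disk.sum())
        depression = spot_depth * ndimage.gaussian_filter(disks, smooth_sigma)
        stack[k] = bg_level - depression + rng.normal(0.0, noise_sd, (h, w))
        records.append(
            {
                "well_index": k,
                "n_spots": int(counts[k]),
                "total_area": area,
                "centroids": centers,
            }
        )
    return stack, pd.DataFrame(records)
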