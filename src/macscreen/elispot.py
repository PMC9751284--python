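"""ELISpot well-image analysis.

Spots are dark precipitate disks left on a light membrane by individual
antibody-secreting cells.  The counting procedure: register the plate's well
images to a common centre, take a pixel-wise median projection across wells
to obtain a spot-free background, subtract each well from that background to
enhance spot contrast, threshold the deviation at a robust multiple of its
noise scale, and count size-filtered connected components.  Spot count and
total spot area are the per-well readouts; the binary mask is kept for
visual validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

__all__ = [
    "SpotResult",
    "register_wells",
    "median_background",
    "detect_spots",
    "analyze_stack",
]


@dataclass
class SpotResult:
    """Per-well spot detection output."""

    n_spots: int
    total_area: int
    mask: np.ndarray
    centroids: list
    areas: list


def _integer_shift(image: np.ndarray, reference: np.ndarray) -> tuple[int, int]:
    """Integer translation maximizing circular cross-correlation with reference."""
    a = image - image.mean()
    b = reference - reference.mean()
    corr = np.real(np.fft.ifft2(np.fft.fft2(b) * np.conj(np.fft.fft2(a))))
    peak = np.unravel_index(np.argmax(corr), corr.shape)
    shift = [int(p) for p in peak]
    for axis, size in enumerate(corr.shape):
        if shift[axis] > size // 2:
            shift[axis] -= size
    return shift[0], shift[1]


def register_wells(stack: np.ndarray) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Align a stack of well images by integer translation.

    Each image is shifted (circularly) by the integer translation maximizing
    its cross-correlation with the stack mean, iterated once.  Returns the
    aligned stack and the applied (row, col) shifts.  Idempotent on an
    already-aligned stack.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("need a stack of >= 2 equally shaped images")
    reference = stack.mean(axis=0)
    aligned = np.empty_like(stack)
    shifts = []
    for k, img in enumerate(stack):
        dy, dx = _integer_shift(img, reference)
        aligned[k] = np.roll(img, (dy, dx), axis=(0, 1))
        shifts.append((dy, dx))
    return aligned, shifts


def median_background(stack: np.ndarray) -> np.ndarray:
    """Pixel-wise median projection: a clean background devoid of spots.

    Spots occupy different positions in different wells, so at any pixel the
    majority of wells show bare membrane and the median suppresses the
    spots.  For an even stack size the lower median (element ``(n-1)//2`` of
    the sorted values) is used, so the background is always an observed
    intensity rather than an average of two.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 3:
        raise ValueError("need a stack of >= 3 images for a spot-free median")
    return np.sort(stack, axis=0)[(stack.shape[0] - 1) // 2]


def detect_spots(
    image: np.ndarray,
    background: np.ndarray,
    k_sigma: float = 5.0,
    min_area: int = 4,
    max_area: int = 2000,
    polarity: str = "dark",
) -> SpotResult:
    """Threshold the background-relative deviation and count components.

    ``deviation = background - image`` for dark spots (``image -
    background`` for light).  The threshold is ``k_sigma`` times a robust
    noise scale (1.4826 x median absolute deviation of the deviation image,
    median-centred); 8-connected components with area in
    ``[min_area, max_area]`` are reported as spots.  Adding a constant to
    both image and background changes nothing.
    """
    image = np.asarray(image, dtype=float)
    background = np.asarray(background, dtype=float)
    if image.shape != background.shape:
        raise ValueError("image and background shapes differ")
    deviation = background - image if polarity == "dark" else image - background
    med = np.median(deviation)
    mad = np.median(np.abs(deviation - med))
    robust_sd = 1.4826 * mad
    if robust_sd == 0:
        if np.all(deviation == 0):
            return SpotResult(0, 0, np.zeros_like(image, dtype=bool), [], [])
        robust_sd = np.std(deviation) or 1.0
    mask = deviation > med + k_sigma * robust_sd
    labels = measure.label(mask, connectivity=2)
    centroids, areas = [], []
    final = np.zeros_like(mask)
    for region in measure.regionprops(labels):
        if min_area <= region.area <= max_area:
            centroids.append(tuple(region.centroid))
            areas.append(int(region.area))
            final[labels == region.label] = True
    return SpotResult(
        n_spots=len(areas),
        total_area=int(sum(areas)),
        mask=final,
        centroids=centroids,
        areas=areas,
    )


def analyze_stack(
    stack: np.ndarray,
    k_sigma: float = 5.0,
    min_area: int = 4,
    max_area: int = 2000,
    register: bool = True,
) -> tuple[pd.DataFrame, list[SpotResult]]:
    """Full per-plate pipeline: register, median background, detect, tally.

    Returns a per-well table (well_index, n_spots, total_area) and the list
    of full :class:`SpotResult` objects (masks included).  Detection runs on
    the aligned images against the shared median background.
    """
    stack = np.asarray(stack, dtype=float)
    aligned = stack
    if register:
        aligned, _ = register_wells(stack)
    background = median_background(aligned)
    results = [
        detect_spots(img, background, k_sigma=k_sigma, min_area=min_area, max_area=max_area)
        for img in aligned
    ]
    table = pd.DataFrame(
        {
            "well_index": np.arange(len(results)),
            "n_spots": [r.n_spots for r in results],
            "total_area": [r.total_area for r in results],
        }
    )
    return table, results
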