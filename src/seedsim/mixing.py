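"""Mixing-uniformity analysis of fluidised seed beds from photographs.

Seeds painted black and white are photographed during fluidisation; each
image is binarized, divided into a square grid (5x5 by default) and the
per-cell white fraction is turned into a particle-count-weighted binary
mixing entropy,

    S = [ sum_j w_j s_j ] / s_max,
    s_j = -(x_j ln x_j + (1 - x_j) ln(1 - x_j)),   w_j = n_j / sum_k n_k,
    s_max = -(xbar ln xbar + (1 - xbar) ln(1 - xbar)),

with the convention 0 ln 0 = 0.  S = 1 marks a fully mixed bed and S = 0
a fully segregated one.  The entropy expression is the standard
grid-based binary mixing entropy (reconstructed; the weighting is by
seed-pixel count per cell).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.filters import threshold_otsu

__all__ = [
    "GridFractions",
    "binarize",
    "grid_fractions",
    "mixing_entropy",
    "entropy_timeseries",
]

BLACK, WHITE, BACKGROUND = 0, 1, -1


@dataclass
class GridFractions:
    """Per-cell seed-pixel counts and white fractions on a square grid."""

    n_pixels: np.ndarray   # (g, g) ints
    x_white: np.ndarray    # (g, g) floats in [0, 1]; NaN for empty cells
    x_bar: float           # overall white fraction

    def __post_init__(self) -> None:
        valid = self.n_pixels > 0
        x = self.x_white[valid]
        if np.any((x < 0) | (x > 1)):
            raise ValueError("cell white fractions must lie in [0, 1]")


def _to_grey(image) -> np.ndarray:
    if isinstance(image, (str, Path)):
        image = Image.open(image)
    if isinstance(image, Image.Image):
        arr = np.asarray(image.convert("L"), dtype=float)
    else:
        arr = np.asarray(image, dtype=float)
        if arr.ndim == 3:
            arr = arr.mean(axis=2)
    return arr


def binarize(
    image,
    threshold: float | str = "otsu",
    crop: tuple[int, int, int, int] | None = None,
    background_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Label pixels as black seed (0), white seed (1) or background (-1).

    ``threshold`` is either a grey-level cut or ``"otsu"``; ``crop`` is an
    optional (row0, row1, col0, col1) box restricting analysis to the bed
    region, and ``background_mask`` marks pixels (True) to exclude.
    """
    grey = _to_grey(image)
    if crop is not None:
        r0, r1, c0, c1 = crop
        grey = grey[r0:r1, c0:c1]
        if background_mask is not None:
            background_mask = background_mask[r0:r1, c0:c1]
    if grey.size == 0:
        raise ValueError("empty image")
    labels = np.full(grey.shape, BACKGROUND, dtype=int)
    seed = np.ones(grey.shape, dtype=bool)
    if background_mask is not None:
        seed &= ~background_mask
    if not seed.any():
        raise ValueError("no seed pixels left after masking")
    vals = grey[seed]
    if threshold == "otsu":
        if np.ptp(vals) == 0:
            thr = vals.flat[0] - 0.5  # uniform image: everything "white"
        else:
            thr = threshold_otsu(vals)
    else:
        thr = float(threshold)
    labels[seed] = np.where(grey[seed] > thr, WHITE, BLACK)
    return labels


def grid_fractions(labels: np.ndarray, grid: int = 5) -> GridFractions:
    """Per-cell seed-pixel counts and white fractions on a grid x grid mesh."""
    if grid < 2:
        raise ValueError("grid must be at least 2 per side")
    n = np.zeros((grid, grid), dtype=int)
    x = np.full((grid, grid), np.nan)
    rows = np.array_split(np.arange(labels.shape[0]), grid)
    cols = np.array_split(np.arange(labels.shape[1]), grid)
    for i, rr in enumerate(rows):
        for j, cc in enumerate(cols):
            cell = labels[np.ix_(rr, cc)]
            seed = cell != BACKGROUND
            n[i, j] = int(seed.sum())
            if n[i, j] > 0:
                x[i, j] = float((cell[seed] == WHITE).mean())
    total = n.sum()
    if total == 0:
        raise ValueError("no seed pixels in any cell")
    x_bar = float(np.nansum(n * np.nan_to_num(x)) / total)
    return GridFractions(n_pixels=n, x_white=x, x_bar=x_bar)


def _binary_entropy(x: float) -> float:
    if x <= 0.0 or x >= 1.0:
        return 0.0
    return -(x * math.log(x) + (1.0 - x) * math.log(1.0 - x))


def mixing_entropy(g: GridFractions) -> float:
    """Normalized mixing entropy S in [0, 1] of a grid of white fractions.

    1 for a uniformly mixed bed (every cell at the overall fraction),
    0 for full segregation (every cell pure).  Undefined (error) when the
    bed is single-coloured overall.
    """
    if g.x_bar <= 0.0 or g.x_bar >= 1.0:
        raise ValueError(
            f"overall white fraction {g.x_bar} leaves the entropy undefined"
        )
    total = g.n_pixels.sum()
    if total == 0:
        raise ValueError("no seed pixels")
    s_max = _binary_entropy(g.x_bar)
    s = 0.0
    for nj, xj in zip(g.n_pixels.flat, g.x_white.flat):
        if nj > 0:
            s += (nj / total) * _binary_entropy(float(xj))
    return s / s_max


def entropy_timeseries(
    images: list,
    times: list | np.ndarray | None = None,
    grid: int = 5,
    threshold: float | str = "otsu",
    crop=None,
) -> pd.DataFrame:
    """Mixing entropy per image, sorted by timestamp.

    ``times`` gives the acquisition time of each image; without it the
    images are indexed 0, 1, 2, ... in the order given.  Unreadable
    images are skipped with a warning.
    """
    if len(images) == 0:
        raise ValueError("at least one image is required")
    if times is None:
        times = np.arange(len(images), dtype=float)
    times = np.asarray(times, dtype=float)
    if len(times) != len(images):
        raise ValueError("times and images lengths differ")
    rows = []
    for t, img in sorted(zip(times, images), key=lambda p: p[0]):
        try:
            labels = binarize(img, threshold=threshold, crop=crop)
            s = mixing_entropy(grid_fractions(labels, grid=grid))
        except (OSError, ValueError) as exc:
            warnings.warn(f"skipping image at t={t}: {exc}", RuntimeWarning, stacklevel=2)
            continue
        rows.append({"time_s": t, "entropy": s})
    return pd.DataFrame(rows, columns=["time_s", "entropy"])
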