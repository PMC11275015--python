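"""Shared annulus bookkeeping used by azimuthal integration and calibration.

Pixel (i, j) has its centre at (i + 0.5, j + 0.5) in a 0-based row/column
frame; radii are Euclidean distances from that centre to the beam centre.
Bin k collects pixels with floor(r / bin_width) == k.
"""

from __future__ import annotations

import numpy as np


def pixel_radii(shape: tuple[int, int], center: tuple[float, float]) -> np.ndarray:
    """Distance (pixels) from each pixel centre to ``center`` (row, col)."""
    n_rows, n_cols = shape
    rows = np.arange(n_rows, dtype=float) + 0.5
    cols = np.arange(n_cols, dtype=float) + 0.5
    dr = rows - center[0]
    dc = cols - center[1]
    return np.hypot(dr[:, None], dc[None, :])


def annular_stats(
    values: np.ndarray,
    center: tuple[float, float],
    bin_width: float = 1.0,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-annulus (sum, n_pixels) arrays indexed by bin number.

    ``mask`` (optional boolean array, True = exclude) removes pixels from
    both sums and counts.  Accumulation visits pixels in row-major order,
    matching a naive per-pixel loop bit for bit.
    """
    values = np.asarray(values, dtype=float)
    r = pixel_radii(values.shape, center)
    bins = np.floor(r / bin_width).astype(np.intp)
    if mask is not None:
        keep = ~np.asarray(mask, dtype=bool)
        bins = bins[keep]
        vals = values[keep]
    else:
        bins = bins.ravel()
        vals = values.ravel()
    n_bins = int(bins.max()) + 1 if bins.size else 0
    sums = np.bincount(bins, weights=vals, minlength=n_bins)
    counts = np.bincount(bins, minlength=n_bins)
    return sums, counts
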