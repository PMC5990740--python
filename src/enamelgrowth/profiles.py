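"""Intensity transects and band-spacing detection on rendered sections.

Raster-side counterpart of the polyline estimators: incremental lines
appear as dark bands, so spacings are recovered as distances between
prominent intensity minima along a transect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .section import Point2D
from .simulate import AffineTransform

__all__ = ["TransectProfile", "BandSpacingResult", "sample_transect",
           "detect_band_spacing"]


@dataclass
class TransectProfile:
    """Intensity sampled at fixed steps along a straight transect."""

    positions: np.ndarray      # µm from the transect start
    intensities: np.ndarray


@dataclass
class BandSpacingResult:
    """Detected dark-band positions (µm) and successive spacings."""

    band_positions: np.ndarray
    spacings: np.ndarray
    flagged: bool = False      # fewer than two detectable minima


def sample_transect(image: np.ndarray, transform: AffineTransform,
                    start: Point2D, end: Point2D,
                    step: float = 0.25) -> TransectProfile:
    """Bilinear intensity sampling every ``step`` µm from start to end."""
    a, b = start.as_array(), end.as_array()
    length = float(np.linalg.norm(b - a))
    if length == 0:
        raise ValueError("transect has zero length")
    n = int(np.floor(length / step)) + 1
    pos = np.arange(n) * step
    pts = a[None, :] + (pos / length)[:, None] * (b - a)[None, :]
    rc = transform.to_pixel(pts)
    nrows, ncols = image.shape
    inside = ((rc[:, 0] >= 0) & (rc[:, 0] <= nrows - 1) &
              (rc[:, 1] >= 0) & (rc[:, 1] <= ncols - 1))
    if not np.all(inside):
        lo, hi = transform.to_world([[0, 0]])[0], transform.to_world(
            [[nrows - 1, ncols - 1]])[0]
        raise ValueError(
            "transect leaves the image; valid extent is "
            f"u in [{lo[0]:.2f}, {hi[0]:.2f}], v in [{lo[1]:.2f}, "
            f"{hi[1]:.2f}] um")
    vals = ndimage.map_coordinates(image, rc.T, order=1, mode="nearest")
    return TransectProfile(positions=pos, intensities=vals)


def detect_band_spacing(profile: TransectProfile,
                        min_prominence: float = 0.1) -> BandSpacingResult:
    """Dark bands as intensity minima with prominence >= threshold."""
    idx, _ = signal.find_peaks(-profile.intensities,
                               prominence=min_prominence)
    pos = profile.positions[idx]
    if len(pos) < 2:
        return BandSpacingResult(pos, np.array([]), flagged=True)
    return BandSpacingResult(pos, np.diff(pos))
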