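"""Cell-body segmentation from a membrane-marker channel.

The whole-cell channel (e.g. myr-RFP) is segmented with an automatic
bimodal-histogram threshold: the intensity histogram is split into 1000
bins, smoothed by local quadratic regression over a 5% window, and the
threshold is placed at the minimum between the two lowest-intensity modes
(background and cell body).  The cell edge is the set of border pixels of
the surviving connected regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks, savgol_filter
from scipy.spatial import cKDTree

from .config import FrameImage

#: Number of histogram bins used by the automatic threshold.
HISTOGRAM_BINS = 1000
#: Fraction of bins included in each local quadratic fit.
SMOOTH_SPAN = 0.05
#: Connected body regions smaller than this many pixels are discarded.
MIN_REGION_PX = 10


class EdgeDetectionError(RuntimeError):
    """Raised when the intensity histogram is not bimodal."""


@dataclass
class CellEdgeMask:
    body_mask: np.ndarray
    edge_pixels: np.ndarray  # (n, 2) array of (row, col)
    threshold_used: float
    _tree: cKDTree | None = field(default=None, repr=False, compare=False)

    @property
    def tree(self) -> cKDTree:
        if self._tree is None:
            if len(self.edge_pixels) == 0:
                raise EdgeDetectionError("edge mask has no edge pixels")
            self._tree = cKDTree(self.edge_pixels.astype(np.float64))
        return self._tree

    def contains(self, point_xy: tuple[float, float]) -> bool:
        """True when the (x, y) point falls on a cell-body pixel."""
        r = int(round(point_xy[1]))
        c = int(round(point_xy[0]))
        h, w = self.body_mask.shape
        return 0 <= r < h and 0 <= c < w and bool(self.body_mask[r, c])


def _smooth_histogram(counts: np.ndarray) -> np.ndarray:
    window = int(round(SMOOTH_SPAN * len(counts)))
    window = max(window + (window + 1) % 2, 5)  # odd, at least 5
    return savgol_filter(counts.astype(np.float64), window, polyorder=2, mode="interp")


def bimodal_threshold(values: np.ndarray) -> float:
    """Threshold at the smoothed-histogram minimum between the two
    lowest-intensity modes."""
    values = np.asarray(values).ravel()
    if np.unique(values).size < 2:
        raise EdgeDetectionError("image has fewer than two distinct intensities")
    counts, edges = np.histogram(values, bins=HISTOGRAM_BINS)
    centers = 0.5 * (edges[:-1] + edges[1:])
    smoothed = _smooth_histogram(counts)
    # ignore micro-wiggles of the smoother in near-empty histogram tails;
    # pad so modes in the outermost bins are still found
    padded = np.concatenate([[-np.inf], smoothed, [-np.inf]])
    peaks, _ = find_peaks(padded, prominence=0.01 * smoothed.max())
    peaks -= 1
    if len(peaks) < 2:
        raise EdgeDetectionError("smoothed intensity histogram is not bimodal")
    lo, hi = np.sort(peaks)[:2]
    valley = lo + int(np.argmin(smoothed[lo:hi + 1]))
    return float(centers[valley])


def find_cell_edge(rfp_frame: FrameImage) -> CellEdgeMask:
    """Segment the cell body and return its border pixels.

    Raises
    ------
    EdgeDetectionError
        When the histogram has fewer than two modes (caller may fall back
        to a fixed threshold via :func:`edge_from_threshold`).
    """
    threshold = bimodal_threshold(rfp_frame.pixels)
    return edge_from_threshold(rfp_frame, threshold)


def edge_from_threshold(rfp_frame: FrameImage, threshold: float) -> CellEdgeMask:
    """Build a CellEdgeMask from an explicit body threshold."""
    body = rfp_frame.pixels > threshold
    labels, n = ndimage.label(body, structure=np.ones((3, 3)))
    if n:
        sizes = np.bincount(labels.ravel())
        keep = np.flatnonzero(sizes >= MIN_REGION_PX)
        keep = keep[keep > 0]
        body = np.isin(labels, keep)
    # Border pixels: body pixels with a non-body 4-neighbor (image frame
    # counts as non-body).
    interior = ndimage.binary_erosion(
        body, structure=ndimage.generate_binary_structure(2, 1), border_value=0
    )
    edge = body & ~interior
    return CellEdgeMask(
        body_mask=body,
        edge_pixels=np.argwhere(edge),
        threshold_used=float(threshold),
    )


def distance_to_edge(
    point_xy: tuple[float, float], edge: CellEdgeMask, pixel_size_um: float
) -> float:
    """Unsigned Euclidean distance (µm) from an (x, y) point to the
    nearest edge pixel."""
    d, _ = edge.tree.query([point_xy[1], point_xy[0]])
    return float(d) * pixel_size_um
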