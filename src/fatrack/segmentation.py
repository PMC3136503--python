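"""Per-frame focal-adhesion segmentation and property measurement.

The detection scheme is: high-pass filter each frame with a round averaging
kernel (background suppression), threshold the filtered image to call
adhesion pixels, then split each connected above-threshold region at
intensity saddle points ("water" segmentation) so that touching adhesions
receive separate labels.  Properties (area, axial ratio, mean intensity,
centroid, distance to cell edge) are measured on the raw normalized frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve
from skimage.measure import label as cc_label
from skimage.morphology import h_maxima, local_maxima
from skimage.segmentation import watershed

from .config import AnalysisConfig, FrameImage


@dataclass
class AdhesionBlob:
    """One segmented adhesion in one frame.

    ``rows``/``cols`` hold the member pixel coordinates; ``centroid`` is
    the unweighted pixel centroid in (x, y) = (col, row) order.
    """

    blob_id: int
    frame_index: int
    rows: np.ndarray
    cols: np.ndarray
    image_shape: tuple[int, int]
    area_px: int
    area_um2: float
    centroid: tuple[float, float]
    mean_intensity: float
    axial_ratio: float
    dist_to_edge_um: float | None = None
    lineage_id: int | None = None

    @property
    def pixel_set(self) -> set[tuple[int, int]]:
        return set(zip(self.rows.tolist(), self.cols.tolist()))


def disk_kernel(radius_px: int) -> np.ndarray:
    """Flat round averaging kernel normalized to unit sum."""
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    yy, xx = np.mgrid[-radius_px:radius_px + 1, -radius_px:radius_px + 1]
    k = (yy**2 + xx**2 <= radius_px**2).astype(np.float64)
    return k / k.sum()


def high_pass_filter(frame: FrameImage | np.ndarray, radius_px: int = 11) -> np.ndarray:
    """Subtract the local round-kernel average from the image.

    Borders are handled by edge replication.  The output may be negative;
    constant images map to (numerically) zero.
    """
    img = frame.pixels if isinstance(frame, FrameImage) else np.asarray(frame, dtype=np.float64)
    if 2 * radius_px + 1 > min(img.shape):
        raise ValueError("filter radius too large for image")
    kernel = disk_kernel(radius_px)
    padded = np.pad(img, radius_px, mode="edge")
    background = fftconvolve(padded, kernel, mode="valid")
    return img - background


def threshold_mask(filtered: np.ndarray, threshold: float) -> np.ndarray:
    """Binary mask of adhesion pixels: filtered intensity >= threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return np.asarray(filtered) >= threshold


def water_segment(
    mask: np.ndarray,
    frame: FrameImage | np.ndarray,
    large_adhesion_px: int = 40,
    min_adhesion_px: int = 1,
    smoothing_sigma: float = 1.0,
    split_min_depth: float = 0.05,
) -> np.ndarray:
    """Split mask regions at intensity saddles into one label per maximum.

    Seeds are the local intensity maxima (8-connected, plateaus merged) of
    the Gaussian-smoothed in-mask image whose prominence exceeds
    ``split_min_depth``; labels grow from the seeds in decreasing intensity
    order (watershed on the inverted image restricted to the mask).  Two
    post-passes reproduce the classic water-algorithm conventions:

    * interior holes of each labeled adhesion are filled;
    * a single pixel bridging two adhesions of at least
      ``large_adhesion_px`` pixels is reassigned to the adhesion whose
      centroid is nearest (ties go to the lower label id).
    """
    img = frame.pixels if isinstance(frame, FrameImage) else np.asarray(frame, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.shape:
        raise ValueError("mask and frame shapes differ")
    if not mask.any():
        return np.zeros(img.shape, dtype=np.int32)

    smoothed = ndimage.gaussian_filter(img, smoothing_sigma)
    in_mask = np.where(mask, smoothed, 0.0)

    # Prominence-filtered maxima: saddles shallower than split_min_depth do
    # not split a region (robustness against pixel noise on flat adhesions).
    if split_min_depth > 0:
        seeds = h_maxima(in_mask, split_min_depth, footprint=np.ones((3, 3))) > 0
    else:
        seeds = local_maxima(in_mask, connectivity=2)
    seeds &= mask
    markers = cc_label(seeds, connectivity=2)
    labels = watershed(-smoothed, markers=markers, mask=mask, connectivity=2).astype(np.int32)

    # Components whose maximum fell below the prominence cut get no seed;
    # keep each as a single adhesion.
    orphan = mask & (labels == 0)
    if orphan.any():
        extra = cc_label(orphan, connectivity=2)
        labels[orphan] = extra[orphan] + labels.max()

    labels = _fill_holes(labels)
    labels = _reassign_bridges(labels, large_adhesion_px)

    if min_adhesion_px > 1:
        sizes = np.bincount(labels.ravel())
        small = np.flatnonzero(sizes < min_adhesion_px)
        labels[np.isin(labels, small[small > 0])] = 0

    return _relabel_sequential(labels)


def _fill_holes(labels: np.ndarray) -> np.ndarray:
    """Fill interior holes of each label (hole pixels must be unlabeled)."""
    out = labels.copy()
    for sl, lab in zip(ndimage.find_objects(labels), range(1, labels.max() + 1)):
        if sl is None:
            continue
        sub = labels[sl] == lab
        filled = ndimage.binary_fill_holes(sub)
        add = filled & ~sub & (labels[sl] == 0)
        if add.any():
            out[sl][add] = lab
    return out


def _neighbor_label_pairs(labels: np.ndarray):
    """Yield (pixel index array, here, there) for pixels adjacent to a
    different positive label (8-connectivity)."""
    shifts = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    for dr, dc in shifts:
        shifted = np.full_like(labels, 0)
        src = labels[max(dr, 0) or None: labels.shape[0] + min(dr, 0) or None,
                     max(dc, 0) or None: labels.shape[1] + min(dc, 0) or None]
        shifted[max(-dr, 0) or None: labels.shape[0] + min(-dr, 0) or None,
                max(-dc, 0) or None: labels.shape[1] + min(-dc, 0) or None] = src
        different = (labels > 0) & (shifted > 0) & (labels != shifted)
        if different.any():
            rr, cc = np.nonzero(different)
            yield rr, cc, labels[rr, cc], shifted[rr, cc]


def _reassign_bridges(labels: np.ndarray, large_px: int) -> np.ndarray:
    """Move single bridge pixels between two large adhesions to the
    nearer-centroid label.

    A bridge pixel is an articulation pixel: removing it disconnects the
    two adjacent large labels within their shared mask component.
    """
    sizes = np.bincount(labels.ravel())
    if (sizes[1:] >= large_px).sum() < 2:
        return labels
    candidates: dict[tuple[int, int], set[int]] = {}
    for rr, cc, here, there in _neighbor_label_pairs(labels):
        for r, c, a, b in zip(rr, cc, here, there):
            if sizes[a] >= large_px and sizes[b] >= large_px:
                candidates.setdefault((int(r), int(c)), {int(a)}).add(int(b))
    if not candidates:
        return labels

    centroids = np.array(ndimage.center_of_mass(labels > 0, labels, np.arange(1, labels.max() + 1)))
    mask = labels > 0
    out = labels.copy()
    for (r, c), labs in sorted(candidates.items()):
        own = int(labels[r, c])
        others = sorted(labs - {own})
        if not others:
            continue
        # articulation test: does removing this pixel disconnect own from other?
        comp = _component_containing(mask, r, c)
        comp[r, c] = False
        relabeled, _ = ndimage.label(comp, structure=np.ones((3, 3)))
        for other in others:
            own_comp = np.unique(relabeled[(labels == own) & comp])
            oth_comp = np.unique(relabeled[(labels == other) & comp])
            own_comp = own_comp[own_comp > 0]
            oth_comp = oth_comp[oth_comp > 0]
            if len(own_comp) and len(oth_comp) and not np.intersect1d(own_comp, oth_comp).size:
                d_own = np.hypot(*(centroids[own - 1] - (r, c)))
                d_oth = np.hypot(*(centroids[other - 1] - (r, c)))
                if d_oth < d_own or (d_oth == d_own and other < own):
                    out[r, c] = other
                break
    return out


def _component_containing(mask: np.ndarray, r: int, c: int) -> np.ndarray:
    comps, _ = ndimage.label(mask, structure=np.ones((3, 3)))
    return comps == comps[r, c]


def _relabel_sequential(labels: np.ndarray) -> np.ndarray:
    vals = np.unique(labels)
    vals = vals[vals > 0]
    lut = np.zeros(labels.max() + 1, dtype=np.int32)
    lut[vals] = np.arange(1, len(vals) + 1, dtype=np.int32)
    return lut[labels]


def _ellipse_axes(rows: np.ndarray, cols: np.ndarray, weights: np.ndarray) -> float:
    """Axial ratio (major/minor) of the intensity-weighted second-moment
    ellipse; each pixel contributes a 1/12 unit-square variance so lines
    and single pixels stay finite."""
    w = weights.astype(np.float64)
    if w.sum() <= 0:
        w = np.ones_like(w)
    w = w / w.sum()
    r0 = (w * rows).sum()
    c0 = (w * cols).sum()
    mrr = (w * (rows - r0) ** 2).sum() + 1.0 / 12.0
    mcc = (w * (cols - c0) ** 2).sum() + 1.0 / 12.0
    mrc = (w * (rows - r0) * (cols - c0)).sum()
    tr = mrr + mcc
    det = mrr * mcc - mrc**2
    disc = max(tr**2 / 4.0 - det, 0.0)
    lam1 = tr / 2.0 + np.sqrt(disc)
    lam2 = tr / 2.0 - np.sqrt(disc)
    return float(np.sqrt(lam1 / max(lam2, 1e-300)))


def measure_blobs(
    labels: np.ndarray,
    frame: FrameImage,
    edge=None,
) -> list[AdhesionBlob]:
    """Measure every labeled adhesion on the raw normalized frame.

    ``edge`` is an optional CellEdgeMask; when given, the distance from
    each blob centroid to the nearest cell-edge pixel is recorded in µm.
    """
    n = int(labels.max())
    if n == 0:
        return []
    img = frame.pixels
    px = frame.pixel_size_um
    blobs: list[AdhesionBlob] = []
    for sl, lab in zip(ndimage.find_objects(labels), range(1, n + 1)):
        if sl is None:
            continue
        sub = labels[sl] == lab
        rr, cc = np.nonzero(sub)
        rows = rr + sl[0].start
        cols = cc + sl[1].start
        vals = img[rows, cols]
        area = rows.size
        centroid = (float(cols.mean()), float(rows.mean()))  # (x, y)
        blob = AdhesionBlob(
            blob_id=lab,
            frame_index=frame.frame_index,
            rows=rows.astype(np.int32),
            cols=cols.astype(np.int32),
            image_shape=img.shape,
            area_px=int(area),
            area_um2=float(area * px**2),
            centroid=centroid,
            mean_intensity=float(vals.mean()),
            axial_ratio=_ellipse_axes(rows.astype(float), cols.astype(float), vals),
        )
        if edge is not None:
            from .cell_edge import distance_to_edge
            blob.dist_to_edge_um = distance_to_edge(centroid, edge, px)
        blobs.append(blob)
    return blobs


def segment_frame(frame: FrameImage, config: AnalysisConfig, edge=None) -> list[AdhesionBlob]:
    """High-pass -> threshold -> water segmentation -> measurement."""
    filtered = high_pass_filter(frame, config.filter_radius_px)
    mask = threshold_mask(filtered, config.detection_threshold)
    labels = water_segment(
        mask, frame,
        large_adhesion_px=config.large_adhesion_px,
        min_adhesion_px=config.min_adhesion_px,
        split_min_depth=config.split_min_depth,
    )
    return measure_blobs(labels, frame, edge=edge)
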