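"""Linking per-frame adhesion blobs into lineages.

The tracker follows a sequential birth-death-merge model.  For each pair
of consecutive frames, every live adhesion claims the next-frame blob it
overlaps most (fraction of its own pixels); adhesions with no overlap fall
back to the nearest centroid within a distance cap.  Next-frame blobs that
were overlapped but not claimed are marked as split births.  When several
lineages claim one target, claimants without pixel overlap die, and among
true merges the larger adhesion continues when areas differ by at least
10%, otherwise the one whose centroid is closer to the target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .config import AnalysisConfig
from .segmentation import AdhesionBlob

BIRTH_NEW = "new"
BIRTH_SPLIT = "split"
DEATH_DISAPPEAR = "disappear"
DEATH_MERGED = "merged_into"
DEATH_CENSORED = "censored"

#: Relative area difference at or above which the larger merge partner wins.
MERGE_SIZE_FRACTION = 0.10


@dataclass
class Lineage:
    """One adhesion tracked from birth to death."""

    lineage_id: int
    blobs: list[AdhesionBlob] = field(default_factory=list)
    birth_frame: int = 0
    death_frame: int = 0
    birth_type: str = BIRTH_NEW
    death_type: str = DEATH_CENSORED
    merged_into: int | None = None

    @property
    def blob_refs(self) -> list[tuple[int, int]]:
        return [(b.frame_index, b.blob_id) for b in self.blobs]

    @property
    def length(self) -> int:
        return len(self.blobs)

    @property
    def intensity_series(self) -> np.ndarray:
        return np.array([b.mean_intensity for b in self.blobs])

    @property
    def position_series(self) -> np.ndarray:
        return np.array([b.centroid for b in self.blobs])

    @property
    def dist_series(self) -> np.ndarray:
        return np.array([
            b.dist_to_edge_um if b.dist_to_edge_um is not None else np.nan
            for b in self.blobs
        ])

    def longevity_min(self, frame_interval_min: float = 1.0) -> float:
        return self.length * frame_interval_min


@dataclass
class ForwardMatch:
    """Result of matching the blobs of frame t onto frame t+1.

    ``assignment[i]`` is the index into ``blobs_t1`` claimed by blob i of
    ``blobs_t`` (None for a death candidate); ``overlap_px[i]`` is the
    shared pixel count with that target.  ``split_births`` are t+1 blob
    indices that overlap some t blob but were not claimed by any.
    """

    assignment: list[int | None]
    overlap_px: list[int]
    split_births: set[int]


def _overlap_matrix(
    blobs_t: Sequence[AdhesionBlob], blobs_t1: Sequence[AdhesionBlob]
) -> np.ndarray:
    """Pixel-overlap counts between every pair of blobs (dense, small n)."""
    shape = blobs_t[0].image_shape
    target = np.full(shape, -1, dtype=np.int32)
    for j, b in enumerate(blobs_t1):
        target[b.rows, b.cols] = j
    counts = np.zeros((len(blobs_t), len(blobs_t1)), dtype=np.int64)
    for i, b in enumerate(blobs_t):
        hits = target[b.rows, b.cols]
        hits = hits[hits >= 0]
        if hits.size:
            counts[i, :] += np.bincount(hits, minlength=len(blobs_t1))
    return counts


def match_forward(
    blobs_t: Sequence[AdhesionBlob],
    blobs_t1: Sequence[AdhesionBlob],
    max_distance_px: float = 3.0,
) -> ForwardMatch:
    """Claim, for each blob at t, its corresponding blob at t+1.

    Overlap claims use the fraction of the earlier blob's pixels shared
    with the candidate; ties are broken by larger candidate area, then by
    lower blob id.  Blobs with no overlap claim the nearest centroid
    within ``max_distance_px`` (may be ``inf``).
    """
    if not blobs_t or not blobs_t1:
        return ForwardMatch([None] * len(blobs_t), [0] * len(blobs_t), set())

    counts = _overlap_matrix(blobs_t, blobs_t1)
    areas_t1 = np.array([b.area_px for b in blobs_t1])
    ids_t1 = np.array([b.blob_id for b in blobs_t1])
    # lexsort-style argmax: overlap count, then candidate area, then -id
    order_key = (
        counts.astype(np.float64) * (areas_t1.max() + 1) * (ids_t1.max() + 1)
        + areas_t1[np.newaxis, :] * (ids_t1.max() + 1)
        + (ids_t1.max() - ids_t1)[np.newaxis, :]
    )
    assignment: list[int | None] = []
    overlap_px: list[int] = []

    tree = cKDTree([b.centroid for b in blobs_t1])
    for i, b in enumerate(blobs_t):
        if counts[i].any():
            j = int(np.argmax(order_key[i]))
            assignment.append(j)
            overlap_px.append(int(counts[i, j]))
        else:
            d, j = tree.query(b.centroid)
            if d <= max_distance_px:
                assignment.append(int(j))
                overlap_px.append(0)
            else:
                assignment.append(None)
                overlap_px.append(0)

    claimed = {j for j in assignment if j is not None}
    overlapped = set(np.flatnonzero(counts.sum(axis=0) > 0).tolist())
    split_births = overlapped - claimed
    return ForwardMatch(assignment, overlap_px, split_births)


@dataclass
class Transition:
    """Resolved fate of each frame-t blob: ('continue', j), ('death',
    DEATH_DISAPPEAR, None) or ('death', DEATH_MERGED, j)."""

    fates: list[tuple]


def resolve_merges(
    match: ForwardMatch,
    blobs_t: Sequence[AdhesionBlob],
    blobs_t1: Sequence[AdhesionBlob],
) -> Transition:
    """Resolve contested targets into continuations and deaths."""
    fates: list[tuple] = [None] * len(blobs_t)  # type: ignore[list-item]
    groups: dict[int, list[int]] = {}
    for i, j in enumerate(match.assignment):
        if j is None:
            fates[i] = ("death", DEATH_DISAPPEAR, None)
        else:
            groups.setdefault(j, []).append(i)

    for j, claimants in groups.items():
        if len(claimants) == 1:
            fates[claimants[0]] = ("continue", j)
            continue
        # claimants that do not overlap the target have died, not merged
        true_merge = []
        for i in claimants:
            if match.overlap_px[i] > 0:
                true_merge.append(i)
            else:
                fates[i] = ("death", DEATH_DISAPPEAR, None)
        if not true_merge:
            continue
        if len(true_merge) == 1:
            fates[true_merge[0]] = ("continue", j)
            continue
        winner = _merge_winner(true_merge, blobs_t, blobs_t1[j])
        for i in true_merge:
            fates[i] = ("continue", j) if i == winner else ("death", DEATH_MERGED, j)
    return Transition(fates)


def _merge_winner(
    claimants: list[int], blobs_t: Sequence[AdhesionBlob], target: AdhesionBlob
) -> int:
    areas = np.array([blobs_t[i].area_px for i in claimants], dtype=float)
    amax = areas.max()
    # partners within 10% of the largest are "same size"; among them the
    # centroid nearest the target continues
    close = [i for i, a in zip(claimants, areas) if (amax - a) / amax < MERGE_SIZE_FRACTION]
    if len(close) == 1:
        return close[0]
    tx, ty = target.centroid
    dists = [np.hypot(blobs_t[i].centroid[0] - tx, blobs_t[i].centroid[1] - ty) for i in close]
    order = sorted(zip(dists, [blobs_t[i].blob_id for i in close], close))
    return order[0][2]


def build_lineages(
    frame_blobs: Sequence[Sequence[AdhesionBlob]],
    config: AnalysisConfig | None = None,
) -> list[Lineage]:
    """Track blobs across all frames into a full set of lineages.

    Every blob of every frame belongs to exactly one lineage; lineages
    still alive in the final frame are marked censored.
    """
    config = config or AnalysisConfig()
    if not frame_blobs:
        raise ValueError("need at least one frame")

    lineages: list[Lineage] = []
    live: dict[int, Lineage] = {}  # index of blob in current frame -> lineage

    def _new_lineage(blob: AdhesionBlob, frame: int, birth_type: str) -> Lineage:
        lin = Lineage(
            lineage_id=len(lineages),
            blobs=[blob],
            birth_frame=frame,
            death_frame=frame,
            birth_type=birth_type,
        )
        blob.lineage_id = lin.lineage_id
        lineages.append(lin)
        return lin

    for i, blob in enumerate(frame_blobs[0]):
        live[i] = _new_lineage(blob, 0, BIRTH_NEW)

    for t in range(len(frame_blobs) - 1):
        blobs_t = list(frame_blobs[t])
        blobs_t1 = list(frame_blobs[t + 1])
        match = match_forward(blobs_t, blobs_t1, config.max_link_distance_px)
        trans = resolve_merges(match, blobs_t, blobs_t1)

        next_live: dict[int, Lineage] = {}
        for i, fate in enumerate(trans.fates):
            lin = live.get(i)
            if lin is None:
                continue
            if fate[0] == "continue":
                j = fate[1]
                lin.blobs.append(blobs_t1[j])
                blobs_t1[j].lineage_id = lin.lineage_id
                lin.death_frame = t + 1
                next_live[j] = lin
            else:
                lin.death_type = fate[1]
                lin.death_frame = t
                if fate[1] == DEATH_MERGED:
                    lin.merged_into = fate[2]

        for j, blob in enumerate(blobs_t1):
            if j not in next_live:
                birth = BIRTH_SPLIT if j in match.split_births else BIRTH_NEW
                next_live[j] = _new_lineage(blob, t + 1, birth)

        live = next_live

    last = len(frame_blobs) - 1
    for lin in live.values():
        lin.death_type = DEATH_CENSORED
        lin.death_frame = last
    # record the lineage id (not blob index) that each merged lineage joined
    for lin in lineages:
        if lin.death_type == DEATH_MERGED and lin.merged_into is not None:
            t1 = lin.death_frame + 1
            if t1 < len(frame_blobs):
                target_blob = frame_blobs[t1][lin.merged_into]
                lin.merged_into = target_blob.lineage_id
    return lineages
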