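"""Ground-truthed synthetic adhesion movies and pipeline scoring.

Three validation regimes emulate the properties of real TIRF adhesion
data: *stationary* (a grid of unmoving circular adhesions spanning the
observed radius and intensity ranges), *moving* (discs sliding at constant
speed to probe tracking limits), and *kinetic* (discs whose intensity
follows logarithmic assembly, a plateau, and logarithmic disassembly).
All regimes share a Gaussian background noise model (mean 0, variance
2×10⁻³); the same noise perturbs the adhesion pixels themselves.  Every
movie carries per-adhesion ground truth so pipeline output can be scored
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AnalysisConfig, FrameImage
from .kinetics import PhaseDecomposition
from .tracking import Lineage

#: Background noise variance of the simulated camera field.
NOISE_VARIANCE = 2e-3
#: Planted disc radii (pixels): ten values spanning the observed range.
DEFAULT_RADII = tuple(np.linspace(0.5, 5.0, 10))
#: Planted mean intensities: 0.05 to 0.47 in steps of 0.03.
DEFAULT_INTENSITIES = tuple(np.round(np.arange(0.05, 0.47 + 1e-9, 0.03), 3))
#: Fixed lifespan (frames) of stationary-simulation adhesions.
DEFAULT_LIFESPAN = 25
#: Default plateau length (frames) of kinetic-simulation adhesions.
DEFAULT_STABILITY = 5
#: Intensity floor of kinetic schedules, as a fraction of peak.
KINETIC_FLOOR_FRAC = 0.1
#: Floor fraction used for *imaged* kinetic movies: keeps the whole
#: schedule above the segmentation detection floor (~0.17 normalized) so
#: planted phase lengths are observable quantities.
KINETIC_MOVIE_FLOOR_FRAC = 0.4
#: Disc radius for imaged kinetic movies: a mature-adhesion size for
#: which mean-intensity noise (∝ 1/sqrt(area)) and partial-pixel rim
#: dilution (∝ 2/radius) are small enough to resolve phase boundaries.
KINETIC_MOVIE_RADIUS = 5.0

_SUBPIX = 16  # supersampling factor for anti-aliased disc rendering


@dataclass
class AdhesionTruth:
    """Ground truth for one planted adhesion."""

    adhesion_id: int
    radius_px: float
    birth_frame: int
    death_frame: int
    centers: np.ndarray          # (life, 2) float (row, col) per life frame
    intensities: np.ndarray      # (life,) pre-noise mean intensity schedule
    kinetics: dict | None = None

    @property
    def life_frames(self) -> range:
        return range(self.birth_frame, self.death_frame + 1)

    @property
    def longevity(self) -> int:
        return self.death_frame - self.birth_frame + 1


@dataclass
class SimulatedMovie:
    frames: list[FrameImage]
    truth: list[AdhesionTruth]
    noise_variance: float
    seed: int | None
    regime: str
    clip_fraction: float = 0.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape

    @property
    def pixel_array(self) -> np.ndarray:
        return np.stack([f.pixels for f in self.frames])


def disc_coverage(
    center_rc: tuple[float, float], radius: float, shape: tuple[int, int]
) -> tuple[tuple[slice, slice], np.ndarray]:
    """Area-weighted coverage of a disc over the pixel grid.

    Each pixel is sampled on a 16×16 subgrid; the returned array holds the
    fraction of the pixel inside the disc, so sub-pixel discs (r = 0.5 px)
    are rendered with physically meaningful total flux.
    """
    cr, cc = center_rc
    r0 = max(int(np.floor(cr - radius - 1)), 0)
    r1 = min(int(np.ceil(cr + radius + 1)), shape[0] - 1)
    c0 = max(int(np.floor(cc - radius - 1)), 0)
    c1 = min(int(np.ceil(cc + radius + 1)), shape[1] - 1)
    if r1 < r0 or c1 < c0:
        return (slice(0, 0), slice(0, 0)), np.zeros((0, 0))
    off = (np.arange(_SUBPIX) + 0.5) / _SUBPIX - 0.5
    rr = np.arange(r0, r1 + 1)[:, None] + off[None, :]   # (nr, s)
    cc_ = np.arange(c0, c1 + 1)[:, None] + off[None, :]  # (nc, s)
    d2 = ((rr - cr) ** 2)[:, :, None, None] + ((cc_ - cc) ** 2)[None, None, :, :]
    cov = (d2 <= radius**2).mean(axis=(1, 3))
    return (slice(r0, r1 + 1), slice(c0, c1 + 1)), cov


def _finalize_movie(
    canvas: np.ndarray,
    truth: list[AdhesionTruth],
    noise_variance: float,
    seed: int | None,
    regime: str,
    config: AnalysisConfig,
) -> SimulatedMovie:
    """Add seeded Gaussian noise, clip to [0, 1], wrap as FrameImage."""
    rng = np.random.default_rng(seed)
    noisy = canvas + rng.normal(0.0, np.sqrt(noise_variance), size=canvas.shape)
    clipped = float(np.mean((noisy < 0) | (noisy > 1)))
    noisy = np.clip(noisy, 0.0, 1.0)
    frames = [
        FrameImage(noisy[t], frame_index=t,
                   pixel_size_um=config.pixel_size_um,
                   frame_interval_min=config.frame_interval_min)
        for t in range(noisy.shape[0])
    ]
    return SimulatedMovie(frames=frames, truth=truth, noise_variance=noise_variance,
                          seed=seed, regime=regime, clip_fraction=clipped)


def simulate_stationary(
    radii=DEFAULT_RADII,
    intensities=DEFAULT_INTENSITIES,
    lifespan_frames: int = DEFAULT_LIFESPAN,
    pre_frames: int = 2,
    post_frames: int = 2,
    spacing_px: int | None = None,
    noise_variance: float = NOISE_VARIANCE,
    seed: int | None = None,
    config: AnalysisConfig | None = None,
) -> SimulatedMovie:
    """Grid of unmoving discs: rows vary radius, columns vary intensity.

    Each adhesion appears at ``pre_frames`` and persists for exactly
    ``lifespan_frames`` frames, so tracked longevity can be compared with
    the planted value.  Grid spacing defaults to 4× the largest radius.
    """
    config = config or AnalysisConfig()
    radii = np.asarray(radii, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    spacing = spacing_px or int(np.ceil(4 * radii.max()))
    if spacing <= 2 * radii.max():
        raise ValueError("grid too dense: discs would overlap")
    margin = spacing
    h = 2 * margin + (len(radii) - 1) * spacing
    w = 2 * margin + (len(intensities) - 1) * spacing
    n_frames = pre_frames + lifespan_frames + post_frames
    birth, death = pre_frames, pre_frames + lifespan_frames - 1

    base = np.zeros((h, w))
    truth: list[AdhesionTruth] = []
    for i, radius in enumerate(radii):
        for j, intensity in enumerate(intensities):
            center = (float(margin + i * spacing), float(margin + j * spacing))
            sl, cov = disc_coverage(center, radius, (h, w))
            base[sl] += intensity * cov
            truth.append(AdhesionTruth(
                adhesion_id=len(truth),
                radius_px=float(radius),
                birth_frame=birth,
                death_frame=death,
                centers=np.tile(center, (lifespan_frames, 1)),
                intensities=np.full(lifespan_frames, intensity),
            ))
    canvas = np.zeros((n_frames, h, w))
    canvas[birth:death + 1] = base
    return _finalize_movie(canvas, truth, noise_variance, seed, "stationary", config)


def simulate_moving(
    radii=DEFAULT_RADII,
    speeds_px_per_frame=(0.0, 0.5, 1.0, 2.0),
    intensity: float = 0.4,
    n_frames: int = 20,
    noise_variance: float = NOISE_VARIANCE,
    seed: int | None = None,
    config: AnalysisConfig | None = None,
) -> SimulatedMovie:
    """Discs sliding at constant speed; one row per (radius, speed) pair.

    Speed 0 reduces to the stationary regime.  Adhesions that would leave
    the field have their truth record truncated at the exit frame.
    """
    config = config or AnalysisConfig()
    radii = np.asarray(radii, dtype=float)
    speeds = np.asarray(speeds_px_per_frame, dtype=float)
    if np.any(speeds < 0):
        raise ValueError("speeds must be non-negative")
    spacing = int(np.ceil(4 * radii.max()))
    margin = spacing
    pairs = [(r, s) for r in radii for s in speeds]
    h = 2 * margin + (len(pairs) - 1) * spacing
    travel = speeds.max() * (n_frames - 1)
    w = int(2 * margin + np.ceil(travel))

    canvas = np.zeros((n_frames, h, w))
    truth: list[AdhesionTruth] = []
    for k, (radius, speed) in enumerate(pairs):
        row = float(margin + k * spacing)
        centers = []
        death = n_frames - 1
        for t in range(n_frames):
            col = margin + speed * t
            if col + radius >= w:
                death = t - 1
                break
            centers.append((row, float(col)))
            sl, cov = disc_coverage((row, col), radius, (h, w))
            canvas[t][sl] += intensity * cov
        truth.append(AdhesionTruth(
            adhesion_id=k,
            radius_px=float(radius),
            birth_frame=0,
            death_frame=death,
            centers=np.asarray(centers),
            intensities=np.full(len(centers), intensity),
            kinetics={"speed_px_per_frame": float(speed)},
        ))
    return _finalize_movie(canvas, truth, noise_variance, seed, "moving", config)


def kinetic_schedule(
    assembly_len: int,
    disassembly_len: int,
    stability_len: int = DEFAULT_STABILITY,
    peak_intensity: float = 0.45,
    floor_frac: float = KINETIC_FLOOR_FRAC,
) -> tuple[np.ndarray, dict]:
    """Logarithmic rise, plateau, logarithmic fall intensity schedule.

    The schedule starts at ``floor_frac × peak`` and rises exponentially
    to the peak over ``assembly_len`` frames; the implied per-frame rates
    ``ln(peak/floor)/(len-1)`` are recorded in the returned truth dict.
    """
    if peak_intensity <= 0:
        raise ValueError("peak intensity must be positive")
    if assembly_len < 2 or disassembly_len < 2 or stability_len < 0:
        raise ValueError("invalid phase lengths")
    floor = floor_frac * peak_intensity
    k_a = np.log(peak_intensity / floor) / (assembly_len - 1)
    k_d = np.log(peak_intensity / floor) / (disassembly_len - 1)
    rise = floor * np.exp(k_a * np.arange(assembly_len))
    plateau = np.full(stability_len, peak_intensity)
    fall = peak_intensity * np.exp(-k_d * np.arange(disassembly_len))
    schedule = np.concatenate([rise, plateau, fall])
    meta = {
        "assembly_len": assembly_len,
        "stability_len": stability_len,
        "disassembly_len": disassembly_len,
        "assembly_rate": float(k_a),
        "disassembly_rate": float(k_d),
        "peak_intensity": float(peak_intensity),
        "floor_intensity": float(floor),
    }
    return schedule, meta


def simulate_kinetic(
    assembly_len: int,
    disassembly_len: int,
    stability_len: int = DEFAULT_STABILITY,
    peak_intensity: float = 0.45,
    radius_px: float = KINETIC_MOVIE_RADIUS,
    n_replicates: int = 4,
    floor_frac: float = KINETIC_MOVIE_FLOOR_FRAC,
    pre_frames: int = 2,
    post_frames: int = 2,
    noise_variance: float = NOISE_VARIANCE,
    seed: int | None = None,
    config: AnalysisConfig | None = None,
) -> SimulatedMovie:
    """A set of identical adhesions going through one kinetic schedule.

    All adhesions share the phase lengths, plateau length, peak intensity
    and radius; rates are controlled through the time spent reaching the
    peak.  Replicates are laid out on a square grid.
    """
    config = config or AnalysisConfig()
    schedule, meta = kinetic_schedule(
        assembly_len, disassembly_len, stability_len, peak_intensity, floor_frac
    )
    life = len(schedule)
    n_cols = int(np.ceil(np.sqrt(n_replicates)))
    n_rows = int(np.ceil(n_replicates / n_cols))
    spacing = int(np.ceil(4 * radius_px))
    margin = spacing
    h = 2 * margin + (n_rows - 1) * spacing
    w = 2 * margin + (n_cols - 1) * spacing
    n_frames = pre_frames + life + post_frames

    base = np.zeros((h, w))
    truth: list[AdhesionTruth] = []
    for k in range(n_replicates):
        i, j = divmod(k, n_cols)
        center = (float(margin + i * spacing), float(margin + j * spacing))
        sl, cov = disc_coverage(center, radius_px, (h, w))
        base[sl] += cov
        truth.append(AdhesionTruth(
            adhesion_id=k,
            radius_px=float(radius_px),
            birth_frame=pre_frames,
            death_frame=pre_frames + life - 1,
            centers=np.tile(center, (life, 1)),
            intensities=schedule,
            kinetics=meta,
        ))
    canvas = np.zeros((n_frames, h, w))
    for t, value in enumerate(schedule):
        canvas[pre_frames + t] = base * value
    return _finalize_movie(canvas, truth, noise_variance, seed, "kinetic", config)


def simulate_kinetic_series(
    assembly_len: int,
    disassembly_len: int,
    stability_len: int = DEFAULT_STABILITY,
    peak_intensity: float = 0.45,
    radius_px: float = KINETIC_MOVIE_RADIUS,
    floor_frac: float = KINETIC_FLOOR_FRAC,
    noise_variance: float = NOISE_VARIANCE,
    seed: int | None = None,
) -> tuple[np.ndarray, dict]:
    """Noisy mean-intensity series of one kinetic adhesion.

    Emulates the series a tracked lineage would report: pixel noise is
    averaged over the disc's area, so the noise on the mean scales as
    1/sqrt(n_pixels).
    """
    schedule, meta = kinetic_schedule(
        assembly_len, disassembly_len, stability_len, peak_intensity, floor_frac
    )
    rng = np.random.default_rng(seed)
    n_pixels = max(1.0, np.pi * radius_px**2)
    noisy = schedule + rng.normal(0.0, np.sqrt(noise_variance / n_pixels), size=schedule.size)
    return np.clip(noisy, 0.0, 1.0), meta


# ---------------------------------------------------------------------------
# scoring against ground truth
# ---------------------------------------------------------------------------

#: A planted adhesion counts as detected when a single lineage's blob
#: contains the true center in at least this fraction of its life frames.
DETECTION_COVERAGE = 0.9


def score_against_truth(
    movie: SimulatedMovie,
    lineages: list[Lineage],
    decompositions: dict[int, PhaseDecomposition] | None = None,
) -> pd.DataFrame:
    """Per-planted-adhesion detection/tracking/property recovery metrics.

    For every truth record, the lineage whose blob contains the planted
    center in the most life frames is taken as its recovered lineage;
    ``tracking_accuracy`` is that lineage's coverage fraction,
    ``detected`` requires coverage ≥ 0.9 and ``full_life`` coverage of
    every planted frame.
    """
    shape = movie.shape
    n_frames = len(movie.frames)
    lin_map = np.full((n_frames, *shape), -1, dtype=np.int32)
    blob_by = {}
    for lin in lineages:
        for blob in lin.blobs:
            lin_map[blob.frame_index][blob.rows, blob.cols] = lin.lineage_id
            blob_by[(lin.lineage_id, blob.frame_index)] = blob
    by_id = {lin.lineage_id: lin for lin in lineages}

    rows = []
    for tr in movie.truth:
        life = tr.longevity
        hits: dict[int, int] = {}
        for idx, t in enumerate(tr.life_frames):
            r = int(round(tr.centers[idx][0]))
            c = int(round(tr.centers[idx][1]))
            lid = int(lin_map[t, r, c])
            if lid >= 0:
                hits[lid] = hits.get(lid, 0) + 1
        if hits:
            best_lid = max(hits, key=lambda k: (hits[k], -k))
            coverage = hits[best_lid] / life
            lin = by_id[best_lid]
            areas, means = [], []
            for t in tr.life_frames:
                blob = blob_by.get((best_lid, t))
                if blob is not None:
                    areas.append(blob.area_px)
                    means.append(blob.mean_intensity)
            rec = {
                "lineage_id": best_lid,
                "tracking_accuracy": coverage,
                "longevity_recovered": lin.length,
                "area_px_recovered": float(np.mean(areas)) if areas else np.nan,
                "intensity_recovered": float(np.mean(means)) if means else np.nan,
            }
        else:
            coverage = 0.0
            rec = {
                "lineage_id": -1,
                "tracking_accuracy": 0.0,
                "longevity_recovered": 0,
                "area_px_recovered": np.nan,
                "intensity_recovered": np.nan,
            }
        row = {
            "adhesion_id": tr.adhesion_id,
            "radius_px": tr.radius_px,
            "intensity_planted": float(np.max(tr.intensities)),
            "longevity_planted": life,
            "area_px_planted": np.pi * tr.radius_px**2,
            "detected": coverage >= DETECTION_COVERAGE,
            "full_life": coverage >= 1.0,
            **rec,
        }
        row["longevity_error"] = row["longevity_recovered"] - life
        row["area_error_px"] = row["area_px_recovered"] - row["area_px_planted"]
        row["intensity_error"] = (
            row["intensity_recovered"] - float(np.mean(tr.intensities))
        )
        if tr.kinetics and "assembly_len" in tr.kinetics:
            row.update({f"planted_{k}": v for k, v in tr.kinetics.items()})
            dec = (decompositions or {}).get(row["lineage_id"])
            if dec is not None:
                row["recovered_assembly_len"] = dec.assembly.n_points if dec.assembly else np.nan
                row["recovered_assembly_rate"] = dec.assembly.rate if dec.assembly else np.nan
                row["recovered_disassembly_len"] = (
                    dec.disassembly.n_points if dec.disassembly else np.nan
                )
                row["recovered_disassembly_rate"] = (
                    dec.disassembly.rate if dec.disassembly else np.nan
                )
                row["recovered_stability_len"] = (
                    dec.stability_length if dec.stability_length is not None else np.nan
                )
        if tr.kinetics and "speed_px_per_frame" in tr.kinetics:
            row["speed_px_per_frame"] = tr.kinetics["speed_px_per_frame"]
        rows.append(row)
    return pd.DataFrame(rows)


def detection_floor(scores: pd.DataFrame, min_fraction: float = 0.5) -> float:
    """Lowest planted intensity from which detection is reliable.

    A planted intensity level is reliable when at least ``min_fraction``
    of its adhesions (across radii) are detected; the floor is the lowest
    level such that it and every brighter level are reliable.  NaN when no
    level qualifies.
    """
    frac = scores.groupby("intensity_planted")["detected"].mean().sort_index()
    ok = frac >= min_fraction
    # walk down from the brightest level while reliability holds
    floor = np.nan
    for level in ok.index[::-1]:
        if ok[level]:
            floor = float(level)
        else:
            break
    return floor
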