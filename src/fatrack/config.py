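"""Core data containers and run configuration.

Intensities are kept on a fixed absolute scale (camera full-scale mapped to
1.0) so that the same adhesion is comparable across frames; per-frame
rescaling would corrupt the kinetic rate fits downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np


@dataclass(frozen=True)
class AnalysisConfig:
    """Parameters of a full analysis run.

    Attributes
    ----------
    detection_threshold : float
        Threshold applied to the high-pass-filtered image to call adhesion
        pixels, in normalized intensity units.  Sensible values lie in
        (0.05, 0.10) for typical TIRF data.
    filter_radius_px : int
        Radius of the round averaging kernel used for high-pass filtering.
    large_adhesion_px : int
        Minimum area (pixels) for an adhesion to participate in the
        bridge-pixel reassignment rule during water segmentation.
    min_adhesion_px : int
        Minimum blob area kept after segmentation.
    split_min_depth : float
        Minimum intensity drop between two local maxima for them to seed
        separate adhesions (saddle depth); shallower structure is treated
        as noise on a single adhesion.
    max_link_distance_px : float
        Cap on the nearest-centroid fallback used to link a blob with no
        pixel overlap in the next frame.  The default (3 px) keeps the
        expected number of spurious noise-blob captures per frame well
        below one at the reference noise level while still bridging
        one-frame detection dropouts; ``inf`` disables the cap.
    min_rate_points : int
        Minimum lineage length (intensity time points) for rate analysis.
    min_phase_length : int
        Minimum assembly/disassembly window length for the phase search.
    fit_alpha : float
        Significance level for keeping a log-linear phase fit.
    bootstrap_reps : int
        Bootstrap replicates for median-difference comparisons.
    bootstrap_max_n : int
        Per-group sample-size cutoff above which the rank-sum test is used
        instead of the bootstrap.
    pixel_size_um : float
        Lateral calibration, micrometres per pixel.
    frame_interval_min : float
        Minutes between consecutive frames.
    seed : int
        Master seed; stage seeds are derived deterministically from it.
    """

    detection_threshold: float = 0.1
    filter_radius_px: int = 11
    large_adhesion_px: int = 40
    min_adhesion_px: int = 1
    split_min_depth: float = 0.05
    max_link_distance_px: float = 3.0
    min_rate_points: int = 20
    min_phase_length: int = 10
    fit_alpha: float = 0.05
    bootstrap_reps: int = 50_000
    bootstrap_max_n: int = 2000
    pixel_size_um: float = 0.215
    frame_interval_min: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.detection_threshold < 1.0:
            raise ValueError("detection_threshold must lie in (0, 1)")
        if self.min_phase_length < 2:
            raise ValueError("min_phase_length must be >= 2")
        for name in ("filter_radius_px", "large_adhesion_px", "min_adhesion_px",
                     "min_rate_points", "bootstrap_reps", "bootstrap_max_n"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.fit_alpha < 1.0:
            raise ValueError("fit_alpha must lie in (0, 1)")
        if self.pixel_size_um <= 0 or self.frame_interval_min <= 0:
            raise ValueError("calibration values must be positive")

    def replace(self, **kwargs) -> "AnalysisConfig":
        """Return a copy with the given fields replaced."""
        d = asdict(self)
        d.update(kwargs)
        return AnalysisConfig(**d)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        h = np.uint32(self.seed)
        for ch in stage:
            h = np.uint32(h * np.uint32(31) + np.uint32(ord(ch)))
        return int(h % np.uint32(2**31 - 1))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FrameImage:
    """A single normalized fluorescence frame.

    ``pixels`` holds dimensionless intensities in [0, 1]; the full camera
    range maps to 1.0.
    """

    pixels: np.ndarray
    frame_index: int = 0
    pixel_size_um: float = 0.215
    frame_interval_min: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        lo, hi = float(self.pixels.min(initial=0.0)), float(self.pixels.max(initial=0.0))
        if lo < 0.0 or hi > 1.0 + 1e-12:
            raise ValueError(f"pixel values outside [0, 1]: min={lo}, max={hi}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape
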