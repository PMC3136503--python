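"""Assembly/disassembly kinetics of adhesion intensity time series.

Adhesions assemble and disassemble with log-linear intensity progression.
The assembly phase is anchored at the start of a lineage's mean-intensity
series and the disassembly phase at its end; each candidate window is
normalized by its anchor point (first point for assembly, last point for
disassembly), log-transformed, and fit by ordinary least squares against
time in minutes.  Phase lengths are chosen by exhaustive search for the
pair of non-overlapping windows maximizing the sum of adjusted R² values,
with ties resolved toward the longest combined phases.  The stability
(maturity) phase is the gap between the two windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

ASSEMBLY = "assembly"
DISASSEMBLY = "disassembly"


@dataclass
class PhaseFit:
    """A log-linear fit of one phase over one window.

    ``rate`` is reported positive for both phases (min⁻¹); ``window`` is
    an inclusive (start, end) index pair into the series.
    """

    phase: str
    window: tuple[int, int]
    rate: float
    slope: float
    adjusted_r2: float
    p_value: float
    n_points: int


@dataclass
class PhaseDecomposition:
    assembly: PhaseFit | None
    disassembly: PhaseFit | None
    series_floored: bool = False

    @property
    def stability_length(self) -> int | None:
        """Frames between the assembly and disassembly windows."""
        if self.assembly is None or self.disassembly is None:
            return None
        return self.disassembly.window[0] - self.assembly.window[1] - 1


def adjusted_r2(r2: float, n: int) -> float:
    """Adjusted R² for the single-regressor linear model."""
    if n <= 2:
        return r2
    return 1.0 - (1.0 - r2) * (n - 1) / (n - 2)


def fit_phase(
    series: np.ndarray,
    window: tuple[int, int],
    phase: str,
    frame_interval_min: float = 1.0,
) -> PhaseFit:
    """OLS fit of log-normalized intensity against time over a window.

    The series is normalized by the first (assembly) or last (disassembly)
    point of the window before the log transform, so the fit is invariant
    to overall intensity scale.  Rates are in min⁻¹ and reported positive;
    the p-value is the two-sided t-test on the slope.
    """
    if phase not in (ASSEMBLY, DISASSEMBLY):
        raise ValueError(f"unknown phase: {phase}")
    start, end = window
    seg = np.asarray(series, dtype=np.float64)[start:end + 1]
    if seg.size < 2:
        raise ValueError("window must contain at least 2 points")
    if np.any(seg <= 0):
        raise ValueError("nonpositive intensity in fit window")
    anchor = seg[0] if phase == ASSEMBLY else seg[-1]
    y = np.log(seg / anchor)
    t = np.arange(seg.size, dtype=np.float64) * frame_interval_min
    res = stats.linregress(t, y)
    slope = float(res.slope)
    r2 = float(res.rvalue**2)
    p = float(res.pvalue) if np.isfinite(res.pvalue) else 1.0
    return PhaseFit(
        phase=phase,
        window=(start, end),
        rate=slope if phase == ASSEMBLY else -slope,
        slope=slope,
        adjusted_r2=adjusted_r2(r2, seg.size),
        p_value=p,
        n_points=seg.size,
    )


def _floor_positive(series: np.ndarray) -> tuple[np.ndarray, bool]:
    """Floor nonpositive intensities at a tiny fraction of the series
    maximum so the log transform stays defined; flag such series."""
    series = np.asarray(series, dtype=np.float64)
    top = series.max()
    if top <= 0:
        raise ValueError("series has no positive intensity")
    floor = top * np.finfo(np.float64).eps
    if np.any(series < floor):
        return np.maximum(series, floor), True
    return series, False


def decompose_phases(
    series: np.ndarray,
    min_phase_length: int = 10,
    frame_interval_min: float = 1.0,
) -> PhaseDecomposition:
    """Select assembly/disassembly windows by the maximum-adjusted-R² search.

    All assembly lengths ``a >= min_phase_length`` anchored at the series
    start and disassembly lengths ``d >= min_phase_length`` anchored at the
    end with ``a + d <= len(series)`` are evaluated; the pair maximizing
    the sum of adjusted R² wins, ties going to the largest ``a + d`` (then
    the larger ``a``).  A series too short for both phases gets the single
    feasible phase with the best adjusted R².
    """
    series = np.asarray(series, dtype=np.float64)
    n = series.size
    m = int(min_phase_length)
    if n < m:
        raise ValueError(f"series length {n} below minimum phase length {m}")
    series, floored = _floor_positive(series)

    asm = {
        a: fit_phase(series, (0, a - 1), ASSEMBLY, frame_interval_min)
        for a in range(m, n + 1)
    }
    dis = {
        d: fit_phase(series, (n - d, n - 1), DISASSEMBLY, frame_interval_min)
        for d in range(m, n + 1)
    }

    if n >= 2 * m:
        best: tuple | None = None
        for a in range(m, n - m + 1):
            fa = asm[a]
            ra = fa.adjusted_r2 if np.isfinite(fa.adjusted_r2) else -np.inf
            for d in range(m, n - a + 1):
                fd = dis[d]
                rd = fd.adjusted_r2 if np.isfinite(fd.adjusted_r2) else -np.inf
                key = (ra + rd, a + d, a)
                if best is None or key > best[0]:
                    best = (key, fa, fd)
        assert best is not None
        return PhaseDecomposition(assembly=best[1], disassembly=best[2], series_floored=floored)

    # too short for both phases: keep the better single fit
    def _score(f: PhaseFit) -> tuple:
        r = f.adjusted_r2 if np.isfinite(f.adjusted_r2) else -np.inf
        return (r, f.n_points)

    best_a = max(asm.values(), key=_score)
    best_d = max(dis.values(), key=_score)
    if _score(best_a) >= _score(best_d):
        return PhaseDecomposition(assembly=best_a, disassembly=None, series_floored=floored)
    return PhaseDecomposition(assembly=None, disassembly=best_d, series_floored=floored)


def smooth_for_display(series: np.ndarray, span: float = 0.3) -> np.ndarray:
    """Lowess-smoothed copy of a series, for plotting only.

    Never used in rate fitting; rates always come from the raw series.
    """
    if not 0.0 < span <= 1.0:
        raise ValueError("span must lie in (0, 1]")
    from statsmodels.nonparametric.smoothers_lowess import lowess

    series = np.asarray(series, dtype=np.float64)
    x = np.arange(series.size, dtype=np.float64)
    return lowess(series, x, frac=span, return_sorted=False)
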