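"""Results filtering, spatial statistics, and two-sample comparisons.

Rate and phase-length populations are filtered before comparison:
lineages must live at least ``min_rate_points`` frames, split-born
lineages are excluded from assembly statistics, merge-death lineages from
disassembly statistics, and only fits whose slope p-value clears
``fit_alpha`` are kept.  Comparisons between conditions use a percentile
bootstrap on the median difference for small samples and the Wilcoxon
rank-sum test for large ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cell_edge import CellEdgeMask, distance_to_edge
from .config import AnalysisConfig
from .kinetics import ASSEMBLY, DISASSEMBLY, PhaseDecomposition
from .tracking import BIRTH_SPLIT, DEATH_MERGED, Lineage

#: Band width (µm) used for "near the cell edge" classification.
EDGE_BAND_UM = 5.0


@dataclass
class RateRecord:
    lineage_id: int
    phase: str
    rate: float
    p_value: float
    adjusted_r2: float
    n_points: int
    longevity_min: float
    condition: str = ""
    birth_dist_um: float | None = None
    death_dist_um: float | None = None


def filter_for_rates(
    lineages: list[Lineage],
    decompositions: dict[int, PhaseDecomposition],
    config: AnalysisConfig,
    condition: str = "",
) -> list[RateRecord]:
    """Rate records passing the lifetime/birth/death/significance gates."""
    records: list[RateRecord] = []
    for lin in lineages:
        dec = decompositions.get(lin.lineage_id)
        if dec is None or lin.length < config.min_rate_points:
            continue
        longevity = lin.length * config.frame_interval_min
        if dec.assembly is not None and lin.birth_type != BIRTH_SPLIT:
            f = dec.assembly
            if f.rate > 0 and f.p_value <= config.fit_alpha:
                records.append(RateRecord(
                    lineage_id=lin.lineage_id, phase=ASSEMBLY, rate=f.rate,
                    p_value=f.p_value, adjusted_r2=f.adjusted_r2,
                    n_points=f.n_points, longevity_min=longevity,
                    condition=condition,
                ))
        if dec.disassembly is not None and lin.death_type != DEATH_MERGED:
            f = dec.disassembly
            if f.rate > 0 and f.p_value <= config.fit_alpha:
                records.append(RateRecord(
                    lineage_id=lin.lineage_id, phase=DISASSEMBLY, rate=f.rate,
                    p_value=f.p_value, adjusted_r2=f.adjusted_r2,
                    n_points=f.n_points, longevity_min=longevity,
                    condition=condition,
                ))
    return records


def filter_for_phase_lengths(
    lineages: list[Lineage],
    decompositions: dict[int, PhaseDecomposition],
    config: AnalysisConfig,
    condition: str = "",
) -> pd.DataFrame:
    """Phase-length records for lineages where both phases were observed.

    Requires a non-split birth, a non-merge death, and both fits
    significant at ``fit_alpha``.
    """
    rows = []
    for lin in lineages:
        dec = decompositions.get(lin.lineage_id)
        if dec is None or dec.assembly is None or dec.disassembly is None:
            continue
        if lin.birth_type == BIRTH_SPLIT or lin.death_type == DEATH_MERGED:
            continue
        if dec.assembly.p_value > config.fit_alpha or dec.disassembly.p_value > config.fit_alpha:
            continue
        rows.append({
            "lineage_id": lin.lineage_id,
            "condition": condition,
            "assembly_len": dec.assembly.n_points,
            "stability_len": dec.stability_length,
            "disassembly_len": dec.disassembly.n_points,
        })
    return pd.DataFrame(rows, columns=[
        "lineage_id", "condition", "assembly_len", "stability_len", "disassembly_len",
    ])


def birth_death_positions(
    lineages: list[Lineage],
    edges: CellEdgeMask | list[CellEdgeMask],
    pixel_size_um: float,
) -> pd.DataFrame:
    """Distance (µm) of each lineage's first/last centroid to the cell
    edge, with 5 µm band membership flags."""
    rows = []
    for lin in lineages:
        birth_edge = _edge_for_frame(edges, lin.birth_frame)
        death_edge = _edge_for_frame(edges, lin.death_frame)
        bd = distance_to_edge(tuple(lin.blobs[0].centroid), birth_edge, pixel_size_um)
        dd = distance_to_edge(tuple(lin.blobs[-1].centroid), death_edge, pixel_size_um)
        rows.append({
            "lineage_id": lin.lineage_id,
            "birth_dist_um": bd,
            "death_dist_um": dd,
            "born_within_5um": bd < EDGE_BAND_UM,
            "died_within_5um": dd < EDGE_BAND_UM,
            "birth_inside_cell": birth_edge.contains(tuple(lin.blobs[0].centroid)),
            "death_inside_cell": death_edge.contains(tuple(lin.blobs[-1].centroid)),
        })
    return pd.DataFrame(rows)


def _edge_for_frame(edges, frame: int) -> CellEdgeMask:
    if isinstance(edges, CellEdgeMask):
        return edges
    try:
        return edges[frame]
    except (IndexError, TypeError) as exc:
        raise ValueError(f"no edge mask available for frame {frame}") from exc


@dataclass
class BootstrapResult:
    p_value: float
    median_a: float
    median_b: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    percent_change: float
    percent_change_ci: tuple[float, float]
    reps: int


def bootstrap_median_diff(
    sample_a: np.ndarray,
    sample_b: np.ndarray,
    reps: int = 50_000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> BootstrapResult:
    """Percentile-bootstrap comparison of two sample medians.

    Each group is resampled with replacement ``reps`` times; the two-sided
    p-value is ``2·min(P(diff<=0), P(diff>=0))`` on the bootstrap
    distribution of median differences, bounded to [2/reps, 1].  Also
    returns percentile CIs on each median and on the percent change of the
    median (b relative to a).
    """
    a = np.asarray(sample_a, dtype=np.float64)
    b = np.asarray(sample_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if reps < 1000:
        raise ValueError("use at least 1000 bootstrap replicates")
    rng = np.random.default_rng(seed)

    med_a = np.empty(reps)
    med_b = np.empty(reps)
    chunk = max(1, min(reps, int(5e6 // max(a.size, b.size, 1)) or 1))
    done = 0
    while done < reps:
        k = min(chunk, reps - done)
        med_a[done:done + k] = np.median(a[rng.integers(0, a.size, size=(k, a.size))], axis=1)
        med_b[done:done + k] = np.median(b[rng.integers(0, b.size, size=(k, b.size))], axis=1)
        done += k

    diff = med_b - med_a
    p = 2.0 * min(np.mean(diff <= 0.0), np.mean(diff >= 0.0))
    p = float(min(max(p, 2.0 / reps), 1.0))

    lo, hi = 100 * alpha / 2, 100 * (1 - alpha / 2)
    obs_a, obs_b = float(np.median(a)), float(np.median(b))
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * (med_b - med_a) / med_a
    return BootstrapResult(
        p_value=p,
        median_a=obs_a,
        median_b=obs_b,
        ci_a=tuple(np.percentile(med_a, [lo, hi])),
        ci_b=tuple(np.percentile(med_b, [lo, hi])),
        percent_change=100.0 * (obs_b - obs_a) / obs_a if obs_a != 0 else np.nan,
        percent_change_ci=tuple(np.percentile(pct[np.isfinite(pct)], [lo, hi])),
        reps=reps,
    )


def rank_sum_test(sample_a: np.ndarray, sample_b: np.ndarray) -> float:
    """Two-sided Wilcoxon/Mann-Whitney rank-sum p-value (tie-corrected
    normal approximation)."""
    a = np.asarray(sample_a, dtype=np.float64)
    b = np.asarray(sample_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def compare_samples(
    sample_a: np.ndarray,
    sample_b: np.ndarray,
    config: AnalysisConfig | None = None,
    seed: int | None = None,
) -> dict:
    """Dispatch a two-sample comparison: bootstrap for small samples,
    rank-sum when both groups exceed the cutoff (bootstrap cost grows with
    sample size)."""
    config = config or AnalysisConfig()
    a = np.asarray(sample_a, dtype=np.float64)
    b = np.asarray(sample_b, dtype=np.float64)
    report: dict = {
        "n_a": int(a.size),
        "n_b": int(b.size),
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
    }
    report["percent_change"] = (
        100.0 * (report["median_b"] - report["median_a"]) / report["median_a"]
        if report["median_a"] != 0 else float("nan")
    )
    if min(a.size, b.size) > config.bootstrap_max_n:
        report["method"] = "rank_sum"
        report["p_value"] = rank_sum_test(a, b)
    else:
        report["method"] = "bootstrap"
        boot = bootstrap_median_diff(a, b, reps=config.bootstrap_reps, seed=seed)
        report["p_value"] = boot.p_value
        report["ci_a"] = boot.ci_a
        report["ci_b"] = boot.ci_b
        report["percent_change_ci"] = boot.percent_change_ci
    return report
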