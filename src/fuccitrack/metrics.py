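"""Trajectory statistics: migration measures, doubling times, daughter
heterogeneity and synchrony, per-phase dynamics and the terminal speed
jump.

All quantities are reported in physical units via the movie calibration:
distances in µm, times in hours, speeds in µm/h.  For a track with ``n``
positions there are ``n − 1`` steps; the trajectory time is
``(n − 1) · Δt``, total distance is the summed step length, displacement
the straight line from first to last position, directionality their
ratio (1 for a straight path, 0 for a closed loop) and average speed
distance over time.

The *terminal speed jump* is a per-cell event in the hour before
division: an instantaneous speed during the final hour of G2/M that is
at least 2.5-fold the mean instantaneous speed over the last two hours
before division and at least 3-fold each adjacent step speed within that
final hour.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from fuccitrack.tracking import LineageTree, Track, categorize

__all__ = [
    "MeasureRow",
    "JumpCriterion",
    "PairFilter",
    "trajectory_measures",
    "instantaneous_speeds",
    "doubling_times",
    "summarize_durations",
    "daughter_pair_differences",
    "division_synchrony",
    "phase_durations",
    "per_phase_dynamics",
    "detect_terminal_speed_jump",
]


@dataclass(frozen=True)
class MeasureRow:
    """Per-cell migration measures.

    ``directionality`` is NaN when the cell never moved (zero total
    distance); such cells are excluded from summaries.
    """

    cell_id: str
    trajectory_time_h: float
    total_distance_um: float
    displacement_um: float
    directionality: float
    avg_speed_um_h: float


@dataclass(frozen=True)
class JumpCriterion:
    """Terminal-speed-jump thresholds (see module docstring)."""

    jump_window_h: float = 1.0
    baseline_window_h: float = 2.0
    baseline_fold: float = 2.5
    neighbor_fold: float = 3.0

    def __post_init__(self) -> None:
        if self.jump_window_h > self.baseline_window_h:
            raise ValueError("jump window cannot exceed baseline window")
        if self.baseline_fold <= 1 or self.neighbor_fold <= 1:
            raise ValueError("fold thresholds must exceed 1")


@dataclass(frozen=True)
class PairFilter:
    """Daughter-pair selection: both daughters must be observed at least
    ``min_trajectory_time_h`` and their trajectory times may differ by at
    most ``max_pair_time_diff_h``.  Defaults are the thresholds used for
    the breast-cancer (BT549) analysis: 10 h and 3 h."""

    min_trajectory_time_h: float = 10.0
    max_pair_time_diff_h: float = 3.0

    def __post_init__(self) -> None:
        if self.min_trajectory_time_h <= 0 or self.max_pair_time_diff_h <= 0:
            raise ValueError("filter thresholds must be positive")


def _positions(track: Track) -> np.ndarray:
    p = np.asarray(track.positions, dtype=float)
    if len(p) < 2:
        raise ValueError(f"track {track.id} needs >= 2 frames for trajectory statistics")
    return p


def trajectory_measures(track: Track, pixel_size_um: float, frame_interval_min: float) -> MeasureRow:
    """Total distance, displacement, directionality and average speed."""
    p = _positions(track)
    steps = np.linalg.norm(np.diff(p, axis=0), axis=1) * pixel_size_um
    total = float(steps.sum())
    disp = float(np.linalg.norm(p[-1] - p[0]) * pixel_size_um)
    time_h = (len(p) - 1) * frame_interval_min / 60.0
    return MeasureRow(
        cell_id=track.id,
        trajectory_time_h=time_h,
        total_distance_um=total,
        displacement_um=disp,
        directionality=disp / total if total > 0 else math.nan,
        avg_speed_um_h=total / time_h,
    )


def instantaneous_speeds(track: Track, pixel_size_um: float, frame_interval_min: float) -> np.ndarray:
    """Per-step speeds in µm/h; length ``n − 1``.

    Step ``t`` runs from frame ``birth + t`` to ``birth + t + 1``.
    """
    p = _positions(track)
    return np.linalg.norm(np.diff(p, axis=0), axis=1) * pixel_size_um / (frame_interval_min / 60.0)


def doubling_times(lineage: LineageTree, frame_interval_min: float) -> list[tuple[str, float]]:
    """Doubling time of each dividing daughter cell, in hours.

    A daughter that itself divides has been observed over one complete
    cycle, so its trajectory time (birth to division) is a direct
    doubling-time measurement.
    """
    cats = categorize(lineage)
    return [
        (t.id, (t.division_frame - t.birth_frame) * frame_interval_min / 60.0)
        for t in cats["DividingDaughterCells"]
    ]


def summarize_durations(hours: list[float], frame_interval_min: float) -> dict[str, float]:
    """Mean, sd, median and mode of a duration sample.

    The mode of this continuous quantity is taken as the midpoint of the
    tallest histogram bin, with bin width equal to the frame interval.
    """
    if not hours:
        return {"n": 0, "mean": math.nan, "sd": math.nan, "median": math.nan, "mode": math.nan}
    arr = np.asarray(hours, dtype=float)
    width = frame_interval_min / 60.0
    lo = arr.min() - width / 2
    nbins = max(1, int(np.ceil((arr.max() - lo) / width)))
    counts, edges = np.histogram(arr, bins=nbins, range=(lo, lo + nbins * width))
    k = int(np.argmax(counts))
    return {
        "n": len(arr),
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
        "median": float(np.median(arr)),
        "mode": float((edges[k] + edges[k + 1]) / 2),
    }


def _sibling_pairs(lineage: LineageTree):
    for t in lineage:
        present = [d for d in t.daughter_ids if d in lineage.tracks]
        if len(present) >= 2:
            yield from itertools.combinations(sorted(present), 2)


def daughter_pair_differences(
    lineage: LineageTree,
    measures: dict[str, MeasureRow],
    pair_filter: PairFilter | None = None,
) -> pd.DataFrame:
    """Absolute per-pair differences of the four migration measures.

    Only sibling pairs in which both daughters pass the trajectory-time
    filter are kept; a multi-daughter division contributes every
    unordered sibling pair.  Columns: the two cell ids and |Δ| of total
    distance, displacement, directionality and average speed.
    """
    pair_filter = pair_filter or PairFilter()
    rows = []
    for a_id, b_id in _sibling_pairs(lineage):
        if a_id not in measures or b_id not in measures:
            continue
        a, b = measures[a_id], measures[b_id]
        if min(a.trajectory_time_h, b.trajectory_time_h) < pair_filter.min_trajectory_time_h:
            continue
        if abs(a.trajectory_time_h - b.trajectory_time_h) > pair_filter.max_pair_time_diff_h:
            continue
        rows.append(
            {
                "cell_a": a_id,
                "cell_b": b_id,
                "d_total_distance_um": abs(a.total_distance_um - b.total_distance_um),
                "d_displacement_um": abs(a.displacement_um - b.displacement_um),
                "d_directionality": abs(a.directionality - b.directionality),
                "d_avg_speed_um_h": abs(a.avg_speed_um_h - b.avg_speed_um_h),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cell_a", "cell_b", "d_total_distance_um", "d_displacement_um",
            "d_directionality", "d_avg_speed_um_h",
        ],
    )


def division_synchrony(lineage: LineageTree, frame_interval_min: float) -> list[float]:
    """|Δ division time| in hours over sibling pairs where both divide."""
    out = []
    for a_id, b_id in _sibling_pairs(lineage):
        a, b = lineage[a_id], lineage[b_id]
        if a.division_frame is None or b.division_frame is None:
            continue
        out.append(abs(a.division_frame - b.division_frame) * frame_interval_min / 60.0)
    return out


def phase_durations(labels: list[str], frame_interval_min: float) -> dict[str, dict[str, float]]:
    """Duration (h) and fraction of each phase over a complete cycle.

    Fractions are over G1 + S + G2M only; Unknown time is reported
    separately and excluded from the denominator.

    Raises
    ------
    ValueError
        If every frame is Unknown.
    """
    step_h = frame_interval_min / 60.0
    counts = {p: labels.count(p) for p in ("G1", "S", "G2M", "Unknown")}
    known = counts["G1"] + counts["S"] + counts["G2M"]
    if known == 0:
        raise ValueError("no called phases: all frames Unknown")
    return {
        p: {
            "duration_h": counts[p] * step_h,
            "fraction": (counts[p] / known) if p != "Unknown" else math.nan,
        }
        for p in counts
    }


def per_phase_dynamics(
    track: Track,
    labels: list[str],
    pixel_size_um: float,
    frame_interval_min: float,
) -> dict[str, dict[str, float]]:
    """Mean instantaneous speed and directionality per phase.

    Steps are attributed to the phase of their starting frame.  Per-phase
    directionality is that of the sub-path through the positions labelled
    with the phase.  Phases absent from the labels get NaN entries.
    """
    if len(labels) != track.n_frames:
        raise ValueError(
            f"labels length {len(labels)} does not match track length {track.n_frames}"
        )
    p = _positions(track)
    speeds = instantaneous_speeds(track, pixel_size_um, frame_interval_min)
    out: dict[str, dict[str, float]] = {}
    for phase in ("G1", "S", "G2M"):
        step_mask = np.array([lab == phase for lab in labels[:-1]])
        frame_mask = np.array([lab == phase for lab in labels])
        if not frame_mask.any():
            out[phase] = {"mean_speed_um_h": math.nan, "directionality": math.nan}
            continue
        sub = p[frame_mask]
        sub_steps = np.linalg.norm(np.diff(sub, axis=0), axis=1).sum()
        disp = np.linalg.norm(sub[-1] - sub[0])
        out[phase] = {
            "mean_speed_um_h": float(speeds[step_mask].mean()) if step_mask.any() else math.nan,
            "directionality": float(disp / sub_steps) if sub_steps > 0 else math.nan,
        }
    return out


def detect_terminal_speed_jump(
    track: Track,
    labels: list[str],
    pixel_size_um: float,
    frame_interval_min: float,
    criterion: JumpCriterion | None = None,
) -> tuple[bool, list[int]]:
    """Detect terminal speed jumps before a division.

    Candidate steps lie in the final ``jump_window_h`` before the
    division and start on a G2/M-labelled frame.  A step speed qualifies
    when it is at least ``baseline_fold`` times the mean speed over the
    final ``baseline_window_h`` (the baseline includes the candidate) and
    at least ``neighbor_fold`` times each adjacent step speed that also
    falls inside the jump window.

    Returns the per-cell flag and the qualifying step indices (step ``t``
    starts at frame ``birth_frame + t``).

    Raises
    ------
    ValueError
        On a non-dividing track or one shorter than the baseline window.
    """
    criterion = criterion or JumpCriterion()
    if track.division_frame is None:
        raise ValueError(f"track {track.id} does not divide")
    if len(labels) != track.n_frames:
        raise ValueError("labels must align with the track")
    speeds = instantaneous_speeds(track, pixel_size_um, frame_interval_min)
    step_h = frame_interval_min / 60.0
    n_base = int(round(criterion.baseline_window_h / step_h))
    n_jump = int(round(criterion.jump_window_h / step_h))
    if len(speeds) < n_base:
        raise ValueError(
            f"track {track.id} has {len(speeds)} steps; baseline window needs {n_base}"
        )
    baseline = float(speeds[-n_base:].mean())
    first_jump_idx = len(speeds) - n_jump
    jumps = []
    for t in range(first_jump_idx, len(speeds)):
        if labels[t] != "G2M":
            continue
        v = speeds[t]
        if v < criterion.baseline_fold * baseline:
            continue
        ok = True
        for nb in (t - 1, t + 1):
            if first_jump_idx <= nb < len(speeds) and v < criterion.neighbor_fold * speeds[nb]:
                ok = False
                break
        if ok:
            jumps.append(t)
    return bool(jumps), jumps
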