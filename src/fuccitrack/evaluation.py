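"""Tracking-accuracy evaluation against a reference annotation.

The location error compares tracker output with expert-consensus
reference coordinates per cell per frame, axis-wise (|Δx| and |Δy| in
µm, as the original benchmark plots them), together with the maximum
pixel deviation and a flag for the conventional 20 px accuracy bound.
Correction rate — corrected frames over total frames — quantifies how
much scripted (or manual) intervention a track needed.  Intensity
profiles document that tracking quality does not depend on fluorescence
brightness.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from skimage import measure

from fuccitrack.fucci import _disk_mean
from fuccitrack.image_io import Movie
from fuccitrack.tracking import Track

__all__ = [
    "EvaluationResult",
    "location_error",
    "correction_rate",
    "intensity_profiles",
    "masks_to_reference_table",
    "read_reference_table",
    "ACCURACY_BOUND_PX",
]

#: Conventional per-coordinate accuracy bound (px) for "accurate" tracking.
ACCURACY_BOUND_PX = 20.0


@dataclass
class EvaluationResult:
    """Axis-wise location errors and summary statistics.

    ``per_frame`` has one row per evaluated (cell, frame) with |Δx| and
    |Δy| in µm and px; ``mean_dx_um``/``mean_dy_um`` with their sds
    summarize them, ``max_abs_px`` is the largest single-coordinate
    deviation and ``within_bound`` says whether it stays under the 20 px
    bound.
    """

    per_frame: pd.DataFrame
    mean_dx_um: float
    sd_dx_um: float
    mean_dy_um: float
    sd_dy_um: float
    max_abs_px: float
    within_bound: bool


def read_reference_table(path: str | Path) -> dict[str, np.ndarray]:
    """Read a reference annotation CSV (cell_id, frame, x, y; 0-based
    frames) into per-cell ``(n, 3)`` arrays of (frame, x, y)."""
    df = pd.read_csv(path)
    need = {"cell_id", "frame", "x", "y"}
    if not need.issubset(df.columns):
        raise ValueError(f"reference table needs columns {sorted(need)}")
    return {
        str(cid): block[["frame", "x", "y"]].to_numpy(float)
        for cid, block in df.groupby("cell_id", sort=False)
    }


def _match_tracks_to_reference(
    tracks: list[Track], reference: dict[str, np.ndarray]
) -> dict[str, str]:
    """Match each track to the nearest reference cell at the track's
    first frame; ambiguous matches raise."""
    assignment: dict[str, str] = {}
    claimed: dict[str, str] = {}
    for t in tracks:
        x0, y0 = t.positions[0]
        best, best_d = None, np.inf
        for rid, arr in reference.items():
            row = arr[arr[:, 0] == t.birth_frame]
            if row.size == 0:
                continue
            d = float(np.hypot(row[0, 1] - x0, row[0, 2] - y0))
            if d < best_d:
                best, best_d = rid, d
        if best is None:
            raise ValueError(f"no reference cell covers frame {t.birth_frame} for track {t.id}")
        if best in claimed:
            raise ValueError(
                f"ambiguous matching: tracks {claimed[best]} and {t.id} both nearest "
                f"to reference {best}"
            )
        claimed[best] = t.id
        assignment[t.id] = best
    return assignment


def location_error(
    tracks: list[Track],
    reference: dict[str, np.ndarray],
    pixel_size_um: float,
) -> EvaluationResult:
    """Axis-wise coordinate error of tracks against the reference.

    Raises
    ------
    ValueError
        If a matched pair shares no frames, or two tracks claim the same
        reference cell.
    """
    assignment = _match_tracks_to_reference(tracks, reference)
    rows = []
    for t in tracks:
        arr = reference[assignment[t.id]]
        ref_by_frame = {int(f): (x, y) for f, x, y in arr}
        overlap = [
            f for f in range(t.birth_frame, t.last_frame + 1) if f in ref_by_frame
        ]
        if not overlap:
            raise ValueError(
                f"track {t.id} and reference {assignment[t.id]} share no frames"
            )
        for f in overlap:
            x, y = t.position_at(f)
            xt, yt = ref_by_frame[f]
            rows.append(
                {
                    "cell_id": t.id,
                    "reference_id": assignment[t.id],
                    "frame": f,
                    "dx_px": abs(x - xt),
                    "dy_px": abs(y - yt),
                    "dx_um": abs(x - xt) * pixel_size_um,
                    "dy_um": abs(y - yt) * pixel_size_um,
                }
            )
    df = pd.DataFrame(rows)
    max_abs_px = float(df[["dx_px", "dy_px"]].to_numpy().max())
    return EvaluationResult(
        per_frame=df,
        mean_dx_um=float(df["dx_um"].mean()),
        sd_dx_um=float(df["dx_um"].std(ddof=1)) if len(df) > 1 else 0.0,
        mean_dy_um=float(df["dy_um"].mean()),
        sd_dy_um=float(df["dy_um"].std(ddof=1)) if len(df) > 1 else 0.0,
        max_abs_px=max_abs_px,
        within_bound=max_abs_px <= ACCURACY_BOUND_PX,
    )


def correction_rate(track: Track) -> float:
    """Corrected frames over total frames, in [0, 1]."""
    return len(track.corrected_frames) / track.n_frames


def intensity_profiles(movie: Movie, tracks: list[Track], diameter_px: float) -> pd.DataFrame:
    """Raw mean intensity per cell per frame along each track.

    For RGB movies the mean is over all three channels.  Rows are frames
    (0-based), columns cells; entries are NaN where a cell is absent.
    """
    data: dict[str, pd.Series] = {}
    for t in tracks:
        vals, frames = [], []
        for i, (x, y) in enumerate(t.positions):
            f = t.birth_frame + i
            vals.append(float(_disk_mean(movie.frame(f), x, y, diameter_px).mean()))
            frames.append(f)
        data[t.id] = pd.Series(vals, index=frames)
    return pd.DataFrame(data)


def masks_to_reference_table(mask_stack_path: str | Path, out_csv: str | Path) -> pd.DataFrame:
    """Convert a labeled-mask TIFF stack to a reference coordinate CSV.

    Each page is a 16-bit label image (0 = background); the centroid of
    every label on every page becomes one (cell_id, frame, x, y) row, the
    format :func:`read_reference_table` reads.
    """
    stack = tifffile.imread(Path(mask_stack_path))
    if stack.ndim == 2:
        stack = stack[None]
    rows = []
    for f, page in enumerate(stack):
        for region in measure.regionprops(page.astype(np.int64)):
            cy, cx = region.centroid
            rows.append({"cell_id": int(region.label), "frame": f, "x": cx, "y": cy})
    df = pd.DataFrame(rows, columns=["cell_id", "frame", "x", "y"])
    df.to_csv(out_csv, index=False)
    return df
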