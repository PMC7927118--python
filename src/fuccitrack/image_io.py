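"""Calibrated movie container and table I/O.

Movies are multi-page TIFF stacks (8- or 16-bit, grayscale or RGB) paired
with a physical calibration supplied by the caller: the microscope's pixel
size in micrometres and the acquisition interval in minutes.  Calibration
is never read from TIFF metadata — vendor dialects are too inconsistent —
so the user states it explicitly, exactly once.

Coordinate conventions used throughout the package: ``x`` is the column
and ``y`` the row, both 0-based with pixel centres at integer positions.
Exported tables use 1-based frame numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "Movie",
    "load_stack",
    "save_stack",
    "read_track_table",
    "write_track_table",
]

#: Column names used by coordinate tables (CSV and XLSX sheets).
TRACK_TABLE_COLUMNS = ["Cell_ID", "Frame", "X_px", "Y_px"]


@dataclass(frozen=True)
class Movie:
    """An image stack with physical calibration.

    Parameters
    ----------
    frames
        Array of shape ``(T, H, W)`` for grayscale or ``(T, H, W, 3)``
        for RGB; non-negative intensities.
    pixel_size_um
        Micrometres per pixel; must be positive.
    frame_interval_min
        Minutes between consecutive frames; must be positive.
    bit_depth
        8 or 16, matching the storage dtype.
    """

    frames: np.ndarray
    pixel_size_um: float
    frame_interval_min: float
    bit_depth: int

    def __post_init__(self) -> None:
        if self.frames.ndim not in (3, 4):
            raise ValueError(f"frames must be T×H×W or T×H×W×3, got shape {self.frames.shape}")
        if self.frames.ndim == 4 and self.frames.shape[-1] != 3:
            raise ValueError(f"RGB movies need 3 samples per pixel, got {self.frames.shape[-1]}")
        if self.frames.shape[0] < 1:
            raise ValueError("movie needs at least one frame")
        if self.pixel_size_um <= 0:
            raise ValueError(f"pixel_size_um must be positive, got {self.pixel_size_um}")
        if self.frame_interval_min <= 0:
            raise ValueError(f"frame_interval_min must be positive, got {self.frame_interval_min}")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape_hw(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def is_rgb(self) -> bool:
        return self.frames.ndim == 4

    def frame(self, i: int) -> np.ndarray:
        """Frame ``i`` (0-based); equals page ``i`` of the source TIFF."""
        return self.frames[i]


def _bit_depth_of(arr: np.ndarray) -> int:
    if arr.dtype == np.uint8:
        return 8
    if arr.dtype == np.uint16:
        return 16
    raise ValueError(f"unsupported dtype {arr.dtype}; expected uint8 or uint16")


def load_stack(path: str | Path, pixel_size_um: float, frame_interval_min: float) -> Movie:
    """Read a multi-page TIFF stack into a calibrated :class:`Movie`.

    A stack whose pages carry 3 samples per pixel is loaded as RGB
    (``T×H×W×3``); otherwise as grayscale (``T×H×W``).  A single-page
    file becomes a movie with ``T == 1``.

    Raises
    ------
    OSError
        If the file cannot be read as TIFF.
    ValueError
        If pages disagree in shape, the dtype is not 8/16-bit unsigned,
        or the calibration is non-positive.
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"no such file: {path}")
    with tifffile.TiffFile(path) as tif:
        shapes = {page.shape for page in tif.pages}
        if len(shapes) > 1:
            raise ValueError(f"mixed page shapes in {path}: {sorted(shapes)}")
        n_pages = len(tif.pages)
        arr = tif.asarray()
    page_ndim = len(next(iter(shapes)))
    if arr.ndim == page_ndim:  # single page (gray or RGB) → 1-frame stack
        arr = arr[None]
    if n_pages != arr.shape[0]:
        raise ValueError(f"page count {n_pages} does not match stack axis {arr.shape[0]}")
    return Movie(
        frames=arr,
        pixel_size_um=float(pixel_size_um),
        frame_interval_min=float(frame_interval_min),
        bit_depth=_bit_depth_of(arr),
    )


def save_stack(movie: Movie, path: str | Path) -> None:
    """Write a movie back to a multi-page TIFF, pixel-exact."""
    tifffile.imwrite(
        Path(path),
        movie.frames,
        photometric="rgb" if movie.is_rgb else "minisblack",
    )


def read_track_table(path: str | Path) -> dict[str, np.ndarray]:
    """Read a per-cell coordinate table.

    The table (CSV or XLSX) holds one block per cell with columns
    ``Cell_ID, Frame, X_px, Y_px``; frame numbers are 1-based and must be
    strictly increasing and contiguous within each cell.

    Returns
    -------
    dict
        Maps cell id to an ``(n, 3)`` float array of ``(frame, x, y)``
        rows, frames converted to 0-based indices.

    Raises
    ------
    ValueError
        If any cell's frame sequence has a gap or is not increasing; the
        message names the offending cell.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    missing = [c for c in TRACK_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"track table {path} missing columns {missing}")
    out: dict[str, np.ndarray] = {}
    for cell_id, block in df.groupby("Cell_ID", sort=False):
        frames = block["Frame"].to_numpy(dtype=np.int64)
        diffs = np.diff(frames)
        if np.any(diffs != 1):
            raise ValueError(
                f"cell {cell_id!r}: frame sequence has gaps or is not strictly "
                f"increasing (frames {frames.tolist()})"
            )
        out[str(cell_id)] = np.column_stack(
            [frames - 1, block["X_px"].to_numpy(float), block["Y_px"].to_numpy(float)]
        )
    return out


def tracks_to_table(tracks) -> pd.DataFrame:
    """Coordinate table (1-based frames) for a collection of tracks."""
    rows = []
    for t in tracks:
        for i, (x, y) in enumerate(t.positions):
            rows.append((t.id, t.birth_frame + i + 1, x, y))
    return pd.DataFrame(rows, columns=TRACK_TABLE_COLUMNS)


def write_track_table(tracks, path: str | Path) -> None:
    """Write tracks as a coordinate table (CSV or XLSX by extension)."""
    df = tracks_to_table(tracks)
    path = Path(path)
    if path.suffix.lower() == ".xlsx":
        df.to_excel(path, index=False)
    else:
        df.to_csv(path, index=False)
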