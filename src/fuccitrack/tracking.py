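"""Frame-to-frame tracking, scripted curation and lineage reconstruction.

Each selected cell is followed from the first frame by minimum-distance
linking: a square search window (a fraction of the image side) is cropped
around the cell's last position, nuclei are segmented inside it, and the
detection closest to the last position becomes the new position — provided
it lies within a distance gate.  An exceeded gate marks the track *lost*
rather than force-linking, the headless analogue of pausing a supervised
tracker for inspection.

Curation is scripted rather than interactive: correction events override a
frame's position (optionally snapped to the nearest detected centroid) and
division events close the parent track and seed its daughters.  Lineage
labels follow the convention ``C<k>`` for first-frame ancestors and
``C<k>.1``, ``C<k>.2`` … for daughters, so the label itself encodes the
pedigree and the generation is the number of dots in the label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from fuccitrack.detection import Detection, DetectionParams, segment
from fuccitrack.image_io import Movie

__all__ = [
    "Track",
    "CorrectionEvent",
    "DivisionEvent",
    "TrackerParams",
    "LineageTree",
    "step_track",
    "track_cell",
    "build_lineage",
    "categorize",
    "CATEGORY_NAMES",
]

CATEGORY_NAMES = (
    "AllCells",
    "DividingCells",
    "NonDividingCells",
    "DaughterCells",
    "DividingDaughterCells",
)


@dataclass
class Track:
    """One cell's trajectory from birth to its end.

    ``positions[i]`` is the ``(x, y)`` pixel position at frame
    ``birth_frame + i``; the list covers exactly
    ``[birth_frame, last_frame]``.  If the cell divides,
    ``division_frame == last_frame`` and each daughter's ``birth_frame``
    is ``division_frame + 1``.
    """

    id: str
    birth_frame: int
    positions: list[tuple[float, float]]
    parent_id: str | None = None
    division_frame: int | None = None
    daughter_ids: list[str] = field(default_factory=list)
    corrected_frames: set[int] = field(default_factory=set)
    end_reason: str = "movie_end"  # divided | lost | movie_end | excluded

    @property
    def last_frame(self) -> int:
        return self.birth_frame + len(self.positions) - 1

    @property
    def n_frames(self) -> int:
        return len(self.positions)

    def position_at(self, frame: int) -> tuple[float, float]:
        if not self.birth_frame <= frame <= self.last_frame:
            raise ValueError(f"frame {frame} outside track {self.id} [{self.birth_frame}, {self.last_frame}]")
        return self.positions[frame - self.birth_frame]

    def validate(self) -> None:
        if self.division_frame is not None and self.division_frame != self.last_frame:
            raise ValueError(f"track {self.id}: division_frame must equal last_frame")
        if self.parent_id is not None:
            stem, _, leaf = self.id.rpartition(".")
            if stem != self.parent_id or not leaf.isdigit():
                raise ValueError(f"track {self.id}: id does not encode parent {self.parent_id}")


@dataclass(frozen=True)
class CorrectionEvent:
    """Scripted override of one frame's position.

    With ``use_center_of_mass`` the given point is snapped to the nearest
    detected centroid in the local window (for bright nuclei); without it
    the exact point is recorded (for nuclei too dim to segment).
    """

    cell_id: str
    frame: int
    x: float
    y: float
    use_center_of_mass: bool = False


@dataclass(frozen=True)
class DivisionEvent:
    """Scripted division mark: closes ``cell_id`` at ``frame`` and seeds
    one daughter track per given position (two or more)."""

    cell_id: str
    frame: int
    daughter_seed_positions: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.daughter_seed_positions) < 2:
            raise ValueError("a division needs at least 2 daughter seeds")


@dataclass(frozen=True)
class TrackerParams:
    """Detection settings plus the linking distance gate (px).

    ``gate_px=None`` defaults to half the search-window side.
    """

    detection: DetectionParams = field(default_factory=DetectionParams)
    gate_px: float | None = None

    def __post_init__(self) -> None:
        if self.gate_px is not None and self.gate_px <= 0:
            raise ValueError(f"gate_px must be positive, got {self.gate_px}")


def step_track(
    last_position: tuple[float, float],
    detections: list[Detection],
    gate_px: float,
) -> Detection | None:
    """Pick the detection nearest to the last position, within the gate.

    Ties are broken by scan order (smallest y, then smallest x).  Returns
    ``None`` when no detection lies within ``gate_px``.
    """
    lx, ly = last_position
    best: Detection | None = None
    best_key: tuple[float, float, float] | None = None
    for d in detections:
        key = (math.hypot(d.x - lx, d.y - ly), d.y, d.x)
        if best_key is None or key < best_key:
            best, best_key = d, key
    if best is None or best_key[0] > gate_px:
        return None
    return best


def _crop_roi(img, cx: float, cy: float, side: int):
    """Square crop of given side centred on (cx, cy), clipped to bounds.

    Returns the crop and its (x0, y0) offset in full-frame coordinates.
    """
    h, w = img.shape[:2]
    half = side // 2
    x0 = int(max(0, min(round(cx) - half, w - side)))
    y0 = int(max(0, min(round(cy) - half, h - side)))
    x0, y0 = max(0, x0), max(0, y0)
    return img[y0 : y0 + side, x0 : x0 + side], x0, y0


def _detect_in_roi(movie: Movie, frame: int, center: tuple[float, float], params: TrackerParams):
    img = movie.frame(frame)
    if movie.is_rgb:
        img = img.mean(axis=-1)
    side = max(8, int(round(params.detection.roi_fraction * min(movie.shape_hw))))
    roi, x0, y0 = _crop_roi(img, center[0], center[1], side)
    dets = segment(roi, params.detection, frame)
    shifted = [
        Detection(d.frame, d.x + x0, d.y + y0, d.area_px, d.mean_intensity) for d in dets
    ]
    gate = params.gate_px if params.gate_px is not None else side / 2
    return shifted, gate


def track_cell(
    movie: Movie,
    seed_xy: tuple[float, float],
    params: TrackerParams | None = None,
    corrections: list[CorrectionEvent] | None = None,
    divisions: list[DivisionEvent] | None = None,
    root_id: str = "C1",
) -> list[Track]:
    """Track one first-frame cell and all of its descendants.

    The seed must lie inside frame 0 — cells are selected only from the
    first frame.  Returns the root track followed by daughter tracks in
    breadth-first order.

    Raises
    ------
    ValueError
        If the seed is outside the image, or a division event refers to a
        frame outside its cell's lifetime.
    """
    params = params or TrackerParams()
    h, w = movie.shape_hw
    if not (0 <= seed_xy[0] < w and 0 <= seed_xy[1] < h):
        raise ValueError(f"seed {seed_xy} outside image {w}×{h}")

    corr_by: dict[tuple[str, int], CorrectionEvent] = {
        (c.cell_id, c.frame): c for c in (corrections or [])
    }
    div_by: dict[str, DivisionEvent] = {d.cell_id: d for d in (divisions or [])}

    done: list[Track] = []
    queue: list[Track] = [Track(id=root_id, birth_frame=0, positions=[tuple(map(float, seed_xy))])]
    while queue:
        tr = queue.pop(0)
        division = div_by.get(tr.id)
        if division is not None and division.frame < tr.birth_frame:
            raise ValueError(f"division for {tr.id} at frame {division.frame} precedes its birth")
        f = tr.birth_frame
        while True:
            if division is not None and f == division.frame:
                tr.division_frame = f
                tr.end_reason = "divided"
                for k, seed in enumerate(division.daughter_seed_positions, start=1):
                    did = f"{tr.id}.{k}"
                    tr.daughter_ids.append(did)
                    if f + 1 < movie.n_frames:
                        queue.append(
                            Track(
                                id=did,
                                parent_id=tr.id,
                                birth_frame=f + 1,
                                positions=[tuple(map(float, seed))],
                            )
                        )
                break
            f += 1
            if f >= movie.n_frames:
                tr.end_reason = "movie_end"
                break
            corr = corr_by.get((tr.id, f))
            if corr is not None:
                if corr.use_center_of_mass:
                    dets, gate = _detect_in_roi(movie, f, (corr.x, corr.y), params)
                    hit = step_track((corr.x, corr.y), dets, gate)
                    pos = (hit.x, hit.y) if hit is not None else (corr.x, corr.y)
                else:
                    pos = (corr.x, corr.y)
                tr.positions.append((float(pos[0]), float(pos[1])))
                tr.corrected_frames.add(f)
                continue
            dets, gate = _detect_in_roi(movie, f, tr.positions[-1], params)
            hit = step_track(tr.positions[-1], dets, gate)
            if hit is None:
                tr.end_reason = "lost"
                break
            tr.positions.append((hit.x, hit.y))
        if division is not None and division.frame > tr.last_frame:
            raise ValueError(
                f"division for {tr.id} at frame {division.frame} beyond track end {tr.last_frame}"
            )
        done.append(tr)
    return done


def tracks_from_positions(per_cell: dict[str, "object"]) -> list[Track]:
    """Rebuild tracks (with lineage links) from coordinate-table data.

    ``per_cell`` maps lineage labels to ``(n, 3)`` arrays of
    ``(frame, x, y)`` as returned by
    :func:`fuccitrack.image_io.read_track_table`.  Parent/daughter links
    and division frames are reconstructed from the label convention: the
    parent of ``C3.2`` is ``C3``, which must end on the frame before
    ``C3.2`` begins.
    """
    tracks: dict[str, Track] = {}
    for cid, arr in per_cell.items():
        stem, _, leaf = cid.rpartition(".")
        parent = stem if stem and leaf.isdigit() and stem in per_cell else None
        tracks[cid] = Track(
            id=cid,
            parent_id=parent,
            birth_frame=int(arr[0, 0]),
            positions=[(float(x), float(y)) for _, x, y in arr],
        )
    for t in tracks.values():
        if t.parent_id is not None:
            p = tracks[t.parent_id]
            p.division_frame = p.last_frame
            p.end_reason = "divided"
            p.daughter_ids.append(t.id)
    for t in tracks.values():
        t.daughter_ids.sort()
    return list(tracks.values())


class LineageTree:
    """Rooted forest of tracks keyed by lineage label.

    The generation of a track is the number of dots in its label: roots
    (first-frame ancestors) are generation 0, their daughters 1, and so
    on.
    """

    def __init__(self, tracks: dict[str, Track], roots: list[str]):
        self.tracks = tracks
        self.roots = roots

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks.values())

    def __getitem__(self, track_id: str) -> Track:
        return self.tracks[track_id]

    @staticmethod
    def generation(track_id: str) -> int:
        return track_id.count(".")

    def generation_counts(self) -> dict[int, int]:
        """Number of tracks per generation, e.g. ``{0: 1, 1: 2}``."""
        counts: dict[int, int] = {}
        for tid in self.tracks:
            g = self.generation(tid)
            counts[g] = counts.get(g, 0) + 1
        return counts

    def daughters_of(self, track_id: str) -> list[Track]:
        return [self.tracks[d] for d in self.tracks[track_id].daughter_ids if d in self.tracks]


def build_lineage(tracks: list[Track]) -> LineageTree:
    """Assemble tracks into a lineage forest, validating links.

    Raises
    ------
    ValueError
        On a daughter whose parent is missing, on a label that does not
        encode its declared parent, or on duplicate labels.
    """
    by_id: dict[str, Track] = {}
    for t in tracks:
        if t.id in by_id:
            raise ValueError(f"duplicate track id {t.id}")
        t.validate()
        by_id[t.id] = t
    roots = []
    for t in tracks:
        if t.parent_id is None:
            roots.append(t.id)
        elif t.parent_id not in by_id:
            raise ValueError(f"orphan track {t.id}: parent {t.parent_id} absent")
        else:
            parent = by_id[t.parent_id]
            if parent.division_frame is None or parent.division_frame + 1 != t.birth_frame:
                raise ValueError(
                    f"track {t.id}: birth frame {t.birth_frame} does not follow "
                    f"parent division at {parent.division_frame}"
                )
    return LineageTree(by_id, roots)


def categorize(lineage: LineageTree) -> dict[str, list[Track]]:
    """Partition tracks into the five trajectory categories.

    ``AllCells`` is every track; ``DividingCells`` those with a recorded
    division and ``NonDividingCells`` the complement (a disjoint cover of
    ``AllCells``); ``DaughterCells`` those with a parent; and
    ``DividingDaughterCells`` — daughters that divide — are the cells
    observed over a complete cycle, whose trajectory time is a direct
    doubling-time measurement.
    """
    all_cells = list(lineage)
    dividing = [t for t in all_cells if t.division_frame is not None]
    non_dividing = [t for t in all_cells if t.division_frame is None]
    daughters = [t for t in all_cells if t.parent_id is not None]
    dividing_daughters = [t for t in daughters if t.division_frame is not None]
    return {
        "AllCells": all_cells,
        "DividingCells": dividing,
        "NonDividingCells": non_dividing,
        "DaughterCells": daughters,
        "DividingDaughterCells": dividing_daughters,
    }
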