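"""Synthetic time-lapse movies of moving, dividing, FUCCI-oscillating
nuclei with complete ground truth.

The generator emulates the study conditions of a live-imaging migration
assay: nuclei are isotropic Gaussian blobs performing a persistent random
walk at a fixed mean speed, dividing when their age reaches a per-cell
cycle length drawn from a truncated normal distribution, with the cycle
partitioned into G1/S/G2M by fixed fractions.  Defaults follow an
epithelial (RPE-like) PIP-FUCCI imaging setup: 0.65 µm/px, 10 min frame
interval, mean speed 9.3 µm/h, cycle length 21.5 ± 4.8 h and phase
fractions 0.22/0.59/0.19.

FUCCI reporter dynamics are rendered as piecewise-linear channel
programs over the cycle: in two-channel mode red (Cdt1) is high through
G1 and declines through S while green (Geminin) rises early in S and
stays high through G2/M; in three-channel mode blue (PIP) is high in G1,
destroyed at S entry and re-accumulating in G2, green marks S and G2/M,
and red (PCNA) is a constant bystander.  Optional jump injection makes
the last two hours before a division constant-speed and scales one step
in the final hour, producing terminal speed jumps that satisfy the
detection criterion by construction.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from fuccitrack.fucci import SignalTrace
from fuccitrack.image_io import Movie
from fuccitrack.tracking import Track

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "simulate_lineage",
    "simulate_movie",
    "simulate_fucci_traces",
    "fucci_program_2ch",
    "fucci_program_3ch",
]


@dataclass(frozen=True)
class SimulationParams:
    """Generator settings; defaults emulate an RPE-like FUCCI assay."""

    n_cells: int = 10
    height: int = 256
    width: int = 256
    sigma_px: float = 3.0
    peak_intensity: float = 200.0
    noise_sd: float = 5.0
    mean_speed_um_h: float = 9.3
    persistence: float = 0.6
    pixel_size_um: float = 0.65
    frame_interval_min: float = 10.0
    n_frames: int = 100
    cycle_mean_h: float | None = 21.5  # None disables division entirely
    cycle_sd_h: float = 4.8
    phase_fractions: tuple[float, float, float] = (0.22, 0.59, 0.19)
    fucci_mode: str = "none"  # none | two_channel | three_channel
    jump_probability: float = 0.0
    jump_fold: float = 4.0
    bit_depth: int = 8

    def __post_init__(self) -> None:
        if abs(sum(self.phase_fractions) - 1.0) > 1e-9:
            raise ValueError(f"phase fractions must sum to 1, got {self.phase_fractions}")
        if self.sigma_px <= 0:
            raise ValueError("sigma_px must be positive")
        if not 0 <= self.persistence < 1:
            raise ValueError("persistence must be in [0, 1)")
        if self.fucci_mode not in ("none", "two_channel", "three_channel"):
            raise ValueError(f"unknown fucci_mode {self.fucci_mode!r}")
        if self.jump_probability > 0 and self.jump_fold <= 3.0:
            # the detection criterion needs >= max(3, 2.5·(11+f)/12)-fold spikes
            raise ValueError("jump_fold must exceed 3 for injected jumps to qualify")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")

    @property
    def step_h(self) -> float:
        return self.frame_interval_min / 60.0

    @property
    def step_px(self) -> float:
        return self.mean_speed_um_h * self.step_h / self.pixel_size_um


@dataclass
class GroundTruth:
    """Everything the generator knows: true tracks (with division links),
    per-cell phase labels, injected jump step indices and a crowding
    warning raised when the requested density cannot guarantee the
    minimum nucleus separation."""

    tracks: list[Track]
    phases: dict[str, list[str]]
    jump_steps: dict[str, list[int]]
    cycle_h: dict[str, float]
    crowding_warning: bool
    seed: int

    @property
    def tracks_by_id(self) -> dict[str, Track]:
        return {t.id: t for t in self.tracks}


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v > 0:
            return v
    raise RuntimeError("cycle-length distribution is almost entirely non-positive")


def _phase_of(age_h: float, cycle_h: float, fractions: tuple[float, float, float]) -> str:
    u = min(age_h / cycle_h, 1.0)
    if u < fractions[0]:
        return "G1"
    if u < fractions[0] + fractions[1]:
        return "S"
    return "G2M"


def _place_initial(rng, params: SimulationParams):
    """Random seeding with minimum separation 4σ; flags a warning when
    the density defeats rejection sampling."""
    margin = 6 * params.sigma_px
    min_sep = 4 * params.sigma_px
    placed: list[tuple[float, float]] = []
    warning = False
    for _ in range(params.n_cells):
        ok = False
        for _ in range(2000):
            x = rng.uniform(margin, params.width - margin)
            y = rng.uniform(margin, params.height - margin)
            if all((x - px) ** 2 + (y - py) ** 2 >= min_sep**2 for px, py in placed):
                placed.append((x, y))
                ok = True
                break
        if not ok:
            warning = True
            placed.append(
                (rng.uniform(margin, params.width - margin), rng.uniform(margin, params.height - margin))
            )
    return placed, warning


class _Cell:
    __slots__ = (
        "id", "parent_id", "birth_frame", "positions", "direction",
        "cycle_h", "division_frame", "jump_step",
    )

    def __init__(self, cid, parent_id, birth_frame, pos, direction, cycle_h, division_frame, jump_step):
        self.id = cid
        self.parent_id = parent_id
        self.birth_frame = birth_frame
        self.positions = [pos]
        self.direction = direction
        self.cycle_h = cycle_h
        self.division_frame = division_frame
        self.jump_step = jump_step


def _make_cell(rng, params: SimulationParams, cid, parent_id, birth_frame, pos, want_jumps):
    direction = rng.normal(size=2)
    direction /= np.linalg.norm(direction)
    if params.cycle_mean_h is None:
        cycle_h = math.inf
        division_frame = None
    else:
        cycle_h = _truncated_normal(rng, params.cycle_mean_h, params.cycle_sd_h)
        division_frame = birth_frame + int(math.ceil(cycle_h / params.step_h))
        if division_frame >= params.n_frames:
            division_frame = None
    jump_step = None
    if want_jumps and division_frame is not None and rng.random() < params.jump_probability:
        n_jump = int(round(1.0 / params.step_h))
        n_base = int(round(2.0 / params.step_h))
        n_steps = division_frame - birth_frame
        if n_steps >= n_base:
            candidates = [
                t for t in range(n_steps - n_jump, n_steps)
                if _phase_of(t * params.step_h, cycle_h, params.phase_fractions) == "G2M"
            ]
            if candidates:
                jump_step = int(rng.choice(candidates))
    return _Cell(cid, parent_id, birth_frame, pos, direction, cycle_h, division_frame, jump_step)


def simulate_lineage(params: SimulationParams, seed: int) -> GroundTruth:
    """Simulate motion, division and phases without rendering images.

    Returns ground-truth tracks whose division links, ids and categories
    behave exactly like tracker output, plus per-cell phase labels and
    injected jump indices.
    """
    rng = np.random.default_rng(seed)
    margin = 4 * params.sigma_px
    starts, warning = _place_initial(rng, params)
    want_jumps = params.jump_probability > 0
    n_base = int(round(2.0 / params.step_h))

    active: list[_Cell] = [
        _make_cell(rng, params, f"C{k + 1}", None, 0, np.array(p), want_jumps)
        for k, p in enumerate(starts)
    ]
    finished: list[_Cell] = []

    for f in range(1, params.n_frames):
        spawned: list[_Cell] = []
        still: list[_Cell] = []
        for cell in active:
            if cell.division_frame is not None and cell.division_frame == f - 1:
                # divided on the previous frame: spawn daughters
                perp = np.array([-cell.direction[1], cell.direction[0]])
                offset = 1.5 * params.sigma_px
                base = np.array(cell.positions[-1])
                for k, sgn in ((1, 1.0), (2, -1.0)):
                    pos = base + sgn * offset * perp
                    pos[0] = np.clip(pos[0], margin, params.width - margin)
                    pos[1] = np.clip(pos[1], margin, params.height - margin)
                    spawned.append(
                        _make_cell(rng, params, f"{cell.id}.{k}", cell.id, f, pos, want_jumps)
                    )
                finished.append(cell)
                continue
            step_idx = f - 1 - cell.birth_frame  # step taken into frame f
            in_calm_window = (
                cell.jump_step is not None
                and step_idx >= (cell.division_frame - cell.birth_frame) - n_base
            )
            if not in_calm_window:
                fresh = rng.normal(size=2)
                fresh /= np.linalg.norm(fresh)
                d = params.persistence * cell.direction + (1 - params.persistence) * fresh
                cell.direction = d / np.linalg.norm(d)
            length = params.step_px
            if cell.jump_step is not None and step_idx == cell.jump_step:
                length *= params.jump_fold
            # steer away from crowding neighbours: nuclei keep a minimum
            # separation of 4σ so segmented regions never merge
            pos = np.array(cell.positions[-1])
            others = [
                np.array(o.positions[-1]) for o in active if o is not cell
            ] + [np.array(o.positions[-1]) for o in spawned]
            if others:
                dists = [np.linalg.norm(pos - q) for q in others]
                nearest = others[int(np.argmin(dists))]
                if min(dists) < 6 * params.sigma_px:
                    away = pos - nearest
                    norm = np.linalg.norm(away)
                    if norm > 0:
                        cell.direction = away / norm
            x, y = pos
            dx, dy = cell.direction * length
            if not margin <= x + dx <= params.width - margin:
                cell.direction[0] *= -1
                dx = -dx
            if not margin <= y + dy <= params.height - margin:
                cell.direction[1] *= -1
                dy = -dy
            cell.positions.append((x + dx, y + dy))
            still.append(cell)
        active = still + spawned
    finished.extend(active)

    tracks: list[Track] = []
    phases: dict[str, list[str]] = {}
    jump_steps: dict[str, list[int]] = {}
    cycle_hours: dict[str, float] = {}
    for cell in finished:
        divided = cell.division_frame is not None and cell.division_frame <= params.n_frames - 1
        tr = Track(
            id=cell.id,
            parent_id=cell.parent_id,
            birth_frame=cell.birth_frame,
            positions=[(float(x), float(y)) for x, y in cell.positions],
            division_frame=cell.division_frame if divided else None,
            end_reason="divided" if divided else "movie_end",
        )
        if divided and cell.division_frame < params.n_frames - 1:
            tr.daughter_ids = [f"{cell.id}.1", f"{cell.id}.2"]
        tracks.append(tr)
        phases[cell.id] = [
            _phase_of(i * params.step_h, cell.cycle_h, params.phase_fractions)
            for i in range(len(cell.positions))
        ]
        cycle_hours[cell.id] = cell.cycle_h
        if cell.jump_step is not None and divided:
            jump_steps[cell.id] = [cell.jump_step]
    tracks.sort(key=lambda t: (t.birth_frame, t.id))
    return GroundTruth(tracks=tracks, phases=phases, jump_steps=jump_steps,
                       cycle_h=cycle_hours, crowding_warning=warning, seed=seed)


# ---------------------------------------------------------------------------
# FUCCI channel programs (piecewise linear over cycle progress u ∈ [0, 1])

def _ramp(u: float, u0: float, u1: float, v0: float, v1: float) -> float:
    if u <= u0:
        return v0
    if u >= u1:
        return v1
    return v0 + (v1 - v0) * (u - u0) / (u1 - u0)


def fucci_program_2ch(u: float, fractions=(0.22, 0.59, 0.19)) -> tuple[float, float, float]:
    """Noise-free (red, green, blue) multipliers at cycle progress ``u``.

    Red (Cdt1): 1 through G1, declining to 0.15 across S, gone shortly
    after G2 entry.  Green (Geminin): absent in G1, rising over the first
    5% of S, high through S and G2/M.
    """
    a1 = fractions[0]
    a2 = fractions[0] + fractions[1]
    if u < a1:
        r, g = 1.0, 0.0
    elif u < a2:
        s = (u - a1) / (a2 - a1)
        r = _ramp(s, 0.0, 1.0, 1.0, 0.15)
        g = _ramp(s, 0.0, 0.05, 0.0, 1.0)
    else:
        m = (u - a2) / (1 - a2)
        r = _ramp(m, 0.0, 0.05, 0.15, 0.0)
        g = 1.0
    return r, g, 0.0


def fucci_program_3ch(u: float, fractions=(0.22, 0.59, 0.19)) -> tuple[float, float, float]:
    """Noise-free (red, green, blue) multipliers at cycle progress ``u``.

    Blue (PIP degron): high in G1, destroyed over the first 3% of S,
    re-accumulating over the first 20% of G2/M.  Green (Geminin): rises
    over the first 8% of S, high through G2/M.  Red (PCNA): constant
    bystander.
    """
    a1 = fractions[0]
    a2 = fractions[0] + fractions[1]
    r = 0.5
    if u < a1:
        g, b = 0.0, 1.0
    elif u < a2:
        s = (u - a1) / (a2 - a1)
        g = _ramp(s, 0.0, 0.08, 0.0, 1.0)
        b = _ramp(s, 0.0, 0.03, 1.0, 0.0)
    else:
        m = (u - a2) / (1 - a2)
        g = 1.0
        b = _ramp(m, 0.0, 0.20, 0.0, 1.0)
    return r, g, b


def _program(mode: str):
    if mode == "two_channel":
        return fucci_program_2ch
    if mode == "three_channel":
        return fucci_program_3ch
    raise ValueError(f"fucci_mode {mode!r} has no channel program")


def simulate_fucci_traces(
    n_cells: int,
    mode: str,
    params: SimulationParams | None = None,
    seed: int = 0,
    noise_sd: float = 0.02,
) -> list[tuple[SignalTrace, list[str]]]:
    """Raw signal traces over one full cycle per cell, with true labels.

    Each cell draws its own cycle length; raw intensities are the channel
    program scaled to an arbitrary per-cell brightness with additive
    Gaussian noise (``noise_sd`` is on the unit program scale), so the
    internal normalization step has real work to do.
    """
    params = params or SimulationParams()
    rng = np.random.default_rng(seed)
    out = []
    program = _program(mode)
    for k in range(n_cells):
        cycle_h = _truncated_normal(rng, params.cycle_mean_h or 21.5, params.cycle_sd_h)
        n = int(math.ceil(cycle_h / params.step_h)) + 1
        scale = rng.uniform(80.0, 200.0)
        offset = rng.uniform(2.0, 10.0)
        rgb = np.empty((n, 3))
        labels = []
        for i in range(n):
            age = i * params.step_h
            u = min(age / cycle_h, 1.0)
            rgb[i] = program(u, params.phase_fractions)
            labels.append(_phase_of(age, cycle_h, params.phase_fractions))
        rgb = rgb * scale + offset + rng.normal(0.0, noise_sd * scale, size=rgb.shape)
        rgb = np.clip(rgb, 0.0, None)
        trace = SignalTrace(
            cell_id=f"C{k + 1}",
            frames=np.arange(n),
            r=rgb[:, 0],
            g=rgb[:, 1],
            b=rgb[:, 2] if mode == "three_channel" else None,
            diameter_px=10.0,
        )
        out.append((trace, labels))
    return out


def _render_frames(params: SimulationParams, truth: GroundTruth, rng) -> np.ndarray:
    rgb = params.fucci_mode != "none"
    shape = (params.n_frames, params.height, params.width, 3) if rgb else (
        params.n_frames, params.height, params.width)
    frames = np.zeros(shape, dtype=float)
    reach = int(math.ceil(4 * params.sigma_px))
    program = _program(params.fucci_mode) if rgb else None
    step_h = params.step_h
    for t in truth.tracks:
        cyc = truth.cycle_h.get(t.id, math.inf)
        for i, (x, y) in enumerate(t.positions):
            f = t.birth_frame + i
            xi, yi = int(round(x)), int(round(y))
            x0, x1 = max(0, xi - reach), min(params.width, xi + reach + 1)
            y0, y1 = max(0, yi - reach), min(params.height, yi + reach + 1)
            yy, xx = np.mgrid[y0:y1, x0:x1]
            blob = params.peak_intensity * np.exp(
                -((xx - x) ** 2 + (yy - y) ** 2) / (2 * params.sigma_px**2)
            )
            if rgb:
                u = min(i * step_h / cyc, 1.0) if math.isfinite(cyc) else 0.0
                mult = program(u, params.phase_fractions)
                for c in range(3):
                    frames[f, y0:y1, x0:x1, c] += blob * mult[c]
            else:
                frames[f, y0:y1, x0:x1] += blob
    if params.noise_sd > 0:
        frames += rng.normal(0.0, params.noise_sd, size=frames.shape)
    top = 255 if params.bit_depth == 8 else 65535
    dtype = np.uint8 if params.bit_depth == 8 else np.uint16
    return np.clip(frames, 0, top).astype(dtype)


def simulate_movie(params: SimulationParams | None = None, seed: int = 0) -> tuple[Movie, GroundTruth]:
    """Render a calibrated movie of the simulated lineage.

    Grayscale for ``fucci_mode="none"``, RGB otherwise.  Deterministic:
    identical params and seed give bit-identical output.
    """
    params = params or SimulationParams()
    truth = simulate_lineage(params, seed)
    rng = np.random.default_rng(seed + 1_000_003)
    frames = _render_frames(params, truth, rng)
    movie = Movie(
        frames=frames,
        pixel_size_um=params.pixel_size_um,
        frame_interval_min=params.frame_interval_min,
        bit_depth=params.bit_depth,
    )
    return movie, truth
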