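"""FUCCI signal extraction, normalization and cell-cycle phase calling.

FUCCI reporters tag cell-cycle-regulated proteins so that the colour of a
nucleus encodes its phase.  Two reporter systems are supported:

* **Two-channel** (Cdt1-red / Geminin-green): Cdt1 is high in G1 and
  declines through S; Geminin accumulates through S and G2.  Phases are
  called from three thresholds on the normalized signals — the minimum
  signal MS, the minimum green signal in S (MGSS) and the minimum red
  signal in S (MRSS), all defaulting to 0.1.  A frame is Unknown when
  both channels sit below MS, S when both green ≥ MGSS and red ≥ MRSS,
  G1 when red is present but green < MGSS, and G2/M when green is present
  but red < MRSS (precedence in that order).

* **Three-channel** (PCNA-red / Geminin-green / PIP-blue): the PIP degron
  is destroyed during replication, so blue is high in G1 and G2 but low
  in S, while Geminin marks S and G2.  The green/blue ratio ρ drives the
  call: G1 when ρ ≤ MGBr-G1 (default 0.5), G2/M when ρ ≥ MGBr-G2
  (default 0.7) with blue at least MBS-G2 (default 0.1), otherwise S.
  The red PCNA channel is carried along but unused by the rule.

Mitosis is not separated from G2; the joint class is labelled ``G2M``.
Signals are means over a disk whose diameter should not exceed the cell
diameter, and each channel is min–max normalized over the cell's own
time series ("internal RGB normalization"), so calls are robust to
absolute brightness differences between cells.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import median_filter
from skimage.draw import disk

from fuccitrack.image_io import Movie
from fuccitrack.tracking import Track

__all__ = [
    "SignalTrace",
    "FucciParams2",
    "FucciParams3",
    "PHASES",
    "extract_signal",
    "normalize_signals",
    "call_phases_2ch",
    "call_phases_3ch",
    "correct_phase",
]

PHASES = ("G1", "S", "G2M", "Unknown")

_EPS = 1e-6  # guards the green/blue ratio against division by zero


@dataclass
class SignalTrace:
    """Per-frame channel intensities along one track.

    Raw traces hold channel means over the signal disk; normalized traces
    (``normalized=True``) hold per-channel min–max rescaled values in
    [0, 1].  ``b`` is ``None`` for two-channel data.
    """

    cell_id: str
    frames: np.ndarray  # frame indices, 0-based, contiguous
    r: np.ndarray
    g: np.ndarray
    b: np.ndarray | None
    diameter_px: float
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.diameter_px <= 0:
            raise ValueError(f"diameter_px must be positive, got {self.diameter_px}")
        n = len(self.frames)
        for name in ("r", "g", "b"):
            ch = getattr(self, name)
            if ch is not None and len(ch) != n:
                raise ValueError(f"channel {name} length {len(ch)} != {n} frames")

    def __len__(self) -> int:
        return len(self.frames)


def _disk_mean(img: np.ndarray, cx: float, cy: float, diameter_px: float) -> np.ndarray:
    """Mean over the disk centred at (cx, cy), clipped to image bounds.

    Returns one value per channel (length-1 for grayscale).
    """
    h, w = img.shape[:2]
    radius = max(diameter_px / 2.0, 0.5)
    rr, cc = disk((cy, cx), radius, shape=(h, w))
    if rr.size == 0:  # centre off-image after clipping: nearest pixel
        rr = np.array([int(np.clip(round(cy), 0, h - 1))])
        cc = np.array([int(np.clip(round(cx), 0, w - 1))])
    vals = img[rr, cc].astype(float)
    if vals.ndim == 1:
        return np.array([vals.mean()])
    return vals.mean(axis=0)


def extract_signal(rgb_movie: Movie, track: Track, diameter_px: float) -> SignalTrace:
    """Raw per-frame channel means over the signal disk along a track.

    The disk diameter should not exceed the cell diameter; it may be set
    globally and overridden per cell.

    Raises
    ------
    ValueError
        If the track extends beyond the movie, or the movie is not RGB.
    """
    if not rgb_movie.is_rgb:
        raise ValueError("FUCCI extraction needs an RGB movie")
    if track.last_frame >= rgb_movie.n_frames:
        raise ValueError(
            f"track {track.id} runs to frame {track.last_frame} but movie has "
            f"{rgb_movie.n_frames} frames"
        )
    n = track.n_frames
    r = np.empty(n)
    g = np.empty(n)
    b = np.empty(n)
    for i, (x, y) in enumerate(track.positions):
        means = _disk_mean(rgb_movie.frame(track.birth_frame + i), x, y, diameter_px)
        r[i], g[i], b[i] = means
    frames = np.arange(track.birth_frame, track.last_frame + 1)
    return SignalTrace(track.id, frames, r, g, b, diameter_px)


def _minmax(ch: np.ndarray) -> np.ndarray:
    lo, hi = float(ch.min()), float(ch.max())
    if hi == lo:
        return np.zeros_like(ch, dtype=float)
    return (ch - lo) / (hi - lo)


def normalize_signals(trace: SignalTrace, median_window: int = 0) -> SignalTrace:
    """Min–max rescale each channel over the cell's own time series.

    A constant channel maps to all zeros.  ``median_window`` (odd, e.g. 3)
    applies a pre-smoothing median filter; it is off by default.

    Raises
    ------
    ValueError
        If the trace has fewer than 2 frames.
    """
    if len(trace) < 2:
        raise ValueError("normalization needs a trace of length >= 2")

    def prep(ch):
        if ch is None:
            return None
        ch = np.asarray(ch, dtype=float)
        if median_window and median_window > 1:
            ch = median_filter(ch, size=median_window, mode="nearest")
        return _minmax(ch)

    return replace(trace, r=prep(trace.r), g=prep(trace.g), b=prep(trace.b), normalized=True)


@dataclass(frozen=True)
class FucciParams2:
    """Two-channel thresholds: minimum signal (MS), minimum green in S
    (MGSS), minimum red in S (MRSS); defaults all 0.1."""

    ms: float = 0.1
    mgss: float = 0.1
    mrss: float = 0.1

    def __post_init__(self) -> None:
        for name in ("ms", "mgss", "mrss"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class FucciParams3:
    """Three-channel thresholds: maximum green/blue ratio in G1
    (MGBr-G1, 0.5), minimum green/blue ratio in G2 (MGBr-G2, 0.7) and
    minimum blue signal in G2 (MBS-G2, 0.1)."""

    mgbr_g1: float = 0.5
    mgbr_g2: float = 0.7
    mbs_g2: float = 0.1

    def __post_init__(self) -> None:
        if self.mgbr_g1 > self.mgbr_g2:
            raise ValueError("mgbr_g1 must not exceed mgbr_g2")


def _require_normalized(trace: SignalTrace) -> None:
    if not trace.normalized:
        raise ValueError("phase calling needs a normalized trace; run normalize_signals first")


def call_phases_2ch(trace: SignalTrace, params: FucciParams2 | None = None) -> list[str]:
    """Call phases from a normalized Cdt1-red / Geminin-green trace.

    Per frame, in order of precedence: Unknown when both channels are
    below MS; S when green ≥ MGSS and red ≥ MRSS; G1 when red ≥ MS with
    green < MGSS; G2/M when green ≥ MS with red < MRSS.
    """
    _require_normalized(trace)
    params = params or FucciParams2()
    labels = []
    for r, g in zip(trace.r, trace.g):
        if r < params.ms and g < params.ms:
            labels.append("Unknown")
        elif g >= params.mgss and r >= params.mrss:
            labels.append("S")
        elif r >= params.ms and g < params.mgss:
            labels.append("G1")
        elif g >= params.ms and r < params.mrss:
            labels.append("G2M")
        else:
            labels.append("Unknown")
    return labels


def call_phases_3ch(trace: SignalTrace, params: FucciParams3 | None = None) -> list[str]:
    """Call phases from a normalized PCNA/Geminin/PIP trace.

    With ρ = green / (blue + ε): G1 when ρ ≤ MGBr-G1; G2/M when
    ρ ≥ MGBr-G2 and blue ≥ MBS-G2; otherwise S.

    Raises
    ------
    ValueError
        If the blue channel is missing.
    """
    _require_normalized(trace)
    if trace.b is None:
        raise ValueError("three-channel calling needs a blue (PIP) channel")
    params = params or FucciParams3()
    labels = []
    for g, b in zip(trace.g, trace.b):
        rho = g / (b + _EPS)
        if rho <= params.mgbr_g1:
            labels.append("G1")
        elif rho >= params.mgbr_g2 and b >= params.mbs_g2:
            labels.append("G2M")
        else:
            labels.append("S")
    return labels


def correct_phase(labels: list[str], phase: str, from_frame: int, till_frame: int) -> list[str]:
    """Overwrite a 1-based inclusive frame range with the given phase.

    Mirrors scripted curation of miscalled stretches; frames outside the
    range are untouched.
    """
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}; expected one of {PHASES}")
    if not 1 <= from_frame <= till_frame <= len(labels):
        raise ValueError(
            f"invalid range [{from_frame}, {till_frame}] for {len(labels)} frames"
        )
    out = list(labels)
    out[from_frame - 1 : till_frame] = [phase] * (till_frame - from_frame + 1)
    return out
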