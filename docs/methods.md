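# Methods

This note records the models, decision rules, parameter choices and known
limitations behind `fuccitrack`, at the level of detail a user needs to
judge what the package's results do and do not mean.

## Segmentation

Both detectors start from an intensity frame rescaled to [0, 1].

**Equalization + threshold.** Contrast-limited histogram equalization
(`clahe_clip`, default 0.01) is applied over a single window spanning the
input. During tracking the input is already a small region of interest
around the cell, so the equalization is effectively local; using one
window rather than a tile grid keeps segmentation exactly
translation-equivariant, which a tiled kernel is not. The equalized image
is binarized with a global Otsu threshold and every 8-connected
above-threshold region with at least `min_area_px` pixels (default 9)
becomes a candidate nucleus.

Two guards handle noise-dominated inputs. First, if the binary mask
covers more than 10% of the pixels the threshold has almost certainly
split the background noise mode (nuclei are sparse in these assays), and
the image is rethresholded with Otsu in the raw intensity domain.
Second, a prominence filter drops regions whose mean raw intensity is
below mean + 3·sd of the background, the background being estimated from
the lower 75% of the frame's intensities. Both guards are no-ops on
clean images.

**Watershed.** The same foreground mask is flooded from h-maxima markers
of the lightly smoothed (Gaussian, σ = 1 px) intensity surface, with
suppression depth `h_minima` (default 0.05 of the dynamic range) guarding
against over-segmentation. Touching nuclei that merge into one
thresholded region are split along the ridge between their peaks; a mask
without any interior peak falls back to connected-component labelling.

**Positioning.** A nucleus position is the unweighted centre of mass of
its binary region — every pixel weighs equally. Intensity-weighted
centroids were deliberately not used: the decision rule operates on
binary regions, and the unweighted centroid is what the binarization
pipeline naturally defines. On rendered Gaussian nuclei (σ = 3 px, peak
200, noise sd 5) this positions nuclei to about 0.3 px.

## Tracking

Tracking is per-cell and greedy. For each frame a square search window
(side = `roi_fraction` × the shorter image side, default 0.25) is cropped
around the last position, segmented, and the nearest detection is linked
if its distance is at most `gate_px` (default: half the window side).
Ties are broken in scan order (smallest y, then x). A link beyond the
gate marks the track `lost` rather than force-linking — the headless
analogue of a supervised tracker pausing for inspection — because a
forced link is precisely the identity-switch failure mode this design
avoids.

Curation is scripted. A correction event replaces one frame's position,
either with the exact given point or snapped to the nearest detected
centroid (for bright nuclei); corrected frames are recorded so correction
rates can be computed. A division event closes the mother at the marked
frame and seeds one daughter per given position on the next frame.
Automatic mitosis detection is out of scope by design; divisions are
events supplied by the user (or the simulator).

Cells are seeded only on the first frame. Lineage labels encode the
pedigree (`C3.2` is the second daughter of `C3`), the generation is the
number of dots in the label, and multi-daughter divisions (three or more
seeds) are supported. The five trajectory categories follow from the
pedigree: dividing ∪ non-dividing = all (disjoint), daughters are cells
with a parent, and dividing daughters — daughters that divide — are the
cells observed over exactly one full cycle, which is why their trajectory
times are direct per-cell doubling-time measurements.

## FUCCI phase calling

Signals are channel means over a disk of diameter `diameter_px` centred
on the track, clipped to the image; the disk should not exceed the cell
diameter, and the diameter can be overridden per cell. Each channel is
min–max normalized over the cell's own time series (a constant channel
maps to zero), making calls invariant to absolute brightness. An
optional 3-frame median pre-filter exists but is off by default.

The two rule sets are threshold classifiers on the normalized signals:

- **Two-channel** (red = Cdt1, green = Geminin; MS = MGSS = MRSS = 0.1):
  evaluated in precedence order Unknown (both < MS), S (ĝ ≥ MGSS and
  r̂ ≥ MRSS), G1 (r̂ ≥ MS, ĝ < MGSS), G2/M (ĝ ≥ MS, r̂ < MRSS). The
  layout follows the reporter biology — Cdt1 peaks in G1 and declines
  through S while Geminin accumulates through S/G2 — so red-only = G1,
  both = S, green-only = G2/M.
- **Three-channel** (green = Geminin, blue = PIP degron; the PCNA red
  channel is carried but unused): with ρ = ĝ/(b̂ + 10⁻⁶), G1 when
  ρ ≤ MGBr-G1 (0.5), G2/M when ρ ≥ MGBr-G2 (0.7) and b̂ ≥ MBS-G2 (0.1),
  otherwise S. The PIP degron is destroyed during replication, so blue
  without green marks G1, green without blue marks S, and both mark G2.

Mitosis is not separated from G2; the joint class is `G2M`. Phase
corrections overwrite a 1-based inclusive frame range, mirroring
interactive curation. Normalization spans the whole trace rather than a
sliding window; for traces that cover only part of a cycle the extrema
are then not the cycle extrema, which is the main caveat when calling
phases on censored tracks.

## Trajectory statistics

All statistics are computed in physical units from the calibration
(µm/px, min/frame). For a track of n positions: T = (n−1)Δt, D = Σ‖Δp‖,
L = ‖p_n − p_1‖, directionality L/D (NaN for zero-distance tracks,
excluded from summaries), mean speed D/T, instantaneous speeds per step.
Steps are attributed to the phase of their starting frame; per-phase
directionality is computed on the sub-path of positions carrying that
label. Phase fractions are over called frames only (G1+S+G2M), with
Unknown time reported separately.

Doubling-time summaries report mean, sd, median and mode; the mode of
this continuous quantity is the midpoint of the tallest histogram bin
with bin width equal to one frame interval, the natural resolution of the
measurement. Daughter-pair heterogeneity uses all unordered sibling
pairs from divisions with two or more daughters, filtered to pairs where
both siblings were observed ≥ 10 h with trajectory times within 3 h of
each other (defaults; both configurable). Synchrony uses sibling pairs
in which both cells divide.

**Terminal speed jump.** A dividing cell is flagged when some step in
its final hour before division, starting on a G2/M-labelled frame, has
speed ≥ 2.5× the mean instantaneous speed over the final 2 h (the
baseline includes the candidate step, since the window is defined purely
by time) and ≥ 3× each temporally adjacent step speed that falls inside
the final-hour window. "Neighbouring" speeds are the adjacent steps of
the same cell, not of other cells: the criterion is stated per cell.
The 2 h baseline window is time-defined, not restricted to G2/M frames;
only the candidate step must be G2/M.

## Evaluation

Tracks are matched to reference cells by nearest position at the track's
first frame, with a uniqueness check that raises on ambiguous matches.
Errors are reported axis-wise (|Δx|, |Δy| in µm, mean ± sd) with the
maximum single-coordinate deviation in pixels and a flag for the 20 px
accuracy convention, matching how tracking benchmarks present location
error. Reference annotations are plain CSV tables; a converter reduces
labeled-mask TIFF stacks (16-bit label images per frame) to that format
by taking per-label centroids.

## Synthetic data generator

The generator defines the conditions under which the package's claims
are tested, so its defaults are fixed to an epithelial (RPE-like)
PIP-FUCCI imaging setup: 0.65 µm/px, 10 min frame interval, mean speed
9.3 µm/h, cycle length normal 21.5 ± 4.8 h truncated positive, phase
fractions 0.22/0.59/0.19, nuclei as isotropic Gaussian blobs (σ = 3 px,
peak 200) on additive Gaussian noise (sd 5, 8-bit by default).

Motion is a persistent random walk: the heading is an exponentially
smoothed unit vector (`persistence`, default 0.6) and the step length is
constant at the mean speed. Cells steer away from any neighbour closer
than 6σ, so nuclei never approach within the 4σ separation below which
thresholded regions merge — the generator guarantees the spacing its
consumers assume. Boundaries reflect by flipping the offending heading
component, preserving step length. Divisions replace the mother by two
daughters offset ±1.5σ perpendicular to her heading; the offset only
needs to exercise the division plumbing, no mitotic appearance model is
attempted.

FUCCI reporter dynamics are piecewise-linear programmes over cycle
progress u ∈ [0, 1]. Two-channel: red 1 through G1, declining linearly
to 0.15 across S, gone within the first 5% of G2/M; green rising over
the first 5% of S, then 1. Three-channel: blue 1 in G1, destroyed over
the first 3% of S, re-accumulating over the first 20% of G2/M; green
rising over the first 8% of S, then 1; red constant. The ramp widths
keep each signal on the correct side of the default thresholds except
within a frame or two of each true transition, so phase-recovery tests
exclude ±1 frame around transitions and demand ≥ 95% elsewhere.
Trace-level simulation multiplies the programme by a random per-cell
brightness (80–200) with a baseline offset and 2% additive noise, so the
internal normalization is actually exercised.

Jump injection makes a dividing cell's last two hours straight and
constant-speed, then scales one uniformly chosen final-hour G2/M step by
`jump_fold` (default 4). A spike of fold f in a 12-step baseline of
otherwise constant speed satisfies the detection criterion exactly when
f ≥ max(3, 2.5(11+f)/12), i.e. f > 3, which the parameter validation
enforces — injected jumps are detectable by construction, making recall
a meaningful end-to-end check.

Everything is deterministic given the seed; the movie renderer draws its
noise from a seed offset so that lineage-only simulation and full
rendering agree on the ground truth.

What the generator does *not* emulate: anisotropic or deforming nuclei,
intensity variation between and within cells (beyond the FUCCI
programme), photobleaching, cell death, out-of-focus drift, and
cell–cell contact. Passing tests therefore demonstrate the correctness
of the algorithms under the stated geometry and noise, not segmentation
robustness on difficult real microscopy.

## Problem sizes and numerical choices

The test suite and the acceptance script use deliberately moderate sizes
chosen to give stable statistics: 10 cells × 100 frames for tracking
recovery (≈1000 scored cell-frames), 50 cells per FUCCI rule (≈6000
scored frames), 50 first-frame cells over 60 h for doubling times
(≈100 complete cycles, standard error ≈0.3 h), 200 random lineages for
the category identities, 1000 random walks for the metric identities,
and ≈30 injected jumps plus ≈30 clean dividers for the jump detector.

Numerical conventions: x is the column and y the row, 0-based, pixel
centres at integers; exported tables use 1-based frame numbers.
Equidistant link candidates resolve in scan order. The speed–distance
identity mean(v)·T = D holds to 1e−9 relative and is tested at that
tolerance. Division of the green/blue ratio is guarded by ε = 10⁻⁶.
Directionality of a zero-length path and phase statistics of all-Unknown
traces are errors or NaN, never silently zero.

## Known limitations

- Greedy per-cell nearest-neighbour linking has no global assignment
  step; two cells crossing paths can swap identities unless corrected.
  This is inherent to the supervised design, which assumes a human (or
  script) resolves such events.
- Seeding is restricted to the first frame, so cells entering the field
  later are not trackable; evaluation against references that include
  late-appearing cells will cover only the first-frame cohort.
- Phase calling assumes the normalization window spans close to a full
  cycle (see above).
- The jump criterion's neighbour test needs at least one adjacent step
  inside the final-hour window; tracks barely longer than the baseline
  window are rejected rather than guessed at.
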