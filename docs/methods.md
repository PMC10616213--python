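# Methods

## Coordinate model

All analysis happens in *centered display pixels*: (0, 0) at the center of the
5760×1200 stimulus, +x rightward, +y downward. Annotation and rendering use
native top-left video pixels internally and convert at the module boundary
(save time for AOI tables, render time for overlays), so the two conventions
never mix inside the math.

The display is modeled as three coplanar 24-inch 1920×1200 panels in a linear
formation. Physical scale comes from the pixel pitch (default 0.02692 cm/px =
51.69 cm active width / 1920 px) and the perpendicular viewing distance
(default 65 cm). A centered pixel offset x maps to eccentricity
θ = atan(x·pitch/d); the display's physical half-width (three panels plus the
two bezels at each junction, 0.68 cm each) subtends ≈50.5°, i.e. a ≈101°
total field of view. The 50 px bezel-correction bands applied by the graphics
driver at each junction are metadata only: no per-band remapping rule exists
for them, they occlude two thin slivers of the video, and gaze and AOIs share
the single undivided video coordinate space. The 2×50 occluded pixels are
treated as cosmetic.

## Surface pooling

The tracker maps gaze onto marker-delimited surfaces in normalized
coordinates (x_norm rightward, y_norm upward within the surface). One surface
spanning the full 100° registers poorly, so the display is split into nine
full-height vertical strips of 640 px. Pooling rules, per timestamp:

- among surfaces reporting `on_surf`, take the record whose normalized point
  lies deepest inside the unit square (maximize
  min(x, 1−x, y, 1−y)); ties break to the lower surface index. This is
  deterministic and invariant to the order the nine files are supplied in.
- with no on-surface record, the sample is flagged off-screen and coordinates
  come from the least-out-of-bounds surface (same depth criterion).

Task time t = 0 is the first registration of the dedicated full-screen dummy
surface (callers pass `t0`; it defaults to the earliest timestamp).
Synchronization is audited by a unique marker shown between scenes: its
`on_surf` registrations arrive in clusters (>1 s apart), clusters are matched
to the scheduled onsets in order, and per-scene discrepancies are reported in
ms (NaN, never zero, for an undetected marker). The irreducible detection
latency is one world-camera frame, 33 ms at 30 fps.

## Preprocessing

Fixed order, each stage with its parameter (units, default):

| stage | parameter | default | rationale |
|---|---|---|---|
| median filter | window (samples) | 3 | removes one-sample spikes without attenuating saccade peaks the way a moving average would; boundary samples pass through unchanged |
| gap classification | confidence threshold | 0.8 | strict comparison: a sample at exactly 0.8 is kept; off-display samples are gaps regardless of confidence |
| short-gap interpolation | max gap (ms) | 75 | gaps shorter than a blink are tracker flicker; linear fill between the flanking valid samples; ties at 75 ms do not fill; runs touching the stream ends never fill |
| gap extension | pad (ms) | 100 | the pupil is partially occluded around a blink; every sample within ±100 ms (inclusive) of a remaining gap becomes a gap |
| resampling | target rate (Hz) | 240 | the two 120 Hz eye cameras sample in anti-phase and their merged stream is irregular; a uniform grid is required for frame matching |

Gap duration is measured between the flanking valid timestamps. Resampling
uses shape-preserving piecewise cubic Hermite (PCHIP) interpolation computed
independently per contiguous valid segment: it reproduces linear input
exactly, never overshoots monotone data, and never bridges an invalid span —
crossing gaps is exclusively the interpolation stage's job, which prevents
cubic extrapolation through blinks. Segments with fewer than two valid
samples are emitted invalid. Confidence and the on-screen flag are carried to
the grid by nearest neighbor (the tracker defines them per raw sample; any
interpolation would manufacture values). Gap statistics (percent missing
after classification, interpolation, padding) are reported per participant.

Numerical conventions: a 1 ns slack is used for inclusive/exclusive boundary
comparisons on the time axis (five orders of magnitude below the 4.17 ms
sample period), and the "strictly below 75 ms" rule is enforced with a 1 µs
tolerance so grid-aligned gaps are classified by their true duration rather
than by float rounding.

## AOI annotation

AOIs are axis-aligned rectangles, one box per frame per object, 0-based frame
indices, visibility on the closed range [first_frame, last_frame]
(duration = (last − first + 1)/fps). Boxes are stored as integers in centered
coordinates with an object id and an optional free-text label.

Three routes produce trajectories:

- **Semi-automatic tracking.** The reference tracker is deliberately simple
  and fully deterministic: the previous frame's box content (padded by 6 px
  so the object edges carry contrast) is matched by normalized
  cross-correlation against a ±24 px search window in the next frame, over a
  set of candidate template sizes — ±1 px per axis (resolves slow growth of
  small boxes) plus relative scales ±2 %/±4 % (matters once boxes are large).
  The best peak updates box position and size; a peak below 0.5 halts
  tracking with status "lost" (typical when an object grows to cover much of
  the scene, or leaves the frame). Keyframe corrections override the box at a
  frame; a correction after a loss resumes tracking, and the blind span is
  bridged by linear box interpolation so the trajectory stays
  frame-contiguous. The tracker is a pluggable contract — anything that maps
  (frames, initial box) to a box sequence with a loss signal fits.
- **Keyframe interpolation.** Box edges are blended linearly between drawn
  keyframes and rounded to integer pixels; keyframes reproduce exactly.
- **Manual tables** in the same CSV schema.

Trajectory summaries report median/min/max width and height and a mean
velocity: angular distance between the first and last box midpoints divided
by visibility duration, negative for right-to-left motion.

## Margins and matching

A margin m (degrees of visual angle) compensates eye-tracking inaccuracy. Per
frame and per box: the right expansion is deg_to_px(θ(x_right) + m) − x_right
and the left one symmetric, each evaluated at its own edge eccentricity, so
margins grow toward the display periphery; top and bottom use the box-center
y eccentricity, computed in the vertical plane through the viewer (horizontal
eccentricity is ignored for the vertical margin — the simplest reading
consistent with using the center y; a slant-distance variant would shrink
vertical margins by <15% at the extreme corners). At m = 0 all four margins
are exactly zero. Expanded boxes may poke past the display edge; off-screen
gaze is handled by gap classification, not clamping.

Each 240 Hz sample maps to the 25 fps frame containing it (half-open
intervals [k/fps, (k+1)/fps)) and is tested against that frame's expanded box
with closed boundaries on all four sides. Runs of hit samples form visits;
entry/exit are the first/last hit sample timestamps, and gap samples close
visits exactly like misses. Then, in this order (merge before filter):

1. while the gap to the next visit is < 100 ms, the gap time is pooled into
   the previous dwell and the visits combine;
2. merged visits shorter than 100 ms are dropped.

Time to first entry uses the first *retained* visit: an early sub-100 ms
touch contains no fixation, so it does not count as an entry. Dwell
percentage is total dwell over appearance time, reported uncapped with a
warning if pad/merge arithmetic pushes it past 100%. Because entry/exit land
on sample timestamps, each visit boundary can lose up to one sample period
(1/240 s) against the continuous-time expectation.

## Synthetic scenarios and what they show

`synthfix` scripts a recording end to end: objects on linear or parabolic
paths with linear size ramps (boxes must stay on the display; gaze
excursions, not objects, go off-screen), a gaze signal that pursues a target
object (optional pursuit lag), blinks as runs of confidence < 0.8,
off-screen intervals with no surface hit, and two 120 Hz eye streams offset
by half a period. Angular noise is applied in degrees and projected through
the tangent model, so pixel noise grows peripherally like real tracker error;
an optional eccentricity gain scales noise (and an off-screen probability)
with |θ| to emulate the accuracy loss head-mounted trackers show at 40–50°.
A constant per-scenario angular offset emulates calibration inaccuracy — the
error component that AOI margins exist to absorb. Everything derives from one
integer seed; a fixed seed yields byte-identical files.

Ground truth comes from interval arithmetic on the script itself (pursuit
intervals ∩ AOI lifetime, minus blink/off-screen spans ≥ 75 ms dilated by
±100 ms, then the same merge/filter rules in continuous time), independent of
the sample-level pipeline. It is exact for noiseless, lag-free scripts and a
qualitative reference otherwise.

Two canonical scenarios fix the test conditions: a 10 s perfectly tracked AOI
in a 10.5 s recording (blink-free: dwell 100%, time to first entry 0; with
three 200 ms blinks at 2.0005/5.0005/8.0005 s: dwell 8.8 s = 88%, each blink
costing 0.4 s after padding — onsets sit off the 240 Hz grid so
sample-timestamp quantization stays below one period per boundary), and a
three-object scenario with 0.5° noise, a (1.0°, −0.8°) calibration offset,
80 ms pursuit lag and two blinks, on which dwell percentage must rise
monotonically with margin.

What passing these tests does **not** show: the generator emulates neither
video-based pupil detection (confidence is scripted, not earned), nor
slippage, saccadic structure, smooth-pursuit gain below 1, or real fiducial
detection dropouts. Results on real recordings depend on those factors;
the synthetic scenarios validate the *pipeline arithmetic*, not the tracker
hardware.

## Interfaces and formats

Per-surface gaze exports use the tracker's CSV dialect (world_timestamp,
world_index, gaze_timestamp, x_norm, y_norm, x_scaled, y_scaled, on_surf,
confidence; extra columns ignored; malformed rows skipped with a count).
Pooled gaze, AOI tables and metrics are plain UTF-8 CSV with '.' decimals.
Configuration is one YAML file (geometry, preprocessing, matching, margins,
style); command-line flags override it, and every `analyze` run writes a
resolved-config snapshot next to its output. Frame stacks for tracking and
overlays are `.npy` arrays, multi-page TIFF, or PNG directories; compressed
video containers are an external conversion step. Overlay colors come from a
fixed 26-color discriminative alphabet, assigned in deterministic (sorted)
order and cycling beyond 26; at 240 Hz up to 10 gaze dots per participant are
drawn per frame, none thinned.

## Known limitations

- Rectangles only; round signs or cyclists do not fill their box.
- Frame-by-frame dwell measures, no fixation/saccade event detection (a
  fixation-based analysis can be layered on the same hit tests).
- The vertical-margin plane and the per-scene marker-cluster heuristic are
  documented conventions, not the only defensible ones.
- The reference tracker assumes mostly rigid appearance between consecutive
  frames; it loses heavily deforming or occluded objects (by design — it
  signals "lost" rather than guessing).
- Dwell percentages are uncapped; merge arithmetic at AOI boundaries can
  exceed 100% by up to the pad duration in adversarial cases.
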