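# Methods

## Scope and model

`bactrack` quantifies 2-D swimming behaviour of bacteria from video, under
the assumptions that (i) cells are small high-contrast blobs (a few to a few
tens of px²) against a roughly uniform background, (ii) their motion between
frames is locally well approximated by constant velocity, and (iii) the
population is large enough that discarding questionable tracks is cheaper
than modelling their failure modes. Detection, linking and selection are
deliberately simple and fast; accuracy is recovered statistically by
stringent selection rather than per-object modelling.

## Detection

Frames are converted to 8-bit luminance (Rec. 601 weights) and blurred with
a `blur_kernel`×`blur_kernel` Gaussian (default 3; the kernel's sigma
follows the conventional `0.3·((k−1)/2 − 1) + 0.8` mapping). The default
segmentation computes an 11×11 Gaussian-weighted local mean and marks pixels
beyond it by `adaptive_offset` grey levels (default 5) in the configured
polarity as candidates, and by `marker_offset` (default 10) as markers.
Candidate regions (8-connected, so thin diagonal rods stay one object)
survive only if they contain a marker pixel. The marker gate trades recall
for precision: faint noise clusters pass the candidate threshold far more
often than they pass the stricter one. Both offsets are configurable
because their best values depend on contrast and noise of the recording;
the 5-grey-level gap between them is a starting point, not a calibration.

Rectangles are fitted per region: the minimum-area rotated rectangle over
the region's pixel-corner points (rod-shaped mode, via rotating-calipers on
the convex hull) or the axis-aligned bounding box (coccoid mode). Using
pixel corners rather than centres makes an n×m pixel block measure exactly
n×m, so areas are unbiased for small objects. Centres are real-valued;
coordinates use the image convention (origin at the top-left pixel centre,
y downward), `time = frame_index / fps`.

The two fallback modes are a plain adaptive threshold (no gate) and a
global threshold `mean + s·global_offset·SD` of the frame (s = ±1 by
polarity), smoothed by a moving average over `rolling_window_s` seconds
(default 5) to damp frame-to-frame flicker.

## Linking

Each live ID carries a constant-velocity FIR filter over its last
`filter_window` (default 5) raw positions: an ordinary least-squares linear
fit in time, optionally followed by one re-weighting pass with Gaussian
weights `exp(−r²/2σ²)` on the residuals (σ² = mean squared residual). The
fit is exact on linear motion — noiseless straight swimming is reproduced
measurement-for-measurement — and a single aberrant measurement is damped.
The fit's slope provides the velocity used to predict the next frame's
position; during misses the prediction coasts at that velocity.

Assignment is greedy least-distance: the globally closest
(prediction, detection) pair is bound and removed, repeatedly, until the
smallest remaining distance exceeds the gate. Greedy is not the
minimum-total-cost assignment (a documented property, see the tests), but
it is linear in spirit, deterministic (ties break by ID then detection
order), and behaves identically at the densities this tool targets. The
gate is expressed as a top apparent speed (`max_linking_speed_um_s`,
default 120 µm/s): it should be ~2× the fastest expected swimming speed,
because the constant-velocity prediction overshoots by a few per-frame
displacements when a cell reorients sharply, and the gate must absorb that
error without capturing a neighbour. Unmatched IDs are written as gap
points (width = height = 0, position = prediction, last angle carried);
after `track_expiry_s` seconds (default 1) without a detection the ID is
retired and its trailing gap points — pure extrapolation — are dropped.
IDs are never reused.

## Track selection

Selection is two-staged with an exclusion ledger. Coarse: a track whose
mean rectangle area (gap zeros included, so briefly-detected IDs average
near zero) falls outside `[0.20, 5] × avg_bacterial_area_px2`, or that is
shorter than `min_track_time_s`, is dropped whole. `avg_bacterial_area_px2`
is user-supplied (seeded at 20 px² for rods, 12 px² for cocci) rather than
estimated from data, for determinism. Scrubbing removes gap placeholders
and, optionally, points whose area exceeds `point_area_outlier_mult`
(default 1.5) times the track's mean — the signature of two cells
overlapping for a frame. Splitting cuts at gap runs longer than
`max_consecutive_gaps` and at step distances above the Tukey outer fence
(Q3 + 3·IQR, quartiles by linear interpolation); every piece re-enters the
pipeline from the coarse stage, and recursion terminates because pieces
strictly shrink. When more than `distance_outlier_auto_disable_frac`
(default 0.2) of all steps in a table are fence outliers — typical when
most objects are immotile and the distance distribution collapses — the
fence criterion disables itself for that table and the report flags it.
A related caveat: on *noiseless* synthetic renders the step-distance
distribution is so narrow that the fence sits just above the median and
splitting fires frequently; this is an artefact of the unrealistically
clean distances, and disappears at realistic pixel noise.

Fine checks run in order (first failure recorded): minimum duration; the
gap-run bound; gap fraction (missing frames over the segment's span at the
frame cadence, robust to earlier scrubbing); mean area inside the
`[p, 100−p]` percentile band of all candidate tracks' mean areas
(two-sided by default; one-sided upper mode available since the band's
lower edge can bite on legitimate small cells); mean position at least
`edge_margin_frac` of the frame dimension away from every edge (IDs near
the border are prone to false reassignment when cells enter the frame).
If several pieces of one original ID pass, the longest wins (ties: more
points, then earlier start). An optional `max_track_time_s` truncates
accepted tracks at the exact relative time or the closest earlier point if
that timestamp fell in a gap; `drop_short_after_truncation` then discards
tracks that were actually shortened yet ended below the limit — tracks
already below the limit were never shortened and are unaffected.

Every finally rejected ID increments exactly one counter, so
`tracks_in = tracks_accepted + Σ exclusions` always holds. Attribution: a
rejected ID that was split is attributed to the cause of its first split
(gap run or distance outlier) — the split is what destroyed it, and its
fragments' individual failures (usually "too short") carry no information;
an ID never split is attributed to the criterion that rejected its longest
candidate piece.

## Motility statistics

Positions are used as stored (filtered); no further smoothing precedes
differencing. Total distance is the sum of consecutive Euclidean steps
(across gaps the actual Δt is used); speed is total distance over duration;
maximum displacement is the largest pairwise distance; the arc–chord ratio
is path length over first-to-last distance (NaN for a closed path, never an
exception). Percent motile is the share of steps whose instantaneous speed
reaches `motile_speed_threshold_um_s` (default 5 µm/s — comfortably above
centroid-jitter speeds at typical calibrations, well below genuine
swimming). A turn point is an interior point whose adjacent displacement
vectors both span adjacent frames (heading across a gap is unreliable),
both exceed `turn_min_step_px` (default 0.5 px, a noise floor), and enclose
more than `turn_angle_threshold_deg` (default 30°). Turn-point counting is
a *threshold* detector: reorientations smaller than the threshold are
invisible by construction, so the measured rate is a lower bound on the
true reorientation rate, with the gap shrinking as the reorientation-angle
distribution broadens.

## Synthetic scenes

The generator emulates the study conditions the pipeline targets: 30 fps,
10x-objective-like calibration (3 px/µm default), 50 cells of ~7×3 px
swimming at 20 µm/s with Poisson tumbling at 0.5 Hz, rendered as filled
rotated ellipses (dark 60 on background 200, or inverted) with additive
Gaussian pixel noise. Tumbles are instantaneous single-frame reorientations
drawn from a wrapped normal with 150° dispersion — a broad reorientation
approximating the near-uniform tumble angles of peritrichously flagellated
swimmers. An immotile fraction jitters around its anchor (0.1 px SD).
Trajectories reflect specularly off the frame border; with
`min_separation_px` set, each cell is instead confined to its own grid
territory, guaranteeing a minimum pairwise distance — the regime in which
identity-preserving linking can be *required* to be perfect, used by the
recovery tests. What the generator does not emulate: optics (PSF, defocus,
shading), cell–cell interactions or collisions, size variation within a
scene, and gradual illumination drift; passing tests therefore demonstrate
the correctness of the algorithmic chain under known ground truth, not
robustness to every artefact of real microscopy.

Video I/O is a self-contained RIFF/AVI layer supporting lossless 8-bit
frames and Motion-JPEG (per-frame JPEG via Pillow). Lossless mode is used
wherever tests require pixel-exact round trips; MJPEG matches the overlay
output format and keeps large fixtures small.

## Problem sizes and numerical choices

Recovery checks run on a 640×640 px, 30 s, 50-cell noiseless scene
(identity recovery: raw track count, ≥99 % of positions within 2 px, zero
switches) and a 512×512, 15 s, 20-cell scene for speed recovery within 5 %;
tumble-rate recovery (within 25 % at the 30° threshold) is measured on
simulated trajectories directly, because the position filter smears a
single-frame reorientation over its window and converts part of each turn
to sub-threshold angles. Quartiles use linear interpolation; comparisons
against fences and bands use a 1e-9 tolerance; CSVs are written with
shortest round-trip float formatting and read back with round-trip parsing,
so write → read → write is byte-identical. Parallelism is one video per
worker process with file-based results only, which makes multi-worker runs
byte-identical to serial ones.

## Known limitations

Greedy linking can, in principle, mis-assign crossing cells that approach
within the gate; density beyond a few hundred cells per frame increases
both ID switches and fence splits; the rotated-rectangle fit is meaningful
only for elongated cells; and all statistics inherit the calibration error
of `px_per_um` and `fps`.
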