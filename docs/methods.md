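# Methods

This note documents the models, conventions and numerical choices behind
`larvatrack`, and what the synthetic assays do and do not establish
about performance on real recordings.

## Coordinates, units, conventions

Image coordinates follow raster order: origin at the top-left, x to the
right, y downward, so positive vertical velocity means sinking.  The
centre of pixel (row r, col c) sits at `((c+0.5)·s, (r+0.5)·s)` mm for
pixel scale `s` (mm/px).  Positions are carried in mm, times in
seconds, speeds in cm/s, densities in kg/m³, ages in days.

## Synthetic actography

Each simulated larva follows one of four motion models on a continuous
(sub-pixel) plane bounded by the container walls:

* **sinker** — constant vertical speed drawn once per larva from
  N(mean, sd), truncated below at a configurable floor (default 0);
  a sinker reaching the bottom settles there and is relabelled.
* **swimmer** — correlated random walk: per frame the heading gains a
  N(0, (1−p)·π) increment, where p is the persistence parameter
  (p = 1 is a straight line); speed is constant; walls reflect both the
  position and the heading.  Swimming speeds are package defaults, not
  literature estimates: published behavioural data for these larvae
  describe activity budgets, not swimming kinematics.
* **settled** — motionless, resting one pixel above the bottom wall.
* **crawler** — settled height with a ±x random walk whose direction
  flips with probability (1−p)/2 per frame.

A bout schedule can switch a larva between models at fixed times.
Frames are rendered by painting each larva as a filled ellipse (major
axis vertical) over pixels whose centres fall inside it — no
anti-aliasing, giving a crisp segmentation target — then adding
Gaussian read noise and quantising to uint8.  Larvae are darker than
the background by default (contrast sign configurable).  Ground truth
records the continuous positions, per-frame behaviour labels, true
ellipse areas and drawn fall speeds.  All generators are deterministic:
one `numpy` generator seeded from the scene config drives parameter
draws, per-step kinematics and rendering noise in a fixed order.

Defaults mirror the laboratory protocol: 25 frames per second, 90-min
recordings split into six 15-min sequences alternating cold white light
(CWL) and infrared (IR), flat containers that constrain motion to the
camera plane, and a 9 × 20 cm settling column for free-fall runs.

What the generator does **not** emulate: hydrodynamic wall effects,
acceleration transients, 3-D motion and defocus, illumination drift,
debris, larva–larva contact and occlusion beyond simple overlap, and
shape change during crawling.  Passing the recovery tests therefore
shows the measurement chain is unbiased under the stated image model,
not that segmentation or linking are robust to every field artefact.

## Synthetic count sheets

Larval survival follows a piecewise-linear curve through (0 d, 100 %),
(t95, 95 %), (t50, 50 %), (t5, 5 %), continued at the last slope to
zero.  These anchors are the protocol's longevity definitions, and the
piecewise-linear interpolant is the weakest assumption consistent with
them.  After a metamorphosis onset age, each surviving larva
metamorphoses with a fixed daily hazard (binomial increments between
sampling days); polyps persist.  Observed counts at ages > 0 carry
multiplicative Gaussian counting noise with relative SD 0.03, the
precision of repeated manual counts; the age-0 count is exact because
containers are seeded by counting.  Default cohort sizes (100–150 per
replicate, three replicates, counts every other day) match the rearing
protocol.

## Synthetic density assays

Body density is uniform between the bounds implied by the requested
20 %/80 % quantiles (point mass when they coincide); each tube's sunk
count is Binomial(n, P(D > tube density)) with n = 20 larvae per tube
by default, using the protocol's eight-tube ladder (1024 and
1027–1039 kg/m³).

## Segmentation

Contrast stretching maps the `p_low`–`p_high` percentile range linearly
onto [0, 255] (constant frames pass through with a warning).  The
standalone function defaults to the (1, 99) percentiles; the stack
pipeline defaults to the full min/max range because an affine rescale
leaves Otsu's partition invariant, whereas inner-percentile clipping
can merge the larva population (often < 1 % of pixels) with the clipped
tail of the background noise and shatter the threshold into speckle.
Thresholding is Otsu on the gray-level histogram (fixed thresholds
available); foreground is darker-than-threshold by default.  Connected
components use 8-connectivity; components below `min_area_px`
(default 3), above `max_area_px`, or touching the frame border (partial
larvae bias area) are dropped.  Area is pixel count × s²; the
projected-surface-area trait takes the largest component per photograph
and reports mean ± SD across photographs.  On noise-free renders the
mask equals the painted pixel set exactly, which the suite asserts.

## Linking and velocities

Tracks are built greedily per frame: candidate (track, detection) pairs
within `gate · (gap+1)` mm are committed in order of increasing
distance, ties broken by lower track id then detection label; tracks
survive up to `max_gap_frames` missed frames (default 2); leftover
detections seed new tracks.  At assay densities (10–30 well-separated
larvae) this coincides with globally optimal matching, verified against
a brute-force assignment oracle on ≤ 3 particles.  The recommended gate
is three times the fastest expected per-frame displacement, floored at
a few pixels — below the centroid quantisation jump of slow movers the
geometric rule alone would break tracks.  Velocities are per-step
finite differences (length = positions − 1), optionally smoothed by a
centred moving average (default window 5 at 25 fps); a gap bridged by
the linker contributes one long step at its true Δt.

## Behaviour classification

Steps are labelled: inside the bottom band (default 5 % of container
height) *settled* below a speed noise floor (default 0.01 cm/s) and
*crawling* above it; outside the band *free fall* when the smoothed
vertical velocity exceeds the noise floor downward, else *swimming*
(which deliberately includes hovering: station-keeping against negative
buoyancy requires active ciliary swimming).  Runs shorter than
`min_bout_s` (default 2 s) are absorbed into their longer neighbour.
Each candidate free-fall bout must then satisfy three gates or be
relabelled swimming: net downward speed above the noise floor; at least
90 % of steps non-upward, where "non-upward" tolerates vy down to minus
the noise floor because pixel-quantised centroids of slow sinkers
produce many exact-zero steps; and cumulative horizontal path below
`straightness_max` (default 0.5) times the net vertical drop.  The path
(rather than net-dx) criterion is what separates a meandering swimmer
that happens to descend — large sideways travel — from a passive sinker
that barely moves sideways.  Segments tile the tracked time exactly
once under a frame dwell-time convention: a detection at frame i covers
[tᵢ, tᵢ+Δt), so a larva tracked through a whole sequence accumulates
exactly the sequence duration and the activity-frequency endpoints 0 %
and 100 % are attainable exactly.

These decision rules are a documented surrogate: the original scoring
was semi-automated with manual curation, and no operational definition
of "swimming track" was published.

## Free-fall speed

One estimate per track: net vertical displacement ÷ elapsed time over
the free-fall-labelled steps whose midpoints lie inside the region of
interest (default 5 cm high, centred in the column, to avoid wall
effects), requiring at least `min_steps` (default 5) such steps.  Net
displacement over a long transit is robust to quantisation jitter,
unlike averaging per-step speeds.  Estimates are tagged by experimental
temperature group (19–21 °C vs 21–23 °C, boundary at 21 °C inclusive
to the cooler group).

## Survival analysis

Survival and metamorphosis rates are raw ratios to the initial count.
Longevity crossings interpolate linearly between the bracketing sampled
ages (a sampled-day convention is available); the curve is *not*
monotonized first — counting noise can transiently raise counts and
only the first downward crossing defines the metric; an exact touch of
a threshold at a sampled age counts as crossing there.  Uncrossed
thresholds are censored at the experiment duration.  Replicate
summaries report mean ± SD over non-censored replicates with the
censored count alongside; a metric censored in every replicate is
reported as a bound.  Healthy larvae alone enter the numerator; damaged
larvae are transferred but never counted, per the rate definitions.

## Buoyancy analysis

The fraction less dense than each tube is 1 − sunk/total; with n = 20
per tube, sampling noise makes non-monotone fractions likely, so they
are monotonized by pooled-adjacent-violators (weighted by tube size,
via `scipy.optimize.isotonic_regression`) with a warning rather than
rejected.  Quantiles interpolate linearly between adjacent tube
densities (a step convention is available) and are flagged censored
below the lightest or above the densest tube.  Seawater density is the
EOS-80 one-atmosphere polynomial in practical salinity and temperature,
validated for 0–42 psu and 0–40 °C against the published check value
ρ(35, 5) = 1027.67547 kg/m³; laboratory reference values measured at
the bench can be supplied instead, since hydrometer readings of natural
seawater need not match the polynomial at nominal (S, T).  Buoyancy is
the sign of body − seawater density with a ±0.5 kg/m³ neutrality
tolerance.

## Validation problem sizes

The end-to-end checks run at desk scale by design: free-fall recovery
renders a 256 × 256, 60-s (1500-frame) column with a 30-larva cohort
whose speeds are stratified over the normal quantiles of
N(0.23, 0.08 cm/s) — stratification pins the cohort mean at the nominal
value so the check isolates pipeline bias from sampling luck — plus an
exactness case at one pixel per frame (0.1 cm/s at 25 fps and
0.04 mm/px); activity-frequency endpoints use ten-larva, 2-min stacks;
longevity recovery uses anchors (3.5, 32, 64) days sampled every other
day, noise-free and across 100 noisy seeds; buoyancy round-trips 2000
larvae per tube.

## Known limitations

Greedy linking can swap identities when larvae cross; swimming scored
from 2-D projections underestimates motion along the optical axis even
in flat containers; the free-fall/swimming discrimination is
kinematic and cannot recognise a larva swimming straight downward at
constant speed; density quantiles are bounded by the tube ladder and
censored outside it; and the survival generator treats deaths as
deterministic given the curve, so replicate spread reflects counting
noise and metamorphosis stochasticity only.
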