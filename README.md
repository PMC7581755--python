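# larvatrack

Quantification of the larval traits that set the dispersal potential of
sessile marine invertebrates with nonfeeding (lecithotrophic) larvae,
such as Mediterranean octocorals.  For these species, migration happens
once per generation, during the planktonic larval phase, and predicting
it requires a handful of measurable traits: how long larvae survive and
stay competent to metamorphose, how big and how dense they are, how fast
they sink when passive, and how much of the time they actively swim.

`larvatrack` turns the three laboratory data streams used to measure
those traits into numbers:

* **video actography** — still-water recordings of larvae are segmented
  (contrast stretch → Otsu threshold → connected components), linked
  into individual tracks by gated nearest-neighbour matching, and
  classified frame-by-frame into *settled*, *crawling*, *free fall* and
  *swimming* bouts;
* **count sheets** — healthy-larva and polyp counts per replicate
  container over weeks of rearing;
* **dual-density assays** — sink/float outcomes of larvae injected into
  a ladder of solutions of known density.

Because the original videos and cultures are not redistributable, the
package ships a first-class synthetic-data generator that renders
ground-truthed videos (elliptical larvae under sinker / swimmer /
settled / crawler motion models), count sheets and assay tables, so the
whole pipeline is testable end to end against known truth.

## The quantities computed

* **Survival rate** at age *t*: `100 · n_healthy(t) / n_initial`;
  **metamorphosis rate**: `100 · n_polyps(t) / n_initial` (cumulative
  curve monotonized by running maximum, since tiny fresh polyps are
  detected with delay).
* **Larval longevity** (minimum / half / maximum): ages at which the
  survival curve first crosses 95 %, 50 % and 5 %, located by linear
  interpolation between sampled ages; thresholds never crossed are
  right-censored at the experiment duration (reported as "> D days").
* **Projected planar surface area**: foreground pixel count ×
  (mm/px)², taking the maximum component per photograph.
* **Body density**: the daily frequency distribution of the fraction of
  larvae less dense than each tube, monotonized by
  pooled-adjacent-violators when counting noise makes it dip, with the
  20 % and 80 % quantiles interpolated between tube densities.
  Buoyancy is the sign of (body density − seawater density), seawater
  density from the one-atmosphere EOS-80 equation of state.
* **Free-fall speed**: for each track classified as free-falling, net
  vertical displacement ÷ elapsed time over the steps inside a central
  region of interest (default 5 cm, mid-column, away from walls).
* **Swimming activity frequency** per 15-min light sequence:
  `F = 100 · Σ(swimming-track time) / (n_larvae × sequence duration)`,
  with the first two sequences flagged as the kinesthetic-stimulation
  window and excluded from pooled per-light summaries.

## Worked example

```python
import numpy as np
from larvatrack import (
    MotionModel, SceneConfig, generate_motility_frames, segment_stack,
    link_detections, estimate_freefall_speed, generate_survival_counts,
    longevity_by_replicate, aggregate_replicates, generate_density_assay,
    assay_to_distribution, seawater_density, buoyancy_class)

# free-fall assay: ten passive sinkers in a settling column
scene = SceneConfig(width_px=256, height_px=256, pixel_scale=0.4,
                    duration_s=40.0, fps=25.0, larva_axes=(2.5, 1.0), seed=42)
larvae = [MotionModel(kind="sinker", fall_speed_mean=0.23, fall_speed_sd=0.08,
                      initial_xy_mm=(x, 20.0))
          for x in np.linspace(10, 90, 10)]
stack, truth = generate_motility_frames(scene, larvae)
tracks = link_detections(segment_stack(stack), max_link_dist_mm=1.0)
est = estimate_freefall_speed(tracks, container_height_cm=scene.container_height_cm)
speeds = [e.speed_cm_s for e in est]
print(f"free-fall speed: {np.mean(speeds):.3f} +/- {np.std(speeds, ddof=1):.3f} cm/s")

# longevity from a survival count sheet
counts = generate_survival_counts(n_initial=130, t95=3.5, t50=32, t5=64, seed=1)
half = aggregate_replicates(
    [m.t_half for m in longevity_by_replicate(counts).values()])
print(f"median larval longevity: {half.mean:.1f} +/- {half.sd:.1f} days")

# buoyancy from a dual-density assay
tubes = [1024, 1027, 1029, 1031, 1033, 1035, 1037, 1039]
assay = generate_density_assay(1029.0, 1034.0, tubes, n_per_tube=20, seed=3)
dist = assay_to_distribution(assay)
sw = seawater_density(38.0, 20.0)
label, margin = buoyancy_class(dist.q20.value, sw)
print(f"q20-q80: {dist.q20.value:.1f}-{dist.q80.value:.1f} kg/m3; "
      f"seawater {sw:.1f} -> {label} ({margin:+.1f})")
```

prints

```
free-fall speed: 0.229 +/- 0.053 cm/s
median larval longevity: 32.0 +/- 1.1 days
q20-q80: 1028.6-1033.0 kg/m3; seawater 1027.1 -> negative (+1.5)
```

The ten simulated larvae were drawn around a true mean fall speed of
0.23 cm/s and the full video pipeline (render → segment → link →
classify → measure) recovers 0.229 cm/s; the count sheets were generated
with a half-longevity of 32 days and 3 % counting noise, recovered as
32.0 ± 1.1 days over three replicates; the assayed cohort straddles
densities above seawater at 38 psu / 20 °C, so even its lightest
quintile is negatively buoyant (sinks when inactive).

## Command line

Each stage is also a shell command operating on TIFF/PNG stacks and CSV
tables: `larvatrack simulate | segment | track | motility | buoyancy |
survival`.  See `larvatrack <cmd> --help`.

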