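"""Behavioural scoring of larval tracks.

Tracks are partitioned into bouts of four behaviours:

* ``settled`` — inside the bottom band of the container, essentially
  motionless;
* ``crawling`` — inside the bottom band but displacing;
* ``free_fall`` — in the water column, sustained nearly-straight
  downward motion (passive sinking of a nonswimming larva);
* ``swimming`` — everything else in the water column, including hovering
  and any sustained upward motion (sustained station-keeping against
  negative buoyancy requires active ciliary swimming).

From the bouts the module derives the two headline motility traits:
individual free-fall speed, measured as net vertical displacement over
elapsed time while the larva transits a central region of interest (to
avoid wall and injection effects), and swimming activity frequency, the
percentage of larva-time spent swimming within a light-exposure
sequence:  F = 100 * (cumulative swimming time) / (n_larvae * sequence
duration).

Time accounting uses a frame dwell-time convention: a detection at frame
``i`` represents the interval ``[t_i, t_i + dt)``, so a larva tracked in
every frame of a sequence accumulates exactly the sequence duration and
the frequency endpoints 0 % and 100 % are exactly attainable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .imaging import FrameStack, segment_stack
from .tracking import Track, link_detections, track_velocities

BOTTOM_BAND_FRACTION = 0.05  # default: lowest 5 % of the container height


@dataclass
class BehaviorSegment:
    """A maximal bout of one behaviour within a track."""

    track_id: int
    start_s: float
    end_s: float
    label: str
    mean_vy_cm_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class FreeFallEstimate:
    """Free-fall speed of one larva through the measurement window."""

    track_id: int
    speed_cm_s: float
    temp_group: str
    age_days: float | None
    roi_cm: tuple[float, float]  # (top, bottom) below the water surface
    n_steps: int


def split_light_sequences(
    total_duration_s: float,
    sequence_duration_s: float,
    first_label: str = "CWL",
    labels: tuple[str, str] = ("CWL", "IR"),
) -> list[tuple[tuple[float, float], str]]:
    """Divide a recording into contiguous alternating light sequences.

    A 90-min recording at 15-min sequences yields six windows labelled
    CWL, IR, CWL, IR, CWL, IR.  The total duration must be a positive
    integer multiple of the sequence duration.
    """
    if sequence_duration_s <= 0 or total_duration_s <= 0:
        raise ValueError("durations must be positive")
    n = total_duration_s / sequence_duration_s
    if abs(n - round(n)) > 1e-9:
        raise ValueError("total duration must be a multiple of the sequence duration")
    if first_label not in labels:
        raise ValueError(f"first_label must be one of {labels}")
    start = labels.index(first_label)
    out = []
    for i in range(int(round(n))):
        t0 = i * sequence_duration_s
        out.append(((t0, t0 + sequence_duration_s), labels[(start + i) % 2]))
    return out


def _merge_equal_runs(runs: list[list]) -> list[list]:
    merged = [runs[0]]
    for run in runs[1:]:
        if run[0] == merged[-1][0]:
            merged[-1][2] = run[2]
        else:
            merged.append(run)
    return merged


def classify_track(
    track: Track,
    container_height_mm: float,
    bottom_band_mm: float | None = None,
    noise_floor_cm_s: float = 0.01,
    straightness_max: float = 0.5,
    min_bout_s: float = 2.0,
    smoothing_window: int = 5,
    downward_frac: float = 0.9,
) -> list[BehaviorSegment]:
    """Partition a track into behaviour bouts.

    Per-step labels (settled / crawling inside the bottom band by the
    speed noise floor; free fall / swimming outside it) are smoothed into
    bouts of at least ``min_bout_s``; each free-fall bout must then show
    net downward speed above the noise floor, a ratio of cumulative
    horizontal path to net vertical drop below ``straightness_max`` and at least
    ``downward_frac`` of its steps non-upward (upward means vy below
    minus the noise floor — pixel quantisation makes exact-zero steps
    common in slow sinkers), otherwise it is relabelled swimming.

    The returned segments tile the tracked time exactly once, covering
    ``[t_first, t_last + dt)`` (frame dwell-time convention).
    """
    if len(track) < 2:
        raise ValueError("cannot classify a track with fewer than 2 detections")
    if bottom_band_mm is None:
        bottom_band_mm = BOTTOM_BAND_FRACTION * container_height_mm
    v = track_velocities(track, smoothing_window)  # cm/s
    t = track.times
    y = track.y_mm
    x = track.x_mm
    n_steps = len(v)
    dwell = track.median_dt

    y_mid = 0.5 * (y[:-1] + y[1:])
    in_band = y_mid >= container_height_mm - bottom_band_mm
    speed = np.hypot(v[:, 0], v[:, 1])
    labels = np.empty(n_steps, dtype=object)
    labels[in_band & (speed < noise_floor_cm_s)] = "settled"
    labels[in_band & (speed >= noise_floor_cm_s)] = "crawling"
    down = ~in_band & (v[:, 1] > noise_floor_cm_s)
    labels[down] = "free_fall"
    labels[~in_band & ~down] = "swimming"

    # runs as [label, first_step, last_step]
    runs: list[list] = []
    for k in range(n_steps):
        if runs and runs[-1][0] == labels[k]:
            runs[-1][2] = k
        else:
            runs.append([labels[k], k, k])

    def run_duration(run: list) -> float:
        end = t[run[2] + 1] if run[2] + 1 < len(t) else t[-1] + dwell
        return float(end - t[run[1]])

    # absorb sub-bout runs into their longer neighbour
    while len(runs) > 1:
        durs = [run_duration(r) for r in runs]
        i = int(np.argmin(durs))
        if durs[i] >= min_bout_s:
            break
        if i == 0:
            j = 1
        elif i == len(runs) - 1:
            j = i - 1
        else:
            j = i - 1 if durs[i - 1] >= durs[i + 1] else i + 1
        runs[i][0] = runs[j][0]
        runs = _merge_equal_runs(runs)

    # bout-level free-fall validation
    for run in runs:
        if run[0] != "free_fall":
            continue
        a, b = run[1], run[2]
        dy = y[b + 1] - y[a]
        elapsed = t[b + 1] - t[a]
        net_vy = (dy / elapsed) / 10.0 if elapsed > 0 else 0.0
        frac_down = float(np.mean(v[a : b + 1, 1] > -noise_floor_cm_s))
        # cumulative horizontal path, not net dx: a meandering swimmer that
        # happens to descend has large sideways travel; a passive sinker
        # barely any
        horiz_path = float(np.sum(np.abs(np.diff(x[a : b + 2]))))
        straight = horiz_path / max(abs(dy), 1e-12)
        if not (net_vy > noise_floor_cm_s and straight < straightness_max
                and frac_down >= downward_frac):
            run[0] = "swimming"
    runs = _merge_equal_runs(runs)

    segments = []
    for ri, run in enumerate(runs):
        a, b = run[1], run[2]
        start = float(t[a])
        end = float(t[-1] + dwell) if ri == len(runs) - 1 else float(t[b + 1])
        segments.append(
            BehaviorSegment(
                track_id=track.track_id,
                start_s=start,
                end_s=end,
                label=run[0],
                mean_vy_cm_s=float(np.mean(v[a : b + 1, 1])),
            )
        )
    return segments


def temperature_group(temperature_c: float) -> str:
    """Assign a free-fall measurement to its experimental temperature group."""
    return "19-21C" if temperature_c <= 21.0 else "21-23C"


def estimate_freefall_speed(
    tracks: Sequence[Track],
    container_height_cm: float,
    roi_center_cm: float | None = None,
    roi_height_cm: float = 5.0,
    temperature_c: float = 20.0,
    age_days: float | None = None,
    min_steps: int = 5,
    **classify_kwargs,
) -> list[FreeFallEstimate]:
    """Free-fall speed of each sinking larva through the central ROI.

    Free fall is measured over a window (default 5 cm high, centred in
    the container) away from the walls.  For each track, the estimate is
    the net vertical displacement divided by elapsed time over its
    free-fall-labelled steps whose midpoints lie inside the ROI; tracks
    with fewer than ``min_steps`` such steps are skipped.  Net
    displacement is robust to pixel-quantisation jitter, unlike a mean
    of per-step speeds.
    """
    if roi_center_cm is None:
        roi_center_cm = container_height_cm / 2.0
    if roi_height_cm > container_height_cm:
        raise ValueError("ROI taller than the container")
    top_cm = roi_center_cm - roi_height_cm / 2.0
    bot_cm = roi_center_cm + roi_height_cm / 2.0
    if top_cm < 0 or bot_cm > container_height_cm:
        raise ValueError("ROI extends outside the container")
    top_mm, bot_mm = top_cm * 10.0, bot_cm * 10.0

    group = temperature_group(temperature_c)
    out: list[FreeFallEstimate] = []
    for track in tracks:
        if len(track) < 2:
            continue
        segments = classify_track(track, container_height_mm=container_height_cm * 10.0,
                                  **classify_kwargs)
        y_mid = 0.5 * (track.y_mm[:-1] + track.y_mm[1:])
        t_mid = 0.5 * (track.times[:-1] + track.times[1:])
        in_ff = np.zeros(len(y_mid), dtype=bool)
        for seg in segments:
            if seg.label == "free_fall":
                in_ff |= (t_mid >= seg.start_s) & (t_mid < seg.end_s)
        ks = np.flatnonzero(in_ff & (y_mid >= top_mm) & (y_mid <= bot_mm))
        if len(ks) < min_steps:
            continue
        a, b = ks[0], ks[-1]
        elapsed = track.times[b + 1] - track.times[a]
        if elapsed <= 0:
            continue
        speed = (track.y_mm[b + 1] - track.y_mm[a]) / elapsed / 10.0
        out.append(
            FreeFallEstimate(
                track_id=track.track_id,
                speed_cm_s=float(speed),
                temp_group=group,
                age_days=age_days,
                roi_cm=(top_cm, bot_cm),
                n_steps=int(len(ks)),
            )
        )
    return out


def swimming_activity_frequency(
    segments: Sequence[BehaviorSegment],
    n_larvae: int,
    interval: tuple[float, float],
) -> float:
    """Swimming activity frequency (%) within a light sequence.

    100 times the cumulative swimming-segment time overlapping the
    interval, divided by the maximum potential tracking duration
    (number of larvae times interval duration).
    """
    if n_larvae < 1:
        raise ValueError("n_larvae must be at least 1")
    t0, t1 = interval
    if not t1 > t0:
        raise ValueError("interval must have positive duration")
    swim = 0.0
    for seg in segments:
        if seg.label != "swimming":
            continue
        swim += max(0.0, min(seg.end_s, t1) - max(seg.start_s, t0))
    return 100.0 * swim / (n_larvae * (t1 - t0))


def motility_assay(
    stack: FrameStack,
    n_larvae: int,
    sequence_duration_s: float = 900.0,
    first_label: str = "CWL",
    max_link_dist_mm: float = 2.0,
    max_gap_frames: int = 2,
    replicate: int = 1,
    segment_kwargs: dict | None = None,
    classify_kwargs: dict | None = None,
) -> pd.DataFrame:
    """End-to-end activity scoring of one recorded vial.

    Segments and links the stack, classifies every track, and returns
    one row per light sequence with the swimming activity frequency.
    """
    duration = float(stack.timestamps[-1] - stack.timestamps[0]) + float(
        np.median(np.diff(stack.timestamps))
    )
    sequences = split_light_sequences(duration, sequence_duration_s, first_label)
    detections = segment_stack(stack, **(segment_kwargs or {}))
    tracks = link_detections(detections, max_link_dist_mm, max_gap_frames)
    height_mm = stack.metadata.get("container_height_cm", stack.height_mm / 10.0) * 10.0
    segments: list[BehaviorSegment] = []
    for tr in tracks:
        if len(tr) >= 2:
            segments.extend(
                classify_track(tr, container_height_mm=height_mm,
                               **(classify_kwargs or {}))
            )
    rows = []
    for i, (interval, light) in enumerate(sequences, start=1):
        freq = swimming_activity_frequency(segments, n_larvae, interval)
        rows.append((replicate, i, light, interval[0], interval[1], n_larvae, freq))
    return pd.DataFrame(
        rows,
        columns=["replicate", "sequence_index", "light", "start_s", "end_s",
                 "n_larvae", "frequency_pct"],
    )


def summarize_motility(
    frequencies: pd.DataFrame,
    n_stimulation_sequences: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sequence table plus pooled per-light summaries.

    Swimming activity in the first two 15-min sequences is depressed by
    the kinesthetic stimulation of transferring the larvae, so those
    sequences are flagged ``stimulation_window`` and excluded from the
    pooled per-light means (computed over the remaining sequences,
    normally 3-6, grouped by light label across replicates).  Cells with
    a single contributing replicate get an NaN SD; missing sequences
    simply lower ``n``.
    """
    req = {"replicate", "sequence_index", "light", "frequency_pct"}
    missing = req - set(frequencies.columns)
    if missing:
        raise ValueError(f"frequency table lacks columns {sorted(missing)}")
    per_seq = frequencies.copy()
    per_seq["stimulation_window"] = per_seq["sequence_index"] <= n_stimulation_sequences
    usable = per_seq[~per_seq["stimulation_window"]]
    pooled = (
        usable.groupby("light")["frequency_pct"]
        .agg(mean_frequency_pct="mean", sd_frequency_pct="std", n="count")
        .reset_index()
    )
    return per_seq, pooled
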