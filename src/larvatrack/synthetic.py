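"""Ground-truthed synthetic assays: larval videos, count sheets, density tubes.

This module emulates the three laboratory data streams of a planula
trait-quantification campaign so that every downstream stage can be
tested against known truth:

* actography videos — dark elliptical larvae on a light background,
  moving under one of four behavioural repertoires (passive sinker,
  correlated-random-walk swimmer, settled, bottom crawler) inside a
  still-water container filmed at fixed frame rate;
* survival / metamorphosis count sheets — per-replicate healthy-larva and
  polyp counts every few days, drawn from a survival curve anchored at
  the 95/50/5 % longevity crossings, with multiplicative counting noise;
* dual-density buoyancy assays — binomial sink/float outcomes of larvae
  injected into a ladder of solutions of known density.

All generators are deterministic under a fixed seed: identical
parameters and seed give byte-identical frames and tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .buoyancy import DensityAssay
from .imaging import FrameStack

BEHAVIOR_LABELS = ("swimming", "free_fall", "settled", "crawling")
_KIND_TO_LABEL = {
    "swimmer": "swimming",
    "sinker": "free_fall",
    "settled": "settled",
    "crawler": "crawling",
}
_VALID_KINDS = tuple(_KIND_TO_LABEL)


@dataclass
class MotionModel:
    """Behavioural repertoire of one simulated larva.

    kind
        Base behaviour: ``sinker`` (passive free fall at a constant speed
        drawn from N(fall_speed_mean, fall_speed_sd), truncated at
        ``min_fall_speed``), ``swimmer`` (correlated random walk at
        ``swim_speed``), ``settled`` (motionless on the bottom) or
        ``crawler`` (horizontal random walk along the bottom).
    direction_persistence
        In [0, 1]; 1 keeps the heading forever (straight line), 0 draws a
        fresh heading every frame.  The per-step turning angle is
        N(0, (1 - persistence) * pi).
    bout_schedule
        Optional ``(start_s, end_s, kind)`` triples overriding the base
        behaviour inside non-overlapping windows of the recording.
    initial_xy_mm, heading0
        Optional fixed start position (image coordinates, y down) and
        initial heading in radians (0 = rightward, pi/2 = downward);
        drawn uniformly at random when omitted.
    axes_mm
        Optional per-larva (major, minor) ellipse axes in mm overriding
        the scene default; the major axis is rendered vertical.
    """

    kind: str
    fall_speed_mean: float = 0.0  # cm/s
    fall_speed_sd: float = 0.0  # cm/s
    swim_speed: float = 0.0  # cm/s
    direction_persistence: float = 0.8
    bout_schedule: tuple[tuple[float, float, str], ...] = ()
    initial_xy_mm: tuple[float, float] | None = None
    heading0: float | None = None
    axes_mm: tuple[float, float] | None = None
    min_fall_speed: float = 0.0  # cm/s, truncation floor for drawn speeds

    def __post_init__(self) -> None:
        if self.kind not in _VALID_KINDS:
            raise ValueError(f"unknown motion kind {self.kind!r}")
        if self.fall_speed_mean < 0 or self.fall_speed_sd < 0 or self.swim_speed < 0:
            raise ValueError("speeds must be non-negative")
        if not 0.0 <= self.direction_persistence <= 1.0:
            raise ValueError("direction_persistence must lie in [0, 1]")
        bouts = sorted(self.bout_schedule)
        for (s0, e0, k) in bouts:
            if e0 <= s0:
                raise ValueError("bout end must exceed bout start")
            if k not in _VALID_KINDS:
                raise ValueError(f"unknown bout kind {k!r}")
        for (_, e0, _), (s1, _, _) in zip(bouts, bouts[1:]):
            if s1 < e0:
                raise ValueError("bout intervals must not overlap")
        self.bout_schedule = tuple(bouts)

    def kind_at(self, t: float) -> str:
        for s0, e0, k in self.bout_schedule:
            if s0 <= t < e0:
                return k
        return self.kind


@dataclass
class SceneConfig:
    """Geometry, optics and timing of a simulated recording.

    Defaults follow the actography protocol: 25 frames per second, dark
    larvae (negative contrast) on a light background.  The container is
    assumed to fill the frame; ``container_height_cm`` defaults to the
    frame height.
    """

    width_px: int
    height_px: int
    pixel_scale: float  # mm/px
    duration_s: float
    fps: float = 25.0
    background_level: float = 200.0
    noise_sd: float = 2.0  # gray levels
    larva_axes: tuple[float, float] = (1.0, 0.5)  # (major, minor) mm
    larva_contrast: float = 120.0  # gray levels below background
    container_height_cm: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.width_px < 2 or self.height_px < 2:
            raise ValueError("frame must be at least 2x2 pixels")
        major, minor = self.larva_axes
        if major <= 0 or minor <= 0:
            raise ValueError("larva axes must be positive")
        if major > self.height_px * self.pixel_scale or minor > self.width_px * self.pixel_scale:
            raise ValueError("larva axes must fit inside the frame")
        if self.container_height_cm is None:
            self.container_height_cm = self.height_px * self.pixel_scale / 10.0

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))

    @property
    def width_mm(self) -> float:
        return self.width_px * self.pixel_scale

    @property
    def height_mm(self) -> float:
        return self.height_px * self.pixel_scale


@dataclass
class GroundTruth:
    """True per-larva trajectories and labels for a simulated stack.

    Arrays are (n_larvae, n_frames); positions are continuous (sub-pixel)
    mm in image coordinates.  ``labels`` holds integer codes into
    :data:`BEHAVIOR_LABELS`.
    """

    x_mm: np.ndarray
    y_mm: np.ndarray
    labels: np.ndarray
    timestamps: np.ndarray
    area_mm2: np.ndarray  # (n_larvae,) true projected ellipse area
    fall_speed_cm_s: np.ndarray  # (n_larvae,) NaN for non-sinkers

    @property
    def n_larvae(self) -> int:
        return self.x_mm.shape[0]

    def label_names(self, larva: int) -> list[str]:
        return [BEHAVIOR_LABELS[c] for c in self.labels[larva]]

    def to_dataframe(self) -> pd.DataFrame:
        n_l, n_f = self.x_mm.shape
        return pd.DataFrame(
            {
                "larva": np.repeat(np.arange(n_l), n_f),
                "frame": np.tile(np.arange(n_f), n_l),
                "time_s": np.tile(self.timestamps, n_l),
                "x_mm": self.x_mm.ravel(),
                "y_mm": self.y_mm.ravel(),
                "label": [BEHAVIOR_LABELS[c] for c in self.labels.ravel()],
            }
        )


def _paint_ellipse(
    frame: np.ndarray,
    x_mm: float,
    y_mm: float,
    semi_x_mm: float,
    semi_y_mm: float,
    scale: float,
    value: float,
) -> None:
    """Paint pixels whose centers fall inside the ellipse (no anti-aliasing)."""
    h, w = frame.shape
    r0 = max(int(math.floor((y_mm - semi_y_mm) / scale - 0.5)), 0)
    r1 = min(int(math.ceil((y_mm + semi_y_mm) / scale - 0.5)) + 1, h)
    c0 = max(int(math.floor((x_mm - semi_x_mm) / scale - 0.5)), 0)
    c1 = min(int(math.ceil((x_mm + semi_x_mm) / scale - 0.5)) + 1, w)
    if r1 <= r0 or c1 <= c0:
        return
    rows = (np.arange(r0, r1) + 0.5) * scale
    cols = (np.arange(c0, c1) + 0.5) * scale
    dy = (rows[:, None] - y_mm) / semi_y_mm
    dx = (cols[None, :] - x_mm) / semi_x_mm
    inside = dx * dx + dy * dy <= 1.0
    frame[r0:r1, c0:c1][inside] = value


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lo: float) -> float:
    if sd == 0:
        return max(mean, lo)
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v >= lo:
            return float(v)
    return lo


def generate_motility_frames(
    scene: SceneConfig, larvae: Sequence[MotionModel]
) -> tuple[FrameStack, GroundTruth]:
    """Simulate larval motion and render it into a calibrated frame stack.

    Each larva follows its motion model on a continuous (sub-pixel) 2-D
    plane; walls reflect movers, sinkers that reach the bottom settle
    there.  Frames are rendered by painting each larva as a filled
    ellipse (pixel-center inclusion) at intensity
    ``background_level - larva_contrast``, then adding Gaussian noise and
    quantising to uint8.

    Returns the stack and the per-frame ground truth (continuous
    positions, behaviour labels, true areas and fall speeds).
    """
    rng = np.random.default_rng(scene.seed)
    n_frames = scene.n_frames
    dt = 1.0 / scene.fps
    times = np.arange(n_frames) / scene.fps
    w_mm, h_mm = scene.width_mm, scene.height_mm

    for m in larvae:
        for s0, e0, _ in m.bout_schedule:
            if e0 > scene.duration_s:
                raise ValueError("bout schedule extends past the recording")

    n = len(larvae)
    x = np.zeros((n, n_frames))
    y = np.zeros((n, n_frames))
    labels = np.zeros((n, n_frames), dtype=np.int8)
    areas = np.zeros(n)
    fall_speeds = np.full(n, np.nan)

    states = []
    for i, m in enumerate(larvae):
        major, minor = m.axes_mm if m.axes_mm is not None else scene.larva_axes
        sx, sy = minor / 2.0, major / 2.0  # semi-axes, major vertical
        areas[i] = math.pi * sx * sy
        # one-pixel standoff keeps resting larvae off the frame border
        y_rest = h_mm - sy - scene.pixel_scale
        fall = np.nan
        if m.kind == "sinker" or any(k == "sinker" for _, _, k in m.bout_schedule):
            fall = _truncated_normal(rng, m.fall_speed_mean, m.fall_speed_sd,
                                     m.min_fall_speed)
            fall_speeds[i] = fall
        if m.initial_xy_mm is not None:
            px, py = m.initial_xy_mm
            if not (0 <= px <= w_mm and 0 <= py <= h_mm):
                raise ValueError(f"larva {i} initial position outside the frame")
        else:
            px = rng.uniform(sx, w_mm - sx)
            if m.kind in ("settled", "crawler"):
                py = y_rest
            else:
                py = rng.uniform(sy, min(0.6 * h_mm, h_mm - sy))
        if m.kind in ("settled", "crawler"):
            py = min(py, y_rest)
        heading = m.heading0 if m.heading0 is not None else rng.uniform(0, 2 * math.pi)
        crawl_dir = 1.0 if rng.uniform() < 0.5 else -1.0
        states.append(
            dict(px=px, py=py, heading=heading, crawl_dir=crawl_dir, fall=fall,
                 sx=sx, sy=sy, y_rest=y_rest, settled_now=False)
        )

    for f in range(n_frames):
        t = times[f]
        for i, m in enumerate(larvae):
            st = states[i]
            kind = m.kind_at(t)
            if kind == "sinker" and st["settled_now"]:
                kind = "settled"
            x[i, f], y[i, f] = st["px"], st["py"]
            labels[i, f] = BEHAVIOR_LABELS.index(_KIND_TO_LABEL[kind])
            # advance to the next frame
            if kind == "sinker":
                st["py"] += (st["fall"] * 10.0) * dt  # cm/s -> mm/s
                if st["py"] >= st["y_rest"]:
                    st["py"] = st["y_rest"]
                    st["settled_now"] = True
            elif kind == "swimmer":
                turn_sd = (1.0 - m.direction_persistence) * math.pi
                if turn_sd > 0:
                    st["heading"] += rng.normal(0.0, turn_sd)
                step = (m.swim_speed * 10.0) * dt
                nx = st["px"] + step * math.cos(st["heading"])
                ny = st["py"] + step * math.sin(st["heading"])
                if nx < st["sx"] or nx > w_mm - st["sx"]:
                    st["heading"] = math.pi - st["heading"]
                    nx = min(max(nx, st["sx"]), w_mm - st["sx"])
                if ny < st["sy"] or ny > st["y_rest"]:
                    st["heading"] = -st["heading"]
                    ny = min(max(ny, st["sy"]), st["y_rest"])
                st["px"], st["py"] = nx, ny
            elif kind == "crawler":
                if rng.uniform() < (1.0 - m.direction_persistence) / 2.0:
                    st["crawl_dir"] *= -1.0
                nx = st["px"] + st["crawl_dir"] * (m.swim_speed * 10.0) * dt
                if nx < st["sx"] or nx > w_mm - st["sx"]:
                    st["crawl_dir"] *= -1.0
                    nx = min(max(nx, st["sx"]), w_mm - st["sx"])
                st["px"] = nx
                st["py"] = st["y_rest"]
            # settled: stays put

    value = max(scene.background_level - scene.larva_contrast, 0.0)
    frames = np.empty((n_frames, scene.height_px, scene.width_px), dtype=np.uint8)
    for f in range(n_frames):
        img = np.full((scene.height_px, scene.width_px), scene.background_level,
                      dtype=float)
        for i in range(n):
            st = states[i]
            _paint_ellipse(img, x[i, f], y[i, f], st["sx"], st["sy"],
                           scene.pixel_scale, value)
        if scene.noise_sd > 0:
            img += rng.normal(0.0, scene.noise_sd, img.shape)
        frames[f] = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    stack = FrameStack(
        frames=frames,
        timestamps=times,
        pixel_scale=scene.pixel_scale,
        metadata={
            "fps": scene.fps,
            "container_height_cm": scene.container_height_cm,
            "seed": scene.seed,
        },
    )
    truth = GroundTruth(
        x_mm=x, y_mm=y, labels=labels, timestamps=times,
        area_mm2=areas, fall_speed_cm_s=fall_speeds,
    )
    return stack, truth


def survival_curve(
    t: np.ndarray | float, t95: float, t50: float, t5: float
) -> np.ndarray:
    """Survival (%) at age ``t`` for a curve anchored at the longevity crossings.

    Piecewise-linear through (0, 100), (t95, 95), (t50, 50), (t5, 5) and
    declining to zero by continuing the t50 -> t5 slope past t5.
    """
    if not (0 < t95 <= t50 <= t5):
        raise ValueError("longevity anchors must satisfy 0 < t95 <= t50 <= t5")
    t_zero = t5 + (t5 - t50) * (5.0 / 45.0) if t5 > t50 else t5 + 1e-9
    xs = [0.0, t95, t50, t5, t_zero]
    ys = [100.0, 95.0, 50.0, 5.0, 0.0]
    return np.interp(np.asarray(t, dtype=float), xs, ys)


def generate_survival_counts(
    n_initial: int,
    t95: float,
    t50: float,
    t5: float,
    meta_onset: float = 20.0,
    meta_rate: float = 0.0,
    sample_every: float = 2.0,
    n_replicates: int = 3,
    count_noise: float = 0.03,
    duration: float | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate healthy-larva / polyp count sheets for replicate containers.

    Larval survivors follow :func:`survival_curve`; after ``meta_onset``
    each surviving larva metamorphoses with hazard ``meta_rate`` per day
    (binomial increments between sampling days), and polyps persist.
    Observed counts at ages > 0 get multiplicative Gaussian counting
    noise of relative SD ``count_noise`` (default 3 %, the precision of
    repeated manual counts); the age-0 count is exact because containers
    are seeded by counting.

    Returns a tidy table with columns ``replicate, age_days, n_initial,
    n_healthy, n_polyps`` (polyp counts cumulative).
    """
    if not 0.0 <= count_noise < 1.0:
        raise ValueError("count_noise must lie in [0, 1)")
    if n_initial <= 0 or n_replicates < 1 or sample_every <= 0:
        raise ValueError("n_initial, n_replicates and sample_every must be positive")
    rng = np.random.default_rng(seed)
    if duration is None:
        t_zero = t5 + (t5 - t50) * (5.0 / 45.0) if t5 > t50 else t5
        duration = math.ceil(t_zero / sample_every) * sample_every
    ages = np.arange(0.0, duration + 1e-9, sample_every)
    _ = survival_curve(0.0, t95, t50, t5)  # validates anchors

    rows = []
    for rep in range(1, n_replicates + 1):
        m_cum = 0
        prev_age = 0.0
        for age in ages:
            survivors = int(round(survival_curve(age, t95, t50, t5) / 100.0 * n_initial))
            if meta_rate > 0 and age > meta_onset:
                at_risk = max(survivors - m_cum, 0)
                window = min(age, duration) - max(prev_age, meta_onset)
                if window > 0 and at_risk > 0:
                    p = 1.0 - math.exp(-meta_rate * window)
                    m_cum += int(rng.binomial(at_risk, p))
            healthy = max(survivors - m_cum, 0)
            obs_h, obs_p = healthy, m_cum
            if count_noise > 0 and age > 0:
                obs_h = int(round(healthy * (1.0 + rng.normal(0.0, count_noise))))
                obs_h = min(max(obs_h, 0), n_initial)
                if m_cum > 0:
                    obs_p = int(round(m_cum * (1.0 + rng.normal(0.0, count_noise))))
                    obs_p = min(max(obs_p, 0), n_initial)
            rows.append((rep, float(age), n_initial, obs_h, obs_p))
            prev_age = age
    return pd.DataFrame(
        rows, columns=["replicate", "age_days", "n_initial", "n_healthy", "n_polyps"]
    )


def generate_density_assay(
    q20: float,
    q80: float,
    gradient_densities: Sequence[float],
    n_per_tube: int = 20,
    day: float = 0.0,
    salinity_psu: float = 38.0,
    temperature_c: float = 20.0,
    seed: int = 0,
) -> DensityAssay:
    """Simulate sink/float outcomes across a density-gradient tube series.

    Larval body density is uniform between the bounds implied by the
    requested 20 % and 80 % quantiles (a point mass when they coincide).
    Each tube receives ``n_per_tube`` independent larvae; the sunk count
    is binomial with success probability P(body density > tube density).
    """
    dens = np.asarray(gradient_densities, dtype=float)
    if dens.ndim != 1 or len(dens) < 1:
        raise ValueError("at least one gradient density required")
    if np.any(np.diff(dens) <= 0):
        raise ValueError("gradient densities must be strictly increasing")
    if q20 > q80:
        raise ValueError("q20 must not exceed q80")
    if n_per_tube < 1:
        raise ValueError("n_per_tube must be at least 1")
    rng = np.random.default_rng(seed)
    if q80 > q20:
        width = (q80 - q20) / 0.6
        lo = q20 - 0.2 * width
        p_sink = np.clip((lo + width - dens) / width, 0.0, 1.0)
    else:
        p_sink = (q20 > dens).astype(float)
    n_sunk = rng.binomial(n_per_tube, p_sink)
    return DensityAssay(
        day=day,
        densities=dens,
        n_sunk=np.asarray(n_sunk, dtype=int),
        n_total=np.full(len(dens), n_per_tube, dtype=int),
        salinity_psu=salinity_psu,
        temperature_c=temperature_c,
    )
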