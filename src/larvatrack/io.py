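"""Reading and writing the pipeline's on-disk formats.

Frame stacks travel as multi-page TIFF or directories of zero-padded
PNGs; detections, tracks, behaviour segments, count sheets and density
assays as tidy CSV; scene/motion configurations as YAML.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .buoyancy import DensityAssay
from .imaging import Detection, FrameStack
from .synthetic import GroundTruth, MotionModel, SceneConfig
from .tracking import Track


def write_frames(stack: FrameStack, path: str | Path) -> None:
    """Write a stack as multi-page TIFF (``.tif``) or a PNG directory."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, stack.frames)
    else:
        path.mkdir(parents=True, exist_ok=True)
        width = max(4, len(str(len(stack) - 1)))
        for i, frame in enumerate(stack.frames):
            iio.imwrite(path / f"frame_{i:0{width}d}.png", frame)


def read_frames(
    path: str | Path, pixel_scale: float, fps: float, **metadata
) -> FrameStack:
    """Read a TIFF stack or a directory of numbered PNG/TIFF frames."""
    path = Path(path)
    if path.is_dir():
        files = sorted(
            (p for p in path.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff")),
            key=lambda p: [int(s) if s.isdigit() else s
                           for s in re.split(r"(\d+)", p.name)],
        )
        if not files:
            raise ValueError(f"no image frames found in {path}")
        frames = np.stack([iio.imread(p) for p in files])
    else:
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
    times = np.arange(len(frames)) / fps
    metadata.setdefault("fps", fps)
    return FrameStack(frames=frames, timestamps=times, pixel_scale=pixel_scale,
                      metadata=metadata)


def detections_to_dataframe(detections: Sequence[Detection]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (d.frame_index, d.time, d.x_mm, d.y_mm, d.area_mm2, d.label)
            for d in detections
        ],
        columns=["frame", "time_s", "x_mm", "y_mm", "area_mm2", "label"],
    )


def dataframe_to_detections(df: pd.DataFrame) -> list[Detection]:
    return [
        Detection(
            frame_index=int(r.frame),
            time=float(r.time_s),
            x_mm=float(r.x_mm),
            y_mm=float(r.y_mm),
            area_mm2=float(r.area_mm2),
            bbox_px=(0, 0, 0, 0),
            label=int(getattr(r, "label", 0)),
        )
        for r in df.itertuples(index=False)
    ]


def dataframe_to_tracks(df: pd.DataFrame) -> list[Track]:
    tracks = []
    for tid, grp in df.sort_values(["track_id", "frame"]).groupby("track_id"):
        tracks.append(
            Track(
                track_id=int(tid),
                frames=grp["frame"].to_numpy(dtype=int),
                times=grp["time_s"].to_numpy(dtype=float),
                x_mm=grp["x_mm"].to_numpy(dtype=float),
                y_mm=grp["y_mm"].to_numpy(dtype=float),
                area_mm2=grp["area_mm2"].to_numpy(dtype=float)
                if "area_mm2" in grp
                else np.zeros(len(grp)),
            )
        )
    return tracks


def ground_truth_to_csv(truth: GroundTruth, path: str | Path) -> None:
    truth.to_dataframe().to_csv(path, index=False)


def read_density_assays(path: str | Path) -> list[DensityAssay]:
    """Read assays from CSV with columns day, tube_density_kgm3, n_sunk, n_total."""
    df = pd.read_csv(path)
    assays = []
    for day, grp in df.groupby("day"):
        grp = grp.sort_values("tube_density_kgm3")
        assays.append(
            DensityAssay(
                day=float(day),
                densities=grp["tube_density_kgm3"].to_numpy(dtype=float),
                n_sunk=grp["n_sunk"].to_numpy(dtype=int),
                n_total=grp["n_total"].to_numpy(dtype=int),
            )
        )
    return assays


def load_scene_config(path: str | Path) -> tuple[SceneConfig, list[MotionModel]]:
    """Load a simulation configuration (scene + larvae) from YAML.

    Top-level keys: ``scene`` (SceneConfig fields) and ``larvae`` (list
    of MotionModel fields; tuple-valued fields accept YAML lists).
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    scene_cfg = dict(cfg.get("scene", {}))
    if "larva_axes" in scene_cfg:
        scene_cfg["larva_axes"] = tuple(scene_cfg["larva_axes"])
    scene = SceneConfig(**scene_cfg)
    larvae = []
    for entry in cfg.get("larvae", []):
        entry = dict(entry)
        n = int(entry.pop("count", 1))
        for key in ("initial_xy_mm", "axes_mm"):
            if entry.get(key) is not None:
                entry[key] = tuple(entry[key])
        if entry.get("bout_schedule"):
            entry["bout_schedule"] = tuple(
                (float(s), float(e), str(k)) for s, e, k in entry["bout_schedule"]
            )
        larvae.extend(MotionModel(**entry) for _ in range(n))
    return scene, larvae
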