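"""Segmentation and planar-morphometry of larvae in calibrated frame stacks.

Larvae are imaged as dark (by default) elliptical blobs on a light
background.  The measurement chain is: percentile contrast stretching ->
thresholding (Otsu or fixed) -> connected-component labelling -> area /
centroid extraction in millimetre units via the pixel calibration.

Coordinate convention: image origin at the top-left corner, x to the
right, y downward (raster order), so a positive vertical velocity means
sinking.  The centre of pixel (row r, col c) sits at physical position
``((c + 0.5) * pixel_scale, (r + 0.5) * pixel_scale)`` in mm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage import measure


@dataclass
class FrameStack:
    """A calibrated grayscale image sequence.

    Parameters
    ----------
    frames : (n_frames, height, width) array
        Gray-level frames, all the same shape.
    timestamps : (n_frames,) array of float
        Acquisition times in seconds, strictly increasing.
    pixel_scale : float
        Physical size of one pixel in mm/px (> 0).
    metadata : dict
        Free-form acquisition metadata (fps, container geometry, ...).
    """

    frames: np.ndarray
    timestamps: np.ndarray
    pixel_scale: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, height, width) array")
        if len(self.timestamps) != len(self.frames):
            raise ValueError("one timestamp per frame required")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if not self.pixel_scale > 0:
            raise ValueError("pixel_scale must be positive")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of each frame in pixels."""
        return self.frames.shape[1:]

    @property
    def height_mm(self) -> float:
        return self.frames.shape[1] * self.pixel_scale

    @property
    def width_mm(self) -> float:
        return self.frames.shape[2] * self.pixel_scale


@dataclass
class Detection:
    """A single segmented larva in one frame.

    Centroid is in mm (image coordinates, y down); area in mm^2.
    ``label`` is the per-frame connected-component label.
    """

    frame_index: int
    time: float
    x_mm: float
    y_mm: float
    area_mm2: float
    bbox_px: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col)
    label: int

    @property
    def centroid(self) -> tuple[float, float]:
        return (self.x_mm, self.y_mm)


def preprocess_contrast(
    frame: np.ndarray, p_low: float = 1.0, p_high: float = 99.0
) -> np.ndarray:
    """Linearly stretch frame intensities between two percentiles.

    Intensities at or below the ``p_low`` percentile map to 0 and at or
    above the ``p_high`` percentile to 255; the mapping is linear in
    between.  Invariant to an additive offset of the whole frame.  When
    the two percentiles coincide (e.g. a small blob on a dominant uniform
    background) the full min/max range is used instead; a constant frame
    is returned unchanged with a warning.

    Returns a float array in [0, 255].
    """
    frame = np.asarray(frame, dtype=float)
    lo, hi = np.percentile(frame, [p_low, p_high])
    if hi == lo:
        lo, hi = frame.min(), frame.max()
    if hi == lo:
        warnings.warn("constant frame: contrast stretch is a no-op", stacklevel=2)
        return frame.copy()
    out = (frame - lo) * (255.0 / (hi - lo))
    return np.clip(out, 0.0, 255.0)


def binarize(
    frame: np.ndarray,
    method: str = "otsu",
    threshold: float | None = None,
    dark_foreground: bool = True,
) -> np.ndarray:
    """Threshold a (preprocessed) frame into a boolean larva mask.

    With ``dark_foreground`` (the default) pixels strictly below the
    threshold are foreground; with light-on-dark polarity, pixels
    strictly above it.  ``method="otsu"`` picks the threshold from the
    gray-level histogram; ``method="fixed"`` uses the supplied value.
    A constant frame yields an empty mask.
    """
    frame = np.asarray(frame, dtype=float)
    if method == "fixed":
        if threshold is None:
            raise ValueError("method 'fixed' requires a threshold value")
        thr = float(threshold)
    elif method == "otsu":
        if frame.min() == frame.max():
            return np.zeros(frame.shape, dtype=bool)
        # Otsu on the empirical histogram; 256 bins suit 8-bit-like data.
        from skimage.filters import threshold_otsu

        thr = threshold_otsu(frame, nbins=256)
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return (frame < thr) if dark_foreground else (frame > thr)


def detect_objects(
    mask: np.ndarray,
    pixel_scale: float,
    frame_index: int = 0,
    time: float = 0.0,
    min_area_px: int = 3,
    max_area_px: int | None = None,
    exclude_border: bool = True,
) -> list[Detection]:
    """Extract larva detections from a binary mask.

    Connected components (8-connectivity) with pixel area inside
    ``[min_area_px, max_area_px]`` become detections; components touching
    the frame border are dropped when ``exclude_border`` because partial
    larvae bias the area measurement.  Centroids and areas are converted
    to mm via ``pixel_scale``.  An empty list is a valid result.
    """
    if not pixel_scale > 0:
        raise ValueError("pixel_scale must be positive")
    labels = measure.label(np.asarray(mask, dtype=bool), connectivity=2)
    h, w = labels.shape
    # drop sub-minimum components before regionprops; noisy frames can
    # speckle into thousands of 1-2 px islands
    if labels.max() > 0 and min_area_px > 1:
        sizes = np.bincount(labels.ravel())
        small = np.flatnonzero(sizes < min_area_px)
        if len(small) > 0:
            labels[np.isin(labels, small)] = 0
    out: list[Detection] = []
    for region in measure.regionprops(labels):
        if region.area < min_area_px:
            continue
        if max_area_px is not None and region.area > max_area_px:
            continue
        minr, minc, maxr, maxc = region.bbox
        if exclude_border and (minr == 0 or minc == 0 or maxr == h or maxc == w):
            continue
        r, c = region.centroid
        out.append(
            Detection(
                frame_index=frame_index,
                time=time,
                x_mm=(c + 0.5) * pixel_scale,
                y_mm=(r + 0.5) * pixel_scale,
                area_mm2=region.area * pixel_scale**2,
                bbox_px=(minr, minc, maxr, maxc),
                label=region.label,
            )
        )
    return out


def segment_stack(
    stack: FrameStack,
    method: str = "otsu",
    threshold: float | None = None,
    dark_foreground: bool = True,
    p_low: float = 0.0,
    p_high: float = 100.0,
    min_area_px: int = 3,
    max_area_px: int | None = None,
    exclude_border: bool = True,
    stretch: bool = True,
) -> list[Detection]:
    """Run the full segmentation chain on every frame of a stack.

    The default stretch uses the full min/max range: an affine rescale
    leaves Otsu's partition unchanged, whereas inner-percentile clipping
    can merge the (small) larva population with the clipped tail of the
    background noise when larvae cover less than ``p_low`` percent of
    the frame.  Tighter percentiles remain available for stacks with
    gross outlier pixels.

    Returns all detections ordered by frame.
    """
    detections: list[Detection] = []
    for i, frame in enumerate(stack.frames):
        f = preprocess_contrast(frame, p_low, p_high) if stretch else frame
        mask = binarize(f, method=method, threshold=threshold,
                        dark_foreground=dark_foreground)
        detections.extend(
            detect_objects(
                mask,
                stack.pixel_scale,
                frame_index=i,
                time=float(stack.timestamps[i]),
                min_area_px=min_area_px,
                max_area_px=max_area_px,
                exclude_border=exclude_border,
            )
        )
    return detections


def measure_surface_area(
    detections: Sequence[Detection],
) -> tuple[float, float, np.ndarray]:
    """Projected planar surface area of one larva imaged repeatedly.

    The trait is the maximum projected planar area per photograph; when a
    frame contains several components (e.g. debris below the area filter
    slipped through), the largest is taken as the larva.  Returns
    ``(mean, sd, per_frame_areas)`` in mm^2; sd is NaN for a single frame.
    """
    if len(detections) == 0:
        raise ValueError("surface area requires at least one detection")
    per_frame: dict[int, float] = {}
    for det in detections:
        cur = per_frame.get(det.frame_index, 0.0)
        per_frame[det.frame_index] = max(cur, det.area_mm2)
    areas = np.array([per_frame[k] for k in sorted(per_frame)])
    mean = float(areas.mean())
    sd = float(areas.std(ddof=1)) if len(areas) > 1 else float("nan")
    return mean, sd, areas
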