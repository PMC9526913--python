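"""Phase-contrast cell segmentation.

A raw phase-contrast frame is converted into a labelled mask of individual
cell regions by an eight-step pipeline:

1. background adjustment (subtract a large-window local-median background),
2. texture enhancement (local standard-deviation filter; adherent cells
   carry strong local intensity texture, the background is smooth),
3. binarization (Otsu threshold on the enhanced image, plus an offset),
4. removal of small objects,
5. binary erosion,
6. removal of small objects (again, after erosion),
7. hole filling,
8. removal of frame-touching objects.

Steps 4 and 6 share one default area threshold but are independently
configurable. Touching cells are deliberately not split (no watershed):
the downstream population statistics are computed over whatever regions
the pipeline yields, and keeping the pipeline minimal keeps it auditable.

All operations are deterministic; connectivity is 8-neighbour throughout
and the frame border is the outermost one-pixel ring.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology, transform
from skimage.filters import threshold_otsu

logger = logging.getLogger(__name__)

TIME_STEP_H = 6.0
#: default micrometres per pixel: one tiled frame covers 16 mm^2 / 64 tiles
#: = 0.25 mm^2 at 1000x1000 px, i.e. 0.5 um/px.
DEFAULT_PIXEL_SIZE_UM = 0.5


@dataclass
class ImageFrame:
    """One field of view: a grayscale intensity grid plus acquisition metadata.

    Parameters
    ----------
    intensity : ndarray, shape (H, W)
        Grayscale intensities (any numeric dtype; converted to float64).
    clone_id : str
        Clone lot identifier.
    fov_index : int
        0-based field-of-view index within the well.
    time_h : float
        Hours post-seeding; must sit on the 6-h acquisition grid.
    pixel_size : float
        Micrometres per pixel.
    """

    intensity: np.ndarray
    clone_id: str = "clone"
    fov_index: int = 0
    time_h: float = 6.0
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensity, dtype=np.float64)
        if arr.ndim != 2:
            raise ValueError(f"intensity must be 2-D, got shape {arr.shape}")
        if arr.shape[0] < 64 or arr.shape[1] < 64:
            raise ValueError(f"frame must be at least 64x64, got {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("intensity contains non-finite values")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        rem = float(self.time_h) % TIME_STEP_H
        if min(rem, TIME_STEP_H - rem) > 1e-9 or self.time_h <= 0:
            raise ValueError(
                f"time_h={self.time_h} is not a positive multiple of "
                f"{TIME_STEP_H} h"
            )
        self.intensity = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape


@dataclass
class LabelMask:
    """Integer label grid: 0 = background, 1..n = individual cell regions.

    Labels are kept consecutive (1..n) by every operation that can remove
    regions. ``source`` records provenance back to the segmented frame.
    """

    labels: np.ndarray
    source: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError("labels must be 2-D")
        if not np.issubdtype(lab.dtype, np.integer):
            if not np.array_equal(lab, lab.astype(np.int64)):
                raise ValueError("labels must be integer-valued")
            lab = lab.astype(np.int64)
        if lab.min() < 0:
            raise ValueError("labels must be non-negative")
        self.labels = lab.astype(np.int32, copy=False)

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def areas_px(self) -> np.ndarray:
        """Pixel area of each label, index i -> label i+1."""
        return np.bincount(self.labels.ravel(), minlength=self.n_labels + 1)[1:]


@dataclass
class SegmentationParams:
    """Tunable parameters of the eight-step pipeline.

    ``background_window_px`` is the side of the local-median window used
    for background estimation (large relative to a cell). The median is
    computed on a grid block-averaged by ``background_downsample`` and
    resampled back, which is the standard practical form for windows of
    this size. ``texture_window_px`` is the local-SD filter window.
    ``min_object_area_px`` / ``min_object_area_px_post`` are the two
    small-object thresholds (steps 4 and 6); they default equal because
    no separate published values exist.
    """

    background_window_px: int = 101
    background_downsample: int = 4
    texture_window_px: int = 7
    threshold_method: str = "otsu"
    threshold_offset: float = 0.0
    min_object_area_px: int = 64
    min_object_area_px_post: int | None = None
    erosion_radius_px: int = 1

    def __post_init__(self) -> None:
        for name in ("background_window_px", "background_downsample",
                     "texture_window_px", "erosion_radius_px"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.min_object_area_px < 1:
            raise ValueError("min_object_area_px must be >= 1")
        if self.min_object_area_px_post is None:
            self.min_object_area_px_post = self.min_object_area_px
        if self.min_object_area_px_post < 1:
            raise ValueError("min_object_area_px_post must be >= 1")
        if self.threshold_method not in ("otsu",):
            raise ValueError(f"unknown threshold method {self.threshold_method!r}")


def _relabel(binary_or_labels: np.ndarray) -> np.ndarray:
    """Consecutive 8-connected labelling of the foreground."""
    return measure.label(binary_or_labels > 0, connectivity=2).astype(np.int32)


def _binary_remove_small(binary: np.ndarray, min_area_px: int) -> np.ndarray:
    """Drop 8-connected foreground components below ``min_area_px``."""
    lab = _relabel(binary)
    if lab.max() == 0:
        return lab > 0
    areas = np.bincount(lab.ravel())
    small = np.nonzero(areas < min_area_px)[0]
    small = small[small > 0]
    out = binary.copy()
    if small.size:
        out[np.isin(lab, small)] = False
    return out


def estimate_background(intensity: np.ndarray, window_px: int,
                        downsample: int = 4) -> np.ndarray:
    """Local-median background surface at an effective ``window_px`` scale."""
    if downsample > 1:
        small = transform.downscale_local_mean(intensity, (downsample, downsample))
        win = max(3, int(round(window_px / downsample)) | 1)
        bg_small = ndi.median_filter(small, size=win, mode="reflect")
        bg = transform.resize(bg_small, intensity.shape, order=1, mode="edge",
                              anti_aliasing=False)
    else:
        win = max(3, window_px | 1)
        bg = ndi.median_filter(intensity, size=win, mode="reflect")
    return bg


def local_sd(intensity: np.ndarray, window_px: int) -> np.ndarray:
    """Local standard deviation in a square window (texture enhancement)."""
    win = max(3, window_px | 1)
    mean = ndi.uniform_filter(intensity, size=win, mode="reflect")
    mean_sq = ndi.uniform_filter(intensity * intensity, size=win, mode="reflect")
    var = np.maximum(mean_sq - mean * mean, 0.0)
    return np.sqrt(var)


def remove_small_objects(mask: LabelMask | np.ndarray,
                         min_area_px: int) -> LabelMask:
    """Drop every connected region smaller than ``min_area_px`` pixels.

    Surviving regions are relabelled consecutively 1..n.
    """
    if min_area_px < 1:
        raise ValueError("min_area_px must be >= 1")
    mask = _as_mask(mask)
    areas = mask.areas_px()
    keep = mask.labels.copy()
    drop = np.nonzero(areas < min_area_px)[0] + 1
    if drop.size:
        keep[np.isin(mask.labels, drop)] = 0
    return LabelMask(_relabel(keep), source=dict(mask.source))


def fill_holes(mask: LabelMask | np.ndarray) -> LabelMask:
    """Fill background holes fully enclosed by a single labelled region."""
    mask = _as_mask(mask)
    out = mask.labels.copy()
    objects = ndi.find_objects(mask.labels)
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        region = mask.labels[sl] == lab
        filled = ndi.binary_fill_holes(region)
        add = filled & ~region
        # only claim pixels that are background, never another label
        add &= mask.labels[sl] == 0
        out[sl][add] = lab
    return LabelMask(out, source=dict(mask.source))


def remove_border_touching(mask: LabelMask | np.ndarray) -> LabelMask:
    """Remove every region with a pixel on the outermost 1-px frame ring."""
    mask = _as_mask(mask)
    lab = mask.labels
    border = np.unique(np.concatenate([
        lab[0, :], lab[-1, :], lab[:, 0], lab[:, -1]]))
    border = border[border > 0]
    keep = lab.copy()
    if border.size:
        keep[np.isin(lab, border)] = 0
    return LabelMask(_relabel(keep), source=dict(mask.source))


def _as_mask(mask: LabelMask | np.ndarray) -> LabelMask:
    return mask if isinstance(mask, LabelMask) else LabelMask(np.asarray(mask))


class FrameSegmenter:
    """Eight-step phase-contrast segmentation pipeline.

    sklearn-style parameter handling (``get_params`` / ``set_params``);
    ``segment`` (alias ``transform``) maps an :class:`ImageFrame` to a
    :class:`LabelMask`. The pipeline has no random state.
    """

    def __init__(self, params: SegmentationParams | None = None, **overrides):
        base = params if params is not None else SegmentationParams()
        if overrides:
            base = replace(base, **overrides)
        self.params = base

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self.params, k) for k in vars(self.params)}

    def set_params(self, **kwargs) -> "FrameSegmenter":
        self.params = replace(self.params, **kwargs)
        return self

    def segment(self, frame: ImageFrame) -> LabelMask:
        p = self.params
        img = frame.intensity

        # (1) background adjustment
        flat = img - estimate_background(img, p.background_window_px,
                                         p.background_downsample)
        # (2) texture enhancement
        enhanced = local_sd(flat, p.texture_window_px)
        # (3) binarization
        if np.allclose(enhanced.max(), enhanced.min()):
            warnings.warn(
                f"degenerate frame (constant enhanced intensity) for clone "
                f"{frame.clone_id} fov {frame.fov_index} t={frame.time_h} h; "
                "returning empty mask", stacklevel=2)
            return LabelMask(np.zeros(frame.shape, dtype=np.int32),
                             source=self._provenance(frame))
        thr = threshold_otsu(enhanced) + p.threshold_offset
        binary = enhanced > thr
        # (4) removal of small objects
        binary = _binary_remove_small(binary, p.min_object_area_px)
        # (5) erosion; border_value=1 keeps frame-edge objects attached to
        # the border so step 8 still recognises and removes them
        if p.erosion_radius_px > 0:
            binary = ndi.binary_erosion(
                binary, structure=morphology.disk(p.erosion_radius_px),
                border_value=1)
        # (6) removal of small objects
        binary = _binary_remove_small(binary, p.min_object_area_px_post)
        # (7) fill holes
        binary = ndi.binary_fill_holes(binary)
        # (8) removal of frame-touching objects
        mask = remove_border_touching(LabelMask(_relabel(binary)))
        mask.source = self._provenance(frame)
        logger.info("segmented clone=%s fov=%d t=%gh: %d objects",
                    frame.clone_id, frame.fov_index, frame.time_h, mask.n_labels)
        return mask

    # transformer alias so the segmenter composes with pipeline-style code
    def transform(self, frames: Sequence[ImageFrame] | ImageFrame):
        if isinstance(frames, ImageFrame):
            return self.segment(frames)
        return [self.segment(f) for f in frames]

    @staticmethod
    def _provenance(frame: ImageFrame) -> dict:
        return {"clone_id": frame.clone_id, "fov_index": frame.fov_index,
                "time_h": frame.time_h, "pixel_size": frame.pixel_size}


def segment_frame(frame: ImageFrame,
                  params: SegmentationParams | None = None) -> LabelMask:
    """Run the eight-step pipeline on one frame (functional form)."""
    return FrameSegmenter(params).segment(frame)
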