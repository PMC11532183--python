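"""Tissue detection and Sirius-Red collagen segmentation.

The segmentation works in optical-density (OD) space: per-channel
``OD = -log10(I/255)`` linearizes stain concentration, and projecting the
OD vector of each pixel onto a unit Sirius-Red stain vector yields a scalar
"SR optical density" that is high on red collagen and low on the pale
counterstain.  Collagen is then the set of tissue pixels whose SR-projected
OD exceeds a threshold (Otsu over tissue pixels by default).

Conventions: arrays are row-major with origin at the top-left; all masks
share the image's (H, W) shape.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Union

import numpy as np
from skimage.filters import threshold_otsu
from skimage.morphology import closing, disk, remove_small_objects

from fibroquant.synth import COLLAGEN_RGB, PARENCHYMA_RGB

__all__ = [
    "SlideImage",
    "SegmentationParams",
    "CollagenSegmentation",
    "detect_tissue",
    "compute_sr_od",
    "segment_collagen",
    "default_stain_vectors",
]

StainVectors = Union[Literal["auto"], tuple[np.ndarray, np.ndarray]]


@dataclass
class SlideImage:
    """An RGB slide plus its digitization metadata (µm per pixel)."""

    pixels: np.ndarray  # (H, W, 3) uint8
    um_per_px: float = 0.25
    slide_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("pixels must be an (H, W, 3) RGB array")
        if px.dtype != np.uint8:
            raise ValueError("pixels must be 8-bit per channel (uint8)")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")
        self.pixels = px


def _od_vector(rgb: tuple[int, int, int]) -> np.ndarray:
    v = -np.log10(np.maximum(np.asarray(rgb, dtype=float), 1.0) / 255.0)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("stain color must not be pure white")
    return v / n


def default_stain_vectors() -> tuple[np.ndarray, np.ndarray]:
    """Unit OD-space vectors of the SR-red stain and the pale counterstain,
    fit to the synthetic palette; real slides should supply measured
    vectors."""
    return _od_vector(COLLAGEN_RGB), _od_vector(PARENCHYMA_RGB)


@dataclass
class SegmentationParams:
    """Tunable segmentation parameters.

    background_brightness_threshold / background_saturation_threshold:
        a pixel is background when its HSV value exceeds the brightness
        threshold AND its saturation is below the saturation threshold
        (near-white scanner background).
    stain_vectors:
        "auto" (default palette vectors) or an explicit (sr_red, counterstain)
        pair of non-collinear 3-vectors in OD space.
    od_threshold:
        explicit SR-OD cutoff, or "otsu" for Otsu over tissue-pixel OD.
    """

    background_brightness_threshold: float = 220.0
    background_saturation_threshold: float = 0.08
    stain_vectors: StainVectors = "auto"
    od_threshold: Union[float, Literal["otsu"]] = "otsu"
    min_object_px: int = 10
    closing_radius_px: int = 1

    def __post_init__(self) -> None:
        if not (0 <= self.background_brightness_threshold <= 255):
            raise ValueError("background_brightness_threshold must be in 0-255")
        if not (0.0 <= self.background_saturation_threshold <= 1.0):
            raise ValueError("background_saturation_threshold must be in [0, 1]")
        if self.min_object_px < 0 or self.closing_radius_px < 0:
            raise ValueError("min_object_px and closing_radius_px must be >= 0")
        if self.stain_vectors != "auto":
            sr, counter = (np.asarray(v, dtype=float) for v in self.stain_vectors)
            if sr.shape != (3,) or counter.shape != (3,):
                raise ValueError("stain vectors must be 3-vectors")
            cosang = abs(np.dot(sr, counter) / (np.linalg.norm(sr) * np.linalg.norm(counter)))
            if cosang > 1 - 1e-6:
                raise ValueError("stain vectors must not be collinear")
        if self.od_threshold != "otsu" and float(self.od_threshold) <= 0:
            raise ValueError("od_threshold must be positive or 'otsu'")

    def resolved_sr_vector(self) -> np.ndarray:
        if self.stain_vectors == "auto":
            return default_stain_vectors()[0]
        v = np.asarray(self.stain_vectors[0], dtype=float)
        return v / np.linalg.norm(v)


@dataclass
class CollagenSegmentation:
    """Masks and per-pixel SR optical density produced by segmentation."""

    tissue_mask: np.ndarray
    collagen_mask: np.ndarray
    sr_od: np.ndarray
    params_used: SegmentationParams = field(default_factory=SegmentationParams)

    def __post_init__(self) -> None:
        if self.collagen_mask.shape != self.tissue_mask.shape:
            raise ValueError("masks must share shape")
        if np.any(self.collagen_mask & ~self.tissue_mask):
            raise ValueError("collagen mask must be contained in tissue mask")


def detect_tissue(image: SlideImage, params: SegmentationParams | None = None) -> np.ndarray:
    """Boolean tissue mask: everything that is not bright, unsaturated
    background, morphologically closed and cleaned of small specks."""
    params = params or SegmentationParams()
    px = image.pixels.astype(np.float64)
    value = px.max(axis=2)
    spread = value - px.min(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        saturation = np.where(value > 0, spread / np.maximum(value, 1e-12), 0.0)
    background = (value > params.background_brightness_threshold) & (
        saturation < params.background_saturation_threshold
    )
    mask = ~background
    if not mask.any():
        warnings.warn("image is entirely background; tissue mask is empty", stacklevel=2)
        return mask
    if params.closing_radius_px > 0:
        mask = closing(mask, disk(params.closing_radius_px))
    if params.min_object_px > 0:
        # removes components strictly smaller than min_object_px
        mask = remove_small_objects(mask, max_size=params.min_object_px - 1)
    return mask


def compute_sr_od(image: SlideImage, params: SegmentationParams | None = None) -> np.ndarray:
    """Per-pixel Sirius-Red optical density.

    Per-channel OD = -log10(max(I, 1)/255) (the max(·,1) caps saturated black
    pixels at a finite OD), projected onto the unit SR stain vector and
    clipped at zero.  Pure white maps to exactly 0.
    """
    params = params or SegmentationParams()
    od = -np.log10(np.maximum(image.pixels.astype(np.float64), 1.0) / 255.0)
    sr = params.resolved_sr_vector()
    projected = od @ sr
    return np.maximum(projected, 0.0)


def segment_collagen(
    image: SlideImage, params: SegmentationParams | None = None
) -> CollagenSegmentation:
    """Full segmentation: tissue detection, SR-OD map, collagen thresholding.

    Collagen = tissue pixels whose SR-projected OD exceeds the threshold
    (Otsu over tissue-pixel OD values when ``od_threshold == "otsu"``),
    followed by small-object removal.
    """
    params = params or SegmentationParams()
    tissue = detect_tissue(image, params)
    sr_od = compute_sr_od(image, params)

    if not tissue.any():
        warnings.warn("empty tissue mask; collagen mask is empty", stacklevel=2)
        collagen = np.zeros_like(tissue)
        return CollagenSegmentation(tissue, collagen, sr_od, params)

    tissue_od = sr_od[tissue]
    if params.od_threshold == "otsu":
        if np.ptp(tissue_od) == 0:
            # Uniform OD: nothing separable from the counterstain.
            collagen = np.zeros_like(tissue)
            return CollagenSegmentation(tissue, collagen, sr_od, params)
        thr = float(threshold_otsu(tissue_od))
    else:
        thr = float(params.od_threshold)

    collagen = tissue & (sr_od > thr)
    if params.min_object_px > 0:
        collagen = remove_small_objects(collagen, max_size=params.min_object_px - 1)
    return CollagenSegmentation(tissue, collagen, sr_od, params)
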