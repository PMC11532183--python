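"""Per-biopsy fibrosis features: ECA, EnC, the extended battery, heatmaps.

Two features carry the contractual semantics of the pipeline:

ECA (Estimated Collagen Area)
    ``100 * collagen_pixels / tissue_pixels`` — the percentage of the tissue
    section occupied by Sirius-Red-positive collagen.

EnC (Entropy of Collagen)
    mean local Shannon entropy of the quantized SR optical density.  For each
    support pixel the OD values of the tissue pixels inside a centered
    ``entropy_window_px`` square are binned into ``entropy_bins`` equal-width
    bins spanning the slide's tissue OD range; the pixel's local entropy is
    the Shannon entropy of that histogram, and EnC is the mean over the
    support (tissue pixels by default).  A perfectly uniform OD field has
    EnC = 0; the maximum is log(entropy_bins) in the configured base.

Everything else is an extended battery of intensity, texture and morphology
features computed per 32x32-pixel ROI and aggregated to slide level; the
battery is a named, versioned registry (`FEATURE_REGISTRY`) so downstream
tables are self-describing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from matplotlib import colormaps
from scipy import stats as sps
from skimage.measure import label as sk_label
from skimage.measure import perimeter as sk_perimeter

from fibroquant.segmentation import CollagenSegmentation, SlideImage

__all__ = [
    "FeatureParams",
    "BiopsyFeatures",
    "RoiFeatureMaps",
    "Heatmap",
    "FEATURE_REGISTRY",
    "FEATURE_REGISTRY_VERSION",
    "compute_eca",
    "compute_enc",
    "local_entropy_map",
    "compute_roi_features",
    "extract_features",
    "render_heatmap",
]


@dataclass
class FeatureParams:
    roi_px: int = 32
    roi_min_tissue_fraction: float = 0.5
    entropy_window_px: int = 9
    entropy_bins: int = 8
    entropy_log_base: Literal["e", "2"] = "e"
    entropy_support: Literal["tissue", "collagen"] = "tissue"

    def __post_init__(self) -> None:
        if self.roi_px < 1:
            raise ValueError("roi_px must be positive")
        if not (0.0 <= self.roi_min_tissue_fraction <= 1.0):
            raise ValueError("roi_min_tissue_fraction must be in [0, 1]")
        if self.entropy_window_px < 1 or self.entropy_window_px % 2 == 0:
            raise ValueError("entropy_window_px must be odd and positive")
        if self.entropy_bins < 2:
            raise ValueError("entropy_bins must be >= 2")
        if self.entropy_log_base not in ("e", "2"):
            raise ValueError("entropy_log_base must be 'e' or '2'")
        if self.entropy_support not in ("tissue", "collagen"):
            raise ValueError("entropy_support must be 'tissue' or 'collagen'")

    @property
    def log_base_value(self) -> float:
        return math.e if self.entropy_log_base == "e" else 2.0


FEATURE_REGISTRY_VERSION = "1.0"

_ROI_FEATURES = {
    "collagen_fraction": "collagen pixels / tissue pixels within the ROI",
    "od_mean": "mean SR optical density over ROI tissue pixels",
    "od_sd": "sd of SR optical density over ROI tissue pixels",
    "od_skewness": "skewness of SR OD over ROI tissue pixels (0 if constant)",
    "od_kurtosis": "excess kurtosis of SR OD over ROI tissue pixels (0 if constant)",
    "entropy_mean": "mean local SR-OD entropy over ROI tissue pixels",
    "glcm_contrast": "co-occurrence contrast of quantized SR OD (tissue pairs only)",
    "glcm_energy": "co-occurrence energy (angular second moment)",
    "glcm_homogeneity": "co-occurrence inverse difference moment",
    "glcm_correlation": "co-occurrence correlation (1 for zero-variance ROIs)",
    "collagen_components": "number of 8-connected collagen components in the ROI",
    "collagen_perimeter_density": "collagen perimeter / ROI tissue pixels",
    "collagen_anisotropy": "elongation of collagen pixel cloud, (l1-l2)/(l1+l2)",
}

#: Named registry of the slide-level extended feature battery.
FEATURE_REGISTRY: dict[str, str] = {
    "eca_percent": "Estimated Collagen Area, % of tissue pixels that are collagen",
    "enc": "Entropy of Collagen, mean local entropy of quantized SR OD",
    **{f"{k}_roi_mean": f"tissue-weighted ROI mean of: {v}" for k, v in _ROI_FEATURES.items()},
    **{f"{k}_roi_sd": f"tissue-weighted ROI sd of: {v}" for k, v in _ROI_FEATURES.items()},
}


@dataclass
class RoiFeatureMaps:
    """Per-ROI feature grids for one slide.

    grids[name] is an (n_rows, n_cols) float array; excluded ROIs (tissue
    fraction below the threshold) hold NaN.  `tissue_fraction` and
    `tissue_px` cover every ROI, excluded or not.
    """

    grids: dict[str, np.ndarray]
    tissue_fraction: np.ndarray
    tissue_px: np.ndarray
    included: np.ndarray
    roi_px: int


@dataclass
class BiopsyFeatures:
    slide_id: str
    eca_percent: float
    enc: float
    extended: dict[str, float]
    roi_maps: RoiFeatureMaps | None = None


@dataclass
class Heatmap:
    base_image: np.ndarray
    overlay: np.ndarray  # (H, W, 3) uint8, blended
    alpha: float
    feature_name: str
    value_range: tuple[float, float]

    def save(self, path) -> None:
        from PIL import Image

        Image.fromarray(self.overlay).save(path)


def compute_eca(seg: CollagenSegmentation) -> float:
    """Estimated Collagen Area: 100 * collagen pixels / tissue pixels."""
    n_tissue = int(np.count_nonzero(seg.tissue_mask))
    if n_tissue == 0:
        raise ValueError("ECA is undefined: tissue mask is empty")
    return 100.0 * float(np.count_nonzero(seg.collagen_mask)) / n_tissue


def _windowed_counts(indicator: np.ndarray, window: int) -> np.ndarray:
    """Exact integer counts of True pixels in a centered window x window
    square (truncated at image borders), via an integral image."""
    h, w = indicator.shape
    r = window // 2
    ii = np.zeros((h + 1, w + 1), dtype=np.int64)
    np.cumsum(np.cumsum(indicator.astype(np.int64), axis=0), axis=1, out=ii[1:, 1:])
    rows = np.arange(h)
    cols = np.arange(w)
    top = np.clip(rows - r, 0, h)
    bot = np.clip(rows + r + 1, 0, h)
    left = np.clip(cols - r, 0, w)
    right = np.clip(cols + r + 1, 0, w)
    return (
        ii[bot[:, None], right[None, :]]
        - ii[top[:, None], right[None, :]]
        - ii[bot[:, None], left[None, :]]
        + ii[top[:, None], left[None, :]]
    )


def quantize_od(
    sr_od: np.ndarray, tissue_mask: np.ndarray, bins: int
) -> np.ndarray:
    """Quantize SR OD into ``bins`` equal-width bins spanning the slide's
    tissue OD range.  Values outside the range clip into the end bins; a
    degenerate (constant) range maps everything to bin 0."""
    tissue_od = sr_od[tissue_mask]
    lo = float(tissue_od.min())
    hi = float(tissue_od.max())
    if hi <= lo:
        return np.zeros_like(sr_od, dtype=np.int64)
    q = np.floor((sr_od - lo) / (hi - lo) * bins).astype(np.int64)
    return np.clip(q, 0, bins - 1)


def local_entropy_map(
    seg: CollagenSegmentation, params: FeatureParams | None = None
) -> np.ndarray:
    """Per-pixel local entropy of the quantized SR OD.

    The histogram at each pixel counts only the tissue pixels inside the
    window, so background never dilutes border entropies.  Pixels whose
    window contains no tissue hold 0.
    """
    params = params or FeatureParams()
    if not seg.tissue_mask.any():
        raise ValueError("local entropy is undefined: tissue mask is empty")
    q = quantize_od(seg.sr_od, seg.tissue_mask, params.entropy_bins)
    h, w = q.shape
    counts = np.zeros((params.entropy_bins, h, w), dtype=np.int64)
    for b in range(params.entropy_bins):
        counts[b] = _windowed_counts((q == b) & seg.tissue_mask, params.entropy_window_px)
    total = counts.sum(axis=0)
    entropy = np.zeros((h, w), dtype=np.float64)
    safe_total = np.maximum(total, 1)
    for b in range(params.entropy_bins):
        p = counts[b] / safe_total
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(p > 0, -p * np.log(p), 0.0)
        entropy += term
    if params.entropy_log_base == "2":
        entropy /= math.log(2.0)
    entropy[total == 0] = 0.0
    return entropy


def compute_enc(
    seg: CollagenSegmentation, params: FeatureParams | None = None
) -> float:
    """Entropy of Collagen: mean local SR-OD entropy over the support mask."""
    params = params or FeatureParams()
    support = seg.tissue_mask if params.entropy_support == "tissue" else seg.collagen_mask
    if not support.any():
        raise ValueError(
            f"EnC is undefined: {params.entropy_support} support mask is empty"
        )
    emap = local_entropy_map(seg, params)
    return float(emap[support].mean())


def _masked_glcm(q: np.ndarray, mask: np.ndarray, levels: int) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix of quantized levels over
    offsets (0,1) and (1,0) averaged, counting only pairs where both pixels
    are tissue."""
    glcm = np.zeros((levels, levels), dtype=np.float64)
    for off in ((0, 1), (1, 0)):
        dy, dx = off
        a = q[: q.shape[0] - dy, : q.shape[1] - dx]
        b = q[dy:, dx:]
        valid = mask[: mask.shape[0] - dy, : mask.shape[1] - dx] & mask[dy:, dx:]
        if valid.any():
            np.add.at(glcm, (a[valid], b[valid]), 1.0)
            np.add.at(glcm, (b[valid], a[valid]), 1.0)
    s = glcm.sum()
    if s > 0:
        glcm /= s
    return glcm


def _glcm_props(glcm: np.ndarray) -> tuple[float, float, float, float]:
    """(contrast, energy, homogeneity, correlation) of a normalized GLCM."""
    levels = glcm.shape[0]
    i = np.arange(levels)[:, None]
    j = np.arange(levels)[None, :]
    contrast = float((glcm * (i - j) ** 2).sum())
    energy = float((glcm**2).sum())
    homogeneity = float((glcm / (1.0 + np.abs(i - j))).sum())
    pi = glcm.sum(axis=1)
    pj = glcm.sum(axis=0)
    mu_i = float((np.arange(levels) * pi).sum())
    mu_j = float((np.arange(levels) * pj).sum())
    var_i = float(((np.arange(levels) - mu_i) ** 2 * pi).sum())
    var_j = float(((np.arange(levels) - mu_j) ** 2 * pj).sum())
    if var_i <= 0 or var_j <= 0:
        correlation = 1.0
    else:
        cov = float((glcm * (i - mu_i) * (j - mu_j)).sum())
        correlation = cov / math.sqrt(var_i * var_j)
    return contrast, energy, homogeneity, correlation


def _roi_slices(h: int, w: int, roi_px: int):
    n_rows = (h + roi_px - 1) // roi_px
    n_cols = (w + roi_px - 1) // roi_px
    for r in range(n_rows):
        for c in range(n_cols):
            yield r, c, slice(r * roi_px, min((r + 1) * roi_px, h)), slice(
                c * roi_px, min((c + 1) * roi_px, w)
            )


def compute_roi_features(
    seg: CollagenSegmentation, params: FeatureParams | None = None
) -> tuple[RoiFeatureMaps, dict[str, float]]:
    """Tile the slide into non-overlapping ROIs and compute the per-ROI
    battery; slide-level extended features are tissue-weighted means and sds
    over the included ROIs (tissue fraction >= roi_min_tissue_fraction).

    Partial tiles at the right/bottom edge are included, with their tissue
    fraction taken over the actual tile area.
    """
    params = params or FeatureParams()
    h, w = seg.tissue_mask.shape
    roi = params.roi_px
    n_rows = (h + roi - 1) // roi
    n_cols = (w + roi - 1) // roi

    emap = local_entropy_map(seg, params)
    q = quantize_od(seg.sr_od, seg.tissue_mask, params.entropy_bins)

    grids = {name: np.full((n_rows, n_cols), np.nan) for name in _ROI_FEATURES}
    tissue_fraction = np.zeros((n_rows, n_cols))
    tissue_px = np.zeros((n_rows, n_cols), dtype=np.int64)

    for r, c, sy, sx in _roi_slices(h, w, roi):
        t = seg.tissue_mask[sy, sx]
        n_t = int(t.sum())
        area = t.size
        tissue_px[r, c] = n_t
        tissue_fraction[r, c] = n_t / area
        if n_t == 0:
            continue
        col = seg.collagen_mask[sy, sx]
        od = seg.sr_od[sy, sx][t]
        grids["collagen_fraction"][r, c] = float(col.sum()) / n_t
        grids["od_mean"][r, c] = float(od.mean())
        grids["od_sd"][r, c] = float(od.std(ddof=0))
        if np.ptp(od) == 0:
            grids["od_skewness"][r, c] = 0.0
            grids["od_kurtosis"][r, c] = 0.0
        else:
            grids["od_skewness"][r, c] = float(sps.skew(od))
            grids["od_kurtosis"][r, c] = float(sps.kurtosis(od))
        grids["entropy_mean"][r, c] = float(emap[sy, sx][t].mean())
        glcm = _masked_glcm(q[sy, sx], t, params.entropy_bins)
        con, ene, hom, cor = _glcm_props(glcm)
        grids["glcm_contrast"][r, c] = con
        grids["glcm_energy"][r, c] = ene
        grids["glcm_homogeneity"][r, c] = hom
        grids["glcm_correlation"][r, c] = cor
        if col.any():
            lab = sk_label(col, connectivity=2)
            grids["collagen_components"][r, c] = float(lab.max())
            grids["collagen_perimeter_density"][r, c] = float(sk_perimeter(col)) / n_t
            ys, xs = np.nonzero(col)
            if len(ys) >= 3:
                cov = np.cov(np.vstack([ys, xs]))
                evals = np.linalg.eigvalsh(cov)
                l2, l1 = float(evals[0]), float(evals[1])
                grids["collagen_anisotropy"][r, c] = (
                    (l1 - l2) / (l1 + l2) if (l1 + l2) > 0 else 0.0
                )
            else:
                grids["collagen_anisotropy"][r, c] = 0.0
        else:
            grids["collagen_components"][r, c] = 0.0
            grids["collagen_perimeter_density"][r, c] = 0.0
            grids["collagen_anisotropy"][r, c] = 0.0

    included = tissue_fraction >= params.roi_min_tissue_fraction
    if not included.any():
        raise ValueError(
            "all ROIs excluded: no ROI reaches tissue fraction "
            f">= {params.roi_min_tissue_fraction}"
        )

    maps = RoiFeatureMaps(
        grids=grids,
        tissue_fraction=tissue_fraction,
        tissue_px=tissue_px,
        included=included,
        roi_px=roi,
    )

    extended: dict[str, float] = {}
    wts = tissue_px[included].astype(np.float64)
    wsum = wts.sum()
    for name, grid in grids.items():
        vals = grid[included]
        ok = np.isfinite(vals)
        v, wv = vals[ok], wts[ok]
        if wv.sum() == 0:
            mean = sd = float("nan")
        else:
            mean = float(np.average(v, weights=wv))
            sd = float(math.sqrt(np.average((v - mean) ** 2, weights=wv)))
        extended[f"{name}_roi_mean"] = mean
        extended[f"{name}_roi_sd"] = sd
    del wsum
    return maps, extended


def extract_features(
    seg: CollagenSegmentation,
    params: FeatureParams | None = None,
    slide_id: str = "",
) -> BiopsyFeatures:
    """Full per-biopsy feature vector: ECA, EnC, and the extended battery."""
    params = params or FeatureParams()
    eca = compute_eca(seg)
    enc = compute_enc(seg, params)
    maps, extended = compute_roi_features(seg, params)
    extended = {"eca_percent": eca, "enc": enc, **extended}
    return BiopsyFeatures(
        slide_id=slide_id, eca_percent=eca, enc=enc, extended=extended, roi_maps=maps
    )


def render_heatmap(
    image: SlideImage,
    roi_grid: np.ndarray,
    feature_name: str = "",
    alpha: float = 0.5,
    roi_px: int = 32,
    cmap: str = "viridis",
    value_range: tuple[float, float] | None = None,
) -> Heatmap:
    """Overlay a per-ROI feature grid on the slide.

    The grid is nearest-neighbor upsampled to image size and alpha-blended;
    NaN cells (excluded ROIs) stay fully transparent.
    """
    h, w = image.pixels.shape[:2]
    n_rows = (h + roi_px - 1) // roi_px
    n_cols = (w + roi_px - 1) // roi_px
    grid = np.asarray(roi_grid, dtype=float)
    if grid.shape != (n_rows, n_cols):
        raise ValueError(
            f"grid shape {grid.shape} does not match the {n_rows}x{n_cols} "
            f"tiling of a {h}x{w} image at roi_px={roi_px}"
        )
    finite = grid[np.isfinite(grid)]
    if value_range is None:
        if finite.size == 0:
            value_range = (0.0, 1.0)
        else:
            lo, hi = float(finite.min()), float(finite.max())
            value_range = (lo, hi if hi > lo else lo + 1.0)
    lo, hi = value_range
    norm = np.clip((grid - lo) / (hi - lo), 0.0, 1.0)

    cm = colormaps[cmap]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        colors = (cm(np.nan_to_num(norm, nan=0.0))[:, :, :3] * 255).astype(np.float64)
    up = np.repeat(np.repeat(colors, roi_px, axis=0), roi_px, axis=1)[:h, :w]
    valid = np.repeat(np.repeat(np.isfinite(grid), roi_px, axis=0), roi_px, axis=1)[:h, :w]

    base = image.pixels.astype(np.float64)
    blended = base.copy()
    blended[valid] = (1.0 - alpha) * base[valid] + alpha * up[valid]
    overlay = np.clip(np.rint(blended), 0, 255).astype(np.uint8)
    return Heatmap(
        base_image=image.pixels,
        overlay=overlay,
        alpha=alpha,
        feature_name=feature_name,
        value_range=value_range,
    )
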