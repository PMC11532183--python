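"""Image and table readers/writers.

TIFF handling goes through tifffile, everything else through Pillow.  The
µm-per-pixel scale is read from the TIFF resolution tags when present and
otherwise falls back to the 0.25 µm/pixel of a 40x scan, with a warning.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from fibroquant.segmentation import SlideImage

__all__ = ["read_image", "write_image", "DEFAULT_UM_PER_PX"]

DEFAULT_UM_PER_PX = 0.25


def _um_per_px_from_tiff(page) -> float | None:
    tags = page.tags
    if "XResolution" not in tags:
        return None
    num, den = tags["XResolution"].value
    if num == 0:
        return None
    px_per_unit = num / den
    unit = tags["ResolutionUnit"].value if "ResolutionUnit" in tags else None
    unit = getattr(unit, "value", unit)
    if unit == 3:  # centimeter
        return 10_000.0 / px_per_unit
    if unit == 2:  # inch
        return 25_400.0 / px_per_unit
    return None


def _to_rgb(arr: np.ndarray, path: Path) -> np.ndarray:
    if arr.ndim == 2:
        warnings.warn(f"{path.name}: grayscale image promoted to RGB", stacklevel=3)
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise IOError(f"{path}: expected an RGB image, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        raise IOError(f"{path}: expected 8-bit channels, got {arr.dtype}")
    return arr


def read_image(path, um_per_px: float | None = None) -> SlideImage:
    """Read a TIFF/PNG slide as 8-bit RGB with µm/pixel metadata.

    An explicit ``um_per_px`` wins; otherwise TIFF resolution tags are used,
    and failing that the 0.25 µm default (with a warning).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such image file: {path}")
    suffix = path.suffix.lower()
    meta_um = None
    if suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            arr = tf.pages[0].asarray()
            meta_um = _um_per_px_from_tiff(tf.pages[0])
    else:
        try:
            arr = np.asarray(Image.open(path))
        except Exception as exc:  # pillow raises many concrete types
            raise IOError(f"cannot read image {path}: {exc}") from exc
    arr = _to_rgb(np.asarray(arr), path)
    if um_per_px is None:
        if meta_um is not None:
            um_per_px = float(meta_um)
        else:
            warnings.warn(
                f"{path.name}: no pixel-size metadata; assuming "
                f"{DEFAULT_UM_PER_PX} um/pixel",
                stacklevel=2,
            )
            um_per_px = DEFAULT_UM_PER_PX
    return SlideImage(pixels=arr, um_per_px=um_per_px, slide_id=path.stem)


def write_image(path, image: SlideImage) -> None:
    """Write a slide as TIFF (with resolution tags) or PNG."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        px_per_cm = 10_000.0 / image.um_per_px
        tifffile.imwrite(
            path,
            image.pixels,
            photometric="rgb",
            resolution=(px_per_cm, px_per_cm),
            resolutionunit="CENTIMETER",
        )
    else:
        Image.fromarray(image.pixels).save(path)
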