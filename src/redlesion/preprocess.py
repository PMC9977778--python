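"""Pre-processing: green-channel extraction, CLAHE, and field-of-view masking.

Fundus photographs carry most of the lesion/vessel contrast in the green
channel, which is therefore extracted and contrast-enhanced with CLAHE before
detection.  Intensities are normalised to [0, 1] throughout so that the
detector's thresholds (``diff_th``, ``intensity_th``) live on a unit scale.

The bright circular field of view (FOV) is delimited so that detection can be
restricted to pixels whose entire verification circle (radius ``a0 + d``)
lies inside the imaged area; quarter circles straddling the black rim would
otherwise see large dark-to-light transitions and become spurious candidates.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import exposure, morphology

import imageio.v3 as iio

__all__ = [
    "load_image",
    "extract_green",
    "enhance_contrast",
    "compute_fov_mask",
]

_EIGHT_CONN = np.ones((3, 3), dtype=bool)


def load_image(path) -> np.ndarray:
    """Read a PNG/JPEG/TIFF raster as a numpy array (8- or 16-bit)."""
    return np.asarray(iio.imread(path))


def extract_green(pixels: np.ndarray) -> np.ndarray:
    """Extract the green channel and rescale it to [0, 1].

    Accepts 3-channel RGB (channel index 1 is used), or an already-extracted
    single-channel image.  Integer inputs are divided by their dtype maximum;
    floating inputs must already lie in [0, 1] and pass through unchanged.
    """
    arr = np.asarray(pixels)
    if arr.ndim == 3:
        if arr.shape[2] != 3:
            raise ValueError(
                f"expected 1 or 3 channels, got shape {arr.shape}")
        arr = arr[:, :, 1]
    elif arr.ndim != 2:
        raise ValueError(f"expected a 2-D or 3-D raster, got shape {arr.shape}")

    if np.issubdtype(arr.dtype, np.integer):
        scale = float(np.iinfo(arr.dtype).max)
        g = arr.astype(np.float64) / scale
    elif np.issubdtype(arr.dtype, np.floating):
        g = arr.astype(np.float64)
        if not np.isfinite(g).all():
            raise ValueError("floating-point image contains non-finite values")
        if g.min() < 0.0 or g.max() > 1.0:
            raise ValueError("floating-point image must lie in [0, 1]")
    else:
        raise ValueError(f"unsupported pixel dtype {arr.dtype}")
    return g


def enhance_contrast(g: np.ndarray,
                     clip_limit: float = 0.01,
                     tile_grid: tuple[int, int] = (8, 8)) -> np.ndarray:
    """Contrast Limited Adaptive Histogram Equalization on a [0, 1] image.

    ``clip_limit`` is the fraction of each tile histogram at which counts are
    clipped; ``tile_grid`` is the number of (rows, cols) of tiles the image is
    divided into.  The output is clipped back to [0, 1] and keeps the input
    shape.  A constant image is returned unchanged (degenerate histogram).
    """
    g = np.asarray(g, dtype=np.float64)
    if not np.isfinite(g).all():
        raise ValueError("image contains non-finite values")
    if clip_limit <= 0:
        raise ValueError("clip_limit must be positive")
    tr, tc = int(tile_grid[0]), int(tile_grid[1])
    if tr < 1 or tc < 1:
        raise ValueError("tile_grid must be at least (1, 1)")
    if g.max() - g.min() < 1e-12:
        return g.copy()
    kernel = (max(1, g.shape[0] // tr), max(1, g.shape[1] // tc))
    out = exposure.equalize_adapthist(g, kernel_size=kernel,
                                      clip_limit=clip_limit)
    return np.clip(out, 0.0, 1.0)


def compute_fov_mask(g: np.ndarray,
                     fov_threshold: float = 0.10,
                     erosion_radius: int = 13,
                     closing_radius: int = 5) -> np.ndarray:
    """Boolean mask of the usable field of view.

    Pixels above ``fov_threshold`` are closed morphologically, the largest
    8-connected component is kept, and the result is eroded with a disk of
    ``erosion_radius`` (normally ``a0 + d``) so that every retained pixel's
    full verification circle lies inside the imaged area.
    """
    g = np.asarray(g, dtype=np.float64)
    bright = g > float(fov_threshold)
    if not bright.any():
        raise ValueError("no pixel above fov_threshold: not a usable image")
    if closing_radius > 0:
        bright = ndimage.binary_closing(
            bright, structure=morphology.disk(closing_radius))
    labels, n = ndimage.label(bright, structure=_EIGHT_CONN)
    if n == 0:
        raise ValueError("field of view vanished during closing")
    largest = 1 + np.argmax(ndimage.sum_labels(bright, labels,
                                               index=range(1, n + 1)))
    component = labels == largest
    if erosion_radius > 0:
        component = ndimage.binary_erosion(
            component, structure=morphology.disk(erosion_radius),
            border_value=0)
    return component
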