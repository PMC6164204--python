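"""Image preprocessing: grayscale conversion, resizing, denoising, contrast
enhancement, and the two image-quality scores (PSNR, CII) used to choose
between them.

On real cytology acquisitions the working choice is median filtering (3x3)
followed by CLAHE; the five filters and three enhancers are all provided so
that the choice can be reproduced by ranking PSNR and CII on degraded images.

Conventions used throughout: images are 2-D float arrays on the 8-bit domain
[0, 255]; all windowed operations use reflect padding at the borders; outputs
are clipped back to [0, 255].
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import exposure, transform

from .errors import FormatError

__all__ = [
    "to_grayscale",
    "resize_image",
    "denoise",
    "enhance",
    "psnr",
    "cii",
    "local_contrast",
    "DENOISE_METHODS",
    "ENHANCE_METHODS",
]

DENOISE_METHODS = ("median", "gaussian", "laplacian", "wiener", "mean")
ENHANCE_METHODS = ("hist_eq", "intensity_adjust", "clahe")

#: Default working resolution for full-size cytology scans.
DEFAULT_RESIZE = (1052, 1052)


def _as_float(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise FormatError(f"expected a 2-D grayscale image, got ndim={image.ndim}")
    if image.size == 0:
        raise FormatError("empty image")
    return image


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert an RGB image to luminance with weights (0.299, 0.587, 0.114).

    2-D input is passed through unchanged (already gray).
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 2:
        return image
    if image.ndim != 3 or image.shape[-1] != 3:
        raise FormatError(
            f"expected an (H, W) or (H, W, 3) image, got shape {image.shape}"
        )
    return image @ np.array([0.299, 0.587, 0.114])


def resize_image(image: np.ndarray, target: tuple[int, int] = DEFAULT_RESIZE) -> np.ndarray:
    """Bilinear resize to ``target`` (H, W); RGB input keeps its channels."""
    th, tw = target
    if th < 1 or tw < 1:
        raise ValueError(f"target size must be positive, got {target}")
    image = np.asarray(image, dtype=np.float64)
    if image.shape[:2] == (th, tw):
        return image.copy()
    out_shape = (th, tw) + image.shape[2:]
    return transform.resize(
        image, out_shape, order=1, mode="reflect",
        anti_aliasing=False, preserve_range=True,
    )


def _wiener_local(image: np.ndarray, window: int) -> np.ndarray:
    """Locally adaptive Wiener filter (lee-style).

    Local mean/variance over a window x window neighbourhood; the noise power
    is estimated as the mean of the local variances.  Flat regions collapse to
    the local mean, structured regions are preserved.
    """
    mean = ndimage.uniform_filter(image, size=window, mode="reflect")
    sqmean = ndimage.uniform_filter(image**2, size=window, mode="reflect")
    var = np.maximum(sqmean - mean**2, 0.0)
    noise = var.mean()
    gain = np.where(var > noise, (var - noise) / np.maximum(var, 1e-12), 0.0)
    return mean + gain * (image - mean)


def denoise(image: np.ndarray, method: str = "median", window: int = 3) -> np.ndarray:
    """Apply one of the five denoising filters.

    method -- median | gaussian | laplacian | wiener | mean
    window -- odd neighbourhood size (default 3)

    "laplacian" is used as a sharpener (input minus Laplacian) so that its
    output is an image comparable to the others by PSNR.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    image = _as_float(image)
    if method == "median":
        out = ndimage.median_filter(image, size=window, mode="reflect")
    elif method == "gaussian":
        out = ndimage.gaussian_filter(image, sigma=window / 6.0, mode="reflect")
    elif method == "laplacian":
        out = image - ndimage.laplace(image, mode="reflect")
    elif method == "wiener":
        out = _wiener_local(image, window)
    elif method == "mean":
        out = ndimage.uniform_filter(image, size=window, mode="reflect")
    else:
        raise ValueError(f"unknown denoise method {method!r}; choose from {DENOISE_METHODS}")
    return np.clip(out, 0.0, 255.0)


def _hist_eq(image: np.ndarray) -> np.ndarray:
    """Classic 256-bin global histogram equalization.

    Gray level v maps to 255 * (cdf(v) - cdf_min) / (1 - cdf_min), where
    cdf_min is the CDF at the lowest occupied bin, so the darkest occupied
    level maps to 0 and the brightest to 255.  A constant image is returned
    unchanged.
    """
    levels = np.clip(np.rint(image), 0, 255).astype(np.intp)
    hist = np.bincount(levels.ravel(), minlength=256).astype(np.float64)
    cdf = np.cumsum(hist) / levels.size
    cdf_min = cdf[np.nonzero(hist)[0][0]]
    if cdf_min >= 1.0:
        return image.copy()
    lut = 255.0 * (cdf - cdf_min) / (1.0 - cdf_min)
    return lut[levels]


def _intensity_adjust(image: np.ndarray, saturation: float = 0.01) -> np.ndarray:
    """Linear contrast stretch saturating ``saturation`` mass at each tail."""
    lo, hi = np.percentile(image, [100 * saturation, 100 * (1 - saturation)])
    if hi <= lo:
        return image.copy()
    return np.clip((image - lo) / (hi - lo) * 255.0, 0.0, 255.0)


def _clahe(image: np.ndarray, clip_limit: float = 0.01) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    8x8 tile grid, 256 histogram bins, clip limit as a fraction of the tile
    pixel count (default 0.01).
    """
    if image.max() == image.min():
        return image.copy()
    h, w = image.shape
    kernel = (max(1, h // 8), max(1, w // 8))
    out = exposure.equalize_adapthist(
        np.clip(image, 0, 255).astype(np.uint8),
        kernel_size=kernel, clip_limit=clip_limit, nbins=256,
    )
    return out * 255.0


def enhance(image: np.ndarray, method: str = "clahe", **kwargs) -> np.ndarray:
    """Apply one of the three contrast enhancers (hist_eq | intensity_adjust | clahe)."""
    image = _as_float(image)
    if method == "hist_eq":
        out = _hist_eq(image)
    elif method == "intensity_adjust":
        out = _intensity_adjust(image, **kwargs)
    elif method == "clahe":
        out = _clahe(image, **kwargs)
    else:
        raise ValueError(f"unknown enhance method {method!r}; choose from {ENHANCE_METHODS}")
    return np.clip(out, 0.0, 255.0)


def psnr(reference: np.ndarray, test: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB: 10*log10(255^2 / MSE).

    Identical images have MSE 0 and return +inf (valid limiting case).
    """
    reference = _as_float(reference)
    test = _as_float(test)
    if reference.shape != test.shape:
        raise ValueError(f"shape mismatch: {reference.shape} vs {test.shape}")
    mse = np.mean((reference - test) ** 2)
    if mse == 0:
        return float("inf")
    return float(10.0 * np.log10(255.0**2 / mse))


def local_contrast(image: np.ndarray, window: int = 3, eps: float = 1e-6) -> float:
    """Mean Michelson-style local contrast: (max-min)/(max+min+eps) over
    sliding window x window neighbourhoods (reflect-padded)."""
    image = _as_float(image)
    mx = ndimage.maximum_filter(image, size=window, mode="reflect")
    mn = ndimage.minimum_filter(image, size=window, mode="reflect")
    return float(np.mean((mx - mn) / (mx + mn + eps)))


def cii(enhanced: np.ndarray, original: np.ndarray) -> float:
    """Contrast improvement index: local contrast of the enhanced image over
    local contrast of the original.  > 1 means contrast was improved.

    Two constant images have zero contrast each; the ratio is defined as 1.0
    in that case (nothing was gained, nothing lost).
    """
    if np.asarray(enhanced).shape != np.asarray(original).shape:
        raise ValueError("shape mismatch between enhanced and original")
    c_orig = local_contrast(original)
    c_enh = local_contrast(enhanced)
    if c_orig == 0.0:
        return 1.0 if c_enh == 0.0 else float("inf")
    return c_enh / c_orig
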