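"""Image preprocessing: raw RGB photograph -> clean binary grain mask.

The chain mirrors how grain photographs on white paper are usually prepared
for contour analysis: 2x bilinear downsampling (speed), Gaussian denoising,
HSV conversion (grains are strongly saturated against near-achromatic
paper), mean-shift color smoothing (flattens texture inside grains and
paper), channel extraction and Otsu thresholding.

Images are numpy arrays: ``(H, W, 3)`` uint8 for color, ``(H, W)`` for
grayscale, origin top-left, 0-based ``(row, col)`` indexing throughout the
package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import color as skcolor

log = logging.getLogger(__name__)

_GRAY_CHANNELS = ("saturation", "value", "luma")


@dataclass
class PreprocessConfig:
    """Tunable parameters of the preprocessing chain.

    downsample_factor
        1 (already at working resolution), 2, or any power of two; each
        factor of 2 is one bilinear 2x2 reduction pass.
    gaussian_kernel, gaussian_sigma
        Odd kernel size in pixels; sigma <= 0 derives sigma from the kernel
        size (0.3*((k-1)/2 - 1) + 0.8, the common convention).
    meanshift_spatial_radius, meanshift_color_radius
        Flat-kernel window of the mean-shift filter, pixels / intensity
        units on the 0-255 channel scale.
    hsv_gray_channel
        Which scalar feeds Otsu: "saturation" (default; grains saturated,
        paper near zero), "value", or "luma" (Rec.601 luma of the
        mean-shifted RGB image).
    foreground_high
        Polarity of the mask; None picks it from the channel (high class is
        grain for saturation, low class for value/luma on a light
        background).
    min_area
        Connected components smaller than this (pixels, post-downsampling)
        are dropped as dust.
    """

    downsample_factor: int = 2
    gaussian_kernel: int = 5
    gaussian_sigma: float = 0.0
    meanshift_spatial_radius: int = 10
    meanshift_color_radius: float = 20.0
    meanshift_max_iter: int = 5
    hsv_gray_channel: str = "saturation"
    foreground_high: bool | None = None
    min_area: int = 30

    def __post_init__(self) -> None:
        f = self.downsample_factor
        if f < 1 or (f & (f - 1)) != 0:
            raise ValueError("downsample_factor must be a power of two >= 1")
        if self.gaussian_kernel < 1 or self.gaussian_kernel % 2 == 0:
            raise ValueError("gaussian_kernel must be odd and >= 1")
        if self.hsv_gray_channel not in _GRAY_CHANNELS:
            raise ValueError(f"hsv_gray_channel must be one of {_GRAY_CHANNELS}")


@dataclass
class PreprocessResult:
    mask: np.ndarray            # (H, W) bool, True = grain
    image: np.ndarray           # downsampled RGB, for overlays
    gray: np.ndarray            # channel fed to Otsu
    threshold: int
    config: PreprocessConfig = field(repr=False, default_factory=PreprocessConfig)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def downsample_bilinear(image: np.ndarray) -> np.ndarray:
    """Halve each dimension by replacing non-overlapping 2x2 windows with
    their bilinear midpoint, i.e. the per-channel mean of the four pixels.

    Output size is floor(H/2) x floor(W/2); a trailing odd row/column is
    dropped.  Values are rounded half-up to keep the result integral and
    platform-independent.
    """
    img = np.asarray(image)
    if img.shape[0] < 2 or img.shape[1] < 2:
        raise ValueError("image must be at least 2x2 pixels")
    h2, w2 = img.shape[0] // 2, img.shape[1] // 2
    img = img[: 2 * h2, : 2 * w2]
    if img.ndim == 2:
        blocks = img.reshape(h2, 2, w2, 2).astype(np.float64)
    else:
        blocks = img.reshape(h2, 2, w2, 2, img.shape[2]).astype(np.float64)
    mean = blocks.mean(axis=(1, 3))
    out = np.clip(_round_half_up(mean), 0, 255)
    return out.astype(image.dtype if np.issubdtype(np.asarray(image).dtype, np.integer) else np.uint8)


def _gaussian_kernel_1d(size: int, sigma: float) -> np.ndarray:
    if sigma <= 0:
        sigma = 0.3 * ((size - 1) * 0.5 - 1) + 0.8
    r = size // 2
    x = np.arange(-r, r + 1, dtype=np.float64)
    k = np.exp(-(x**2) / (2.0 * sigma**2))
    return k / k.sum()


def gaussian_smooth(image: np.ndarray, kernel: int = 5, sigma: float = 0.0) -> np.ndarray:
    """Separable Gaussian convolution with a normalized discrete kernel,
    reflected borders.  Integer input comes back rounded to the same dtype;
    float input stays float (useful for impulse-response checks)."""
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError("kernel size must be odd and >= 1")
    img = np.asarray(image)
    k1 = _gaussian_kernel_1d(kernel, sigma)
    out = img.astype(np.float64)
    for axis in (0, 1):
        out = ndi.correlate1d(out, k1, axis=axis, mode="reflect")
    if np.issubdtype(img.dtype, np.integer):
        return np.clip(_round_half_up(out), 0, 255).astype(img.dtype)
    return out


def rgb_to_hsv(image: np.ndarray) -> np.ndarray:
    """Standard RGB -> HSV, every channel rescaled to the 0-255 uint8 range
    (hue included, so downstream thresholds live on one scale)."""
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("rgb_to_hsv expects an (H, W, 3) color image")
    hsv = skcolor.rgb2hsv(img.astype(np.float64) / 255.0)
    return np.clip(_round_half_up(hsv * 255.0), 0, 255).astype(np.uint8)


def meanshift_smooth(
    image: np.ndarray,
    spatial_radius: int = 10,
    color_radius: float = 20.0,
    max_iter: int = 5,
) -> np.ndarray:
    """Mean-shift color filtering with a flat joint spatial/color kernel.

    Each pixel's mean-shift trajectory (window mean of pixels within the
    spatial square of half-width ``spatial_radius`` whose color lies within
    ``color_radius``) runs until the color shift is below half an intensity
    unit or ``max_iter`` iterations; the pixel takes the mode color.
    Constant images are fixed points, and regions whose colors differ by
    much more than ``color_radius`` never mix.
    """
    if spatial_radius < 1 or color_radius <= 0:
        raise ValueError("spatial_radius and color_radius must be positive")
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("meanshift_smooth expects an (H, W, 3) image")
    from ._meanshift import meanshift_filter

    out = meanshift_filter(
        np.ascontiguousarray(img, dtype=np.float32),
        int(spatial_radius),
        float(color_radius) ** 2,
        int(max_iter),
    )
    return np.clip(_round_half_up(out.astype(np.float64)), 0, 255).astype(np.uint8)


def otsu_threshold(gray: np.ndarray) -> int:
    """Otsu's threshold on the 256-bin histogram: the t in 0..255 maximizing
    the between-class variance of classes {<= t} and {> t}.  When the
    maximum is a plateau (empty histogram valley between well-separated
    modes) the plateau midpoint is returned, so the threshold sits centrally
    between the modes rather than at the valley's edge."""
    g = np.asarray(gray)
    hist = np.bincount(np.clip(g, 0, 255).astype(np.int64).ravel(), minlength=256).astype(np.float64)
    n = hist.sum()
    if np.count_nonzero(hist) < 2:
        raise ValueError("Otsu threshold undefined: image has a single intensity")
    omega = np.cumsum(hist) / n                      # P(class0) for t = 0..255
    mu = np.cumsum(hist * np.arange(256)) / n        # first moment up to t
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = -1.0
    ties = np.flatnonzero(sigma_b == sigma_b.max())
    return int(round(ties.mean()))


def binarize_otsu(gray: np.ndarray, foreground_high: bool = True) -> np.ndarray:
    """Threshold a grayscale image by Otsu's criterion and return the grain
    mask.  ``foreground_high`` picks which side of the threshold is grain
    (high for the saturation channel, low for brightness channels on a
    light background)."""
    g = np.asarray(gray)
    if g.ndim != 2:
        raise ValueError("binarize_otsu expects a 2-D grayscale image")
    t = otsu_threshold(g)
    return (g > t) if foreground_high else (g <= t)


def _remove_small(mask: np.ndarray, min_area: int) -> np.ndarray:
    if min_area <= 1 or not mask.any():
        return mask
    labels, n = ndi.label(mask, structure=np.ones((3, 3), dtype=bool))
    areas = np.bincount(labels.ravel())
    keep = areas >= min_area
    keep[0] = False
    return keep[labels]


def preprocess_pipeline(image: np.ndarray, config: PreprocessConfig | None = None) -> PreprocessResult:
    """Full chain: downsample -> Gaussian -> HSV -> mean shift -> channel
    extraction -> Otsu -> small-component suppression."""
    cfg = config or PreprocessConfig()
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("preprocess_pipeline expects an RGB image")

    f = cfg.downsample_factor
    while f > 1:
        img = downsample_bilinear(img)
        f //= 2
    img = gaussian_smooth(img, cfg.gaussian_kernel, cfg.gaussian_sigma)

    if cfg.hsv_gray_channel == "luma":
        ms = meanshift_smooth(img, cfg.meanshift_spatial_radius,
                              cfg.meanshift_color_radius, cfg.meanshift_max_iter)
        gray = np.clip(_round_half_up(
            0.299 * ms[:, :, 0] + 0.587 * ms[:, :, 1] + 0.114 * ms[:, :, 2]), 0, 255
        ).astype(np.uint8)
    else:
        hsv = rgb_to_hsv(img)
        ms = meanshift_smooth(hsv, cfg.meanshift_spatial_radius,
                              cfg.meanshift_color_radius, cfg.meanshift_max_iter)
        gray = ms[:, :, 1] if cfg.hsv_gray_channel == "saturation" else ms[:, :, 2]

    fg_high = cfg.foreground_high
    if fg_high is None:
        fg_high = cfg.hsv_gray_channel == "saturation"
    mask = binarize_otsu(gray, foreground_high=fg_high)
    mask = _remove_small(mask, cfg.min_area)
    log.debug("preprocess: %d foreground pixels", int(mask.sum()))
    return PreprocessResult(mask=mask, image=img, gray=gray,
                            threshold=otsu_threshold(gray), config=cfg)
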