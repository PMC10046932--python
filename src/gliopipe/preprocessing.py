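"""Grayscale conversion, local noise statistics, Wiener-type adaptive
filtering, and unsharp sharpening.

The adaptive filter shrinks each pixel toward its local window mean by the
ratio of the global noise variance to the local variance:

    out = in - min(1, sigma_n^2 / sigma_local^2) * (in - local_mean)

so flat regions (local variance close to the noise floor) are replaced by
the local mean while edges (high local variance) pass through nearly
untouched.  The ratio is clamped at 1 to avoid overshoot where the local
variance falls below the noise estimate, standard Wiener-filter practice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from sklearn.base import BaseEstimator, TransformerMixin

#: ITU-R BT.601 luminance weights for RGB -> gray.
_LUMA = np.array([0.299, 0.587, 0.114])

_VAR_EPS = 1e-12  # guard against zero local variance in flat windows


def check_gray_image(img: np.ndarray) -> np.ndarray:
    """Validate a 2D intensity image with finite values in [0, 1]."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected a 2D grayscale image, got shape {img.shape}")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    if img.min() < 0 or img.max() > 1:
        raise ValueError("image intensities must lie in [0, 1]")
    return img


@dataclass(frozen=True)
class NoiseStats:
    """Local first/second moments of an image plus a global noise estimate.

    ``global_noise_variance`` is the mean of the local window variances,
    which for a stationary noise field converges on the noise variance.
    """

    global_noise_variance: float
    local_mean: np.ndarray
    local_variance: np.ndarray
    window_size: int


def to_grayscale(rgb_image: np.ndarray) -> np.ndarray:
    """Convert an (H, W, 3) image in [0, 1] to luminance-weighted grayscale."""
    rgb = np.asarray(rgb_image, dtype=np.float64)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got shape {rgb.shape}")
    if rgb.min() < 0 or rgb.max() > 1:
        raise ValueError("RGB values must lie in [0, 1]")
    return np.clip(rgb @ _LUMA, 0.0, 1.0)


def estimate_noise(img: np.ndarray, window_size: int = 3) -> NoiseStats:
    """Moving-window mean/variance (reflective borders) and the global
    noise-variance estimate (mean of local variances)."""
    img = check_gray_image(img)
    if window_size % 2 == 0 or window_size < 3:
        raise ValueError("window_size must be odd and >= 3")
    if window_size > min(img.shape):
        raise ValueError("window_size exceeds image extent")
    local_mean = ndi.uniform_filter(img, size=window_size, mode="reflect")
    local_sq = ndi.uniform_filter(img * img, size=window_size, mode="reflect")
    local_var = np.maximum(local_sq - local_mean**2, 0.0)
    return NoiseStats(
        global_noise_variance=float(local_var.mean()),
        local_mean=local_mean,
        local_variance=local_var,
        window_size=window_size,
    )


def adaptive_filter(img: np.ndarray, stats: NoiseStats) -> np.ndarray:
    """Apply the Wiener-type shrinkage toward the local mean.

    Limiting behavior: zero global noise variance leaves the image
    untouched; where the local variance equals the global estimate, the
    output is exactly the local mean; where the local variance dominates
    (edges), the pixel is nearly preserved.
    """
    img = check_gray_image(img)
    if stats.local_mean.shape != img.shape:
        raise ValueError("stats shape does not match image")
    ratio = np.minimum(
        1.0, stats.global_noise_variance / np.maximum(stats.local_variance, _VAR_EPS)
    )
    out = img - ratio * (img - stats.local_mean)
    return np.clip(out, 0.0, 1.0)


def denoise(img: np.ndarray, window_size: int = 3) -> np.ndarray:
    """Convenience: estimate noise stats then adaptive-filter in one call."""
    return adaptive_filter(img, estimate_noise(img, window_size))


def sharpen(img: np.ndarray, amount: float = 1.0, sigma: float = 1.0) -> np.ndarray:
    """Unsharp masking: ``clip(in + amount * (in - gaussian_blur(in)))``."""
    img = check_gray_image(img)
    if amount < 0:
        raise ValueError("amount must be nonnegative")
    if amount == 0:
        return img.copy()
    blurred = ndi.gaussian_filter(img, sigma=sigma, mode="reflect")
    return np.clip(img + amount * (img - blurred), 0.0, 1.0)


class AdaptiveDenoiser(TransformerMixin, BaseEstimator):
    """sklearn-style transformer applying the adaptive filter to a stack of
    images, optionally followed by unsharp sharpening.

    Parameters
    ----------
    window_size : int, default 3
        Odd side length of the local-statistics window.
    sharpen_amount : float, default 0.0
        Unsharp-mask strength applied after denoising; 0 disables it.
    """

    def __init__(self, window_size: int = 3, sharpen_amount: float = 0.0):
        self.window_size = window_size
        self.sharpen_amount = sharpen_amount

    def fit(self, X, y=None):
        X = np.asarray(X)
        if X.ndim != 3:
            raise ValueError("expected a stack of 2D images with shape (n, H, W)")
        self.n_features_in_ = X.shape[1] * X.shape[2]
        return self

    def transform(self, X):
        X = np.asarray(X)
        if X.ndim != 3:
            raise ValueError("expected a stack of 2D images with shape (n, H, W)")
        out = np.empty_like(X, dtype=np.float64)
        for i, img in enumerate(X):
            filtered = denoise(img, self.window_size)
            if self.sharpen_amount > 0:
                filtered = sharpen(filtered, self.sharpen_amount)
            out[i] = filtered
        return out
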