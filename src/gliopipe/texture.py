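"""LBP-GLCM ("LBGLCM") texture features.

The texture descriptor is computed in two stages: an 8-neighbor local
binary pattern turns the intensity image into a map of 8-bit codes, and a
gray-level co-occurrence matrix built over the quantized code map yields
five Haralick-style statistics:

    energy       sum p^2                      in (0, 1], 1 for a constant image
    entropy      -sum p ln p                  in [0, ln L^2], nats
    contrast     sum p (x - y)^2
    homogeneity  sum p / (1 + (x - y)^2)      in (0, 1]
    correlation  sum p (x - mu_i)(y - mu_j) / (sigma_i sigma_j)   in [-1, 1]

Co-occurrences are accumulated symmetrically at distance 1 along the four
standard directions (0, 45, 90, 135 degrees) and the per-angle feature
vectors are averaged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import graycomatrix
from sklearn.base import BaseEstimator, TransformerMixin

from .preprocessing import check_gray_image

#: Neighbor offsets clockwise from the top-left; the first offset maps to
#: the most significant bit of the 8-bit code.
_LBP_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, 1),
                (1, 1), (1, 0), (1, -1), (0, -1)]

_VALID_ANGLES = (0, 45, 90, 135)

FEATURE_NAMES = ("energy", "entropy", "contrast", "homogeneity", "correlation")


@dataclass(frozen=True)
class GLCMatrix:
    """Normalized co-occurrence matrix over quantized LBP codes, with its
    marginal means/standard deviations."""

    probs: np.ndarray  # (L, L), nonnegative, sums to 1
    levels: int
    distance: int
    angle: int  # degrees
    row_mean: float
    col_mean: float
    row_std: float
    col_std: float


@dataclass(frozen=True)
class FeatureVector:
    energy: float
    entropy: float
    contrast: float
    homogeneity: float
    correlation: float

    def to_array(self) -> np.ndarray:
        return np.array([self.energy, self.entropy, self.contrast,
                         self.homogeneity, self.correlation])


def lbp(img: np.ndarray) -> np.ndarray:
    """8-neighbor, radius-1 local binary pattern with reflective borders.

    Each neighbor >= center contributes a 1 bit; bits are packed clockwise
    from the top-left neighbor, most significant bit first.  A constant
    image therefore maps to all-255 codes.
    """
    img = check_gray_image(img)
    if img.shape[0] < 3 or img.shape[1] < 3:
        raise ValueError("image must be at least 3x3 for the LBP operator")
    padded = np.pad(img, 1, mode="reflect")
    h, w = img.shape
    codes = np.zeros((h, w), dtype=np.uint8)
    for bit, (dy, dx) in enumerate(_LBP_OFFSETS):
        neighbor = padded[1 + dy:1 + dy + h, 1 + dx:1 + dx + w]
        codes |= (neighbor >= img).astype(np.uint8) << (7 - bit)
    return codes


def quantize_codes(codes: np.ndarray, levels: int) -> np.ndarray:
    """Map 8-bit codes onto ``levels`` equal bins (floor of code*L/256)."""
    if 256 % levels != 0 or not (1 <= levels <= 256):
        raise ValueError("levels must divide 256")
    return (codes.astype(np.int64) * levels) // 256


def build_glcm(lbp_img: np.ndarray, distance: int = 1, angle: int = 0,
               levels: int = 32) -> GLCMatrix:
    """Symmetric, normalized co-occurrence matrix of the quantized code map
    at the given pixel offset."""
    codes = np.asarray(lbp_img)
    if codes.min() < 0 or codes.max() > 255:
        raise ValueError("LBP codes must lie in [0, 255]")
    if distance < 1:
        raise ValueError("distance must be >= 1")
    if angle not in _VALID_ANGLES:
        raise ValueError(f"angle must be one of {_VALID_ANGLES}")
    q = quantize_codes(codes, levels).astype(np.uint8)
    raw = graycomatrix(q, distances=[distance], angles=[np.deg2rad(angle)],
                       levels=levels, symmetric=True, normed=False)
    counts = raw[:, :, 0, 0].astype(np.float64)
    total = counts.sum()
    if total == 0:
        raise ValueError("image too small: no valid pixel pairs at this offset")
    probs = counts / total
    idx = np.arange(levels, dtype=np.float64)
    p_row = probs.sum(axis=1)
    p_col = probs.sum(axis=0)
    mu_i = float(idx @ p_row)
    mu_j = float(idx @ p_col)
    sig_i = float(np.sqrt(((idx - mu_i) ** 2) @ p_row))
    sig_j = float(np.sqrt(((idx - mu_j) ** 2) @ p_col))
    return GLCMatrix(probs=probs, levels=levels, distance=distance, angle=angle,
                     row_mean=mu_i, col_mean=mu_j, row_std=sig_i, col_std=sig_j)


def _probs(g: GLCMatrix | np.ndarray) -> np.ndarray:
    return g.probs if isinstance(g, GLCMatrix) else np.asarray(g, dtype=np.float64)


def energy(g: GLCMatrix | np.ndarray) -> float:
    """Sum of squared entries; 1 exactly when a single entry holds all mass."""
    p = _probs(g)
    return float((p * p).sum())


def entropy(g: GLCMatrix | np.ndarray) -> float:
    """Shannon entropy -sum p ln p in nats, with 0 ln 0 = 0."""
    p = _probs(g)
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def contrast(g: GLCMatrix | np.ndarray) -> float:
    """Intensity-difference moment sum p(x,y) (x - y)^2."""
    p = _probs(g)
    x, y = np.indices(p.shape)
    return float((p * (x - y) ** 2).sum())


def homogeneity(g: GLCMatrix | np.ndarray) -> float:
    """Inverse difference moment sum p / (1 + (x - y)^2), in (0, 1]."""
    p = _probs(g)
    x, y = np.indices(p.shape)
    return float((p / (1.0 + (x - y) ** 2)).sum())


def correlation(g: GLCMatrix | np.ndarray) -> float:
    """Marginal-normalized covariance, in [-1, 1].

    A single-level image has zero marginal spread; that degenerate case is
    defined as perfect correlation, 1.0.
    """
    p = _probs(g)
    if isinstance(g, GLCMatrix):
        mu_i, mu_j, sig_i, sig_j = g.row_mean, g.col_mean, g.row_std, g.col_std
    else:
        idx = np.arange(p.shape[0], dtype=np.float64)
        p_row, p_col = p.sum(axis=1), p.sum(axis=0)
        mu_i, mu_j = float(idx @ p_row), float(idx @ p_col)
        sig_i = float(np.sqrt(((idx - mu_i) ** 2) @ p_row))
        sig_j = float(np.sqrt(((idx - mu_j) ** 2) @ p_col))
    if sig_i < 1e-12 or sig_j < 1e-12:
        return 1.0
    x, y = np.indices(p.shape)
    return float((p * (x - mu_i) * (y - mu_j)).sum() / (sig_i * sig_j))


def features_from_glcm(g: GLCMatrix | np.ndarray) -> FeatureVector:
    return FeatureVector(energy=energy(g), entropy=entropy(g),
                         contrast=contrast(g), homogeneity=homogeneity(g),
                         correlation=correlation(g))


def extract_features(img: np.ndarray, levels: int = 32, distance: int = 1,
                     angles: tuple[int, ...] = _VALID_ANGLES,
                     mask: np.ndarray | None = None) -> FeatureVector:
    """LBP -> per-angle GLCM -> five statistics, averaged over angles.

    Features are computed on the whole image by default; passing ``mask``
    restricts the analysis window to the mask's bounding box (texture of
    the segmented region).
    """
    img = check_gray_image(img)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("mask is empty")
        ys, xs = np.nonzero(mask)
        img = img[max(ys.min(), 0):ys.max() + 1, max(xs.min(), 0):xs.max() + 1]
        if img.shape[0] < 3 or img.shape[1] < 3:
            raise ValueError("masked region smaller than the 3x3 LBP support")
    codes = lbp(img)
    vectors = [features_from_glcm(build_glcm(codes, distance, a, levels))
               for a in angles]
    stacked = np.stack([v.to_array() for v in vectors])
    return FeatureVector(*stacked.mean(axis=0))


class LBGLCMExtractor(TransformerMixin, BaseEstimator):
    """sklearn-style transformer mapping a stack of images to the five
    angle-averaged LBP-GLCM statistics.

    Parameters
    ----------
    levels : int, default 32
        GLCM quantization bins over the 256 LBP codes (must divide 256).
    distance : int, default 1
        Pixel-pair offset distance.
    angles : tuple of int, default (0, 45, 90, 135)
        Co-occurrence directions in degrees.
    """

    def __init__(self, levels: int = 32, distance: int = 1,
                 angles: tuple[int, ...] = _VALID_ANGLES):
        self.levels = levels
        self.distance = distance
        self.angles = angles

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
        return np.stack([
            extract_features(img, self.levels, self.distance, self.angles).to_array()
            for img in X
        ])

    def get_feature_names_out(self, input_features=None):
        return np.asarray(FEATURE_NAMES, dtype=object)
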