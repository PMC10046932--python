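"""Fuzzy c-means tumor segmentation with morphological cleanup.

Pixels are clustered on intensity alone into ``c`` fuzzy clusters.  Each
pixel j holds a membership V_ij in [0, 1] for every cluster i, columns
summing to 1, computed from inverse distance ratios raised to 2/(m-1):

    V_ij = 1 / sum_l ( |a_j - c_i| / |a_j - c_l| )^(2/(m-1))

Centers are the membership-weighted means  c_i = sum_j V_ij^m a_j / sum_j V_ij^m.
The two updates alternate until the largest membership change drops below a
tolerance.  Defuzzification assigns each pixel its maximum-membership
cluster; the cluster with the brightest center is taken as tumor, then a
binary opening, hole filling, and a minimum-area rule on the largest
connected component yield the final mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from sklearn.base import BaseEstimator, ClusterMixin

from .preprocessing import check_gray_image

_ZERO_DIST = 1e-15


@dataclass
class FuzzyPartition:
    """State of a fuzzy c-means run: memberships (c, N), sorted centers,
    the fuzziness exponent, the stopping tolerance, the number of
    iterations executed, and whether the tolerance was reached."""

    memberships: np.ndarray
    centers: np.ndarray
    fuzziness: float
    tolerance: float
    iterations_run: int
    converged: bool


@dataclass
class TumorMask:
    """Binary tumor mask plus the index of the cluster it came from."""

    pixels: np.ndarray  # bool (H, W)
    tumor_cluster_index: int


def _memberships_tolerant(values: np.ndarray, centers: np.ndarray,
                          m: float) -> np.ndarray:
    """Membership update; pixels at zero distance to one or more centers
    split their unit membership equally among those centers."""
    dist = np.abs(values[None, :] - centers[:, None])  # (c, N)
    zero = dist < _ZERO_DIST
    any_zero = zero.any(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = dist ** (-2.0 / (m - 1.0))
        V = inv / inv.sum(axis=0, keepdims=True)
    if any_zero.any():
        cols = zero[:, any_zero]
        V[:, any_zero] = cols / cols.sum(axis=0, keepdims=True)
    return V


def fcm_memberships(pixel_values: np.ndarray, centers: np.ndarray,
                    m: float) -> np.ndarray:
    """Membership matrix (c, N) for the given centers.

    A pixel coinciding exactly with a center gets membership 1 there and 0
    elsewhere; duplicate centers are rejected.
    """
    values = np.asarray(pixel_values, dtype=np.float64).ravel()
    centers = np.asarray(centers, dtype=np.float64).ravel()
    if m <= 1:
        raise ValueError("fuzziness m must be > 1")
    if len(np.unique(centers)) != centers.size:
        raise ValueError("cluster centers must be distinct")
    return _memberships_tolerant(values, centers, m)


def fcm_update_centers(pixel_values: np.ndarray, memberships: np.ndarray,
                       m: float) -> np.ndarray:
    """Weighted-mean center update: c_i = sum_j V_ij^m a_j / sum_j V_ij^m."""
    values = np.asarray(pixel_values, dtype=np.float64).ravel()
    V = np.asarray(memberships, dtype=np.float64)
    Vm = V**m
    wsum = Vm.sum(axis=1)
    if np.any(wsum <= 0):
        raise ValueError("a cluster has all-zero membership weights")
    return (Vm @ values) / wsum


def fcm_objective(pixel_values: np.ndarray, memberships: np.ndarray,
                  centers: np.ndarray, m: float) -> float:
    """FCM objective sum_i sum_j V_ij^m |a_j - c_i|^2 (non-increasing under
    the alternating updates)."""
    values = np.asarray(pixel_values, dtype=np.float64).ravel()
    d2 = (values[None, :] - np.asarray(centers)[:, None]) ** 2
    return float((np.asarray(memberships) ** m * d2).sum())


def fcm_init(img: np.ndarray, c: int, seed: int = 0) -> FuzzyPartition:
    """Draw ``c`` centers uniformly from the image's intensity range (sorted
    ascending) and compute the corresponding memberships."""
    img = check_gray_image(img)
    if not (2 <= c <= 10):
        raise ValueError("cluster count c must be in [2, 10]")
    rng = np.random.default_rng(seed)
    lo, hi = float(img.min()), float(img.max())
    if hi - lo < _ZERO_DIST:
        # Degenerate constant image: spread centers over a token interval so
        # they are distinct; the singularity rule handles the memberships.
        lo, hi = lo - 1e-6 * (c - 1), hi + 1e-6 * (c - 1)
    centers = np.sort(rng.uniform(lo, hi, size=c))
    while len(np.unique(centers)) != c:  # vanishingly unlikely ties
        centers = np.sort(rng.uniform(lo, hi, size=c))
    values = img.ravel()
    V = _memberships_tolerant(values, centers, 2.0)
    return FuzzyPartition(memberships=V, centers=centers, fuzziness=2.0,
                          tolerance=np.inf, iterations_run=0, converged=False)


def fcm_run(img: np.ndarray, c: int = 3, m: float = 2.0, eps: float = 1e-5,
            max_iter: int = 100, seed: int = 0) -> FuzzyPartition:
    """Alternate membership and center updates until the maximum absolute
    membership change falls below ``eps`` or ``max_iter`` is reached.

    Non-convergence is flagged on the returned partition, not raised.
    """
    img = check_gray_image(img)
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if m <= 1:
        raise ValueError("fuzziness m must be > 1")
    part = fcm_init(img, c, seed)
    values = img.ravel()
    V = part.memberships
    centers = part.centers
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        centers = fcm_update_centers(values, V, m)
        V_new = _memberships_tolerant(values, centers, m)
        delta = float(np.abs(V_new - V).max())
        V = V_new
        if delta < eps:
            converged = True
            break
    order = np.argsort(centers)
    return FuzzyPartition(memberships=V[order], centers=centers[order],
                          fuzziness=m, tolerance=eps, iterations_run=it,
                          converged=converged)


def threshold_partition(partition: FuzzyPartition, img: np.ndarray) -> TumorMask:
    """Defuzzify: each pixel goes to its maximum-membership cluster (ties to
    the brighter center); the brightest cluster is declared tumor."""
    img = check_gray_image(img)
    c = partition.memberships.shape[0]
    order = np.argsort(partition.centers)
    # Scan clusters from brightest to darkest so argmax ties resolve bright.
    V_sorted = partition.memberships[order][::-1]
    labels_desc = np.argmax(V_sorted, axis=0)
    labels = (c - 1) - labels_desc  # index into ascending-center order
    tumor_idx = int(order[c - 1])
    mask = (labels == c - 1).reshape(img.shape)
    return TumorMask(pixels=mask, tumor_cluster_index=tumor_idx)


def morph_cleanup(mask: TumorMask | np.ndarray, min_area: int = 4) -> TumorMask:
    """Binary opening (3x3), hole filling, then keep the largest connected
    component if its area reaches ``min_area``, else an empty mask."""
    if isinstance(mask, TumorMask):
        pixels, idx = mask.pixels, mask.tumor_cluster_index
    else:
        pixels, idx = np.asarray(mask, dtype=bool), -1
    struct = np.ones((3, 3), dtype=bool)
    opened = ndi.binary_opening(pixels, structure=struct)
    filled = ndi.binary_fill_holes(opened)
    labeled, n = ndi.label(filled)
    if n == 0:
        return TumorMask(pixels=np.zeros_like(pixels), tumor_cluster_index=idx)
    sizes = ndi.sum_labels(np.ones_like(labeled), labeled, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] < min_area:
        return TumorMask(pixels=np.zeros_like(pixels), tumor_cluster_index=idx)
    return TumorMask(pixels=labeled == best, tumor_cluster_index=idx)


def tumor_stats(mask: TumorMask | np.ndarray,
                brain_mask: np.ndarray) -> tuple[float, int]:
    """(tumor-affected percent of the brain region, defective pixel count)."""
    pixels = mask.pixels if isinstance(mask, TumorMask) else np.asarray(mask, bool)
    brain = np.asarray(brain_mask, dtype=bool)
    brain_count = int(brain.sum())
    if brain_count == 0:
        raise ValueError("brain mask is empty")
    count = int(pixels.sum())
    return 100.0 * count / brain_count, count


def segment_image(img: np.ndarray, c: int = 3, m: float = 2.0,
                  eps: float = 1e-5, max_iter: int = 100, seed: int = 0,
                  min_area: int | None = None,
                  min_separation: float = 0.05) -> TumorMask:
    """Full segmentation path: FCM, defuzzification, morphological cleanup.

    ``min_area`` defaults to 0.1% of the image pixels.  A slice is declared
    tumor-free when the brightest cluster fails either of two gates that
    encode "a tumor is a bright minority region":

    * separation: its center must sit at least ``min_separation`` above the
      next center (on a tumor-free brain the top cluster is either the
      upper tail of the tissue noise, hugging the tissue center, or the
      tissue itself after the spare cluster drifts into the background);
    * area: its crisp support must not exceed ``max_area_fraction`` of the
      image (a "tumor" covering most of the brain is the brain).
    """
    img = check_gray_image(img)
    if min_area is None:
        min_area = max(1, int(round(0.001 * img.size)))
    max_area_fraction = 0.35
    part = fcm_run(img, c=c, m=m, eps=eps, max_iter=max_iter, seed=seed)
    empty = TumorMask(pixels=np.zeros(img.shape, dtype=bool),
                      tumor_cluster_index=int(len(part.centers) - 1))
    if part.centers[-1] - part.centers[-2] < min_separation:
        return empty
    raw = threshold_partition(part, img)
    if raw.pixels.sum() > max_area_fraction * img.size:
        return empty
    return morph_cleanup(raw, min_area=min_area)


class FuzzyCMeans(ClusterMixin, BaseEstimator):
    """sklearn-style fuzzy c-means on scalar intensities.

    Parameters
    ----------
    n_clusters : int, default 3
        Number of fuzzy clusters (background / brain / tumor by default).
    fuzziness : float, default 2.0
        Membership softness exponent m > 1.
    tol : float, default 1e-5
        Stop when the largest absolute membership change drops below this.
    max_iter : int, default 100
    random_state : int, default 0
        Seed for the uniform center initialization.

    Attributes
    ----------
    cluster_centers_ : ndarray (n_clusters,), ascending
    memberships_ : ndarray (n_clusters, n_samples)
    labels_ : ndarray (n_samples,) crisp maximum-membership labels
    n_iter_ : int
    converged_ : bool
    """

    def __init__(self, n_clusters: int = 3, fuzziness: float = 2.0,
                 tol: float = 1e-5, max_iter: int = 100, random_state: int = 0):
        self.n_clusters = n_clusters
        self.fuzziness = fuzziness
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def _flatten(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 2 and X.shape[1] == 1:
            X = X[:, 0]
        if X.ndim != 1:
            raise ValueError("expected scalar intensities of shape (n,) or (n, 1)")
        return X

    def fit(self, X, y=None):
        values = self._flatten(X)
        # Reuse the image-based driver on a 1-row "image"; clip guards the
        # [0, 1] contract of the imaging path.
        img = np.clip(values, 0.0, 1.0).reshape(1, -1)
        part = fcm_run(img, c=self.n_clusters, m=self.fuzziness, eps=self.tol,
                       max_iter=self.max_iter, seed=self.random_state)
        self.cluster_centers_ = part.centers
        self.memberships_ = part.memberships
        self.n_iter_ = part.iterations_run
        self.converged_ = part.converged
        c = self.n_clusters
        self.labels_ = (c - 1) - np.argmax(part.memberships[::-1], axis=0)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        values = self._flatten(X)
        V = fcm_memberships(values, self.cluster_centers_, self.fuzziness)
        c = self.n_clusters
        return (c - 1) - np.argmax(V[::-1], axis=0)
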