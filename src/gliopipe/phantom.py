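"""Synthetic brain phantoms with ground-truth tumor masks.

A phantom is an elliptical "brain" region at mid intensity on a dark
background, optionally containing a bright, irregular tumor blob of
controllable area, plus additive Gaussian noise.  Every phantom carries its
exact tumor mask, so segmentation and classification stages can be scored
against a known truth.  Generation is fully deterministic given the spec and
its seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

BACKGROUND_LEVEL = 0.05
BRAIN_LEVEL = 0.45

LABEL_TUMOR = "tumor"
LABEL_NORMAL = "normal"


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic brain slice.

    Parameters
    ----------
    height, width : int
        Image size in pixels, at least 16 each.
    has_tumor : bool
        Whether a tumor blob is placed.  ``tumor_area_fraction`` must be 0
        exactly when this is False.
    tumor_area_fraction : float
        Target tumor area as a fraction of the brain-ellipse area, in
        (0, 0.4] for tumor phantoms.
    tumor_contrast : float
        Intensity offset of the tumor above the brain level, in [0.1, 0.5].
    noise_variance : float
        Variance of the additive zero-mean Gaussian noise (intensity^2).
    seed : int
        Seed of the per-phantom random generator.
    """

    height: int = 64
    width: int = 64
    has_tumor: bool = True
    tumor_area_fraction: float = 0.1
    tumor_contrast: float = 0.3
    noise_variance: float = 0.002
    seed: int = 0

    def validate(self) -> None:
        if self.height < 16 or self.width < 16:
            raise ValueError("phantom size must be at least 16x16")
        if self.has_tumor:
            if not (0.0 < self.tumor_area_fraction <= 0.4):
                raise ValueError(
                    "tumor_area_fraction must be in (0, 0.4] for tumor phantoms"
                )
            if not (0.1 <= self.tumor_contrast <= 0.5):
                raise ValueError("tumor_contrast must be in [0.1, 0.5]")
        elif self.tumor_area_fraction != 0.0:
            raise ValueError("tumor_area_fraction must be 0 when has_tumor is False")
        if self.noise_variance < 0:
            raise ValueError("noise_variance must be nonnegative")


@dataclass(frozen=True)
class LabeledImage:
    """A phantom image together with its class label and truth mask."""

    image: np.ndarray  # float64 (H, W) in [0, 1]
    label: str  # "tumor" | "normal"
    truth_mask: np.ndarray  # bool (H, W)
    spec: PhantomSpec


def _ellipse_mask(u: np.ndarray, v: np.ndarray, cu: float, cv: float,
                  ru: float, rv: float) -> np.ndarray:
    return ((u - cu) / ru) ** 2 + ((v - cv) / rv) ** 2 <= 1.0


def make_phantom(spec: PhantomSpec) -> LabeledImage:
    """Generate one phantom deterministically from ``spec``.

    The brain ellipse covers 40-70% of the image; the tumor is a union of
    1-3 overlapping ellipses placed fully inside the brain, rescaled once so
    its pixel count lands near ``tumor_area_fraction`` of the brain area.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width

    # Brain ellipse in pixel coordinates; semi-axis fractions keep the area
    # fraction pi*fa*fb/4 inside [0.44, 0.64] of the image.
    fa = rng.uniform(0.78, 0.92)
    fb = rng.uniform(0.72, 0.88)
    cy = h / 2.0 + rng.uniform(-0.02, 0.02) * h
    cx = w / 2.0 + rng.uniform(-0.02, 0.02) * w
    a = fa * h / 2.0
    b = fb * w / 2.0

    yy, xx = np.mgrid[0:h, 0:w]
    # Normalized coordinates: the brain is the unit disc in (u, v).
    u = (yy - cy) / a
    v = (xx - cx) / b
    brain = u * u + v * v <= 1.0
    brain_area = int(brain.sum())

    tumor = np.zeros((h, w), dtype=bool)
    if spec.has_tumor:
        # In normalized coordinates a scaled copy of the brain ellipse with
        # scale s has area fraction s^2 of the brain, so s = sqrt(fraction)
        # is the natural starting size.
        s = float(np.sqrt(spec.tumor_area_fraction))
        n_blobs = int(rng.integers(1, 4))
        shape_jitter = rng.uniform(0.85, 1.18)
        # Keep the whole blob union inside the unit disc with a margin.
        reach = s * max(shape_jitter, 1 / shape_jitter) * (1.0 + 0.45 * (n_blobs > 1))
        rho_max = max(0.0, 1.0 - reach - 0.05)
        rho = rng.uniform(0.0, rho_max)
        phi = rng.uniform(0.0, 2 * np.pi)
        cu0, cv0 = rho * np.cos(phi), rho * np.sin(phi)
        sat_phis = rng.uniform(0.0, 2 * np.pi, size=2)
        sat_scales = rng.uniform(0.35, 0.5, size=2)

        def rasterize(scale: float) -> np.ndarray:
            m = _ellipse_mask(u, v, cu0, cv0,
                              scale * shape_jitter, scale / shape_jitter)
            for k in range(n_blobs - 1):
                sk = scale * sat_scales[k]
                m |= _ellipse_mask(u, v,
                                   cu0 + scale * np.cos(sat_phis[k]),
                                   cv0 + scale * np.sin(sat_phis[k]),
                                   sk, sk)
            return m & brain

        tumor = rasterize(s)
        target = spec.tumor_area_fraction * brain_area
        actual = tumor.sum()
        if actual > 0 and not (0.85 * target <= actual <= 1.15 * target):
            tumor = rasterize(s * float(np.sqrt(target / actual)))

    img = np.full((h, w), BACKGROUND_LEVEL, dtype=np.float64)
    img[brain] = BRAIN_LEVEL
    img[tumor] = BRAIN_LEVEL + spec.tumor_contrast
    if spec.noise_variance > 0:
        img = img + rng.normal(0.0, np.sqrt(spec.noise_variance), size=(h, w))
    img = np.clip(img, 0.0, 1.0)

    label = LABEL_TUMOR if tumor.any() else LABEL_NORMAL
    return LabeledImage(image=img, label=label, truth_mask=tumor, spec=spec)


def brain_mask(spec_or_item: "PhantomSpec | LabeledImage") -> np.ndarray:
    """Recover the brain-ellipse mask of a phantom (noise-free geometry)."""
    spec = spec_or_item.spec if isinstance(spec_or_item, LabeledImage) else spec_or_item
    clean = make_phantom(replace(spec, noise_variance=0.0))
    return clean.image > (BACKGROUND_LEVEL + BRAIN_LEVEL) / 2.0


def make_dataset(n: int, tumor_fraction: float,
                 base_spec: PhantomSpec | None = None,
                 seed: int = 0) -> list[LabeledImage]:
    """Generate ``n`` phantoms with exactly ``round(n * tumor_fraction)``
    tumor-labeled items, per-item geometry jittered reproducibly from ``seed``.
    """
    if n < 2:
        raise ValueError("n must be at least 2")
    if not (0.0 <= tumor_fraction <= 1.0):
        raise ValueError("tumor_fraction must be in [0, 1]")
    if base_spec is None:
        base_spec = PhantomSpec()
    n_tumor = int(round(n * tumor_fraction))

    rng = np.random.default_rng(seed)
    labels = np.array([True] * n_tumor + [False] * (n - n_tumor))
    rng.shuffle(labels)

    base_frac = base_spec.tumor_area_fraction if base_spec.has_tumor else 0.1
    items = []
    for is_tumor in labels:
        child_seed = int(rng.integers(0, 2**31 - 1))
        frac = float(np.clip(base_frac * rng.uniform(0.7, 1.3), 0.02, 0.4))
        contrast = float(np.clip(base_spec.tumor_contrast * rng.uniform(0.85, 1.15),
                                 0.1, 0.5))
        spec = replace(
            base_spec,
            has_tumor=bool(is_tumor),
            tumor_area_fraction=frac if is_tumor else 0.0,
            tumor_contrast=contrast,
            seed=child_seed,
        )
        items.append(make_phantom(spec))
    return items


def write_dataset(items: list[LabeledImage], out_dir: str | Path,
                  fmt: str = "png") -> Path:
    """Write phantoms as images plus a manifest CSV; returns the manifest path.

    ``fmt`` is ``png`` (8-bit) or ``nii`` (float NIfTI).
    """
    from . import io as gio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "label", "tumor_area_fraction", "seed"])
        for i, item in enumerate(items):
            ext = "nii" if fmt == "nii" else "png"
            name = f"phantom_{i:05d}.{ext}"
            gio.write_image(item.image, out / name)
            writer.writerow([name, item.label,
                            f"{item.spec.tumor_area_fraction:.6f}", item.spec.seed])
    return manifest
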