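"""Synthetic DBT phantom cohorts with microcalcification clusters.

Clinical DBT datasets of biopsy-proven microcalcification clusters (MCs)
are private; this module generates seeded stand-in cohorts that reproduce
the statistical structure the classification method relies on:

* anisotropic sampling (~0.1 mm in-plane, 1 mm between slices);
* a cluster of bright punctate spots whose rendering is sharp on exactly
  one *focus slice* and increasingly Gaussian-blurred with slice distance;
* class-dependent morphology — benign clusters are few, coarse and compact;
  malignant clusters are numerous, finer, more variable in size and more
  scattered (optionally elongated), echoing pleomorphic clinical patterns
  qualitatively (no clinical realism is claimed);
* two views (CC/MLO) per lesion re-rendered from one shared cluster draw;
* an 8:1:1 train/val/test split applied per class at the lesion level.

Everything is a pure function of (parameters, seed): identical inputs give
bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy.ndimage import gaussian_filter

from .preprocess import DbtRoi, INTENSITY_MAX, random_augmentation_op

__all__ = [
    "PhantomParams",
    "LesionRecord",
    "Cohort",
    "render_lesion",
    "generate_cohort",
    "augmentation_plan",
    "split_counts",
]

VIEWS = ("CC", "MLO")


@dataclass(frozen=True)
class PhantomParams:
    """Generator configuration.

    Spot radii are in pixels (physical size at 0.1 mm/px); cluster radii
    are fractions of the smaller in-plane extent so the cluster scales with
    the ROI.  ``blur_slope`` is the Gaussian sigma added per slice of
    distance from the focus slice, the knob that creates the focus-slice
    signal.
    """

    n_benign: int = 100
    n_malignant: int = 100
    roi_shape: tuple[int, int, int] = (300, 300, 12)  # (width, height, depth)
    spacing: tuple[float, float, float] = (0.1, 0.1, 1.0)
    spots_benign: tuple[int, int] = (3, 8)
    spots_malignant: tuple[int, int] = (10, 25)
    spot_radius_benign: tuple[float, float] = (4.0, 6.0)
    spot_radius_malignant: tuple[float, float] = (2.0, 6.0)  # finer, more variable
    spot_peak_intensity: tuple[float, float] = (500.0, 900.0)
    blur_slope: float = 0.9
    cluster_radius_frac_benign: float = 0.13
    cluster_radius_frac_malignant: float = 0.23
    background_texture_scale: float = 12.0
    background_mean: float = 250.0
    background_amplitude: float = 50.0
    noise_sd: float = 8.0
    view_jitter_px: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_benign < 0 or self.n_malignant < 0:
            raise ValueError("lesion counts must be non-negative")
        w, h, d = self.roi_shape
        if d < 2:
            raise ValueError("ROI depth must be at least 2 slices")
        dx, dy, dz = self.spacing
        if not dz / dx > 1:
            raise ValueError("spacing must be anisotropic (dz/dx > 1)")
        for lo, hi in (
            self.spots_benign,
            self.spots_malignant,
            self.spot_radius_benign,
            self.spot_radius_malignant,
            self.spot_peak_intensity,
        ):
            if lo > hi or lo < 0:
                raise ValueError("ranges must satisfy 0 <= low <= high")

    @classmethod
    def easy_desk(cls, n_benign: int = 50, n_malignant: int = 50, seed: int = 0
                  ) -> "PhantomParams":
        """Small, low-noise preset for desk-scale training experiments."""
        return cls(
            n_benign=n_benign,
            n_malignant=n_malignant,
            roi_shape=(64, 64, 12),
            spots_benign=(3, 8),
            spots_malignant=(10, 25),
            spot_radius_benign=(3.0, 4.5),
            spot_radius_malignant=(1.5, 4.0),
            noise_sd=4.0,
            seed=seed,
        )


@dataclass(frozen=True)
class LesionRecord:
    """One view of one lesion in a cohort manifest."""

    lesion_id: str
    patient_id: str
    view: str
    label: str  # "benign" | "malignant"
    split: str  # "train" | "val" | "test"
    volume_path: str = ""
    mask_path: str = ""
    focus_slice_gt: int | None = None

    def __post_init__(self) -> None:
        if self.view not in VIEWS:
            raise ValueError(f"view must be one of {VIEWS}, got {self.view!r}")
        if self.label not in ("benign", "malignant"):
            raise ValueError(f"bad label {self.label!r}")
        if self.split not in ("train", "val", "test"):
            raise ValueError(f"bad split {self.split!r}")


@dataclass
class Cohort:
    """In-memory cohort: manifest records plus rendered volumes.

    ``volumes`` maps (lesion_id, view) to (roi, mask, focus_slice_gt).
    """

    params: PhantomParams
    records: list[LesionRecord]
    volumes: dict[tuple[str, str], tuple[DbtRoi, np.ndarray, int]]

    def subset(self, split: str) -> list[LesionRecord]:
        return [r for r in self.records if r.split == split]


def _draw_cluster(params: PhantomParams, label: str, rng: np.random.Generator) -> dict:
    """Lesion-level latent draw shared by both views."""
    w, h, _ = params.roi_shape
    if label == "benign":
        n_lo, n_hi = params.spots_benign
        r_lo, r_hi = params.spot_radius_benign
        cluster_r = params.cluster_radius_frac_benign * min(w, h)
        elongation = 1.0
    else:
        n_lo, n_hi = params.spots_malignant
        r_lo, r_hi = params.spot_radius_malignant
        cluster_r = params.cluster_radius_frac_malignant * min(w, h)
        elongation = float(rng.uniform(1.0, 2.0))
    if min(w, h) / 2 <= r_hi + 2:
        raise ValueError(
            f"ROI in-plane size {(w, h)} too small for spots of radius {r_hi}"
        )
    n_spots = int(rng.integers(n_lo, n_hi + 1))
    theta = rng.uniform(0, 2 * np.pi)
    rot = np.array(
        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    )
    # uniform in an ellipse with semi-axes cluster_r*elongation, cluster_r/elongation
    u = rng.uniform(0, 1, size=n_spots)
    ang = rng.uniform(0, 2 * np.pi, size=n_spots)
    pts = np.stack(
        [
            np.sqrt(u) * np.cos(ang) * cluster_r * elongation,
            np.sqrt(u) * np.sin(ang) * cluster_r / elongation,
        ],
        axis=1,
    ) @ rot.T
    radii = rng.uniform(r_lo, r_hi, size=n_spots)
    peaks = rng.uniform(*params.spot_peak_intensity, size=n_spots)
    return {"offsets": pts, "radii": radii, "peaks": peaks}


def _render_spots(
    shape_hw: tuple[int, int],
    centers_xy: np.ndarray,
    radii: np.ndarray,
    peaks: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Sharp spot image (antialiased disks, max-composited) and support mask."""
    h, w = shape_hw
    img = np.zeros((h, w))
    mask = np.zeros((h, w), dtype=bool)
    for (cx, cy), r, peak in zip(centers_xy, radii, peaks):
        x0, x1 = int(np.floor(cx - r - 2)), int(np.ceil(cx + r + 2)) + 1
        y0, y1 = int(np.floor(cy - r - 2)), int(np.ceil(cy + r + 2)) + 1
        x0, x1 = max(0, x0), min(w, x1)
        y0, y1 = max(0, y0), min(h, y1)
        if x0 >= x1 or y0 >= y1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dist = np.hypot(xx - cx, yy - cy)
        coverage = np.clip(r + 0.5 - dist, 0.0, 1.0)  # soft 1-px rim
        patch = peak * coverage
        img[y0:y1, x0:x1] = np.maximum(img[y0:y1, x0:x1], patch)
        mask[y0:y1, x0:x1] |= dist <= r
    return img, mask


def render_lesion(
    params: PhantomParams,
    label: str,
    rng: np.random.Generator,
    cluster: dict | None = None,
) -> tuple[DbtRoi, np.ndarray, int]:
    """Render one view of one lesion.

    Returns the raw 10-bit ROI, the per-slice mask of unblurred spot
    support (identical across slices — spots do not move in z), and the
    ground-truth focus slice, drawn uniformly from interior slices.

    The background texture is a single smooth 2D field shared by all
    slices: over a ~1 cm stack the tissue pattern varies far more slowly
    than the MC sharpness does, and a z-constant background makes the
    focus-slice statistic exact in the noise-free limit.
    """
    if label not in ("benign", "malignant"):
        raise ValueError(f"bad label {label!r}")
    w, h, d = params.roi_shape
    if cluster is None:
        cluster = _draw_cluster(params, label, rng)

    # per-view re-projection jitter of the shared cluster geometry
    offsets = cluster["offsets"] + rng.normal(
        0.0, params.view_jitter_px, size=cluster["offsets"].shape
    )
    radii = cluster["radii"]
    margin = radii + 1.5
    centers = np.stack(
        [
            np.clip(w / 2 + offsets[:, 0], margin, w - 1 - margin),
            np.clip(h / 2 + offsets[:, 1], margin, h - 1 - margin),
        ],
        axis=1,
    )
    sharp, support = _render_spots((h, w), centers, radii, cluster["peaks"])
    if not support.any():
        raise ValueError("ROI too small to contain any spot")

    bg_field = gaussian_filter(
        rng.standard_normal((h, w)), params.background_texture_scale
    )
    sd = bg_field.std()
    if sd > 0:
        bg_field = bg_field / sd
    background = params.background_mean + params.background_amplitude * bg_field

    focus = int(rng.integers(1, d - 1))  # interior slice, never first/last
    vol = np.empty((h, w, d))
    for k in range(d):
        sigma = params.blur_slope * abs(k - focus)
        spots_k = gaussian_filter(sharp, sigma) if sigma > 0 else sharp
        vol[:, :, k] = background + spots_k
    if params.noise_sd > 0:
        vol += rng.normal(0.0, params.noise_sd, size=vol.shape)
    vol = np.clip(np.round(vol), 0, INTENSITY_MAX).astype(np.uint16)
    mask = np.repeat(support[:, :, None], d, axis=2).astype(np.uint8)
    roi = DbtRoi(intensities=vol, spacing=params.spacing, normalized=False)
    return roi, mask, focus


def split_counts(n: int) -> tuple[int, int, int]:
    """8:1:1 split sizes: train = round(0.8 n), val = floor(0.1 n), rest test.

    Reproduces the reference cohort bookkeeping exactly
    (173 -> 138/17/18, 322 -> 258/32/32).
    """
    if n < 3:
        raise ValueError(f"cannot split a class of {n} lesions 8:1:1")
    train = int(np.floor(0.8 * n + 0.5))
    val = int(np.floor(0.1 * n))
    test = n - train - val
    return train, val, test


def generate_cohort(params: PhantomParams) -> Cohort:
    """Generate the full two-view cohort with per-class 8:1:1 splits.

    Lesions map one-to-one to patients; splitting is at the lesion level so
    no patient appears in more than one split.
    """
    rng = np.random.default_rng(params.seed)
    records: list[LesionRecord] = []
    volumes: dict[tuple[str, str], tuple[DbtRoi, np.ndarray, int]] = {}
    lesion_counter = 0
    for label, n in (("benign", params.n_benign), ("malignant", params.n_malignant)):
        n_train, n_val, n_test = split_counts(n)
        splits = ["train"] * n_train + ["val"] * n_val + ["test"] * n_test
        order = rng.permutation(n)
        assigned = [""] * n
        for j, idx in enumerate(order):
            assigned[int(idx)] = splits[j]
        for i in range(n):
            lesion_counter += 1
            lesion_id = f"L{lesion_counter:04d}"
            patient_id = f"P{lesion_counter:04d}"
            cluster = _draw_cluster(params, label, rng)
            for view in VIEWS:
                roi, mask, focus = render_lesion(params, label, rng, cluster=cluster)
                records.append(
                    LesionRecord(
                        lesion_id=lesion_id,
                        patient_id=patient_id,
                        view=view,
                        label=label,
                        split=assigned[i],
                        focus_slice_gt=focus,
                    )
                )
                volumes[(lesion_id, view)] = (roi, mask, focus)
    return Cohort(params=params, records=records, volumes=volumes)


def augmentation_plan(
    n_benign_train: int,
    n_malignant_train: int,
    factors: tuple[int, int],
    seed: int = 0,
    max_shift: int = 20,
    max_angle: float = 20.0,
) -> tuple[tuple[int, int], list[tuple]]:
    """Per-class augmentation bookkeeping.

    With factors (f_b, f_m) each original training sample contributes f
    samples per epoch (the first is the untouched original, the rest are
    random translate/flip/rotate ops), so the augmented counts are
    (n_b * f_b, n_m * f_m).  The op list is a pure function of the seed.
    """
    f_b, f_m = factors
    if f_b < 1 or f_m < 1 or int(f_b) != f_b or int(f_m) != f_m:
        raise ValueError("augmentation factors must be integers >= 1")
    counts = (n_benign_train * f_b, n_malignant_train * f_m)
    rng = np.random.default_rng(seed)
    ops: list[tuple] = []
    for n, f in ((n_benign_train, f_b), (n_malignant_train, f_m)):
        for _ in range(n):
            ops.append(("identity",))
            for _ in range(f - 1):
                ops.append(random_augmentation_op(rng, max_shift, max_angle))
    return counts, ops
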