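"""Preprocessing chain for DBT lesion volumes.

Raw tomosynthesis reconstructions carry 10-bit intensities (0–1023) on an
anisotropic grid (~0.1 mm in-plane, ~1 mm between slices).  The chain here
mirrors the classification pipeline's input handling: crop a fixed
300x300x12 region around the lesion, min–max normalize the whole volume to
[0, 1], pick an N-slice slab centered on the focus slice for the 3D branch,
and resize the focus slice to 224x224 for the 2D branch.  Training-time
augmentation is geometric and strictly in-plane: translation, horizontal
flip and rotation, never mixing slices.

Array layout is ``(h, w, d)`` with the reconstruction (z) axis last and
0-based slice indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

__all__ = [
    "DbtRoi",
    "SlabConfig",
    "crop_roi",
    "minmax_normalize",
    "select_slab",
    "resize_slice",
    "augment_sample",
    "random_augmentation_op",
    "INTENSITY_MAX",
]

INTENSITY_MAX = 1023  # 10-bit detector scale


@dataclass
class DbtRoi:
    """An anisotropic DBT region of interest.

    ``intensities`` has shape (h, w, d).  Raw volumes hold integral values
    in [0, 1023]; after normalization values lie in [0, 1] and
    ``value_range`` records the source min/max used.
    """

    intensities: np.ndarray
    spacing: tuple[float, float, float] = (0.1, 0.1, 1.0)
    normalized: bool = False
    value_range: tuple[float, float] = (0.0, float(INTENSITY_MAX))

    def __post_init__(self) -> None:
        a = np.asarray(self.intensities)
        if a.ndim != 3 or a.shape[2] < 1:
            raise ValueError(f"expected a 3D (h, w, d) array, got shape {a.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if self.normalized:
            if a.min() < 0.0 or a.max() > 1.0:
                raise ValueError("normalized ROI must have values in [0, 1]")
        else:
            # detector output is integral, but resampled/averaged rasters
            # may carry fractions; only the 10-bit range is enforced
            if a.min() < 0 or a.max() > INTENSITY_MAX:
                raise ValueError(f"raw ROI must have values in [0, {INTENSITY_MAX}]")
        self.intensities = a

    @property
    def depth(self) -> int:
        return self.intensities.shape[2]


@dataclass(frozen=True)
class SlabConfig:
    """Slab extraction / 2D-resize configuration.

    ``n_slices`` follows the tested values {4, 6, 8, 10, 12}; 8 is the
    default (the best-performing slab depth).
    """

    n_slices: int = 8
    center_policy: str = "focus_centered"
    resize_2d: tuple[int, int] = (224, 224)

    def __post_init__(self) -> None:
        if self.n_slices < 2 or self.n_slices % 2 != 0:
            raise ValueError(f"n_slices must be even and >= 2, got {self.n_slices}")
        if self.center_policy != "focus_centered":
            raise ValueError(f"unknown center policy {self.center_policy!r}")


def crop_roi(
    volume: np.ndarray,
    center: tuple[int, int, int],
    size: tuple[int, int, int] = (300, 300, 12),
) -> np.ndarray:
    """Crop a fixed-size box centered on a lesion, edge-replicating at borders.

    ``center`` is (x, y, z) = (column, row, slice); ``size`` is
    (width, height, depth).  The output always has exactly the requested
    shape; regions falling outside the volume are filled by replicating the
    nearest edge voxel.
    """
    vol = np.asarray(volume)
    if vol.ndim != 3:
        raise ValueError("volume must be 3D (h, w, d)")
    cx, cy, cz = center
    w, h, d = size
    vh, vw, vd = vol.shape
    if not (0 <= cx < vw and 0 <= cy < vh and 0 <= cz < vd):
        raise ValueError(f"center {center} outside volume of shape {vol.shape}")
    if w > 2 * vw or h > 2 * vh or d > 2 * vd:
        raise ValueError(f"requested size {size} exceeds twice the volume extent")

    starts = (cy - h // 2, cx - w // 2, cz - d // 2)
    out_shape = (h, w, d)
    pads = []
    slices = []
    for start, extent, avail in zip(starts, out_shape, vol.shape):
        stop = start + extent
        pads.append((max(0, -start), max(0, stop - avail)))
        slices.append(slice(max(0, start), min(avail, stop)))
    crop = vol[tuple(slices)]
    if any(p != (0, 0) for p in pads):
        crop = np.pad(crop, pads, mode="edge")
    return crop


def minmax_normalize(roi: DbtRoi) -> DbtRoi:
    """Linear min–max rescaling of the whole volume into [0, 1].

    P_out = (P_in - P_min) / (P_max - P_min), with P_min/P_max the extremes
    of the whole source image, so the darkest voxel maps to 0 and the
    brightest to 1.
    """
    if roi.normalized:
        raise ValueError("ROI is already normalized")
    a = roi.intensities.astype(np.float64)
    p_min, p_max = float(a.min()), float(a.max())
    if p_max == p_min:
        raise ValueError("constant image: min–max normalization is undefined")
    out = (a - p_min) / (p_max - p_min)
    return DbtRoi(
        intensities=out,
        spacing=roi.spacing,
        normalized=True,
        value_range=(p_min, p_max),
    )


def select_slab(roi: DbtRoi, focus_idx: int, cfg: SlabConfig) -> np.ndarray:
    """Extract the N-slice slab around the focus slice.

    The window is [focus - N/2, focus + N/2 - 1] (one extra slice below the
    focus, keeping it nearest the window center); if it overruns the volume
    it is shifted minimally so it fits, and always contains the focus slice.
    """
    n = cfg.n_slices
    depth = roi.depth
    if n > depth:
        raise ValueError(f"slab of {n} slices exceeds ROI depth {depth}")
    if not 0 <= focus_idx < depth:
        raise ValueError(f"focus index {focus_idx} outside depth {depth}")
    start = focus_idx - n // 2
    start = min(max(start, 0), depth - n)
    return roi.intensities[:, :, start : start + n]


def resize_slice(slice_2d: np.ndarray, target: tuple[int, int] = (224, 224)) -> np.ndarray:
    """Bilinear resize of one slice; output values stay within the input range."""
    a = np.asarray(slice_2d, dtype=np.float64)
    if a.ndim != 2:
        raise ValueError("expected a 2D slice")
    th, tw = target
    if th <= 0 or tw <= 0:
        raise ValueError(f"target size must be positive, got {target}")
    if a.shape == (th, tw):
        return a.copy()
    return _sk_resize(a, (th, tw), order=1, anti_aliasing=False, preserve_range=True)


def _translate(plane: np.ndarray, dx: int, dy: int) -> np.ndarray:
    h, w = plane.shape
    pad = max(abs(dx), abs(dy))
    if pad == 0:
        return plane.copy()
    padded = np.pad(plane, pad, mode="edge")
    return padded[pad - dy : pad - dy + h, pad - dx : pad - dx + w]


def _apply_plane(sample: np.ndarray, fn) -> np.ndarray:
    """Apply a 2D transform to a slice or identically to every slab slice."""
    if sample.ndim == 2:
        return fn(sample)
    if sample.ndim == 3:
        return np.stack([fn(sample[:, :, k]) for k in range(sample.shape[2])], axis=2)
    raise ValueError("sample must be a 2D slice or a 3D (h, w, d) slab")


def augment_sample(sample: np.ndarray, op_spec: tuple, rng=None) -> np.ndarray:
    """Apply one geometric, in-plane augmentation.

    ``op_spec`` is one of ``("translate", (dx, dy))``, ``("hflip",)``, or
    ``("rotate", degrees)``.  Slabs are transformed slice by slice with the
    same parameters (never across slices); borders are edge-replicated.
    The label-irrelevant geometry is all that changes.
    """
    sample = np.asarray(sample, dtype=np.float64)
    kind = op_spec[0]
    if kind == "identity":
        return sample.copy()
    if kind == "translate":
        dx, dy = op_spec[1]
        return _apply_plane(sample, lambda p: _translate(p, int(dx), int(dy)))
    if kind == "hflip":
        return _apply_plane(sample, lambda p: p[:, ::-1].copy())
    if kind == "rotate":
        angle = float(op_spec[1])
        return _apply_plane(
            sample,
            lambda p: ndimage.rotate(
                p, angle, reshape=False, order=1, mode="nearest"
            ),
        )
    raise ValueError(f"unknown augmentation op {kind!r}")


def random_augmentation_op(
    rng: np.random.Generator,
    max_shift: int = 20,
    max_angle: float = 20.0,
) -> tuple:
    """Draw one op spec uniformly over the three op families."""
    kind = rng.integers(3)
    if kind == 0:
        dx = int(rng.integers(-max_shift, max_shift + 1))
        dy = int(rng.integers(-max_shift, max_shift + 1))
        return ("translate", (dx, dy))
    if kind == 1:
        return ("hflip",)
    return ("rotate", float(rng.uniform(-max_angle, max_angle)))
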