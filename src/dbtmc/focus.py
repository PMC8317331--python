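"""Focus-slice selection for microcalcification clusters.

In a DBT stack the cluster is sharp on exactly one slice and blurred
elsewhere.  The focus slice is defined as the slice maximizing the mean
gray level over microcalcification pixels:

    G(k) = sum_i sum_j p_ij^k / sum_i N_i ,   focus = argmax_k G(k)

where the sums run over the M segmented microcalcifications of slice k,
N_i pixels each, p_ij^k their intensities.  The statistic presupposes a
delineation of the microcalcifications; this module supplies a simple
parameterized detector (per-slice percentile threshold, 8-connected
components, minimum-size filter) and also accepts oracle masks (from the
phantom generator) so the statistic can be evaluated independently of
segmentation error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label as cc_label

from .preprocess import DbtRoi

__all__ = [
    "MicrocalcSegmentation",
    "FocusProfile",
    "segment_microcalcifications",
    "segmentation_from_mask",
    "focus_score",
    "find_focus",
]


@dataclass
class MicrocalcSegmentation:
    """Per-slice binary masks with 8-connected component bookkeeping.

    ``masks`` has shape (h, w, d).  ``component_counts[k]`` is M for slice
    k; ``component_sizes[k]`` lists N_i for its components.
    """

    masks: np.ndarray
    component_counts: list[int]
    component_sizes: list[list[int]]
    source: str = "auto_segmentation"  # or "oracle_mask"

    def __post_init__(self) -> None:
        m = np.asarray(self.masks).astype(bool)
        if m.ndim != 3:
            raise ValueError("masks must be 3D (h, w, d)")
        for k in range(m.shape[2]):
            if sum(self.component_sizes[k]) != int(m[:, :, k].sum()):
                raise ValueError(f"component sizes inconsistent with mask on slice {k}")
            if len(self.component_sizes[k]) != self.component_counts[k]:
                raise ValueError(f"component count inconsistent on slice {k}")
        self.masks = m


@dataclass(frozen=True)
class FocusProfile:
    """Per-slice focus scores G(k) (NaN where no MCs) and the argmax index."""

    g: np.ndarray
    focus_idx: int
    segmentation_source: str


def _components(mask_2d: np.ndarray, min_size: int) -> tuple[np.ndarray, list[int]]:
    labels = cc_label(mask_2d, connectivity=2)  # 8-connectivity in 2D
    sizes = np.bincount(labels.ravel())
    keep = np.zeros_like(mask_2d, dtype=bool)
    kept_sizes: list[int] = []
    for comp in range(1, labels.max() + 1):
        if sizes[comp] >= min_size:
            keep |= labels == comp
            kept_sizes.append(int(sizes[comp]))
    return keep, kept_sizes


def segment_microcalcifications(
    roi: DbtRoi, q: float = 99.5, min_size: int = 2
) -> MicrocalcSegmentation:
    """Detect microcalcification pixels slice by slice.

    Each slice is thresholded at its own q-th intensity percentile, then
    8-connected components smaller than ``min_size`` pixels are discarded.
    An empty segmentation (no component anywhere) is a valid result.
    """
    vol = np.asarray(roi.intensities, dtype=np.float64)
    h, w, d = vol.shape
    masks = np.zeros((h, w, d), dtype=bool)
    counts: list[int] = []
    sizes: list[list[int]] = []
    for k in range(d):
        plane = vol[:, :, k]
        thr = np.percentile(plane, q)
        cand = plane > thr
        keep, kept_sizes = _components(cand, min_size)
        masks[:, :, k] = keep
        counts.append(len(kept_sizes))
        sizes.append(kept_sizes)
    return MicrocalcSegmentation(
        masks=masks, component_counts=counts, component_sizes=sizes,
        source="auto_segmentation",
    )


def segmentation_from_mask(mask: np.ndarray, min_size: int = 1) -> MicrocalcSegmentation:
    """Wrap an oracle (ground-truth) mask into the segmentation container."""
    m = np.asarray(mask).astype(bool)
    if m.ndim != 3:
        raise ValueError("oracle mask must be 3D (h, w, d)")
    counts: list[int] = []
    sizes: list[list[int]] = []
    masks = np.zeros_like(m)
    for k in range(m.shape[2]):
        keep, kept_sizes = _components(m[:, :, k], min_size)
        masks[:, :, k] = keep
        counts.append(len(kept_sizes))
        sizes.append(kept_sizes)
    return MicrocalcSegmentation(
        masks=masks, component_counts=counts, component_sizes=sizes,
        source="oracle_mask",
    )


def focus_score(roi: DbtRoi, seg: MicrocalcSegmentation) -> FocusProfile:
    """Evaluate G(k) on every slice and select the focus slice.

    G(k) is the mean intensity over the segmented microcalcification
    pixels of slice k.  Slices without components are excluded from the
    argmax (G = NaN there); ties break toward the lowest slice index.
    """
    vol = np.asarray(roi.intensities, dtype=np.float64)
    if seg.masks.shape != vol.shape:
        raise ValueError(
            f"segmentation shape {seg.masks.shape} != ROI shape {vol.shape}"
        )
    d = vol.shape[2]
    g = np.full(d, np.nan)
    for k in range(d):
        if seg.component_counts[k] > 0:
            m = seg.masks[:, :, k]
            g[k] = vol[:, :, k][m].sum() / m.sum()
    if np.all(np.isnan(g)):
        raise ValueError("no microcalcifications found in any slice")
    focus_idx = int(np.nanargmax(g))  # nanargmax returns the first maximum
    return FocusProfile(g=g, focus_idx=focus_idx, segmentation_source=seg.source)


def find_focus(
    roi: DbtRoi,
    oracle_mask: np.ndarray | None = None,
    q: float = 99.5,
    min_size: int = 2,
) -> FocusProfile:
    """Convenience wrapper: segment (or use the oracle mask) and score."""
    if oracle_mask is not None:
        seg = segmentation_from_mask(oracle_mask)
    else:
        seg = segment_microcalcifications(roi, q=q, min_size=min_size)
    return focus_score(roi, seg)
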