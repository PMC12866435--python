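"""Projection and cell-type region-of-interest construction.

The quantification mirrors an ImageJ-style macro: maximum-intensity
projection of the z-stack, per-marker smoothing with a disk-shaped mean
filter (radius 5 px), automatic thresholding into a cell-type ROI, and
exclusion of the microglial (Iba1) ROI from the astrocyte (GFAP) and
neuron (beta-tubulin) ROIs because of spillover between those channels.
The non-cell background mask is the complement of the union of all
cell-type ROIs and the nuclei ROI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, morphology

from .io import Projection, RunConfig, ZStack

__all__ = [
    "CellTypeMasks",
    "ThresholdResult",
    "max_project",
    "mean_filter",
    "auto_threshold",
    "build_cell_masks",
]


def max_project(stack: ZStack) -> Projection:
    """Reduce a z-stack to its per-pixel maximum over z."""
    if stack.pixels.shape[0] < 1 or stack.pixels.size == 0:
        raise ValueError("cannot project an empty stack")
    return Projection(
        pixels=stack.pixels.max(axis=0),
        channel_map=dict(stack.channel_map),
        pixel_size_um=stack.pixel_size_um,
        z_step_um=stack.z_step_um,
        well_id=stack.well_id,
        condition=stack.condition,
        experiment_id=stack.experiment_id,
        fov_id=stack.fov_id,
    )


def mean_filter(img: np.ndarray, radius: int) -> np.ndarray:
    """Disk-footprint mean filter with edge replication.

    ``radius`` follows the ImageJ convention: the footprint is the set of
    pixels within Euclidean distance ``radius`` of the center, so radius 0
    is the identity.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    img = np.asarray(img, dtype=np.float64)
    if radius == 0:
        return img.copy()
    footprint = morphology.disk(radius).astype(np.float64)
    kernel = footprint / footprint.sum()
    return ndi.convolve(img, kernel, mode="nearest")


class ThresholdResult(NamedTuple):
    mask: np.ndarray
    threshold: float
    degenerate: bool


def auto_threshold(
    img: np.ndarray,
    method: str = "otsu",
    fixed_value: float | None = None,
) -> ThresholdResult:
    """Threshold an image into a boolean ROI, ``mask = img > threshold``.

    A constant image has no automatic threshold; it yields an empty mask
    flagged ``degenerate`` (with a warning) rather than an exception, so a
    blank channel does not abort a batch run.  The input dtype is passed
    through unchanged so integer images keep their exact histogram binning.
    """
    img = np.asarray(img)
    if img.size == 0:
        raise ValueError("empty image")
    if method == "fixed":
        if fixed_value is None:
            raise ValueError("method 'fixed' requires fixed_value")
        thr = float(fixed_value)
        return ThresholdResult(img > thr, thr, False)
    if img.min() == img.max():
        warnings.warn("constant image: automatic threshold undefined, returning empty mask")
        return ThresholdResult(np.zeros(img.shape, dtype=bool), float(img.flat[0]), True)
    if method == "otsu":
        thr = float(filters.threshold_otsu(img))
    elif method == "li":
        thr = float(filters.threshold_li(img))
    elif method == "triangle":
        thr = float(filters.threshold_triangle(img))
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return ThresholdResult(img > thr, thr, False)


@dataclass
class CellTypeMasks:
    """Boolean per-cell-type ROIs on the projection grid.

    ``masks`` holds gfap/btub (Iba1-excluded), iba1 when present, and dapi;
    ``noncell_mask`` is everything belonging to no ROI.  ``provenance``
    records the threshold method and value used per channel.
    """

    masks: dict[str, np.ndarray]
    noncell_mask: np.ndarray
    provenance: dict[str, dict] = field(default_factory=dict)

    @property
    def areas(self) -> dict[str, int]:
        return {name: int(mask.sum()) for name, mask in self.masks.items()}

    def validate(self) -> None:
        iba1 = self.masks.get("iba1")
        if iba1 is not None:
            assert not np.any(self.masks["gfap"] & iba1), "Iba1 exclusion violated for GFAP"
            assert not np.any(self.masks["btub"] & iba1), "Iba1 exclusion violated for btub"
        union = np.zeros_like(self.noncell_mask)
        for mask in self.masks.values():
            union |= mask
        assert not np.any(self.noncell_mask & union), "non-cell mask overlaps a cell ROI"


def build_cell_masks(proj: Projection, cfg: RunConfig | None = None) -> CellTypeMasks:
    """Smooth + threshold each marker channel and apply the Iba1 exclusion.

    Requires gfap and btub channels; iba1 is optional (co-culture) and when
    absent the exclusion is a no-op.  DAPI contributes only to the non-cell
    background mask, not to colocalization targets.
    """
    cfg = cfg or RunConfig()
    for required in ("gfap", "btub", "dapi"):
        if required not in proj.channel_map:
            raise ValueError(f"projection is missing required channel {required!r}")

    names = ["dapi", "gfap", "btub"] + (["iba1"] if proj.has_iba1 else [])
    raw_masks: dict[str, np.ndarray] = {}
    provenance: dict[str, dict] = {}
    for name in names:
        smoothed = mean_filter(proj.channel(name), cfg.mean_filter_radius)
        res = auto_threshold(smoothed, method=cfg.threshold_method)
        raw_masks[name] = res.mask
        provenance[name] = {
            "method": cfg.threshold_method,
            "threshold": res.threshold,
            "degenerate": res.degenerate,
            "filter_radius": cfg.mean_filter_radius,
        }

    masks = dict(raw_masks)
    if "iba1" in masks:
        masks["gfap"] = masks["gfap"] & ~masks["iba1"]
        masks["btub"] = masks["btub"] & ~masks["iba1"]

    union = np.zeros(proj.pixels.shape[1:], dtype=bool)
    for mask in masks.values():
        union |= mask
    out = CellTypeMasks(masks=masks, noncell_mask=~union, provenance=provenance)
    out.validate()
    return out
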