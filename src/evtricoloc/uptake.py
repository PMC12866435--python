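"""CFSE+ extracellular-vesicle signal quantification and colocalization.

The measurement chain per field of view:

1. background — mean/SD of the CFSE channel over non-cell pixels;
2. CFSE+ detection — background-subtracted pixels above ``k``·SD,
   8-connected components, with components strictly larger than the
   aggregate gate (default 60 px) removed as autofluorescent debris;
3. colocalization — pixel overlap of the retained CFSE+ area with each
   cell-type ROI, normalized to that ROI's area;
4. rotation null — the same overlap after rotating one channel 90 degrees
   about the image center, estimating the coincidental overlap expected
   from coverage alone (two independent signals at 50% coverage still
   overlap 50%);
5. condition summaries with PBS-control subtraction, and Grubbs-based
   outlier flagging of images by their non-cell CFSE background.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skimage import measure

from .io import Projection, RunConfig
from .segmentation import CellTypeMasks

__all__ = [
    "Background",
    "CfseDetection",
    "TypeColoc",
    "UptakeMeasurement",
    "estimate_background",
    "detect_cfse_positive",
    "colocalize",
    "rotation_null",
    "measure_uptake",
    "summarize_condition",
    "flag_outliers",
]


class Background(NamedTuple):
    mean: float
    sd: float
    n_px: int


def estimate_background(proj_cfse: np.ndarray, noncell_mask: np.ndarray, min_px: int = 100) -> Background:
    """Mean and SD of CFSE intensity over non-cell pixels (sample SD, n-1)."""
    proj_cfse = np.asarray(proj_cfse, dtype=np.float64)
    if proj_cfse.shape != noncell_mask.shape:
        raise ValueError("CFSE image and non-cell mask shapes differ")
    values = proj_cfse[noncell_mask]
    if values.size < min_px:
        raise ValueError(
            f"only {values.size} non-cell pixels (< {min_px}); "
            "review cell-type thresholds before trusting the background estimate"
        )
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return Background(mean=float(values.mean()), sd=sd, n_px=int(values.size))


@dataclass
class CfseDetection:
    """Retained CFSE+ objects after debris gating."""

    cfse_mask: np.ndarray          # retained (gated) CFSE+ pixels
    labels: np.ndarray             # labels of retained components
    threshold: float               # absolute intensity cut applied
    n_objects: int
    n_gated: int                   # components removed as > gate_px
    gated_mask: np.ndarray         # pixels of the removed large components

    @property
    def area_px(self) -> int:
        return int(self.cfse_mask.sum())


def detect_cfse_positive(
    proj_cfse: np.ndarray,
    background: Background,
    k: float = 3.0,
    gate_px: int = 60,
) -> CfseDetection:
    """Threshold the CFSE channel and gate out large debris.

    CFSE+ pixels satisfy ``(img - background.mean) > k * background.sd``.
    8-connected components strictly larger than ``gate_px`` pixels are
    removed ("over 60 pixels in size"): a 60-px object is kept, a 61-px
    object is not.
    """
    if gate_px <= 0:
        raise ValueError("gate_px must be positive")
    if k <= 0:
        raise ValueError("k must be positive")
    proj_cfse = np.asarray(proj_cfse, dtype=np.float64)
    raw_mask = (proj_cfse - background.mean) > k * background.sd
    labels, n_comp = measure.label(raw_mask, connectivity=2, return_num=True)
    if n_comp == 0:
        empty = np.zeros(proj_cfse.shape, dtype=bool)
        return CfseDetection(empty, labels, background.mean + k * background.sd, 0, 0, empty.copy())
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    keep = sizes <= gate_px
    keep[0] = False
    kept_mask = keep[labels]
    gated_mask = raw_mask & ~kept_mask
    kept_labels = np.where(kept_mask, labels, 0)
    return CfseDetection(
        cfse_mask=kept_mask,
        labels=kept_labels,
        threshold=background.mean + k * background.sd,
        n_objects=int(keep.sum()),
        n_gated=int(n_comp - keep.sum()),
        gated_mask=gated_mask,
    )


class TypeColoc(NamedTuple):
    colocalized_px: int
    normalized: float | None       # colocalized px / cell-type area; None if area 0
    cfse_fraction: float | None    # colocalized px / total CFSE+ px; None if no CFSE+


def colocalize(cfse_mask: np.ndarray, masks: CellTypeMasks | dict) -> dict[str, TypeColoc]:
    """Pixel-overlap colocalization of the CFSE+ area with each cell-type ROI.

    ``normalized`` divides by the ROI area ("normalized to the total area
    per image that was identified for that cell type"); a type with zero
    area is reported as missing (None), not as 0.
    """
    type_masks = masks.masks if isinstance(masks, CellTypeMasks) else masks
    cfse_area = int(np.asarray(cfse_mask).sum())
    out: dict[str, TypeColoc] = {}
    for name, mask in type_masks.items():
        if mask.shape != cfse_mask.shape:
            raise ValueError(f"shape mismatch between CFSE mask and {name!r} mask")
        area = int(mask.sum())
        overlap = int(np.logical_and(cfse_mask, mask).sum())
        out[name] = TypeColoc(
            colocalized_px=overlap,
            normalized=(overlap / area) if area > 0 else None,
            cfse_fraction=(overlap / cfse_area) if cfse_area > 0 else None,
        )
    return out


def _center_crop_square(img: np.ndarray) -> np.ndarray:
    h, w = img.shape
    side = min(h, w)
    r0 = (h - side) // 2
    c0 = (w - side) // 2
    return img[r0 : r0 + side, c0 : c0 + side]


def rotation_null(
    cfse_mask: np.ndarray,
    masks: CellTypeMasks | dict,
    direction: str = "ccw",
    rotate: str = "celltype",
) -> dict[str, TypeColoc]:
    """Randomized specificity control: rotate one channel 90 degrees.

    The cell-type mask (default; configurable to the CFSE mask) is rotated
    about the image center and colocalization re-measured, leaving only
    the overlap expected by coincidence from the two coverages.  Non-square
    rasters are center-cropped to the largest centered square first.
    """
    if direction not in {"cw", "ccw"}:
        raise ValueError("direction must be 'cw' or 'ccw'")
    if rotate not in {"celltype", "cfse"}:
        raise ValueError("rotate must be 'celltype' or 'cfse'")
    k = 1 if direction == "ccw" else -1
    type_masks = masks.masks if isinstance(masks, CellTypeMasks) else masks
    cfse_sq = _center_crop_square(np.asarray(cfse_mask, dtype=bool))
    out: dict[str, TypeColoc] = {}
    for name, mask in type_masks.items():
        mask_sq = _center_crop_square(np.asarray(mask, dtype=bool))
        if rotate == "celltype":
            pair = {name: np.rot90(mask_sq, k=k)}
            out.update(colocalize(cfse_sq, pair))
        else:
            pair = {name: mask_sq}
            out.update(colocalize(np.rot90(cfse_sq, k=k), pair))
    return out


@dataclass
class UptakeMeasurement:
    """Per-image uptake quantification record."""

    image_id: str
    condition: str
    experiment_id: str = ""
    background_mean: float = 0.0
    background_sd: float = 0.0
    cfse_threshold: float = 0.0
    total_cfse_area_px: int = 0
    cell_area_px: int = 0
    cfse_area_per_cell_area: float = 0.0
    n_objects: int = 0
    n_gated: int = 0
    coloc: dict[str, TypeColoc] = field(default_factory=dict)
    null_coloc: dict[str, TypeColoc] = field(default_factory=dict)
    outlier_flag: bool = False

    def to_row(self) -> dict:
        row = {
            "image_id": self.image_id,
            "condition": self.condition,
            "experiment_id": self.experiment_id,
            "background_mean": self.background_mean,
            "background_sd": self.background_sd,
            "cfse_threshold": self.cfse_threshold,
            "total_cfse_area_px": self.total_cfse_area_px,
            "cell_area_px": self.cell_area_px,
            "cfse_area_per_cell_area": self.cfse_area_per_cell_area,
            "n_objects": self.n_objects,
            "n_gated": self.n_gated,
            "outlier_flag": self.outlier_flag,
        }
        for name, tc in self.coloc.items():
            row[f"coloc_px_{name}"] = tc.colocalized_px
            row[f"coloc_norm_{name}"] = tc.normalized
        for name, tc in self.null_coloc.items():
            row[f"null_norm_{name}"] = tc.normalized
        return row


def measure_uptake(
    proj: Projection,
    masks: CellTypeMasks,
    cfg: RunConfig | None = None,
    image_id: str = "",
) -> UptakeMeasurement:
    """Run the full per-image chain: background, detection, colocalization,
    rotation null.  DAPI is not a colocalization target."""
    cfg = cfg or RunConfig()
    cfse = proj.channel("cfse")
    bg = estimate_background(cfse, masks.noncell_mask, min_px=cfg.min_noncell_px)
    det = detect_cfse_positive(cfse, bg, k=cfg.cfse_k, gate_px=cfg.gate_px)
    targets = {n: m for n, m in masks.masks.items() if n != "dapi"}
    coloc = colocalize(det.cfse_mask, targets)
    null = rotation_null(det.cfse_mask, targets, direction=cfg.rotation_direction, rotate=cfg.rotate_channel)
    cell_area = int(sum(m.sum() for m in masks.masks.values()))
    return UptakeMeasurement(
        image_id=image_id or proj.fov_id,
        condition=proj.condition,
        experiment_id=proj.experiment_id,
        background_mean=bg.mean,
        background_sd=bg.sd,
        cfse_threshold=det.threshold,
        total_cfse_area_px=det.area_px,
        cell_area_px=cell_area,
        cfse_area_per_cell_area=det.area_px / cell_area if cell_area else 0.0,
        n_objects=det.n_objects,
        n_gated=det.n_gated,
        coloc=coloc,
        null_coloc=null,
    )


def _grubbs_critical(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value from the t-distribution closed form."""
    t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))


def flag_outliers(values: Sequence[float], alpha: float = 0.05) -> np.ndarray:
    """Iterative two-sided Grubbs test; returns flags aligned to input order.

    Used on per-image non-cell CFSE background intensities to discard
    fields of view with anomalous autofluorescence.  Fewer than 3 values
    cannot be tested: a warning is issued and nothing is flagged.
    """
    values = np.asarray(values, dtype=np.float64)
    flags = np.zeros(values.shape, dtype=bool)
    if values.size < 3:
        warnings.warn("fewer than 3 values: outlier test not applicable")
        return flags
    active = list(range(values.size))
    while len(active) >= 3:
        sub = values[active]
        sd = sub.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(sub - sub.mean())
        i_max = int(np.argmax(dev))
        g = dev[i_max] / sd
        if g > _grubbs_critical(len(active), alpha):
            flags[active[i_max]] = True
            del active[i_max]
        else:
            break
    return flags


_SUMMARY_METRICS = ("cfse_area_per_cell_area", "total_cfse_area_px")


def summarize_condition(
    measurements: Iterable[UptakeMeasurement],
    control_condition: str = "PBS",
    dye_control: str = "CFSE",
    outlier_alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-condition summaries with PBS-control subtraction.

    Outliers (Grubbs on background means) are excluded from summaries but
    retained, flagged, in the per-image table.  Reported uptake metrics are
    the condition mean minus the PBS mean; ``exceeds_both_controls`` tests
    the condition mean against both the PBS and dye-only control means.
    Microglia colocalization averages only images whose Iba1 ROI is
    non-empty (only images containing microglia are informative for it).
    """
    measurements = list(measurements)
    if not measurements:
        raise ValueError("no measurements")
    flags = flag_outliers([m.background_mean for m in measurements], alpha=outlier_alpha)
    for m, f in zip(measurements, flags):
        m.outlier_flag = bool(f)
    kept = [m for m in measurements if not m.outlier_flag]
    conditions = sorted({m.condition for m in kept})
    if control_condition not in conditions:
        raise ValueError(f"control condition {control_condition!r} absent from measurements")

    coloc_types = sorted({t for m in kept for t in m.coloc})
    rows = []
    for cond in conditions:
        group = [m for m in kept if m.condition == cond]
        row: dict = {"condition": cond, "n_images": len(group)}
        for metric in _SUMMARY_METRICS:
            vals = np.array([getattr(m, metric) for m in group], dtype=float)
            row[f"{metric}_mean"] = vals.mean()
            row[f"{metric}_sd"] = vals.std(ddof=1) if len(vals) > 1 else 0.0
        for t in coloc_types:
            sel = [m.coloc[t].normalized for m in group if t in m.coloc]
            if t == "iba1":
                sel = [v for v in sel if v is not None]  # only images containing microglia
            vals = np.array([v for v in sel if v is not None], dtype=float)
            row[f"coloc_norm_{t}_mean"] = vals.mean() if vals.size else np.nan
            row[f"coloc_norm_{t}_sd"] = vals.std(ddof=1) if vals.size > 1 else 0.0
            nulls = np.array(
                [m.null_coloc[t].normalized for m in group if t in m.null_coloc and m.null_coloc[t].normalized is not None],
                dtype=float,
            )
            row[f"null_norm_{t}_mean"] = nulls.mean() if nulls.size else np.nan
        rows.append(row)
    table = pd.DataFrame(rows)

    ctrl = table.loc[table["condition"] == control_condition].iloc[0]
    dye = table.loc[table["condition"] == dye_control].iloc[0] if dye_control in set(table["condition"]) else None
    sub_cols = [c for c in table.columns if c.endswith("_mean") and not c.startswith("null_")]
    for c in sub_cols:
        table[c.replace("_mean", "_ctrl_sub")] = table[c] - ctrl[c]
    if dye is not None:
        table["exceeds_both_controls"] = (
            (table["cfse_area_per_cell_area_mean"] > ctrl["cfse_area_per_cell_area_mean"])
            & (table["cfse_area_per_cell_area_mean"] > dye["cfse_area_per_cell_area_mean"])
        )
        table.loc[table["condition"].isin([control_condition, dye_control]), "exceeds_both_controls"] = False
    return table
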