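"""Live/dead nuclei counting and LDH percent cytotoxicity.

Nuclei counting follows the published macro: mean filter of radius 1,
threshold, distance-transform watershed to split touching nuclei, and a
minimum-size particle filter.  Percent dead is the PI/Hoechst count
ratio.  The LDH assay corrects each well (A490 - A680) and scales the
control-subtracted signal between the untreated (PBS) and fully lysed
control means.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import feature, measure, segmentation

from .segmentation import auto_threshold, mean_filter

__all__ = [
    "NucleiCount",
    "count_nuclei",
    "percent_dead",
    "ldh_cytotoxicity",
    "read_plate",
]


def count_nuclei(
    img: np.ndarray,
    min_size_px: int = 10,
    filter_radius: int = 1,
    threshold_method: str = "otsu",
    watershed_min_distance: int = 5,
) -> int:
    """Count nuclei in a single-channel image.

    A blank (constant) image counts zero.  Overlapping nuclei are split by
    watershedding the Euclidean distance transform from its local maxima;
    objects below ``min_size_px`` pixels are discarded as speckle.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.size == 0:
        raise ValueError("empty image")
    smoothed = mean_filter(img, filter_radius)
    mask, _, degenerate = auto_threshold(smoothed, method=threshold_method)
    if degenerate or not mask.any():
        return 0
    distance = ndi.distance_transform_edt(mask)
    coords = feature.peak_local_max(
        distance, min_distance=watershed_min_distance, labels=mask, exclude_border=False
    )
    if len(coords) == 0:
        labels = measure.label(mask, connectivity=2)
    else:
        markers = np.zeros(mask.shape, dtype=np.int32)
        markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
        labels = segmentation.watershed(-distance, markers, mask=mask)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    return int(np.count_nonzero(sizes >= min_size_px))


@dataclass
class NucleiCount:
    image_id: str
    hoechst_count: int
    pi_count: int

    @property
    def percent_dead(self) -> float:
        return percent_dead(self.hoechst_count, self.pi_count)


def percent_dead(hoechst_count: int, pi_count: int) -> float:
    """100 * PI-stained nuclei / Hoechst-stained nuclei."""
    if hoechst_count <= 0:
        raise ValueError("hoechst_count must be positive for a valid ratio")
    return 100.0 * pi_count / hoechst_count


_ROLES = {"control", "treated", "lysis"}


def _check_plate(plate: pd.DataFrame) -> None:
    missing = {"well", "role", "a490", "a680"} - set(plate.columns)
    if missing:
        raise ValueError(f"plate table missing column(s): {sorted(missing)}")
    bad = set(plate["role"]) - _ROLES
    if bad:
        raise ValueError(f"unknown well role(s): {sorted(bad)}")
    for role in _ROLES - {"treated"}:
        if not (plate["role"] == role).any():
            raise ValueError(f"plate has no {role!r} wells")
    if not np.all(np.isfinite(plate[["a490", "a680"]].to_numpy(dtype=float))):
        raise ValueError("absorbances must be finite")


def ldh_cytotoxicity(plate: pd.DataFrame, literal_denominator: bool = False) -> pd.DataFrame:
    """Percent cytotoxicity per treated well from a plate-reader table.

    Each well is corrected as ``A = A490 - A680``; then::

        % = 100 * (A_treated - mean A_control) / (mean A_lysis - mean A_control)

    so a treated well equal to the control mean reads 0% and one equal to
    the lysis mean reads 100%.  ``literal_denominator=True`` divides by
    (control - lysis) instead, the sign-inverted variant some protocol
    texts describe.
    """
    _check_plate(plate)
    plate = plate.copy()
    plate["corrected"] = plate["a490"].astype(float) - plate["a680"].astype(float)
    ctrl_mean = plate.loc[plate["role"] == "control", "corrected"].mean()
    lysis_mean = plate.loc[plate["role"] == "lysis", "corrected"].mean()
    denom = (ctrl_mean - lysis_mean) if literal_denominator else (lysis_mean - ctrl_mean)
    if denom == 0:
        raise ValueError("degenerate plate: lysis and control means are equal")
    treated = plate[plate["role"] == "treated"].copy()
    treated["percent_cytotoxicity"] = 100.0 * (treated["corrected"] - ctrl_mean) / denom
    return treated[["well", "corrected", "percent_cytotoxicity"]].reset_index(drop=True)


def read_plate(path: str | Path) -> pd.DataFrame:
    """Read a plate CSV/TSV with columns well, role, a490, a680."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    plate = pd.read_csv(path, sep=sep)
    plate.columns = [c.strip().lower() for c in plate.columns]
    _check_plate(plate)
    return plate
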