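"""Synthetic confocal scenes, cytokine tables and plate readings with ground truth.

The scene generator emulates the study's 20x fields of view: 12-slice
z-stacks with DAPI nuclei (disks), GFAP astrocytes (smooth blobs covering
~20% of the field), beta-tubulin neurons (dilated random-walk filaments,
~35% coverage, deliberately dense to reproduce the low signal-to-noise of
neuronal colocalization), sparse Iba1 microglia (~3%, omitted for
co-culture scenes), and a CFSE channel of Gaussian puncta planted inside
chosen cell-type masks at known fractions plus rare large autofluorescent
debris strictly above the 60-px aggregate gate.  Every object gets a focal
plane so signal spreads across z; Poisson photon noise and Gaussian read
noise are added on top of a flat background.

All randomness flows from the single seed in the config; identical
configs produce identical scenes.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import morphology

from .io import ZStack

__all__ = [
    "SceneConfig",
    "SyntheticGroundTruth",
    "generate_scene",
    "generate_cytokine_table",
    "generate_plate",
    "tri_inflammatory_effects",
    "generate_live_dead_pair",
    "random_coverage_mask",
    "CYTOKINE_PANEL",
]

CYTOKINE_PANEL = (
    "EGF", "Eotaxin", "Fractalkine", "G-CSF", "GM-CSF", "GRO/KC", "IFNg",
    "IL-1a", "IL-1b", "IL-2", "IL-4", "IL-5", "IL-6", "IL-10", "IL-12p70",
    "IL-13", "IL-17A", "IL-18", "IP-10", "Leptin", "LIX", "MCP-1",
    "MIP-1a", "MIP-2", "RANTES", "TNFa", "VEGF",
)


@dataclass
class SceneConfig:
    """Study-condition parameters of one synthetic field of view."""

    seed: int
    image_size: int = 512
    n_z: int = 12
    n_nuclei: int = 120
    nucleus_radius: tuple[int, int] = (7, 10)
    coverage: dict[str, float] = dc_field(
        default_factory=lambda: {"gfap": 0.20, "btub": 0.35, "iba1": 0.03}
    )
    include_iba1: bool = True
    n_puncta: int = 150
    puncta_sigma: float = 1.5
    puncta_amplitude: float = 800.0
    fractions: dict[str, float] = dc_field(
        default_factory=lambda: {"gfap": 0.35, "btub": 0.35, "iba1": 0.05}
    )
    placement: str = "mask"            # 'mask' honors fractions; 'uniform' ignores them
    n_debris: int = 3
    debris_radius: int = 9             # area ~254 px, well above the 60-px gate
    debris_amplitude: float = 1500.0
    cell_amplitude: float = 500.0
    background_mean: float = 100.0
    read_noise_sd: float = 5.0
    photon_noise: bool = True
    z_sigma: float = 1.5               # focal spread across slices
    pixel_size_um: float = 0.62
    z_step_um: float = 1.24

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is required")
        if self.image_size <= 0 or self.n_z < 1:
            raise ValueError("image_size and n_z must be positive")
        if self.placement not in {"mask", "uniform"}:
            raise ValueError("placement must be 'mask' or 'uniform'")
        fracs = {t: f for t, f in self.fractions.items() if self.include_iba1 or t != "iba1"}
        if any(not 0 <= f <= 1 for f in fracs.values()):
            raise ValueError("fractions must lie in [0, 1]")
        if sum(fracs.values()) > 1 + 1e-9:
            raise ValueError("per-type CFSE fractions must sum to <= 1")
        if self.n_debris < 0 or self.debris_radius <= 0:
            raise ValueError("debris parameters must be non-negative / positive")


@dataclass
class SyntheticGroundTruth:
    """Planted truth for one scene."""

    masks: dict[str, np.ndarray]              # dapi/gfap/btub/(iba1), Iba1-excluded
    noncell_mask: np.ndarray
    puncta: pd.DataFrame                      # row, col, sigma, amplitude, assigned_type, z0
    debris: pd.DataFrame                      # row, col, radius, area_px, z0
    cfse_footprint_mask: np.ndarray           # union of punctum footprints (2*sigma disks)
    debris_mask: np.ndarray
    true_cfse_fraction: dict[str, float]      # share of planted CFSE area in each type
    true_normalized_coloc: dict[str, float]   # planted CFSE area in type / type area
    n_nuclei: int


def _disk_patch(shape: tuple[int, int], r0: float, c0: float, radius: float):
    r_lo = min(max(int(np.floor(r0 - radius)), 0), shape[0])
    r_hi = max(min(int(np.ceil(r0 + radius)) + 1, shape[0]), r_lo)
    c_lo = min(max(int(np.floor(c0 - radius)), 0), shape[1])
    c_hi = max(min(int(np.ceil(c0 + radius)) + 1, shape[1]), c_lo)
    rr, cc = np.ogrid[r_lo:r_hi, c_lo:c_hi]
    inside = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2
    return (slice(r_lo, r_hi), slice(c_lo, c_hi)), inside


def _paint_disk(img: np.ndarray, r0: float, c0: float, radius: float, value: float) -> None:
    sl, inside = _disk_patch(img.shape, r0, c0, radius)
    patch = img[sl]
    patch[inside] = np.maximum(patch[inside], value)


def _mask_disk(mask: np.ndarray, r0: float, c0: float, radius: float) -> None:
    sl, inside = _disk_patch(mask.shape, r0, c0, radius)
    mask[sl] |= inside


def _paint_gaussian(img: np.ndarray, r0: float, c0: float, sigma: float, amplitude: float) -> None:
    half = int(np.ceil(4 * sigma))
    r_lo = max(int(round(r0)) - half, 0)
    r_hi = min(int(round(r0)) + half + 1, img.shape[0])
    c_lo = max(int(round(c0)) - half, 0)
    c_hi = min(int(round(c0)) + half + 1, img.shape[1])
    rr, cc = np.ogrid[r_lo:r_hi, c_lo:c_hi]
    patch = amplitude * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma**2))
    # compact support: clip tails at the 2-sigma level so a punctum's
    # rendered footprint is exactly its 2-sigma disk even without noise
    patch[patch < amplitude * np.exp(-2.0)] = 0.0
    region = img[r_lo:r_hi, c_lo:c_hi]
    np.maximum(region, patch, out=region)


class _PlaneStack:
    """Per-focal-plane 2-D accumulators for one channel."""

    def __init__(self, shape: tuple[int, int]):
        self.shape = shape
        self.planes: dict[int, np.ndarray] = {}

    def plane(self, z0: int) -> np.ndarray:
        if z0 not in self.planes:
            self.planes[z0] = np.zeros(self.shape, dtype=np.float64)
        return self.planes[z0]

    def render(self, n_z: int, z_sigma: float) -> np.ndarray:
        out = np.zeros((n_z,) + self.shape, dtype=np.float64)
        zs = np.arange(n_z)
        for z0, img in self.planes.items():
            weights = np.exp(-((zs - z0) ** 2) / (2 * z_sigma**2))
            for z, w in zip(zs, weights):
                if w > 1e-4:
                    out[z] += w * img
        return out


def _sample_in_mask(rng: np.random.Generator, mask: np.ndarray, n: int, type_name: str) -> np.ndarray:
    coords = np.argwhere(mask)
    if coords.shape[0] == 0:
        raise ValueError(f"cannot place puncta: eroded mask for type {type_name!r} is empty")
    idx = rng.integers(0, coords.shape[0], size=n)
    return coords[idx]


def generate_scene(cfg: SceneConfig) -> tuple[ZStack, SyntheticGroundTruth]:
    """Generate one synthetic field of view plus its ground truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    shape = (cfg.image_size, cfg.image_size)
    n_z = cfg.n_z

    def rand_plane() -> int:
        return int(rng.integers(1, max(n_z - 1, 2)))

    channel_names = ["dapi", "gfap", "btub"] + (["iba1"] if cfg.include_iba1 else []) + ["cfse"]
    channel_map = {name: i for i, name in enumerate(channel_names)}
    accum = {name: _PlaneStack(shape) for name in channel_names}

    # --- nuclei -----------------------------------------------------------
    dapi_mask = np.zeros(shape, dtype=bool)
    for _ in range(cfg.n_nuclei):
        r0 = rng.uniform(0, shape[0])
        c0 = rng.uniform(0, shape[1])
        radius = rng.uniform(*cfg.nucleus_radius)
        amp = cfg.cell_amplitude * rng.uniform(0.8, 1.2)
        _mask_disk(dapi_mask, r0, c0, radius)
        _paint_disk(accum["dapi"].plane(rand_plane()), r0, c0, radius, amp)

    # --- astrocyte blobs (and microglia, smaller/sparser) -----------------
    def grow_blobs(target: float, radius_range, n_lobes, channel: str) -> np.ndarray:
        mask = np.zeros(shape, dtype=bool)
        guard = 0
        while mask.mean() < target and guard < 4000:
            guard += 1
            r, c = rng.uniform(0, shape[0]), rng.uniform(0, shape[1])
            z0 = rand_plane()
            amp = cfg.cell_amplitude * rng.uniform(0.8, 1.2)
            for _ in range(int(rng.integers(n_lobes[0], n_lobes[1] + 1))):
                radius = rng.uniform(*radius_range)
                _mask_disk(mask, r, c, radius)
                _paint_disk(accum[channel].plane(z0), r, c, radius, amp)
                step = rng.uniform(0.5, 1.2) * radius
                ang = rng.uniform(0, 2 * np.pi)
                r += step * np.sin(ang)
                c += step * np.cos(ang)
        return mask

    gfap_mask = grow_blobs(cfg.coverage.get("gfap", 0.2), (9, 16), (4, 7), "gfap")
    iba1_mask = None
    if cfg.include_iba1:
        iba1_mask = grow_blobs(cfg.coverage.get("iba1", 0.03), (5, 9), (2, 4), "iba1")

    # --- neuron filaments: persistent random walks, dilated to width ~3 ---
    btub_thin = np.zeros(shape, dtype=bool)
    plane_thin: dict[int, np.ndarray] = {}
    target = cfg.coverage.get("btub", 0.35)
    selem = morphology.disk(3)
    guard = 0
    while True:
        # dilated coverage approximated as 5x the thin-trace coverage (width 1 -> 3+)
        if btub_thin.mean() * 6.0 >= target or guard >= 3000:
            break
        guard += 1
        z0 = rand_plane()
        if z0 not in plane_thin:
            plane_thin[z0] = np.zeros(shape, dtype=bool)
        r, c = rng.uniform(0, shape[0]), rng.uniform(0, shape[1])
        ang = rng.uniform(0, 2 * np.pi)
        for _ in range(int(rng.integers(300, 700))):
            ri, ci = int(round(r)) % shape[0], int(round(c)) % shape[1]
            btub_thin[ri, ci] = True
            plane_thin[z0][ri, ci] = True
            ang += rng.normal(0, 0.15)
            r += 1.5 * np.sin(ang)
            c += 1.5 * np.cos(ang)
    btub_mask = ndi.binary_dilation(btub_thin, structure=selem)
    for z0, thin in plane_thin.items():
        amp = cfg.cell_amplitude
        dil = ndi.binary_dilation(thin, structure=selem)
        plane = accum["btub"].plane(z0)
        np.maximum(plane, dil * amp, out=plane)

    # --- apply the Iba1 exclusion to the truth ROIs -----------------------
    if iba1_mask is not None:
        gfap_mask = gfap_mask & ~iba1_mask
        btub_mask = btub_mask & ~iba1_mask
    masks: dict[str, np.ndarray] = {"dapi": dapi_mask, "gfap": gfap_mask, "btub": btub_mask}
    if iba1_mask is not None:
        masks["iba1"] = iba1_mask
    union = dapi_mask | gfap_mask | btub_mask | (iba1_mask if iba1_mask is not None else False)
    noncell = ~union

    # --- CFSE puncta ------------------------------------------------------
    erode = morphology.disk(int(np.ceil(2 * cfg.puncta_sigma)))
    footprint_r = 2 * cfg.puncta_sigma
    puncta_rows: list[dict] = []
    cfse_footprint = np.zeros(shape, dtype=bool)

    def place_puncta(n: int, where: np.ndarray | None, label: str) -> None:
        if n <= 0:
            return
        if where is None:
            coords = np.column_stack([
                rng.uniform(0, shape[0], size=n),
                rng.uniform(0, shape[1], size=n),
            ])
        else:
            safe = ndi.binary_erosion(where, structure=erode)
            coords = _sample_in_mask(rng, safe, n, label).astype(float)
            coords += rng.uniform(-0.4, 0.4, size=coords.shape)
        for r0, c0 in coords:
            z0 = rand_plane()
            amp = cfg.puncta_amplitude * rng.uniform(0.8, 1.2)
            _paint_gaussian(accum["cfse"].plane(z0), r0, c0, cfg.puncta_sigma, amp)
            _mask_disk(cfse_footprint, r0, c0, footprint_r)
            puncta_rows.append({
                "row": r0, "col": c0, "sigma": cfg.puncta_sigma,
                "amplitude": amp, "assigned_type": label, "z0": z0,
            })

    if cfg.placement == "uniform":
        place_puncta(cfg.n_puncta, None, "uniform")
    else:
        fracs = {t: f for t, f in cfg.fractions.items() if t in masks}
        n_assigned = {t: int(round(f * cfg.n_puncta)) for t, f in fracs.items()}
        for t, n in n_assigned.items():
            place_puncta(n, masks[t], t)
        n_unbound = cfg.n_puncta - sum(n_assigned.values())
        place_puncta(n_unbound, noncell, "unbound")

    # --- debris: bright blobs strictly larger than the gate ---------------
    debris_mask = np.zeros(shape, dtype=bool)
    debris_rows: list[dict] = []
    for _ in range(cfg.n_debris):
        r0 = rng.uniform(cfg.debris_radius, shape[0] - cfg.debris_radius)
        c0 = rng.uniform(cfg.debris_radius, shape[1] - cfg.debris_radius)
        z0 = rand_plane()
        single = np.zeros(shape, dtype=bool)
        _mask_disk(single, r0, c0, cfg.debris_radius)
        debris_mask |= single
        _paint_disk(accum["cfse"].plane(z0), r0, c0, cfg.debris_radius, cfg.debris_amplitude)
        debris_rows.append({
            "row": r0, "col": c0, "radius": cfg.debris_radius,
            "area_px": int(single.sum()), "z0": z0,
        })

    # --- render stack and add noise ---------------------------------------
    stack = np.zeros((n_z, len(channel_names)) + shape, dtype=np.float64)
    for name, acc in accum.items():
        stack[:, channel_map[name]] = acc.render(n_z, cfg.z_sigma)
    stack += cfg.background_mean
    if cfg.photon_noise:
        stack = rng.poisson(np.clip(stack, 0, None)).astype(np.float64)
    if cfg.read_noise_sd > 0:
        stack += rng.normal(0.0, cfg.read_noise_sd, size=stack.shape)
    np.clip(stack, 0, 65535, out=stack)

    zstack = ZStack(
        pixels=stack,
        channel_map=channel_map,
        pixel_size_um=cfg.pixel_size_um,
        z_step_um=cfg.z_step_um,
    )

    # --- planted colocalization truth -------------------------------------
    footprint_area = int(cfse_footprint.sum())
    true_fraction: dict[str, float] = {}
    true_norm: dict[str, float] = {}
    for t in ("gfap", "btub", "iba1"):
        if t not in masks:
            continue
        overlap = int((cfse_footprint & masks[t]).sum())
        area = int(masks[t].sum())
        true_fraction[t] = overlap / footprint_area if footprint_area else 0.0
        true_norm[t] = overlap / area if area else float("nan")

    truth = SyntheticGroundTruth(
        masks=masks,
        noncell_mask=noncell,
        puncta=pd.DataFrame(puncta_rows),
        debris=pd.DataFrame(debris_rows),
        cfse_footprint_mask=cfse_footprint,
        debris_mask=debris_mask,
        true_cfse_fraction=true_fraction,
        true_normalized_coloc=true_norm,
        n_nuclei=cfg.n_nuclei,
    )
    return zstack, truth


def random_coverage_mask(
    shape: tuple[int, int],
    coverage: float,
    seed: int,
    smoothing_sigma: float = 8.0,
) -> np.ndarray:
    """Smooth random blob mask with exact coverage (quantile threshold)."""
    rng = np.random.default_rng(seed)
    noise = ndi.gaussian_filter(rng.normal(size=shape), smoothing_sigma)
    thr = np.quantile(noise, 1.0 - coverage)
    return noise > thr


def generate_cytokine_table(
    n_cytokines: int = 27,
    cultures: Sequence[str] = ("co", "tri"),
    treatments: Sequence[str] = ("PBS", "HEK293T", "MDA-MB-231", "231-Br"),
    effects: dict | None = None,
    lod: float | Sequence[float] = 1.0,
    n_reps: int = 4,
    n_experiments: int = 2,
    control_treatment: str = "PBS",
    baseline_log_mean: float = 3.0,
    baseline_log_sd: float = 1.0,
    experiment_sd: float = 0.3,
    noise_sd: float = 0.25,
    seed: int = 0,
) -> pd.DataFrame:
    """Log-normal cytokine concentrations with experiment offsets and
    planted multiplicative group effects.

    ``effects`` maps ``(culture, treatment)`` to a scalar or length-
    ``n_cytokines`` array of fold shifts (1.0 = no effect).  Replicate
    structure defaults to the study's 2 experiments x 3-4 technical
    replicates.  Values below the LOD are flagged ``below_lod``.
    """
    if control_treatment not in treatments:
        raise ValueError(f"missing control group {control_treatment!r} in treatments")
    rng = np.random.default_rng(seed)
    if n_cytokines <= len(CYTOKINE_PANEL):
        names = list(CYTOKINE_PANEL[:n_cytokines])
    else:
        names = [f"CK{i:02d}" for i in range(n_cytokines)]
    lod_arr = np.broadcast_to(np.asarray(lod, dtype=float), (n_cytokines,))
    baseline = np.exp(rng.normal(baseline_log_mean, baseline_log_sd, size=n_cytokines))
    exp_offset = np.exp(rng.normal(0.0, experiment_sd, size=(n_experiments, n_cytokines)))
    effects = effects or {}

    rows = []
    for e in range(n_experiments):
        for culture in cultures:
            for treatment in treatments:
                eff = np.broadcast_to(
                    np.asarray(effects.get((culture, treatment), 1.0), dtype=float),
                    (n_cytokines,),
                )
                for rep in range(n_reps):
                    noise = np.exp(rng.normal(0.0, noise_sd, size=n_cytokines))
                    conc = baseline * exp_offset[e] * eff * noise
                    for i, name in enumerate(names):
                        rows.append({
                            "cytokine": name,
                            "experiment": f"exp{e + 1}",
                            "culture": culture,
                            "treatment": treatment,
                            "replicate": rep + 1,
                            "concentration": conc[i],
                            "lod": lod_arr[i],
                            "below_lod": bool(conc[i] < lod_arr[i]),
                        })
    return pd.DataFrame(rows)


def tri_inflammatory_effects(
    n_cytokines: int = 27,
    n_inflammatory: int = 10,
    shift: float = 3.0,
    treatments: Sequence[str] = ("PBS", "HEK293T", "MDA-MB-231", "231-Br"),
) -> dict:
    """Planted microglia-dependent inflammatory shift.

    All tri-culture groups share a ``shift``-fold elevation of the first
    ``n_inflammatory`` cytokines, emulating the baseline inflammatory tone
    that microglia contribute regardless of treatment; co-culture groups
    are unshifted.
    """
    eff = np.ones(n_cytokines)
    eff[:n_inflammatory] = shift
    return {("tri", t): eff for t in treatments}


def generate_plate(
    true_cytotoxicity: Sequence[float] = (0.0, 0.0, 0.0, 0.0),
    n_control: int = 3,
    n_lysis: int = 1,
    control_abs: float = 0.3,
    lysis_abs: float = 1.3,
    a680: float = 0.05,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Plate readings (A490/A680 per well) with planted cytotoxicity.

    Treated wells interpolate between the control and lysis corrected
    absorbances according to their true cytotoxicity (%).  The lysis
    signal must exceed the control signal.
    """
    if lysis_abs <= control_abs:
        raise ValueError("lysis signal must exceed control signal")
    rng = np.random.default_rng(seed)
    rows = []

    def add(role: str, n: int, values: Sequence[float]) -> None:
        for i, v in enumerate(values[:n] if role != "treated" else values):
            rows.append({
                "well": f"{role}_{i + 1}",
                "role": role,
                "a490": v + a680 + (rng.normal(0, noise_sd) if noise_sd > 0 else 0.0),
                "a680": a680,
            })

    add("control", n_control, [control_abs] * n_control)
    add("lysis", n_lysis, [lysis_abs] * n_lysis)
    treated_abs = [control_abs + t / 100.0 * (lysis_abs - control_abs) for t in true_cytotoxicity]
    add("treated", len(treated_abs), treated_abs)
    truth = {"true_cytotoxicity": list(true_cytotoxicity)}
    return pd.DataFrame(rows), truth


def generate_live_dead_pair(
    n_cells: int = 80,
    frac_dead: float = 0.25,
    image_size: int = 512,
    nucleus_radius: tuple[float, float] = (5.0, 8.0),
    min_separation: float = 20.0,
    amplitude: float = 500.0,
    background_mean: float = 50.0,
    noise_sd: float = 5.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Hoechst/PI image pair with planted total and dead nuclei counts.

    Nuclei are placed with a minimum center separation (rejection
    sampling) so counts are well defined; the PI channel contains the dead
    subset only.
    """
    rng = np.random.default_rng(seed)
    centers: list[tuple[float, float]] = []
    guard = 0
    margin = nucleus_radius[1]
    while len(centers) < n_cells and guard < 200000:
        guard += 1
        r = rng.uniform(margin, image_size - margin)
        c = rng.uniform(margin, image_size - margin)
        if all((r - r2) ** 2 + (c - c2) ** 2 >= min_separation**2 for r2, c2 in centers):
            centers.append((r, c))
    if len(centers) < n_cells:
        raise ValueError("could not place all nuclei at the requested separation")
    n_dead = int(round(frac_dead * n_cells))
    dead_idx = set(rng.choice(n_cells, size=n_dead, replace=False).tolist())

    hoechst = np.zeros((image_size, image_size), dtype=np.float64)
    pi = np.zeros_like(hoechst)
    for i, (r, c) in enumerate(centers):
        radius = rng.uniform(*nucleus_radius)
        _paint_disk(hoechst, r, c, radius, amplitude)
        if i in dead_idx:
            _paint_disk(pi, r, c, radius, amplitude)
    for img in (hoechst, pi):
        img += background_mean + rng.normal(0, noise_sd, size=img.shape)
        np.clip(img, 0, None, out=img)
    return hoechst, pi, {"n_total": n_cells, "n_dead": n_dead}
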