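"""Image-stack and table I/O, run configuration, and run manifests.

Images are multi-channel confocal z-stacks (TIFF / OME-TIFF) with a named
channel map over ``{dapi, gfap, btub, iba1, cfse}``; ``iba1`` is optional
for co-culture fields of view that contain no microglia.  Pixels are
promoted to float64 on read so that background subtraction may go negative
mid-computation regardless of the acquisition bit depth (8/12/16-bit are
all accepted without rescaling).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

CHANNEL_NAMES = ("dapi", "gfap", "btub", "iba1", "cfse")

__all__ = [
    "CHANNEL_NAMES",
    "ZStack",
    "Projection",
    "RunConfig",
    "read_stack",
    "write_stack",
    "write_results",
]


@dataclass
class ZStack:
    """A calibrated multi-channel z-stack, axes ``(z, channel, row, col)``."""

    pixels: np.ndarray
    channel_map: dict[str, int]
    pixel_size_um: float = 1.0
    z_step_um: float = 1.24
    well_id: str = ""
    condition: str = ""
    experiment_id: str = ""
    fov_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 4:
            raise ValueError(f"expected 4-D (z, channel, row, col) pixels, got shape {self.pixels.shape}")
        nz, nc = self.pixels.shape[:2]
        if nz < 1 or self.pixels.size == 0:
            raise ValueError("zero-size image stack")
        if not np.all(np.isfinite(self.pixels)) or np.any(self.pixels < 0):
            raise ValueError("intensities must be finite and non-negative")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        indices = list(self.channel_map.values())
        if len(set(indices)) != len(indices):
            raise ValueError("channel indices must be distinct")
        for name, idx in self.channel_map.items():
            if not 0 <= idx < nc:
                raise ValueError(f"channel {name!r} index {idx} out of range for {nc}-channel stack")

    @property
    def n_z(self) -> int:
        return self.pixels.shape[0]

    @property
    def has_iba1(self) -> bool:
        return "iba1" in self.channel_map

    def channel(self, name: str) -> np.ndarray:
        """Return the (z, row, col) sub-stack for a named channel."""
        return self.pixels[:, self.channel_map[name]]

    def _meta(self) -> dict:
        return {
            "channel_map": dict(self.channel_map),
            "pixel_size_um": self.pixel_size_um,
            "z_step_um": self.z_step_um,
            "well_id": self.well_id,
            "condition": self.condition,
            "experiment_id": self.experiment_id,
            "fov_id": self.fov_id,
        }


@dataclass
class Projection:
    """A maximum-intensity projection, axes ``(channel, row, col)``."""

    pixels: np.ndarray
    channel_map: dict[str, int]
    pixel_size_um: float = 1.0
    z_step_um: float = 1.24
    well_id: str = ""
    condition: str = ""
    experiment_id: str = ""
    fov_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3:
            raise ValueError(f"expected 3-D (channel, row, col) pixels, got shape {self.pixels.shape}")

    @property
    def has_iba1(self) -> bool:
        return "iba1" in self.channel_map

    def channel(self, name: str) -> np.ndarray:
        return self.pixels[self.channel_map[name]]


def read_stack(path: str | Path, channel_map: Mapping[str, int]) -> ZStack:
    """Read a TIFF/OME-TIFF z-stack.

    The file is interpreted as ``(z, channel, row, col)``; a 3-D file is
    treated as a single z-slice.  Metadata stored by :func:`write_stack`
    (an OME-style JSON description) is restored when present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        pixels = tif.asarray()
        desc = ""
        if tif.is_ome and tif.ome_metadata:
            import xml.etree.ElementTree as ET

            try:
                root = ET.fromstring(tif.ome_metadata)
                ns = root.tag.split("}")[0] + "}"
                node = root.find(f".//{ns}Description")
                desc = node.text or "" if node is not None else ""
            except ET.ParseError:
                desc = ""
        if not desc:
            desc = tif.pages[0].description or ""
    if pixels.ndim == 3:
        pixels = pixels[np.newaxis]
    if pixels.ndim != 4 or pixels.size == 0:
        raise ValueError(f"unreadable stack layout in {path}: shape {pixels.shape}")
    meta: dict = {}
    if desc:
        try:
            parsed = json.loads(desc)
            if isinstance(parsed, dict):
                meta = parsed.get("evtricoloc", {})
        except (json.JSONDecodeError, UnicodeDecodeError):
            meta = {}
    return ZStack(
        pixels=pixels,
        channel_map=dict(channel_map),
        pixel_size_um=float(meta.get("pixel_size_um", 1.0)),
        z_step_um=float(meta.get("z_step_um", 1.24)),
        well_id=str(meta.get("well_id", "")),
        condition=str(meta.get("condition", "")),
        experiment_id=str(meta.get("experiment_id", "")),
        fov_id=str(meta.get("fov_id", "")),
    )


def write_stack(stack: ZStack, path: str | Path, dtype: str = "uint16") -> Path:
    """Write a z-stack as OME-TIFF (ZCYX) with metadata in the description.

    Intensities are rounded into the target integer dtype; synthetic scenes
    are generated inside the uint16 range so the round trip is exact.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    info = np.iinfo(np.dtype(dtype))
    data = np.clip(np.rint(stack.pixels), info.min, info.max).astype(dtype)
    tifffile.imwrite(
        path,
        data,
        ome=True,
        metadata={
            "axes": "ZCYX",
            "Description": json.dumps({"evtricoloc": stack._meta()}),
        },
    )
    return path


def _config_hash(config: Mapping) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    config: Mapping | None = None,
    seed: int | None = None,
    sep: str = ",",
) -> dict:
    """Write result tables as CSV/TSV plus a JSON run manifest.

    Column order is preserved as given (callers construct tables with a
    stable schema), floats are written at full precision, and the manifest
    records a config hash and the seed so identical runs produce
    byte-identical outputs.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable: {exc}") from exc

    ext = ".tsv" if sep == "\t" else ".csv"
    manifest = {
        "config_hash": _config_hash(config or {}),
        "seed": seed,
        "tables": {},
    }
    for name, table in tables.items():
        fname = f"{name}{ext}"
        table.to_csv(out_dir / fname, sep=sep, index=False, lineterminator="\n")
        manifest["tables"][name] = {"file": fname, "n_rows": int(len(table))}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


@dataclass
class RunConfig:
    """Resolved run configuration; defaults follow the published protocol
    where it states a value (smoothing radii 5 and 1, 60-px aggregate gate,
    discovery Q = 0.05)."""

    channel_map: dict[str, int] = field(
        default_factory=lambda: {"dapi": 0, "gfap": 1, "btub": 2, "iba1": 3, "cfse": 4}
    )
    mean_filter_radius: int = 5        # cell-marker smoothing, px
    nuclei_filter_radius: int = 1      # live/dead smoothing, px
    threshold_method: str = "otsu"     # per-channel ROI threshold
    cfse_k: float = 3.0                # CFSE+ cut: background mean + k*SD
    gate_px: int = 60                  # components strictly larger are debris
    min_noncell_px: int = 100
    nuclei_min_size_px: int = 10
    outlier_alpha: float = 0.05
    fdr_q: float = 0.05
    lod_impute: str = "half"           # half | lod | sqrt2
    rotation_direction: str = "ccw"
    rotate_channel: str = "celltype"   # which raster the 90-degree null rotates
    seed: int = 0

    def validate(self) -> None:
        known = {"otsu", "li", "triangle", "fixed"}
        if self.threshold_method not in known:
            raise ValueError(f"threshold_method must be one of {sorted(known)}")
        if self.lod_impute not in {"half", "lod", "sqrt2"}:
            raise ValueError("lod_impute must be 'half', 'lod' or 'sqrt2'")
        if self.rotation_direction not in {"cw", "ccw"}:
            raise ValueError("rotation_direction must be 'cw' or 'ccw'")
        if self.rotate_channel not in {"celltype", "cfse"}:
            raise ValueError("rotate_channel must be 'celltype' or 'cfse'")
        if self.gate_px <= 0:
            raise ValueError("gate_px must be positive")
        if self.cfse_k <= 0:
            raise ValueError("cfse_k must be positive")
        bad = set(self.channel_map) - set(CHANNEL_NAMES)
        if bad:
            raise ValueError(f"unknown channel name(s) in channel_map: {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        allowed = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - allowed
        if bad:
            raise ValueError(f"unknown config field(s): {sorted(bad)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
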