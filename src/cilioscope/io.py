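"""Field loading and tabular result persistence.

A *field* is one multi-channel 2D fluorescence image of ciliated
fibroblasts.  Channels are addressed by biological role rather than by
index so the downstream analysis never depends on acquisition order:

========== =========================== =========
role       typical stain               required
========== =========================== =========
nucleus    DAPI                        yes
axoneme    acetylated-alpha-tubulin    yes
membrane   ARL13B                      yes
basal_body pericentrin (PCNT)          no
transport  IFT88                       no
========== =========================== =========

Pixel coordinates are 0-based ``(row, col)`` with the origin top-left;
every physical output is expressed in µm (length) or µm² (area) so the
pixel convention never leaks downstream.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

MANDATORY_ROLES = ("nucleus", "axoneme", "membrane")
OPTIONAL_ROLES = ("basal_body", "transport")
ALL_ROLES = MANDATORY_ROLES + OPTIONAL_ROLES

#: Canonical per-cilium table columns, in order.
MEASUREMENT_COLUMNS = [
    "line_id",
    "field_id",
    "cilium_id",
    "raw_length_um",
    "length_um",
    "ift_area_um2",
    "class",
    "anchored",
]


class ChannelMapError(ValueError):
    """Invalid role→channel mapping."""


@dataclass
class FieldImage:
    """One multi-channel field with role-keyed planes and µm calibration.

    Parameters
    ----------
    planes
        Mapping from channel role to a 2D float array in ``[0, 1]``.
    pixel_size_um
        Physical edge length of one pixel, in µm (> 0).
    field_id, line_id
        Identifiers carried through to the measurement tables.
    """

    planes: dict[str, np.ndarray]
    pixel_size_um: float
    field_id: str = "field"
    line_id: str = "line"

    def __post_init__(self) -> None:
        if not self.planes:
            raise ValueError("FieldImage requires at least one plane")
        shapes = {p.shape for p in self.planes.values()}
        if len(shapes) != 1:
            raise ValueError(f"planes differ in shape: {sorted(shapes)}")
        if not self.pixel_size_um > 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        for role, plane in self.planes.items():
            if plane.ndim != 2:
                raise ValueError(f"plane {role!r} is not 2D")
            if not np.all(np.isfinite(plane)) or plane.min() < 0:
                raise ValueError(f"plane {role!r} has non-finite or negative values")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.planes.values())).shape

    def plane(self, role: str) -> np.ndarray:
        if role not in self.planes:
            raise KeyError(f"field {self.field_id!r} has no {role!r} plane")
        return self.planes[role]

    def has(self, role: str) -> bool:
        return role in self.planes


def _normalize_plane(arr: np.ndarray) -> np.ndarray:
    """Scale a raw plane to [0, 1] by its dtype maximum (integer data) or
    pass floats through (assumed already on a physical [0, 1] scale)."""
    arr = np.asarray(arr)
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(np.float64) / np.iinfo(arr.dtype).max
    out = arr.astype(np.float64)
    if out.size and out.max() > 1.0:  # unnormalized float export
        out = out / out.max()
    return out


def _pixel_size_from_ome(path: Path) -> float | None:
    try:
        with tifffile.TiffFile(path) as tif:
            xml = tif.ome_metadata
    except Exception:
        return None
    if not xml:
        return None
    try:
        root = ET.fromstring(xml)
    except ET.ParseError:
        return None
    for el in root.iter():
        if el.tag.endswith("Pixels") and "PhysicalSizeX" in el.attrib:
            try:
                v = float(el.attrib["PhysicalSizeX"])
            except ValueError:
                return None
            return v if v > 0 else None
    return None


def validate_channel_map(channel_map: dict[str, int], n_channels: int) -> None:
    missing = [r for r in MANDATORY_ROLES if r not in channel_map]
    if missing:
        raise ChannelMapError(f"missing mandatory role(s): {', '.join(missing)}")
    unknown = [r for r in channel_map if r not in ALL_ROLES]
    if unknown:
        raise ChannelMapError(
            f"unknown role(s) {unknown}; valid roles are {list(ALL_ROLES)}"
        )
    for role, idx in channel_map.items():
        if not 0 <= int(idx) < n_channels:
            raise ChannelMapError(
                f"channel index out of range for role {role!r}: "
                f"{idx} (file has {n_channels} channels)"
            )
    indices = list(channel_map.values())
    if len(set(indices)) != len(indices):
        raise ChannelMapError(f"channel indices are not unique: {indices}")


def load_field(
    path: str | Path,
    channel_map: dict[str, int],
    pixel_size_um: float | str | None = "from-metadata",
    field_id: str | None = None,
    line_id: str = "line",
) -> FieldImage:
    """Load a multi-channel TIFF / OME-TIFF into a :class:`FieldImage`.

    ``pixel_size_um`` may be a positive number or ``"from-metadata"`` in
    which case the OME ``PhysicalSizeX`` attribute is used; if neither is
    available an error is raised.  Intensities are normalized to [0, 1]
    per plane (integer dtype maximum) so downstream thresholds are
    acquisition-independent.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"field image not found: {path}")
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise ValueError(f"expected a (C, Y, X) stack, got shape {stack.shape}")
    validate_channel_map(channel_map, n_channels=stack.shape[0])

    if pixel_size_um is None or pixel_size_um == "from-metadata":
        px = _pixel_size_from_ome(path)
        if px is None:
            raise ValueError(
                f"{path}: pixel size not found in metadata; pass pixel_size_um"
            )
        pixel_size_um = px
    pixel_size_um = float(pixel_size_um)
    if not pixel_size_um > 0:
        raise ValueError(f"pixel_size_um must be > 0, got {pixel_size_um}")

    planes = {
        role: _normalize_plane(stack[int(idx)]) for role, idx in channel_map.items()
    }
    return FieldImage(
        planes=planes,
        pixel_size_um=pixel_size_um,
        field_id=field_id or path.stem,
        line_id=line_id,
    )


def load_field_by_role(
    paths: dict[str, str | Path],
    pixel_size_um: float,
    field_id: str = "field",
    line_id: str = "line",
) -> FieldImage:
    """Load one single-channel TIFF per role (the per-role-file dialect)."""
    missing = [r for r in MANDATORY_ROLES if r not in paths]
    if missing:
        raise ChannelMapError(f"missing mandatory role(s): {', '.join(missing)}")
    planes = {}
    for role, p in paths.items():
        p = Path(p)
        if not p.exists():
            raise FileNotFoundError(f"field image not found: {p}")
        planes[role] = _normalize_plane(tifffile.imread(p))
    return FieldImage(planes, float(pixel_size_um), field_id=field_id, line_id=line_id)


def save_field(field_img: FieldImage, path: str | Path) -> list[str]:
    """Write a field as OME-TIFF (uint16, role order fixed) with pixel size
    embedded as ``PhysicalSizeX/Y``.  Returns the role order written."""
    path = Path(path)
    roles = [r for r in ALL_ROLES if field_img.has(r)]
    stack = np.stack(
        [
            np.clip(field_img.planes[r], 0.0, 1.0) * np.iinfo(np.uint16).max
            for r in roles
        ]
    ).astype(np.uint16)
    tifffile.imwrite(
        path,
        stack,
        ome=True,
        photometric="minisblack",
        metadata={
            "axes": "CYX",
            "PhysicalSizeX": field_img.pixel_size_um,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": field_img.pixel_size_um,
            "PhysicalSizeYUnit": "µm",
            "Channel": {"Name": roles},
        },
    )
    return roles


def write_measurements(table: pd.DataFrame, path: str | Path) -> None:
    """Write a per-cilium measurement table as UTF-8 CSV ("." decimal).

    Floats are formatted to 6 significant digits so that a
    write → read → write cycle is byte-identical.
    """
    missing = [c for c in MEASUREMENT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"measurement table missing column(s): {', '.join(missing)}")
    keys = table[["line_id", "field_id", "cilium_id"]]
    if keys.duplicated().any():
        raise ValueError("duplicate (line_id, field_id, cilium_id) keys")
    out = table[MEASUREMENT_COLUMNS].copy()
    out.to_csv(path, index=False, float_format="%.6g", encoding="utf-8")


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read a per-cilium measurement table, validating the key columns."""
    df = pd.read_csv(path)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: malformed measurement CSV, missing column(s): "
            f"{', '.join(missing)}"
        )
    for col in ("raw_length_um", "length_um", "ift_area_um2"):
        vals = df[col].dropna()
        if (vals < 0).any():
            raise ValueError(f"{path}: negative values in {col}")
    return df
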