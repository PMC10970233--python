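"""Domain types and I/O shared by every stage of the Q-FISH pipeline.

The package operates on 3D stacks of raw photon counts with anisotropic
voxels (default 30 x 30 x 200 nm, lateral x lateral x axial).  Photon
counts are never rescaled anywhere in the pipeline: detection smooths a
*copy* of the data and quantification fits the raw counts.

Conventions
-----------
* Voxel indices are 0-based, ordered ``(z, y, x)``, and refer to the
  voxel center; the physical position of index ``i`` along an axis is
  ``i * voxel_size`` for that axis.
* Nucleus masks are 2D polygons in pixel coordinates ``(x, y)`` applied
  to every z-plane; membership uses the even-odd rule with boundary
  points counted as inside.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd
import tifffile

if TYPE_CHECKING:  # pragma: no cover
    from .quantify import TelomereFeatures

log = logging.getLogger("qfish3d")

PHASE_LABELS = frozenset(
    {"interphase", "metaphase", "anaphase", "telophase", "M-phase", "unknown"}
)


class FormatError(ValueError):
    """Raised for image/table inputs that violate the expected format."""


@dataclass(frozen=True)
class VoxelGeometry:
    """Physical voxel size in nanometres, ``(dx, dy, dz)``.

    ``dz`` is the axial step between planes.  The defaults match a 3D
    STED acquisition sampled at 30 x 30 nm laterally with 200 nm axial
    steps.
    """

    dx_nm: float = 30.0
    dy_nm: float = 30.0
    dz_nm: float = 200.0

    def __post_init__(self) -> None:
        for name in ("dx_nm", "dy_nm", "dz_nm"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")

    def to_dict(self) -> dict:
        return {"dx_nm": self.dx_nm, "dy_nm": self.dy_nm, "dz_nm": self.dz_nm}

    @classmethod
    def from_dict(cls, d: dict) -> "VoxelGeometry":
        return cls(float(d["dx_nm"]), float(d["dy_nm"]), float(d["dz_nm"]))

    def scale_nm(self) -> np.ndarray:
        """Per-axis physical scale in (z, y, x) order."""
        return np.array([self.dz_nm, self.dy_nm, self.dx_nm], dtype=float)


@dataclass
class ImageStack3D:
    """A 3D grid of non-negative photon counts indexed ``(z, y, x)``.

    Raw stacks hold integer counts; smoothed stacks hold floats.  The
    shape is fixed after construction.
    """

    voxels: np.ndarray
    geometry: VoxelGeometry = field(default_factory=VoxelGeometry)
    channel_name: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise FormatError(f"expected a 3D array, got ndim={self.voxels.ndim}")
        if self.voxels.size and self.voxels.min() < 0:
            raise ValueError("photon counts must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def index_to_nm(self, index: Sequence[float]) -> np.ndarray:
        """Physical (z, y, x) position in nm of a (fractional) voxel index."""
        return np.asarray(index, dtype=float) * self.geometry.scale_nm()


@dataclass
class NucleusMask:
    """A closed 2D polygon (pixel coordinates, ``(x, y)`` vertex pairs)
    delineating the nucleus, applied to all z-planes.

    An optional ``per_plane`` dict may override the polygon for
    individual z indices.
    """

    polygon: np.ndarray
    per_plane: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.polygon = _validate_polygon(self.polygon)
        self.per_plane = {int(z): _validate_polygon(p) for z, p in self.per_plane.items()}

    def polygon_for_plane(self, z: int) -> np.ndarray:
        return self.per_plane.get(int(z), self.polygon)

    def to_json(self, path: str | Path) -> None:
        payload = {"polygon": np.asarray(self.polygon).tolist()}
        if self.per_plane:
            payload["per_plane"] = {str(z): p.tolist() for z, p in self.per_plane.items()}
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "NucleusMask":
        payload = json.loads(Path(path).read_text())
        per_plane = {
            int(z): np.asarray(p, dtype=float)
            for z, p in payload.get("per_plane", {}).items()
        }
        return cls(np.asarray(payload["polygon"], dtype=float), per_plane)


def _validate_polygon(polygon: np.ndarray) -> np.ndarray:
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
        raise ValueError("polygon must be an (n >= 3, 2) array of (x, y) vertices")
    # drop an explicit closing vertex; closure is implicit
    if np.allclose(poly[0], poly[-1]) and poly.shape[0] > 3:
        poly = poly[:-1]
    if abs(_shoelace_area(poly)) <= 0.0:
        raise ValueError("degenerate polygon with zero area")
    return poly


def _shoelace_area(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def points_in_polygon(poly: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Even-odd point-in-polygon test; boundary points count as inside.

    ``xs``/``ys`` are broadcastable arrays of point coordinates.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    inside = np.zeros(np.broadcast(xs, ys).shape, dtype=bool)
    on_edge = np.zeros_like(inside)
    n = len(poly)
    eps = 1e-9 * max(1.0, float(np.abs(poly).max()))
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        # even-odd ray casting (ray towards +x)
        crosses = (y1 > ys) != (y2 > ys)
        if np.any(crosses):
            with np.errstate(divide="ignore", invalid="ignore"):
                x_int = x1 + (ys - y1) * (x2 - x1) / (y2 - y1)
            inside ^= crosses & (xs < x_int)
        # boundary-inclusive: point on the closed segment
        dx, dy = x2 - x1, y2 - y1
        seg_len2 = dx * dx + dy * dy
        cross = (xs - x1) * dy - (ys - y1) * dx
        t = ((xs - x1) * dx + (ys - y1) * dy) / seg_len2 if seg_len2 > 0 else 0.0
        on_edge |= (np.abs(cross) <= eps * max(1.0, np.sqrt(seg_len2))) & (t >= -eps) & (
            t <= 1 + eps
        )
    return inside | on_edge


@dataclass
class AcquisitionMetadata:
    """Opaque acquisition metadata (laser powers, adaptive-illumination
    levels, dwell times).  Carried through unmodified, never interpreted."""

    entries: dict = field(default_factory=dict)


@dataclass
class CellRecord:
    """One cell's phase label and per-telomere feature table.

    ``phase`` is an input label (e.g. from a nuclear-speckle co-stain),
    never inferred from the image.
    """

    cell_id: str
    phase: str = "unknown"
    features: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.phase not in PHASE_LABELS:
            raise ValueError(
                f"unknown phase {self.phase!r}; expected one of {sorted(PHASE_LABELS)}"
            )


# ---------------------------------------------------------------------------
# Stack I/O
# ---------------------------------------------------------------------------

def read_stack(
    path: str | Path,
    geometry: VoxelGeometry | None = None,
    channel_name: str = "",
) -> ImageStack3D:
    """Read a multi-page grayscale 8/16-bit TIFF as a z-stack.

    Plane order equals z order.  Voxel geometry comes from the caller
    (config/CLI), not from TIFF tags, because microscope TIFF tag
    dialects are unreliable.
    """
    with tifffile.TiffFile(str(path)) as tf:
        shapes = set()
        for page in tf.pages:
            if page.samplesperpixel != 1:
                raise FormatError(f"{path}: expected grayscale pages, got multi-sample data")
            shapes.add(page.shape)
        if len(shapes) > 1:
            raise FormatError(f"{path}: inconsistent plane shapes {sorted(shapes)}")
        arr = tf.asarray()
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise FormatError(
            f"{path}: expected a grayscale multi-page TIFF, got shape {arr.shape}"
        )
    if arr.dtype not in (np.uint8, np.uint16):
        raise FormatError(f"{path}: expected 8/16-bit grayscale data, got {arr.dtype}")
    return ImageStack3D(arr, geometry or VoxelGeometry(), channel_name)


def write_stack(stack: ImageStack3D, path: str | Path) -> None:
    """Write a stack as an uncompressed 16-bit multi-page TIFF."""
    data = np.asarray(stack.voxels)
    if not np.issubdtype(data.dtype, np.integer):
        data = np.rint(data).astype(np.int64)
    if data.max(initial=0) > np.iinfo(np.uint16).max:
        raise FormatError("photon counts exceed the 16-bit range")
    tifffile.imwrite(str(path), data.astype(np.uint16), photometric="minisblack")


# ---------------------------------------------------------------------------
# Feature table I/O
# ---------------------------------------------------------------------------

FEATURE_COLUMNS = [
    "cell_id",
    "phase",
    "spot_id",
    "z_nm",
    "y_nm",
    "x_nm",
    "n_voxels",
    "peak_counts",
    "brightness_peak",
    "background_a",
    "fwhm_x_nm",
    "fwhm_y_nm",
    "fwhm_z_nm",
    "volume_um3",
    "integrated_brightness",
    "signal_density",
    "r2_x",
    "r2_y",
    "quality_flag",
]


def write_features(records: Sequence[CellRecord], path: str | Path) -> pd.DataFrame:
    """Write per-telomere features (one row per spot) to a CSV file.

    Column order is deterministic; cells without spots contribute no
    rows.
    """
    if not records:
        raise ValueError("no records to write")
    rows = []
    for rec in records:
        for feat in rec.features:
            row = {"cell_id": rec.cell_id, "phase": rec.phase}
            row.update(dataclasses.asdict(feat))
            rows.append(row)
    df = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    df.to_csv(path, index=False)
    return df


def read_features(path: str | Path) -> list[CellRecord]:
    """Read a feature CSV written by :func:`write_features` back into
    :class:`CellRecord` objects."""
    from .quantify import TelomereFeatures  # local import avoids a cycle

    df = pd.read_csv(path)
    records: list[CellRecord] = []
    feat_fields = [f.name for f in dataclasses.fields(TelomereFeatures)]
    for (cell_id, phase), grp in df.groupby(["cell_id", "phase"], sort=False):
        feats = []
        for _, row in grp.iterrows():
            kwargs = {}
            for name in feat_fields:
                val = row[name]
                if isinstance(val, float) and np.isnan(val):
                    val = None
                kwargs[name] = val
            kwargs["spot_id"] = int(kwargs["spot_id"])
            kwargs["n_voxels"] = int(kwargs["n_voxels"])
            feats.append(TelomereFeatures(**kwargs))
        records.append(CellRecord(str(cell_id), str(phase), feats))
    return records


# ---------------------------------------------------------------------------
# Masking
# ---------------------------------------------------------------------------

def apply_mask(stack: ImageStack3D, mask: NucleusMask) -> ImageStack3D:
    """Zero all voxels whose lateral center falls outside the nucleus
    polygon; voxels inside are passed through unchanged.

    Masking is idempotent and leaves raw counts untouched inside the
    polygon.
    """
    nz, ny, nx = stack.shape
    ys, xs = np.mgrid[0:ny, 0:nx]
    out = np.array(stack.voxels, copy=True)
    default_inside = points_in_polygon(mask.polygon, xs, ys)
    for z in range(nz):
        poly = mask.polygon_for_plane(z)
        inside = default_inside if poly is mask.polygon else points_in_polygon(poly, xs, ys)
        out[z][~inside] = 0
    return ImageStack3D(out, stack.geometry, stack.channel_name, dict(stack.metadata))
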