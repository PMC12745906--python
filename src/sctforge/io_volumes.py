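"""Volume containers, NIfTI I/O, grid resampling, and intensity normalization.

All volumes are 3D scalar grids indexed ``(z, y, x)`` (axial slices along the
first axis), with voxel-center coordinates ``origin + index * spacing`` in mm.
Two normalization contracts are provided for network input preparation:

* MR volumes are scaled by their per-volume maximum into [0, 1].
* CT volumes are mapped onto a 12-bit raw scale, ``raw = clip(HU + 1024, 0,
  4095)``, then divided by 4095. The offset is the standard CT storage
  convention (air = -1024 HU stored as 0); the divisor makes the unit
  interval attainable at the 12-bit ceiling (3071 HU).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "Volume",
    "RegionMask",
    "VolumeFormatError",
    "ContractError",
    "DegenerateInputError",
    "KINDS",
    "HU_MIN",
    "HU_MAX",
    "TWELVE_BIT_MAX",
    "read_volume",
    "write_volume",
    "normalize_mr",
    "normalize_ct",
    "denormalize_ct",
    "resample_to_grid",
    "background_value",
]

#: Value semantics a Volume may carry.
KINDS = ("HU", "MR", "NORM01", "DOSE", "LABEL")

HU_MIN = -1024.0          # lower clip of the 12-bit representable HU range
HU_MAX = 3071.0           # upper clip (HU_MIN + TWELVE_BIT_MAX)
TWELVE_BIT_MAX = 4095.0   # divisor of the 12-bit normalization

#: Fill value used for voxels outside a volume's field of view, per kind.
_BACKGROUND = {"HU": HU_MIN, "MR": 0.0, "NORM01": 0.0, "DOSE": 0.0, "LABEL": 0.0}


class VolumeFormatError(ValueError):
    """A file could not be read as a volume, or its header is invalid."""


class ContractError(ValueError):
    """An operation's input violates its stated preconditions."""


class DegenerateInputError(ValueError):
    """Input is structurally valid but degenerate for the operation."""


def background_value(kind: str) -> float:
    """Out-of-field fill value for a volume kind (HU -> -1024, else 0)."""
    return _BACKGROUND[kind]


@dataclass
class Volume:
    """A 3D scalar grid with physical spacing and origin.

    Parameters
    ----------
    data : ndarray, shape (Z, Y, X)
        Scalar values, axial slices along the first axis.
    spacing : tuple of float
        Voxel size in mm per axis, (z, y, x) order. Strictly positive.
    origin : tuple of float
        World coordinate (mm) of the voxel-center at index (0, 0, 0).
    kind : str
        One of :data:`KINDS`, declaring the value semantics.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    kind: str = "HU"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ContractError(f"Volume data must be 3D, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ContractError("spacing and origin must have 3 components")
        if any(s <= 0 for s in self.spacing):
            raise ContractError(f"spacing must be strictly positive, got {self.spacing}")
        if self.kind not in KINDS:
            raise ContractError(f"unknown volume kind {self.kind!r}; expected one of {KINDS}")
        # NaN marks not-evaluated voxels (e.g. gamma below threshold); infinities are invalid
        if np.isinf(self.data).any():
            raise ContractError("Volume data must not contain infinities")
        if self.kind == "NORM01":
            lo, hi = float(self.data.min()), float(self.data.max())
            if lo < -1e-9 or hi > 1 + 1e-9:
                raise ContractError(f"NORM01 volume has values outside [0,1]: [{lo}, {hi}]")
        if self.kind == "LABEL" and not np.allclose(self.data, np.round(self.data)):
            raise ContractError("LABEL volume must hold integer values")

    # -- grid helpers -------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def same_grid(self, other: "Volume | RegionMask") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map fractional (z,y,x) indices to world mm coordinates."""
        idx = np.asarray(idx, dtype=float)
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)

    def world_to_voxel(self, pts: np.ndarray) -> np.ndarray:
        """Map world mm coordinates to fractional (z,y,x) indices."""
        pts = np.asarray(pts, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def with_data(self, data: np.ndarray, kind: str | None = None) -> "Volume":
        return replace(self, data=data, kind=self.kind if kind is None else kind)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class RegionMask:
    """A named boolean region defined on a parent volume grid."""

    data: np.ndarray
    region_name: str
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ContractError("RegionMask data must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ContractError("RegionMask spacing must be strictly positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def count(self) -> int:
        return int(self.data.sum())

    @classmethod
    def from_volume(cls, parent: Volume, data: np.ndarray, name: str) -> "RegionMask":
        if data.shape != parent.shape:
            raise ContractError("mask shape differs from parent volume")
        return cls(data=data, region_name=name, spacing=parent.spacing, origin=parent.origin)


# -- NIfTI I/O --------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def read_volume(path: str | Path, kind: str | None = None) -> Volume:
    """Read a NIfTI volume.

    Spacing and origin come from the header affine; ``kind`` comes from the
    argument, or a JSON sidecar (``<stem>.json`` with a ``kind`` key), in that
    order. Raises :class:`VolumeFormatError` for unreadable files or
    non-positive header spacing.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
        arr = np.asanyarray(img.dataobj).astype(np.float64)
    except Exception as exc:  # nibabel raises a zoo of types
        raise VolumeFormatError(f"cannot read volume {path}: {exc}") from exc
    if arr.ndim != 3:
        raise VolumeFormatError(f"{path}: expected a 3D volume, got shape {arr.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise VolumeFormatError(f"{path}: non-positive voxel spacing in header: {zooms}")
    origin_xyz = img.affine[:3, 3]
    if kind is None:
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            kind = json.loads(sidecar.read_text()).get("kind")
    if kind is None:
        raise VolumeFormatError(
            f"{path}: volume kind not given and no JSON sidecar found; "
            f"pass kind= or write a sidecar with a 'kind' key"
        )
    # on-disk order is (x, y, z); internal order is (z, y, x)
    data = np.ascontiguousarray(arr.T)
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    origin = (float(origin_xyz[2]), float(origin_xyz[1]), float(origin_xyz[0]))
    return Volume(data=data, spacing=spacing, origin=origin, kind=kind)


def write_volume(vol: Volume, path: str | Path, sidecar: bool = True) -> Path:
    """Write a volume as NIfTI (+ JSON sidecar carrying ``kind``)."""
    path = Path(path)
    sz, sy, sx = vol.spacing
    oz, oy, ox = vol.origin
    affine = np.diag([sx, sy, sz, 1.0])
    affine[:3, 3] = [ox, oy, oz]
    img = nib.Nifti1Image(np.ascontiguousarray(vol.data.T).astype(np.float64), affine)
    nib.save(img, str(path))
    if sidecar:
        _sidecar_path(path).write_text(json.dumps({"kind": vol.kind}))
    return path


# -- normalization ----------------------------------------------------------

def normalize_mr(v: Volume) -> Volume:
    """Scale an MR volume by its per-volume maximum into [0, 1].

    Raises :class:`DegenerateInputError` if the volume maximum is not
    strictly positive (an all-zero or negative volume carries no usable
    intensity scale).
    """
    if v.kind != "MR":
        raise ContractError(f"normalize_mr expects an MR volume, got kind {v.kind!r}")
    vmax = float(v.data.max())
    if vmax <= 0:
        raise DegenerateInputError("MR volume maximum must be strictly positive")
    out = np.clip(v.data / vmax, 0.0, 1.0)
    return Volume(data=out, spacing=v.spacing, origin=v.origin, kind="NORM01")


def normalize_ct(v: Volume) -> Volume:
    """Map HU onto a 12-bit raw scale and divide by 4095.

    ``raw = clip(HU + 1024, 0, 4095)``; output is ``raw / 4095``. Air
    (-1024 HU) maps to 0, the 12-bit ceiling (3071 HU) maps to 1.
    """
    if v.kind != "HU":
        raise ContractError(f"normalize_ct expects an HU volume, got kind {v.kind!r}")
    raw = np.clip(v.data - HU_MIN, 0.0, TWELVE_BIT_MAX)
    return Volume(data=raw / TWELVE_BIT_MAX, spacing=v.spacing, origin=v.origin, kind="NORM01")


def denormalize_ct(v: Volume, atol: float = 1e-6) -> Volume:
    """Invert :func:`normalize_ct`: ``HU = v * 4095 - 1024``.

    Values must lie in [0, 1] (within ``atol``); the composition
    ``denormalize_ct(normalize_ct(x))`` is the identity on HU in
    [-1024, 3071].
    """
    lo, hi = float(v.data.min()), float(v.data.max())
    if lo < -atol or hi > 1 + atol:
        raise ContractError(f"denormalize_ct input outside [0,1]: range [{lo}, {hi}]")
    data = np.clip(v.data, 0.0, 1.0) * TWELVE_BIT_MAX + HU_MIN
    return Volume(data=data, spacing=v.spacing, origin=v.origin, kind="HU")


# -- resampling -------------------------------------------------------------

def resample_to_grid(v: Volume, target: Volume, mode: str | None = None) -> Volume:
    """Resample ``v`` onto ``target``'s grid.

    ``mode`` is ``"linear"`` or ``"nearest"``; by default LABEL volumes use
    nearest-neighbour and everything else linear. Out-of-field voxels are
    filled with the kind's background (HU -> -1024, else 0). Identical grids
    return a bitwise copy. An empty field-of-view overlap produces a warning
    and a background-filled volume.
    """
    if mode is None:
        mode = "nearest" if v.kind == "LABEL" else "linear"
    if mode not in ("linear", "nearest"):
        raise ContractError(f"unknown resampling mode {mode!r}")
    if v.same_grid(target):
        return Volume(data=v.data.copy(), spacing=v.spacing, origin=v.origin, kind=v.kind)

    bg = background_value(v.kind)
    tz, ty, tx = target.shape
    idx = np.indices(target.shape, dtype=float).reshape(3, -1).T
    world = target.voxel_to_world(idx)
    src = v.world_to_voxel(world).T  # (3, N) fractional source indices

    inside = np.all((src >= -0.5) & (src <= (np.array(v.shape)[:, None] - 0.5)), axis=0)
    if not inside.any():
        warnings.warn("resample_to_grid: fields of view do not overlap; output is background", stacklevel=2)
    order = 1 if mode == "linear" else 0
    out = map_coordinates(v.data.astype(np.float64), src, order=order, mode="constant", cval=bg)
    out = out.reshape(target.shape)
    if v.kind == "LABEL":
        out = np.round(out)
    return Volume(data=out, spacing=target.spacing, origin=target.origin, kind=v.kind)
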