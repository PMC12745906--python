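"""Immobilization-mask template extraction, anchor-point spline deformation,
rigid board registration, and composition of the full synthetic CT (sCT_F).

The thermoplastic shell of a template mask acquisition is adapted to each
subject by a 3D thin-plate-spline deformation interpolating paired anchor
points (nose tip, lateral face edges, posterior neck — the regions where the
shell contacts the patient); the rigid board + spacer bars are then aligned
by least-squares rigid (Kabsch) registration of spacer landmarks; finally the
devices are composited onto the synthetic CT outside the body. A physicist's
visual review is replaced by automated QA numbers (body-device overlap
fraction, shell-skin distance statistics).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.interpolate import RBFInterpolator

from .io_volumes import ContractError, RegionMask, Volume

__all__ = [
    "AnchorSet",
    "DeformationField",
    "RigidTransform",
    "extract_template",
    "fit_deformation",
    "warp_mask",
    "register_board",
    "apply_rigid",
    "compose_sct_f",
    "auto_anchors",
    "deform_shells",
    "read_anchors",
    "shell_skin_distances",
]


@dataclass
class AnchorSet:
    """Paired anchor points (mm, (z,y,x) order): source on the template,
    target on the subject."""

    source: np.ndarray
    target: np.ndarray

    def __post_init__(self) -> None:
        self.source = np.atleast_2d(np.asarray(self.source, dtype=float))
        self.target = np.atleast_2d(np.asarray(self.target, dtype=float))
        if self.source.shape != self.target.shape or self.source.shape[1] != 3:
            raise ContractError("source and target must be equal-length (N,3) arrays")
        if len(self.source) < 4:
            raise ContractError("need at least 4 anchor pairs")
        if not (np.isfinite(self.source).all() and np.isfinite(self.target).all()):
            raise ContractError("anchor coordinates must be finite")
        centered = self.source - self.source.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-6) < 3:
            raise ContractError("source anchors are coplanar; 3D spline needs non-coplanar points")

    def inverted(self) -> "AnchorSet":
        return AnchorSet(source=self.target.copy(), target=self.source.copy())


@dataclass
class DeformationField:
    """Per-voxel displacement vectors (mm) on a volume grid, (z,y,x,3)."""

    displacement: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.displacement.ndim != 4 or self.displacement.shape[-1] != 3:
            raise ContractError("displacement must have shape (Z, Y, X, 3)")
        if not np.isfinite(self.displacement).all():
            raise ContractError("displacement field must be finite")


@dataclass
class RigidTransform:
    """x -> R @ x + t in mm coordinates, with the landmark-fit residual."""

    rotation: np.ndarray     # (3,3)
    translation: np.ndarray  # (3,)
    residual_rms: float = 0.0

    def apply(self, pts: np.ndarray) -> np.ndarray:
        return np.atleast_2d(pts) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation, self.residual_rms)


# -- template extraction ----------------------------------------------------

def extract_template(with_mask: Volume, without_mask: Volume,
                     threshold_hu: float = 100.0) -> Volume:
    """Isolate the immobilization-device HU from a masked/bare CT pair.

    The voxelwise difference, thresholded at ``threshold_hu`` to suppress
    noise, defines the device support (device material replaces air, so the
    difference there is large); the returned template carries the masked
    acquisition's HU on that support and 0 elsewhere.
    """
    if not with_mask.same_grid(without_mask):
        raise ContractError("extract_template requires identical grids")
    diff = with_mask.data - without_mask.data
    support = np.abs(diff) > threshold_hu
    out = np.where(support, with_mask.data, 0.0)
    return Volume(out, with_mask.spacing, with_mask.origin, kind="HU")


# -- spline deformation -----------------------------------------------------

def fit_deformation(anchors: AnchorSet, grid: Volume) -> DeformationField:
    """Thin-plate-spline displacement field interpolating the anchors.

    Interpolating (zero smoothing) with an affine polynomial term: exact at
    every source anchor and reproducing any affine displacement (including
    pure translations) everywhere.
    """
    src = anchors.source
    if len(np.unique(src.round(9), axis=0)) != len(src):
        disp = anchors.target - anchors.source
        uniq, inv = np.unique(src.round(9), axis=0, return_inverse=True)
        for i in range(len(uniq)):
            d = disp[inv == i]
            if len(d) > 1 and not np.allclose(d, d[0]):
                raise ContractError("duplicate source anchors with conflicting targets")
        raise ContractError("duplicate source anchor points")
    interp = RBFInterpolator(src, anchors.target - src, kernel="thin_plate_spline",
                             degree=1, smoothing=0.0)
    idx = np.indices(grid.shape, dtype=float).reshape(3, -1).T
    pts = grid.voxel_to_world(idx)
    disp = interp(pts).reshape(*grid.shape, 3)
    return DeformationField(disp, grid.spacing, grid.origin)


def warp_mask(shells: Volume, field: DeformationField, order: int | None = None) -> Volume:
    """Backward (pull) warp of a shell volume through a displacement field.

    ``out(x) = shells(x + field(x))`` with linear HU interpolation (nearest
    for LABEL volumes). To deform template shells *onto* a subject, the field
    must be fitted on inverted anchor pairs (see :func:`deform_shells`).
    """
    if shells.shape != field.displacement.shape[:3] or not np.allclose(shells.spacing, field.spacing):
        raise ContractError("field must be defined on the shell volume's grid")
    if order is None:
        order = 0 if shells.kind == "LABEL" else 1
    idx = np.indices(shells.shape, dtype=float)
    sample_idx = idx + np.moveaxis(field.displacement, -1, 0) / np.asarray(shells.spacing).reshape(3, 1, 1, 1)
    out = ndimage.map_coordinates(shells.data.astype(np.float64), sample_idx.reshape(3, -1),
                                  order=order, mode="constant", cval=0.0).reshape(shells.shape)
    if shells.kind == "LABEL":
        out = np.round(out)
    return Volume(out, shells.spacing, shells.origin, kind=shells.kind)


def deform_shells(shells: Volume, components: Volume | None, anchors: AnchorSet,
                  grid: Volume) -> tuple[Volume, Volume | None]:
    """Deform template shells onto the subject defined by ``anchors``
    (source on template, target on subject). Fits the pull field on inverted
    pairs and warps HU (linear) and component labels (nearest)."""
    field = fit_deformation(anchors.inverted(), grid)
    warped = warp_mask(shells, field)
    warped_comp = warp_mask(components, field) if components is not None else None
    return warped, warped_comp


# -- rigid board registration -----------------------------------------------

def register_board(board_landmarks: np.ndarray, target_landmarks: np.ndarray) -> RigidTransform:
    """Least-squares rigid (Kabsch) fit mapping board spacer landmarks onto
    the deformed shells' connection landmarks; reports residual RMS (mm)."""
    P = np.atleast_2d(np.asarray(board_landmarks, dtype=float))
    Q = np.atleast_2d(np.asarray(target_landmarks, dtype=float))
    if P.shape != Q.shape or P.shape[1] != 3:
        raise ContractError("landmark sets must be equal-shape (N,3)")
    if len(P) < 3:
        raise ContractError("rigid registration needs at least 3 landmark pairs")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = qc - R @ pc
    res = np.sqrt(np.mean(np.sum((P @ R.T + t - Q) ** 2, axis=1)))
    return RigidTransform(R, t, float(res))


def apply_rigid(vol: Volume, transform: RigidTransform, order: int | None = None) -> Volume:
    """Resample a volume through a rigid transform (output grid = input grid):
    ``out(x) = vol(T^{-1} x)``."""
    if order is None:
        order = 0 if vol.kind == "LABEL" else 1
    inv = transform.inverse()
    idx = np.indices(vol.shape, dtype=float).reshape(3, -1).T
    pts = vol.voxel_to_world(idx)
    src = vol.world_to_voxel(inv.apply(pts)).T
    out = ndimage.map_coordinates(vol.data.astype(np.float64), src, order=order,
                                  mode="constant", cval=0.0).reshape(vol.shape)
    if vol.kind == "LABEL":
        out = np.round(out)
    return Volume(out, vol.spacing, vol.origin, kind=vol.kind)


# -- composition ------------------------------------------------------------

def compose_sct_f(sct: Volume, warped_shells: Volume | None, transformed_board: Volume | None,
                  body: RegionMask) -> tuple[Volume, dict]:
    """Overlay deformed devices onto the synthetic CT to form sCT_F.

    Body voxels always keep the sCT HU; outside the body, device HU replaces
    background wherever a device is present (shells take precedence over the
    board where both land on a voxel). Returns the composed volume and QA
    numbers: the fraction of device voxels that collided with the body (those
    are dropped) per device and overall.
    """
    out = sct.data.copy()
    body_arr = body.data
    qa: dict[str, float] = {}
    n_dev = n_overlap = 0
    for name, dev in (("board", transformed_board), ("shells", warped_shells)):
        if dev is None:
            continue
        if not sct.same_grid(dev):
            raise ContractError(f"{name} not on the working grid")
        present = dev.data != 0
        overlap = present & body_arr
        place = present & ~body_arr
        out[place] = dev.data[place]
        qa[f"{name}_body_overlap_fraction"] = (
            float(overlap.sum() / present.sum()) if present.any() else 0.0
        )
        n_dev += int(present.sum())
        n_overlap += int(overlap.sum())
    qa["device_body_overlap_fraction"] = n_overlap / n_dev if n_dev else 0.0
    return Volume(out, sct.spacing, sct.origin, kind="HU"), qa


# -- anchors ----------------------------------------------------------------

def read_anchors(path: str | Path) -> AnchorSet:
    """Anchor file: JSON list of {"source": [z,y,x], "target": [z,y,x]} in mm."""
    entries = json.loads(Path(path).read_text())
    return AnchorSet(
        source=np.array([e["source"] for e in entries], dtype=float),
        target=np.array([e["target"] for e in entries], dtype=float),
    )


def auto_anchors(body: RegionMask) -> np.ndarray:
    """Characteristic mask-contact points on a head surface, in mm.

    Returns six named surface points in fixed order: nose tip (most anterior
    at mid-height), left/right lateral face edges, posterior neck point (most
    posterior at low z), vertex (most superior), and chin-level anterior
    point — the regions where a thermoplastic shell contacts the patient.
    Computing these on template and subject gives paired anchors.
    """
    arr = body.data
    if not arr.any():
        raise ContractError("empty body mask")
    zs, ys, xs = np.nonzero(arr)
    sp = np.asarray(body.spacing)
    z_mid = int(round(zs.mean()))
    z_low = int(np.percentile(zs, 20))

    def at_plane(z):
        m = arr[z]
        yy, xx = np.nonzero(m)
        return yy, xx

    yy, xx = at_plane(z_mid)
    x_mid = int(round(xx.mean()))
    # nose tip: most anterior (min y) at mid z, central x
    central = np.abs(xx - x_mid) <= 2
    nose = (z_mid, yy[central].min(), x_mid)
    # lateral edges at mid z
    left = (z_mid, int(round(yy[xx == xx.min()].mean())), xx.min())
    right = (z_mid, int(round(yy[xx == xx.max()].mean())), xx.max())
    # posterior neck at low z
    yy2, xx2 = at_plane(z_low)
    neck = (z_low, yy2.max(), int(round(xx2[yy2 == yy2.max()].mean())))
    # vertex: most superior slice centroid
    z_top = zs.min()
    yy3, xx3 = at_plane(z_top)
    vertex = (z_top, int(round(yy3.mean())), int(round(xx3.mean())))
    # anterior point at low z (chin level)
    chin = (z_low, yy2.min(), int(round(xx2[yy2 == yy2.min()].mean())))
    pts = np.array([nose, left, right, neck, vertex, chin], dtype=float)
    return pts * sp + np.asarray(body.origin)


def shell_skin_distances(shell: Volume | np.ndarray, body: RegionMask) -> np.ndarray:
    """Distance (mm) from each nonzero shell voxel to the body surface."""
    arr = shell.data if isinstance(shell, Volume) else np.asarray(shell)
    dist = ndimage.distance_transform_edt(~body.data, sampling=body.spacing)
    return dist[arr != 0]
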