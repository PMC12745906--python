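"""Digital head phantoms: paired MR/CT volumes, a template CT knowledge base,
immobilization-mask geometry, and dose grids.

The generator emulates the paired data a clinical MR-only planning study would
acquire. Each subject is an ellipsoidal head (air / brain / skull tissue
classes) with per-subject shape jitter. CT holds per-tissue Hounsfield means
plus Gaussian noise. The MR mapping is deliberately *not* invertible from HU
alone: brain is bright while skull and air are both dark, mimicking the
bone/air ambiguity of T1-weighted imaging that motivates conditioning the
synthesis network on a CT template knowledge base. A smooth multiplicative
modulation field stands in for receive-coil shading.

All generators are pure functions of (spec, seed): the same spec yields the
same volumes on every call.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .io_volumes import ContractError, RegionMask, Volume

__all__ = [
    "PhantomSpec",
    "DoseSpec",
    "GenerationError",
    "generate_head_pair",
    "generate_template_ct",
    "generate_cohort",
    "generate_mask_phantom",
    "generate_dose",
    "toy_dose_model",
    "MASK_COMPONENTS",
]

#: Component labels written by :func:`generate_mask_phantom`.
MASK_COMPONENTS = {
    1: "anterior_shell",
    2: "posterior_shell",
    3: "board",
    4: "spacer_left",
    5: "spacer_right",
}

LABEL_AIR, LABEL_BRAIN, LABEL_SKULL = 0, 1, 2


class GenerationError(RuntimeError):
    """Phantom geometry could not be realised under the given spec."""


@dataclass
class PhantomSpec:
    """Parameters of the head phantom family.

    Geometry is in mm on a (z, y, x) grid; axes are z superior-inferior,
    y anterior(low index)-posterior(high index), x left-right. Defaults give a
    desk-scale 64x96x96 grid at 2 mm isotropic spacing.
    """

    shape: tuple[int, int, int] = (64, 96, 96)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    # head ellipsoid semi-axes (z, y, x) in mm, with uniform +- jitter fractions
    semi_axes: tuple[float, float, float] = (52.0, 70.0, 58.0)
    semi_axis_jitter: float = 0.08
    center_jitter_mm: float = 3.0
    skull_thickness_mm: float = 6.0
    skull_thickness_jitter: float = 0.15
    # CT tissue model (HU)
    air_hu: float = -1000.0
    brain_hu: float = 40.0
    skull_hu: float = 700.0
    skull_hu_jitter: float = 60.0
    ct_noise_sd: float = 20.0
    # device materials (HU); thermoplastic is mildly attenuating, board denser
    mask_hu: float = 150.0
    board_hu: float = 300.0
    mask_offset_mm: float = 6.0
    mask_shell_thickness_mm: float = 2.0
    # MR intensity model (arbitrary units): brain bright, skull ~ air (dark)
    mr_air: float = 30.0
    mr_brain: float = 800.0
    mr_skull: float = 60.0
    mr_noise_sd: float = 30.0
    bias_field_amplitude: float = 0.15
    bias_field_sigma_vox: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes):
            raise ContractError("semi-axes must be positive")
        if self.skull_thickness_mm >= min(self.semi_axes):
            raise ContractError("skull thickness must be smaller than the smallest semi-axis")
        if not (self.air_hu < self.brain_hu < self.skull_hu):
            raise ContractError("tissue HU means must be ordered air < brain < skull")
        if any(s <= 0 for s in self.spacing):
            raise ContractError("spacing must be positive")


@dataclass
class DoseSpec:
    """Focal dose targets and (optional) beam geometry for the toy dose model.

    ``centers`` are target positions in mm (z, y, x); ``peaks`` in Gy;
    ``widths`` are Gaussian sigma in mm (scalar per target). ``beams`` are
    cardinal entry directions from {"+z","-z","+y","-y","+x","-x"} used by
    :func:`toy_dose_model`.
    """

    centers: list[tuple[float, float, float]] = field(default_factory=list)
    peaks: list[float] = field(default_factory=list)
    widths: list[float] = field(default_factory=list)
    beams: list[str] = field(default_factory=lambda: ["-y", "+x", "-x"])
    mu_water_per_mm: float = 0.005  # ~6 MV effective attenuation of water

    def __post_init__(self) -> None:
        if not (len(self.centers) == len(self.peaks) == len(self.widths)):
            raise ContractError("centers, peaks, widths must have equal length")
        if any(p <= 0 for p in self.peaks) or any(w <= 0 for w in self.widths):
            raise ContractError("peak doses and widths must be positive")


# -- head pair --------------------------------------------------------------

def _world_grid(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    axes = [np.arange(n) * s for n, s in zip(spec.shape, spec.spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _head_labels(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    jit = rng.uniform(-spec.semi_axis_jitter, spec.semi_axis_jitter, size=3)
    semi = np.asarray(spec.semi_axes) * (1.0 + jit)
    thick = spec.skull_thickness_mm * (
        1.0 + rng.uniform(-spec.skull_thickness_jitter, spec.skull_thickness_jitter)
    )
    extent = np.array(spec.shape) * np.array(spec.spacing)
    center = extent / 2.0 + rng.uniform(-spec.center_jitter_mm, spec.center_jitter_mm, size=3)
    zz, yy, xx = _world_grid(spec)
    r_out = (
        ((zz - center[0]) / semi[0]) ** 2
        + ((yy - center[1]) / semi[1]) ** 2
        + ((xx - center[2]) / semi[2]) ** 2
    )
    inner = semi - thick
    r_in = (
        ((zz - center[0]) / inner[0]) ** 2
        + ((yy - center[1]) / inner[1]) ** 2
        + ((xx - center[2]) / inner[2]) ** 2
    )
    labels = np.zeros(spec.shape, dtype=np.int16)
    labels[r_out <= 1.0] = LABEL_SKULL
    labels[r_in <= 1.0] = LABEL_BRAIN
    return labels


def _smooth_field(shape, sigma, amplitude, rng) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    peak = np.abs(f).max()
    if peak > 0:
        f = f / peak * amplitude
    return f


def generate_head_pair(
    spec: PhantomSpec,
) -> tuple[Volume, Volume, Volume, dict[str, RegionMask]]:
    """Generate one subject: (CT, MR, labels, {BODY, bone, brain} masks).

    CT is per-tissue HU plus i.i.d. Gaussian noise; MR maps tissues to
    intensities with brain bright and skull/air both dark, modulated by a
    smooth multiplicative field and additive noise. Deterministic in
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    labels = _head_labels(spec, rng)

    hu_means = {LABEL_AIR: spec.air_hu, LABEL_BRAIN: spec.brain_hu}
    hu_means[LABEL_SKULL] = spec.skull_hu + rng.uniform(-spec.skull_hu_jitter, spec.skull_hu_jitter)
    ct = np.choose(labels, [hu_means[LABEL_AIR], hu_means[LABEL_BRAIN], hu_means[LABEL_SKULL]])
    ct = ct + spec.ct_noise_sd * rng.standard_normal(spec.shape)

    mr_means = np.array([spec.mr_air, spec.mr_brain, spec.mr_skull])
    mr = mr_means[labels].astype(np.float64)
    bias = _smooth_field(spec.shape, spec.bias_field_sigma_vox, spec.bias_field_amplitude, rng)
    mr = mr * (1.0 + bias) + spec.mr_noise_sd * rng.standard_normal(spec.shape)
    mr = np.clip(mr, 0.0, None)

    ct_vol = Volume(ct, spec.spacing, kind="HU")
    mr_vol = Volume(mr, spec.spacing, kind="MR")
    lab_vol = Volume(labels, spec.spacing, kind="LABEL")
    masks = {
        "BODY": RegionMask.from_volume(ct_vol, labels > LABEL_AIR, "BODY"),
        "bone": RegionMask.from_volume(ct_vol, labels == LABEL_SKULL, "bone"),
        "brain": RegionMask.from_volume(ct_vol, labels == LABEL_BRAIN, "brain"),
    }
    return ct_vol, mr_vol, lab_vol, masks


_TEMPLATE_NAMESPACE = 0x7E41  # seed namespace separating the template from subjects


def generate_template_ct(spec: PhantomSpec, with_labels: bool = False):
    """The fixed 'healthy head' CT knowledge base.

    Drawn from a seed namespace disjoint from any subject's, with noise
    reduced 4x (a template would be averaged/denoised); identical across
    calls for a given spec.
    """
    seed_seq = np.random.SeedSequence([spec.seed, _TEMPLATE_NAMESPACE])
    child_seed = int(seed_seq.generate_state(1)[0] % (2**31))
    tpl_spec = replace(spec, seed=child_seed, ct_noise_sd=spec.ct_noise_sd / 4.0)
    ct, _, labels, _ = generate_head_pair(tpl_spec)
    return (ct, labels) if with_labels else ct


def generate_cohort(spec: PhantomSpec, n_subjects: int):
    """Generate ``n_subjects`` independent subjects from disjoint seed streams."""
    seeds = np.random.SeedSequence(spec.seed).generate_state(n_subjects) % (2**31)
    return [generate_head_pair(replace(spec, seed=int(s))) for s in seeds]


# -- immobilization mask phantom -------------------------------------------

def generate_mask_phantom(
    head_ct: Volume, labels: Volume, spec: PhantomSpec
) -> tuple[Volume, Volume]:
    """Add a thermoplastic mask + frameless board to a head phantom.

    Builds (1) an anterior face shell and posterior support shell at
    ``mask_offset_mm`` from the skin, (2) a posterior board slab with two
    lateral spacer bars. Returns the masked CT and a component label volume
    over :data:`MASK_COMPONENTS`. Device voxels never overwrite body voxels.
    """
    if not head_ct.same_grid(labels):
        raise ContractError("head_ct and labels must share a grid")
    sp = np.asarray(head_ct.spacing)
    if spec.mask_offset_mm < max(head_ct.spacing):
        raise GenerationError(
            f"mask offset {spec.mask_offset_mm} mm below voxel spacing; shell would touch the body"
        )
    body = labels.data > LABEL_AIR
    if not body.any():
        raise GenerationError("empty body in head phantom")
    dist = ndimage.distance_transform_edt(~body, sampling=head_ct.spacing)
    band = (dist >= spec.mask_offset_mm) & (
        dist < spec.mask_offset_mm + spec.mask_shell_thickness_mm
    )

    zs, ys, xs = np.nonzero(body)
    y_c = ys.mean()
    z_lo, z_hi = zs.min(), zs.max()
    in_z = np.zeros(head_ct.shape, dtype=bool)
    in_z[z_lo : z_hi + 1] = True
    yy = np.arange(head_ct.shape[1])[None, :, None]

    comp = np.zeros(head_ct.shape, dtype=np.int16)
    shell_ant = band & in_z & (yy < y_c)
    shell_post = band & in_z & (yy >= y_c)
    comp[shell_ant] = 1
    comp[shell_post] = 2

    # board: posterior slab beyond the posterior shell, central 80% in x
    post_extent = np.nonzero(comp == 2)[1]
    if post_extent.size == 0:
        raise GenerationError("posterior shell empty; grid too small for the mask geometry")
    y_board0 = int(post_extent.max()) + 1
    board_thick_vox = max(1, int(round(6.0 / sp[1])))
    nx = head_ct.shape[2]
    x0, x1 = int(0.1 * nx), int(0.9 * nx)
    board_thick_vox = min(board_thick_vox, head_ct.shape[1] - y_board0)
    if board_thick_vox < 1:
        raise GenerationError("grid too small in y for the board slab")
    board = np.zeros(head_ct.shape, dtype=bool)
    board[z_lo : z_hi + 1, y_board0 : y_board0 + board_thick_vox, x0:x1] = True
    comp[board & (comp == 0)] = 3

    # spacer bars: lateral columns joining posterior shell level to the board
    shell_xs = np.nonzero(comp == 2)[2]
    xl, xr = int(shell_xs.min()), int(shell_xs.max())
    z_mid = (z_lo + z_hi) // 2
    dz = max(1, int(round(10.0 / sp[0])))
    bar_w = max(1, int(round(6.0 / sp[2])))
    y_shell_post = int(post_extent.max())
    for lab, xc in ((4, xl), (5, xr)):
        sl = np.s_[
            z_mid - dz : z_mid + dz + 1,
            y_shell_post : y_board0 + board_thick_vox,
            max(0, xc - bar_w // 2) : min(nx, xc + bar_w // 2 + 1),
        ]
        block = np.zeros(head_ct.shape, dtype=bool)
        block[sl] = True
        comp[block & (comp == 0)] = lab

    if np.any((comp > 0) & body):
        raise GenerationError("device voxels overlap the body")

    hu = {1: spec.mask_hu, 2: spec.mask_hu, 3: spec.board_hu, 4: spec.board_hu, 5: spec.board_hu}
    with_mask = head_ct.data.copy()
    for lab, val in hu.items():
        with_mask[comp == lab] = val
    return (
        Volume(with_mask, head_ct.spacing, head_ct.origin, kind="HU"),
        Volume(comp, head_ct.spacing, head_ct.origin, kind="LABEL"),
    )


# -- dose -------------------------------------------------------------------

def generate_dose(grid: Volume, spec: DoseSpec) -> Volume:
    """Sum of isotropic Gaussian dose blobs on ``grid``; max ~ max peak."""
    dose = np.zeros(grid.shape, dtype=np.float64)
    if spec.centers:
        zz, yy, xx = np.meshgrid(
            *[np.arange(n) * s + o for n, s, o in zip(grid.shape, grid.spacing, grid.origin)],
            indexing="ij",
        )
        for c, p, w in zip(spec.centers, spec.peaks, spec.widths):
            r2 = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2
            dose += p * np.exp(-0.5 * r2 / w**2)
    return Volume(dose, grid.spacing, grid.origin, kind="DOSE")


_BEAM_AXES = {"z": 0, "y": 1, "x": 2}


def toy_dose_model(ct: Volume, spec: DoseSpec) -> Volume:
    """Ray-attenuation dose surrogate sensitive to HU errors.

    For each cardinal beam and each target, ray intensity is attenuated by
    ``exp(-integral mu ds)`` with ``mu = mu_water * max(0, 1 + HU/1000)``
    (air ~ 0, water ~ mu_water, bone > water), then deposited with a
    Gaussian lateral profile about the beam axis through the target. The
    model is deterministic and monotone: raising HU anywhere upstream of a
    point can only lower the dose there. It is a deliberately simplified
    surrogate for treatment-planning dose recalculation, not a clinical
    dose engine.
    """
    if not spec.beams:
        raise ContractError("toy_dose_model requires at least one beam direction")
    mu = spec.mu_water_per_mm * np.clip(1.0 + ct.data / 1000.0, 0.0, None)
    coords = [np.arange(n) * s + o for n, s, o in zip(ct.shape, ct.spacing, ct.origin)]
    dose = np.zeros(ct.shape, dtype=np.float64)
    n_rays = len(spec.beams) * max(1, len(spec.centers))
    for beam in spec.beams:
        sign, axis_name = beam[0], beam[1]
        if sign not in "+-" or axis_name not in _BEAM_AXES:
            raise ContractError(f"beam {beam!r} not of form +/-{{z,y,x}}")
        ax = _BEAM_AXES[axis_name]
        step = ct.spacing[ax]
        mu_w = mu if sign == "+" else np.flip(mu, axis=ax)
        # attenuation to voxel center: half-voxel entry + cumulative upstream
        cum = np.cumsum(mu_w, axis=ax) * step - 0.5 * step * mu_w
        att = np.exp(-cum)
        if sign == "-":
            att = np.flip(att, axis=ax)
        lateral_axes = [a for a in range(3) if a != ax]
        for c, p, w in zip(spec.centers, spec.peaks, spec.widths):
            g = np.ones(ct.shape, dtype=np.float64)
            for a in lateral_axes:
                prof = np.exp(-0.5 * ((coords[a] - c[a]) / w) ** 2)
                shape = [1, 1, 1]
                shape[a] = -1
                g = g * prof.reshape(shape)
            # longitudinal confinement so dose stays focal along the beam too
            prof_l = np.exp(-0.5 * ((coords[ax] - c[ax]) / (3.0 * w)) ** 2)
            shape = [1, 1, 1]
            shape[ax] = -1
            dose += (p / n_rays) * att * g * prof_l.reshape(shape)
    return Volume(dose, ct.spacing, ct.origin, kind="DOSE")
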