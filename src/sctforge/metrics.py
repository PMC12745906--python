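"""Region-masked HU-fidelity metrics: PSNR, SSIM, RMSE, MAE.

PSNR uses the 12-bit raw scale (MAX_I = 4096 by default); since the raw scale
is HU plus a constant offset, HU differences and raw differences coincide, so
RMSE/MAE are reported directly in HU. SSIM follows the standard luminance/
contrast/structure product with stabilizers C1 = 0.01^2 and C2 = 0.03^2 on
intensities rescaled to [0, 1]; local statistics use a 7x7 uniform window per
axial slice (computed on the full volume, then averaged over the region's
voxels only, avoiding masked-window edge bias).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter

from .io_volumes import ContractError, RegionMask, Volume, normalize_ct

__all__ = ["MetricsReport", "psnr", "ssim", "rmse", "mae", "report", "bone_mask_from_hu"]

MAX_I_DEFAULT = 4096.0


def _check(sct: Volume, ref: Volume, region: RegionMask) -> np.ndarray:
    if not sct.same_grid(ref):
        raise ContractError("sct and ref must share a grid")
    if region.shape != sct.shape:
        raise ContractError("region mask shape differs from volumes")
    if region.count == 0:
        raise ContractError(f"region {region.region_name!r} is empty")
    return region.data


def psnr(sct: Volume, ref: Volume, region: RegionMask, max_i: float = MAX_I_DEFAULT) -> float:
    """Peak signal-to-noise ratio, dB: ``10 log10(MAX_I^2 / MSE)`` over the
    region. Returns ``inf`` when the MSE is zero (flagged, not an error)."""
    m = _check(sct, ref, region)
    mse = float(np.mean((sct.data[m] - ref.data[m]) ** 2))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(max_i**2 / mse)


def rmse(sct: Volume, ref: Volume, region: RegionMask) -> float:
    """Root mean square HU difference over the region."""
    m = _check(sct, ref, region)
    return float(np.sqrt(np.mean((sct.data[m] - ref.data[m]) ** 2)))


def mae(sct: Volume, ref: Volume, region: RegionMask) -> float:
    """Mean absolute HU difference over the region."""
    m = _check(sct, ref, region)
    return float(np.mean(np.abs(sct.data[m] - ref.data[m])))


def _to_unit(v: Volume) -> np.ndarray:
    if v.kind == "HU":
        return normalize_ct(v).data
    if v.kind == "NORM01":
        return v.data
    raise ContractError(f"ssim expects HU or NORM01 volumes, got {v.kind!r}")


def ssim(sct: Volume, ref: Volume, region: RegionMask, window: int = 7,
         c1: float = 0.01**2, c2: float = 0.03**2) -> float:
    """Mean structural similarity over the region.

    Local means/variances/covariance via a ``window x window`` uniform filter
    per axial slice on unit-range intensities; the local SSIM map is averaged
    over region voxels.
    """
    m = _check(sct, ref, region)
    if window > min(sct.shape[1], sct.shape[2]):
        raise ContractError("SSIM window larger than slice extent")
    x = _to_unit(sct)
    y = _to_unit(ref)
    size = (1, window, window)  # 2D window applied slice-wise
    mu_x = uniform_filter(x, size=size)
    mu_y = uniform_filter(y, size=size)
    xx = uniform_filter(x * x, size=size) - mu_x**2
    yy = uniform_filter(y * y, size=size) - mu_y**2
    xy = uniform_filter(x * y, size=size) - mu_x * mu_y
    num = (2 * mu_x * mu_y + c1) * (2 * xy + c2)
    den = (mu_x**2 + mu_y**2 + c1) * (xx + yy + c2)
    return float(np.mean((num / den)[m]))


def bone_mask_from_hu(ref: Volume, body: RegionMask, threshold_hu: float = 150.0) -> RegionMask:
    """Fallback bone region: reference-CT HU >= threshold inside BODY (used
    when no tissue label volume is available)."""
    data = body.data & (ref.data >= threshold_hu)
    return RegionMask(data, "bone", ref.spacing, ref.origin)


@dataclass
class MetricsReport:
    """Per-region (and, for cohorts, per-subject) metric table.

    ``table`` has columns [subject, region, psnr_db, ssim, rmse_hu, mae_hu,
    n_voxels]; ``summary`` aggregates mean and SD across subjects per region
    (equal to the single rows when only one subject is supplied).
    """

    table: pd.DataFrame
    summary: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def report(cases, regions_order: tuple[str, ...] = ("BODY", "bone", "brain")) -> MetricsReport:
    """Evaluate PSNR/SSIM/RMSE/MAE per region for one or more subjects.

    ``cases`` is either a single ``(sct, ref, regions)`` triple or a list of
    them, where ``regions`` maps region names to :class:`RegionMask`. Infinite
    PSNR (identical volumes) is kept as ``inf`` in the table and excluded
    from cohort means with a flag column.
    """
    if isinstance(cases, tuple):
        cases = [cases]
    rows = []
    for subj, (sct, ref, regions) in enumerate(cases):
        for name in regions_order:
            if name not in regions:
                continue
            reg = regions[name]
            rows.append({
                "subject": subj,
                "region": name,
                "psnr_db": psnr(sct, ref, reg),
                "ssim": ssim(sct, ref, reg),
                "rmse_hu": rmse(sct, ref, reg),
                "mae_hu": mae(sct, ref, reg),
                "n_voxels": reg.count,
            })
    table = pd.DataFrame(rows)
    table["psnr_infinite"] = ~np.isfinite(table["psnr_db"])
    finite = table.replace([np.inf, -np.inf], np.nan)
    summary = (
        finite.groupby("region", sort=False)[["psnr_db", "ssim", "rmse_hu", "mae_hu"]]
        .agg(["mean", "std"])
    )
    return MetricsReport(table=table, summary=summary)
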