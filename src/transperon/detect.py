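"""Diffraction-limited spot detection in 3D stacks.

Candidates are local maxima of a Laplacian-of-Gaussian response above a
(robust or absolute) threshold; each candidate is refined by a least-squares
3D Gaussian fit and filtered on a fit-quality score.  Detected spots are then
assigned to cells and compartments via label masks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares

from .config import DetectionParams
from .errors import ValidationError
from .simulate import CellGeometry, CellRegion

NUCLEAR = "nuclear"
CYTOPLASMIC = "cytoplasmic"
UNASSIGNED = "unassigned"


@dataclass
class Spot:
    """One detected (or simulated) fluorescent spot.

    ``position`` is physical (z, y, x) micrometres where voxel index i maps to
    i * voxel_size (voxel-centre convention, 0-based).
    """

    position: tuple[float, float, float]
    intensity: float
    sigma_fit: tuple[float, float, float]
    quality: float
    channel: str = ""
    cell_id: int | None = None
    compartment: str = UNASSIGNED

    def __post_init__(self):
        if not 0.0 <= self.quality <= 1.0:
            raise ValidationError("spot quality must lie in [0, 1]")
        if self.compartment != UNASSIGNED and self.cell_id is None:
            raise ValidationError("compartment set but cell_id unassigned")


def _gaussian3d(params, grids):
    amp, cz, cy, cx, sz, sy, sx, off = params
    e = (
        ((grids[0] - cz) / sz) ** 2
        + ((grids[1] - cy) / sy) ** 2
        + ((grids[2] - cx) / sx) ** 2
    )
    return amp * np.exp(-0.5 * e) + off


def _fit_spot(image, center_vox, window, sigma0_vox):
    """Least-squares 3D Gaussian fit in a window around a candidate voxel.

    Returns (center_vox, amplitude, sigmas_vox, quality) or None on failure.
    Quality is R^2 of the fit, clipped to [0, 1].
    """
    half = window // 2
    lo = [max(0, int(c) - half) for c in center_vox]
    hi = [min(s, int(c) + half + 1) for c, s in zip(center_vox, image.shape)]
    patch = image[tuple(slice(l, h) for l, h in zip(lo, hi))].astype(float)
    if patch.size < 8 or any(h - l < 3 for l, h in zip(lo, hi)):
        return None
    grids = np.meshgrid(
        *[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij", sparse=True
    )
    off0 = float(patch.min())
    amp0 = float(patch.max() - off0)
    if amp0 <= 0:
        return None
    p0 = [amp0, *center_vox, *sigma0_vox, off0]
    lower = [0.0] + [l - 0.5 for l in lo] + [0.2] * 3 + [-np.inf]
    upper = [np.inf] + [h - 0.5 for h in hi] + [float(window)] * 3 + [np.inf]

    def resid(p):
        return (_gaussian3d(p, grids) - patch).ravel()

    try:
        sol = least_squares(resid, p0, bounds=(lower, upper), method="trf", xtol=1e-10)
    except Exception:
        return None
    res = sol.fun
    ss_res = float(np.sum(res**2))
    ss_tot = float(np.sum((patch - patch.mean()) ** 2))
    quality = 0.0 if ss_tot <= 0 else float(np.clip(1.0 - ss_res / ss_tot, 0.0, 1.0))
    amp, cz, cy, cx, sz, sy, sx, _ = sol.x
    center = (cz, cy, cx)
    if any(c < l - 0.5 or c > h - 0.5 for c, l, h in zip(center, lo, hi)):
        return None
    return center, float(amp), (float(sz), float(sy), float(sx)), quality


def detect_spots(
    image: np.ndarray,
    voxel_size,
    params: DetectionParams | None = None,
    channel: str = "",
) -> list[Spot]:
    """Detect spots in a single-channel 3D stack.

    Returns spots sorted by descending fitted intensity.  A constant image
    yields an empty list; non-finite voxels raise ``ValidationError``.
    """
    params = params or DetectionParams()
    image = np.asarray(image)
    if image.ndim == 2:
        image = image[None]
    if image.ndim != 3:
        raise ValidationError("image must be a 2D or 3D single-channel array")
    if not np.all(np.isfinite(image)):
        raise ValidationError("image contains non-finite voxels")
    voxel = np.asarray(voxel_size, dtype=float)
    if voxel.shape != (3,) or np.any(voxel <= 0):
        raise ValidationError("voxel_size must be a positive (z, y, x) triple")

    sigma_vox = np.minimum(
        np.asarray(params.smoothing_sigma) / voxel, np.asarray(image.shape) / 4.0
    )
    sigma_vox = np.clip(sigma_vox, 0.5, None)
    response = -ndimage.gaussian_laplace(image.astype(float), sigma_vox)

    if params.threshold_mode == "robust-zscore":
        med = float(np.median(response))
        mad = float(np.median(np.abs(response - med)))
        threshold = med + params.threshold_value * 1.4826 * mad
    else:
        threshold = params.threshold_value

    foot = tuple(
        max(3, 2 * int(np.floor(params.min_separation / v)) + 1) for v in voxel
    )
    local_max = response == ndimage.maximum_filter(response, size=foot, mode="nearest")
    candidates = np.argwhere(local_max & (response > threshold))
    if len(candidates) == 0:
        return []

    # greedy suppression: keep brighter candidate when two fall within
    # min_separation (physical distance)
    order = np.argsort(-response[tuple(candidates.T)])
    candidates = candidates[order]
    kept: list[np.ndarray] = []
    for c in candidates:
        pos = c * voxel
        if all(np.linalg.norm(pos - k * voxel) >= params.min_separation for k in kept):
            kept.append(c)

    sigma0 = np.clip(np.asarray(params.smoothing_sigma) / voxel, 0.5, None)
    spots = []
    for c in kept:
        fit = _fit_spot(image, tuple(c), params.fit_window, tuple(sigma0))
        if fit is None:
            continue
        center_vox, amp, sig_vox, quality = fit
        if quality < params.quality_min:
            continue
        pos_um = tuple(float(cc * vv) for cc, vv in zip(center_vox, voxel))
        sig_um = tuple(float(ss * vv) for ss, vv in zip(sig_vox, voxel))
        spots.append(
            Spot(
                position=pos_um,
                intensity=amp,
                sigma_fit=sig_um,
                quality=quality,
                channel=channel,
            )
        )
    spots.sort(key=lambda s: -s.intensity)
    return spots


def _as_geometry(regions) -> CellGeometry:
    if isinstance(regions, CellGeometry):
        return regions
    regions = list(regions)
    if not regions:
        raise ValidationError("no cell regions given")
    voxel = regions[0].voxel_size
    extent = [0, 0, 0]
    for r in regions:
        for ax in range(3):
            extent[ax] = max(extent[ax], r.origin[ax] + r.cell_mask.shape[ax])
    return CellGeometry(regions, tuple(extent), voxel)


def assign_spots_to_cells(spots, regions) -> list[Spot]:
    """Set each spot's cell_id from the containing cell mask.

    Spots outside every cell stay unassigned (kept, flagged).  Overlapping
    cell masks raise ``ValidationError``.
    """
    geometry = _as_geometry(regions)
    occupancy = np.zeros(geometry.field_shape, dtype=np.int32)
    for r in geometry:
        sl = tuple(slice(o, o + s) for o, s in zip(r.origin, r.cell_mask.shape))
        occupancy[sl] += r.cell_mask
    if int(occupancy.max(initial=0)) > 1:
        raise ValidationError("cell masks overlap; labels must be disjoint")
    labels = geometry.cell_labels
    voxel = np.asarray(geometry.voxel_size)

    out = []
    for s in spots:
        idx = tuple(int(round(p / v)) for p, v in zip(s.position, voxel))
        if all(0 <= i < n for i, n in zip(idx, labels.shape)) and labels[idx] > 0:
            out.append(replace(s, cell_id=int(labels[idx])))
        else:
            out.append(replace(s, cell_id=None, compartment=UNASSIGNED))
    return out


def classify_compartment(spot: Spot, region: CellRegion) -> Spot:
    """Label an assigned spot nuclear or cytoplasmic via the nucleus mask.

    Voxels on the nucleus mask (boundary included) count as nuclear.
    """
    if spot.cell_id is None:
        raise ValidationError("spot must be assigned to a cell first")
    if not region.nucleus_mask.any():
        raise ValidationError(f"cell {region.cell_id} lacks a nucleus mask")
    idx = tuple(
        int(round(p / v)) - o
        for p, v, o in zip(spot.position, region.voxel_size, region.origin)
    )
    inside = all(0 <= i < n for i, n in zip(idx, region.nucleus_mask.shape))
    nuclear = inside and bool(region.nucleus_mask[idx])
    return replace(spot, compartment=NUCLEAR if nuclear else CYTOPLASMIC)


def classify_compartments(spots, geometry: CellGeometry) -> list[Spot]:
    """Vector convenience over :func:`classify_compartment`; skips unassigned."""
    by_id = {r.cell_id: r for r in geometry}
    out = []
    for s in spots:
        if s.cell_id is None:
            out.append(s)
        else:
            out.append(classify_compartment(s, by_id[s.cell_id]))
    return out
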