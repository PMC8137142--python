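"""Ground-truthed synthetic inputs: cell geometry, two-channel spot fields,
rendered image stacks, pulldown/control count matrices, and locus-pair blobs.

Every generator is deterministic given its seed; per-cell randomness is
derived by ``numpy.random.SeedSequence`` spawning so results do not depend on
iteration order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .config import SimulationConfig
from .errors import SizingError, ValidationError

log = logging.getLogger(__name__)

# voxels of clearance between a cell's bounding box and its neighbours/field edge
_BOX_MARGIN_UM = 0.4


def round_half_up(x: float) -> int:
    """round() with deterministic half-up behaviour (3.5 -> 4, 4.5 -> 5)."""
    return int(math.floor(x + 0.5))


# --------------------------------------------------------------------------- #
# cell geometry
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class CellRegion:
    """One cell's masks, cropped to a bounding box within the full frame.

    ``origin`` is the (z, y, x) voxel offset of the crop in the full frame;
    masks share that coordinate frame.
    """

    cell_id: int
    cell_mask: np.ndarray  # bool, (z, y, x) crop
    nucleus_mask: np.ndarray  # bool, same crop
    origin: tuple[int, int, int]
    voxel_size: tuple[float, float, float]

    def __post_init__(self):
        if self.cell_mask.shape != self.nucleus_mask.shape:
            raise ValidationError("cell and nucleus masks must share one shape")
        if not bool(np.all(self.cell_mask[self.nucleus_mask])):
            raise ValidationError("nucleus mask must lie inside the cell mask")

    @property
    def n_voxels(self) -> int:
        return int(self.cell_mask.sum())

    def volume_um3(self) -> float:
        return self.n_voxels * float(np.prod(self.voxel_size))

    def contains_um(self, pos_um) -> bool:
        """Whether a physical (z, y, x) position falls inside the cell mask."""
        idx = tuple(
            int(round(p / v)) - o
            for p, v, o in zip(pos_um, self.voxel_size, self.origin)
        )
        if any(i < 0 or i >= s for i, s in zip(idx, self.cell_mask.shape)):
            return False
        return bool(self.cell_mask[idx])


class CellGeometry:
    """Collection of disjoint cell regions plus full-frame label volumes."""

    def __init__(self, regions, field_shape, voxel_size):
        self.regions: list[CellRegion] = list(regions)
        self.field_shape = tuple(int(s) for s in field_shape)
        self.voxel_size = tuple(float(v) for v in voxel_size)

    def __len__(self):
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def __getitem__(self, i):
        return self.regions[i]

    def region_by_id(self, cell_id: int) -> CellRegion:
        for r in self.regions:
            if r.cell_id == cell_id:
                return r
        raise KeyError(f"no cell with id {cell_id}")

    def _labels(self, attr: str) -> np.ndarray:
        out = np.zeros(self.field_shape, dtype=np.uint16)
        for r in self.regions:
            sl = tuple(
                slice(o, o + s) for o, s in zip(r.origin, r.cell_mask.shape)
            )
            mask = getattr(r, attr)
            out[sl][mask] = r.cell_id
        return out

    @property
    def cell_labels(self) -> np.ndarray:
        return self._labels("cell_mask")

    @property
    def nucleus_labels(self) -> np.ndarray:
        return self._labels("nucleus_mask")


def _ellipsoid_mask(shape, center_vox, radii_vox) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=float)
    for g, c, r in zip(grids, center_vox, radii_vox):
        acc = acc + ((g - c) / r) ** 2
    return acc <= 1.0


def generate_cell_geometry(config: SimulationConfig) -> CellGeometry:
    """Lay out ``n_cells`` non-overlapping ellipsoidal cells on a grid.

    Each cell carries one nucleus strictly inside it.  Cell radii are jittered
    per cell (±10 %) so the population is not perfectly uniform.
    """
    vz, vy, vx = config.voxel_size
    rz, ry, rx = config.cell_radius
    margin = _BOX_MARGIN_UM
    box_um = (2 * (rz + margin), 2 * (ry + margin), 2 * (rx + margin))
    box_vox = tuple(
        int(math.ceil(b / v)) for b, v in zip(box_um, config.voxel_size)
    )

    n = config.n_cells
    if n == 0:
        shape = config.field_shape or box_vox
        return CellGeometry([], shape, config.voxel_size)

    ncols = int(math.ceil(math.sqrt(n)))
    nrows = int(math.ceil(n / ncols))
    auto_shape = (box_vox[0], nrows * box_vox[1], ncols * box_vox[2])
    shape = config.field_shape or auto_shape
    if any(s < a for s, a in zip(shape, auto_shape)):
        raise SizingError(
            f"field_shape {shape} cannot hold {n} cells of cell_radius "
            f"{config.cell_radius} at voxel_size {config.voxel_size}; "
            f"need at least {auto_shape}"
        )
    if any(2 * r < 3 * v for r, v in zip(config.cell_radius, config.voxel_size)):
        raise SizingError(
            "cell_radius too small for voxel_size: each axis needs >= 3 voxels"
        )

    ss = np.random.SeedSequence(config.rng_seed, spawn_key=(0,))
    streams = [np.random.default_rng(s) for s in ss.spawn(n)]

    regions = []
    for i in range(n):
        rng = streams[i]
        row, col = divmod(i, ncols)
        origin = (0, row * box_vox[1], col * box_vox[2])
        scale = rng.uniform(0.9, 1.0, size=3)
        radii_um = (rz * scale[0], ry * scale[1], rx * scale[2])
        radii_vox = tuple(r / v for r, v in zip(radii_um, config.voxel_size))
        center = tuple((s - 1) / 2.0 for s in box_vox)
        cell = _ellipsoid_mask(box_vox, center, radii_vox)

        nuc_radii = tuple(r * config.nucleus_radius_frac for r in radii_vox)
        # offset the nucleus randomly but keep it strictly inside the cell
        max_off = tuple(
            max(0.0, 0.8 * (rc - rn) - 1.0) for rc, rn in zip(radii_vox, nuc_radii)
        )
        off = tuple(rng.uniform(-m, m) for m in max_off)
        nuc_center = tuple(c + o for c, o in zip(center, off))
        nucleus = _ellipsoid_mask(box_vox, nuc_center, nuc_radii)
        nucleus &= cell

        regions.append(
            CellRegion(
                cell_id=i + 1,
                cell_mask=cell,
                nucleus_mask=nucleus,
                origin=origin,
                voxel_size=config.voxel_size,
            )
        )
    return CellGeometry(regions, shape, config.voxel_size)


# --------------------------------------------------------------------------- #
# spot fields
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class SpotFieldTruth:
    """Ground truth for one cell's two-channel spot field.

    Positions are physical (z, y, x) micrometres in the full-frame frame.
    ``pairing`` holds (index_a, index_b) ground-truth co-localized pairs.
    """

    cell_id: int
    spots_a: np.ndarray  # (nA, 3)
    spots_b: np.ndarray  # (nB, 3)
    pairing: tuple[tuple[int, int], ...]
    true_rho: float
    jitter_sigma: float

    @property
    def n_a(self) -> int:
        return len(self.spots_a)

    @property
    def n_b(self) -> int:
        return len(self.spots_b)

    def paired_fraction(self) -> float:
        if self.n_a == 0:
            return float("nan")
        return len(self.pairing) / self.n_a


def _sample_positions(region: CellRegion, n: int, rng, min_sep: float = 0.0,
                      nuclear_fraction: float | None = None) -> np.ndarray:
    """Uniform positions (µm, full frame) over the cell mask.

    With ``min_sep`` > 0 positions are rejection-sampled to keep pairwise
    distances above it.  ``nuclear_fraction`` biases the requested share of
    spots into the nucleus mask.
    """
    if n == 0:
        return np.zeros((0, 3))
    voxel = np.asarray(region.voxel_size)
    origin = np.asarray(region.origin)

    def draw(mask, k):
        idx = np.argwhere(mask)
        if len(idx) == 0:
            raise SizingError("empty mask: cell_radius/voxel_size too small")
        picks = idx[rng.integers(0, len(idx), size=k)]
        sub = rng.uniform(-0.5, 0.5, size=(k, 3))
        return (picks + sub + origin) * voxel

    if nuclear_fraction is None:
        pool_masks = [(region.cell_mask, n)]
    else:
        n_nuc = rng.binomial(n, nuclear_fraction)
        cyto = region.cell_mask & ~region.nucleus_mask
        pool_masks = [(region.nucleus_mask, n_nuc), (cyto, n - n_nuc)]

    kept: list[np.ndarray] = []
    for mask, k in pool_masks:
        if k == 0:
            continue
        if min_sep <= 0:
            kept.extend(draw(mask, k))
            continue
        added = 0
        for _ in range(200 * k):
            cand = draw(mask, 1)[0]
            if all(np.linalg.norm(cand - q) >= min_sep for q in kept):
                kept.append(cand)
                added += 1
                if added == k:
                    break
        else:
            raise SizingError(
                f"could not place {k} spots with min_spot_separation={min_sep}"
            )
    if not kept:
        return np.zeros((0, 3))
    return np.asarray(kept)


def simulate_spot_pair_field(
    region: CellRegion, config: SimulationConfig, rng=None
) -> SpotFieldTruth:
    """Draw one cell's channel-A/-B spot field with known pairing.

    Channel A gets a Poisson(``spots_per_cell_mean``) number of uniform spots;
    ``round_half_up(true_rho * nA)`` of them are duplicated into channel B with
    isotropic Gaussian jitter, and the remaining channel-B spots (Poisson with
    mean ``mean_b * (1 - true_rho)``) are uniform background.
    """
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence(config.rng_seed, spawn_key=(1, region.cell_id))
        )
    if not 0 <= config.true_rho <= 1:  # re-checked for plain-dict callers
        raise ValidationError("true_rho must lie in [0, 1]")

    n_a = int(rng.poisson(config.spots_per_cell_mean))
    spots_a = _sample_positions(
        region, n_a, rng, config.min_spot_separation, config.nuclear_fraction
    )

    n_pairs = round_half_up(config.true_rho * n_a)
    paired_idx = rng.choice(n_a, size=n_pairs, replace=False) if n_pairs else []
    paired_idx = np.sort(np.asarray(paired_idx, dtype=int))
    partners = spots_a[paired_idx] + rng.normal(
        0.0, config.jitter_sigma, size=(n_pairs, 3)
    )

    n_bg = int(rng.poisson(config.mean_b * (1.0 - config.true_rho)))
    background = _sample_positions(
        region, n_bg, rng, config.min_spot_separation, config.nuclear_fraction
    )
    spots_b = np.vstack([partners, background]) if (n_pairs or n_bg) else np.zeros((0, 3))
    pairing = tuple((int(ia), ib) for ib, ia in enumerate(paired_idx))
    return SpotFieldTruth(
        cell_id=region.cell_id,
        spots_a=spots_a,
        spots_b=spots_b,
        pairing=pairing,
        true_rho=config.true_rho,
        jitter_sigma=config.jitter_sigma,
    )


def simulate_spot_fields(geometry: CellGeometry, config: SimulationConfig):
    """Spot fields for every cell, each from its own spawned RNG stream."""
    ss = np.random.SeedSequence(config.rng_seed, spawn_key=(1,))
    streams = ss.spawn(len(geometry))
    return [
        simulate_spot_pair_field(region, config, np.random.default_rng(s))
        for region, s in zip(geometry, streams)
    ]


def truths_to_table(truths) -> pd.DataFrame:
    """Long-format truth table: (cell_id, channel, x_um, y_um, z_um, pair_id)."""
    rows = []
    for t in truths:
        pair_of_a = {ia: pid for pid, (ia, _) in enumerate(t.pairing)}
        pair_of_b = {ib: pid for pid, (_, ib) in enumerate(t.pairing)}
        for i, (z, y, x) in enumerate(t.spots_a):
            rows.append((t.cell_id, "A", x, y, z, pair_of_a.get(i, -1)))
        for i, (z, y, x) in enumerate(t.spots_b):
            rows.append((t.cell_id, "B", x, y, z, pair_of_b.get(i, -1)))
    return pd.DataFrame(
        rows, columns=["cell_id", "channel", "x_um", "y_um", "z_um", "pair_id"]
    )


# --------------------------------------------------------------------------- #
# rendering
# --------------------------------------------------------------------------- #


def _add_gaussians(canvas: np.ndarray, positions_vox, sigmas_vox, amplitude: float):
    """Accumulate 3D Gaussians (amplitude at the centre) onto ``canvas``."""
    shape = canvas.shape
    half = [int(math.ceil(5 * s)) for s in sigmas_vox]
    clipped = 0
    for pos in positions_vox:
        lo = [int(math.floor(p)) - h for p, h in zip(pos, half)]
        hi = [int(math.floor(p)) + h + 1 for p, h in zip(pos, half)]
        if any(p < -0.5 or p > s - 0.5 for p, s in zip(pos, shape)):
            clipped += 1  # centre outside the field of view
        if any(h <= 0 or l >= s for l, h, s in zip(lo, hi, shape)):
            continue
        lo_c = [max(0, l) for l in lo]
        hi_c = [min(s, h) for h, s in zip(hi, shape)]
        grids = np.ogrid[tuple(slice(l, h) for l, h in zip(lo_c, hi_c))]
        expo = np.zeros(tuple(h - l for l, h in zip(lo_c, hi_c)))
        for g, p, s in zip(grids, pos, sigmas_vox):
            expo = expo + ((g - p) / s) ** 2
        sl = tuple(slice(l, h) for l, h in zip(lo_c, hi_c))
        canvas[sl] += amplitude * np.exp(-0.5 * expo)
    if clipped:
        log.warning("%d spot(s) clipped at the field-of-view boundary", clipped)


def _apply_noise(img: np.ndarray, config: SimulationConfig, rng) -> np.ndarray:
    out = img
    if config.noise_model in ("poisson", "poisson+gaussian"):
        out = rng.poisson(np.clip(out, 0, None)).astype(float)
    if config.noise_model in ("gaussian", "poisson+gaussian"):
        out = out + rng.normal(0.0, config.gaussian_noise_sigma, size=out.shape)
    return out


def render_image(
    truth: SpotFieldTruth, region: CellRegion, config: SimulationConfig, rng=None
) -> np.ndarray:
    """Render one cell's crop as a (3, z, y, x) stack: channels (A, B, nuclear).

    Spots become 3D Gaussians of per-axis ``psf_sigma`` and amplitude
    ``peak_intensity`` on top of ``background_level``; the nuclear channel is
    the nucleus mask at ``nuclear_stain_level``.  Deterministic given the RNG.
    """
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence(config.rng_seed, spawn_key=(2, region.cell_id))
        )
    voxel = np.asarray(config.voxel_size)
    sigmas_vox = np.asarray(config.psf_sigma) / voxel
    origin = np.asarray(region.origin)
    shape = region.cell_mask.shape

    stack = np.full((3,) + shape, float(config.background_level))
    for ch, spots in ((0, truth.spots_a), (1, truth.spots_b)):
        if len(spots):
            pos_vox = spots / voxel - origin
            _add_gaussians(stack[ch], pos_vox, sigmas_vox, config.peak_intensity)
    stack[2][region.nucleus_mask] += config.nuclear_stain_level
    for ch in range(3):
        stack[ch] = _apply_noise(stack[ch], config, rng)
    return stack


def render_field(truths, geometry: CellGeometry, config: SimulationConfig) -> np.ndarray:
    """Render all cells into one full-frame (3, z, y, x) stack."""
    stack = np.full((3,) + geometry.field_shape, float(config.background_level))
    voxel = np.asarray(config.voxel_size)
    sigmas_vox = np.asarray(config.psf_sigma) / voxel
    by_id = {t.cell_id: t for t in truths}
    for region in geometry:
        t = by_id.get(region.cell_id)
        if t is None:
            continue
        for ch, spots in ((0, t.spots_a), (1, t.spots_b)):
            if len(spots):
                _add_gaussians(stack[ch], spots / voxel, sigmas_vox, config.peak_intensity)
        sl = tuple(slice(o, o + s) for o, s in zip(region.origin, region.cell_mask.shape))
        stack[2][sl][region.nucleus_mask] += config.nuclear_stain_level
    rng = np.random.default_rng(np.random.SeedSequence(config.rng_seed, spawn_key=(2,)))
    for ch in range(3):
        stack[ch] = _apply_noise(stack[ch], config, rng)
    return stack


# --------------------------------------------------------------------------- #
# count matrices
# --------------------------------------------------------------------------- #


def simulate_count_matrix(
    n_genes: int,
    enriched_ids=(),
    fold: float = 4.0,
    dispersion: float = 0.1,
    lib_size: float = 1_000_000,
    rng_seed: int = 0,
    abundance_range: tuple[float, float] = (10.0, 1000.0),
    n_replicates: int = 1,
) -> pd.DataFrame:
    """Paired pulldown/control counts with a planted enriched gene subset.

    Control mean abundances are log-uniform over ``abundance_range`` and then
    scaled so each column's expected sum equals ``lib_size``.  Pulldown means
    are the control means times ``fold`` for ``enriched_ids`` (×1 otherwise);
    counts are NB with variance = mu + dispersion * mu**2 (Poisson when
    dispersion == 0).  With ``n_replicates`` == 1 columns are
    (pulldown, control); otherwise (pulldown_1.., control_1..), each an
    independent library.
    """
    if fold < 1:
        raise ValidationError("fold must be >= 1")
    if dispersion < 0:
        raise ValidationError("dispersion must be >= 0")
    genes = [f"gene_{i:05d}" for i in range(n_genes)]
    enriched = set(enriched_ids)
    unknown = enriched - set(genes)
    if unknown:
        raise ValidationError(f"enriched_ids not in gene labels: {sorted(unknown)[:5]}")

    rng = np.random.default_rng(rng_seed)
    lo, hi = abundance_range
    rel = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_genes))
    ctrl_mu = rel * (lib_size / rel.sum())
    boost = np.array([fold if g in enriched else 1.0 for g in genes])
    pull_rel = rel * boost
    pull_mu = pull_rel * (lib_size / pull_rel.sum())

    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")

    def draw(mu):
        if dispersion == 0:
            return rng.poisson(mu)
        r = 1.0 / dispersion
        p = r / (r + mu)
        return rng.negative_binomial(r, p)

    if n_replicates == 1:
        cols = {"pulldown": draw(pull_mu), "control": draw(ctrl_mu)}
    else:
        cols = {}
        for i in range(1, n_replicates + 1):
            cols[f"pulldown_{i}"] = draw(pull_mu)
        for i in range(1, n_replicates + 1):
            cols[f"control_{i}"] = draw(ctrl_mu)
    return pd.DataFrame(cols, index=pd.Index(genes, name="gene"))


# --------------------------------------------------------------------------- #
# locus pairs
# --------------------------------------------------------------------------- #


def _lens_overlap(d: float, r: float) -> float:
    """Intersection area of two radius-r circles at distance d, over pi*r^2."""
    if d >= 2 * r:
        return 0.0
    if d <= 0:
        return 1.0
    area = 2 * r * r * math.acos(d / (2 * r)) - 0.5 * d * math.sqrt(4 * r * r - d * d)
    return area / (math.pi * r * r)


def simulate_locus_pair(
    overlap_target: float,
    rng_seed=0,
    radius_px: float = 10.0,
    shape: tuple[int, int] = (64, 64),
    intensity: float = 1000.0,
    background: float = 50.0,
    noise_sigma: float = 0.0,
):
    """Two-channel 2D image of two tagged-locus blobs with known overlap.

    Overlap is the intersection area over the smaller blob's area.  Returns
    ``(image, truth)`` where image is (2, y, x) and truth records the target,
    the rasterized overlap, centres, and radius.
    """
    if not 0 <= overlap_target <= 1:
        raise ValidationError("overlap_target must lie in [0, 1]")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    r = float(radius_px)
    h, w = shape
    sep_max = 2 * r + 3.0  # distance used for overlap_target == 0
    if min(h, w) < 2 * r + sep_max + 4:
        raise SizingError(
            f"shape {shape} too small for radius_px={radius_px}; "
            f"needs >= {int(2 * r + sep_max + 4)} per axis"
        )

    if overlap_target >= 1.0:
        d = 0.0
    elif overlap_target <= 0.0:
        d = sep_max
    else:
        d = brentq(lambda x: _lens_overlap(x, r) - overlap_target, 0.0, 2 * r)

    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    theta = rng.uniform(0, 2 * math.pi)
    jig = rng.uniform(-0.5, 0.5, size=2)
    c_a = np.array([cy + jig[0] - 0.5 * d * math.sin(theta),
                    cx + jig[1] - 0.5 * d * math.cos(theta)])
    c_b = np.array([cy + jig[0] + 0.5 * d * math.sin(theta),
                    cx + jig[1] + 0.5 * d * math.cos(theta)])

    yy, xx = np.mgrid[0:h, 0:w]

    def disk(c):
        return (yy - c[0]) ** 2 + (xx - c[1]) ** 2 <= r * r

    mask_a, mask_b = disk(c_a), disk(c_b)
    img = np.full((2, h, w), float(background))
    img[0][mask_a] += intensity
    img[1][mask_b] += intensity
    if noise_sigma > 0:
        img += rng.normal(0.0, noise_sigma, size=img.shape)

    smaller = min(mask_a.sum(), mask_b.sum())
    measured = (mask_a & mask_b).sum() / smaller if smaller else 0.0
    truth = {
        "overlap_target": float(overlap_target),
        "overlap_rasterized": float(measured),
        "center_a": tuple(c_a),
        "center_b": tuple(c_b),
        "radius_px": r,
    }
    return img, truth


def simulate_locus_cohort(
    class_probs: tuple[float, float, float],
    n_cells: int,
    rng_seed: int = 0,
    **kwargs,
):
    """Cohort of locus-pair images drawn from (co-localized, adjacent,
    not co-localized) class probabilities.

    Per-class overlap targets: co-localized in [0.93, 1], adjacent in
    [0.12, 0.6], not co-localized exactly 0.  Returns (images, truth frame).
    """
    probs = np.asarray(class_probs, dtype=float)
    if probs.min() < 0 or not math.isclose(probs.sum(), 1.0, abs_tol=1e-9):
        raise ValidationError("class_probs must be non-negative and sum to 1")
    ss = np.random.SeedSequence(rng_seed)
    pick_rng = np.random.default_rng(ss)
    streams = ss.spawn(n_cells)
    labels = ("co-localized", "adjacent", "not co-localized")
    images, rows = [], []
    classes = pick_rng.choice(3, size=n_cells, p=probs)
    for i, (cls, s) in enumerate(zip(classes, streams)):
        rng = np.random.default_rng(s)
        if cls == 0:
            target = rng.uniform(0.93, 1.0)
        elif cls == 1:
            target = rng.uniform(0.12, 0.6)
        else:
            target = 0.0
        img, truth = simulate_locus_pair(target, rng, **kwargs)
        images.append(img)
        rows.append(
            {
                "cell_id": i + 1,
                "true_class": labels[cls],
                "overlap_target": truth["overlap_target"],
                "overlap_rasterized": truth["overlap_rasterized"],
            }
        )
    return images, pd.DataFrame(rows)
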