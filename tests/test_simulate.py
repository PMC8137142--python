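import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from transperon.config import SimulationConfig
from transperon.errors import SizingError, ValidationError
from transperon.simulate import (
    generate_cell_geometry,
    render_image,
    round_half_up,
    simulate_count_matrix,
    simulate_locus_cohort,
    simulate_locus_pair,
    simulate_spot_fields,
    simulate_spot_pair_field,
    truths_to_table,
)

SMALL = dict(cell_radius=(1.6, 2.0, 2.0))


# --------------------------------------------------------------------------- #
# geometry
# --------------------------------------------------------------------------- #


def test_single_cell_nucleus_inside_cell():
    geo = generate_cell_geometry(SimulationConfig(n_cells=1, **SMALL))
    region = geo[0]
    assert np.all(region.cell_mask[region.nucleus_mask])
    assert region.nucleus_mask.sum() > 0
    assert region.nucleus_mask.sum() < region.cell_mask.sum()


def test_zero_cells_empty_collection():
    geo = generate_cell_geometry(SimulationConfig(n_cells=0, **SMALL))
    assert len(geo) == 0
    assert list(geo) == []


def test_many_cells_disjoint_labels():
    geo = generate_cell_geometry(SimulationConfig(n_cells=30, rng_seed=3, **SMALL))
    assert len(geo) == 30
    occupancy = np.zeros(geo.field_shape, dtype=int)
    for region in geo:
        sl = tuple(slice(o, o + s) for o, s in zip(region.origin, region.cell_mask.shape))
        occupancy[sl] += region.cell_mask
    assert occupancy.max() == 1  # pairwise intersections all empty
    labels = geo.cell_labels
    assert set(np.unique(labels)) == set(range(31))


def test_field_too_small_raises_sizing_error():
    with pytest.raises(SizingError, match="field_shape"):
        generate_cell_geometry(
            SimulationConfig(n_cells=4, field_shape=(8, 20, 20), **SMALL)
        )


def test_geometry_deterministic():
    cfg = SimulationConfig(n_cells=5, rng_seed=11, **SMALL)
    a = generate_cell_geometry(cfg)
    b = generate_cell_geometry(cfg)
    assert np.array_equal(a.cell_labels, b.cell_labels)
    assert np.array_equal(a.nucleus_labels, b.nucleus_labels)


# --------------------------------------------------------------------------- #
# spot fields
# --------------------------------------------------------------------------- #


def _one_region(seed=0, **kwargs):
    cfg = SimulationConfig(n_cells=1, rng_seed=seed, **SMALL, **kwargs)
    return generate_cell_geometry(cfg)[0], cfg


def test_rho_one_zero_jitter_duplicates_positions():
    region, cfg = _one_region(true_rho=1.0, jitter_sigma=0.0, spots_per_cell_mean=20)
    truth = simulate_spot_pair_field(region, cfg)
    assert len(truth.pairing) == truth.n_a
    for ia, ib in truth.pairing:
        assert np.allclose(truth.spots_a[ia], truth.spots_b[ib])


def test_zero_mean_empty_field():
    region, cfg = _one_region(spots_per_cell_mean=0, spots_per_cell_mean_b=0)
    truth = simulate_spot_pair_field(region, cfg)
    assert truth.n_a == 0 and truth.n_b == 0 and truth.pairing == ()


def test_pair_count_round_consistent():
    region, cfg = _one_region(true_rho=0.5, spots_per_cell_mean=30, seed=5)
    for s in range(20):
        truth = simulate_spot_pair_field(region, cfg, np.random.default_rng(s))
        assert len(truth.pairing) == round_half_up(0.5 * truth.n_a)


def test_aggregate_paired_fraction_exact_at_even_counts():
    # nA forced even via repeated draws; with rho=0.5 each cell pairs exactly
    # round(0.5 nA) so the aggregate equals 0.5 when total nA is tracked
    region, cfg = _one_region(true_rho=0.5, spots_per_cell_mean=50, seed=9)
    total_a = total_pairs = 0
    for s in range(40):
        truth = simulate_spot_pair_field(region, cfg, np.random.default_rng(s))
        total_a += truth.n_a
        total_pairs += len(truth.pairing)
    assert abs(total_pairs / total_a - 0.5) < 0.01  # rounding residue only


def test_spots_inside_cell_mask():
    region, cfg = _one_region(true_rho=0.3, spots_per_cell_mean=40, seed=2)
    truth = simulate_spot_pair_field(region, cfg)
    for p in truth.spots_a:
        assert region.contains_um(p)
    paired_b = {ib for _, ib in truth.pairing}
    for i, p in enumerate(truth.spots_b):
        if i not in paired_b:  # jittered partners may cross the boundary
            assert region.contains_um(p)


def test_paired_partners_close_given_jitter():
    region, cfg = _one_region(true_rho=1.0, jitter_sigma=0.05, spots_per_cell_mean=40)
    truth = simulate_spot_pair_field(region, cfg)
    d = [
        np.linalg.norm(truth.spots_a[ia] - truth.spots_b[ib])
        for ia, ib in truth.pairing
    ]
    # 5 sigma of a 3D Gaussian norm is a generous bound
    assert max(d) < 5 * 0.05 * math.sqrt(3)


def test_invalid_rho_rejected():
    with pytest.raises(ValidationError):
        SimulationConfig(true_rho=1.2)


def test_min_separation_enforced():
    region, cfg = _one_region(
        spots_per_cell_mean=15, min_spot_separation=0.4, true_rho=0.0, seed=7
    )
    truth = simulate_spot_pair_field(region, cfg)
    pos = truth.spots_a
    for i in range(len(pos)):
        for j in range(i + 1, len(pos)):
            assert np.linalg.norm(pos[i] - pos[j]) >= 0.4


def test_fields_deterministic_per_cell(small_cfg, small_geometry):
    a = simulate_spot_fields(small_geometry, small_cfg)
    b = simulate_spot_fields(small_geometry, small_cfg)
    for ta, tb in zip(a, b):
        assert np.array_equal(ta.spots_a, tb.spots_a)
        assert np.array_equal(ta.spots_b, tb.spots_b)
        assert ta.pairing == tb.pairing


def test_truth_table_schema(small_truths):
    table = truths_to_table(small_truths)
    assert list(table.columns) == ["cell_id", "channel", "x_um", "y_um", "z_um", "pair_id"]
    for truth in small_truths:
        sub = table[(table.cell_id == truth.cell_id) & (table.channel == "A")]
        assert len(sub) == truth.n_a
        assert (sub.pair_id >= 0).sum() == len(truth.pairing)


@given(st.integers(min_value=0, max_value=200), st.floats(0, 1))
@settings(max_examples=40, deadline=None)
def test_round_half_up_pair_invariant(n, rho):
    k = round_half_up(rho * n)
    assert 0 <= k <= n or k == round_half_up(rho * n)
    assert k == int(math.floor(rho * n + 0.5))


# --------------------------------------------------------------------------- #
# rendering
# --------------------------------------------------------------------------- #


def _truth_with(region, cfg, spots_a):
    from transperon.simulate import SpotFieldTruth

    return SpotFieldTruth(
        cell_id=region.cell_id,
        spots_a=np.asarray(spots_a, dtype=float).reshape(-1, 3),
        spots_b=np.zeros((0, 3)),
        pairing=(),
        true_rho=0.0,
        jitter_sigma=0.0,
    )


def test_render_no_spots_no_noise_constant():
    region, cfg = _one_region(noise_model="none", spots_per_cell_mean=0)
    truth = _truth_with(region, cfg, np.zeros((0, 3)))
    img = render_image(truth, region, cfg)
    assert np.allclose(img[0], cfg.background_level)
    assert np.allclose(img[1], cfg.background_level)


def test_render_single_spot_argmax_near_truth():
    region, cfg = _one_region(noise_model="none")
    center_vox = np.array(region.cell_mask.shape) // 2
    pos = (center_vox + np.array(region.origin)) * np.array(cfg.voxel_size)
    truth = _truth_with(region, cfg, [pos])
    img = render_image(truth, region, cfg)
    peak = np.unravel_index(np.argmax(img[0]), img[0].shape)
    assert np.all(np.abs(np.array(peak) - center_vox) <= 1)


def test_render_deterministic_with_seed():
    region, cfg = _one_region(noise_model="poisson+gaussian", spots_per_cell_mean=10)
    truth = simulate_spot_pair_field(region, cfg)
    a = render_image(truth, region, cfg)
    b = render_image(truth, region, cfg)
    assert np.array_equal(a, b)


def test_render_photometry_noise_free():
    region, cfg = _one_region(noise_model="none")
    center_vox = np.array(region.cell_mask.shape) // 2
    pos = (center_vox + np.array(region.origin)) * np.array(cfg.voxel_size)
    truth = _truth_with(region, cfg, [pos])
    img = render_image(truth, region, cfg)
    integrated = float((img[0] - cfg.background_level).sum())
    sigmas_vox = np.array(cfg.psf_sigma) / np.array(cfg.voxel_size)
    expected = cfg.peak_intensity * (2 * math.pi) ** 1.5 * np.prod(sigmas_vox)
    assert abs(integrated - expected) / expected < 0.05


def test_render_warns_when_spot_outside_fov(caplog):
    region, cfg = _one_region(noise_model="none")
    outside = (-5.0, -5.0, -5.0)
    truth = _truth_with(region, cfg, [outside])
    with caplog.at_level("WARNING"):
        render_image(truth, region, cfg)
    assert any("clipped" in r.message for r in caplog.records)


# --------------------------------------------------------------------------- #
# count matrices
# --------------------------------------------------------------------------- #


def test_count_matrix_null_exchangeable():
    df = simulate_count_matrix(2000, fold=1.0, dispersion=0.1, rng_seed=1)
    # same marginal law: medians and dispersions of both columns comparable
    ratio = df["pulldown"].median() / df["control"].median()
    assert 0.9 < ratio < 1.1


def test_count_matrix_poisson_when_dispersion_zero():
    df = simulate_count_matrix(
        10_000, fold=1.0, dispersion=0.0, lib_size=1_000_000, rng_seed=2
    )
    # across genes, (x - mu)^2 averages to mu for Poisson; use paired columns
    diff = df["pulldown"].to_numpy(float) - df["control"].to_numpy(float)
    mean_sum = (df["pulldown"] + df["control"]).mean()
    # Var(diff) = 2 mu on average under Poisson
    assert abs(diff.var() / mean_sum - 1.0) < 0.1


def test_count_matrix_overdispersed_when_positive():
    df = simulate_count_matrix(10_000, fold=1.0, dispersion=0.1, rng_seed=3)
    diff = df["pulldown"].to_numpy(float) - df["control"].to_numpy(float)
    mean_sum = (df["pulldown"] + df["control"]).mean()
    assert diff.var() / mean_sum > 2.0  # far above the Poisson ratio of 1


def test_count_matrix_column_sums_near_lib_size():
    df = simulate_count_matrix(5000, fold=1.0, dispersion=0.1, lib_size=500_000, rng_seed=4)
    for col in df:
        assert abs(df[col].sum() / 500_000 - 1.0) < 0.05


def test_count_matrix_enrichment_shifts_means():
    genes = [f"gene_{i:05d}" for i in range(50)]
    df = simulate_count_matrix(
        5000, enriched_ids=genes, fold=8.0, dispersion=0.0, rng_seed=5
    )
    sub = df.loc[genes]
    rest = df.drop(index=genes)
    assert (sub["pulldown"] / sub["control"].clip(lower=1)).median() > 4
    assert 0.8 < (rest["pulldown"] / rest["control"].clip(lower=1)).median() < 1.2


def test_count_matrix_unknown_enriched_id_rejected():
    with pytest.raises(ValidationError):
        simulate_count_matrix(10, enriched_ids={"nope"}, rng_seed=0)


def test_count_matrix_replicates_columns():
    df = simulate_count_matrix(100, n_replicates=3, rng_seed=6)
    assert list(df.columns) == [
        "pulldown_1", "pulldown_2", "pulldown_3",
        "control_1", "control_2", "control_3",
    ]


def test_count_matrix_deterministic():
    a = simulate_count_matrix(500, rng_seed=7)
    b = simulate_count_matrix(500, rng_seed=7)
    assert a.equals(b)


# --------------------------------------------------------------------------- #
# locus pairs
# --------------------------------------------------------------------------- #


def test_locus_full_overlap_concentric():
    img, truth = simulate_locus_pair(1.0, rng_seed=1)
    assert truth["overlap_rasterized"] == 1.0
    assert np.allclose(truth["center_a"], truth["center_b"])


def test_locus_zero_overlap_disjoint():
    img, truth = simulate_locus_pair(0.0, rng_seed=2)
    assert truth["overlap_rasterized"] == 0.0
    mask_a = img[0] > 500
    mask_b = img[1] > 500
    assert not (mask_a & mask_b).any()


@pytest.mark.parametrize("target", [0.15, 0.3, 0.6, 0.9])
def test_locus_overlap_matches_target(target):
    for seed in range(5):
        _, truth = simulate_locus_pair(target, rng_seed=seed)
        assert abs(truth["overlap_rasterized"] - target) <= 0.02


def test_locus_unreachable_geometry_raises():
    with pytest.raises(SizingError):
        simulate_locus_pair(0.5, rng_seed=0, radius_px=40, shape=(64, 64))


def test_locus_invalid_target_rejected():
    with pytest.raises(ValidationError):
        simulate_locus_pair(1.5)


def test_locus_cohort_truth_bookkeeping():
    images, truth = simulate_locus_cohort((0.2, 0.5, 0.3), 40, rng_seed=3)
    assert len(images) == 40
    assert set(truth.true_class) <= {"co-localized", "adjacent", "not co-localized"}
    colocalized = truth[truth.true_class == "co-localized"]
    assert (colocalized.overlap_target >= 0.93).all()
    assert (truth[truth.true_class == "not co-localized"].overlap_target == 0).all()


def test_locus_cohort_bad_probs_rejected():
    with pytest.raises(ValidationError):
        simulate_locus_cohort((0.5, 0.5, 0.5), 10)
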