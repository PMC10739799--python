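"""Scene generator: determinism, mask/region consistency, density
calibration (Poisson oracle), cluster/artifact/vessel behavior, mosaics."""

import dataclasses

import numpy as np
import pytest

from gobletseg.synthetic import Mosaic, SceneParams, generate_mosaic, generate_scene


def test_zero_density_empty_scene():
    s = generate_scene(SceneParams(width_px=64, height_px=64,
                                   target_density=0.0, seed=1))
    assert not s.mask.any()
    assert s.true_density == 0.0
    assert s.regions == []


def test_equal_seeds_bit_identical():
    p = SceneParams(width_px=96, height_px=96, seed=11)
    s1, s2 = generate_scene(p), generate_scene(p)
    np.testing.assert_array_equal(s1.image.pixels, s2.image.pixels)
    np.testing.assert_array_equal(s1.mask, s2.mask)
    np.testing.assert_array_equal(s1.labels, s2.labels)
    assert s1.true_density == s2.true_density


def test_different_seeds_differ():
    p1 = SceneParams(width_px=64, height_px=64, seed=0)
    p2 = dataclasses.replace(p1, seed=1)
    assert not np.array_equal(generate_scene(p1).image.pixels,
                              generate_scene(p2).image.pixels)


def test_mask_equals_union_of_region_pixels(small_scene):
    union = np.zeros_like(small_scene.mask)
    seen = np.zeros_like(small_scene.mask)
    for r in small_scene.regions:
        ys, xs = r.pixels[:, 0], r.pixels[:, 1]
        assert not seen[ys, xs].any()  # pixel in exactly one region
        seen[ys, xs] = True
        union[ys, xs] = True
    np.testing.assert_array_equal(union, small_scene.mask)


def test_true_density_is_count_over_area(small_scene):
    p = small_scene.params
    assert small_scene.true_density == pytest.approx(
        len(small_scene.regions) / p.area_mm2)


def test_realized_count_poisson_calibrated():
    """Mean placed count over many seeds within 3 SE of density*area."""
    p = SceneParams(width_px=128, height_px=128, target_density=1500.0)
    n_rep = 150
    counts = [len(generate_scene(dataclasses.replace(p, seed=s)).regions)
              for s in range(n_rep)]
    lam = p.target_density * p.area_mm2
    se = np.sqrt(lam / n_rep)
    assert abs(np.mean(counts) - lam) < 3 * se


def test_cells_brighter_than_local_background(isolated_scene):
    img = isolated_scene.image.pixels.astype(float)
    fg = img[isolated_scene.mask].mean()
    bg = img[~isolated_scene.mask].mean()
    assert fg > bg + 0.15 * 65535


def test_vessels_only_darken():
    base = SceneParams(width_px=96, height_px=96, target_density=0.0,
                       artifact_rate=0.0, noise_sd=0.0, seed=5)
    dark = generate_scene(dataclasses.replace(base, vessel_count=4,
                                              vessel_shadow_depth=0.8))
    lit = generate_scene(dataclasses.replace(base, vessel_count=0))
    assert dark.image.pixels.astype(int).sum() < lit.image.pixels.astype(int).sum()
    assert (dark.image.pixels.astype(int) <= lit.image.pixels.astype(int) + 1).all()


def test_artifacts_not_in_mask():
    base = SceneParams(width_px=96, height_px=96, target_density=0.0,
                       noise_sd=0.0, vessel_count=0, seed=3)
    with_art = generate_scene(dataclasses.replace(base, artifact_rate=300.0))
    assert not with_art.mask.any()                    # no cells placed
    no_art = generate_scene(dataclasses.replace(base, artifact_rate=0.0))
    assert with_art.image.pixels.sum() > no_art.image.pixels.sum()  # but bright spots exist


def test_clustered_cells_touch(small_scene):
    from scipy import ndimage
    labels = small_scene.labels
    by_cluster = {}
    for r in small_scene.regions:
        if r.cluster_id >= 0:
            by_cluster.setdefault(r.cluster_id, []).append(r)
    multi = {k: v for k, v in by_cluster.items() if len(v) > 1}
    assert multi, "default cluster_prob should produce clusters"
    structure = np.ones((3, 3))
    for members in multi.values():
        m = np.zeros(labels.shape, dtype=bool)
        for r in members:
            m[r.pixels[:, 0], r.pixels[:, 1]] = True
        n_comp = ndimage.label(m, structure=structure)[1]
        assert n_comp == 1  # members merge under 8-connectivity


def test_degenerate_geometry_rejected():
    with pytest.raises(ValueError, match="degenerate"):
        generate_scene(SceneParams(cell_area_mean=5.0, cell_area_sd=1.0,
                                   um_per_px=10.0))


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        SceneParams(cluster_prob=1.5)
    with pytest.raises(ValueError):
        SceneParams(cell_ecc_range=(0.5, 1.0))
    with pytest.raises(ValueError):
        SceneParams(width_px=0)


# ---- mosaics -------------------------------------------------------------

def _tiny_params(seed=0):
    return SceneParams(width_px=48, height_px=48, um_per_px=2.0,
                       target_density=1200.0, vessel_count=1,
                       artifact_rate=0.0, seed=seed)


def test_mosaic_spacing_from_region():
    field = {(r, c): 1000.0 for r in range(8) for c in range(8)}
    # 8 x 8 tiles covering a 20 x 20 mm^2 region -> 2.5 mm pitch
    m = generate_mosaic(8, 8, field, _tiny_params(), spacing_mm=20.0 / 8)
    assert m.spacing_mm == pytest.approx(2.5)
    assert len(m.tiles) == 64


def test_mosaic_single_tile():
    m = generate_mosaic(1, 1, {(0, 0): 1500.0}, _tiny_params())
    assert isinstance(m, Mosaic) and len(m.tiles) == 1


def test_mosaic_missing_density_errors():
    with pytest.raises(ValueError, match="missing"):
        generate_mosaic(2, 2, {(0, 0): 1.0, (0, 1): 1.0, (1, 0): 1.0},
                        _tiny_params())


def test_mosaic_density_ramp_monotone_in_expectation():
    """Linear ramp 1000 -> 2000 across columns: mean realized density per
    column increases, averaged over repeated mosaics."""
    cols = 4
    ramp = {(r, c): 1000.0 + 1000.0 * c / (cols - 1)
            for r in range(2) for c in range(cols)}
    col_mean = np.zeros(cols)
    n_rep = 12
    for rep in range(n_rep):
        m = generate_mosaic(2, cols, ramp, _tiny_params(seed=rep))
        for (r, c), scene in m.items():
            col_mean[c] += scene.true_density / (2 * n_rep)
    assert all(a < b for a, b in zip(col_mean, col_mean[1:]))


def test_mosaic_deterministic():
    field = {(0, 0): 1500.0, (0, 1): 500.0}
    m1 = generate_mosaic(1, 2, field, _tiny_params(3))
    m2 = generate_mosaic(1, 2, field, _tiny_params(3))
    for pos in field:
        np.testing.assert_array_equal(m1.tiles[pos].image.pixels,
                                      m2.tiles[pos].image.pixels)
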