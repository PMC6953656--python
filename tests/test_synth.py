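"""Synthetic worlds, species pools, sampling and ground-truth dissimilarity."""

import numpy as np
import pandas as pd
import pytest

from betascape.raster import RasterGrid
from betascape.synth import (
    SpeciesPool,
    expected_abundance,
    generate_species_pool,
    generate_world,
    sample_occurrences,
    true_pair_dissimilarity,
    two_patch_effort,
)


class TestGenerateWorld:
    def test_same_seed_bit_identical(self):
        w1 = generate_world(seed=5)
        w2 = generate_world(seed=5)
        for name in w1.env_names:
            assert np.array_equal(w1.env_stack[name].values, w2.env_stack[name].values)
        assert np.array_equal(w1.class_grid.values, w2.class_grid.values)

    def test_gradient_only_strictly_monotone_in_row(self):
        w = generate_world(n_env_vars=1, gradient_only=True, seed=0)
        vals = next(iter(w.env_stack.values())).values
        assert (np.diff(vals[:, 0]) > 0).all()
        assert np.allclose(vals, vals[:, :1])  # constant along rows

    def test_single_class_grid_is_zero(self):
        w = generate_world(n_classes=1, seed=1)
        assert (w.class_grid.values == 0).all()

    def test_class_labels_contiguous_from_zero(self):
        w = generate_world(n_classes=4, seed=2)
        labels = np.unique(w.class_grid.values)
        assert labels.tolist() == list(range(labels.size))

    def test_degenerate_extent_rejected(self):
        with pytest.raises(ValueError, match="extent"):
            generate_world(extent=(0, 0, 0, 10))

    def test_tiny_grid_rejected(self):
        with pytest.raises(ValueError, match="8 x 8"):
            generate_world(grid_shape=(4, 24))


def manual_pool(world, optima, breadths, intensities, centers, radii):
    nv = len(world.env_names)
    n = len(intensities)
    return SpeciesPool(
        env_names=world.env_names,
        niche_optimum=np.broadcast_to(np.asarray(optima, float), (n, nv)).copy(),
        niche_breadth=np.broadcast_to(np.asarray(breadths, float), (n, nv)).copy(),
        max_intensity=np.asarray(intensities, float),
        range_center=np.asarray(centers, float),
        range_radius=np.asarray(radii, float),
    )


class TestSpeciesPool:
    def test_same_seed_identical_optima(self, small_world):
        p1 = generate_species_pool(small_world, 10, seed=3)
        p2 = generate_species_pool(small_world, 10, seed=3)
        assert np.array_equal(p1.niche_optimum, p2.niche_optimum)

    def test_optima_within_observed_ranges(self, small_world):
        pool = generate_species_pool(small_world, 30, seed=4)
        env = small_world.env_array()
        lo, hi = env.min(axis=(1, 2)), env.max(axis=(1, 2))
        assert (pool.niche_optimum >= lo).all() and (pool.niche_optimum <= hi).all()

    def test_infinite_breadth_flattens_abundance(self, small_world):
        center = small_world.reference_grid().cell_center(8, 8)
        pool = manual_pool(
            small_world, 50.0, 1e12, [2.0], [[center[1], center[0]]], [1e6]
        )
        lam = expected_abundance(small_world, pool)[0]
        assert np.allclose(lam, 2.0)

    def test_zero_radius_restricts_to_center_pixel(self, small_world):
        lon, lat = small_world.reference_grid().cell_center(5, 6)
        pool = manual_pool(small_world, 50.0, 1e12, [1.0], [[lat, lon]], [0.0])
        lam = expected_abundance(small_world, pool)[0]
        assert lam[5, 6] > 0
        lam[5, 6] = 0
        assert (lam == 0).all()

    def test_breadth_must_be_positive(self, small_world):
        with pytest.raises(ValueError, match="positive"):
            manual_pool(small_world, 50.0, 0.0, [1.0], [[0, 0]], [1.0])


class TestSampleOccurrences:
    def test_effort_on_one_pixel_confines_records(self, small_world, small_pool):
        eff = np.zeros(small_world.grid_shape)
        eff[4, 4] = 1.0
        effort = RasterGrid(eff, small_world.reference_grid().transform)
        occ = sample_occurrences(small_world, small_pool, effort, 200, seed=0)
        lon0, lat0 = small_world.reference_grid().cell_center(4, 4)
        a = small_world.reference_grid().transform[0]
        assert (np.abs(occ["decimalLongitude"] - lon0) <= a / 2).all()
        assert (np.abs(occ["decimalLatitude"] - lat0) <= a / 2).all()

    def test_single_species_pool(self, small_world):
        pool = manual_pool(small_world, 50.0, 1e12, [1.0], [[40.0, 0.0]], [1e6])
        effort = two_patch_effort(small_world)
        occ = sample_occurrences(small_world, pool, effort, 50, seed=1)
        assert (occ["species"] == "sp0000").all()

    def test_disjoint_ranges_give_pure_regions(self, small_world):
        # two species on opposite corners with non-overlapping discs
        g = small_world.reference_grid()
        lon_a, lat_a = g.cell_center(2, 2)
        lon_b, lat_b = g.cell_center(13, 13)
        pool = manual_pool(
            small_world,
            50.0,
            1e12,
            [1.0, 1.0],
            [[lat_a, lon_a], [lat_b, lon_b]],
            [2.0, 2.0],
        )
        effort = RasterGrid(np.ones(small_world.grid_shape), g.transform)
        occ = sample_occurrences(small_world, pool, effort, 10_000, seed=2)
        # oracle: check every record coordinate against the range indicators
        d_a = np.hypot(occ["decimalLatitude"] - lat_a, occ["decimalLongitude"] - lon_a)
        d_b = np.hypot(occ["decimalLatitude"] - lat_b, occ["decimalLongitude"] - lon_b)
        jitter_slack = np.hypot(g.transform[0], g.transform[0]) / 2
        is_a = occ["species"] == "sp0000"
        assert (d_a[is_a] <= 2.0 + jitter_slack).all()
        assert (d_b[~is_a] <= 2.0 + jitter_slack).all()

    def test_zero_effort_over_support_raises(self, small_world, small_pool):
        effort = RasterGrid(np.zeros(small_world.grid_shape), small_world.reference_grid().transform)
        with pytest.raises(ValueError, match="effort"):
            sample_occurrences(small_world, small_pool, effort, 10, seed=0)

    def test_sampling_converges_to_expected_composition(self, small_world, small_pool):
        """Empirical per-pixel composition approaches the expected one at n=1e5."""
        effort = RasterGrid(
            np.ones(small_world.grid_shape), small_world.reference_grid().transform
        )
        n = 100_000
        occ = sample_occurrences(small_world, small_pool, effort, n, seed=3)
        lam = expected_abundance(small_world, small_pool)
        g = small_world.reference_grid()
        row, col = g.rowcol(occ["decimalLongitude"], occ["decimalLatitude"])
        # pick the busiest pixel and compare relative species abundance
        pix = row * small_world.grid_shape[1] + col
        busiest = np.bincount(pix).argmax()
        r, c = divmod(busiest, small_world.grid_shape[1])
        sel = (row == r) & (col == c)
        m = int(sel.sum())
        expected_p = lam[:, r, c] / lam[:, r, c].sum()
        ids = np.array(small_pool.species_ids)
        observed = occ.loc[sel, "species"].value_counts()
        for k, sp in enumerate(ids):
            p = expected_p[k]
            se = np.sqrt(p * (1 - p) / m)
            obs = observed.get(sp, 0) / m
            assert abs(obs - p) <= 3 * se + 1e-9


class TestTruePairDissimilarity:
    def test_identity_zero(self, small_world, small_pool):
        assert true_pair_dissimilarity(small_world, small_pool, (3, 3), (3, 3)) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_species_sets_one(self, small_world):
        g = small_world.reference_grid()
        lon_a, lat_a = g.cell_center(2, 2)
        lon_b, lat_b = g.cell_center(13, 13)
        pool = manual_pool(
            small_world, 50.0, 1e12, [1.0, 1.0], [[lat_a, lon_a], [lat_b, lon_b]], [1.0, 1.0]
        )
        assert true_pair_dissimilarity(small_world, pool, (2, 2), (13, 13)) == 1.0

    def test_hand_set_intensities(self, small_world):
        """Communities (2, 2) and (2, 0) -> Horn-Morisita 1/3."""
        g = small_world.reference_grid()
        lon_a, lat_a = g.cell_center(4, 4)
        lon_b, lat_b = g.cell_center(4, 10)
        # species 0 spans both cells; species 1 only reaches cell A
        r_wide = 2 * abs(lon_b - lon_a)
        pool = manual_pool(
            small_world,
            50.0,
            1e12,
            [2.0, 2.0],
            [[lat_a, lon_a], [lat_a, lon_a]],
            [r_wide, 0.0],
        )
        d = true_pair_dissimilarity(small_world, pool, (4, 4), (4, 10))
        assert d == pytest.approx(1 / 3, abs=1e-12)

    def test_cell_without_support_raises(self, small_world):
        g = small_world.reference_grid()
        lon, lat = g.cell_center(0, 0)
        pool = manual_pool(small_world, 50.0, 1e12, [1.0], [[lat, lon]], [0.5])
        with pytest.raises(ValueError, match="all-zero"):
            true_pair_dissimilarity(small_world, pool, (0, 0), (15, 15))

    def test_monotone_in_environmental_distance(self):
        """With unrestricted ranges on a gradient world, dissimilarity from a
        reference cell never decreases as environmental distance grows."""
        w = generate_world(grid_shape=(12, 12), n_env_vars=1, gradient_only=True, seed=6)
        pool = generate_species_pool(w, 20, seed=7, radius_frac=(5.0, 5.0))
        ref = (0, 0)
        ds = [true_pair_dissimilarity(w, pool, ref, (r, 0)) for r in range(12)]
        assert all(b >= a - 1e-9 for a, b in zip(ds, ds[1:]))
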