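"""Closed-form map evaluation: geometry, linearity, truncation."""

from dataclasses import replace

import numpy as np
import pytest

from shellmap import (
    AtomicModel,
    AtomSite,
    DensityMap,
    GridSpec,
    analytic_atom_image,
    compare_maps,
    compute_omega_map,
    lookup_scattering,
    make_toy_model,
    packaged_g_decomposition,
    truncation_radius,
)


@pytest.fixture(scope="module")
def g21():
    return packaged_g_decomposition()


def single_atom_model(box=20.0, element="C", b=0.0, d=2.0, occ=1.0):
    at = AtomSite(element, (box / 2, box / 2, box / 2), b_iso=b, resolution=d,
                  occupancy=occ, id=("A", 1, "", "C1", ""))
    return AtomicModel((at,), (box, box, box))


class TestComputeOmegaMap:
    def test_empty_model_is_zero(self, g21):
        grid = GridSpec((10.0, 10.0, 10.0), (10, 10, 10))
        m = compute_omega_map(AtomicModel((), (10.0, 10.0, 10.0)), grid, g21)
        assert np.all(m.values == 0)

    def test_single_atom_line_matches_analytic_profile(self, g21):
        model = single_atom_model(box=20.0)
        grid = GridSpec(model.cell, (40, 40, 40))
        dmap = compute_omega_map(model, grid, g21, cutoff_sigma=8.0)
        line = dmap.values[:, 20, 20]
        x = grid.axis_coords(0)
        # expected: the analytic radial image summed over periodic images
        # (the slowly decaying ripples of neighbors reach the line)
        sm = lookup_scattering("C", "electron")
        expected = np.zeros_like(x)
        for tx in range(-2, 3):
            for ty in range(-2, 3):
                for tz in range(-2, 3):
                    p = np.array([10.0 + 20 * tx, 10.0 + 20 * ty, 10.0 + 20 * tz])
                    r = np.sqrt((x - p[0]) ** 2 + (10.0 - p[1]) ** 2
                                + (10.0 - p[2]) ** 2)
                    ru, inv = np.unique(r, return_inverse=True)
                    if ru.size == 1:
                        ru = np.append(ru, ru[0] + 1.0)
                    expected += analytic_atom_image(sm, 2.0, 0.0, g21,
                                                    ru).values[inv]
        peak = analytic_atom_image(sm, 2.0, 0.0, g21, np.array([0.0])).origin_value
        assert np.max(np.abs(line - expected)) < 1e-6 * peak

    def test_two_atoms_superpose(self, g21):
        a = AtomSite("C", (7.0, 10.0, 10.0), 5.0, 2.0, 1.0, ("A", 1, "", "C1", ""))
        b = AtomSite("O", (13.0, 10.0, 10.0), 15.0, 2.0, 1.0, ("A", 2, "", "O1", ""))
        cell = (20.0, 20.0, 20.0)
        grid = GridSpec(cell, (40, 40, 40))
        both = compute_omega_map(AtomicModel((a, b), cell), grid, g21)
        m_a = compute_omega_map(AtomicModel((a,), cell), grid, g21)
        m_b = compute_omega_map(AtomicModel((b,), cell), grid, g21)
        np.testing.assert_allclose(
            both.values, m_a.values + m_b.values, atol=1e-12
        )

    def test_translation_equivariance(self, g21):
        model = make_toy_model("pair", 2, 20.0, seed=0)
        grid = GridSpec(model.cell, (40, 40, 40))
        m0 = compute_omega_map(model, grid, g21)
        step = grid.spacing[0]
        shifted = AtomicModel(
            tuple(
                replace(a, position=(a.position[0] + step, a.position[1],
                                     a.position[2]))
                for a in model.atoms
            ),
            model.cell,
        )
        m1 = compute_omega_map(shifted, grid, g21)
        np.testing.assert_allclose(
            m1.values, np.roll(m0.values, 1, axis=0), atol=1e-10
        )

    def test_occupancy_scales_contribution(self, g21):
        grid = GridSpec((20.0, 20.0, 20.0), (40, 40, 40))
        full = compute_omega_map(single_atom_model(occ=1.0), grid, g21)
        half = compute_omega_map(single_atom_model(occ=0.5), grid, g21)
        np.testing.assert_allclose(half.values, 0.5 * full.values, rtol=0,
                                   atol=1e-15)

    def test_coarse_grid_rejected_and_warned(self, g21):
        model = single_atom_model(d=2.0)
        with pytest.raises(ValueError, match="alias"):
            compute_omega_map(model, GridSpec(model.cell, (13, 13, 13)), g21)
        with pytest.warns(UserWarning, match="finer grid"):
            compute_omega_map(model, GridSpec(model.cell, (25, 25, 25)), g21)

    def test_unknown_element_rejected(self, g21):
        model = AtomicModel(
            (AtomSite("Zz", (5.0, 5.0, 5.0), 0.0, 2.0),), (10.0, 10.0, 10.0)
        )
        grid = GridSpec(model.cell, (20, 20, 20))
        with pytest.raises(KeyError):
            compute_omega_map(model, grid, g21)


class TestTruncationRadius:
    def test_monotone_in_resolution(self, g21):
        mu, nu, _ = g21.arrays()
        radii = [
            truncation_radius(mu * D, nu * D * D, 5.0) for D in (1.0, 2.0, 4.0)
        ]
        assert radii[0] < radii[1] < radii[2]

    def test_degenerate_cutoff_is_outermost_shell(self, g21):
        mu, nu, _ = g21.arrays()
        assert truncation_radius(mu, nu, 0.0) == pytest.approx(mu.max())

    def test_doubling_cutoff_changes_map_negligibly(self, g21):
        model = single_atom_model(box=16.0)
        grid = GridSpec(model.cell, (32, 32, 32))
        m5 = compute_omega_map(model, grid, g21, cutoff_sigma=5.0)
        m10 = compute_omega_map(model, grid, g21, cutoff_sigma=10.0)
        peak = np.abs(m10.values).max()
        assert np.max(np.abs(m5.values - m10.values)) < 1e-5 * peak


class TestCompareMaps:
    def test_identical_maps(self, g21):
        grid = GridSpec((10.0, 10.0, 10.0), (8, 8, 8))
        vals = np.random.default_rng(0).normal(size=(8, 8, 8))
        m = DensityMap(grid, vals)
        c = compare_maps(m, m)
        assert c.max_abs_diff == 0 and c.rms_diff == 0
        assert c.correlation == pytest.approx(1.0)

    def test_constant_offset(self):
        grid = GridSpec((10.0, 10.0, 10.0), (8, 8, 8))
        vals = np.random.default_rng(1).normal(size=(8, 8, 8))
        c = compare_maps(DensityMap(grid, vals + 1.0), DensityMap(grid, vals))
        assert c.max_abs_diff == pytest.approx(1.0)

    def test_grid_mismatch_rejected(self):
        a = DensityMap(GridSpec((10.0,) * 3, (8, 8, 8)), np.zeros((8, 8, 8)))
        b = DensityMap(GridSpec((10.0,) * 3, (9, 9, 9)), np.zeros((9, 9, 9)))
        with pytest.raises(ValueError):
            compare_maps(a, b)
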