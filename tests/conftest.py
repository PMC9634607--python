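"""Shared fixtures: the expensive fits and reference maps are computed once
per session and reused across module and acceptance tests."""

from dataclasses import replace

import numpy as np
import pytest

from shellmap import (
    AtomicModel,
    FitConfig,
    GridSpec,
    RadialProfile,
    direct_structure_factors,
    fit_decomposition,
    interference_G,
    lookup_scattering,
    make_toy_model,
    numeric_atom_image,
    synthesize_map,
)
from shellmap.shell_fit import nested_fits

G_FIT_STEP = 0.002
CARBON_FIT_STEP = 0.004


@pytest.fixture(scope="session")
def g_profile():
    r = np.arange(0.0, 11.0001, G_FIT_STEP)
    return RadialProfile(r, interference_G(r), 1.0)


@pytest.fixture(scope="session")
def g_fit21(g_profile):
    """Fresh 21-term fit of G over [0, 10]."""
    cfg = FitConfig(
        n_terms=21, domain_radius=10.0, grid_step=G_FIT_STEP, seed=0,
        n_restarts=0, tail_fraction=0.1,
    )
    return fit_decomposition(g_profile, cfg, target_id="G")


@pytest.fixture(scope="session")
def carbon_model():
    return lookup_scattering("C", "electron")


@pytest.fixture(scope="session")
def carbon_profile_d2(carbon_model):
    """Immobile carbon image at D = 2 A on [0, 10.4] A (fit grid + tail)."""
    r = np.arange(0.0, 10.4001, CARBON_FIT_STEP)
    return numeric_atom_image(carbon_model, 2.0, 0.0, r)


@pytest.fixture(scope="session")
def carbon_fit12(carbon_profile_d2):
    """12-term decomposition of the immobile carbon image over r <= 8 A."""
    cfg = FitConfig(
        n_terms=12, domain_radius=8.0, grid_step=CARBON_FIT_STEP, seed=0,
        n_restarts=1,
    )
    return fit_decomposition(carbon_profile_d2, cfg, target_id="C, D = 2 A")


@pytest.fixture(scope="session")
def helix_setup():
    """100-atom toy body, its grid and the D = 2 A Fourier reference map."""
    model = make_toy_model("helix", 100, 40.0, seed=1)
    grid = GridSpec(cell=model.cell, divisions=(80, 80, 80))
    ref = synthesize_map(direct_structure_factors(model, 2.0), grid)
    return model, grid, ref


@pytest.fixture(scope="session")
def g_fit_sweep(g_profile):
    """Nested warm-started fits of G with M = 1..6."""
    cfg = FitConfig(
        n_terms=1, domain_radius=10.0, grid_step=G_FIT_STEP, seed=0,
        n_restarts=0, tail_fraction=0.1,
    )
    return nested_fits(g_profile, list(range(1, 7)), cfg, target_id="G")


@pytest.fixture(scope="session")
def two_group_model():
    """Two spatially separated 20-atom groups at D = 2 and D = 5 A."""
    base_a = make_toy_model("blob", 20, 16.0, seed=11)
    base_b = make_toy_model("blob", 20, 16.0, seed=12)
    shift_a = np.array([10.0, 20.0, 20.0]) - 8.0
    shift_b = np.array([30.0, 20.0, 20.0]) - 8.0
    atoms = []
    for part, shift, d in ((base_a, shift_a, 2.0), (base_b, shift_b, 5.0)):
        for a in part.atoms:
            atoms.append(
                replace(a, position=tuple(np.array(a.position) + shift),
                        resolution=d)
            )
    model = AtomicModel(tuple(atoms), (40.0, 40.0, 40.0))
    group_a = AtomicModel(tuple(model.atoms[:20]), model.cell)
    group_b = AtomicModel(tuple(model.atoms[20:]), model.cell)
    return model, group_a, group_b
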