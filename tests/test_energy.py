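"""Hamiltonian terms, coefficient table, and local-update oracles."""

import math

import numpy as np
import pytest

import fgmem as fg
from conftest import jiggled


# ---------------------------------------------------------------------------
# coefficients
# ---------------------------------------------------------------------------

def test_rho_cases():
    assert fg.rho(1, 5.0) == 5.0
    assert fg.rho(-1, 5.0) == 1.0
    assert fg.rho(1, 1.0) == 1.0
    with pytest.raises(ValueError):
        fg.rho(0, 5.0)


@pytest.mark.parametrize("c,lolo,lold", [(8.37, 4.24, 2.62), (5.0, 2.6, 1.8)])
def test_bending_coefficient_closed_forms(c, lolo, lold):
    # kappa_ij = (c + 1/c)/2, (2 + c + 1/c)/4, 1 for the three bond types
    assert round(fg.bond_coefficient(1, 1, c), 2) == lolo
    assert round(fg.bond_coefficient(1, -1, c), 2) == lold
    assert fg.bond_coefficient(-1, -1, c) == 1.0
    assert np.isclose(fg.bond_coefficient(1, 1, c), (c + 1 / c) / 2)
    assert np.isclose(fg.bond_coefficient(1, -1, c), (2 + c + 1 / c) / 4)


def test_tension_coefficient_variants():
    for si in (1, -1):
        for sj in (1, -1):
            assert fg.bond_coefficient(si, sj, 8.37, fg.MODEL1, "tension") == 1.0
            assert (fg.bond_coefficient(si, sj, 8.37, fg.MODEL2, "tension")
                    == fg.bond_coefficient(si, sj, 8.37, fg.MODEL2, "bending"))


def test_coefficient_symmetries():
    # invariant under c <-> 1/c and under swapping the two labels
    for c in (1.0, 2.5, 8.37):
        for si, sj in ((1, 1), (1, -1), (-1, -1)):
            assert np.isclose(fg.bond_coefficient(si, sj, c),
                              fg.bond_coefficient(si, sj, 1 / c))
            assert fg.bond_coefficient(si, sj, c) == fg.bond_coefficient(sj, si, c)


def test_model_params_canonicalizes_c():
    p = fg.ModelParams(lambda_=0.1, kappa=5.0, c=0.2)
    assert np.isclose(p.c, 5.0)
    with pytest.raises(ValueError):
        fg.ModelParams(lambda_=-1.0, kappa=5.0)
    with pytest.raises(ValueError):
        fg.ModelParams(lambda_=0.1, kappa=0.0)
    with pytest.raises(ValueError):
        fg.ModelParams(lambda_=0.1, kappa=5.0, phi0=1.5)


# ---------------------------------------------------------------------------
# total energy
# ---------------------------------------------------------------------------

def test_uniform_phase_has_zero_aggregation(icosphere4, params_model2):
    icosphere4.sigma[:] = 1
    assert fg.total_energy(icosphere4, params_model2).s0 == 0.0


def test_s0_counts_boundary_bonds(icosahedron):
    # one Ld triangle on the icosahedron: 3 boundary bonds, S0 = 6
    icosahedron.sigma[:] = 1
    icosahedron.sigma[7] = -1
    p = fg.ModelParams(lambda_=1.0, kappa=1.0, c=3.0)
    e = fg.total_energy(icosahedron, p)
    assert e.s0 == 6.0
    # brute force: sum 1 - s_i s_j over bonds
    s = icosahedron.sigma
    brute = sum(1 - int(s[t0]) * int(s[t1])
                for t0, t1 in icosahedron.bond_tri)
    assert e.s0 == brute


def test_tetrahedron_bending_energy(tetrahedron):
    # adjacent face normals of a regular tetrahedron: n_i . n_j = -1/3,
    # so S2 = 6 bonds * (1 - (-1/3)) = 8 with unit coefficients
    p = fg.ModelParams(lambda_=0.0, kappa=1.0, c=1.0)
    e = fg.total_energy(tetrahedron, p)
    assert np.isclose(e.s2, 8.0)
    assert e.s0 == 0.0


def test_scaling_law(icosphere4, params_model2):
    # r -> alpha r: S1 -> alpha^2 S1, S0 and S2 unchanged
    e = fg.total_energy(icosphere4, params_model2)
    scaled = icosphere4.copy()
    scaled.pos *= 1.7
    e2 = fg.total_energy(scaled, params_model2)
    assert np.isclose(e2.s1, 1.7**2 * e.s1)
    assert np.isclose(e2.s2, e.s2)
    assert e2.s0 == e.s0


def test_model1_equals_model2_at_c_eq_1(rng):
    # with c = 1 the two-phase distinction vanishes: both variants reduce
    # to the uniform fluid membrane with gamma = kappa_ij = 1
    for seed in range(5):
        r = np.random.default_rng(seed)
        surf = fg.build_icosphere(2)
        fg.assign_sigma_random(surf, r.uniform(0, 1), r)
        surf = jiggled(surf, r, scale=0.1)
        p1 = fg.ModelParams(lambda_=0.3, kappa=4.0, c=1.0, variant=fg.MODEL1)
        p2 = fg.ModelParams(lambda_=0.3, kappa=4.0, c=1.0, variant=fg.MODEL2)
        assert fg.total_energy(surf, p1).total == fg.total_energy(surf, p2).total


def test_degenerate_triangle_raises(tetrahedron, params_model2):
    tetrahedron.pos[0] = tetrahedron.pos[1]
    with pytest.raises(ValueError, match="degenerate"):
        fg.total_energy(tetrahedron, params_model2)


def test_s0_is_twice_boundary_count(icosphere4, params_model2):
    e = fg.total_energy(icosphere4, params_model2)
    stats = fg.domain_components(icosphere4)
    assert e.s0 == 2 * stats.boundary_bonds


# ---------------------------------------------------------------------------
# local updates vs full-recompute oracle
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("variant", [fg.MODEL1, fg.MODEL2])
def test_delta_vertex_matches_full_recompute(variant, rng):
    surf = fg.build_icosphere(2)
    fg.assign_sigma_random(surf, 0.6, rng)
    surf = jiggled(surf, rng, scale=0.05)
    p = fg.ModelParams(lambda_=0.4, kappa=6.0, c=4.2, variant=variant)
    e0 = fg.total_energy(surf, p).total
    for _ in range(50):
        v = int(rng.integers(surf.n_vertices))
        new = surf.pos[v] + 0.1 * rng.standard_normal(3)
        d = fg.delta_energy_vertex_move(surf, p, v, new)
        trial = surf.copy()
        trial.pos[v] = new
        full = fg.total_energy(trial, p).total - e0
        assert d == pytest.approx(full, rel=1e-9, abs=1e-12)


def test_delta_vertex_identity_move(icosphere4, params_model2):
    d = fg.delta_energy_vertex_move(icosphere4, params_model2, 3,
                                    icosphere4.pos[3])
    assert d == pytest.approx(0.0, abs=1e-12)


def test_delta_vertex_degenerate_is_inf(tetrahedron, params_model2):
    assert fg.delta_energy_vertex_move(tetrahedron, params_model2, 0,
                                       tetrahedron.pos[1]) == math.inf


@pytest.mark.parametrize("variant", [fg.MODEL1, fg.MODEL2])
def test_delta_flip_matches_full_recompute(variant, rng):
    surf = fg.build_icosphere(3)
    fg.assign_sigma_random(surf, 0.5, rng)
    surf = jiggled(surf, rng, scale=0.05)
    p = fg.ModelParams(lambda_=0.4, kappa=6.0, c=4.2, variant=variant)
    checked = 0
    for b in rng.permutation(surf.n_bonds):
        prop = fg.flip_candidate(surf, int(b), rng)
        if prop is None:
            continue
        e0 = fg.total_energy(surf, p).total
        d = fg.delta_energy_flip(surf, p, prop)
        fg.apply_flip(surf, prop)
        full = fg.total_energy(surf, p).total - e0
        assert d == pytest.approx(full, rel=1e-9, abs=1e-12)
        checked += 1
        if checked >= 60:
            break
    assert checked >= 50


def test_delta_flip_coplanar_patch_has_no_bending_term():
    # square pyramid with a fan-triangulated flat base: flipping a base bond
    # keeps every touched normal pair unchanged, so delta S is pure tension:
    # gamma * (new diagonal^2 - old diagonal^2)
    pos = np.array([
        [0.1, -0.3, 0.0],   # base center, placed so the flip quad is convex
        [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [-1.0, 0.0, 0.0], [0.0, -1.0, 0.0],
        [0.0, 0.0, 1.0],    # apex
    ])
    tri = np.array([[0, 2, 1], [0, 3, 2], [0, 4, 3], [0, 1, 4],   # flat base
                    [5, 1, 2], [5, 2, 3], [5, 3, 4], [5, 4, 1]])  # sides
    surf = fg.TriSurface.from_triangles(pos, tri)
    p = fg.ModelParams(lambda_=0.7, kappa=3.0, c=1.0, variant=fg.MODEL2)
    b = next(i for i in range(surf.n_bonds)
             if set(surf.bond_v[i]) == {0, 2})  # interior bond of the base
    prop = fg.flip_candidate(surf, b)
    assert prop is not None
    d = fg.delta_energy_flip(surf, p, prop)
    expected = np.sum((pos[1] - pos[3])**2) - np.sum((pos[0] - pos[2])**2)
    assert d == pytest.approx(expected, abs=1e-12)
    # and flip followed by reverse flip accumulates zero
    fg.apply_flip(surf, prop)
    prop2 = fg.flip_candidate(surf, b)
    d2 = fg.delta_energy_flip(surf, p, prop2)
    assert d + d2 == pytest.approx(0.0, abs=1e-12)
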