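"""Triangulated-sphere construction, invariants, and bond-flip topology."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fgmem as fg
from conftest import jiggled


@pytest.mark.parametrize("subdivision,n", [(1, 12), (2, 42), (4, 162), (8, 642)])
def test_icosphere_counts(subdivision, n):
    surf = fg.build_icosphere(subdivision)
    assert surf.n_vertices == 10 * subdivision**2 + 2 == n
    assert surf.n_triangles == 2 * n - 4
    assert surf.n_bonds == 3 * n - 6
    assert surf.euler_characteristic == 2
    surf.validate()


def test_icosphere_full_lattice_size():
    # the production lattice: subdivision 24 gives 5762 vertices
    surf = fg.build_icosphere(24)
    assert surf.n_vertices == 5762
    assert surf.n_triangles == 2 * 5762 - 4
    assert surf.n_bonds == 3 * 5762 - 6


def test_icosphere_outward_normals(icosphere4):
    p = icosphere4.pos
    t = icosphere4.tri
    normals = np.cross(p[t[:, 1]] - p[t[:, 0]], p[t[:, 2]] - p[t[:, 0]])
    centroids = (p[t[:, 0]] + p[t[:, 1]] + p[t[:, 2]]) / 3
    assert np.all(np.einsum("ij,ij->i", normals, centroids) > 0)


def test_icosphere_rejects_bad_subdivision():
    with pytest.raises(ValueError):
        fg.build_icosphere(0)


def test_mean_bond_length_scaling():
    surf = fg.build_icosphere(3, mean_bond_length=1.3)
    d = surf.pos[surf.bond_v[:, 0]] - surf.pos[surf.bond_v[:, 1]]
    assert np.isclose(np.linalg.norm(d, axis=1).mean(), 1.3)


@pytest.mark.parametrize("nt,phi0,nto", [(20, 0.5, 10), (320, 0.7, 224),
                                         (320, 1.0, 320), (320, 0.0, 0)])
def test_assign_sigma_exact_count(nt, phi0, nto, rng):
    subdivision = {20: 1, 320: 4}[nt]
    surf = fg.build_icosphere(subdivision)
    fg.assign_sigma_random(surf, phi0, rng)
    assert surf.n_lo == nto
    assert surf.n_lo + surf.n_ld == surf.n_triangles


def test_assign_sigma_deterministic_and_validates(rng):
    surf = fg.build_icosphere(3)
    fg.assign_sigma_random(surf, 0.4, np.random.default_rng(7))
    ref = surf.sigma.copy()
    fg.assign_sigma_random(surf, 0.4, np.random.default_rng(7))
    assert np.array_equal(surf.sigma, ref)
    with pytest.raises(ValueError):
        fg.assign_sigma_random(surf, 1.3, rng)


def test_tetrahedron_flips_all_rejected(tetrahedron, rng):
    # opposite diagonal of any bond is already a bond of the tetrahedron
    for b in range(tetrahedron.n_bonds):
        assert fg.flip_candidate(tetrahedron, b, rng) is None


def test_icosahedron_flip_degrees(icosahedron, rng):
    prop = fg.flip_candidate(icosahedron, 0, rng)
    assert prop is not None
    u, w = prop.old_diagonal
    a, c = prop.new_diagonal
    fg.apply_flip(icosahedron, prop)
    assert icosahedron.v_nb[u] == 4 and icosahedron.v_nb[w] == 4
    assert icosahedron.v_nb[a] == 6 and icosahedron.v_nb[c] == 6
    assert icosahedron.n_bonds == 30 and icosahedron.n_triangles == 20
    icosahedron.validate()


def test_flip_apply_revert_bit_identical(icosphere4, rng):
    before = {f: getattr(icosphere4, f).copy()
              for f in ("pos", "tri", "sigma", "bond_v", "bond_tri",
                        "tri_bonds", "v_bonds", "v_nb", "v_tris", "v_nt")}
    for b in rng.choice(icosphere4.n_bonds, size=50, replace=False):
        prop = fg.flip_candidate(icosphere4, int(b), rng)
        if prop is None:
            continue
        fg.apply_flip(icosphere4, prop)
        fg.revert_flip(icosphere4, prop)
    for f, arr in before.items():
        assert np.array_equal(arr, getattr(icosphere4, f)), f


def test_flip_sigma_rule_conserves_lo_count(icosphere4, rng):
    nto = icosphere4.n_lo
    n_same = n_diff = 0
    for b in range(icosphere4.n_bonds):
        prop = fg.flip_candidate(icosphere4, b, rng)
        if prop is None:
            continue
        if prop.sigma_old[0] == prop.sigma_old[1]:
            assert prop.sigma_new == prop.sigma_old
            n_same += 1
        else:
            assert sorted(prop.sigma_new) == [-1, 1]
            n_diff += 1
        fg.apply_flip(icosphere4, prop)
        assert icosphere4.n_lo == nto
        fg.revert_flip(icosphere4, prop)
    assert n_same > 0 and n_diff > 0


def test_apply_flip_rejects_stale_proposal(icosphere4, rng):
    prop = fg.flip_candidate(icosphere4, 5, rng)
    fg.apply_flip(icosphere4, prop)
    with pytest.raises(ValueError):
        fg.apply_flip(icosphere4, prop)


def test_flip_storm_preserves_topology(rng):
    surf = fg.build_icosphere(4)
    fg.assign_sigma_random(surf, 0.7, rng)
    surf = jiggled(surf, rng, scale=0.02)
    nto = surf.n_lo
    for k in range(5):
        accepted = fg.flip_storm(surf, 20_000, seed=100 + k)
        assert accepted > 0
        assert surf.n_lo == nto
        assert surf.euler_characteristic == 2
        assert np.all(surf.v_nb[:surf.n_vertices] >= 3)
        surf.validate()


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_flip_storm_property_small_mesh(seed):
    """Random flip storms on the 42-vertex sphere never break manifoldness."""
    surf = fg.build_icosphere(2)
    fg.assign_sigma_random(surf, 0.5, np.random.default_rng(seed))
    nto = surf.n_lo
    fg.flip_storm(surf, 2_000, seed=seed)
    assert surf.n_lo == nto
    surf.validate()


def test_from_triangles_rejects_bad_input():
    pos = np.eye(3)
    with pytest.raises(ValueError):  # open surface
        fg.TriSurface.from_triangles(pos, np.array([[0, 1, 2]]))
    tetra = fg.build_tetrahedron()
    bad = tetra.tri.copy()
    bad[0] = bad[0][[0, 2, 1]]  # inconsistent winding
    with pytest.raises(ValueError):
        fg.TriSurface.from_triangles(tetra.pos, bad)
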