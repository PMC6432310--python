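"""Shape descriptors, domain statistics, and morphology classification."""

import numpy as np
import pytest

import fgmem as fg
from fgmem.observables import DomainStats, _neck_ratios, DEFAULT_THRESHOLDS


def cloud_surface(pos):
    """Wrap a point cloud in a dummy icosphere topology for shape tests."""
    surf = fg.build_icosphere(3)
    assert surf.n_vertices == pos.shape[0]
    surf.pos[:] = pos
    return surf


def test_semi_axes_sphere():
    surf = fg.build_icosphere(3, radius=2.0)
    d1, d2, d3 = fg.semi_axes(surf)
    assert d1 >= d2 >= d3
    # extents of the discrete vertex set fall slightly short of the true
    # diameter when no vertex sits at a principal-axis pole
    assert np.allclose([d1, d2, d3], 4.0, rtol=0.05)


@pytest.mark.parametrize("stretch,kind", [((3, 1, 1), "prolate"),
                                          ((3, 3, 1), "oblate")])
def test_semi_axes_prolate_oblate(stretch, kind):
    surf = fg.build_icosphere(3, radius=1.0)
    surf.pos *= np.array(stretch, dtype=float)
    d1, d2, d3 = fg.semi_axes(surf)
    if kind == "prolate":  # D1 > D2 ~ D3
        assert d1 > 2 * d2
        assert d2 == pytest.approx(d3, rel=0.05)
    else:  # oblate: D1 ~ D2 > D3
        assert d1 == pytest.approx(d2, rel=0.05)
        assert d2 > 2 * d3


def test_semi_axes_rigid_motion_invariant(rng):
    surf = fg.build_icosphere(3)
    surf.pos *= np.array([2.0, 1.0, 0.5])
    d = fg.semi_axes(surf)
    # random rotation + translation
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    moved = surf.copy()
    moved.pos = surf.pos @ q.T + np.array([5.0, -3.0, 1.0])
    d2 = fg.semi_axes(moved)
    assert np.allclose(d, d2, rtol=1e-9)


def test_domain_components_uniform_and_single_defect(icosahedron):
    icosahedron.sigma[:] = 1
    stats = fg.domain_components(icosahedron)
    assert stats.lo_sizes == (20,)
    assert stats.ld_sizes == ()
    assert stats.boundary_bonds == 0
    icosahedron.sigma[4] = -1
    stats = fg.domain_components(icosahedron)
    assert stats.lo_sizes == (19,)
    assert stats.ld_sizes == (1,)
    assert stats.boundary_bonds == 3


def test_component_sizes_partition_phases(icosphere4):
    stats = fg.domain_components(icosphere4)
    assert sum(stats.lo_sizes) == icosphere4.n_lo
    assert sum(stats.ld_sizes) == icosphere4.n_ld


def test_random_mixing_boundary_fraction(rng):
    # at phi0 = 0.5 a bond is a boundary bond with probability 2 phi (1-phi)
    surf = fg.build_icosphere(8)
    fracs = []
    for seed in range(5):
        fg.assign_sigma_random(surf, 0.5, np.random.default_rng(seed))
        fracs.append(fg.domain_components(surf).boundary_bonds / surf.n_bonds)
    assert np.mean(fracs) == pytest.approx(0.5, rel=0.05)


def test_boundary_equals_half_s0(icosphere4, params_model2):
    e = fg.total_energy(icosphere4, params_model2)
    stats = fg.domain_components(icosphere4)
    assert stats.boundary_bonds * 2 == e.s0


def test_mean_triangle_areas_closed_form():
    # unit-edge equilateral triangles: area sqrt(3)/4
    surf = fg.build_tetrahedron(edge=1.0)
    surf.sigma[:] = 1
    ao, ad = fg.mean_triangle_areas(surf)
    assert ao == pytest.approx(np.sqrt(3) / 4)
    assert ad is None
    assert fg.area_fraction_lo(surf) == 1.0


def test_area_fraction_interpolates(icosphere4):
    frac = fg.area_fraction_lo(icosphere4)
    assert 0.0 < frac < 1.0


def make_stats(lo_sizes, ld_sizes, boundary=10, nt=320):
    return DomainStats(lo_sizes=tuple(sorted(lo_sizes, reverse=True)),
                       ld_sizes=tuple(sorted(ld_sizes, reverse=True)),
                       boundary_bonds=boundary,
                       labels=np.zeros(nt, dtype=np.int64))


@pytest.mark.parametrize("lo,ld,expected", [
    ([150, 74], [96], "two_circular"),
    ([224], [48, 48], "stripe"),
    ([224], [96], "one_circular"),
    ([80, 75, 69], [96], "multi_circular_raft"),
    ([2] * 112, [1] * 96, "random"),
])
def test_classify_morphology_cases(lo, ld, expected):
    label = fg.classify_morphology(make_stats(lo, ld))
    assert label.label == expected
    assert label.n_lo_components == len(lo)
    assert label.n_ld_components == len(ld)


def test_budding_flag_on_necked_domain(rng):
    # a pinched-off Lo cap: nearly the whole sphere area belongs to the Lo
    # component but its boundary loop is tiny -> isoperimetric ratio << 1
    surf = fg.build_icosphere(4, radius=1.0)
    z = surf.pos[:, 2]
    # triangles entirely below z ~ 0.95 are Lo; a small polar cap is Ld
    cap = np.array([np.all(z[t] > 0.92) for t in surf.tri])
    surf.sigma[:] = 1
    surf.sigma[cap] = -1
    assert surf.n_ld > 0
    stats = fg.domain_components(surf)
    q = _neck_ratios(surf, stats, DEFAULT_THRESHOLDS)
    assert q is not None and q < 0.5
    label = fg.classify_morphology(stats, surface=surf)
    assert label.label == "budding_candidate"


def test_hemispherical_cap_not_flagged_as_neck(rng):
    # a hemispherical Lo cap has isoperimetric ratio ~ 1/2 (boundary =
    # equator), above the budding cutoff
    surf = fg.build_icosphere(4, radius=1.0)
    z = surf.pos[:, 2]
    upper = np.array([np.all(z[t] >= -1e-9) for t in surf.tri])
    surf.sigma[:] = -1
    surf.sigma[upper] = 1
    stats = fg.domain_components(surf)
    label = fg.classify_morphology(stats, surface=surf)
    assert label.label == "one_circular"
    assert label.neck_evidence is not None
    assert label.neck_evidence > 0.4


def test_measure_record_is_consistent(icosphere4, params_model2):
    e = fg.total_energy(icosphere4, params_model2)
    rec = fg.measure(icosphere4, sweep=7, energy=e)
    assert rec.sweep == 7
    assert rec.boundary_bonds == e.s0 / 2
    assert rec.d1 >= rec.d2 >= rec.d3
    assert 0 <= rec.area_fraction_lo <= 1
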