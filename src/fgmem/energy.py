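"""Hamiltonian of the two-phase fluid membrane and exact local updates.

The energy of a configuration (vertex positions r, triangulation T, phase
labels sigma) is

    S = lambda * S0 + S1 + kappa * S2

with all three sums running over bonds ij, where (i, j) are the two
triangles sharing the bond:

    S0 = sum_ij (1 - sigma_i sigma_j)            aggregation / line tension
    S1 = sum_ij gamma_ij * l_ij^2                Gaussian (tension) energy
    S2 = sum_ij kappa_ij * (1 - n_i . n_j)       bending energy

l_ij is the Euclidean bond length and n_i the unit outward normal of
triangle i.  The phase enters the elastic coefficients through the metric
ratio rho = c (Lo) or 1 (Ld):

    kappa_ij = (rho_i + 1/rho_i + rho_j + 1/rho_j) / 4
             = (c + 1/c)/2      on (Lo, Lo) bonds
             = (2 + c + 1/c)/4  on (Lo, Ld) boundary bonds
             = 1                on (Ld, Ld) bonds

Model 1 keeps gamma_ij = 1 (canonical Gaussian energy); Model 2 sets
gamma_ij = kappa_ij.  Both are symmetric under c <-> 1/c, so ModelParams
canonicalizes c >= 1.  Temperature is fixed at kB*T = 1.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Tuple

import numpy as np
from numba import njit

from .mesh import MAX_DEGREE, TriSurface, FlipProposal, _find_bond, _flip_geometry

MODEL1 = "model1"
MODEL2 = "model2"

#: squared-norm floor below which a triangle normal is treated as degenerate
DEGENERATE_NORMAL2 = 1e-24

__all__ = [
    "MODEL1",
    "MODEL2",
    "ModelParams",
    "EnergyBreakdown",
    "rho",
    "bond_coefficient",
    "total_energy",
    "delta_energy_vertex_move",
    "delta_energy_flip",
]


@dataclasses.dataclass(frozen=True)
class ModelParams:
    """Model couplings; ``c`` is canonicalized to c >= 1 (c <-> 1/c symmetry)."""

    lambda_: float
    kappa: float
    c: float = 1.0
    phi0: float = 0.5
    variant: str = MODEL2

    def __post_init__(self):
        if self.lambda_ < 0:
            raise ValueError(f"lambda must be >= 0, got {self.lambda_}")
        if self.kappa <= 0:
            raise ValueError(f"kappa must be > 0, got {self.kappa}")
        if self.c <= 0:
            raise ValueError(f"c must be > 0, got {self.c}")
        if self.c < 1.0:
            object.__setattr__(self, "c", 1.0 / self.c)
        if not 0.0 <= self.phi0 <= 1.0:
            raise ValueError(f"phi0 must be in [0, 1], got {self.phi0}")
        if self.variant not in (MODEL1, MODEL2):
            raise ValueError(f"variant must be '{MODEL1}' or '{MODEL2}'")

    @property
    def is_model2(self) -> bool:
        return self.variant == MODEL2


@dataclasses.dataclass(frozen=True)
class EnergyBreakdown:
    """The three Hamiltonian terms (unweighted) plus the couplings."""

    s0: float
    s1: float
    s2: float
    lambda_: float
    kappa: float

    @property
    def total(self) -> float:
        return self.lambda_ * self.s0 + self.s1 + self.kappa * self.s2


def rho(sigma: int, c: float) -> float:
    """Metric ratio of a triangle: c in the Lo phase, 1 in the Ld phase."""
    if sigma not in (1, -1):
        raise ValueError(f"sigma must be +1 or -1, got {sigma}")
    return float(c) if sigma == 1 else 1.0


@njit(cache=True, inline="always")
def _kappa_ij(si, sj, c):
    ri = c if si > 0 else 1.0
    rj = c if sj > 0 else 1.0
    return 0.25 * (ri + 1.0 / ri + rj + 1.0 / rj)


@njit(cache=True, inline="always")
def _gamma_ij(si, sj, c, model2):
    if model2:
        return _kappa_ij(si, sj, c)
    return 1.0


def bond_coefficient(sigma_i: int, sigma_j: int, c: float, variant: str = MODEL2,
                     which: str = "bending") -> float:
    """Effective coefficient of a bond between triangles with labels sigma_i/j.

    ``which='bending'`` returns kappa_ij (both variants);
    ``which='tension'`` returns gamma_ij (1 in Model 1, kappa_ij in Model 2).
    """
    ri, rj = rho(sigma_i, c), rho(sigma_j, c)
    kij = 0.25 * (ri + 1.0 / ri + rj + 1.0 / rj)
    if which == "bending":
        return kij
    if which == "tension":
        return 1.0 if variant == MODEL1 else kij
    raise ValueError(f"which must be 'tension' or 'bending', got {which!r}")


# ---------------------------------------------------------------------------
# numba geometry helpers
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _vert_sub(pos, i, v, px, py, pz):
    """Coordinates of vertex i with vertex v virtually moved to (px,py,pz)."""
    if i == v:
        return px, py, pz
    return pos[i, 0], pos[i, 1], pos[i, 2]


@njit(cache=True, inline="always")
def _normal_of(ax, ay, az, bx, by, bz, cx, cy, cz):
    """Unit normal of triangle (a, b, c); last element is |cross|^2."""
    ux, uy, uz = bx - ax, by - ay, bz - az
    vx, vy, vz = cx - ax, cy - ay, cz - az
    nx = uy * vz - uz * vy
    ny = uz * vx - ux * vz
    nz = ux * vy - uy * vx
    n2 = nx * nx + ny * ny + nz * nz
    if n2 < DEGENERATE_NORMAL2:
        return 0.0, 0.0, 0.0, n2
    inv = 1.0 / math.sqrt(n2)
    return nx * inv, ny * inv, nz * inv, n2


@njit(cache=True, inline="always")
def _tri_normal(pos, tri, t):
    i, j, k = tri[t, 0], tri[t, 1], tri[t, 2]
    return _normal_of(pos[i, 0], pos[i, 1], pos[i, 2],
                      pos[j, 0], pos[j, 1], pos[j, 2],
                      pos[k, 0], pos[k, 1], pos[k, 2])


@njit(cache=True, inline="always")
def _tri_normal_sub(pos, tri, t, v, px, py, pz):
    i, j, k = tri[t, 0], tri[t, 1], tri[t, 2]
    ax, ay, az = _vert_sub(pos, i, v, px, py, pz)
    bx, by, bz = _vert_sub(pos, j, v, px, py, pz)
    cx, cy, cz = _vert_sub(pos, k, v, px, py, pz)
    return _normal_of(ax, ay, az, bx, by, bz, cx, cy, cz)


# ---------------------------------------------------------------------------
# total energy
# ---------------------------------------------------------------------------

@njit(cache=True)
def _total_energy(pos, tri, sigma, bond_v, bond_tri, c, model2):
    nt = tri.shape[0]
    nb = bond_v.shape[0]
    normals = np.empty((nt, 3), dtype=np.float64)
    bad = np.int64(-1)
    for t in range(nt):
        nx, ny, nz, n2 = _tri_normal(pos, tri, t)
        if n2 < DEGENERATE_NORMAL2:
            bad = t
        normals[t, 0] = nx
        normals[t, 1] = ny
        normals[t, 2] = nz
    s0 = 0.0
    s1 = 0.0
    s2 = 0.0
    for b in range(nb):
        u, w = bond_v[b, 0], bond_v[b, 1]
        t0, t1 = bond_tri[b, 0], bond_tri[b, 1]
        si, sj = sigma[t0], sigma[t1]
        dx = pos[u, 0] - pos[w, 0]
        dy = pos[u, 1] - pos[w, 1]
        dz = pos[u, 2] - pos[w, 2]
        l2 = dx * dx + dy * dy + dz * dz
        s0 += 1.0 - si * sj
        s1 += _gamma_ij(si, sj, c, model2) * l2
        dot = (normals[t0, 0] * normals[t1, 0] + normals[t0, 1] * normals[t1, 1]
               + normals[t0, 2] * normals[t1, 2])
        s2 += _kappa_ij(si, sj, c) * (1.0 - dot)
    return s0, s1, s2, bad


def total_energy(surface: TriSurface, params: ModelParams) -> EnergyBreakdown:
    """Full recompute of (S0, S1, S2) over all bonds."""
    s0, s1, s2, bad = _total_energy(surface.pos, surface.tri, surface.sigma,
                                    surface.bond_v, surface.bond_tri,
                                    params.c, params.is_model2)
    if bad >= 0:
        raise ValueError(f"degenerate (zero-area) triangle {bad}: normal undefined")
    return EnergyBreakdown(s0=float(s0), s1=float(s1), s2=float(s2),
                           lambda_=params.lambda_, kappa=params.kappa)


# ---------------------------------------------------------------------------
# local energy differences
# ---------------------------------------------------------------------------

@njit(cache=True)
def _delta_vertex(pos, tri, sigma, bond_v, bond_tri, tri_bonds, v_tris, v_nt,
                  v, px, py, pz, c, model2, scratch):
    """(dS1, dS2, ok) for moving vertex v to (px, py, pz).

    Only bonds of the star triangles of v contribute; S0 cannot change.
    ok = False marks a degenerate proposed triangle (auto-reject).
    """
    nt_star = v_nt[v]
    m = 0
    for idx in range(nt_star):
        t = v_tris[v, idx]
        for e in range(3):
            b = tri_bonds[t, e]
            seen = False
            for q in range(m):
                if scratch[q] == b:
                    seen = True
                    break
            if not seen:
                scratch[m] = b
                m += 1
    d1 = 0.0
    d2 = 0.0
    for q in range(m):
        b = scratch[q]
        u, w = bond_v[b, 0], bond_v[b, 1]
        t0, t1 = bond_tri[b, 0], bond_tri[b, 1]
        si, sj = sigma[t0], sigma[t1]
        gam = _gamma_ij(si, sj, c, model2)
        kij = _kappa_ij(si, sj, c)
        # before
        dx = pos[u, 0] - pos[w, 0]
        dy = pos[u, 1] - pos[w, 1]
        dz = pos[u, 2] - pos[w, 2]
        l2b = dx * dx + dy * dy + dz * dz
        n0x, n0y, n0z, _ = _tri_normal(pos, tri, t0)
        n1x, n1y, n1z, _ = _tri_normal(pos, tri, t1)
        d1 -= gam * l2b
        d2 -= kij * (1.0 - (n0x * n1x + n0y * n1y + n0z * n1z))
        # after (vertex v virtually at p)
        ux, uy, uz = _vert_sub(pos, u, v, px, py, pz)
        wx, wy, wz = _vert_sub(pos, w, v, px, py, pz)
        dx = ux - wx
        dy = uy - wy
        dz = uz - wz
        l2a = dx * dx + dy * dy + dz * dz
        n0x, n0y, n0z, n2a = _tri_normal_sub(pos, tri, t0, v, px, py, pz)
        if n2a < DEGENERATE_NORMAL2:
            return 0.0, 0.0, False
        n1x, n1y, n1z, n2b = _tri_normal_sub(pos, tri, t1, v, px, py, pz)
        if n2b < DEGENERATE_NORMAL2:
            return 0.0, 0.0, False
        d1 += gam * l2a
        d2 += kij * (1.0 - (n0x * n1x + n0y * n1y + n0z * n1z))
    return d1, d2, True


@njit(cache=True, inline="always")
def _pair_terms(l2, si, sj, dot, c, model2):
    s0 = 1.0 - si * sj
    s1 = _gamma_ij(si, sj, c, model2) * l2
    s2 = _kappa_ij(si, sj, c) * (1.0 - dot)
    return s0, s1, s2


@njit(cache=True)
def _delta_flip(pos, tri, sigma, bond_v, bond_tri, v_bonds, v_nb,
                b, sn0, sn1, c, model2):
    """(dS0, dS1, dS2, ok) for flipping bond b with new labels (sn0, sn1).

    Only the five-bond quadrilateral patch contributes: the flipped diagonal
    plus its four boundary bonds (whose coefficients and normals change).
    ok = False marks a degenerate post-flip triangle (auto-reject).
    """
    u, w, t0, t1, a, cc = _flip_geometry(tri, bond_v, bond_tri, b)
    b_wa = _find_bond(v_bonds, v_nb, bond_v, w, a)
    b_au = _find_bond(v_bonds, v_nb, bond_v, a, u)
    b_uc = _find_bond(v_bonds, v_nb, bond_v, u, cc)
    b_cw = _find_bond(v_bonds, v_nb, bond_v, cc, w)

    d0 = 0.0
    d1 = 0.0
    d2 = 0.0
    # --- before: exact bond terms from the current tables -----------------
    patch = (b, b_wa, b_au, b_uc, b_cw)
    for q in range(5):
        pb = patch[q]
        pu, pw = bond_v[pb, 0], bond_v[pb, 1]
        pt0, pt1 = bond_tri[pb, 0], bond_tri[pb, 1]
        dx = pos[pu, 0] - pos[pw, 0]
        dy = pos[pu, 1] - pos[pw, 1]
        dz = pos[pu, 2] - pos[pw, 2]
        l2 = dx * dx + dy * dy + dz * dz
        n0x, n0y, n0z, _ = _tri_normal(pos, tri, pt0)
        n1x, n1y, n1z, _ = _tri_normal(pos, tri, pt1)
        dot = n0x * n1x + n0y * n1y + n0z * n1z
        e0, e1, e2 = _pair_terms(l2, sigma[pt0], sigma[pt1], dot, c, model2)
        d0 -= e0
        d1 -= e1
        d2 -= e2

    # --- after: new triangles t0' = (a, u, c), t1' = (c, w, a) -------------
    m0x, m0y, m0z, q0 = _normal_of(pos[a, 0], pos[a, 1], pos[a, 2],
                                   pos[u, 0], pos[u, 1], pos[u, 2],
                                   pos[cc, 0], pos[cc, 1], pos[cc, 2])
    if q0 < DEGENERATE_NORMAL2:
        return 0.0, 0.0, 0.0, False
    m1x, m1y, m1z, q1 = _normal_of(pos[cc, 0], pos[cc, 1], pos[cc, 2],
                                   pos[w, 0], pos[w, 1], pos[w, 2],
                                   pos[a, 0], pos[a, 1], pos[a, 2])
    if q1 < DEGENERATE_NORMAL2:
        return 0.0, 0.0, 0.0, False
    # new diagonal a-c, between t0' and t1'
    dx = pos[a, 0] - pos[cc, 0]
    dy = pos[a, 1] - pos[cc, 1]
    dz = pos[a, 2] - pos[cc, 2]
    l2 = dx * dx + dy * dy + dz * dz
    dot = m0x * m1x + m0y * m1y + m0z * m1z
    e0, e1, e2 = _pair_terms(l2, sn0, sn1, dot, c, model2)
    d0 += e0
    d1 += e1
    d2 += e2
    # the four boundary bonds: outer triangle unchanged, inner one replaced
    for q in range(4):
        if q == 0:  # (w, a) now borders t1'
            pb, old_inner, snew = b_wa, t0, sn1
            mx, my, mz = m1x, m1y, m1z
        elif q == 1:  # (a, u) still borders t0'
            pb, old_inner, snew = b_au, t0, sn0
            mx, my, mz = m0x, m0y, m0z
        elif q == 2:  # (u, c) now borders t0'
            pb, old_inner, snew = b_uc, t1, sn0
            mx, my, mz = m0x, m0y, m0z
        else:  # (c, w) still borders t1'
            pb, old_inner, snew = b_cw, t1, sn1
            mx, my, mz = m1x, m1y, m1z
        t_out = bond_tri[pb, 0]
        if t_out == old_inner:
            t_out = bond_tri[pb, 1]
        pu, pw = bond_v[pb, 0], bond_v[pb, 1]
        dx = pos[pu, 0] - pos[pw, 0]
        dy = pos[pu, 1] - pos[pw, 1]
        dz = pos[pu, 2] - pos[pw, 2]
        l2 = dx * dx + dy * dy + dz * dz
        ox, oy, oz, _ = _tri_normal(pos, tri, t_out)
        dot = mx * ox + my * oy + mz * oz
        e0, e1, e2 = _pair_terms(l2, snew, sigma[t_out], dot, c, model2)
        d0 += e0
        d1 += e1
        d2 += e2
    return d0, d1, d2, True


# ---------------------------------------------------------------------------
# public wrappers
# ---------------------------------------------------------------------------

def delta_energy_vertex_move(surface: TriSurface, params: ModelParams,
                             vertex_id: int, new_position: np.ndarray) -> float:
    """Exact delta S for moving one vertex; +inf for a degenerate proposal."""
    if not 0 <= vertex_id < surface.n_vertices:
        raise IndexError(f"no vertex {vertex_id}")
    p = np.asarray(new_position, dtype=np.float64)
    scratch = np.empty(3 * MAX_DEGREE, dtype=np.int64)
    d1, d2, ok = _delta_vertex(surface.pos, surface.tri, surface.sigma,
                               surface.bond_v, surface.bond_tri,
                               surface.tri_bonds, surface.v_tris, surface.v_nt,
                               vertex_id, p[0], p[1], p[2],
                               params.c, params.is_model2, scratch)
    if not ok:
        return math.inf
    return float(d1 + params.kappa * d2)


def delta_energy_flip(surface: TriSurface, params: ModelParams,
                      proposal: FlipProposal) -> float:
    """Exact delta S for a flip proposal; +inf for a degenerate proposal."""
    d0, d1, d2, ok = _delta_flip(surface.pos, surface.tri, surface.sigma,
                                 surface.bond_v, surface.bond_tri,
                                 surface.v_bonds, surface.v_nb,
                                 proposal.bond,
                                 np.int64(proposal.sigma_new[0]),
                                 np.int64(proposal.sigma_new[1]),
                                 params.c, params.is_model2)
    if not ok:
        return math.inf
    return float(params.lambda_ * d0 + d1 + params.kappa * d2)
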