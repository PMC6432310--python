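"""Closed triangulated spheres with fluid (bond-flip) connectivity.

The surface is a genus-0 triangulation of the sphere: ``N`` vertices,
``NT = 2N - 4`` triangles and ``NB = 3N - 6`` bonds, with a binary phase
label sigma = +1 (liquid-ordered, Lo) or -1 (liquid-disordered, Ld) carried
by every *triangle*.  Connectivity changes only through bond flips, which
replace the shared diagonal of two adjacent triangles by the opposite
diagonal; vertex and triangle counts are conserved, and so is the number of
Lo triangles.

All tables are flat numpy arrays so that the Monte Carlo kernels (numba)
can mutate them in place:

==============  ======================================================
``pos``         (N, 3) float64 vertex positions
``tri``         (NT, 3) int64 vertex triples, counter-clockwise seen
                from outside (outward normals)
``sigma``       (NT,) int64 phase label, +1 Lo / -1 Ld
``bond_v``      (NB, 2) int64 vertex endpoints
``bond_tri``    (NB, 2) int64 the two incident triangles
``tri_bonds``   (NT, 3) int64; entry k is the bond of the directed edge
                ``tri[t, k] -> tri[t, (k+1) % 3]``
``v_bonds``     (N, MAX_DEGREE) int64 incident bonds, first ``v_nb[v]``
                entries valid
``v_tris``      (N, MAX_DEGREE) int64 incident triangles, first
                ``v_nt[v]`` entries valid
==============  ======================================================

Vertex coordination is capped at ``MAX_DEGREE``; flips that would exceed
the cap are rejected along with the standard fluid-mesh guards
(duplicate diagonal, coordination < 3).
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
from numba import njit

MAX_DEGREE = 24

__all__ = [
    "MAX_DEGREE",
    "TriSurface",
    "FlipProposal",
    "build_icosphere",
    "build_tetrahedron",
    "assign_sigma_random",
    "flip_candidate",
    "apply_flip",
    "revert_flip",
    "flip_storm",
]


# ---------------------------------------------------------------------------
# surface container
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TriSurface:
    """A closed, oriented triangulated sphere with per-triangle phase labels."""

    pos: np.ndarray
    tri: np.ndarray
    sigma: np.ndarray
    bond_v: np.ndarray
    bond_tri: np.ndarray
    tri_bonds: np.ndarray
    v_bonds: np.ndarray
    v_nb: np.ndarray
    v_tris: np.ndarray
    v_nt: np.ndarray

    # -- counts ------------------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return self.pos.shape[0]

    @property
    def n_triangles(self) -> int:
        return self.tri.shape[0]

    @property
    def n_bonds(self) -> int:
        return self.bond_v.shape[0]

    @property
    def n_lo(self) -> int:
        """Number of liquid-ordered (sigma = +1) triangles."""
        return int(np.sum(self.sigma > 0))

    @property
    def n_ld(self) -> int:
        return int(np.sum(self.sigma < 0))

    @property
    def euler_characteristic(self) -> int:
        return self.n_vertices - self.n_bonds + self.n_triangles

    # -- construction ------------------------------------------------------
    @classmethod
    def from_triangles(cls, pos: np.ndarray, tri: np.ndarray,
                       sigma: Optional[np.ndarray] = None) -> "TriSurface":
        """Build the full adjacency bookkeeping from positions and triangles.

        Raises ``ValueError`` if the triangle soup is not a closed oriented
        2-manifold (every edge shared by exactly two triangles, traversed
        once in each direction).
        """
        pos = np.ascontiguousarray(pos, dtype=np.float64)
        tri = np.ascontiguousarray(tri, dtype=np.int64)
        n = pos.shape[0]
        nt = tri.shape[0]
        if sigma is None:
            sigma = np.ones(nt, dtype=np.int64)
        else:
            sigma = np.ascontiguousarray(sigma, dtype=np.int64)
            if sigma.shape != (nt,) or not np.all(np.abs(sigma) == 1):
                raise ValueError("sigma must be one label in {+1,-1} per triangle")

        edge_first: dict[tuple[int, int], int] = {}  # directed (u,w) -> bond
        bond_v: list[list[int]] = []
        bond_tri: list[list[int]] = []
        tri_bonds = np.full((nt, 3), -1, dtype=np.int64)
        for t in range(nt):
            a, b, c = tri[t]
            if a == b or b == c or a == c:
                raise ValueError(f"triangle {t} has a repeated vertex")
            for k in range(3):
                u = int(tri[t, k])
                w = int(tri[t, (k + 1) % 3])
                if (u, w) in edge_first:
                    raise ValueError(
                        f"directed edge {u}->{w} traversed twice: inconsistent winding")
                if (w, u) in edge_first:
                    bidx = edge_first[(w, u)]
                    if bond_tri[bidx][1] != -1:
                        raise ValueError(f"edge {{{u},{w}}} shared by >2 triangles")
                    bond_tri[bidx][1] = t
                else:
                    bidx = len(bond_v)
                    bond_v.append([u, w])
                    bond_tri.append([t, -1])
                edge_first[(u, w)] = bidx
                tri_bonds[t, k] = bidx
        for bidx, (t0, t1) in enumerate(bond_tri):
            if t1 == -1:
                raise ValueError(f"boundary edge {bond_v[bidx]}: surface is not closed")

        nb = len(bond_v)
        bond_v_arr = np.array(bond_v, dtype=np.int64)
        bond_tri_arr = np.array(bond_tri, dtype=np.int64)

        v_nb = np.zeros(n, dtype=np.int64)
        v_bonds = np.full((n, MAX_DEGREE), -1, dtype=np.int64)
        for bidx in range(nb):
            for v in bond_v_arr[bidx]:
                if v_nb[v] >= MAX_DEGREE:
                    raise ValueError(f"vertex {v} exceeds MAX_DEGREE={MAX_DEGREE}")
                v_bonds[v, v_nb[v]] = bidx
                v_nb[v] += 1
        v_nt = np.zeros(n, dtype=np.int64)
        v_tris = np.full((n, MAX_DEGREE), -1, dtype=np.int64)
        for t in range(nt):
            for v in tri[t]:
                v_tris[v, v_nt[v]] = t
                v_nt[v] += 1
        if np.any(v_nb < 3):
            raise ValueError("vertex with coordination < 3")
        return cls(pos, tri, sigma, bond_v_arr, bond_tri_arr, tri_bonds,
                   v_bonds, v_nb, v_tris, v_nt)

    def copy(self) -> "TriSurface":
        return TriSurface(*(np.copy(getattr(self, f.name))
                            for f in dataclasses.fields(self)))

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        """Check every structural invariant; raise ``ValueError`` on failure."""
        n, nt, nb = self.n_vertices, self.n_triangles, self.n_bonds
        if nt != 2 * n - 4 or nb != 3 * n - 6:
            raise ValueError(f"sphere counts violated: N={n}, NT={nt}, NB={nb}")
        if self.euler_characteristic != 2:
            raise ValueError("Euler characteristic != 2")
        if not np.all(np.abs(self.sigma) == 1):
            raise ValueError("sigma outside {+1,-1}")
        # rebuild adjacency independently and compare canonical forms
        ref = TriSurface.from_triangles(self.pos, self.tri, self.sigma)

        def canon_bonds(s: TriSurface) -> set[tuple[int, int]]:
            return {(min(u, w), max(u, w)) for u, w in s.bond_v}

        if canon_bonds(ref) != canon_bonds(self):
            raise ValueError("bond table does not match triangle table")
        # per-bond incidence
        for b in range(nb):
            u, w = self.bond_v[b]
            for t in self.bond_tri[b]:
                verts = set(self.tri[t])
                if u not in verts or w not in verts:
                    raise ValueError(f"bond {b} not an edge of its incident triangle {t}")
            t0, t1 = self.bond_tri[b]
            if t0 == t1:
                raise ValueError(f"bond {b} lists the same triangle twice")
        # tri_bonds consistency
        for t in range(nt):
            for k in range(3):
                b = self.tri_bonds[t, k]
                e = {self.tri[t, k], self.tri[t, (k + 1) % 3]}
                if set(self.bond_v[b]) != e:
                    raise ValueError(f"tri_bonds[{t},{k}] does not match edge")
                if t not in self.bond_tri[b]:
                    raise ValueError(f"triangle {t} missing from bond_tri[{b}]")
        # vertex tables
        if np.any(self.v_nb < 3):
            raise ValueError("vertex coordination < 3")
        for v in range(n):
            bs = set(self.v_bonds[v, :self.v_nb[v]].tolist())
            ref_bs = {b for b in range(nb) if v in self.bond_v[b]}
            if bs != ref_bs:
                raise ValueError(f"v_bonds wrong at vertex {v}")
            ts = set(self.v_tris[v, :self.v_nt[v]].tolist())
            ref_ts = {t for t in range(nt) if v in self.tri[t]}
            if ts != ref_ts:
                raise ValueError(f"v_tris wrong at vertex {v}")


# ---------------------------------------------------------------------------
# lattice construction
# ---------------------------------------------------------------------------

def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array([
        [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
        [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
        [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
    ], dtype=np.float64)
    verts /= np.linalg.norm(verts[0])
    faces = np.array([
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ], dtype=np.int64)
    # enforce outward winding (convex body centred at the origin)
    for i, (a, b, c) in enumerate(faces):
        nrm = np.cross(verts[b] - verts[a], verts[c] - verts[a])
        if np.dot(nrm, verts[a] + verts[b] + verts[c]) < 0:
            faces[i, 1], faces[i, 2] = faces[i, 2], faces[i, 1]
    return verts, faces


def build_icosphere(subdivision: int, *, mean_bond_length: float = 0.7,
                    radius: Optional[float] = None) -> TriSurface:
    """Geodesic icosphere of frequency ``subdivision`` (N = 10 l^2 + 2).

    Each icosahedron edge is split into ``subdivision`` segments and the
    lattice is projected to a sphere.  By default the sphere is scaled so
    the mean bond length is ``mean_bond_length`` (model units); the
    partition function is scale invariant, so the initial radius only sets
    the starting point of thermalization.  All triangles start as Lo
    (sigma = +1).
    """
    if subdivision < 1:
        raise ValueError("subdivision must be >= 1")
    f = int(subdivision)
    verts, faces = _icosahedron()
    if f == 1:
        pts = [v for v in verts]
        tris = [tuple(t) for t in faces]
    else:
        pts = [v.copy() for v in verts]
        edge_idx: dict[tuple[int, int, int], int] = {}

        def epoint(g1: int, g2: int, k: int) -> int:
            # point k/f of the way from g1 to g2, welded across faces
            if g1 > g2:
                g1, g2, k = g2, g1, f - k
            key = (g1, g2, k)
            if key not in edge_idx:
                edge_idx[key] = len(pts)
                pts.append(((f - k) * verts[g1] + k * verts[g2]) / f)
            return edge_idx[key]

        tris = []
        for ia, ib, ic in faces:
            idx = {}
            for i in range(f + 1):
                for j in range(f + 1 - i):
                    h = f - i - j
                    if (i, j) == (0, 0):
                        g = int(ia)
                    elif (i, j) == (f, 0):
                        g = int(ib)
                    elif (i, j) == (0, f):
                        g = int(ic)
                    elif j == 0:
                        g = epoint(int(ia), int(ib), i)
                    elif i == 0:
                        g = epoint(int(ia), int(ic), j)
                    elif h == 0:
                        g = epoint(int(ib), int(ic), j)
                    else:
                        g = len(pts)
                        pts.append((h * verts[ia] + i * verts[ib] + j * verts[ic]) / f)
                    idx[(i, j)] = g
            for i in range(f):
                for j in range(f - i):
                    tris.append((idx[(i, j)], idx[(i + 1, j)], idx[(i, j + 1)]))
                    if i + j < f - 1:
                        tris.append((idx[(i + 1, j)], idx[(i + 1, j + 1)],
                                     idx[(i, j + 1)]))
    pos = np.asarray(pts, dtype=np.float64)
    pos /= np.linalg.norm(pos, axis=1)[:, None]
    tri = np.asarray(tris, dtype=np.int64)
    surf = TriSurface.from_triangles(pos, tri)
    if radius is None:
        d = surf.pos[surf.bond_v[:, 0]] - surf.pos[surf.bond_v[:, 1]]
        radius = mean_bond_length / float(np.mean(np.linalg.norm(d, axis=1)))
    surf.pos *= radius
    return surf


def build_tetrahedron(edge: float = 1.0) -> TriSurface:
    """Regular tetrahedron (the minimal closed triangulation), for tests."""
    pos = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                   dtype=np.float64)
    pos *= edge / np.sqrt(8.0)
    tri = np.array([[0, 1, 2], [0, 2, 3], [0, 3, 1], [1, 3, 2]], dtype=np.int64)
    # fix outward winding
    for i, (a, b, c) in enumerate(tri):
        nrm = np.cross(pos[b] - pos[a], pos[c] - pos[a])
        if np.dot(nrm, pos[a] + pos[b] + pos[c]) < 0:
            tri[i, 1], tri[i, 2] = tri[i, 2], tri[i, 1]
    return TriSurface.from_triangles(pos, tri)


def assign_sigma_random(surface: TriSurface, phi0: float,
                        rng: np.random.Generator) -> TriSurface:
    """Randomly label exactly ``round(phi0 * NT)`` triangles as Lo (in place).

    This is the random two-phase coexistence initial condition: Lo triangles
    uniformly scattered at the fixed composition phi0 = NTo / NT.
    """
    if not 0.0 <= phi0 <= 1.0:
        raise ValueError(f"phi0 must be in [0, 1], got {phi0}")
    nt = surface.n_triangles
    nto = int(round(phi0 * nt))
    surface.sigma[:] = -1
    lo = rng.choice(nt, size=nto, replace=False)
    surface.sigma[lo] = 1
    return surface


# ---------------------------------------------------------------------------
# numba flip primitives (shared by the public API and the MC kernel)
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _find_bond(v_bonds, v_nb, bond_v, u, w):
    """Bond id joining vertices u and w, or -1."""
    for k in range(v_nb[u]):
        b = v_bonds[u, k]
        if bond_v[b, 0] + bond_v[b, 1] - u == w:
            return b
    return np.int64(-1)


@njit(cache=True, inline="always")
def _third_vertex(tri, t, u, w):
    for k in range(3):
        x = tri[t, k]
        if x != u and x != w:
            return x
    return np.int64(-1)


@njit(cache=True, inline="always")
def _traverses(tri, t, u, w):
    """True if triangle t contains the directed edge u -> w."""
    for k in range(3):
        if tri[t, k] == u and tri[t, (k + 1) % 3] == w:
            return True
    return False


@njit(cache=True)
def _flip_geometry(tri, bond_v, bond_tri, b):
    """Resolve the flip quadrilateral of bond b.

    Returns (u, w, t0, t1, a, c) where t0 = (u, w, a) traverses u -> w and
    t1 = (w, u, c) traverses w -> u (both cyclically); (a, c) is the new
    diagonal.  After the flip: t0 = (a, u, c), t1 = (c, w, a).
    """
    u = bond_v[b, 0]
    w = bond_v[b, 1]
    ta = bond_tri[b, 0]
    tb = bond_tri[b, 1]
    if _traverses(tri, ta, u, w):
        t0, t1 = ta, tb
    else:
        t0, t1 = tb, ta
    a = _third_vertex(tri, t0, u, w)
    c = _third_vertex(tri, t1, u, w)
    return u, w, t0, t1, a, c


@njit(cache=True)
def _flip_legal(tri, bond_v, bond_tri, v_bonds, v_nb, b):
    u, w, t0, t1, a, c = _flip_geometry(tri, bond_v, bond_tri, b)
    if t0 == t1 or a < 0 or c < 0 or a == c:
        return False
    if v_nb[u] <= 3 or v_nb[w] <= 3:
        return False
    if v_nb[a] >= MAX_DEGREE or v_nb[c] >= MAX_DEGREE:
        return False
    if _find_bond(v_bonds, v_nb, bond_v, a, c) >= 0:
        return False
    return True


@njit(cache=True, inline="always")
def _vlist_remove(table, counts, v, value):
    n = counts[v]
    for k in range(n):
        if table[v, k] == value:
            table[v, k] = table[v, n - 1]
            table[v, n - 1] = -1
            counts[v] = n - 1
            return


@njit(cache=True)
def _apply_flip(tri, sigma, bond_v, bond_tri, tri_bonds,
                v_bonds, v_nb, v_tris, v_nt, b, s_new0, s_new1):
    """Flip bond b in place; caller guarantees legality."""
    u, w, t0, t1, a, c = _flip_geometry(tri, bond_v, bond_tri, b)
    b_wa = _find_bond(v_bonds, v_nb, bond_v, w, a)
    b_au = _find_bond(v_bonds, v_nb, bond_v, a, u)
    b_uc = _find_bond(v_bonds, v_nb, bond_v, u, c)
    b_cw = _find_bond(v_bonds, v_nb, bond_v, c, w)
    # new triangles keep the boundary edge directions of the old ones
    tri[t0, 0] = a
    tri[t0, 1] = u
    tri[t0, 2] = c
    tri[t1, 0] = c
    tri[t1, 1] = w
    tri[t1, 2] = a
    sigma[t0] = s_new0
    sigma[t1] = s_new1
    bond_v[b, 0] = a
    bond_v[b, 1] = c
    for k in range(2):
        if bond_tri[b_wa, k] == t0:
            bond_tri[b_wa, k] = t1
        if bond_tri[b_uc, k] == t1:
            bond_tri[b_uc, k] = t0
    tri_bonds[t0, 0] = b_au
    tri_bonds[t0, 1] = b_uc
    tri_bonds[t0, 2] = b
    tri_bonds[t1, 0] = b_cw
    tri_bonds[t1, 1] = b_wa
    tri_bonds[t1, 2] = b
    _vlist_remove(v_bonds, v_nb, u, b)
    _vlist_remove(v_bonds, v_nb, w, b)
    v_bonds[a, v_nb[a]] = b
    v_nb[a] += 1
    v_bonds[c, v_nb[c]] = b
    v_nb[c] += 1
    _vlist_remove(v_tris, v_nt, u, t1)
    _vlist_remove(v_tris, v_nt, w, t0)
    v_tris[a, v_nt[a]] = t1
    v_nt[a] += 1
    v_tris[c, v_nt[c]] = t0
    v_nt[c] += 1


@njit(cache=True)
def _flip_storm(tri, sigma, bond_v, bond_tri, tri_bonds,
                v_bonds, v_nb, v_tris, v_nt, n_attempts, seed):
    """Accept every topologically legal flip for n_attempts random bonds.

    Pure connectivity stress (no energy); returns the number accepted.
    """
    np.random.seed(seed)
    nb = bond_v.shape[0]
    n_acc = 0
    for _ in range(n_attempts):
        b = np.random.randint(nb)
        if not _flip_legal(tri, bond_v, bond_tri, v_bonds, v_nb, b):
            continue
        u, w, t0, t1, a, c = _flip_geometry(tri, bond_v, bond_tri, b)
        s0 = sigma[t0]
        s1 = sigma[t1]
        if s0 == s1:
            sn0, sn1 = s0, s1
        elif np.random.random() < 0.5:
            sn0, sn1 = np.int64(1), np.int64(-1)
        else:
            sn0, sn1 = np.int64(-1), np.int64(1)
        _apply_flip(tri, sigma, bond_v, bond_tri, tri_bonds,
                    v_bonds, v_nb, v_tris, v_nt, b, sn0, sn1)
        n_acc += 1
    return n_acc


# ---------------------------------------------------------------------------
# public flip API
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class FlipProposal:
    """A legal bond flip: new diagonal, new sigma pair, and undo snapshot."""

    bond: int
    triangles: tuple[int, int]
    old_diagonal: tuple[int, int]
    new_diagonal: tuple[int, int]
    sigma_old: tuple[int, int]
    sigma_new: tuple[int, int]
    _undo: Optional[dict] = dataclasses.field(default=None, repr=False)


def flip_candidate(surface: TriSurface, bond_id: int,
                   rng: Optional[np.random.Generator] = None) -> Optional[FlipProposal]:
    """Propose flipping ``bond_id``; ``None`` if topologically illegal.

    The new triangles inherit sigma from the old pair: equal labels are kept;
    unequal labels are reassigned to a random side (drawn from ``rng``), so
    the Lo triangle count is conserved either way.
    """
    if not 0 <= bond_id < surface.n_bonds:
        raise IndexError(f"no bond {bond_id}")
    if not _flip_legal(surface.tri, surface.bond_v, surface.bond_tri,
                       surface.v_bonds, surface.v_nb, bond_id):
        return None
    u, w, t0, t1, a, c = _flip_geometry(surface.tri, surface.bond_v,
                                        surface.bond_tri, bond_id)
    s0 = int(surface.sigma[t0])
    s1 = int(surface.sigma[t1])
    if s0 == s1:
        s_new = (s0, s1)
    else:
        if rng is None:
            rng = np.random.default_rng()
        s_new = (1, -1) if rng.random() < 0.5 else (-1, 1)
    return FlipProposal(bond=int(bond_id), triangles=(int(t0), int(t1)),
                        old_diagonal=(int(u), int(w)),
                        new_diagonal=(int(a), int(c)),
                        sigma_old=(s0, s1), sigma_new=s_new)


def apply_flip(surface: TriSurface, proposal: FlipProposal) -> TriSurface:
    """Apply a proposal in place, recording an exact undo snapshot."""
    b = proposal.bond
    t0, t1 = proposal.triangles
    u, w = proposal.old_diagonal
    a, c = proposal.new_diagonal
    if (set(surface.bond_v[b]) != {u, w} or set(surface.bond_tri[b]) != {t0, t1}):
        raise ValueError("proposal is stale: surface changed since flip_candidate")
    quad_bonds = [b]
    for x, y in ((w, a), (a, u), (u, c), (c, w)):
        qb = int(_find_bond(surface.v_bonds, surface.v_nb, surface.bond_v, x, y))
        if qb < 0:
            raise ValueError("proposal inconsistent with surface connectivity")
        quad_bonds.append(qb)
    verts = (u, w, a, c)
    proposal._undo = {
        "tri": (surface.tri[t0].copy(), surface.tri[t1].copy()),
        "sigma": (int(surface.sigma[t0]), int(surface.sigma[t1])),
        "tri_bonds": (surface.tri_bonds[t0].copy(), surface.tri_bonds[t1].copy()),
        "bond_v": {qb: surface.bond_v[qb].copy() for qb in quad_bonds},
        "bond_tri": {qb: surface.bond_tri[qb].copy() for qb in quad_bonds},
        "v_bonds": {v: (surface.v_bonds[v].copy(), int(surface.v_nb[v])) for v in verts},
        "v_tris": {v: (surface.v_tris[v].copy(), int(surface.v_nt[v])) for v in verts},
    }
    _apply_flip(surface.tri, surface.sigma, surface.bond_v, surface.bond_tri,
                surface.tri_bonds, surface.v_bonds, surface.v_nb,
                surface.v_tris, surface.v_nt, b,
                np.int64(proposal.sigma_new[0]), np.int64(proposal.sigma_new[1]))
    return surface


def revert_flip(surface: TriSurface, proposal: FlipProposal) -> TriSurface:
    """Restore the exact pre-flip state recorded by :func:`apply_flip`."""
    undo = proposal._undo
    if undo is None:
        raise ValueError("proposal was never applied")
    t0, t1 = proposal.triangles
    surface.tri[t0], surface.tri[t1] = undo["tri"]
    surface.sigma[t0], surface.sigma[t1] = undo["sigma"]
    surface.tri_bonds[t0], surface.tri_bonds[t1] = undo["tri_bonds"]
    for qb, row in undo["bond_v"].items():
        surface.bond_v[qb] = row
    for qb, row in undo["bond_tri"].items():
        surface.bond_tri[qb] = row
    for v, (row, cnt) in undo["v_bonds"].items():
        surface.v_bonds[v] = row
        surface.v_nb[v] = cnt
    for v, (row, cnt) in undo["v_tris"].items():
        surface.v_tris[v] = row
        surface.v_nt[v] = cnt
    proposal._undo = None
    return surface


def flip_storm(surface: TriSurface, n_attempts: int, seed: int) -> int:
    """Run ``n_attempts`` random legal flips in place (topology stress test)."""
    return int(_flip_storm(surface.tri, surface.sigma, surface.bond_v,
                           surface.bond_tri, surface.tri_bonds,
                           surface.v_bonds, surface.v_nb,
                           surface.v_tris, surface.v_nt,
                           n_attempts, seed))
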