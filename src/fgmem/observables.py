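"""Shape, energy, and domain-morphology observables.

Shape is summarized by three diameters D1 >= D2 >= D3, the full extents of
the vertex cloud along the principal axes of its gyration tensor: prolate
(elongated) surfaces have D1 > D2 ~ D3, oblate (flattened) ones
D1 ~ D2 > D3, so the middle diameter D2 discriminates stripe from
two-circular morphologies.  Domains are connected components of
same-phase triangles under bond adjacency; the boundary-bond count equals
S0 / 2 exactly.  The morphology classifier operationalizes the phase names
(random / circular / stripe / raft / budding) from the component
statistics with documented thresholds.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .energy import EnergyBreakdown
from .mesh import TriSurface

__all__ = [
    "DomainStats",
    "MorphologyLabel",
    "MorphologyThresholds",
    "ObservableRecord",
    "semi_axes",
    "domain_components",
    "triangle_areas",
    "mean_triangle_areas",
    "area_fraction_lo",
    "classify_morphology",
    "measure",
]


# ---------------------------------------------------------------------------
# shape
# ---------------------------------------------------------------------------

def semi_axes(surface: TriSurface) -> tuple[float, float, float]:
    """Diameters (D1, D2, D3), descending, along gyration-tensor axes."""
    x = surface.pos - surface.pos.mean(axis=0)
    gyr = x.T @ x / x.shape[0]
    _, vecs = np.linalg.eigh(gyr)
    proj = x @ vecs
    extents = proj.max(axis=0) - proj.min(axis=0)
    d3, d2, d1 = np.sort(extents)
    return float(d1), float(d2), float(d3)


# ---------------------------------------------------------------------------
# domains
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class DomainStats:
    """Connected same-phase triangle components and boundary statistics."""

    lo_sizes: tuple[int, ...]       # component sizes, descending
    ld_sizes: tuple[int, ...]
    boundary_bonds: int             # number of (Lo, Ld) bonds (= S0 / 2)
    labels: np.ndarray              # per-triangle component id

    @property
    def n_lo_components(self) -> int:
        return len(self.lo_sizes)

    @property
    def n_ld_components(self) -> int:
        return len(self.ld_sizes)


def domain_components(surface: TriSurface) -> DomainStats:
    """Flood-fill triangles across bonds joining equal sigma."""
    nt = surface.n_triangles
    t0 = surface.bond_tri[:, 0]
    t1 = surface.bond_tri[:, 1]
    same = surface.sigma[t0] == surface.sigma[t1]
    adj = sp.coo_matrix((np.ones(int(same.sum())),
                         (t0[same], t1[same])), shape=(nt, nt))
    n_comp, labels = connected_components(adj, directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    comp_sigma = np.empty(n_comp, dtype=np.int64)
    comp_sigma[labels] = surface.sigma
    lo = sorted((int(s) for s in sizes[comp_sigma > 0]), reverse=True)
    ld = sorted((int(s) for s in sizes[comp_sigma < 0]), reverse=True)
    return DomainStats(lo_sizes=tuple(lo), ld_sizes=tuple(ld),
                       boundary_bonds=int((~same).sum()), labels=labels)


def triangle_areas(surface: TriSurface) -> np.ndarray:
    p = surface.pos
    t = surface.tri
    cross = np.cross(p[t[:, 1]] - p[t[:, 0]], p[t[:, 2]] - p[t[:, 0]])
    return 0.5 * np.linalg.norm(cross, axis=1)


def mean_triangle_areas(surface: TriSurface) -> tuple[Optional[float], Optional[float]]:
    """Mean triangle area (a_o, a_d) per phase; None for an empty phase."""
    areas = triangle_areas(surface)
    lo = surface.sigma > 0
    ao = float(areas[lo].mean()) if lo.any() else None
    ad = float(areas[~lo].mean()) if (~lo).any() else None
    return ao, ad


def area_fraction_lo(surface: TriSurface) -> float:
    """Lo area fraction NTo*ao / (NTo*ao + NTd*ad); equals phi0 iff ao = ad."""
    areas = triangle_areas(surface)
    lo = surface.sigma > 0
    total = float(areas.sum())
    return float(areas[lo].sum()) / total if total > 0 else math.nan


# ---------------------------------------------------------------------------
# morphology classification
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class MorphologyThresholds:
    """Cutoffs for the categorical morphology label.

    ``random_min_components``: more Lo fragments than this (with small mean
    size) is the unseparated mixture.  ``raft_max_components``: upper count
    for the multi-circular raft.  ``comparable_ratio``: max size ratio
    between the largest and smallest raft patch.  ``neck_isoperimetric``:
    a domain whose boundary satisfies L^2 / (4 pi A) below this is flagged
    as pinched through a narrow neck (budding evidence).  Reference values:
    a flat circular patch has L^2 / (4 pi A) ~ 1, a hemispherical cap 1/2,
    and a nearly closed bud much less, so the default cutoff 0.3 sits
    between the cap and the bud.
    """

    random_min_components: int = 7
    random_max_mean_fraction: float = 0.05
    raft_max_components: int = 6
    comparable_ratio: float = 10.0
    neck_isoperimetric: float = 0.3
    neck_min_triangles: int = 10


DEFAULT_THRESHOLDS = MorphologyThresholds()


@dataclasses.dataclass(frozen=True)
class MorphologyLabel:
    label: str
    n_lo_components: int
    n_ld_components: int
    boundary_fraction: float
    neck_evidence: Optional[float] = None  # min isoperimetric ratio, if computed


def _neck_ratios(surface: TriSurface, stats: DomainStats,
                 thresholds: MorphologyThresholds) -> Optional[float]:
    """Min isoperimetric ratio L^2/(4 pi A) over large Lo components."""
    areas = triangle_areas(surface)
    t0 = surface.bond_tri[:, 0]
    t1 = surface.bond_tri[:, 1]
    boundary = surface.sigma[t0] != surface.sigma[t1]
    if not boundary.any():
        return None
    d = surface.pos[surface.bond_v[:, 0]] - surface.pos[surface.bond_v[:, 1]]
    lengths = np.linalg.norm(d, axis=1)
    best = None
    lo_ids = {lab for lab, s in zip(stats.labels, surface.sigma) if s > 0}
    for comp in lo_ids:
        mask = stats.labels == comp
        if int(mask.sum()) < thresholds.neck_min_triangles:
            continue
        area = float(areas[mask].sum())
        on_boundary = boundary & (mask[t0] | mask[t1])
        perim = float(lengths[on_boundary].sum())
        if area <= 0 or perim <= 0:
            continue
        q = perim * perim / (4.0 * math.pi * area)
        if best is None or q < best:
            best = q
    return best


def classify_morphology(stats: DomainStats,
                        surface: Optional[TriSurface] = None,
                        thresholds: MorphologyThresholds = DEFAULT_THRESHOLDS,
                        ) -> MorphologyLabel:
    """Categorical domain morphology from component statistics.

    Budding evidence (narrow-neck flag) is only evaluated when ``surface``
    is given, since it needs bond lengths and triangle areas.
    """
    n_lo = stats.n_lo_components
    n_ld = stats.n_ld_components
    nt = int(stats.labels.shape[0])
    nb_total = 3 * (nt + 4) // 2 - 6  # NB from NT = 2N - 4
    bfrac = stats.boundary_bonds / nb_total
    t = thresholds
    mean_lo = (sum(stats.lo_sizes) / n_lo / nt) if n_lo else 0.0

    label = "random"
    if n_lo == 0 or n_ld == 0:
        label = "one_circular" if n_lo <= 1 and n_ld <= 1 else "random"
    elif n_lo == 1 and n_ld == 1:
        label = "one_circular"
    elif n_lo == 2 and n_ld == 1:
        label = "two_circular"
    elif n_lo == 1 and n_ld == 2:
        label = "stripe"
    elif (3 <= n_lo <= t.raft_max_components and n_ld == 1
          and stats.lo_sizes[0] <= t.comparable_ratio * stats.lo_sizes[-1]):
        label = "multi_circular_raft"
    elif n_lo >= t.random_min_components and mean_lo <= t.random_max_mean_fraction:
        label = "random"
    neck = None
    if surface is not None and label != "random":
        neck = _neck_ratios(surface, stats, t)
        if neck is not None and neck < t.neck_isoperimetric:
            label = "budding_candidate"
    return MorphologyLabel(label=label, n_lo_components=n_lo,
                           n_ld_components=n_ld, boundary_fraction=bfrac,
                           neck_evidence=neck)


# ---------------------------------------------------------------------------
# per-measurement record
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ObservableRecord:
    """One measurement row of a trajectory."""

    sweep: int
    s0: float
    s1_per_n: float
    s2_per_nb: float
    d1: float
    d2: float
    d3: float
    n_lo_components: int
    n_ld_components: int
    boundary_bonds: int
    ao: Optional[float]
    ad: Optional[float]
    area_fraction_lo: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def measure(surface: TriSurface, sweep: int,
            energy: EnergyBreakdown) -> ObservableRecord:
    """Assemble the standard observable row for one configuration."""
    d1, d2, d3 = semi_axes(surface)
    stats = domain_components(surface)
    ao, ad = mean_triangle_areas(surface)
    return ObservableRecord(
        sweep=sweep,
        s0=energy.s0,
        s1_per_n=energy.s1 / surface.n_vertices,
        s2_per_nb=energy.s2 / surface.n_bonds,
        d1=d1, d2=d2, d3=d3,
        n_lo_components=stats.n_lo_components,
        n_ld_components=stats.n_ld_components,
        boundary_bonds=stats.boundary_bonds,
        ao=ao, ad=ad,
        area_fraction_lo=area_fraction_lo(surface),
    )
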