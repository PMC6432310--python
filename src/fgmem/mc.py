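"""Metropolis sampler for the fluid two-phase membrane.

One Monte Carlo sweep (MCS) is N vertex-move attempts plus N bond-flip
attempts, randomly interleaved.  A vertex move displaces one vertex by a
vector drawn uniformly from a ball of radius R and is accepted with
probability min(1, exp(-dS)) at kB*T = 1; R is tuned during thermalization
toward ~50% acceptance and frozen afterwards.  A flip picks a uniformly
random bond, rejects topologically illegal flips outright, and otherwise
Metropolis-accepts using the exact local energy difference.  The number of
Lo triangles is conserved by construction, so the composition phi0 never
drifts.  The surface is recentred on the origin after every sweep (the
energy is translation invariant; the partition function fixes the centre
of mass).

All randomness inside the compiled kernel is driven by numba's RNG, which
is reseeded before every block of sweeps with a seed drawn from the
Python-side master generator; a run is therefore fully reproducible from
(seed, config) and can be checkpointed via the master generator's state.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional

import numpy as np
import pandas as pd
from numba import njit

from . import observables as obs
from .energy import (EnergyBreakdown, ModelParams, _delta_flip, _delta_vertex,
                     total_energy)
from .mesh import (MAX_DEGREE, TriSurface, _apply_flip, _flip_geometry,
                   _flip_legal, assign_sigma_random, build_icosphere)

__all__ = ["MCState", "RunSchedule", "vertex_move_update", "flip_update",
           "sweep", "tune_radius", "run"]

#: bounds for the tuned move radius (model length units)
R_MIN, R_MAX = 1e-6, 1e3

_SEED_MOD = 2**31 - 1


def equilibrium_bond_length(params: ModelParams) -> float:
    """Mean bond length implied by the scale-invariance identity.

    <S1>/N = 3/2 (large N) with S1 = sum gamma_ij l_ij^2 over NB ~ 3N bonds
    gives <gamma l^2> ~ 1/2; under random mixing at composition phi0 the
    mean tension coefficient is the binomial average of the three gamma
    cases, so l0 = sqrt(1/(2 gamma_bar)).
    """
    from .energy import bond_coefficient

    p = params.phi0
    gbar = (p * p * bond_coefficient(1, 1, params.c, params.variant, "tension")
            + 2 * p * (1 - p) * bond_coefficient(1, -1, params.c,
                                                 params.variant, "tension")
            + (1 - p) ** 2 * bond_coefficient(-1, -1, params.c,
                                              params.variant, "tension"))
    return math.sqrt(0.5 / gbar)


@dataclasses.dataclass
class RunSchedule:
    """Sweep bookkeeping for one simulation.

    The move radius is tuned every ``tuning_interval`` sweeps during the
    ``thermalization`` phase only; observables are recorded every
    ``measure_interval`` sweeps during the ``measurement`` phase.
    """

    thermalization: int
    measurement: int
    measure_interval: int = 100
    tuning_interval: int = 500
    checkpoint_interval: Optional[int] = None
    seed: int = 0

    def __post_init__(self):
        if self.thermalization < 0 or self.measurement < 0:
            raise ValueError("sweep counts must be >= 0")
        if self.measure_interval < 1 or self.tuning_interval < 1:
            raise ValueError("intervals must be >= 1")


@dataclasses.dataclass
class MCState:
    """Mutable simulation state: surface, couplings, radius, RNG, counters."""

    surface: TriSurface
    params: ModelParams
    move_radius: float
    rng: np.random.Generator
    sweep: int = 0
    vertex_accepted: int = 0
    vertex_attempted: int = 0
    flip_accepted: int = 0
    flip_attempted: int = 0
    energy: Optional[EnergyBreakdown] = None
    # running component accumulators fed by accepted-move deltas
    _acc_s0: float = 0.0
    _acc_s1: float = 0.0
    _acc_s2: float = 0.0

    @classmethod
    def initial(cls, params: ModelParams, subdivision: int, seed: int,
                move_radius: Optional[float] = None,
                mean_bond_length: Optional[float] = None) -> "MCState":
        """Icosphere + random sigma at phi0: the random-coexistence start.

        By default the sphere is scaled so the initial Gaussian energy sits
        at the scale-invariant fixed point <gamma l^2> = (3/2) N / NB under
        random mixing, which removes the slowly relaxing global breathing
        mode from thermalization.  Pass ``mean_bond_length`` to override.
        """
        rng = np.random.default_rng(seed)
        if mean_bond_length is None:
            mean_bond_length = equilibrium_bond_length(params)
        surface = build_icosphere(subdivision, mean_bond_length=mean_bond_length)
        assign_sigma_random(surface, params.phi0, rng)
        if move_radius is None:
            move_radius = 0.15 * mean_bond_length
        state = cls(surface=surface, params=params, move_radius=move_radius,
                    rng=rng)
        state.recompute_energy()
        return state

    @property
    def vertex_acceptance(self) -> float:
        return self.vertex_accepted / max(1, self.vertex_attempted)

    @property
    def flip_acceptance(self) -> float:
        return self.flip_accepted / max(1, self.flip_attempted)

    def recompute_energy(self) -> EnergyBreakdown:
        """Full recompute; resets the incremental accumulators."""
        self.energy = total_energy(self.surface, self.params)
        self._acc_s0 = self.energy.s0
        self._acc_s1 = self.energy.s1
        self._acc_s2 = self.energy.s2
        return self.energy

    def energy_drift(self) -> float:
        """Relative gap between accumulated and freshly recomputed energy."""
        fresh = total_energy(self.surface, self.params)
        acc_total = (self.params.lambda_ * self._acc_s0 + self._acc_s1
                     + self.params.kappa * self._acc_s2)
        return abs(acc_total - fresh.total) / max(1.0, abs(fresh.total))


# ---------------------------------------------------------------------------
# compiled update kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _try_vertex(pos, tri, sigma, bond_v, bond_tri, tri_bonds, v_tris, v_nt,
                R, kap, c, model2, scratch):
    """One vertex-move attempt on a random vertex; mutates pos if accepted."""
    n = pos.shape[0]
    v = np.random.randint(n)
    while True:
        dx = np.random.uniform(-R, R)
        dy = np.random.uniform(-R, R)
        dz = np.random.uniform(-R, R)
        if dx * dx + dy * dy + dz * dz <= R * R:
            break
    px = pos[v, 0] + dx
    py = pos[v, 1] + dy
    pz = pos[v, 2] + dz
    d1, d2, ok = _delta_vertex(pos, tri, sigma, bond_v, bond_tri, tri_bonds,
                               v_tris, v_nt, v, px, py, pz, c, model2, scratch)
    if not ok:
        return False, 0.0, 0.0
    ds = d1 + kap * d2
    if ds <= 0.0 or np.random.random() < math.exp(-ds):
        pos[v, 0] = px
        pos[v, 1] = py
        pos[v, 2] = pz
        return True, d1, d2
    return False, 0.0, 0.0


@njit(cache=True)
def _try_flip(pos, tri, sigma, bond_v, bond_tri, tri_bonds,
              v_bonds, v_nb, v_tris, v_nt, lam, kap, c, model2):
    """One flip attempt on a random bond; mutates connectivity if accepted."""
    nb = bond_v.shape[0]
    b = np.random.randint(nb)
    if not _flip_legal(tri, bond_v, bond_tri, v_bonds, v_nb, b):
        return False, 0.0, 0.0, 0.0
    u, w, t0, t1, a, cc = _flip_geometry(tri, bond_v, bond_tri, b)
    s0 = sigma[t0]
    s1 = sigma[t1]
    if s0 == s1:
        sn0, sn1 = s0, s1
    elif np.random.random() < 0.5:
        sn0, sn1 = np.int64(1), np.int64(-1)
    else:
        sn0, sn1 = np.int64(-1), np.int64(1)
    d0, d1, d2, ok = _delta_flip(pos, tri, sigma, bond_v, bond_tri,
                                 v_bonds, v_nb, b, sn0, sn1, c, model2)
    if not ok:
        return False, 0.0, 0.0, 0.0
    ds = lam * d0 + d1 + kap * d2
    if ds <= 0.0 or np.random.random() < math.exp(-ds):
        _apply_flip(tri, sigma, bond_v, bond_tri, tri_bonds,
                    v_bonds, v_nb, v_tris, v_nt, b, sn0, sn1)
        return True, d0, d1, d2
    return False, 0.0, 0.0, 0.0


@njit(cache=True)
def _recenter(pos):
    n = pos.shape[0]
    cx = 0.0
    cy = 0.0
    cz = 0.0
    for i in range(n):
        cx += pos[i, 0]
        cy += pos[i, 1]
        cz += pos[i, 2]
    cx /= n
    cy /= n
    cz /= n
    for i in range(n):
        pos[i, 0] -= cx
        pos[i, 1] -= cy
        pos[i, 2] -= cz


@njit(cache=True)
def _run_sweeps(pos, tri, sigma, bond_v, bond_tri, tri_bonds,
                v_bonds, v_nb, v_tris, v_nt,
                nsweeps, R, lam, kap, c, model2, seed):
    """Run full sweeps (N vertex + N flip attempts, randomly interleaved).

    Returns acceptance counters and the summed energy-component deltas of
    all accepted moves (dS0, dS1, dS2).
    """
    np.random.seed(seed)
    n = pos.shape[0]
    scratch = np.empty(3 * MAX_DEGREE, dtype=np.int64)
    order = np.empty(2 * n, dtype=np.uint8)
    acc_v = 0
    att_v = 0
    acc_f = 0
    att_f = 0
    a0 = 0.0
    a1 = 0.0
    a2 = 0.0
    for _ in range(nsweeps):
        for i in range(n):
            order[i] = 0
        for i in range(n, 2 * n):
            order[i] = 1
        for i in range(2 * n - 1, 0, -1):  # Fisher-Yates interleave
            j = np.random.randint(i + 1)
            tmp = order[i]
            order[i] = order[j]
            order[j] = tmp
        for i in range(2 * n):
            if order[i] == 0:
                att_v += 1
                acc, d1, d2 = _try_vertex(pos, tri, sigma, bond_v, bond_tri,
                                          tri_bonds, v_tris, v_nt,
                                          R, kap, c, model2, scratch)
                if acc:
                    acc_v += 1
                    a1 += d1
                    a2 += d2
            else:
                att_f += 1
                acc, d0, d1, d2 = _try_flip(pos, tri, sigma, bond_v, bond_tri,
                                            tri_bonds, v_bonds, v_nb,
                                            v_tris, v_nt, lam, kap, c, model2)
                if acc:
                    acc_f += 1
                    a0 += d0
                    a1 += d1
                    a2 += d2
        _recenter(pos)
    return acc_v, att_v, acc_f, att_f, a0, a1, a2


# ---------------------------------------------------------------------------
# python driver
# ---------------------------------------------------------------------------

def _kernel_args(state: MCState):
    s = state.surface
    return (s.pos, s.tri, s.sigma, s.bond_v, s.bond_tri, s.tri_bonds,
            s.v_bonds, s.v_nb, s.v_tris, s.v_nt)


@njit(cache=True)
def _seeded_single(pos, tri, sigma, bond_v, bond_tri, tri_bonds,
                   v_bonds, v_nb, v_tris, v_nt,
                   kind, R, lam, kap, c, model2, seed):
    np.random.seed(seed)
    scratch = np.empty(3 * MAX_DEGREE, dtype=np.int64)
    if kind == 0:
        acc, d1, d2 = _try_vertex(pos, tri, sigma, bond_v, bond_tri, tri_bonds,
                                  v_tris, v_nt, R, kap, c, model2, scratch)
        return acc, 0.0, d1, d2
    acc, d0, d1, d2 = _try_flip(pos, tri, sigma, bond_v, bond_tri, tri_bonds,
                                v_bonds, v_nb, v_tris, v_nt, lam, kap, c, model2)
    return acc, d0, d1, d2


def _single_update(state: MCState, kind: int) -> bool:
    p = state.params
    seed = int(state.rng.integers(_SEED_MOD))
    acc, d0, d1, d2 = _seeded_single(*_kernel_args(state), kind,
                                     state.move_radius, p.lambda_, p.kappa,
                                     p.c, p.is_model2, seed)
    if kind == 0:
        state.vertex_attempted += 1
        state.vertex_accepted += int(acc)
    else:
        state.flip_attempted += 1
        state.flip_accepted += int(acc)
    if acc:
        state._acc_s0 += d0
        state._acc_s1 += d1
        state._acc_s2 += d2
    return bool(acc)


def vertex_move_update(state: MCState) -> bool:
    """One Metropolis vertex-move attempt; True if accepted."""
    return _single_update(state, 0)


def flip_update(state: MCState) -> bool:
    """One Metropolis bond-flip attempt; True if accepted."""
    return _single_update(state, 1)


def _sweep_block(state: MCState, nsweeps: int) -> tuple[int, int, int, int]:
    """Run ``nsweeps`` sweeps through the compiled kernel; update counters."""
    p = state.params
    seed = int(state.rng.integers(_SEED_MOD))
    acc_v, att_v, acc_f, att_f, a0, a1, a2 = _run_sweeps(
        *_kernel_args(state), nsweeps, state.move_radius,
        p.lambda_, p.kappa, p.c, p.is_model2, seed)
    state.vertex_accepted += acc_v
    state.vertex_attempted += att_v
    state.flip_accepted += acc_f
    state.flip_attempted += att_f
    state._acc_s0 += a0
    state._acc_s1 += a1
    state._acc_s2 += a2
    state.sweep += nsweeps
    return acc_v, att_v, acc_f, att_f


def sweep(state: MCState) -> MCState:
    """One full sweep: N vertex moves + N flips, then recentring."""
    _sweep_block(state, 1)
    return state


def tune_radius(state: MCState, window_acceptance: float,
                target: float = 0.5) -> MCState:
    """Multiplicative control of the move radius toward the target acceptance.

    Acceptance decreases monotonically with R, so R is scaled by
    acceptance/target (clipped to [1/2, 2] per adjustment).
    """
    factor = min(2.0, max(0.5, window_acceptance / target))
    state.move_radius = min(R_MAX, max(R_MIN, state.move_radius * factor))
    return state


def _measure(state: MCState, block_acc_v: float, block_acc_f: float) -> dict:
    e = state.recompute_energy()
    s = state.surface
    rec = obs.measure(s, sweep=state.sweep, energy=e)
    d = rec.to_dict()
    d["vertex_acceptance"] = block_acc_v
    d["flip_acceptance"] = block_acc_f
    d["move_radius"] = state.move_radius
    return d


def run(params: ModelParams, schedule: RunSchedule, subdivision: int,
        state: Optional[MCState] = None,
        mean_bond_length: Optional[float] = None) -> tuple[pd.DataFrame, MCState]:
    """Thermalize (with radius tuning) then measure; fully seeded.

    Returns one observable row per measurement interval and the final state.
    Pass ``state`` to continue from a checkpoint instead of building the
    random initial configuration.
    """
    if state is None:
        state = MCState.initial(params, subdivision, schedule.seed,
                                mean_bond_length=mean_bond_length)
    therm_end = schedule.thermalization
    total = schedule.thermalization + schedule.measurement
    # --- thermalization with tuning --------------------------------------
    while state.sweep < therm_end:
        block = min(schedule.tuning_interval, therm_end - state.sweep)
        acc_v, att_v, _, _ = _sweep_block(state, block)
        tune_radius(state, acc_v / max(1, att_v))
    # --- measurement (R frozen) ------------------------------------------
    rows = []
    while state.sweep < total:
        block = min(schedule.measure_interval, total - state.sweep)
        acc_v, att_v, acc_f, att_f = _sweep_block(state, block)
        rows.append(_measure(state, acc_v / max(1, att_v),
                             acc_f / max(1, att_f)))
    return pd.DataFrame(rows), state
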