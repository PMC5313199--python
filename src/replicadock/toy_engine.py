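"""Coarse-grained bead force field and BAOAB Langevin dynamics.

The engine stands in for an all-atom MD code at desk scale: beads
interact through 12-6 Lennard-Jones terms (receptor–ligand cross pairs,
with per-receptor-bead well-depth overrides encoding sticky sites, and
non-bonded intra-ligand pairs), harmonic bonds, and the two restraint
types used to keep binding partners folded — positional restraints and
pair-distance restraints, both of the Amber form k·(Δ)² without the ½.

Integration uses the BAOAB splitting of Langevin dynamics, which gives
accurate configurational averages at large time steps; with γ = 0 it
reduces to velocity Verlet and conserves energy in the small-dt limit.
Units follow :mod:`replicadock.units` (Å, kcal/mol, ps, amu).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .units import ACCEL_FACTOR, KB

__all__ = [
    "ToyForceField",
    "RestraintSet",
    "SimulationState",
    "compute_energy_forces",
    "cross_interaction_energy",
    "langevin_step",
    "run_segment",
    "draw_maxwell_boltzmann",
]


@dataclass
class ToyForceField:
    """Bead-level pair potential for a receptor/ligand toy system.

    ``eps_cross`` holds one Lennard-Jones well depth per *receptor* bead
    (kcal/mol), applied to every cross pair with that bead — sticky decoy
    sites and the native site are simply deeper entries.  ``sigma`` (Å)
    is shared by all LJ pairs.  ``bonds`` are (i, j, r0, k_b) harmonic
    terms on global atom indices; bonded pairs are excluded from the
    intra-ligand LJ term.
    """

    sigma: float
    eps_cross: np.ndarray          # (n_receptor,) kcal/mol, ≥ 0
    eps_intra_ligand: float = 0.0
    bonds: list = field(default_factory=list)

    def __post_init__(self):
        self.eps_cross = np.asarray(self.eps_cross, dtype=float)
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if np.any(self.eps_cross < 0) or self.eps_intra_ligand < 0:
            raise ValueError("LJ well depths must be non-negative")


@dataclass
class RestraintSet:
    """Positional and pair-distance harmonic restraints, energy k·(Δ)²."""

    positional: list = field(default_factory=list)    # (atom, ref_coord, k)
    pair_distance: list = field(default_factory=list)  # (i, j, r_ref, k)

    def __post_init__(self):
        for *_ , k in self.positional:
            if k < 0:
                raise ValueError("restraint force constants must be >= 0")
        for *_, k in self.pair_distance:
            if k < 0:
                raise ValueError("restraint force constants must be >= 0")
        self._pos_cache = None

    def _pos_arrays(self):
        if self._pos_cache is None:
            idx = np.array([i for i, _, _ in self.positional], dtype=int)
            refs = np.array([r for _, r, _ in self.positional], dtype=float)
            ks = np.array([k for _, _, k in self.positional], dtype=float)
            self._pos_cache = (idx, refs, ks)
        return self._pos_cache


@dataclass
class SimulationState:
    """Coordinates, velocities, step counter, RNG stream, temperature.

    ``frozen_dof`` is an optional boolean mask (n_atoms, 3); frozen
    degrees of freedom receive neither drift, noise, nor force.
    """

    coords: np.ndarray
    velocities: np.ndarray
    step: int
    rng: np.random.Generator
    temperature: float
    frozen_dof: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.array(self.coords, dtype=float)
        self.velocities = np.array(self.velocities, dtype=float)
        if self.coords.shape != self.velocities.shape:
            raise ValueError("coords and velocities shapes differ")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.frozen_dof is not None:
            self.frozen_dof = np.asarray(self.frozen_dof, dtype=bool)
            if self.frozen_dof.shape != self.coords.shape:
                raise ValueError("frozen_dof mask shape mismatch")
            self.velocities[self.frozen_dof] = 0.0

    def copy(self) -> "SimulationState":
        import copy as _copy
        return SimulationState(self.coords.copy(), self.velocities.copy(),
                               self.step, _copy.deepcopy(self.rng),
                               self.temperature,
                               None if self.frozen_dof is None
                               else self.frozen_dof.copy())


def _lj(eps, sigma, r):
    sr6 = (sigma / r) ** 6
    e = 4.0 * eps * (sr6 * sr6 - sr6)
    # dE/dr = 4ε(−12 σ¹²/r¹³ + 6 σ⁶/r⁷)
    de = 4.0 * eps * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r
    return e, de


def cross_interaction_energy(system, ff: ToyForceField, coords) -> float:
    """Receptor–ligand LJ energy only (kcal/mol), no cutoff."""
    coords = np.asarray(coords, dtype=float)
    rc = coords[system.receptor_idx]
    lc = coords[system.ligand_idx]
    r = cdist(rc, lc)
    eps = ff.eps_cross[:, None]
    sr6 = (ff.sigma / r) ** 6
    return float(np.sum(4.0 * eps * (sr6 * sr6 - sr6)))


def compute_energy_forces(system, ff: ToyForceField, restraints: RestraintSet,
                          bias_fn, coords):
    """Total energy, forces and per-term breakdown at one frame.

    ``bias_fn`` is a closure ``coords -> BiasResult`` (or None for an
    unbiased evaluation).  Breakdown keys: pair, bond, positional,
    pair_distance, bias, guard, plus ``interaction`` (the receptor–ligand
    cross LJ alone, re-reported for analysis).  Forces are −∇(total).
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    forces = np.zeros((n, 3))
    breakdown = {}

    # --- cross LJ (receptor x ligand), no cutoff
    ri, li = system.receptor_idx, system.ligand_idx
    vec = coords[ri][:, None, :] - coords[li][None, :, :]   # (nr, nl, 3)
    r = np.sqrt(np.einsum("ijk,ijk->ij", vec, vec))
    eps = ff.eps_cross[:, None]
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        # non-finite values are caught by the final finiteness check
        e_cross_mat, de = _lj(eps, ff.sigma, r)
        e_cross = float(e_cross_mat.sum())
        f_pair = (-de / r)[:, :, None] * vec                 # on receptor beads
    np.add.at(forces, ri, f_pair.sum(axis=1))
    np.add.at(forces, li, -f_pair.sum(axis=0))

    # --- intra-ligand LJ over non-bonded ligand pairs
    e_intra = 0.0
    if ff.eps_intra_ligand > 0.0 and len(li) > 1:
        bonded = {tuple(sorted((i, j))) for i, j, *_ in ff.bonds}
        for a in range(len(li)):
            for b in range(a + 1, len(li)):
                i, j = int(li[a]), int(li[b])
                if (i, j) in bonded:
                    continue
                v = coords[i] - coords[j]
                d = float(np.linalg.norm(v))
                e, de1 = _lj(ff.eps_intra_ligand, ff.sigma, d)
                e_intra += e
                f = -de1 * v / d
                forces[i] += f
                forces[j] -= f
    breakdown["pair"] = e_cross + e_intra

    # --- harmonic bonds k_b (r − r0)²
    e_bond = 0.0
    for i, j, r0, kb in ff.bonds:
        v = coords[i] - coords[j]
        d = float(np.linalg.norm(v))
        e_bond += kb * (d - r0) ** 2
        f = -2.0 * kb * (d - r0) * v / d
        forces[i] += f
        forces[j] -= f
    breakdown["bond"] = e_bond

    # --- positional restraints k |x − x_ref|²
    e_pos = 0.0
    if restraints.positional:
        idx, refs, ks = restraints._pos_arrays()
        dv = coords[idx] - refs
        e_pos = float(np.sum(ks * np.einsum("ij,ij->i", dv, dv)))
        np.add.at(forces, idx, -2.0 * ks[:, None] * dv)
    breakdown["positional"] = e_pos

    # --- pair-distance restraints k (d − r_ref)²
    e_pd = 0.0
    for i, j, r_ref, k in restraints.pair_distance:
        v = coords[i] - coords[j]
        d = float(np.linalg.norm(v))
        e_pd += k * (d - r_ref) ** 2
        f = -2.0 * k * (d - r_ref) * v / d
        forces[i] += f
        forces[j] -= f
    breakdown["pair_distance"] = e_pd

    # --- ambiguity bias / dissociation guard
    if bias_fn is not None:
        res = bias_fn(coords)
        breakdown["bias"] = res.energy
        breakdown["guard"] = res.guard_energy
        breakdown["_bias_result"] = res
        forces += res.forces
    else:
        breakdown["bias"] = 0.0
        breakdown["guard"] = 0.0

    breakdown["interaction"] = e_cross
    total = sum(v for k, v in breakdown.items()
                if k not in ("interaction", "_bias_result"))
    if not np.isfinite(total) or not np.all(np.isfinite(forces)):
        bad = [k for k, v in breakdown.items()
               if k != "_bias_result" and not np.all(np.isfinite(v))]
        raise FloatingPointError(f"non-finite energy in term(s): {bad}")
    return total, forces, breakdown


def draw_maxwell_boltzmann(rng, masses, temperature, frozen_dof=None):
    """Velocities (Å/ps) from the Maxwell–Boltzmann distribution."""
    masses = np.asarray(masses, dtype=float)
    sd = np.sqrt(KB * temperature * ACCEL_FACTOR / masses)
    v = rng.normal(size=(len(masses), 3)) * sd[:, None]
    if frozen_dof is not None:
        v[frozen_dof] = 0.0
    return v


def langevin_step(state: SimulationState, forces, force_fn, dt: float,
                  gamma: float, masses):
    """One BAOAB Langevin update; returns (state, forces_at_new_coords).

    B: half-kick, A: half-drift, O: Ornstein–Uhlenbeck velocity
    refresh, A: half-drift, B: half-kick with re-evaluated forces.
    γ = 0 turns O into the identity (velocity Verlet); the update is
    deterministic for a fixed RNG stream.  ``force_fn(coords)`` must
    return the force array at the drifted coordinates.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    m = np.asarray(masses, dtype=float)[:, None]
    x = state.coords
    v = state.velocities
    frozen = state.frozen_dof

    accel = forces * ACCEL_FACTOR / m
    v = v + 0.5 * dt * accel
    x = x + 0.5 * dt * v
    if gamma > 0.0:
        c1 = np.exp(-gamma * dt)
        sd = np.sqrt((1.0 - c1 * c1) * KB * state.temperature * ACCEL_FACTOR / m)
        v = c1 * v + sd * state.rng.normal(size=v.shape)
    x = x + 0.5 * dt * v
    if frozen is not None:
        x = np.where(frozen, state.coords, x)
    new_forces = force_fn(x)
    v = v + 0.5 * dt * new_forces * ACCEL_FACTOR / m
    if frozen is not None:
        v = np.where(frozen, 0.0, v)
    new_state = SimulationState(x, v, state.step + 1, state.rng,
                                state.temperature, frozen)
    return new_state, new_forces


def run_segment(state: SimulationState, energy_force_fn, n_steps: int,
                record_every: int, dt: float, gamma: float, masses):
    """Advance ``n_steps`` BAOAB steps, recording every ``record_every``.

    ``energy_force_fn(coords)`` returns (energy, forces, breakdown); the
    breakdown of each recorded frame is stored alongside the frame.
    Bit-reproducible for a fixed RNG state.  Returns
    (final_state, frames, records).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    frames, records = [], []
    _, forces, _ = energy_force_fn(state.coords)

    def force_only(x):
        return energy_force_fn(x)[1]

    for k in range(1, n_steps + 1):
        state, forces = langevin_step(state, forces, force_only, dt, gamma,
                                      masses)
        # stride on the global step counter, so recording stays aligned
        # across segment boundaries (replica-exchange rounds)
        if record_every > 0 and state.step % record_every == 0:
            energy, _, breakdown = energy_force_fn(state.coords)
            frames.append(state.coords.copy())
            rec = {"step": state.step, "total": energy}
            rec.update({k2: v for k2, v in breakdown.items()
                        if k2 != "_bias_result"})
            res = breakdown.get("_bias_result")
            rec["d_ave12"] = None if res is None else res.d_ave12
            rec["n_pairs"] = None if res is None else res.n_pairs
            rec["guard_active"] = None if res is None else res.guard_active
            records.append(rec)
    return state, frames, records
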