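"""Hamiltonian replica-exchange controller.

All replicas share the temperature, force field and restraints and
differ only in their bias window.  After every ``exchange_interval``
dynamics steps, neighbouring replica pairs attempt a coordinate swap
accepted with the Metropolis probability min(1, e^(−Δ)), where

    Δ = β·[E_i(x_j) + E_j(x_i) − E_i(x_i) − E_j(x_j)]

and E_i is the bias (window + guard) energy of replica slot i — the
only Hamiltonian term that differs between replicas, so every other
contribution cancels from Δ.  Attempts alternate between even pairs
(0-1, 2-3, …) and odd pairs (1-2, 3-4, …).  On acceptance, coordinates
and velocities move between slots while the windows stay attached to
their slots; replica slot 0 is the reference replica whose window admits
receptor–ligand contact without penalty.  Velocities are not rescaled
(equal temperatures).  Runs are deterministic for a fixed master seed:
each replica and the exchange decision sequence get independent child
RNG streams.
"""

from __future__ import annotations

import numpy as np

from .ambiguity_bias import ReplicaLadder, evaluate_bias
from .store import ExchangeRecord, TrajectoryStore
from .toy_engine import (SimulationState, compute_energy_forces,
                         draw_maxwell_boltzmann, run_segment)
from .units import KB

__all__ = [
    "exchange_delta",
    "attempt_exchanges",
    "run_hremd",
    "acceptance_statistics",
    "demultiplex",
]


def _bias_energy_of(system, groups, coords, window, **bias_opts) -> float:
    res = evaluate_bias(system, groups, coords, window, **bias_opts)
    return res.total_energy


def exchange_delta(coords_i, coords_j, window_i, window_j, system, groups,
                   beta: float, **bias_opts) -> float:
    """Dimensionless Metropolis exponent for swapping configurations i, j.

    Antisymmetric under exchanging the roles of i and j; zero whenever
    both configurations are penalty-free under both windows, which is the
    overlap situation the ladder is tuned to make frequent.
    """
    e_ii = _bias_energy_of(system, groups, coords_i, window_i, **bias_opts)
    e_jj = _bias_energy_of(system, groups, coords_j, window_j, **bias_opts)
    e_ij = _bias_energy_of(system, groups, coords_j, window_i, **bias_opts)
    e_ji = _bias_energy_of(system, groups, coords_i, window_j, **bias_opts)
    return beta * (e_ij + e_ji - e_ii - e_jj)


def attempt_exchanges(states: list, ladder: ReplicaLadder, system, groups,
                      beta: float, rng: np.random.Generator, phase: int,
                      step: int, **bias_opts) -> list:
    """Attempt swaps for one phase of neighbour pairs; mutates ``states``.

    ``phase`` 0 attempts pairs (0,1), (2,3), …; phase 1 attempts
    (1,2), (3,4), ….  Accepted swaps exchange coordinates and velocities
    between the two replica slots.  Returns the new exchange records.
    """
    records = []
    n = len(states)
    start = 0 if phase % 2 == 0 else 1
    for i in range(start, n - 1, 2):
        j = i + 1
        delta = exchange_delta(states[i].coords, states[j].coords,
                               ladder[i], ladder[j], system, groups, beta,
                               **bias_opts)
        accepted = bool(rng.random() < np.exp(-min(delta, 700.0)))
        if accepted:
            states[i].coords, states[j].coords = \
                states[j].coords, states[i].coords
            states[i].velocities, states[j].velocities = \
                states[j].velocities, states[i].velocities
        records.append(ExchangeRecord(step=step, pair=(i, j), delta=delta,
                                      accepted=accepted))
    return records


def run_hremd(system, ff, restraints, groups, ladder: ReplicaLadder,
              n_steps: int, exchange_interval: int, seed: int,
              dt: float = 0.01, gamma: float = 0.1,
              temperature: float = 300.0, record_every: int = 10,
              initial_coords=None, frozen_dof=None,
              **bias_opts) -> TrajectoryStore:
    """Run a full H-REMD simulation; returns the populated store.

    Every replica starts from the same coordinates with independent
    Maxwell–Boltzmann velocities.  ``bias_opts`` are forwarded to
    :func:`replicadock.ambiguity_bias.evaluate_bias` (cutoff, exponent,
    normalization, guard options).
    """
    n_rep = len(ladder)
    masses = system.masses
    beta = 1.0 / (KB * temperature)
    x0 = system.coords if initial_coords is None else np.asarray(initial_coords,
                                                                 dtype=float)

    seq = np.random.SeedSequence(seed)
    children = seq.spawn(n_rep + 1)
    exchange_rng = np.random.default_rng(children[-1])

    states = []
    for r in range(n_rep):
        rng = np.random.default_rng(children[r])
        v = draw_maxwell_boltzmann(rng, masses, temperature, frozen_dof)
        states.append(SimulationState(x0.copy(), v, 0, rng, temperature,
                                      frozen_dof))

    def make_fn(window):
        def bias_fn(coords):
            return evaluate_bias(system, groups, coords, window, **bias_opts)

        def energy_force_fn(coords):
            return compute_energy_forces(system, ff, restraints, bias_fn,
                                         coords)
        return energy_force_fn

    fns = [make_fn(ladder[r]) for r in range(n_rep)]

    store = TrajectoryStore(n_replicas=n_rep, elements=system.elements,
                            exchange_interval=exchange_interval,
                            record_every=record_every)
    n_rounds = n_steps // exchange_interval
    leftover = n_steps - n_rounds * exchange_interval
    for round_idx in range(n_rounds):
        for r in range(n_rep):
            states[r], frames, recs = run_segment(
                states[r], fns[r], exchange_interval, record_every, dt,
                gamma, masses)
            store.frames[r].extend(frames)
            store.records[r].extend(recs)
        step_now = (round_idx + 1) * exchange_interval
        store.exchanges.extend(attempt_exchanges(
            states, ladder, system, groups, beta, exchange_rng,
            phase=round_idx % 2, step=step_now, **bias_opts))
    if leftover:
        for r in range(n_rep):
            states[r], frames, recs = run_segment(
                states[r], fns[r], leftover, record_every, dt, gamma, masses)
            store.frames[r].extend(frames)
            store.records[r].extend(recs)
    return store


def acceptance_statistics(records) -> dict:
    """Per-neighbour-pair and overall exchange acceptance ratios.

    Pairs with zero attempts are reported as None (undefined).  Returns
    ``{"pairs": {(i, j): ratio_or_None}, "overall": ratio}``.
    """
    attempts, accepted = {}, {}
    for rec in records:
        attempts[rec.pair] = attempts.get(rec.pair, 0) + 1
        accepted[rec.pair] = accepted.get(rec.pair, 0) + int(rec.accepted)
    pairs = {p: (accepted[p] / attempts[p]) if attempts[p] else None
             for p in attempts}
    total_att = sum(attempts.values())
    overall = (sum(accepted.values()) / total_att) if total_att else None
    return {"pairs": pairs, "overall": overall}


def demultiplex(store: TrajectoryStore):
    """Follow continuous walkers through accepted swaps.

    Returns a list of per-walker frame lists: walker w starts in replica
    slot w; each accepted exchange swaps the walkers occupying the two
    slots.  The multiset of frames at every recording time equals the
    multiset across replica slots, by construction.
    """
    n = store.n_replicas
    n_frames = min(len(store.frames[r]) for r in range(n))

    # group exchange records by attempt step
    by_step = {}
    for rec in store.exchanges:
        by_step.setdefault(rec.step, []).append(rec)
    for step, recs in by_step.items():
        slots = [s for rec in recs for s in rec.pair]
        if len(set(slots)) != len(slots):
            raise ValueError(f"inconsistent exchange log at step {step}: "
                             "replica appears in two pairs")

    walker_frames = [[] for _ in range(n)]
    slot_of_walker = list(range(n))
    frame_idx = 0
    for step in sorted(by_step) if by_step else []:
        # frames recorded before this attempt belong to the current occupancy
        upto = min(step // store.record_every, n_frames) \
            if store.record_every > 0 else 0
        while frame_idx < upto:
            for w in range(n):
                walker_frames[w].append(store.frames[slot_of_walker[w]][frame_idx])
            frame_idx += 1
        for rec in by_step[step]:
            if rec.accepted:
                i, j = rec.pair
                wi = slot_of_walker.index(i)
                wj = slot_of_walker.index(j)
                slot_of_walker[wi], slot_of_walker[wj] = j, i
    while frame_idx < n_frames:
        for w in range(n):
            walker_frames[w].append(store.frames[slot_of_walker[w]][frame_idx])
        frame_idx += 1
    return walker_frames
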