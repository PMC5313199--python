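"""Replica-exchange mechanics: Metropolis deltas, swap bookkeeping,
demultiplexing, and statistical correctness on the analytic pair system."""

import numpy as np
import pytest

from replicadock.ambiguity_bias import BiasWindow, ReplicaLadder
from replicadock.hremd import (acceptance_statistics, attempt_exchanges,
                               demultiplex, exchange_delta, run_hremd)
from replicadock.store import ExchangeRecord, TrajectoryStore
from replicadock.units import KB


@pytest.fixture(scope="module")
def pair_setup(harmonic_pair):
    hp = harmonic_pair
    beta = 1.0 / (KB * hp.temperature)
    return hp, beta


def sep_coords(hp, r):
    coords = hp.system.coords.copy()
    coords[1, 0] = r
    return coords


class TestExchangeDelta:
    def test_identical_windows_give_zero(self, pair_setup):
        hp, beta = pair_setup
        w = BiasWindow(4.0, 8.0, 2.5)
        delta = exchange_delta(sep_coords(hp, 5.0), sep_coords(hp, 7.0),
                               w, w, hp.system, hp.groups, beta)
        assert delta == pytest.approx(0.0, abs=1e-12)

    def test_both_inside_both_windows_give_zero(self, pair_setup):
        hp, beta = pair_setup
        wi, wj = BiasWindow(3.0, 8.0, 2.5), BiasWindow(4.0, 9.0, 2.5)
        delta = exchange_delta(sep_coords(hp, 5.0), sep_coords(hp, 6.5),
                               wi, wj, hp.system, hp.groups, beta)
        assert delta == pytest.approx(0.0, abs=1e-12)

    def test_antisymmetry_under_role_swap(self, pair_setup):
        """Swapping the two configurations between the windows negates Δ,
        so an accepted exchange is exactly reversible."""
        hp, beta = pair_setup
        wi, wj = BiasWindow(3.0, 5.0, 2.5), BiasWindow(6.0, 8.0, 2.5)
        x_a, x_b = sep_coords(hp, 4.5), sep_coords(hp, 7.0)
        d_fwd = exchange_delta(x_a, x_b, wi, wj, hp.system, hp.groups, beta)
        d_back = exchange_delta(x_b, x_a, wi, wj, hp.system, hp.groups, beta)
        assert d_fwd == pytest.approx(-d_back, rel=1e-12)
        assert d_fwd != 0.0

    def test_known_penalty_value(self, pair_setup):
        """One config penalized only under the other window: Δ = β·k·Δd²."""
        hp, beta = pair_setup
        wi = BiasWindow(3.0, 8.0, 2.5)       # admits both configs
        wj = BiasWindow(6.0, 8.0, 2.5)       # penalizes r = 5 by 2.5·1²
        delta = exchange_delta(sep_coords(hp, 5.0), sep_coords(hp, 7.0),
                               wi, wj, hp.system, hp.groups, beta)
        assert delta == pytest.approx(beta * 2.5, rel=1e-12)


class TestAttemptExchanges:
    def _states(self, hp, rs):
        from replicadock.toy_engine import SimulationState

        states = []
        for i, r in enumerate(rs):
            rng = np.random.default_rng(100 + i)
            states.append(SimulationState(sep_coords(hp, r),
                                          np.zeros((2, 3)), 0, rng, 300.0,
                                          hp.frozen_dof))
        return states

    def test_zero_delta_always_swaps(self, pair_setup):
        hp, beta = pair_setup
        w = BiasWindow(3.0, 9.0, 2.5)
        ladder = ReplicaLadder((w, w), verbatim=True)
        states = self._states(hp, [5.0, 7.0])
        rng = np.random.default_rng(0)
        recs = attempt_exchanges(states, ladder, hp.system, hp.groups, beta,
                                 rng, phase=0, step=10)
        assert recs[0].accepted
        assert states[0].coords[1, 0] == pytest.approx(7.0)
        assert states[1].coords[1, 0] == pytest.approx(5.0)

    def test_even_phase_pairs(self, pair_setup):
        hp, beta = pair_setup
        w = [BiasWindow(3.0 + 0.1 * i, 9.0 + 0.1 * i, 2.5) for i in range(6)]
        ladder = ReplicaLadder(tuple(w), verbatim=True)
        states = self._states(hp, [5.0] * 6)
        rng = np.random.default_rng(0)
        recs = attempt_exchanges(states, ladder, hp.system, hp.groups, beta,
                                 rng, phase=0, step=1)
        assert [r.pair for r in recs] == [(0, 1), (2, 3), (4, 5)]
        recs = attempt_exchanges(states, ladder, hp.system, hp.groups, beta,
                                 rng, phase=1, step=2)
        assert [r.pair for r in recs] == [(1, 2), (3, 4)]

    def test_metropolis_rate_at_ln2(self, rng):
        """Acceptance frequency at forced Δ = ln 2 is 0.5 ± sampling error."""
        delta = np.log(2.0)
        n = 10 ** 4
        accepted = np.sum(rng.random(n) < np.exp(-delta))
        assert accepted / n == pytest.approx(0.5, abs=0.015)


class TestAcceptanceStatistics:
    def test_all_accepted(self):
        recs = [ExchangeRecord(10 * i, (0, 1), 0.0, True) for i in range(5)]
        stats = acceptance_statistics(recs)
        assert stats["pairs"][(0, 1)] == 1.0
        assert stats["overall"] == 1.0

    def test_partial_ratio(self):
        recs = [ExchangeRecord(i, (0, 1), 0.1, i < 3) for i in range(10)]
        assert acceptance_statistics(recs)["pairs"][(0, 1)] == pytest.approx(0.3)

    def test_no_attempts_undefined(self):
        stats = acceptance_statistics([])
        assert stats["overall"] is None
        assert stats["pairs"] == {}


class TestRunHremd:
    def test_exchange_round_count(self, harmonic_pair):
        hp = harmonic_pair
        # 3 windows: even rounds attempt (0,1), odd rounds attempt (1,2),
        # so 10 rounds leave exactly 10 attempt records
        ladder = ReplicaLadder((BiasWindow(1.0, 9.0, 2.5),
                                BiasWindow(4.0, 9.0, 2.5),
                                BiasWindow(5.0, 9.5, 2.5)))
        store = run_hremd(hp.system, hp.ff, hp.restraints, hp.groups, ladder,
                          n_steps=1000, exchange_interval=100, seed=4,
                          record_every=50, frozen_dof=hp.frozen_dof)
        assert len(store.exchanges) == 10
        assert [e.pair for e in store.exchanges] == [(0, 1), (1, 2)] * 5
        assert store.n_frames(0) == 20

    def test_determinism(self, harmonic_pair):
        hp = harmonic_pair
        ladder = ReplicaLadder((BiasWindow(1.0, 9.0, 2.5),
                                BiasWindow(5.0, 9.0, 2.5)))
        kwargs = dict(n_steps=500, exchange_interval=100, seed=9,
                      record_every=25, frozen_dof=hp.frozen_dof)
        s1 = run_hremd(hp.system, hp.ff, hp.restraints, hp.groups, ladder,
                       **kwargs)
        s2 = run_hremd(hp.system, hp.ff, hp.restraints, hp.groups, ladder,
                       **kwargs)
        for r in range(2):
            for a, b in zip(s1.frames[r], s2.frames[r]):
                np.testing.assert_array_equal(a, b)
        assert [(e.step, e.pair, e.delta, e.accepted) for e in s1.exchanges] \
            == [(e.step, e.pair, e.delta, e.accepted) for e in s2.exchanges]

    def test_replica_moments_match_quadrature(self, harmonic_pair):
        """Short detailed-balance check: per-replica mean/width of the
        separation match the exact quadrature density.  (The full KS test
        at 10⁵ samples runs in the acceptance suite.)"""
        hp = harmonic_pair
        ladder = ReplicaLadder((BiasWindow(1.0, 9.0, 2.5),
                                BiasWindow(7.0, 9.0, 2.5)))
        store = run_hremd(hp.system, hp.ff, hp.restraints, hp.groups, ladder,
                          n_steps=30000, exchange_interval=250, seed=2,
                          record_every=3, frozen_dof=hp.frozen_dof)
        for r in range(2):
            seps = hp.separations(store.frames[r])
            grid, pdf, _ = hp.density(ladder[r])
            mean = np.trapezoid(grid * pdf, grid)
            var = np.trapezoid((grid - mean) ** 2 * pdf, grid)
            assert seps.mean() == pytest.approx(mean, abs=0.06)
            # second moments relax on the slow 1/γ timescale; generous band
            assert seps.std() == pytest.approx(np.sqrt(var), rel=0.25)


class TestDemultiplex:
    def _store_with_log(self, n_replicas, n_rounds, per_round, accepted):
        store = TrajectoryStore(n_replicas=n_replicas, elements=["C"],
                                exchange_interval=per_round, record_every=1)
        step = 0
        for rnd in range(n_rounds):
            for _ in range(per_round):
                step += 1
                for r in range(n_replicas):
                    store.frames[r].append(
                        np.array([[float(r), float(step), 0.0]]))
                    store.records[r].append({"step": step})
            phase = rnd % 2
            start = 0 if phase == 0 else 1
            for i in range(start, n_replicas - 1, 2):
                acc = accepted(rnd, (i, i + 1))
                store.exchanges.append(
                    ExchangeRecord(step, (i, i + 1), 0.0, acc))
        return store

    def test_no_swaps_identity(self):
        store = self._store_with_log(2, 3, 2, lambda rnd, pair: False)
        walkers = demultiplex(store)
        for w in range(2):
            for frame, ref in zip(walkers[w], store.frames[w]):
                np.testing.assert_array_equal(frame, ref)

    def test_single_swap_reroutes_walker(self):
        # only round 2 (an even phase, where pair (0,1) is attempted) swaps
        store = self._store_with_log(
            2, 4, 2, lambda rnd, pair: rnd == 2 and pair == (0, 1))
        walkers = demultiplex(store)
        slots = [f[0, 0] for f in walkers[0]]
        assert slots == [0.0] * 6 + [1.0] * 2

    def test_frame_multiset_conserved_random_log(self, rng):
        store = self._store_with_log(
            4, 6, 3, lambda rnd, pair: bool(rng.random() < 0.5))
        walkers = demultiplex(store)
        n_frames = len(store.frames[0])
        for t in range(n_frames):
            from_walkers = sorted(w[t][0, 0] for w in walkers)
            from_slots = sorted(store.frames[r][t][0, 0] for r in range(4))
            assert from_walkers == from_slots

    def test_inconsistent_log_rejected(self):
        store = self._store_with_log(2, 1, 2, lambda rnd, pair: False)
        store.exchanges.append(ExchangeRecord(2, (0, 1), 0.0, False))
        with pytest.raises(ValueError, match="inconsistent"):
            demultiplex(store)
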