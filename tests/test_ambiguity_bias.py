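"""The weighted ambiguity distance, bias windows, forces and the guard."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from replicadock.ambiguity_bias import (LADDER_PRESETS, BiasWindow,
                                        NoContactPairsError, ReplicaLadder,
                                        bias_energy, bias_forces,
                                        dissociation_guard, evaluate_bias,
                                        weighted_mean_distance)
from replicadock.surface_selection import ContactPairList, SurfaceGroups


def make_pairs(distances, n_r=30, n_l=20):
    """A synthetic pair list along the x axis with prescribed distances."""
    d = np.asarray(distances, dtype=float)
    n = len(d)
    return ContactPairList(receptor_idx=np.arange(n),
                           ligand_idx=np.arange(n) + n,
                           distances=d, cutoff=10.0, n_full=n_r * n_l)


def double_loop_d_ave(distances, p, m):
    """Literal evaluation of the printed formula."""
    s = 0.0
    for d in distances:
        s += 1.0 / d ** p
    return (s / m) ** (-1.0 / p)


class TestWeightedMeanDistance:
    def test_single_pair_returns_its_distance(self):
        pairs = make_pairs([5.0])
        for p in (6, 12):
            assert weighted_mean_distance(pairs, p) == pytest.approx(5.0)

    def test_equal_distances_collapse_to_that_distance(self):
        pairs = make_pairs([7.3] * 12)
        for p in (6, 12):
            assert weighted_mean_distance(pairs, p) == pytest.approx(
                7.3, rel=1e-12)

    @pytest.mark.parametrize("exponent", [6, 12])
    def test_matches_double_loop_oracle(self, exponent, rng):
        for _ in range(20):
            d = rng.uniform(3.0, 10.0, size=rng.integers(1, 200))
            pairs = make_pairs(d)
            got = weighted_mean_distance(pairs, exponent)
            want = double_loop_d_ave(d, exponent, len(d))
            assert got == pytest.approx(want, rel=1e-12)

    def test_full_normalization_divides_by_group_product(self, rng):
        d = rng.uniform(3.0, 9.0, 40)
        pairs = make_pairs(d, n_r=30, n_l=20)
        got = weighted_mean_distance(pairs, 12, normalization="full")
        want = double_loop_d_ave(d, 12, 600)
        assert got == pytest.approx(want, rel=1e-12)

    def test_power_mean_inequality(self, rng):
        for _ in range(50):
            d = rng.uniform(2.0, 10.0, size=rng.integers(2, 100))
            pairs = make_pairs(d)
            d12 = weighted_mean_distance(pairs, 12)
            d6 = weighted_mean_distance(pairs, 6)
            assert d12 <= d6 + 1e-12

    def test_bounds_by_minimum_distance(self, rng):
        for _ in range(50):
            d = rng.uniform(1.0, 10.0, size=rng.integers(1, 150))
            pairs = make_pairs(d)
            d12 = weighted_mean_distance(pairs, 12)
            assert d.min() - 1e-12 <= d12 <= d.min() * len(d) ** (1 / 12) + 1e-12

    def test_rescaling_stability(self, rng):
        """Evaluation at 1e-2 scale gives the rescaled result (no overflow)."""
        d = rng.uniform(5.0, 10.0, 50)
        big = weighted_mean_distance(make_pairs(d), 12)
        small = weighted_mean_distance(make_pairs(d * 1e-2), 12)
        assert small == pytest.approx(big * 1e-2, rel=1e-12)

    def test_empty_list_signals_guard_regime(self):
        with pytest.raises(NoContactPairsError):
            weighted_mean_distance(make_pairs([]), 12)

    def test_tiny_distance_rejected(self):
        with pytest.raises(ValueError, match="numerical range"):
            weighted_mean_distance(make_pairs([0.01]), 12)


class TestBiasEnergy:
    @pytest.mark.parametrize("d, window, expected", [
        (5.0, BiasWindow(4.0, 6.0, 2.5), 0.0),
        (3.0, BiasWindow(4.0, 6.0, 2.5), 2.5),
        (7.0, BiasWindow(4.0, 6.0, 5.0), 5.0),
    ])
    def test_piecewise_values(self, d, window, expected):
        assert bias_energy(d, window) == pytest.approx(expected)

    def test_continuity_at_edges(self):
        w = BiasWindow(4.0, 6.0, 2.5)
        for edge in (4.0, 6.0):
            left = bias_energy(edge - 1e-9, w)
            right = bias_energy(edge + 1e-9, w)
            assert abs(left - right) < 1e-14

    def test_window_validation(self):
        with pytest.raises(ValueError):
            BiasWindow(6.0, 4.0, 2.5)
        with pytest.raises(ValueError):
            BiasWindow(0.0, 4.0, 2.5)
        with pytest.raises(ValueError):
            BiasWindow(4.0, 6.0, -1.0)


def bias_closure_energy(coords, pair_idx, window, exponent=12):
    """Energy as a pure function of coordinates, for finite differencing."""
    ri, li = pair_idx
    d = np.linalg.norm(coords[ri] - coords[li], axis=1)
    pairs = ContactPairList(ri, li, d, 10.0, len(ri))
    return bias_energy(weighted_mean_distance(pairs, exponent), window)


class TestBiasForces:
    def _random_config(self, rng, n_pairs=8):
        coords = rng.uniform(-5, 5, (2 * n_pairs, 3))
        ri = np.arange(n_pairs)
        li = np.arange(n_pairs) + n_pairs
        return coords, (ri, li)

    def test_zero_inside_window(self, rng):
        coords, idx = self._random_config(rng)
        d = np.linalg.norm(coords[idx[0]] - coords[idx[1]], axis=1)
        pairs = ContactPairList(idx[0], idx[1], d, 10.0, len(d))
        d_ave = weighted_mean_distance(pairs, 12)
        window = BiasWindow(d_ave - 1.0, d_ave + 1.0, 2.5)
        energy, forces = bias_forces(coords, pairs, window)
        assert energy == 0.0
        assert np.all(forces == 0.0)

    @pytest.mark.parametrize("side", ["below", "above"])
    def test_matches_finite_differences(self, side, rng):
        for _ in range(10):
            coords, idx = self._random_config(rng)
            d = np.linalg.norm(coords[idx[0]] - coords[idx[1]], axis=1)
            pairs = ContactPairList(idx[0], idx[1], d, 10.0, len(d))
            d_ave = weighted_mean_distance(pairs, 12)
            window = (BiasWindow(d_ave + 0.7, d_ave + 2.0, 2.5) if side == "below"
                      else BiasWindow(max(0.1, d_ave - 2.0), d_ave - 0.7, 2.5))
            _, forces = bias_forces(coords, pairs, window)
            h = 1e-5
            for atom in list(idx[0][:2]) + list(idx[1][:2]):
                for ax in range(3):
                    cp, cm = coords.copy(), coords.copy()
                    cp[atom, ax] += h
                    cm[atom, ax] -= h
                    fd = -(bias_closure_energy(cp, idx, window)
                           - bias_closure_energy(cm, idx, window)) / (2 * h)
                    assert forces[atom, ax] == pytest.approx(
                        fd, rel=1e-5, abs=1e-9)

    def test_net_force_and_torque_vanish(self, rng):
        coords, idx = self._random_config(rng)
        d = np.linalg.norm(coords[idx[0]] - coords[idx[1]], axis=1)
        pairs = ContactPairList(idx[0], idx[1], d, 10.0, len(d))
        window = BiasWindow(d.min() + 3.0, d.min() + 4.0, 2.5)
        _, forces = bias_forces(coords, pairs, window)
        np.testing.assert_allclose(forces.sum(axis=0), 0.0, atol=1e-12)
        torque = np.cross(coords, forces).sum(axis=0)
        np.testing.assert_allclose(torque, 0.0, atol=1e-10)

    def test_shortest_contact_dominates(self):
        """Force on a 4 Å pair exceeds the 9 Å pair's by ≳ (9/4)^13 / 2."""
        coords = np.array([[0.0, 0, 0], [0, 10, 0],
                           [4.0, 0, 0], [0, 19.0, 0]])
        ri, li = np.array([0, 1]), np.array([2, 3])
        d = np.array([4.0, 9.0])
        pairs = ContactPairList(ri, li, d, 10.0, 2)
        window = BiasWindow(6.0, 8.0, 2.5)  # d_ave ≈ 4.2 -> repulsive regime
        _, forces = bias_forces(coords, pairs, window)
        f_short = np.linalg.norm(forces[0])
        f_long = np.linalg.norm(forces[1])
        assert f_short / f_long >= (9.0 / 4.0) ** 13 / len(d)

    def test_conservative_closed_loop(self):
        """Work along a closed coordinate loop is ~0 (conservative field)."""
        ri, li = np.array([0, 1]), np.array([2, 3])
        base = np.array([[0.0, 0, 0], [0, 4.5, 0], [3.5, 0, 0], [0, 9.0, 0]])
        window = BiasWindow(5.0, 7.0, 2.5)
        theta = np.linspace(0, 2 * np.pi, 101)
        # move atom 2 along a small circle
        path = base[None].repeat(101, axis=0)
        path[:, 2, 0] += 0.4 * np.cos(theta) - 0.4
        path[:, 2, 1] += 0.4 * np.sin(theta)
        work = 0.0
        for a, b in zip(path[:-1], path[1:]):
            mid = 0.5 * (a + b)
            d = np.linalg.norm(mid[ri] - mid[li], axis=1)
            pairs = ContactPairList(ri, li, d, 10.0, 2)
            _, forces = bias_forces(mid, pairs, window)
            work += np.sum(forces * (b - a))
        assert abs(work) < 1e-6


class TestDissociationGuard:
    def _groups(self):
        return SurfaceGroups(np.array([0, 1]), np.array([2, 3]), {})

    def test_inactive_when_any_pair_in_range(self):
        coords = np.array([[0.0, 0, 0], [0, 3, 0], [8.0, 0, 0], [50, 0, 0]])
        e, f = dissociation_guard(self._groups(), coords, cutoff=10.0, k=2.5)
        assert e == 0.0 and np.all(f == 0.0)

    def test_energy_substitution(self):
        coords = np.array([[0.0, 0, 0], [0, 1, 0], [12.0, 0, 0], [50, 0, 0]])
        e, f = dissociation_guard(self._groups(), coords, cutoff=10.0, k=2.5)
        assert e == pytest.approx(10.0)
        # equal and opposite along the pair axis
        np.testing.assert_allclose(f[0], -f[2], atol=1e-12)
        assert f[0, 0] > 0  # pulls the receptor atom toward the ligand

    def test_tie_break_lowest_lexicographic(self):
        coords = np.array([[0.0, 0, 0], [0, 0.0, 12.0],
                           [12.0, 0, 0], [0, 0, 24.0]])
        # pairs (0,2) and (1,3) both at exactly 12 Å
        e, f = dissociation_guard(self._groups(), coords, cutoff=10.0, k=1.0)
        assert e == pytest.approx(4.0)
        assert np.any(f[0] != 0) and np.all(f[1] == 0)


class TestEvaluateBias:
    def test_bound_pose_reports_d_ave(self, toy, toy_groups):
        res = evaluate_bias(toy.system, toy_groups, toy.native_pose,
                            BiasWindow(3.0, 6.0, 2.5))
        assert not res.guard_active
        assert res.d_ave12 is not None and res.d_ave12 > 0
        assert res.n_pairs > 0

    def test_separated_pose_activates_guard(self, toy, toy_groups):
        coords = toy.system.coords.copy()
        lig = toy.system.ligand_idx
        coords[lig] = coords[lig] * 3.0  # push the ligand far out
        res = evaluate_bias(toy.system, toy_groups, coords,
                            BiasWindow(3.0, 6.0, 2.5))
        assert res.guard_active
        assert res.d_ave12 is None
        assert res.guard_energy > 0 and res.energy == 0.0

    def test_exactly_one_term_nonzero(self, toy, toy_groups, rng):
        lig = toy.system.ligand_idx
        for _ in range(20):
            coords = toy.system.coords.copy()
            coords[lig] += rng.normal(scale=6.0, size=(len(lig), 3))
            if np.any(np.linalg.norm(
                    coords[lig][:, None] - coords[toy.system.receptor_idx],
                    axis=-1) < 0.5):
                continue  # skip unphysical overlaps
            res = evaluate_bias(toy.system, toy_groups, coords,
                                BiasWindow(6.0, 7.0, 2.5))
            assert res.energy == 0.0 or res.guard_energy == 0.0


class TestReplicaLadder:
    @pytest.mark.parametrize("name, n", [("ladder6", 6), ("ladder10", 10),
                                         ("ladder12", 12)])
    def test_presets_shipped_verbatim(self, name, n):
        ladder = LADDER_PRESETS[name]
        assert len(ladder) == n
        assert ladder[0].d_low == 4.0 and ladder[0].d_up == 6.0

    def test_preset_ladder10_values(self):
        lows = [w.d_low for w in LADDER_PRESETS["ladder10"].windows]
        np.testing.assert_allclose(lows, 4.0 + 0.5 * np.arange(10))

    def test_decreasing_low_rejected(self):
        with pytest.raises(ValueError, match="increase"):
            ReplicaLadder((BiasWindow(5.0, 7.0), BiasWindow(4.0, 6.0)))

    def test_gap_without_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ReplicaLadder((BiasWindow(4.0, 5.0), BiasWindow(6.0, 8.0)))

    def test_verbatim_flag_bypasses_validation(self):
        ReplicaLadder((BiasWindow(4.0, 5.0), BiasWindow(6.0, 8.0)),
                      verbatim=True)


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(min_value=1.0, max_value=10.0), min_size=2,
                max_size=60))
def test_power_mean_inequality_property(distances):
    """d_ave-12 ≤ d_ave-6, with equality only for equal distances."""
    pairs = make_pairs(distances)
    d12 = weighted_mean_distance(pairs, 12)
    d6 = weighted_mean_distance(pairs, 6)
    assert d12 <= d6 * (1 + 1e-12)
    assert min(distances) <= d12 * (1 + 1e-12)
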