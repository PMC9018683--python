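import itertools

import numpy as np
import pytest

from ssnmrpipe.synthetic import (SyntheticTruth, TrajectoryEnsemble,
                                 make_helix_model,
                                 simulate_trajectory_ensemble,
                                 simulate_two_state_series)
from ssnmrpipe.trajectory import (ContactSpec, contact_occupancy,
                                  distance_map_difference, estimate_barrier,
                                  free_energy_surface, pairwise_distance_map,
                                  rmsf, tica_fit, tica_transform)


def _ensemble(model, schedules, n_frames):
    return simulate_trajectory_ensemble(
        model, len(schedules), n_frames, 0.0,
        SyntheticTruth(contact_schedule=schedules), seed=5)


class TestContactOccupancy:
    def test_always_in_contact(self, helix20):
        ens = _ensemble(helix20, [{(3, 17): np.ones(20, bool)}], 20)
        occ = contact_occupancy(ens, ContactSpec(pairs=[(3, 17)]))
        assert occ.occupancy[(3, 17)] == 100.0

    def test_pooled_formula_arithmetic(self, helix20):
        # 30/100 and 50/100 frames pooled -> 40%
        scheds = [{(3, 17): np.arange(100) < 30},
                  {(3, 17): np.arange(100) < 50}]
        ens = _ensemble(helix20, scheds, 100)
        occ = contact_occupancy(ens, ContactSpec(pairs=[(3, 17)]))
        assert occ.occupancy[(3, 17)] == pytest.approx(40.0)

    def test_per_simulation_average_flag(self, helix20):
        scheds = [{(3, 17): np.arange(100) < 30},
                  {(3, 17): np.arange(100) < 50}]
        ens = _ensemble(helix20, scheds, 100)
        occ = contact_occupancy(ens, ContactSpec(pairs=[(3, 17)]),
                                per_simulation_average=True)
        assert occ.occupancy[(3, 17)] == pytest.approx(40.0)

    def test_simulation_order_invariance(self, helix20):
        scheds = [{(3, 17): np.arange(50) < 10},
                  {(3, 17): np.arange(50) < 35}]
        a = contact_occupancy(_ensemble(helix20, scheds, 50),
                              ContactSpec(pairs=[(3, 17)]))
        b = contact_occupancy(_ensemble(helix20, scheds[::-1], 50),
                              ContactSpec(pairs=[(3, 17)]))
        assert a.occupancy == b.occupancy

    def test_pooling_identity(self, helix20):
        # combined occupancy equals the frame-weighted double-sum value
        s1 = {(3, 17): np.arange(40) < 8}
        s2 = {(3, 17): np.arange(60) < 30}
        e1 = simulate_trajectory_ensemble(
            helix20, 1, 40, 0.0, [s1], seed=1)
        e2 = simulate_trajectory_ensemble(
            helix20, 1, 60, 0.0, [s2], seed=2)
        pooled = TrajectoryEnsemble(
            topology=helix20,
            simulations=e1.simulations + e2.simulations)
        occ = contact_occupancy(pooled, ContactSpec(pairs=[(3, 17)]))
        assert occ.occupancy[(3, 17)] == pytest.approx(100 * (8 + 30) / 100)

    def test_missing_residue(self, helix20):
        ens = _ensemble(helix20, [{(3, 17): np.ones(5, bool)}], 5)
        with pytest.raises(KeyError):
            contact_occupancy(ens, ContactSpec(pairs=[(3, 99)]))

    def test_counters_consistent(self, helix20):
        ens = _ensemble(helix20, [{(3, 17): np.arange(30) < 12}], 30)
        occ = contact_occupancy(ens, ContactSpec(pairs=[(3, 17)]))
        assert occ.contact_frames[(0, 0, (3, 17))] == 12
        assert occ.total_frames[(0, 0)] == 30


class TestRmsf:
    def test_static_zero(self, helix20):
        frames = np.repeat(helix20.coords[None], 5, axis=0)
        assert np.allclose(rmsf(frames), 0.0)

    def test_gaussian_analytic(self):
        # iid sigma per coordinate, no superposition -> RMSF = sigma*sqrt(3)
        rng = np.random.default_rng(8)
        base = rng.normal(size=(30, 3)) * 10
        sigma = 0.5
        frames = base[None] + rng.normal(0, sigma, size=(10**4, 30, 3))
        vals = rmsf(frames, superpose=False)
        assert np.allclose(vals, sigma * np.sqrt(3), rtol=0.05)

    def test_superposition_removes_rigid_motion(self, helix20, rng):
        from ssnmrpipe.docking import quaternion_to_matrix
        sigma = 0.2
        frames = helix20.coords[None] + rng.normal(
            0, sigma, size=(50, helix20.n_atoms, 3))
        ref_vals = rmsf(frames, superpose=True)
        moved = np.empty_like(frames)
        for f in range(len(frames)):
            q = rng.normal(size=4)
            q /= np.linalg.norm(q)
            moved[f] = frames[f] @ quaternion_to_matrix(q).T \
                + rng.normal(0, 5, 3)
        moved_vals = rmsf(moved, superpose=True)
        assert np.allclose(moved_vals, ref_vals, atol=0.05)

    def test_needs_two_frames(self, helix20):
        with pytest.raises(ValueError):
            rmsf(helix20.coords[None])


class TestPairwiseDistanceMap:
    def test_two_atoms(self):
        m = pairwise_distance_map(np.array([[0, 0, 0], [5.0, 0, 0]]))
        assert m[0, 1] == pytest.approx(5.0)

    def test_symmetric_zero_diagonal(self, helix20):
        m = pairwise_distance_map(helix20.coords)
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 0.0)

    def test_difference_of_identical_zero(self, helix20):
        m = pairwise_distance_map(helix20.coords)
        assert np.allclose(distance_map_difference(m, m), 0.0)

    def test_difference_shape_mismatch(self):
        with pytest.raises(ValueError):
            distance_map_difference(np.zeros((3, 3)), np.zeros((4, 4)))

    def test_mean_over_frames(self):
        frames = np.array([[[0, 0, 0], [4.0, 0, 0]],
                           [[0, 0, 0], [6.0, 0, 0]]])
        m = pairwise_distance_map(frames)
        assert m[0, 1] == pytest.approx(5.0)


class TestTica:
    def test_white_noise_eigenvalues_small(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(10**5, 4))
        model = tica_fit(x, lag=1, n_components=4)
        assert np.all(np.abs(model.eigenvalues) <= 0.1)

    def test_two_state_leading_eigenvalue(self):
        series, states = simulate_two_state_series(0.05, 10**5, seed=2)
        model = tica_fit(series, lag=1, n_components=1)
        # oracle: long-run lag-1 autocorrelation of the hidden states
        oracle = np.corrcoef(states[:-1], states[1:])[0, 1]
        assert model.eigenvalues[0] == pytest.approx(0.9, abs=0.02)
        assert model.eigenvalues[0] == pytest.approx(oracle, abs=0.02)

    def test_collinear_features_survive_floor(self):
        series, _ = simulate_two_state_series(0.1, 5000, seed=4)
        x = np.column_stack([series, series, series * 2.0])
        model = tica_fit(x, lag=1, n_components=3)
        assert model.n_components >= 1
        assert np.isfinite(model.eigenvalues).all()

    def test_c0_orthonormal_components(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(20000, 3)) @ np.diag([1.0, 2.0, 0.5])
        model = tica_fit(x, lag=2, n_components=3)
        gram = model.components.T @ model.c0 @ model.components
        np.testing.assert_allclose(gram, np.eye(3), atol=1e-8)

    def test_eigenvalues_sorted_real(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(5000, 5))
        model = tica_fit(x, lag=1, n_components=5)
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)
        assert model.eigenvalues.dtype.kind == "f"

    def test_multiple_series_no_cross_boundary(self):
        # two constant-but-different series: lagged products never straddle
        a = np.full((100, 1), 1.0)
        b = np.full((100, 1), -1.0)
        noise = np.random.default_rng(7).normal(0, 1e-3, size=(100, 1))
        model = tica_fit([a + noise, b + noise], lag=10, n_components=1)
        assert np.isfinite(model.eigenvalues).all()

    def test_lag_too_long(self):
        with pytest.raises(ValueError, match="lag"):
            tica_fit(np.zeros((5, 2)), lag=10)

    def test_transform_shape(self):
        series, _ = simulate_two_state_series(0.1, 2000, seed=9)
        model = tica_fit(series, lag=1, n_components=1)
        proj = tica_transform(model, series)
        assert proj.shape == (2000, 1)


class TestFes:
    def test_minimum_zero(self, rng):
        proj = rng.normal(size=(5000, 2))
        fes = free_energy_surface(proj, n_bins=20)
        assert np.nanmin(fes.free_energy[np.isfinite(fes.free_energy)]) == 0.0

    def test_uniform_flat(self, rng):
        proj = rng.uniform(0, 1, size=(200000, 2))
        fes = free_energy_surface(proj, n_bins=8)
        occupied = fes.free_energy[np.isfinite(fes.free_energy)]
        assert occupied.max() < 0.2

    def test_sample_count_invariance(self, rng):
        proj = rng.normal(size=(4000, 2))
        edges = (np.linspace(-4, 4, 11), np.linspace(-4, 4, 11))
        f1 = free_energy_surface(proj, n_bins=10)
        f2 = free_energy_surface(np.repeat(proj, 3, axis=0), n_bins=10)
        np.testing.assert_allclose(f1.free_energy, f2.free_energy, atol=1e-12)

    def test_empty_bins_inf(self):
        proj = np.array([[0.0, 0.0], [10.0, 10.0]])
        fes = free_energy_surface(proj, n_bins=5)
        assert np.isinf(fes.free_energy).any()


def _brute_force_minimax(f, start, goal):
    """Oracle: enumerate all simple paths on a small grid."""
    nx, ny = f.shape
    best = [np.inf]

    def dfs(pos, visited, cost):
        cost = max(cost, f[pos])
        if cost >= best[0]:
            return
        if pos == goal:
            best[0] = cost
            return
        x, y = pos
        for dx, dy in itertools.product((-1, 0, 1), repeat=2):
            if (dx, dy) == (0, 0):
                continue
            nxt = (x + dx, y + dy)
            if 0 <= nxt[0] < nx and 0 <= nxt[1] < ny and nxt not in visited:
                dfs(nxt, visited | {nxt}, cost)

    dfs(start, {start}, f[start])
    return best[0]


class TestBarrier:
    def test_matches_brute_force_oracle(self, rng):
        from ssnmrpipe.trajectory import FESGrid
        for trial in range(5):
            f = rng.uniform(0, 3, size=(4, 4))
            f[0, 0] = 0.0
            f[3, 3] = 0.2
            fes = FESGrid(x_edges=np.arange(5), y_edges=np.arange(5),
                          free_energy=f)
            got = estimate_barrier(fes, (0, 0), (3, 3))
            oracle = _brute_force_minimax(f, (0, 0), (3, 3)) - max(f[0, 0],
                                                                   f[3, 3])
            assert got == pytest.approx(oracle, abs=1e-12)

    def test_two_gaussian_mixture(self, rng):
        proj = np.vstack([rng.normal(0, 0.5, size=(20000, 2)),
                          rng.normal(3.0, 0.5, size=(20000, 2))])
        fes = free_energy_surface(proj, n_bins=12)
        a = fes.bin_of(0.0, 0.0)
        b = fes.bin_of(3.0, 3.0)
        barrier = estimate_barrier(fes, a, b)
        assert 0.0 < barrier < np.inf

    def test_disconnected_inf(self):
        from ssnmrpipe.trajectory import FESGrid
        f = np.full((5, 5), np.inf)
        f[0, 0] = 0.0
        f[4, 4] = 0.0
        fes = FESGrid(x_edges=np.arange(6), y_edges=np.arange(6),
                      free_energy=f)
        assert estimate_barrier(fes, (0, 0), (4, 4)) == np.inf

    def test_basin_outside_grid(self):
        from ssnmrpipe.trajectory import FESGrid
        fes = FESGrid(x_edges=np.arange(4), y_edges=np.arange(4),
                      free_energy=np.zeros((3, 3)))
        with pytest.raises(ValueError):
            estimate_barrier(fes, (0, 0), (9, 9))
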