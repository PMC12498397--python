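"""Reweighting, WHAM reconstruction, surface features, minimax paths."""

import numpy as np
import pandas as pd
import pytest

from photomech import (Axis, BiasState, FESGrid, Hill, KB, PathNotFoundError,
                       UmbrellaWindow, beta, double_well_potential,
                       find_features, harmonic_potential, linear_potential,
                       minimum_energy_path, path_max_F, reweight_samples,
                       split_by_attack, wham)

KT = KB * 300.0


def _sample_from_density(energy_fn, lo, hi, n, seed, temperature=300.0):
    """Exact inverse-CDF sampling from exp(-beta V) on a fine grid."""
    grid = np.linspace(lo, hi, 200_001)
    logp = -beta(temperature) * energy_fn(grid)
    p = np.exp(logp - logp.max())
    cdf = np.cumsum(p)
    cdf /= cdf[-1]
    rng = np.random.default_rng(seed)
    return np.interp(rng.random(n), cdf, grid)


def _grid_from_array(F, lo=0.0, hi=1.0):
    F = np.asarray(F, dtype=float)
    if F.ndim == 1:
        ax1, ax2 = Axis("s1", lo, hi, len(F)), None
    else:
        ax1 = Axis("s1", lo, hi, F.shape[0])
        ax2 = Axis("s2", lo, hi, F.shape[1])
    return FESGrid(axis1=ax1, axis2=ax2, F=F.copy(),
                   counts=np.full_like(F, 100.0),
                   sampled_mask=np.ones_like(F, dtype=bool))


class TestReweighting:
    def test_zero_bias_gives_uniform_weights(self):
        df = pd.DataFrame({"s1": [2.5, 3.0, 4.0], "s2": [4.0, 3.0, 2.5]})
        w = reweight_samples(df, BiasState())
        assert np.allclose(w, 1.0)

    def test_two_point_weight_ratio_equals_boltzmann_factor(self):
        state = BiasState()
        state.hills = [Hill(center=3.0, sigma=0.2, height=2.0,
                            deposit_time=0.0)]
        df = pd.DataFrame({"s1": [2.5, 2.5], "s2": [3.0, 3.6]})
        w = reweight_samples(df, state)
        dv = (state.hills_energy(np.array([3.0]))
              - state.hills_energy(np.array([3.6])))[0]
        assert w[0] / w[1] == pytest.approx(np.exp(dv / KT), rel=1e-10)

    def test_reweighted_histogram_recovers_unbiased_density(self):
        """Samples from a biased Boltzmann density, reweighted, match the
        unbiased analytic density (weighted-KS below sampling error)."""
        pot = harmonic_potential(k=20.0, center=3.0)
        state = BiasState()
        state.hills = [Hill(center=c, sigma=0.3, height=h, deposit_time=0.0)
                       for c, h in ((2.6, 4.0), (3.4, 3.0))]

        def biased(x):
            return pot.energy(x[:, None]) + state.hills_energy(x)

        x = _sample_from_density(biased, 1.0, 5.0, 100_000, seed=4)
        w = reweight_samples(pd.DataFrame({"s1": x}), state,
                             cv_columns=("s1",))
        order = np.argsort(x)
        ecdf = np.cumsum(w[order]) / w.sum()
        grid = np.linspace(1.0, 5.0, 20_001)
        p = np.exp(-pot.energy(grid[:, None]) / KT)
        cdf = np.cumsum(p) / p.sum()
        cdf_at_x = np.interp(x[order], grid, cdf)
        ks = np.max(np.abs(ecdf - cdf_at_x))
        n_eff = w.sum() ** 2 / np.sum(w**2)
        assert ks < 1.63 / np.sqrt(n_eff)       # 99% KS band


class TestWHAM:
    def test_single_unbiased_window_is_boltzmann_inversion(self):
        pot = double_well_potential(barrier=6.0, spacing=1.0, tilt=2.0)
        x = _sample_from_density(lambda g: pot.energy(g[:, None]),
                                 -1.2, 1.2, 300_000, seed=7)
        grid_spec = (Axis("s1", -1.2, 1.2, 48), None)
        grid, st = wham([(None, pd.DataFrame({"s1": x}))], grid_spec,
                        min_count=200, check_overlap=False)
        c = grid.axis1.centers
        mask = grid.sampled_mask
        F_true = pot.energy(c[:, None])
        diff = grid.F[mask] - F_true[mask]
        diff -= diff.mean()
        assert np.sqrt(np.mean(diff**2)) < 0.35     # ~0.15 kT

    def test_two_overlapping_windows_recover_a_linear_slope(self):
        slope = 3.0
        k = 50.0
        grid_spec = (Axis("s1", 2.0, 5.0, 60), None)
        windows, dfs = [], []
        for i, c in enumerate((3.2, 3.8)):
            win = UmbrellaWindow(index=i, center=c, force_constant=k)
            mean = c - slope / k
            sd = np.sqrt(KT / k)
            rng = np.random.default_rng(10 + i)
            dfs.append(pd.DataFrame({"s1": rng.normal(mean, sd, 200_000)}))
            windows.append(win)
        grid, st = wham(list(zip(windows, dfs)), grid_spec, min_count=500)
        assert st.converged
        c = grid.axis1.centers[grid.sampled_mask]
        F = grid.F[grid.sampled_mask]
        fit = np.polyfit(c, F, 1)
        assert fit[0] == pytest.approx(slope, rel=0.05)

    def test_non_overlapping_windows_raise_with_gap(self):
        k = 400.0
        windows, dfs = [], []
        for i, c in enumerate((2.5, 5.5)):
            win = UmbrellaWindow(index=i, center=c, force_constant=k)
            rng = np.random.default_rng(i)
            dfs.append(pd.DataFrame({"s1": rng.normal(c, 0.05, 5000)}))
            windows.append(win)
        with pytest.raises(ValueError, match="gap"):
            wham(list(zip(windows, dfs)), (Axis("s1", 2.0, 6.0, 60), None))

    def test_constant_bias_shift_leaves_the_surface_unchanged(self):
        """A flat extra bias applied to every window only shifts the
        window free energies; F is gauge-invariant."""
        slope = 2.0
        k = 50.0
        windows, dfs = [], []
        for i, c in enumerate((3.2, 3.8)):
            win = UmbrellaWindow(index=i, center=c, force_constant=k)
            rng = np.random.default_rng(20 + i)
            dfs.append(pd.DataFrame(
                {"s1": rng.normal(c - slope / k, np.sqrt(KT / k), 50_000)}))
            windows.append(win)
        spec = (Axis("s1", 2.0, 5.0, 60), None)
        g0, _ = wham(list(zip(windows, dfs)), spec, min_count=100)
        flat = BiasState(meta_cv=0)
        flat.hills = [Hill(center=3.5, sigma=1e6, height=5.0,
                           deposit_time=0.0)]
        g1, _ = wham(list(zip(windows, dfs)), spec, min_count=100,
                     meta_states=[flat, flat], bias_time_average=0.0)
        m = g0.sampled_mask & g1.sampled_mask
        assert np.allclose(g0.F[m], g1.F[m], atol=1e-6)

    def test_restart_from_converged_f_converges_immediately(self):
        k = 50.0
        windows, dfs = [], []
        for i, c in enumerate((3.2, 3.8)):
            win = UmbrellaWindow(index=i, center=c, force_constant=k)
            rng = np.random.default_rng(30 + i)
            dfs.append(pd.DataFrame(
                {"s1": rng.normal(c, np.sqrt(KT / k), 20_000)}))
            windows.append(win)
        spec = (Axis("s1", 2.0, 5.0, 60), None)
        _, st = wham(list(zip(windows, dfs)), spec, min_count=50)
        assert st.converged
        _, st2 = wham(list(zip(windows, dfs)), spec, min_count=50,
                      f_init=st.f)
        assert st2.iterations <= 2


class TestSplitByAttack:
    def test_rule_and_tie_break(self):
        df = pd.DataFrame({"alpha": [60.0, 135.0, 90.0],
                           "s1": [1, 2, 3], "s2": [1, 2, 3]})
        cis, trans = split_by_attack(df)
        assert list(cis["alpha"]) == [60.0, 90.0]
        assert list(trans["alpha"]) == [135.0]

    def test_partition_property(self, rng):
        df = pd.DataFrame({"alpha": rng.uniform(0, 180, 5000)})
        cis, trans = split_by_attack(df)
        assert len(cis) + len(trans) == len(df)


class TestFindFeatures:
    def test_single_well_paraboloid(self):
        x = np.linspace(-1, 1, 21)
        F = x[:, None] ** 2 + x[None, :] ** 2
        feats = find_features(_grid_from_array(10 * F), min_depth=0.5)
        minima = [f for f in feats if f.kind == "minimum"]
        saddles = [f for f in feats if f.kind == "saddle"]
        assert len(minima) == 1 and len(saddles) == 0

    def test_flat_grid_has_no_features(self):
        feats = find_features(_grid_from_array(np.zeros((10, 10))),
                              min_depth=0.0)
        assert feats == []

    def test_double_well_minima_saddle_and_barrier(self):
        """Two wells separated by a 5 kJ/mol ridge with a 5 kJ/mol pass."""
        x = np.linspace(-1.5, 1.5, 41)
        X, Y = np.meshgrid(x, x, indexing="ij")
        F = 5.0 * ((X**2 - 1.0) ** 2 + Y**2)
        grid = _grid_from_array(F, lo=-1.5, hi=1.5)
        feats = find_features(grid, min_depth=2.5)
        minima = [f for f in feats if f.kind == "minimum"]
        saddles = [f for f in feats if f.kind == "saddle"]
        assert len(minima) == 2
        assert len(saddles) == 1
        bin_span = 5.0 * (x[1] - x[0]) * 4  # max |dF| across one bin
        assert saddles[0].depth == pytest.approx(5.0, abs=bin_span)

    def test_shallow_minima_are_filtered_by_depth(self):
        F = np.array([[0.0, 1.0, 0.4, 1.0, 5.0]])
        grid = _grid_from_array(F.T)
        deep = find_features(grid, min_depth=0.3)
        shallow = find_features(grid, min_depth=0.8)
        assert sum(f.kind == "minimum" for f in deep) == 2
        assert sum(f.kind == "minimum" for f in shallow) == 1


def _minimax_oracle(F, start, end):
    """Brute force: smallest level L such that start..end are connected
    through bins with F <= L (checked by BFS per candidate level)."""
    levels = np.unique(F)
    for L in levels:
        ok = F <= L
        if not (ok[start] and ok[end]):
            continue
        stack, seen = [start], {start}
        while stack:
            i, j = stack.pop()
            if (i, j) == end:
                return L
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    a, b = i + di, j + dj
                    if (0 <= a < F.shape[0] and 0 <= b < F.shape[1]
                            and ok[a, b] and (a, b) not in seen):
                        seen.add((a, b))
                        stack.append((a, b))
    raise AssertionError("disconnected")


class TestMinimumEnergyPath:
    def test_monotone_ramp_takes_the_straight_path(self):
        F = np.tile(np.linspace(0, 5, 12), (1, 1)).reshape(12, 1)
        grid = _grid_from_array(F)
        path = minimum_energy_path(grid, (0, 0), (11, 0))
        assert len(path) == 12
        assert path_max_F(grid, path) == pytest.approx(5.0)

    def test_path_crosses_the_lower_of_two_saddles(self):
        F = np.full((5, 5), 10.0)
        F[0, :] = [0, 1, 8, 1, 0]        # ridge row with two passes
        F[:, 0] = 0                       # left basin column
        F[:, 4] = 0                       # right basin column
        F[2, 1:4] = [2, 2, 2]            # lower pass through the middle
        grid = _grid_from_array(F)
        path = minimum_energy_path(grid, (4, 0), (4, 4))
        assert path_max_F(grid, path) == pytest.approx(2.0)

    def test_minimax_value_matches_brute_force_on_random_grids(self, rng):
        """100 random grids up to 8×8: Dijkstra minimax equals the
        level-threshold connectivity oracle."""
        for trial in range(100):
            n1 = rng.integers(3, 9)
            n2 = rng.integers(3, 9)
            F = rng.uniform(0, 10, size=(n1, n2))
            start = (0, 0)
            end = (int(n1 - 1), int(n2 - 1))
            grid = _grid_from_array(F)
            path = minimum_energy_path(grid, start, end)
            assert path_max_F(grid, path) == pytest.approx(
                _minimax_oracle(F, start, end), abs=1e-12)

    def test_tie_break_prefers_lower_integrated_F(self):
        """Among equal-minimax paths the cheaper one is returned,
        checked against exhaustive simple-path enumeration on 3×3."""
        F = np.array([[0.0, 5.0, 0.0],
                      [1.0, 9.0, 3.0],
                      [0.0, 5.0, 0.0]])
        grid = _grid_from_array(F)
        path = minimum_energy_path(grid, (0, 0), (2, 2))

        best = None
        def dfs(node, seen, maxF, sumF):
            nonlocal best
            if node == (2, 2):
                cand = (maxF, sumF)
                if best is None or cand < best:
                    best = cand
                return
            i, j = node
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    a, b = i + di, j + dj
                    if (di, dj) != (0, 0) and 0 <= a < 3 and 0 <= b < 3 \
                            and (a, b) not in seen:
                        dfs((a, b), seen | {(a, b)},
                            max(maxF, F[a, b]), sumF + F[a, b])
        dfs((0, 0), {(0, 0)}, F[0, 0], F[0, 0])
        got = (path_max_F(grid, path), sum(F[i, j] for i, j in path))
        assert got == pytest.approx(best)

    def test_disconnected_bins_raise_with_contour_level(self):
        F = np.zeros((5, 5))
        mask = np.ones_like(F, dtype=bool)
        mask[:, 2] = False                 # unsampled wall
        grid = _grid_from_array(F)
        grid.sampled_mask = mask
        with pytest.raises(PathNotFoundError, match="contour"):
            minimum_energy_path(grid, (2, 0), (2, 4))
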