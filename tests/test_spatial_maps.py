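"""Rate maps, autocorrelograms, gridness scores and symmetry statistics."""

import numpy as np
import pytest

from gridscape import spatial_maps as sm
from gridscape.errors import (EmptyInputError, InsufficientSamplingError,
                              UndefinedEllipseError)
from gridscape.geometry import make_connected
from gridscape.spatial_maps import (Autocorrelogram, RateMap, autocorrelogram,
                                    ellipticity, firing_field_map,
                                    half_map_similarity, hgs, local_global_hgs,
                                    rate_map, synthetic_lattice_map)
from gridscape.trajectory import Trajectory


def _grid_traj(n=4000, side=1.0, seed=0):
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0, side, size=(n, 2))
    return Trajectory(t=np.arange(n) * 0.01, pos=pos,
                      heading=np.zeros(n), speed=np.ones(n))


class TestFiringField:
    def test_constant_response_empty(self):
        traj = _grid_traj(100)
        pts = firing_field_map(traj, np.ones(100), 0.8)
        assert len(pts) == 0

    def test_indicator_response(self):
        traj = _grid_traj(1000)
        resp = (traj.x < 0.5).astype(float)
        pts = firing_field_map(traj, resp, 0.5)
        assert (pts[:, 0] < 0.5).all()
        assert len(pts) == int(resp.sum())

    def test_count_matches_quantile_recount(self, rng):
        traj = _grid_traj(2000)
        resp = rng.normal(size=2000)
        pts = firing_field_map(traj, resp, 0.8)
        assert len(pts) == int((resp > np.quantile(resp, 0.8)).sum())

    def test_empty_response_raises(self):
        with pytest.raises(EmptyInputError):
            firing_field_map(_grid_traj(10), np.array([]), 0.8)


class TestRateMap:
    def test_constant_response(self):
        traj = _grid_traj(5000)
        rm = rate_map(traj, np.full(5000, 3.0), 0.1, smoothing_sigma=0)
        vals = rm.grid[rm.visited]
        np.testing.assert_allclose(vals, 3.0)

    def test_monotone_along_x(self):
        traj = _grid_traj(20000)
        rm = rate_map(traj, traj.x, 0.2, smoothing_sigma=0)
        col_means = np.nanmean(rm.grid, axis=0)
        assert (np.diff(col_means) > 0).all()

    def test_gaussian_bump_peak_location(self):
        traj = _grid_traj(40000)
        resp = np.exp(-((traj.x - 0.6) ** 2 + (traj.y - 0.3) ** 2) / (2 * 0.05 ** 2))
        rm = rate_map(traj, resp, 0.05, smoothing_sigma=1.0)
        iy, ix = np.unravel_index(np.nanargmax(rm.grid), rm.grid.shape)
        x = rm.extent[0] + (ix + 0.5) * rm.bin_size
        y = rm.extent[1] + (iy + 0.5) * rm.bin_size
        assert abs(x - 0.6) <= rm.bin_size and abs(y - 0.3) <= rm.bin_size

    def test_negative_responses_rectified(self):
        traj = _grid_traj(5000)
        rm = rate_map(traj, np.full(5000, -1.0), 0.1, smoothing_sigma=0)
        np.testing.assert_allclose(rm.grid[rm.visited], 0.0)


def naive_autocorrelogram(grid, visited):
    """Literal O(N^4) double loop over lags and pixels (independent oracle)."""
    ny, nx = grid.shape
    out = np.full((2 * ny - 1, 2 * nx - 1), np.nan)
    for ty in range(-(ny - 1), ny):
        for tx in range(-(nx - 1), nx):
            a, b = [], []
            for y in range(ny):
                for x in range(nx):
                    ys, xs = y - ty, x - tx
                    if 0 <= ys < ny and 0 <= xs < nx and visited[y, x] and visited[ys, xs]:
                        a.append(grid[y, x])
                        b.append(grid[ys, xs])
            M = len(a)
            if M < sm.MIN_OVERLAP_PIXELS:
                continue
            a, b = np.array(a), np.array(b)
            num = M * (a * b).sum() - a.sum() * b.sum()
            den = np.sqrt((M * (a ** 2).sum() - a.sum() ** 2)
                          * (M * (b ** 2).sum() - b.sum() ** 2))
            if den > 1e-12 * M ** 2:
                out[ny - 1 + ty, nx - 1 + tx] = num / den
    return out


class TestAutocorrelogram:
    def test_zero_lag_is_one(self):
        rm = synthetic_lattice_map("hex", spacing=0.3, side=1.2, bin_size=0.05)
        ac = autocorrelogram(rm)
        cy, cx = ac.center
        assert ac.r[cy, cx] == pytest.approx(1.0)

    def test_point_symmetry(self):
        rm = synthetic_lattice_map("hex", spacing=0.3, side=1.2, bin_size=0.05,
                                   angle=0.3)
        ac = autocorrelogram(rm)
        r, flipped = ac.r, ac.r[::-1, ::-1]
        both = np.isfinite(r) & np.isfinite(flipped)
        np.testing.assert_allclose(r[both], flipped[both], atol=1e-9)

    def test_matches_naive_double_loop(self, rng):
        """FFT implementation vs literal quadruple loop on a 16x16 map."""
        grid = rng.normal(size=(16, 16))
        visited = rng.uniform(size=(16, 16)) > 0.15
        rm = RateMap(grid=np.where(visited, grid, np.nan),
                     occupancy=visited.astype(float), bin_size=1.0,
                     extent=(0, 0, 16, 16))
        ac = autocorrelogram(rm)
        oracle = naive_autocorrelogram(np.where(visited, grid, 0.0), visited)
        cy = oracle.shape[0] // 2
        L = ac.max_lag_bins
        oracle = oracle[cy - L:cy + L + 1, cy - L:cy + L + 1]
        both = np.isfinite(ac.r) & np.isfinite(oracle)
        assert both.sum() > 100
        np.testing.assert_allclose(ac.r[both], oracle[both], atol=1e-10)
        # masking agrees as well
        np.testing.assert_array_equal(np.isfinite(ac.r), np.isfinite(oracle))

    def test_hex_lattice_six_peaks(self):
        rm = synthetic_lattice_map("hex", spacing=0.3, side=1.8, bin_size=0.03)
        ac = autocorrelogram(rm, max_lag=0.75)
        peaks = sm._ring_peaks(ac)
        assert len(peaks) == 6
        radii = np.hypot(peaks[:, 0], peaks[:, 1]) * ac.bin_size
        np.testing.assert_allclose(radii, 0.3, rtol=0.12)
        ang = np.sort(np.mod(np.degrees(np.arctan2(peaks[:, 1], peaks[:, 0])), 360))
        gaps = np.diff(np.concatenate([ang, [ang[0] + 360]]))
        np.testing.assert_allclose(gaps, 60, atol=8)

    def test_stripe_pattern_ridge(self):
        n = 60
        xs = (np.arange(n) + 0.5) * 0.03
        X, _ = np.meshgrid(xs, xs)
        k = 2 * np.pi / 0.4
        rm = RateMap(grid=np.cos(k * X), occupancy=np.ones((n, n)),
                     bin_size=0.03, extent=(0, 0, 1.8, 1.8))
        ac = autocorrelogram(rm)
        cy, cx = ac.center
        lag_bins = int(round(0.4 / 0.03))
        assert ac.r[cy, cx + lag_bins] > 0.9       # ridge at tau_x = 2pi/k
        assert ac.r[cy + lag_bins, cx] > 0.9       # constant along y

    def test_degenerate_map_warns(self):
        rm = RateMap(grid=np.ones((8, 8)), occupancy=np.ones((8, 8)),
                     bin_size=1.0, extent=(0, 0, 8, 8))
        with pytest.warns(UserWarning):
            ac = autocorrelogram(rm)
        cy, cx = ac.center
        off_center = np.delete(ac.r.ravel(), cy * ac.r.shape[1] + cx)
        assert np.isnan(off_center).all()


class TestHGS:
    def test_hexagonal_lattice_high(self):
        rm = synthetic_lattice_map("hex", spacing=0.3, side=1.8, bin_size=0.03)
        assert hgs(autocorrelogram(rm, max_lag=0.75)) > 1.0

    def test_square_lattice_negative(self):
        rm = synthetic_lattice_map("square", spacing=0.3, side=1.8, bin_size=0.03)
        assert hgs(autocorrelogram(rm, max_lag=0.75)) < 0.0

    def test_rotationally_symmetric_autocorrelogram_scores_zero(self):
        """All rotations of a polar-symmetric pattern are identical -> HGS ~ 0."""
        L = 25
        yy, xx = np.indices((2 * L + 1, 2 * L + 1))
        rad = np.hypot(yy - L, xx - L)
        ac = Autocorrelogram(r=np.cos(2 * np.pi * rad / 10.0),
                             n_pixels_used=np.full((2 * L + 1, 2 * L + 1), 1000),
                             bin_size=0.03)
        assert abs(hgs(ac)) < 0.05

    def test_rotation_invariance(self):
        base = hgs(autocorrelogram(
            synthetic_lattice_map("hex", 0.3, 1.8, 0.03), max_lag=0.75))
        rot = hgs(autocorrelogram(
            synthetic_lattice_map("hex", 0.3, 1.8, 0.03, angle=0.3), max_lag=0.75))
        assert rot == pytest.approx(base, abs=0.05)

    def test_scale_invariance(self):
        a = hgs(autocorrelogram(
            synthetic_lattice_map("hex", 0.3, 1.8, 0.03), max_lag=0.75))
        b = hgs(autocorrelogram(
            synthetic_lattice_map("hex", 0.6, 3.6, 0.06), max_lag=1.5))
        assert b == pytest.approx(a, abs=0.05)

    def test_noise_degrades_gridness_monotonically(self):
        """Mean HGS over seeds decreases as lattice noise grows."""
        levels = np.linspace(0.0, 1.8, 10)
        means = []
        for noise in levels:
            vals = [hgs(autocorrelogram(
                synthetic_lattice_map("hex", 0.3, 1.8, 0.03,
                                      noise=noise, seed=s), max_lag=0.75))
                for s in range(10)]
            means.append(np.mean(vals))
        # strictly decreasing trend up to small jitter between adjacent levels
        assert means[0] > means[-1] + 0.5
        assert all(means[i + 1] < means[i] + 0.1 for i in range(9))


class TestEllipticity:
    def test_circular_ring_unity(self):
        rm = synthetic_lattice_map("hex", spacing=0.3, side=1.8, bin_size=0.03)
        assert ellipticity(autocorrelogram(rm, max_lag=0.75)) == pytest.approx(1.0, abs=0.05)

    def test_stretched_lattice(self):
        rm = synthetic_lattice_map("hex", spacing=0.3, side=1.8, bin_size=0.03,
                                   stretch_x=1.5)
        assert ellipticity(autocorrelogram(rm, max_lag=0.9)) == pytest.approx(1.5, abs=0.1)

    def test_too_few_peaks_raises(self):
        # a single central bump has no ring peaks at all
        n = 60
        xs = (np.arange(n) + 0.5) * 0.03
        X, Y = np.meshgrid(xs, xs)
        grid = np.exp(-((X - 0.9) ** 2 + (Y - 0.9) ** 2) / (2 * 0.2 ** 2))
        rm = RateMap(grid=grid, occupancy=np.ones((n, n)), bin_size=0.03,
                     extent=(0, 0, 1.8, 1.8))
        with pytest.raises(UndefinedEllipseError):
            ellipticity(autocorrelogram(rm, max_lag=0.75))


class TestHalfMapSimilarity:
    def test_mirror_symmetric_map(self):
        n = 40
        xs = (np.arange(n) + 0.5) * 0.05
        X, Y = np.meshgrid(xs, xs)
        grid = np.cos(2 * np.pi * np.abs(X - 1.0) / 0.4) + 0.3 * Y
        rm = RateMap(grid=grid, occupancy=np.ones((n, n)), bin_size=0.05,
                     extent=(0, 0, 2, 2))
        assert half_map_similarity(rm, "vertical") == pytest.approx(1.0, abs=1e-9)

    def test_constant_halves_flagged(self):
        grid = np.where(np.arange(20)[None, :] < 10, 1.0, 2.0) * np.ones((20, 20))
        rm = RateMap(grid=grid, occupancy=np.ones((20, 20)), bin_size=0.1,
                     extent=(0, 0, 2, 2))
        with pytest.warns(UserWarning):
            assert np.isnan(half_map_similarity(rm, "vertical"))

    def test_matches_bruteforce_on_shifted_lattice(self):
        n = 40
        xs = (np.arange(n) + 0.5) * 0.05
        X, Y = np.meshgrid(xs, xs)
        grid = np.cos(2 * np.pi * X / 0.37 + 0.8) * np.cos(2 * np.pi * Y / 0.41)
        rm = RateMap(grid=grid, occupancy=np.ones((n, n)), bin_size=0.05,
                     extent=(0, 0, 2, 2))
        got = half_map_similarity(rm, "vertical")
        left = grid[:, :20]
        right = grid[:, 20:][:, ::-1]
        expected = np.corrcoef(left.ravel(), right.ravel())[0, 1]
        assert got == pytest.approx(expected, abs=1e-12)


class TestLocalGlobal:
    @staticmethod
    def _connected_fixture(seed=0, mismatch=False):
        env = make_connected("square", "square", 1.8, 0.8, 0.2)
        rng = np.random.default_rng(seed)
        pts = env.sample_interior(rng, 30000)
        n = len(pts)
        traj = Trajectory(t=np.arange(n) * 0.01, pos=pts,
                          heading=np.zeros(n), speed=np.ones(n))
        k = 2 * np.pi / 0.45

        def lattice(x, y, theta):
            c, s = np.cos(theta), np.sin(theta)
            xr, yr = c * x - s * y, s * x + c * y
            return (np.cos(k * xr) + np.cos(k * (xr / 2 + np.sqrt(3) * yr / 2))
                    + np.cos(k * (xr / 2 - np.sqrt(3) * yr / 2)) + 3) / 6

        if mismatch:
            resp = np.where(traj.x < 0, lattice(traj.x, traj.y, 0.0),
                            lattice(traj.x, traj.y, 0.5))
        else:
            resp = lattice(traj.x, traj.y, 0.0)
        return env, traj, resp

    def test_continuous_lattice_global_at_least_local(self):
        env, traj, resp = self._connected_fixture()
        loc, glob = local_global_hgs(env, traj, resp, bin_size=0.05)
        assert glob >= loc - 0.05

    def test_mismatched_lattices_degrade_global(self):
        env, traj, resp = self._connected_fixture(mismatch=True)
        loc_m, glob_m = local_global_hgs(env, traj, resp, bin_size=0.05)
        _, glob_c = local_global_hgs(*self._connected_fixture(), bin_size=0.05)
        assert loc_m > glob_m          # locally hexagonal, globally broken
        assert glob_m < glob_c         # and worse than the seamless lattice

    def test_corridor_only_samples_error(self):
        env = make_connected("square", "square", 1.8, 0.8, 0.5)
        n = 500
        pos = np.column_stack([np.random.default_rng(0).uniform(-0.2, 0.2, n),
                               np.zeros(n)])
        traj = Trajectory(t=np.arange(n) * 0.01, pos=pos,
                          heading=np.zeros(n), speed=np.ones(n))
        with pytest.raises(InsufficientSamplingError):
            local_global_hgs(env, traj, np.ones(n))
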