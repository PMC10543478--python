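"""Tests of rate-map estimation and circular-track linearization."""

import numpy as np
import pytest

from gridpop.core import Geometry, SpikeTrain, Trajectory
from gridpop.ratemaps import average_rate_map, linearize, linearized_position
from gridpop.synthetic import spikes_from_rate, synth_trajectory


def brute_force_rate_map(traj, spikes, origin, shape, bin_size, sigma,
                         unvisited_radius):
    """Direct evaluation of the kernel-ratio estimator at every bin center."""
    ox, oy = origin
    dt = np.median(np.diff(traj.times))
    sx = np.interp(spikes.spike_times, traj.times, traj.positions[:, 0])
    sy = np.interp(spikes.spike_times, traj.times, traj.positions[:, 1])
    out = np.zeros(shape)
    mask = np.zeros(shape, dtype=bool)
    for iy in range(shape[0]):
        for ix in range(shape[1]):
            x = ox + ix * bin_size
            y = oy + iy * bin_size
            d2s = (sx - x) ** 2 + (sy - y) ** 2
            num = np.exp(-d2s / (2 * sigma ** 2)).sum()
            d2t = ((traj.positions[:, 0] - x) ** 2
                   + (traj.positions[:, 1] - y) ** 2)
            den = dt * np.exp(-d2t / (2 * sigma ** 2)).sum()
            visited = np.sqrt(d2t.min()) <= unvisited_radius
            mask[iy, ix] = visited
            if visited and den > 0:
                out[iy, ix] = num / den
    return out, mask


class TestAverageRateMap:
    def test_no_spikes_gives_zero_map(self, small_arena):
        traj = synth_trajectory(small_arena, duration=60.0, seed=0)
        m = average_rate_map(traj, SpikeTrain(spike_times=np.array([])),
                             geometry=small_arena)
        assert np.all(m.values == 0)
        assert m.visited_mask.any()
        assert not m.visited_mask.all()  # corners never visited

    def test_matches_direct_formula_evaluation(self):
        """Estimator equals the kernel-ratio formula computed point by point."""
        geom = Geometry(kind="arena", outer_radius=8.0)
        traj = synth_trajectory(geom, duration=30.0, speed=8.0, seed=1)
        spikes = spikes_from_rate(lambda x, y: np.full_like(x, 4.0), traj,
                                  seed=2)
        m = average_rate_map(traj, spikes, geometry=geom)
        ref, ref_mask = brute_force_rate_map(
            traj, spikes, geom.grid_origin, (geom.n_bins, geom.n_bins),
            1.0, 3.0, 3.0)
        np.testing.assert_array_equal(m.visited_mask, ref_mask)
        np.testing.assert_allclose(m.values, np.where(ref_mask, ref, 0.0),
                                   atol=1e-9)

    def test_single_spike_peaks_at_spike_location(self):
        geom = Geometry(kind="arena", outer_radius=10.0)
        n = 2000
        rng = np.random.default_rng(3)
        ang = rng.uniform(0, 2 * np.pi, n)
        rad = 9.0 * np.sqrt(rng.uniform(0, 1, n))
        traj = Trajectory(times=0.02 * np.arange(n),
                          positions=np.column_stack([rad * np.cos(ang),
                                                     rad * np.sin(ang)]))
        # pick a spike well inside the arena so boundary occupancy falloff
        # cannot shift the maximum outward
        interior = np.nonzero(np.hypot(rad * np.cos(ang),
                                       rad * np.sin(ang)) < 4.0)[0]
        idx = interior[len(interior) // 2]
        t_spike = traj.times[idx]
        x0, y0 = traj.positions[idx]
        m = average_rate_map(traj, SpikeTrain(spike_times=np.array([t_spike])),
                             geometry=geom)
        iy, ix = np.unravel_index(np.argmax(m.values), m.shape)
        X, Y = m.bin_centers()
        assert abs(X[iy, ix] - x0) <= 1.5
        assert abs(Y[iy, ix] - y0) <= 1.5

    def test_homogeneous_rate_recovery(self, small_arena):
        """A 5-Hz homogeneous Poisson cell estimates to ~5 Hz everywhere."""
        traj = synth_trajectory(small_arena, duration=600.0, seed=4)
        spikes = spikes_from_rate(lambda x, y: np.full_like(x, 5.0), traj,
                                  seed=5)
        m = average_rate_map(traj, spikes, geometry=small_arena)
        mean_rate = m.values[m.visited_mask].mean()
        assert abs(mean_rate - 5.0) < 0.5

    def test_spike_count_conservation(self, small_arena):
        """Σ rate·occupancy over bins ≈ total spike count (edge effects <5%)."""
        traj = synth_trajectory(small_arena, duration=600.0, seed=6)
        spikes = spikes_from_rate(lambda x, y: np.full_like(x, 5.0), traj,
                                  seed=7)
        m = average_rate_map(traj, spikes, geometry=small_arena)
        dt = traj.median_dt
        X, Y = m.bin_centers()
        occ = np.zeros(m.shape)
        ox, oy = m.origin
        ix = np.round((traj.positions[:, 0] - ox)).astype(int)
        iy = np.round((traj.positions[:, 1] - oy)).astype(int)
        np.add.at(occ, (iy, ix), dt)
        total = (m.values * occ).sum()
        assert abs(total - len(spikes)) / len(spikes) < 0.05

    def test_translation_invariance(self):
        geom = Geometry(kind="arena", outer_radius=10.0)
        traj = synth_trajectory(geom, duration=60.0, seed=8)
        spikes = spikes_from_rate(lambda x, y: np.full_like(x, 6.0), traj,
                                  seed=9)
        m1 = average_rate_map(traj, spikes, geometry=geom)
        shift = np.array([13.0, -27.0])
        geom2 = Geometry(kind="arena", outer_radius=10.0,
                         center=(13.0, -27.0))
        traj2 = Trajectory(times=traj.times, positions=traj.positions + shift)
        m2 = average_rate_map(traj2, spikes, geometry=geom2)
        np.testing.assert_allclose(m1.values, m2.values, atol=1e-9)

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError):
            Trajectory(times=np.array([]), positions=np.empty((0, 2)))

    def test_spike_outside_time_range_rejected(self, small_arena):
        traj = synth_trajectory(small_arena, duration=10.0, seed=0)
        bad = SpikeTrain(spike_times=np.array([traj.times[-1] + 5.0]))
        with pytest.raises(ValueError):
            average_rate_map(traj, bad, geometry=small_arena)


def circle_trajectory(radius, n_turns, n=2000, clockwise=True, t0=0.0):
    """Exact circular path at constant angular speed."""
    t = t0 + 0.02 * np.arange(n)
    ang0 = np.pi / 4
    sweep = 2 * np.pi * n_turns * np.linspace(0, 1, n)
    ang = ang0 - sweep if clockwise else ang0 + sweep
    return Trajectory(times=t, positions=np.column_stack(
        [radius * np.cos(ang), radius * np.sin(ang)]))


class TestLinearize:
    def test_stationary_animal(self):
        t = np.arange(50) * 0.02
        pos = np.tile([70.0, 0.0], (50, 1))
        traj = Trajectory(times=t, positions=pos)
        lin = linearize(traj, SpikeTrain(spike_times=np.array([0.5])))
        assert lin.total_distance == 0.0
        assert (lin.rates > 0).sum() == 1

    def test_full_clockwise_lap_is_circumference(self):
        traj = circle_trajectory(75.0, 1.0, clockwise=True)
        pos = linearized_position(traj, radius_convention=75.0)
        assert abs(pos[-1] - 2 * np.pi * 75.0) < 1.0  # ~471 cm
        assert abs(pos[-1] - 471.0) < 1.5

    def test_reversal_returns_to_zero(self):
        fwd = circle_trajectory(70.0, 0.5, clockwise=True)
        n = len(fwd.times)
        back = np.vstack([fwd.positions, fwd.positions[::-1][1:]])
        t = 0.02 * np.arange(2 * n - 1)
        traj = Trajectory(times=t, positions=back)
        pos = linearized_position(traj, radius_convention=70.0)
        assert abs(pos[-1]) < 1.0

    def test_midline_convention_gives_424(self):
        traj = circle_trajectory(67.5, 1.0, clockwise=True)
        pos = linearized_position(traj, radius_convention=67.5)
        assert abs(pos[-1] - 424.0) < 1.5

    def test_center_crossing_rejected(self):
        traj = Trajectory(times=np.array([0.0, 1.0]),
                          positions=np.array([[0.0, 0.0], [1.0, 0.0]]))
        with pytest.raises(ValueError):
            linearize(traj, SpikeTrain(spike_times=np.array([])))

    def test_concatenation_additivity(self):
        """Cumulative angle over a concatenated path equals the sum of the
        segment displacements."""
        a = circle_trajectory(70.0, 0.4, clockwise=True)
        b = circle_trajectory(70.0, 0.3, clockwise=False,
                              t0=a.times[-1] + 0.02)
        # rotate b to start where a ends
        ang_a_end = np.arctan2(a.positions[-1, 1], a.positions[-1, 0])
        ang_b_start = np.arctan2(b.positions[0, 1], b.positions[0, 0])
        rot = ang_a_end - ang_b_start
        R = np.array([[np.cos(rot), -np.sin(rot)], [np.sin(rot), np.cos(rot)]])
        b_pos = b.positions @ R.T
        joint = Trajectory(times=np.concatenate([a.times, b.times[1:]]),
                           positions=np.vstack([a.positions, b_pos[1:]]))
        pa = linearized_position(a, radius_convention=70.0)
        pb = linearized_position(
            Trajectory(times=b.times, positions=b_pos),
            radius_convention=70.0)
        pj = linearized_position(joint, radius_convention=70.0)
        assert abs(pj[-1] - (pa[-1] + pb[-1])) < 1e-6

    def test_rate_definition_spikes_over_timestamps(self):
        """Per-bin rate = spikes / timestamps / Δt."""
        traj = circle_trajectory(75.0, 1.0)
        rng = np.random.default_rng(1)
        st = SpikeTrain(spike_times=np.sort(
            rng.uniform(traj.times[0], traj.times[-1], 200)))
        lin = linearize(traj, st, radius_convention=75.0)
        dt = traj.median_dt
        pos = linearized_position(traj, radius_convention=75.0)
        spike_pos = np.interp(st.spike_times, traj.times, pos)
        k = len(lin.rates) // 2
        lo, hi = lin.bin_edges[k], lin.bin_edges[k + 1]
        n_ts = ((pos >= lo) & (pos < hi)).sum()
        n_sp = ((spike_pos >= lo) & (spike_pos < hi)).sum()
        expected = n_sp / n_ts / dt if n_ts else 0.0
        assert np.isclose(lin.rates[k], expected)
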