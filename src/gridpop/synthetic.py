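"""Idealized grid-cell simulator: rate maps, modules, trajectories, spikes.

A grid cell's firing field is modeled as the sum of three planar cosine
gratings whose stripe directions are the lattice orientation ``θ`` and
``θ ± 60°`` (wavevectors at ``θ + 30° + k·60°``, magnitude ``4π/(√3·λ)``).
The summed gratings range over [-1.5, 3] and are rescaled affinely to
``[0, peak_rate]``, producing smooth fields whose maxima form a hexagonal
lattice with nearest-neighbor distance ``λ`` along directions ``θ + k·60°``.
"""

from __future__ import annotations

import warnings

import numpy as np

from .core import Geometry, GridParams, RateMap, SpikeTrain, Trajectory

__all__ = [
    "ideal_rate_map",
    "ideal_rate_field",
    "make_module",
    "slice_to_track",
    "synth_trajectory",
    "spikes_from_rate",
]

_GRATING_MIN = -1.5
_GRATING_MAX = 3.0


def _wavevectors(params: GridParams) -> np.ndarray:
    """Three grating wavevectors, shape (3, 2)."""
    k = 4 * np.pi / (np.sqrt(3.0) * params.spacing)
    angles = np.deg2rad(params.orientation + 30.0 + 60.0 * np.arange(3))
    return k * np.column_stack([np.cos(angles), np.sin(angles)])


def grating_sum(params: GridParams, x: np.ndarray, y: np.ndarray,
                center: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Sum of the three cosine gratings at points (x, y), range [-1.5, 3]."""
    px, py = params.phase
    dx = np.asarray(x, dtype=float) - center[0] - px
    dy = np.asarray(y, dtype=float) - center[1] - py
    ks = _wavevectors(params)
    total = np.zeros(np.broadcast(dx, dy).shape)
    for kx, ky in ks:
        total += np.cos(kx * dx + ky * dy)
    return total


def ideal_rate_field(params: GridParams,
                     center: tuple[float, float] = (0.0, 0.0)):
    """Continuous rate function ``f(x, y) -> Hz`` for exact evaluation."""

    def f(x, y):
        s = grating_sum(params, x, y, center)
        return params.peak_rate * (s - _GRATING_MIN) / (_GRATING_MAX - _GRATING_MIN)

    return f


def ideal_rate_map(params: GridParams, geometry: Geometry) -> RateMap:
    """Noise-free hexagonal rate map of one grid cell on the geometry grid.

    Values lie in ``[0, peak_rate]``; bins outside the environment mask are
    zero and marked unvisited.
    """
    if params.spacing > 2 * geometry.outer_radius:
        warnings.warn(
            "grid spacing exceeds the environment diameter; "
            "no complete firing field may fit", stacklevel=2)
    X, Y = geometry.bin_centers()
    rate = ideal_rate_field(params, geometry.center)(X, Y)
    mask = geometry.mask()
    rate = np.where(mask, rate, 0.0)
    return RateMap(values=rate, visited_mask=mask,
                   origin=geometry.grid_origin, bin_size=geometry.bin_size)


def make_module(n_cells: int,
                spacing_mean: float = 45.0,
                spacing_sd: float = 0.0,
                orient_mean: float = 14.9,
                orient_sd: float = 0.0,
                peak_rate: float = 10.0,
                seed: int | np.random.SeedSequence = 0) -> list[GridParams]:
    """Draw parameters for a module of comodular grid cells.

    Spacing and orientation are drawn from normal distributions (the defaults
    are a 45-cm module at 14.9° with no variability; realistic variability is
    about 5 cm and 3°); each cell's 2D phase is uniform over its lattice unit
    cell, so field positions are unbiased over the plane.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if spacing_sd < 0 or orient_sd < 0:
        raise ValueError("standard deviations must be >= 0")
    rng = np.random.default_rng(seed)
    out: list[GridParams] = []
    for _ in range(n_cells):
        spacing = float(rng.normal(spacing_mean, spacing_sd))
        while spacing <= 0:  # pathological only for huge sds
            spacing = float(rng.normal(spacing_mean, spacing_sd))
        orient = float(rng.normal(orient_mean, orient_sd)) % 60.0
        p = GridParams(spacing=spacing, orientation=orient, peak_rate=peak_rate)
        u, v = rng.uniform(0.0, 1.0, size=2)
        a1, a2 = p.lattice_vectors()
        phase = u * a1 + v * a2
        out.append(GridParams(spacing=spacing, orientation=orient,
                              phase=(float(phase[0]), float(phase[1])),
                              peak_rate=peak_rate))
    return out


def slice_to_track(rate_map: RateMap, track: Geometry) -> RateMap:
    """Restrict a rate map to the track annulus (the circular-track slice).

    Bins outside the track mask are zeroed and marked unvisited; bins inside
    keep their rates.  The track must overlap the map's grid.
    """
    X, Y = rate_map.bin_centers()
    r = np.hypot(X - track.center[0], Y - track.center[1])
    track_mask = (r >= track.inner_radius) & (r <= track.outer_radius)
    new_mask = rate_map.visited_mask & track_mask
    if not new_mask.any():
        raise ValueError("track does not overlap the rate map")
    return RateMap(values=np.where(new_mask, rate_map.values, 0.0),
                   visited_mask=new_mask, origin=rate_map.origin,
                   bin_size=rate_map.bin_size)


def synth_trajectory(geometry: Geometry,
                     duration: float,
                     speed: float = 15.0,
                     dt: float = 0.02,
                     seed: int | np.random.SeedSequence = 0,
                     reversal_prob: float = 0.001,
                     n_laps: float | None = None) -> Trajectory:
    """Simulate a plausible foraging path confined to the environment.

    In an arena the heading performs a bounded random walk with reflection at
    the wall; on a track the animal progresses in angle at roughly ``speed``
    with small radial jitter and reverses direction with probability
    ``reversal_prob`` per step (animals on the real track were free to turn
    around).  ``n_laps`` overrides ``duration`` on a track with a steady
    no-reversal path completing that many clockwise laps.
    """
    if duration <= 0 and n_laps is None:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    cx, cy = geometry.center

    if geometry.kind == "track" and n_laps is not None:
        r_mid = 0.5 * (geometry.inner_radius + geometry.outer_radius)
        total_angle = 2 * np.pi * n_laps
        duration = total_angle * r_mid / speed
        n = max(int(np.ceil(duration / dt)) + 1, 2)
        t = dt * np.arange(n)
        phi0 = rng.uniform(0, 2 * np.pi)
        phi = phi0 - (speed / r_mid) * t  # clockwise
        rr = r_mid + 0.3 * (geometry.outer_radius - geometry.inner_radius) \
            * np.sin(2 * np.pi * t / 7.0 + rng.uniform(0, 2 * np.pi))
        x = cx + rr * np.cos(phi)
        y = cy + rr * np.sin(phi)
        return Trajectory(times=t, positions=np.column_stack([x, y]))

    n = max(int(np.ceil(duration / dt)) + 1, 1)
    t = dt * np.arange(n)
    pos = np.empty((n, 2))
    margin = max(geometry.bin_size, 1.0)

    if geometry.kind == "arena":
        r_max = geometry.outer_radius - margin
        p = np.array([cx, cy]) + rng.uniform(-0.3, 0.3, 2) * r_max
        heading = rng.uniform(0, 2 * np.pi)
        sigma_h = 1.5  # rad / sqrt(s) heading diffusion
        pos[0] = p
        for i in range(1, n):
            heading += sigma_h * np.sqrt(dt) * rng.standard_normal()
            step = speed * dt * np.array([np.cos(heading), np.sin(heading)])
            cand = p + step
            if np.hypot(cand[0] - cx, cand[1] - cy) > r_max:
                # turn back toward the center with some scatter
                heading = np.arctan2(cy - p[1], cx - p[0]) \
                    + rng.uniform(-0.8, 0.8)
                cand = p + speed * dt * np.array([np.cos(heading),
                                                  np.sin(heading)])
                d = np.hypot(cand[0] - cx, cand[1] - cy)
                if d > r_max:
                    cand = np.array([cx, cy]) + (cand - [cx, cy]) * r_max / d
            p = cand
            pos[i] = p
    else:
        r_lo = geometry.inner_radius + margin
        r_hi = geometry.outer_radius - margin
        r_mid = 0.5 * (r_lo + r_hi)
        phi = rng.uniform(0, 2 * np.pi)
        rr = r_mid
        direction = 1.0  # +1 = clockwise
        sigma_phi = 0.3  # rad / sqrt(s) angular noise
        sigma_r = 3.0    # cm / sqrt(s) radial jitter
        for i in range(n):
            pos[i] = (cx + rr * np.cos(phi), cy + rr * np.sin(phi))
            if rng.uniform() < reversal_prob:
                direction = -direction
            phi -= direction * (speed / rr) * dt
            phi += sigma_phi * np.sqrt(dt) * rng.standard_normal()
            rr += sigma_r * np.sqrt(dt) * rng.standard_normal()
            rr = float(np.clip(rr, r_lo, r_hi))
    return Trajectory(times=t, positions=pos)


def spikes_from_rate(rate_source,
                     traj: Trajectory,
                     seed: int | np.random.SeedSequence = 0,
                     cell_id: str | None = None) -> SpikeTrain:
    """Inhomogeneous Poisson spikes from the rate at the animal's position.

    ``rate_source`` is a :class:`RateMap` (nearest-bin lookup) or a callable
    ``f(x, y) -> Hz``.  The rate is held constant over each trajectory
    sampling interval; the spike count per interval is Poisson with mean
    ``rate·Δt`` and spike times are uniform within the interval.
    """
    rng = np.random.default_rng(seed)
    p = traj.positions
    if isinstance(rate_source, RateMap):
        rates = rate_source.value_at(p)
    elif callable(rate_source):
        rates = np.asarray(rate_source(p[:, 0], p[:, 1]), dtype=float)
    else:
        raise TypeError("rate_source must be a RateMap or a callable")
    if np.any(rates < 0):
        raise ValueError("negative firing rates")
    if len(traj.times) < 2:
        return SpikeTrain(spike_times=np.array([]), cell_id=cell_id)
    dts = np.diff(traj.times)
    lam = rates[:-1] * dts
    counts = rng.poisson(lam)
    spikes = []
    idx = np.nonzero(counts)[0]
    for i in idx:
        spikes.append(traj.times[i] + dts[i] * rng.uniform(size=counts[i]))
    if spikes:
        times = np.sort(np.concatenate(spikes))
    else:
        times = np.array([])
    return SpikeTrain(spike_times=times, cell_id=cell_id)
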