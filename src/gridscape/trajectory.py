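"""Curvature-constrained random foraging inside an arena.

The virtual animal is a point moving by Euler steps

    x' = sigma * cos(Theta),   y' = sigma * sin(Theta)

whose speed ``sigma`` equals the distance to the nearest wall (capped), so it
slows down near borders and never crosses them, and whose heading ``Theta``
performs a bounded random walk: each step the turn rate is ``gamma * rho``
with ``gamma`` drawn uniformly from [-1, 1] and ``rho`` the maximum turn rate.
Steps that would leave the arena are rejected and the turn redrawn; after
repeated failures the heading is reflected off the wall normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateArenaError, OutsideArenaError
from .geometry import Environment, TransformingEnvironment

_MAX_REDRAWS = 10


@dataclass
class TrajectoryParams:
    """Kinematic parameters of the forager.

    dt : integration step (s); rho : maximum turn rate (rad/s), so the
    per-step heading change is bounded by ``rho * dt``; speed_cap : upper
    bound on speed (units/s) so arena size does not dictate dynamics;
    speed_floor : lower bound on speed (units/s). The wall-distance speed
    rule alone makes the log wall distance a recurrent random walk, so the
    forager would spend most of the session at microscopic wall distances;
    the floor bounds those excursions while preserving the slow-near-wall
    behavior. seed : RNG seed for the turn sequence and start point.

    For multi-compartment arenas the forager can run "trips": with
    ``goals`` set (a sequence of waypoints, e.g. the two room centers), the
    random turn is biased toward the current goal — still within the same
    per-step turn bound — and the goal advances cyclically whenever the
    forager comes within ``goal_radius`` of it. ``trip_bias`` in [0, 1]
    scales the bias (0 = pure random foraging).
    """

    dt: float = 0.01
    rho: float = 20.0
    speed_cap: float = 0.5
    speed_floor: float = 0.05
    seed: int = 0
    goals: tuple | None = None
    goal_radius: float = 0.45
    trip_bias: float = 0.5
    goal_dwell: float = 20.0   # s of unbiased foraging after reaching a goal

    def __post_init__(self):
        if self.dt <= 0 or self.rho <= 0 or self.speed_cap <= 0:
            raise ValueError("dt, rho and speed_cap must be positive")
        if not (0 <= self.speed_floor <= self.speed_cap):
            raise ValueError("need 0 <= speed_floor <= speed_cap")
        if not (0 <= self.trip_bias <= 1):
            raise ValueError("trip_bias must be in [0, 1]")


@dataclass
class Trajectory:
    t: np.ndarray
    pos: np.ndarray          # (N, 2)
    heading: np.ndarray      # radians
    speed: np.ndarray        # units/s, the sigma actually used per step
    dt: float = 0.01

    def __len__(self):
        return len(self.t)

    @property
    def x(self):
        return self.pos[:, 0]

    @property
    def y(self):
        return self.pos[:, 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "x": self.x, "y": self.y,
                             "theta": self.heading, "speed": self.speed})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        df = pd.read_csv(path)
        t = df["t"].to_numpy()
        dt = float(t[1] - t[0]) if len(t) > 1 else 0.01
        return cls(t=t, pos=df[["x", "y"]].to_numpy(),
                   heading=df["theta"].to_numpy(), speed=df["speed"].to_numpy(), dt=dt)


def _is_transforming(env) -> bool:
    return isinstance(env, TransformingEnvironment)


def simulate_trajectory(env: Environment | TransformingEnvironment, duration: float,
                        params: TrajectoryParams | None = None,
                        start: tuple[float, float] | None = None) -> Trajectory:
    """Simulate foraging for ``duration`` seconds; deterministic given the seed.

    The start point is sampled uniformly inside the arena unless given.
    Every sample is guaranteed inside the arena at its own timestamp (the
    transforming arena is queried at the current time).
    """
    if params is None:
        params = TrajectoryParams()
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(params.seed)
    n = int(round(duration / params.dt))
    transforming = _is_transforming(env)

    if transforming:
        def dist(x, y, t):
            return env.distance_to_wall(x, y, t)

        def inside(x, y, t):
            return env.contains(x, y, t)
    else:
        def dist(x, y, t):
            return env.wall_distance_unchecked(x, y)

        def inside(x, y, t):
            return bool(env.contains(x, y))

    if start is None:
        start = tuple(env.sample_interior(rng, 1)[0])
    x, y = float(start[0]), float(start[1])
    if not inside(x, y, 0.0):
        raise OutsideArenaError("start point outside the arena")
    if dist(x, y, 0.0) <= 1e-12:
        raise DegenerateArenaError("arena too small for any step")

    theta = float(rng.uniform(0, 2 * np.pi))
    dt, rho = params.dt, params.rho
    cap, floor = params.speed_cap, params.speed_floor
    max_turn = rho * dt
    goals = None if params.goals is None else [tuple(g) for g in params.goals]
    goal_idx = 0
    bias = params.trip_bias
    r_goal = params.goal_radius
    bias_off_until = 0.0   # forage freely for goal_dwell s after each arrival
    wall_contact = 0       # consecutive steps pinned at a wall while biased

    def draw_turn(x, y, theta, t_now=np.inf):
        g = float(rng.uniform(-1.0, 1.0))
        if goals is not None and bias > 0 and t_now >= bias_off_until:
            gx, gy = goals[goal_idx]
            err = np.arctan2(np.sin(np.arctan2(gy - y, gx - x) - theta),
                             np.cos(np.arctan2(gy - y, gx - x) - theta))
            g = float(np.clip(g + bias * np.clip(err, -1.0, 1.0), -1.0, 1.0))
        return g * max_turn

    t_arr = np.arange(n) * dt
    pos = np.empty((n, 2))
    head = np.empty(n)
    spd = np.empty(n)
    pos[0] = (x, y)
    head[0] = theta
    spd[0] = min(max(dist(x, y, 0.0), floor), cap)

    for i in range(1, n):
        t_now = t_arr[i]
        d = dist(x, y, t_now)
        sigma = min(max(d, floor), cap)
        new_theta = theta + draw_turn(x, y, theta, t_now)
        step = sigma * dt
        nx, ny = x + step * np.cos(new_theta), y + step * np.sin(new_theta)
        if not inside(nx, ny, t_now):
            # the floored step can overshoot very close to a wall; a step of
            # length d * dt < d is inside by construction (pure
            # speed-equals-wall-distance law), so fall back to it
            sigma = d
            step = sigma * dt
            nx, ny = x + step * np.cos(new_theta), y + step * np.sin(new_theta)
            if not inside(nx, ny, t_now):
                ok = False
                for _ in range(_MAX_REDRAWS):
                    new_theta = theta + draw_turn(x, y, theta, t_now)
                    nx, ny = x + step * np.cos(new_theta), y + step * np.sin(new_theta)
                    if inside(nx, ny, t_now):
                        ok = True
                        break
                if not ok:
                    # reflect the heading off the wall normal and stay in place
                    new_theta = _reflect_heading(env, x, y, theta, transforming, t_now)
                    nx, ny = x, y
                    sigma = 0.0
        x, y, theta = nx, ny, new_theta
        if goals is not None:
            if np.hypot(goals[goal_idx][0] - x, goals[goal_idx][1] - y) < r_goal:
                goal_idx = (goal_idx + 1) % len(goals)
                bias_off_until = t_now + params.goal_dwell
                wall_contact = 0
            elif t_now >= bias_off_until:
                # goal bias can pin the forager against a wall between it and
                # the goal; after sustained wall contact, forage freely for a
                # while so the wall-escape dynamics can act
                wall_contact = wall_contact + 1 if d < floor else 0
                if wall_contact > 300:
                    bias_off_until = t_now + 5.0
                    wall_contact = 0
        pos[i] = (x, y)
        head[i] = theta
        spd[i] = sigma
    return Trajectory(t=t_arr, pos=pos, heading=head, speed=spd, dt=dt)


def _reflect_heading(env, x, y, theta, transforming, t_now) -> float:
    if transforming:
        b = env.breadth(t_now)
        # nearest rectangle wall normal
        d = [(x, (-1.0, 0.0)), (env.length - x, (1.0, 0.0)),
             (y, (0.0, -1.0)), (b - y, (0.0, 1.0))]
        nx_, ny_ = min(d)[1]
    else:
        qx, qy = env.nearest_wall_point(x, y)
        nrm = np.hypot(qx - x, qy - y)
        if nrm < 1e-12:
            return theta + np.pi
        nx_, ny_ = (qx - x) / nrm, (qy - y) / nrm
    hx, hy = np.cos(theta), np.sin(theta)
    dot = hx * nx_ + hy * ny_
    rx, ry = hx - 2 * dot * nx_, hy - 2 * dot * ny_
    return float(np.arctan2(ry, rx))


def speed_series(traj: Trajectory) -> np.ndarray:
    """Per-step displacement norms divided by dt (units/s).

    The first element is 0 by convention so the series aligns with samples.
    """
    if len(traj) < 2:
        raise ValueError("need at least 2 samples")
    d = np.linalg.norm(np.diff(traj.pos, axis=0), axis=1) / traj.dt
    return np.concatenate([[0.0], d])
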