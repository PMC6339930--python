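"""Arena geometry: construction of 2-D foraging enclosures and geometric queries.

Arenas are closed planar regions (possibly with a hole, as in an annulus)
represented by shapely polygons. The module builds every enclosure family used
in the geometry experiments — regular polygons, two-compartment connected
rooms, concave shapes (annulus / horseshoe / S), convex square vs. trapezoid,
and a rectangle that widens into a square over time — and answers the two
queries the foraging simulator needs: point containment and distance to the
nearest wall.

Coordinates are continuous 2-D Cartesian "arena units"; no physical unit
mapping is implied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import shapely
import shapely.ops
from shapely.geometry import Polygon, box

from .errors import InvalidShapeError, InvalidTransformError, OutsideArenaError

# vertices used to render a full circle as a polyline
ARC_VERTICES = 360

# thickness of the dividing wall when two connected rooms abut (distance 0)
_ABUT_WALL = 0.02


def _circle_coords(radius: float, center=(0.0, 0.0), theta0=0.0, theta1=2 * np.pi,
                   n: int | None = None) -> np.ndarray:
    """Polyline approximation of a circular arc (endpoints included)."""
    if n is None:
        n = max(8, int(round(ARC_VERTICES * abs(theta1 - theta0) / (2 * np.pi))))
    th = np.linspace(theta0, theta1, n + 1)
    return np.column_stack([center[0] + radius * np.cos(th),
                            center[1] + radius * np.sin(th)])


@dataclass
class Environment:
    """A closed 2-D arena.

    Attributes
    ----------
    polygon : shapely.Polygon
        Free space of the arena. Its exterior ring is the outer wall; interior
        rings (holes) are inner walls such as the annulus core.
    label : str
        Human-readable tag (e.g. ``"annulus(r_out=2, r_in=1)"``).
    meta : dict
        Construction parameters, kept for serialization and for analyses that
        need them (e.g. compartment membership in connected arenas).
    """

    polygon: Polygon
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.polygon.is_valid or self.polygon.is_empty:
            raise InvalidShapeError(f"invalid arena polygon for {self.label!r}")
        shapely.prepare(self.polygon)
        self._boundary = self.polygon.boundary

    # -- queries ---------------------------------------------------------

    @property
    def bounding_box(self) -> tuple[float, float, float, float]:
        return self.polygon.bounds

    @property
    def area(self) -> float:
        return self.polygon.area

    def contains(self, x, y) -> np.ndarray | bool:
        """Strict interior test (boundary points are outside). Vectorized."""
        return shapely.contains_xy(self.polygon, x, y)

    def distance_to_wall(self, x: float, y: float) -> float:
        """Euclidean distance from an interior point to the nearest wall.

        Raises :class:`OutsideArenaError` if the point is not strictly inside.
        """
        if not shapely.contains_xy(self.polygon, x, y):
            raise OutsideArenaError(f"point ({x}, {y}) outside arena {self.label!r}")
        return float(shapely.distance(self._boundary, shapely.points(x, y)))

    def wall_distance_unchecked(self, x: float, y: float) -> float:
        """Distance to the nearest wall without the containment check (hot path)."""
        return float(shapely.distance(self._boundary, shapely.points(x, y)))

    def nearest_wall_point(self, x: float, y: float) -> tuple[float, float]:
        p = shapely.points(x, y)
        q = shapely.ops.nearest_points(self._boundary, p)[0]
        return q.x, q.y

    def sample_interior(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        """Uniform interior samples by rejection from the bounding box."""
        xmin, ymin, xmax, ymax = self.bounding_box
        out = np.empty((n, 2))
        got = 0
        while got < n:
            k = max(4 * (n - got), 16)
            pts = rng.uniform((xmin, ymin), (xmax, ymax), size=(k, 2))
            ok = shapely.contains_xy(self.polygon, pts[:, 0], pts[:, 1])
            take = min(int(ok.sum()), n - got)
            out[got:got + take] = pts[ok][:take]
            got += take
        return out

    # -- export ----------------------------------------------------------

    def boundary_table(self) -> np.ndarray:
        """Closed polyline table (x, y per row); rings separated by NaN rows."""
        rings = [np.asarray(self.polygon.exterior.coords)]
        for hole in self.polygon.interiors:
            rings.append(np.full((1, 2), np.nan))
            rings.append(np.asarray(hole.coords))
        return np.vstack(rings)

    def to_csv(self, path) -> None:
        np.savetxt(path, self.boundary_table(), delimiter=",", header="x,y", comments="")


@dataclass
class TransformingEnvironment:
    """A rectangle that widens into a square during the session.

    The arena is ``[0, length] x [0, breadth(t)]`` with ``breadth`` growing
    from ``breadth_start`` to ``breadth_end == length`` according to
    ``schedule``. ``config_label(t)`` is 1 while the arena is still
    rectangular and 2 once the breadth reaches 99% of the final square side.

    Schedules
    ---------
    ``"linear"``
        breadth interpolates linearly over the whole session.
    ``"hold-ramp-hold"``
        breadth holds at the start value, ramps linearly during a middle
        window of the session, then holds at the final value. The default
        window (30%-50% of the session) puts the configuration switch at
        mid-session, so the decoder study sees both configurations in equal
        measure.
    """

    length: float
    breadth_start: float
    breadth_end: float
    total_time: float
    schedule: str = "linear"
    ramp: tuple[float, float] = (0.3, 0.5)  # ramp window as fractions of total_time
    label: str = "transforming"

    def __post_init__(self):
        if self.breadth_end != self.length:
            raise InvalidTransformError("final breadth must equal length (square)")
        if not (0 < self.breadth_start < self.breadth_end):
            raise InvalidTransformError("breadth must grow from a positive start")
        if self.schedule not in ("linear", "hold-ramp-hold"):
            raise InvalidTransformError(f"unknown schedule {self.schedule!r}")

    def breadth(self, t: float) -> float:
        frac = np.clip(t / self.total_time, 0.0, 1.0)
        if self.schedule == "linear":
            u = frac
        else:
            a, b = self.ramp
            u = np.clip((frac - a) / (b - a), 0.0, 1.0)
        return self.breadth_start + (self.breadth_end - self.breadth_start) * float(u)

    def config_label(self, t: float) -> int:
        return 2 if self.breadth(t) >= 0.99 * self.length else 1

    @property
    def base(self) -> Environment:
        return self.env_at(0.0)

    def env_at(self, t: float) -> Environment:
        b = self.breadth(t)
        return Environment(box(0.0, 0.0, self.length, b),
                           label=f"{self.label}@t={t:g}",
                           meta={"kind": "rectangle", "length": self.length, "breadth": b})

    @property
    def bounding_box(self) -> tuple[float, float, float, float]:
        return (0.0, 0.0, self.length, self.breadth_end)

    # analytic fast paths (axis-aligned rectangle) used by the simulator
    def contains(self, x: float, y: float, t: float = 0.0) -> bool:
        b = self.breadth(t)
        return bool((0.0 < x < self.length) and (0.0 < y < b))

    def distance_to_wall(self, x: float, y: float, t: float = 0.0) -> float:
        if not self.contains(x, y, t):
            raise OutsideArenaError(f"point ({x}, {y}) outside arena at t={t}")
        b = self.breadth(t)
        return min(x, self.length - x, y, b - y)

    def sample_interior(self, rng: np.random.Generator, n: int = 1, t: float = 0.0) -> np.ndarray:
        b = self.breadth(t)
        return rng.uniform((0.0, 0.0), (self.length, b), size=(n, 2))


# -- constructors ---------------------------------------------------------

def make_polygon(n_sides: int, radius: float = 1.0, center=(0.0, 0.0)) -> Environment:
    """Regular n-gon inscribed in a circle: vertex k at angle 2*pi*k/n."""
    if n_sides < 3:
        raise InvalidShapeError("a polygon needs at least 3 sides")
    if radius <= 0:
        raise InvalidShapeError("radius must be positive")
    k = np.arange(n_sides)
    ang = 2 * np.pi * k / n_sides
    verts = np.column_stack([center[0] + radius * np.cos(ang),
                             center[1] + radius * np.sin(ang)])
    return Environment(Polygon(verts), label=f"polygon(n={n_sides})",
                       meta={"kind": "polygon", "n_sides": n_sides,
                             "radius": radius, "center": tuple(center)})


def _room(shape: str, size: float, cx: float) -> Polygon:
    if shape == "square":
        return box(cx - size / 2, -size / 2, cx + size / 2, size / 2)
    if shape == "circle":
        return Polygon(_circle_coords(size / 2, center=(cx, 0.0)))
    raise InvalidShapeError(f"unknown room shape {shape!r}")


def make_connected(shape_a: str, shape_b: str, room_size: float = 1.8,
                   corridor_width: float = 0.8, distance_d: float = 0.8) -> Environment:
    """Two rooms joined by an axis-aligned rectangular corridor.

    The rooms (square side or circle diameter = ``room_size``) are separated
    by ``distance_d`` along x and joined by a corridor of width
    ``corridor_width`` and length ``distance_d`` centered on the shared axis.
    ``distance_d = 0`` degenerates to two abutting rooms sharing a doorway of
    width ``corridor_width`` in a thin dividing wall.
    """
    if room_size <= 0 or corridor_width <= 0 or distance_d < 0:
        raise InvalidShapeError("room_size and corridor_width must be positive, distance >= 0")
    if corridor_width > room_size:
        raise InvalidShapeError("corridor wider than the room face")
    gap = max(distance_d, _ABUT_WALL)
    cx = gap / 2 + room_size / 2
    a = _room(shape_a, room_size, -cx)
    b = _room(shape_b, room_size, +cx)
    # the corridor reaches into the rooms so that curved (circle) room walls
    # still get a full-width opening; the overlap is absorbed by the union
    reach = gap / 2 + room_size / 4
    corridor = box(-reach, -corridor_width / 2, reach, corridor_width / 2)
    union = shapely.union_all([a, b, corridor])
    if union.geom_type != "Polygon":
        raise InvalidShapeError("connected arena did not form a single closed boundary")
    return Environment(union, label=f"connected({shape_a}-{shape_b}, d={distance_d})",
                       meta={"kind": "connected", "shape_a": shape_a, "shape_b": shape_b,
                             "room_size": room_size, "corridor_width": corridor_width,
                             "distance_d": distance_d, "gap": gap})


def compartment_of(env: Environment, x, y=None) -> np.ndarray:
    """Compartment membership for a connected arena.

    Returns -1 for the left room, +1 for the right room and 0 for the
    corridor, based on the x coordinate relative to the corridor span.
    """
    if env.meta.get("kind") != "connected":
        raise InvalidShapeError("compartment membership is defined for connected arenas only")
    x = np.asarray(x)
    half = env.meta["gap"] / 2
    return np.where(x < -half, -1, np.where(x > half, 1, 0))


def _horseshoe_coords(r_outer: float, r_inner: float, center=(0.0, 0.0),
                      invert: bool = False) -> np.ndarray:
    """Closed band between two concentric semicircles plus straight caps."""
    outer = _circle_coords(r_outer, center, 0.0, np.pi)
    if r_inner > 0:
        inner = _circle_coords(r_inner, center, np.pi, 0.0)
        coords = np.vstack([outer, inner])
    else:
        coords = outer  # half disc: arc closes along its base chord
    if invert:
        coords = coords * np.array([1.0, -1.0]) + np.array([0.0, 2 * center[1]])
    # snap arc endpoints so concatenated horseshoes share exact boundary points
    return np.round(coords, 12)


def make_concave(kind: str, r_outer: float, r_inner: float) -> Environment:
    """Concave arenas: ``annulus``, ``horseshoe`` or ``s_shape``.

    ``r_inner = 0`` degenerates to a disc (annulus) or half-disc (horseshoe).
    The S shape concatenates two horseshoes, one inverted, joined at a common
    end.
    """
    if not (r_outer > r_inner >= 0):
        raise InvalidShapeError("need r_outer > r_inner >= 0")
    meta = {"kind": kind, "r_outer": r_outer, "r_inner": r_inner}
    label = f"{kind}(r_out={r_outer:g}, r_in={r_inner:g})"
    if kind == "annulus":
        shell = _circle_coords(r_outer)
        holes = [_circle_coords(r_inner)] if r_inner > 0 else None
        return Environment(Polygon(shell, holes), label=label, meta=meta)
    if kind == "horseshoe":
        return Environment(Polygon(_horseshoe_coords(r_outer, r_inner)), label=label, meta=meta)
    if kind == "s_shape":
        up = Polygon(_horseshoe_coords(r_outer, r_inner))
        lo = Polygon(_horseshoe_coords(r_outer, r_inner,
                                       center=(-(r_outer + r_inner), 0.0), invert=True))
        union = shapely.union_all([up, lo])
        if union.geom_type != "Polygon":  # pragma: no cover - construction guarantee
            raise InvalidShapeError("S shape did not form a single closed boundary")
        return Environment(union, label=label, meta=meta)
    raise InvalidShapeError(f"unknown concave kind {kind!r}")


def make_rectangle(length: float, breadth: float, origin=(0.0, 0.0)) -> Environment:
    if length <= 0 or breadth <= 0:
        raise InvalidShapeError("rectangle sides must be positive")
    return Environment(box(origin[0], origin[1], origin[0] + length, origin[1] + breadth),
                       label=f"rectangle({length:g}x{breadth:g})",
                       meta={"kind": "rectangle", "length": length, "breadth": breadth})


def make_square(side: float = 1.8) -> Environment:
    env = make_rectangle(side, side)
    env.label = f"square({side:g})"
    env.meta = {"kind": "square", "side": side}
    return env


def make_trapezoid(side_left: float = 0.2, side_right: float = 1.0,
                   length: float = 1.9) -> Environment:
    """Isosceles trapezoid with vertical parallel sides (narrow left, broad right)."""
    if not (0 < side_left < side_right) or length <= 0:
        raise InvalidShapeError("need 0 < side_left < side_right and positive length")
    verts = [(0.0, -side_left / 2), (length, -side_right / 2),
             (length, side_right / 2), (0.0, side_left / 2)]
    return Environment(Polygon(verts), label="trapezoid",
                       meta={"kind": "trapezoid", "side_left": side_left,
                             "side_right": side_right, "length": length})


def make_transforming(length: float, breadth_start: float, breadth_end: float,
                      total_time: float, schedule: str = "linear",
                      ramp: tuple[float, float] = (0.3, 0.5)) -> TransformingEnvironment:
    """Rectangle ``length x breadth_start`` growing into a ``length``-sided square."""
    return TransformingEnvironment(length, breadth_start, breadth_end, total_time,
                                   schedule=schedule, ramp=ramp)


# -- module-level query wrappers (spec'd operation signatures) -------------

def contains(env: Environment, point) -> bool:
    x, y = point
    return bool(env.contains(x, y))


def distance_to_wall(env: Environment, point) -> float:
    x, y = point
    return env.distance_to_wall(x, y)


def equal_area_split_x(env: Environment, tol: float = 1e-9) -> float:
    """Abscissa of the vertical cut dividing the arena into two equal areas."""
    xmin, ymin, xmax, ymax = env.bounding_box
    half = env.area / 2

    def left_area(x):
        return env.polygon.intersection(box(xmin - 1, ymin - 1, x, ymax + 1)).area

    lo, hi = xmin, xmax
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if left_area(mid) < half:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


ENV_BUILDERS: dict[str, Callable] = {
    "polygon": make_polygon,
    "connected": make_connected,
    "annulus": lambda **kw: make_concave("annulus", **kw),
    "horseshoe": lambda **kw: make_concave("horseshoe", **kw),
    "s_shape": lambda **kw: make_concave("s_shape", **kw),
    "square": make_square,
    "rectangle": make_rectangle,
    "trapezoid": make_trapezoid,
}


def env_from_config(cfg: dict) -> Environment:
    """Build an arena from a plain ``{"kind": ..., **params}`` mapping."""
    cfg = dict(cfg)
    kind = cfg.pop("kind", None)
    if kind == "concave":
        kind = cfg.pop("concave_kind")
    if kind not in ENV_BUILDERS:
        raise InvalidShapeError(f"unknown arena kind {kind!r}")
    return ENV_BUILDERS[kind](**cfg)
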