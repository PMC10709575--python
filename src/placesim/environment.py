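"""Virtual square arena, random-walk agent, visibility and Poisson drive.

The virtual animal follows a fixed-speed random walk (Gaussian heading
increments, reflective walls) through a square arena containing bar-shaped
objects.  Each object is decomposed into features (7 by default), each
wired to one oblique dendrite.  A feature drives its synapse at the cue
rate (80 Hz) when it lies inside the 90° visual field and is resolvable at
the current distance; otherwise the synapse idles at the background theta
rate (3 Hz).  Resolution falls off with distance: the first
⌈decay(r)·n_features⌉ features of an object (fixed order) are resolvable
at object distance r.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .config import ArenaConfig, ObjectConfig, TrajectoryConfig, VisualConfig


@dataclass
class CueObject:
    object_id: str
    position: np.ndarray           # (2,) center, unrotated
    extent: np.ndarray             # (2,) width, height
    n_features: int = 7

    def feature_ids(self) -> list[str]:
        return [f"{self.object_id}:{k}" for k in range(self.n_features)]

    def feature_positions(self) -> np.ndarray:
        """Feature anchor points, spread along the object's long axis."""
        w, h = self.extent
        k = np.arange(self.n_features)
        frac = (k + 0.5) / self.n_features - 0.5
        pts = np.tile(self.position, (self.n_features, 1)).astype(float)
        if h >= w:
            pts[:, 1] += frac * h
        else:
            pts[:, 0] += frac * w
        return pts


@dataclass
class Arena:
    side_length: float
    objects: list[CueObject]
    rotation: float = 0.0          # degrees, rigid rotation about the center

    @classmethod
    def from_config(cls, cfg: ArenaConfig) -> "Arena":
        objs = [CueObject(o.object_id, np.array([o.x, o.y]),
                          np.array([o.width, o.height]), o.n_features)
                for o in cfg.objects]
        for o in objs:
            if np.any(o.position < 0) or np.any(o.position > cfg.side_length):
                raise ValueError(f"object {o.object_id} outside the arena")
        return cls(cfg.side_length, objs, cfg.rotation_deg)

    @property
    def center(self) -> np.ndarray:
        return np.array([self.side_length / 2, self.side_length / 2])

    def _rot(self, pts: np.ndarray) -> np.ndarray:
        a = math.radians(self.rotation)
        c, s = math.cos(a), math.sin(a)
        R = np.array([[c, -s], [s, c]])
        return (np.atleast_2d(pts) - self.center) @ R.T + self.center

    def object_center(self, obj: CueObject) -> np.ndarray:
        return self._rot(obj.position)[0]

    def feature_positions(self, obj: CueObject) -> np.ndarray:
        return self._rot(obj.feature_positions())

    def all_feature_ids(self) -> list[str]:
        return [fid for o in self.objects for fid in o.feature_ids()]


def rotate_arena(arena: Arena, angle: float) -> Arena:
    """Rigidly rotate all objects about the arena center (new Arena)."""
    return Arena(arena.side_length,
                 [replace(o, position=o.position.copy(),
                          extent=o.extent.copy()) for o in arena.objects],
                 (arena.rotation + angle) % 360.0)


@dataclass
class TrajectoryState:
    position: np.ndarray
    heading: float                 # degrees in [0, 360)
    speed: float                   # arena units / s
    time: float = 0.0              # s


@dataclass
class VisualField:
    fov: float = 90.0              # degrees
    max_range: float = 1.2
    full_resolution_fraction: float = 0.35

    def __post_init__(self):
        if not (0 < self.fov <= 360):
            raise ValueError("fov must lie in (0, 360]")

    @classmethod
    def from_config(cls, cfg: VisualConfig) -> "VisualField":
        return cls(cfg.fov_deg, cfg.max_range, cfg.full_resolution_fraction)

    def resolution_decay(self, r: float) -> float:
        """Fraction of an object's features resolvable at distance ``r``.

        Full resolution out to ``full_resolution_fraction·max_range``, then
        linear to zero at ``max_range`` (set the fraction to 0 for a pure
        linear fall-off from the origin).
        """
        if r >= self.max_range:
            return 0.0
        r0 = self.full_resolution_fraction * self.max_range
        if r <= r0:
            return 1.0
        return (self.max_range - r) / (self.max_range - r0)


def initial_trajectory_state(cfg: TrajectoryConfig, rng=None,
                             arena: Arena | None = None) -> TrajectoryState:
    """Start state; with ``rng`` the position and heading are randomized
    (uniform inside the arena with a 10% wall margin), so different seeds
    give genuinely different explorations."""
    if rng is None:
        return TrajectoryState(position=np.array([cfg.x0, cfg.y0], dtype=float),
                               heading=cfg.heading0_deg % 360.0,
                               speed=cfg.speed)
    L = arena.side_length if arena is not None else 1.0
    pos = rng.uniform(0.1 * L, 0.9 * L, size=2)
    return TrajectoryState(position=pos, heading=rng.uniform(0.0, 360.0),
                           speed=cfg.speed)


def step_trajectory(state: TrajectoryState, dt_env: float, rng,
                    arena: Arena, heading_std_deg: float = 12.0
                    ) -> TrajectoryState:
    """Advance the random walk one environment step (reflective walls)."""
    if dt_env <= 0:
        raise ValueError("dt_env must be positive")
    heading = (state.heading + rng.normal(0.0, heading_std_deg)) % 360.0
    a = math.radians(heading)
    pos = state.position + state.speed * dt_env * np.array([math.cos(a),
                                                            math.sin(a)])
    L = arena.side_length
    vx, vy = math.cos(a), math.sin(a)
    for d in range(2):
        v = (vx, vy)[d]
        if pos[d] < 0:
            pos[d] = -pos[d]
            v = -v
        elif pos[d] > L:
            pos[d] = 2 * L - pos[d]
            v = -v
        if d == 0:
            vx = v
        else:
            vy = v
    heading = math.degrees(math.atan2(vy, vx)) % 360.0
    return TrajectoryState(position=pos, heading=heading, speed=state.speed,
                           time=state.time + dt_env)


def _bearing_within(agent_pos, heading_deg, target, half_fov_deg) -> bool:
    d = target - agent_pos
    bearing = math.degrees(math.atan2(d[1], d[0]))
    diff = (bearing - heading_deg + 180.0) % 360.0 - 180.0
    return abs(diff) <= half_fov_deg


def visible_features(state: TrajectoryState, arena: Arena,
                     vf: VisualField) -> set[str]:
    """Feature ids currently in view.

    A feature is visible iff its bearing lies within ±fov/2 of the heading,
    its distance is within range, and it is among the first
    ⌈decay(r)·n_features⌉ features of its object at object distance r.
    """
    out: set[str] = set()
    for obj in arena.objects:
        center = arena.object_center(obj)
        r = float(np.linalg.norm(center - state.position))
        n_res = math.ceil(vf.resolution_decay(r) * obj.n_features)
        if n_res == 0:
            continue
        pts = arena.feature_positions(obj)
        fids = obj.feature_ids()
        for k in range(n_res):
            fr = float(np.linalg.norm(pts[k] - state.position))
            if fr <= vf.max_range and _bearing_within(
                    state.position, state.heading, pts[k], vf.fov / 2):
                out.add(fids[k])
    return out


def presynaptic_rates(visible: set[str], synapse_map: dict[str, str],
                      cue_rate_hz: float = 80.0,
                      background_rate_hz: float = 3.0) -> dict[str, float]:
    """Per-synapse Poisson rate: cue rate if the mapped feature is in view.

    ``synapse_map`` maps feature id → synapse id and must be one-to-one.
    Synapses without a visible feature (including background-only ones)
    run at the background rate.
    """
    targets = list(synapse_map.values())
    if len(set(targets)) != len(targets):
        raise ValueError("feature→synapse map must be one-to-one")
    rates = {sid: background_rate_hz for sid in targets}
    for fid in visible:
        if fid in synapse_map:
            rates[synapse_map[fid]] = cue_rate_hz
    return rates


def poisson_spike_train(rate_fn, t0: float, t1: float, rng,
                        dt_piece: float = 100.0) -> np.ndarray:
    """Inhomogeneous Poisson spike times (ms) on [t0, t1).

    ``rate_fn(t_ms) → Hz`` must be piecewise constant on the ``dt_piece``
    grid; each piece is sampled as a homogeneous process (Poisson count,
    uniform placement), which is exact for piecewise-constant rates.
    """
    if t1 <= t0:
        raise ValueError("need t1 > t0")
    times = []
    t = t0
    while t < t1:
        t_end = min(t + dt_piece, t1)
        rate = float(rate_fn(t))
        if rate > 0:
            lam = rate * (t_end - t) / 1000.0
            n = rng.poisson(lam)
            if n:
                times.append(t + rng.random(n) * (t_end - t))
        t = t_end
    if not times:
        return np.empty(0)
    return np.sort(np.concatenate(times))
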