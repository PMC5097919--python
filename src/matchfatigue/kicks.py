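"""Finishing-kick ball speed and accuracy from 240-Hz 3-D trajectories.

Axes are right-handed with y horizontal toward the goal centre, z vertical
up and x lateral.  Ball release velocity is estimated from the ten frames
after foot contact: the horizontal components are the slopes of ordinary
least-squares lines fitted to the raw (unfiltered) x(t) and y(t)
displacements; the vertical component comes from a quadratic fit of z(t)
whose curvature is fixed at −g/2 (free-flight constraint), i.e. an OLS line
fitted to z(t) + ½·g·t².  Accuracy is the Euclidean distance from the point
where the fitted flight crosses the goal plane to the nearest point of the
1 × 1 m target square.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BallTrajectory",
    "GoalTarget",
    "KickResult",
    "fit_horizontal_velocity",
    "fit_vertical_velocity",
    "ball_speed",
    "goal_plane_crossing",
    "accuracy",
    "analyze_kick",
    "summarize_set",
]

G_DEFAULT = 9.81
MS_TO_KMH = 3.6


@dataclass
class BallTrajectory:
    kick_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    contact_index: int

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if not (0 <= self.contact_index < len(self.t)):
            raise ValueError("contact_index out of range")

    def airborne(self, n_frames: int) -> tuple[np.ndarray, ...]:
        """The n_frames samples following foot contact, time relative to contact."""
        i0 = self.contact_index + 1
        i1 = i0 + n_frames
        if i1 > len(self.t):
            raise ValueError(
                f"need {n_frames} airborne frames after contact, have {len(self.t) - i0}"
            )
        tc = self.t[self.contact_index]
        return self.t[i0:i1] - tc, self.x[i0:i1], self.y[i0:i1], self.z[i0:i1]


@dataclass
class GoalTarget:
    """Axis-aligned 1 × 1 m target square centred in the goal mouth."""

    plane_y: float = 10.0
    target_centre: tuple[float, float] = (0.0, 1.0)   # (x, z) m
    target_half_width: float = 0.5
    target_half_height: float = 0.5
    goal_half_width: float = 1.5    # futsal goal mouth: 3 m wide x 2 m high
    goal_height: float = 2.0


@dataclass
class KickResult:
    kick_id: str
    vx: float
    vy: float
    vz: float
    speed_kmh: float
    crossing: tuple[float, float] | None = None   # (x, z) on the goal plane
    accuracy_m: float | None = None
    flags: list = field(default_factory=list)


def _ols_line(t: np.ndarray, u: np.ndarray) -> tuple[float, float]:
    """Least-squares slope and intercept of u(t)."""
    slope, intercept = np.polyfit(t, u, 1)
    return float(slope), float(intercept)


def fit_horizontal_velocity(
    traj: BallTrajectory, n_frames: int = 10
) -> tuple[float, float]:
    """OLS slopes of x(t) and y(t) over the post-contact window (m·s⁻¹)."""
    if n_frames < 2:
        raise ValueError("need at least 2 frames for a slope")
    t, x, y, _ = traj.airborne(n_frames)
    vx, _ = _ols_line(t, x)
    vy, _ = _ols_line(t, y)
    return vx, vy


def fit_vertical_velocity(
    traj: BallTrajectory, n_frames: int = 10, g: float = G_DEFAULT
) -> float:
    """Vertical release velocity (m·s⁻¹) under the fixed-curvature model.

    Fits z(t) = z0 + vz·t − ½·g·t² by OLS on z + ½·g·t²; t is measured from
    foot contact, so the slope is vz at contact directly.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    t, _, _, z = traj.airborne(n_frames)
    vz, _ = _ols_line(t, z + 0.5 * g * t ** 2)
    return vz


def ball_speed(traj: BallTrajectory, n_frames: int = 10, g: float = G_DEFAULT) -> KickResult:
    """Release speed: Euclidean norm of the fitted components, in km·h⁻¹."""
    vx, vy = fit_horizontal_velocity(traj, n_frames)
    vz = fit_vertical_velocity(traj, n_frames, g)
    speed = MS_TO_KMH * float(np.sqrt(vx * vx + vy * vy + vz * vz))
    return KickResult(kick_id=traj.kick_id, vx=vx, vy=vy, vz=vz, speed_kmh=speed)


def goal_plane_crossing(
    traj: BallTrajectory,
    goal: GoalTarget,
    n_frames: int = 10,
    g: float = G_DEFAULT,
) -> tuple[tuple[float, float], list]:
    """(x, z) where the fitted flight crosses the goal plane, plus flags.

    Solves y(t*) = plane_y from the fitted linear y and evaluates the fitted
    x and constrained z at t*.  A crossing below floor level or outside the
    goal frame is flagged, not rejected: every attempt that crossed the goal
    line is scored.
    """
    t, x, y, z = traj.airborne(n_frames)
    vy, y0 = _ols_line(t, y)
    if vy <= 0:
        raise ValueError("ball does not travel toward the goal plane (vy <= 0)")
    t_star = (goal.plane_y - y0) / vy
    vx, x0 = _ols_line(t, x)
    vz, z0 = _ols_line(t, z + 0.5 * g * t ** 2)
    x_star = x0 + vx * t_star
    z_star = z0 + vz * t_star - 0.5 * g * t_star ** 2
    flags = []
    if z_star < 0:
        flags.append("below_ground")
    if abs(x_star) > goal.goal_half_width or not (0 <= z_star <= goal.goal_height):
        flags.append("outside_goal_frame")
    return (float(x_star), float(z_star)), flags


def accuracy(crossing: tuple[float, float], goal: GoalTarget) -> float:
    """Distance (m) from the crossing point to the nearest point of the
    closed target square; 0 inside or on the boundary."""
    cx, cz = goal.target_centre
    x, z = crossing
    nx = float(np.clip(x, cx - goal.target_half_width, cx + goal.target_half_width))
    nz = float(np.clip(z, cz - goal.target_half_height, cz + goal.target_half_height))
    return float(np.hypot(x - nx, z - nz))


def analyze_kick(
    traj: BallTrajectory,
    goal: GoalTarget | None = None,
    n_frames: int = 10,
    g: float = G_DEFAULT,
    crossing_override: tuple[float, float] | None = None,
) -> KickResult:
    """Full speed + accuracy analysis of one kick.

    ``crossing_override`` substitutes a frontal-camera measurement of the
    goal-plane crossing for the trajectory-derived one; the accuracy
    geometry is shared between the two input paths.
    """
    goal = goal or GoalTarget()
    res = ball_speed(traj, n_frames, g)
    if crossing_override is not None:
        res.crossing = crossing_override
    else:
        res.crossing, res.flags = goal_plane_crossing(traj, goal, n_frames, g)
    res.accuracy_m = accuracy(res.crossing, goal)
    return res


def summarize_set(results: list[KickResult]) -> tuple[float, float]:
    """Set means of speed (km·h⁻¹) and accuracy (m) over the attempts."""
    if not results:
        raise ValueError("empty kick set")
    speeds = [r.speed_kmh for r in results]
    accs = [r.accuracy_m for r in results if r.accuracy_m is not None]
    mean_acc = float(np.mean(accs)) if accs else float("nan")
    return float(np.mean(speeds)), mean_acc
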