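"""Continuous 2D arena with two differential-drive agents and two reward spots.

The arena hosts the embodied ("dynamic") version of the Battle of the Exes:
two circular agents start at mirrored poses, two reward spots sit at mirrored
positions on the far side, and a round ends as soon as one agent reaches a
spot.  Each agent carries six proximity sensors (high-reward, low-reward and
other-agent; one left and one right of the heading) whose activations feed
the reactive control laws.

Geometry, kinematic constants and the sensor model are configuration, not
physics constants: the game is defined up to an embodiment, and every number
here can be overridden through :class:`ArenaConfig`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence, Tuple

__all__ = [
    "ArenaConfig",
    "AgentPose",
    "SensorArray",
    "MotorCommand",
    "RoundEndVerdict",
    "read_sensors",
    "step_kinematics",
    "check_round_end",
    "wrap_angle",
]

TWO_PI = 2.0 * math.pi


def wrap_angle(theta: float) -> float:
    """Wrap an angle to the interval (-pi, pi]."""
    theta = math.fmod(theta, TWO_PI)
    if theta > math.pi:
        theta -= TWO_PI
    elif theta <= -math.pi:
        theta += TWO_PI
    return theta


class AgentPose(NamedTuple):
    """Planar pose of one agent: position in arena units, heading in radians."""

    x: float
    y: float
    heading: float


class SensorArray(NamedTuple):
    """The six proximity readings, each a dimensionless activation in [0, 1].

    ``sH`` senses the high-reward spot, ``sL`` the low-reward spot and ``sA``
    the other agent; each entity is sensed by a left and a right sensor offset
    from the heading by ``+-sensor_halfangle``.
    """

    sH_left: float
    sH_right: float
    sL_left: float
    sL_right: float
    sA_left: float
    sA_right: float


class MotorCommand(NamedTuple):
    """Left/right wheel speed commands (dimensionless, clamped downstream)."""

    m_left: float
    m_right: float


@dataclass
class ArenaConfig:
    """Geometry, sensing and kinematic constants of the arena.

    Defaults describe a 20 x 20 arena with the two agents starting at
    mirrored poses facing the two reward spots on the opposite side.  The
    high-reward spot is drawn physically larger than the low-reward spot
    (``high_spot_radius`` > ``low_spot_radius``); proximity sensors respond
    to the distance to the entity *surface*, so the bigger spot produces the
    stronger reading at equal center distance and is the more salient
    attractor.

    Parameters
    ----------
    width, height:
        Arena extent in length units.
    agent_radius:
        Body radius of each agent.
    spot_positions:
        The two fixed spot locations; which one holds the high reward is
        re-drawn at random every round.  Must be mirror images about the
        vertical midline ``x = width / 2``.
    agent_start_poses:
        Round-start ``(x, y, heading)`` of the two agents, side by side
        facing the spots, also mirrored about the midline.
    tie_radius:
        Radius of the tie circle around each spot: if the trailing agent is
        inside the circle of the spot the leader just reached, the round is
        a tie.
    spot_reach_radius:
        Distance at which a spot counts as reached (boundary inclusive).
    high_spot_radius, low_spot_radius:
        Visual radii of the spots, used only by the sensor model.
    avoid_gain:
        Gain of the agent-proximity sensors driving collision avoidance.
        Values above 1 make the mutual repulsion between nearby bodies an
        effective symmetry breaker in contested approaches.
    low_spot_gain:
        Gain of the low-spot sensors relative to the high-spot sensors.
        A smaller spot subtends a smaller visual angle, so it drives its
        sensor more weakly at every distance; this is what makes the big
        reward the primary reactive attractor for both agents.
    sensor_range:
        Linear-falloff range of the reward-spot sensors; defaults to the
        arena diagonal so spots are salient from anywhere.
    agent_sensor_range:
        Range of the agent-proximity sensor.  Much shorter than the spot
        range: collision avoidance is a late, local reflex rather than a
        global repeller.
    sensor_halfangle:
        Angular offset of the left/right sensors from the heading.
    dt:
        Integration step in seconds.
    speed_scale:
        Length units per second produced by a unit wheel command.
    wheelbase:
        Wheel separation; defaults to the agent diameter.
    max_steps:
        Step cap per round; hitting it scores the round as a tie.
    motor_noise:
        Standard deviation of zero-mean Gaussian noise added to each wheel
        command at every step.  This is what breaks the perfect mirror
        symmetry of the round-start configuration.
    """

    width: float = 20.0
    height: float = 20.0
    agent_radius: float = 0.5
    spot_positions: Tuple[Tuple[float, float], Tuple[float, float]] = (
        (6.0, 14.0),
        (14.0, 14.0),
    )
    agent_start_poses: Tuple[Tuple[float, float, float], Tuple[float, float, float]] = (
        (8.5, 3.0, math.pi / 2),
        (11.5, 3.0, math.pi / 2),
    )
    tie_radius: float = 3.0
    spot_reach_radius: float = 1.0
    high_spot_radius: float = 2.0
    low_spot_radius: float = 1.0
    low_spot_gain: float = 0.5
    avoid_gain: float = 1.0
    sensor_range: Optional[float] = None
    agent_sensor_range: float = 3.0
    sensor_halfangle: float = math.pi / 4
    dt: float = 0.1
    speed_scale: float = 1.0
    wheelbase: float = 1.0
    max_steps: int = 1000
    motor_noise: float = 0.05

    def __post_init__(self) -> None:
        if self.sensor_range is None:
            self.sensor_range = math.hypot(self.width, self.height)
        if not (self.tie_radius > self.spot_reach_radius > 0):
            raise ValueError("require tie_radius > spot_reach_radius > 0")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        mid = self.width / 2.0
        (x0, y0), (x1, y1) = self.spot_positions
        if not (math.isclose(y0, y1) and math.isclose(x0 - mid, mid - x1)):
            raise ValueError("spot positions must mirror about the arena midline")
        (ax0, ay0, ah0), (ax1, ay1, ah1) = self.agent_start_poses
        if not (
            math.isclose(ay0, ay1)
            and math.isclose(ax0 - mid, mid - ax1)
            # mirroring across the vertical midline maps heading h to pi - h
            and math.isclose(wrap_angle(ah0 + ah1 - math.pi), 0.0, abs_tol=1e-9)
        ):
            raise ValueError("start poses must mirror about the arena midline")


class RoundEndVerdict(NamedTuple):
    """Outcome of the per-step termination check.

    ``kind`` is one of ``"none"``, ``"reached"`` or ``"timeout"``; for
    ``"reached"``, ``reached`` lists every ``(agent_index, spot_label)`` pair
    that crossed the reach threshold this step (two entries when both agents
    arrive simultaneously).
    """

    kind: str
    reached: Tuple[Tuple[int, str], ...] = ()


def _sensor_pair(
    dx: float,
    dy: float,
    heading: float,
    entity_radius: float,
    sensor_range: float,
    halfangle: float,
) -> Tuple[float, float]:
    """Left/right activation for one entity at offset (dx, dy) from the agent.

    Activation = linear falloff of the surface distance times a cosine
    angular tuning centred ``+-halfangle`` off the heading, both clipped at
    zero, so every reading lies in [0, 1] and vanishes outside the sensor's
    range or field of view.
    """
    d = math.hypot(dx, dy) - entity_radius
    if d >= sensor_range:
        return 0.0, 0.0
    prox = 1.0 - d / sensor_range
    if prox > 1.0:
        prox = 1.0
    beta = wrap_angle(math.atan2(dy, dx) - heading)
    left = math.cos(beta - halfangle)
    right = math.cos(beta + halfangle)
    return (prox * left if left > 0.0 else 0.0, prox * right if right > 0.0 else 0.0)


def read_sensors(
    pose_self: AgentPose,
    pose_other: AgentPose,
    spot_high: Sequence[float],
    spot_low: Sequence[float],
    cfg: ArenaConfig,
) -> SensorArray:
    """Compute the six proximity readings for one agent.

    The closer an entity, the higher the reading; the reading on the side
    the entity lies on is the higher of the pair.  Raises ``ValueError`` on
    a non-finite pose (corrupted simulation state).
    """
    if not (
        math.isfinite(pose_self.x)
        and math.isfinite(pose_self.y)
        and math.isfinite(pose_self.heading)
    ):
        raise ValueError("non-finite agent pose: simulation state is corrupted")
    x, y, th = pose_self
    rng_, half = cfg.sensor_range, cfg.sensor_halfangle
    hl, hr = _sensor_pair(
        spot_high[0] - x, spot_high[1] - y, th, cfg.high_spot_radius, rng_, half
    )
    ll, lr = _sensor_pair(
        spot_low[0] - x, spot_low[1] - y, th, cfg.low_spot_radius, rng_, half
    )
    ll *= cfg.low_spot_gain
    lr *= cfg.low_spot_gain
    al, ar = _sensor_pair(
        pose_other.x - x, pose_other.y - y, th, cfg.agent_radius,
        cfg.agent_sensor_range, half,
    )
    al *= cfg.avoid_gain
    ar *= cfg.avoid_gain
    return SensorArray(hl, hr, ll, lr, al, ar)


def step_kinematics(pose: AgentPose, cmd: MotorCommand, cfg: ArenaConfig) -> AgentPose:
    """Advance one agent by one Euler step of differential-drive kinematics.

    Linear speed is ``speed_scale * (m_left + m_right) / 2``; angular speed is
    ``speed_scale * (m_right - m_left) / wheelbase``.  The position is clamped
    so the body stays inside the arena and the heading is wrapped to
    (-pi, pi].
    """
    v = 0.5 * cfg.speed_scale * (cmd.m_left + cmd.m_right)
    omega = cfg.speed_scale * (cmd.m_right - cmd.m_left) / cfg.wheelbase
    x = pose.x + v * math.cos(pose.heading) * cfg.dt
    y = pose.y + v * math.sin(pose.heading) * cfg.dt
    r = cfg.agent_radius
    if x < r:
        x = r
    elif x > cfg.width - r:
        x = cfg.width - r
    if y < r:
        y = r
    elif y > cfg.height - r:
        y = cfg.height - r
    return AgentPose(x, y, wrap_angle(pose.heading + omega * cfg.dt))


def check_round_end(
    pose_a: AgentPose,
    pose_b: AgentPose,
    spot_high: Sequence[float],
    spot_low: Sequence[float],
    cfg: ArenaConfig,
    steps: int,
) -> RoundEndVerdict:
    """Decide whether the round ends at this step.

    A spot is reached when the agent's center is within
    ``spot_reach_radius`` of it (boundary inclusive).  Both agents reaching
    in the same step yields a verdict naming both (scored as a tie by the
    game engine).  Hitting ``max_steps`` without a reach is a timeout.
    """
    reached = []
    for idx, pose in ((0, pose_a), (1, pose_b)):
        for label, spot in (("high", spot_high), ("low", spot_low)):
            if math.hypot(pose.x - spot[0], pose.y - spot[1]) <= cfg.spot_reach_radius:
                reached.append((idx, label))
                break
    if reached:
        return RoundEndVerdict("reached", tuple(reached))
    if steps >= cfg.max_steps:
        return RoundEndVerdict("timeout")
    return RoundEndVerdict("none")
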