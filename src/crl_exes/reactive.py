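"""Reactive layer: pre-wired Braitenberg control laws and their combination.

Two reflexes are wired into every agent: attraction to reward spots
(crossed excitatory / direct inhibitory sensor-motor connections) and
repulsion from the other agent (direct excitatory / crossed inhibitory).
Each law contributes a differential steering term on top of a shared
forward-speed constant ``f``; the adaptive layer can switch the two
attraction behaviors off through an inhibition mask, but avoidance is
always on.
"""

from __future__ import annotations

from dataclasses import dataclass

from .arena import MotorCommand, SensorArray

__all__ = [
    "ReactiveConfig",
    "InhibitionMask",
    "reward_seeking",
    "collision_avoidance",
    "combine_behaviors",
    "clamp_command",
]


@dataclass(frozen=True)
class ReactiveConfig:
    """Constants of the reactive layer.

    ``f`` is the baseline forward speed each wheel receives when no stimulus
    is present.  ``m_min``/``m_max`` bound the summed wheel commands before
    they reach the kinematics.
    """

    f: float = 0.3
    m_min: float = -1.0
    m_max: float = 1.0

    def __post_init__(self) -> None:
        if self.f < 0:
            raise ValueError("forward speed constant f must be >= 0")
        if self.m_min >= self.m_max:
            raise ValueError("require m_min < m_max")


@dataclass(frozen=True)
class InhibitionMask:
    """Which attraction behaviors are currently allowed to drive the wheels.

    Collision avoidance is never inhibited, so it has no flag here.
    """

    high_seek_active: bool = True
    low_seek_active: bool = True

FULL_MASK = InhibitionMask(True, True)


def clamp_command(m_left: float, m_right: float, cfg: ReactiveConfig) -> MotorCommand:
    """Clamp both wheel commands to the configured bounds."""
    return MotorCommand(
        min(max(m_left, cfg.m_min), cfg.m_max),
        min(max(m_right, cfg.m_min), cfg.m_max),
    )


def reward_seeking(s_left: float, s_right: float, cfg: ReactiveConfig) -> MotorCommand:
    """Attraction law: turn toward the side with the stronger spot reading.

    ``m_left = f + s_right - s_left`` and symmetrically for the right wheel,
    so the wheel opposite the stimulus spins faster and the agent turns in.
    With both sensors silent the command is straight ahead at speed ``f``.
    """
    return MotorCommand(cfg.f + s_right - s_left, cfg.f + s_left - s_right)


def collision_avoidance(
    sA_left: float, sA_right: float, cfg: ReactiveConfig
) -> MotorCommand:
    """Repulsion law: turn away from the side where the other agent looms.

    ``m_left = f + sA_left - sA_right``: the wheel on the stimulated side
    spins faster, steering the agent away from the other body.
    """
    return MotorCommand(cfg.f + sA_left - sA_right, cfg.f + sA_right - sA_left)


def combine_behaviors(
    sensors: SensorArray, mask: InhibitionMask, cfg: ReactiveConfig
) -> MotorCommand:
    """Superpose the active behaviors into one wheel command.

    The differential terms of every active behavior are summed on top of a
    single forward-speed constant (``f`` is contributed once, not once per
    behavior); inhibited attractors contribute nothing.  The result is
    clamped to ``[m_min, m_max]``.
    """
    diff = sensors.sA_left - sensors.sA_right  # avoidance, always on
    if mask.high_seek_active:
        diff += sensors.sH_right - sensors.sH_left
    if mask.low_seek_active:
        diff += sensors.sL_right - sensors.sL_left
    return clamp_command(cfg.f + diff, cfg.f - diff, cfg)
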