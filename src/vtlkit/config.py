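"""Arena geometry and trajectory-model parameter containers.

The arena is the circular well of a fly culture plate, imaged from above and
normalised so that the well maps to a circle 430 pixels in diameter.  The
coordinate origin sits at the upper-left corner of the frame, outside the
circle; ``x`` grows rightward and ``y`` grows downward.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


class ParameterError(ValueError):
    """An invalid simulation/tracking parameter value."""


#: Normalised well diameter, in pixels.
NORMALIZED_DIAMETER_PX = 430

#: Physical well diameter in mm, used for optional px -> mm conversion.
WELL_DIAMETER_MM = 35.0


@dataclass(frozen=True)
class ArenaConfig:
    """Geometry, photoperiod and rendering settings of one circular well.

    Parameters
    ----------
    diameter_px
        Well diameter in pixels after normalisation (430 by default).
    fps
        Acquisition frame rate in frames per second.
    light_on, light_off
        Clock hours (0-24) of the 12L12D photoperiod transitions.
    frame_size
        Side length of the square rendered frame, in pixels.
    background_level, object_level
        8-bit gray levels of the lit well floor and of an animal body; animals
        are darker than their surroundings.
    noise_sd
        Standard deviation of the additive Gaussian sensor noise (gray levels).
    object_axes
        Ellipse semi-axes of a rendered animal, in pixels.  The default
        (15, 7) gives a 30 x 14 px body, about 3 mm at 430 px per 35 mm well.
    """

    diameter_px: int = NORMALIZED_DIAMETER_PX
    fps: float = 7.2
    light_on: float = 8.0
    light_off: float = 20.0
    frame_size: int = 470
    background_level: int = 200
    object_level: int = 60
    noise_sd: float = 3.0
    object_axes: tuple[float, float] = (15.0, 7.0)

    def __post_init__(self) -> None:
        if self.diameter_px <= 0:
            raise ParameterError("diameter_px must be positive")
        if self.fps <= 0:
            raise ParameterError("fps must be positive")
        if not (0 <= self.light_on < 24 and 0 <= self.light_off < 24):
            raise ParameterError("light_on/light_off must be clock hours in [0, 24)")
        if self.light_on == self.light_off:
            raise ParameterError("light_on and light_off must differ")
        if self.object_level >= self.background_level:
            raise ParameterError("object_level must be darker than background_level")
        if self.frame_size < self.diameter_px:
            raise ParameterError("frame_size must accommodate the arena circle")
        if min(self.object_axes) <= 0:
            raise ParameterError("object_axes must be positive")

    @property
    def radius(self) -> float:
        return self.diameter_px / 2.0

    @property
    def center(self) -> tuple[float, float]:
        """Arena centre (x, y) in frame coordinates."""
        c = self.frame_size / 2.0
        return (c, c)

    def replace(self, **changes) -> "ArenaConfig":
        return replace(self, **changes)


@dataclass(frozen=True)
class BehaviorParams:
    """Two-state (active/rest) semi-Markov trajectory model parameters.

    Dwell times in each state are exponential with the given means; active
    steps are random-heading displacements drawn so that they always exceed
    the 3 px rest rule, while rest-state jitter stays strictly below
    ``rest_jitter_px`` (itself < 3 px), so the immobility-based sleep scoring
    recovers the generating states exactly.

    ``social_attraction`` is the probability that an active step is aimed at
    the nearest neighbour instead of a uniform heading; ``dark_rest_multiplier``
    scales rest dwell means during the dark phase, producing the night-time
    sleep consolidation that latency measures rely on.
    """

    mean_active_bout_s: float = 300.0
    mean_rest_bout_s: float = 600.0
    active_step_mean_px: float = 12.0
    rest_jitter_px: float = 1.0
    social_attraction: float = 0.2
    dark_rest_multiplier: float = 2.0
    #: Turning-angle SD (radians per frame) of the correlated walk: active
    #: locomotion is runs with gradual turns, not frame-wise diffusion.
    heading_turn_sd: float = 0.6
    seed: int = 0
    rest_threshold_px: float = field(default=3.0, repr=False)
    #: Hard-core body-contact distance: animals are rigid bodies and cannot
    #: interpenetrate, so centroids stay at least a body width apart
    #: (2 x the 7 px ellipse semi-minor axis).
    min_separation_px: float = field(default=14.0, repr=False)

    def __post_init__(self) -> None:
        if self.mean_active_bout_s < 0 or self.mean_rest_bout_s < 0:
            raise ParameterError("bout means must be non-negative")
        if self.mean_active_bout_s == 0 and self.mean_rest_bout_s == 0:
            raise ParameterError("at least one bout mean must be positive")
        if not (0 < self.rest_jitter_px < self.rest_threshold_px):
            raise ParameterError(
                f"rest_jitter_px must lie in (0, {self.rest_threshold_px}) so rest "
                "frames satisfy the immobility rule"
            )
        if self.active_step_mean_px <= self.rest_threshold_px:
            raise ParameterError(
                "active_step_mean_px must exceed the rest threshold so active "
                "steps are never scored as rest"
            )
        if not 0.0 <= self.social_attraction <= 1.0:
            raise ParameterError("social_attraction must be a probability")
        if self.dark_rest_multiplier <= 0:
            raise ParameterError("dark_rest_multiplier must be positive")

    def replace(self, **changes) -> "BehaviorParams":
        return replace(self, **changes)
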