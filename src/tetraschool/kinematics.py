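"""Burst-and-coast kinematics of a single fish.

A fish moves in discrete kicks: at the kick onset it chooses a new heading,
then glides along a straight line while its speed decays quasi-exponentially
with relaxation time tau0.  A kick is characterized by its length l and
duration tau; the glide covers exactly l over tau, so the position at the
end of kick n is position + l * e(heading).

The printed experimental means (l = 0.07 m, tau = 0.5 s, v0 = 0.14 m/s,
tau0 = 0.8 s) are not mutually consistent with an exponential speed decay
integrating to l; this package honors the kick length exactly and derives
the peak speed v_peak = l / (tau0 * (1 - exp(-tau/tau0))), exposing the
printed v0 only as the reference constant ``V0_REFERENCE``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .angles import wrap_angle

__all__ = [
    "TAU0_DEFAULT",
    "V0_REFERENCE",
    "FishState",
    "KickStatistics",
    "sample_kick",
    "peak_speed",
    "glide_fraction",
    "glide_position",
    "glide_speed",
    "apply_kick",
    "heading_noise",
]

#: default glide relaxation time, seconds
TAU0_DEFAULT = 0.8
#: mean measured peak speed, m/s — reference only, not used by the dynamics
V0_REFERENCE = 0.14


@dataclass(frozen=True)
class FishState:
    """Kinematic state of one fish between two kicks.

    ``position`` is the position at the onset of the current kick and
    ``heading`` the (constant) gliding direction of this kick.
    """

    id: int
    position: np.ndarray  # (2,) metres, at kick onset
    heading: float  # radians in (-pi, pi]
    kick_start: float  # seconds
    kick_duration: float  # seconds, > 0
    kick_length: float  # metres, > 0

    def __post_init__(self) -> None:
        if self.kick_duration <= 0 or self.kick_length <= 0:
            raise ValueError("kick duration and length must be positive")
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        object.__setattr__(self, "heading", wrap_angle(self.heading))

    @property
    def kick_end(self) -> float:
        return self.kick_start + self.kick_duration


@dataclass(frozen=True)
class KickStatistics:
    """Statistics of kick lengths and durations.

    ``mode="fixed"`` always returns the means; ``mode="sampled"`` draws
    independent gamma variates with the given means and coefficient of
    variation, truncated below at 10% of the mean (the experimental
    distributions are bell-shaped with these means; their exact form is not
    published).
    """

    mean_length: float = 0.07  # metres
    mean_duration: float = 0.5  # seconds
    mean_peak_speed: float = V0_REFERENCE  # m/s, reference constant
    relaxation_time: float = TAU0_DEFAULT  # tau0, seconds
    variability_cv: float = 0.3
    mode: str = "sampled"

    def __post_init__(self) -> None:
        if min(self.mean_length, self.mean_duration, self.mean_peak_speed, self.relaxation_time) <= 0:
            raise ValueError("kick statistics must be positive")
        if self.variability_cv < 0:
            raise ValueError("variability_cv must be >= 0")
        if self.mode not in ("fixed", "sampled"):
            raise ValueError(f"unknown kick mode {self.mode!r}")


def _truncated_gamma(rng: np.random.Generator, mean: float, cv: float, size) -> np.ndarray:
    """Gamma variates with given mean and CV, resampled below 0.1 * mean."""
    if cv == 0.0:
        return np.full(size, mean)
    shape = 1.0 / cv**2
    scale = mean * cv**2
    draws = rng.gamma(shape, scale, size=size)
    floor = 0.1 * mean
    while True:
        low = draws < floor
        if not low.any():
            return draws
        draws[low] = rng.gamma(shape, scale, size=int(low.sum()))


def sample_kick(rng: np.random.Generator, stats: KickStatistics, size=None):
    """Draw kick (length, duration) pairs; scalars if ``size`` is None."""
    shape = () if size is None else size
    if stats.mode == "fixed":
        length = np.full(shape, stats.mean_length)
        duration = np.full(shape, stats.mean_duration)
    else:
        length = _truncated_gamma(rng, stats.mean_length, stats.variability_cv, shape)
        duration = _truncated_gamma(rng, stats.mean_duration, stats.variability_cv, shape)
    if size is None:
        return float(length), float(duration)
    return length, duration


def peak_speed(kick_length: float, kick_duration: float, tau0: float = TAU0_DEFAULT) -> float:
    """Speed right after the kick, such that the glide integrates to the kick length."""
    return kick_length / (tau0 * (1.0 - np.exp(-kick_duration / tau0)))


def glide_fraction(s, kick_duration: float, tau0: float = TAU0_DEFAULT):
    """Fraction of the kick length covered a time ``s`` after the kick onset.

    f(0) = 0 and f(tau) = 1, so the kick displacement is exact at kick end.
    """
    return (1.0 - np.exp(-np.asarray(s, dtype=float) / tau0)) / (
        1.0 - np.exp(-kick_duration / tau0)
    )


def glide_position(state: FishState, t: float, tau0: float = TAU0_DEFAULT) -> np.ndarray:
    """Position of the fish at time ``t`` within its current kick window."""
    s = t - state.kick_start
    if s < 0 or s > state.kick_duration + 1e-12:
        raise ValueError(
            f"t={t} outside kick window [{state.kick_start}, {state.kick_end}]"
        )
    frac = glide_fraction(min(s, state.kick_duration), state.kick_duration, tau0)
    direction = np.array([np.cos(state.heading), np.sin(state.heading)])
    return state.position + state.kick_length * frac * direction


def glide_speed(state: FishState, t: float, tau0: float = TAU0_DEFAULT) -> float:
    """Instantaneous speed at time ``t`` within the current kick window."""
    s = t - state.kick_start
    if s < 0 or s > state.kick_duration + 1e-12:
        raise ValueError(
            f"t={t} outside kick window [{state.kick_start}, {state.kick_end}]"
        )
    return peak_speed(state.kick_length, state.kick_duration, tau0) * np.exp(-min(s, state.kick_duration) / tau0)


def apply_kick(state: FishState, delta_phi: float, new_length: float, new_duration: float,
               tau0: float = TAU0_DEFAULT) -> FishState:
    """Advance a fish past the end of its current kick.

    The fish moves to the glide endpoint of the old kick, turns by
    ``delta_phi`` (applied before wrapping, so turns larger than pi are
    meaningful), and starts a new kick of the given length and duration.
    """
    if new_length <= 0 or new_duration <= 0:
        raise ValueError("new kick length and duration must be positive")
    endpoint = glide_position(state, state.kick_end, tau0)
    return replace(
        state,
        position=endpoint,
        heading=wrap_angle(state.heading + delta_phi),
        kick_start=state.kick_end,
        kick_duration=new_duration,
        kick_length=new_length,
    )


def heading_noise(rng: np.random.Generator, gamma_r: float, size=None):
    """Spontaneous heading fluctuation: gamma_r times a standard normal draw."""
    if gamma_r < 0:
        raise ValueError("gamma_r must be >= 0")
    draw = rng.standard_normal() if size is None else rng.standard_normal(size)
    return gamma_r * draw
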