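"""Analytic school configurations with known observable values.

These generators produce small synthetic snapshots — rings, aligned lines,
mirrored pairs, random clouds — whose polarization, milling index and
dispersion can be written down in closed form.  They are used to test the
observables and the interaction kernel, and are exposed on the command line
for quick inspection.
"""

from __future__ import annotations

import numpy as np

from .angles import wrap_angle
from .observables import SchoolSnapshot

__all__ = [
    "milling_ring",
    "aligned_line",
    "mirrored_pair",
    "radial_ring",
    "random_cloud",
]


def milling_ring(n: int = 4, radius: float = 1.0, speed: float = 0.14,
                 ccw: bool = True, time: float = 0.0) -> SchoolSnapshot:
    """n fish on a circle, all moving tangentially: a perfect mill (M = 1)."""
    theta = 2.0 * np.pi * np.arange(n) / n
    positions = radius * np.column_stack([np.cos(theta), np.sin(theta)])
    offset = np.pi / 2 if ccw else -np.pi / 2
    headings = wrap_angle(theta + offset)
    return SchoolSnapshot(time, positions, headings, np.full(n, speed))


def radial_ring(n: int = 4, radius: float = 1.0, speed: float = 0.14,
                outward: bool = True, time: float = 0.0) -> SchoolSnapshot:
    """n fish on a circle moving radially: zero milling, zero polarization (n>=3)."""
    theta = 2.0 * np.pi * np.arange(n) / n
    positions = radius * np.column_stack([np.cos(theta), np.sin(theta)])
    headings = wrap_angle(theta if outward else theta + np.pi)
    return SchoolSnapshot(time, positions, headings, np.full(n, speed))


def aligned_line(n: int = 5, spacing: float = 0.1, heading: float = 0.0,
                 speed: float = 0.14, time: float = 0.0) -> SchoolSnapshot:
    """n fish on a line abreast, all sharing one heading: P = 1."""
    lateral = np.array([-np.sin(heading), np.cos(heading)])
    offsets = (np.arange(n) - (n - 1) / 2.0) * spacing
    positions = offsets[:, None] * lateral[None, :]
    return SchoolSnapshot(time, positions, np.full(n, wrap_angle(heading)),
                          np.full(n, speed))


def mirrored_pair(separation: float = 0.1, heading: float = 0.0,
                  speed: float = 0.14, time: float = 0.0) -> SchoolSnapshot:
    """Two fish side by side, mirror images about their common heading axis."""
    lateral = np.array([-np.sin(heading), np.cos(heading)])
    positions = np.vstack([separation / 2.0 * lateral, -separation / 2.0 * lateral])
    return SchoolSnapshot(time, positions, np.full(2, wrap_angle(heading)),
                          np.full(2, speed))


def random_cloud(n: int, rng: np.random.Generator, radius: float = 1.0,
                 speed_mean: float = 0.14, time: float = 0.0) -> SchoolSnapshot:
    """Uniform disc of fish with uniform random headings and positive speeds."""
    r = radius * np.sqrt(rng.uniform(size=n))
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    positions = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    headings = rng.uniform(-np.pi, np.pi, size=n)
    speeds = speed_mean * (0.5 + rng.uniform(size=n))
    return SchoolSnapshot(time, positions, headings, speeds)
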