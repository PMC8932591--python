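"""Shared angle utilities.

Every heading, viewing angle and relative heading in the package is kept in
the half-open interval (-pi, pi]; a single wrapping helper is used everywhere
so that no two modules can drift apart in their convention.
"""

from __future__ import annotations

import numpy as np

__all__ = ["wrap_angle"]

_TWO_PI = 2.0 * np.pi


def wrap_angle(angle):
    """Wrap an angle (scalar or array, radians) into (-pi, pi].

    The positive boundary is kept: ``wrap_angle(pi) == pi`` and
    ``wrap_angle(-pi) == pi``.
    """
    wrapped = np.mod(np.asarray(angle, dtype=float) + np.pi, _TWO_PI) - np.pi
    wrapped = np.where(wrapped == -np.pi, np.pi, wrapped)
    if np.ndim(angle) == 0:
        return float(wrapped)
    return wrapped
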