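"""Pairwise social interaction of burst-and-coast fish.

At each kick the focal fish turns by the sum of pairwise contributions from a
small set of neighbors.  Each pairwise contribution is the sum of an
attraction term and an alignment term, and each term factorizes into a radial
intensity and two angular modulations of definite parity:

    dphi_ij = F_att(d) * O_att(psi) * E_att(phi)
            + F_ali(d) * E_ali(psi) * O_ali(phi)

where ``d`` is the inter-fish distance, ``psi`` the viewing angle at which
the focal fish perceives the neighbor (measured from its own heading), and
``phi`` the relative heading of the neighbor.  ``O`` denotes odd and ``E``
even angular functions; the numerical coefficients are empirical fits for
*Hemigrammus rhodostomus* and are fixed, while the strengths (gamma) and
ranges (l, d) are free model parameters.

The *influence* of a neighbor is the absolute value of its pairwise
contribution; a fish reacts only to its ``k`` most influential neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .angles import wrap_angle

__all__ = [
    "InteractionParams",
    "RelativeState",
    "relative_state",
    "f_att",
    "o_att",
    "e_att",
    "f_ali",
    "e_ali",
    "o_ali",
    "pairwise_turn",
    "influence",
    "select_influential",
]


@dataclass(frozen=True)
class InteractionParams:
    """Strengths, ranges and neighbor count of the social interaction.

    Parameters
    ----------
    gamma_att, gamma_ali:
        Dimensionless intensities of attraction and alignment.  The values
        fitted on pairs of H. rhodostomus are 0.12 and 0.09.
    l_att, l_ali:
        Interaction ranges in metres (0.20 m for experimental pairs; the
        phase-diagram experiments use 0.28 m).
    d_att:
        Distance in metres below which attraction turns into repulsion
        (about one body length, 0.03 m), preventing collisions.
    d_ali:
        Distance scale of the alignment intensity, metres.
    k:
        Number of most influential neighbors the focal fish reacts to.
    """

    gamma_att: float = 0.12
    gamma_ali: float = 0.09
    l_att: float = 0.20
    l_ali: float = 0.20
    d_att: float = 0.03
    d_ali: float = 0.06
    k: int = 1

    def __post_init__(self) -> None:
        if self.l_att <= 0 or self.l_ali <= 0 or self.d_att <= 0 or self.d_ali <= 0:
            raise ValueError("interaction ranges and distance scales must be positive")
        if self.gamma_att < 0 or self.gamma_ali < 0:
            raise ValueError("interaction strengths must be nonnegative")
        if int(self.k) < 1:
            raise ValueError("k (number of influential neighbors) must be >= 1")


class RelativeState(NamedTuple):
    """Relative state (d, psi, phi) of a neighbor seen by the focal fish.

    d is the Euclidean distance (m), psi the viewing angle and phi the
    relative heading, both wrapped to (-pi, pi].  Fields may be numpy arrays
    for batched evaluation.
    """

    d: float
    psi: float
    phi: float

    @property
    def degenerate(self):
        """True where the neighbor coincides with the focal fish (psi undefined)."""
        return self.d == 0.0


def relative_state(focal_position, focal_heading, neighbor_position, neighbor_heading) -> RelativeState:
    """Relative state of a neighbor (or an array of neighbors) w.r.t. a focal fish.

    For a coincident neighbor (d = 0) the viewing angle is undefined; it is
    set to 0 by convention, which zeroes the attraction term (O_att(0) = 0).
    """
    focal_position = np.asarray(focal_position, dtype=float)
    neighbor_position = np.asarray(neighbor_position, dtype=float)
    offset = neighbor_position - focal_position
    d = np.hypot(offset[..., 0], offset[..., 1])
    bearing = np.arctan2(offset[..., 1], offset[..., 0])
    psi = np.where(d == 0.0, 0.0, wrap_angle(bearing - focal_heading))
    phi = wrap_angle(np.asarray(neighbor_heading, dtype=float) - focal_heading)
    if np.ndim(d) == 0:
        return RelativeState(float(d), float(psi), float(phi))
    return RelativeState(d, psi, phi)


def f_att(d, params: InteractionParams):
    """Radial attraction intensity: repulsive below d_att, ~1/d at long range."""
    d = np.asarray(d, dtype=float)
    out = params.gamma_att * (d / params.d_att - 1.0) / (1.0 + (d / params.l_att) ** 2)
    return float(out) if out.ndim == 0 else out


def o_att(psi):
    """Odd angular modulation of attraction (max near lateral neighbors)."""
    psi = np.asarray(psi, dtype=float)
    out = 1.395 * np.sin(psi) * (1.0 - 0.33 * np.cos(psi))
    return float(out) if out.ndim == 0 else out


def e_att(phi):
    """Even relative-heading modulation of attraction."""
    phi = np.asarray(phi, dtype=float)
    out = 0.9326 * (1.0 - 0.48 * np.cos(phi) - 0.31 * np.cos(2.0 * phi))
    return float(out) if out.ndim == 0 else out


def f_ali(d, params: InteractionParams):
    """Radial alignment intensity: gamma_ali at contact, Gaussian cutoff at l_ali."""
    d = np.asarray(d, dtype=float)
    out = params.gamma_ali * (d / params.d_ali + 1.0) * np.exp(-((d / params.l_ali) ** 2))
    return float(out) if out.ndim == 0 else out


def e_ali(psi):
    """Even viewing-angle modulation of alignment (strongest ahead)."""
    psi = np.asarray(psi, dtype=float)
    out = 0.9012 * (1.0 + 0.6 * np.cos(psi) - 0.32 * np.cos(2.0 * psi))
    return float(out) if out.ndim == 0 else out


def o_ali(phi):
    """Odd relative-heading modulation of alignment (restoring toward phi = 0)."""
    phi = np.asarray(phi, dtype=float)
    out = 1.6385 * np.sin(phi) * (1.0 + 0.3 * np.cos(2.0 * phi))
    return float(out) if out.ndim == 0 else out


def pairwise_turn(rel: RelativeState, params: InteractionParams):
    """Heading-change contribution (radians) of one neighbor to the focal fish.

    Sum of the attraction and alignment products.  Under a mirror reflection
    about the focal heading axis, (psi, phi) -> (-psi, -phi), and the odd/even
    structure flips the sign of the result.
    """
    att = f_att(rel.d, params) * o_att(rel.psi) * e_att(rel.phi)
    ali = f_ali(rel.d, params) * e_ali(rel.psi) * o_ali(rel.phi)
    return att + ali


def influence(rel: RelativeState, params: InteractionParams):
    """Influence of a neighbor: absolute pairwise heading-change contribution."""
    return np.abs(pairwise_turn(rel, params))


def select_influential(focal_index: int, positions, headings, params: InteractionParams):
    """Rank neighbors of ``focal_index`` by influence and keep the top k.

    Parameters
    ----------
    focal_index:
        Index of the focal fish in the state arrays.
    positions, headings:
        Arrays of shape (N, 2) and (N,) with every fish's position and
        current heading at the evaluation instant.
    params:
        Interaction parameters; ``params.k`` neighbors are returned (all
        N - 1 if k exceeds it).

    Returns
    -------
    ids : ndarray of int
        Neighbor indices, influence descending; ties broken by lower index.
    rel : RelativeState
        Batched relative states of the selected neighbors, same order.
    """
    positions = np.asarray(positions, dtype=float)
    headings = np.asarray(headings, dtype=float)
    n = positions.shape[0]
    if n < 2:
        empty = np.empty(0)
        return np.empty(0, dtype=int), RelativeState(empty, empty, empty)
    others = np.delete(np.arange(n), focal_index)
    rel = relative_state(
        positions[focal_index], headings[focal_index], positions[others], headings[others]
    )
    infl = influence(rel, params)
    # stable sort on -influence keeps ascending-id order among exact ties
    order = np.argsort(-infl, kind="stable")[: min(int(params.k), n - 1)]
    ids = others[order]
    return ids, RelativeState(rel.d[order], rel.psi[order], rel.phi[order])
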