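"""Collective-state order parameters and school diagnostics.

Three observables characterize a school snapshot:

- dispersion ``D``: root-mean-square distance of fish to the school
  barycenter (metres); unbounded growth signals group break-up;
- polarization ``P`` in [0, 1]: norm of the mean heading unit vector;
- milling ``M`` in [0, 1]: absolute mean of sin(phibar_i - thetabar_i),
  where thetabar_i and phibar_i are the position angle and the velocity
  direction of fish i in the barycenter frame (positions and velocities
  both taken relative to the barycenter) — a coherent vortex gives 1.

Phases are classified from replicate-and-time means: Dispersion when D
exceeds a threshold (5 m by default, 7 m in the group-size experiments),
otherwise Schooling / Milling / Intermittent / Swarming by the P and M
inequalities against 0.4.

Diagnostics of the interaction topology are also provided: the number of
distinct most-influential-neighbor identities (DMIN) and distinct
first-nearest-neighbor identities (DFNN) across the school at an instant,
the per-fish nearest-neighbor distance, and a partition of the school into
"3-groups" by closure of the directed 3-nearest-neighbor relation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
import numpy as np

from . import _engine
from .kernel import InteractionParams

__all__ = [
    "SchoolSnapshot",
    "ObservableSeries",
    "PhaseLabel",
    "PhaseThresholds",
    "barycenter",
    "dispersion",
    "polarization",
    "milling",
    "classify_phase",
    "nearest_neighbor_distance",
    "count_distinct_influential",
    "count_distinct_nearest",
    "three_group_partition",
    "pdf_along_cut",
    "observable_series",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SchoolSnapshot:
    """Positions, headings and speeds of all N fish at one sampling instant."""

    time: float
    positions: np.ndarray  # (N, 2) metres
    headings: np.ndarray  # (N,) radians
    speeds: np.ndarray  # (N,) m/s

    def __post_init__(self) -> None:
        n = len(self.positions)
        if len(self.headings) != n or len(self.speeds) != n:
            raise ValueError("positions, headings and speeds must have equal length")
        if np.any(np.asarray(self.speeds) < 0):
            raise ValueError("speeds must be nonnegative")

    @property
    def n_fish(self) -> int:
        return len(self.positions)

    @property
    def velocities(self) -> np.ndarray:
        return self.speeds[:, None] * np.column_stack(
            [np.cos(self.headings), np.sin(self.headings)]
        )


@dataclass(frozen=True)
class ObservableSeries:
    """Time series of the three order parameters on the sampling grid."""

    times: np.ndarray
    dispersion: np.ndarray
    polarization: np.ndarray
    milling: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("sampling grid must be strictly increasing")


class PhaseLabel(str, Enum):
    SCHOOLING = "Schooling"
    MILLING = "Milling"
    INTERMITTENT = "Intermittent"
    SWARMING = "Swarming"
    DISPERSION = "Dispersion"


@dataclass(frozen=True)
class PhaseThresholds:
    """Classification thresholds (P/M against 0.4; D against d_max metres)."""

    p: float = 0.4
    m: float = 0.4
    d_max: float = 5.0


def barycenter(snapshot: SchoolSnapshot):
    """Barycenter position, mean velocity, and barycenter heading.

    The heading is the direction of the mean velocity vector; if that vector
    vanishes (e.g. a symmetric mill) the heading is undefined and 0 is
    returned by convention.
    """
    pos = np.mean(snapshot.positions, axis=0)
    vel = np.mean(snapshot.velocities, axis=0)
    if np.hypot(*vel) == 0.0:
        log.debug("barycenter velocity vanishes at t=%s; heading set to 0", snapshot.time)
        heading = 0.0
    else:
        heading = float(np.arctan2(vel[1], vel[0]))
    return pos, vel, heading


def dispersion(snapshot: SchoolSnapshot, mean_square: bool = False) -> float:
    """RMS distance to the barycenter, metres (mean-square with the flag)."""
    center = np.mean(snapshot.positions, axis=0)
    sq = np.sum((snapshot.positions - center) ** 2, axis=1)
    ms = float(np.mean(sq))
    return ms if mean_square else float(np.sqrt(ms))


def polarization(snapshot: SchoolSnapshot) -> float:
    """Norm of the mean heading unit vector, in [0, 1]."""
    ex = np.mean(np.cos(snapshot.headings))
    ey = np.mean(np.sin(snapshot.headings))
    return float(np.hypot(ex, ey))


def milling(snapshot: SchoolSnapshot) -> float:
    """Milling index in [0, 1].

    For each fish, sin(phibar - thetabar) is the normalized cross product of
    its barycenter-frame position and barycenter-frame velocity; fish
    exactly at the barycenter (or with vanishing relative velocity) have an
    undefined term and are excluded from the mean.
    """
    if snapshot.n_fish < 2:
        raise ValueError("milling requires at least 2 fish")
    center = np.mean(snapshot.positions, axis=0)
    u = snapshot.positions - center
    v = snapshot.velocities - np.mean(snapshot.velocities, axis=0)
    ru = np.hypot(u[:, 0], u[:, 1])
    rv = np.hypot(v[:, 0], v[:, 1])
    # 1e-12 (m, m/s) absorbs round-off in the barycenter subtraction
    ok = (ru > 1e-12) & (rv > 1e-12)
    if not np.all(ok):
        log.debug("milling: excluding %d degenerate term(s) at t=%s",
                  int(np.sum(~ok)), snapshot.time)
    if not np.any(ok):
        return 0.0
    cross = u[ok, 0] * v[ok, 1] - u[ok, 1] * v[ok, 0]
    return float(abs(np.mean(cross / (ru[ok] * rv[ok]))))


def classify_phase(mean_p: float, mean_m: float, mean_d: float,
                   thresholds: PhaseThresholds = PhaseThresholds()) -> PhaseLabel:
    """Phase of a cell from its replicate-and-time means.

    The dispersion test precedes the P/M tests; on the measure-zero P/M
    boundaries the first matching rule in the order Schooling, Milling,
    Intermittent, Swarming applies.
    """
    if mean_d > thresholds.d_max:
        return PhaseLabel.DISPERSION
    if mean_p >= thresholds.p and mean_m <= thresholds.m:
        return PhaseLabel.SCHOOLING
    if mean_p <= thresholds.p and mean_m >= thresholds.m:
        return PhaseLabel.MILLING
    if mean_p > thresholds.p and mean_m > thresholds.m:
        return PhaseLabel.INTERMITTENT
    return PhaseLabel.SWARMING


def _pairwise_distances(positions: np.ndarray) -> np.ndarray:
    diff = positions[:, None, :] - positions[None, :, :]
    return np.hypot(diff[..., 0], diff[..., 1])


def nearest_neighbor_distance(snapshot: SchoolSnapshot):
    """Per-fish distance to its nearest neighbor, and the school mean."""
    if snapshot.n_fish < 2:
        raise ValueError("nearest_neighbor_distance requires at least 2 fish")
    d = _pairwise_distances(snapshot.positions)
    np.fill_diagonal(d, np.inf)
    per_fish = d.min(axis=1)
    return per_fish, float(per_fish.mean())


def count_distinct_influential(snapshot: SchoolSnapshot, params: InteractionParams) -> int:
    """Number of distinct most-influential-neighbor identities (DMIN).

    Each fish picks its single most influential neighbor (k = 1 selection,
    regardless of ``params.k``); the count of distinct identities in those N
    choices is returned.
    """
    if snapshot.n_fish < 2:
        raise ValueError("requires at least 2 fish")
    choice = _engine.influence_argmax_nb(
        np.ascontiguousarray(snapshot.positions, dtype=float),
        np.ascontiguousarray(snapshot.headings, dtype=float),
        params.gamma_att, params.gamma_ali, params.l_att, params.l_ali,
        params.d_att, params.d_ali,
    )
    return int(np.unique(choice).size)


def count_distinct_nearest(snapshot: SchoolSnapshot) -> int:
    """Number of distinct first-nearest-neighbor identities (DFNN)."""
    if snapshot.n_fish < 2:
        raise ValueError("requires at least 2 fish")
    choice = _engine.nearest_argmin_nb(np.ascontiguousarray(snapshot.positions, dtype=float))
    return int(np.unique(choice).size)


def three_group_partition(snapshot: SchoolSnapshot) -> list[set[int]]:
    """Partition of the school by closure of the directed 3-nearest-neighbor map.

    Starting from the lowest-id unassigned fish, a group absorbs the three
    nearest neighbors of each of its members, recursively; when a closure
    reaches a fish already assigned to an earlier group the two groups are
    merged.  The result is a disjoint cover of all N fish in which every
    group has at least 4 members.
    """
    n = snapshot.n_fish
    if n < 4:
        raise ValueError("three_group_partition requires at least 4 fish")
    d = _pairwise_distances(snapshot.positions)
    np.fill_diagonal(d, np.inf)
    # three nearest, distance ties broken by lower id (stable argsort)
    nn3 = np.argsort(d, axis=1, kind="stable")[:, :3]
    group_of = np.full(n, -1, dtype=int)
    groups: list[set[int]] = []
    for seed in range(n):
        if group_of[seed] >= 0:
            continue
        gid = len(groups)
        groups.append({seed})
        group_of[seed] = gid
        stack = [seed]
        while stack:
            x = stack.pop()
            for nb in nn3[x]:
                other = group_of[nb]
                if other == gid:
                    continue
                if other == -1:
                    group_of[nb] = gid
                    groups[gid].add(nb)
                    stack.append(nb)
                else:  # contact with an earlier group: merge into it
                    for member in groups[gid]:
                        group_of[member] = other
                    groups[other] |= groups[gid]
                    groups[gid] = set()
                    gid = other
    return [g for g in groups if g]


def pdf_along_cut(samples: np.ndarray, bins=50, range_=(0.0, 1.0)):
    """Normalized histogram (density) and mean of pooled observable samples."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("empty sample set")
    density, edges = np.histogram(samples, bins=bins, range=range_, density=True)
    return density, edges, float(samples.mean())


def observable_series(record, mean_square: bool = False) -> ObservableSeries:
    """Order-parameter time series of a :class:`~tetraschool.simulator.TrajectoryRecord`."""
    n_t = len(record.times)
    d = np.empty(n_t)
    p = np.empty(n_t)
    m = np.empty(n_t)
    for t in range(n_t):
        snap = SchoolSnapshot(record.times[t], record.positions[t],
                              record.headings[t], record.speeds[t])
        d[t] = dispersion(snap, mean_square=mean_square)
        p[t] = polarization(snap)
        m[t] = milling(snap) if snap.n_fish >= 2 else 0.0
    return ObservableSeries(record.times, d, p, m)


def snapshot_at(record, index: int) -> SchoolSnapshot:
    """The ``index``-th sampling instant of a trajectory record as a snapshot."""
    return SchoolSnapshot(record.times[index], record.positions[index],
                          record.headings[index], record.speeds[index])
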