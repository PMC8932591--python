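"""Asynchronous event-driven simulation of a burst-and-coast school.

Each fish is an independent kicker: its kick-end events are interleaved in
global time order (ties broken by fish id).  When a fish's kick ends it is
moved to its glide endpoint, every other fish is interpolated to that exact
instant along its own glide, the focal fish ranks its neighbors by influence,
sums the pairwise turns of the top ``k``, adds Gaussian heading noise, and
starts a freshly sampled kick.

All randomness is pre-drawn from named ``SeedSequence`` children (school
initialization, per-fish kick sampling, per-fish noise) before the loop
starts, so a run is a pure function of its configuration and both engines —
the compiled fast path and the pure-Python reference path — consume the
same draws.

Two engines are provided:

- ``engine="fast"`` (default): compiled event loop in :mod:`tetraschool._engine`.
- ``engine="python"``: a readable reference built on :mod:`tetraschool.kernel`
  and :mod:`tetraschool.kinematics` with a heapq event queue; used for
  cross-validation and small-N experiments.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import _engine
from .angles import wrap_angle
from .kernel import InteractionParams, pairwise_turn, select_influential
from .kinematics import FishState, KickStatistics, glide_fraction, peak_speed, sample_kick

__all__ = [
    "SimulationConfig",
    "TrajectoryRecord",
    "DrawSet",
    "draw_randomness",
    "initial_radius",
    "init_school",
    "step",
    "run",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one simulation run."""

    n_fish: int = 100
    params: InteractionParams = field(default_factory=InteractionParams)
    gamma_r: float = 0.2
    kick_stats: KickStatistics = field(default_factory=KickStatistics)
    n_kicks_per_fish: int = 2000
    transient_seconds: float = 100.0
    sampling_dt: float = 1.0
    seed: int | Sequence[int] = 0
    n_replicates: int = 20
    record_kicks: bool = True

    def __post_init__(self) -> None:
        if self.n_fish < 1:
            raise ValueError("n_fish must be >= 1")
        if self.n_kicks_per_fish < 1:
            raise ValueError("n_kicks_per_fish must be >= 1")
        if self.sampling_dt <= 0:
            raise ValueError("sampling_dt must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.gamma_r < 0:
            raise ValueError("gamma_r must be >= 0")
        if self.n_kicks_per_fish * self.kick_stats.mean_duration <= self.transient_seconds:
            raise ValueError(
                "run too short: n_kicks_per_fish * mean_duration must exceed transient_seconds"
            )


@dataclass(frozen=True)
class DrawSet:
    """Pre-drawn randomness of one run (see module docstring)."""

    positions: np.ndarray  # (N, 2) initial positions
    headings: np.ndarray  # (N,) initial headings
    staggers: np.ndarray  # (N,) first kick onsets in [0, mean_duration)
    kick_len: np.ndarray  # (N, n_kicks + 1); entry 0 is the initial kick
    kick_dur: np.ndarray  # (N, n_kicks + 1)
    noise: np.ndarray  # (N, n_kicks) standard normal draws


@dataclass
class TrajectoryRecord:
    """Snapshots on the sampling grid plus (optionally) every kick event."""

    config: SimulationConfig
    times: np.ndarray  # (T,)
    positions: np.ndarray  # (T, N, 2)
    headings: np.ndarray  # (T, N)
    speeds: np.ndarray  # (T, N)
    kick_time: Optional[np.ndarray] = None  # (E,)
    kick_fish: Optional[np.ndarray] = None  # (E,)
    kick_dphi_s: Optional[np.ndarray] = None  # (E,) social turn
    kick_dphi_r: Optional[np.ndarray] = None  # (E,) noise turn
    kick_selected: Optional[np.ndarray] = None  # (E, k) neighbor ids, -1 padded
    kick_rel: Optional[np.ndarray] = None  # (E, k, 2) focal-frame neighbor offsets

    @property
    def n_fish(self) -> int:
        return self.positions.shape[1]

    def post_transient(self, transient_seconds: Optional[float] = None) -> np.ndarray:
        """Boolean mask of sampling instants after the initial transient."""
        if transient_seconds is None:
            transient_seconds = self.config.transient_seconds
        return self.times >= transient_seconds


def initial_radius(n_fish: int, l_att: float) -> float:
    """Radius of the initial disc: mean spacing ~ half the attraction range."""
    return np.sqrt(n_fish / np.pi) * l_att / 2.0


def draw_randomness(config: SimulationConfig) -> DrawSet:
    """Draw every random number the run will consume, in named streams."""
    n = config.n_fish
    n_kicks = config.n_kicks_per_fish
    root = np.random.SeedSequence(config.seed)
    ss_init, ss_kick, ss_noise = root.spawn(3)
    rng_init = np.random.default_rng(ss_init)
    radius = initial_radius(n, config.params.l_att)
    r = radius * np.sqrt(rng_init.uniform(size=n))
    theta = rng_init.uniform(0.0, 2.0 * np.pi, size=n)
    positions = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    headings = rng_init.uniform(-np.pi, np.pi, size=n)
    staggers = rng_init.uniform(0.0, config.kick_stats.mean_duration, size=n)
    kick_len = np.empty((n, n_kicks + 1))
    kick_dur = np.empty((n, n_kicks + 1))
    noise = np.empty((n, n_kicks))
    kick_children = ss_kick.spawn(n)
    noise_children = ss_noise.spawn(n)
    for i in range(n):
        rng_i = np.random.default_rng(kick_children[i])
        kick_len[i], kick_dur[i] = sample_kick(rng_i, config.kick_stats, size=n_kicks + 1)
        noise[i] = np.random.default_rng(noise_children[i]).standard_normal(n_kicks)
    return DrawSet(positions, headings, staggers, kick_len, kick_dur, noise)


def init_school(config: SimulationConfig, draws: Optional[DrawSet] = None):
    """Initial fish states and event queue.

    Positions are uniform in a disc of radius ``initial_radius``; headings
    uniform in (-pi, pi); first kick onsets staggered uniformly within one
    mean kick duration to realize asynchrony (a fish rests at its initial
    position until its first onset).

    Returns
    -------
    states : list of FishState
    queue : list of (kick_end_time, fish_id) heap entries
    """
    if draws is None:
        draws = draw_randomness(config)
    states = []
    queue: list[tuple[float, int]] = []
    for i in range(config.n_fish):
        state = FishState(
            id=i,
            position=draws.positions[i],
            heading=draws.headings[i],
            kick_start=draws.staggers[i],
            kick_duration=draws.kick_dur[i, 0],
            kick_length=draws.kick_len[i, 0],
        )
        states.append(state)
        heapq.heappush(queue, (state.kick_end, i))
    return states, queue


def _position_at(state: FishState, t: float, tau0: float) -> np.ndarray:
    """Glide interpolation clamped to the kick window (rest before first onset)."""
    s = min(max(t - state.kick_start, 0.0), state.kick_duration)
    frac = glide_fraction(s, state.kick_duration, tau0)
    return state.position + state.kick_length * frac * np.array(
        [np.cos(state.heading), np.sin(state.heading)]
    )


def step(queue, states, config: SimulationConfig, draws: DrawSet, kick_counts):
    """Process the earliest kick-end event batch (pure-Python reference path).

    All events sharing the earliest time are evaluated against the common
    pre-update state in ascending fish id order (the (time, id) heap key),
    then applied together, so that exactly simultaneous kicks do not see
    each other's updated headings.  Mutates ``states``, ``queue`` and
    ``kick_counts`` in place and returns the list of event record dicts.
    """
    if not queue:
        raise ValueError("event queue is empty")
    tau0 = config.kick_stats.relaxation_time
    n = config.n_fish
    t_ev = queue[0][0]
    batch = []
    while queue and queue[0][0] == t_ev:
        batch.append(heapq.heappop(queue)[1])
    events = []
    updates = []
    for i in batch:
        state = states[i]
        endpoint = state.position + state.kick_length * np.array(
            [np.cos(state.heading), np.sin(state.heading)]
        )
        dphi_s = 0.0
        selected = np.empty(0, dtype=int)
        rel_sel = np.empty((0, 2))
        if n > 1:
            positions = np.empty((n, 2))
            headings = np.empty(n)
            for j, other in enumerate(states):
                positions[j] = endpoint if j == i else _position_at(other, t_ev, tau0)
                headings[j] = other.heading
            selected, rel = select_influential(i, positions, headings, config.params)
            dphi_s = float(np.sum(pairwise_turn(rel, config.params)))
            # focal frame (heading -> +y) offsets of the selected neighbors
            a = 0.5 * np.pi - state.heading
            ca, sa = np.cos(a), np.sin(a)
            offsets = positions[selected] - endpoint
            rel_sel = np.column_stack(
                [ca * offsets[:, 0] - sa * offsets[:, 1],
                 sa * offsets[:, 0] + ca * offsets[:, 1]]
            )
        dphi_r = config.gamma_r * draws.noise[i, kick_counts[i]]
        updates.append((i, endpoint, dphi_s + dphi_r))
        events.append({
            "time": t_ev,
            "fish": i,
            "dphi_s": dphi_s,
            "dphi_r": dphi_r,
            "selected": selected,
            "rel": rel_sel,
        })
    for i, endpoint, dphi in updates:
        kick_counts[i] += 1
        idx = kick_counts[i]
        new_state = FishState(
            id=i,
            position=endpoint,
            heading=wrap_angle(states[i].heading + dphi),
            kick_start=t_ev,
            kick_duration=draws.kick_dur[i, idx],
            kick_length=draws.kick_len[i, idx],
        )
        states[i] = new_state
        if kick_counts[i] < config.n_kicks_per_fish:
            heapq.heappush(queue, (new_state.kick_end, i))
    return events


def _sample_times(config: SimulationConfig, draws: DrawSet) -> np.ndarray:
    """Sampling grid 0, dt, 2dt, ... limited to the span every fish covers."""
    coverage = draws.staggers + draws.kick_dur.sum(axis=1)
    t_cov = float(coverage.min())
    n_samples = int(np.floor(t_cov / config.sampling_dt + 1e-9)) + 1
    return np.arange(n_samples) * config.sampling_dt


def _run_python(config: SimulationConfig, draws: DrawSet) -> TrajectoryRecord:
    tau0 = config.kick_stats.relaxation_time
    states, queue = init_school(config, draws)
    kick_counts = np.zeros(config.n_fish, dtype=int)
    sample_times = _sample_times(config, draws)
    n = config.n_fish
    snap_pos = np.empty((len(sample_times), n, 2))
    snap_head = np.empty((len(sample_times), n))
    snap_speed = np.empty((len(sample_times), n))
    events = []
    si = 0

    def emit_until(t_limit: float) -> None:
        nonlocal si
        while si < len(sample_times) and sample_times[si] <= t_limit:
            ts = sample_times[si]
            for j, st in enumerate(states):
                snap_pos[si, j] = _position_at(st, ts, tau0)
                snap_head[si, j] = st.heading
                s = min(max(ts - st.kick_start, 0.0), st.kick_duration)
                snap_speed[si, j] = peak_speed(st.kick_length, st.kick_duration, tau0) * np.exp(-s / tau0)
            si += 1

    total = config.n_fish * config.n_kicks_per_fish
    while len(events) < total:
        emit_until(queue[0][0])
        events.extend(step(queue, states, config, draws, kick_counts))
    emit_until(np.inf)

    k = int(config.params.k)
    rec = TrajectoryRecord(config, sample_times, snap_pos, snap_head, snap_speed)
    if config.record_kicks:
        rec.kick_time = np.array([e["time"] for e in events])
        rec.kick_fish = np.array([e["fish"] for e in events], dtype=np.int64)
        rec.kick_dphi_s = np.array([e["dphi_s"] for e in events])
        rec.kick_dphi_r = np.array([e["dphi_r"] for e in events])
        rec.kick_selected = np.full((total, k), -1, dtype=np.int64)
        rec.kick_rel = np.zeros((total, k, 2))
        for m, e in enumerate(events):
            nsel = min(len(e["selected"]), k)
            rec.kick_selected[m, :nsel] = e["selected"][:nsel]
            rec.kick_rel[m, :nsel] = e["rel"][:nsel]
    return rec


def _run_fast(config: SimulationConfig, draws: DrawSet) -> TrajectoryRecord:
    n = config.n_fish
    p = config.params
    pos = draws.positions.copy()
    heading = wrap_angle(draws.headings.copy())
    t_start = draws.staggers.copy()
    cur_len = draws.kick_len[:, 0].copy()
    cur_dur = draws.kick_dur[:, 0].copy()
    sample_times = _sample_times(config, draws)
    n_samples = len(sample_times)
    snap_pos = np.empty((n_samples, n, 2))
    snap_head = np.empty((n_samples, n))
    snap_speed = np.empty((n_samples, n))
    total = n * config.n_kicks_per_fish
    k = int(p.k)
    if config.record_kicks:
        ev_time = np.empty(total)
        ev_fish = np.empty(total, dtype=np.int64)
        ev_dphi_s = np.empty(total)
        ev_dphi_r = np.empty(total)
        ev_sel = np.empty((total, k), dtype=np.int64)
        ev_rel = np.zeros((total, k, 2))
    else:
        ev_time = np.empty(0)
        ev_fish = np.empty(0, dtype=np.int64)
        ev_dphi_s = np.empty(0)
        ev_dphi_r = np.empty(0)
        ev_sel = np.empty((0, k), dtype=np.int64)
        ev_rel = np.empty((0, k, 2))
    _engine.simulate_core(
        pos, heading, t_start, cur_len, cur_dur,
        draws.kick_len, draws.kick_dur, draws.noise,
        p.gamma_att, p.gamma_ali, p.l_att, p.l_ali, p.d_att, p.d_ali,
        k, config.gamma_r, config.kick_stats.relaxation_time,
        sample_times, snap_pos, snap_head, snap_speed,
        config.record_kicks, ev_time, ev_fish, ev_dphi_s, ev_dphi_r,
        ev_sel, ev_rel,
    )
    rec = TrajectoryRecord(config, sample_times, snap_pos, snap_head, snap_speed)
    if config.record_kicks:
        rec.kick_time = ev_time
        rec.kick_fish = ev_fish
        rec.kick_dphi_s = ev_dphi_s
        rec.kick_dphi_r = ev_dphi_r
        rec.kick_selected = ev_sel
        rec.kick_rel = ev_rel
    return rec


def run(config: SimulationConfig, engine: str = "fast",
        draws: Optional[DrawSet] = None) -> TrajectoryRecord:
    """Run one simulation, fully determined by ``config`` (and its seed).

    ``draws`` may be supplied to override the seeded randomness, e.g. to
    rotate an initial condition while keeping identical kick/noise draws.
    """
    if draws is None:
        draws = draw_randomness(config)
    if engine == "fast":
        return _run_fast(config, draws)
    if engine == "python":
        return _run_python(config, draws)
    raise ValueError(f"unknown engine {engine!r}")
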