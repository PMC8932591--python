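"""Naive fixed-time-step school simulator, used as an independent oracle.

Time advances in 1 ms increments; a fish kicks when the grid time crosses
its kick-end threshold, and the kick is then resolved at the exact threshold
time (fish crossing within the same step are resolved in (time, id) order).
The implementation is deliberately simple — plain dictionaries, no event
queue — and is built directly on the public kernel/kinematics API together
with the same pre-drawn randomness the event-driven engine consumes.
"""

from __future__ import annotations

import numpy as np

from tetraschool.angles import wrap_angle
from tetraschool.kernel import pairwise_turn, select_influential
from tetraschool.kinematics import glide_fraction
from tetraschool.simulator import DrawSet, SimulationConfig


def run_fixed_step(config: SimulationConfig, draws: DrawSet, dt: float = 1e-3):
    """Simulate until every fish has performed its kicks; return kick log.

    Returns a list of (time, fish, position_after, heading_after) tuples in
    processing order.
    """
    n = config.n_fish
    tau0 = config.kick_stats.relaxation_time
    pos = draws.positions.copy().astype(float)
    heading = wrap_angle(draws.headings.copy())
    t_start = draws.staggers.copy()
    cur_len = draws.kick_len[:, 0].copy()
    cur_dur = draws.kick_dur[:, 0].copy()
    kicks_done = np.zeros(n, dtype=int)
    log = []
    t = 0.0
    n_kicks = config.n_kicks_per_fish
    while np.any(kicks_done < n_kicks):
        t += dt
        due = sorted(
            (i for i in range(n)
             if kicks_done[i] < n_kicks and t >= t_start[i] + cur_dur[i]),
            key=lambda i: (t_start[i] + cur_dur[i], i),
        )
        while due:
            # exactly simultaneous kicks are evaluated against the common
            # pre-update state, then applied together
            t_ev = t_start[due[0]] + cur_dur[due[0]]
            batch = [i for i in due if t_start[i] + cur_dur[i] == t_ev]
            due = [i for i in due if i not in batch]
            results = []
            for i in batch:
                endpoint = pos[i] + cur_len[i] * np.array(
                    [np.cos(heading[i]), np.sin(heading[i])]
                )
                dphi_s = 0.0
                if n > 1:
                    positions = np.empty((n, 2))
                    for j in range(n):
                        if j == i:
                            positions[j] = endpoint
                        else:
                            s = min(max(t_ev - t_start[j], 0.0), cur_dur[j])
                            frac = glide_fraction(s, cur_dur[j], tau0)
                            positions[j] = pos[j] + cur_len[j] * frac * np.array(
                                [np.cos(heading[j]), np.sin(heading[j])]
                            )
                    _, rel = select_influential(i, positions, heading, config.params)
                    dphi_s = float(np.sum(pairwise_turn(rel, config.params)))
                dphi_r = config.gamma_r * draws.noise[i, kicks_done[i]]
                results.append((i, endpoint, dphi_s + dphi_r))
            for i, endpoint, dphi in results:
                pos[i] = endpoint
                heading[i] = wrap_angle(heading[i] + dphi)
                t_start[i] = t_ev
                kicks_done[i] += 1
                idx = kicks_done[i]
                cur_len[i] = draws.kick_len[i, idx]
                cur_dur[i] = draws.kick_dur[i, idx]
                log.append((t_ev, i, endpoint.copy(), heading[i]))
    return log
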