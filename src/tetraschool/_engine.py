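"""Compiled event-driven core of the school simulation.

The loop processes N * n_kicks kick-end events in global time order (ties by
fish id).  All random numbers (kick lengths/durations and heading noise) are
pre-drawn by the caller, so the loop itself is deterministic and its draw
order is independent of the event schedule.  Scalar helpers mirror the pure
Python formulas in :mod:`tetraschool.kernel` and :mod:`tetraschool.kinematics`
exactly.
"""

from __future__ import annotations

import numpy as np
from numba import njit

TWO_PI = 2.0 * np.pi


@njit(cache=True)
def wrap_angle_nb(a):
    w = (a + np.pi) % TWO_PI - np.pi
    if w == -np.pi:
        w = np.pi
    return w


@njit(cache=True)
def pair_turn_nb(dx, dy, h_focal, h_nb, g_att, g_ali, l_att, l_ali, d_att, d_ali):
    """Pairwise heading-change contribution from one neighbor (scalar)."""
    d = np.sqrt(dx * dx + dy * dy)
    if d == 0.0:
        psi = 0.0
    else:
        psi = wrap_angle_nb(np.arctan2(dy, dx) - h_focal)
    phi = wrap_angle_nb(h_nb - h_focal)
    sp = np.sin(psi)
    cp = np.cos(psi)
    sf = np.sin(phi)
    cf = np.cos(phi)
    c2p = 2.0 * cp * cp - 1.0
    c2f = 2.0 * cf * cf - 1.0
    fa = g_att * (d / d_att - 1.0) / (1.0 + (d / l_att) ** 2)
    oa = 1.395 * sp * (1.0 - 0.33 * cp)
    ea = 0.9326 * (1.0 - 0.48 * cf - 0.31 * c2f)
    fl = g_ali * (d / d_ali + 1.0) * np.exp(-((d / l_ali) ** 2))
    el = 0.9012 * (1.0 + 0.6 * cp - 0.32 * c2p)
    ol = 1.6385 * sf * (1.0 + 0.3 * c2f)
    return fa * oa * ea + fl * el * ol


@njit(cache=True)
def _glide_frac_nb(s, tau, denom, tau0):
    """Covered fraction of the kick; denom caches 1 - exp(-tau/tau0)."""
    if s <= 0.0:
        return 0.0
    if s > tau:
        s = tau
    return (1.0 - np.exp(-s / tau0)) / denom


@njit(cache=True)
def _emit_snapshot(si, ts, pos, heading, t_start, cur_len, cur_dur,
                   cos_h, sin_h, denom, tau0,
                   snap_pos, snap_head, snap_speed):
    n = pos.shape[0]
    for j in range(n):
        s = ts - t_start[j]
        fr = _glide_frac_nb(s, cur_dur[j], denom[j], tau0)
        snap_pos[si, j, 0] = pos[j, 0] + cur_len[j] * fr * cos_h[j]
        snap_pos[si, j, 1] = pos[j, 1] + cur_len[j] * fr * sin_h[j]
        snap_head[si, j] = heading[j]
        vpk = cur_len[j] / (tau0 * denom[j])
        sc = s
        if sc < 0.0:
            sc = 0.0
        elif sc > cur_dur[j]:
            sc = cur_dur[j]
        snap_speed[si, j] = vpk * np.exp(-sc / tau0)


@njit(cache=True)
def simulate_core(pos, heading, t_start, cur_len, cur_dur,
                  kick_len, kick_dur, noise,
                  g_att, g_ali, l_att, l_ali, d_att, d_ali, k, gamma_r, tau0,
                  sample_times, snap_pos, snap_head, snap_speed,
                  record_kicks, ev_time, ev_fish, ev_dphi_s, ev_dphi_r,
                  ev_sel, ev_rel):
    """Run the full event loop in place.

    ``pos``/``heading``/``t_start``/``cur_len``/``cur_dur`` hold each fish's
    current-kick state and are mutated.  ``kick_len``/``kick_dur`` have shape
    (N, n_kicks + 1) (entry 0 is the initial kick), ``noise`` (N, n_kicks).
    Snapshot arrays are filled on the ``sample_times`` grid; kick-event
    arrays are filled when ``record_kicks`` is true.
    """
    n = pos.shape[0]
    n_kicks = noise.shape[1]
    kick_idx = np.zeros(n, np.int64)
    next_end = np.empty(n)
    for i in range(n):
        next_end[i] = t_start[i] + cur_dur[i]
    n_samples = sample_times.shape[0]
    si = 0
    turns = np.empty(n)
    infl = np.empty(n)
    nx = np.empty(n)
    ny = np.empty(n)
    # per-kick caches: heading direction and glide-decay denominator
    cos_h = np.empty(n)
    sin_h = np.empty(n)
    denom = np.empty(n)
    for j in range(n):
        cos_h[j] = np.cos(heading[j])
        sin_h[j] = np.sin(heading[j])
        denom[j] = 1.0 - np.exp(-cur_dur[j] / tau0)
    tied = np.empty(n, np.int64)
    batch_ex = np.empty(n)
    batch_ey = np.empty(n)
    batch_dphi = np.empty(n)
    total_events = n * n_kicks
    ev = 0
    while ev < total_events:
        # earliest pending kick end; exact ties form one batch, evaluated
        # against the common pre-update state, in ascending fish id order
        t_ev = 1.0e300
        for j in range(n):
            if kick_idx[j] < n_kicks and next_end[j] < t_ev:
                t_ev = next_end[j]
        n_tied = 0
        for j in range(n):
            if kick_idx[j] < n_kicks and next_end[j] == t_ev:
                tied[n_tied] = j
                n_tied += 1
        while si < n_samples and sample_times[si] <= t_ev:
            _emit_snapshot(si, sample_times[si], pos, heading, t_start,
                           cur_len, cur_dur, cos_h, sin_h, denom, tau0,
                           snap_pos, snap_head, snap_speed)
            si += 1
        ksel = k
        if ksel > n - 1:
            ksel = n - 1
        for b in range(n_tied):
            i = tied[b]
            # focal fish moves to the glide endpoint of its ending kick
            ex = pos[i, 0] + cur_len[i] * cos_h[i]
            ey = pos[i, 1] + cur_len[i] * sin_h[i]
            dphi_s = 0.0
            if record_kicks:
                for r in range(ev_sel.shape[1]):
                    ev_sel[ev, r] = -1
            if n > 1:
                chi = cos_h[i]
                shi = sin_h[i]
                for j in range(n):
                    if j == i:
                        infl[j] = -2.0
                        turns[j] = 0.0
                        continue
                    s = t_ev - t_start[j]
                    fr = _glide_frac_nb(s, cur_dur[j], denom[j], tau0)
                    xj = pos[j, 0] + cur_len[j] * fr * cos_h[j]
                    yj = pos[j, 1] + cur_len[j] * fr * sin_h[j]
                    nx[j] = xj
                    ny[j] = yj
                    dx = xj - ex
                    dy = yj - ey
                    # sin/cos of the viewing angle psi = bearing - heading_i
                    # and of the relative heading phi = heading_j - heading_i,
                    # from the cached per-fish heading trig (no atan2 needed)
                    d = np.sqrt(dx * dx + dy * dy)
                    if d == 0.0:
                        sp = 0.0
                        cp = 1.0
                    else:
                        sp = (dy * chi - dx * shi) / d
                        cp = (dx * chi + dy * shi) / d
                    sf = sin_h[j] * chi - cos_h[j] * shi
                    cf = cos_h[j] * chi + sin_h[j] * shi
                    c2p = 2.0 * cp * cp - 1.0
                    c2f = 2.0 * cf * cf - 1.0
                    fa = g_att * (d / d_att - 1.0) / (1.0 + (d / l_att) ** 2)
                    oa = 1.395 * sp * (1.0 - 0.33 * cp)
                    ea = 0.9326 * (1.0 - 0.48 * cf - 0.31 * c2f)
                    fl = g_ali * (d / d_ali + 1.0) * np.exp(-((d / l_ali) ** 2))
                    el = 0.9012 * (1.0 + 0.6 * cp - 0.32 * c2p)
                    ol = 1.6385 * sf * (1.0 + 0.3 * c2f)
                    t_pair = fa * oa * ea + fl * el * ol
                    turns[j] = t_pair
                    infl[j] = np.abs(t_pair)
                ca = shi  # cos(pi/2 - h) = sin h
                sa = chi  # sin(pi/2 - h) = cos h
                for r in range(ksel):
                    best = -1
                    best_infl = -1.0
                    for j in range(n):
                        if infl[j] > best_infl:
                            best_infl = infl[j]
                            best = j
                    dphi_s += turns[best]
                    infl[best] = -2.0
                    if record_kicks:
                        ev_sel[ev, r] = best
                        dx = nx[best] - ex
                        dy = ny[best] - ey
                        # focal frame: focal at origin, heading mapped to +y (north)
                        ev_rel[ev, r, 0] = ca * dx - sa * dy
                        ev_rel[ev, r, 1] = sa * dx + ca * dy
            dphi_r = gamma_r * noise[i, kick_idx[i]]
            if record_kicks:
                ev_time[ev] = t_ev
                ev_fish[ev] = i
                ev_dphi_s[ev] = dphi_s
                ev_dphi_r[ev] = dphi_r
            batch_ex[b] = ex
            batch_ey[b] = ey
            batch_dphi[b] = dphi_s + dphi_r
            ev += 1
        for b in range(n_tied):
            i = tied[b]
            heading[i] = wrap_angle_nb(heading[i] + batch_dphi[b])
            pos[i, 0] = batch_ex[b]
            pos[i, 1] = batch_ey[b]
            t_start[i] = t_ev
            kick_idx[i] += 1
            cur_len[i] = kick_len[i, kick_idx[i]]
            cur_dur[i] = kick_dur[i, kick_idx[i]]
            next_end[i] = t_ev + cur_dur[i]
            cos_h[i] = np.cos(heading[i])
            sin_h[i] = np.sin(heading[i])
            denom[i] = 1.0 - np.exp(-cur_dur[i] / tau0)
    # remaining sample instants are covered by every fish's final kick
    while si < n_samples:
        _emit_snapshot(si, sample_times[si], pos, heading, t_start,
                       cur_len, cur_dur, cos_h, sin_h, denom, tau0,
                       snap_pos, snap_head, snap_speed)
        si += 1


@njit(cache=True)
def influence_argmax_nb(positions, headings, g_att, g_ali, l_att, l_ali, d_att, d_ali):
    """Most influential neighbor (k = 1) of every fish in one snapshot."""
    n = positions.shape[0]
    out = np.empty(n, np.int64)
    for i in range(n):
        best = -1
        best_infl = -1.0
        for j in range(n):
            if j == i:
                continue
            t_pair = pair_turn_nb(positions[j, 0] - positions[i, 0],
                                  positions[j, 1] - positions[i, 1],
                                  headings[i], headings[j],
                                  g_att, g_ali, l_att, l_ali, d_att, d_ali)
            a = np.abs(t_pair)
            if a > best_infl:
                best_infl = a
                best = j
        out[i] = best
    return out


@njit(cache=True)
def nearest_argmin_nb(positions):
    """Nearest neighbor of every fish in one snapshot (ties: lower id)."""
    n = positions.shape[0]
    out = np.empty(n, np.int64)
    for i in range(n):
        best = -1
        best_d = 1.0e300
        for j in range(n):
            if j == i:
                continue
            dx = positions[j, 0] - positions[i, 0]
            dy = positions[j, 1] - positions[i, 1]
            d2 = dx * dx + dy * dy
            if d2 < best_d:
                best_d = d2
                best = j
        out[i] = best
    return out
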