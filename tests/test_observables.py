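"""Order parameters, phase classification, and school diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tetraschool import (
    InteractionParams,
    PhaseLabel,
    PhaseThresholds,
    SchoolSnapshot,
    barycenter,
    classify_phase,
    count_distinct_influential,
    count_distinct_nearest,
    dispersion,
    milling,
    nearest_neighbor_distance,
    pdf_along_cut,
    polarization,
    relative_state,
    influence,
    three_group_partition,
)
from tetraschool.fixtures import aligned_line, milling_ring, radial_ring, random_cloud

SWEEP = InteractionParams(gamma_att=0.04, gamma_ali=0.2, l_att=0.28, l_ali=0.28, k=1)


def snap(positions, headings, speeds=None, time=0.0):
    positions = np.asarray(positions, dtype=float)
    headings = np.asarray(headings, dtype=float)
    if speeds is None:
        speeds = np.full(len(headings), 0.14)
    return SchoolSnapshot(time, positions, headings, np.asarray(speeds, dtype=float))


class TestBarycenter:
    def test_two_fish_symmetric(self):
        s = snap([[1, 0], [-1, 0]], [np.pi / 2, np.pi / 2])
        pos, vel, heading = barycenter(s)
        assert np.allclose(pos, 0.0)
        assert heading == pytest.approx(np.pi / 2)

    def test_symmetric_mill_velocity_cancels(self):
        pos, vel, heading = barycenter(milling_ring(4))
        assert np.allclose(vel, 0.0, atol=1e-15)

    def test_zero_velocity_heading_degenerate(self):
        s = snap([[0, 0], [1, 0]], [0.3, 1.1], speeds=[0.0, 0.0])
        _, vel, heading = barycenter(s)
        assert np.all(vel == 0.0)
        assert heading == 0.0

    def test_matches_direct_summation(self, rng):
        s = random_cloud(20, rng)
        pos, vel, _ = barycenter(s)
        assert np.allclose(pos, s.positions.sum(axis=0) / 20, atol=1e-12)
        assert np.allclose(vel, s.velocities.sum(axis=0) / 20, atol=1e-12)


class TestDispersion:
    def test_coincident_fish(self):
        s = snap([[2, 3]] * 4, [0, 0, 0, 0])
        assert dispersion(s) == 0.0

    def test_two_fish_rms(self):
        s = snap([[1, 0], [-1, 0]], [0, 0])
        assert dispersion(s) == pytest.approx(1.0)

    def test_unit_square_corners(self):
        s = snap([[0, 0], [1, 0], [0, 1], [1, 1]], [0] * 4)
        assert dispersion(s) == pytest.approx(np.sqrt(0.5), abs=1e-12)
        assert dispersion(s, mean_square=True) == pytest.approx(0.5, abs=1e-12)


class TestPolarization:
    def test_identical_headings(self):
        assert polarization(aligned_line(7)) == pytest.approx(1.0)

    def test_north_south_cancellation(self):
        s = snap(np.random.default_rng(0).uniform(size=(6, 2)),
                 [np.pi / 2] * 3 + [-np.pi / 2] * 3)
        assert polarization(s) == pytest.approx(0.0, abs=1e-15)

    def test_fourfold_symmetry(self):
        s = snap(np.zeros((4, 2)), [0, np.pi / 2, np.pi, 3 * np.pi / 2])
        assert polarization(s) == pytest.approx(0.0, abs=1e-15)

    def test_random_headings_scale_decreasing_in_n(self, rng):
        """Uncorrelated headings: mean P decays with N (~1/sqrt(N))."""
        means = []
        for n in (10, 40, 160):
            vals = [polarization(snap(np.zeros((n, 2)),
                                      rng.uniform(-np.pi, np.pi, n)))
                    for _ in range(300)]
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]
        # consistent with the sqrt scaling: quadrupling N halves mean P
        assert means[1] / means[0] == pytest.approx(0.5, abs=0.15)
        assert means[2] / means[1] == pytest.approx(0.5, abs=0.15)


class TestMilling:
    def test_perfect_mill(self):
        assert milling(milling_ring(4)) == pytest.approx(1.0)
        assert milling(milling_ring(9, ccw=False)) == pytest.approx(1.0)

    def test_radial_motion_no_milling(self):
        assert milling(radial_ring(4)) == pytest.approx(0.0, abs=1e-15)

    def test_opposite_rotators_cancel(self):
        ccw = milling_ring(4)
        headings = ccw.headings.copy()
        headings[2:] += np.pi  # two fish reversed
        s = snap(ccw.positions, headings, ccw.speeds)
        assert milling(s) == pytest.approx(0.0, abs=1e-12)

    def test_fish_at_barycenter_excluded(self):
        """A motionless fish at the barycenter has an undefined term and is
        dropped; the index then equals the direct formula over the others."""
        base = milling_ring(4)
        positions = np.vstack([base.positions, [0.0, 0.0]])
        headings = np.append(base.headings, 0.3)
        speeds = np.append(base.speeds, 0.0)
        s = snap(positions, headings, speeds)
        # brute force over the four ring fish, barycenter frame included
        vels = s.velocities
        v_b = vels.mean(axis=0)
        u = positions - positions.mean(axis=0)
        terms = []
        for i in range(4):
            vbar = vels[i] - v_b
            terms.append(np.sin(np.arctan2(vbar[1], vbar[0]) - np.arctan2(u[i, 1], u[i, 0])))
        assert milling(s) == pytest.approx(abs(np.mean(terms)), abs=1e-12)


class TestClassifyPhase:
    @pytest.mark.parametrize(
        "p,m,d,expected",
        [
            (0.9, 0.22, 0.5, PhaseLabel.SCHOOLING),
            (0.16, 0.6, 0.3, PhaseLabel.MILLING),
            (0.2, 0.2, 10.0, PhaseLabel.DISPERSION),  # D test precedes P/M
            (0.2, 0.2, 0.2, PhaseLabel.SWARMING),
            (0.7, 0.6, 0.2, PhaseLabel.INTERMITTENT),
            (0.4, 0.4, 0.2, PhaseLabel.SCHOOLING),  # boundary: first rule wins
        ],
    )
    def test_labels(self, p, m, d, expected):
        assert classify_phase(p, m, d) is expected

    def test_group_size_threshold(self):
        assert classify_phase(0.2, 0.2, 6.0, PhaseThresholds(d_max=7.0)) is PhaseLabel.SWARMING


class TestNearestNeighbor:
    def test_pair(self):
        per, mean = nearest_neighbor_distance(snap([[0, 0], [0.3, 0]], [0, 0]))
        assert np.allclose(per, 0.3)
        assert mean == pytest.approx(0.3)

    def test_equilateral_triangle(self):
        s = 0.4
        pts = [[0, 0], [s, 0], [s / 2, s * np.sqrt(3) / 2]]
        per, mean = nearest_neighbor_distance(snap(pts, [0, 0, 0]))
        assert np.allclose(per, s)

    def test_matches_exhaustive_pairs(self, rng):
        s = random_cloud(20, rng)
        per, mean = nearest_neighbor_distance(s)
        for i in range(20):
            dists = [np.linalg.norm(s.positions[i] - s.positions[j])
                     for j in range(20) if j != i]
            assert per[i] == pytest.approx(min(dists), abs=1e-12)


class TestDistinctNeighborCounts:
    def test_all_choose_same_fish(self):
        # fish 0 far on the left; 1..3 clustered: fish 1-3 pick within the
        # cluster, fish 0 picks into the cluster -> small distinct count
        s = snap([[0, 0], [1, 0], [1.01, 0], [1.02, 0]], [0, 0, 0, 0])
        assert count_distinct_nearest(s) <= 3

    def test_pair_is_mutual(self):
        s = snap([[0, 0], [0.3, 0]], [0, 0.1])
        assert count_distinct_nearest(s) == 2
        assert count_distinct_influential(s, SWEEP) == 2

    def test_collinear_triple(self):
        s = snap([[0, 0], [1, 0], [3, 0]], [0, 0, 0])
        # nearest map {0->1, 1->0, 2->1} -> 2 distinct
        assert count_distinct_nearest(s) == 2

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=20)
    def test_dmin_matches_exhaustive_argmax(self, seed):
        rng = np.random.default_rng(seed)
        n = 15
        pos = rng.uniform(-1, 1, (n, 2))
        head = rng.uniform(-np.pi, np.pi, n)
        s = SchoolSnapshot(0.0, pos, head, np.full(n, 0.14))
        choices = set()
        for i in range(n):
            best, best_infl = -1, -1.0
            for j in range(n):
                if j == i:
                    continue
                val = influence(relative_state(pos[i], head[i], pos[j], head[j]), SWEEP)
                if val > best_infl:
                    best, best_infl = j, val
            choices.add(best)
        assert count_distinct_influential(s, SWEEP) == len(choices)

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=20)
    def test_counts_within_bounds(self, seed):
        rng = np.random.default_rng(seed)
        s = random_cloud(12, rng)
        assert 1 <= count_distinct_influential(s, SWEEP) <= 12
        assert 1 <= count_distinct_nearest(s) <= 12


class TestThreeGroupPartition:
    def test_four_fish_single_group(self, rng):
        s = random_cloud(4, rng)
        groups = three_group_partition(s)
        assert len(groups) == 1
        assert groups[0] == {0, 1, 2, 3}

    def test_two_distant_clusters(self, rng):
        a = rng.uniform(0, 0.1, (4, 2))
        b = rng.uniform(0, 0.1, (4, 2)) + 10.0
        s = snap(np.vstack([a, b]), np.zeros(8))
        groups = three_group_partition(s)
        assert len(groups) == 2
        assert {frozenset(g) for g in groups} == {frozenset(range(4)), frozenset(range(4, 8))}

    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(4, 40))
    @settings(deadline=None, max_examples=30)
    def test_partition_covers_with_groups_of_four_or_more(self, seed, n):
        rng = np.random.default_rng(seed)
        s = random_cloud(n, rng)
        groups = three_group_partition(s)
        all_ids = sorted(i for g in groups for i in g)
        assert all_ids == list(range(n))  # disjoint cover
        assert all(len(g) >= 4 for g in groups)
        assert 1 <= len(groups) <= int(np.ceil(n / 4))


class TestPdfAlongCut:
    def test_constant_series(self):
        density, edges, mean = pdf_along_cut(np.full(100, 0.37))
        assert mean == pytest.approx(0.37)
        assert np.sum(density > 0) == 1
        assert np.sum(density * np.diff(edges)) == pytest.approx(1.0)

    def test_bimodal_mixture_detected(self, rng):
        samples = np.concatenate([
            rng.normal(0.2, 0.02, 5000), rng.normal(0.95, 0.02, 5000)
        ]).clip(0, 1)
        density, edges, _ = pdf_along_cut(samples, bins=50)
        centers = 0.5 * (edges[:-1] + edges[1:])
        low_peak = density[(centers > 0.1) & (centers < 0.3)].max()
        high_peak = density[centers > 0.85].max()
        trough = density[(centers > 0.4) & (centers < 0.8)].max()
        assert low_peak > 5 * trough and high_peak > 5 * trough

    def test_uniform_samples_flat(self, rng):
        density, _, _ = pdf_along_cut(rng.uniform(size=200_000), bins=50)
        assert np.allclose(density, 1.0, atol=0.05)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pdf_along_cut(np.empty(0))


class TestRigidMotionInvariance:
    @given(seed=st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=20)
    def test_order_parameters_invariant(self, seed):
        rng = np.random.default_rng(seed)
        s = random_cloud(15, rng)
        angle = rng.uniform(-np.pi, np.pi)
        shift = rng.uniform(-10, 10, 2)
        rot = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
        s2 = SchoolSnapshot(0.0, s.positions @ rot.T + shift,
                            s.headings + angle, s.speeds)
        assert dispersion(s2) == pytest.approx(dispersion(s), abs=1e-10)
        assert polarization(s2) == pytest.approx(polarization(s), abs=1e-10)
        assert milling(s2) == pytest.approx(milling(s), abs=1e-10)
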