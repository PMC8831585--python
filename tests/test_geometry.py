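"""Spline interpolation, curvature and pairwise-distance statistics."""

import numpy as np
import pytest

from mifish.decoding import Allocation, ProbeAssignment
from mifish.detection import Dot
from mifish.geometry import (curvature_peaks, curvature_profile,
                             interpolate_structure,
                             pairwise_distance_matrix)
from mifish.scheme import ColorScheme, Probe


def synthetic_scheme(n):
    """n single-color probes in genomic order (dye identity irrelevant)."""
    dyes = ["a488", "tmr", "a594", "cy5", "a700", "ir800"]
    return ColorScheme([
        Probe(f"p{i:03d}", "chrX", 1_000_000 * i, 1_000_000 * i + 1000,
              frozenset({dyes[i % 6]}))
        for i in range(n)
    ])


def allocation_from_points(points_um, scheme):
    alloc = Allocation(0)
    for probe, p in zip(scheme.probes, points_um):
        if p is None:
            alloc.assignments[probe.probe_id] = ProbeAssignment(probe.probe_id)
            continue
        d = Dot(x=p[0] * 1000 / 130.0, y=p[1] * 1000 / 130.0,
                z=p[2] * 1000 / 200.0, channel=next(iter(probe.dyes)))
        alloc.assignments[probe.probe_id] = ProbeAssignment(
            probe.probe_id, [d], float("nan"), "assigned")
    return alloc


def structure_from_points(points_um):
    scheme = synthetic_scheme(len(points_um))
    return interpolate_structure(allocation_from_points(points_um, scheme),
                                 scheme)


class TestInterpolation:
    def test_spline_passes_through_inputs(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 10, (8, 3))
        s = structure_from_points(pts)
        recon = s.spline(s.t_knots)
        assert np.allclose(recon, pts, atol=1e-9)

    def test_segment_count(self):
        pts = np.column_stack([np.arange(16.0), np.zeros(16), np.zeros(16)])
        pts += np.random.default_rng(1).normal(0, 0.1, pts.shape)
        s = structure_from_points(pts)
        assert s.n_segments == 15

    def test_missing_probes_skipped(self):
        pts = [np.array([i, 0.0, 0.0]) for i in range(6)]
        pts[2] = None
        scheme = synthetic_scheme(6)
        s = interpolate_structure(allocation_from_points(pts, scheme), scheme)
        assert len(s.probe_ids) == 5
        assert "p002" not in s.probe_ids

    def test_fewer_than_three_points_rejected(self):
        scheme = synthetic_scheme(2)
        alloc = allocation_from_points(
            [np.zeros(3), np.ones(3)], scheme)
        with pytest.raises(ValueError):
            interpolate_structure(alloc, scheme)


class TestCurvature:
    def test_straight_line_zero_curvature(self):
        pts = np.column_stack([np.linspace(0, 10, 12),
                               np.linspace(0, 5, 12),
                               np.linspace(0, 2, 12)])
        s = structure_from_points(pts)
        _, k = curvature_profile(s)
        assert np.all(k < 1e-9)

    def test_circle_curvature_is_inverse_radius(self):
        r = 2.0
        theta = np.linspace(0, 2 * np.pi, 400)
        pts = np.column_stack([r * np.cos(theta), r * np.sin(theta),
                               np.zeros_like(theta)])
        s = structure_from_points(pts)
        t, k = curvature_profile(s)
        # natural end conditions distort the first/last segments
        interior = (t > s.t_knots[10]) & (t < s.t_knots[-11])
        assert np.allclose(k[interior], 1.0 / r, atol=1e-3)

    def test_helix_closed_form(self):
        r, c = 1.0, 0.3
        th = np.linspace(0, 4 * np.pi, 500)
        pts = np.column_stack([r * np.cos(th), r * np.sin(th), c * th])
        s = structure_from_points(pts)
        t, k = curvature_profile(s)
        interior = (t > s.t_knots[10]) & (t < s.t_knots[-11])
        assert np.allclose(k[interior], r / (r**2 + c**2), atol=1e-3)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(0, 5, (10, 3))
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = pts @ q.T + np.array([3.0, -2.0, 7.0])
        _, k1 = curvature_profile(structure_from_points(pts))
        _, k2 = curvature_profile(structure_from_points(moved))
        assert np.allclose(k1, k2, rtol=1e-6, atol=1e-9)


class TestPeaks:
    def test_global_maximum_reported_as_one(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 5, (10, 3))
        profile = curvature_profile(structure_from_points(pts))
        peaks = curvature_peaks(profile)
        assert peaks
        assert max(v for _, v in peaks) == pytest.approx(1.0)
        assert all(0.1 < v <= 1.0 for _, v in peaks)

    def test_small_secondary_peak_excluded(self):
        t = np.linspace(0, 1, 101)
        k = np.exp(-0.5 * ((t - 0.3) / 0.05) ** 2)
        k += 0.05 * np.exp(-0.5 * ((t - 0.8) / 0.05) ** 2)
        peaks = curvature_peaks((t, k))
        assert len(peaks) == 1
        assert peaks[0][0] == pytest.approx(0.3, abs=0.02)

    def test_constant_profile_has_no_strict_peaks(self):
        t = np.linspace(0, 1, 50)
        assert curvature_peaks((t, np.full(50, 0.7))) == []

    def test_zero_profile_empty(self):
        t = np.linspace(0, 1, 50)
        assert curvature_peaks((t, np.zeros(50))) == []

    def test_peak_count_scale_invariant(self):
        rng = np.random.default_rng(6)
        pts = rng.uniform(0, 5, (12, 3))
        p1 = curvature_peaks(curvature_profile(structure_from_points(pts)))
        p2 = curvature_peaks(curvature_profile(structure_from_points(3.0 * pts)))
        assert len(p1) == len(p2)


class TestPairwiseDistances:
    def test_symmetric_samples_and_missing_pairs(self):
        scheme = synthetic_scheme(4)
        pts = [np.array([float(i), 0.0, 0.0]) for i in range(4)]
        full = allocation_from_points(pts, scheme)
        partial_pts = list(pts)
        partial_pts[1] = None
        partial = allocation_from_points(partial_pts, scheme)
        table = pairwise_distance_matrix([full, partial], scheme)
        by_pair = {(r.probe_i, r.probe_j): r for r in table.itertuples()}
        assert by_pair[("p000", "p003")].n_samples == 2
        assert by_pair[("p000", "p001")].n_samples == 1  # p001 missing once
        assert by_pair[("p000", "p002")].median_um == pytest.approx(2.0)

    def test_chain_scaling_monotone(self, scheme):
        # pure (unconfined) chain model: log median distance grows
        # monotonically with log genomic distance across all 120 pairs
        from mifish.simulate import simulate_structures
        from scipy.stats import spearmanr

        scenes = simulate_structures(
            scheme, 150, seed=41, g2_fraction=0.0, step_scale_nm=150.0,
            territory_radius_nm=np.inf)
        allocs = []
        for scene in scenes:
            for allele in (0, 1):
                pts = [scene_dot.pos_nm / 1000.0
                       for scene_dot in scene.dots
                       if scene_dot.allele == allele]
                allocs.append(allocation_from_points(pts, scheme))
        table = pairwise_distance_matrix(allocs, scheme, min_samples=5)
        rho = spearmanr(np.log(table["genomic_distance_bp"]),
                        np.log(table["median_um"])).statistic
        assert rho > 0.9

    def test_empty_input_rejected(self, scheme):
        with pytest.raises(ValueError):
            pairwise_distance_matrix([], scheme)
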