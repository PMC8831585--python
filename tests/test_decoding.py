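"""Homolog clustering and combinatorial barcode decoding."""

import numpy as np
import pytest

from mifish.detection import Dot
from mifish.decoding import (AlleleCluster, cluster_homologs,
                             colocalization_threshold, decode_cluster,
                             decoding_accuracy, random_allocation_null,
                             select_candidates)
from mifish.simulate import simulate_structures


def _dot(x_um, y_um, z_um, channel, intensity=1000.0, dot_id=0):
    return Dot(x=x_um * 1000 / 130.0, y=y_um * 1000 / 130.0,
               z=z_um * 1000 / 200.0, channel=channel,
               intensity=intensity, dot_id=dot_id)


def ideal_cluster_from_scene(scene, scheme, allele, jitter_nm=25.0, seed=0):
    """Cluster of dots at the true positions of one allele (+ jitter)."""
    rng = np.random.default_rng(seed)
    dots = []
    for t in scene.dots:
        if t.allele != allele:
            continue
        for dye, photons in t.photons.items():
            p = t.pos_nm + rng.normal(0, jitter_nm, 3)
            dots.append(Dot(x=p[0] / 130.0, y=p[1] / 130.0, z=p[2] / 200.0,
                            channel=dye, intensity=photons * rng.normal(1, 0.03),
                            dot_id=len(dots)))
    centroid = np.mean([d.pos_nm for d in dots], axis=0) / 1000.0
    return AlleleCluster(0, 0, dots, centroid)


class TestThresholds:
    def test_same_cube_quarter_micron(self):
        assert colocalization_threshold("tmr", "cy5") == 0.25

    def test_different_cube_055(self):
        assert colocalization_threshold("a488", "a594") == 0.55

    def test_same_dye_rejected(self):
        with pytest.raises(ValueError):
            colocalization_threshold("cy5", "cy5")

    def test_unknown_dye_rejected(self):
        with pytest.raises(KeyError):
            colocalization_threshold("cy5", "gfp")


class TestClusterHomologs:
    def _two_clouds(self, sep_um=10.0, n=12, seed=0):
        rng = np.random.default_rng(seed)
        dots = []
        for k, cx in enumerate((5.0, 5.0 + sep_um)):
            for _ in range(n):
                dots.append(_dot(cx + rng.normal(0, 0.8),
                                 5 + rng.normal(0, 0.8),
                                 3 + rng.normal(0, 0.4), "cy5",
                                 dot_id=len(dots)))
        return dots

    def test_well_separated_clouds_partitioned_exactly(self):
        dots = self._two_clouds()
        clusters = cluster_homologs(dots, seed=1)
        sizes = sorted(len(c.dots) for c in clusters)
        assert sizes == [12, 12]
        for c in clusters:
            xs = [d.x_nm / 1000 for d in c.dots]
            assert np.ptp(xs) < 5.0

    def test_far_outlier_dropped(self):
        # an isolated dot ~8 um from its cloud joins the nearest k-means
        # cluster but fails the 40-px (5.2-um) radius filter
        dots = self._two_clouds()
        dots.append(_dot(5.0, 13.0, 3.0, "cy5", dot_id=99))
        clusters = cluster_homologs(dots, radius_px=40.0, seed=1)
        dropped = [d for c in clusters for d in c.outliers]
        assert any(d.dot_id == 99 for d in dropped)
        assert sum(len(c.dots) for c in clusters) == 24

    def test_deterministic_under_seed(self):
        dots = self._two_clouds(seed=5)
        a = cluster_homologs(dots, seed=3)
        b = cluster_homologs(dots, seed=3)
        assert [[d.dot_id for d in c.dots] for c in a] == \
            [[d.dot_id for d in c.dots] for c in b]

    def test_close_centroids_flagged_merged(self):
        # one tight blob split in two: sub-micron centroid separation
        rng = np.random.default_rng(2)
        dots = [_dot(5 + rng.normal(0, 0.15), 5 + rng.normal(0, 0.15),
                     3 + rng.normal(0, 0.1), "cy5", dot_id=i)
                for i in range(20)]
        clusters = cluster_homologs(dots, seed=1)
        assert all(c.merged_flag for c in clusters)

    def test_too_few_dots_rejected(self):
        with pytest.raises(ValueError):
            cluster_homologs([_dot(1, 1, 1, "cy5")])


class TestSelectCandidates:
    def test_top_ten_by_intensity(self, scheme):
        dots = [_dot(1 + 0.1 * i, 1, 1, "a488", intensity=100.0 + i,
                     dot_id=i) for i in range(12)]
        cluster = AlleleCluster(0, 0, dots, np.zeros(3))
        cands = select_candidates(cluster, scheme)
        assert len(cands["a488"]) == 10
        assert min(d.intensity for d in cands["a488"]) == 102.0

    def test_ir800_keeps_two(self, scheme):
        dots = [_dot(1, 1, 1 + 0.3 * i, "ir800", intensity=50.0 + i,
                     dot_id=i) for i in range(3)]
        cluster = AlleleCluster(0, 0, dots, np.zeros(3))
        assert len(select_candidates(cluster, scheme)["ir800"]) == 2

    def test_empty_channel_empty_list(self, scheme):
        cluster = AlleleCluster(0, 0, [], np.zeros(3))
        cands = select_candidates(cluster, scheme)
        assert all(v == [] for v in cands.values())


class TestDecodeCluster:
    def test_ideal_cluster_fully_decoded(self, scheme):
        scene = simulate_structures(scheme, 1, seed=8, g2_fraction=0.0)[0]
        cluster = ideal_cluster_from_scene(scene, scheme, allele=0)
        alloc = decode_cluster(cluster, scheme)
        assert alloc.n_assigned == 16
        assert decoding_accuracy(alloc, scene, scheme) == 1.0

    def test_pair_beyond_threshold_left_missing(self, scheme):
        # the a488+a594 probe rendered as two dots 0.6 um apart exceeds
        # the 0.55-um different-cube cut-off
        probe_id = scheme.dual_pairs[frozenset({"a488", "a594"})]
        dots = [
            _dot(5.0, 5.0, 3.0, "a488", 1000, 0),
            _dot(5.6, 5.0, 3.0, "a594", 1000, 1),
        ]
        cluster = AlleleCluster(0, 0, dots, np.array([5.3, 5.0, 3.0]))
        alloc = decode_cluster(cluster, scheme)
        assert alloc.assignments[probe_id].status == "missing"

    def test_pair_inside_threshold_assigned(self, scheme):
        probe_id = scheme.dual_pairs[frozenset({"a488", "a594"})]
        dots = [
            _dot(5.0, 5.0, 3.0, "a488", 1000, 0),
            _dot(5.4, 5.0, 3.0, "a594", 1000, 1),
        ]
        cluster = AlleleCluster(0, 0, dots, np.array([5.2, 5.0, 3.0]))
        alloc = decode_cluster(cluster, scheme)
        a = alloc.assignments[probe_id]
        assert a.status == "assigned"
        assert a.coloc_distance_um == pytest.approx(0.4, abs=0.01)

    def test_split_dot_suppressed_not_reassigned(self, scheme):
        # a split cy5+tmr probe shows two tmr dots 0.3 um apart; once
        # the probe is assigned using the brighter one, the dim copy is
        # suppressed and cannot seed another dual probe
        pid_cy5_tmr = scheme.dual_pairs[frozenset({"cy5", "tmr"})]
        pid_488_tmr = scheme.dual_pairs[frozenset({"a488", "tmr"})]
        dots = [
            _dot(5.0, 5.0, 3.0, "cy5", 2000, 0),    # true cy5
            _dot(5.02, 5.0, 3.0, "tmr", 2000, 1),   # its tmr partner
            _dot(5.0, 5.3, 3.0, "tmr", 1500, 2),    # dim split copy
            _dot(5.05, 5.35, 3.0, "a488", 1500, 3),  # bystander a488
        ]
        cluster = AlleleCluster(0, 0, dots, np.array([5.0, 5.1, 3.0]))
        alloc = decode_cluster(cluster, scheme)
        assert alloc.assignments[pid_cy5_tmr].status == "assigned"
        assert {d.dot_id for d in alloc.assignments[pid_cy5_tmr].dots} == {0, 1}
        # the split copy must not complete the a488+tmr probe
        assert alloc.assignments[pid_488_tmr].status == "missing"
        assert alloc.split_suppressed >= 1
        alloc.validate()

    def test_no_dot_serves_two_probes(self, scheme):
        scenes = simulate_structures(scheme, 5, seed=13, g2_fraction=0.0)
        for scene in scenes:
            for allele in (0, 1):
                cluster = ideal_cluster_from_scene(scene, scheme, allele,
                                                   jitter_nm=60.0, seed=allele)
                alloc = decode_cluster(cluster, scheme)
                alloc.validate()  # raises on reuse

    def test_threshold_relaxation_monotone(self, scheme):
        # widening the same-cube threshold to 0.55 um can only add pairs
        scenes = simulate_structures(scheme, 4, seed=17, g2_fraction=0.0)
        for scene in scenes:
            cluster = ideal_cluster_from_scene(scene, scheme, 0,
                                               jitter_nm=80.0, seed=3)
            strict = decode_cluster(cluster, scheme)
            relaxed = decode_cluster(cluster, scheme, coloc_override_um=0.55)
            n_dual_strict = sum(1 for a in strict.assigned if len(a.dots) == 2)
            n_dual_relaxed = sum(1 for a in relaxed.assigned if len(a.dots) == 2)
            assert n_dual_relaxed >= n_dual_strict

    def test_outlier_dot_dropped(self, scheme):
        scene = simulate_structures(scheme, 1, seed=21, g2_fraction=0.0)[0]
        cluster = ideal_cluster_from_scene(scene, scheme, 0)
        # displace the ir800 single far from everything
        for d in cluster.dots:
            if d.channel == "ir800":
                d.x += 8000.0 / 130.0
                d.y += 8000.0 / 130.0
        alloc = decode_cluster(cluster, scheme)
        ir = [p for p in scheme.single_probes if "ir800" in p.dyes][0]
        assert alloc.assignments[ir.probe_id].status in ("outlier", "missing")


class TestRandomNull:
    def test_reproducible_under_seed(self, scheme):
        scene = simulate_structures(scheme, 1, seed=23, g2_fraction=0.0)[0]
        cluster = ideal_cluster_from_scene(scene, scheme, 0)
        a = random_allocation_null(cluster, scheme, n_random=5,
                                   n_reiterate=3, seed=9)
        b = random_allocation_null(cluster, scheme, n_random=5,
                                   n_reiterate=3, seed=9)
        for x, y in zip(a, b):
            assert {p: v.status for p, v in x.assignments.items()} == \
                {p: v.status for p, v in y.assignments.items()}

    def test_no_valid_pairs_leaves_duals_missing(self, scheme):
        # dots of each channel isolated: nothing co-localizes
        dots = [_dot(2.0 * i, 2.0 * i, 2.0, ch, 100, i)
                for i, ch in enumerate(
                    ["a488", "tmr", "a594", "cy5", "a700", "ir800"])]
        cluster = AlleleCluster(0, 0, dots, np.zeros(3))
        alloc = random_allocation_null(cluster, scheme, n_random=3,
                                       n_reiterate=2, seed=1)[0]
        for pid in scheme.dual_pairs.values():
            assert alloc.assignments[pid].status == "missing"

    def test_null_accuracy_below_decoder(self, scheme):
        scenes = simulate_structures(scheme, 10, seed=29, g2_fraction=0.0)
        dec, nul = [], []
        for scene in scenes:
            cluster = ideal_cluster_from_scene(scene, scheme, 0, seed=5)
            dec.append(decoding_accuracy(
                decode_cluster(cluster, scheme), scene, scheme))
            null = random_allocation_null(cluster, scheme, n_random=10,
                                          n_reiterate=5, seed=7)[0]
            nul.append(decoding_accuracy(null, scene, scheme))
        assert np.mean(dec) > np.mean(nul)


class TestAccuracyScoring:
    def test_perfect_and_empty(self, scheme):
        scene = simulate_structures(scheme, 1, seed=31, g2_fraction=0.0)[0]
        cluster = ideal_cluster_from_scene(scene, scheme, 0)
        alloc = decode_cluster(cluster, scheme)
        assert decoding_accuracy(alloc, scene, scheme) == 1.0
        for a in alloc.assignments.values():
            a.status = "missing"
        assert decoding_accuracy(alloc, scene, scheme) == 0.0

    def test_one_wrong_is_fifteen_sixteenths(self, scheme):
        scene = simulate_structures(scheme, 1, seed=37, g2_fraction=0.0)[0]
        cluster = ideal_cluster_from_scene(scene, scheme, 0)
        alloc = decode_cluster(cluster, scheme)
        victim = alloc.assignments[scheme.probes[0].probe_id]
        for d in victim.dots:
            d.x += 5000.0 / 130.0  # move far from truth
        assert decoding_accuracy(alloc, scene, scheme) == pytest.approx(15 / 16)
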