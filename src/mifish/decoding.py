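"""Combinatorial barcode decoding: dots -> probe identities.

A diploid nucleus carries two copies of the probed chromosome, so the
FISH dots first get partitioned into two homolog clusters (k-means,
k = 2, with a radius outlier filter).  Within a cluster, dual-color
probes are decoded by co-localization: a pair of dots in two channels
closer than the channel pair's threshold (0.25 um when the two dyes
share a dichroic cube, 0.55 um otherwise) is a candidate for the dual
probe encoded by that dye pair.  Probes with a unique candidate pair are
assigned first; contested probes take the shortest pair.  Dots of the
same color closer than 0.50 um to an assigned dot are suppressed as
split signals, assigned dots farther than 5 um from every other
assigned dot are dropped as outliers, and single-color probes receive
the brightest remaining dot of their channel (single-color probes carry
twice the oligos, hence brighter dots).

A randomized allocation variant serves as the negative control: it keeps
the co-localization constraint but draws dots at random and ranks the
resulting allocations by a fixed priority list of quality criteria.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .detection import Dot
from .psf import AXIAL_NM, LATERAL_NM
from .scheme import ColorScheme, DYES
from .simulate import SceneTruth

__all__ = [
    "AlleleCluster",
    "ProbeAssignment",
    "Allocation",
    "colocalization_threshold",
    "cluster_homologs",
    "select_candidates",
    "decode_cluster",
    "random_allocation_null",
    "decoding_accuracy",
    "SAME_CUBE_UM",
    "DIFFERENT_CUBE_UM",
    "SPLIT_RADIUS_UM",
    "OUTLIER_RADIUS_UM",
]

SAME_CUBE_UM = 0.25
DIFFERENT_CUBE_UM = 0.55
SPLIT_RADIUS_UM = 0.50
OUTLIER_RADIUS_UM = 5.0
CLUSTER_RADIUS_PX = 40.0

#: top-K candidate dots per channel per cluster; ir800 labels only one
#: probe, so only the two brightest dots are considered there
CANDIDATES_PER_CHANNEL = 10
CANDIDATES_IR800 = 2

_Z_TO_LAT = AXIAL_NM / LATERAL_NM


def colocalization_threshold(dye_a: str, dye_b: str) -> float:
    """Co-localization cut-off (um) for a dye pair.

    0.25 um when both dyes are imaged through the same dichroic cube,
    0.55 um when a cube change (mechanical movement) separates them.
    """
    if dye_a == dye_b:
        raise ValueError("co-localization needs two distinct dyes")
    try:
        ga, gb = DYES[dye_a].dichroic_group, DYES[dye_b].dichroic_group
    except KeyError as e:
        raise KeyError(f"unknown dye {e.args[0]!r}") from None
    return SAME_CUBE_UM if ga == gb else DIFFERENT_CUBE_UM


def _pos_um(dot: Dot) -> np.ndarray:
    return dot.pos_nm / 1000.0


def _dist_um(a: Dot, b: Dot) -> float:
    return float(np.linalg.norm(_pos_um(a) - _pos_um(b)))


@dataclass
class AlleleCluster:
    """Dots attributed to one chromosome homolog."""

    cluster_id: int
    nucleus_id: int
    dots: list[Dot]
    centroid_um: np.ndarray
    merged_flag: bool = False  # centroids suspiciously close
    outliers: list[Dot] = field(default_factory=list)


@dataclass
class ProbeAssignment:
    """Decoded dots for one probe in one cluster."""

    probe_id: str
    dots: list[Dot] = field(default_factory=list)
    coloc_distance_um: float = float("nan")  # dual probes only
    status: str = "missing"  # assigned | missing | outlier


@dataclass
class Allocation:
    """Full probe->dot assignment for one homolog cluster."""

    cluster_id: int
    assignments: dict[str, ProbeAssignment] = field(default_factory=dict)
    split_suppressed: int = 0

    @property
    def assigned(self) -> list[ProbeAssignment]:
        return [a for a in self.assignments.values() if a.status == "assigned"]

    @property
    def n_assigned(self) -> int:
        return len(self.assigned)

    def probe_position_um(self, probe_id: str) -> np.ndarray | None:
        """Probe 3D position: midpoint of the dot pair for dual probes,
        the dot itself for single-color probes."""
        a = self.assignments.get(probe_id)
        if a is None or a.status != "assigned":
            return None
        return np.mean([_pos_um(d) for d in a.dots], axis=0)

    def validate(self) -> None:
        """Invariant: no dot serves two probes."""
        seen: set[int] = set()
        for a in self.assigned:
            for d in a.dots:
                key = id(d)
                if key in seen:
                    raise AssertionError(
                        f"dot reused across probes (probe {a.probe_id})"
                    )
                seen.add(key)


# ---------------------------------------------------------------------------
# homolog clustering


def cluster_homologs(
    dots: list[Dot],
    radius_px: float = CLUSTER_RADIUS_PX,
    seed: int | None = None,
    nucleus_id: int = -1,
) -> list[AlleleCluster]:
    """Partition one nucleus's dots into two homolog clusters.

    k-means with k = 2 on coordinates in lateral-pixel units (z scaled
    by the voxel anisotropy 200/130), best of 10 restarts under the
    seed.  Dots farther than ``radius_px`` from their centroid are
    dropped as outliers.  Clusters whose centroids are closer than 1 um
    are flagged as possibly merged homologs.
    """
    if len(dots) < 2:
        raise ValueError("need at least 2 dots to split homologs")
    coords = np.array([[d.x, d.y, d.z * _Z_TO_LAT] for d in dots])
    km = KMeans(n_clusters=2, n_init=10, random_state=seed)
    labels = km.fit_predict(coords)

    sep_um = float(
        np.linalg.norm((km.cluster_centers_[0] - km.cluster_centers_[1]))
        * LATERAL_NM / 1000.0
    )
    merged = sep_um < 1.0

    clusters = []
    for k in range(2):
        members, outliers = [], []
        for dot, lab, xyz in zip(dots, labels, coords):
            if lab != k:
                continue
            if np.linalg.norm(xyz - km.cluster_centers_[k]) > radius_px:
                outliers.append(dot)
            else:
                dot.cluster_id = k
                members.append(dot)
        centroid_um = (
            np.mean([_pos_um(d) for d in members], axis=0)
            if members else np.full(3, np.nan)
        )
        clusters.append(
            AlleleCluster(k, nucleus_id, members, centroid_um, merged, outliers)
        )
    return clusters


def select_candidates(
    cluster: AlleleCluster,
    scheme: ColorScheme,
    k_default: int = CANDIDATES_PER_CHANNEL,
    k_ir800: int = CANDIDATES_IR800,
) -> dict[str, list[Dot]]:
    """Top-K brightest dots per channel (K = 10; 2 for ir800).

    Channels not used by the scheme are omitted; channels with fewer
    dots keep what they have.
    """
    out: dict[str, list[Dot]] = {}
    for channel in scheme.channels:
        k = k_ir800 if channel == "ir800" else k_default
        chan_dots = [d for d in cluster.dots if d.channel == channel]
        chan_dots.sort(key=lambda d: -d.intensity)
        out[channel] = chan_dots[:k]
    return out


# ---------------------------------------------------------------------------
# deterministic decoding


def _candidate_pairs(
    candidates: dict[str, list[Dot]],
    scheme: ColorScheme,
    coloc_override: float | None = None,
) -> dict[str, list[tuple[float, Dot, Dot]]]:
    """Valid (distance, dot_a, dot_b) pairs per dual probe, sorted by
    distance.  Only dye pairs present in the scheme's code are
    enumerated."""
    pairs: dict[str, list[tuple[float, Dot, Dot]]] = {}
    for dyes, probe_id in scheme.dual_pairs.items():
        da, db = sorted(dyes)
        thr = (coloc_override if coloc_override is not None
               else colocalization_threshold(da, db))
        plist = []
        for a in candidates.get(da, []):
            for b in candidates.get(db, []):
                dist = _dist_um(a, b)
                if dist < thr:
                    plist.append((dist, a, b))
        plist.sort(key=lambda t: (t[0], -(t[1].intensity + t[2].intensity),
                                  t[1].dot_id, t[2].dot_id))
        pairs[probe_id] = plist
    return pairs


def decode_cluster(
    cluster: AlleleCluster,
    scheme: ColorScheme,
    split_radius_um: float = SPLIT_RADIUS_UM,
    outlier_radius_um: float = OUTLIER_RADIUS_UM,
    allow_multi_assignment: bool = False,
    coloc_override_um: float | None = None,
    candidates: dict[str, list[Dot]] | None = None,
) -> Allocation:
    """Assign the cluster's dots to the scheme's probes.

    Dual-color probes are decoded from co-localized inter-channel dot
    pairs: probes whose current candidate list holds exactly one pair
    are assigned first (their dots cannot belong to any other probe);
    contested probes take the shortest pair, ties broken by intensity
    sum then stable dot id.  Assigning a dot suppresses same-channel
    dots within ``split_radius_um`` (split FISH signals).  Single-color
    probes then receive the brightest unused dot of their channel, and
    assigned dots farther than ``outlier_radius_um`` from every other
    assigned dot are discarded as outliers.

    ``allow_multi_assignment=True`` reproduces the relaxed variant in
    which a dot may serve several dual-color probes;
    ``coloc_override_um`` replaces both co-localization thresholds
    (e.g. 0.55 um for the relaxed same-cube analysis).
    """
    if candidates is None:
        candidates = select_candidates(cluster, scheme)
    alloc = Allocation(cluster.cluster_id)
    for p in scheme.probes:
        alloc.assignments[p.probe_id] = ProbeAssignment(p.probe_id)

    used: set[int] = set()        # dot ids (by identity) already assigned
    suppressed: set[int] = set()  # split-signal dots

    def usable(dot: Dot) -> bool:
        return id(dot) not in used and id(dot) not in suppressed

    def mark_used(dot: Dot) -> None:
        # same-color dots near an assigned dot are treated as split
        # fragments of that signal and cleared from the remaining dual
        # candidate lists; a genuine fragment carries only part of the
        # probe's oligos, so only dots dimmer than the assigned one
        # qualify
        used.add(id(dot))
        for other in candidates.get(dot.channel, []):
            if (id(other) not in used
                    and other.intensity <= dot.intensity
                    and _dist_um(dot, other) < split_radius_um):
                if id(other) not in suppressed:
                    suppressed.add(id(other))
                    alloc.split_suppressed += 1

    all_pairs = _candidate_pairs(candidates, scheme, coloc_override_um)

    if allow_multi_assignment:
        for probe_id, plist in all_pairs.items():
            if plist:
                dist, a, b = plist[0]
                alloc.assignments[probe_id] = ProbeAssignment(
                    probe_id, [a, b], dist, "assigned")
                used.add(id(a))
                used.add(id(b))
    else:
        # probes encountered exactly once in the initial pair list are
        # unambiguous and are assigned first; all remaining (contested)
        # probes then take the globally shortest surviving pair
        static_unique = {p for p, v in all_pairs.items() if len(v) == 1}
        unassigned = set(all_pairs)
        while unassigned:
            live: dict[str, list[tuple[float, Dot, Dot]]] = {}
            for probe_id in unassigned:
                plist = [t for t in all_pairs[probe_id]
                         if usable(t[1]) and usable(t[2])]
                if plist:
                    live[probe_id] = plist
            if not live:
                break
            pool = {p: v for p, v in live.items() if p in static_unique}
            if not pool:
                pool = live
            probe_id = min(
                pool,
                key=lambda p: (pool[p][0][0],
                               -(pool[p][0][1].intensity
                                 + pool[p][0][2].intensity), p),
            )
            dist, a, b = pool[probe_id][0]
            alloc.assignments[probe_id] = ProbeAssignment(
                probe_id, [a, b], dist, "assigned")
            mark_used(a)
            mark_used(b)
            unassigned.discard(probe_id)

    # single-color probes: brightest dot of the channel not yet selected
    # (split suppression only clears dual-probe candidate lists)
    for probe in scheme.single_probes:
        channel = next(iter(probe.dyes))
        avail = [d for d in candidates.get(channel, []) if id(d) not in used]
        if not avail:
            continue
        best = max(avail, key=lambda d: (d.intensity, -d.dot_id))
        alloc.assignments[probe.probe_id] = ProbeAssignment(
            probe.probe_id, [best], float("nan"), "assigned")
        mark_used(best)

    _drop_spatial_outliers(alloc, outlier_radius_um)
    for a in alloc.assigned:
        for d in a.dots:
            d.probe_id = a.probe_id
    if not allow_multi_assignment:
        alloc.validate()
    return alloc


def _drop_spatial_outliers(alloc: Allocation, radius_um: float) -> None:
    """Drop assignments whose dot lies > radius from all other assigned
    dots (isolated signals far from the cluster body)."""
    assigned = alloc.assigned
    all_dots = [d for a in assigned for d in a.dots]
    if len(all_dots) < 2:
        return
    pos = np.array([_pos_um(d) for d in all_dots])
    owner = [a for a in assigned for _ in a.dots]
    dmat = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    np.fill_diagonal(dmat, np.inf)
    for i, a in enumerate(owner):
        if a.status == "assigned" and dmat[i].min() > radius_um:
            a.status = "outlier"


# ---------------------------------------------------------------------------
# randomized allocation null


def _allocation_score(alloc: Allocation, scheme: ColorScheme) -> tuple:
    """Rank key for a randomized allocation, by the null procedure's
    priority list: total dot intensity, dots doubly allocated, pairs
    within 0.55 um, failed allocations, same-channel dots closer than
    0.25 um — lexicographically, higher-priority criteria first."""
    assigned = alloc.assigned
    total_intensity = sum(d.intensity for a in assigned for d in a.dots)
    counts: dict[int, int] = {}
    for a in assigned:
        for d in a.dots:
            counts[id(d)] = counts.get(id(d), 0) + 1
    n_double = sum(1 for v in counts.values() if v > 1)
    n_coloc_ok = sum(
        1 for a in assigned
        if len(a.dots) == 2 and a.coloc_distance_um < DIFFERENT_CUBE_UM
    )
    n_failed = len(scheme) - len(assigned)
    dots = [d for a in assigned for d in a.dots]
    n_close_same = sum(
        1 for d1, d2 in itertools.combinations(dots, 2)
        if d1.channel == d2.channel and id(d1) != id(d2)
        and _dist_um(d1, d2) < SAME_CUBE_UM
    )
    return (total_intensity, -n_double, n_coloc_ok, -n_failed, -n_close_same)


def random_allocation_null(
    cluster: AlleleCluster,
    scheme: ColorScheme,
    n_random: int = 100,
    n_reiterate: int = 20,
    seed: int | None = None,
) -> list[Allocation]:
    """Randomized dot allocation used as a negative control.

    For each dual-color probe the first dot is drawn at random from the
    channel's candidates and re-drawn (up to ``n_random`` times) until a
    partner within 0.55 um exists; a random such partner completes the
    pair.  Single-color probes draw a random remaining dot.  The whole
    assignment is reiterated ``n_reiterate`` times and the resulting
    allocations are ranked (best first) by the priority criteria of
    :func:`_allocation_score`.  Deterministic under the seed.
    """
    rng = np.random.default_rng(seed)
    candidates = select_candidates(cluster, scheme)
    allocations: list[Allocation] = []
    for _ in range(max(n_reiterate, 1)):
        alloc = Allocation(cluster.cluster_id)
        for p in scheme.probes:
            alloc.assignments[p.probe_id] = ProbeAssignment(p.probe_id)
        used: set[int] = set()
        dual_ids = list(scheme.dual_pairs.values())
        rng.shuffle(dual_ids)
        for probe_id in dual_ids:
            probe = scheme.probe(probe_id)
            da, db = sorted(probe.dyes)
            ca = candidates.get(da, [])
            cb = candidates.get(db, [])
            if not ca or not cb:
                continue
            for _ in range(max(n_random, 1)):
                a = ca[rng.integers(len(ca))]
                partners = [b for b in cb
                            if _dist_um(a, b) < DIFFERENT_CUBE_UM]
                if partners:
                    b = partners[rng.integers(len(partners))]
                    dist = _dist_um(a, b)
                    alloc.assignments[probe_id] = ProbeAssignment(
                        probe_id, [a, b], dist, "assigned")
                    used.add(id(a))
                    used.add(id(b))
                    break
        for probe in scheme.single_probes:
            channel = next(iter(probe.dyes))
            avail = [d for d in candidates.get(channel, [])
                     if id(d) not in used]
            if not avail:
                continue
            pick = avail[rng.integers(len(avail))]
            alloc.assignments[probe.probe_id] = ProbeAssignment(
                probe.probe_id, [pick], float("nan"), "assigned")
            used.add(id(pick))
        allocations.append(alloc)
    allocations.sort(key=lambda a: _allocation_score(a, scheme), reverse=True)
    return allocations


# ---------------------------------------------------------------------------
# synthetic-truth scoring


def decoding_accuracy(
    alloc: Allocation,
    truth: SceneTruth,
    scheme: ColorScheme,
    tol_nm: float = 500.0,
) -> float:
    """Fraction of the scheme's probes correctly decoded in a cluster.

    A probe counts correct when every one of its assigned dots lies
    within ``tol_nm`` of a true emitter of that probe (either allele —
    homolog territories are far apart compared to ``tol_nm``); missing
    or outlier probes count incorrect.  The default tolerance of 500 nm
    is half the typical nearest distance between same-channel loci
    (same-dye probes sit >= 9 Mb apart, ~1 um or more in space), so it
    separates "right dot, imperfectly localized" from "wrong dot".
    """
    truth_by_probe: dict[str, list[np.ndarray]] = {}
    for t in truth.dots:
        truth_by_probe.setdefault(t.probe_id, []).append(t.pos_nm)
    missing_in_truth = [p.probe_id for p in scheme.probes
                       if p.probe_id not in truth_by_probe]
    if missing_in_truth:
        raise ValueError(f"scheme probes absent from truth: {missing_in_truth}")

    n_correct = 0
    for probe in scheme.probes:
        a = alloc.assignments.get(probe.probe_id)
        if a is None or a.status != "assigned":
            continue
        ok = all(
            min(np.linalg.norm(d.pos_nm - t) for t in truth_by_probe[probe.probe_id])
            <= tol_nm
            for d in a.dots
        )
        n_correct += ok
    return n_correct / len(scheme)
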