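"""Chromosome-trace geometry: splines, curvature, distance scaling.

Decoded probe positions of one homolog, ordered along the genome, are
interpolated with a natural cubic spline (chord-length parameterization)
to visualize the folding path.  The curvature of the space curve
r(t) = (x(t), y(t), z(t)),

    k = |r' x r''| / |r'|^3,

is evaluated analytically from the piecewise polynomials, normalized per
structure by its maximum, and summarized by its strict local maxima
("curvature peaks") above a threshold.  Pairwise 3D distances between
probes, aggregated as per-pair medians over many cells, quantify how
physical separation grows with genomic separation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .decoding import Allocation
from .scheme import ColorScheme

__all__ = [
    "AlleleStructure",
    "interpolate_structure",
    "curvature_profile",
    "curvature_peaks",
    "pairwise_distance_matrix",
]

SAMPLES_PER_SEGMENT = 50


@dataclass
class AlleleStructure:
    """Cubic-spline trace through one homolog's decoded probe positions."""

    cluster_id: int
    probe_ids: list[str]          # present probes, genomic order
    points_um: np.ndarray         # (n, 3) positions of present probes
    spline: CubicSpline
    t_knots: np.ndarray           # chord-length parameter at each probe
    t_samples: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_segments(self) -> int:
        return len(self.probe_ids) - 1


def interpolate_structure(
    alloc: Allocation,
    scheme: ColorScheme,
    samples_per_segment: int = SAMPLES_PER_SEGMENT,
) -> AlleleStructure:
    """Natural cubic spline through the present probes in genomic order.

    Missing probes are skipped; fewer than three present probes cannot
    support a cubic spline and raise ``ValueError``.  The parameter is
    cumulative chord length, and the curve is sampled on a uniform grid
    of ``samples_per_segment`` points per inter-probe segment.
    """
    probe_ids, pts = [], []
    for probe in scheme.probes:
        pos = alloc.probe_position_um(probe.probe_id)
        if pos is not None:
            probe_ids.append(probe.probe_id)
            pts.append(pos)
    if len(pts) < 3:
        raise ValueError(
            f"cubic spline needs >= 3 present probes, got {len(pts)}"
        )
    points = np.asarray(pts)
    chord = np.linalg.norm(np.diff(points, axis=0), axis=1)
    if np.any(chord == 0):
        # coincident consecutive probes: nudge parameter to stay monotone
        chord = np.maximum(chord, 1e-9)
    t = np.concatenate([[0.0], np.cumsum(chord)])
    spline = CubicSpline(t, points, axis=0, bc_type="natural")
    n_seg = len(points) - 1
    t_samples = np.concatenate([
        np.linspace(t[i], t[i + 1], samples_per_segment, endpoint=False)
        for i in range(n_seg)
    ] + [t[-1:]])
    return AlleleStructure(alloc.cluster_id, probe_ids, points, spline, t,
                           t_samples)


def curvature_profile(
    structure: AlleleStructure,
) -> tuple[np.ndarray, np.ndarray]:
    """Curvature k(t) = |r' x r''| / |r'|^3 at the structure's samples.

    Derivatives come analytically from the piecewise cubic polynomials.
    Samples where the speed |r'| vanishes are skipped (returned t and k
    arrays exclude them).  k is non-negative by construction.
    """
    t = structure.t_samples
    d1 = structure.spline.derivative(1)(t)
    d2 = structure.spline.derivative(2)(t)
    speed_sq = np.sum(d1**2, axis=1)
    ok = speed_sq > 1e-20
    cross = np.cross(d1[ok], d2[ok])
    k = np.linalg.norm(cross, axis=1) / speed_sq[ok] ** 1.5
    return t[ok], k


def curvature_peaks(
    profile: tuple[np.ndarray, np.ndarray],
    peak_threshold: float = 0.1,
) -> list[tuple[float, float]]:
    """Strict local maxima of the per-structure normalized curvature.

    The profile is divided by its maximum (normalized range (0, 1]) and
    peaks are interior samples strictly greater than both neighbors with
    normalized value > ``peak_threshold``.  A constant (plateau) profile
    has no strict maxima and yields an empty list; an all-zero profile
    likewise.
    """
    t, k = profile
    if len(k) == 0:
        return []
    kmax = float(k.max())
    if kmax <= 0:
        return []
    kn = k / kmax
    peaks = []
    for i in range(len(kn)):
        left_ok = i == 0 or kn[i] > kn[i - 1]
        right_ok = i == len(kn) - 1 or kn[i] > kn[i + 1]
        if left_ok and right_ok and kn[i] > peak_threshold:
            peaks.append((float(t[i]), float(kn[i])))
    return peaks


def pairwise_distance_matrix(
    allocations: list[Allocation],
    scheme: ColorScheme,
    min_samples: int = 1,
) -> pd.DataFrame:
    """Per probe pair: 3D distance samples over clusters, plus medians.

    For every cluster and every unordered pair of probes present in its
    allocation, the Euclidean distance between the probe positions
    (dual-color probe = midpoint of its dot pair) contributes one
    sample.  Returns a DataFrame with columns probe_i, probe_j,
    genomic_distance_bp, n_samples, median_um and the raw samples.
    """
    if not allocations:
        raise ValueError("need at least one allocation")
    ids = [p.probe_id for p in scheme.probes]
    mids = {p.probe_id: p.midpoint for p in scheme.probes}
    samples: dict[tuple[str, str], list[float]] = {
        (a, b): [] for i, a in enumerate(ids) for b in ids[i + 1:]
    }
    for alloc in allocations:
        pos = {pid: alloc.probe_position_um(pid) for pid in ids}
        for (a, b), bucket in samples.items():
            pa, pb = pos[a], pos[b]
            if pa is not None and pb is not None:
                bucket.append(float(np.linalg.norm(pa - pb)))
    rows = []
    for (a, b), vals in samples.items():
        if len(vals) < min_samples:
            continue
        rows.append({
            "probe_i": a, "probe_j": b,
            "genomic_distance_bp": abs(mids[b] - mids[a]),
            "n_samples": len(vals),
            "median_um": float(np.median(vals)) if vals else np.nan,
            "samples_um": vals,
        })
    return pd.DataFrame(rows)
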