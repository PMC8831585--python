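"""Concordance of FISH-derived distances with Hi-C and compartments.

Hi-C measures population-averaged contact frequencies between genomic
bins; imaging measures physical distances in single cells.  The two are
compared here exactly as in chromatin-tracing validation studies:
per-probe-pair median 3D distance should anti-correlate with Hi-C
contact frequency, while a FISH "contact frequency" (fraction of cells
with the pair closer than 1 um) should correlate positively.  A/B
compartments come from the sign of the Hi-C eigenvector track
(|value| <= 0.01 is left unassigned as uncertain), and lamina distances
of A-compartment probes are expected to exceed those of B-compartment
probes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .scheme import ColorScheme

__all__ = [
    "ContactMatrix",
    "EigenvectorTrack",
    "ab_compartments",
    "probe_pair_contact_freq",
    "fish_contact_frequency",
    "correlate_fish_hic",
    "lamina_by_compartment",
]


@dataclass
class ContactMatrix:
    """Binned symmetric contact-frequency matrix for one chromosome."""

    chrom: str
    bin_size: int
    matrix: np.ndarray
    start_bp: int = 0  # genomic coordinate of bin 0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, float)
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("contact matrix must be square")
        if not np.allclose(m, m.T, equal_nan=True):
            raise ValueError("contact matrix must be symmetric")
        if np.nanmin(m) < 0:
            raise ValueError("contact frequencies must be non-negative")
        self.matrix = m

    def bin_of(self, pos_bp: float) -> int:
        b = int((pos_bp - self.start_bp) // self.bin_size)
        if not 0 <= b < self.matrix.shape[0]:
            raise IndexError(f"position {pos_bp} outside matrix range")
        return b

    @classmethod
    def from_pairs_file(cls, path: str | Path, chrom: str,
                        bin_size: int) -> "ContactMatrix":
        """Read a sparse 3-column text format: bin_start_i, bin_start_j,
        frequency (TSV, '#' comments; symmetric completion applied)."""
        df = pd.read_csv(path, sep=r"\s+", comment="#", header=None,
                         names=["chrom", "start_i", "start_j", "freq"])
        df = df[df["chrom"] == chrom]
        if df.empty:
            raise ValueError(f"no rows for {chrom} in {path}")
        start = int(min(df["start_i"].min(), df["start_j"].min()))
        stop = int(max(df["start_i"].max(), df["start_j"].max()))
        n = (stop - start) // bin_size + 1
        mat = np.zeros((n, n))
        i = ((df["start_i"] - start) // bin_size).astype(int)
        j = ((df["start_j"] - start) // bin_size).astype(int)
        mat[i, j] = df["freq"]
        mat[j, i] = df["freq"]
        return cls(chrom, bin_size, mat, start)


@dataclass
class EigenvectorTrack:
    """Per-bin leading-eigenvector values with a declared sign convention."""

    chrom: str
    bin_size: int
    values: np.ndarray
    start_bp: int = 0
    sign_convention: str | None = "A-positive"  # which sign denotes A

    def value_at(self, pos_bp: float) -> float:
        b = int((pos_bp - self.start_bp) // self.bin_size)
        if not 0 <= b < len(self.values):
            raise IndexError(f"position {pos_bp} outside track range")
        return float(self.values[b])

    @classmethod
    def from_bedgraph(cls, path: str | Path, chrom: str,
                      sign_convention: str = "A-positive") -> "EigenvectorTrack":
        """Read a bedGraph-like TSV (chrom, start, end, value)."""
        df = pd.read_csv(path, sep=r"\s+", comment="#", header=None,
                         names=["chrom", "start", "end", "value"])
        df = df[df["chrom"] == chrom].sort_values("start")
        if df.empty:
            raise ValueError(f"no rows for {chrom} in {path}")
        bin_size = int((df["end"] - df["start"]).iloc[0])
        start = int(df["start"].min())
        n = (int(df["start"].max()) - start) // bin_size + 1
        vals = np.full(n, np.nan)
        vals[((df["start"] - start) // bin_size).astype(int)] = df["value"]
        return cls(chrom, bin_size, vals, start, sign_convention)


def ab_compartments(
    track: EigenvectorTrack, min_abs: float = 0.01
) -> np.ndarray:
    """Per-bin compartment labels 'A' / 'B' / 'unassigned'.

    Bins with |eigenvector| <= ``min_abs`` (or NaN) are uncertain and
    left unassigned; otherwise the sign decides per the track's declared
    convention.
    """
    if track.sign_convention is None:
        raise ValueError("eigenvector track lacks a sign convention")
    a_positive = track.sign_convention == "A-positive"
    labels = np.full(len(track.values), "unassigned", dtype=object)
    v = track.values
    with np.errstate(invalid="ignore"):
        pos = v > min_abs
        neg = v < -min_abs
    labels[pos] = "A" if a_positive else "B"
    labels[neg] = "B" if a_positive else "A"
    return labels


def probe_pair_contact_freq(
    matrix: ContactMatrix, scheme: ColorScheme
) -> pd.DataFrame:
    """Hi-C contact frequency for every unordered probe pair.

    Probe positions are their genomic midpoints mapped to matrix bins;
    returns columns probe_i, probe_j, hic_freq (120 rows for the chr2
    default scheme).
    """
    rows = []
    probes = [p for p in scheme.probes if p.chrom == matrix.chrom]
    if len(probes) < 2:
        raise ValueError("need >= 2 probes on the matrix chromosome")
    for i, a in enumerate(probes):
        for b in probes[i + 1:]:
            rows.append({
                "probe_i": a.probe_id,
                "probe_j": b.probe_id,
                "hic_freq": float(
                    matrix.matrix[matrix.bin_of(a.midpoint),
                                  matrix.bin_of(b.midpoint)]
                ),
            })
    return pd.DataFrame(rows)


def fish_contact_frequency(
    distance_samples: dict[tuple[str, str], list[float]] | pd.DataFrame,
    threshold_um: float = 1.0,
) -> pd.DataFrame:
    """Fraction of clusters with a probe pair in 'contact' (<= threshold).

    Accepts either a {(probe_i, probe_j): [distances um]} mapping or the
    DataFrame of :func:`mifish.geometry.pairwise_distance_matrix` (its
    ``samples_um`` column).  The threshold is inclusive: a pair exactly
    at 1.0 um counts as a contact.  Pairs with no samples are omitted.
    """
    if isinstance(distance_samples, pd.DataFrame):
        items = [
            ((r["probe_i"], r["probe_j"]), r["samples_um"])
            for _, r in distance_samples.iterrows()
        ]
    else:
        items = list(distance_samples.items())
    rows = []
    for (a, b), vals in items:
        vals = np.asarray(vals, float)
        if vals.size == 0:
            continue
        rows.append({
            "probe_i": a, "probe_j": b,
            "n_samples": int(vals.size),
            "contact_freq": float(np.mean(vals <= threshold_um)),
        })
    return pd.DataFrame(rows)


def correlate_fish_hic(x, y) -> tuple[float, float, int]:
    """(Pearson r, Spearman rho, n) between paired per-pair statistics.

    Pairs with non-finite values on either side are dropped; constant
    input leaves the correlation undefined and raises ``ValueError``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need >= 3 finite pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    r = float(stats.pearsonr(x, y).statistic)
    rho = float(stats.spearmanr(x, y).statistic)
    return r, rho, int(len(x))


def lamina_by_compartment(
    probe_norm_distances: dict[str, list[float]],
    probe_compartment: dict[str, str],
) -> tuple[pd.DataFrame, float | None]:
    """Per-probe median lamina distance and the A-minus-B contrast.

    ``probe_norm_distances`` maps probe_id -> normalized lamina
    distances of its dots over the dataset; ``probe_compartment`` maps
    probe_id -> 'A' / 'B' / 'unassigned'.  Returns the per-probe table
    and median(A probes) - median(B probes), or None when either
    compartment is absent.
    """
    rows = []
    for pid, vals in probe_norm_distances.items():
        vals = np.asarray(vals, float)
        vals = vals[np.isfinite(vals)]
        rows.append({
            "probe_id": pid,
            "compartment": probe_compartment.get(pid, "unassigned"),
            "n": int(vals.size),
            "median_norm_distance": float(np.median(vals)) if vals.size else np.nan,
        })
    table = pd.DataFrame(rows)
    a = table.loc[table["compartment"] == "A", "median_norm_distance"].dropna()
    b = table.loc[table["compartment"] == "B", "median_norm_distance"].dropna()
    summary = float(a.median() - b.median()) if len(a) and len(b) else None
    return table, summary
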