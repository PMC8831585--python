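"""Combinatorial color-coding design for miFISH probes.

A miFISH experiment resolves many loci in a single hybridization round by
spectral barcoding: each probe is labelled either with one dye
(single-color probe, all oligos carry the same fluorophore) or with two
dyes in alternating order along the oligo tiling (dual-color probe,
detected as two co-localized dots in two channels).  The default design
targets 16 loci on the q-arm of human chromosome 2 with 6 spectrally
separable dyes: the 10 dual-color probes use all C(5,2) = 10 unordered
pairs of the five shorter-wavelength dyes, and each of the 6 dyes
additionally labels exactly one single-color probe.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "Dye",
    "Probe",
    "ColorScheme",
    "DYES",
    "DYE_NAMES",
    "dichroic_group",
    "build_chr2_scheme",
    "read_probe_file",
    "expected_channel_counts",
    "probe_pair_table",
]


@dataclass(frozen=True)
class Dye:
    """A fluorescent dye / imaging channel.

    ``dichroic_group`` partitions channels by the dichroic-mirror cube
    used to image them; co-localization thresholds depend on whether two
    dyes share a cube (see :mod:`mifish.decoding`).
    """

    name: str
    emission_nm: float
    dichroic_group: int


#: The six miFISH dyes, keyed by the channel-naming dialect used in the
#: deposited datasets (cy5 denotes AT647N, tmr denotes AT542, etc.).
DYES: dict[str, Dye] = {
    "a488": Dye("a488", 525.0, 3),   # AF488, own cube
    "tmr": Dye("tmr", 562.0, 1),     # AT542, multi-band cube 1
    "a594": Dye("a594", 617.0, 2),   # AF594, cube 2
    "cy5": Dye("cy5", 664.0, 1),     # AT647N, cube 1 (reference channel)
    "a700": Dye("a700", 723.0, 2),   # AF700, cube 2
    "ir800": Dye("ir800", 814.0, 1),  # AF790, cube 1
}

DYE_NAMES: tuple[str, ...] = tuple(DYES)

#: Dyes eligible for dual-color combinations (AF790 is excluded: its long
#: emission wavelength gives too dim/broad dots for reliable pairing).
DUAL_DYES: tuple[str, ...] = ("a488", "tmr", "a594", "cy5", "a700")

_DICHROIC_OF_DAPI = 1


def dichroic_group(channel: str) -> int:
    """Dichroic-cube group of a channel ('dapi' shares cube 1)."""
    if channel == "dapi":
        return _DICHROIC_OF_DAPI
    try:
        return DYES[channel].dichroic_group
    except KeyError:
        raise KeyError(f"unknown channel {channel!r}") from None


@dataclass(frozen=True)
class Probe:
    """One miFISH probe: a genomic interval plus its dye set.

    Intervals are 0-based half-open (BED convention); the probe's point
    position is the interval midpoint.  Dual-color probes split their
    oligos between two dyes (350 each by default), single-color probes
    put all 700 on one dye, which doubles their per-channel brightness.
    """

    probe_id: str
    chrom: str
    start: int
    end: int
    dyes: frozenset[str]
    oligos_per_dye: int = 350

    def __post_init__(self) -> None:
        if not 1 <= len(self.dyes) <= 2:
            raise ValueError(
                f"probe {self.probe_id}: needs 1 or 2 dyes, got {len(self.dyes)}"
            )
        if self.end <= self.start:
            raise ValueError(f"probe {self.probe_id}: end must exceed start")
        unknown = self.dyes - set(DYES)
        if unknown:
            raise ValueError(f"probe {self.probe_id}: unknown dye(s) {sorted(unknown)}")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    @property
    def is_dual(self) -> bool:
        return len(self.dyes) == 2


@dataclass
class ColorScheme:
    """An ordered (genomic order) probe set with its dual-color code map.

    ``dual_pairs`` maps each unordered dye pair to at most one probe, so
    an observed co-localized dot pair decodes to a unique probe identity.
    """

    probes: list[Probe]
    dual_pairs: dict[frozenset[str], str] = field(init=False)

    def __post_init__(self) -> None:
        self.probes = sorted(self.probes, key=lambda p: (p.chrom, p.midpoint))
        pairs: dict[frozenset[str], str] = {}
        for p in self.probes:
            if p.is_dual:
                if p.dyes in pairs:
                    raise ValueError(
                        f"dye pair {sorted(p.dyes)} used by both "
                        f"{pairs[p.dyes]} and {p.probe_id}"
                    )
                pairs[p.dyes] = p.probe_id
        self.dual_pairs = pairs

    def __len__(self) -> int:
        return len(self.probes)

    def __iter__(self):
        return iter(self.probes)

    @property
    def dual_probes(self) -> list[Probe]:
        return [p for p in self.probes if p.is_dual]

    @property
    def single_probes(self) -> list[Probe]:
        return [p for p in self.probes if not p.is_dual]

    def probe(self, probe_id: str) -> Probe:
        for p in self.probes:
            if p.probe_id == probe_id:
                return p
        raise KeyError(f"no probe {probe_id!r}")

    def probes_with_dye(self, dye: str) -> list[Probe]:
        return [p for p in self.probes if dye in p.dyes]

    @property
    def channels(self) -> list[str]:
        """Dye channels actually used by this scheme."""
        return [d for d in DYE_NAMES if self.probes_with_dye(d)]


# Default chr2 q-arm layout: 11 probes every 3 Mb from 55 Mb, then 5 more
# probes stepping 20 Mb.  The dye assignment interleaves the 6
# single-color probes and the 10 dual-color pairs so that consecutive
# probes never share a dye and probes sharing a dye are >= 9 Mb apart —
# the layout property a combinatorial design needs so that the
# same-color split-dot filter cannot collide with a genuine neighbor.
# Exact deposited coordinates can be supplied via a probe file instead.
_CHR2_SPAN_BP = 66_000
_DEFAULT_DYE_LAYOUT: tuple[frozenset[str], ...] = tuple(
    frozenset(s) for s in (
        {"a488", "cy5"}, {"a700", "tmr"}, {"a594"}, {"cy5"}, {"a488"},
        {"tmr"}, {"a700"}, {"a594", "cy5"}, {"ir800"}, {"a488", "tmr"},
        {"a594", "a700"}, {"cy5", "tmr"}, {"a488", "a700"},
        {"a594", "tmr"}, {"a700", "cy5"}, {"a488", "a594"},
    )
)


def _default_chr2_midpoints_bp() -> list[int]:
    mids = [55_000_000 + 3_000_000 * i for i in range(11)]  # 55..85 Mb
    for _ in range(5):
        mids.append(mids[-1] + 20_000_000)  # 105, 125, 145, 165, 185 Mb
    return mids


def build_chr2_scheme(coords_file: str | Path | None = None) -> ColorScheme:
    """Build the 16-probe chr2 coding scheme (or read one from a file).

    Without a file, returns the nominal layout: consecutive probes spaced
    3 Mb (ten gaps) then 20 Mb (five gaps), each spanning 66 kb, with the
    10 dual-color dye pairs and 6 single-color probes assigned
    deterministically.
    """
    if coords_file is not None:
        return read_probe_file(coords_file)

    probes = []
    for i, mid in enumerate(_default_chr2_midpoints_bp()):
        dyes = _DEFAULT_DYE_LAYOUT[i]
        oligos = 700 if len(dyes) == 1 else 350
        probes.append(
            Probe(
                probe_id=f"chr2_{i + 1:02d}",
                chrom="chr2",
                start=mid - _CHR2_SPAN_BP // 2,
                end=mid + _CHR2_SPAN_BP // 2,
                dyes=dyes,
                oligos_per_dye=oligos,
            )
        )
    return ColorScheme(probes)


def read_probe_file(path: str | Path) -> ColorScheme:
    """Read a BED-like probe definition file.

    Tab- or whitespace-separated columns: chrom, start, end, probe_id,
    dye1[, dye2].  A header line and '#' comments are ignored.
    """
    probes = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if (not probes and fields[0].lower() in {"chrom", "chr", "#chrom"}
                    and not fields[1].lstrip("-").isdigit()):
                continue  # header line (may follow comments)
            if len(fields) not in (5, 6):
                raise ValueError(
                    f"{path}:{lineno}: expected 5 or 6 columns, got {len(fields)}"
                )
            chrom, start, end, probe_id = fields[0], fields[1], fields[2], fields[3]
            dyes = frozenset(fields[4:])
            try:
                probes.append(
                    Probe(probe_id, chrom, int(start), int(end), dyes)
                )
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: {e}") from None
    if not probes:
        raise ValueError(f"{path}: no probes found")
    return ColorScheme(probes)


def expected_channel_counts(scheme: ColorScheme, n_alleles: int) -> dict[str, int]:
    """Expected dot count per dye channel for ``n_alleles`` chromosome copies.

    Every probe containing a dye contributes one dot per allele in that
    dye's channel, so for the chr2 default at 2 alleles this is 10 dots in
    each of the five dual-combination channels and 2 in ir800.
    """
    if n_alleles < 1:
        raise ValueError("n_alleles must be >= 1")
    return {
        dye: n_alleles * len(scheme.probes_with_dye(dye)) for dye in DYE_NAMES
    }


def probe_pair_table(scheme: ColorScheme) -> pd.DataFrame:
    """All unordered probe pairs with their genomic separation.

    Returns a DataFrame with columns ``probe_i``, ``probe_j`` (i before j
    in genomic order) and ``genomic_distance_bp`` (midpoint distance);
    C(16,2) = 120 rows for the chr2 default.
    """
    if len(scheme) < 2:
        raise ValueError("need at least 2 probes")
    rows = [
        (a.probe_id, b.probe_id, abs(b.midpoint - a.midpoint))
        for a, b in itertools.combinations(scheme.probes, 2)
    ]
    return pd.DataFrame(rows, columns=["probe_i", "probe_j", "genomic_distance_bp"])
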