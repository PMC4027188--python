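"""Plasmid substrates, transposon-end variants and cleavage-site geometry.

The experimental substrate is a supercoiled plasmid carrying a
mini-transposon bounded by two 30-bp inverted-repeat ends, each flanked by
the TA target-site duplication.  Transposase cleaves each end on two
strands: the non-transferred strand (NTS) is nicked a few nucleotides
*inside* the element, while the transferred strand (TS) is cut exactly at
the junction between element and flanking DNA, exposing the 3'-OH that is
later joined to the target.

Coordinates
-----------
The plasmid is circular.  Bases are numbered 1..L; "boundary" b denotes the
phosphodiester position between base b and base b+1 (boundary 0 sits
between base L and base 1).  The element occupies bases 1..element_length,
so boundary 0 is the left junction and boundary ``element_length`` the
right junction.  The forward ("fwd") strand runs 5'->3' with increasing
coordinate; the reverse ("rev") strand runs 5'->3' with decreasing
coordinate.

End-variant positions follow the convention used for mariner ends: negative
integers index flanking DNA, positive integers index the element, and there
is no position 0.  A point mutation is named after the base it places on
the NTS, e.g. ``-1T`` or ``+1C``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple

__all__ = [
    "EndVariant",
    "Substrate",
    "CleavageSiteMap",
    "Cut",
    "WT_END",
    "POINT_MUTATION_POSITIONS",
    "FIVE_G_SPAN",
    "WT_NTS_BASE",
    "point_mutant_end",
    "five_g_end",
    "build_mutant_catalog",
    "cleavage_positions",
    "etf_strand_lengths",
    "write_catalog_tsv",
    "read_end_fasta",
]

#: positions probed by the symmetric point-mutant panel
POINT_MUTATION_POSITIONS = (-2, -1, 1, 2, 3, 4)

#: span replaced by five consecutive G:C pairs in the "5G" end
FIVE_G_SPAN = (-2, -1, 1, 2, 3)

#: wild-type NTS base at each mutagenised position, inferred from the fact
#: that each position was substituted with the three non-wild-type bases
WT_NTS_BASE = {-2: "T", -1: "A", 1: "T", 2: "T", 3: "A", 4: "C"}

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class EndVariant:
    """One transposon end, identified symbolically by its mutation set.

    The catalytic phenotype of an end is summarised by three unitless
    multipliers rather than by sequence:

    ``nts_factor``
        multiplier on the NTS-nicking rate at this end.
    ``ts_factor``
        multiplier on the TS-cleavage chemistry rate at this end.
    ``competence``
        in [0, 1]; how well this half-site drives the coordinated
        conformational transition that licenses TS cleavage.
    """

    name: str
    mutated_positions: tuple[int, ...] = ()
    nts_factor: float = 1.0
    ts_factor: float = 1.0
    competence: float = 1.0

    def __post_init__(self) -> None:
        for f, label in ((self.nts_factor, "nts_factor"), (self.ts_factor, "ts_factor")):
            if not math.isfinite(f) or f < 0:
                raise ValueError(f"{label} must be finite and >= 0, got {f}")
        if not (0.0 <= self.competence <= 1.0):
            raise ValueError(f"competence must lie in [0, 1], got {self.competence}")
        pos = tuple(self.mutated_positions)
        if any(p == 0 for p in pos):
            raise ValueError("position 0 does not exist in the end-numbering convention")
        if self.name == "5G":
            if tuple(sorted(pos)) != FIVE_G_SPAN:
                raise ValueError("the 5G end mutates exactly positions -2..+3 (no 0)")
        elif not set(pos) <= set(POINT_MUTATION_POSITIONS):
            raise ValueError(
                f"point-mutant positions must be drawn from {POINT_MUTATION_POSITIONS}"
            )
        object.__setattr__(self, "mutated_positions", pos)

    @property
    def is_wild_type(self) -> bool:
        return not self.mutated_positions


WT_END = EndVariant("WT")

# Default phenotype factors per mutation class.  The underlying gel data are
# qualitative; these values are chosen once so that the noiseless default
# kinetics reproduce the observed rank order of phenotypes (see
# docs/methods.md): 5G ends are all-but-dead even for nicking; -1 flank
# mutants nick normally but barely support the coordinated transition;
# +1C/+1G/+2G show a mild nicking defect on top of a transition defect;
# the remaining internal positions and the -2 flank position are mild.
_FACTOR_PRESETS: dict[str, tuple[float, float, float]] = {
    "5G": (1e-5, 0.01, 0.05),
    "minus1": (1.0, 0.3, 0.01),
    "strong_plus": (0.5, 0.2, 0.5),
    "mild_plus": (1.0, 0.5, 0.8),
    "minus2": (1.0, 0.9, 0.9),
}

_STRONG_PLUS_MUTANTS = {"+1C", "+1G", "+2G"}


def _mutation_name(position: int, base: str) -> str:
    sign = "+" if position > 0 else "-"
    return f"{sign}{abs(position)}{base}"


def point_mutant_end(position: int, base: str) -> EndVariant:
    """Build the EndVariant for a single-bp substitution at ``position``."""
    if position not in POINT_MUTATION_POSITIONS:
        raise ValueError(f"position must be one of {POINT_MUTATION_POSITIONS}")
    base = base.upper()
    if base not in _BASES:
        raise ValueError(f"base must be one of {_BASES}")
    if base == WT_NTS_BASE[position]:
        raise ValueError(f"{base} is the wild-type base at position {position:+d}")
    name = _mutation_name(position, base)
    if position == -1:
        preset = "minus1"
    elif position == -2:
        preset = "minus2"
    elif name in _STRONG_PLUS_MUTANTS:
        preset = "strong_plus"
    else:
        preset = "mild_plus"
    nts, ts, comp = _FACTOR_PRESETS[preset]
    return EndVariant(name, (position,), nts, ts, comp)


def five_g_end() -> EndVariant:
    """The '5G' end: five consecutive G:C pairs spanning positions -2..+3."""
    nts, ts, comp = _FACTOR_PRESETS["5G"]
    return EndVariant("5G", FIVE_G_SPAN, nts, ts, comp)


@dataclass(frozen=True)
class CleavageSiteMap:
    """Signed offsets of the two single-strand cuts from the junction.

    ``nts_offset`` is measured into the element along the NTS (default 3 nt
    inside); ``ts_offset`` likewise for the TS (default 0: the TS is cut
    exactly at the junction).
    """

    nts_offset: int = 3
    ts_offset: int = 0

    def __post_init__(self) -> None:
        if not (isinstance(self.nts_offset, int) and isinstance(self.ts_offset, int)):
            raise TypeError("cleavage offsets must be integers")


def _default_digest_site(element_length: int, backbone_length: int) -> int:
    # Place the restriction site asymmetrically in the backbone so that the
    # two junction-to-site arcs differ (by 500 bp with the default geometry);
    # the asymmetry is what resolves SEB-Left from SEB-Right on a gel.
    return element_length + max(1, (backbone_length - 500) // 2)


@dataclass(frozen=True)
class Substrate:
    """A circular mini-transposon donor plasmid."""

    name: str
    left_end: EndVariant = WT_END
    right_end: EndVariant = WT_END
    element_length: int = 1500
    backbone_length: int = 2500
    digest_site: int | None = None
    flank_dinucleotide: str = "TA"

    def __post_init__(self) -> None:
        if self.element_length < 60:
            raise ValueError("element_length must cover two 30-bp ends (>= 60 bp)")
        if self.backbone_length <= 0:
            raise ValueError("backbone_length must be positive")
        site = self.digest_site
        if site is None:
            site = _default_digest_site(self.element_length, self.backbone_length)
            object.__setattr__(self, "digest_site", site)
        if not (self.element_length < site < self.total_length):
            raise ValueError("digest_site must lie strictly within the backbone")
        if len(self.flank_dinucleotide) != 2 or not set(self.flank_dinucleotide) <= set(_BASES):
            raise ValueError("flank_dinucleotide must be a 2-letter DNA sequence")

    @property
    def total_length(self) -> int:
        return self.element_length + self.backbone_length

    def end(self, which: str) -> EndVariant:
        if which == "left":
            return self.left_end
        if which == "right":
            return self.right_end
        raise ValueError("end must be 'left' or 'right'")

    @property
    def is_symmetric(self) -> bool:
        return self.left_end == self.right_end


class Cut(NamedTuple):
    """A single-strand break at boundary ``position`` on ``strand``."""

    strand: str  # "fwd" or "rev"
    position: int  # boundary coordinate in [0, total_length)


def cleavage_positions(
    substrate: Substrate, end: str, site_map: CleavageSiteMap = CleavageSiteMap()
) -> tuple[Cut, Cut]:
    """Absolute circular-map cuts ``(nts_cut, ts_cut)`` for one end.

    Because the two ends are inverted repeats, the NTS and TS swap physical
    strands between left and right ends: the left-end TS 3'-OH sits on the
    reverse strand at boundary 0, the right-end TS 3'-OH on the forward
    strand at boundary ``element_length``.
    """
    e = substrate.element_length
    if end == "left":
        nts = Cut("fwd", site_map.nts_offset % substrate.total_length)
        ts = Cut("rev", site_map.ts_offset % substrate.total_length)
    elif end == "right":
        nts = Cut("rev", (e - site_map.nts_offset) % substrate.total_length)
        ts = Cut("fwd", (e - site_map.ts_offset) % substrate.total_length)
    else:
        raise ValueError("end must be 'left' or 'right'")
    return nts, ts


class EtfStrandLengths(NamedTuple):
    fwd: int
    rev: int


def etf_strand_lengths(
    element_length: int, site_map: CleavageSiteMap = CleavageSiteMap()
) -> EtfStrandLengths:
    """Single-strand lengths of the excised transposon fragment (ETF).

    Each ETF strand carries a TS terminus (cut at the junction) at one end
    and a recessed NTS terminus (cut ``nts_offset`` inside the element) at
    the other, so with the default map both strands are
    ``element_length - nts_offset`` nt long and the duplex carries a 3-nt
    3' overhang at each end.
    """
    k = site_map.nts_offset
    if element_length <= 2 * k:
        raise ValueError("element_length must exceed twice the NTS offset")
    n = element_length - k - site_map.ts_offset
    return EtfStrandLengths(n, n)


def build_mutant_catalog(
    element_length: int = 1500,
    backbone_length: int = 2500,
    digest_site: int | None = None,
) -> list[Substrate]:
    """Enumerate the experimental substrate panel for a fixed geometry.

    Returns the wild-type donor, the 18 symmetric single-bp mutants (three
    non-wild-type substitutions at each of positions -2, -1, +1, +2, +3,
    +4, carried by both ends), the 5G x 5G double mutant, and the
    heteroduplex pairings used for the crosstalk experiments.
    """
    geom = dict(
        element_length=element_length,
        backbone_length=backbone_length,
        digest_site=digest_site,
    )

    def sub(left: EndVariant, right: EndVariant) -> Substrate:
        return Substrate(f"{left.name} × {right.name}", left, right, **geom)

    catalog = [sub(WT_END, WT_END)]
    for pos in POINT_MUTATION_POSITIONS:
        for base in _BASES:
            if base == WT_NTS_BASE[pos]:
                continue
            end = point_mutant_end(pos, base)
            catalog.append(sub(end, end))
    catalog.append(sub(five_g_end(), five_g_end()))
    # heteroduplex substrates (one mutant end paired with a wild-type end)
    catalog.append(sub(WT_END, five_g_end()))
    catalog.append(sub(WT_END, point_mutant_end(-1, "T")))
    catalog.append(sub(point_mutant_end(-1, "T"), WT_END))
    catalog.append(sub(WT_END, point_mutant_end(1, "A")))
    catalog.append(sub(WT_END, point_mutant_end(1, "C")))
    catalog.append(sub(WT_END, point_mutant_end(1, "G")))
    return catalog


def symmetric_point_mutants(catalog: Iterable[Substrate]) -> list[Substrate]:
    """The symmetric single-bp mutant subset of a catalog."""
    return [
        s
        for s in catalog
        if s.is_symmetric
        and len(s.left_end.mutated_positions) == 1
        and not s.left_end.is_wild_type
    ]


def write_catalog_tsv(catalog: Iterable[Substrate], path) -> None:
    """Write a substrate catalog as TSV (one row per substrate)."""
    import pandas as pd

    rows = []
    for s in catalog:
        rows.append(
            {
                "name": s.name,
                "left": s.left_end.name,
                "right": s.right_end.name,
                "left_positions": ",".join(map(str, s.left_end.mutated_positions)),
                "right_positions": ",".join(map(str, s.right_end.mutated_positions)),
                "left_nts_factor": s.left_end.nts_factor,
                "left_ts_factor": s.left_end.ts_factor,
                "left_competence": s.left_end.competence,
                "right_nts_factor": s.right_end.nts_factor,
                "right_ts_factor": s.right_end.ts_factor,
                "right_competence": s.right_end.competence,
                "element_length": s.element_length,
                "backbone_length": s.backbone_length,
                "digest_site": s.digest_site,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_end_fasta(path, require_ta_flank: bool = True) -> dict[str, str]:
    """Read optional user-supplied transposon-end sequences from FASTA.

    Sequences are purely annotational — the kinetic model identifies ends
    symbolically.  A record may be the bare 30-bp end or carry a 2-nt flank
    prefix; flanked records are checked for the TA target-site duplication.
    """
    from Bio import SeqIO

    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if require_ta_flank and len(seq) > 30 and not seq.startswith("TA"):
            raise ValueError(
                f"end sequence {rec.id!r} includes flanking DNA but lacks the TA flank"
            )
        out[rec.id] = seq
    return out
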