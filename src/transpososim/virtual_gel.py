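"""Virtual gels: map molecular states to the observable band patterns.

Two readouts are modelled.

*Native* agarose electrophoresis distinguishes topological species classes
of the deproteinated reaction: supercoiled substrate (SC), open-circular
nicked intermediate (OC), the linear single-end-break product (LIN), the
double-end-break products (plasmid backbone plus excised transposon
fragment, BB+ETF) and integration products.

*Denaturing* (alkaline) electrophoresis resolves single strands.  The
reaction products are first cut within the backbone with a restriction
enzyme, radiolabelled either on every 5' end (kinase after
dephosphorylation) or on restriction-generated 3' ends (Klenow fill-in),
then denatured; the predicted band table lists single-strand fragment
lengths with their label counts and molar abundances.

The restriction cut is modelled as a blunt double-strand break at one
coordinate: the enzyme's few-nt stagger is below gel resolution, and only
the routing of the fill-in label — which targets restriction 3' termini —
matters for any observable, so restriction termini are flagged explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .kinetic_models import D, INTEGRATED, N, SYNAPSED, U, MoleculeState
from .simulator import TimeCourse
from .substrate_model import CleavageSiteMap, Cut, Substrate, cleavage_positions

__all__ = [
    "SC",
    "OC",
    "LIN",
    "BB_ETF",
    "NATIVE_CLASSES",
    "Break",
    "CutMap",
    "Fragment",
    "native_species",
    "build_cutmap",
    "single_strand_fragments",
    "label_and_band",
    "lane_profile",
    "seb_band_table",
    "ascii_gel",
    "BAND_MERGE_TOLERANCE",
]

SC = "SC"
OC = "OC"
LIN = "LIN"
BB_ETF = "BB_ETF"

#: native-gel species classes, in electrophoretic bookkeeping order
NATIVE_CLASSES = (SC, OC, LIN, BB_ETF, INTEGRATED)

#: default relative length difference below which strands co-migrate;
#: 0 means only exactly equal lengths co-migrate (e.g. the two complementary
#: strands of an unreacted substrate), which keeps the diagnostic band
#: counts of the SEB strand-analysis experiment resolvable
BAND_MERGE_TOLERANCE = 0.0


class Break(NamedTuple):
    """A single-strand break: ``strand`` in {fwd, rev}, boundary ``position``."""

    strand: str
    position: int
    kind: str  # "nick", "transposition_cut" or "restriction"


@dataclass(frozen=True)
class CutMap:
    """All strand breaks on one molecule of a circular plasmid map."""

    total_length: int
    breaks: tuple[Break, ...] = ()
    circular: bool = True

    def __post_init__(self) -> None:
        for b in self.breaks:
            if b.strand not in ("fwd", "rev"):
                raise ValueError(f"unknown strand {b.strand!r}")
            if not (0 <= b.position < self.total_length):
                raise ValueError("break positions must lie on the circular map")

    def strand_positions(self, strand: str) -> list[int]:
        return sorted({b.position for b in self.breaks if b.strand == strand})

    @property
    def restriction_boundaries(self) -> frozenset[int]:
        return frozenset(b.position for b in self.breaks if b.kind == "restriction")


class Fragment(NamedTuple):
    """A single-strand fragment between boundaries ``start`` and ``end``.

    Coordinates are circular boundaries; ``start == end`` with
    ``circular=True`` denotes an uncut circular strand.  For a forward
    strand the 5' terminus sits at ``start`` and the 3' terminus at
    ``end``; a reverse strand runs the other way, so its 3' terminus is at
    ``start``.
    """

    strand: str
    start: int
    end: int
    length: int
    circular: bool = False

    @property
    def three_prime_boundary(self) -> int:
        return self.end if self.strand == "fwd" else self.start


def native_species(state: MoleculeState) -> str:
    """Native-gel class of a molecule in ``state``.

    No breaks -> SC; nicked but no fully-cut end -> OC (open circular);
    exactly one double-strand-broken end -> LIN (the SEB product); both
    ends broken -> BB+ETF (the two excision products); integrated
    molecules are their own class.
    """
    if state.phase == INTEGRATED:
        return INTEGRATED
    n_dsb = (state.left == D) + (state.right == D)
    if n_dsb == 2:
        return BB_ETF
    if n_dsb == 1:
        return LIN
    if N in (state.left, state.right):
        return OC
    return SC


def build_cutmap(
    state: MoleculeState,
    sub: Substrate,
    site_map: CleavageSiteMap = CleavageSiteMap(),
    digest: bool = False,
) -> CutMap:
    """Place the strand breaks implied by ``state`` on the plasmid map.

    An N end contributes its NTS nick; a D end both its NTS and TS cuts.
    ``digest=True`` adds the blunt restriction break on both strands.  The
    integrated state is mapped like the double-end-break state: the donor
    plasmid carries the same four transposition cuts, and the fate of the
    excised fragment in the target is outside the gel model.
    """
    breaks: list[Break] = []
    for end in ("left", "right"):
        status = state.end(end)
        if status == U:
            continue
        nts, ts = cleavage_positions(sub, end, site_map)
        if status == N:
            breaks.append(Break(nts.strand, nts.position, "nick"))
        else:  # D
            breaks.append(Break(nts.strand, nts.position, "transposition_cut"))
            breaks.append(Break(ts.strand, ts.position, "transposition_cut"))
    if digest:
        breaks.append(Break("fwd", sub.digest_site, "restriction"))
        breaks.append(Break("rev", sub.digest_site, "restriction"))
    has_dsb = digest or D in (state.left, state.right)
    return CutMap(sub.total_length, tuple(breaks), circular=not has_dsb)


def single_strand_fragments(cm: CutMap) -> list[Fragment]:
    """Fragments of each physical strand between consecutive breaks.

    Per strand the fragment lengths sum to the full map length; an uncut
    strand of a circular molecule is returned as one circular fragment.
    """
    out: list[Fragment] = []
    length = cm.total_length
    for strand in ("fwd", "rev"):
        cuts = cm.strand_positions(strand)
        if not cuts:
            if not cm.circular:
                raise ValueError("a linear molecule needs >= 1 break per strand")
            out.append(Fragment(strand, 0, 0, length, circular=True))
            continue
        for a, b in zip(cuts, cuts[1:] + [cuts[0] + length]):
            out.append(Fragment(strand, a % length, b % length, b - a))
    return out


def _merge_bands(rows: list[dict], tolerance: float) -> pd.DataFrame:
    """Co-migrate fragments whose relative length difference <= tolerance."""
    rows = sorted(rows, key=lambda r: -r["length"])
    bands: list[dict] = []
    for r in rows:
        if bands and (bands[-1]["_ref"] - r["length"]) <= tolerance * bands[-1]["_ref"]:
            b = bands[-1]
            b["molar_abundance"] += r["molar_abundance"]
            b["intensity"] += r["intensity"]
            b["length"] = max(b["length"], r["length"])  # report the slower edge
        else:
            bands.append(dict(r, _ref=r["length"]))
    df = pd.DataFrame(
        [{k: v for k, v in b.items() if k != "_ref"} for b in bands],
        columns=["length", "label_count", "molar_abundance", "intensity"],
    )
    return df


def label_and_band(
    fragments: Sequence[Fragment],
    labeling: str,
    restriction_ends: Iterable[int] = (),
    abundances: Sequence[float] | None = None,
    tolerance: float = BAND_MERGE_TOLERANCE,
) -> pd.DataFrame:
    """Predicted denaturing-gel band table for a set of strand fragments.

    ``five_prime_kinase`` places one label on every linear fragment
    (dephosphorylation + PNK labels all 5' ends); ``three_prime_fill_in``
    labels only fragments whose 3' terminus lies at a restriction cut
    (Klenow fill-in of the recessed restriction ends), which is why
    transposition-cut termini — including both ends of the excised
    transposon — carry no fill-in label.

    Rows: length (nt), label_count per fragment, molar_abundance,
    intensity = molar_abundance * label_count; sorted by length
    descending, with fragments closer than ``tolerance`` (relative length)
    merged into one band.
    """
    if labeling not in ("five_prime_kinase", "three_prime_fill_in"):
        raise ValueError(f"unknown labeling mode {labeling!r}")
    restriction_ends = frozenset(restriction_ends)
    if abundances is None:
        abundances = [1.0] * len(fragments)
    rows = []
    for frag, ab in zip(fragments, abundances):
        if labeling == "five_prime_kinase":
            label = 0 if frag.circular else 1
        else:
            label = int(
                not frag.circular and frag.three_prime_boundary in restriction_ends
            )
        rows.append(
            {
                "length": frag.length,
                "label_count": label,
                "molar_abundance": ab,
                "intensity": ab * label,
            }
        )
    return _merge_bands(rows, tolerance)


def _duplex_arc(cm: CutMap, sub: Substrate) -> list[int]:
    """Boundaries at which the duplex itself is severed (DSB loci)."""
    loci = set(cm.restriction_boundaries)
    fwd = set(cm.strand_positions("fwd"))
    rev = set(cm.strand_positions("rev"))
    # a transposon end with cuts on both strands (TS at the junction, NTS a
    # few nt inside) severs the duplex at the junction
    for end, junction in (("left", 0), ("right", sub.element_length)):
        near = range(junction - 10, junction + 11)
        if any(p % cm.total_length in fwd for p in near) and any(
            p % cm.total_length in rev for p in near
        ):
            loci.add(junction % cm.total_length)
    return sorted(loci)


def _fragment_segment(frag: Fragment, loci: Sequence[int], length: int) -> int:
    """Index of the duplex segment (arc between DSB loci) holding a fragment."""
    mid = (frag.start + (frag.length / 2.0)) % length
    for i, a in enumerate(loci):
        b = loci[(i + 1) % len(loci)]
        span = (b - a) % length or length
        if (mid - a) % length < span:
            return i
    raise AssertionError("unreachable")


def seb_band_table(
    sub: Substrate,
    site_map: CleavageSiteMap = CleavageSiteMap(),
    cleaved_end: str = "left",
    partner_nicked: bool = True,
    labeling: str = "five_prime_kinase",
    tolerance: float = BAND_MERGE_TOLERANCE,
) -> pd.DataFrame:
    """Band table of the gel-purified SEB digest fragment, denatured.

    Models the SEB strand-analysis experiment: digest the reaction in the
    backbone, purify the transposon-containing fragment of the linear
    single-end-break species on a native gel, end-label, denature.  With a
    nick at the partner-end NTS the duplex releases three labelled strands
    of similar molar abundance; without it, two.
    """
    partner = "right" if cleaved_end == "left" else "left"
    ends = {cleaved_end: D, partner: N if partner_nicked else U}
    state = MoleculeState(SYNAPSED, ends["left"], ends["right"], True)
    cm = build_cutmap(state, sub, site_map, digest=True)
    frags = single_strand_fragments(cm)
    loci = _duplex_arc(cm, sub)
    # keep only fragments of the duplex segment containing the element interior
    mid_el = Fragment("fwd", 0, 0, sub.element_length)  # pseudo-fragment at element midpoint
    target_seg = _fragment_segment(mid_el, loci, cm.total_length)
    kept = [f for f in frags if _fragment_segment(f, loci, cm.total_length) == target_seg]
    return label_and_band(
        kept, labeling, restriction_ends=cm.restriction_boundaries, tolerance=tolerance
    )


def lane_profile(
    tc: TimeCourse,
    t: float,
    sub: Substrate,
    site_map: CleavageSiteMap = CleavageSiteMap(),
    digest: bool = True,
    labeling: str = "five_prime_kinase",
    tolerance: float = BAND_MERGE_TOLERANCE,
) -> pd.DataFrame:
    """Simulated denaturing-gel lane at time ``t``.

    The molar-abundance-weighted union of the per-state band tables of the
    whole reaction mixture (no purification step).
    """
    dist = tc.at(t)
    rows: list[dict] = []
    seen: dict[tuple, list[Fragment]] = {}
    restriction: frozenset[int] = frozenset()
    for frac, state in zip(dist, tc.states):
        if frac <= 1e-12:
            continue
        key = (state.left, state.right, state.phase == INTEGRATED)
        if key not in seen:
            cm = build_cutmap(state, sub, site_map, digest=digest)
            seen[key] = single_strand_fragments(cm)
            restriction = restriction | cm.restriction_boundaries
        for frag in seen[key]:
            if labeling == "five_prime_kinase":
                label = 0 if frag.circular else 1
            else:
                label = int(
                    not frag.circular and frag.three_prime_boundary in restriction
                )
            rows.append(
                {
                    "length": frag.length,
                    "label_count": label,
                    "molar_abundance": frac,
                    "intensity": frac * label,
                }
            )
    if labeling not in ("five_prime_kinase", "three_prime_fill_in"):
        raise ValueError(f"unknown labeling mode {labeling!r}")
    return _merge_bands(rows, tolerance)


def ascii_gel(
    band_tables: dict[str, pd.DataFrame], height: int = 24, width: int = 8
) -> str:
    """Render lanes of band tables as a plain-text gel cartoon.

    Migration is on a log-length scale (cosmetic only); band darkness
    encodes relative intensity within the gel.
    """
    all_rows = [
        (lane, r.length, r.intensity)
        for lane, df in band_tables.items()
        for r in df.itertuples()
        if r.intensity > 0
    ]
    if not all_rows:
        return "(no labelled bands)"
    lo = min(l for _, l, _ in all_rows)
    hi = max(l for _, l, _ in all_rows)
    peak = max(i for _, _, i in all_rows)
    span = np.log(hi / lo) if hi > lo else 1.0
    shades = " .:=#"
    grid = {lane: [" "] * height for lane in band_tables}
    for lane, length, inten in all_rows:
        row = int(round((np.log(hi / length) / span) * (height - 1)))
        shade = shades[min(4, 1 + int(3 * inten / peak))]
        grid[lane][row] = shade
    lanes = list(band_tables)
    head = " " + "".join(f"{lane[:width]:^{width}}" for lane in lanes)
    lines = [head]
    for r in range(height):
        lines.append("|" + "".join(f"{grid[lane][r] * 3:^{width}}" for lane in lanes) + "|")
    return "\n".join(lines)
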