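"""MspJI-family enzyme models, cleavage geometry, and theoretical digests.

The geometric facts this module encodes:

* An MFRE (MspJI-family, Type IV) enzyme cleaves double-stranded DNA a fixed
  distance (16 bp by default) 3' of a 5-methylcytosine, leaving a 4-base 5'
  overhang.  We work in post-end-repair coordinates, i.e. the overhang is
  already blunted and a fragment is fully described by duplex start/end.
* A fully methylated (both-strand) palindromic site is cleaved on both sides,
  excising a fragment in which the m5C on each strand is the 17th base from
  that strand's 3' end.
* If ``x`` is the signed offset between the top-strand m5C and the base
  paired with the bottom-strand m5C (top index minus bottom index), the
  excised fragment has length ``l_x = x + 33``.  ``x`` cannot be 0 (the two
  methylated cytosines would have to be base-paired with each other), so no
  correctly cut fragment can be 33 bp long.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .sequence import (
    IUPAC_SETS,
    expand_degenerate,
    iupac_match,
    is_palindrome,
    reverse_complement,
    set_to_code,
    ReferenceGenome,
)

__all__ = [
    "EnzymeModel",
    "MSPJI",
    "FSPEI",
    "LPNPI",
    "GENERIC_MFRE",
    "BUILTIN_ENZYMES",
    "MotifModel",
    "MethylSite",
    "Methylome",
    "Cut",
    "FragmentCategory",
    "FragmentAnnotation",
    "offset_x",
    "ccmd_length",
    "constrained_site",
    "expected_cuts",
    "fragments_from_cuts",
    "digest",
    "classify_fragments",
    "classify_read_cutting",
    "CleavageDistances",
    "cleavage_distances",
    "bin_distance",
    "DISTANCE_BINS",
]

CUT_DISTANCE = 16  # bases 3' of the m5C at which the blunted fragment ends


@dataclass(frozen=True)
class EnzymeModel:
    """An MFRE's m5C sequence-context requirement and cleavage geometry.

    ``context`` is the required sequence read 5'->3' on the methylated
    strand; ``m5c_index`` marks the methylated C within it.  ``cut_distance``
    is the number of bases 3' of the m5C after which the (post-end-repair)
    fragment ends.
    """

    name: str
    context: str
    m5c_index: int
    cut_distance: int = CUT_DISTANCE
    overhang: int = 4  # informational; overhangs are modeled as blunted

    def __post_init__(self) -> None:
        if not (0 <= self.m5c_index < len(self.context)):
            raise ValueError("m5c_index outside context")
        if "C" not in IUPAC_SETS[self.context[self.m5c_index]]:
            raise ValueError("context symbol at m5c_index must allow C")
        if self.cut_distance < 0:
            raise ValueError("cut_distance must be >= 0")


MSPJI = EnzymeModel("MspJI", "CNNR", 0)
FSPEI = EnzymeModel("FspEI", "CC", 1)
LPNPI = EnzymeModel("LpnPI", "CCDG", 1)
#: Idealized MFRE with no flanking requirement beyond the m5C itself; useful
#: for simulations that should exercise the pipeline geometry without the
#: site-constraint effects of a real enzyme.
GENERIC_MFRE = EnzymeModel("generic", "C", 0)

BUILTIN_ENZYMES = {e.name: e for e in (MSPJI, FSPEI, LPNPI, GENERIC_MFRE)}


@dataclass(frozen=True)
class MotifModel:
    """A methyltransferase motif with its methylated positions.

    ``top_m5c_index`` is the 0-based index of the methylated C on the top
    strand; ``bottom_m5c_index`` is the top-strand index of the G paired
    with the bottom-strand m5C.
    """

    motif: str
    top_m5c_index: int
    bottom_m5c_index: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "motif", self.motif.upper())
        n = len(self.motif)
        for idx in (self.top_m5c_index, self.bottom_m5c_index):
            if not (0 <= idx < n):
                raise ValueError("methylated index outside motif")
        if "C" not in IUPAC_SETS[self.motif[self.top_m5c_index]]:
            raise ValueError(
                f"motif position {self.top_m5c_index} of {self.motif} cannot be C"
            )
        if "G" not in IUPAC_SETS[self.motif[self.bottom_m5c_index]]:
            raise ValueError(
                f"motif position {self.bottom_m5c_index} of {self.motif} cannot be G"
            )
        if self.top_m5c_index == self.bottom_m5c_index:
            raise ValueError(
                "top and bottom m5C are base-paired (x = 0); no such motif can exist"
            )

    @classmethod
    def palindromic(cls, motif: str, top_m5c_index: int) -> "MotifModel":
        """Build the model for a palindromic motif; the bottom-strand m5C is
        forced to the mirror position."""
        if not is_palindrome(motif):
            raise ValueError(f"{motif} is not palindromic")
        return cls(motif, top_m5c_index, len(motif) - 1 - top_m5c_index)

    @property
    def x(self) -> int:
        return offset_x(self)

    @property
    def ccmd_len(self) -> int:
        return ccmd_length(self.x)

    def ccmd_motif_start(self) -> int:
        """0-based start of the motif within a correctly cut (16,16) read."""
        return 16 - self.bottom_m5c_index


def offset_x(motif_model: MotifModel) -> int:
    """Signed offset between top-strand m5C and the bottom-strand m5C's
    paired base: top index minus bottom index.

    Examples: x = 1 for AGCT, x = -2 for CCWGG, x = -1 for CG.
    """
    x = motif_model.top_m5c_index - motif_model.bottom_m5c_index
    if x == 0:  # unreachable through the constructor, kept for direct calls
        raise ValueError("x cannot be 0")
    return x


def ccmd_length(x: int) -> int:
    """Correctly cut fragment length l_x = x + 33 (x != 0, so l_x != 33)."""
    if x == 0:
        raise ValueError("x cannot be 0, so l_x cannot be 33")
    return x + 33


def _intersect(a: str, b: str) -> str | None:
    bases = IUPAC_SETS[a] & IUPAC_SETS[b]
    if not bases:
        return None
    return set_to_code(bases)


class IncompatibleMotifError(ValueError):
    """No instance of the motif is cleavable by the enzyme."""


def constrained_site(motif_model: MotifModel, enzyme: EnzymeModel) -> str:
    """The enzyme-constrained version of a motif.

    The enzyme's context is applied at the top-strand m5C (reading 3'-ward
    on the top strand) and, reverse-complemented, at the bottom-strand m5C.
    Cleavable genome positions are exactly those matching the result, e.g.
    GATC under MspJI becomes YNNGATCNNR.
    """
    motif = motif_model.motif
    ctx = enzyme.context.upper()
    # Extended coordinates relative to motif position 0.
    top_start = motif_model.top_m5c_index - enzyme.m5c_index
    rc_ctx = reverse_complement(ctx)
    # Within rc_ctx, the base paired with the bottom-strand m5C sits at
    # index len(ctx)-1-m5c_index; align it onto bottom_m5c_index.
    bot_start = motif_model.bottom_m5c_index - (len(ctx) - 1 - enzyme.m5c_index)
    lo = min(0, top_start, bot_start)
    hi = max(len(motif), top_start + len(ctx), bot_start + len(ctx))
    symbols = ["N"] * (hi - lo)
    for i, sym in enumerate(motif):
        symbols[i - lo] = sym
    for start, pattern in ((top_start, ctx), (bot_start, rc_ctx)):
        for k, sym in enumerate(pattern):
            pos = start + k - lo
            merged = _intersect(symbols[pos], sym)
            if merged is None:
                raise IncompatibleMotifError(
                    f"{motif} is not cleavable by {enzyme.name}: conflict at "
                    f"motif offset {start + k}"
                )
            symbols[pos] = merged
    return "".join(symbols)


@dataclass(frozen=True)
class MethylSite:
    """One methylated cytosine.

    For ``strand == 'top'`` the position is the top-strand coordinate of the
    C itself; for ``strand == 'bottom'`` it is the top-strand coordinate of
    the G whose paired bottom-strand base is the methylated C.
    """

    record: str
    position: int
    strand: str  # 'top' | 'bottom'
    motif_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("top", "bottom"):
            raise ValueError("strand must be 'top' or 'bottom'")


class Methylome:
    """Collection of methylated cytosines with full/hemi bookkeeping."""

    def __init__(self, sites: Iterable[MethylSite] = ()):
        self.sites: list[MethylSite] = list(sites)

    def add_full_site(self, record: str, start: int, motif_model: MotifModel,
                      motif_id: str = "") -> None:
        """Register both strands' m5C for a motif instance at ``start``."""
        self.sites.append(MethylSite(record, start + motif_model.top_m5c_index,
                                     "top", motif_id))
        self.sites.append(MethylSite(record, start + motif_model.bottom_m5c_index,
                                     "bottom", motif_id))

    def add_hemi_site(self, record: str, start: int, motif_model: MotifModel,
                      motif_id: str = "") -> None:
        """Register the top-strand m5C only."""
        self.sites.append(MethylSite(record, start + motif_model.top_m5c_index,
                                     "top", motif_id))

    def validate(self, genome: ReferenceGenome) -> None:
        for site in self.sites:
            base = genome[site.record][site.position]
            want = "C" if site.strand == "top" else "G"
            if base != want:
                raise ValueError(
                    f"{site.record}:{site.position} ({site.strand}) is {base}, "
                    f"expected {want}"
                )

    def __len__(self) -> int:
        return len(self.sites)


@dataclass(frozen=True)
class Cut:
    """A realized or expected cleavage boundary (post-end-repair coordinate).

    ``side`` records which side of its originating m5C the cut falls on:
    a top-strand m5C produces a cut 3'-ward ('right' boundary of the excised
    fragment), a bottom-strand m5C a cut 5'-ward on the top strand ('left').
    """

    record: str
    position: int  # boundary in 0-based half-open coordinates
    site: MethylSite
    side: str  # 'left' | 'right'
    enzyme: str


class FragmentCategory(enum.Enum):
    MOTIF_CLEAVED = "motif-cleaved"
    INTERSTITIAL = "interstitial"
    OVERLAP_SHORT = "overlap-short"
    OVERLAP_LONG = "overlap-long"
    CONCATENATED = "concatenated"
    OTHER = "other"


@dataclass
class FragmentAnnotation:
    record: str
    start: int
    end: int
    category: FragmentCategory | None = None
    left_cut: Cut | None = None   # None at record boundaries
    right_cut: Cut | None = None
    missed_cuts: list[Cut] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def expected_cut_flags(self) -> tuple[bool, bool]:
        return (self.left_cut is not None, self.right_cut is not None)


def _context_matches(genome_seq: str, pos: int, strand: str,
                     enzyme: EnzymeModel) -> bool:
    """Does the enzyme context hold around the m5C at ``pos``?"""
    ctx = enzyme.context
    if strand == "top":
        start = pos - enzyme.m5c_index
        pattern = ctx
    else:
        start = pos - (len(ctx) - 1 - enzyme.m5c_index)
        pattern = reverse_complement(ctx)
    end = start + len(ctx)
    if start < 0 or end > len(genome_seq):
        return False
    window = genome_seq[start:end]
    if "N" in window:
        return False
    return iupac_match(window, pattern)


def expected_cuts(genome: ReferenceGenome, methylome: Methylome,
                  enzymes: Sequence[EnzymeModel]) -> list[Cut]:
    """All cleavage boundaries implied by the methylome.

    A top-strand m5C at p whose context matches an enzyme yields a boundary
    at p + cut_distance + 1 (so the m5C is the 17th base from the 3' end of
    the upstream fragment); a bottom-strand m5C paired at q yields a
    boundary at q - cut_distance.
    """
    cuts: list[Cut] = []
    for site in methylome.sites:
        seq = genome[site.record]
        for enzyme in enzymes:
            if not _context_matches(seq, site.position, site.strand, enzyme):
                continue
            if site.strand == "top":
                pos = site.position + enzyme.cut_distance + 1
                side = "right"
            else:
                pos = site.position - enzyme.cut_distance
                side = "left"
            if 0 < pos < len(seq):
                cuts.append(Cut(site.record, pos, site, side, enzyme.name))
            break  # one cut per site even if several enzymes match
    return cuts


def fragments_from_cuts(genome: ReferenceGenome, realized: Sequence[Cut],
                        missed: Sequence[Cut] = ()) -> list[FragmentAnnotation]:
    """Tile each record into fragments between realized cut boundaries.

    ``missed`` carries expected-but-unrealized cuts (incomplete digestion)
    so classification can mark spanning fragments as concatenated.
    """
    fragments: list[FragmentAnnotation] = []
    for name, seq in genome.records:
        rec_cuts = sorted((c for c in realized if c.record == name),
                          key=lambda c: c.position)
        rec_missed = [c for c in missed if c.record == name]
        boundaries: list[tuple[int, Cut | None]] = [(0, None)]
        for cut in rec_cuts:
            if boundaries[-1][0] == cut.position:
                continue  # coincident cuts collapse to one boundary
            boundaries.append((cut.position, cut))
        if boundaries[-1][0] != len(seq):
            boundaries.append((len(seq), None))
        else:
            boundaries[-1] = (len(seq), None)
        for (start, left), (end, right) in zip(boundaries, boundaries[1:]):
            frag = FragmentAnnotation(name, start, end, None, left, right)
            frag.missed_cuts = [c for c in rec_missed if start < c.position < end]
            fragments.append(frag)
    return fragments


def _site_interval(site_sites: list[MethylSite], cut_distance: int) -> tuple[int, int]:
    """Excision interval [left, right) of a fully methylated site."""
    top = next(s for s in site_sites if s.strand == "top")
    bottom = next(s for s in site_sites if s.strand == "bottom")
    return bottom.position - cut_distance, top.position + cut_distance + 1


def full_site_intervals(methylome: Methylome,
                        cut_distance: int = CUT_DISTANCE
                        ) -> dict[str, list[tuple[int, int]]]:
    """Excision intervals [left, right) of fully methylated sites.

    Top/bottom m5C entries within one motif length (<= 8 bp) of each other
    with the same motif id are paired into one double-stranded site;
    unpaired (hemi) entries yield no interval.
    """
    intervals: dict[str, list[tuple[int, int]]] = {}
    for record in {s.record for s in methylome.sites}:
        rec_sites = sorted((s for s in methylome.sites if s.record == record),
                           key=lambda s: s.position)
        tops = [s for s in rec_sites if s.strand == "top"]
        bottoms = [s for s in rec_sites if s.strand == "bottom"]
        used: set[int] = set()
        ivs = []
        for t in tops:
            for j, b in enumerate(bottoms):
                if j in used or b.motif_id != t.motif_id:
                    continue
                if b.position != t.position and abs(b.position - t.position) <= 8:
                    used.add(j)
                    ivs.append((b.position - cut_distance,
                                t.position + cut_distance + 1))
                    break
        intervals[record] = sorted(ivs)
    return intervals


def _clusters(intervals: list[tuple[int, int]]) -> list[list[tuple[int, int]]]:
    """Group excision intervals into chains of mutually overlapping sites."""
    out: list[list[tuple[int, int]]] = []
    for iv in intervals:
        if out and iv[0] < out[-1][-1][1]:
            out[-1].append(iv)
        else:
            out.append([iv])
    return out


def classify_fragments(fragments: list[FragmentAnnotation],
                       methylome: Methylome,
                       cut_distance: int = CUT_DISTANCE) -> list[FragmentAnnotation]:
    """Assign each fragment one of the six digest categories.

    motif-cleaved: exactly the excision interval of one isolated fully
    methylated site. interstitial: intersects no excision interval and spans
    no unrealized cut. overlap-short / overlap-long: pieces arising from two
    sites whose excision intervals overlap (closer than the excised length,
    i.e. < ~30 bp apart), short when the inter-site cuts were realized, long
    (one merged piece) when not. concatenated: spans an expected but
    unrealized cut. other: >= 3 clustered sites or mixed provenance.
    """
    by_record: dict[str, list[list[tuple[int, int]]]] = {}
    for record, ivs in full_site_intervals(methylome, cut_distance).items():
        by_record[record] = _clusters(ivs)

    for frag in fragments:
        clusters = by_record.get(frag.record, [])
        touching = [cl for cl in clusters
                    if any(iv[0] < frag.end and iv[1] > frag.start for iv in cl)]
        if not touching:
            frag.category = (FragmentCategory.CONCATENATED if frag.missed_cuts
                             else FragmentCategory.INTERSTITIAL)
            continue
        if len(touching) > 1:
            # Spans several separated site clusters: only possible with
            # unrealized cuts in between.
            frag.category = (FragmentCategory.OTHER if len(touching) > 2
                             else FragmentCategory.CONCATENATED)
            continue
        cluster = touching[0]
        span = (cluster[0][0], max(iv[1] for iv in cluster))
        if len(cluster) == 1:
            if (frag.start, frag.end) == span:
                frag.category = FragmentCategory.MOTIF_CLEAVED
            else:
                # Partial overlap with one site's interval: the fragment
                # spans an unrealized cut of that site (or runs off the
                # record end).
                frag.category = (FragmentCategory.CONCATENATED
                                 if frag.missed_cuts else FragmentCategory.OTHER)
            continue
        if len(cluster) == 2:
            if (frag.start, frag.end) == span and frag.missed_cuts:
                frag.category = FragmentCategory.OVERLAP_LONG
            elif frag.start >= span[0] and frag.end <= span[1]:
                frag.category = FragmentCategory.OVERLAP_SHORT
            else:
                frag.category = (FragmentCategory.CONCATENATED
                                 if frag.missed_cuts else FragmentCategory.OTHER)
            continue
        frag.category = FragmentCategory.OTHER
    return fragments


def digest(genome: ReferenceGenome, methylome: Methylome,
           enzymes: Sequence[EnzymeModel],
           classify: bool = True) -> list[FragmentAnnotation]:
    """Theoretical (complete) digest: cuts, fragments, categories."""
    methylome.validate(genome)
    cuts = expected_cuts(genome, methylome, enzymes)
    fragments = fragments_from_cuts(genome, cuts)
    if classify:
        cut_distance = enzymes[0].cut_distance if enzymes else CUT_DISTANCE
        classify_fragments(fragments, methylome, cut_distance)
    return fragments


def classify_read_cutting(read_start: int, read_end: int,
                          fragment: FragmentAnnotation,
                          tolerance: int = 4) -> str:
    """How a mapped read relates to a theoretical fragment's cut sites.

    'exact' = both ends coincide with the expected boundaries; 'approximate'
    = both within ``tolerance`` bp; 'one-cut' = exactly one end within
    tolerance; 'neither' otherwise.
    """
    if read_end <= read_start:
        raise ValueError("read interval is empty or unmapped")
    d_left = abs(read_start - fragment.start)
    d_right = abs(read_end - fragment.end)
    if d_left == 0 and d_right == 0:
        return "exact"
    if d_left <= tolerance and d_right <= tolerance:
        return "approximate"
    if d_left <= tolerance or d_right <= tolerance:
        return "one-cut"
    return "neither"


DISTANCE_BINS = ("-13", "14", "15", "16", "17", "18", "19+")


def bin_distance(d: int) -> str:
    """Report bin for a cleavage distance: <14 -> '-13', >18 -> '19+'."""
    if d < 14:
        return "-13"
    if d > 18:
        return "19+"
    return str(d)


@dataclass(frozen=True)
class CleavageDistances:
    """Distances between a read's motif instance and the read ends.

    ``d1 <= d2`` by convention; ``d_top``/``d_bottom`` preserve which end is
    which (top-strand m5C to 3' end, bottom-strand G to 5' end). A correctly
    cut and trimmed (CCMD) read has d1 = d2 = 16.
    """

    d_top: int
    d_bottom: int

    @property
    def pair(self) -> tuple[int, int]:
        return tuple(sorted((self.d_top, self.d_bottom)))  # type: ignore[return-value]

    @property
    def bins(self) -> tuple[str, str]:
        d1, d2 = self.pair
        return bin_distance(d1), bin_distance(d2)

    def is_ccmd(self) -> bool:
        return self.d_top == 16 and self.d_bottom == 16


def _motif_occurrences(read: str, motif_model: MotifModel) -> list[tuple[int, str]]:
    """(start, orientation) of motif matches in a top-strand-oriented read."""
    motif = motif_model.motif
    rc = reverse_complement(motif)
    n = len(motif)
    hits: list[tuple[int, str]] = []
    for s in range(len(read) - n + 1):
        window = read[s : s + n]
        if iupac_match(window, motif):
            hits.append((s, "fwd"))
        if rc != motif and iupac_match(window, rc):
            hits.append((s, "rev"))
    return hits


def cleavage_distances(read: str, motif_model: MotifModel) -> CleavageDistances | None:
    """(d1,d2) for the motif instance closest to the center of the read.

    Distances count bases strictly between the indicated base and the read
    end. Returns None when the read contains no motif instance (such reads
    are excluded from flank tables).
    """
    read = read.upper()
    hits = _motif_occurrences(read, motif_model)
    if not hits:
        return None
    n = len(motif_model.motif)
    L = len(read)
    center = (L - n) / 2
    s, orient = min(hits, key=lambda h: (abs(h[0] - center), h[0], h[1]))
    if orient == "fwd":
        d_top = L - 1 - (s + motif_model.top_m5c_index)
        d_bottom = s + motif_model.bottom_m5c_index
    else:
        # The read shows the bottom strand; compute on the reverse complement
        # where the motif matches forward at the mirrored position.
        s_rc = L - n - s
        d_top = L - 1 - (s_rc + motif_model.top_m5c_index)
        d_bottom = s_rc + motif_model.bottom_m5c_index
    return CleavageDistances(d_top, d_bottom)
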