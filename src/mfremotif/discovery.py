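"""Column-wise KL-divergence IUPAC consensus calling and the iterative
multi-motif discovery loop.

Reads of one length are stacked into an ungapped alignment. Each column's
base distribution is compared, by Kullback-Leibler divergence, against the
distribution expected under every one of the 15 IUPAC symbols (the genome's
base frequencies restricted to the symbol's allowed bases and renormalized);
the symbol with the smallest divergence is assigned. Leading and trailing
N runs are trimmed, the remaining string is scored for complexity, and
strings scoring >= 10 are candidate motifs. The methylated positions follow
from the read length alone: in a correctly cut read the top-strand m5C is
the 17th base from the 3' end and the G opposite the bottom-strand m5C the
17th from the 5' end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .enzymes import (
    EnzymeModel,
    MotifModel,
    cleavage_distances,
    constrained_site,
    _motif_occurrences,
)
from .filtering import (
    BACKGROUND_RANGE,
    SEARCH_RANGE,
    DiagnosticProfile,
    MappedRead,
    MappedReadSet,
    base_filter,
    candidate_lengths,
    copy_number_filter,
    diagnostics,
)
from .sequence import ReferenceGenome, iupac_match, reverse_complement

__all__ = [
    "SYMBOL_ORDER",
    "KL_EPSILON",
    "ConsensusCaller",
    "Consensus",
    "assign_iupac",
    "call_consensus",
    "complexity_score",
    "per_base_specificity",
    "CandidateMotif",
    "infer_methylated_positions",
    "subtract_motif_reads",
    "DiscoveryConfig",
    "discover_motifs",
    "site_representation",
    "SiteRepresentation",
]

#: Symbols ordered concrete -> 2-base -> 3-base -> N. argmin over this order
#: makes ties resolve toward the most specific, alphabetically first symbol.
SYMBOL_ORDER = "ACGTMRWSYKVHDBN"

_SYMBOL_MASKS = np.zeros((15, 4), dtype=float)
for _i, _code in enumerate(SYMBOL_ORDER):
    from .sequence import IUPAC_SETS as _SETS
    for _j, _b in enumerate("ACGT"):
        if _b in _SETS[_code]:
            _SYMBOL_MASKS[_i, _j] = 1.0

#: Smoothing floor applied to both observed and expected distributions
#: before the divergence is computed. 1e-3 (a per-mille pseudofrequency)
#: keeps the penalty for observed mass on a symbol's forbidden bases strong
#: enough to be discriminative while letting moderately contaminated motif
#: columns (non-CCMD fractions up to ~0.2) still beat the unrestricted N
#: model, which is the regime in which the method is expected to work.
KL_EPSILON = 1e-3

COMPLEXITY_SCORES = {
    **{b: 8 for b in "ACGT"},
    **{b: 4 for b in "RYMKSW"},
    **{b: 2 for b in "HBVD"},
    "N": 0,
}

_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


def _floor_renorm(dist: np.ndarray, eps: float = KL_EPSILON) -> np.ndarray:
    floored = np.maximum(dist, eps)
    return floored / floored.sum(axis=-1, keepdims=True)


class ConsensusCaller:
    """Vectorized per-column IUPAC assignment for a fixed background.

    Precomputes the 15 expected distributions once; ``assign`` then maps an
    (n_columns, 4) count matrix to a symbol string in one matmul.
    """

    def __init__(self, background: dict[str, float], eps: float = KL_EPSILON):
        bg = np.array([background[b] for b in "ACGT"], dtype=float)
        if np.any(bg <= 0) or not np.isclose(bg.sum(), 1.0, atol=1e-6):
            raise ValueError("background frequencies must be positive and sum to 1")
        self.background = bg
        self.eps = eps
        expected = _SYMBOL_MASKS * bg  # restrict, then renormalize
        expected /= expected.sum(axis=1, keepdims=True)
        self._log_expected = np.log(_floor_renorm(expected, eps))

    def assign_columns(self, counts: np.ndarray) -> str:
        """IUPAC symbol per column for an (n_columns, 4) count matrix."""
        counts = np.asarray(counts, dtype=float)
        totals = counts.sum(axis=1, keepdims=True)
        if np.any(totals == 0):
            raise ValueError("empty alignment column")
        obs = _floor_renorm(counts / totals, self.eps)
        # KL(obs || expected_s) = sum obs*log obs - obs @ log expected_s
        self_term = np.sum(obs * np.log(obs), axis=1, keepdims=True)
        kl = self_term - obs @ self._log_expected.T
        best = np.argmin(kl, axis=1)
        return "".join(SYMBOL_ORDER[i] for i in best)


def assign_iupac(column_counts: dict[str, float] | np.ndarray,
                 background: dict[str, float],
                 eps: float = KL_EPSILON) -> str:
    """IUPAC symbol minimizing KL(observed || expected) for one column."""
    if isinstance(column_counts, dict):
        counts = np.array([column_counts.get(b, 0) for b in "ACGT"], dtype=float)
    else:
        counts = np.asarray(column_counts, dtype=float)
    caller = ConsensusCaller(background, eps)
    return caller.assign_columns(counts[None, :])[0]


@dataclass
class Consensus:
    """An N-trimmed consensus string with its placement in the source reads."""

    string: str
    start: int  # 0-based offset of the trimmed string within the reads
    read_length: int
    counts: np.ndarray = field(repr=False, default=None)  # (read_length, 4)

    @property
    def trimmed_pfm(self) -> np.ndarray:
        return self.counts[self.start : self.start + len(self.string)]


def _count_matrix(sequences: list[str], weights: list[int] | None = None
                  ) -> np.ndarray:
    L = len(sequences[0])
    arr = np.frombuffer("".join(sequences).encode(), dtype=np.uint8)
    arr = arr.reshape(len(sequences), L)
    counts = np.zeros((L, 4), dtype=float)
    w = np.asarray(weights, dtype=float) if weights is not None else None
    for b, j in _BASE_INDEX.items():
        mask = arr == ord(b)
        counts[:, j] = (mask * w[:, None]).sum(axis=0) if w is not None \
            else mask.sum(axis=0)
    return counts


def call_consensus(sequences: list[str],
                   background: dict[str, float],
                   weights: list[int] | None = None,
                   eps: float = KL_EPSILON) -> Consensus | None:
    """Per-column consensus of same-length, ungapped reads, N-trimmed.

    Interior N's are retained; only leading/trailing N runs are removed.
    Returns None for an empty bin or an all-N consensus.
    """
    if not sequences:
        return None
    L = len(sequences[0])
    if any(len(s) != L for s in sequences):
        raise ValueError("all reads in a bin must have the same length")
    counts = _count_matrix(sequences, weights)
    caller = ConsensusCaller(background, eps)
    symbols = caller.assign_columns(counts)
    stripped = symbols.strip("N")
    if not stripped:
        return None
    start = len(symbols) - len(symbols.lstrip("N"))
    return Consensus(stripped, start, L, counts)


def complexity_score(symbols: str) -> int:
    """Sum of per-symbol scores after removing all N's, one C and one G.

    ACGT score 8, two-base symbols 4, three-base symbols 2. The removed C
    and G are the freebies guaranteed by base filtering. CCGG scores 16,
    CRYG scores 8, CNNG scores 0; candidates need >= 10.
    """
    symbols = symbols.upper().replace("N", "")
    for freebie in "CG":
        idx = symbols.find(freebie)
        if idx >= 0:
            symbols = symbols[:idx] + symbols[idx + 1:]
    return sum(COMPLEXITY_SCORES[s] for s in symbols)


CANDIDATE_THRESHOLD = 10


def per_base_specificity(symbols: str) -> float:
    """Complexity score per non-N symbol; ranks candidate motifs."""
    non_n = sum(1 for s in symbols if s != "N")
    if non_n == 0:
        return 0.0
    return complexity_score(symbols) / non_n


@dataclass
class CandidateMotif:
    symbols: str
    start: int
    source_length: int
    complexity: int
    specificity: float
    n_unique_reads: int
    n_total_reads: int

    def to_motif_model(self) -> MotifModel:
        top, bottom = infer_methylated_positions(self.start, len(self.symbols),
                                                 self.source_length)
        return MotifModel(self.symbols, top, bottom)


def infer_methylated_positions(motif_start: int, motif_len: int,
                               read_length: int) -> tuple[int, int]:
    """Methylated positions implied by the source read length.

    For a presumed (16,16) read of length L, the top-strand m5C is the 17th
    base from the 3' end (0-based read index L-17) and the bottom-strand
    m5C's paired G the 17th from the 5' end (read index 16); both are
    translated into motif coordinates against ``motif_start``.
    """
    if read_length == 33:
        raise ValueError("no correctly cut read can have length 33 (x = 0)")
    top = (read_length - 17) - motif_start
    bottom = 16 - motif_start
    for name, idx in (("top", top), ("bottom", bottom)):
        if not (0 <= idx < motif_len):
            raise ValueError(
                f"inferred {name} m5C (motif index {idx}) falls outside the "
                f"motif; motif placement inconsistent with read length "
                f"{read_length}"
            )
    return top, bottom


def subtract_motif_reads(readset: MappedReadSet, motif_model: MotifModel) -> int:
    """Remove reads derived from the motif with exact cleavage on >= 1 end.

    A read is removed when any motif instance in it (either orientation) has
    a cleavage distance of exactly 16 on at least one end — i.e. (16,16),
    (x,16) and (16,x) reads, not only (16,16). Returns the number of unique
    reads removed.
    """
    doomed = []
    n = len(motif_model.motif)
    for read in readset:
        L = len(read.sequence)
        for s, orient in _motif_occurrences(read.sequence, motif_model):
            if orient == "fwd":
                d_top = L - 1 - (s + motif_model.top_m5c_index)
                d_bottom = s + motif_model.bottom_m5c_index
            else:
                s_rc = L - n - s
                d_top = L - 1 - (s_rc + motif_model.top_m5c_index)
                d_bottom = s_rc + motif_model.bottom_m5c_index
            if d_top == 16 or d_bottom == 16:
                doomed.append(read.sequence)
                break
    readset.remove(doomed)
    return len(doomed)


@dataclass
class DiscoveryConfig:
    search_range: tuple[int, int] = SEARCH_RANGE
    background_range: tuple[int, int] = BACKGROUND_RANGE
    threshold_multiplier: float = 2.0
    #: Minimum unique reads a length bin needs (after copy-number and base
    #: filtering) before a consensus is called. Random-read simulations show
    #: correct deduction needs a few tens of unique examples, and a
    #: consensus from a handful of reads is spuriously over-specific.
    min_candidate_reads: int = 20
    complexity_threshold: int = CANDIDATE_THRESHOLD
    weight_by_copy_number: bool = False
    max_iterations: int = 20
    eps: float = KL_EPSILON


@dataclass
class DiscoveredMotif:
    model: MotifModel
    candidate: CandidateMotif
    iteration: int


def _length_candidates(readset: MappedReadSet, profile: DiagnosticProfile,
                       background: dict[str, float], config: DiscoveryConfig
                       ) -> list[CandidateMotif]:
    out: list[CandidateMotif] = []
    for L in candidate_lengths(profile, config.threshold_multiplier):
        if L == 33:
            continue  # no correctly cut read can be 33 bp
        bin_reads = copy_number_filter(readset.length_bin(L),
                                       profile.background_redundancy)
        bin_reads = [r for r in bin_reads if base_filter(r.sequence)]
        if len(bin_reads) < config.min_candidate_reads:
            continue
        weights = [r.copy_number for r in bin_reads] \
            if config.weight_by_copy_number else None
        cons = call_consensus([r.sequence for r in bin_reads], background,
                              weights, config.eps)
        if cons is None:
            continue
        score = complexity_score(cons.string)
        if score < config.complexity_threshold:
            continue
        try:
            infer_methylated_positions(cons.start, len(cons.string), L)
        except ValueError:
            continue
        out.append(CandidateMotif(
            symbols=cons.string,
            start=cons.start,
            source_length=L,
            complexity=score,
            specificity=per_base_specificity(cons.string),
            n_unique_reads=len(bin_reads),
            n_total_reads=sum(r.copy_number for r in bin_reads),
        ))
    return out


def discover_motifs(readset: MappedReadSet, genome: ReferenceGenome,
                    config: DiscoveryConfig | None = None
                    ) -> list[DiscoveredMotif]:
    """Iterative multi-motif discovery on a mapped, collapsed read set.

    Background levels are established once from reads in the background
    length range; then, repeatedly: find candidate lengths, copy-number- and
    base-filter each bin, call the consensus, keep candidates with
    complexity >= 10, accept the one with the highest per-base specificity,
    infer its methylated positions from its source length, and delete every
    read with an exactly cleaved instance of it, until no candidates remain.
    A candidate that repeats an accepted motif — its string, or a string
    containing an accepted motif (either orientation) — is discarded:
    double-slipped (17,17) reads of an accepted motif survive subtraction
    (no exactly cleaved end) and would otherwise re-report the motif,
    embedded in a weakly specified consensus, from length l_x+2.
    """
    config = config or DiscoveryConfig()
    readset = readset.copy()  # subtraction must not mutate the caller's set
    background = genome.base_frequencies
    profile = diagnostics(readset, config.search_range, config.background_range)
    accepted: list[DiscoveredMotif] = []
    accepted_strings: set[str] = set()

    def repeats_accepted(symbols: str) -> bool:
        rc = reverse_complement(symbols)
        return any(a in symbols or a in rc for a in accepted_strings)

    for iteration in range(1, config.max_iterations + 1):
        candidates = [
            c for c in _length_candidates(readset, profile, background, config)
            if not repeats_accepted(c.symbols)
        ]
        valid = []
        for c in candidates:
            try:
                c.to_motif_model()
            except ValueError:
                continue
            valid.append(c)
        if not valid:
            break
        best = max(valid, key=lambda c: (c.specificity, c.complexity,
                                         -len(c.symbols), c.symbols))
        model = best.to_motif_model()
        accepted.append(DiscoveredMotif(model, best, iteration))
        accepted_strings.add(best.symbols)
        removed = subtract_motif_reads(readset, model)
        # Refresh per-length metrics on the reduced set; background levels
        # stay fixed from the initial profile.
        new_profile = diagnostics(readset, config.search_range,
                                  config.background_range)
        profile = DiagnosticProfile(
            table=new_profile.table,
            background_n_reads=profile.background_n_reads,
            background_redundancy=profile.background_redundancy,
            background_base_filter=profile.background_base_filter,
            search_range=config.search_range,
            background_range=config.background_range,
        )
        if removed == 0:
            break
    return accepted


@dataclass
class SiteRepresentation:
    """Fraction of genomic motif instances supported by correctly cut reads."""

    motif: str
    detected: int
    total: int
    constrained_motif: str | None = None
    constrained_detected: int | None = None
    constrained_total: int | None = None

    @property
    def fraction(self) -> float:
        return self.detected / self.total if self.total else 0.0

    @property
    def constrained_fraction(self) -> float | None:
        if self.constrained_total is None:
            return None
        return (self.constrained_detected / self.constrained_total
                if self.constrained_total else 0.0)


def _genome_instances(genome: ReferenceGenome, pattern: str) -> list[tuple[str, int]]:
    """Top-strand occurrences of a pattern; for non-palindromic patterns the
    reverse-complement occurrences are included as well (reported at their
    top-strand start)."""
    rc = reverse_complement(pattern)
    patterns = [pattern] if rc == pattern else [pattern, rc]
    hits = []
    n = len(pattern)
    for name, seq in genome.records:
        for pat in patterns:
            for s in range(len(seq) - n + 1):
                if "N" not in seq[s:s + n] and iupac_match(seq[s:s + n], pat):
                    hits.append((name, s))
    return sorted(set(hits))


def site_representation(genome: ReferenceGenome, motif_model: MotifModel,
                        readset: MappedReadSet,
                        enzyme: EnzymeModel | None = None,
                        read_classes: frozenset[tuple[int, int]] = frozenset({(16, 16)}),
                        ) -> SiteRepresentation:
    """Per-site detection report for a discovered motif.

    A genomic instance counts as detected when at least one read whose
    cleavage-distance pair is in ``read_classes`` (default (16,16) only;
    (16,17)/(15,16) can be added) covers it at the matching offset.
    Multi-mapping reads credit all of their loci.
    """
    motif = motif_model.motif
    instances = set(_genome_instances(genome, motif))
    detected: set[tuple[str, int]] = set()
    n = len(motif)
    for read in readset:
        dist = cleavage_distances(read.sequence, motif_model)
        if dist is None or dist.pair not in read_classes:
            continue
        for s, orient in _motif_occurrences(read.sequence, motif_model):
            for locus in read.loci:
                if locus.strand == "+":
                    g = locus.start + s
                else:
                    g = locus.start + (len(read.sequence) - n - s)
                if (locus.record, g) in instances:
                    detected.add((locus.record, g))
    result = SiteRepresentation(motif, len(detected), len(instances))
    if enzyme is not None:
        constrained = constrained_site(motif_model, enzyme)
        offset = constrained.index(motif) if motif in constrained else None
        c_instances = set(_genome_instances(genome, constrained))
        if offset is not None:
            # Constrained instances reported at the coordinate of the core
            # motif so they can be intersected with detections.
            c_cores = {(rec, s + offset) for rec, s in c_instances}
        else:
            c_cores = c_instances
        result.constrained_motif = constrained
        result.constrained_total = len(c_cores)
        result.constrained_detected = len(c_cores & detected)
    return result
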