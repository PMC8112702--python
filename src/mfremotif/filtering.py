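"""Read filtering: reference matching, deduplication, size/base filters,
and the per-length diagnostic profile used to pick candidate read lengths.

Three filters enrich for correctly cut, methyl-derived (CCMD) reads:

* reference filter — keep reads that match the reference exactly (no
  mismatches, no gaps) on either strand, oriented to the top strand;
* size filter — keep lengths in the search range (default 26-40 bp, the
  possible correctly-cut lengths for motifs up to 8 bp); lengths 41-80 bp
  serve as background;
* base filter — keep reads with a C as the 17th base from the 3' end and a
  G as the 17th base from the 5' end, the invariant positions of the two
  strands' m5C in a correctly cut read. About 1 read in 16 passes by chance
  in random 50% G+C sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .sequence import ReferenceGenome, reverse_complement

__all__ = [
    "Locus",
    "MappedRead",
    "MappedReadSet",
    "reference_filter",
    "base_filter",
    "size_filter",
    "DiagnosticProfile",
    "diagnostics",
    "candidate_lengths",
    "copy_number_filter",
    "analytic_base_filter_rate",
    "SEARCH_RANGE",
    "BACKGROUND_RANGE",
]

SEARCH_RANGE = (26, 40)
BACKGROUND_RANGE = (41, 80)
MIN_INDEX_K = 20  # shortest read length the exact-match index supports


@dataclass(frozen=True)
class Locus:
    record: str
    start: int
    strand: str  # '+' if the stored (top-strand) sequence matches forward


@dataclass
class MappedRead:
    sequence: str  # oriented to the reference top strand
    copy_number: int
    loci: tuple[Locus, ...]

    @property
    def multi_mapping(self) -> bool:
        return len(self.loci) > 1

    def __len__(self) -> int:
        return len(self.sequence)


class MappedReadSet:
    """Unique, top-strand-oriented, exactly mapped reads with copy counts."""

    def __init__(self, reads: Iterable[MappedRead] = ()):
        self.reads: dict[str, MappedRead] = {}
        for r in reads:
            self.add(r)

    def add(self, read: MappedRead) -> None:
        existing = self.reads.get(read.sequence)
        if existing is None:
            self.reads[read.sequence] = read
        else:
            existing.copy_number += read.copy_number

    def remove(self, sequences: Iterable[str]) -> None:
        for s in sequences:
            self.reads.pop(s, None)

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads.values())

    def total_reads(self) -> int:
        return sum(r.copy_number for r in self.reads.values())

    def by_length(self) -> dict[int, list[MappedRead]]:
        bins: dict[int, list[MappedRead]] = {}
        for r in self.reads.values():
            bins.setdefault(len(r.sequence), []).append(r)
        return bins

    def length_bin(self, length: int) -> list[MappedRead]:
        return [r for r in self.reads.values() if len(r.sequence) == length]

    def subset(self, sequences: Iterable[str]) -> "MappedReadSet":
        out = MappedReadSet()
        for s in sequences:
            if s in self.reads:
                out.reads[s] = self.reads[s]
        return out

    def copy(self) -> "MappedReadSet":
        """Shallow copy: reads are shared, membership is independent."""
        out = MappedReadSet()
        out.reads = dict(self.reads)
        return out


def _kmer_index(genome: ReferenceGenome, k: int) -> dict[str, list[tuple[str, int]]]:
    index: dict[str, list[tuple[str, int]]] = {}
    for name, seq in genome.records:
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i : i + k], []).append((name, i))
    return index


def reference_filter(reads: Iterable[str], genome: ReferenceGenome,
                     min_length: int = MIN_INDEX_K,
                     max_length: int = 80) -> tuple[MappedReadSet, int]:
    """Exact-match mapping of reads to the reference, both strands.

    Returns the collapsed, top-strand-oriented read set and the number of
    raw reads discarded (non-matching or out of the length window). A read
    matching only the reverse strand is stored as its reverse complement;
    a read matching both strands (palindromic or repeat-straddling) is
    stored as the lexicographically smaller of the two forms, with strand
    recorded per locus. All exact-match loci are recorded; multi-mapping
    reads carry a flag and every locus.
    """
    if genome.total_length() == 0:
        raise ValueError("empty reference")
    # Collapse raw reads first; mapping then runs once per unique sequence.
    raw_counts: dict[str, int] = {}
    discarded = 0
    for read in reads:
        read = read.upper()
        if not (min_length <= len(read) <= max_length) or "N" in read:
            discarded += 1
            continue
        raw_counts[read] = raw_counts.get(read, 0) + 1

    k = min([min_length] + [len(s) for s in raw_counts]) if raw_counts else min_length
    index = _kmer_index(genome, k)
    sequences = {name: seq for name, seq in genome.records}

    def find_loci(seq: str) -> list[tuple[str, int]]:
        hits = []
        for name, i in index.get(seq[:k], ()):
            if sequences[name][i : i + len(seq)] == seq:
                hits.append((name, i))
        return hits

    out = MappedReadSet()
    for seq, count in raw_counts.items():
        fwd = find_loci(seq)
        rc = reverse_complement(seq)
        rev = find_loci(rc) if rc != seq else []
        if not fwd and not rev:
            discarded += count
            continue
        if fwd and not rev:
            stored, loci = seq, [Locus(n, i, "+") for n, i in fwd]
        elif rev and not fwd:
            # rc matches the top strand: the top-strand rendering of the
            # read is rc itself.
            stored, loci = rc, [Locus(n, i, "-") for n, i in rev]
        else:
            stored = min(seq, rc)
            f_strand, r_strand = ("+", "-") if stored == seq else ("-", "+")
            loci = [Locus(n, i, f_strand) for n, i in fwd] + \
                   [Locus(n, i, r_strand) for n, i in rev]
        out.add(MappedRead(stored, count, tuple(loci)))
    return out, discarded


def base_filter(read: str) -> bool:
    """C as the 17th base from the 3' end and G as the 17th from the 5' end.

    Reads shorter than 17 cannot host both positions; a 33-base read has the
    two positions coincide and can never pass (consistent with l_x != 33).
    """
    L = len(read)
    if L < 17:
        return False
    i3 = L - 17  # 17th base from the 3' end, 0-based
    i5 = 16      # 17th base from the 5' end
    if i3 == i5:
        return False
    return read[i3] == "C" and read[i5] == "G"


def analytic_base_filter_rate(base_frequencies: Mapping[str, float]) -> float:
    """Expected pass fraction of i.i.d. reads: P(C) * P(G)."""
    return base_frequencies["C"] * base_frequencies["G"]


def size_filter(readset: MappedReadSet,
                search_range: tuple[int, int] = SEARCH_RANGE,
                background_range: tuple[int, int] = BACKGROUND_RANGE,
                ) -> tuple[MappedReadSet, MappedReadSet]:
    """Partition reads by length into search and background sets."""
    s_lo, s_hi = search_range
    b_lo, b_hi = background_range
    if s_lo > s_hi or b_lo > b_hi or not (s_hi < b_lo or b_hi < s_lo):
        raise ValueError("search and background ranges must be disjoint")
    search, background = MappedReadSet(), MappedReadSet()
    for r in readset:
        L = len(r.sequence)
        if s_lo <= L <= s_hi:
            search.reads[r.sequence] = r
        elif b_lo <= L <= b_hi:
            background.reads[r.sequence] = r
    return search, background


@dataclass
class DiagnosticProfile:
    """Per-length read metrics and their background means.

    ``table`` has one row per length: n_reads (copy-weighted), n_unique,
    mean_redundancy (= n_reads / n_unique), base_filter_fraction (fraction
    of unique reads passing the base filter). Background values are the
    unweighted means of each per-length metric over the background range.
    """

    table: pd.DataFrame
    background_n_reads: float
    background_redundancy: float
    background_base_filter: float
    search_range: tuple[int, int] = SEARCH_RANGE
    background_range: tuple[int, int] = BACKGROUND_RANGE

    def metrics(self, length: int) -> tuple[float, float, float]:
        if length not in self.table.index:
            return (0.0, 0.0, 0.0)
        row = self.table.loc[length]
        return (row["n_reads"], row["mean_redundancy"], row["base_filter_fraction"])


def diagnostics(readset: MappedReadSet,
                search_range: tuple[int, int] = SEARCH_RANGE,
                background_range: tuple[int, int] = BACKGROUND_RANGE,
                ) -> DiagnosticProfile:
    rows = []
    for L, reads in sorted(readset.by_length().items()):
        n_reads = sum(r.copy_number for r in reads)
        n_unique = len(reads)
        passed = sum(1 for r in reads if base_filter(r.sequence))
        rows.append({
            "length": L,
            "n_reads": n_reads,
            "n_unique": n_unique,
            "mean_redundancy": n_reads / n_unique if n_unique else 0.0,
            "base_filter_fraction": passed / n_unique if n_unique else 0.0,
        })
    table = pd.DataFrame(rows).set_index("length") if rows else pd.DataFrame(
        columns=["n_reads", "n_unique", "mean_redundancy", "base_filter_fraction"])
    b_lo, b_hi = background_range
    if b_lo > b_hi:
        raise ValueError("empty background range")
    bg = table[(table.index >= b_lo) & (table.index <= b_hi)]
    # Unweighted mean over lengths; absent lengths contribute nothing.
    return DiagnosticProfile(
        table=table,
        background_n_reads=float(bg["n_reads"].mean()) if len(bg) else 0.0,
        background_redundancy=float(bg["mean_redundancy"].mean()) if len(bg) else 0.0,
        background_base_filter=float(bg["base_filter_fraction"].mean()) if len(bg) else 0.0,
        search_range=search_range,
        background_range=background_range,
    )


def candidate_lengths(profile: DiagnosticProfile,
                      threshold_multiplier: float = 2.0) -> list[int]:
    """Search-range lengths where any diagnostic metric exceeds
    ``threshold_multiplier`` times its background mean."""
    s_lo, s_hi = profile.search_range
    out = []
    for L in profile.table.index:
        if not (s_lo <= L <= s_hi):
            continue
        n, red, bf = profile.metrics(L)
        if (n > threshold_multiplier * profile.background_n_reads
                or red > threshold_multiplier * profile.background_redundancy
                or bf > threshold_multiplier * profile.background_base_filter):
            out.append(int(L))
    return out


def copy_number_filter(reads: Sequence[MappedRead],
                       background_redundancy: float) -> list[MappedRead]:
    """Drop reads with copy number at or below the background redundancy."""
    return [r for r in reads if r.copy_number > background_redundancy]
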