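"""Deconvolution of composite (degenerate) apparent motifs.

A degenerate consensus can reflect genuine tolerance of the
methyltransferase, or the inappropriate merging of independent substrate
sequences: two separate motifs, the two strands of one non-palindromic
motif, or base-dependent variants of one site. These are told apart by the
frequencies of the non-degenerate instances of the apparent motif among
base-filtered reads of the source length: merged cases leave some instances
unsupported, true degeneracy supports all of them at similar frequency.

This module also strips enzyme-constraint bases that over-specify a motif:
an MFRE's own context requirement shows up as extra called bases around the
methyltransferase motif (GATC digested by MspJI is called as YNNGATCNNR).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import pandas as pd

from .enzymes import EnzymeModel, IncompatibleMotifError, MotifModel, constrained_site
from .filtering import MappedRead
from .sequence import (
    IUPAC_SETS,
    ReferenceGenome,
    expand_degenerate,
    is_palindrome,
    reverse_complement,
)

__all__ = [
    "InstanceFrequencyTable",
    "instance_frequencies",
    "DegeneracyClass",
    "DegeneracyVerdict",
    "classify_degeneracy",
    "trim_enzyme_constraint",
]

MAX_INSTANCES = 4096  # guard against exploding an all-N pattern


@dataclass
class InstanceFrequencyTable:
    """Support for each non-degenerate instance of an apparent motif.

    ``table`` rows: instance, read_count (reads of the source length with
    the instance at the expected motif offset), genome_sites (top-strand
    occurrences), read_fraction (share of motif-bearing reads).
    """

    apparent: str
    table: pd.DataFrame
    source_length: int

    def counts(self) -> dict[str, int]:
        return dict(zip(self.table["instance"], self.table["read_count"]))


def instance_frequencies(motif_model: MotifModel,
                         read_bin: list[MappedRead],
                         genome: ReferenceGenome | None = None,
                         ) -> InstanceFrequencyTable:
    """Count each concrete instance at the motif's expected read offset.

    Reads are top-strand oriented but derive from either strand of the
    site, so a non-palindromic source shows up as both the instance and its
    reverse complement — which is exactly the signal the classifier uses.
    """
    apparent = motif_model.motif
    cardinality = 1
    for sym in apparent:
        cardinality *= len(IUPAC_SETS[sym])
    if cardinality > MAX_INSTANCES:
        raise ValueError(
            f"{apparent} expands to {cardinality} instances (limit {MAX_INSTANCES})")
    instances = sorted(expand_degenerate(apparent))
    L = motif_model.ccmd_len
    s0 = motif_model.ccmd_motif_start()
    counts = {inst: 0 for inst in instances}
    n = len(apparent)
    for read in read_bin:
        if len(read.sequence) != L:
            continue
        window = read.sequence[s0 : s0 + n]
        if window in counts:
            counts[window] += 1
    total = sum(counts.values())
    rows = []
    for inst in instances:
        genome_sites = None
        if genome is not None:
            genome_sites = sum(
                seq.count(inst) for _, seq in genome.records
            )
        rows.append({
            "instance": inst,
            "read_count": counts[inst],
            "genome_sites": genome_sites,
            "read_fraction": counts[inst] / total if total else 0.0,
        })
    return InstanceFrequencyTable(apparent, pd.DataFrame(rows), L)


class DegeneracyClass(enum.Enum):
    MULTIPLE_MOTIFS = "multiple_motifs"
    NON_PALINDROMIC_PAIR = "non_palindromic_pair"
    BASE_DEPENDENCY = "base_dependency"
    TRUE_DEGENERACY = "true_degeneracy"


@dataclass
class DegeneracyVerdict:
    category: DegeneracyClass
    resolved_motifs: list[str]
    survivors: list[str]
    apparent: str


def _varying_block(survivors: list[str]) -> tuple[int, int]:
    """[first, last] index range over which the survivors differ."""
    n = len(survivors[0])
    varying = [i for i in range(n) if len({s[i] for s in survivors}) > 1]
    return varying[0], varying[-1]


def classify_degeneracy(table: InstanceFrequencyTable,
                        min_fraction: float = 0.1,
                        similar_ratio: float = 4.0) -> DegeneracyVerdict:
    """Resolve a degenerate apparent motif from its instance frequencies.

    Instances with read support below ``min_fraction`` of the top instance
    are deemed absent. If every instance survives at similar frequency
    (max/min <= ``similar_ratio``) the degeneracy is genuine. Survivors
    forming a strand pair {s, revcomp(s)} indicate one non-palindromic
    motif. Several palindromic survivors indicate either multiple motifs or
    base dependency within one motif; the two are frequency-indistinguishable,
    so we label base_dependency when the survivors share at least two fixed
    bases flanking the varying block on each side, multiple_motifs otherwise.
    """
    counts = table.counts()
    if not counts or max(counts.values()) == 0:
        raise ValueError("no instance of the apparent motif has read support")
    top = max(counts.values())
    survivors = sorted(inst for inst, c in counts.items()
                       if c >= min_fraction * top)
    if not survivors:
        raise ValueError("empty survivor set")
    apparent = table.apparent

    if len(survivors) == len(counts):
        supported = [c for c in counts.values() if c > 0]
        if len(supported) == len(counts) and max(supported) <= similar_ratio * min(supported):
            return DegeneracyVerdict(DegeneracyClass.TRUE_DEGENERACY,
                                     [apparent], survivors, apparent)

    if len(survivors) == 1:
        return DegeneracyVerdict(DegeneracyClass.MULTIPLE_MOTIFS,
                                 survivors, survivors, apparent)

    if len(survivors) == 2:
        a, b = survivors
        if a == reverse_complement(b) and not is_palindrome(a):
            return DegeneracyVerdict(DegeneracyClass.NON_PALINDROMIC_PAIR,
                                     [a, b], survivors, apparent)

    if all(is_palindrome(s) for s in survivors):
        first, last = _varying_block(survivors)
        n = len(apparent)
        linked_frame = first >= 2 and (n - 1 - last) >= 2
        category = (DegeneracyClass.BASE_DEPENDENCY if linked_frame
                    else DegeneracyClass.MULTIPLE_MOTIFS)
        return DegeneracyVerdict(category, survivors, survivors, apparent)

    return DegeneracyVerdict(DegeneracyClass.BASE_DEPENDENCY,
                             survivors, survivors, apparent)


def trim_enzyme_constraint(motif_model: MotifModel,
                           enzymes: list[EnzymeModel]) -> MotifModel:
    """Strip flanking bases that merely restate an enzyme's context.

    Tries every left/right trim of the apparent motif; if re-applying an
    enzyme's context to the trimmed core reconstructs the apparent motif
    exactly, the most-trimmed such core is returned (YNNGATCNNR under MspJI
    becomes GATC). Idempotent; returns the input unchanged when no trim
    reconstructs it.
    """
    apparent = motif_model.motif
    n = len(apparent)
    best = motif_model
    best_trim = 0
    for lt in range(0, n - 1):
        for rt in range(0, n - lt - 1):
            if lt + rt <= best_trim or lt + rt == 0:
                continue
            top = motif_model.top_m5c_index - lt
            bottom = motif_model.bottom_m5c_index - lt
            core = apparent[lt : n - rt]
            try:
                core_model = MotifModel(core, top, bottom)
            except ValueError:
                continue
            for enzyme in enzymes:
                try:
                    reconstructed = constrained_site(core_model, enzyme)
                except IncompatibleMotifError:
                    continue
                # The reconstruction must restore exactly the trimmed flanks.
                if len(reconstructed) == n and reconstructed == apparent:
                    best = core_model
                    best_trim = lt + rt
                    break
    return best
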