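"""Core sequence types and IUPAC algebra.

Everything downstream (digest geometry, filtering, consensus calling)
works on plain upper-case strings over the 15-letter IUPAC DNA alphabet.
Coordinates are 0-based half-open internally; report writers convert to
1-based inclusive.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

__all__ = [
    "IUPAC_SETS",
    "IUPAC_COMPLEMENT",
    "set_to_code",
    "reverse_complement",
    "iupac_match",
    "expand_degenerate",
    "is_palindrome",
    "ReferenceGenome",
    "read_fasta",
    "read_reads",
    "write_fasta",
]

#: IUPAC code -> allowed concrete bases (frozensets so they can key dicts).
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "M": frozenset("AC"),
    "R": frozenset("AG"),
    "W": frozenset("AT"),
    "S": frozenset("CG"),
    "Y": frozenset("CT"),
    "K": frozenset("GT"),
    "V": frozenset("ACG"),
    "H": frozenset("ACT"),
    "D": frozenset("AGT"),
    "B": frozenset("CGT"),
    "N": frozenset("ACGT"),
}

_BASE_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

_SET_TO_CODE = {bases: code for code, bases in IUPAC_SETS.items()}

#: IUPAC code -> code of the complemented base set.
IUPAC_COMPLEMENT: dict[str, str] = {
    code: _SET_TO_CODE[frozenset(_BASE_COMPLEMENT[b] for b in bases)]
    for code, bases in IUPAC_SETS.items()
}


def set_to_code(bases: Iterable[str]) -> str:
    """Return the IUPAC code for a nonempty subset of {A,C,G,T}."""
    key = frozenset(bases)
    try:
        return _SET_TO_CODE[key]
    except KeyError:
        raise ValueError(f"not a valid IUPAC base set: {sorted(key)}") from None


def _validate(seq: str) -> None:
    bad = set(seq) - IUPAC_SETS.keys()
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC string (involution)."""
    seq = seq.upper()
    _validate(seq)
    return "".join(IUPAC_COMPLEMENT[c] for c in reversed(seq))


def iupac_match(seq: str, pattern: str) -> bool:
    """True iff every base of ``seq`` is allowed by the aligned ``pattern`` symbol.

    ``seq`` may itself be degenerate, in which case containment is required
    (every base allowed by the seq symbol must be allowed by the pattern
    symbol); for concrete sequences this is plain membership.
    """
    seq, pattern = seq.upper(), pattern.upper()
    if len(seq) != len(pattern):
        raise ValueError(f"length mismatch: {len(seq)} vs {len(pattern)}")
    _validate(seq)
    _validate(pattern)
    return all(IUPAC_SETS[s] <= IUPAC_SETS[p] for s, p in zip(seq, pattern))


def expand_degenerate(pattern: str) -> set[str]:
    """All concrete DNA instances of a degenerate pattern.

    Cardinality is the product of allowed-set sizes, so callers should guard
    against highly degenerate patterns (an all-N 8-mer has 65,536 instances).
    """
    pattern = pattern.upper()
    _validate(pattern)
    return {
        "".join(combo)
        for combo in product(*(sorted(IUPAC_SETS[c]) for c in pattern))
    }


def is_palindrome(seq: str) -> bool:
    """True iff the IUPAC string equals its own reverse complement."""
    return seq.upper() == reverse_complement(seq)


@dataclass
class ReferenceGenome:
    """Named reference sequences plus overall base frequencies.

    The base composition (computed over both strands is unnecessary: A/T and
    C/G are symmetric only per strand, so we report top-strand fractions,
    which is what the consensus caller needs as its null model). N bases are
    excluded from the tally.
    """

    records: list[tuple[str, str]]
    _freqs: dict[str, float] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("reference must contain at least one record")
        cleaned = []
        for name, seq in self.records:
            seq = seq.upper()
            if not seq:
                raise ValueError(f"record {name!r} has an empty sequence")
            bad = set(seq) - set("ACGTN")
            if bad:
                raise ValueError(f"record {name!r} has non-ACGTN bases: {sorted(bad)}")
            cleaned.append((name, seq))
        self.records = cleaned

    @property
    def base_frequencies(self) -> dict[str, float]:
        if self._freqs is None:
            counts = {b: 0 for b in "ACGT"}
            for _, seq in self.records:
                for b in "ACGT":
                    counts[b] += seq.count(b)
            total = sum(counts.values())
            if total == 0:
                raise ValueError("reference contains no unambiguous bases")
            self._freqs = {b: counts[b] / total for b in "ACGT"}
        return self._freqs

    def __getitem__(self, name: str) -> str:
        for rec, seq in self.records:
            if rec == name:
                return seq
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.records]

    def total_length(self) -> int:
        return sum(len(seq) for _, seq in self.records)


def _open_maybe_gzip(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path: str | Path) -> ReferenceGenome:
    """Load a multi-record FASTA reference (gzip transparent)."""
    with _open_maybe_gzip(path) as handle:
        records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(handle, "fasta")]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return ReferenceGenome(records)


def read_reads(path: str | Path, fmt: str | None = None) -> Iterator[str]:
    """Yield read sequences from FASTA or FASTQ (qualities ignored).

    Format is sniffed from the extension unless given explicitly.
    """
    path = Path(path)
    if fmt is None:
        stem = path.name[:-3] if path.suffix == ".gz" else path.name
        fmt = "fastq" if stem.endswith((".fastq", ".fq")) else "fasta"
    with _open_maybe_gzip(path) as handle:
        for rec in SeqIO.parse(handle, fmt):
            yield str(rec.seq).upper()


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    with open(path, "w") as out:
        for name, seq in records:
            out.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                out.write(seq[i : i + 70] + "\n")
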