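"""Synthetic data generation: mock read sets, the minimum-read experiment,
and full genome + methylome + digest fixtures with realistic imperfection.

Two families of simulation live here:

* the *minimal-examples* experiment — purely in-silico correctly-cut reads
  (motif centered per the cleavage geometry, random flanks at a chosen G+C)
  mixed with a controlled fraction of non-CCMD reads, fed one read at a
  time to the consensus caller to measure how many unique examples are
  needed before the motif is deduced correctly and stably;
* genome fixtures — a random reference with planted, (partially) methylated
  motif instances, digested in silico with per-end cleavage slippage,
  incomplete digestion, background reads and a geometric read-duplication
  model, together with a truth manifest, for end-to-end pipeline tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .discovery import KL_EPSILON, ConsensusCaller, _count_matrix
from .enzymes import (
    GENERIC_MFRE,
    Cut,
    EnzymeModel,
    Methylome,
    MotifModel,
    expected_cuts,
    fragments_from_cuts,
)
from .sequence import (
    IUPAC_COMPLEMENT,
    IUPAC_SETS,
    ReferenceGenome,
    is_palindrome,
    reverse_complement,
    write_fasta,
)

__all__ = [
    "gc_background",
    "gen_ccmd_reads",
    "gen_nonccmd_reads",
    "MinReadsResult",
    "min_reads_experiment",
    "min_reads_grid",
    "random_palindromic_motif",
    "FixtureConfig",
    "FixtureTruthSet",
    "gen_genome_fixture",
]


def gc_background(gc: float) -> dict[str, float]:
    """Base frequencies of an i.i.d. sequence with the given G+C fraction."""
    if not 0 < gc < 1:
        raise ValueError("gc must be in (0, 1)")
    return {"A": (1 - gc) / 2, "C": gc / 2, "G": gc / 2, "T": (1 - gc) / 2}


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    bg = gc_background(gc)
    probs = [bg[b] for b in "ACGT"]
    return "".join(rng.choice(list("ACGT"), size=n, p=probs))


def _concrete_instance(rng: np.random.Generator, motif: str) -> str:
    """Resolve degenerate positions uniformly among permitted bases."""
    return "".join(
        c if len(IUPAC_SETS[c]) == 1 else rng.choice(sorted(IUPAC_SETS[c]))
        for c in motif
    )


def gen_ccmd_reads(motif_model: MotifModel, n: int, gc: float,
                   rng: np.random.Generator) -> list[str]:
    """Mock correctly cut (16,16) reads: motif at its geometric position,
    i.i.d. flanks at the given G+C, degenerate positions drawn uniformly."""
    if n < 1:
        raise ValueError("n must be >= 1")
    L = motif_model.ccmd_len
    s0 = motif_model.ccmd_motif_start()
    m = len(motif_model.motif)
    reads = []
    for _ in range(n):
        inst = _concrete_instance(rng, motif_model.motif)
        left = _random_bases(rng, s0, gc)
        right = _random_bases(rng, L - s0 - m, gc)
        reads.append(left + inst + right)
    return reads


def gen_nonccmd_reads(motif_model: MotifModel, n: int, gc: float,
                      rng: np.random.Generator) -> list[str]:
    """Length-matched random reads with only the base-filter C/G forced."""
    if n < 1:
        raise ValueError("n must be >= 1")
    L = motif_model.ccmd_len
    reads = []
    for _ in range(n):
        seq = list(_random_bases(rng, L, gc))
        seq[L - 17] = "C"  # 17th from the 3' end
        seq[16] = "G"      # 17th from the 5' end
        reads.append("".join(seq))
    return reads


@dataclass
class MinReadsResult:
    """Outcome of the incremental minimum-read experiment.

    ``largest_incorrect`` per replicate is the largest set size ``a`` whose
    call was wrong while sizes a+1 .. a+window were all right; the minimum
    sufficient set is a+1. Replicates that never stabilize within
    ``max_reads`` report None and make the experiment not determinable.
    """

    largest_incorrect: list[int | None]
    window: int
    max_reads: int
    gc: float
    non_ccmd_fraction: float

    @property
    def determinable(self) -> bool:
        return all(a is not None for a in self.largest_incorrect)

    @property
    def min_sufficient(self) -> list[int | None]:
        return [None if a is None else a + 1 for a in self.largest_incorrect]

    @property
    def mean_min_sufficient(self) -> float | None:
        if not self.determinable:
            return None
        return float(np.mean([a + 1 for a in self.largest_incorrect]))


def _non_ccmd_schedule(i: int, fraction: float) -> bool:
    """Deterministic round-robin: read i (1-based) is non-CCMD iff the
    running count of non-CCMD reads must increase to keep every prefix at
    the target fraction."""
    import math
    return math.floor(i * fraction) > math.floor((i - 1) * fraction)


def min_reads_experiment(motif_model: MotifModel, gc: float,
                         non_ccmd_fraction: float,
                         replicates: int = 25,
                         stability_window: int = 50,
                         max_reads: int = 100_000,
                         seed: int | np.random.Generator = 0,
                         eps: float = KL_EPSILON) -> MinReadsResult:
    """Incremental largest-incorrect-set experiment for one condition.

    Reads are added one at a time (CCMD and non-CCMD interleaved
    deterministically at the target fraction); after each addition the
    KL-divergence consensus caller runs on the whole set, and the call is
    correct when the N-trimmed consensus equals the planted motif at its
    geometric position. Per replicate, the experiment stops once
    ``stability_window`` consecutive sizes have all been correct; the last
    incorrect size is recorded.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    caller = ConsensusCaller(gc_background(gc), eps)
    L = motif_model.ccmd_len
    s0 = motif_model.ccmd_motif_start()
    motif = motif_model.motif
    m = len(motif)
    results: list[int | None] = []
    base_idx = {b: i for i, b in enumerate("ACGT")}
    for _ in range(replicates):
        counts = np.zeros((L, 4), dtype=float)
        seen: set[str] = set()
        last_incorrect = 0
        size = 0
        stabilized = False
        while size < max_reads:
            want_non_ccmd = _non_ccmd_schedule(size + 1, non_ccmd_fraction)
            while True:
                read = (gen_nonccmd_reads(motif_model, 1, gc, rng)[0]
                        if want_non_ccmd
                        else gen_ccmd_reads(motif_model, 1, gc, rng)[0])
                if read not in seen:  # unique reads only
                    seen.add(read)
                    break
            size += 1
            for j, b in enumerate(read):
                counts[j, base_idx[b]] += 1
            symbols = caller.assign_columns(counts)
            stripped = symbols.strip("N")
            start = len(symbols) - len(symbols.lstrip("N"))
            correct = stripped == motif and start == s0
            if not correct:
                last_incorrect = size
            elif size - last_incorrect >= stability_window:
                stabilized = True
                break
        results.append(last_incorrect if stabilized else None)
    return MinReadsResult(results, stability_window, max_reads, gc,
                          non_ccmd_fraction)


def min_reads_grid(motif_model: MotifModel,
                   gc_values: Sequence[float],
                   fractions: Sequence[float],
                   replicates: int = 25,
                   stability_window: int = 50,
                   max_reads: int = 100_000,
                   seed: int = 0) -> dict[tuple[float, float], MinReadsResult]:
    """The experiment over a (G+C, non-CCMD fraction) grid."""
    rng = np.random.default_rng(seed)
    out = {}
    for gc in gc_values:
        for f in fractions:
            out[(gc, f)] = min_reads_experiment(
                motif_model, gc, f, replicates, stability_window, max_reads,
                rng)
    return out


def random_palindromic_motif(rng: np.random.Generator,
                             min_len: int = 4, max_len: int = 8) -> MotifModel:
    """A random palindromic motif model with |x| <= 7.

    Odd lengths get a self-complementary (W or S) center; the methylated C
    is placed at a random non-central position, its mirror G forced.
    """
    n = int(rng.integers(min_len, max_len + 1))
    half = n // 2
    left = [str(rng.choice(list("ACGT"))) for _ in range(half)]
    top = int(rng.choice([i for i in range(n) if i != n - 1 - i]))
    mirror = n - 1 - top
    if top < half:
        left[top] = "C"
    else:
        left[mirror] = "G"
    symbols = left + ([str(rng.choice(["W", "S"]))] if n % 2 else [])
    symbols = symbols + [IUPAC_COMPLEMENT[c] for c in reversed(left)]
    motif = "".join(symbols)
    assert is_palindrome(motif)
    return MotifModel(motif, top, mirror)


@dataclass
class FixtureConfig:
    """Study conditions for a full end-to-end fixture.

    Defaults emulate the imperfections seen in real MFRE digests: ~25% of
    cut ends land 1 bp farther from the m5C than expected, with a small
    minority 1 bp short; read families are duplicated with geometric copy
    counts (methyl-derived fragments amplify far above the background, as
    in the observed redundancy of ~245 at the correctly cut length versus
    ~13 in the background).
    """

    genome_length: int = 100_000
    gc: float = 0.5
    sites_per_motif: int = 150
    methylation_fraction: float = 1.0  # fully methylated probability per site
    hemi_fraction: float = 0.0         # of the remaining sites
    slip_plus_probability: float = 0.25
    slip_minus_probability: float = 0.02
    incomplete_digest: float = 0.0     # per-cut drop probability
    background_reads_per_length: float = 15.0
    background_length_range: tuple[int, int] = (26, 80)
    ccmd_copy_mean: float = 60.0
    background_copy_mean: float = 5.0
    contaminant_rate: float = 0.02     # non-reference reads per mapped unique
    min_site_spacing: int = 90
    seed: int = 0


@dataclass
class FixtureTruthSet:
    """A reproducible genome + methylome + digest + read set with truth."""

    genome: ReferenceGenome
    methylome: Methylome
    motif_models: list[MotifModel]
    planted_sites: list[tuple[str, int, str, str]]  # record, start, motif, state
    fragments: list
    reads: list[tuple[str, int, str]]  # sequence, copy_number, provenance
    config: FixtureConfig

    def raw_reads(self, rng: np.random.Generator | None = None) -> list[str]:
        """Expanded (duplicated) read list, optionally shuffled."""
        out = []
        for seq, copies, _ in self.reads:
            out.extend([seq] * copies)
        if rng is not None:
            rng.shuffle(out)
        return out

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(outdir / "genome.fasta", self.genome.records)
        with open(outdir / "reads.fasta", "w") as fh:
            i = 0
            for seq, copies, prov in self.reads:
                for _ in range(copies):
                    fh.write(f">read{i} {prov}\n{seq}\n")
                    i += 1
        with open(outdir / "truth.json", "w") as fh:
            json.dump({
                "motifs": [
                    {"motif": m.motif, "top_m5c_index": m.top_m5c_index,
                     "bottom_m5c_index": m.bottom_m5c_index}
                    for m in self.motif_models
                ],
                "planted_sites": [list(s) for s in self.planted_sites],
                "config": {k: (list(v) if isinstance(v, tuple) else v)
                           for k, v in vars(self.config).items()},
            }, fh, indent=1)
        with open(outdir / "sites.bed", "w") as fh:
            for record, start, motif, state in self.planted_sites:
                fh.write(f"{record}\t{start}\t{start + len(motif)}\t{state}\n")


def _geometric_copies(rng: np.random.Generator, mean: float) -> int:
    return int(rng.geometric(1.0 / max(mean, 1.0)))


def gen_genome_fixture(motif_models: Sequence[MotifModel],
                       config: FixtureConfig | None = None,
                       enzymes: Sequence[EnzymeModel] = (GENERIC_MFRE,),
                       ) -> FixtureTruthSet:
    """Random genome with planted methylated sites, digested in silico."""
    config = config or FixtureConfig()
    rng = np.random.default_rng(config.seed)
    record = "chr"
    genome_chars = list(_random_bases(rng, config.genome_length, config.gc))

    # Plant motif instances at spaced positions; overwriting the random
    # sequence keeps coordinates exact.
    planted: list[tuple[str, int, str, str]] = []
    methylome = Methylome()
    occupied: list[int] = []
    max_len = max(len(m.motif) for m in motif_models)
    if config.genome_length < config.min_site_spacing * 2:
        raise ValueError("genome too short to place sites")
    for mi, model in enumerate(motif_models):
        placed = 0
        attempts = 0
        while placed < config.sites_per_motif:
            attempts += 1
            if attempts > config.sites_per_motif * 200:
                raise ValueError(f"cannot place {model.motif} in genome")
            pos = int(rng.integers(20, config.genome_length - max_len - 20))
            if any(abs(pos - o) < config.min_site_spacing for o in occupied):
                continue
            inst = _concrete_instance(rng, model.motif)
            genome_chars[pos : pos + len(inst)] = inst
            occupied.append(pos)
            u = rng.random()
            if u < config.methylation_fraction:
                state = "full"
                methylome.add_full_site(record, pos, model, motif_id=str(mi))
            elif u < config.methylation_fraction + config.hemi_fraction:
                state = "hemi"
                methylome.add_hemi_site(record, pos, model, motif_id=str(mi))
            else:
                state = "unmethylated"
            planted.append((record, pos, inst, state))
            placed += 1
    genome = ReferenceGenome([(record, "".join(genome_chars))])
    methylome.validate(genome)

    cuts = expected_cuts(genome, methylome, list(enzymes))
    realized: list[Cut] = []
    missed: list[Cut] = []
    shifts: dict[int, int] = {}
    for cut in cuts:
        if rng.random() < config.incomplete_digest:
            missed.append(cut)
            continue
        # Per-end slippage: cutting 1 bp beyond the expected distance is
        # common; 1 bp short is rare. "Beyond" moves a right cut right and
        # a left cut left.
        shift = 0
        u = rng.random()
        if u < config.slip_plus_probability:
            shift = 1 if cut.side == "right" else -1
        elif u < config.slip_plus_probability + config.slip_minus_probability:
            shift = -1 if cut.side == "right" else 1
        pos = cut.position + shift
        if 0 < pos < config.genome_length:
            realized.append(Cut(cut.record, pos, cut.site, cut.side, cut.enzyme))
    fragments = fragments_from_cuts(genome, realized, missed)

    seq = genome[record]
    reads: list[tuple[str, int, str]] = []
    seen: dict[str, int] = {}

    def add_read(s: str, copies: int, prov: str) -> None:
        if s in seen:
            reads[seen[s]] = (s, reads[seen[s]][1] + copies, reads[seen[s]][2])
        else:
            seen[s] = len(reads)
            reads.append((s, copies, prov))

    # Sequenced inserts: excised fragments short enough to be size-selected.
    for frag in fragments:
        if frag.left_cut is None or frag.right_cut is None:
            continue
        if not (20 <= frag.length <= 80):
            continue
        fseq = seq[frag.start : frag.end]
        if rng.random() < 0.5:  # strand orientation is random
            fseq = reverse_complement(fseq)
        add_read(fseq, _geometric_copies(rng, config.ccmd_copy_mean), "fragment")

    # Background: randomly broken genomic pieces across the length range.
    b_lo, b_hi = config.background_length_range
    for L in range(b_lo, b_hi + 1):
        n_bg = rng.poisson(config.background_reads_per_length)
        for _ in range(n_bg):
            start = int(rng.integers(0, config.genome_length - L))
            s = seq[start : start + L]
            add_read(s, _geometric_copies(rng, config.background_copy_mean),
                     "background")

    # Contaminants: random sequence that will not match the reference.
    n_cont = int(config.contaminant_rate * len(reads))
    for _ in range(n_cont):
        L = int(rng.integers(b_lo, b_hi + 1))
        add_read(_random_bases(rng, L, config.gc), 1, "contaminant")

    return FixtureTruthSet(genome, methylome, list(motif_models), planted,
                           fragments, reads, config)
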