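"""Report writers: TSV tables, BED intervals, PFM matrices, flank matrices.

All writers are deterministic for fixed inputs so reports can be
regenerated byte-identically.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .discovery import DiscoveredMotif, SiteRepresentation
from .enzymes import (
    DISTANCE_BINS,
    FragmentAnnotation,
    MotifModel,
    cleavage_distances,
)
from .filtering import DiagnosticProfile, MappedReadSet

__all__ = [
    "write_diagnostics",
    "write_fragments_bed",
    "write_fragment_summary",
    "write_motif_report",
    "write_pfm",
    "flank_matrix",
    "write_readset_fasta",
]


def write_diagnostics(profile: DiagnosticProfile, path: str | Path) -> None:
    table = profile.table.copy()
    table.to_csv(path, sep="\t", float_format="%.6g")


def write_fragments_bed(fragments: Sequence[FragmentAnnotation],
                        path: str | Path) -> None:
    with open(path, "w") as fh:
        for frag in fragments:
            if frag.left_cut is None and frag.right_cut is None:
                name = "uncut"  # whole record untouched by the digest
            else:
                name = frag.category.value if frag.category else "unclassified"
            fh.write(f"{frag.record}\t{frag.start}\t{frag.end}\t{name}\n")


def write_fragment_summary(fragments: Sequence[FragmentAnnotation],
                           path: str | Path) -> None:
    rows: dict[str, dict[str, float]] = {}
    for frag in fragments:
        cat = frag.category.value if frag.category else "uncut"
        row = rows.setdefault(cat, {"fragments": 0, "total_bp": 0})
        row["fragments"] += 1
        row["total_bp"] += frag.length
    pd.DataFrame(rows).T.sort_index().to_csv(path, sep="\t")


def write_motif_report(motifs: Sequence[DiscoveredMotif],
                       representations: Sequence[SiteRepresentation | None],
                       path: str | Path) -> None:
    """One row per discovered motif, 1-based methylated positions."""
    rows = []
    for disc, rep in zip(motifs, representations):
        model = disc.model
        row = {
            "motif": model.motif,
            "top_m5c_position": model.top_m5c_index + 1,
            "bottom_m5c_position": model.bottom_m5c_index + 1,
            "offset_x": model.x,
            "ccmd_length": model.ccmd_len,
            "source_read_length": disc.candidate.source_length,
            "complexity_score": disc.candidate.complexity,
            "per_base_specificity": round(disc.candidate.specificity, 4),
            "unique_reads": disc.candidate.n_unique_reads,
            "total_reads": disc.candidate.n_total_reads,
        }
        if rep is not None:
            row["sites_detected"] = f"{rep.detected}/{rep.total}"
            row["pct_detected"] = round(100 * rep.fraction, 1)
            if rep.constrained_motif is not None:
                row["constrained_motif"] = rep.constrained_motif
                row["constrained_sites_detected"] = (
                    f"{rep.constrained_detected}/{rep.constrained_total}")
                cf = rep.constrained_fraction
                row["constrained_pct_detected"] = (
                    round(100 * cf, 1) if cf is not None else "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_pfm(counts: np.ndarray, path: str | Path) -> None:
    """Position count matrix, rows A/C/G/T x columns, logo-tool friendly."""
    df = pd.DataFrame(counts.T.astype(int), index=list("ACGT"),
                      columns=[str(i + 1) for i in range(counts.shape[0])])
    df.to_csv(path, sep="\t")


def flank_matrix(readset: MappedReadSet, motif_model: MotifModel,
                 weight_by_copy: bool = True,
                 base_filtered_only: bool = False) -> pd.DataFrame:
    """Cleavage-distance matrix: rows = short flank bin, cols = long flank.

    Mirrors the flank-length analysis of motif-containing reads; reads
    without the motif are excluded.
    """
    from .filtering import base_filter

    mat = pd.DataFrame(0, index=list(DISTANCE_BINS), columns=list(DISTANCE_BINS))
    for read in readset:
        if base_filtered_only and not base_filter(read.sequence):
            continue
        dist = cleavage_distances(read.sequence, motif_model)
        if dist is None:
            continue
        short, long_ = dist.bins
        mat.loc[short, long_] += read.copy_number if weight_by_copy else 1
    return mat


def write_readset_fasta(readset: MappedReadSet, path: str | Path) -> None:
    """Unique reads with copy number and loci encoded in headers."""
    with open(path, "w") as fh:
        for i, read in enumerate(sorted(readset, key=lambda r: r.sequence)):
            loci = ";".join(f"{l.record}:{l.start}:{l.strand}" for l in read.loci)
            flag = " multi" if read.multi_mapping else ""
            fh.write(f">u{i} copies={read.copy_number} loci={loci}{flag}\n")
            fh.write(read.sequence + "\n")
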