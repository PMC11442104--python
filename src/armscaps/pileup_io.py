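"""Per-position allele counts (pileups) from alignment files.

Everything downstream of alignment starts here: for a genomic region we
extract, per reference position, the number of aligned reads supporting
each of A/C/G/T after base-quality, mapping-quality and read-flag filters.
The *SNP-index* of an allele at a position is the fraction of covering
reads that carry that allele; it is the single statistic the whole
selection stage is built on.

Coordinates are 1-based inclusive everywhere a user sees them.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Union

import numpy as np
import pandas as pd
import pysam
from pyfaidx import Fasta

BASES = ("A", "C", "G", "T")

#: reads with any of these flags never contribute to a pileup:
#: unmapped, secondary, QC-fail, duplicate, supplementary
EXCLUDE_FLAGS = 0x4 | 0x100 | 0x200 | 0x400 | 0x800

DEFAULT_MIN_BASE_QUALITY = 13
DEFAULT_MIN_MAPPING_QUALITY = 20


class PileupError(ValueError):
    """Raised for invalid pileup requests (bad region, missing index...)."""


@dataclass(frozen=True)
class RegionSpec:
    """A 1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise PileupError(f"region start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise PileupError(
                f"region end {self.end} precedes start {self.start}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class PileupColumn:
    """Filtered read-base counts for one cultivar at one reference position."""

    chrom: str
    pos: int  # 1-based
    ref_base: str
    counts: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = {b: int(self.counts.get(b, 0)) for b in BASES if self.counts.get(b, 0)}

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


def snp_index(column: PileupColumn, allele: str) -> float:
    """Fraction of reads at ``column`` carrying ``allele``.

    Undefined (raises) at depth 0: an uncovered position carries no
    evidence and must never be silently reported as index 0.
    """
    if allele not in BASES:
        raise PileupError(f"allele must be one of {BASES}, got {allele!r}")
    depth = column.depth
    if depth == 0:
        raise PileupError(
            f"SNP-index undefined at zero depth ({column.chrom}:{column.pos})"
        )
    return column.counts.get(allele, 0) / depth


ReferenceLike = Union[Fasta, Mapping[str, str]]


def reference_base(reference: ReferenceLike, chrom: str, pos: int) -> str:
    """Uppercase reference base at a 1-based position."""
    return fetch_sequence(reference, chrom, pos, pos)


def fetch_sequence(reference: ReferenceLike, chrom: str, start: int, end: int) -> str:
    """Uppercase reference sequence for a 1-based inclusive interval."""
    if isinstance(reference, Fasta):
        if chrom not in reference:
            raise PileupError(f"chromosome {chrom!r} absent from reference")
        return str(reference[chrom][start - 1 : end]).upper()
    if chrom not in reference:
        raise PileupError(f"chromosome {chrom!r} absent from reference")
    seq = reference[chrom]
    if end > len(seq):
        raise PileupError(
            f"interval {chrom}:{start}-{end} exceeds reference length {len(seq)}"
        )
    return str(seq[start - 1 : end]).upper()


def _as_alignment(alignment: Union[str, os.PathLike, pysam.AlignmentFile]) -> pysam.AlignmentFile:
    if isinstance(alignment, pysam.AlignmentFile):
        return alignment
    return open_alignment(os.fspath(alignment))


def open_alignment(path: str) -> pysam.AlignmentFile:
    """Open a BAM/SAM for random access, indexing on the fly if needed.

    Plain SAM (the text format used by the test fixtures) cannot be
    region-queried, so it is converted to a coordinate-sorted, indexed BAM
    in a temporary directory that lives as long as the handle.
    """
    lower = path.lower()
    if lower.endswith(".sam") or not _has_index(path):
        tmpdir = tempfile.mkdtemp(prefix="armscaps_bam_")
        bam = os.path.join(tmpdir, os.path.basename(path) + ".sorted.bam")
        pysam.sort("-o", bam, path)
        pysam.index(bam)
        return pysam.AlignmentFile(bam)
    return pysam.AlignmentFile(path)


def _has_index(path: str) -> bool:
    for ext in (".bai", ".csi"):
        if os.path.exists(path + ext):
            return True
        root, _ = os.path.splitext(path)
        if os.path.exists(root + ext):
            return True
    return False


def extract_pileup(
    alignment: Union[str, os.PathLike, pysam.AlignmentFile],
    reference: ReferenceLike,
    region: RegionSpec,
    min_base_quality: int = DEFAULT_MIN_BASE_QUALITY,
    min_mapping_quality: int = DEFAULT_MIN_MAPPING_QUALITY,
) -> List[PileupColumn]:
    """Count aligned A/C/G/T per reference position in ``region``.

    Duplicate, secondary, supplementary, unmapped and QC-fail reads are
    excluded; so are read bases below ``min_base_quality``, reads below
    ``min_mapping_quality``, and bases aligned as insertions/deletions or
    reference skips. Positions with zero depth after filtering, and
    positions whose reference base is N, are not emitted.
    """
    af = _as_alignment(alignment)
    if region.chrom not in af.references:
        raise PileupError(
            f"chromosome {region.chrom!r} absent from alignment header"
        )
    # validates the chromosome against the reference too
    ref_seq = fetch_sequence(reference, region.chrom, region.start, region.end)

    def _keep(read: pysam.AlignedSegment) -> bool:
        return (
            not read.flag & EXCLUDE_FLAGS
            and read.mapping_quality >= min_mapping_quality
        )

    try:
        acgt = af.count_coverage(
            region.chrom,
            region.start - 1,
            region.end,
            quality_threshold=min_base_quality,
            read_callback=_keep,
        )
    except ValueError as exc:
        raise PileupError(str(exc)) from exc
    acgt = np.asarray(acgt)  # rows in A, C, G, T order
    covered = np.nonzero(acgt.sum(axis=0) > 0)[0]
    columns: List[PileupColumn] = []
    for i in covered:
        ref_base = ref_seq[i]
        if ref_base not in BASES:
            continue
        counts = {
            b: int(acgt[j, i]) for j, b in enumerate(BASES) if acgt[j, i]
        }
        columns.append(
            PileupColumn(
                chrom=region.chrom,
                pos=region.start + int(i),
                ref_base=ref_base,
                counts=counts,
            )
        )
    return columns


def columns_to_frame(columns: Iterable[PileupColumn]) -> pd.DataFrame:
    """Tabulate columns as chrom, pos, ref, A, C, G, T, depth."""
    rows = [
        {
            "chrom": c.chrom,
            "pos": c.pos,
            "ref": c.ref_base,
            **{b: c.counts.get(b, 0) for b in BASES},
            "depth": c.depth,
        }
        for c in columns
    ]
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "A", "C", "G", "T", "depth"]
    )


def write_pileup_tsv(columns: Iterable[PileupColumn], path: str) -> None:
    columns_to_frame(columns).to_csv(path, sep="\t", index=False)


def index_columns(columns: Iterable[PileupColumn]) -> Dict[int, PileupColumn]:
    """Position-keyed lookup for a single-chromosome column list."""
    return {c.pos: c for c in columns}
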