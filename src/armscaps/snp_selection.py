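"""Target-SNP selection: find cultivar-B-specific SNP positions.

The selection stage scans matched pileups of two cultivars aligned to a
shared reference and keeps positions where cultivar A supports only the
reference base (up to a tolerance) while cultivar B carries exactly one
non-reference allele whose SNP-index falls in the requested range. The
default range [1, 1] selects homozygous cultivar-B SNPs; the
HeteroSelect filter replaces the fixed range with a depth-dependent
binomial confidence interval for a chosen ploidy/dosage, and the
ProgenySNP filter additionally requires a segregating (heterozygous)
state in a progeny bulk.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .pileup_io import BASES, PileupColumn, index_columns, snp_index
from .snpindex_sim import SnpIndexInterval, snp_index_interval

LABEL_HOMOZYGOUS = "homozygous"
LABEL_CANDIDATE = "candidate"  # heterozygous candidate, dosage not yet assigned
LABEL_HET_DIPLOID = "heterozygous_diploid"
TETRAPLOID_LABELS = {1: "simplex", 2: "duplex", 3: "triplex"}


class SelectionError(ValueError):
    """Raised on invalid selection inputs (mismatched regions, bad dosage)."""


@dataclass
class SnpSite:
    """A cultivar-B-specific SNP with per-cultivar SNP-index and depth."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    index_A: float
    index_B: float
    depth_A: int
    depth_B: int
    label: str = LABEL_CANDIDATE


@dataclass
class SelectionFilters:
    """Knobs for :func:`select_target_snps`.

    ``max_depth=None`` resolves at call time to 3x the region's mean
    depth, a cheap guard against collapsed repeats. ``index_B_range`` is
    inclusive unless ``index_B_open`` is set (HeteroSelect feeds on the
    open interval (0, 1): any site with both alleles observed).
    """

    min_depth: int = 6
    max_depth: Optional[int] = None
    tolA: float = 0.0
    index_B_range: Tuple[float, float] = (1.0, 1.0)
    index_B_open: bool = False
    ploidy: int = 2
    dosage: int = 1
    confidence: float = 0.95


def _mean_depth(cols: Sequence[PileupColumn]) -> float:
    if not cols:
        return 0.0
    return float(np.mean([c.depth for c in cols]))


def _in_range(x: float, lo: float, hi: float, open_: bool) -> bool:
    if open_:
        return lo < x < hi
    return lo <= x <= hi


def select_target_snps(
    cols_a: Sequence[PileupColumn],
    cols_b: Sequence[PileupColumn],
    reference,
    filters: Optional[SelectionFilters] = None,
) -> List[SnpSite]:
    """Emit cultivar-B-specific SNP sites from matched pileups.

    A position qualifies when (a) both cultivars' depths are within
    [min_depth, max_depth]; (b) every non-reference base in cultivar A
    has SNP-index <= tolA (cultivar A shows no polymorphism); and
    (c) exactly one non-reference base in cultivar B clears tolA, and its
    SNP-index lies in ``index_B_range``. Positions with two or more
    cultivar-B alleles above tolA are rejected as multi-allelic: a marker
    needs a single discriminating allele.
    """
    filters = filters or SelectionFilters()
    chroms_a = {c.chrom for c in cols_a}
    chroms_b = {c.chrom for c in cols_b}
    if chroms_a and chroms_b and chroms_a != chroms_b:
        raise SelectionError(
            f"pileups cover different chromosomes: {chroms_a} vs {chroms_b}"
        )

    max_a = filters.max_depth
    max_b = filters.max_depth
    if max_a is None:
        max_a = max(filters.min_depth, int(round(3 * _mean_depth(cols_a))))
        max_b = max(filters.min_depth, int(round(3 * _mean_depth(cols_b))))

    by_pos_b = index_columns(cols_b)
    lo, hi = filters.index_B_range
    sites: List[SnpSite] = []
    for col_a in cols_a:
        col_b = by_pos_b.get(col_a.pos)
        if col_b is None:
            continue
        if not (filters.min_depth <= col_a.depth <= max_a):
            continue
        if not (filters.min_depth <= col_b.depth <= max_b):
            continue
        ref = col_a.ref_base
        # (b) cultivar A non-polymorphic up to tolA
        if any(
            snp_index(col_a, b) > filters.tolA
            for b in BASES
            if b != ref and b in col_a.counts
        ):
            continue
        # (c) exactly one discriminating allele in cultivar B
        alts = [
            b
            for b in BASES
            if b != ref and b in col_b.counts and snp_index(col_b, b) > filters.tolA
        ]
        if len(alts) != 1:
            continue
        alt = alts[0]
        idx_b = snp_index(col_b, alt)
        if not _in_range(idx_b, lo, hi, filters.index_B_open):
            continue
        idx_a = snp_index(col_a, alt) if alt in col_a.counts else 0.0
        label = LABEL_HOMOZYGOUS if idx_b == 1.0 else LABEL_CANDIDATE
        sites.append(
            SnpSite(
                chrom=col_a.chrom,
                pos=col_a.pos,
                ref_allele=ref,
                alt_allele=alt,
                index_A=idx_a,
                index_B=idx_b,
                depth_A=col_a.depth,
                depth_B=col_b.depth,
                label=label,
            )
        )
    return sites


def hetero_select(
    sites: Iterable[SnpSite],
    ploidy: int,
    dosage: int,
    confidence: float = 0.95,
) -> List[SnpSite]:
    """Keep sites whose index_B is inside the dosage's confidence interval.

    The interval depends on each site's cultivar-B depth; kept sites are
    relabelled by dosage class (simplex/duplex/triplex for ploidy 4,
    heterozygous_diploid for ploidy 2).
    """
    if not 1 <= dosage <= ploidy - 1:
        raise SelectionError(
            f"dosage must satisfy 1 <= dosage < ploidy, got {dosage}/{ploidy}"
        )
    if ploidy == 2:
        label = LABEL_HET_DIPLOID
    elif ploidy == 4:
        label = TETRAPLOID_LABELS[dosage]
    else:
        label = f"dosage{dosage}_of_{ploidy}"
    cache: Dict[int, SnpIndexInterval] = {}
    kept: List[SnpSite] = []
    for site in sites:
        iv = cache.get(site.depth_B)
        if iv is None:
            iv = snp_index_interval(site.depth_B, dosage, ploidy, confidence)
            cache[site.depth_B] = iv
        if iv.contains(site.index_B):
            kept.append(replace(site, label=label))
    return kept


def progeny_filter(
    sites: Iterable[SnpSite],
    progeny_cols: Sequence[PileupColumn],
    confidence: float = 0.95,
    min_depth: int = 6,
    max_depth: Optional[int] = None,
) -> List[SnpSite]:
    """Keep sites that look heterozygous in a progeny bulk.

    A randomly bulked F2 (or an F1) of the two cultivars should carry both
    alleles in equal ratio at every truly segregating site, so the bulk's
    SNP-index of the cultivar-B allele is tested against the dosage-1,
    ploidy-2 interval at the bulk's depth. Sites missing from the bulk's
    pileup (depth 0) are dropped: no evidence of segregation.
    """
    by_pos = index_columns(progeny_cols)
    if max_depth is None:
        max_depth = max(min_depth, int(round(3 * _mean_depth(progeny_cols))))
    cache: Dict[int, SnpIndexInterval] = {}
    kept: List[SnpSite] = []
    for site in sites:
        col = by_pos.get(site.pos)
        if col is None:
            continue
        if not (min_depth <= col.depth <= max_depth):
            continue
        iv = cache.get(col.depth)
        if iv is None:
            iv = snp_index_interval(col.depth, 1, 2, confidence)
            cache[col.depth] = iv
        if iv.contains(snp_index(col, site.alt_allele)):
            kept.append(site)
    return kept


SITE_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "index_A",
    "index_B",
    "depth_A",
    "depth_B",
    "label",
]


def sites_to_frame(sites: Iterable[SnpSite]) -> pd.DataFrame:
    rows = [
        {
            "chrom": s.chrom,
            "pos": s.pos,
            "ref": s.ref_allele,
            "alt": s.alt_allele,
            "index_A": s.index_A,
            "index_B": s.index_B,
            "depth_A": s.depth_A,
            "depth_B": s.depth_B,
            "label": s.label,
        }
        for s in sites
    ]
    return pd.DataFrame(rows, columns=SITE_COLUMNS)


def write_sites_tsv(sites: Iterable[SnpSite], path: str) -> None:
    sites_to_frame(sites).to_csv(path, sep="\t", index=False)


def read_sites_tsv(path: str) -> List[SnpSite]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        SnpSite(
            chrom=str(r.chrom),
            pos=int(r.pos),
            ref_allele=str(r.ref),
            alt_allele=str(r.alt),
            index_A=float(r.index_A),
            index_B=float(r.index_B),
            depth_A=int(r.depth_A),
            depth_B=int(r.depth_B),
            label=str(r.label),
        )
        for r in df.itertuples()
    ]
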