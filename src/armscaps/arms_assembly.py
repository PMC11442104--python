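"""Assembly of tri- and tetra-primer ARMS markers, plus an in-silico PCR oracle.

A *tri-ARMS* marker combines two same-orientation allele-specific
primers at two nearby SNPs (one per cultivar) with a single shared
common primer of the opposite orientation; the two alleles give bands
whose size difference equals the spacing between the specific primers'
3' ends. A *tetra-ARMS* marker works at a single SNP: the two specific
primers face opposite directions and two flanking common primers give an
outer control band plus one inner band per allele.

Distance conventions (stated once, used everywhere): the specific-primer
spacing is measured between 3' ends, i.e. between the SNP positions; the
common-primer search window extends 100-700 bp from the 3' end of the
nearest specific primer, and the common primer's whole footprint must
fall inside it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .pileup_io import RegionSpec, ReferenceLike
from .primer_design import (
    FORWARD,
    KIND_A,
    KIND_B,
    REVERSE,
    CommonCandidates,
    Primer,
    PrimerParams,
    RegionMask,
    _best_index,
    candidate_primer,
    encode,
    enumerate_common_candidates,
    reduce_candidates,
    reverse_complement,
)
from .snp_selection import LABEL_HOMOZYGOUS, SnpSite

SPACING_MIN = 100
SPACING_MAX = 300
COMMON_WINDOW_MIN = 100
COMMON_WINDOW_MAX = 700
MIN_BAND_SEPARATION = 50
MAX_PRODUCT = 2000


@dataclass
class TriArmsMarker:
    """Two same-orientation specific primers sharing one common primer."""

    specific_A: Primer
    specific_B: Primer
    common: Primer
    product_A: int
    product_B: int
    #: distance between the specific primers' 5' ends == band-size difference
    spacing: int
    #: distance between their 3' ends (the two SNP positions); the
    #: 100-300 bp pairing rule is applied to this
    snp_spacing: int = 0
    trans_risk: bool = False  # heterozygous sites: cis linkage unverified

    @property
    def chrom(self) -> str:
        return self.common.chrom

    @property
    def position(self) -> int:
        """Anchor coordinate: the leftmost targeted SNP."""
        return min(self.specific_A.target_pos, self.specific_B.target_pos)

    @property
    def amplicon(self) -> RegionSpec:
        start = min(self.specific_A.start, self.specific_B.start, self.common.start)
        end = max(self.specific_A.end, self.specific_B.end, self.common.end)
        return RegionSpec(self.chrom, start, end)

    @property
    def primers(self) -> List[Primer]:
        return [self.specific_A, self.specific_B, self.common]

    @property
    def total_penalty(self) -> float:
        return sum(p.penalty for p in self.primers)


@dataclass
class TetraArmsMarker:
    """Opposite-orientation specific primers at one SNP, two common primers."""

    specific_A: Primer
    specific_B: Primer
    common_left: Primer
    common_right: Primer
    product_outer: int
    product_A: int
    product_B: int

    @property
    def chrom(self) -> str:
        return self.common_left.chrom

    @property
    def position(self) -> int:
        return self.specific_A.target_pos

    @property
    def amplicon(self) -> RegionSpec:
        return RegionSpec(self.chrom, self.common_left.start, self.common_right.end)

    @property
    def primers(self) -> List[Primer]:
        return [self.specific_A, self.specific_B, self.common_left, self.common_right]

    @property
    def total_penalty(self) -> float:
        return sum(p.penalty for p in self.primers)


def _product_size(fwd: Primer, rev: Primer) -> int:
    """Inclusive span from the forward 5' end through the reverse 5' end."""
    return rev.end - fwd.start + 1


def assemble_tri_arms(
    primers: Sequence[Primer],
    reference: ReferenceLike,
    mask: RegionMask,
    params: Optional[PrimerParams] = None,
    min_band_separation: int = MIN_BAND_SEPARATION,
) -> List[TriArmsMarker]:
    """Pair A- and B-specific primers of the same orientation with a common one.

    For every (A-specific, B-specific) pair in the same orientation whose
    3'-end spacing is within [100, 300] bp, a common primer of the
    opposite orientation is sought 100-700 bp beyond the nearer specific
    primer; the minimum-total-penalty marker per pair is emitted. Band
    separation equals the spacing, so the [100, 300] rule already
    guarantees resolvable bands.
    """
    params = params or PrimerParams()
    markers: List[TriArmsMarker] = []
    for orientation in (FORWARD, REVERSE):
        spec_a = [p for p in primers if p.kind == KIND_A and p.orientation == orientation]
        spec_b = [p for p in primers if p.kind == KIND_B and p.orientation == orientation]
        # cache common-candidate enumerations keyed by search window
        cand_cache: Dict[Tuple[int, int], CommonCandidates] = {}
        for pa in spec_a:
            for pb in spec_b:
                if pa.target_pos == pb.target_pos:
                    continue
                snp_spacing = abs(pa.target_pos - pb.target_pos)
                if not SPACING_MIN <= snp_spacing <= SPACING_MAX:
                    continue
                spacing = (
                    abs(pa.start - pb.start)
                    if orientation == FORWARD
                    else abs(pa.end - pb.end)
                )
                if spacing < min_band_separation:
                    continue
                if orientation == FORWARD:
                    near = max(pa.three_prime_pos, pb.three_prime_pos)
                    win = (near + COMMON_WINDOW_MIN, near + COMMON_WINDOW_MAX)
                    common_orient = REVERSE
                else:
                    near = min(pa.three_prime_pos, pb.three_prime_pos)
                    win = (max(1, near - COMMON_WINDOW_MAX), near - COMMON_WINDOW_MIN)
                    common_orient = FORWARD
                if win[1] < win[0]:
                    continue
                cands = cand_cache.get(win)
                if cands is None:
                    cands = enumerate_common_candidates(
                        RegionSpec(pa.chrom, win[0], win[1]),
                        common_orient,
                        reference,
                        mask,
                        params,
                    )
                    cand_cache[win] = cands
                best = _best_index(cands, reference)
                if best is None:
                    continue
                common = candidate_primer(cands, best, reference)
                if orientation == FORWARD:
                    product_a = _product_size(pa, common)
                    product_b = _product_size(pb, common)
                else:
                    product_a = _product_size(common, pa)
                    product_b = _product_size(common, pb)
                trans_risk = not (
                    pa.site_label == LABEL_HOMOZYGOUS
                    and pb.site_label == LABEL_HOMOZYGOUS
                )
                markers.append(
                    TriArmsMarker(
                        specific_A=pa,
                        specific_B=pb,
                        common=common,
                        product_A=product_a,
                        product_B=product_b,
                        spacing=spacing,
                        snp_spacing=snp_spacing,
                        trans_risk=trans_risk,
                    )
                )
    markers.sort(key=lambda m: (m.position, m.total_penalty))
    return markers


def assemble_tetra_arms(
    primers: Sequence[Primer],
    reference: ReferenceLike,
    mask: RegionMask,
    params: Optional[PrimerParams] = None,
    min_band_separation: int = MIN_BAND_SEPARATION,
) -> List[TetraArmsMarker]:
    """Build a four-primer marker at every SNP carrying both opposite-
    orientation specific primers.

    Left (forward) and right (reverse) common primers are sought in the
    100-700 bp flanking windows; among all (left, right) candidate pairs
    the minimum-penalty pair whose inner bands differ by at least
    ``min_band_separation`` is chosen, tie-broken by leftmost common
    primer. At most one marker per SNP.
    """
    params = params or PrimerParams()
    markers: List[TetraArmsMarker] = []
    by_pos: Dict[int, List[Primer]] = {}
    for p in primers:
        if p.kind in (KIND_A, KIND_B) and p.target_pos is not None:
            by_pos.setdefault(p.target_pos, []).append(p)
    for pos in sorted(by_pos):
        group = by_pos[pos]
        combos = []
        for a_orient in (FORWARD, REVERSE):
            b_orient = REVERSE if a_orient == FORWARD else FORWARD
            pa = next((p for p in group if p.kind == KIND_A and p.orientation == a_orient), None)
            pb = next((p for p in group if p.kind == KIND_B and p.orientation == b_orient), None)
            if pa is not None and pb is not None:
                combos.append((pa, pb))
        best_marker: Optional[TetraArmsMarker] = None
        best_key = None
        for pa, pb in combos:
            fwd_spec, rev_spec = (pa, pb) if pa.orientation == FORWARD else (pb, pa)
            left = enumerate_common_candidates(
                RegionSpec(pa.chrom, max(1, pos - COMMON_WINDOW_MAX), pos - COMMON_WINDOW_MIN),
                FORWARD, reference, mask, params,
            )
            right = enumerate_common_candidates(
                RegionSpec(pa.chrom, pos + COMMON_WINDOW_MIN, pos + COMMON_WINDOW_MAX),
                REVERSE, reference, mask, params,
            )
            if len(left) == 0 or len(right) == 0:
                continue
            # products depend only on the left start / right end: reduce
            left = reduce_candidates(left, by="start")
            right = reduce_candidates(right, by="end")
            # inner band of the forward specific depends only on the right
            # common primer's 5' end; the reverse specific's only on the left
            # common primer's 5' end -- evaluate all pairs vectorized
            left_ends = left.ends  # footprint right edge (5' end is .starts)
            prod_rev = rev_spec.end - left.starts + 1
            prod_fwd = right.ends - fwd_spec.start + 1
            sep = np.abs(prod_fwd[None, :] - prod_rev[:, None])
            total_pen = left.penalties[:, None] + right.penalties[None, :]
            ok = sep >= min_band_separation
            if not ok.any():
                continue
            total_pen = np.where(ok, total_pen, np.inf)
            li, ri = np.unravel_index(np.argmin(total_pen), total_pen.shape)
            # deterministic tie-break: leftmost common primer, then leftmost right
            pen = total_pen[li, ri]
            ties = np.argwhere(total_pen == pen)
            li, ri = min(
                (int(a), int(b)) for a, b in ties
            )
            common_left = candidate_primer(left, int(li), reference)
            common_right = candidate_primer(right, int(ri), reference)
            product_a = (
                _product_size(pa, common_right)
                if pa.orientation == FORWARD
                else _product_size(common_left, pa)
            )
            product_b = (
                _product_size(pb, common_right)
                if pb.orientation == FORWARD
                else _product_size(common_left, pb)
            )
            marker = TetraArmsMarker(
                specific_A=pa,
                specific_B=pb,
                common_left=common_left,
                common_right=common_right,
                product_outer=_product_size(common_left, common_right),
                product_A=product_a,
                product_B=product_b,
            )
            key = (marker.total_penalty, common_left.start)
            if best_key is None or key < best_key:
                best_key, best_marker = key, marker
        if best_marker is not None:
            markers.append(best_marker)
    return markers


# ---------------------------------------------------------------------------
# in-silico PCR oracle

class AmbiguousAmplificationError(RuntimeError):
    """A primer pair amplifies at more than one locus on the template."""


def _anneal_sites(primer_seq: str, template_codes: np.ndarray, tail: str) -> np.ndarray:
    """0-based template offsets where an oligo anneals.

    ``tail`` selects which end of the match is the 3' end: 'right' for a
    top-strand (forward-style) match, 'left' for a bottom-strand match of
    an already reverse-complemented oligo. The 3'-terminal base must
    match perfectly; at most one mismatch is tolerated elsewhere (room
    for the deliberate ARMS substitution).
    """
    p = encode(primer_seq)
    L = len(p)
    n = len(template_codes) - L + 1
    if n <= 0:
        return np.array([], dtype=int)
    mism = np.zeros(n, dtype=np.int64)
    for j in range(L):
        mism += template_codes[j : n + j] != p[j]
    term = 0 if tail == "left" else L - 1
    term_ok = template_codes[term : n + term] == p[term]
    return np.nonzero((mism <= 1) & term_ok)[0]


def in_silico_pcr(
    fwd: Primer, rev: Primer, template: str, max_product: int = MAX_PRODUCT
) -> Optional[int]:
    """Predict the amplicon size of a primer pair on a haplotype sequence.

    Returns the inclusive span between the two primers' 5' ends, or None
    when no product forms (3'-terminal mismatch, >1 internal mismatch,
    primers not facing each other, or span above ``max_product``).
    Multiple amplifiable loci raise: such primers are non-specific.
    """
    codes = encode(template.upper())
    fwd_sites = _anneal_sites(fwd.seq, codes, tail="right")
    rev_sites = _anneal_sites(reverse_complement(rev.seq), codes, tail="left")
    products = []
    for f in fwd_sites:
        for r in rev_sites:
            r_end = r + len(rev.seq) - 1
            if r_end <= f + len(fwd.seq) - 1:
                continue  # reverse primer must lie beyond the forward one
            size = r_end - f + 1
            if size <= max_product:
                products.append(size)
    if not products:
        return None
    if len(products) > 1:
        raise AmbiguousAmplificationError(
            f"{len(products)} products for {fwd.seq}/{rev.seq}"
        )
    return products[0]


def apply_alleles(reference_seq: str, alleles: Dict[int, str], offset: int = 0) -> str:
    """Build a haplotype by substituting 1-based positions with alleles.

    ``offset`` shifts coordinates when ``reference_seq`` is a slice
    starting at reference position offset+1.
    """
    out = list(reference_seq)
    for pos, base in alleles.items():
        i = pos - 1 - offset
        if 0 <= i < len(out):
            out[i] = base
    return "".join(out)


# ---------------------------------------------------------------------------
# density profile and genome-wide thinning

def marker_density_profile(
    markers: Dict[str, Sequence],
    sites: Sequence[SnpSite],
    bin_size: int = 1_000_000,
) -> pd.DataFrame:
    """Per-bin SNP and marker counts.

    ``markers`` maps a marker-type name (e.g. 'tri', 'tetra', 'caps') to
    a sequence of markers exposing ``.position``. Bin 1 covers positions
    1..bin_size. Used to reproduce the qualitative trend that tri-ARMS
    output tracks SNP density while tetra-ARMS remain available in
    SNP-sparse regions.
    """
    def bin_of(pos: int) -> int:
        return (pos - 1) // bin_size + 1

    counts: Dict[int, Dict[str, int]] = {}
    for s in sites:
        b = bin_of(s.pos)
        counts.setdefault(b, {})["snps"] = counts.get(b, {}).get("snps", 0) + 1
    for name, mlist in markers.items():
        for m in mlist:
            b = bin_of(m.position)
            counts.setdefault(b, {})[name] = counts.get(b, {}).get(name, 0) + 1
    if not counts:
        return pd.DataFrame(columns=["bin", "snps", *markers.keys()])
    rows = []
    for b in sorted(counts):
        row = {"bin": b, "snps": counts[b].get("snps", 0)}
        for name in markers:
            row[name] = counts[b].get(name, 0)
        rows.append(row)
    return pd.DataFrame(rows, columns=["bin", "snps", *markers.keys()])


def best_per_interval(markers: Sequence, bin_size: int = 1_000_000) -> List:
    """Genome-wide thinning: the minimum-penalty marker per bin."""
    best: Dict[Tuple[str, int], object] = {}
    for m in markers:
        key = (m.chrom, (m.position - 1) // bin_size)
        cur = best.get(key)
        if cur is None or m.total_penalty < cur.total_penalty:
            best[key] = m
    return [best[k] for k in sorted(best)]


# ---------------------------------------------------------------------------
# TSV output

def tri_markers_to_frame(markers: Iterable[TriArmsMarker]) -> pd.DataFrame:
    rows = [
        {
            "chrom": m.chrom,
            "snp_A": m.specific_A.target_pos,
            "snp_B": m.specific_B.target_pos,
            "orientation": m.specific_A.orientation,
            "spacing": m.spacing,
            "snp_spacing": m.snp_spacing,
            "product_A": m.product_A,
            "product_B": m.product_B,
            "primer_A": m.specific_A.seq,
            "primer_B": m.specific_B.seq,
            "primer_common": m.common.seq,
            "trans_risk": m.trans_risk,
            "total_penalty": round(m.total_penalty, 4),
        }
        for m in markers
    ]
    return pd.DataFrame(rows)


def tetra_markers_to_frame(markers: Iterable[TetraArmsMarker]) -> pd.DataFrame:
    rows = [
        {
            "chrom": m.chrom,
            "snp": m.position,
            "product_outer": m.product_outer,
            "product_A": m.product_A,
            "product_B": m.product_B,
            "primer_A": m.specific_A.seq,
            "primer_B": m.specific_B.seq,
            "primer_left": m.common_left.seq,
            "primer_right": m.common_right.seq,
            "total_penalty": round(m.total_penalty, 4),
        }
        for m in markers
    ]
    return pd.DataFrame(rows)
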