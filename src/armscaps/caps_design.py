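"""CAPS marker design: SNPs that create or destroy a restriction site.

A CAPS marker genotypes a SNP by PCR-amplifying the surrounding region
with ordinary (common-style) primers and digesting the product with a
restriction enzyme whose recognition site overlaps the SNP in exactly
one allele: the cut allele falls into two (or more) fragments, the
other stays intact, and the alleles separate on a gel.

Recognition sequences are IUPAC strings matched on the top strand; for
non-palindromic enzymes the reverse-complement pattern is matched as
well with the cut offset mirrored (the shipped defaults AluI AG^CT and
EcoRI G^AATTC are palindromic so strand choice is immaterial).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .pileup_io import RegionSpec, ReferenceLike, fetch_sequence
from .primer_design import (
    FORWARD,
    REVERSE,
    Primer,
    PrimerParams,
    RegionMask,
    candidate_primer,
    enumerate_common_candidates,
    reduce_candidates,
    reverse_complement,
)
from .snp_selection import SnpSite

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

PRODUCT_MIN = 200
PRODUCT_MAX = 1000
MIN_BAND_SEPARATION = 50

DEFAULT_ENZYME_TSV = os.path.join(os.path.dirname(__file__), "data", "enzymes.tsv")


@dataclass(frozen=True)
class RestrictionEnzyme:
    """An enzyme's recognition motif and top-strand cut position.

    ``cut_offset`` counts bases from the 5' edge of the recognition site
    to the cut: AluI (AG^CT) has offset 2, EcoRI (G^AATTC) offset 1.
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        rec = self.recognition.upper()
        if len(rec) < 4:
            raise ValueError(f"{self.name}: recognition site shorter than 4 bp")
        if any(b not in IUPAC for b in rec):
            raise ValueError(f"{self.name}: non-IUPAC base in {rec!r}")
        if not 0 <= self.cut_offset <= len(rec):
            raise ValueError(f"{self.name}: cut offset outside recognition site")
        object.__setattr__(self, "recognition", rec)

    @property
    def site_length(self) -> int:
        return len(self.recognition)

    @property
    def is_palindromic(self) -> bool:
        return self.recognition == reverse_complement_iupac(self.recognition)

    def patterns(self) -> List[Tuple[str, int]]:
        """(pattern, cut_offset) pairs to scan on the top strand."""
        pats = [(self.recognition, self.cut_offset)]
        if not self.is_palindromic:
            pats.append(
                (
                    reverse_complement_iupac(self.recognition),
                    self.site_length - self.cut_offset,
                )
            )
        return pats


def reverse_complement_iupac(pattern: str) -> str:
    return pattern.translate(_IUPAC_COMPLEMENT)[::-1]


def iupac_match(pattern: str, seq: str) -> bool:
    """Exact-length IUPAC match of ``seq`` against ``pattern``."""
    if len(seq) != len(pattern):
        return False
    return all(b in IUPAC[p] for p, b in zip(pattern, seq))


def read_enzyme_tsv(path: str = DEFAULT_ENZYME_TSV) -> List[RestrictionEnzyme]:
    """Load an enzyme table: columns name, recognition, cut_offset."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        RestrictionEnzyme(str(r.name), str(r.recognition), int(r.cut_offset))
        for r in df.itertuples(index=False)
    ]


def scan_sites(sequence: str, enzyme: RestrictionEnzyme) -> List[int]:
    """0-based cut positions (bases to the left of the cut) in ``sequence``."""
    cuts = []
    for pattern, offset in enzyme.patterns():
        m = len(pattern)
        for i in range(len(sequence) - m + 1):
            if iupac_match(pattern, sequence[i : i + m]):
                cuts.append(i + offset)
    return sorted(set(cuts))


def digest(product_sequence: str, enzyme: RestrictionEnzyme) -> List[int]:
    """Fragment lengths after complete digestion, left-to-right.

    Every recognition-site match contributes a cut; with none, the whole
    product is returned intact as a single fragment.
    """
    seq = product_sequence.upper()
    cuts = [c for c in scan_sites(seq, enzyme) if 0 < c < len(seq)]
    edges = [0, *cuts, len(seq)]
    return [b - a for a, b in zip(edges, edges[1:])]


def find_discriminating_enzymes(
    site: SnpSite,
    reference: ReferenceLike,
    enzymes: Sequence[RestrictionEnzyme],
) -> List[Tuple[RestrictionEnzyme, RegionSpec, str]]:
    """Enzymes whose recognition site overlaps the SNP in exactly one allele.

    For each enzyme, every window of recognition length covering the SNP
    is tested against both allele sequences. The enzyme discriminates
    when one allele has at least one matching window and the other has
    none — if both alleles can be cut somewhere over the SNP the band
    patterns collapse. Returns (enzyme, matching window, cut allele).
    """
    hits: List[Tuple[RestrictionEnzyme, RegionSpec, str]] = []
    for enzyme in enzymes:
        m = enzyme.site_length
        left = site.pos - m + 1
        if left < 1:
            continue
        context = fetch_sequence(reference, site.chrom, left, site.pos + m - 1)
        i_snp = site.pos - left  # == m - 1
        ref_ctx = context[:i_snp] + site.ref_allele + context[i_snp + 1 :]
        alt_ctx = context[:i_snp] + site.alt_allele + context[i_snp + 1 :]
        windows: Dict[str, List[int]] = {"ref": [], "alt": []}
        for w in range(m):  # window starts at reference pos left + w
            for name, ctx in (("ref", ref_ctx), ("alt", alt_ctx)):
                if any(
                    iupac_match(pat, ctx[w : w + m]) for pat, _ in enzyme.patterns()
                ):
                    windows[name].append(w)
        if bool(windows["ref"]) == bool(windows["alt"]):
            continue
        cut_allele = "ref" if windows["ref"] else "alt"
        w = windows[cut_allele][0]
        hits.append(
            (
                enzyme,
                RegionSpec(site.chrom, left + w, left + w + m - 1),
                cut_allele,
            )
        )
    return hits


@dataclass
class CapsMarker:
    """An amplify-and-digest marker at one SNP."""

    site: SnpSite
    enzyme: RestrictionEnzyme
    fwd: Primer
    rev: Primer
    product_size: int
    cut_allele: str  # 'ref' or 'alt'
    fragments_ref: List[int]  # sorted
    fragments_alt: List[int]  # sorted

    @property
    def chrom(self) -> str:
        return self.site.chrom

    @property
    def position(self) -> int:
        return self.site.pos

    @property
    def amplicon(self) -> RegionSpec:
        return RegionSpec(self.chrom, self.fwd.start, self.rev.end)

    @property
    def primers(self) -> List[Primer]:
        return [self.fwd, self.rev]

    @property
    def total_penalty(self) -> float:
        return self.fwd.penalty + self.rev.penalty


def _patterns_distinguishable(a: Sequence[int], b: Sequence[int], sep: int) -> bool:
    """A band in one pattern must differ by >= sep from every band in the
    other (in either direction) for a gel to tell the genotypes apart."""
    def has_unique_band(x: Sequence[int], y: Sequence[int]) -> bool:
        return any(all(abs(f - g) >= sep for g in y) for f in x)

    return has_unique_band(a, b) or has_unique_band(b, a)


def design_caps_marker(
    site: SnpSite,
    enzyme_hits: Sequence[Tuple[RestrictionEnzyme, RegionSpec, str]],
    reference: ReferenceLike,
    mask: RegionMask,
    params: Optional[PrimerParams] = None,
    product_range: Tuple[int, int] = (PRODUCT_MIN, PRODUCT_MAX),
    min_band_separation: int = MIN_BAND_SEPARATION,
) -> Optional[CapsMarker]:
    """Best CAPS marker at a SNP, or None.

    Polymorphism-free, depth-valid primers are enumerated in the two
    flanking windows; candidate pairs are ranked by summed penalty and
    the first pair whose product is within ``product_range`` and whose
    allele-resolved digestion patterns (counting *all* recognition sites
    in the product, invariant ones included) are distinguishable at
    ``min_band_separation`` wins.
    """
    params = params or PrimerParams()
    product_min, product_max = product_range
    half = product_max // 2
    for enzyme, window, cut_allele in enzyme_hits:
        fwd_cands = enumerate_common_candidates(
            RegionSpec(site.chrom, max(1, site.pos - half + 1), window.start - 1),
            FORWARD, reference, mask, params,
        )
        rev_cands = enumerate_common_candidates(
            RegionSpec(site.chrom, window.end + 1, site.pos + half),
            REVERSE, reference, mask, params,
        )
        if len(fwd_cands) == 0 or len(rev_cands) == 0:
            continue
        # product sequence depends only on (fwd.start, rev.end): reduce
        fwd_cands = reduce_candidates(fwd_cands, by="start")
        rev_cands = reduce_candidates(rev_cands, by="end")
        sizes = rev_cands.ends[None, :] - fwd_cands.starts[:, None] + 1
        pens = fwd_cands.penalties[:, None] + rev_cands.penalties[None, :]
        ok = (sizes >= product_min) & (sizes <= product_max)
        if not ok.any():
            continue
        pens = np.where(ok, pens, np.inf)
        flat_order = np.argsort(pens, axis=None, kind="stable")
        # distinguishability rarely changes across nearby pairs; cap the
        # number of digested pairs to bound runtime
        n_ok = min(int(ok.sum()), 500)
        for flat in flat_order[:n_ok]:
            fi, ri = np.unravel_index(int(flat), pens.shape)
            fwd = candidate_primer(fwd_cands, int(fi), reference)
            rev = candidate_primer(rev_cands, int(ri), reference)
            product_seq = fetch_sequence(reference, site.chrom, fwd.start, rev.end)
            i_snp = site.pos - fwd.start
            ref_product = (
                product_seq[:i_snp] + site.ref_allele + product_seq[i_snp + 1 :]
            )
            alt_product = (
                product_seq[:i_snp] + site.alt_allele + product_seq[i_snp + 1 :]
            )
            frags_ref = digest(ref_product, enzyme)
            frags_alt = digest(alt_product, enzyme)
            if frags_ref == frags_alt:
                continue
            if not _patterns_distinguishable(frags_ref, frags_alt, min_band_separation):
                continue
            return CapsMarker(
                site=site,
                enzyme=enzyme,
                fwd=fwd,
                rev=rev,
                product_size=len(product_seq),
                cut_allele=cut_allele,
                fragments_ref=sorted(frags_ref),
                fragments_alt=sorted(frags_alt),
            )
    return None


def caps_markers_to_frame(markers: Iterable[CapsMarker]) -> pd.DataFrame:
    rows = [
        {
            "chrom": m.chrom,
            "snp": m.position,
            "enzyme": m.enzyme.name,
            "cut_allele": m.cut_allele,
            "product_size": m.product_size,
            "fragments_ref": ",".join(map(str, m.fragments_ref)),
            "fragments_alt": ",".join(map(str, m.fragments_alt)),
            "primer_fwd": m.fwd.seq,
            "primer_rev": m.rev.seq,
            "total_penalty": round(m.total_penalty, 4),
        }
        for m in markers
    ]
    return pd.DataFrame(rows)
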