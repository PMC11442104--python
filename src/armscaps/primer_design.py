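"""Allele-specific and common primer design at selected SNP sites.

Allele-specific (ARMS) primers put the discriminating SNP under the
primer's 3'-terminal base, so extension only proceeds on the matching
allele, and additionally carry a deliberate destabilizing substitution at
the third base from the 3' end ("2 bases upstream of the terminal
nucleotide") which sharpens allele discrimination during annealing. Up
to four specific primers exist per SNP: {cultivar-A allele, cultivar-B
allele} x {forward, reverse}.

Common primers pair with the specific ones and must sit on *consensus*
sequence: an exact reference match whose footprint shows no polymorphism
between the cultivars and whose coverage depth is within bounds in both.

Melting temperatures are nearest-neighbor (SantaLucia 1998 unified
parameters) at 50 mM monovalent salt and 50 nM total oligo. Candidate
ranking is by a penalty |Tm - Tm_opt| + 0.5 * |len - len_opt| with a
deterministic tie-break, so design is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .pileup_io import (
    BASES,
    PileupColumn,
    RegionSpec,
    ReferenceLike,
    fetch_sequence,
    snp_index,
)
from .snp_selection import SnpSite

# ---------------------------------------------------------------------------
# sequence utilities

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: deliberate-mismatch table: the original primer base is replaced by a
#: non-complementary base that can never silently restore a perfect match
SUBSTITUTION = {"A": "C", "C": "A", "G": "T", "T": "G"}

#: distance of the deliberate mismatch from the 3' end (1-based; the
#: terminal base itself is offset 1)
MISMATCH_OFFSET = 3


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_percent(seq: str) -> float:
    return 100.0 * sum(1 for b in seq if b in "GC") / len(seq)


def max_homopolymer_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


# ---------------------------------------------------------------------------
# nearest-neighbor melting temperature (SantaLucia 1998, unified)

_NN_DH = {
    "AA": -7.9, "TT": -7.9, "AT": -7.2, "TA": -7.2,
    "CA": -8.5, "TG": -8.5, "GT": -8.4, "AC": -8.4,
    "CT": -7.8, "AG": -7.8, "GA": -8.2, "TC": -8.2,
    "CG": -10.6, "GC": -9.8, "GG": -8.0, "CC": -8.0,
}
_NN_DS = {
    "AA": -22.2, "TT": -22.2, "AT": -20.4, "TA": -21.3,
    "CA": -22.7, "TG": -22.7, "GT": -22.4, "AC": -22.4,
    "CT": -21.0, "AG": -21.0, "GA": -22.2, "TC": -22.2,
    "CG": -27.2, "GC": -24.4, "GG": -19.9, "CC": -19.9,
}
_END_DH = {"A": 2.3, "T": 2.3, "G": 0.1, "C": 0.1}
_END_DS = {"A": 4.1, "T": 4.1, "G": -2.8, "C": -2.8}
_SYM_DS = -1.4

R_GAS = 1.987  # cal / (mol K)
NA_MILLIMOLAR = 50.0
DNAC1_NM = 25.0  # higher-concentration strand, nM
DNAC2_NM = 25.0  # lower-concentration strand, nM

_SALT_FACTOR = 0.368 * math.log(NA_MILLIMOLAR / 1000.0)  # per NN stack
_K_ASYM = (DNAC1_NM - DNAC2_NM / 2.0) * 1e-9
_K_SELF = DNAC1_NM * 1e-9

MIN_TM_LENGTH = 8


def melting_temperature(seq: str) -> float:
    """Nearest-neighbor Tm (deg C) of ``seq`` against its perfect complement.

    Conditions are fixed: 50 mM monovalent salt, 50 nM total oligo
    (SantaLucia 1998 salt correction on the entropy). Symmetric to
    reverse complementation, as a duplex property must be.
    """
    seq = seq.upper()
    if len(seq) < MIN_TM_LENGTH:
        raise ValueError(f"sequence too short for Tm ({len(seq)} < {MIN_TM_LENGTH})")
    if any(b not in "ACGT" for b in seq):
        raise ValueError(f"ambiguous bases in sequence {seq!r}")
    dh = _END_DH[seq[0]] + _END_DH[seq[-1]]
    ds = _END_DS[seq[0]] + _END_DS[seq[-1]]
    for i in range(len(seq) - 1):
        pair = seq[i : i + 2]
        dh += _NN_DH[pair]
        ds += _NN_DS[pair]
    if seq == reverse_complement(seq):
        ds += _SYM_DS
        k = _K_SELF
    else:
        k = _K_ASYM
    ds += _SALT_FACTOR * (len(seq) - 1)
    return 1000.0 * dh / (ds + R_GAS * math.log(k)) - 273.15


_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_DH_VEC = np.zeros(16)
_DS_VEC = np.zeros(16)
for _i, _a in enumerate("ACGT"):
    for _j, _b in enumerate("ACGT"):
        _DH_VEC[4 * _i + _j] = _NN_DH[_a + _b]
        _DS_VEC[4 * _i + _j] = _NN_DS[_a + _b]
_END_DH_VEC = np.array([_END_DH[b] for b in "ACGT"])
_END_DS_VEC = np.array([_END_DS[b] for b in "ACGT"])


def encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _tm_windows(codes: np.ndarray, length: int) -> np.ndarray:
    """Tm of every ``length``-mer window of an encoded A/C/G/T array.

    Vectorized twin of :func:`melting_temperature` (asymmetric-duplex
    branch); windows containing non-ACGT codes yield garbage and must be
    masked out by the caller.
    """
    safe = np.minimum(codes, 3).astype(np.int64)
    dinuc = 4 * safe[:-1] + safe[1:]
    dh_steps = np.concatenate([[0.0], np.cumsum(_DH_VEC[dinuc])])
    ds_steps = np.concatenate([[0.0], np.cumsum(_DS_VEC[dinuc])])
    n = len(codes) - length + 1
    idx = np.arange(n)
    dh = dh_steps[idx + length - 1] - dh_steps[idx]
    ds = ds_steps[idx + length - 1] - ds_steps[idx]
    dh = dh + _END_DH_VEC[safe[idx]] + _END_DH_VEC[safe[idx + length - 1]]
    ds = ds + _END_DS_VEC[safe[idx]] + _END_DS_VEC[safe[idx + length - 1]]
    ds = ds + _SALT_FACTOR * (length - 1)
    return 1000.0 * dh / (ds + R_GAS * math.log(_K_ASYM)) - 273.15


# ---------------------------------------------------------------------------
# parameters and the Primer record

@dataclass
class PrimerParams:
    """Hard constraints and optima for primer candidates.

    Length/Tm/GC defaults mirror common PCR-design practice (22-mers near
    60 deg C); ``max_nonref_freq`` is the minor-allele frequency above
    which a pileup position counts as polymorphic for footprint masking —
    high enough to ignore scattered base-call errors, low enough to catch
    any real allele (a simplex tetraploid SNP sits at 0.25).
    """

    len_min: int = 18
    len_opt: int = 22
    len_max: int = 28
    tm_min: float = 57.0
    tm_opt: float = 60.0
    tm_max: float = 63.0
    gc_min: float = 30.0
    gc_max: float = 70.0
    max_single_base_run: int = 4
    min_depth: int = 6
    max_depth: Optional[int] = None
    max_nonref_freq: float = 0.10
    penalty_len_weight: float = 0.5

    def __post_init__(self) -> None:
        if not self.len_min <= self.len_opt <= self.len_max:
            raise ValueError("primer length bounds must satisfy min <= opt <= max")
        if not self.tm_min <= self.tm_opt <= self.tm_max:
            raise ValueError("Tm bounds must satisfy min <= opt <= max")


FORWARD = "forward"
REVERSE = "reverse"
KIND_A = "specific_A"
KIND_B = "specific_B"
KIND_COMMON = "common"


@dataclass
class Primer:
    """An oriented oligo with its footprint on the reference strand.

    ``seq`` is always written 5'->3' on the primer's own strand; ``start``
    and ``end`` are 1-based inclusive reference coordinates regardless of
    orientation. For specific primers ``mismatch_pos`` is the 1-based
    offset of the deliberate substitution from the 3' end (always 3).
    """

    seq: str
    chrom: str
    start: int
    end: int
    orientation: str
    kind: str
    tm: float
    gc: float
    penalty: float
    target_pos: Optional[int] = None
    allele: Optional[str] = None
    mismatch_pos: Optional[int] = None
    site_label: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.seq) != self.end - self.start + 1:
            raise ValueError(
                f"primer length {len(self.seq)} != footprint "
                f"{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def three_prime_pos(self) -> int:
        """Reference coordinate under the primer's 3'-terminal base."""
        return self.end if self.orientation == FORWARD else self.start

    @property
    def five_prime_pos(self) -> int:
        return self.start if self.orientation == FORWARD else self.end


def primer_penalty(candidate, params: PrimerParams) -> float:
    """Soft score among hard-valid candidates; 0 at the joint optimum."""
    if isinstance(candidate, Primer):
        tm, length = candidate.tm, len(candidate.seq)
    else:
        tm, length = candidate
    return abs(tm - params.tm_opt) + params.penalty_len_weight * abs(
        length - params.len_opt
    )


# ---------------------------------------------------------------------------
# footprint masks from pileups

class RegionMask:
    """Per-position footprint validity over a region, from two pileups.

    ``polymorphic``: either cultivar shows a non-reference base above
    ``max_nonref_freq``, or the position is a known SNP site.
    ``depth_ok``: both cultivars' depths are within [min_depth, max_depth]
    (absent positions have depth 0 and fail).
    """

    def __init__(
        self,
        region: RegionSpec,
        cols_a: Sequence[PileupColumn],
        cols_b: Sequence[PileupColumn],
        params: PrimerParams,
        known_sites: Iterable[SnpSite] = (),
    ) -> None:
        self.region = region
        n = len(region)
        self.polymorphic = np.zeros(n, dtype=bool)
        self.depth_ok = np.ones(n, dtype=bool)
        for cols in (cols_a, cols_b):
            max_depth = params.max_depth
            if max_depth is None:
                depths = [c.depth for c in cols]
                max_depth = max(
                    params.min_depth, int(round(3 * np.mean(depths))) if depths else 0
                )
            covered = np.zeros(n, dtype=bool)
            for col in cols:
                if not (region.start <= col.pos <= region.end):
                    continue
                i = col.pos - region.start
                covered[i] = True
                if not (params.min_depth <= col.depth <= max_depth):
                    self.depth_ok[i] = False
                for b in BASES:
                    if b != col.ref_base and b in col.counts:
                        if snp_index(col, b) > params.max_nonref_freq:
                            self.polymorphic[i] = True
            self.depth_ok &= covered
        for site in known_sites:
            if region.start <= site.pos <= region.end:
                self.polymorphic[site.pos - region.start] = True

    def _slice(self, start: int, end: int) -> slice:
        return slice(start - self.region.start, end - self.region.start + 1)

    def contains(self, start: int, end: int) -> bool:
        return self.region.start <= start and end <= self.region.end

    def footprint_clean(self, start: int, end: int, ignore_pos: Optional[int] = None) -> bool:
        """True when a footprint has valid depth and no polymorphism
        (optionally exempting the target SNP position itself)."""
        if not self.contains(start, end):
            return False
        sl = self._slice(start, end)
        if not self.depth_ok[sl].all():
            return False
        poly = self.polymorphic[sl]
        if ignore_pos is not None and start <= ignore_pos <= end:
            poly = poly.copy()
            poly[ignore_pos - start] = False
        return not poly.any()


# ---------------------------------------------------------------------------
# allele-specific primers

def _specific_candidate(
    reference: ReferenceLike,
    site: SnpSite,
    allele: str,
    orientation: str,
    length: int,
) -> Tuple[str, int, int]:
    """Build the (seq, start, end) of one allele-specific candidate."""
    if orientation == FORWARD:
        start, end = site.pos - length + 1, site.pos
        context = fetch_sequence(reference, site.chrom, start, end - 1)
        primer = context + allele
    else:
        start, end = site.pos, site.pos + length - 1
        context = fetch_sequence(reference, site.chrom, start + 1, end)
        primer = reverse_complement(allele + context)
    i = length - MISMATCH_OFFSET  # third base from the 3' end
    primer = primer[:i] + SUBSTITUTION[primer[i]] + primer[i + 1 :]
    return primer, start, end


def design_specific_primers(
    site: SnpSite,
    reference: ReferenceLike,
    mask: RegionMask,
    params: Optional[PrimerParams] = None,
) -> List[Primer]:
    """Design up to four ARMS primers at one SNP site.

    For each allele (cultivar-A reference allele, cultivar-B alternative
    allele) and each orientation, candidate lengths len_min..len_max are
    scanned with the 3' end fixed on the SNP; candidates violating
    Tm/GC/homopolymer bounds, containing another polymorphism, or lying
    on out-of-range coverage are rejected, and the minimum-penalty
    survivor per (allele, orientation) is returned. An empty slot simply
    yields no primer; a site with all four slots empty is unusable for
    ARMS.
    """
    params = params or PrimerParams()
    primers: List[Primer] = []
    for kind, allele in ((KIND_A, site.ref_allele), (KIND_B, site.alt_allele)):
        for orientation in (FORWARD, REVERSE):
            best: Optional[Primer] = None
            best_key = None
            for length in range(params.len_min, params.len_max + 1):
                try:
                    seq, start, end = _specific_candidate(
                        reference, site, allele, orientation, length
                    )
                except Exception:
                    continue
                if not mask.footprint_clean(start, end, ignore_pos=site.pos):
                    continue
                gc = gc_percent(seq)
                if not params.gc_min <= gc <= params.gc_max:
                    continue
                if max_homopolymer_run(seq) > params.max_single_base_run:
                    continue
                try:
                    tm = melting_temperature(seq)
                except ValueError:
                    continue
                if not params.tm_min <= tm <= params.tm_max:
                    continue
                penalty = primer_penalty((tm, length), params)
                key = (penalty, start, seq)
                if best_key is None or key < best_key:
                    best_key = key
                    best = Primer(
                        seq=seq,
                        chrom=site.chrom,
                        start=start,
                        end=end,
                        orientation=orientation,
                        kind=kind,
                        tm=tm,
                        gc=gc,
                        penalty=penalty,
                        target_pos=site.pos,
                        allele=allele,
                        mismatch_pos=MISMATCH_OFFSET,
                        site_label=site.label,
                    )
            if best is not None:
                primers.append(best)
    return primers


# ---------------------------------------------------------------------------
# common primers

@dataclass
class CommonCandidates:
    """Vectorized enumeration result: parallel candidate arrays."""

    chrom: str
    orientation: str
    starts: np.ndarray  # 1-based footprint start
    lengths: np.ndarray
    tms: np.ndarray
    gcs: np.ndarray
    penalties: np.ndarray

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def ends(self) -> np.ndarray:
        return self.starts + self.lengths - 1


def enumerate_common_candidates(
    window: RegionSpec,
    orientation: str,
    reference: ReferenceLike,
    mask: RegionMask,
    params: Optional[PrimerParams] = None,
) -> CommonCandidates:
    """All valid common-primer candidates whose footprint lies in ``window``.

    A candidate is an exact reference substring (reverse-complemented for
    reverse orientation) that is polymorphism-free, depth-valid in both
    cultivars, and within GC/Tm/homopolymer bounds.
    """
    params = params or PrimerParams()
    empty = CommonCandidates(
        window.chrom, orientation,
        *(np.array([], dtype=int) for _ in range(2)),
        *(np.array([], dtype=float) for _ in range(3)),
    )
    ws = max(window.start, mask.region.start)
    we = min(window.end, mask.region.end)
    if we - ws + 1 < params.len_min:
        return empty
    seq = fetch_sequence(reference, window.chrom, ws, we)
    codes = encode(seq)
    n = len(codes)
    ok = (codes < 4)
    sl = slice(ws - mask.region.start, we - mask.region.start + 1)
    ok &= mask.depth_ok[sl] & ~mask.polymorphic[sl]
    ok_cum = np.concatenate([[0], np.cumsum(ok)])
    gc_cum = np.concatenate([[0], np.cumsum((codes == 1) | (codes == 2))])
    run_limit = params.max_single_base_run
    bad = np.zeros(n, dtype=np.int64)
    if n > run_limit:
        same = np.ones(n, dtype=np.int64)
        for k in range(1, run_limit + 1):
            same[k:] &= codes[k:] == codes[:-k]
            same[:k] = 0
        bad = same  # run of (run_limit+1) identical bases ends here
    bad_cum = np.concatenate([[0], np.cumsum(bad)])

    all_starts, all_lens, all_tms, all_gcs, all_pens = [], [], [], [], []
    for length in range(params.len_min, min(params.len_max, n) + 1):
        m = n - length + 1
        i = np.arange(m)
        valid = (ok_cum[i + length] - ok_cum[i]) == length
        gc_frac = 100.0 * (gc_cum[i + length] - gc_cum[i]) / length
        valid &= (gc_frac >= params.gc_min) & (gc_frac <= params.gc_max)
        # homopolymer: any over-long run fully inside the window
        lo = np.minimum(i + run_limit, n)
        hi = np.minimum(i + length, n)
        valid &= (bad_cum[hi] - bad_cum[lo]) == 0
        if not valid.any():
            continue
        tms = _tm_windows(codes, length)
        valid &= (tms >= params.tm_min) & (tms <= params.tm_max)
        if not valid.any():
            continue
        idx = np.nonzero(valid)[0]
        all_starts.append(ws + idx)
        all_lens.append(np.full(len(idx), length))
        all_tms.append(tms[idx])
        all_gcs.append(gc_frac[idx])
        all_pens.append(
            np.abs(tms[idx] - params.tm_opt)
            + params.penalty_len_weight * abs(length - params.len_opt)
        )
    if not all_starts:
        return empty
    return CommonCandidates(
        chrom=window.chrom,
        orientation=orientation,
        starts=np.concatenate(all_starts),
        lengths=np.concatenate(all_lens),
        tms=np.concatenate(all_tms),
        gcs=np.concatenate(all_gcs),
        penalties=np.concatenate(all_pens),
    )


def reduce_candidates(cands: CommonCandidates, by: str) -> CommonCandidates:
    """Keep the best candidate per distinct footprint edge.

    Product sizes (and amplicon sequences) depend only on the footprint
    start of a forward primer / end of a reverse primer, so for pairwise
    assembly searches it suffices to retain the minimum-penalty candidate
    per distinct edge (``by`` is 'start' or 'end'); ties broken by
    shorter length for determinism.
    """
    if len(cands) == 0:
        return cands
    keys = cands.starts if by == "start" else cands.ends
    order = np.lexsort((cands.lengths, cands.penalties, keys))
    keep: Dict[int, int] = {}
    for i in order:
        keep.setdefault(int(keys[i]), int(i))
    idx = np.array(sorted(keep.values()), dtype=int)
    return CommonCandidates(
        chrom=cands.chrom,
        orientation=cands.orientation,
        starts=cands.starts[idx],
        lengths=cands.lengths[idx],
        tms=cands.tms[idx],
        gcs=cands.gcs[idx],
        penalties=cands.penalties[idx],
    )


def candidate_primer(
    cands: CommonCandidates, i: int, reference: ReferenceLike
) -> Primer:
    """Materialize candidate ``i`` as a Primer (5'->3' on its own strand)."""
    start = int(cands.starts[i])
    length = int(cands.lengths[i])
    end = start + length - 1
    seq = fetch_sequence(reference, cands.chrom, start, end)
    if cands.orientation == REVERSE:
        seq = reverse_complement(seq)
    return Primer(
        seq=seq,
        chrom=cands.chrom,
        start=start,
        end=end,
        orientation=cands.orientation,
        kind=KIND_COMMON,
        tm=float(cands.tms[i]),
        gc=float(cands.gcs[i]),
        penalty=float(cands.penalties[i]),
    )


def _best_index(cands: CommonCandidates, reference: ReferenceLike) -> Optional[int]:
    if len(cands) == 0:
        return None
    order = np.lexsort((cands.starts, cands.penalties))
    best = order[0]
    # tie-break: smaller start, then lexicographic sequence
    ties = order[
        (cands.penalties[order] == cands.penalties[best])
        & (cands.starts[order] == cands.starts[best])
    ]
    if len(ties) > 1:
        best = min(
            ties, key=lambda j: candidate_primer(cands, int(j), reference).seq
        )
    return int(best)


def design_common_primer(
    window: RegionSpec,
    orientation: str,
    reference: ReferenceLike,
    pileups_a: Optional[Sequence[PileupColumn]] = None,
    pileups_b: Optional[Sequence[PileupColumn]] = None,
    known_sites: Iterable[SnpSite] = (),
    params: Optional[PrimerParams] = None,
    mask: Optional[RegionMask] = None,
) -> Optional[Primer]:
    """Best common primer inside ``window``, or None if none qualifies.

    Either a prebuilt :class:`RegionMask` or the two cultivars' pileups
    must be supplied.
    """
    params = params or PrimerParams()
    if mask is None:
        if pileups_a is None or pileups_b is None:
            raise ValueError("either mask or both pileup lists are required")
        mask = RegionMask(window, pileups_a, pileups_b, params, known_sites)
    cands = enumerate_common_candidates(window, orientation, reference, mask, params)
    best = _best_index(cands, reference)
    if best is None:
        return None
    return candidate_primer(cands, best, reference)


# ---------------------------------------------------------------------------
# TSV serialization (handoff to the assembly stages)

PRIMER_COLUMNS = [
    "chrom", "start", "end", "orientation", "kind", "target_pos",
    "allele", "seq", "tm", "gc", "penalty", "mismatch_pos", "site_label",
]


def primers_to_frame(primers: Iterable[Primer]) -> pd.DataFrame:
    rows = [
        {
            "chrom": p.chrom,
            "start": p.start,
            "end": p.end,
            "orientation": p.orientation,
            "kind": p.kind,
            "target_pos": p.target_pos,
            "allele": p.allele,
            "seq": p.seq,
            "tm": round(p.tm, 3),
            "gc": round(p.gc, 3),
            "penalty": round(p.penalty, 4),
            "mismatch_pos": p.mismatch_pos,
            "site_label": p.site_label,
        }
        for p in primers
    ]
    return pd.DataFrame(rows, columns=PRIMER_COLUMNS)


def write_primers_tsv(primers: Iterable[Primer], path: str) -> None:
    primers_to_frame(primers).to_csv(path, sep="\t", index=False)


def read_primers_tsv(path: str) -> List[Primer]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out: List[Primer] = []
    for r in df.itertuples():
        out.append(
            Primer(
                seq=str(r.seq),
                chrom=str(r.chrom),
                start=int(r.start),
                end=int(r.end),
                orientation=str(r.orientation),
                kind=str(r.kind),
                tm=float(r.tm),
                gc=float(r.gc),
                penalty=float(r.penalty),
                target_pos=None if pd.isna(r.target_pos) else int(r.target_pos),
                allele=None if pd.isna(r.allele) else str(r.allele),
                mismatch_pos=None if pd.isna(r.mismatch_pos) else int(r.mismatch_pos),
                site_label=None if pd.isna(r.site_label) else str(r.site_label),
            )
        )
    return out
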