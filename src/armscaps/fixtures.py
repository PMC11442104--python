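"""Synthetic references and alignments with controlled SNP truth.

The generator emulates the pipeline's real inputs — two cultivars (and
optionally a progeny bulk) resequenced against a shared reference — at
desk scale and fully seeded. Reads are synthesized pre-aligned (perfect
full-match CIGARs, uniform qualities): the pipeline consumes alignments,
so putting an aligner in the loop would only add nondeterminism. At
each declared SNP a read carries the variant allele with probability
dosage/ploidy independently per covered site, so per-position variant
counts are Binomial(local depth, dosage/ploidy) exactly as the
SNP-index model assumes. Uniform substitution errors are injected at a
configurable per-base rate.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pysam

DEFAULT_CHROM = "chr1"
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SnpSpec:
    """Truth for one SNP: position, alleles, per-cultivar variant dosage."""

    pos: int  # 1-based
    ref: str
    alt: str
    dosage_A: int
    dosage_B: int


@dataclass
class FixtureSpec:
    """Study conditions for one synthetic dataset.

    Defaults describe a small but realistic short-read resequencing
    experiment: 100 kb of 45% GC sequence at 30x with 100 bp reads and a
    0.1% substitution-error rate, diploid unless stated otherwise.
    """

    genome_length: int = 100_000
    gc_content: float = 0.45
    snp_specs: List[SnpSpec] = field(default_factory=list)
    ploidy: int = 2
    depth: float = 30.0
    read_length: int = 100
    error_rate: float = 0.001
    seed: int = 0
    chrom: str = DEFAULT_CHROM

    def __post_init__(self) -> None:
        if self.genome_length < self.read_length:
            raise ValueError("genome shorter than a read")
        positions = [s.pos for s in self.snp_specs]
        if len(set(positions)) != len(positions):
            raise ValueError("duplicate SNP positions")
        if positions != sorted(positions):
            raise ValueError("SNP positions must be sorted")
        for s in self.snp_specs:
            if not (self.read_length <= s.pos <= self.genome_length - self.read_length):
                raise ValueError(
                    f"SNP at {s.pos} closer than read_length to a genome end"
                )
            if not (0 <= s.dosage_A <= self.ploidy and 0 <= s.dosage_B <= self.ploidy):
                raise ValueError(f"dosage outside [0, ploidy] at {s.pos}")


def generate_reference(spec: FixtureSpec) -> str:
    """Seeded pseudo-random genome at the requested GC content."""
    rng = np.random.default_rng(spec.seed)
    gc = spec.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    seq = rng.choice(_BASES, size=spec.genome_length, p=probs)
    # force declared reference alleles
    for s in spec.snp_specs:
        seq[s.pos - 1] = s.ref
    return "".join(seq)


def random_snp_specs(
    n: int,
    spec: FixtureSpec,
    reference: str,
    dosage_A: int = 0,
    dosage_B: Optional[int] = None,
    min_spacing: int = 40,
    region: Optional[Tuple[int, int]] = None,
    seed_offset: int = 1,
) -> List[SnpSpec]:
    """Place ``n`` SNPs uniformly with a minimum spacing.

    ``dosage_B=None`` defaults to the ploidy (the fully homozygous
    cultivar-B-specific case). Alt alleles are drawn uniformly from the
    three non-reference bases.
    """
    if dosage_B is None:
        dosage_B = spec.ploidy
    rng = np.random.default_rng(spec.seed + seed_offset)
    lo = spec.read_length if region is None else max(region[0], spec.read_length)
    hi = (
        spec.genome_length - spec.read_length
        if region is None
        else min(region[1], spec.genome_length - spec.read_length)
    )
    chosen: List[int] = []
    candidates = rng.permutation(np.arange(lo, hi + 1))
    for pos in candidates:
        if all(abs(int(pos) - c) >= min_spacing for c in chosen):
            chosen.append(int(pos))
            if len(chosen) == n:
                break
    if len(chosen) < n:
        raise ValueError(f"could not place {n} SNPs with spacing {min_spacing}")
    chosen.sort()
    specs = []
    for pos in chosen:
        ref = reference[pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        specs.append(SnpSpec(pos, ref, alt, dosage_A, dosage_B))
    return specs


def paired_snp_specs(
    n_pairs: int,
    spec: FixtureSpec,
    reference: str,
    pair_spacing: Tuple[int, int] = (120, 280),
    cluster_spacing: int = 2_000,
    dosage_A: int = 0,
    dosage_B: Optional[int] = None,
    seed_offset: int = 2,
) -> List[SnpSpec]:
    """Place SNPs in pairs 120-280 bp apart: the geometry tri-ARMS needs.

    Pairs are spread ``cluster_spacing`` bp apart so markers stay
    independent. Dosages as in :func:`random_snp_specs`.
    """
    if dosage_B is None:
        dosage_B = spec.ploidy
    rng = np.random.default_rng(spec.seed + seed_offset)
    lo = spec.read_length
    hi = spec.genome_length - spec.read_length
    span = hi - lo
    if n_pairs * cluster_spacing > span:
        raise ValueError("genome too short for the requested pair count")
    specs: List[SnpSpec] = []
    for i in range(n_pairs):
        anchor = lo + i * cluster_spacing + int(rng.integers(0, cluster_spacing // 4))
        gap = int(rng.integers(pair_spacing[0], pair_spacing[1] + 1))
        for pos in (anchor, anchor + gap):
            if pos > hi:
                raise ValueError("pair placement overflows the genome")
            ref = reference[pos - 1]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            specs.append(SnpSpec(pos, ref, alt, dosage_A, dosage_B))
    specs.sort(key=lambda s: s.pos)
    return specs


def enzyme_site_snp_specs(
    n: int,
    spec: FixtureSpec,
    reference: str,
    motif: str = "AGCT",
    mutate_offset: int = 1,
    alt: str = "A",
    avoid: Sequence[int] = (),
    min_spacing: int = 1_000,
    dosage_A: int = 0,
    dosage_B: Optional[int] = None,
    seed_offset: int = 3,
) -> List[SnpSpec]:
    """Plant SNPs that destroy a restriction motif in the variant allele.

    Scans the reference for ``motif`` occurrences and declares a SNP at
    ``mutate_offset`` within the motif whose alternative allele breaks
    it — a guaranteed CAPS-discriminating site (cut allele = reference).
    """
    if dosage_B is None:
        dosage_B = spec.ploidy
    ref_base = motif[mutate_offset]
    if alt == ref_base:
        raise ValueError("alt allele must differ from the motif base")
    rng = np.random.default_rng(spec.seed + seed_offset)
    lo = spec.read_length
    hi = spec.genome_length - spec.read_length
    occurrences = []
    i = reference.find(motif)
    while i != -1:
        pos = i + 1 + mutate_offset  # 1-based SNP position
        if lo <= pos <= hi:
            occurrences.append(pos)
        i = reference.find(motif, i + 1)
    rng.shuffle(occurrences)
    chosen: List[int] = []
    blocked = list(avoid)
    for pos in occurrences:
        if all(abs(pos - b) >= min_spacing for b in blocked):
            chosen.append(pos)
            blocked.append(pos)
            if len(chosen) == n:
                break
    if len(chosen) < n:
        raise ValueError(f"only {len(chosen)} clean {motif} occurrences found")
    return [
        SnpSpec(pos, ref_base, alt, dosage_A, dosage_B) for pos in sorted(chosen)
    ]


def write_reference_fasta(reference: str, path: str, chrom: str = DEFAULT_CHROM) -> None:
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(reference), 60):
            fh.write(reference[i : i + 60] + "\n")


def _sample_reads(
    spec: FixtureSpec,
    reference: str,
    dosages: Dict[int, Tuple[str, float]],
    rng: np.random.Generator,
) -> List[Tuple[int, str]]:
    """(0-based start, read sequence) pairs at ~spec.depth mean coverage."""
    n_reads = int(round(spec.genome_length * spec.depth / spec.read_length))
    starts = np.sort(
        rng.integers(0, spec.genome_length - spec.read_length + 1, size=n_reads)
    )
    reads: List[Tuple[int, str]] = []
    snp_positions = np.array(sorted(dosages), dtype=int)
    for start in starts:
        start = int(start)
        bases = list(reference[start : start + spec.read_length])
        if len(snp_positions):
            lo = np.searchsorted(snp_positions, start + 1)
            hi = np.searchsorted(snp_positions, start + spec.read_length, side="right")
            for pos in snp_positions[lo:hi]:
                alt, p = dosages[int(pos)]
                if p > 0 and rng.random() < p:
                    bases[int(pos) - 1 - start] = alt
        if spec.error_rate > 0:
            n_err = rng.binomial(spec.read_length, spec.error_rate)
            for i in rng.integers(0, spec.read_length, size=n_err):
                cur = bases[int(i)]
                bases[int(i)] = str(
                    rng.choice([b for b in "ACGT" if b != cur])
                )
        reads.append((start, "".join(bases)))
    return reads


def _write_sam(
    reads: Sequence[Tuple[int, str]],
    spec: FixtureSpec,
    path: str,
    sample: str,
) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": spec.chrom, "LN": spec.genome_length}],
        "RG": [{"ID": sample, "SM": sample}],
    }
    with pysam.AlignmentFile(path, "wh", header=header) as out:
        for i, (start, seq) in enumerate(reads):
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"{sample}_read{i}"
            a.query_sequence = seq
            a.flag = 0
            a.reference_id = 0
            a.reference_start = start
            a.mapping_quality = 60
            a.cigarstring = f"{len(seq)}M"
            a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            a.set_tag("RG", sample)
            out.write(a)


def generate_alignments(
    spec: FixtureSpec,
    reference: str,
    outdir: str,
    progeny: bool = False,
) -> Dict[str, str]:
    """Write SAM files for cultivars A and B (and optionally an F2 bulk).

    Returns a dict with paths for keys 'reference', 'A', 'B' (and
    'progeny'), plus 'manifest' recording the truth for assertions. The
    progeny bulk carries each segregating allele at dosage 1 of ploidy 2
    (F1-equivalent heterozygosity at every declared SNP).
    """
    os.makedirs(outdir, exist_ok=True)
    ref_path = os.path.join(outdir, "reference.fasta")
    write_reference_fasta(reference, ref_path, spec.chrom)

    paths = {"reference": ref_path}
    rng = np.random.default_rng(spec.seed + 1000)
    samples = {
        "A": {s.pos: (s.alt, s.dosage_A / spec.ploidy) for s in spec.snp_specs},
        "B": {s.pos: (s.alt, s.dosage_B / spec.ploidy) for s in spec.snp_specs},
    }
    if progeny:
        segregating = {
            s.pos: (s.alt, 0.5) for s in spec.snp_specs if s.dosage_A != s.dosage_B
        }
        samples["progeny"] = segregating
    for name, dosages in samples.items():
        sam_path = os.path.join(outdir, f"cultivar_{name}.sam")
        reads = _sample_reads(spec, reference, dosages, rng)
        _write_sam(reads, spec, sam_path, name)
        paths[name] = sam_path

    manifest = {
        "chrom": spec.chrom,
        "genome_length": spec.genome_length,
        "ploidy": spec.ploidy,
        "depth": spec.depth,
        "read_length": spec.read_length,
        "error_rate": spec.error_rate,
        "seed": spec.seed,
        "snps": [
            {
                "pos": s.pos,
                "ref": s.ref,
                "alt": s.alt,
                "dosage_A": s.dosage_A,
                "dosage_B": s.dosage_B,
            }
            for s in spec.snp_specs
        ],
    }
    manifest_path = os.path.join(outdir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    paths["manifest"] = manifest_path
    return paths


def haplotypes(spec: FixtureSpec, reference: str) -> Dict[str, str]:
    """Variant-carrying haplotype per cultivar (alt applied wherever
    dosage > 0) plus the reference haplotype, for in-silico PCR."""
    hap_a = list(reference)
    hap_b = list(reference)
    for s in spec.snp_specs:
        if s.dosage_A > 0:
            hap_a[s.pos - 1] = s.alt
        if s.dosage_B > 0:
            hap_b[s.pos - 1] = s.alt
    return {"ref": reference, "A": "".join(hap_a), "B": "".join(hap_b)}


def simulate_pileup_counts(
    n_sites: int,
    depth: int,
    dosage: int,
    ploidy: int,
    seed: int,
) -> np.ndarray:
    """Variant read counts for ``n_sites`` positions at fixed depth.

    A fast path for statistical tests of the dosage filters: equivalent
    to generating reads and piling them up, because per-site variant
    counts are Binomial(depth, dosage/ploidy) by construction.
    """
    rng = np.random.default_rng(seed)
    return rng.binomial(depth, dosage / ploidy, size=n_sites)
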