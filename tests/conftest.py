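"""Shared fixtures: hand-built SAM files and a full synthetic pipeline run."""

from __future__ import annotations

import textwrap
from dataclasses import dataclass, field, replace
from typing import Dict, List

import pytest
from pyfaidx import Fasta

from armscaps import fixtures as fx
from armscaps.arms_assembly import assemble_tetra_arms, assemble_tri_arms
from armscaps.caps_design import (
    design_caps_marker,
    find_discriminating_enzymes,
    read_enzyme_tsv,
)
from armscaps.pileup_io import RegionSpec, extract_pileup, open_alignment
from armscaps.primer_design import PrimerParams, RegionMask, design_specific_primers
from armscaps.snp_selection import SelectionFilters, select_target_snps

SAM_HEADER = "@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:chr1\tLN:{length}\n"


def write_sam(path, reads, ref_length=500):
    """reads: list of (name, flag, pos_1based, mapq, cigar, seq)."""
    lines = [SAM_HEADER.format(length=ref_length).rstrip("\n")]
    for name, flag, pos, mapq, cigar, seq in reads:
        lines.append(
            "\t".join(
                [
                    name, str(flag), "chr1", str(pos), str(mapq), cigar,
                    "*", "0", "0", seq, "I" * len(seq),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")
    return str(path)


@pytest.fixture()
def tiny_reference(tmp_path):
    """A 500 bp single-chromosome reference with an A at position 100."""
    seq = ("ACGT" * 125)[:500]
    # force position 100 (1-based) to A for the pileup examples
    seq = seq[:99] + "A" + seq[100:]
    fasta = tmp_path / "ref.fa"
    fasta.write_text(">chr1\n" + "\n".join(textwrap.wrap(seq, 60)) + "\n")
    return {"path": str(fasta), "seq": seq, "fasta": Fasta(str(fasta))}


@dataclass
class PipelineRun:
    """A full marker-design run on one synthetic dataset, with truth."""

    spec: fx.FixtureSpec
    reference_seq: str
    paths: Dict[str, str]
    fasta: Fasta
    region: RegionSpec
    cols_a: list
    cols_b: list
    sites: list
    params: PrimerParams
    mask: RegionMask
    primers: list
    tri: list
    tetra: list
    caps: list
    haplotypes: Dict[str, str]


def run_pipeline(spec: fx.FixtureSpec, reference: str, outdir) -> PipelineRun:
    paths = fx.generate_alignments(spec, reference, str(outdir))
    fasta = Fasta(paths["reference"])
    region = RegionSpec(spec.chrom, 1, spec.genome_length)
    cols_a = extract_pileup(open_alignment(paths["A"]), fasta, region)
    cols_b = extract_pileup(open_alignment(paths["B"]), fasta, region)
    sites = select_target_snps(cols_a, cols_b, fasta, SelectionFilters())
    params = PrimerParams()
    mask = RegionMask(region, cols_a, cols_b, params, known_sites=sites)
    primers = []
    for site in sites:
        primers.extend(design_specific_primers(site, fasta, mask, params))
    tri = assemble_tri_arms(primers, fasta, mask, params)
    tetra = assemble_tetra_arms(primers, fasta, mask, params)
    enzymes = read_enzyme_tsv()
    caps = []
    for site in sites:
        hits = find_discriminating_enzymes(site, fasta, enzymes)
        if hits:
            marker = design_caps_marker(site, hits, fasta, mask, params)
            if marker is not None:
                caps.append(marker)
    return PipelineRun(
        spec=spec,
        reference_seq=reference,
        paths=paths,
        fasta=fasta,
        region=region,
        cols_a=cols_a,
        cols_b=cols_b,
        sites=sites,
        params=params,
        mask=mask,
        primers=primers,
        tri=tri,
        tetra=tetra,
        caps=caps,
        haplotypes=fx.haplotypes(spec, reference),
    )


def standard_fixture_spec(seed: int = 11) -> fx.FixtureSpec:
    """100 kb diploid genome, 40 SNPs (18 tri-suitable pairs + 4 planted
    AluI-destroying SNPs), 30x coverage — the standard study conditions."""
    spec = fx.FixtureSpec(genome_length=100_000, seed=seed)
    reference = fx.generate_reference(spec)
    pairs = fx.paired_snp_specs(18, spec, reference, cluster_spacing=5_000)
    planted = fx.enzyme_site_snp_specs(
        4, spec, reference, avoid=[s.pos for s in pairs]
    )
    snps = sorted(pairs + planted, key=lambda s: s.pos)
    spec.snp_specs = snps
    spec.__post_init__()
    return spec


@pytest.fixture(scope="session")
def e2e(tmp_path_factory) -> PipelineRun:
    """The standard end-to-end run, shared across test modules."""
    spec = standard_fixture_spec()
    reference = fx.generate_reference(spec)
    outdir = tmp_path_factory.mktemp("e2e")
    return run_pipeline(spec, reference, outdir)
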