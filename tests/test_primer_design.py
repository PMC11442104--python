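"""Melting temperature, allele-specific and common primer design."""

import numpy as np
import pytest
from Bio.SeqUtils import MeltingTemp as bio_mt

from armscaps.pileup_io import PileupColumn, RegionSpec
from armscaps.primer_design import (
    FORWARD,
    REVERSE,
    Primer,
    PrimerParams,
    RegionMask,
    design_common_primer,
    design_specific_primers,
    encode,
    gc_percent,
    max_homopolymer_run,
    melting_temperature,
    primer_penalty,
    reverse_complement,
    _tm_windows,
)
from armscaps.snp_selection import SnpSite


def uniform_pileups(region, seq, depth=30):
    """Error-free pileups matching the reference everywhere."""
    return [
        PileupColumn("chr1", pos, seq[pos - 1], {seq[pos - 1]: depth})
        for pos in range(region.start, region.end + 1)
    ]


class TestMeltingTemperature:
    def test_gc_rich_melts_higher(self):
        assert melting_temperature("GCGCGCGCGC") > melting_temperature("AAAAAAAAAA")

    @pytest.mark.parametrize(
        "seq", ["AGGCATCGATTGCGCCAC", "ACGTACGTACGTACGTACGT", "TTTTGGGGCCCCAAAA"]
    )
    def test_duplex_symmetry(self, seq):
        assert melting_temperature(seq) == pytest.approx(
            melting_temperature(reverse_complement(seq))
        )

    def test_matches_independent_nearest_neighbor_calculator(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            seq = "".join(rng.choice(list("ACGT"), size=20))
            assert melting_temperature(seq) == pytest.approx(
                float(bio_mt.Tm_NN(seq)), abs=0.5
            )

    def test_ambiguous_bases_rejected(self):
        with pytest.raises(ValueError):
            melting_temperature("ACGTNACGTNAC")

    def test_vectorized_windows_equal_scalar(self):
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        codes = encode(seq)
        for length in (18, 22, 28):
            tms = _tm_windows(codes, length)
            for i in (0, 57, 211):
                assert tms[i] == pytest.approx(
                    melting_temperature(seq[i : i + length]), abs=1e-9
                )


# the worked example: a 50 nt reference with a T>C SNP at position 25
EXAMPLE_REF = "TTGACCTAGGCATCGATTGCGCAATGCCTAGGATCGTTACGGCATTGACC"


class TestSpecificPrimers:
    @pytest.fixture()
    def example(self):
        region = RegionSpec("chr1", 1, 50)
        site = SnpSite("chr1", 25, "T", "C", 0.0, 1.0, 30, 30, "homozygous")
        reference = {"chr1": EXAMPLE_REF}
        pileups = uniform_pileups(region, EXAMPLE_REF)
        params = PrimerParams(
            len_min=18, len_opt=18, len_max=18, tm_min=0, tm_opt=60, tm_max=100,
            gc_min=0, gc_max=100, min_depth=1, max_depth=100,
        )
        mask = RegionMask(region, pileups, pileups, params, known_sites=[site])
        return site, reference, mask, params

    def test_forward_alt_specific_sequence(self, example):
        site, reference, mask, params = example
        primers = design_specific_primers(site, reference, mask, params)
        fwd_alt = next(
            p for p in primers if p.kind == "specific_B" and p.orientation == FORWARD
        )
        assert (fwd_alt.start, fwd_alt.end) == (8, 25)
        assert fwd_alt.seq == "AGGCATCGATTGCGCCAC"
        assert fwd_alt.seq[-1] == site.alt_allele
        assert fwd_alt.mismatch_pos == 3

    def test_forward_ref_specific_sequence(self, example):
        site, reference, mask, params = example
        primers = design_specific_primers(site, reference, mask, params)
        fwd_ref = next(
            p for p in primers if p.kind == "specific_A" and p.orientation == FORWARD
        )
        assert fwd_ref.seq == "AGGCATCGATTGCGCCAT"
        assert fwd_ref.seq[-1] == site.ref_allele

    def test_reverse_primer_three_prime_is_allele_complement(self, example):
        site, reference, mask, params = example
        primers = design_specific_primers(site, reference, mask, params)
        rev_alt = next(
            p for p in primers if p.kind == "specific_B" and p.orientation == REVERSE
        )
        assert rev_alt.seq[-1] == reverse_complement(site.alt_allele)
        assert (rev_alt.start, rev_alt.end) == (25, 42)

    def test_exactly_one_internal_difference_from_own_haplotype(self, example):
        """Each specific primer matches its allele's haplotype everywhere
        except the single deliberate substitution."""
        site, reference, mask, params = example
        for p in design_specific_primers(site, reference, mask, params):
            hap = EXAMPLE_REF
            if p.kind == "specific_B":
                hap = hap[:24] + "C" + hap[25:]
            window = hap[p.start - 1 : p.end]
            primer_on_ref = (
                p.seq if p.orientation == FORWARD else reverse_complement(p.seq)
            )
            diffs = [i for i, (a, b) in enumerate(zip(primer_on_ref, window)) if a != b]
            assert len(diffs) == 1
            # ... and the difference is two bases in from the 3' terminus
            expected = len(p.seq) - 3 if p.orientation == FORWARD else 2
            assert diffs == [expected]

    def test_nearby_polymorphism_blocks_a_slot(self):
        region = RegionSpec("chr1", 1, 50)
        site = SnpSite("chr1", 25, "T", "C", 0.0, 1.0, 30, 30, "homozygous")
        blocker = SnpSite("chr1", 15, "G", "A", 0.0, 1.0, 30, 30, "homozygous")
        reference = {"chr1": EXAMPLE_REF}
        pileups = uniform_pileups(region, EXAMPLE_REF)
        params = PrimerParams(
            len_min=18, len_opt=18, len_max=18, tm_min=0, tm_opt=60, tm_max=100,
            gc_min=0, gc_max=100, min_depth=1, max_depth=100,
        )
        mask = RegionMask(region, pileups, pileups, params, known_sites=[site, blocker])
        primers = design_specific_primers(site, reference, mask, params)
        assert all(p.orientation == REVERSE for p in primers)

    def test_design_is_deterministic(self, example):
        site, reference, mask, params = example
        first = design_specific_primers(site, reference, mask, params)
        second = design_specific_primers(site, reference, mask, params)
        assert [(p.seq, p.start, p.end) for p in first] == [
            (p.seq, p.start, p.end) for p in second
        ]


class TestCommonPrimer:
    def make_window(self, seed=8, n=120, depth=30):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=n))
        region = RegionSpec("chr1", 1, n)
        pileups = uniform_pileups(region, seq, depth)
        return seq, region, pileups

    def test_best_equals_exhaustive_enumeration(self):
        seq, region, pileups = self.make_window()
        params = PrimerParams(min_depth=1, max_depth=100)
        mask = RegionMask(region, pileups, pileups, params)
        primer = design_common_primer(region, FORWARD, {"chr1": seq}, mask=mask,
                                      params=params)
        assert primer is not None
        # brute force over every substring obeying the hard constraints
        best = None
        for start in range(1, len(seq) + 1):
            for L in range(params.len_min, params.len_max + 1):
                end = start + L - 1
                if end > len(seq):
                    continue
                cand = seq[start - 1 : end]
                gc = gc_percent(cand)
                if not (params.gc_min <= gc <= params.gc_max):
                    continue
                if max_homopolymer_run(cand) > params.max_single_base_run:
                    continue
                tm = melting_temperature(cand)
                if not (params.tm_min <= tm <= params.tm_max):
                    continue
                pen = primer_penalty((tm, L), params)
                if best is None or (pen, start, cand) < best:
                    best = (pen, start, cand)
        assert best is not None
        assert primer.penalty == pytest.approx(best[0], abs=1e-9)
        assert (primer.start, primer.seq) == (best[1], best[2])

    def test_common_primer_is_reference_substring(self):
        seq, region, pileups = self.make_window(seed=9)
        params = PrimerParams(min_depth=1, max_depth=100)
        mask = RegionMask(region, pileups, pileups, params)
        for orientation in (FORWARD, REVERSE):
            p = design_common_primer(region, orientation, {"chr1": seq}, mask=mask,
                                     params=params)
            assert p is not None
            footprint = seq[p.start - 1 : p.end]
            expected = footprint if orientation == FORWARD else reverse_complement(footprint)
            assert p.seq == expected

    def test_window_riddled_with_snps_yields_none(self):
        seq, region, pileups = self.make_window(seed=10)
        params = PrimerParams(min_depth=1, max_depth=100)
        sites = [
            SnpSite("chr1", pos, seq[pos - 1], "A" if seq[pos - 1] != "A" else "G",
                    0.0, 1.0, 30, 30, "homozygous")
            for pos in range(10, 120, 12)
        ]
        mask = RegionMask(region, pileups, pileups, params, known_sites=sites)
        assert design_common_primer(region, FORWARD, {"chr1": seq}, mask=mask,
                                    params=params) is None

    def test_window_shorter_than_min_length_yields_none(self):
        seq, region, pileups = self.make_window()
        params = PrimerParams(min_depth=1, max_depth=100)
        mask = RegionMask(region, pileups, pileups, params)
        short = RegionSpec("chr1", 10, 20)
        assert design_common_primer(short, FORWARD, {"chr1": seq}, mask=mask,
                                    params=params) is None

    def test_out_of_range_depth_excludes_positions(self):
        seq, region, pileups = self.make_window(depth=3)  # below min_depth 6
        params = PrimerParams()
        mask = RegionMask(region, pileups, pileups, params)
        assert design_common_primer(region, FORWARD, {"chr1": seq}, mask=mask,
                                    params=params) is None


class TestPenalty:
    def test_optimum_scores_zero(self):
        params = PrimerParams()
        assert primer_penalty((params.tm_opt, params.len_opt), params) == 0.0

    def test_formula(self):
        params = PrimerParams(tm_opt=60.0, len_opt=22)
        assert primer_penalty((62.0, 22), params) == pytest.approx(2.0)
        assert primer_penalty((60.0, 26), params) == pytest.approx(2.0)
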