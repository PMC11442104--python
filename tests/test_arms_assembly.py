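"""Tri-/tetra-ARMS assembly geometry, the in-silico PCR oracle, density profile."""

import numpy as np
import pytest

from armscaps.arms_assembly import (
    AmbiguousAmplificationError,
    TetraArmsMarker,
    TriArmsMarker,
    assemble_tetra_arms,
    assemble_tri_arms,
    best_per_interval,
    in_silico_pcr,
    marker_density_profile,
)
from armscaps.pileup_io import RegionSpec
from armscaps.primer_design import FORWARD, REVERSE, Primer, reverse_complement
from armscaps.snp_selection import SnpSite


def make_primer(seq, start, orientation, kind, target_pos=None, allele=None,
                label="homozygous"):
    end = start + len(seq) - 1
    return Primer(
        seq=seq, chrom="chr1", start=start, end=end, orientation=orientation,
        kind=kind, tm=60.0, gc=50.0, penalty=0.0, target_pos=target_pos,
        allele=allele, mismatch_pos=3 if kind != "common" else None,
        site_label=label,
    )


class TestProductArithmetic:
    def test_tri_product_sizes_from_coordinates(self):
        """Footprints 983-1000 / 1183-1200 with a reverse common primer at
        1480-1499 give 517 and 317 bp products, 200 bp apart."""
        pa = make_primer("A" * 18, 983, FORWARD, "specific_A", target_pos=1000)
        pb = make_primer("C" * 18, 1183, FORWARD, "specific_B", target_pos=1200)
        common = make_primer("G" * 20, 1480, REVERSE, "common")
        product_a = common.end - pa.start + 1
        product_b = common.end - pb.start + 1
        marker = TriArmsMarker(pa, pb, common, product_a, product_b,
                               spacing=abs(pa.start - pb.start),
                               snp_spacing=200)
        assert (marker.product_A, marker.product_B) == (517, 317)
        assert marker.product_A - marker.product_B == marker.spacing == 200

    def test_tetra_product_sizes_from_coordinates(self):
        """SNP at 1000 with specifics 983-1000 (fwd) and 1000-1017 (rev),
        commons at 701-720 (fwd) and 1395-1414 (rev)."""
        pa = make_primer("A" * 18, 983, FORWARD, "specific_A", target_pos=1000)
        pb = make_primer("C" * 18, 1000, REVERSE, "specific_B", target_pos=1000)
        left = make_primer("G" * 20, 701, FORWARD, "common")
        right = make_primer("T" * 20, 1395, REVERSE, "common")
        product_a = right.end - pa.start + 1
        product_b = pb.end - left.start + 1
        outer = right.end - left.start + 1
        assert (product_a, product_b, outer) == (432, 317, 714)
        # fixed arithmetic identity: inner products overlap by the two
        # specific footprints' combined span at the SNP
        assert product_a + product_b == outer + (pb.end - pa.start + 1)
        marker = TetraArmsMarker(pa, pb, left, right, outer, product_a, product_b)
        assert marker.product_outer > max(marker.product_A, marker.product_B)


class TestAssemblyRules:
    def test_full_pipeline_emits_tri_and_tetra(self, e2e):
        assert len(e2e.tri) >= 1
        assert len(e2e.tetra) >= 1

    def test_spacing_window_enforced(self, e2e):
        for m in e2e.tri:
            assert 100 <= m.snp_spacing <= 300
            assert abs(m.product_A - m.product_B) == m.spacing

    def test_common_primer_distance_rule(self, e2e):
        for m in e2e.tri:
            if m.specific_A.orientation == FORWARD:
                near = max(m.specific_A.end, m.specific_B.end)
                assert near + 100 <= m.common.start <= m.common.end <= near + 700
            else:
                near = min(m.specific_A.start, m.specific_B.start)
                assert near - 700 <= m.common.start <= m.common.end <= near - 100

    def test_out_of_window_pairs_not_assembled(self, e2e):
        pairs = {
            (min(m.specific_A.target_pos, m.specific_B.target_pos),
             max(m.specific_A.target_pos, m.specific_B.target_pos))
            for m in e2e.tri
        }
        for lo, hi in pairs:
            assert 100 <= hi - lo <= 300

    def test_tetra_band_separation(self, e2e):
        for m in e2e.tetra:
            assert abs(m.product_A - m.product_B) >= 50
            assert m.product_outer > max(m.product_A, m.product_B)

    def test_one_tetra_marker_per_snp(self, e2e):
        positions = [m.position for m in e2e.tetra]
        assert len(positions) == len(set(positions))


class TestInSilicoPcr:
    def test_markers_amplify_predicted_sizes_on_both_haplotypes(self, e2e):
        """Every emitted marker yields exactly the predicted allele-resolved
        products, and specific primers never amplify the other allele."""
        haps = e2e.haplotypes
        assert e2e.tri and e2e.tetra
        for m in e2e.tri:
            fwd_oriented = m.specific_A.orientation == FORWARD
            for spec_p, hap, expected in (
                (m.specific_A, "A", m.product_A),
                (m.specific_B, "B", m.product_B),
            ):
                f, r = (spec_p, m.common) if fwd_oriented else (m.common, spec_p)
                assert in_silico_pcr(f, r, haps[hap]) == expected
                other = "B" if hap == "A" else "A"
                assert in_silico_pcr(f, r, haps[other]) is None
        for m in e2e.tetra:
            assert in_silico_pcr(m.common_left, m.common_right, haps["A"]) == m.product_outer
            for spec_p, hap, expected in (
                (m.specific_A, "A", m.product_A),
                (m.specific_B, "B", m.product_B),
            ):
                if spec_p.orientation == FORWARD:
                    f, r = spec_p, m.common_right
                else:
                    f, r = m.common_left, spec_p
                assert in_silico_pcr(f, r, haps[hap]) == expected
                other = "B" if hap == "A" else "A"
                assert in_silico_pcr(f, r, haps[other]) is None

    def test_no_product_beyond_size_cap(self):
        template = "A" * 50 + "CTGACTGACTGAGGCCTTAA" + "G" * 3000 + "TTAAGGCCTCAGTCAGTCAG" + "T" * 50
        fwd = make_primer("CTGACTGACTGAGGCCTTAA", 51, FORWARD, "common")
        rev_site = reverse_complement("TTAAGGCCTCAGTCAGTCAG")
        rev = make_primer(rev_site, 3071, REVERSE, "common")
        assert in_silico_pcr(fwd, rev, template) is None

    def test_multiple_loci_raise(self):
        unit = "ACGTACGTCCAGGTTACGATCGATCG"
        template = (unit + "T" * 200) * 2 + reverse_complement(unit)
        fwd = make_primer(unit[:20], 1, FORWARD, "common")
        # the reverse primer anneals where the template carries revcomp(unit):
        # two forward sites x one reverse site -> two possible products
        rev = make_primer(unit[:20], 1, REVERSE, "common")
        with pytest.raises(AmbiguousAmplificationError):
            in_silico_pcr(fwd, rev, template)

    def test_trans_risk_flag_set_for_heterozygous_sites(self):
        """Tri pairs built on heterozygous-labelled sites carry the warning
        that cis linkage of the two cultivar alleles is unverified."""
        seq = np.random.default_rng(12).choice(list("ACGT"), size=700)
        reference = {"chr1": "".join(seq)}
        from armscaps.primer_design import PrimerParams, RegionMask
        from armscaps.pileup_io import PileupColumn

        region = RegionSpec("chr1", 1, 700)
        ref = reference["chr1"]
        pileups = [
            PileupColumn("chr1", pos, ref[pos - 1], {ref[pos - 1]: 30})
            for pos in range(1, 701)
        ]
        params = PrimerParams(tm_min=0, tm_max=100, gc_min=0, gc_max=100,
                              min_depth=1, max_depth=100)
        mask = RegionMask(region, pileups, pileups, params)
        primers = [
            make_primer(ref[82:99] + "A", 83, FORWARD, "specific_A",
                        target_pos=100, label="heterozygous_diploid"),
            make_primer(ref[282:299] + "C", 283, FORWARD, "specific_B",
                        target_pos=300, label="heterozygous_diploid"),
        ]
        markers = assemble_tri_arms(primers, reference, mask, params)
        assert markers and all(m.trans_risk for m in markers)


class TestDensityProfile:
    def test_empty_inputs(self):
        df = marker_density_profile({"tri": [], "tetra": []}, [])
        assert df.empty

    def test_binning(self):
        marker = TriArmsMarker(
            make_primer("A" * 18, 1_499_983, FORWARD, "specific_A", 1_500_000),
            make_primer("C" * 18, 1_500_183, FORWARD, "specific_B", 1_500_200),
            make_primer("G" * 20, 1_500_480, REVERSE, "common"),
            517, 317, 200, 200,
        )
        sites = [SnpSite("chr1", 1_500_000, "A", "G", 0, 1, 30, 30, "homozygous")]
        df = marker_density_profile({"tri": [marker]}, sites, bin_size=1_000_000)
        assert list(df["bin"]) == [2]
        assert df.iloc[0]["tri"] == 1 and df.iloc[0]["snps"] == 1

    def test_best_per_interval_keeps_minimum_penalty(self, e2e):
        thinned = best_per_interval(e2e.tetra, bin_size=10_000)
        bins = [(m.chrom, (m.position - 1) // 10_000) for m in thinned]
        assert len(bins) == len(set(bins))
        source_positions = {m.position for m in e2e.tetra}
        for t in thinned:
            assert t.position in source_positions
            bin_mates = [
                m for m in e2e.tetra
                if (m.position - 1) // 10_000 == (t.position - 1) // 10_000
            ]
            assert t.total_penalty == min(m.total_penalty for m in bin_mates)
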