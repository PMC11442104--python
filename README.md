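# armscaps

Automated design of **ARMS** (Amplification Refractory Mutation System) and
**CAPS** (Cleaved Amplified Polymorphic Sequences) DNA markers from the
resequencing alignments of two cultivars against a shared reference genome.

DNA markers closely linked to trait genes are the workhorse of
marker-assisted selection, cross verification and cultivar identification,
but designing them by hand means finding a SNP that discriminates the two
parents, checking its genotype is what you think it is at the available
coverage depth, and building primers that actually discriminate the alleles.
`armscaps` automates the whole chain for breeders and geneticists working
with short-read resequencing data: BAM/SAM alignments in, ranked markers and
an annotated HTML report out.

## The statistics and design rules at the core

**SNP-index.** At a position covered by *n* reads, the SNP-index of an
allele is the fraction of reads carrying it. A SNP is *cultivar-B-specific*
when cultivar A shows only the reference base (index of every other base
≤ tol_A, default 0) and cultivar B carries exactly one non-reference allele.

**Binomial confidence intervals for genotype calls.** With variant dosage
*d* in a sample of ploidy *k*, the variant read count is
X ~ Binomial(n, d/k), so the observed index X/n has an exact central
confidence interval with endpoints q/n and r/n, where q and r are the
smallest integers with CDF ≥ α/2 and ≥ 1 − α/2 (α = 1 − confidence). These
intervals drive three decisions:

* *HeteroSelect* — keep a site as simplex/duplex/triplex (tetraploid) or
  heterozygous (diploid) only if its observed index lies in the interval
  for that dosage at the site's depth;
* *ProgenySNP* — keep a site only if a bulked progeny shows an index inside
  the dosage-1/ploidy-2 interval (the F1-equivalent heterozygous state);
* *minimal usable depth* — for diploids the 95% interval at depth 5 is
  [0, 1] (heterozygotes cannot be told from homozygotes) while at depth 6
  it is (0.1667, 0.8333); the three tetraploid dosage classes separate at
  depth 58.

**ARMS primers.** An allele-specific primer places its 3′-terminal base on
the SNP (the allele itself for a forward primer, its complement for a
reverse one) and carries a deliberate destabilizing substitution at the
third base from the 3′ end (A→C, C→A, G→T, T→G), so extension fails on the
mismatched allele. Two same-orientation specific primers at SNPs 100–300 bp
apart plus one opposite common primer form a *tri-ARMS* marker (alleles
differ by band size); opposite-orientation specific primers at one SNP plus
two flanking common primers form a *tetra-ARMS* marker (outer control band
plus one band per allele). Common primers sit on consensus sequence:
polymorphism-free, coverage within bounds in both cultivars, and within
length/Tm/GC constraints (nearest-neighbor Tm, SantaLucia 1998, 50 mM
monovalent salt, 50 nM oligo).

**CAPS markers.** A restriction enzyme whose recognition site overlaps the
SNP in exactly one allele turns a plain PCR product into allele-resolved
fragment patterns after digestion. AluI (AG^CT) and EcoRI (G^AATTC) ship by
default; the enzyme table is a user-extensible TSV.

Every emitted marker is validated in silico: amplifying the reconstructed
cultivar haplotypes with the marker's primers (and digesting, for CAPS)
must reproduce the predicted band sizes exactly.

## Worked example

No external data is needed — the `armscaps.fixtures` module synthesizes a
reference and pre-aligned reads with known SNP truth:

```python
from armscaps import fixtures as fx
from armscaps import (RegionSpec, extract_pileup, open_alignment,
                      select_target_snps, SelectionFilters,
                      design_specific_primers, PrimerParams, RegionMask,
                      assemble_tri_arms, assemble_tetra_arms, in_silico_pcr)
from pyfaidx import Fasta

spec = fx.FixtureSpec(genome_length=100_000, depth=30, seed=11)
reference = fx.generate_reference(spec)
spec.snp_specs = fx.paired_snp_specs(18, spec, reference, cluster_spacing=5_000)
spec.__post_init__()
paths = fx.generate_alignments(spec, reference, "demo")

fasta = Fasta(paths["reference"])
region = RegionSpec("chr1", 1, spec.genome_length)
cols_a = extract_pileup(open_alignment(paths["A"]), fasta, region)
cols_b = extract_pileup(open_alignment(paths["B"]), fasta, region)
sites = select_target_snps(cols_a, cols_b, fasta, SelectionFilters())
print(f"{len(sites)} cultivar-B-specific SNP sites selected")

params = PrimerParams()
mask = RegionMask(region, cols_a, cols_b, params, known_sites=sites)
primers = [p for s in sites for p in design_specific_primers(s, fasta, mask, params)]
print(f"{len(primers)} allele-specific primers designed")

tri = assemble_tri_arms(primers, fasta, mask, params)
tetra = assemble_tetra_arms(primers, fasta, mask, params)
print(f"{len(tri)} tri-ARMS and {len(tetra)} tetra-ARMS markers assembled")
```

prints

```
35 cultivar-B-specific SNP sites selected
95 allele-specific primers designed
29 tri-ARMS and 15 tetra-ARMS markers assembled
```

Five of the 40 planted SNPs are lost to simulated sequencing error or to
multi-allelic pileups — exactly the sites a marker should avoid. Inspecting
the first marker and confirming it against the cultivar haplotypes:

```
first tri-ARMS marker at chr1:1219:
  A-specific  GCAGGACAGAGCGGAGATCCAGA
  B-specific  AACCCAGGTCCCACTTCCAGGC
  common      TGGCATCGACACTCGACCGAGT
  predicted bands: A 332 bp, B 590 bp
  in-silico PCR of the A-specific pair on cultivar A: 332 bp
  ... and on cultivar B: None
```

The A-specific pair amplifies the predicted 332 bp band on cultivar A and
nothing on cultivar B — the 3′-terminal mismatch blocks it.

### Command line

The same pipeline is exposed as five subcommands, run in order:

```sh
armscaps target_SNP_selection --ref ref.fa --bam-a A.bam --bam-b B.bam \
    --region chr1:1-100000 --out snps.tsv
armscaps ARMS_preparation --snps snps.tsv --ref ref.fa \
    --bam-a A.bam --bam-b B.bam --out primers.tsv
armscaps tri_ARMS   --primers primers.tsv --ref ref.fa --bam-a A.bam \
    --bam-b B.bam --out-tsv tri.tsv   --out-html tri.html
armscaps tetra_ARMS --primers primers.tsv --ref ref.fa --bam-a A.bam \
    --bam-b B.bam --out-tsv tetra.tsv --out-html tetra.html
armscaps CAPS --snps snps.tsv --ref ref.fa --bam-a A.bam --bam-b B.bam \
    --out-tsv caps.tsv --out-html caps.html
```

`target_SNP_selection` accepts `--hetero-select PLOIDY:DOSAGE` (e.g. `4:1`
for potato simplex sites) and `--progeny-bam` for the progeny-segregation
filter. The HTML reports highlight, base by base, amplicon positions that
are polymorphic between the cultivars or outside the accepted coverage
range, so unreliable markers are visible at a glance. A sixth subcommand,
`SNP_index_interval`, tabulates the confidence intervals over a depth range.

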