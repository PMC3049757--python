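# estmarker

Molecular-marker discovery from assembled EST collections. Given a set of
unigenes (non-redundant consensus transcripts), their ORF/intron
annotations, and per-position mapped-read evidence from two genotypes,
`estmarker`:

* mines **SSRs** (microsatellites): maximal perfect di-/tri-/tetra-nucleotide
  tandem repeats with ≥ 4 units and ≥ 17 bp total length, normalised to
  canonical motifs (lexicographic minimum over cyclic rotations and the
  reverse complement) and localised relative to the ORF (5'-UTR / ORF /
  3'-UTR / other);
* calls **SNVs** (SNPs and indels) between the two genotypes: an allele
  qualifies at a position when it has ≥ 2 supporting reads (mapping quality
  ≥ 20) and accumulated phred base quality ≥ 40; a position with ≥ 2
  qualifying alleles is a variant;
* annotates each SNV with a **filter cascade** for marker selection:
  `VKS` (indel, not a SNP), `HVR4` (unigene with > 4 SNVs per 100 bp),
  `CS60` (another SNV < 60 bp away), `I60` (intron junction < 60 bp),
  `CL60` (sequence end < 60 bp), `NVSM1`/`NVSM2` (variable within, or not
  sequenced in, one of the two genotypes), `CEF` (no allele-specific
  restriction site — not scorable as a CAPS). Survivors with an empty tag
  set (or `CEF` only) are clean candidates for multiplexed genotyping;
  survivors with an empty tag set are additionally **CAPS**-detectable;
* decides **CAPS detectability** by building both allele sequences of a
  ±60 bp window and testing, for a configurable panel of restriction
  enzymes (IUPAC sites, both strands), whether any recognition site
  *spanning the SNP* is gained or lost, reporting the per-allele digestion
  fragment lengths;
* computes **codon-usage statistics** from full-length ORFs: the 64-codon
  count table, GC3 (G+C fraction at third codon positions, stops
  excluded), the XCG/XCC CpG-suppression ratio, and stop-codon usage;
* emits the standard **summary tables**: SSR class/motif/localisation
  tables, the transition/transversion spectrum, per-filter attrition and
  per-unigene variation density.

A seeded synthetic-data generator (`estmarker.synthetic_data`) produces
unigene sets and two-genotype read evidence with known planted truth —
including the filter tags each planted variant should receive — so the
whole pipeline is testable without any external data.

The package is aimed at researchers developing SSR/SNP/CAPS marker panels
from transcriptome assemblies of species without a reference genome, and
at anyone who needs a transparent, fully testable reimplementation of
this marker-selection logic.

## Worked example

Simulate a 200-unigene two-genotype dataset, mine SSRs, call and filter
SNVs (with CAPS annotation), and summarise:

```
$ estmarker simulate --seed 5 --out demo
wrote 200 unigenes, 631998 observations, 5 planted SSRs, 102 planted SNVs

$ estmarker find-ssrs demo/unigenes.fasta --gff demo/annotations.gff3 --out demo/ssrs.tsv
found 5 SSR loci in 200 unigenes

$ estmarker call-snvs demo/unigenes.fasta demo/observations.tsv \
      --gff demo/annotations.gff3 --cef --out demo/snvs.vcf
called 40 SNVs

$ estmarker find-caps demo/snvs.vcf demo/unigenes.fasta --out demo/caps.tsv
14 CAPS hits

$ estmarker report --ssrs demo/ssrs.tsv --vcf demo/snvs.vcf \
      --unigenes demo/unigenes.fasta --out demo/report
SSRs: 5 in 5 unigenes
SNVs: 40 (37 SNPs, 3 indels); transitions 51.0%
```

At the default simulated depth (2.4 reads per position and genotype,
emulating a modestly covered 454 survey) only 40 of the 102 planted
variants reach the two-reads-per-allele evidence threshold — discovery is
depth-limited, exactly as in a real EST survey. With
`coverage_mean: 20` and `base_error_rate: 0` in a simulation config the
pipeline recovers 100% of the planted variants with exactly the expected
filter tags (this is what the acceptance script measures).

Codon usage from the simulated full-length ORFs:

```
$ estmarker codon-usage demo/orfs.fasta --out demo/codon_table.tsv
n_orfs      193
n_codons    27878
GC3         0.427
XCG/XCC     0.95
stop_TAA    0.404
stop_TAG    0.130
stop_TGA    0.466
```

GC3 tracks the configured background GC (0.42) and XCG/XCC ≈ 1 because
the generator plants no CpG suppression; real dicot transcriptomes show
XCG/XCC well below 1.

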