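# Methods

## Scope and data model

`estmarker` implements the marker-discovery computation that sits
*downstream* of read cleaning, assembly and mapping: it consumes assembled
unigenes (FASTA), ORF/intron annotations (GFF3) and per-position,
per-genotype read evidence, and produces SSR loci, filtered SNVs, CAPS
calls, codon statistics and summary tables. Read mapping itself is out of
scope; the evidence model is a tab-separated table of
`(unigene, position, genotype, read, allele, base quality, mapping
quality)` tuples — the minimal sufficient statistic the caller needs.
Alleles are single bases, `-` for a single-base deletion at the position,
or `+SEQ` for an insertion immediately after it; this minimal indel
dialect exists to exercise the indel (`VKS`) path of the cascade, not to
model alignment ambiguity.

Internally all coordinates are 0-based half-open; GFF3 and VCF are 1-based
and converted only at the file boundary. The written VCF is version 4.0
with one `##FILTER` header per cascade code, tags semicolon-joined in a
fixed order, and `.` (rather than `PASS`) for untagged records. Because
the VCF writer receives unigene *lengths* rather than sequences, indel ALT
alleles are encoded as `D` / `I<SEQ>` tokens instead of anchor-base style.

## SSR mining

A locus is a maximal perfect tandem run of a 2–4 bp unit. Defaults:
≥ 4 complete units and ≥ 17 bp total span; a run may end mid-unit (the
partial unit counts toward the span, not the unit count). Degenerate
units (powers of a shorter unit, e.g. `ACAC`) are suppressed so every
repeat is reported once under its shortest period; runs are split at `N`.
Canonical motifs are the lexicographic minimum over all cyclic rotations
of the unit and of its reverse complement, making the 2k representatives
of a motif family collapse to one label (`GA`, `CT`, `TC` → `AG`).

Mismatch-tolerant (score-based) repeat detection is deliberately not
implemented: the operative selection criteria are the unit lengths, the
unit-count rule and the length floor, all configurable. Overlapping
candidate runs of different unit lengths are resolved by a deterministic
rule — longer locus wins, equal length prefers the shorter unit, then the
leftmost — chosen for reproducibility; the scanner is verified against a
brute-force every-position oracle.

Localisation is strict containment: a locus entirely upstream of the ORF
is 5'-UTR, entirely inside is ORF, entirely downstream is 3'-UTR;
boundary-straddling loci and loci on ORF-less unigenes are "other". For
minus-strand ORFs the UTR labels follow coding orientation.

## SNV calling and the cascade

Observations below the mapping-quality threshold (default 20) are
discarded. Per position, each allele's read count and accumulated phred
base quality are computed pooled across genotypes; an allele qualifies
with count ≥ 2 and accumulated quality ≥ 40. A position with ≥ 2
qualifying alleles is an SNV; it is an insertion/deletion if any
qualifying allele is an indel token, else a SNP. The numeric defaults are
this package's own: they suppress singleton sequencing errors (a lone
miscall can neither reach two reads nor 40 accumulated quality) while
letting two concordant good-quality reads qualify; all three are
configurable. Accumulated quality is an uncapped sum over reads. The two
cultivars are treated as inbred lines — no diploid genotype likelihoods.

Filters (all distances strict `<`, centre-to-centre):

* `VKS` — the variant is not a SNP.
* `HVR4` — unigene-level density: the unigene's SNV count × 100 / length
  exceeds 4; every SNV of such a unigene is tagged. A sliding-window
  variant of this rule was considered and rejected as the default because
  the density criterion is stated per sequence; the unigene-level reading
  is also the only one that makes "all SNVs of the sequence are
  discarded" well defined.
* `CS60` — another SNV of the same unigene closer than 60 bp (both tagged).
* `I60` — an intron junction closer than 60 bp.
* `CL60` — a sequence end closer than 60 bp (`min(pos, len−1−pos)`).
* `NVSM1` / `NVSM2` — the second / first genotype has ≥ 2 qualifying
  alleles at the position ("variable within"), or zero observations
  passing mapping quality ("not sequenced").
* `CEF` — no enzyme in the panel distinguishes the two alleles (below).

Tagging is idempotent and order-independent. The Golden-Gate-style
candidate set is the SNVs whose tag set is empty or `{CEF}` (clean
60 bp flanks, biallelic between genotypes); the CAPS candidate set is the
SNVs with an empty tag set.

## CAPS detection

For a biallelic SNP, both allele sequences of a ±60 bp window (clipped to
the unigene) are built and each enzyme's recognition sites located by
IUPAC-expanded regex on the top strand plus, for non-palindromic sites,
the reverse complement, reported in top-strand coordinates. An enzyme is
a hit iff its set of sites *overlapping the SNP position* differs between
alleles — distant shared sites cannot mask detectability, and no
uniqueness constraint is imposed on other sites in the window (fragment
lengths per allele are reported so the user can judge gel resolvability).
The built-in panel is 22 common, inexpensive 4–6-cutters; it is
user-extensible via a `name / site / cut_offset` TSV, since any real
panel depends on what the lab stocks. Indels never receive `CEF` (they
are already excluded by `VKS`).

## Codon usage

Full-length ORFs must start `ATG`, end `TAA`/`TAG`/`TGA`, have length a
multiple of 3 (≥ 6) and contain no internal stop — a mechanical stand-in
for manual frame-shift screening. The codon table counts all codons
including the terminal stop. GC3 excludes stop codons by default (their
third base is fixed by termination, not synonymous drift); this is
switchable. XCG/XCC is the CpG-suppression measure: counts of codons of
the form N‑C‑G over N‑C‑C, i.e. a CpG at codon positions 2–3 versus its
unmethylatable counterpart.

## Synthetic data

The generator emulates a two-genotype normalized-EST survey. Defaults
(all configurable): unigene length 626 ± 250 bp (floor 150); 96% of
unigenes carry one plus-strand ORF flanked by UTRs; intron junctions
Poisson(0.4) per unigene (≈ 33% of unigenes with ≥ 1); ~4% of unigenes
carry one planted SSR drawn from an AG/AAG/AAAT-biased motif catalogue;
planted variants Poisson(0.7 per kb) with transition:transversion odds
2.1, 5.5% indels, and 55% of SNP sites additionally variable within one
genotype; read depth Poisson(2.4) per position and genotype (the depth
implied by ~9.3 reads of ~320 bp per 626 bp unigene split between two
genotypes); base qualities ~N(32, 4), mapping qualities ~N(40, 3),
uniform miscall rate 10⁻³ applied to base calls only.

Planted ORFs are built codon-wise (no internal stops by construction;
stop codons drawn 41.4/17.5/41.1% TAA/TAG/TGA). Planted SSRs are
inserted whole — frame-aligned codon insertion for tri-motifs inside
ORFs, with frame protection rejecting non-tri motifs there — and their
flanks are adjusted so the run is maximal, guaranteeing exact-coordinate
recoverability. Planted variants avoid the SSR span. The expected filter
tags of every planted variant are recorded from the planted geometry
alone (edge/intron/neighbour distances, per-unigene density,
within-genotype status) by an independent re-statement of the cascade
rules, giving a dual-route check against `apply_filters`.

Determinism: each unigene draws from `default_rng((seed, index))` (reads
from `(seed, index, 1)`), so one seed fixes all outputs byte-for-byte and
per-unigene content is stable under reordering.

What the generator does **not** model: 454 homopolymer errors, chimeric
or partial reads, alignment/mapping ambiguity, paralog collapse,
expression-level or normalization-efficiency effects, codon bias (codons
are drawn i.i.d. from the background base composition, so simulated
XCG/XCC ≈ 1 and GC3 ≈ the configured GC). Passing recovery tests
therefore demonstrates the correctness of the detection/filter logic
under the stated evidence model, not robustness to mapping artefacts —
which is precisely why the cascade exists in the first place.

## Problem sizes and numerical choices

The test suite and acceptance script run the recovery pipeline on 200
unigenes at depth 20 with zero error rate — the regime in which every
planted variant is recoverable by construction (two qualifying reads per
allele are essentially certain at Poisson(20) depth) — and verify the SSR
scanner against its brute-force oracle on 1,000 random 1 kb sequences and
the CAPS finder against an exhaustive site-expansion oracle on 500 random
SNP windows. Percentages are rounded to the precision of the table being
reproduced (integers for class/motif shares and the spectrum, one decimal
for attrition and density, two decimals for sub-percent attrition). Ties
and degenerate inputs (empty marker sets, unigenes without ORFs,
zero-length classes) return empty tables or raise explicit
undefined-value errors rather than dividing by zero.
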