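# Methods

## The genotyping problem

*STA1* is a chimeric gene: its promoter and the first stretch of its open
reading frame are homologous to *FLO11*, the remainder of the ORF to *SGA1*.
Both parents are present in essentially every *S. cerevisiae* genome, so
neither whole-gene alignment coverage nor generic PCR can interrogate *STA1*
without interference. All methods in this package therefore pivot on the
short regions where the chimera is *private*: a 79-bp window in the ORF
(+65..+143 relative to the start codon, delimited by the Sdia-f/Sdia-r qPCR
primers) and a 101-bp window (−923..−823) inside the 1162-bp promoter region
(−1370..−209) whose deletion distinguishes poorly from highly diastatic
strains.

## Coordinate convention

Relative coordinates are 1-based inclusive and anchored at the start codon:
+1 is the first base of the ATG, −1 the base immediately upstream, and there
is no position 0. Under this convention −1370..−209 spans exactly 1162 bases
and +65..+143 spans 79. Internal storage is 0-based half-open;
`coords.CoordMap` converts in both directions, survives excision of the
promoter deletion (deleted positions raise `KeyError`), and is
property-tested for round-trip identity.

## Synthetic locus and genomes

`synthetic` builds the study system from seeded uniform-random sequence:

- **Parents.** A 3.6-kb *FLO11*-like sequence (2.5-kb promoter + coding
  head) and a 2.5-kb *SGA1*-like coding sequence, redrawn until they share
  no canonical 21-mer, so parent-versus-parent ambiguity cannot leak into
  tests of chimera-versus-parent ambiguity.
- **Locus.** Promoter −2500..−1 and ORF bases +1..+104 from the
  *FLO11*-like parent, +105..+2604 from the *SGA1*-like parent (the
  junction, +105, falls inside the ORF diagnostic window, as in the real
  chimera). The two diagnostic windows are then overwritten with
  locus-private random sequence — modelling the divergence that makes them
  diagnostic in reality — and the published detection primers are planted at
  the published product geometry: SD-5A/SD-6B → 868 bp, STA1_UAS_Fw/Rv →
  599 bp, STA1_UAS_Q_Fw/Rv → 223 bp, Sdia-f/r → 79 bp, the nested full-locus
  pair → 5104 bp (≈5.2 kb), and STA1_1055_F/STA1_2951_R → 1897 bp intact /
  735 bp deleted. Every downstream size assertion is computed by the PCR
  engine from this construction, never hard-coded into the pipeline.
  The deleted variant excises −1370..−209 exactly.
- **Genomes.** A diploid shares one random background (homologous
  chromosomes) of 200 kb by default; each haplotype carries zero or more
  cassette copies (head-to-tail tandem for extra copies — a modelling
  convenience, not a claim about the arrangement of natural multi-copy
  strains, which may be dispersed/subtelomeric) and, by default, one planted
  copy of each parent gene. The parent copies are what make the MAPQ filter
  *necessary*, exactly as *FLO11*/*SGA1* do in real genomes. The matching
  depth reference is the cassette-free background plus the intact locus as a
  separate contig, mirroring the practice of appending the *STA1* sequence
  to a reference genome that lacks it.
- **Reads.** Single-end, fixed length (150 bp default), uniform start
  positions, both strands, independent per-base substitutions
  (0.5% default), constant Phred+33 quality, no indels — depth ratios, the
  quantity of interest, are insensitive to indel realism. `target_coverage`
  is per-haplotype depth: each haplotype receives
  `ceil(coverage × total_length / read_length / n_haplotypes)` reads, so a
  diploid simulated at 50× maps at a genome-wide median near 100×.
- **Mixtures.** A contamination aliquot of size n (default: the background
  pool size) with `k ~ Binomial(n, fraction)` diastatic reads drawn without
  replacement, emulating the fixed-aliquot dilution-series design used to
  establish PCR detection limits at fractions 10⁻¹–10⁻⁶.

What the generator does **not** model: real yeast genome content (repeat
families, subtelomeres, ploidy variation), graded sequence divergence
between the chimera and its parents (divergence is all-or-nothing at the
window boundaries), indel or quality-dependent sequencing error, and GC
bias. Passing tests therefore demonstrate the correctness of the *methods*
under their stated assumptions, not their performance on arbitrary real
strains.

## In-silico PCR

Annealing is an ungapped scan: a primer binds where it aligns with at most
`max_mismatch` mismatches and its 3′-terminal `clamp_len` bases match
exactly. IUPAC codes in the primer match their base set; non-ACGT template
bases never match (conservative on draft assemblies). Defaults
`max_mismatch=0, clamp_len=3` reflect the perfect-match reporting of the
published screen; the tolerance exists for surveying divergent strains and
is an implementation policy, not a literature fact. Amplicons are all
convergent site pairs within `max_amplicon` (10 kb default, accommodating
the 5.2-kb nested product); length is the inclusive distance between the two
primers' 5′ ends. Both orientations are scanned, so predictions are
symmetric under reverse complementation. Cross-pair products in multiplex
reactions are reported but flagged and excluded from classification, which
uses only the two designed products. Multi-FASTA samples are scanned per
record and aggregated as "any record positive".

## Assembly marker calls

Scanning at the default 100% identity / 100% query coverage is exactly
two-strand substring search (tested against that oracle); sub-100 identity
uses the same vectorised full-length Hamming scan, and sub-100 coverage
additionally reports marker prefixes/suffixes overhanging contig edges.
Promoter status is only evaluated for *STA1*-positive assemblies. Because a
fragmented assembly can truncate the locus upstream of the ORF marker, a
missing promoter marker is reported as `deleted` only when some ORF hit has
at least `edge_distance` (default 1.5 kb, comfortably covering the ~1-kb
marker-to-marker span) of assembled sequence on its upstream side;
otherwise the call is `indeterminate`. This three-way outcome is this
package's explicit handling of a situation population surveys leave
implicit. `contiguity_check` cuts the full locus into 100-bp tiles and asks
whether ≥99% of tiles occur verbatim on a single contig strand — a
deliberately simple stand-in for a local aligner that is exact on the
synthetic data this package tests against.

## Diagnostic windows

`uniqueness_profile` counts, for each position of the target, how many
background genomes contain the canonical form (min of k-mer and reverse
complement) of the k-mer starting there, via per-background hash sets —
results are independent of how a background is chunked, provided chunk
overlaps preserve k-mer content. Default k = 21: large enough that a 200-kb
random background collides with a specific 21-mer with probability ~10⁻⁷,
small enough to resolve 79–101-bp windows. Ambiguous target k-mers are
marked maximally non-unique. Windows are maximal zero-runs converted to
base intervals (run p..q ⇒ bases p..q+k−1) and filtered to
`min_len` (default 79, the shortest published window); on the synthetic
locus versus its parents this recovers both diagnostic windows (with k−1
context on each side) and discards the short planted-primer islands.

## Copy number and zygosity

The built-in mapper places each read at *all* of its minimal-mismatch
ungapped positions (pigeonhole seeding: one exact segment of
`read_len // (max_mismatch+1)` bases must exist, candidates verified by full
Hamming comparison against an exhaustive-placement oracle in tests). A
unique best placement gets MAPQ 60; ties get MAPQ 0 — a binary model that
reproduces the semantics the MAPQ ≥ 50 filter depends on (reads shared
between the cassette and a parent copy tie and are removed; reads inside a
diagnostic window are unique and survive). Default `max_mismatch=3` keeps
>99% of 150-bp reads at a 0.5% error rate. Depth is full-read overlap per
base from the filtered alignments; the window statistic and the genome-wide
statistic are both medians. Copies are `round(ploidy × window/genome)` with
exact halves rounded away from zero, the raw ratio always reported
alongside (the binning of fractional ratios into zygosity classes is policy
— nothing in the underlying measurement fixes it). Diploid labels:
(2,2) homozygous intact, (2,1) heterozygous deletion, (2,0) homozygous
deletion, orf=1 hemizygous, orf>2 multi-copy, orf=0 absent; other ploidies
report the raw copy vector.

Degenerate inputs: a zero genome-wide median raises rather than returning a
call; zero-length windows and out-of-bounds windows raise; unplaceable
reads are silently dropped (they carry no positional information).

## ΔΔCt expression

Technical replicates are averaged to one Ct per (sample, biological
replicate, gene) before any difference is taken. ΔCt subtracts the
arithmetic mean of the reference-gene Cts (equivalently, geometric-mean
normalisation of linear quantities — the standard multi-reference rule;
the combination rule is this package's choice, the two-reference design
itself is the published one). ΔΔCt is taken against the calibrator's mean
ΔCt and converted with base 2 (100% efficiency default) or per-gene
(1+E). Sample means are geometric (computed on the log2 scale), which makes
the calibrator's mean relative quantity exactly 1; spread is reported as a
log2-scale standard deviation across biological replicates.

## Problem sizes and numerical choices

The recovery experiments run six genotype states × three seeds on 200-kb
diploid backgrounds at 50× per haplotype with 150-bp reads — large enough
that window medians resolve half-copy differences (the binomial/Poisson
noise of a sub-read-length window's median is ~7% of its mean at these
depths, against the 12.5–25% relative margins the rounding rule needs),
small enough to run in well under a minute per genome on one CPU. The
multiplex experiments use 60-kb backgrounds; scan-oracle suites use 5–10-kb
templates and ≤10⁴ alignments. All randomness flows from
`numpy.random.default_rng` seeds; every generator is byte-deterministic per
seed.

## Known limitations

- The mapper is ungapped and single-end; indels or split reads are out of
  scope (the depth-ratio estimator does not need them on substitution-only
  data, and external SAM input is accepted where a full aligner has been
  used).
- The PCR model has no thermodynamics: no Tm, no dimers, no efficiency —
  product presence is the only signal, which is what the decision table
  consumes.
- Assembly scanning is ungapped Hamming matching; a diverged strain with
  indels in a marker needs relaxed thresholds or an external aligner.
- The zygosity vocabulary is diploid; higher ploidies get raw copy vectors.
- Population-scale prevalence figures (surveys of public assembly
  collections, phylogenies) require external data and are deliberately not
  reproduced here.
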