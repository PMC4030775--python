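# Methods

This note documents the models implemented in `epitrio`, the defaults and
why they are set where they are, what the synthetic-data generator does and
does not emulate, and the numerical/design choices made where more than one
reasonable option existed.

## Inheritance models and the GLR filter

All four models operate on called genotypes plus the per-sample vector of
log10 genotype likelihoods (VCF `GL`, or `PL`/−10). The genotype likelihood
ratio of a call is defined as

    GLR = log10 L(second-best genotype) − log10 L(best genotype) ≤ 0,

and a call passes at threshold t (default −5) when GLR ≤ t. The sign
convention is chosen so that "below −5" selects *confident* calls: the best
genotype must be at least 10⁵-fold more likely than the runner-up. An
all-equal GL vector returns 0 and never passes; a vector with fewer than
two finite entries is uninformative and treated as failing.

The de novo model requires the confident child-het / parents-hom-ref
configuration in all three individuals, then novelty (never seen in any
configured population resource). Rationale for novelty rather than a
frequency cutoff: a true de novo event is by definition absent from
population panels, and the dominant error mode — an undercalled inherited
variant — is typically a known polymorphism.

Recessive-type models (simple recessive, compound het, X-linked) use the
frequency rule instead: drop when any resource allele frequency exceeds
0.005, or when the internal cohort of 294 genomes contains any
homozygote/hemizygote or more than five heterozygotes. All inequalities
are strict; the boundary behaviour is unit-tested. A variant with no
annotation row is treated as novel (keeps) and non-conserved (fails the
conservation clause): both readings follow the novelty-seeking purpose of
the filters.

Compound-het phasing is genotype-based only: a variant counts as paternal
when the father is het and the mother hom-ref (maternal mirrored); sites
where both parents are het are phase-uninformative and excluded from
pairing. This trades a little sensitivity for zero dependence on
read-backed phasing. The X model applies only to male children (hemizygous
alt child, het mother, hom-ref father); the female X-recessive case is
already covered by the autosomal recessive rule applied to X. Male X calls
are diploid-coded in the VCF (0/0 or 1/1) and flagged hemizygous at read
time from pedigree sex — this avoids mixed-ploidy FORMAT arrays while
keeping hemizygosity explicit in every downstream rule.

Expected de novo load: 2 × L × μ with μ = 1.18 × 10⁻⁸ /bp/generation and
haploid length L = 3.0 × 10⁹ bp gives 70.8 mutations per child, the
calibration target of the simulator (below).

## Consequence classification

Classification is purely geometric + codon-table based, strand-aware:

* splice sites are the canonical ±2 intronic dinucleotide flanking
  internal exon boundaries, in transcription orientation (acceptor −1/−2
  before an exon start, donor +1/+2 past an exon end). Both causal splice
  variants the pipeline is designed to detect sit in this window, at −2
  and −1;
* CDS SNVs are translated against the reference codon (synonymous /
  nonsynonymous / stop gain / stop loss). A reference-base mismatch
  between the variant record and the transcript sequence raises — it
  always indicates inconsistent inputs;
* CDS indels are frameshift when |len(alt) − len(ref)| mod 3 ≠ 0, in-frame
  otherwise; everything else is noncoding.

Exon-skip arithmetic: skipping exon k removes its overlap with the CDS;
the skip is in frame iff that overlap is divisible by 3, deleting
overlap/3 residues. A fully coding 132 nt exon gives an in-frame deletion
of 44 amino acids — the configuration that motivates reporting splice
variants as likely loss-of-function even when in frame.

The regulatory screen takes model-surviving *non-coding* variants and
keeps those that are conserved (GERP > 2 or phyloP > 2 or
phastCons > 0.95 or inside a constrained element), fall inside a
regulatory interval, and lie within 50 kb of a candidate-gene span.
Distance is measured to the gene's transcript-union span (0 inside), not
to the TSS — the simplest defensible reading, and configurable.

## Isodisomy and runs of homozygosity

Two chromosome-scale footprints identify isodisomy from trio genotypes
alone:

1. **Mendelian-error pattern.** Each trio genotype is classified by
   exhaustive transmission enumeration (consistent / inconsistent /
   uninformative), and every informative configuration is additionally
   labelled with which single parent's allele pool, sampled twice, could
   alone produce the child. On paternal isodisomy, inconsistent sites are
   overwhelmingly paternal-explicable.
2. **Windowed homozygosity.** The fraction of homozygous calls among the
   child's alt-carrying calls in 500 kb windows tiled from the first
   variant position. Windows with no informative call are reported as
   missing, not 0 — a coverage gap (centromere) is not evidence of
   heterozygosity.

Verdict thresholds (median window homozygosity ≥ 0.98, single-parent
support ≥ 0.95 among inconsistent sites, ≥ 50 inconsistent sites,
≥ 200 informative sites): chosen to tolerate the residual heterozygosity
that a ~0.5% genotype-error rate leaves on a truly isodisomic chromosome
while being unreachable by chance on biparental data, where the median
window homozygosity sits near 0.3. All four are configurable. Only
isodisomy is detectable this way — heterodisomy preserves heterozygosity
and needs haplotype phase; the male X is skipped (hemizygosity mimics
isodisomy). On a verdict, the recessive rescan of that chromosome keeps
the child-homozygous and rarity requirements but drops the het requirement
for the non-contributing parent, and requires the contributing parent to
carry the allele.

ROH scanning uses the same informative set (child alt-carrying calls):
outside an ROH most such calls are heterozygous, which is what localizes
boundaries. A greedy left-to-right scan opens a segment at a homozygous
call, extends until one more het would exceed the tolerance (default 2
per segment), trims to the outermost homozygous calls, and reports
non-overlapping segments spanning ≥ 1 Mb. Defaults detect the 2 Mb class
of autozygous regions while ignoring short Hardy–Weinberg-expected runs;
a tolerance of 0 gives exact boundary recovery at the resolution of the
local inter-variant spacing and is what the boundary-recovery tests use.

## Cohort screen

The QC cascade evaluates six independent clauses in fixed order: allele
balance (major-allele read fraction of a het call > 0.70; hom calls are
exempt, their balance is ~1 by construction), QUAL < 30, QD < 5,
depth < 25 (per-sample genotype depth), cluster (≥ 3 variants within any
10 bp span — a 2-variant rule would flag every MNP), and homopolymer (the
variant inside or immediately abutting a reference run of ≥ 5 identical
bases, the slippage-artifact class). Missing reference context marks the
homopolymer clause unevaluable without failing the record. All triggered
clauses are reported, so the audit table shows every reason, not just the
first. Selection: dominant candidates must be absent from controls;
recessive candidates need control AF < 1% and two qualifying alleles
(a homozygote or two distinct surviving variants in the gene); only
protein-altering classes are considered. Family segregation is modelled
as a genotype-concordance check, not as re-capture simulation.

## The synthetic-data generator

The generator emulates the *statistical structure* of a high-coverage
trio genome screen, not sequencing itself:

* **Genome.** Miniature by default — 22 autosomes + X at 5 Mb each,
  1 segregating site per kb — so a full pipeline run takes seconds. A
  full-length preset scales hg19-proportioned chromosomes to exactly
  3.0 × 10⁹ bp so that simulation-scale de novo counts are calibrated
  against the same L as the analytic expectation (count-only mode is used
  at this scale).
* **Standing variation.** Population AF ~ Beta(0.5, 2) clipped to
  [0.01, 0.99]: a low-frequency-skewed spectrum of *common* variation.
  Parental haplotypes are Bernoulli(AF) per site, so parental genotypes
  are Hardy–Weinberg; the child receives one transmitted haplotype per
  parent. Only trio-polymorphic sites are emitted, as a real trio VCF
  would. Because background variants are common (AF ≥ 1%), they carry
  resource memberships and internal-cohort counts that fail the rarity
  filters — rare events exist only where planted. Consequence: a null
  trio yields a structurally empty candidate report, and every reported
  candidate on synthetic data traces to a planted event.
* **Likelihoods.** Depth ~ Poisson(40) per call (high-coverage WGS with a
  nominal ≥ 25× floor), alt reads ~ Binomial(depth, p) with p ∈
  {ε, ½, 1−ε} for the true genotype and per-read error ε = 0.01; GLs are
  the exact read likelihoods, max-normalized; the call is the GL argmax.
  Genotype errors are injected by drawing the reads from a wrong genotype
  at a quarter of the mean depth, so erroneous calls are exactly the
  weak-margin calls the GLR filter exists to remove — the error rate and
  the filter's behaviour are coupled through the same read model rather
  than asserted independently.
* **Planted events.** De novo mutations: Poisson with mean 2 × total
  length × μ at parent-monomorphic positions. Isodisomy: both child
  homologues copy one parental haplotype. ROH: the parents share an
  ancestral haplotype over the region, so the child is autozygous yet
  Mendelian-consistent. The six causal trio configurations (two de novo
  missense, recessive-via-paternal-isodisomy, recessive splice in a 2 Mb
  ROH, de novo missense, de novo splice) are planted with explicit
  genotypes inside generated transcript models, with the reference codon
  forced so the intended consequence class is guaranteed; scenario sites
  are exempt from error injection (errors stress the background genome,
  scenarios test the decision logic). One scenario transcript is on the
  minus strand so strand-awareness is exercised end to end.
* **Not emulated.** Read-level data, mapping artifacts, indel realism,
  mutation-spectrum/trinucleotide context, recombination (sites are
  exchangeable given the transmitted-haplotype labels; nothing downstream
  uses linkage except UPD/ROH contiguity, which is planted explicitly),
  rare standing variation, and population structure. Passing tests
  therefore demonstrate the correctness of the decision logic under the
  stated genotype/likelihood model — not robustness to alignment or
  calling artifacts in real data.

Determinism: one `numpy` Generator seeded from the config drives every
draw in a fixed iteration order; identical configs are byte-identical
across runs, including annotation tables.

## Numerical and interface choices

* VCF is 1-based; BED and in-memory intervals are 0-based half-open; the
  conversion lives in one module (`formats_io`).
* Multiallelic rows are decomposed to one biallelic record per alt with
  genotypes remapped (other alts collapse to the reference class); the
  GL vector is re-derived by log-sum marginalization over genotypes by
  target-alt dosage, renormalized to max 0. Biallelic rows pass GLs
  through untouched, so write∘read is bit-exact for biallelic inputs.
* Records with a missing genotype are excluded from every inheritance
  model but retained for the Mendelian/homozygosity bookkeeping as
  uninformative — conservative for models, unbiased for windows.
* The per-site QUAL/QD emitted by the simulator are derived from the
  aggregate evidence against hom-ref and the summed depth; they are
  plausible-scale inputs for the screen QC, not a calibrated caller
  model.
* Ties in GL argmax resolve to the lower genotype index (hom-ref first);
  a zero-depth call has an all-equal GL vector, GLR 0, and passes nothing.

## Known limitations

* Heterodisomy and segmental UPD are out of scope (no haplotype phase).
* The compound-het rule misses pairs where both parents are het at one of
  the sites (phase-uninformative without reads).
* Consequence calls are per-transcript geometric classifications; there
  is no HGVS normalization beyond simple labels, no UTR/NMD logic, and
  indels spanning exon boundaries are classified by CDS overlap only.
* The regulatory screen depends entirely on the provided interval and
  conservation inputs; it performs no sequence-based enhancer modelling.
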