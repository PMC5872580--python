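# Methods

## Problem setting

Bulk RNA-Seq quantification of the HLA region fails with a single linear
reference because the classical class I and class II loci are hyperpolymorphic:
a donor typically carries alleles tens of substitutions away from the
reference transcript, so reads either fail to map or map with biased mismatch
penalties. `hlaquant` therefore aligns reads directly against a database of
known allele sequences, calls the donor's 4-digit genotype per locus, and uses
the called alleles as the exon model for expression normalization.

## Allele reference

The reference is any multi-FASTA of allele transcript sequences with HLA
nomenclature headers. Three header dialects are recognised (`A*02:01:01:01`,
`HLA-A*02:01`, and the accessioned `HLA:HLA00005 A*01:01:01:01 3503 bp`
form); the first parseable token wins. Names are truncated to 4-digit
(protein-level) resolution: records that differ only in synonymous or
non-coding fields are kept as multiple sequence representatives of one
callable name, and calls report the 4-digit name.

Twelve loci are supported — A, B, C, E, F, G, DPA1, DPB1, DQA1, DQB1, DRA,
DRB1. Other records (DRB3/4/5 paralogs, pseudogenes) are skipped by default
and counted, or rejected in strict mode; the DRB paralogs in particular
cross-map heavily with DRB1 and would need a dedicated disambiguation step
that is out of scope here. Sequences are uppercased; IUPAC ambiguity codes
other than N are converted to N (strict mode rejects them). Coordinates are
0-based and half-open; only the forward strand is indexed and reads are
searched in both orientations.

The k-mer index maps every k-mer (default k = 16) to all its
(allele, offset) occurrences, excluding k-mers containing N. k = 16 is long
enough to be specific on 1–4 kb transcript alleles and short enough that any
50 bp mate with at most two mismatches still contains an exact seed
(pigeonhole: two substitutions leave a clean stretch of at least
⌈(50−2)/3⌉ = 16 bases).

## Alignment and genotype calling

Alignment is ungapped and end-to-end for both mates, with mismatches summed
over the pair and capped by `max_mismatch` (default 4). Candidate alleles are
those sharing at least one exact k-mer with either mate in either orientation
combination (FR or RF; mates must be on opposite strands, insert size is
unconstrained because allele references are short). Each candidate is then
verified exhaustively over all offsets with a vectorized sliding-window
Hamming distance, so the reported per-allele minimum is exact. Because a
qualifying pair has `min(m1, m2) ≤ ⌊max_mismatch/2⌋ ≤ 2` mismatches on its
cleaner mate, seeding is guaranteed for ≥50 bp reads at the default budget,
and the seeded aligner provably returns the same best-stratum hit set as a
brute-force all-allele, all-offset aligner — a property the test suite checks
directly on random instances. Ungapped alignment is a deliberate restriction:
transcript-to-same-locus-allele alignments of short reads essentially never
require indels, and it keeps the brute-force oracle exact. Base qualities are
ignored by default; an optional switch masks bases below Q13 before alignment.

Only the minimum-mismatch stratum of each pair is retained. Pairs whose best
stratum spans two or more loci are cross-locus-ambiguous: excluded from all
locus counts and votes, but retained in the RPKM denominator. Assigned,
ambiguous and unmapped pairs always sum to the input total.

Calling is a transparent two-pass vote. Pass 1 (group): each pair contributes
one vote split equally over the distinct 2-digit groups in its best stratum;
the top group is always called, and a second group is called only when the
pairs *not* compatible with the top group carry more than θ_het of the
locus's pairs (default 0.15 — the second allele must own at least 15% of
locus-informative reads). The denominator is all locus pairs, so a single
stray read among a hundred (share ≈ 1%) never triggers a false heterozygote.
Pass 2 (allele): within each called group the allele compatible with the most
pairs wins, ties broken by fewer summed mismatches, then lexicographic name
(deterministic; all iteration is sorted). With a single called group, a
within-group heterozygote is still called when a second allele exceeds θ_het
of locus pairs after excluding pairs compatible with the first.

Confidence is `2·s2/(s1+s2)` for heterozygotes — the balance of the minor
allele's support, 1.0 at perfect 1:1 — and `1 − (largest competing allele's
exclusive share)` for homozygotes.

## Expression quantification

RPKM uses read *pairs*: a pair counts once in its locus numerator and once in
the library-size denominator, which defaults to all pairs in the sample
(assigned + ambiguous + unmapped) and can be overridden when HLA reads are a
subset of a larger library. The effective length of a locus is the mean
length of its called allele sequences (the single allele's length when
homozygous, the locus-average length when a locus had too few reads to call).
TPM rescales the profile's RPKM vector to sum to 10^6; it is only defined
when at least one gene is expressed.

External genes enter through a `(gene, count, length_bp)` TSV and share the
same denominator, so HLA loci and, e.g., proteasome subunits are directly
comparable within a sample.

Composite metrics: classical class I is the plain sum RPKM(A)+RPKM(B)+RPKM(C)
— the three heavy chains are reported as one number, and with balanced
per-locus expression the total is simply threefold each locus. Class II is
`min(DPA1,DPB1) + min(DQA1,DQB1) + min(DRA,DRB1)`: each DP/DQ/DR heterodimer
requires one alpha and one beta chain, so the isotype's functional abundance
is limited by its scarcer chain.

## Body-map aggregation

Per-tissue summaries over a cohort: the median of each metric; positivity as
the count of samples **strictly** above a threshold (default 1 RPKM) with the
percentage rounded to the nearest integer (96/123 → 78%, 113/204 → 55%,
29/161 → 18%); and outlier flags for samples strictly above a configurable
threshold on a configurable metric (e.g. classical class I above 900 RPKM).
Proteasome summaries take the median of the three constitutive proteolytic
subunits (PSMB5/6/7) and of the three inducible immunoproteasome subunits
(PSMB8/9/10). Correlations are Spearman's rho with average ranks for ties,
computed across tissue medians (n = number of tissues; reported as
not-computable below 3), with a per-sample mode for within-individual
analyses such as PSMB9 vs TAP1. No multiple-testing correction is applied;
raw rho values are reported.

## Simulator

The simulator emulates the three inputs with known truth:

* **Reference**: a global random root sequence, one locus ancestor mutated
  from it at the between-locus rate (default 0.10), and alleles mutated from
  their ancestor at the within-locus rate (default 0.02, i.e. ~2% pairwise
  divergence on top of shared variants — the order of magnitude of
  within-locus HLA allele divergence at transcript scale). Substitutions
  only, matching the ungapped aligner.
* **Reads**: pair counts multinomial over alleles with weight
  level × allele length (length-proportional sampling makes RPKM an unbiased
  recovery target); uniform fragment starts; mate 2 reverse-complemented from
  the fragment end; i.i.d. per-base substitution errors. Defaults — 50 bp
  reads, 200 bp fragments — mirror a typical short-read bulk RNA-Seq library.
  Heterozygotes default to 1:1 allelic balance (settable).
* **Cohorts**: per-sample metric values drawn log-normally around per-tissue
  medians (dispersion = sigma of the log), optional planted outliers, and
  optional tissue medians generated through a Gaussian copula at latent
  correlation 2·sin(π·ρ/6) so their population Spearman correlation equals a
  target ρ.

Every generator takes an explicit seed and is byte-deterministic; seeds are
never global state. The simulator omits several features of real data —
empirical quality profiles, indels, intronic and chimeric reads, unevenly
covered transcripts, DRB paralog cross-mapping — so passing recovery tests
demonstrates the correctness of the calling and normalization logic under the
stated error model, not robustness to every artefact of a real sequencing run.

## Validation problem sizes

The validation suite runs at desk scale: oracle equivalence on 100 random toy
instances (≤10 alleles of 140–220 bp, 10 pairs each, 1000 pairs total);
genotype recovery over 50 seeded replicates of a 4-allele locus at 35 pairs
per allele, error-free (expected: 100% exact 4-digit calls, given the two
true alleles differ by at least 5 substitutions) and at 0.5% per-base error
(expected ≥95%); RPKM recovery on 2500-pair samples; outlier
plant-and-recover on a 429-sample cohort; correlation recovery over 30
tissues. Tissue-median magnitudes used in examples and tests (e.g. whole
blood classical class I ≈ 1210 RPKM, brain ≈ 38 RPKM, placental HLA-G ≈ 19
RPKM) reflect the published scale of human tissue HLA expression; cohort
statistics here validate the aggregation machinery, not any biological claim.

## Numerical and design choices

* Percent rounding is nearest-integer; positivity is strictly greater-than
  (samples at exactly the threshold are negative). Both are configurable.
* Mismatch counting treats N on either side as a mismatch; k-mers containing
  N never seed.
* The RPKM denominator counting pairs (not mates) is a convention choice; a
  compatibility switch would halve RPKM values, not change any ratio or rank
  statistic.
* All dict iteration affecting calls is over sorted keys, making every output
  reproducible to the byte for a fixed seed.
* Degenerate inputs raise informative errors rather than returning sentinel
  values: empty FASTA, zero mapped reads, all-zero TPM normalization,
  constant vectors in Spearman, fragments longer than their allele.

## Known limitations

* No 6/8-digit resolution, novel-allele discovery, or DRB3/4/5 paralog
  disambiguation; genomic (intron-containing) versus CDS allele sequences are
  not distinguished — each record is treated as the mappable transcript.
* Ungapped alignment cannot place reads across real indel differences between
  a donor allele and its nearest database representative.
* No isoform resolution, GC/length bias correction, or cross-study batch
  correction; differential expression is delegated to dedicated tools.
* Cross-locus-ambiguous reads are dropped from numerators, which slightly
  deflates expression of loci with near-identical paralogs in the reference.
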