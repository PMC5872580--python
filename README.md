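# hlaquant

HLA genotyping and locus-level expression quantification from paired-end
RNA-Seq, with cohort "body-map" aggregation and a ground-truth read simulator.

## What it does and for whom

The human leukocyte antigen (HLA) genes are the most polymorphic loci in the
genome, which makes them invisible to standard single-reference RNA-Seq
pipelines: reads from a donor's alleles mismatch the reference and locus-level
expression is systematically mis-estimated. `hlaquant` addresses this for
immunogenomics analyses that need, per sample:

* **4-digit genotypes** for the classical class I heavy chains (HLA-A, -B, -C),
  the non-classical class I genes (HLA-E, -F, -G) and the six class II chain
  genes (DPA1, DPB1, DQA1, DQB1, DRA, DRB1), called directly against a
  polymorphic allele reference (any IMGT/HLA-style multi-FASTA);
* **locus-level expression** as RPKM and TPM, including composite metrics,
  combined with external gene-level counts (proteasome subunits PSMB5–10,
  TAP1/2, cell-type markers) supplied as plain TSV;
* **cohort aggregation** into tissue medians, threshold positivity fractions
  (e.g. share of samples with HLA-G above 1 RPKM), high-expressor outlier
  flags, proteasome summaries and Spearman rank correlations.

A seeded simulator generates allele references, read pairs and whole cohorts
with known truth, so the entire pipeline is testable end-to-end offline.

## Model and definitions

Reads are aligned **ungapped, end-to-end** to every candidate allele (exact
k-mer seeding, k = 16 by default, followed by an exhaustive sliding-window
verification), keeping for each pair only the minimum-mismatch stratum.
Genotypes are called in two passes per locus: read-pair votes first select the
2-digit serological group(s), then the best-supported 4-digit allele within
each called group. A second group or allele is only called heterozygous when
its exclusive read support exceeds a threshold θ_het (default 0.15) of the
locus-informative pairs.

Expression normalization follows the standard definitions

```
RPKM_g = count_g / ( (length_g / 10^3) · (total_mapped / 10^6) )
TPM_g  = RPKM_g / Σ_j RPKM_j · 10^6
```

where `count_g` is the number of read pairs assigned to locus *g*,
`length_g` the mean length of the called allele sequences, and
`total_mapped` the sample's total read pairs. Two composite metrics
summarize the HLA region:

* classical class I: `RPKM(A) + RPKM(B) + RPKM(C)`;
* class II (heterodimers need both chains, so each isotype is limited by its
  scarcer chain): `min(DPA1, DPB1) + min(DQA1, DQB1) + min(DRA, DRB1)`.

Constitutive proteasome abundance is the median of PSMB5/6/7; the
immunoproteasome is the median of PSMB8/9/10 (LMP7/LMP2/LMP10). Correlations
are Spearman's rank correlation, computed across tissue medians (body-map
view) or across individual samples.

## Worked example

```python
import hlaquant as hq

db = hq.simulate_allele_db(
    ["A", "B", "C", "G"], alleles_per_locus=4, allele_length=1000,
    within_locus_divergence=0.03, between_locus_divergence=0.15, seed=42,
)
hq.build_kmer_index(db, k=16)

genotypes = {"A": ("A*01:01", "A*03:01"), "B": ("B*02:01", None), "G": ("G*01:01", None)}
levels = {"A": 400.0, "B": 410.0, "G": 19.0}
pairs, truth = hq.simulate_sample(db, genotypes, levels, total_pairs=3000, seed=7)

result = hq.type_sample(pairs, db)
profile = hq.quantify_sample("demo", result, db)
```

This prints (via the loop in the example script):

```
A    A*01:01  A*03:01  heterozygous  support 723/703 confidence 0.99
B    B*02:01  -        homozygous    support 1509/0 confidence 1.00
G    G*01:01  -        homozygous    support 65/0 confidence 1.00
RPKM(A) = 475333.3  (truth: 475333.3)
RPKM(B) = 503000.0  (truth: 503000.0)
RPKM(G) = 21666.7  (truth: 21666.7)
classical class I total = 978333.3 RPKM
HLA-G = 21666.7 RPKM
```

All three genotypes are recovered exactly; the heterozygote's two alleles are
supported by a balanced 723/703 pairs (confidence 0.99), and the quantified
RPKM equals the value implied by the simulator's exact per-allele pair counts.
(RPKM values are large because the toy sample contains only HLA reads; in a
whole-transcriptome library `total_mapped` is the full library size.)

The same workflow is available from the shell:

```
hlaquant simulate db --loci A,B,G --alleles-per-locus 3 --seed 5 --out ref.fasta
hlaquant simulate sample --ref ref.fasta --genotype '{"A": ["A*01:01","A*02:01"]}' \
    --levels '{"A": 10}' --seed 6 --out-prefix s1
hlaquant type --ref ref.fasta --fq1 s1_R1.fastq --fq2 s1_R2.fastq \
    --out genotypes.tsv --assignments-out assign.tsv
hlaquant quantify --ref ref.fasta --genotypes genotypes.tsv \
    --assignments assign.tsv --out profile.tsv
hlaquant bodymap --profiles cohort.tsv --manifest manifest.tsv \
    --outlier-threshold 900 --out-dir results/
```

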