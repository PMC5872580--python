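"""HLA genotyping and expression quantification from paired-end RNA-Seq.

The package types classical (A, B, C) and non-classical (E, F, G) HLA
class I loci plus the six HLA class II chain genes (DPA1, DPB1, DQA1,
DQB1, DRA, DRB1) at 4-digit resolution directly from RNA-Seq read
pairs aligned against a polymorphic allele reference.  Read-to-locus
assignments are converted into RPKM/TPM expression values, including a
composite class II metric built from the minimum of each alpha/beta
chain pair, and many samples can be aggregated into tissue-level
body-map statistics (medians, positivity fractions, outlier flags,
proteasome summaries, Spearman correlations).  A seeded read simulator
provides ground truth for end-to-end validation.
"""

from hlaquant.allele_reference import (
    Allele,
    AlleleDatabase,
    AlleleName,
    SUPPORTED_LOCI,
    build_kmer_index,
    parse_allele_fasta,
    parse_allele_name,
)
from hlaquant.typing_engine import (
    AlignmentHit,
    GenotypeCall,
    ReadPair,
    align_read_pair,
    assign_reads_to_loci,
    call_four_digit,
    call_group,
    type_sample,
)
from hlaquant.expression_quant import (
    GeneCount,
    SampleExpressionProfile,
    class_ii_composite,
    classical_class_i_total,
    quantify_sample,
    rpkm,
    rpkm_to_tpm,
)
from hlaquant.bodymap_stats import (
    BodyMapTable,
    CorrelationResult,
    TissueSummary,
    build_bodymap,
    flag_outliers,
    median,
    positivity_fraction,
    proteasome_summary,
    spearman,
)
from hlaquant.read_simulator import (
    SimTruth,
    expected_rpkm,
    simulate_allele_db,
    simulate_cohort,
    simulate_sample,
)

__version__ = "0.1.0"

__all__ = [
    "Allele",
    "AlleleDatabase",
    "AlleleName",
    "AlignmentHit",
    "BodyMapTable",
    "CorrelationResult",
    "GeneCount",
    "GenotypeCall",
    "ReadPair",
    "SUPPORTED_LOCI",
    "SampleExpressionProfile",
    "SimTruth",
    "TissueSummary",
    "align_read_pair",
    "assign_reads_to_loci",
    "build_bodymap",
    "build_kmer_index",
    "call_four_digit",
    "call_group",
    "class_ii_composite",
    "classical_class_i_total",
    "expected_rpkm",
    "flag_outliers",
    "median",
    "parse_allele_fasta",
    "parse_allele_name",
    "positivity_fraction",
    "proteasome_summary",
    "quantify_sample",
    "rpkm",
    "rpkm_to_tpm",
    "simulate_allele_db",
    "simulate_cohort",
    "simulate_sample",
    "spearman",
    "type_sample",
]
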