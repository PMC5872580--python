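"""RPKM/TPM quantification of HLA loci and external genes.

Expression is normalized as reads per kilobase of exon model per
million mapped reads (RPKM): ``count / ((length_bp/1000) *
(total_mapped/1e6))``, where the denominator counts read *pairs* by
default (each pair maps once; cross-locus-ambiguous and unmapped pairs
count in the denominator but never in a locus numerator).  TPM is a
renormalization of RPKM so that all genes in the profile sum to 1e6:
``TPM_g = RPKM_g / sum(RPKM) * 1e6``.

Two composite metrics summarize the polymorphic loci.  Classical
class I expression is the sum of the A, B and C heavy-chain RPKMs.
Class II heterodimers need both an alpha and a beta chain, so class II
expression is the sum over the three isotypes of the limiting chain:
``min(DPA1, DPB1) + min(DQA1, DQB1) + min(DRA, DRB1)``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Mapping, TextIO

from hlaquant.allele_reference import AlleleDatabase
from hlaquant.typing_engine import GenotypeCall, TypingResult

CLASS_II_CHAIN_PAIRS = (("DPA1", "DPB1"), ("DQA1", "DQB1"), ("DRA", "DRB1"))
CLASSICAL_CLASS_I = ("A", "B", "C")
CONSTITUTIVE_PSMB = ("PSMB5", "PSMB6", "PSMB7")
IMMUNO_PSMB = ("PSMB8", "PSMB9", "PSMB10")


@dataclass(frozen=True)
class GeneCount:
    """A gene-level read count with the gene's length in base pairs."""

    gene: str
    count: int
    length_bp: int

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError(f"negative count for {self.gene}")
        if self.length_bp <= 0:
            raise ValueError(f"non-positive length for {self.gene}")


@dataclass
class SampleExpressionProfile:
    """Per-sample RPKM/TPM values plus derived composite metrics."""

    sample: str
    tissue: str = ""
    rpkm: dict[str, float] = field(default_factory=dict)
    tpm: dict[str, float] = field(default_factory=dict)
    classI_classical: float = 0.0
    classII_composite: float = 0.0
    hla_e: float = 0.0
    hla_f: float = 0.0
    hla_g: float = 0.0
    proteasome_constitutive: float | None = None
    proteasome_immuno: float | None = None
    total_mapped_reads: int = 0

    def metric(self, name: str) -> float | None:
        """Look up a composite metric or a plain gene RPKM by name."""
        composites = {
            "classI_classical": self.classI_classical,
            "classII_composite": self.classII_composite,
            "HLA-E": self.hla_e,
            "HLA-F": self.hla_f,
            "HLA-G": self.hla_g,
            "proteasome_constitutive": self.proteasome_constitutive,
            "proteasome_immuno": self.proteasome_immuno,
        }
        if name in composites:
            return composites[name]
        return self.rpkm.get(name)


def rpkm(count: float, length_bp: float, total_mapped: int) -> float:
    """Reads per kilobase per million mapped reads.

    >>> rpkm(100, 1000, 1_000_000)
    100.0
    """
    if length_bp <= 0:
        raise ValueError(f"length_bp must be positive, got {length_bp}")
    if total_mapped <= 0:
        raise ZeroDivisionError(
            f"RPKM undefined: total_mapped must be positive, got {total_mapped}"
        )
    if count < 0:
        raise ValueError(f"count must be non-negative, got {count}")
    return count / ((length_bp / 1_000.0) * (total_mapped / 1_000_000.0))


def class_ii_composite(
    dpa1: float, dpb1: float, dqa1: float, dqb1: float, dra: float, drb1: float
) -> float:
    """Limiting-chain class II metric: sum of the per-isotype chain minima."""
    values = (dpa1, dpb1, dqa1, dqb1, dra, drb1)
    if any(v < 0 for v in values):
        raise ValueError("class II chain RPKMs must be non-negative")
    return min(dpa1, dpb1) + min(dqa1, dqb1) + min(dra, drb1)


def classical_class_i_total(a: float, b: float, c: float) -> float:
    """Classical class I heavy-chain total: RPKM(A) + RPKM(B) + RPKM(C)."""
    if a < 0 or b < 0 or c < 0:
        raise ValueError("class I RPKMs must be non-negative")
    return a + b + c


def rpkm_to_tpm(rpkm_values: Mapping[str, float]) -> dict[str, float]:
    """Rescale a gene→RPKM mapping so the values sum to 1e6."""
    total = sum(rpkm_values.values())
    if total <= 0:
        raise ValueError("TPM undefined: all RPKM values are zero")
    return {g: v / total * 1_000_000.0 for g, v in rpkm_values.items()}


def _locus_effective_length(
    db: AlleleDatabase, call: GenotypeCall | None, locus: str
) -> float | None:
    """Mean sequence length of the called alleles (fallback: locus mean)."""
    if call is not None:
        lengths = [db.mean_length(call.allele1)]
        if call.allele2 is not None:
            lengths.append(db.mean_length(call.allele2))
        return sum(lengths) / len(lengths)
    alleles = db.by_locus.get(locus)
    if not alleles:
        return None
    return sum(a.length_bp for a in alleles) / len(alleles)


def quantify_sample(
    sample: str,
    typing: TypingResult,
    db: AlleleDatabase,
    external_counts: Mapping[str, GeneCount] | None = None,
    total_mapped: int | None = None,
    tissue: str = "",
) -> SampleExpressionProfile:
    """Build the expression profile of one sample from its typing result.

    Per-locus counts are the pairs assigned to the locus; the effective
    length is the mean length of the called allele sequences (single
    allele when homozygous, locus average when the locus was expressed
    too weakly to call).  ``total_mapped`` defaults to the total pairs
    in the sample (assigned + ambiguous + unmapped).  External gene
    counts (proteasome subunits, TAP1/2, marker genes) are merged so
    RPKM/TPM is computed over the union.
    """
    if total_mapped is None:
        total_mapped = typing.total_pairs
    if total_mapped <= 0:
        raise ZeroDivisionError("total_mapped must be positive to quantify a sample")

    rpkm_values: dict[str, float] = {}
    for locus in sorted(db.by_locus):
        count = typing.locus_counts.get(locus, 0)
        eff_len = _locus_effective_length(db, typing.calls.get(locus), locus)
        if eff_len is None:
            continue
        rpkm_values[locus] = rpkm(count, eff_len, total_mapped)

    if external_counts:
        for gene, gc in sorted(external_counts.items()):
            if gc.length_bp <= 0:
                raise ValueError(f"missing or invalid length for external gene {gene}")
            rpkm_values[gene] = rpkm(gc.count, gc.length_bp, total_mapped)

    profile = SampleExpressionProfile(
        sample=sample,
        tissue=tissue,
        rpkm=rpkm_values,
        total_mapped_reads=total_mapped,
    )
    profile.classI_classical = classical_class_i_total(
        *(rpkm_values.get(l, 0.0) for l in CLASSICAL_CLASS_I)
    )
    profile.classII_composite = class_ii_composite(
        *(rpkm_values.get(l, 0.0) for pair in CLASS_II_CHAIN_PAIRS for l in pair)
    )
    profile.hla_e = rpkm_values.get("E", 0.0)
    profile.hla_f = rpkm_values.get("F", 0.0)
    profile.hla_g = rpkm_values.get("G", 0.0)

    if all(g in rpkm_values for g in CONSTITUTIVE_PSMB + IMMUNO_PSMB):
        # median summaries over the proteolytic subunits; computed in
        # bodymap_stats to keep one definition
        from hlaquant.bodymap_stats import proteasome_summary

        const, immuno = proteasome_summary(
            *(rpkm_values[g] for g in CONSTITUTIVE_PSMB + IMMUNO_PSMB)
        )
        profile.proteasome_constitutive = const
        profile.proteasome_immuno = immuno

    if any(v > 0 for v in rpkm_values.values()):
        profile.tpm = rpkm_to_tpm(rpkm_values)
    return profile


#: Composite metric name -> profile attribute.
METRIC_ATTRS = {
    "classI_classical": "classI_classical",
    "classII_composite": "classII_composite",
    "HLA-E": "hla_e",
    "HLA-F": "hla_f",
    "HLA-G": "hla_g",
    "proteasome_constitutive": "proteasome_constitutive",
    "proteasome_immuno": "proteasome_immuno",
}


def set_metric(profile: SampleExpressionProfile, metric: str, value: float) -> None:
    """Set a composite metric or a plain gene RPKM on a profile."""
    attr = METRIC_ATTRS.get(metric)
    if attr is not None:
        setattr(profile, attr, value)
    else:
        profile.rpkm[metric] = value


def profiles_from_cohort_rows(rows: list[dict]) -> list[SampleExpressionProfile]:
    """Rebuild profiles from wide cohort rows (inverse of
    :func:`profiles_to_cohort_rows` up to per-gene TPM detail)."""
    profiles = []
    for row in rows:
        p = SampleExpressionProfile(
            sample=str(row["sample"]), tissue=str(row.get("tissue", "") or "")
        )
        for key, value in row.items():
            if key in ("sample", "tissue") or value is None:
                continue
            try:
                v = float(value)
            except (TypeError, ValueError):
                continue
            if v != v:  # NaN
                continue
            set_metric(p, key, v)
        profiles.append(p)
    return profiles


def read_gene_counts_tsv(handle: TextIO) -> dict[str, GeneCount]:
    """Read an external gene count table (gene, count, length_bp)."""
    reader = csv.DictReader(handle, delimiter="\t")
    required = {"gene", "count", "length_bp"}
    if reader.fieldnames is None or not required.issubset(reader.fieldnames):
        raise ValueError(
            f"gene count table must have columns {sorted(required)}, "
            f"got {reader.fieldnames}"
        )
    out: dict[str, GeneCount] = {}
    for row in reader:
        out[row["gene"]] = GeneCount(
            gene=row["gene"], count=int(row["count"]), length_bp=int(row["length_bp"])
        )
    return out


def write_profile_tsv(profile: SampleExpressionProfile, handle: TextIO) -> None:
    """Write one sample's long-format expression table (gene, rpkm, tpm)."""
    handle.write("gene\trpkm\ttpm\n")
    for gene in sorted(profile.rpkm):
        tpm = profile.tpm.get(gene, 0.0)
        handle.write(f"{gene}\t{profile.rpkm[gene]:.6g}\t{tpm:.6g}\n")
    for metric in ("classI_classical", "classII_composite"):
        handle.write(f"{metric}\t{getattr(profile, metric):.6g}\t-\n")


def profiles_to_cohort_rows(
    profiles: list[SampleExpressionProfile],
) -> list[dict[str, object]]:
    """Wide cohort rows (sample x metrics) for TSV/DataFrame export."""
    rows = []
    for p in profiles:
        row: dict[str, object] = {
            "sample": p.sample,
            "tissue": p.tissue,
            "classI_classical": p.classI_classical,
            "classII_composite": p.classII_composite,
            "HLA-E": p.hla_e,
            "HLA-F": p.hla_f,
            "HLA-G": p.hla_g,
        }
        if p.proteasome_constitutive is not None:
            row["proteasome_constitutive"] = p.proteasome_constitutive
        if p.proteasome_immuno is not None:
            row["proteasome_immuno"] = p.proteasome_immuno
        for gene, v in p.rpkm.items():
            if gene not in row:
                row[gene] = v
        rows.append(row)
    return rows
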