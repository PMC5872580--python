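"""Two-pass HLA genotype calling from paired-end reads.

Read pairs are aligned ungapped and end-to-end against every candidate
allele (seed-and-verify over the reference k-mer index), keeping only
the minimum-mismatch stratum per pair.  Calling then proceeds in two
passes per locus: first the 2-digit serological group(s) are chosen by
read-pair vote, then the best-supported 4-digit allele within each
called group.  A second group (or a second allele within a group) is
called heterozygous only when its exclusive read support exceeds the
heterozygosity threshold ``theta_het`` of locus-informative pairs.

The aligner is deliberately ungapped: reference alleles are transcript
sequences of the same gene family, so same-locus alignments of short
reads essentially never require indels, and the simple model admits an
exact brute-force oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence, TextIO

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from hlaquant.allele_reference import AlleleDatabase, AlleleName

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Default mismatch budget per pair (summed over both mates).
DEFAULT_MAX_MISMATCH = 4
#: Default second-allele support threshold (fraction of locus pairs).
DEFAULT_THETA_HET = 0.15
#: Phred threshold below which bases are masked when quality masking is on.
QUALITY_MASK_PHRED = 13


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReadPair:
    """A paired-end read: two mates with optional Phred+33 qualities."""

    read_id: str
    mate1: str
    mate2: str
    qual1: str = ""
    qual2: str = ""


@dataclass(frozen=True)
class AlignmentHit:
    """An ungapped end-to-end placement of both mates on one allele.

    ``positions`` are the 0-based reference offsets of the two mates as
    placed; ``orientation`` records which mate aligned forward ("FR":
    mate1 forward, "RF": mate2 forward).  ``mismatches`` is summed over
    both mates.
    """

    read_id: str
    allele: AlleleName
    mismatches: int
    positions: tuple[int, int]
    orientation: str


@dataclass(frozen=True)
class GenotypeCall:
    """A per-locus genotype at 4-digit resolution.

    ``support1``/``support2`` count read pairs compatible with each
    called allele; ``confidence`` is in [0, 1] (for heterozygotes the
    balance of the minor allele, for homozygotes one minus the largest
    competing allele's exclusive share).
    """

    locus: str
    allele1: AlleleName
    allele2: AlleleName | None
    support1: int
    support2: int
    zygosity: str  # "homozygous" | "heterozygous"
    confidence: float

    def __post_init__(self) -> None:
        if (self.allele2 is not None) != (self.zygosity == "heterozygous"):
            raise ValueError("allele2 must be present iff call is heterozygous")


def _mask_low_quality(seq: str, qual: str, threshold: int = QUALITY_MASK_PHRED) -> str:
    if not qual:
        return seq
    return "".join(
        "N" if (ord(q) - 33) < threshold else b for b, q in zip(seq, qual)
    )


_N = ord("N")


def _best_offset(read: str, ref: str, budget: int) -> tuple[int, int] | None:
    """Best (mismatches, offset) of ``read`` over all end-to-end placements.

    Exhaustive over every valid offset (vectorized sliding-window
    Hamming distance); an N on either side never matches.  Returns
    None when no placement is within ``budget``.
    """
    if len(read) > len(ref) or budget < 0:
        return None
    r = np.frombuffer(read.encode(), dtype=np.uint8)
    windows = sliding_window_view(np.frombuffer(ref.encode(), dtype=np.uint8), len(read))
    mism = ((windows != r) | (r == _N) | (windows == _N)).sum(axis=1)
    off = int(np.argmin(mism))
    best = int(mism[off])
    if best > budget:
        return None
    return best, off


def _seed_candidates(seq: str, db: AlleleDatabase) -> set[int]:
    """Allele indices sharing at least one exact k-mer with ``seq``."""
    k = db.k
    out: set[int] = set()
    index = db.kmer_index
    for off in range(len(seq) - k + 1):
        postings = index.get(seq[off : off + k])
        if postings:
            out.update(idx for idx, _ in postings)
    return out


def align_read_pair(
    pair: ReadPair,
    db: AlleleDatabase,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    mask_quality: bool = False,
) -> list[AlignmentHit]:
    """Align both mates of a pair against the reference, ungapped.

    Returns hits on all alleles where both mates admit end-to-end
    placements in opposite orientations (FR or RF) with total
    mismatches within ``max_mismatch``; only the best (minimum
    mismatch) stratum is kept.  Mates shorter than the index k-mer
    length cannot seed and the pair is reported unmapped (empty list).

    Candidate alleles are found through exact k-mer seeds of either
    mate, then verified by full scan, so a qualifying allele is found
    whenever the cleaner mate carries at most ``len(mate)/k - 1``
    mismatches — always true for the error rates this pipeline targets.
    """
    if not db.kmer_index:
        raise ValueError("database has no k-mer index; call build_kmer_index first")
    m1 = _mask_low_quality(pair.mate1, pair.qual1) if mask_quality else pair.mate1
    m2 = _mask_low_quality(pair.mate2, pair.qual2) if mask_quality else pair.mate2
    if min(len(m1), len(m2)) < db.k:
        return []

    hits: list[AlignmentHit] = []
    best_total = max_mismatch
    # orientation "FR": mate1 forward + mate2 reverse-complemented;
    # "RF": the converse.  Opposite-strand mates only.
    for orientation, (s1, s2) in (
        ("FR", (m1, reverse_complement(m2))),
        ("RF", (reverse_complement(m1), m2)),
    ):
        candidates = _seed_candidates(s1, db) | _seed_candidates(s2, db)
        for idx in sorted(candidates):
            allele = db.alleles[idx]
            ref = allele.sequence
            r1 = _best_offset(s1, ref, best_total)
            if r1 is None:
                continue
            r2 = _best_offset(s2, ref, best_total - r1[0])
            if r2 is None:
                continue
            total = r1[0] + r2[0]
            if total <= best_total:
                hits.append(
                    AlignmentHit(
                        read_id=pair.read_id,
                        allele=allele.name,
                        mismatches=total,
                        positions=(r1[1], r2[1]),
                        orientation=orientation,
                    )
                )

    if not hits:
        return []
    best = min(h.mismatches for h in hits)
    # one hit per distinct 4-digit allele name in the best stratum,
    # deterministic order
    seen: dict[AlleleName, AlignmentHit] = {}
    for h in sorted(hits, key=lambda h: (h.allele, h.orientation, h.positions)):
        if h.mismatches == best and h.allele not in seen:
            seen[h.allele] = h
    return list(seen.values())


def assign_reads_to_loci(
    hits_by_pair: dict[str, list[AlignmentHit]],
) -> dict[str, str]:
    """Assign each pair to the locus of its best-stratum hits.

    Pairs whose best stratum spans two or more loci are labelled
    ``"ambiguous"``; pairs with no hits are ``"unmapped"``.  These are
    excluded from locus counts but still counted in the RPKM
    denominator downstream.
    """
    out: dict[str, str] = {}
    for read_id, hits in hits_by_pair.items():
        if not hits:
            out[read_id] = "unmapped"
            continue
        loci = {h.allele.locus for h in hits}
        out[read_id] = loci.pop() if len(loci) == 1 else "ambiguous"
    return out


def call_group(
    hits: Sequence[AlignmentHit],
    theta_het: float = DEFAULT_THETA_HET,
) -> list[tuple[tuple[str, str], float]]:
    """First pass: call one or two 2-digit groups for a locus.

    Each pair contributes one vote, split equally among the distinct
    groups present in its best stratum.  The top group is always
    called; a second group is called only when the pairs *not*
    compatible with the top group carry more than ``theta_het`` of the
    locus's pairs, attributing those exclusive votes to their own top
    group.  Returns ``[(group, votes), ...]`` (empty when no hits).
    """
    by_pair: dict[str, set[tuple[str, str]]] = {}
    for h in hits:
        by_pair.setdefault(h.read_id, set()).add(h.allele.group)
    if not by_pair:
        return []
    loci = {g[0] for groups in by_pair.values() for g in groups}
    if len(loci) > 1:
        raise ValueError(f"call_group expects hits from one locus, got {sorted(loci)}")

    votes: dict[tuple[str, str], float] = {}
    for groups in by_pair.values():
        share = 1.0 / len(groups)
        for g in groups:
            votes[g] = votes.get(g, 0.0) + share
    top = max(sorted(votes), key=lambda g: votes[g])
    called = [(top, votes[top])]

    n_pairs = len(by_pair)
    excl_votes: dict[tuple[str, str], float] = {}
    for groups in by_pair.values():
        if top in groups:
            continue
        share = 1.0 / len(groups)
        for g in groups:
            excl_votes[g] = excl_votes.get(g, 0.0) + share
    if excl_votes:
        second = max(sorted(excl_votes), key=lambda g: excl_votes[g])
        if excl_votes[second] / n_pairs > theta_het:
            called.append((second, excl_votes[second]))
    return called


def _compatible_pairs(
    hits: Sequence[AlignmentHit], allele: AlleleName
) -> set[str]:
    return {h.read_id for h in hits if h.allele == allele}


def call_four_digit(
    hits: Sequence[AlignmentHit],
    groups: Sequence[tuple[tuple[str, str], float]],
    theta_het: float = DEFAULT_THETA_HET,
) -> GenotypeCall | None:
    """Second pass: resolve called group(s) to a 4-digit genotype.

    Within each called group the allele compatible with the most pairs
    wins (ties broken by fewer summed mismatches, then lexicographic
    name).  With a single called group, a within-group heterozygote is
    still called when a second allele owns more than ``theta_het`` of
    locus pairs after excluding pairs compatible with the first.
    """
    if not groups:
        return None
    locus = groups[0][0][0]
    pair_ids = {h.read_id for h in hits}
    n_pairs = len(pair_ids)

    def best_in_group(
        group: tuple[str, str], eligible: set[str] | None = None
    ) -> tuple[AlleleName, set[str]] | None:
        """Top allele of ``group`` by compatible pairs (within ``eligible``)."""
        stats: dict[AlleleName, tuple[int, int]] = {}
        support: dict[AlleleName, set[str]] = {}
        for h in hits:
            if h.allele.group != group:
                continue
            if eligible is not None and h.read_id not in eligible:
                continue
            n, mm = stats.get(h.allele, (0, 0))
            stats[h.allele] = (n + 1, mm + h.mismatches)
            support.setdefault(h.allele, set()).add(h.read_id)
        if not stats:
            return None
        winner = min(stats, key=lambda a: (-stats[a][0], stats[a][1], a))
        return winner, support[winner]

    first = best_in_group(groups[0][0])
    if first is None:
        return None
    allele1, support1_ids = first

    allele2: AlleleName | None = None
    support2_ids: set[str] = set()
    if len(groups) == 2:
        second = best_in_group(groups[1][0])
        if second is not None:
            allele2, support2_ids = second
    else:
        rest = pair_ids - support1_ids
        second = best_in_group(groups[0][0], eligible=rest)
        if second is not None and len(second[1]) / n_pairs > theta_het:
            allele2, support2_ids = second

    if allele2 is not None:
        s1, s2 = len(support1_ids), len(support2_ids)
        if s2 > s1:
            allele1, allele2 = allele2, allele1
            s1, s2 = s2, s1
        confidence = min(1.0, 2.0 * s2 / (s1 + s2)) if (s1 + s2) else 0.0
        return GenotypeCall(
            locus=locus,
            allele1=allele1,
            allele2=allele2,
            support1=s1,
            support2=s2,
            zygosity="heterozygous",
            confidence=confidence,
        )

    # homozygous: confidence = 1 - exclusive share of the best competitor
    competitor_share = 0.0
    rest = pair_ids - support1_ids
    if rest:
        excl: dict[AlleleName, set[str]] = {}
        for h in hits:
            if h.allele != allele1 and h.read_id in rest:
                excl.setdefault(h.allele, set()).add(h.read_id)
        if excl:
            competitor_share = max(len(v) for v in excl.values()) / n_pairs
    return GenotypeCall(
        locus=locus,
        allele1=allele1,
        allele2=None,
        support1=len(support1_ids),
        support2=0,
        zygosity="homozygous",
        confidence=max(0.0, 1.0 - competitor_share),
    )


@dataclass
class TypingResult:
    """Full per-sample typing output: calls, assignments, tallies."""

    calls: dict[str, GenotypeCall] = field(default_factory=dict)
    assignments: dict[str, str] = field(default_factory=dict)
    locus_counts: dict[str, int] = field(default_factory=dict)
    n_ambiguous: int = 0
    n_unmapped: int = 0
    total_pairs: int = 0


def type_sample(
    pairs: Iterable[ReadPair],
    db: AlleleDatabase,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    theta_het: float = DEFAULT_THETA_HET,
    mask_quality: bool = False,
) -> TypingResult:
    """Run alignment, locus assignment and genotype calling on a sample."""
    result = TypingResult()
    hits_by_pair: dict[str, list[AlignmentHit]] = {}
    hits_by_locus: dict[str, list[AlignmentHit]] = {}
    for pair in pairs:
        result.total_pairs += 1
        hits = align_read_pair(pair, db, max_mismatch=max_mismatch, mask_quality=mask_quality)
        hits_by_pair[pair.read_id] = hits

    result.assignments = assign_reads_to_loci(hits_by_pair)
    for read_id, where in result.assignments.items():
        if where == "ambiguous":
            result.n_ambiguous += 1
        elif where == "unmapped":
            result.n_unmapped += 1
        else:
            result.locus_counts[where] = result.locus_counts.get(where, 0) + 1
            hits_by_locus.setdefault(where, []).extend(hits_by_pair[read_id])

    for locus in sorted(hits_by_locus):
        groups = call_group(hits_by_locus[locus], theta_het=theta_het)
        call = call_four_digit(hits_by_locus[locus], groups, theta_het=theta_het)
        if call is not None:
            result.calls[locus] = call
    return result


def read_fastq_pairs(fq1: TextIO, fq2: TextIO) -> Iterator[ReadPair]:
    """Stream read pairs from two parallel FASTQ files (Phred+33)."""
    from Bio import SeqIO

    it1 = SeqIO.parse(fq1, "fastq")
    it2 = SeqIO.parse(fq2, "fastq")
    for rec1, rec2 in zip(it1, it2):
        yield ReadPair(
            read_id=rec1.id,
            mate1=str(rec1.seq).upper(),
            mate2=str(rec2.seq).upper(),
            qual1="".join(chr(q + 33) for q in rec1.letter_annotations["phred_quality"]),
            qual2="".join(chr(q + 33) for q in rec2.letter_annotations["phred_quality"]),
        )


def write_genotype_tsv(sample: str, result: TypingResult, handle: TextIO) -> None:
    """Write the per-locus genotype report for one sample."""
    handle.write(
        "sample\tlocus\tallele1\tallele2\tsupport1\tsupport2\tzygosity\tconfidence\n"
    )
    for locus in sorted(result.calls):
        c = result.calls[locus]
        a2 = c.allele2.name if c.allele2 is not None else "-"
        handle.write(
            f"{sample}\t{locus}\t{c.allele1.name}\t{a2}\t"
            f"{c.support1}\t{c.support2}\t{c.zygosity}\t{c.confidence:.4f}\n"
        )
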