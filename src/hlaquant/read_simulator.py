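"""Seeded simulation of allele references, read pairs and cohorts.

Every generator takes an explicit integer seed and is fully
deterministic for a fixed seed, so typing, quantification and
aggregation can be validated end-to-end against known ground truth
without any external data.

The sequence model is deliberately simple: substitution-only
divergence between and within loci (matching the ungapped aligner),
uniform fragment start positions, and i.i.d. per-base substitution
sequencing errors.  Fragments are drawn multinomially over alleles
with weight proportional to expression level times allele length, so
that RPKM — a length-normalized quantity — has a clean expected value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence, TextIO

import numpy as np

from hlaquant.allele_reference import (
    Allele,
    AlleleDatabase,
    AlleleName,
)
from hlaquant.expression_quant import SampleExpressionProfile, rpkm, set_metric
from hlaquant.typing_engine import ReadPair, reverse_complement

_BASES = np.array(list("ACGT"))


@dataclass
class SimTruth:
    """Ground truth emitted alongside simulated reads.

    ``abundances`` holds the exact per-allele pair counts drawn (they
    sum to ``total_pairs``); ``genotypes`` maps each expressed locus to
    its true 4-digit allele pair (second entry None when homozygous).
    """

    genotypes: dict[str, tuple[str, str | None]]
    abundances: dict[str, int]
    read_length: int
    fragment_length: int
    error_rate: float
    seed: int
    total_pairs: int


@dataclass
class CohortTruth:
    """Ground truth for a simulated cohort of expression profiles."""

    tissue_medians: dict[str, dict[str, float]]
    dispersion: float
    planted_outliers: dict[str, list[str]] = field(default_factory=dict)
    target_rho: float | None = None
    seed: int = 0


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length)


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    """Substitute each position with probability ``rate`` (to a new base)."""
    out = seq.copy()
    hit = np.flatnonzero(rng.random(len(seq)) < rate)
    if hit.size:
        # shift by 1..3 mod 4 guarantees a different base
        out[hit] = (out[hit] + rng.integers(1, 4, size=hit.size)) % 4
    return out


def _to_str(seq: np.ndarray) -> str:
    return "".join(_BASES[seq])


def simulate_allele_db(
    loci: Sequence[str],
    alleles_per_locus: int,
    allele_length: int = 1000,
    within_locus_divergence: float = 0.02,
    between_locus_divergence: float = 0.10,
    seed: int = 0,
    alleles_per_group: int = 1,
) -> AlleleDatabase:
    """Generate a synthetic polymorphic allele reference.

    One random ancestral sequence is drawn per locus by mutating a
    common root at the between-locus rate; alleles are then mutated
    from their locus ancestor at the within-locus rate.  Names are
    assigned sequentially as ``locus*GG:PP`` with ``alleles_per_group``
    protein-level alleles per 2-digit group.
    """
    for name, rate in (
        ("within_locus_divergence", within_locus_divergence),
        ("between_locus_divergence", between_locus_divergence),
    ):
        if not (0 <= rate < 0.5):
            raise ValueError(f"{name} must be in [0, 0.5), got {rate}")
    if between_locus_divergence <= within_locus_divergence:
        raise ValueError("between-locus divergence must exceed within-locus divergence")
    if alleles_per_group < 1:
        raise ValueError("alleles_per_group must be >= 1")

    rng = np.random.default_rng(seed)
    root = _random_sequence(rng, allele_length)
    alleles: list[Allele] = []
    for locus in loci:
        ancestor = _mutate(rng, root, between_locus_divergence)
        for i in range(alleles_per_locus):
            seq = _mutate(rng, ancestor, within_locus_divergence)
            group = i // alleles_per_group + 1
            protein = i % alleles_per_group + 1
            name = AlleleName(
                locus=locus,
                field1=f"{group:02d}",
                field2=f"{protein:02d}",
                raw=f"{locus}*{group:02d}:{protein:02d}",
            )
            alleles.append(Allele(name=name, sequence=_to_str(seq)))
    return AlleleDatabase(alleles=alleles)


def _resolve_allele(db: AlleleDatabase, name: str | AlleleName) -> Allele:
    if isinstance(name, AlleleName):
        key = name.name
    else:
        key = name
    for allele in db.alleles:
        if allele.name.name == key:
            return allele
    raise KeyError(f"allele {key} not found in database")


def simulate_sample(
    db: AlleleDatabase,
    genotypes: Mapping[str, tuple[str, str | None]],
    expression_levels: Mapping[str, float],
    total_pairs: int,
    read_length: int = 50,
    fragment_length: int = 200,
    error_rate: float = 0.0,
    seed: int = 0,
    allelic_imbalance: float = 1.0,
) -> tuple[list[ReadPair], SimTruth]:
    """Simulate paired-end reads for one sample with known truth.

    ``genotypes`` maps locus to a 4-digit allele pair (second allele
    None for homozygotes); ``expression_levels`` gives each locus a
    non-negative abundance.  Heterozygous loci split their level
    ``allelic_imbalance : 1`` between allele1 and allele2 (1:1 by
    default).  Pair counts are multinomial with weights level x allele
    length; fragment starts are uniform; mate2 is the reverse
    complement of the fragment end; substitution errors are i.i.d. per
    base at ``error_rate``.
    """
    if total_pairs < 0:
        raise ValueError("total_pairs must be non-negative")
    if fragment_length < read_length:
        raise ValueError("fragment_length must be >= read_length")
    if not (0 <= error_rate < 1):
        raise ValueError("error_rate must be in [0, 1)")

    rng = np.random.default_rng(seed)
    sources: list[Allele] = []
    weights: list[float] = []
    for locus in sorted(genotypes):
        level = expression_levels.get(locus, 0.0)
        if level < 0:
            raise ValueError(f"negative expression level for locus {locus}")
        a1, a2 = genotypes[locus]
        allele1 = _resolve_allele(db, a1)
        if a2 is None:
            split = [(allele1, 1.0)]
        else:
            allele2 = _resolve_allele(db, a2)
            w1 = allelic_imbalance / (1.0 + allelic_imbalance)
            split = [(allele1, w1), (allele2, 1.0 - w1)]
        for allele, frac in split:
            if allele.length_bp < fragment_length:
                raise ValueError(
                    f"fragment length {fragment_length} exceeds allele "
                    f"{allele.name.name} (length {allele.length_bp})"
                )
            sources.append(allele)
            weights.append(level * frac * allele.length_bp)

    total_weight = sum(weights)
    if total_weight <= 0 and total_pairs > 0:
        raise ValueError("no positive expression level among genotyped loci")
    counts = (
        rng.multinomial(total_pairs, np.asarray(weights) / total_weight)
        if total_pairs > 0
        else np.zeros(len(sources), dtype=int)
    )

    pairs: list[ReadPair] = []
    abundances: dict[str, int] = {}
    qual = "I" * read_length
    read_no = 0
    for allele, n in zip(sources, counts):
        abundances[allele.name.name] = abundances.get(allele.name.name, 0) + int(n)
        if n == 0:
            continue
        seq = allele.sequence
        max_start = allele.length_bp - fragment_length
        starts = rng.integers(0, max_start + 1, size=int(n))
        for s in starts:
            frag_end = int(s) + fragment_length
            mate1 = seq[int(s) : int(s) + read_length]
            mate2 = reverse_complement(seq[frag_end - read_length : frag_end])
            if error_rate > 0:
                mate1 = _apply_errors(rng, mate1, error_rate)
                mate2 = _apply_errors(rng, mate2, error_rate)
            pairs.append(
                ReadPair(
                    read_id=f"sim{read_no:07d}",
                    mate1=mate1,
                    mate2=mate2,
                    qual1=qual,
                    qual2=qual,
                )
            )
            read_no += 1

    truth = SimTruth(
        genotypes={
            locus: (
                _resolve_allele(db, g[0]).name.name,
                None if g[1] is None else _resolve_allele(db, g[1]).name.name,
            )
            for locus, g in genotypes.items()
        },
        abundances=abundances,
        read_length=read_length,
        fragment_length=fragment_length,
        error_rate=error_rate,
        seed=seed,
        total_pairs=total_pairs,
    )
    return pairs, truth


def _apply_errors(rng: np.random.Generator, read: str, rate: float) -> str:
    arr = np.frombuffer(read.encode(), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(len(read)) < rate)
    if hit.size == 0:
        return read
    lookup = {ord(b): i for i, b in enumerate("ACGT")}
    for pos in hit:
        base = lookup.get(arr[pos])
        if base is None:
            continue
        arr[pos] = ord("ACGT"[(base + rng.integers(1, 4)) % 4])
    return arr.tobytes().decode()


def expected_rpkm(
    truth: SimTruth, db: AlleleDatabase, total_pairs: int | None = None
) -> dict[str, float]:
    """Per-locus RPKM implied by the simulator's exact pair counts.

    Uses the true per-allele counts and the mean length of the true
    alleles at each locus — the oracle the quantifier is tested against.
    """
    if total_pairs is None:
        total_pairs = truth.total_pairs
    out: dict[str, float] = {}
    for locus, (a1, a2) in truth.genotypes.items():
        names = [a1] if a2 is None or a2 == a1 else [a1, a2]
        count = sum(truth.abundances.get(n, 0) for n in names)
        lengths = [_resolve_allele(db, n).length_bp for n in names]
        mean_len = sum(lengths) / len(lengths)
        out[locus] = rpkm(count, mean_len, total_pairs) if total_pairs > 0 else 0.0
    return out


def correlated_tissue_medians(
    n_tissues: int,
    metric_x: str,
    metric_y: str,
    target_rho: float,
    seed: int = 0,
    log_mean: float = 3.0,
    log_sd: float = 1.0,
) -> dict[str, dict[str, float]]:
    """Log-normal tissue medians for two metrics with a target Spearman rho.

    Uses a Gaussian copula: the latent normals are correlated at
    ``2 sin(pi rho / 6)`` so their (population) Spearman correlation
    equals ``target_rho``; the log-normal transform is monotone and
    preserves ranks.
    """
    if not (-1 <= target_rho <= 1):
        raise ValueError("target_rho must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    r = 2.0 * np.sin(np.pi * target_rho / 6.0)
    z1 = rng.standard_normal(n_tissues)
    z2 = r * z1 + np.sqrt(max(0.0, 1.0 - r * r)) * rng.standard_normal(n_tissues)
    return {
        f"tissue{i + 1:02d}": {
            metric_x: float(np.exp(log_mean + log_sd * z1[i])),
            metric_y: float(np.exp(log_mean + log_sd * z2[i])),
        }
        for i in range(n_tissues)
    }


def simulate_cohort(
    tissue_medians: Mapping[str, Mapping[str, float]],
    samples_per_tissue: int,
    dispersion: float = 0.0,
    seed: int = 0,
    outliers: Sequence[tuple[str, str, int, float]] = (),
    target_rho: float | None = None,
) -> tuple[list[SampleExpressionProfile], dict[str, str], CohortTruth]:
    """Simulate a cohort of expression profiles around tissue medians.

    Each sample's metric value is drawn log-normally around its
    tissue's median (``dispersion`` is the sigma of the log; 0 makes
    every sample equal its median).  ``outliers`` plants, per
    ``(tissue, metric, count, value)`` entry, ``count`` extra samples
    whose metric is fixed at ``value``.  Returns the profiles, the
    sample→tissue manifest, and the ground truth.
    """
    if samples_per_tissue < 1:
        raise ValueError("samples_per_tissue must be >= 1")
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")

    rng = np.random.default_rng(seed)
    profiles: list[SampleExpressionProfile] = []
    manifest: dict[str, str] = {}
    planted: dict[str, list[str]] = {}

    for tissue in sorted(tissue_medians):
        medians = tissue_medians[tissue]
        for i in range(samples_per_tissue):
            sample = f"{tissue}_s{i + 1:03d}"
            profile = SampleExpressionProfile(sample=sample, tissue=tissue)
            for metric in sorted(medians):
                m = medians[metric]
                value = m if dispersion == 0 else float(
                    m * np.exp(dispersion * rng.standard_normal())
                )
                set_metric(profile, metric, value)
            profiles.append(profile)
            manifest[sample] = tissue

    for tissue, metric, count, value in outliers:
        if tissue not in tissue_medians:
            raise KeyError(f"outlier tissue {tissue!r} not in tissue_medians")
        ids = []
        for j in range(count):
            sample = f"{tissue}_out{j + 1:03d}"
            profile = SampleExpressionProfile(sample=sample, tissue=tissue)
            for m_name in sorted(tissue_medians[tissue]):
                set_metric(profile, m_name, tissue_medians[tissue][m_name])
            set_metric(profile, metric, value)
            profiles.append(profile)
            manifest[sample] = tissue
            ids.append(sample)
        planted.setdefault(tissue, []).extend(ids)

    truth = CohortTruth(
        tissue_medians={t: dict(m) for t, m in tissue_medians.items()},
        dispersion=dispersion,
        planted_outliers=planted,
        target_rho=target_rho,
        seed=seed,
    )
    return profiles, manifest, truth


def write_fastq(pairs: Sequence[ReadPair], fq1: TextIO, fq2: TextIO) -> None:
    """Write pairs to two parallel FASTQ streams (Phred+33)."""
    for p in pairs:
        fq1.write(f"@{p.read_id}/1\n{p.mate1}\n+\n{p.qual1 or 'I' * len(p.mate1)}\n")
        fq2.write(f"@{p.read_id}/2\n{p.mate2}\n+\n{p.qual2 or 'I' * len(p.mate2)}\n")


def write_truth_tsv(truth: SimTruth, handle: TextIO) -> None:
    """Write the genotype and abundance truth tables."""
    handle.write("#genotypes\nlocus\tallele1\tallele2\n")
    for locus in sorted(truth.genotypes):
        a1, a2 = truth.genotypes[locus]
        handle.write(f"{locus}\t{a1}\t{a2 or '-'}\n")
    handle.write("#abundances\nallele\tpairs\n")
    for allele in sorted(truth.abundances):
        handle.write(f"{allele}\t{truth.abundances[allele]}\n")
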