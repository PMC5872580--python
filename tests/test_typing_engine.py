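"""Alignment and two-pass genotype calling.

The aligner is checked against a brute-force oracle that tries every
allele, every offset and both mate-orientation combinations with a
plain per-base mismatch count — no index, no seeding, no strata logic.
"""

import numpy as np
import pytest

from hlaquant import (
    ReadPair,
    align_read_pair,
    assign_reads_to_loci,
    build_kmer_index,
    call_four_digit,
    call_group,
    parse_allele_fasta,
    simulate_allele_db,
    simulate_sample,
    type_sample,
)
from hlaquant.typing_engine import reverse_complement

# ---------------------------------------------------------------- oracle


def _mm(read, ref, off):
    return sum(
        1
        for a, b in zip(read, ref[off : off + len(read)])
        if a != b or a == "N" or b == "N"
    )


def brute_force_best_stratum(pair, db, max_mismatch):
    """All-allele, all-offset, both-orientation exhaustive aligner.

    Returns {4-digit allele name: mismatches} for the minimum-mismatch
    stratum, deduplicating synonymous sequence representatives.
    """
    per_name = {}
    for allele in db.alleles:
        ref = allele.sequence
        best = None
        for s1, s2 in (
            (pair.mate1, reverse_complement(pair.mate2)),
            (reverse_complement(pair.mate1), pair.mate2),
        ):
            if len(s1) > len(ref) or len(s2) > len(ref):
                continue
            b1 = min(_mm(s1, ref, o) for o in range(len(ref) - len(s1) + 1))
            b2 = min(_mm(s2, ref, o) for o in range(len(ref) - len(s2) + 1))
            total = b1 + b2
            best = total if best is None else min(best, total)
        if best is not None and best <= max_mismatch:
            key = allele.name
            if key not in per_name or best < per_name[key]:
                per_name[key] = best
    if not per_name:
        return {}
    floor = min(per_name.values())
    return {name: mm for name, mm in per_name.items() if mm == floor}


def _mutate_read(rng, read, n_subs):
    pos = rng.choice(len(read), size=n_subs, replace=False)
    out = list(read)
    for p in pos:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


# ---------------------------------------------------------------- alignment


def test_exact_pair_hits_source_allele(sim_db):
    allele = sim_db.alleles[0]
    seq = allele.sequence
    pair = ReadPair("p0", seq[10:60], reverse_complement(seq[150:200]))
    hits = align_read_pair(pair, sim_db, max_mismatch=0)
    assert any(h.allele == allele.name and h.mismatches == 0 for h in hits)
    for h in hits:
        assert h.mismatches == 0


def test_pair_beyond_budget_is_unmapped(sim_db):
    rng = np.random.default_rng(3)
    allele = sim_db.alleles[0]
    m1 = _mutate_read(rng, allele.sequence[0:50], 5)
    m2 = _mutate_read(rng, reverse_complement(allele.sequence[100:150]), 5)
    hits = align_read_pair(ReadPair("p1", m1, m2), sim_db, max_mismatch=1)
    assert hits == []


def test_mate_shorter_than_k_reports_unmapped(sim_db):
    pair = ReadPair("p2", sim_db.alleles[0].sequence[:10], sim_db.alleles[0].sequence[:50])
    assert align_read_pair(pair, sim_db) == []


def test_rf_orientation_accepted(sim_db):
    allele = sim_db.alleles[2]
    seq = allele.sequence
    pair = ReadPair("p3", reverse_complement(seq[20:70]), seq[180:230])
    hits = align_read_pair(pair, sim_db, max_mismatch=0)
    assert any(h.allele == allele.name and h.orientation == "RF" for h in hits)


def test_equidistant_pair_returns_both_alleles():
    """A pair one substitution from each of two group siblings hits both."""
    base = "".join(
        np.random.default_rng(9).choice(list("ACGT"), size=200)
    )
    a1 = base
    a2 = base[:100] + ("A" if base[100] != "A" else "C") + base[101:]
    db = parse_allele_fasta(f">A*01:01\n{a1}\n>A*01:02\n{a2}\n")
    build_kmer_index(db, k=16)
    # mate1 spans the differing position 100 in neither-allele form
    mid = "G" if base[100] not in "G" else "T"
    m1 = base[80:130][:20] + mid + base[101:130]
    pair = ReadPair("p4", m1, reverse_complement(base[140:190]))
    hits = align_read_pair(pair, db, max_mismatch=2)
    got = {h.allele: h.mismatches for h in hits}
    assert got == brute_force_best_stratum(pair, db, 2)
    assert {n.name for n in got} == {"A*01:01", "A*01:02"}


@pytest.mark.parametrize("error_rate", [0.0, 0.01])
def test_aligner_matches_brute_force_on_random_instances(error_rate):
    """Seeded random toy instances: hit sets equal the exhaustive oracle."""
    rng = np.random.default_rng(int(error_rate * 1000) + 5)
    for rep in range(10):
        db = simulate_allele_db(
            ["A", "B"],
            alleles_per_locus=3,
            allele_length=150,
            within_locus_divergence=0.04,
            between_locus_divergence=0.2,
            seed=100 + rep,
            alleles_per_group=3,
        )
        build_kmer_index(db, k=16)
        pairs, _ = simulate_sample(
            db,
            {"A": ("A*01:01", "A*01:02"), "B": ("B*01:01", None)},
            {"A": 2.0, "B": 1.0},
            total_pairs=12,
            read_length=50,
            fragment_length=100,
            error_rate=error_rate,
            seed=200 + rep,
        )
        for pair in pairs:
            got = {h.allele: h.mismatches for h in align_read_pair(pair, db, 4)}
            assert got == brute_force_best_stratum(pair, db, 4), pair.read_id


# ---------------------------------------------------------------- calling


def _hits_for(db, pairs, max_mismatch=4):
    by_locus = {}
    hits_by_pair = {}
    for p in pairs:
        hits = align_read_pair(p, db, max_mismatch)
        hits_by_pair[p.read_id] = hits
    assignment = assign_reads_to_loci(hits_by_pair)
    for rid, locus in assignment.items():
        if locus not in ("ambiguous", "unmapped"):
            by_locus.setdefault(locus, []).extend(hits_by_pair[rid])
    return by_locus, assignment


def test_single_group_vote(sim_db):
    allele = sim_db.alleles[1]
    pairs = [
        ReadPair(f"r{i}", allele.sequence[i : i + 50],
                 reverse_complement(allele.sequence[i + 100 : i + 150]))
        for i in range(20)
    ]
    by_locus, _ = _hits_for(sim_db, pairs)
    groups = call_group(by_locus[allele.name.locus])
    assert groups[0][0] == allele.name.group
    assert sum(v for _, v in groups) <= 20


def test_stray_read_does_not_trigger_heterozygote():
    """One stray pair among 100 stays below the second-allele threshold."""
    db = simulate_allele_db(["A"], 3, allele_length=400,
                            within_locus_divergence=0.05,
                            between_locus_divergence=0.2, seed=5)
    build_kmer_index(db, 16)
    main, _ = simulate_sample(db, {"A": ("A*02:01", None)}, {"A": 1.0},
                              100, seed=6, fragment_length=150)
    stray, _ = simulate_sample(db, {"A": ("A*03:01", None)}, {"A": 1.0},
                               1, seed=7, fragment_length=150)
    stray = [ReadPair("stray0", p.mate1, p.mate2) for p in stray]
    by_locus, _ = _hits_for(db, main + stray)
    groups = call_group(by_locus["A"], theta_het=0.1)
    assert [g for g, _ in groups] == [("A", "02")]


def test_homozygous_and_heterozygous_recovery(sim_db):
    geno = {"A": ("A*02:01", "A*04:01"), "G": ("G*01:01", None)}
    pairs, _ = simulate_sample(sim_db, geno, {"A": 1.0, "G": 1.0},
                               800, seed=13, fragment_length=200)
    result = type_sample(pairs, sim_db)
    a = result.calls["A"]
    assert a.zygosity == "heterozygous"
    assert {a.allele1.name, a.allele2.name} == {"A*02:01", "A*04:01"}
    assert a.confidence >= 0.9
    assert a.support1 >= a.support2
    g = result.calls["G"]
    assert g.zygosity == "homozygous"
    assert g.allele1.name == "G*01:01"
    assert g.allele2 is None


def test_tie_break_is_lexicographic():
    """Synonymous-sequence alleles resolve deterministically by name."""
    seq = "".join(np.random.default_rng(21).choice(list("ACGT"), size=300))
    db = parse_allele_fasta(f">A*01:02\n{seq}\n>A*01:01\n{seq}\n")
    build_kmer_index(db, 16)
    pairs = [
        ReadPair(f"t{i}", seq[i : i + 50], reverse_complement(seq[i + 100 : i + 150]))
        for i in range(30)
    ]
    by_locus, _ = _hits_for(db, pairs)
    groups = call_group(by_locus["A"])
    call = call_four_digit(by_locus["A"], groups)
    assert call.allele1.name == "A*01:01"
    assert call.zygosity == "homozygous"


def test_assignment_conservation(sim_db):
    """assigned + ambiguous + unmapped = total pairs."""
    pairs, _ = simulate_sample(
        sim_db, {"A": ("A*01:01", None), "G": ("G*02:01", None)},
        {"A": 1.0, "G": 1.0}, 200, seed=17, error_rate=0.01,
    )
    junk = [ReadPair(f"junk{i}", "ACGT" * 13, "TTGCA" * 10) for i in range(5)]
    result = type_sample(pairs + junk, sim_db)
    assigned = sum(result.locus_counts.values())
    assert assigned + result.n_ambiguous + result.n_unmapped == result.total_pairs
    assert result.n_unmapped >= 5


def test_cross_locus_ambiguous_excluded():
    seq = "".join(np.random.default_rng(31).choice(list("ACGT"), size=300))
    db = parse_allele_fasta(f">A*01:01\n{seq}\n>B*01:01\n{seq}\n")
    build_kmer_index(db, 16)
    pair = ReadPair("x", seq[0:50], reverse_complement(seq[100:150]))
    hits = align_read_pair(pair, db, 2)
    assignment = assign_reads_to_loci({"x": hits})
    assert assignment == {"x": "ambiguous"}


def test_locus_counts_follow_assignments(sim_db):
    pairs_a, _ = simulate_sample(sim_db, {"A": ("A*01:01", None)}, {"A": 1.0},
                                 99, seed=23)
    pairs_g, _ = simulate_sample(sim_db, {"G": ("G*01:01", None)}, {"G": 1.0},
                                 1, seed=24)
    pairs_g = [ReadPair("solo", p.mate1, p.mate2) for p in pairs_g]
    result = type_sample(pairs_a + pairs_g, sim_db)
    assert result.locus_counts == {"A": 99, "G": 1}
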