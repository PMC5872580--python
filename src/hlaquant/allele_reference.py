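"""Parsing, validation and k-mer indexing of a polymorphic HLA allele reference.

The reference is a multi-FASTA of allele transcript sequences whose
headers carry standard HLA nomenclature tokens (``A*02:01:01:01``,
``HLA-G*01:01``, or the accessioned form ``HLA:HLA00005 A*01:01:01:01
3503 bp``).  Alleles are truncated to 4-digit (protein-level)
resolution for grouping and calling; records identical at 4-digit
resolution but differing in later fields are kept as synonymous
sequence representatives of one callable name.

Only the twelve loci quantified by the typing pipeline are accepted:
the classical class I heavy chains A, B and C, the non-classical
class I genes E, F and G, and the class II alpha/beta chains DPA1,
DPB1, DQA1, DQB1, DRA and DRB1.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, TextIO

#: Loci accepted by the pipeline.  Anything else (DRB3/4/5, pseudogenes,
#: class II paralogs) is skipped or rejected depending on ``strict``.
SUPPORTED_LOCI = frozenset(
    {"A", "B", "C", "E", "F", "G", "DPA1", "DPB1", "DQA1", "DQB1", "DRA", "DRB1"}
)

#: Deterministic locus order used for reports.
LOCUS_ORDER = ("A", "B", "C", "E", "F", "G", "DPA1", "DPB1", "DQA1", "DQB1", "DRA", "DRB1")

_VALID_BASES = frozenset("ACGTN")
_IUPAC_AMBIG = frozenset("RYSWKMBDHV")

_ALLELE_TOKEN_RE = re.compile(r"^(?:HLA-)?([A-Za-z0-9]+)\*([0-9]+)(?::([0-9]+(?::[0-9]+)*))?$")


class AlleleNameError(ValueError):
    """Raised when a header token cannot be parsed as an HLA allele name."""


class FastaParseError(ValueError):
    """Raised on malformed FASTA input; the message names the offending line."""


@dataclass(frozen=True, order=True)
class AlleleName:
    """An HLA allele name at 4-digit (protein) resolution.

    ``field1`` is the 2-digit serological group, ``field2`` the protein
    number; ``raw`` preserves the original header token so higher-field
    information is not lost.
    """

    locus: str
    field1: str
    field2: str
    raw: str = field(default="", compare=False)

    @property
    def name(self) -> str:
        """The 4-digit name, e.g. ``A*02:01``."""
        return f"{self.locus}*{self.field1}:{self.field2}"

    @property
    def group(self) -> tuple[str, str]:
        """The (locus, 2-digit group) pair used in first-pass calling."""
        return (self.locus, self.field1)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.name


@dataclass(frozen=True)
class Allele:
    """A reference allele: a 4-digit name plus its nucleotide sequence."""

    name: AlleleName
    sequence: str

    @property
    def length_bp(self) -> int:
        return len(self.sequence)


@dataclass
class AlleleDatabase:
    """All reference alleles, bucketed by locus and 2-digit group.

    ``kmer_index`` maps each k-mer to its occurrences as
    ``(allele_index, offset)`` postings over the forward strand;
    it is empty until :func:`build_kmer_index` is called.
    """

    alleles: list[Allele]
    k: int = 0
    kmer_index: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    skipped: int = 0

    def __post_init__(self) -> None:
        self.by_locus: dict[str, list[Allele]] = {}
        self.by_group: dict[tuple[str, str], list[Allele]] = {}
        for allele in self.alleles:
            self.by_locus.setdefault(allele.name.locus, []).append(allele)
            self.by_group.setdefault(allele.name.group, []).append(allele)

    def __len__(self) -> int:
        return len(self.alleles)

    def loci(self) -> list[str]:
        return [loc for loc in LOCUS_ORDER if loc in self.by_locus]

    def representatives(self, name: AlleleName) -> list[Allele]:
        """All sequence representatives sharing a 4-digit name."""
        return [a for a in self.by_group.get(name.group, []) if a.name == name]

    def mean_length(self, name: AlleleName) -> float:
        reps = self.representatives(name)
        if not reps:
            raise KeyError(f"allele {name.name} not in database")
        return sum(a.length_bp for a in reps) / len(reps)

    def to_fasta(self, handle: TextIO, width: int = 60) -> None:
        """Write the normalized reference back out as FASTA."""
        for allele in self.alleles:
            handle.write(f">{allele.name.raw or allele.name.name}\n")
            seq = allele.sequence
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")

    def summary_rows(self) -> list[dict]:
        """Per-allele TSV-ready summary (allele, locus, group, length_bp)."""
        return [
            {
                "allele": a.name.name,
                "locus": a.name.locus,
                "group": a.name.field1,
                "length_bp": a.length_bp,
            }
            for a in self.alleles
        ]


def parse_allele_name(token: str) -> AlleleName:
    """Parse an HLA nomenclature token into a 4-digit :class:`AlleleName`.

    Strips an optional ``HLA-`` prefix, splits on ``*`` and ``:``, and
    retains the first two numeric fields.  Raises
    :class:`AlleleNameError` for tokens that do not follow the
    ``locus*field1:field2[...]`` grammar.

    >>> parse_allele_name("HLA-G*01:01:01:01").name
    'G*01:01'
    """
    if not token:
        raise AlleleNameError("empty allele name token")
    m = _ALLELE_TOKEN_RE.match(token)
    if m is None:
        raise AlleleNameError(f"cannot parse allele name token {token!r}")
    locus, field1, rest = m.group(1), m.group(2), m.group(3)
    if rest is None:
        raise AlleleNameError(
            f"allele token {token!r} lacks a second (protein) field; "
            "4-digit resolution requires locus*field1:field2"
        )
    field2 = rest.split(":")[0]
    return AlleleName(locus=locus, field1=field1, field2=field2, raw=token)


def _find_name_token(header: str) -> AlleleName | None:
    """Locate the allele-nomenclature token in a FASTA header line.

    Handles plain (``A*02:01:01:01``), prefixed (``HLA-A*02:01``) and
    accessioned (``HLA:HLA00005 A*01:01:01:01 3503 bp``) dialects by
    scanning whitespace-separated words for the first parseable token.
    """
    for word in header.split():
        if "*" not in word:
            continue
        try:
            return parse_allele_name(word)
        except AlleleNameError:
            continue
    return None


def _normalize_sequence(seq: str, *, strict: bool, line_no: int) -> str:
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - _VALID_BASES
    if not bad:
        return seq
    ambig = bad & _IUPAC_AMBIG
    if bad - _IUPAC_AMBIG:
        raise FastaParseError(
            f"invalid sequence character(s) {sorted(bad - _IUPAC_AMBIG)} near line {line_no}"
        )
    if strict:
        raise FastaParseError(
            f"IUPAC ambiguity code(s) {sorted(ambig)} near line {line_no} (strict mode)"
        )
    return "".join("N" if c in ambig else c for c in seq)


def parse_allele_fasta(stream: TextIO | str, strict: bool = False) -> AlleleDatabase:
    """Parse an HLA allele reference FASTA into an :class:`AlleleDatabase`.

    Records whose locus is outside :data:`SUPPORTED_LOCI` are skipped
    (counted in ``db.skipped``) unless ``strict`` is true, in which case
    they raise.  Headers without a parseable allele token are likewise
    skipped or rejected.  Sequences are uppercased; IUPAC ambiguity
    codes other than N are converted to N (rejected in strict mode).
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)

    alleles: list[Allele] = []
    skipped = 0
    header: str | None = None
    header_line = 0
    chunks: list[str] = []
    saw_any = False

    def flush(line_no: int) -> None:
        nonlocal skipped
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FastaParseError(f"record at line {header_line} has an empty sequence")
        name = _find_name_token(header)
        if name is None:
            if strict:
                raise FastaParseError(
                    f"header at line {header_line} has no parseable allele token: {header!r}"
                )
            skipped += 1
            return
        if name.locus not in SUPPORTED_LOCI:
            if strict:
                raise FastaParseError(
                    f"unsupported locus {name.locus!r} at line {header_line}"
                )
            skipped += 1
            return
        alleles.append(Allele(name=name, sequence=_normalize_sequence(seq, strict=strict, line_no=line_no)))

    line_no = 0
    for line_no, line in enumerate(stream, start=1):
        line = line.rstrip("\n").rstrip("\r")
        if not line.strip():
            continue
        if line.startswith(">"):
            flush(line_no)
            header = line[1:].strip()
            header_line = line_no
            chunks = []
            saw_any = True
        else:
            if not saw_any:
                raise FastaParseError(f"line {line_no}: sequence data before any FASTA header")
            chunks.append(line.strip())
    flush(line_no)

    if not saw_any:
        raise FastaParseError("empty FASTA input: no records found")
    return AlleleDatabase(alleles=alleles, skipped=skipped)


def build_kmer_index(db: AlleleDatabase, k: int = 16) -> AlleleDatabase:
    """Populate ``db.kmer_index`` with every k-mer occurrence in the reference.

    Each distinct k-mer maps to the complete list of ``(allele_index,
    offset)`` postings over the forward strand; k-mers containing N are
    excluded.  Returns the same database with the index in place.
    """
    if k < 8:
        raise ValueError(f"k must be >= 8, got {k}")
    index: dict[str, list[tuple[int, int]]] = {}
    for idx, allele in enumerate(db.alleles):
        seq = allele.sequence
        if len(seq) < k:
            raise ValueError(
                f"allele {allele.name.name} (length {len(seq)}) is shorter than k={k}"
            )
        for off in range(len(seq) - k + 1):
            kmer = seq[off : off + k]
            if "N" in kmer:
                continue
            index.setdefault(kmer, []).append((idx, off))
    db.k = k
    db.kmer_index = index
    return db


def write_summary_tsv(db: AlleleDatabase, handle: TextIO) -> None:
    """Write the per-allele summary table (allele, locus, group, length_bp)."""
    handle.write("allele\tlocus\tgroup\tlength_bp\n")
    for row in db.summary_rows():
        handle.write(f"{row['allele']}\t{row['locus']}\t{row['group']}\t{row['length_bp']}\n")


def iter_database(db: AlleleDatabase) -> Iterable[Allele]:
    """Alleles in deterministic (locus order, then name) order."""
    for locus in db.loci():
        yield from sorted(db.by_locus[locus], key=lambda a: a.name)
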