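"""Readers and writers for the external formats the pipeline touches.

Every other module consumes and produces the types defined here: FASTQ
reads, categorised FASTA reference sets, and TSV count tables.  Parsing is
delegated to Biopython's SeqIO; this module adds the pipeline's contracts
on top (U->T normalisation, unique ids, closed category vocabulary, and
errors that name the offending record).

Policy decisions deliberately NOT made here: N-containing reads and
low-quality reads pass through parsing untouched — filtering is the
preprocess module's job.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

# Closed vocabulary for reference-set categories.
REFERENCE_CATEGORIES = (
    "genbank_ncrna",
    "rfam_ncrna",
    "known_mirna_mature",
    "known_mirna_hairpin",
    "repeat",
    "exon",
    "intron",
    "genome",
    "transcript",
)


class FormatError(ValueError):
    """Malformed input file (names the record/line where possible)."""


@dataclass
class RawRead:
    """A single sequencing read: id, sequence over {A,C,G,T,N}, optional
    Phred+33 quality string of the same length."""

    id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"read {self.id!r}: empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise FormatError(
                f"read {self.id!r}: quality length {len(self.quality)} != "
                f"sequence length {len(self.sequence)}"
            )

    @property
    def phred(self) -> list[int] | None:
        if self.quality is None:
            return None
        return [ord(c) - 33 for c in self.quality]


@dataclass
class ReferenceSet:
    """An ordered, id-unique collection of (id, sequence) records of one
    category (e.g. the Rfam ncRNA set, the known-mature catalogue, the
    genome)."""

    category: str
    records: list[tuple[str, str]] = field(default_factory=list)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.category not in REFERENCE_CATEGORIES:
            raise FormatError(
                f"unknown reference category {self.category!r}; "
                f"expected one of {REFERENCE_CATEGORIES}"
            )
        seen: set[str] = set()
        for rid, _ in self.records:
            if rid in seen:
                raise FormatError(f"duplicate record id {rid!r} in {self.category} set")
            seen.add(rid)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, rid: str) -> str:
        for r, s in self.records:
            if r == rid:
                return s
        raise KeyError(rid)


@dataclass
class CountTable:
    """Feature-by-library integer counts; every row carries a value
    (possibly 0) for every library."""

    library_ids: list[str]
    counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for fid, row in self.counts.items():
            for lib in self.library_ids:
                row.setdefault(lib, 0)
            for lib, c in row.items():
                if lib not in self.library_ids:
                    raise FormatError(f"row {fid!r}: unknown library {lib!r}")
                if c < 0 or c != int(c):
                    raise FormatError(f"row {fid!r}: negative/non-integer count {c}")

    def total(self, library_id: str) -> int:
        return sum(row[library_id] for row in self.counts.values())


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_fastq(path: str | Path) -> list[RawRead]:
    """Parse a 4-line-record FASTQ file into RawReads, order preserved.

    Malformed records raise FormatError naming the (1-based) line number
    at which the failing record starts.
    """
    reads: list[RawRead] = []
    path = Path(path)
    with open(path) as handle:
        parser = SeqIO.parse(handle, "fastq")
        while True:
            try:
                rec = next(parser)
            except StopIteration:
                break
            except ValueError as exc:
                raise FormatError(
                    f"{path}: malformed FASTQ record near line {4 * len(reads) + 1}: {exc}"
                ) from exc
            qual = "".join(
                chr(q + 33) for q in rec.letter_annotations["phred_quality"]
            )
            reads.append(RawRead(rec.id, _normalize(str(rec.seq)), qual))
    return reads


def write_fastq(reads: Iterable[RawRead], path: str | Path) -> None:
    with open(path, "w") as handle:
        for r in reads:
            qual = r.quality if r.quality is not None else "I" * len(r.sequence)
            handle.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")


def read_fasta(path: str | Path, category: str) -> ReferenceSet:
    """Parse FASTA into a ReferenceSet.

    U residues are normalised to T so a single DNA alphabet flows through
    the pipeline; the id is the first whitespace-delimited header token
    (miRBase-style descriptions are retained but never used for joins).
    """
    records: list[tuple[str, str]] = []
    descriptions: dict[str, str] = {}
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append((rec.id, _normalize(str(rec.seq))))
        desc = rec.description[len(rec.id):].strip()
        if desc:
            descriptions[rec.id] = desc
    return ReferenceSet(category=category, records=records, descriptions=descriptions)


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as handle:
        for rid, seq in records:
            handle.write(f">{rid}\n{seq}\n")


def write_count_table(table: CountTable, path: str | Path) -> None:
    """TSV with a header row of library ids; rows sorted lexicographically
    by feature id so output is deterministic."""
    with open(path, "w") as handle:
        handle.write("feature_id\t" + "\t".join(table.library_ids) + "\n")
        for fid in sorted(table.counts):
            row = table.counts[fid]
            handle.write(
                fid + "\t" + "\t".join(str(row[lib]) for lib in table.library_ids) + "\n"
            )


def read_count_table(path: str | Path) -> CountTable:
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if not header or header[0] != "feature_id":
            raise FormatError(f"{path}: expected 'feature_id' header column")
        libs = header[1:]
        counts: dict[str, dict[str, int]] = {}
        for lineno, line in enumerate(handle, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(libs) + 1:
                raise FormatError(f"{path}: line {lineno}: wrong field count")
            counts[fields[0]] = {
                lib: int(v) for lib, v in zip(libs, fields[1:])
            }
    return CountTable(library_ids=libs, counts=counts)
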