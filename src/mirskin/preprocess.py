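"""Raw reads -> clean, length-filtered, collapsed unique tags.

Mirrors the read-accounting narrative of small-RNA pipelines: raw reads
are adapter-trimmed and quality/length filtered into *clean reads*; the
clean-read multiset is collapsed into unique *tags* carrying per-library
counts; summaries report the 18-30 nt length distribution (reads, not
unique tags) and the fraction of clean reads matching the genome.

Trimming policy (the defaults are the conventional ones for this assay):

* the 3' adapter is located by its leftmost exact >=6 nt prefix seed and
  the read is cut there; reads with no locatable 3' adapter are discarded
  (the insert is presumed longer than the read, hence > 30 nt);
* reads containing the 5' adapter are discarded as ligation artefacts;
* reads with any base below ``min_qual`` (when qualities are present) or
  containing N are discarded;
* inserts outside [min_len, max_len] (default 18-30 nt) are discarded.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .formats import RawRead, ReferenceSet
from .seqindex import SubstringIndex, naive_match

MIN_LEN_DEFAULT = 18
MAX_LEN_DEFAULT = 30


@dataclass
class SequenceTag:
    """A unique clean-read sequence with its per-library read counts —
    the atom every downstream stage operates on."""

    sequence: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class LibrarySummary:
    library_id: str
    raw_reads: int
    clean_reads: int
    unique_tags: int
    genome_matched_reads: int = 0

    def __post_init__(self) -> None:
        if self.clean_reads > self.raw_reads:
            raise ValueError("clean_reads exceeds raw_reads")
        if self.genome_matched_reads > self.clean_reads:
            raise ValueError("genome_matched_reads exceeds clean_reads")


def _find_adapter3(seq: str, adapter3: str, seed_len: int = 6) -> int:
    """Leftmost position where the 3' adapter starts, requiring an exact
    seed of >= seed_len nt that extends exactly for as much of the adapter
    as fits in the read; -1 if not found."""
    seed = adapter3[:seed_len]
    start = 0
    while True:
        i = seq.find(seed, start)
        if i < 0:
            return -1
        k = min(len(seq) - i, len(adapter3))
        if k >= seed_len and seq[i : i + k] == adapter3[:k]:
            return i
        start = i + 1


def clean_reads(
    reads: Iterable[RawRead],
    adapter3: str,
    adapter5: str | None = None,
    min_len: int = MIN_LEN_DEFAULT,
    max_len: int = MAX_LEN_DEFAULT,
    min_qual: int = 20,
) -> list[str]:
    """Filter and trim raw reads; returns the clean insert sequences
    (order preserved).  Filtering is not failure: problem reads are
    silently dropped, and raw = clean + dropped by construction."""
    if not adapter3:
        raise ValueError("adapter3 must be non-empty")
    out: list[str] = []
    for read in reads:
        seq = read.sequence
        if adapter5 and adapter5 in seq:
            continue
        if "N" in seq:
            continue
        if read.quality is not None and any(q < min_qual for q in read.phred):
            continue
        cut = _find_adapter3(seq, adapter3)
        if cut < 0:
            continue  # insert presumed > read length, i.e. > max_len
        insert = seq[:cut]
        if min_len <= len(insert) <= max_len:
            out.append(insert)
    return out


def collapse_tags(clean_by_library: Mapping[str, Iterable[str]]) -> list[SequenceTag]:
    """Collapse per-library clean sequences into unique tags; per-library
    counts sum to that library's clean-read total.  Tags are returned in
    lexicographic sequence order (deterministic, input-order independent)."""
    libraries = list(clean_by_library)
    counters = {lib: Counter(seqs) for lib, seqs in clean_by_library.items()}
    all_seqs = sorted(set().union(*(c.keys() for c in counters.values())) if counters else ())
    return [
        SequenceTag(seq, {lib: counters[lib].get(seq, 0) for lib in libraries})
        for seq in all_seqs
    ]


def length_distribution(
    tags: Iterable[SequenceTag],
    library_id: str | None = None,
    min_len: int = MIN_LEN_DEFAULT,
    max_len: int = MAX_LEN_DEFAULT,
) -> dict[int, int]:
    """Read-count-weighted length histogram with every length in
    [min_len, max_len] present as a key."""
    hist = {k: 0 for k in range(min_len, max_len + 1)}
    for tag in tags:
        n = tag.counts.get(library_id, 0) if library_id else tag.total
        hist[len(tag.sequence)] = hist.get(len(tag.sequence), 0) + n
    return hist


def percent(part: float, whole: float) -> float:
    """Percentage rounded to two decimals, the convention used for all
    reported read fractions."""
    if whole <= 0:
        raise ValueError("whole must be positive")
    return round(part / whole * 100.0, 2)


def match_genome(
    tags: list[SequenceTag],
    genome: ReferenceSet,
    max_mismatch: int = 0,
    library_id: str | None = None,
) -> tuple[set[str], int, float]:
    """Which tags occur in the genome (either strand, <= max_mismatch
    substitutions), how many reads they carry, and that as a percentage
    of clean reads.

    Exact matching uses a k-mer index whose contract is agreement with
    the naive scan; mismatch-tolerant matching uses the naive scan
    directly (only sensible at desk scale).
    """
    if len(genome) == 0:
        raise ValueError("genome reference set is empty")
    lengths = {len(t.sequence) for t in tags}
    matched: set[str] = set()
    if max_mismatch == 0 and tags:
        index = SubstringIndex(genome.records, lengths)
        matched = {t.sequence for t in tags if t.sequence in index}
    else:
        matched = {
            t.sequence
            for t in tags
            if naive_match(t.sequence, genome.records, max_mismatch)
        }

    def reads_of(tag: SequenceTag) -> int:
        return tag.counts.get(library_id, 0) if library_id else tag.total

    matched_reads = sum(reads_of(t) for t in tags if t.sequence in matched)
    clean_total = sum(reads_of(t) for t in tags)
    fraction = percent(matched_reads, clean_total) if clean_total else 0.0
    return matched, matched_reads, fraction


def summarize_library(
    library_id: str,
    raw_reads: int,
    clean: list[str],
    tags: list[SequenceTag],
    genome_matched_reads: int = 0,
) -> LibrarySummary:
    unique = sum(1 for t in tags if t.counts.get(library_id, 0) > 0)
    return LibrarySummary(
        library_id=library_id,
        raw_reads=raw_reads,
        clean_reads=len(clean),
        unique_tags=unique,
        genome_matched_reads=genome_matched_reads,
    )
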