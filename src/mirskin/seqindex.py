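"""Exact-substring lookup over a set of reference records.

Queries are short tags (18-30 nt); references are anything from a 22-nt
mature miRNA to a multi-kilobase synthetic genome.  The index stores every
k-mer of each query length per record, on both strands, so membership and
locate queries are O(1) per tag.  The contract (checked by tests) is exact
agreement with a naive per-record substring scan.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class SubstringIndex:
    """k-mer hash index over (id, sequence) records for a fixed set of
    query lengths; matches sense or antisense occurrences."""

    def __init__(self, records: Iterable[tuple[str, str]], lengths: Iterable[int]):
        self.lengths = sorted(set(lengths))
        self.records = list(records)
        # kmer -> list of (record_id, start_on_plus_strand, strand)
        self._hits: dict[str, list[tuple[str, int, str]]] = defaultdict(list)
        for rid, seq in self.records:
            n = len(seq)
            for k in self.lengths:
                for i in range(n - k + 1):
                    kmer = seq[i : i + k]
                    self._hits[kmer].append((rid, i, "+"))
        self._kmers = set(self._hits)

    def __contains__(self, tag: str) -> bool:
        return tag in self._kmers or revcomp(tag) in self._kmers

    def locate(self, tag: str) -> list[tuple[str, int, int, str]]:
        """All occurrences of tag (either strand) as
        (record_id, start, end, strand) with plus-strand 0-based
        half-open coordinates."""
        out = []
        for rid, start, _ in self._hits.get(tag, ()):
            out.append((rid, start, start + len(tag), "+"))
        rc = revcomp(tag)
        if rc != tag:
            for rid, start, _ in self._hits.get(rc, ()):
                out.append((rid, start, start + len(tag), "-"))
        return sorted(out)


def naive_match(tag: str, records: Iterable[tuple[str, str]], max_mismatch: int = 0) -> bool:
    """Reference oracle: does tag (or its reverse complement) occur in any
    record with <= max_mismatch substitutions?  O(n*m); used directly for
    mismatch-tolerant matching and as the correctness contract for
    SubstringIndex."""
    queries = {tag, revcomp(tag)}
    k = len(tag)
    for _, seq in records:
        if max_mismatch == 0:
            if any(q in seq for q in queries):
                return True
            continue
        for i in range(len(seq) - k + 1):
            window = seq[i : i + k]
            for q in queries:
                mm = sum(a != b for a, b in zip(window, q))
                if mm <= max_mismatch:
                    return True
    return False
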