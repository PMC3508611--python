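"""Hierarchical annotation of tags into small-RNA classes.

Each tag receives exactly one class, resolved in strict priority order

    GenBank ncRNA > Rfam ncRNA > known miRNA > repeat > exon > intron

so that e.g. an rRNA degradation fragment that happens to co-align with a
miRNA hairpin is counted as rRNA, never as miRNA.  A "match" is the tag
occurring as an exact substring of a reference record on either strand
(degradation-fragment logic); a mismatch allowance is configurable but
defaults to 0.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .formats import ReferenceSet
from .preprocess import SequenceTag
from .seqindex import SubstringIndex, naive_match

#: (annotation category, reference-set category) in priority order.
PRIORITY: tuple[tuple[str, str], ...] = (
    ("rRNA_etc_genbank", "genbank_ncrna"),
    ("rRNA_etc_rfam", "rfam_ncrna"),
    ("known_miRNA", "known_mirna_hairpin"),
    ("repeat", "repeat"),
    ("exon", "exon"),
    ("intron", "intron"),
)

UNANNOTATED = "unannotated"
CATEGORIES = tuple(cat for cat, _ in PRIORITY) + (UNANNOTATED,)


@dataclass
class AnnotationRecord:
    tag: SequenceTag
    category: str
    matched_id: str = ""

    def __post_init__(self) -> None:
        if (self.category == UNANNOTATED) != (self.matched_id == ""):
            raise ValueError("matched_id must be empty iff unannotated")


class Annotator:
    """Builds one substring index per reference set and classifies tags
    by the priority rule.  Reference sets are keyed by annotation
    category; the known-miRNA set may be mature or hairpin sequences
    (hairpins catch isomiRs and star reads as substrings)."""

    def __init__(
        self,
        reference_sets: Mapping[str, ReferenceSet],
        tag_lengths: Iterable[int] = range(18, 31),
        max_mismatch: int = 0,
    ):
        known = {cat for cat, _ in PRIORITY}
        for cat in reference_sets:
            if cat not in known:
                raise ValueError(f"unknown annotation category {cat!r}")
        self.reference_sets = dict(reference_sets)
        self.max_mismatch = max_mismatch
        self._indexes: dict[str, SubstringIndex] = {}
        if max_mismatch == 0:
            lengths = list(tag_lengths)
            for cat, refset in self.reference_sets.items():
                self._indexes[cat] = SubstringIndex(refset.records, lengths)

    def _match(self, seq: str, category: str) -> str | None:
        """Lexicographically smallest matching reference id, or None."""
        refset = self.reference_sets[category]
        if self.max_mismatch == 0:
            index = self._indexes[category]
            if seq not in index:
                return None
            return min(rid for rid, *_ in index.locate(seq))
        hits = [
            rid
            for rid, rseq in refset.records
            if naive_match(seq, [(rid, rseq)], self.max_mismatch)
        ]
        return min(hits) if hits else None

    def classify_tag(self, tag: SequenceTag) -> AnnotationRecord:
        for category, _ in PRIORITY:
            if category not in self.reference_sets:
                continue
            rid = self._match(tag.sequence, category)
            if rid is not None:
                return AnnotationRecord(tag, category, rid)
        return AnnotationRecord(tag, UNANNOTATED, "")

    def classify(self, tags: Iterable[SequenceTag]) -> list[AnnotationRecord]:
        return [self.classify_tag(t) for t in tags]


def class_frequencies(
    records: Sequence[AnnotationRecord],
    library_id: str | None = None,
) -> pd.DataFrame:
    """Class-frequency table: one row per category with the percentage of
    unique tags and of reads it holds; each column sums to 100 within
    rounding."""
    tag_n = defaultdict(int)
    read_n = defaultdict(int)
    for rec in records:
        reads = (
            rec.tag.counts.get(library_id, 0) if library_id else rec.tag.total
        )
        tag_n[rec.category] += 1
        read_n[rec.category] += reads
    total_tags = sum(tag_n.values())
    total_reads = sum(read_n.values())
    rows = []
    for cat in CATEGORIES:
        rows.append(
            {
                "category": cat,
                "unique_tags": tag_n.get(cat, 0),
                "reads": read_n.get(cat, 0),
                "unique_pct": 100.0 * tag_n.get(cat, 0) / total_tags if total_tags else 0.0,
                "read_pct": 100.0 * read_n.get(cat, 0) / total_reads if total_reads else 0.0,
            }
        )
    return pd.DataFrame(rows)
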