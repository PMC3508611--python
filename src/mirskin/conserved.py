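"""Conserved-miRNA identification, family grouping, and isomiR analysis.

A tag is *evolutionarily conserved* when an ungapped alignment against a
known-mature catalogue shows at most ``max_mm`` mismatches or more than
``min_identity`` identity.  Alignment slides the shorter sequence fully
along the longer one (terminal overhangs allowed, no gaps); identity is
matched positions over the aligned (overlap) length.  Each tag keeps only
its best hit: fewest mismatches, then highest identity, then the
lexicographically smallest catalogue id — a deterministic, order-free
rule.

The isomiR machinery measures end heterogeneity of reads mapping inside a
hairpin precursor relative to the annotated mature (5' ends of miRNAs are
anchored by Drosha/Dicer processing and Argonaute loading, 3' ends are
ragged), and detects arm switching — the dominant expressed product coming
from the precursor arm opposite the annotated one.
"""

from __future__ import annotations

import math
import re
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .fold import FoldResult, hairpin_loop_span
from .formats import ReferenceSet
from .preprocess import SequenceTag


@dataclass
class ConservedHit:
    tag: SequenceTag
    mirna_id: str
    mismatches: int
    identity: float


@dataclass
class FamilySummary:
    family_name: str
    member_ids: list[str]
    total_reads: dict[str, int]  # library_id -> reads


@dataclass
class IsoformProfile:
    precursor_id: str
    arm: str  # "5p" | "3p" | "unknown"
    isoforms: list[tuple[str, int, int, int]]  # (sequence, start_off, end_off, reads)
    predominant: tuple[str, int, int, int]
    distinct_5p_ends: int
    distinct_3p_ends: int


@dataclass
class ArmUsage:
    precursor_id: str
    annotated_arm: str
    reads_5p: int
    reads_3p: int
    dominant_arm: str
    switched: bool


def align_ungapped(tag_seq: str, mature: str) -> tuple[int, float]:
    """Best (mismatches, identity) over all slide positions of the shorter
    sequence fully within the longer; identity = matches / overlap length."""
    short, long_ = sorted((tag_seq, mature), key=len)
    n, m = len(short), len(long_)
    best_mm, best_id = n + 1, -1.0
    for off in range(m - n + 1):
        window = long_[off : off + n]
        mm = sum(a != b for a, b in zip(short, window))
        ident = (n - mm) / n
        if (mm, -ident) < (best_mm, -best_id):
            best_mm, best_id = mm, ident
    return best_mm, best_id


def _mismatch_budget(max_mm: int, min_identity: float, max_overlap: int) -> int:
    """Largest mismatch count any hit can carry under either rule: the
    identity rule (strict >) caps mismatches at ceil(L*(1-id)) - 1 for
    every overlap length L up to max_overlap."""
    by_identity = max(
        (math.ceil(L * (1 - min_identity) - 1e-9) - 1 for L in range(1, max_overlap + 1)),
        default=0,
    )
    return max(max_mm, by_identity)


def _align_at(tag_seq: str, mature: str, offset: int) -> tuple[int, float] | None:
    """(mismatches, identity) for the shorter placed at `offset` of the
    longer; None when the placement is not fully contained."""
    short, long_ = sorted((tag_seq, mature), key=len)
    if offset < 0 or offset + len(short) > len(long_):
        return None
    window = long_[offset : offset + len(short)]
    mm = sum(a != b for a, b in zip(short, window))
    return mm, (len(short) - mm) / len(short)


def match_conserved(
    tags: Iterable[SequenceTag],
    mature_catalog: ReferenceSet,
    max_mm: int = 2,
    min_identity: float = 0.90,
    algorithm: str = "auto",
) -> list[ConservedHit]:
    """Best conserved hit per tag; a hit exists when mismatches <= max_mm
    OR identity > min_identity (the inclusive reading of the homology
    rule).

    algorithm "naive" scores every tag against every catalogue entry at
    every offset; "seeded" only verifies (entry, offset) pairs sharing
    an exact seed word with the tag — by pigeonhole over the mismatch
    budget the two are equivalent, and tests assert it.  "auto" seeds
    when the seed word stays >= 5 nt.
    """
    tags = list(tags)
    catalog = sorted(mature_catalog.records)  # id order fixes ties
    if not tags or not catalog:
        return []
    min_overlap = min(
        min(len(t.sequence) for t in tags), min(len(s) for _, s in catalog)
    )
    max_overlap = min(
        max(len(t.sequence) for t in tags), max(len(s) for _, s in catalog)
    )
    budget = _mismatch_budget(max_mm, min_identity, max_overlap)
    seed_len = min_overlap // (budget + 1)
    if algorithm == "auto":
        algorithm = "seeded" if seed_len >= 5 else "naive"

    hits: list[ConservedHit] = []
    if algorithm == "naive":
        for tag in tags:
            best: tuple[int, float, str] | None = None
            for rid, seq in catalog:
                mm, ident = align_ungapped(tag.sequence, seq)
                if mm <= max_mm or ident > min_identity:
                    if best is None or (mm, -ident, rid) < (best[0], -best[1], best[2]):
                        best = (mm, ident, rid)
            if best is not None:
                hits.append(ConservedHit(tag, best[2], best[0], best[1]))
        return hits
    if algorithm != "seeded":
        raise ValueError(f"unknown algorithm {algorithm!r}")

    # seed word -> (catalog index, position in mature)
    seeds: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for ci, (_, seq) in enumerate(catalog):
        for pos in range(len(seq) - seed_len + 1):
            seeds[seq[pos : pos + seed_len]].append((ci, pos))
    for tag in tags:
        ts = tag.sequence
        candidates: set[tuple[int, int]] = set()
        for tpos in range(len(ts) - seed_len + 1):
            for ci, cpos in seeds.get(ts[tpos : tpos + seed_len], ()):
                _, seq = catalog[ci]
                # offset of the shorter sequence within the longer
                off = cpos - tpos if len(ts) <= len(seq) else tpos - cpos
                candidates.add((ci, off))
        best: tuple[int, float, str] | None = None
        for ci, off in candidates:
            rid, seq = catalog[ci]
            scored = _align_at(ts, seq, off)
            if scored is None:
                continue
            mm, ident = scored
            if mm <= max_mm or ident > min_identity:
                if best is None or (mm, -ident, rid) < (best[0], -best[1], best[2]):
                    best = (mm, ident, rid)
        if best is not None:
            hits.append(ConservedHit(tag, best[2], best[0], best[1]))
    return hits


_SPECIES_PREFIX = re.compile(r"^[a-z]{2,4}-(?=(let|mir|miR))", re.IGNORECASE)
_ARM_SUFFIX = re.compile(r"-[35]p$")
# duplicate-locus marker (miR-124-1): short trailing number after the
# family number (optionally letter-suffixed); never the family number itself
_DUP_SUFFIX = re.compile(r"(?:(?<=\d)|(?<=\d[a-z]))-\d{1,2}$")
_LETTER_SUFFIX = re.compile(r"(?<=\d)[a-z]+$")


def family_name(mirna_id: str) -> str:
    """Normalise a catalogue id to its family stem: strip species prefix,
    star mark, -5p/-3p arm, duplicate-locus -N, and trailing letter
    variants.  e.g. lpa-miR-124a -> miR-124; let-7i -> let-7."""
    name = mirna_id.strip()
    name = _SPECIES_PREFIX.sub("", name)
    name = name.rstrip("*")
    name = _ARM_SUFFIX.sub("", name)
    name = _DUP_SUFFIX.sub("", name)
    name = _LETTER_SUFFIX.sub("", name)
    return name


def group_families(hits: Sequence[ConservedHit]) -> list[FamilySummary]:
    """Group best hits into miRNA families with per-library read totals;
    family totals equal the sum over members by construction."""
    members: dict[str, set[str]] = defaultdict(set)
    totals: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for hit in hits:
        fam = family_name(hit.mirna_id)
        members[fam].add(hit.mirna_id)
        for lib, n in hit.tag.counts.items():
            totals[fam][lib] += n
    return [
        FamilySummary(fam, sorted(members[fam]), dict(totals[fam]))
        for fam in sorted(members)
    ]


def mirna_count_table(hits: Sequence[ConservedHit], library_ids: Sequence[str]):
    """Per-miRNA read counts (sum of counts of all tags whose best hit is
    that miRNA) — the unit differential expression operates on."""
    from .formats import CountTable

    counts: dict[str, dict[str, int]] = defaultdict(lambda: {lib: 0 for lib in library_ids})
    for hit in hits:
        for lib in library_ids:
            counts[hit.mirna_id][lib] += hit.tag.counts.get(lib, 0)
    return CountTable(library_ids=list(library_ids), counts=dict(counts))


def end_heterogeneity(
    precursor_id: str,
    precursor_seq: str,
    tags: Iterable[SequenceTag],
    annotated_mature: str,
    arm: str = "unknown",
) -> IsoformProfile:
    """IsomiR profile of tags mapping (exactly) inside a precursor,
    keyed by (5' offset, 3' offset) relative to the annotated mature.

    Negative start offsets extend the 5' end, positive 3' offsets extend
    the 3' end.  The predominant isoform is the one with the highest read
    count (ties to the isoform closest to the annotated ends, then
    lexicographic sequence).
    """
    m_start = precursor_seq.find(annotated_mature)
    if m_start < 0:
        raise ValueError(
            f"annotated mature not found in precursor {precursor_id!r}"
        )
    m_end = m_start + len(annotated_mature)
    iso: dict[tuple[str, int, int], int] = defaultdict(int)
    for tag in tags:
        pos = precursor_seq.find(tag.sequence)
        if pos < 0:
            continue
        start_off = pos - m_start
        end_off = (pos + len(tag.sequence)) - m_end
        iso[(tag.sequence, start_off, end_off)] += tag.total
    if not iso:
        raise ValueError(f"no tags map inside precursor {precursor_id!r}")
    isoforms = sorted(
        ((seq, s, e, n) for (seq, s, e), n in iso.items()),
        key=lambda r: (r[1], r[2], r[0]),
    )
    predominant = min(
        isoforms, key=lambda r: (-r[3], abs(r[1]) + abs(r[2]), r[0])
    )
    return IsoformProfile(
        precursor_id=precursor_id,
        arm=arm,
        isoforms=isoforms,
        predominant=predominant,
        distinct_5p_ends=len({s for _, s, _, _ in isoforms}),
        distinct_3p_ends=len({e for _, _, e, _ in isoforms}),
    )


def detect_arm_switch(
    precursor_id: str,
    precursor_seq: str,
    fold: FoldResult,
    tags: Iterable[SequenceTag],
    annotated_arm: str,
) -> ArmUsage | None:
    """Compare read totals on the two precursor arms (defined by the
    hairpin loop of the computed structure) with the annotated arm.

    Reads are assigned by the midpoint of their mapping position; reads
    falling inside the loop are ignored.  Equal counts tie-break to the
    annotated arm (no switch).  Returns None when only loop reads exist
    (no call possible).
    """
    if annotated_arm not in ("5p", "3p"):
        raise ValueError("annotated_arm must be '5p' or '3p'")
    loop_start, loop_end = hairpin_loop_span(fold.structure)
    reads = {"5p": 0, "3p": 0}
    for tag in tags:
        pos = precursor_seq.find(tag.sequence)
        if pos < 0:
            continue
        mid = pos + len(tag.sequence) / 2.0
        if mid < loop_start:
            reads["5p"] += tag.total
        elif mid >= loop_end:
            reads["3p"] += tag.total
        # else: loop read, no arm call
    if reads["5p"] == 0 and reads["3p"] == 0:
        return None
    other = "3p" if annotated_arm == "5p" else "5p"
    dominant = other if reads[other] > reads[annotated_arm] else annotated_arm
    return ArmUsage(
        precursor_id=precursor_id,
        annotated_arm=annotated_arm,
        reads_5p=reads["5p"],
        reads_3p=reads["3p"],
        dominant_arm=dominant,
        switched=dominant != annotated_arm,
    )
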