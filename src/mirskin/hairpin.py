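"""Novel-miRNA prediction from genome-mapped tags.

A tag becomes a candidate novel miRNA when its genomic neighbourhood
folds into a stem-loop and the six classical animal-miRNA candidacy
criteria hold:

1. the putative mature is 20-24 nt and resides on one stem arm;
2. its read frequency is at least 5;
3. the stem-loop folding free energy is at most -18 kcal/mol;
4. the largest bulge (unpaired run) inside the mature is at most 4 nt;
5. mature and star differ in length by at most 5 nt and are separated by
   at most 35 nt;
6. the mature/star duplex asymmetry (difference in unpaired residues
   between the two sides) is at most 5 nt.

Candidates are additionally ranked by the minimal folding free energy
index, MFEI = AMFE / GC%, with AMFE = |MFE| / length x 100; genuine
miRNA precursors concentrate above ~0.97 while tRNA/rRNA/mRNA fragments
fall below.  MFEI is reported positive.

The mapped-mature flanks are searched with ~100 nt windows on both sides
(the mature may sit on either arm); the candidate precursor is then
trimmed to the stem-loop enclosing the mature — the pairing-partner span
plus a small pad — and refolded, so MFE/AMFE/MFEI describe the hairpin
itself rather than an arbitrary genomic window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .fold import FoldResult, fold_rna, pair_table
from .formats import ReferenceSet
from .preprocess import SequenceTag
from .seqindex import SubstringIndex, revcomp

CRITERIA = (
    "mature_on_stem",
    "read_count",
    "mfe",
    "bulge",
    "size_and_spacing",
    "asymmetry",
)

MFE_MAX_DEFAULT = -18.0
MFEI_MIN_DEFAULT = 0.97
MIN_COUNT_DEFAULT = 5


@dataclass
class HairpinCandidate:
    locus: tuple[str, int, int, str]  # (record id, start, end, strand), 0-based half-open
    precursor: str
    fold: FoldResult
    mature: str
    mature_start: int  # within precursor
    arm: str  # "5p" | "3p" | "unknown"
    star: str | None
    star_start: int | None
    mature_read_count: int
    criteria: dict[str, bool]
    mfe: float
    amfe: float
    mfei: float

    @property
    def passed_all(self) -> bool:
        return all(self.criteria.values())


@dataclass
class NovelMiRNASet:
    """Per-library candidate sets merged on exact mature-sequence
    identity."""

    per_library: dict[str, list[str]]  # library -> mature sequences
    shared: set[str]
    union: set[str]

    @property
    def union_count(self) -> int:
        return len(self.union)


def compute_mfei(mfe: float, sequence: str) -> tuple[float, float]:
    """(AMFE, MFEI) of a precursor: AMFE = |MFE|/length x 100,
    MFEI = AMFE / GC% with GC on the 0-100 scale.  Reported positive."""
    if not sequence:
        raise ValueError("empty sequence")
    gc = sum(1 for c in sequence if c in "GC") / len(sequence) * 100.0
    if gc == 0:
        raise ValueError("GC content is zero; MFEI undefined")
    amfe = abs(mfe) / len(sequence) * 100.0
    return amfe, amfe / gc


def _mfei_of(candidate) -> float:
    if isinstance(candidate, (int, float)):
        return float(candidate)
    if isinstance(candidate, Mapping):
        return float(candidate["mfei"])
    return float(candidate.mfei)


def filter_mfei(candidates: Sequence, cutoff: float = MFEI_MIN_DEFAULT) -> list:
    """Keep candidates with MFEI >= cutoff, order preserved.  Accepts
    HairpinCandidates, mappings with an 'mfei' key, or bare numbers."""
    return [c for c in candidates if _mfei_of(c) >= cutoff]


def evaluate_criteria(
    fold: FoldResult,
    mature_start: int,
    mature_end: int,
    read_count: int,
    min_count: int = MIN_COUNT_DEFAULT,
    mfe_max: float = MFE_MAX_DEFAULT,
    max_bulge: int = 4,
    max_size_diff: int = 5,
    max_spacing: int = 35,
    max_asymmetry: int = 5,
    min_paired_fraction: float = 0.6,
) -> tuple[dict[str, bool], str, tuple[str, int] | None]:
    """Evaluate the six candidacy criteria for a mature at
    [mature_start, mature_end) of a folded precursor.

    Returns (criteria flags, arm, star) where star is the
    (sequence, start) inferred from the pairing partners of the mature
    with the canonical 2-nt 3' overhang; star is None when no stem is
    detected (stem-dependent criteria then fail, but the candidate is
    kept with its flags).
    """
    seq = fold.sequence
    n = len(seq)
    if not (0 <= mature_start < mature_end <= n):
        raise ValueError("mature span outside precursor")
    table = pair_table(fold.structure)
    m_len = mature_end - mature_start
    paired = [i for i in range(mature_start, mature_end) if table[i] >= 0]
    partners = [table[i] for i in paired]

    flags = dict.fromkeys(CRITERIA, False)
    flags["read_count"] = read_count >= min_count
    flags["mfe"] = fold.mfe <= mfe_max

    arm = "unknown"
    star: tuple[str, int] | None = None
    if partners:
        if all(p >= mature_end for p in partners):
            arm = "5p"
        elif all(p < mature_start for p in partners):
            arm = "3p"
    if arm != "unknown":
        on_stem = len(paired) / m_len >= min_paired_fraction
        flags["mature_on_stem"] = on_stem and 20 <= m_len <= 24

        # longest unpaired run inside the mature
        run = best_run = 0
        for i in range(mature_start, mature_end):
            run = run + 1 if table[i] < 0 else 0
            best_run = max(best_run, run)
        flags["bulge"] = best_run <= max_bulge

        lo, hi = min(partners), max(partners)
        star_start, star_end = lo, min(hi + 1 + 2, n)  # 2-nt 3' overhang
        star = (seq[star_start:star_end], star_start)
        star_len = star_end - star_start
        if arm == "5p":
            spacing = max(0, star_start - mature_end)
        else:
            spacing = max(0, mature_start - star_end)
        flags["size_and_spacing"] = (
            abs(m_len - star_len) <= max_size_diff and spacing <= max_spacing
        )
        unpaired_mature = m_len - len(paired)
        unpaired_star = (hi - lo + 1) - len(paired)
        flags["asymmetry"] = abs(unpaired_mature - unpaired_star) <= max_asymmetry
    return flags, arm, star


def extract_precursor(
    genome_seq: str,
    start: int,
    end: int,
    window: int = 100,
    near_pad: int = 20,
    trim_pad: int = 6,
    engine: str = "auto",
) -> tuple[str, int, FoldResult, int] | None:
    """Fold both flank windows of a mapped mature at [start, end) of a
    genomic record, trim to the stem-loop enclosing the mature, and
    return (precursor, precursor_start, fold, mature_offset) for the
    lower-MFE arrangement; None when the mature pairs in neither window.
    """
    n = len(genome_seq)
    windows = [
        (max(0, start - near_pad), min(n, end + window)),  # mature on 5p arm
        (max(0, start - window), min(n, end + near_pad)),  # mature on 3p arm
    ]
    best: tuple[float, str, int, FoldResult, int] | None = None
    for w_start, w_end in windows:
        wseq = genome_seq[w_start:w_end]
        if len(wseq) < 40:
            continue
        wfold = fold_rna(wseq, engine=engine)
        table = pair_table(wfold.structure)
        m0, m1 = start - w_start, end - w_start
        partners = [table[i] for i in range(m0, m1) if table[i] >= 0]
        if not partners:
            continue
        lo = max(0, min(m0, min(partners)) - trim_pad)
        hi = min(len(wseq), max(m1, max(partners) + 1) + trim_pad)
        pseq = wseq[lo:hi]
        if len(pseq) < 40:
            lo = max(0, hi - 40)
            pseq = wseq[lo:hi]
        pfold = fold_rna(pseq, engine=engine)
        key = (pfold.mfe, pseq)
        if best is None or key < (best[0], best[1]):
            best = (pfold.mfe, pseq, w_start + lo, pfold, m0 - lo)
    if best is None:
        return None
    _, pseq, p_start, pfold, m_off = best
    return pseq, p_start, pfold, m_off


def _cluster_loci(
    located: list[tuple[str, int, int, str, SequenceTag]], span: int = 30
) -> list[list[tuple[str, int, int, str, SequenceTag]]]:
    """Group mapped tags into loci: same record, starts within `span`."""
    clusters: list[list[tuple[str, int, int, str, SequenceTag]]] = []
    for item in sorted(located, key=lambda x: (x[0], x[1], x[2], x[4].sequence)):
        if (
            clusters
            and item[0] == clusters[-1][0][0]
            and item[1] - clusters[-1][0][1] <= span
        ):
            clusters[-1].append(item)
        else:
            clusters.append([item])
    return clusters


def predict_novel(
    tags: Iterable[SequenceTag],
    genome: ReferenceSet,
    library_id: str | None = None,
    min_count: int = MIN_COUNT_DEFAULT,
    mfe_max: float = MFE_MAX_DEFAULT,
    exclude: set[str] | None = None,
    engine: str = "auto",
    window: int = 100,
) -> list[HairpinCandidate]:
    """Predict novel-miRNA candidates for one library.

    Tags with at least ``min_count`` reads (and not in ``exclude``, e.g.
    known-miRNA-matched sequences) are mapped to the genome; mapped tags
    are clustered into loci; the most abundant tag of each locus is the
    putative mature, its flanks folded and the six criteria evaluated.
    All evaluated candidates are returned with their per-criterion flags
    (use ``passed_all``/``filter_mfei`` downstream).
    """
    exclude = exclude or set()

    def count_of(tag: SequenceTag) -> int:
        return tag.counts.get(library_id, 0) if library_id else tag.total

    eligible = [
        t for t in tags if count_of(t) >= min_count and t.sequence not in exclude
    ]
    if not eligible:
        return []
    index = SubstringIndex(genome.records, {len(t.sequence) for t in eligible})
    located = []
    for tag in eligible:
        loci = index.locate(tag.sequence)
        if loci:
            # deterministic first locus, plus strand preferred
            plus = [l for l in loci if l[3] == "+"]
            rid, s, e, strand = (plus or loci)[0]
            located.append((rid, s, e, strand, tag))
    candidates: list[HairpinCandidate] = []
    for cluster in _cluster_loci(located):
        rid, s, e, strand, tag = max(
            cluster, key=lambda x: (count_of(x[4]), x[4].sequence)
        )
        genome_seq = genome.get(rid)
        if strand == "-":
            genome_seq = revcomp(genome_seq)
            s, e = len(genome_seq) - e, len(genome_seq) - s
        extracted = extract_precursor(genome_seq, s, e, window=window, engine=engine)
        if extracted is None:
            continue
        pseq, p_start, pfold, m_off = extracted
        flags, arm, star = evaluate_criteria(
            pfold, m_off, m_off + len(tag.sequence), count_of(tag),
            min_count=min_count, mfe_max=mfe_max,
        )
        try:
            amfe, mfei = compute_mfei(pfold.mfe, pseq)
        except ValueError:  # GC-free locus: MFEI undefined, score as 0
            amfe, mfei = abs(pfold.mfe) / len(pseq) * 100.0, 0.0
        candidates.append(
            HairpinCandidate(
                locus=(rid, p_start, p_start + len(pseq), strand),
                precursor=pseq,
                fold=pfold,
                mature=tag.sequence,
                mature_start=m_off,
                arm=arm,
                star=star[0] if star else None,
                star_start=star[1] if star else None,
                mature_read_count=count_of(tag),
                criteria=flags,
                mfe=pfold.mfe,
                amfe=amfe,
                mfei=mfei,
            )
        )
    return candidates


def passing(candidates: Iterable[HairpinCandidate]) -> list[HairpinCandidate]:
    return [c for c in candidates if c.passed_all]


def _matures(candidates: Iterable) -> list[str]:
    return [c if isinstance(c, str) else c.mature for c in candidates]


def merge_libraries(set_a: Iterable, set_b: Iterable, labels: tuple[str, str] = ("A", "B")) -> NovelMiRNASet:
    """Merge two libraries' candidate sets on exact mature-sequence
    identity; union size obeys |A| + |B| - |A n B|."""
    a, b = set(_matures(set_a)), set(_matures(set_b))
    return NovelMiRNASet(
        per_library={labels[0]: sorted(a), labels[1]: sorted(b)},
        shared=a & b,
        union=a | b,
    )
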