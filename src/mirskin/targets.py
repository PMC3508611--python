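"""miRNA target-site prediction under plant-style ungapped duplex rules.

Every miRNA-length window of a transcript is paired antiparallel against
the miRNA (position 1 = miRNA 5' end opposite the window's 3'-most base)
and scored per position: Watson-Crick pair = 0, G:U wobble = 0.5
mismatches, anything else = 1.  A window is a predicted site when all
five rules hold:

* total weighted mismatches <= 4;
* no mismatch at positions 10-11 (the slicer-cleavage site);
* no run of three or more adjacent mismatched positions within 2-12;
* weighted mismatches within positions 1-12 <= 2.5;
* duplex energy at least 75% of the miRNA paired to its perfect
  complement (energies from a per-pair model: GC = -3, AU = -2,
  GU = -1, mismatch = 0; the criterion is a ratio, so any consistent
  model honours it).

Scanning is sense-strand only: transcripts are mRNA/3'UTR sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "T"), ("T", "G")}  # rG:rU in DNA alphabet
_PAIR_ENERGY = {**{p: -3.0 for p in (("G", "C"), ("C", "G"))},
                **{p: -2.0 for p in (("A", "T"), ("T", "A"))},
                **{p: -1.0 for p in _WOBBLE}}


@dataclass
class DuplexRules:
    max_total_mismatch: float = 4.0
    max_mismatch_1_12: float = 2.5
    max_adjacent_run_2_12: int = 2
    min_energy_ratio: float = 0.75


@dataclass
class DuplexHit:
    mirna_id: str
    transcript_id: str
    site_start: int  # 0-based on transcript
    site_seq: str
    mismatch_total: float
    mismatch_1_12: float
    max_adjacent_mm_2_12: int
    mm_at_10_11: int
    duplex_energy: float
    perfect_energy: float
    energy_ratio: float

    def passes(self, rules: DuplexRules = DuplexRules()) -> bool:
        return (
            self.mismatch_total <= rules.max_total_mismatch
            and self.mm_at_10_11 == 0
            and self.max_adjacent_mm_2_12 <= rules.max_adjacent_run_2_12
            and self.mismatch_1_12 <= rules.max_mismatch_1_12
            and self.energy_ratio >= rules.min_energy_ratio
        )


def perfect_complement_energy(mirna: str) -> float:
    return sum(-3.0 if b in "GC" else -2.0 for b in mirna)


def score_duplex(
    mirna: str,
    site: str,
    mirna_id: str = "",
    transcript_id: str = "",
    site_start: int = 0,
) -> DuplexHit:
    """Score one ungapped antiparallel duplex; site is given 5'->3' on
    the transcript and must equal the miRNA in length."""
    if len(mirna) != len(site):
        raise ValueError("site length must equal miRNA length (ungapped duplex)")
    L = len(mirna)
    weights: list[float] = []
    energy = 0.0
    for i, mb in enumerate(mirna):  # i = miRNA position-1 (from 5' end)
        tb = site[L - 1 - i]  # antiparallel partner
        pair = (mb, tb)
        if pair in _WC:
            weights.append(0.0)
            energy += _PAIR_ENERGY[pair]
        elif pair in _WOBBLE:
            weights.append(0.5)
            energy += _PAIR_ENERGY[pair]
        else:
            weights.append(1.0)
    total = sum(weights)
    mm_1_12 = sum(weights[: min(12, L)])
    mm_10_11 = sum(1 for i in (9, 10) if i < L and weights[i] > 0)
    run = best_run = 0
    for i in range(1, min(12, L)):  # positions 2..12
        run = run + 1 if weights[i] >= 0.5 else 0
        best_run = max(best_run, run)
    perfect = perfect_complement_energy(mirna)
    return DuplexHit(
        mirna_id=mirna_id,
        transcript_id=transcript_id,
        site_start=site_start,
        site_seq=site,
        mismatch_total=total,
        mismatch_1_12=mm_1_12,
        max_adjacent_mm_2_12=best_run,
        mm_at_10_11=mm_10_11,
        duplex_energy=energy,
        perfect_energy=perfect,
        energy_ratio=energy / perfect,
    )


def scan_transcript(
    mirna: str,
    transcript: str,
    mirna_id: str = "",
    transcript_id: str = "",
    rules: DuplexRules = DuplexRules(),
) -> list[DuplexHit]:
    """All windows of the transcript passing the five duplex rules,
    sorted by position."""
    if len(transcript) < len(mirna):
        raise ValueError("transcript shorter than miRNA")
    L = len(mirna)
    hits = []
    for start in range(len(transcript) - L + 1):
        hit = score_duplex(
            mirna, transcript[start : start + L], mirna_id, transcript_id, start
        )
        if hit.passes(rules):
            hits.append(hit)
    return hits


def scan_many(
    mirnas: Iterable[tuple[str, str]],
    transcripts: Iterable[tuple[str, str]],
    rules: DuplexRules = DuplexRules(),
) -> list[DuplexHit]:
    transcripts = list(transcripts)
    out: list[DuplexHit] = []
    for mid, mseq in mirnas:
        for tid, tseq in transcripts:
            if len(tseq) >= len(mseq):
                out.extend(scan_transcript(mseq, tseq, mid, tid, rules))
    return out
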