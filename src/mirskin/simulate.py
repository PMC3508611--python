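"""Synthetic two-library small-RNA experiment with machine-readable truth.

Everything the pipeline consumes can be generated here at desk scale: a
toy genome with planted miRNA hairpins (every planted precursor is
verified at build time to satisfy the six candidacy criteria, the -18
kcal/mol MFE bound and the 0.97 MFEI bound under the configured folding
engine), contaminant ncRNA/repeat/exon/intron reference sets, two
condition libraries (white/brown) of adapter-flanked 18-30 nt reads
dominated by 22-mers with planted fold changes, decoy loci that attract
reads but fold badly, transcripts carrying perfect target sites, and a
comparative-CT qPCR table consistent with the planted fold changes.

Design choices that emulate the real assay:

* multinomial read sampling — one pooled library per condition, so there
  is no replicate dispersion to model;
* isomiR end noise biased to the 3' end (5' offset 0/-1/+1 with
  probability 0.90/0.05/0.05; 3' offset 0/±1/±2 with probability
  0.70/0.10/0.10/0.05/0.05), matching the observation that miRNA 5' ends
  are processing-anchored;
* per-base substitution errors at a post-quality-filter rate (default
  1e-3);
* a small "junk" fraction of reads that the cleaner must remove
  (N-containing, low-quality, 5'-adapter contaminants).

All generators are deterministic functions of the config seed.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .fold import fold_rna
from .formats import RawRead, ReferenceSet, write_fasta, write_fastq
from .hairpin import compute_mfei, evaluate_criteria
from .seqindex import revcomp

LIBRARIES = ("white", "brown")

# Illumina small-RNA adapters (config inputs in the pipeline; shipped as
# the example defaults).
ADAPTER3_DEFAULT = "TGGAATTCTCGGGTGCCAAGG"
ADAPTER5_DEFAULT = "GTTCAGAGTTCTACAGTCCGACGATC"

#: default planted fold changes (id index, FC, enriched condition),
#: spanning the 2-48x range seen in real two-colour skin libraries.
FC_SPEC_DEFAULT = (
    (0, 48.0, "white"),
    (1, 20.0, "white"),
    (2, 10.0, "white"),
    (3, 8.0, "white"),
    (4, 6.0, "white"),
    (5, 16.0, "brown"),
    (6, 10.0, "brown"),
    (7, 8.0, "brown"),
    (8, 6.0, "brown"),
    (9, 2.5, "white"),
)

CLASS_PROPORTIONS_DEFAULT = {
    "known_mirna": 0.40,
    "novel_mirna": 0.06,
    "genbank_ncrna": 0.08,
    "rfam_ncrna": 0.07,
    "repeat": 0.05,
    "exon": 0.05,
    "intron": 0.05,
    "decoy": 0.02,
    "random": 0.20,
    "junk": 0.02,
}


@dataclass
class SimulationConfig:
    n_reads: int = 100_000
    n_known_mirnas: int = 30
    n_novel_mirnas: int = 10
    n_decoys: int = 5
    n_arm_switched: int = 2
    fc_spec: tuple = FC_SPEC_DEFAULT
    class_proportions: dict = field(default_factory=lambda: dict(CLASS_PROPORTIONS_DEFAULT))
    error_rate: float = 0.001
    adapter3: str = ADAPTER3_DEFAULT
    adapter5: str = ADAPTER5_DEFAULT
    modal_length: int = 22
    read_length: int = 36
    qpcr_replicates: int = 4
    qpcr_noise_sd: float = 0.2
    seed: int = 0
    engine: str = "auto"

    def __post_init__(self) -> None:
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        if not 0 <= self.error_rate <= 0.05:
            raise ValueError("error_rate must be in [0, 0.05]")
        for _, fc, cond in self.fc_spec:
            if fc < 1:
                raise ValueError("planted fold changes must be >= 1")
            if cond not in LIBRARIES:
                raise ValueError(f"unknown condition {cond!r}")
        total = sum(self.class_proportions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"class proportions must sum to 1 (got {total})")


@dataclass
class PlantedMiRNA:
    id: str
    kind: str  # "known" | "novel"
    mature: str  # the expressed predominant product
    annotated_mature: str  # catalogue entry (differs when arm-switched)
    arm: str  # arm of the expressed product
    annotated_arm: str
    precursor: str
    locus: tuple[str, int, int, str]
    proportions: dict[str, float]  # library -> expected read proportion

    @property
    def arm_switched(self) -> bool:
        return self.arm != self.annotated_arm


@dataclass
class TruthSet:
    planted_mirnas: list[PlantedMiRNA]
    planted_fold_changes: dict[str, tuple[float, str]]  # id -> (realized FC, direction)
    planted_classes: dict[str, dict[str, float]]  # category -> library -> clean-read proportion
    decoy_ids: list[str]
    target_sites: list[tuple[str, str, int]]  # (mirna_id, transcript_id, site_start)
    seed: int

    def de_ids(self, min_fc: float = 5.0) -> set[str]:
        return {
            mid for mid, (fc, _) in self.planted_fold_changes.items() if fc >= min_fc
        }

    def null_ids(self, max_fc: float = 1.5) -> set[str]:
        return {
            mid for mid, (fc, _) in self.planted_fold_changes.items() if fc <= max_fc
        }


@dataclass
class SyntheticData:
    """Everything build_genome emits: the genome, every reference set,
    the catalogues, target transcripts, and the truth."""

    genome: ReferenceSet
    references: dict[str, ReferenceSet]  # annotation category -> set
    mature_catalog: ReferenceSet
    hairpin_catalog: ReferenceSet
    transcripts: ReferenceSet
    truth: TruthSet
    config: SimulationConfig


def _random_seq(rng: random.Random, length: int, gc: float = 0.5) -> str:
    g = gc / 2
    a = (1 - gc) / 2
    return "".join(
        rng.choices("ACGT", weights=(a, g, g, a), k=length)
    )


def _design_hairpin(
    rng: random.Random,
    arm: str,
    engine: str,
    mature_len: int = 22,
    loop_len: int = 12,
    ext_len: int = 6,
    n_star_mismatches: int = 2,
    max_tries: int = 200,
) -> tuple[str, str, int, str]:
    """Design a precursor whose mature (on the requested arm) passes all
    six candidacy criteria with comfortable margins (MFE <= -20,
    MFEI >= 1.02) under the configured engine; returns
    (precursor, mature, mature_start, star).

    The star arm carries two interior substitutions relative to the
    perfect complement — real miRNA/miRNA* duplexes have internal
    mismatches, and a perfect star would plant an exact reverse
    complement of the mature (a spurious second mapping locus).
    Margins absorb the few flanking bases the pipeline's precursor
    trimming may add or remove."""
    for _ in range(max_tries):
        mature = _random_seq(rng, mature_len, gc=0.55)
        gc = sum(c in "GC" for c in mature) / mature_len
        if not 0.45 <= gc <= 0.65:
            continue
        star_bases = list(revcomp(mature))
        for pos in rng.sample(range(4, mature_len - 4), n_star_mismatches):
            star_bases[pos] = rng.choice([b for b in "ACGT" if b != star_bases[pos]])
        star = "".join(star_bases)
        loop = _random_seq(rng, loop_len, gc=0.3)
        ext = _random_seq(rng, ext_len, gc=0.6)
        if arm == "5p":
            prec = ext + mature + loop + star + revcomp(ext)
            m_start = ext_len
        else:
            prec = ext + star + loop + mature + revcomp(ext)
            m_start = ext_len + mature_len + loop_len
        fold = fold_rna(prec, engine=engine)
        flags, found_arm, _ = evaluate_criteria(
            fold, m_start, m_start + mature_len, read_count=5
        )
        if not all(flags.values()) or found_arm != arm:
            continue
        if fold.mfe > -20.0:
            continue
        _, mfei = compute_mfei(fold.mfe, prec)
        if mfei < 1.02:
            continue
        return prec, mature, m_start, star
    raise RuntimeError(
        "failed to design a criterion-passing hairpin; rerun with a new seed"
    )


def _design_decoy(rng: random.Random, length: int = 22) -> str:
    """An AT-rich low-structure tag: attracts reads, folds badly."""
    return _random_seq(rng, length, gc=0.12)


def build_genome(config: SimulationConfig) -> SyntheticData:
    """Plant known + novel miRNA precursors and decoy loci in a toy
    genome, emit contaminant reference sets, catalogues and target
    transcripts, and record the truth.

    Build-time verification: every planted precursor must satisfy the
    six criteria plus the MFE/MFEI bounds (with margin) under the
    configured engine, and every planted mature must occur exactly once
    in the genome; violations trigger redesign with fresh randomness.
    """
    rng = random.Random(config.seed * 7919 + 11)
    engine = config.engine
    planted: list[PlantedMiRNA] = []
    chunks: list[str] = []
    pos = 0
    used: list[str] = []

    def spacer() -> str:
        return _random_seq(rng, rng.randint(60, 120), gc=0.38)

    def place(prec: str) -> int:
        nonlocal pos
        chunks.append(spacer())
        pos += len(chunks[-1])
        start = pos
        chunks.append(prec)
        pos += len(prec)
        return start

    n_total = config.n_known_mirnas + config.n_novel_mirnas
    for i in range(n_total):
        known = i < config.n_known_mirnas
        arm = "5p" if i % 2 == 0 else "3p"
        while True:
            prec, mature, m_start, star = _design_hairpin(rng, arm, engine)
            if all(
                mature not in s and revcomp(mature) not in s
                for s in used
            ) and mature not in prec[:m_start] + prec[m_start + len(mature):]:
                break
        start = place(prec)
        used.append(prec)
        if known:
            mid = f"lpa-miR-{100 + i}"
        else:
            mid = f"novel-{i - config.n_known_mirnas + 1}"
        # arm switching is planted on the *last* known miRNAs so it never
        # overlaps the fold-change spec (switched reads do not match the
        # annotated catalogue entry, by design)
        switched = known and i >= config.n_known_mirnas - config.n_arm_switched
        if switched:
            # annotated product on `arm`, expression from the other arm
            expressed = star
            planted.append(
                PlantedMiRNA(
                    id=mid, kind="known",
                    mature=expressed, annotated_mature=mature,
                    arm="3p" if arm == "5p" else "5p", annotated_arm=arm,
                    precursor=prec,
                    locus=("chr1", start, start + len(prec), "+"),
                    proportions={},
                )
            )
        else:
            planted.append(
                PlantedMiRNA(
                    id=mid, kind="known" if known else "novel",
                    mature=mature, annotated_mature=mature,
                    arm=arm, annotated_arm=arm,
                    precursor=prec,
                    locus=("chr1", start, start + len(prec), "+"),
                    proportions={},
                )
            )

    decoy_ids: list[str] = []
    decoy_seqs: dict[str, str] = {}
    for d in range(config.n_decoys):
        while True:
            seq = _design_decoy(rng)
            context = _random_seq(rng, 30, gc=0.12) + seq + _random_seq(rng, 30, gc=0.12)
            if all(seq not in s and revcomp(seq) not in s for s in used):
                break
        place(context)
        used.append(context)
        did = f"decoy-{d + 1}"
        decoy_ids.append(did)
        decoy_seqs[did] = seq
    chunks.append(spacer())
    genome_seq = "".join(chunks)

    # uniqueness audit: every planted mature occurs exactly once
    for p in planted:
        if genome_seq.count(p.mature) != 1:
            raise RuntimeError(
                f"planted mature {p.id} occurs {genome_seq.count(p.mature)} "
                "times in the genome; rerun with a new seed"
            )

    genome = ReferenceSet("genome", [("chr1", genome_seq)])

    # contaminant reference sets (not placed in the genome: they emulate
    # foreign/unassembled sequence, so contaminant reads stay unmapped)
    def contaminants(cat: str, n: int, prefix: str) -> ReferenceSet:
        recs = [
            (f"{prefix}{j + 1}", _random_seq(rng, rng.randint(100, 200), gc=0.5))
            for j in range(n)
        ]
        return ReferenceSet(cat, recs)

    references = {
        "genbank_ncrna": contaminants("genbank_ncrna", 3, "gb-rRNA-"),
        "rfam_ncrna": contaminants("rfam_ncrna", 3, "rfam-tRNA-"),
        "repeat": contaminants("repeat", 2, "rep-"),
        "exon": contaminants("exon", 3, "exon-"),
        "intron": contaminants("intron", 3, "intron-"),
    }

    known_planted = [p for p in planted if p.kind == "known"]
    mature_catalog = ReferenceSet(
        "known_mirna_mature",
        [(p.id, p.annotated_mature) for p in known_planted],
    )
    hairpin_catalog = ReferenceSet(
        "known_mirna_hairpin",
        [(f"{p.id}-precursor", p.precursor) for p in known_planted],
    )

    # expression proportions.  Null miRNAs get lognormal weights; planted
    # fold changes use a 1/sqrt(FC) base so the enriched side stays
    # moderate (mirroring the real tables, where the largest fold changes
    # sit on low-abundance miRNAs).  A single normaliser across both
    # libraries keeps realized fold changes exactly at their nominal
    # values; the per-library miRNA-mass deficit this leaves is absorbed
    # by the random background class.
    class_p = config.class_proportions
    fc_by_index = {i: (fc, cond) for i, fc, cond in config.fc_spec}
    masses = {lib: {} for lib in LIBRARIES}
    for j, p in enumerate(known_planted):
        fc, cond = fc_by_index.get(j, (1.0, None))
        base = 1.0 / math.sqrt(fc) if fc > 1 else rng.lognormvariate(0.0, 0.8)
        for lib in LIBRARIES:
            masses[lib][p.id] = base * (fc if lib == cond else 1.0)
    z = max(sum(m.values()) for m in masses.values()) / class_p["known_mirna"]
    for p in known_planted:
        for lib in LIBRARIES:
            p.proportions[lib] = masses[lib][p.id] / z
    novel_planted = [p for p in planted if p.kind == "novel"]
    for p in novel_planted:
        for lib in LIBRARIES:
            p.proportions[lib] = class_p["novel_mirna"] / len(novel_planted)

    realized_fc: dict[str, tuple[float, str]] = {}
    for p in planted:
        w, b = p.proportions["white"], p.proportions["brown"]
        fc = max(w, b) / min(w, b)
        realized_fc[p.id] = (fc, "white" if w >= b else "brown")

    # per-library component proportions for read drawing; "random"
    # absorbs whatever the miRNA class leaves unused in each library
    class_p_by_lib: dict[str, dict[str, float]] = {}
    for lib in LIBRARIES:
        mirna_mass = sum(p.proportions[lib] for p in known_planted)
        cp = {
            cat: v for cat, v in class_p.items() if cat not in ("known_mirna",)
        }
        cp["random"] = cp["random"] + (class_p["known_mirna"] - mirna_mass)
        class_p_by_lib[lib] = cp

    junk = class_p.get("junk", 0.0)
    planted_classes: dict[str, dict[str, float]] = {}
    for cat in class_p:
        if cat == "junk":
            continue
        planted_classes[cat] = {}
        for lib in LIBRARIES:
            if cat == "known_mirna":
                v = sum(p.proportions[lib] for p in known_planted)
            else:
                v = class_p_by_lib[lib][cat]
            planted_classes[cat][lib] = v / (1 - junk)

    # target transcripts: perfect complement of the first few known
    # matures embedded in random UTR-like sequence
    t_records = []
    target_sites = []
    for k, p in enumerate(known_planted[:5]):
        tid = f"transcript-{k + 1}"
        left = _random_seq(rng, rng.randint(150, 250), gc=0.45)
        right = _random_seq(rng, rng.randint(150, 250), gc=0.45)
        site = revcomp(p.annotated_mature)
        t_records.append((tid, left + site + right))
        target_sites.append((p.id, tid, len(left)))
    transcripts = ReferenceSet("transcript", t_records)

    truth = TruthSet(
        planted_mirnas=planted,
        planted_fold_changes=realized_fc,
        planted_classes=planted_classes,
        decoy_ids=decoy_ids,
        target_sites=target_sites,
        seed=config.seed,
    )
    data = SyntheticData(
        genome=genome,
        references=references,
        mature_catalog=mature_catalog,
        hairpin_catalog=hairpin_catalog,
        transcripts=transcripts,
        truth=truth,
        config=config,
    )
    data._decoy_seqs = decoy_seqs  # internal: read generation needs them
    data._class_p_by_lib = class_p_by_lib
    return data


_OFFSETS_5P = ((0, 0.90), (-1, 0.05), (1, 0.05))
_OFFSETS_3P = ((0, 0.70), (1, 0.10), (-1, 0.10), (2, 0.05), (-2, 0.05))


def _draw(rng: random.Random, table) -> int:
    r = rng.random()
    acc = 0.0
    for value, p in table:
        acc += p
        if r < acc:
            return value
    return table[0][0]


def _mutate(rng: random.Random, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    out = None
    for i in range(len(seq)):
        if rng.random() < rate:
            if out is None:
                out = list(seq)
            out[i] = rng.choice([b for b in "ACGT" if b != seq[i]])
    return seq if out is None else "".join(out)


def simulate_libraries(
    data: SyntheticData,
    end_noise: bool = True,
) -> dict[str, list[RawRead]]:
    """Draw the two condition libraries as RawReads (insert + 3' adapter,
    truncated to the read length, Phred+33 qualities)."""
    config = data.config
    truth = data.truth
    rng = random.Random(config.seed * 104729 + 37)
    out: dict[str, list[RawRead]] = {}
    contaminant_cats = ("genbank_ncrna", "rfam_ncrna", "repeat", "exon", "intron")
    decoys = list(getattr(data, "_decoy_seqs", {}).values())

    for lib in LIBRARIES:
        components: list[tuple[str, object, float]] = []
        for p in truth.planted_mirnas:
            components.append(("mirna", p, p.proportions[lib]))
        cp = getattr(data, "_class_p_by_lib", {}).get(lib, config.class_proportions)
        for cat in contaminant_cats:
            components.append(("contaminant", cat, cp[cat]))
        if decoys:
            components.append(("decoy", None, cp["decoy"]))
        components.append(("random", None, cp["random"]))
        components.append(("junk", None, cp["junk"]))

        reads: list[RawRead] = []
        values = [c[2] for c in components]
        total_p = sum(values)
        for ridx in range(config.n_reads):
            r = rng.random() * total_p
            acc = 0.0
            comp = components[-1]
            for c in components:
                acc += c[2]
                if r < acc:
                    comp = c
                    break
            kind, payload = comp[0], comp[1]
            qual = None
            if kind == "mirna":
                p: PlantedMiRNA = payload
                prec = p.precursor
                m0 = prec.find(p.mature)
                m1 = m0 + len(p.mature)
                if end_noise:
                    m0 = max(0, m0 + _draw(rng, _OFFSETS_5P))
                    m1 = min(len(prec), m1 + _draw(rng, _OFFSETS_3P))
                insert = _mutate(rng, prec[m0:m1], config.error_rate)
            elif kind == "contaminant":
                refset = data.references[payload]
                _, seq = refset.records[rng.randrange(len(refset.records))]
                flen = min(len(seq), rng.randint(18, 28))
                s = rng.randrange(len(seq) - flen + 1)
                insert = _mutate(rng, seq[s : s + flen], config.error_rate)
            elif kind == "decoy":
                insert = _mutate(rng, decoys[rng.randrange(len(decoys))], config.error_rate)
            elif kind == "random":
                flen = max(18, min(30, round(rng.gauss(config.modal_length, 1.5))))
                insert = _random_seq(rng, flen)
            else:  # junk: must be removed by the cleaner
                mode = rng.randrange(3)
                flen = rng.randint(18, 28)
                insert = _random_seq(rng, flen)
                if mode == 0:  # N-containing
                    i = rng.randrange(len(insert))
                    insert = insert[:i] + "N" + insert[i + 1:]
                elif mode == 1:  # low quality base
                    full = (insert + config.adapter3)[: config.read_length]
                    q = ["I"] * len(full)
                    q[rng.randrange(len(full))] = "#"
                    qual = "".join(q)
                else:  # 5' adapter contaminant
                    insert = config.adapter5[-10:] + insert
            full = insert + config.adapter3
            if len(full) < config.read_length:
                full = full + _random_seq(rng, config.read_length - len(full))
            full = full[: config.read_length]
            if qual is None:
                qual = "I" * len(full)
            else:
                qual = (qual + "I" * len(full))[: len(full)]
            reads.append(RawRead(f"{lib}_{ridx}", full, qual))
        out[lib] = reads
    return out


def make_qpcr_table(
    data: SyntheticData,
    assays: list[str] | None = None,
    reference_assay: str = "U6",
    base_ct_reference: float = 20.0,
    base_ct_target: float = 30.0,
    noise_sd: float | None = None,
) -> pd.DataFrame:
    """Stem-loop RT-qPCR CT table consistent with the planted expression:
    CT_target = base - log2(relative abundance) + noise, CT_reference =
    base_ref + noise, so comparative-CT analysis recovers the planted
    fold changes within noise."""
    config = data.config
    truth = data.truth
    rng = random.Random(config.seed * 6553 + 101)
    sd = config.qpcr_noise_sd if noise_sd is None else noise_sd
    if assays is None:
        assays = sorted(truth.de_ids(min_fc=2.0) & {
            p.id for p in truth.planted_mirnas if p.kind == "known"
        })
    by_id = {p.id: p for p in truth.planted_mirnas}
    rows = []
    for cond in LIBRARIES:
        for rep in range(config.qpcr_replicates):
            sample = f"{cond}_{rep + 1}"
            rows.append(
                {
                    "sample": sample, "condition": cond, "assay": reference_assay,
                    "ct": base_ct_reference + rng.gauss(0, sd),
                }
            )
            for assay in assays:
                p = by_id[assay]
                rel = p.proportions[cond] * 1e6
                rows.append(
                    {
                        "sample": sample, "condition": cond, "assay": assay,
                        "ct": base_ct_target - math.log2(rel) + rng.gauss(0, sd),
                    }
                )
    return pd.DataFrame(rows)


def write_bundle(data: SyntheticData, libraries: dict[str, list[RawRead]], outdir: str | Path) -> None:
    """Write genome.fa, refs/<cat>.fa, catalogues, transcripts, FASTQs,
    the qPCR CT table and a truth table under outdir."""
    outdir = Path(outdir)
    (outdir / "refs").mkdir(parents=True, exist_ok=True)
    write_fasta(data.genome.records, outdir / "genome.fa")
    for cat, refset in data.references.items():
        write_fasta(refset.records, outdir / "refs" / f"{cat}.fa")
    write_fasta(data.mature_catalog.records, outdir / "mature.fa")
    write_fasta(data.hairpin_catalog.records, outdir / "hairpin.fa")
    write_fasta(data.transcripts.records, outdir / "transcripts.fa")
    for lib, reads in libraries.items():
        write_fastq(reads, outdir / f"{lib}.fastq")
    make_qpcr_table(data).to_csv(outdir / "ct.tsv", sep="\t", index=False)
    truth_rows = []
    for p in data.truth.planted_mirnas:
        fc, direction = data.truth.planted_fold_changes[p.id]
        truth_rows.append(
            {
                "id": p.id, "kind": p.kind, "mature": p.mature,
                "annotated_mature": p.annotated_mature, "arm": p.arm,
                "annotated_arm": p.annotated_arm,
                "locus": "{}:{}-{}{}".format(*p.locus),
                "proportion_white": p.proportions["white"],
                "proportion_brown": p.proportions["brown"],
                "fold_change": fc, "direction": direction,
            }
        )
    pd.DataFrame(truth_rows).to_csv(outdir / "truth.tsv", sep="\t", index=False)
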