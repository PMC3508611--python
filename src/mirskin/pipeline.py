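"""End-to-end orchestration: preprocess -> annotate -> conserved ->
diffexpr -> novel -> targets, driven by one structured config.

Every stage is a pure function of (inputs, config, seed); the manifest
records the config hash and per-stage row counts so a rerun with the
same config is reproducible and auditable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import annotate as annotate_mod
from . import conserved as conserved_mod
from . import diffexpr as diffexpr_mod
from . import hairpin as hairpin_mod
from . import preprocess as preprocess_mod
from . import targets as targets_mod
from .formats import CountTable, read_fasta, read_fastq, write_count_table

#: annotation category -> reference-set category, in priority order
REFERENCE_CATEGORY = {
    "rRNA_etc_genbank": "genbank_ncrna",
    "rRNA_etc_rfam": "rfam_ncrna",
    "known_miRNA": "known_mirna_hairpin",
    "repeat": "repeat",
    "exon": "exon",
    "intron": "intron",
}


@dataclass
class RunConfig:
    """All pipeline inputs and the study's thresholds, each a named,
    documented key with its conventional default: 18-30 nt length
    window, >= 5 mature reads, MFE <= -18 kcal/mol, MFEI >= 0.97,
    fold change >= 2 at alpha 0.01, duplex energy ratio >= 0.75."""

    output_dir: str
    libraries: dict[str, str]  # library_id -> FASTQ path
    genome: str
    mature_catalog: str
    references: dict[str, str] = field(default_factory=dict)  # annotation category -> FASTA
    hairpin_catalog: str | None = None
    transcripts: str | None = None
    adapter3: str = "TGGAATTCTCGGGTGCCAAGG"
    adapter5: str | None = "GTTCAGAGTTCTACAGTCCGACGATC"
    min_len: int = 18
    max_len: int = 30
    min_qual: int = 20
    max_mm_conserved: int = 2
    min_identity: float = 0.90
    min_fc: float = 2.0
    alpha: float = 0.01
    min_count: int = 5
    mfe_max: float = -18.0
    mfei_min: float = 0.97
    energy_ratio_min: float = 0.75
    engine: str = "auto"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.libraries) != 2:
            raise ValueError("exactly two libraries are expected")
        if not (0 < self.min_len <= self.max_len):
            raise ValueError("invalid length window")
        if not (0 < self.alpha <= 1 and self.min_fc >= 1):
            raise ValueError("invalid differential-expression thresholds")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def input_paths(self) -> list[str]:
        paths = [self.genome, self.mature_catalog, *self.libraries.values()]
        paths += list(self.references.values())
        paths += [p for p in (self.hairpin_catalog, self.transcripts) if p]
        return paths

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_all(config: RunConfig) -> dict:
    """Execute every stage in order; returns the manifest dict (also
    written to manifest.txt).  Missing inputs abort before any stage
    runs; a stage failure aborts with the failing stage named."""
    missing = [p for p in config.input_paths() if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"missing input files: {missing}")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config.digest(), "stages": {}}
    lib_ids = sorted(config.libraries)
    state: dict = {}

    def run_stage(name: str, fn) -> None:
        try:
            manifest["stages"][name] = fn()
        except Exception as exc:  # noqa: BLE001 - abort naming the stage
            raise StageError(name, exc) from exc

    def stage_preprocess() -> int:
        genome = read_fasta(config.genome, "genome")
        clean_by_lib: dict[str, list[str]] = {}
        raw_n: dict[str, int] = {}
        for lib in lib_ids:
            reads = read_fastq(config.libraries[lib])
            raw_n[lib] = len(reads)
            clean_by_lib[lib] = preprocess_mod.clean_reads(
                reads, config.adapter3, config.adapter5,
                config.min_len, config.max_len, config.min_qual,
            )
        tags = preprocess_mod.collapse_tags(clean_by_lib)
        write_count_table(
            CountTable(lib_ids, {t.sequence: dict(t.counts) for t in tags}),
            outdir / "tags.tsv",
        )
        rows = []
        for lib in lib_ids:
            _, matched_reads, pct = preprocess_mod.match_genome(
                tags, genome, library_id=lib
            )
            summary = preprocess_mod.summarize_library(
                lib, raw_n[lib], clean_by_lib[lib], tags, matched_reads
            )
            rows.append({**summary.__dict__, "genome_match_pct": pct})
            hist = preprocess_mod.length_distribution(tags, library_id=lib)
            pd.DataFrame(
                {"length": list(hist), "reads": list(hist.values())}
            ).to_csv(outdir / f"length_hist_{lib}.tsv", sep="\t", index=False)
        pd.DataFrame(rows).to_csv(outdir / "summaries.tsv", sep="\t", index=False)
        state["tags"] = tags
        state["totals"] = {lib: len(clean_by_lib[lib]) for lib in lib_ids}
        return len(tags)

    def stage_annotate() -> int:
        refsets = {
            cat: read_fasta(path, REFERENCE_CATEGORY.get(cat, cat))
            for cat, path in config.references.items()
        }
        if config.hairpin_catalog and "known_miRNA" not in refsets:
            refsets["known_miRNA"] = read_fasta(
                config.hairpin_catalog, "known_mirna_hairpin"
            )
        annotator = annotate_mod.Annotator(
            refsets, tag_lengths=range(config.min_len, config.max_len + 1)
        )
        records = annotator.classify(state["tags"])
        annotate_mod.class_frequencies(records).to_csv(
            outdir / "class_frequencies.tsv", sep="\t", index=False
        )
        pd.DataFrame(
            [
                {"sequence": r.tag.sequence, "category": r.category,
                 "matched_id": r.matched_id}
                for r in records
            ]
        ).to_csv(outdir / "annotations.tsv", sep="\t", index=False)
        state["annotated"] = {
            r.tag.sequence
            for r in records
            if r.category != annotate_mod.UNANNOTATED
        }
        return len(records)

    def stage_conserved() -> int:
        catalog = read_fasta(config.mature_catalog, "known_mirna_mature")
        hits = conserved_mod.match_conserved(
            state["tags"], catalog, config.max_mm_conserved, config.min_identity
        )
        counts = conserved_mod.mirna_count_table(hits, lib_ids)
        write_count_table(counts, outdir / "conserved_counts.tsv")
        fams = conserved_mod.group_families(hits)
        pd.DataFrame(
            [
                {"family": f.family_name, "members": len(f.member_ids),
                 **{f"reads_{lib}": f.total_reads.get(lib, 0) for lib in lib_ids}}
                for f in fams
            ]
        ).to_csv(outdir / "families.tsv", sep="\t", index=False)
        state["counts"] = counts
        state["conserved_seqs"] = {h.tag.sequence for h in hits}
        return len(hits)

    def stage_diffexpr() -> int:
        recs = diffexpr_mod.score_expression(
            state["counts"], state["totals"], lib_ids[0], lib_ids[1]
        )
        called = diffexpr_mod.call_differential(recs, config.min_fc, config.alpha)
        diffexpr_mod.records_to_frame(recs).to_csv(
            outdir / "expression.tsv", sep="\t", index=False
        )
        diffexpr_mod.records_to_frame(called).to_csv(
            outdir / "differential.tsv", sep="\t", index=False
        )
        return len(called)

    def stage_novel() -> int:
        genome = read_fasta(config.genome, "genome")
        exclude = state.get("annotated", set()) | state.get("conserved_seqs", set())
        per_lib: dict[str, list] = {}
        cand_rows = []
        for lib in lib_ids:
            cands = hairpin_mod.predict_novel(
                state["tags"], genome, library_id=lib,
                min_count=config.min_count, mfe_max=config.mfe_max,
                exclude=exclude, engine=config.engine,
            )
            per_lib[lib] = hairpin_mod.passing(cands)
            for c in cands:
                cand_rows.append(
                    {
                        "library": lib, "mature": c.mature,
                        "locus": "{}:{}-{}({})".format(*c.locus),
                        "structure": c.fold.structure, "mfe": c.mfe,
                        "amfe": round(c.amfe, 4), "mfei": round(c.mfei, 4),
                        **{f"criterion_{k}": v for k, v in c.criteria.items()},
                        "passed_all": c.passed_all,
                    }
                )
        pd.DataFrame(cand_rows).to_csv(
            outdir / "novel_candidates.tsv", sep="\t", index=False
        )
        merged = hairpin_mod.merge_libraries(
            per_lib[lib_ids[0]], per_lib[lib_ids[1]], labels=tuple(lib_ids)
        )
        by_mature = {c.mature: c for lib in lib_ids for c in per_lib[lib]}
        final = hairpin_mod.filter_mfei(
            [by_mature[m] for m in sorted(merged.union)], config.mfei_min
        )
        pd.DataFrame(
            [
                {"mature": c.mature, "mfe": c.mfe, "mfei": round(c.mfei, 4),
                 "locus": "{}:{}-{}({})".format(*c.locus)}
                for c in final
            ]
        ).to_csv(outdir / "novel_mirnas.tsv", sep="\t", index=False)
        return len(final)

    def stage_targets() -> int:
        if not config.transcripts:
            return 0
        catalog = read_fasta(config.mature_catalog, "known_mirna_mature")
        transcripts = read_fasta(config.transcripts, "transcript")
        rules = targets_mod.DuplexRules(min_energy_ratio=config.energy_ratio_min)
        hits = targets_mod.scan_many(catalog.records, transcripts.records, rules)
        pd.DataFrame(
            [
                {
                    "mirna_id": h.mirna_id, "transcript_id": h.transcript_id,
                    "site_start": h.site_start, "site": h.site_seq,
                    "mismatch_total": h.mismatch_total,
                    "mismatch_1_12": h.mismatch_1_12,
                    "max_adjacent_mm_2_12": h.max_adjacent_mm_2_12,
                    "mm_at_10_11": h.mm_at_10_11,
                    "energy_ratio": round(h.energy_ratio, 4),
                }
                for h in hits
            ]
        ).to_csv(outdir / "targets.tsv", sep="\t", index=False)
        return len(hits)

    run_stage("preprocess", stage_preprocess)
    run_stage("annotate", stage_annotate)
    run_stage("conserved", stage_conserved)
    run_stage("diffexpr", stage_diffexpr)
    run_stage("novel", stage_novel)
    run_stage("targets", stage_targets)

    with open(outdir / "manifest.txt", "w") as fh:
        fh.write(f"config_hash\t{manifest['config_hash']}\n")
        for name, rows in manifest["stages"].items():
            fh.write(f"{name}\t{rows}\n")
    return manifest
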