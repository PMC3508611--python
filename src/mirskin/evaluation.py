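"""From-scratch benchmark computations over the pipeline.

Each function here re-runs a pipeline capability on freshly generated or
published inputs and measures the outcome: fold-change arithmetic on the
published expression table, read-accounting percentages from the
published library statistics, novel-set algebra, MFEI filtering, and the
simulation studies (differential-expression recovery, hairpin recovery,
target-scanner equivalence with a brute-force rescan, significance-test
calibration, NEL conservation).  Both the test suite and
scripts/acceptance.py call these, so the numbers they report are always
recomputed by the package itself.
"""

from __future__ import annotations

import math
import random

import numpy as np

from . import tables
from .annotate import UNANNOTATED, Annotator
from .conserved import match_conserved, mirna_count_table
from .diffexpr import call_differential, count_significance, normalize_nel, score_expression
from .hairpin import filter_mfei, merge_libraries, passing, predict_novel
from .preprocess import clean_reads, collapse_tags, percent
from .seqindex import revcomp
from .simulate import LIBRARIES, SimulationConfig, build_genome, simulate_libraries
from .targets import scan_transcript

_REFSET_TO_CATEGORY = {
    "genbank_ncrna": "rRNA_etc_genbank",
    "rfam_ncrna": "rRNA_etc_rfam",
    "repeat": "repeat",
    "exon": "exon",
    "intron": "intron",
}


def _derived_seed(seed: int, salt: int) -> int:
    return (seed * 1_000_003 + salt) % (2**31 - 1)


# --- published-table computations --------------------------------------


def fold_change_table_check() -> dict:
    """Recompute every fold change of the published expression table
    from its printed NEL pairs."""
    table = tables.expression_table()
    computed = []
    diffs = []
    for _, row in table.iterrows():
        fc, direction = (
            row["nel_white"] / row["nel_brown"], "white"
        ) if row["nel_white"] >= row["nel_brown"] else (
            row["nel_brown"] / row["nel_white"], "brown"
        )
        computed.append((row["mirna_id"], fc, direction))
        diffs.append(abs(fc - row["fc"]))
    by_id = {mid: (fc, d) for mid, fc, d in computed}
    return {
        "n_rows": len(table),
        "computed": by_id,
        "printed": dict(zip(table["mirna_id"], table["fc"])),
        "directions_printed": dict(zip(table["mirna_id"], table["direction"])),
        "max_abs_diff": max(diffs),
        "n_within_1e4": sum(1 for d in diffs if d <= 1e-4),
    }


def genome_match_percentages() -> dict[str, float]:
    """Genome-matched read percentage per published library."""
    out = {}
    for lib, stats in tables.LIBRARY_STATS.items():
        out[lib] = percent(stats["genome_matched_reads"], stats["clean_reads"])
    return out


def novel_union_from_published_sizes() -> int:
    """Merge two candidate sets with the published per-library sizes and
    overlap; the union count is what the set algebra yields."""
    sizes = tables.NOVEL_SET_SIZES
    shared = [f"shared-{i}" for i in range(sizes["shared"])]
    lib_a = shared + [f"white-only-{i}" for i in range(sizes["white"] - sizes["shared"])]
    lib_b = shared + [f"brown-only-{i}" for i in range(sizes["brown"] - sizes["shared"])]
    return merge_libraries(lib_a, lib_b).union_count


def mfei_filter_count(cutoff: float = 0.97) -> int:
    """Apply the MFEI cutoff to the published novel-miRNA table."""
    rows = tables.novel_mfei_table().to_dict("records")
    return len(filter_mfei(rows, cutoff))


# --- simulation studies -------------------------------------------------


def _one_expression_replicate(seed: int, n_reads: int):
    cfg = SimulationConfig(n_reads=n_reads, seed=seed)
    data = build_genome(cfg)
    libs = simulate_libraries(data)
    clean = {
        lib: clean_reads(reads, cfg.adapter3, cfg.adapter5)
        for lib, reads in libs.items()
    }
    tags = collapse_tags(clean)
    hits = match_conserved(tags, data.mature_catalog)
    counts = mirna_count_table(hits, list(LIBRARIES))
    totals = {lib: len(clean[lib]) for lib in clean}
    records = score_expression(counts, totals, "brown", "white")
    called = {r.mirna_id for r in call_differential(records)}
    return data, tags, clean, called


def de_recovery_study(
    seed: int, n_replicates: int = 20, n_reads: int = 100_000, min_fc: float = 5.0
) -> dict:
    """Planted fold-change recovery: over replicate simulated library
    pairs, the fraction of planted FC >= min_fc miRNAs called
    differential, and the fraction of planted null (FC 1) catalogue
    miRNAs falsely called."""
    de_total = de_found = null_total = null_called = 0
    for rep in range(n_replicates):
        data, _, _, called = _one_expression_replicate(
            _derived_seed(seed, rep), n_reads
        )
        catalog_ids = {
            p.id for p in data.truth.planted_mirnas if p.kind == "known"
        }
        de = data.truth.de_ids(min_fc) & catalog_ids
        null = data.truth.null_ids(1.5) & catalog_ids
        de_total += len(de)
        de_found += len(de & called)
        null_total += len(null)
        null_called += len(null & called)
    return {
        "recall_pct": 100.0 * de_found / de_total,
        "false_call_pct": 100.0 * null_called / null_total,
        "n_replicates": n_replicates,
        "n_reads": n_reads,
    }


def hairpin_recovery_study(seed: int, n_reads: int = 100_000) -> dict:
    """Planted novel-precursor recovery through the full discovery path
    (annotation exclusion, locus clustering, folding, six criteria,
    MFEI cutoff after merging)."""
    cfg = SimulationConfig(n_reads=n_reads, seed=_derived_seed(seed, 7001))
    data = build_genome(cfg)
    libs = simulate_libraries(data)
    clean = {
        lib: clean_reads(reads, cfg.adapter3, cfg.adapter5)
        for lib, reads in libs.items()
    }
    tags = collapse_tags(clean)
    refsets = {
        _REFSET_TO_CATEGORY[cat]: refset for cat, refset in data.references.items()
    }
    refsets["known_miRNA"] = data.hairpin_catalog
    records = Annotator(refsets).classify(tags)
    hits = match_conserved(tags, data.mature_catalog)
    exclude = {
        r.tag.sequence for r in records if r.category != UNANNOTATED
    } | {h.tag.sequence for h in hits}
    per_lib = {
        lib: passing(
            predict_novel(tags, data.genome, library_id=lib, exclude=exclude)
        )
        for lib in LIBRARIES
    }
    merged = merge_libraries(per_lib["white"], per_lib["brown"])
    by_mature = {c.mature: c for lib in LIBRARIES for c in per_lib[lib]}
    final = {
        c.mature
        for c in filter_mfei([by_mature[m] for m in sorted(merged.union)], 0.97)
    }
    truth = {p.mature for p in data.truth.planted_mirnas if p.kind == "novel"}
    return {
        "recall_pct": 100.0 * len(final & truth) / len(truth),
        "precision_pct": 100.0 * len(final & truth) / len(final) if final else 0.0,
        "n_reads": n_reads,
    }


def target_scan_oracle_check(seed: int, transcript_len: int = 2000, n_mirnas: int = 5) -> dict:
    """Window-exact agreement between scan_transcript and a brute-force
    rescan written from the rule definitions alone."""
    wc = {"A": "T", "T": "A", "G": "C", "C": "G"}

    def brute_force_sites(mirna: str, transcript: str) -> list[int]:
        L = len(mirna)
        out = []
        for start in range(len(transcript) - L + 1):
            site = transcript[start : start + L]
            w = []
            for i in range(L):
                m, t = mirna[i], site[L - 1 - i]
                if wc[m] == t:
                    w.append(0.0)
                elif (m, t) in (("G", "T"), ("T", "G")):
                    w.append(0.5)
                else:
                    w.append(1.0)
            if sum(w) > 4 or w[9] > 0 or w[10] > 0 or sum(w[:12]) > 2.5:
                continue
            run = bad = 0
            for i in range(1, 12):
                run = run + 1 if w[i] >= 0.5 else 0
                bad = max(bad, run)
            if bad >= 3:
                continue
            e = sum(
                (-3.0 if mirna[i] in "GC" else -2.0) if w[i] == 0.0
                else (-1.0 if w[i] == 0.5 else 0.0)
                for i in range(L)
            )
            perfect = sum(-3.0 if b in "GC" else -2.0 for b in mirna)
            if e / perfect >= 0.75:
                out.append(start)
        return out

    rng = random.Random(_derived_seed(seed, 31))
    agree = total = 0
    for _ in range(n_mirnas):
        mirna = "".join(rng.choice("ACGT") for _ in range(22))
        transcript = "".join(rng.choice("ACGT") for _ in range(transcript_len))
        for pos in rng.sample(range(transcript_len - 25), 4):
            site = list(revcomp(mirna))
            for p in rng.sample(range(22), rng.randint(0, 3)):
                site[p] = rng.choice([b for b in "ACGT" if b != site[p]])
            transcript = transcript[:pos] + "".join(site) + transcript[pos + 22:]
        expected = brute_force_sites(mirna, transcript)
        got = [h.site_start for h in scan_transcript(mirna, transcript)]
        total += 1
        agree += got == expected
    return {"agreement_fraction": agree / total, "n_instances": total}


def audic_claverie_check(max_count: int = 50) -> float:
    """Worst absolute deviation between count_significance and direct
    term-by-term summation of the posterior predictive tail."""

    def brute(x: int, n1: int, y: int, n2: int) -> float:
        q = n2 / (n1 + n2)
        def pmf(k):
            return math.comb(x + k, k) * (q**k) * ((1 - q) ** (x + 1))
        lower = sum(pmf(k) for k in range(0, y + 1))
        upper = 1.0 - sum(pmf(k) for k in range(0, y))
        return min(1.0, 2 * min(lower, upper))

    worst = 0.0
    for x in range(0, max_count + 1, 5):
        for y in range(0, max_count + 1, 3):
            worst = max(
                worst,
                abs(count_significance(x, 2000, y, 3000) - brute(x, 2000, y, 3000)),
            )
    return worst


def type_i_error_study(
    seed: int, n_features: int = 10_000, depth: int = 200_000, alpha: float = 0.01
) -> dict:
    """Fraction of null features (equal true proportions in both
    libraries) called significant at alpha."""
    rng = np.random.default_rng(_derived_seed(seed, 97))
    w = rng.lognormal(0, 1, n_features)
    w /= w.sum()
    ca = rng.multinomial(depth, w)
    cb = rng.multinomial(depth, w)
    ps = np.array(
        [count_significance(int(a), depth, int(b), depth) for a, b in zip(ca, cb)]
    )
    return {
        "type_i_error": float((ps <= alpha).mean()),
        "alpha": alpha,
        "n_features": n_features,
    }


def nel_conservation_check(seed: int, n_reads: int = 50_000) -> dict:
    """Per-library NEL totals over all tags of a simulated run; each
    must equal 1e6 (reads-per-million is a partition of the library)."""
    cfg = SimulationConfig(n_reads=n_reads, seed=_derived_seed(seed, 13))
    data = build_genome(cfg)
    libs = simulate_libraries(data)
    clean = {
        lib: clean_reads(reads, cfg.adapter3, cfg.adapter5)
        for lib, reads in libs.items()
    }
    tags = collapse_tags(clean)
    worst = 0.0
    sums = {}
    for lib in clean:
        total = len(clean[lib])
        s = sum(normalize_nel(t.counts.get(lib, 0), total) for t in tags)
        sums[lib] = s
        worst = max(worst, abs(s - 1e6))
    return {"nel_sums": sums, "max_abs_deviation": worst}
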