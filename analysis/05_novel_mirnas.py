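"""Novel-miRNA evidence, two ways.

First: the MFEI cutoff (0.97) applied to the published novel-miRNA
table, and the set algebra of the published per-library counts
(55 + 63 with 31 shared -> 87 unique).  Second: the simulated pipeline's
recovered hairpins (from 02_run_pipeline.py) against the planted truth.
"""

from pathlib import Path

import pandas as pd

from mirskin import evaluation, tables

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"


def main() -> None:
    published = tables.novel_mfei_table()
    kept = evaluation.mfei_filter_count(0.97)
    union = evaluation.novel_union_from_published_sizes()
    print(f"published: MFEI range {published['mfei'].min():.4f}-"
          f"{published['mfei'].max():.4f}; cutoff 0.97 retains "
          f"{kept}/{len(published)} novel miRNAs")
    sizes = tables.NOVEL_SET_SIZES
    print(f"published set algebra: |white|={sizes['white']}, "
          f"|brown|={sizes['brown']}, shared={sizes['shared']} -> union {union}")

    novel = pd.read_csv(OUT / "pipeline" / "novel_mirnas.tsv", sep="\t")
    truth = pd.read_csv(OUT / "sim" / "truth.tsv", sep="\t")
    planted = set(truth.query("kind == 'novel'")["mature"])
    found = set(novel["mature"]) if len(novel) else set()
    print(f"simulation: {len(found)} hairpins pass all six criteria + MFEI; "
          f"{len(found & planted)}/{len(planted)} planted precursors recovered, "
          f"{len(found - planted)} false")


if __name__ == "__main__":
    main()
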