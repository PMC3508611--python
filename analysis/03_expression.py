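"""Differential expression, two ways.

First: recompute every fold change of the published white/brown skin
expression table from its printed NEL pairs and report how closely the
printed FC column is reproduced.  Second: compare the simulated
pipeline's differential calls (from 02_run_pipeline.py) against the
generator truth.
"""

from pathlib import Path

import pandas as pd

from mirskin import evaluation

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"


def main() -> None:
    check = evaluation.fold_change_table_check()
    rows = [
        {
            "mirna_id": mid,
            "fc_computed": round(fc, 4),
            "fc_printed": check["printed"][mid],
            "direction": d,
            "abs_diff": round(abs(fc - check["printed"][mid]), 6),
        }
        for mid, (fc, d) in check["computed"].items()
    ]
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "expression_table_check.tsv", sep="\t", index=False)
    print(f"published table: {check['n_rows']} rows, "
          f"{check['n_within_1e4']} reproduce the printed FC within 1e-4 "
          f"(max abs diff {check['max_abs_diff']:.4g}, "
          f"worst row {df.loc[df['abs_diff'].idxmax(), 'mirna_id']})")

    sim_truth = pd.read_csv(OUT / "sim" / "truth.tsv", sep="\t")
    called = pd.read_csv(OUT / "pipeline" / "differential.tsv", sep="\t")
    de_truth = set(
        sim_truth.query("kind == 'known' and fold_change >= 2")["id"]
    )
    called_ids = set(called["mirna_id"]) if len(called) else set()
    print(f"simulation: {len(called_ids)} miRNAs called differential; "
          f"{len(called_ids & de_truth)}/{len(de_truth)} planted FC>=2 recovered, "
          f"{len(called_ids - de_truth)} outside the planted set")


if __name__ == "__main__":
    main()
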