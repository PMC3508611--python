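"""Two-library differential expression of miRNA read counts, plus the
comparative-CT (Livak) qPCR quantities used to validate it.

Counts are normalised to NEL — normalised expression level, reads per
million clean reads — so per-library NEL sums to 1e6 over all features.
Fold change is the ratio of the higher-condition NEL to the lower (>= 1
by construction) with a direction label.  Significance of a count
difference between two libraries without replicates uses the
Audic–Claverie statistic: given x reads of a feature among N1 reads in
library 1, the posterior predictive distribution of its count y among N2
reads in library 2 is negative binomial,

    y | x  ~  NB(r = x + 1,  p = N1 / (N1 + N2)),

and the two-sided p-value doubles the smaller tail (capped at 1).
Benjamini–Hochberg FDR is reported alongside raw p-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .formats import CountTable


@dataclass
class ExpressionRecord:
    mirna_id: str
    nel: dict[str, float]  # library_id -> NEL
    fold_change: float
    direction: str  # library with the higher NEL
    p_value: float
    fdr: float | None = None
    counts: dict[str, int] = field(default_factory=dict)


def normalize_nel(count: int, total_clean_reads: int) -> float:
    """Reads-per-million-clean-reads normalisation."""
    if total_clean_reads <= 0:
        raise ValueError("total_clean_reads must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count / total_clean_reads * 1e6


def fold_change(
    nel_a: float, nel_b: float, labels: tuple[str, str] = ("a", "b")
) -> tuple[float, str]:
    """FC = max/min with the direction naming the larger side; equal
    values give FC 1.0 with direction labels[0]."""
    if nel_a < 0 or nel_b < 0:
        raise ValueError("NEL must be non-negative")
    if nel_a == 0 and nel_b == 0:
        raise ValueError("fold change undefined when both NEL are zero")
    if nel_b > nel_a:
        return nel_b / nel_a, labels[1]
    return (nel_a / nel_b if nel_b > 0 else math.inf), labels[0]


def count_significance(
    count_a: int,
    total_a: int,
    count_b: int,
    total_b: int,
    method: str = "audic-claverie",
) -> float:
    """Two-sided p-value for a count difference between two libraries.

    "audic-claverie" (default): negative-binomial form of the
    Audic–Claverie posterior predictive tail.  "ztest": classical
    two-proportion z-test (normal approximation), kept behind a flag for
    comparison.
    """
    if total_a <= 0 or total_b <= 0:
        raise ValueError("library totals must be positive")
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be non-negative")
    if method == "audic-claverie":
        r = count_a + 1
        p = total_a / (total_a + total_b)
        lower = stats.nbinom.cdf(count_b, r, p)
        upper = stats.nbinom.sf(count_b - 1, r, p)  # P(Y >= count_b)
        return float(min(1.0, 2.0 * min(lower, upper)))
    if method == "ztest":
        p1, p2 = count_a / total_a, count_b / total_b
        pool = (count_a + count_b) / (total_a + total_b)
        se = math.sqrt(pool * (1 - pool) * (1 / total_a + 1 / total_b))
        if se == 0:
            return 1.0
        z = (p1 - p2) / se
        return float(2 * stats.norm.sf(abs(z)))
    raise ValueError(f"unknown method {method!r}")


def score_expression(
    table: CountTable,
    totals: Mapping[str, int],
    lib_a: str,
    lib_b: str,
    method: str = "audic-claverie",
) -> list[ExpressionRecord]:
    """Build ExpressionRecords for every feature of a two-library count
    table.

    Features with zero counts in both libraries are skipped (fold change
    undefined).  A zero in one library gets a reporting-only pseudo-NEL
    of half the smallest nonzero NEL across the table; the significance
    test always sees the raw counts.
    """
    n_a, n_b = totals[lib_a], totals[lib_b]
    nonzero_nels = [
        normalize_nel(c, totals[lib])
        for row in table.counts.values()
        for lib, c in ((lib_a, row[lib_a]), (lib_b, row[lib_b]))
        if c > 0
    ]
    pseudo = min(nonzero_nels) / 2 if nonzero_nels else 0.0
    p_values: list[float] = []
    records: list[ExpressionRecord] = []
    for fid in sorted(table.counts):
        row = table.counts[fid]
        ca, cb = row[lib_a], row[lib_b]
        if ca == 0 and cb == 0:
            continue
        nel_a = normalize_nel(ca, n_a)
        nel_b = normalize_nel(cb, n_b)
        fc, direction = fold_change(
            nel_a if ca > 0 else pseudo,
            nel_b if cb > 0 else pseudo,
            labels=(lib_a, lib_b),
        )
        p = count_significance(ca, n_a, cb, n_b, method=method)
        p_values.append(p)
        records.append(
            ExpressionRecord(
                mirna_id=fid,
                nel={lib_a: nel_a, lib_b: nel_b},
                fold_change=fc,
                direction=direction,
                p_value=p,
                counts={lib_a: ca, lib_b: cb},
            )
        )
    if records:
        fdr = stats.false_discovery_control(p_values, method="bh")
        for rec, q in zip(records, fdr):
            rec.fdr = float(q)
    return records


def call_differential(
    records: Iterable[ExpressionRecord],
    min_fc: float = 2.0,
    alpha: float = 0.01,
) -> list[ExpressionRecord]:
    """Keep records with fold change >= min_fc and p <= alpha, sorted by
    (direction, descending fold change, id) — record-order invariant."""
    kept = [r for r in records if r.fold_change >= min_fc and r.p_value <= alpha]
    return sorted(kept, key=lambda r: (r.direction, -r.fold_change, r.mirna_id))


def records_to_frame(records: Sequence[ExpressionRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"mirna_id": r.mirna_id}
        for lib, v in r.nel.items():
            row[f"nel_{lib}"] = v
        row.update(
            fold_change=r.fold_change,
            direction=r.direction,
            p_value=r.p_value,
            fdr=r.fdr,
        )
        rows.append(row)
    return pd.DataFrame(rows)


# --- comparative-CT (Livak) qPCR quantification -------------------------


def ddct_relative_quantity(
    ct_target: float,
    ct_reference: float,
    ct_target_calibrator: float,
    ct_reference_calibrator: float,
) -> float:
    """RQ = 2^-ddCT with ddCT = (CT_target - CT_ref)_sample -
    (CT_target - CT_ref)_calibrator."""
    for v in (ct_target, ct_reference, ct_target_calibrator, ct_reference_calibrator):
        if not math.isfinite(v):
            raise ValueError("CT values must be finite")
    ddct = (ct_target - ct_reference) - (ct_target_calibrator - ct_reference_calibrator)
    return 2.0 ** (-ddct)


def analyze_qpcr(
    ct: pd.DataFrame,
    reference_assay: str = "U6",
    calibrator_condition: str | None = None,
) -> pd.DataFrame:
    """Per-sample relative quantities from a long CT table with columns
    (sample, condition, assay, ct), normalised to the reference assay and
    calibrated to the mean dCT of the calibrator condition (default: the
    lexicographically first condition)."""
    required = {"sample", "condition", "assay", "ct"}
    if not required.issubset(ct.columns):
        raise ValueError(f"CT table must have columns {sorted(required)}")
    wide = ct.pivot_table(
        index=["sample", "condition"], columns="assay", values="ct"
    ).reset_index()
    if reference_assay not in wide.columns:
        raise ValueError(f"reference assay {reference_assay!r} absent from CT table")
    conditions = sorted(wide["condition"].unique())
    calibrator = calibrator_condition or conditions[0]
    if calibrator not in conditions:
        raise ValueError(f"calibrator condition {calibrator!r} absent")
    assays = [c for c in wide.columns if c not in ("sample", "condition", reference_assay)]
    rows = []
    for assay in assays:
        dct = wide[assay] - wide[reference_assay]
        cal = dct[wide["condition"] == calibrator].mean()
        rq = 2.0 ** (-(dct - cal))
        for sample, cond, v in zip(wide["sample"], wide["condition"], rq):
            rows.append(
                {"assay": assay, "sample": sample, "condition": cond, "rq": float(v)}
            )
    return pd.DataFrame(rows)


def qpcr_fold_changes(rq: pd.DataFrame) -> pd.DataFrame:
    """Condition-level RQ per assay (geometric mean — CT data are
    log-scale, so ratios average geometrically) and the FC between the
    two conditions (higher over lower, with direction)."""
    out = []
    for assay, grp in rq.groupby("assay"):
        means = grp.groupby("condition")["rq"].apply(
            lambda v: float(2.0 ** np.mean(np.log2(v)))
        )
        if len(means) != 2:
            raise ValueError("expected exactly two conditions")
        (c1, v1), (c2, v2) = means.items()
        fc, direction = fold_change(v1, v2, labels=(c1, c2))
        out.append(
            {
                "assay": assay,
                **{f"mean_rq_{c}": float(v) for c, v in means.items()},
                "fold_change": fc,
                "direction": direction,
            }
        )
    return pd.DataFrame(out)
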