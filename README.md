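# mirskin

Small-RNA sequencing analysis of miRNA expression in white versus brown
alpaca skin, rebuilt as a tested, reusable Python pipeline. The package is
for anyone who wants to reproduce, audit or extend this class of two-library
small-RNA study: read cleaning and tag collapsing, hierarchical class
annotation, conserved-miRNA identification with isomiR and arm-usage
analysis, count-based differential expression with stem-loop RT-qPCR
validation, rule-based novel-miRNA hairpin prediction, and duplex-rule
target prediction — plus a synthetic-data generator that replaces the
original raw libraries with desk-scale libraries of known truth.

## The analysis in brief

Raw reads are trimmed of the 3′ adapter, filtered (quality, N bases, 5′
adapter contaminants, 18–30 nt length window) and collapsed into unique
**tags** carrying per-library counts. Tags are assigned one small-RNA class
by the priority rule GenBank ncRNA > Rfam ncRNA > known miRNA > repeat >
exon > intron. Tags aligning to a known-mature catalogue with ≤ 2
mismatches (or > 90 % identity) are **conserved miRNAs**, grouped into
families by name stem.

Expression uses **NEL** (normalised expression level, reads per million
clean reads); per-miRNA fold change is FC = max(NEL)/min(NEL) with the
direction naming the enriched condition, and significance of a count
difference between the two unreplicated libraries is the Audic–Claverie
posterior predictive tail: the count *y* of a feature observed *x* times
among *N₁* reads follows, in a library of *N₂* reads,

    y | x  ~  NegBin(r = x + 1,  p = N₁ / (N₁ + N₂)),

two-sided by doubling the smaller tail. Calls require FC ≥ 2 and p ≤ 0.01.
qPCR validation uses the comparative-CT method, RQ = 2^−ΔΔCT against a U6
snRNA reference.

**Novel miRNAs**: genomic flanks of unannotated, genome-mapped tags are
folded (ViennaRNA by default; a built-in base-pair-energy DP otherwise) and
kept when the six candidacy criteria hold — mature 20–24 nt on a stem arm;
≥ 5 reads; MFE ≤ −18 kcal/mol; bulge ≤ 4 nt; mature/star length difference
≤ 5 nt with ≤ 35 nt spacing; duplex asymmetry ≤ 5 nt — and the minimal
folding free energy index

    MFEI = (|MFE| / length × 100) / GC%

is ≥ 0.97 (high MFEI separates miRNA precursors from tRNA/rRNA/mRNA).
**Target sites** are ungapped antiparallel duplexes scored per position
(Watson–Crick 0, G:U wobble 0.5, other 1) passing: total ≤ 4; none at
positions 10–11; no run of ≥ 3 within 2–12; ≤ 2.5 within 1–12; duplex
energy ≥ 75 % of the perfect complement.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (each regenerates what it needs under `results/`):

```bash
python analysis/01_simulate.py
python analysis/02_run_pipeline.py
python analysis/03_expression.py
```

which prints

```
planted: 30 known miRNAs (10 with FC >= 2), 10 novel precursors, 5 decoy loci
libraries: white (50000 reads), brown (50000 reads)
...
  preprocess   41375 rows
  conserved    986 rows
  diffexpr     10 rows
  novel        10 rows
...
published table: 48 rows, 47 reproduce the printed FC within 1e-4 (max abs diff 0.0008843, worst row miR-143)
simulation: 10 miRNAs called differential; 10/10 planted FC>=2 recovered, 0 outside the planted set
```

i.e. the pipeline recovers every planted fold change with no false calls,
and recomputing the published expression table from its printed NEL pairs
reproduces 47 of 48 printed fold changes to the printed precision (the
miR-143 row of the source table is internally inconsistent by ~9 × 10⁻⁴).
Scripts 04–06 profile isomiR end heterogeneity (3′ ends vary more than 5′),
arm switching, novel-hairpin recovery, and ΔΔCT validation of the fold
changes. The same stages are available as a CLI (`mirskin simulate`,
`mirskin preprocess`, …, `mirskin run --config run.yaml`).

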