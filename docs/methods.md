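# Methods

This note documents the models and procedures the package implements, the
defaults and why they hold, what the synthetic generator does and does not
emulate, and the numerical choices a maintainer would want written down.

## Read cleaning and tags

Reads are trimmed at the leftmost occurrence of the 3′ adapter, located by
an exact ≥ 6 nt prefix seed whose extension must match the adapter exactly
for as much of it as fits in the read. Reads with no locatable 3′ adapter
are discarded: the insert is then presumed longer than the read and
therefore beyond the 30 nt ceiling. Reads containing the 5′ adapter
(ligation artefacts), any N, or — when qualities are present — any base
below Q20 are discarded, as are inserts outside 18–30 nt. Adapter
sequences are configuration inputs; the shipped defaults are the standard
Illumina small-RNA adapters. Cleaning is filtering, never failure: raw =
clean + dropped per library, and collapsing the clean multiset into unique
tags conserves counts exactly (both are tested invariants).

## Annotation

One class per tag, resolved in the fixed priority order GenBank ncRNA >
Rfam ncRNA > known miRNA > repeat > exon > intron, so rRNA/tRNA
degradation fragments are never double-counted as miRNA. A match is the
tag occurring as an exact substring of a reference record on either strand
(degradation-fragment logic); the mismatch allowance is configurable but
defaults to 0. GenBank and Rfam ncRNA are two separate reference sets so
the printed precedence is honoured. Exons and introns are sequence sets
here, not genomic intervals; repeat sequences are a user-supplied set.
Classification is independent of tag order and of reference file order;
ties inside a category report the lexicographically smallest reference id
(reporting only).

## Conserved miRNAs, isomiRs, arms

Conservation requires an ungapped alignment to a known-mature catalogue
with mismatches ≤ 2 **or** identity > 0.90 — the inclusive reading of the
two published thresholds, which are not mutually consistent otherwise
(identity is matched positions over the aligned length, and for 18–30 nt
tags the identity rule never admits more than 2 mismatches anyway).
Alignment slides the shorter sequence fully along the longer one, so
3′/5′-extended isomiRs still match. Each tag keeps its best hit (fewest
mismatches, then highest identity, then smallest id). The production
matcher verifies only (catalogue entry, offset) pairs sharing an exact
seed word with the tag; pigeonhole over the mismatch budget makes this
exactly equivalent to the all-offsets scan, and a test asserts the
equivalence. Family names strip species prefix, star mark, -5p/-3p arm,
duplicate-locus number and trailing letter variants (let-7a → let-7,
miR-124b → miR-124).

IsomiR profiles key reads mapping exactly inside a precursor by their
(5′, 3′) end offsets against the annotated mature; the predominant isoform
is the highest-count one. Arm usage assigns each read to the 5p or 3p arm
by its midpoint relative to the terminal loop of the computed structure
(loop reads are ignored; loop-only precursors give no call) and flags a
switch when the dominant arm differs from the annotated one, with ties
resolved to the annotated arm.

## Differential expression and qPCR

NEL is reads per million clean reads — the convention consistent with the
magnitudes of the published expression table, which does not define its
normalisation. Per-library NEL sums to 10⁶ over all tags (tested).
Fold change is max/min with a direction label; a feature counted in only
one library receives a reporting-only pseudo-NEL of half the smallest
nonzero NEL, and features absent from both are skipped.

The significance test for one pooled library per condition is
Audic–Claverie, evaluated through its negative-binomial identity
(y | x ~ NB(x + 1, N₁/(N₁+N₂))) with scipy, two-sided by doubling the
smaller tail and capping at 1; a brute-force term-by-term summation of the
published formula is kept in the tests as the independent oracle (they
agree to < 10⁻¹⁴). Measured type-I error at α = 0.01 on null simulations is
≈ 0.006 — conservative, as expected for a discrete test. A two-proportion
z-test is available behind a flag. Benjamini–Hochberg FDR is reported
alongside raw p-values; calls use raw p ≤ 0.01 and FC ≥ 2, matching the
published table's thresholds.

ΔΔCT quantification is the Livak closed form RQ = 2^−ΔΔCT against a
reference assay (U6 snRNA) and a calibrator condition; condition-level RQs
are combined by geometric mean, since CT data live on a log₂ scale. No
amplification-efficiency correction is applied beyond the Livak
assumption.

One data caveat carried over from the source study: its prose describes
miR-211 as higher in white skin on both platforms while its expression
table lists miR-211 as brown-enriched; the shipped table follows the
printed table. The printed FC of the miR-143 row (2.2461) is also
inconsistent with its own printed NEL pair (which gives 2.2470); the
package reproduces 47/48 rows to the printed precision and the
discrepancy is surfaced, not patched. The published novel-miRNA table
lists one sequence twice with two different MFEI values; both rows are
kept (the second id is disambiguated with a "b" suffix) and names are
never used as join keys.

## Novel-miRNA prediction

Candidate discovery: tags not annotated to any class and not matching the
mature catalogue, with ≥ 5 reads in the library, are mapped exactly to the
genome (plus strand preferred for determinism); mapped tags are clustered
into loci (starts within 30 nt) and the most abundant tag of a locus is
the putative mature. Both ±100 nt flank windows are folded (the mature may
sit on either arm); the candidate precursor is then trimmed to the
stem-loop enclosing the mature — the span of its pairing partners plus a
6 nt pad — and refolded. Without this trimming, MFEI would be diluted by
arbitrary window flanks and the 0.97 cutoff would not be meaningful; the
trimming mirrors what dedicated hairpin predictors do.

The six criteria are evaluated on the trimmed fold: (1) mature 20–24 nt,
on a single arm, with ≥ 60 % of its bases paired; (2) mature read count
≥ 5; (3) MFE ≤ −18 kcal/mol; (4) longest unpaired run inside the mature
≤ 4 nt; (5) |mature − star| length difference ≤ 5 nt and mature–star
spacing ≤ 35 nt — the reading adopted for the cryptic published
"5 nucleotides and 35 nucleotides" bound; (6) duplex asymmetry (difference
in unpaired residues between the two sides) ≤ 5 nt. The star is inferred
from the pairing partners of the mature with the canonical 2 nt 3′
overhang. A candidate with no detected stem keeps its flags (stem
criteria failed) rather than being silently dropped. Candidates are
deduplicated across libraries by exact mature sequence, and the MFEI ≥
0.97 filter is applied after merging the two libraries, matching the
published "22 novel miRNAs present in the two libraries" accounting. MFEI
uses |MFE| so values are positive. All boundary conditions (20 vs 19 nt,
count 5 vs 4, −18.0 vs −17.9, MFEI 0.97 vs 0.9699) are tested at the
boundary.

Folding: the contract is a deterministic MFE dot-bracket. The default
engine is ViennaRNA's Python bindings; the built-in fallback is a
Nussinov-style DP over per-pair energies (GC −3, AU −2, GU −1, minimum
loop 3) with a fixed-preference traceback, adequate for the ordering
properties the pipeline needs (hairpins fold lower than non-hairpins) but
not for absolute thermodynamics. Published MFEI values are therefore never
reproduced *through* folding — only the MFEI arithmetic and filter counts
are checked against the published table.

## Target prediction

Duplexes are ungapped and antiparallel with position 1 at the miRNA 5′
end; site length equals miRNA length. Watson–Crick pairs weigh 0, G:U
wobbles 0.5, others 1. "No more than two adjacent mismatches in 2–12" is
read as: no run of ≥ 3 consecutive positions with weight ≥ 0.5 in 2–12.
The energy model is per-pair (GC −3, AU −2, GU −1, mismatch 0); the 75 %
criterion is a ratio of duplex to perfect-complement energy, so any
internally consistent model honours it, and the perfect complement scores
exactly 1. Scanning is sense-strand only (inputs are mRNA/3′UTR
sequences); whether full cDNA or 3′UTRs are scanned is the caller's
choice. Every rule quantity is re-derivable: the tests compare the scanner
window-for-window against a brute-force re-implementation.

## Synthetic data: what it emulates, what it does not

The generator plants 30 known miRNAs (two of them arm-switched) and 10
novel precursors in a toy genome, with 5 AT-rich decoy loci that attract
reads but fold badly. Every planted precursor is verified at build time to
pass the six criteria with margin (MFE ≤ −20, MFEI ≥ 1.02) under the
configured engine — the margins absorb the few flanking bases precursor
trimming may move — and every planted mature must occur exactly once in
the genome; violations trigger redesign. Star arms carry two interior
substitutions relative to the perfect complement, as real miRNA/miRNA*
duplexes do; a perfect star would also plant an exact reverse complement
of the mature and create a spurious second mapping locus.

Libraries are multinomial draws (one pooled library per condition exists
in this design, so there is no replicate dispersion to emulate) over:
known miRNAs (40 % of reads), novel miRNAs (6 %), ncRNA/repeat/exon/intron
contaminant fragments (30 %), decoys (2 %), random background (20 %), and
2 % junk reads that the cleaner must remove (N-containing, low-quality,
5′-adapter). Planted fold changes span 2.5–48× in both directions, placed
on a 1/√FC abundance base so large fold changes sit on low-abundance
miRNAs, as in the real expression table; a single normaliser across both
libraries keeps realized fold changes exactly nominal, with the
per-library mass deficit absorbed by the background class. miRNA reads
carry end noise biased to the 3′ end (5′ offset 0/−1/+1 at 0.90/0.05/0.05;
3′ offset 0/±1/±2 at 0.70/0.10/0.10/0.05/0.05) and per-base substitution
errors at 10⁻³, a typical post-quality-filter rate. Reads are 36 nt of
insert + 3′ adapter with Phred+33 qualities. The qPCR table sets
CT_target = base − log₂(relative abundance) + noise against a noisy
reference, so ΔΔCT analysis recovers planted fold changes within noise
(exactly, at zero noise).

Not emulated: Illumina quality-score profiles and error spectra (errors
are uniform substitutions), sequencing at the study's real 1.7–1.9 × 10⁷
depth (defaults are 10⁵ reads per library; the recovery studies use that
scale, chosen to keep a 20-replicate study around a minute), multi-locus
miRNA families, RNA editing, and cross-mapping between paralogues.
Passing the recovery tests therefore shows the pipeline's logic is
correct under a faithful but idealised read model — not that the original
study's exact counts (272/267 conserved, 35/13 differential) would be
reproduced, which would require the original libraries, the contemporary
miRBase catalogue, and the original folding software.

## Numerical and design choices

* Percentages are reported rounded to two decimals (the published
  convention); all internal arithmetic is unrounded.
* Exact substring matching uses a k-mer index contracted (and tested) to
  agree with the naive scan; mismatch-tolerant matching falls back to the
  naive scan and is intended for desk-scale references.
* Best-hit, clustering, and tie-break rules are all total orders
  (count, then sequence; mismatches, then identity, then id), so every
  stage is independent of input order — a tested invariant.
* Fold-change direction ties (exactly equal NEL) resolve to the first
  label; fold changes with a zero side are reported from a half-minimum
  pseudo-NEL and never enter the significance test.
* The pipeline manifest records a SHA-256 config digest and per-stage row
  counts; reruns with the same config are byte-identical.

## Known limitations

Annotation and genome matching are exact-match by default: a read with a
sequencing error in an annotated region falls through to lower classes or
to unannotated (at the default error rate this shifts class frequencies by
under ~2 percentage points, which the class-recovery test tolerance
covers). The conserved matcher is ungapped; indel isomiRs would need the
gapped flag. The Nussinov fallback's energies are not thermodynamic.
Target prediction has no conservation filter and no accessibility model,
matching the scope of the original rule set.
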