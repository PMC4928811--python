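# Methods

## Scope and data model

The pipeline consumes search-engine PSM exports, protein FASTA, gene-region
FASTA + BED and per-gene differential-expression (DE) tables, and produces
consensus comparisons, pattern statistics, digestion-coverage maps,
direct-repeat calls and regulated-gene comparisons. Spectral database
searching, phosphosite-probability computation, read alignment and the
negative-binomial DE model are upstream of this pipeline: their outputs
(scores, FDR flags, localization probabilities, fold-changes and p-values)
are inputs here. BH adjustment is provided as a utility so DE tables may
carry raw p-values only.

All coordinates are 0-based half-open internally; human-facing phosphosite
positions are 1-based (the "S77" convention). PSM tables use a
package-defined TSV schema (documented in `tables_io.PSM_COLUMNS`) with a
column-mapping option, because vendor export schemas vary and none is
assumed. `X` in a protein sequence never matches a cleavage residue, is
never a phosphosite, and makes a peptide's mass undefined (such peptides
fail any mass window).

## Filtering and calling

Two confidence paths mirror practice: an upstream 1% target–decoy FDR flag
(used for whole-extract data) or a per-charge score floor
{z1: 1.5, z2: 2.5, z3: 3.0, z≥4: 3.2} (used when the dataset is too small
for FDR estimation, e.g. immunoprecipitation runs). Rank 1 is required on
both paths. Rejections are tallied under exactly one reason with rank
checked first, making the tally a partition of the input — a reproducibility
choice, since a row can fail several criteria at once.

"Identified" means ≥ 2 *distinct peptide sequences* in a sample;
modification state is ignored for distinctness (the criterion's intent is
independent sequence evidence). A phosphoprotein additionally needs ≥ 1
phosphopeptide and must already be identified: phosphopeptides on
non-identified proteins are discarded.

Localization: events at probability ≥ 0.99 keep their residue; lower events
become `ambiguous` but are retained, so multiplicity counts and the residue
distribution's denominator include them. Site deduplication across peptides
covering the same residue keeps the highest localization probability.

## Consensus order

Totals are the 4-way intersection over {R1, R2} × {vehicle, RA}.
Phosphoproteins are intersected over replicates *within* each condition and
then crossed with the consensus totals — not intersected across conditions —
because condition-specific phosphorylation is exactly the signal of
interest; a 4-way intersection would erase the − and + classes. Each
condition's phosphoproteins are crossed with the all-condition totals (the
natural common reference; the source material does not fully specify this
step). Percentages are rounded to the nearest integer, half away from zero,
matching how such tables are reported.

## Site classes

The P/A/B classes are implemented with the standard kinase-motif reading:
proline-directed (P at +1; CDK/MAPK-type SP), acidic (D/E at +1; SD/SE),
basic (K/R at −3 or −2; PKA/PKC-type), precedence P > A > B, neighbors off
the sequence end treated as non-matching. The exact windows are
convention-dependent, so `SiteClassRule` makes offsets and residue sets
configurable; the default is a documented convention, not a claim about any
particular annotator's rule.

## Digestion

Enzymes are (residue set, terminus) rules; the engine enumerates all
fragments with ≤ `max_missed` internal uncut sites (default 2), ordered by
coordinates. Thermolysin defaults to N-terminal cleavage of V/A/M/I/L/F —
the biochemically standard description — with the C-terminal variant
available through the `terminus` field, since both conventions circulate.
No proline-suppression rule is applied to trypsin. Masses are monoisotopic
(pyteomics residue masses + water), with the phospho shift fixed at
+79.96633 Da. The detectable window defaults to length 7–35 and mass
500–5000 Da — a typical acquisition range, configurable because no single
range is canonical. Coverage is the union of detectable peptides; a site is
"embedded" when covered. Coverage is non-decreasing as windows widen or
missed cleavages grow (tested as a property).

## RARE scanning

Half-sites match `[AG]G[GT]T[CG]A` on the forward strand and its reverse
complement pattern for minus-strand sites; overlapping matches are all
reported and `N` never matches. Soft-masked bases are uppercased by default
(`respect_mask` excludes them). A direct repeat is an ordered same-strand
pair with spacer 0–10 nt (DR0 = abutting, the standard DR nomenclature);
mixed-strand (everted/inverted) arrangements are out of scope. On the minus
strand the "first" half-site is the 5'-most in minus-strand reading order.
Windows are per gene, the gene limits ± 10 kb by default, clipped at
sequence ends; `tss_only` anchors the window at the strand-aware TSS
instead, since both windowing conventions are plausible readings of the
protocol. The summary reports both repeat counts and genes-with-repeat
fractions per spacing, because the two frequencies answer different
questions; a repeat inside two genes' windows counts once per gene.

## Regulated genes

Thresholds are strict inequalities exactly as printed (|log2FC| > 1,
adjusted p < 0.05); boundary ties are excluded. BH adjustment delegates to
`statsmodels.multipletests(method="fdr_bh")`; the test suite checks it
against a literal transcription of the step-up formula. The cross-line
comparison partitions the union of regulated genes into six sets (exclusive
up/down per line, shared concordant, shared discordant) whose percentages
are relative to each line's own regulated total.

## Synthetic data

The generator emulates the study design — 2 cell lines × 2 conditions
(vehicle/RA) × 2 replicates × 2 fractions (cytosolic/nuclear) — with known
truth:

* **Proteomes** are concatenations of peptide units (K/R-terminated
  segments, no internal K/R except where a basic-class site plants one), so
  every peptide's sequence and offset are known. Phosphosites are planted
  inside designated units with residue and motif class forced by writing the
  ±neighborhood (P at +1 for class P; D/E at +1 for A; K/R at −3 plus a
  neutral +1 for B; scrubbed neighbors for "other"), sites ≥ 6 residues
  apart so neighborhoods never interact. Multiplicity (sites per unit),
  residue and class are independent draws from configured mixes — the mixes
  are exact sampling targets, which is what makes the 3-standard-error
  recovery tests meaningful.
* **Defaults** follow the reported phosphoproteome composition: residue
  marginal S/T/Y/ambiguous = 0.70/0.05/0.004/0.246 (S/T/Y rescaled
  conditional on localization, so the recovered marginal serine share is
  ~70%), multiplicity 1P/2P/3P = 0.70/0.25/0.05. Class mix defaults to
  P/A/B/other = 0.40/0.30/0.15/0.15, proline-directed and acidic dominant.
  Detection is independent per (protein, sample) at p = 0.8 — a typical
  shotgun replicate-overlap regime and the value used in the recovery tests
  (both-replicate fraction 0.64). Scores are drawn from pass/fail normal
  components per charge state and known-bad rows (rank 2, or sub-threshold
  score with a cleared FDR flag) can be injected at configured fractions and
  are counted in the truth, giving filter tallies exact expectations.
* **Gene regions** are rejection-sampled to be motif-free before planting
  concrete half-site pairs at recorded positions/spacings/strands, with ≥ 12
  nt separation between planted elements so no cross-element repeat can
  arise; the final sequence is re-scanned and planting is retried until
  recovery is exact by construction.
* **DE tables** give regulated genes |log2FC| in [1.5, 4] and p in
  [1e-8, 1e-4], and null genes |log2FC| < 0.8 with uniform p, so threshold
  selection recovers the planted labels exactly; the overlap and
  concordance structure between the two synthetic lines is configurable.
* **Determinism**: every generator seeds `default_rng([seed, stream_id])`
  with a fixed per-generator stream id, so outputs are byte-identical for a
  seed and stages can be regenerated independently.

What the generator does *not* emulate: spectral noise and intensity models,
chromatographic effects, peptide-level detectability bias, correlated
detection across related proteins, shrunken fold-changes, or the published
identification counts themselves (the underlying raw data are not public,
so those counts are not a recoverable target). Passing tests therefore
demonstrate correctness of the analysis logic under the stated sampling
assumptions, not performance on real spectra.

## Problem sizes and numerics

The test and verification runs use deliberately modest sizes chosen to make
sampling checks well-powered while keeping runs quick: 200 random proteins
(length ≤ 50) for digestion-oracle equivalence; 50 random 5-kb sequences
for scanner-oracle equivalence; 5 planted repeats per spacing DR0–DR10; a
2000-protein proteome for detection-probability recovery; ≥ 10⁴ planted
sites for mix recovery; 2000-gene DE tables. Statistical recovery tests use
3 binomial standard errors with the n of the actual comparison unit
(planted sites for residue mixes, distinct units for multiplicity, emitted
events for the ambiguity share), since repeated emissions of one planted
site are not independent draws of its residue.

Tolerances elsewhere are exact: set algebra, digestion, scanning and BH
adjustment are discrete computations compared for equality; masses are
compared at 1e-4 Da.

## Known limitations

* The FDR flag is consumed, never recomputed; no target–decoy machinery.
* Peptide-to-protein assignment is taken from the input; shared peptides
  and protein grouping are not modeled.
* The scanner does no PWM scoring or conservation filtering; a "perfect
  consensus" match is binary.
* GO/functional enrichment and motif-enrichment analyses are out of scope.
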