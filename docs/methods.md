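# Methods

This note documents the models, conventions and numerical choices behind the
`cpdaa` package, in the spirit of a statistical-software methods appendix.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinate and naming conventions

All protein positions are 1-based and inclusive (Cys333 means the 333rd
residue).  The 20-letter amino-acid alphabet is enforced at ingest;
selenocysteine (U) and ambiguity codes are rejected because no probe
chemistry is defined for them, while X is tolerated with a warning.  The
standard nuclear genetic code is the only one supported.  All tabular IO is
tab-separated UTF-8 with a header row and no quoting.

## Chemoproteomics QC

Peptide-level records carry modification marks as an asterisk immediately
after the modified residue (`MAC*ALRY`); the mark parser is pluggable.
Filters, applied in order and reported as a partition (kept + rejected =
input, with exhaustive reason codes):

1. exactly one modified residue per peptide (`multi_modified` otherwise);
2. clean peptide length in [6, 45] inclusive (`too_short` / `too_long`);
3. replication — at least two observations of the (accession, position)
   residue, counting one per (experiment, peptide) record (`singleton`);
4. sequence verification — the residue letter at the claimed position of
   the canonical sequence must equal the claimed residue type
   (`mismatch`; unknown accessions are `unmapped`).  Verification is a hard
   gate before any residue-level join.

R10:1 reactivity ratios are averaged per residue with a plain arithmetic
mean over non-missing values (no winsorizing); per-probe means are kept
alongside the pooled mean because pooling across probe chemistries is a
genuinely open choice.  Categories: high (R10:1 ≤ 2), medium (2, 5],
low (> 5); residues observed only in experiments without reactivity ratios
are `undetermined` rather than dropped.

## Variant classes

Classes are mutually exclusive with clinical assertions outranking
frequency: pathogenic (incl. likely pathogenic, switchable) >
benign_common (incl. likely benign) > VUS > frequency bins.  Unlabeled
variants with allele frequency strictly greater than 0.05 form the common
(`background`) bin; unlabeled rare bins default to rare (AF < 1e-3) and
rarest (AF < 1e-5), both configurable.  Unlabeled variants with
1e-3 ≤ AF ≤ 0.05 fit no class and are carried with class `none`, excluded
from class-based analyses.  Alleles asserted both pathogenic and benign are
conflicts: reported separately, excluded from analysis.  The *background
comparator set* used by the enrichment analyses is benign_common ∪ common,
chosen over clinically-benign-only because benign assertions alone are too
sparse to be a stable denominator.

## Fisher exact statistics

Every 2×2 enrichment uses the conditional (hypergeometric) two-sided exact
test: the p-value sums the probabilities of all tables with the observed
margins that are no more probable than the observed table.  The reported
odds ratio is the sample cross-product ad/bc.  When any cell is zero, the
Haldane–Anscombe correction adds 0.5 to all four cells before the OR and CI
are computed and the result is flagged `zero_cell`; a table with an
all-zero row or column is additionally flagged `undefined`.  The 95% CI is
the Woolf logit interval exp(log OR ± 1.96·se), se² = Σ 1/cell (corrected
cells when the correction applies).  Within an analysis panel, p-values are
Bonferroni-adjusted with the panel size as the family size; the
nearest-distance comparisons use Benjamini–Hochberg FDR instead, matching
the convention of distance-distribution testing.

Rank-sum comparisons use the two-sided Wilcoxon–Mann–Whitney test: exact
enumeration when both samples have ≤ 50 observations and no ties,
tie-corrected normal approximation otherwise (exact enumeration under ties
is not available in the backing implementation; the fallback is recorded
here as the package's behavior).

## 1D proximity

Distances are |Δposition| between a variant and a CysLysTyr site of the
same protein.  Direct overlaps (distance 0) are excluded from window counts
and from nearest-distance statistics, because sites directly overlapping
variants would otherwise inflate apparent proximity.  Windows are ±6
residues by default (3 and 15 supported), truncated at protein termini
rather than discarded — discarding would bias against short proteins.  The
uniqueness unit for burden counts is the distinct (position, alt_aa) allele
per class.  Sites in proteins with no variant of the tested class still
contribute "not containing" rows: absence is information.

Two counting units are provided for the window odds ratio:

* **window containment** (default): 2×2 {detected vs undetected window} ×
  {contains ≥ 1 variant of the class vs not};
* **variant level**: 2×2 {variant of the class vs baseline class} ×
  {position within 1..6 of a detected site vs not}.

The variant-level unit is the one under which the synthetic generator's
placement odds multiplier is the true odds ratio exactly (see below), so
parameter-recovery checks assert on it; the containment unit is the
default reporting statistic.

## 3D environments

Distances are measured from the residue-type terminal side-chain atom —
SG (cysteine sulfhydryl sulfur), NZ (lysine side-chain nitrogen), OH
(tyrosine phenolic oxygen) — to all atoms of every other mapped residue;
the per-residue minimum is stored (Å, 3 decimals) up to a 10 Å boundary and
sliced to 6/8 Å cutoffs, so 6 Å ⊆ 8 Å ⊆ 10 Å nesting holds by
construction.  8 Å is the primary cutoff (the standard contact-analysis
range).  Parsing uses model 1, the first alternate location, no waters,
no hetero groups, no hydrogens (hydrogens would make results
resolution-dependent).  Residues from *other chains* of the assembly are
included — interface neighbors are exactly the interesting case for
oligomeric proteins — with chain provenance recorded; any chain copy of the
anchor's own sequence position is excluded.  Sequence↔structure map rows
whose residue identities disagree (`aa_match` false) are dropped.  Across
multiple structures of one protein, neighbor sets are unioned keeping each
position's minimum distance; the same rule covers multiple assemblies.
Because per-allele vs per-position counting is ambiguous when one position
carries several alleles, both burden statistics are emitted (allele-level
is primary).  Type enrichment compares deduplicated CpDAAs, not
per-structure environments.

VUS ranking sorts by allele-level VUS burden, ties broken by (accession,
position) ascending — an arbitrary but deterministic rule.  Burden
clustering row-centers the count matrix (no unit-variance scaling) and cuts
an average-linkage Euclidean dendrogram at two groups; the group with the
larger mean total burden is "high".  Identical rows make the cut degenerate
and are flagged.  The candidate filter is the conjunction of five boolean
criteria: pathogenic *and* common/benign variants present, a structure
available, length < 1,000 residues, a variant inside some CpDAA
environment, and chemoproteomic detection.

## Synthetic-data generator

The generator emulates the statistical structure the analyses assume, not
protein biophysics:

* **Proteome** — sequences drawn i.i.d. from mean human proteome amino-acid
  frequencies (Cys 2.3%, Lys 5.7%, Tyr 2.7%); lengths uniform in 200–600 by
  default; coding sequences back-translated with uniform codon choice.
* **Detection** — each C/K/Y site is detected independently with
  per-type probabilities 0.14 / 0.042 / 0.027, matching the detected
  fractions of the real analysis set; reactivity categories mixed 10% high /
  30% medium / 60% low, with the planted value shared by all replicates so
  ingest recovers it exactly.  Deliberate decoys violating each QC filter
  are spiked in at a configurable fraction.
* **Window plant** — pathogenic positions are drawn by *rejection sampling*
  with weight `planted_window_or` inside the ±6 zone of detected sites and
  1 outside, so the variant-level placement odds ratio equals the
  multiplier exactly by construction rather than asymptotically.  The
  window-containment OR is only approximately equal to it because windows
  overlap (a variant placed for one site may fall inside another site's
  window, a non-differential spillover that shrinks the containment OR
  toward 1); recovery is therefore asserted on the variant-level unit.
* **Overlap plant** — each site independently receives an exactly
  overlapping pathogenic variant with Bernoulli odds multiplied by
  `planted_overlap_or` at detected sites; positional placements avoid
  CysLysTyr positions so overlaps come only from this mechanism and the
  site-level overlap OR is exact.
* **Structures** — ideal α-helices (rise 1.5 Å/residue, twist 100°/residue,
  CA radius 2.3 Å; CB at +1.0 Å, terminal side-chain atoms at +1.8 Å), so
  all inter-residue distances have closed forms usable as oracles; an
  optional second chain translated along x creates inter-chain contacts.
* **3D burden plant** — designated detected residues receive a cluster of
  extra VUS alleles at positions within 8 Å of their terminal atom
  (computed analytically on the helix), making them the intended top-ranked
  residues; their codons receive CADD phreds ~N(32, 2) (others ~N(15, 5),
  clipped at 0), and a small fraction of other residues gets deliberately
  incomplete CADD sets.

The whole bundle is a pure function of the configuration (one seed): the
manifest checksums reproduce byte-for-byte.

What the generator does **not** emulate: realistic folds or contact maps
beyond the helix, linkage between variants, transcript structure, realistic
allele-frequency spectra (simple parametric draws per class), detection
biases from tryptic digestion.  Passing tests therefore demonstrate that the
pipeline's statistics recover known planted effects under clean conditions,
not that the biological conclusions transfer to any particular real corpus.

## Problem sizes and determinism

Default bundles use 40 proteins (≈ 900 CysLysTyr sites, ≈ 1,700 variants, 8
structures) and run the full pipeline in about a second.  Parameter-recovery
checks use 100 proteins of length 400–540 (≈ 5,000 sites) per seed and 100
seeds per planted value; CI coverage of the planted odds ratio is required
in ≥ 90 of 100 runs at both OR = 2.0 and OR = 1.0 (type-I control).  The
Fisher implementation is checked against exhaustive integer-combinatorics
enumeration on all 8,280 tables with row margins ≤ 12 (|Δp| < 1e-9), and the
3D environment computation against a brute-force all-atom scan with an
independent fixed-column PDB reader on 50 seeded structures.  All
randomness flows through `numpy.random.default_rng` seeded from the
configuration; result tables are written in sorted order so repeated runs
are byte-identical.

## Known limitations

* Exact rank-sum p-values are unavailable under ties (asymptotic fallback).
* The codon-exchange enrichment enumerates only observed exchanges; never-
  observed exchanges appear only when present in either class.
* mmCIF structures are out of scope (PDB format only); solvent
  accessibility, secondary structure and disulfide detection are not
  computed.
* Live database retrieval (UniProt, ClinVar, gnomAD, OMIM, PDB, dbNSFP) is
  deliberately excluded: the pipeline consumes pre-extracted tables, and
  cross-version consistency is handled by generic sequence verification.
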