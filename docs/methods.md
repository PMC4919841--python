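# Methods

This note documents the models, numerical choices and open design
decisions behind `metaproiq`, and what the synthetic benchmarks do and
do not demonstrate.

## Databases and decoys

Protein databases are plain amino-acid FASTA (nucleotide catalogs must
be translated upstream).  Decoys are exact character reversals with the
`DECOY_` accession prefix, generated from whatever database is being
searched (for step 2 that is the per-sample reduced database, not the
whole catalog).  Reversal preserves length and residue composition, so
the decoy peptide mass distribution matches the target one — the
property the target-decoy FDR estimator relies on.  The combined
non-redundant database de-duplicates by exact sequence string, keeping
the first-seen accession: "non-redundant" refers to sequences shared
across samples' lists, not to accession collisions.

Sequences containing non-canonical letters (B/J/O/U/X/Z) are retained in
databases, but any digestion window touching them is skipped, keeping
mass arithmetic well-defined without rewriting catalog content.

## Digestion and masses

Trypsin/P: cleavage C-terminal to K/R with no proline exception and no
cut at a protein-terminal K/R (an empty peptide).  Up to 2 missed
cleavages; peptide length bounds 7–45 residues (standard bottom-up
range; configurable).  Fixed carbamidomethyl-C (+57.021464 Da) is
applied everywhere; variable oxidation-M (+15.994915 Da) is enumerated
over up to 3 sites per peptide to bound the combinatorics.  N-terminal
methionine excision and protein-terminal modifications are not
modelled.  Monoisotopic residue masses are tabulated to six decimals
from atomic masses (proton 1.007276 Da, water 18.010565 Da); the test
suite cross-checks them against pyteomics.  I and L are distinct at the
search level; they are collapsed only in the taxonomy index, where MS
cannot distinguish them and organism assignment must not pretend it can.

## Spectrum preprocessing

Peaks below 150 m/z are dropped, the 50 most intense peaks are kept,
intensities are square-root transformed and scaled to a maximum of 1.
The √ transform tames dominant fragment peaks so the hyperscore's
intensity sum is not a single-peak statistic.  Preprocessing is made a
fixed point by flagging processed spectra (the transform itself is not
algebraically idempotent); it never moves an m/z value and never adds
peaks.  Exact duplicate m/z values are summed so the peak grid is
strictly increasing.

## Scoring and expect values

The hyperscore is the X!Tandem family score: summed matched peak
intensity × n_b! × n_y! over singly-charged b/y ions (no neutral
losses, no a/c/x/z ions — this keeps hand-checkable oracles feasible),
fragment tolerance ±20 ppm, each peak creditable to at most one
fragment (nearest wins), factorials capped at 10! so the factorial term
cannot overflow-dominate.  A best hit must match at least one fragment;
spectra whose candidates all score zero produce no PSM (breaking such
ties lexicographically would bias the target/decoy balance on noise
spectra).  This scorer is a documented, self-consistent variant, not a
bit-exact X!Tandem clone — refinement passes and version-dependent ion
ladders are out of scope.

Expect values estimate the number of equal-or-better chance matches for
a spectrum.  Scores are log-compressed (t = 4·log₁₀(1+H)) and binned at
width 0.5; a least-squares line is fit to log₁₀(survival) over the
contiguous non-empty bins above the histogram mode (bins beyond the
first empty bin are treated as signal and excluded).  A fit needs at
least 3 usable tail bins, otherwise it is degenerate and the expect
falls back to 1 with a flag.  Because a desk-scale database gives each
spectrum only a handful of in-tolerance candidates, the null is pooled
over the run: the scores of all decoy candidates, augmented with a
deterministic sample of up to 8 decoy peptide forms per spectrum drawn
from a broad (±25 %) mass window (these feed only the null, never the
candidate list).  The per-spectrum expect is then
P(chance ≥ s) × #candidates.  A spectrum with ≥ 100 candidates of its
own gets a classical per-spectrum fit instead.  Target-only searches
(step 1) have no decoy null; their expect defaults to 1, which the
loose step-1 inclusion threshold (expect ≤ 1.0) is designed to absorb —
step 1 is a recall-oriented reduction, FDR control happens in step 2.

## FDR control

PSMs (one best hit per spectrum) are sorted by descending hyperscore;
running FDR = #decoys / max(1, #targets); q-values are the running
minimum from the bottom of the list.  The simple decoys/targets
estimator is standard for two-step searches with small reduced
databases; peptides present in both a target and a decoy protein count
as target (conservative).  Step-2 acceptance requires q ≤ 0.01 and
expect ≤ 0.05.  Protein-level FDR is *not* separately controlled —
protein lists inherit peptide-level control, a known limitation shared
with the workflow this package implements.  The step-3 quantification
search applies the same PSM filter.

## Quantification

Protein groups merge proteins whose observed peptide sets are equal or
nested (transitive closure; the test suite checks it against a
brute-force pairwise-subset closure).  The leading protein ranks by
(#peptide sequences, #PSMs, approximate coverage) with a lexicographic
tie-break; cross-group shared peptides become razor peptides of the
group with most evidence and are quantified there only, so every
feature is used exactly once.

Precursor intensity comes from the MGF PEPMASS line (the synthetic
generator plants it); when absent, the matched-fragment intensity sum
serves as a proxy.  MS1 extracted-ion chromatograms from raw data are
out of scope.  Match-between-runs fits, per ordered run pair, a
piecewise-linear RT map on ≥ 5 shared MS/MS-identified peptides
(alignment window 20 min), then transfers donor peptides absent from
the acceptor when an unidentified acceptor precursor lies within ±10 ppm
m/z and 5 min of the aligned RT; a peptide is never transferred into a
run where it was MS/MS-identified, and each acceptor precursor is
consumed once.

MaxLFQ-style intensities: per group and sample pair, the median of log₂
peptide ratios over peptides seen in both samples (≥ 1 shared peptide,
the minimum ratio count); per connected component of the ratio graph a
least-squares solve of xᵢ − xⱼ = rᵢⱼ (mean anchored), rescaled so the
summed LFQ equals the summed raw intensity.  Samples outside any
component stay missing — imputation happens only in the statistics
layer.  LFQ is therefore *relative* per protein group: the absolute
scale absorbs peptide response factors that no label-free method can
recover, which is why the quantification benchmark evaluates
per-protein-centred log intensities.

## Functional and taxonomic layers

COG annotations are consumed as a precomputed best-hit table
(accession → COG id, category letters); running the alignment itself is
out of scope.  A group is annotated through its leading protein,
falling back to the next ranked member.  By default only the primary
(first-listed) category receives the group's LFQ so category sums equal
total LFQ exactly; a multi-category mode credits every listed letter.
Unannotated groups accumulate under `?`.

The taxonomy layer builds an I/L-collapsed peptide → taxon-set index
from taxon-labelled proteins and assigns each peptide the LCA of its
taxon set.  Peptides with internal missed-cleavage sites are also
resolved through their fully-tryptic sub-peptides (taxon sets
intersected), mirroring how a missed-cleavage variant pins the same
organisms.  Taxon abundance at a rank sums the intensities of peptides
whose LCA lies at or below that rank's node and divides by the
*total* identified peptide intensity of the sample (unassigned peptides
stay in the denominator), so columns sum to ≤ 1.  The
Firmicutes/Bacteroidetes ratio is undefined (NaN), not infinite, when
Bacteroidetes intensity is zero.

## Statistics

Presence filter: rows valid in ≥ ⌈min_frac · n⌉ samples (default
29/32 ≈ 0.906).  Group comparison: Welch's unequal-variance *t*-test on
log₁₀ LFQ (a pooled-variance option exists behind a flag), fold change
= mean difference of log₁₀ values of group 1 − group 2 (anti-symmetric
under swap), Benjamini–Hochberg step-up correction (hand-written,
verified against statsmodels to 1e-12), significance at q < 0.05, with
responder tiers flagged at 2× and 100×.  Fold changes and tests use
observed values only; kNN imputation (k = 1, nearest rows by Euclidean
distance) is applied solely before PCA and clustering.  Mann–Whitney is
exact for group sizes ≤ 8 without ties, otherwise normal approximation
with tie and continuity corrections; a U statistic exactly at its null
mean yields p = 1.  Clustering is average-linkage (UPGMA) on Euclidean
distances for both rows and columns, exported as Newick.

## Synthetic studies: what they emulate and what they do not

The generator plants a ground-truth community: a random catalog
(proteins of 100–600 residues, realistic residue frequencies)
partitioned over a fixed 5-phylum/20-species taxonomy with COG labels;
per-sample protein abundances log-normal (median 10⁷, σ = 0.5 dex) with
optional group-wise phylum multipliers and ±fold differential proteins;
per-peptide response factors 10^N(0, 0.3); b/y-ladder spectra with
5 ppm fragment and 3 ppm precursor jitter (inside the 20/10 ppm
tolerances), each fragment retained with probability 0.7 — and 15 % of
spectra "weak" at 0.35 — so a realistic share of PSMs is marginal;
score-plausible noise spectra (shuffled peaks, catalog-anchored or
uniform precursors); dropouts that keep the precursor but scramble the
fragments, i.e. exactly the events match-between-runs can recover.  All
randomness flows from one mandatory seed with per-sample sub-streams,
so studies regenerate byte-identically.

The reference benchmark conditions are: 1000-protein catalog, 100
expressed proteins, ~800 peptide + 400 noise spectra per sample for the
FDR/gain experiments (ten seeded replicates); 10 proteins × 5 peptides
× 6 samples with CV 10 % and 20 % dropouts for quantification; and a
400-protein catalog, 100 expressed proteins, 4 + 4 samples, a 3:1
Firmicutes multiplier plus twenty 4-fold differential proteins for the
end-to-end biology benchmark.  These sizes keep the full suite within
minutes on one CPU while leaving every mechanism (reduction, decoy
competition, ratio-graph connectivity, presence filtering) genuinely
exercised.

What passing these benchmarks does **not** show: real chromatography
(no co-elution, no peak shapes, no chimeric spectra), isotope
envelopes, charge-state heterogeneity (precursors are 2+), semi-tryptic
or unexpected modifications, database incompleteness, or catalogs at
the 10⁶–10⁷ scale where memory- and speed-oriented engineering
dominates.  Real-data identification counts from million-entry catalogs
are out of reach at desk scale by design.

## Numerical conventions

Ties are broken deterministically everywhere: best hits by (score,
expect, lexicographic peptide), leading proteins and razor winners by
evidence then accession, PCA component signs by making the
largest-magnitude loading positive.  All output tables are sorted, so
fixed inputs give byte-identical outputs.  Expect values are clamped to
(1e-20, 1e3]; LFQ solves use `numpy.linalg.lstsq` on the pairwise ratio
system with a mean-zero anchor row.
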