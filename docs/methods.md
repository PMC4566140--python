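# Methods

This note documents the models, parameter choices and numerical decisions
behind each stage, what the synthetic generator does and does not emulate,
and the known limitations.

## Read cleaning and tag collapsing

Cleaning discards, in order: reads with no locatable 3′ adapter
(`adapter3_null`), reads whose insert is empty after trimming
(`insert_null`), reads containing the 5′ adapter
(`adapter5_contaminant`), poly-A reads (≥ 80% A after trimming;
configurable `polya_frac`), and inserts outside the *exclusive* length
window (defaults 18/30, i.e. 19–29 nt kept). The adapter is located by
the leftmost position where its prefix matches with at most one
substitution over an overlap of at least 8 nt (both configurable); the
length bounds are exposed because sub-19-nt tags do occur in real
libraries and a user may want to keep them. Passing `adapter3=None` skips
adapter location, which makes a second cleaning pass over already-trimmed
reads an identity operation.

Identical raw sequences clean identically, so the implementation trims
each unique sequence once and weights outcomes by multiplicity; results
are read-for-read identical to naive per-read processing.

All sequences are held in DNA letters (U→T) everywhere except the folding
engine's output, which reports RNA.

## Reference mapping, ncRNA exclusion, known miRNAs

Mapping is perfect-match substring search on both strands, with every
occurrence recorded. Tags matching an rRNA/tRNA/snRNA/snoRNA database
record (exact substring, either strand) are excluded before miRNA
identification; multi-class hits resolve rRNA > tRNA > snRNA > snoRNA.

Known-miRNA matching is end-anchored and ungapped with at most two
mismatches: when tag and mature length differ (≤ 2 nt) the shorter slides
within the longer and the minimum Hamming distance over offsets is taken;
the length difference itself is not penalized (isomiR ends are common and
carry no evidence against identity). Indels are not modelled. Ties on
mismatch count keep all co-optimal database entries, the first in
database order flagged primary. Family labels strip the species prefix,
member letter and arm suffix; the merge map joins miR156/157 and
miR165/166 by default since their mature sequences are not reliably
separable in Brassicaceae. The conserved/non-conserved split is a
configuration list (24 conserved families by default); there is no
algorithmic definition.

## Hairpin folding and novel miRNA calling

Folding uses a deliberately minimal single-stem energy model rather than
a full nearest-neighbour parameter set: structures are chains of nested
pairs (Watson–Crick or G:U) closing one hairpin loop of ≥ 3 nt. Adjacent
pairs score a stacking bonus by pair type — WC/WC −2.0, WC/GU −1.0,
GU/GU −0.5 (model units on the kcal/mol scale) — non-adjacent
consecutive pairs pay +2.0 (bulge) or +1.5 (internal loop) with at most
10 unpaired nt per side, and the hairpin loop costs +3.0. No dangles, no
multiloop branching, no pseudoknots. The minimum is found exactly by an
O(n²·B²) dynamic program (numba-compiled) and is verified against
exhaustive enumeration of the entire structure class for sequences up to
26 nt. Ties resolve to the first optimum in scan order (outermost,
leftmost), so folds are deterministic.

The model's energies track stem length and imperfection, which is what
the acceptance criteria consume; they are not measured free energies, and
the MFE threshold (−18) is calibrated on the model's own scale. Long
random windows reach strongly negative model MFE — as real RNA does —
so the discriminating filters are the duplex criteria, not MFE alone.

Candidate windows place the tag near the window 5′ end (15-nt upstream
flank) or mirrored, at total lengths from tag+30 to 350 nt in 10-nt
steps. A window is accepted when: precursor 40–350 nt, mature 20–24 nt
entirely on one arm (not spanning the terminal loop), ≤ 4 unpaired
mature positions (the mature's 2-nt 3′ overhang excluded), asymmetric
bulge ≤ 2 nt, and model MFE ≤ −18. The star is the duplex partner with
2-nt 3′ overhangs and is marked observed when any other tag lies within
±2 nt of its position. Per tag the accepted window with the lowest MFE
(ties: shortest) is kept; overlapping candidates merge into one record
(most abundant tag becomes the mature, the partner marks the star
observed), and records are numbered `rsa-miRn-#` by (reference id,
start).

## Differential expression

RPM = count / clean-library-total × 1e6. Zero RPM becomes 0.01 before
ratios and p-values; exclusion (both libraries < 1 RPM) uses *pre-floor*
values. Fold change is log2(treated/control); significance needs
p ≤ 0.05 and log2FC ≥ 2 (up) or < −0.5 (down, strict).

The exact test is Audic–Claverie: conditional on x, y is negative
binomial with x+1 successes and success probability n1/(n1+n2); the
two-sided p doubles the smaller tail. A single conditioning orientation
is not exactly symmetric under (x, n1) ↔ (y, n2), so both orientations
are evaluated and the smaller doubled-tail reported; the difference is
far below reporting precision but the symmetry then holds exactly.
Numerics are tiered: scipy's `nbinom` tails down to ~1e-280;
arbitrary-precision direct summation (mpmath, 40 digits) for smaller
tails at moderate counts (x+y ≤ 20 000); vectorized log-space summation
(`gammaln` + `logsumexp`) for huge counts, where only the magnitude is
meaningful. P-values below the positive float range are reported as
5e-324 rather than 0. No multiple-testing correction is applied by
default, matching the two-pooled-library design this reproduces; the
thresholds object accepts any alternative cutoffs.

Three rows of the published tables disagree with their own raw counts at
the last printed digit (miR845d and miR857 RPM in the 4th decimal; the
miR5293 fold change prints 2.29 where its own normalized columns give
2.32; CK rRNA prints 7.36% where the counts give 7.35%). The
implementation reproduces the arithmetic, and the regression tests list
these rows explicitly. Published p-values are treated as indicative: the
exact variant behind them is not stated, and while several rows
reproduce to the printed figures (e.g. 130 vs 42 → 2.23e-13), others do
not; no test asserts them.

## Target prediction

Expectation scoring: mismatch 1, G:U 0.5, gap 2, doubled at miRNA
positions 2–13 (position 1 = miRNA 5′ end); matches 0. Default report
cutoff E ≤ 3.0. One gap at most — either a miRNA base unopposed or one
extra target base — never at or flanking positions 10–11; a target
insertion is charged at the position of the preceding miRNA base. Sites
are deduplicated per transcript interval keeping the lowest E.
Cleavage vs translational inhibition follows central complementarity:
any non-match at positions 9–11 → translation. The additional empirical
filters (no non-match at 10–11, ≤ 1 non-match in positions 1–9, ≤ 2
consecutive non-matches) are applied on top and reported reason-by-reason.
All constants are configuration; none are claimed to equal the exact
parameterization of any public server.

## qPCR quantification

Relative expression is 2^−ΔΔCt against a reference gene (default
"5.8S rRNA") and a calibrator condition. Replicate ΔCt values are
averaged per condition before the ΔΔCt step — so the calibrator's mean
fold is exactly 1 — and the standard error comes from per-replicate
folds. Per-replicate fold averaging is available by computing from the
returned per-replicate values. No primer-efficiency correction.

## Synthetic data generator

The generator emulates the *structure* of the study at reduced scale:
two libraries at a 1.08 treated/control depth ratio (defaults 1.0e6 and
1.08e6 reads), ~9% of reads from planted miRNA loci, rRNA/tRNA/snRNA/
snoRNA contamination at fixed fractions (7.3%/0.9%/0.1%/0.05%), a 16–29 nt
insert profile with a 21-nt mode, 3′ adapters on all reads except a 1%
adapter-failure fraction, 50 planted known miRNAs of which 10 carry true
log2 fold changes (±2 to ±4, expected control counts ≥ 150), and planted
novel hairpins (50–330 nt) built as inverted repeats with 0–2 star
mutations and verified against the caller's own criteria before
embedding (rejection sampling, 100 tries). Counts are Poisson around the
expectations (gamma-Poisson overdispersion available, off by default,
matching the no-replicate pooled design). Background reads come from
2 000 unannotated loci with log-uniform weights. Everything derives from
one integer seed; outputs are byte-identical across runs.

Not emulated: sequencing errors beyond adapter failure, quality-score
structure, repeat families, isomiR end heterogeneity, and composition
effects beyond the planted fold changes. Passing recovery tests
therefore demonstrates algorithmic correctness on clean signals, not
performance on real libraries.

One planted fold change sits exactly at +2.0, on the up-regulation
decision boundary, so its flag rate is ~50% by construction; the
20-seed recovery aggregate (~95%) accounts for this.

## Problem sizes in the test and acceptance runs

Unit and pipeline tests use 20–30 k-read libraries (seconds); the
differential-expression recovery runs 20 seeds at the generator's
default 1e6/1.08e6 depths; hairpin recovery plants 20 precursors at
150 k/162 k depth with a reduced background (100 loci) so the fold-heavy
novel stage stays proportionate; oracle equivalence runs over all
0 ≤ x, y ≤ 200 (p-values), 100 random sequences ≤ 26 nt (folding), and
20 random 1–2 kb transcripts (target scanning). These sizes are the
package's own choice of scale for routine verification; all generators
and stages accept larger inputs unchanged.

## Limitations

- The energy model is a stem-counting surrogate: adequate for ranking
  hairpin windows and enforcing duplex criteria, unsuitable for
  quantitative thermodynamics (an external folder can be swapped in
  through the `EnergyModel`/`fold` seam).
- Known-miRNA matching is ungapped; a tag with a true indel relative to
  its mature will be missed.
- Two pooled libraries admit no dispersion estimate; the exact test's
  p-values are conditional on totals and should be read accordingly.
- Family merging and the conserved list are configuration, not
  inference.
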