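# Methods

## The statistic

mRNA molecules must bring their 5' and 3' ends close together ("effective
circularization") for efficient translation initiation.  In a predicted
secondary structure, the two ends are connected by the **exterior loop**:
the nucleotides enclosed by no base pair, plus the closing base pair of each
outermost (depth-0) helix.  The backbone path length of that loop — the
**contour length**

    C_L = L × d,   d = 0.59 nm per link,

is an upper bound on the physical end-to-end separation, and is the single
number this package extracts from every structure.

**Link-counting convention.**  Walking 5'→3' at nesting depth 0, every
unpaired nucleotide is a path node; a depth-0 helix contributes its two
closing nucleotides as nodes joined by one base-pair link, and the walk
resumes after the helix.  A structure with `u` exterior unpaired nucleotides
and `h` depth-0 helices therefore has `u + 2h` nodes and

    L = u + 2h − 1

links.  This is the convention under which the minimum possible contour
length — termini directly base-paired, `u = 0, h = 1` — is exactly one link
(0.59 nm), the smallest value a contour-length distribution over real
molecules can contain.  Two alternatives are selectable
(`LinkConvention.HELIX_SINGLE_NODE`: `L = u + h − 1`;
`LinkConvention.UNPAIRED_ONLY`: `L = max(u − 1, 0)`) for sensitivity
analyses; they compress the distribution by a roughly constant shift and do
not reproduce the 0.59-nm minimum.  A single-nucleotide input yields
`u = 1, h = 0, L = 0, C_L = 0` by convention.

## Structure prediction

Minimum-free-energy (MFE) structures come from ViennaRNA (pinned version in
every structure's `engine` provenance string), at 37 °C with the engine's
default dangling-end model and lonely pairs allowed; `FoldConfig` exposes
temperature, `noLP` and `dangles`.  Golden-file tests freeze a toy hairpin
against the pinned version so an engine upgrade fails loudly instead of
silently shifting contour lengths.  Suboptimal structures are enumerated
exhaustively within an adaptive energy band above the MFE (0.1 kcal/mol,
doubled until k structures exist, capped at 5 kcal/mol) and sorted by free
energy; the band cap keeps the enumeration tractable on 1600-nt sequences,
where the density of states within even 0.5 kcal/mol reaches hundreds of
thousands of structures.

Structures computed elsewhere enter through two parsers: Vienna dot-bracket
text (with optional trailing energy) and mfold connectivity tables (CT,
partner in column 5).  Both enforce the nested-pairing model: involution,
no self-pairs, pseudoknots rejected with a position-bearing error.

## Eligibility filtering

The survey targets full-length native mRNAs: both UTRs annotated, a
polyadenylation signal plus the start of the poly(A) tail in the 3' UTR,
and total length 200–7000 nt.  Every criterion is evaluated (failures
accumulate; no short-circuit) so a filter report lists all reasons at once.
Two rules the source data do not pin down are explicit, configurable
guesses:

* **PAS motifs** default to the canonical `AAUAAA` plus the most common
  variant `AUUAAA`, searched inside the annotated 3' UTR (or the last
  200 nt when unannotated);
* **poly(A) start** is a run of ≥ 8 consecutive A reaching the 3' terminus.

Before folding, the terminal poly(A) run is trimmed by default
(`SurveyConfig.trim_polya`): a homopolymer tail is always unpaired in
predicted structures and would inflate the exterior loop by its full
length, while in vivo it is sequestered by poly(A)-binding protein.

## The random-sequence null model

The control condition is 50 independent sequences of 1600 nt with equal
probability ¼ for each nucleotide.  The generator is numpy's PCG64 with an
explicit seed; reproducibility is byte-exact for a fixed seed.  No attempt
is made to emulate any particular legacy RNG stream, only the distributional
specification.  The synthetic-structure generator used for oracle testing
emits dot-bracket strings whose exterior composition `(u, h)` — and hence
link count — is known by construction, with Watson–Crick-consistent
sequences; it exists so the exterior-loop walk can be validated against
ground truth and an independent brute-force implementation on thousands of
cases.

What the synthetic cohorts do *not* capture: real mRNA base composition,
codon structure, UTR grammar, and the curated species annotations of a
native survey.  Tests passing on synthetic cohorts validate the machinery
(measurement, aggregation, statistics), not any biological claim about
native sequences, which requires the curated GenBank cohort as input.

## Statistics

**Gaussian histogram fit.**  Contour-length samples are binned (default
2 nm, anchored at a multiple of the bin width below the sample minimum;
the bin width is recorded on every fit) and the bin counts are fitted by
least squares with

    f(x) = A · exp(−(x − center)² / w²),

so `w` is the 1/e half-width, `w = √2 σ`.  Parameter uncertainties come
from the fit covariance.  Initialization is the sample mean and `√2 ×`
sample SD; an all-equal sample raises a diagnostic error rather than
returning a degenerate answer.  Under this convention the one-sided 95%
upper bound is `center + 2σ = center + √2 w`; an alternative reading
(`w = σ`, bound `center + 1.645 σ`) is selectable but does not reproduce
the bounds quoted alongside fits stated in the 1/e half-width form.

**Width comparison.**  To compare the spread of two distributions with
different centers, the null width is rescaled by the center ratio (and an
optional GC-composition factor, default 1):
`w_scaled = w_random × (center_native / center_random) × gc_factor`, with
relative uncertainties combined in quadrature.  The excess of the native
width is then expressed as `(w_native − w_scaled) / sd(w_scaled)` in sigma
units.

**Tests and correlations.**  Group contrasts use the two-tailed Welch
unequal-variance t test with Welch–Satterthwaite degrees of freedom
(identical constant samples return `t = 0, p = 1`; conflicting constant
samples are a domain error).  Associations (C_L vs GC%, C_L vs 3'-UTR
length) use Pearson's r with the two-tailed t-transform p-value and an OLS
line `y = a + bx` with a 95% confidence band for the mean response
(statsmodels).  Per-species aggregates are mean ± SEM.  No multiple-testing
correction is applied: contrasts are interpreted per-comparison at
P < 0.05, matching the survey design this package implements.

## Problem sizes and determinism

The shipped analyses use the study's own scales where feasible: the random
control is the full 50 × 1600 nt (≈ 3 min of folding on one CPU); the
MFE-vs-suboptimal stability check runs 20 sequences × (MFE + 5 suboptimal),
a scale chosen to keep the complete-suboptimal enumeration affordable while
leaving the Welch test ample power to flag any real contour-length shift
between MFE and near-optimal structures.  Oracle and calibration suites run at n = 1000 structures,
48-point parameter grids and 2000 test replicates, all seeded and
deterministic.  Engine output is deterministic for a pinned version, so
every pipeline artifact is byte-reproducible given (seed, engine version).

## Known limitations

* The native per-species numbers require the curated GenBank cohort
  (hundreds of accessions with UTR annotations); the package reproduces
  the format and machinery on synthetic cohorts and accepts the native
  cohort as FASTA/GenBank input when available.
* Under the pinned engine at default parameters, the random-control
  contour-length sample (50 × 1600 nt) has a sample SD of ≈ 4.3 nm and a
  fitted 1/e half-width of ≈ 5.9 nm, robust to binning (1–3 nm), to a
  baseline term in the fit, and to `noLP`/`dangles` settings.  A fitted
  width as small as 2.6 nm is not reachable for this distribution with the
  documented fit; the fitted *center* (≈ 7.9 nm) and the overall range are
  engine-stable.  Cross-engine and cross-procedure variability of the
  fitted width is therefore a real caveat when comparing absolute width
  values between studies.
* Contour length bounds the end-to-end separation from above; it is not a
  3D (FRET-style) distance, and no tertiary-structure effects are modeled.
* Pseudoknots are outside the structure model, matching the MFE engines.
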