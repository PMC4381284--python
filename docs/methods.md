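# Methods

This note documents the models, conventions and design choices behind
`sirna-access`, and what its tests do and do not establish.

## Coordinates, alphabets, structures

All coordinates are 1-based with inclusive intervals (the CT-file
convention).  Sequences are normalised to {A, C, G, U}; T maps silently
to U and any other character is rejected, because pairing legality, GC%
and hydrogen-bond weights all need unambiguous bases.  A secondary
structure is a nested pair table over {AU, UA, GC, CG, GU, UG} with no
pseudoknots, no self-pairs and hairpin loops of at least 3 nt; these
invariants are enforced at construction, so no downstream code ever
sees an ill-formed structure.

## The internal folding engine

The engine scores a structure by its hydrogen-bond count — GC = 3,
AU = 2, GU = 1 per pair — and finds the maximum-weight nested structure
by Nussinov-style dynamic programming (O(n³), exact).  This scoring is
a deliberate stand-in for a thermodynamic model: it is dependency-free,
its optima are verifiable by brute-force enumeration on short
sequences, and it shares the hydrogen-bond semantics of the H-b index.
It is *not* a free-energy model; absolute "energies" are negated bond
counts (more negative = more stable).  Analyses that need
folding-server-faithful numbers should supply external CT and ss-count
files, which take precedence over the engine everywhere in the
pipeline.

Determinism: the traceback prefers pairing (i, j) over leaving an end
unpaired, outermost pair first, then the leftmost bifurcation, so equal
-weight optima resolve identically on every run.  The minimum hairpin
size defaults to 3 nt (steric minimum).

Suboptimal enumeration lists *every* nested structure within a score
window of the optimum (default window 5% of the optimal weight) by
branch-and-bound over the canonical first-position decomposition.  It
is exponential and therefore capped at 40 nt; beyond the cap the
engine raises and asks for external structures.

### Surrogate ensembles

The H-b index needs an ensemble of structures per mRNA.  Folding
servers return a suboptimal set whose size is essentially arbitrary —
the ss-count denominator is a free parameter of the analysis, not a
property of the molecule.  For sequences too long to enumerate, the
engine builds a deterministic surrogate ensemble: the optimal fold plus
the optimal folds constrained to leave each of k contiguous windows
(default k = 4) single-stranded, duplicates dropped.  This emulates the
qualitative property that matters for ss-count — alternative structures
expose different regions — while staying exact and reproducible.  It
does not emulate Boltzmann weighting; base-pair probabilities are out
of scope.

## Loop annotation

Every paired position is STEM.  Every unpaired position belongs to the
loop closed by its nearest enclosing pair (standard loop
decomposition), which makes the classification a partition.  A loop
with no interior branch is a hairpin loop; with one branch it is an
internal loop (unpaired on both sides), a one-base bulge (exactly one
unpaired base, one side) or a bulge loop (≥2 unpaired bases, one side);
with two or more branches, a multibranch loop.

Exterior unpaired positions have no canonical name in the literature,
so the package fixes a convention: positions 5′ of the first helix are
LOOP_5P, positions 3′ of the last helix are LOOP_3P, and a segment
between two helices is split at its midpoint — the 5′ half dangles off
the preceding helix (LOOP_3P), the 3′ half leads into the next helix
(LOOP_5P), and an odd middle position goes to LOOP_5P.  A completely
unpaired sequence is all LOOP_5P.  The midpoint tie rule is the one
place where reversing the strand does not exactly mirror 5′↔3′ labels
(the middle position maps to itself); the property tests carve out
exactly that exception.

## Target sites and features

A target site is the exact reverse complement of the guide on the mRNA
— no mismatch tolerance, no seed-only matching.  Multiple exact hits
resolve to the 5′-most with a warning listing all positions.

Element counts are taken on the single optimal structure (the structure
a site would be aligned to), while the H-b index uses the whole
ensemble via its ss-count vector.  Counts are targeted *bases* per
element; counting touched element *instances* is available through
`element_counts_in_site(..., unit="instances")` for sensitivity
analyses.  Unpaired runs are truncated at the site boundary: a run
continuing outside the window contributes only its inside portion.

The H-b index weighs each position by 3 (G/C) or 2 (A/U) hydrogen
bonds.  Because ss-count files do not record pairing partners, a G or C
paired through a GU wobble is counted at 3 bonds rather than 2 — an
approximation inherited from the index's construction; it biases H-b
upward slightly in wobble-rich structures.  The accessibility cut-point
defaults to 25 with strict inequality (H-b < 25 = accessible).

## Thermodynamic terms

ΔG°duplex is a nearest-neighbor sum over the duplex's stacked pairs
plus one initiation penalty and a 0.45 kcal/mol penalty per terminal
AU/UA pair.  The packaged parameter file is the standard Watson–Crick
RNA/RNA set at 37 °C (Xia et al. 1998), expanded to all 16 top-strand
dinucleotides via rotational equivalence and tagged with its source;
any file with the same schema can be substituted.  Wobble pairs are
disallowed inside the duplex (guide and site are exact complements by
construction).

ΔG°break-target = (optimal-fold score) − (score of the best fold with
the site forced single-stranded).  It is ≤ 0, equals 0 when the site is
already open, and grows in magnitude as the site grows.  ΔG°self is the
guide's own optimal-fold score (≤ 0).  ΔG°overall = ΔG°duplex −
ΔG°break-target − ΔG°self, hence never below ΔG°duplex.  When the
internal engine supplies the break/self terms they are on its
bond-count scale rather than kcal/mol; the sign conventions and
identities are scale-free, and external CT energies can be substituted
where absolute calories matter.  The break term uses the
optimal-structure difference, not an ensemble average.

GC bins: main bins <25%, [25, 55] (closed) and >55%; subgroups
[25, 35), [35, 45), [45, 55), [55, 65).  Boundaries are configurable.

## Statistics

Efficacy is coded 1 = VH, 0 = L; H and M siRNAs are excluded from the
two-group analysis.  Logistic models are fitted by maximum likelihood
(Newton/IRLS, tolerance 1e-8, ≤100 iterations).  "Robust" 95% CIs are
Wald intervals from HC1 sandwich standard errors, exponentiated to the
OR scale; classical model-based intervals sit behind `robust=False`.
Separation — reported by the optimizer, or any coefficient diverging
past |15| — raises rather than returning numbers.  Preconditions: n ≥
10 and both classes present (univariable); n > p + 1 and full column
rank (multivariable).

Because the eight element counts partition a fixed-length site, they
sum to a constant and the joint model with an intercept is singular.
The pipeline fits the intercept model when guide lengths vary and
otherwise absorbs the intercept into the compositional predictors
(`intercept=False`), flagging the switch in the output.

Two-group comparisons use Student's unpaired t-test when both groups
pass Shapiro–Wilk at α = 0.05 and the Mann–Whitney U test otherwise;
the rule can be overridden per call.  Fisher's exact test is two-sided
by hypergeometric enumeration; Pearson's chi-square is computed without
continuity correction and warns when an expected count falls below 5;
the one-sample proportion test is the exact binomial, two-sided by the
minimum-likelihood method.  No multiple-testing correction is applied —
the battery reports per-test p-values as-is.

## Synthetic studies

The generator emulates a fixed-size case-control design: it draws an
mRNA (i.i.d. bases at a configurable GC composition, default 0.5;
lengths uniform on 50–120 nt), folds it, places a 19-nt window
uniformly, sets the guide to the window's reverse complement, computes
the features, and draws the efficacy label from
`P(VH) = logit⁻¹(β₀ + β·feature)`.  Draws are accepted until both
groups hold 150 siRNAs (draws for a full group are discarded, bounded
at 10⁶), matching a 150 + 150 retrospective sample; one siRNA per mRNA
by default, at most two.  β = 0 gives an exchangeable null (a KS check
between the groups is logged, never asserted); β₀ = None auto-centres
the intercept at −β·E[feature] from a pilot draw so both groups stay
reachable.  All randomness flows through numpy's PCG64 generator, so a
seed fixes the study bit-for-bit.

The desk-scale lengths keep the exact engine practical; synthetic mRNAs
carry none of the compositional structure of real UTRs/CDS, no RNA-
binding-protein occlusion, and no transcript-length effects.  Passing
tests therefore establish the *pipeline's* correctness and calibration,
not biological conclusions about real transcripts — with externally
folded real mRNAs the same code applies unchanged, but numerical
results will depend on the folding model used.

For replicated simulations (type-I error, power, CI coverage) folding
every mRNA in every replicate is wasteful, so `build_feature_pool`
folds a pool of mRNAs once (default 200) and `replicate_univariable`
re-draws target windows and labels from that pool per replicate.  This
conditions the simulation on a finite mRNA population — standard for
logistic regression, whose inference is conditional on the covariates —
while the label model and quota sampling remain exactly as above.
Calibration at the default study conditions (150 per group, 1000
replicates): type-I error ≈ 0.05 at α = 0.05, mean recovered log-OR
within a few percent of the true 0.3, robust-CI coverage ≈ 0.95; the
acceptance script recomputes all three.

## Fixture study

Three short mRNAs are designed so that only G–C pairs are possible and
the pairing blocks nest uniquely, making the optimal fold forced and
checkable by eye: a stem with an internal loop and both exterior tails;
a stem with a two-base bulge and a one-base bulge; and a multibranch
fold with two hairpins.  Six 19-nt siRNAs (three VH, three L) tile
these structures so that every element class appears in at least one
site.  The resulting feature table is frozen in the repository and
asserted byte-for-byte, which pins the whole
fold→annotate→features→serialize path.

## Numerical and degenerate-input conventions

Integer DP scores make score comparisons exact (no floating-point ties
in the engine).  TSV output formats reals to 4 decimals; bundles are
byte-reproducible for fixed inputs and seed, and the run log records
the package version, seed and a digest of the analysis parameters.
Degenerate statistics are deliberate: identical zero-variance groups
compare at p = 1 (logged), a zero-margin Fisher table returns p = 1
with a warning, and any regression whose preconditions fail appears in
the result bundle as an `NA` row with the reason, rather than aborting
the bundle.

## Known limitations

* The engine's scores are bond counts, not free energies; ΔG values
  mix kcal/mol (duplex) with engine units (break/self) unless external
  energies are supplied.
* No Boltzmann ensemble: ss-counts from surrogate ensembles have small,
  structured denominators.
* Wobble over-weighting in the H-b index (see above).
* Loop annotation ignores coaxial stacking and dangles; pseudoknots are
  rejected outright.
* Exterior-loop 5′/3′ naming is a convention of this package.
* The multivariable element model changes interpretation when the
  intercept is absorbed (coefficients then carry a share of the
  baseline log-odds); compare against the univariable fits when in
  doubt.
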