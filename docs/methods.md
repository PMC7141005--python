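# Methods

This note records the model, the numerical choices, and the places where
the design was genuinely open, in the package's own terms. It states no
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Model and assumptions

The estimator is signature-based, not regression-based: it does not fit
the bulk profile as a linear combination of reference profiles. Instead
it measures, per marker gene, the *deviation* of the sample from the
reference of the type(s) the gene marks,

    D_g = Σ_i ST[g,i] · (S_g − RT[g,i]),

and summarises each cell type's signature over D with a single-sample
GSEA statistic. The assumptions are (a) expression is on a log-like scale
where subtraction is the natural deviation measure — hence the platform
transform (identity for microarray intensities, log2(m+1) for RNA-Seq
TPM/FPKM); (b) a type's markers move together and upward with its
abundance; (c) cross-signature contamination from shared markers is
approximately linear in score space, so it can be removed by solving
`min_{I≥0} ‖C·I − ES‖` with a fixed compensation matrix C. The output is
a relative abundance: non-negative, not normalised to sum to one, and not
comparable *across cell types* in absolute terms.

The deviation formula deserves a note: the sample-minus-reference
difference summed over marking types is the algebraic reading we adopted
for the marker-masked deviation; a ratio or reference-averaged variant
would also be defensible. Subtraction on the log scale is the standard
choice and makes D exactly zero for a sample equal to its reference,
which anchors the scoring.

## ssGSEA scoring

Genes are ordered by decreasing D. The score is the sum over all
positions of (weighted in-set cumulative fraction − out-of-set cumulative
fraction), with hit weights `rank^α` normalised by the in-set total and α
defaulting to 0.25 (the conventional ssGSEA exponent; configurable).
Equivalently, in closed form over tie-averaged ascending ranks ρ:

    score = Σ_hits (ρ^α / Σ_hits ρ^α) · ρ  −  (Σ_miss ρ) / n_miss.

Ties are resolved by *average ranks* rather than by an arbitrary stable
order: this makes the score invariant to the input ordering of tied
genes and gives every gene set a score of exactly 0 on a constant
profile, which is the symmetric behaviour one wants for a degenerate
sample. On tie-free profiles the closed form coincides with the
position-by-position running sum (checked against an independent O(n²)
re-implementation to 1e-9 on random instances). A gene set covering the
whole universe has no miss term.

Each sample is scored independently; there is no cross-sample rank
normalisation, so single-sample input works.

## Compensation matrix

Contribution entry (i, j) is the score of signature i on the deviation
vector of reference profile j. Normalisation: divide each column by its
diagonal; zero parent/subset pairs (CD4+ T vs its eight subsets, CD8+ T
vs its four — compensating a parent against its own subsets would cancel
genuine shared biology); clamp negatives to zero; weight each column's
off-diagonal entries by that column's off-diagonal mass proportion
s/(1+s); finally rescale the column's off-diagonal sum to 0.5 if it still
exceeds it. The cap is applied per column (all sources compensating one
target type) — the axis was an open choice; per column keeps the direct
signal dominant for every estimated type. The calibration solves NNLS
with SciPy's Lawson–Hanson active-set implementation, which is
deterministic; residual norms are reported in the diagnostics.

## Marker selection

Mixtures are simulated per stratum (a user-supplied tumor-like expression
matrix standing in for one cancer type): weights f_1..f_N ~ Uniform(0,1),
mean profile = weighted *average* of reference columns (weights divided
by their sum — sampling from U(0,1) without normalisation would put the
mean off-scale), expression = mean + multivariate-normal noise with the
stratum's gene–gene covariance. The sample covariance over many genes
and few samples is routinely indefinite, so it is projected to the PSD
cone by clipping negative eigenvalues at zero.

Filter G1 keeps genes whose expression correlates with their own type's
fraction (average Pearson r across strata ≥ 0.6; a gene marking k types
uses the mean of its k on-target correlations). Correlations are taken
against the *normalised* weights — the actual composition of the
simulated sample — not the raw Uniform draws; the raw draws differ from
the composition only by the per-sample normalising constant, and using
the composition is both the quantity of interest and the more powerful
target. Filter G2 requires specificity: z = (r_on − mean(r_off)) /
sd(r_off) > 1.5, where the off-target set excludes the gene's own
type(s) and any parent/subset partner of the marked type. The
"deviation of the on-target correlation from the off-target
distribution" admits several formalisations; the z-score is the one
under which a fixed threshold like 1.5 is scale-free, and that is the
reading implemented (a gene marking several types passes on its best z).
The final set is G1 ∩ G2; the bundle is rebuilt restricted to it, and a
cell type losing all markers is an error, not a silent degradation.

## Synthetic data

The bundle generator plants markers at `marker_fold` × a per-gene
background level drawn from U(4, 6) (moderate-abundance transcripts on a
log-like intensity scale, chosen so marker elevation is comparable
across genes), with Gaussian reference noise (sd 0.25 by default).
Defaults — 24 types, 15 markers per type, fold 8, noise 0.25 — define
the standard study conditions used by the recovery checks. Optional
decoy markers (signature members with flat profiles) exercise the
selection filters; optional shared markers between designated type pairs
exercise the compensation step. Bulk mixtures are fraction-weighted
averages of reference columns plus log-scale Gaussian noise clipped at
zero.

Single-cell sets are TPM-like: a delogged reference profile per cell,
multiplicative noise, and a per-cell depth factor emulating library-size
variation. Normalisation is log2(x+1) followed by scaling each cell by
HKbar/HK_i over a designated housekeeping set (default 100 genes standing
in for a genome-wide list); afterwards every cell's mean housekeeping
level is identical to machine precision. Pseudo-bulk aggregates cells by
the gene-wise *mean* (the aggregation statistic was an open choice; the
mean keeps pseudo-bulk on the same scale as cells), and the truth table
is the per-type share of cell counts.

What the generators deliberately do not emulate: single-cell dropout and
count noise, batch effects, tumor-purity/stromal contamination, and
platform-specific probe effects. Passing the recovery checks therefore
shows the pipeline is correct and well-conditioned under its own model
of the data, not that real-tissue accuracy matches the synthetic
figures.

## Evaluation statistic

Per cell type, Pearson r between estimate and truth across samples;
types with zero variance on either side are reported as unavailable and
excluded from n. The scalar summary is `(1/n) Σ (1 − r_i)²` — 0 iff all
r_i = 1, at most 4 — chosen over the alternative `(1/n) Σ (1 − r_i²)`
because a *deviation* should penalise anticorrelation more than
non-correlation; the alternative is available behind
`variant="one_minus_r2"` for comparison.

## Response model

Binary responder/non-responder classification from abundance features:
undersample the majority class (optionally to an explicit per-class
size, e.g. 19/19 out of a 27/64 cohort, leaving the remainder for
testing), sequential backward feature elimination against stratified
fivefold CV AUC (a removal is accepted when CV AUC does not drop — ties
favour fewer features, broken by feature order; never below one
feature), then an RBF-SVM fit on the selected features. C = 1 and
γ = 1/(n_features · Var) ("scale") are the defaults since no principled
values are dictated by the problem; AUC uses decision-function scores,
which need no probability calibration because AUC is rank-based.
Selection runs once on the (balanced) training cohort; holdout cohorts
are scored exactly once and can never influence selection or fitting — a
canary test corrupts holdout labels and asserts the trained model is
unchanged. Degenerate CV folds trigger one logged refold with seed+1. A
single-class holdout has undefined AUC and is reported as None. Models
serialise to JSON (seed, hyperparameters, selected features, balanced
training data); loading refits the deterministic SVM, avoiding binary
pickles.

## Numerical choices and problem sizes

Default thresholds: marker coverage floor 0.5 for alignment (below it the
profile shares too few genes with the reference to score); G1 = 0.6,
G2 = 1.5; compensation cap 0.5; α = 0.25. Missing marker genes are
imputed with the per-sample median of observed marker values, keeping
their deviations mid-rank instead of extreme — the main alternative
(imputing the reference value itself, giving D = 0 exactly) is more
aggressive about asserting absence of signal from absent evidence.
Duplicate gene rows collapse by median, matching the reference
aggregation rule. Gene matching is case-insensitive on symbols; an alias
table can be applied upstream.

The standard check sizes are 100 mixtures over the 24-type bundle for
fraction recovery, 500 simulated samples per stratum for marker
selection, 200 random 3×3 instances for the NNLS oracle, 100 random
instances (universe ≤ 50, set ≤ 10) for the ssGSEA oracle, and 50
permutation repeats for the response-model null; all are driven by
explicit seeds and chosen to make the checks statistically meaningful at
desk scale.

## Known limitations

Relative abundances only; no tumor-purity correction or spatial
information. The compensation matrix is estimated from the reference
alone, so rank noise among off-target markers can contribute spurious
compensation mass up to the 0.5 cap — visible in the recovery check as a
minority of types with lower calibrated correlation than their raw-score
correlation. Marker selection power depends on the tumor covariance
supplied: a covariance estimated from mixtures already containing
immune-fraction variance bounds the attainable on-target correlation
below 1 by construction.
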