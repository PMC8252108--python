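# Methods

## Scope and data model

The package analyses long-format tables of per-sample, per-amino-acid
isotope values: one row per (sample, amino acid, element) holding the
replicate-mean δ value (‰, vs V-PDB for carbon and atmospheric N₂ for
nitrogen), the standard deviation over analytical replicate injections,
and the replicate count. Sample metadata (tissue fraction, nutrition
treatment, study, genet) ride along in the same table. Units are fixed
at ‰ throughout; there is no unit-conversion layer. Missing cells in
dense matrices are carried in an explicit boolean mask, never as a
sentinel value.

The amino-acid registry holds the 15 amino acids that occur in coral
AA-CSIA work and classifies each on two axes: carbon
(essential: Ile, Leu, Lys, Met, Phe, Thr, Val; the rest nonessential)
and nitrogen (trophic: Ala, Asp, Glx, Ile, Leu, Pro, Val; source: Phe,
Met, Lys plus the limited/source-like Gly, Ser, Thr, Tyr, Arg).
Classification is total by construction — a registry cannot contain an
unclassified member — and user-extensible, so alternative binnings can
be declared in configuration. Glutamic acid and glutamine are reported
jointly as Glx because acid hydrolysis converts Gln to Glu; readers
alias Glu→Glx and reject explicit Gln rows rather than silently merging
them. The default "measured-13" panel excludes Arg and Met, which are
rarely recovered reliably from TFA-derivatized hydrolysates.

## Trophic position and its uncertainty

TP is computed from the Glx–Phe δ¹⁵N spacing as
`TP = (δ15N_Glx − δ15N_Phe − β)/Δ + 1` with β = 3.4 ‰ (producer Glx–Phe
offset) and Δ = 7.6 ‰ (per-trophic-step enrichment) by default. The
propagated standard deviation is first-order:

    sd(TP) = sqrt(σ_Glx² + σ_Phe² + σ_β² + ((TP − 1)·σ_Δ)²) / Δ

By default only the analytical replicate SDs of the two amino acids
enter (σ_β = σ_Δ = 0), because β/Δ uncertainties are rarely reported
with data tables; full parameter propagation is available by setting
`sd_beta` / `sd_delta` on `TpParameters`. Tests verify the closed form
against a 10⁶-draw Monte-Carlo oracle to within 2 % relative error;
at the parameter scales used here (σ_Δ/Δ ≲ 3 %) the first-order
approximation is accurate to well under 1 %.

## Mixing model

Percent heterotrophy uses the linear two-end-member mixing model on the
TP scale, `f = (TP_mix − TP_auto)/(TP_het − TP_auto)`, with the
Phillips–Gregg first-order variance

    var(f) = [σ_mix² + f²σ_het² + (1 − f)²σ_auto²] / (TP_het − TP_auto)²

Fractions are **not** clamped to [0, 1]: out-of-range values are
returned as-is with an `in_range=False` flag, because they diagnose
data/end-member inconsistency rather than being a numerical artefact.
The default scenario grid crosses every sample with two heterotrophic
end-members — detritivory (TP_het = 2.0, feeding on primary producers or
algal detritus) and zooplanktivory (TP_het = 3.0) — against an
autotrophic end-member at TP 1.0. Group summaries report mean ± SD over
samples, not SE. The first-order variance degrades when end-member SDs
are large relative to the end-member span (the ratio distribution grows
heavy tails); at the SD scales typical of this application (≤ 0.2 on a
span of 1) the Monte-Carlo discrepancy stays under 2 %.

## Weighted mean and ∑V

The δ¹⁵N-weighted mean over an amino-acid category is the
inverse-variance estimator `Σ(x_i/σ_i²)/Σ(1/σ_i²)`, with default
category sets trophic = {Ala, Leu, Glx} and source = {Lys, Phe}. A
replicate SD of exactly zero implies infinite weight and almost always
indicates degenerate input; it is an error unless an explicit override
substitutes the smallest positive SD present.

∑V is implemented as the mean absolute deviation of trophic-amino-acid
δ¹⁵N values about their within-sample mean,
`∑V = (1/n)·Σ|χ_i|, χ_i = x_i − mean(x)`, over the conventional set
{Ala, Leu, Pro, Asp, Glx}. The phrase "summed variance" in the
literature is loose; the mean-absolute-deviation convention (McCarthy
and colleagues) is used because it reproduces the reported magnitude of
the index (~1 ‰ for producer-like tissue). The amino-acid set is a
parameter, so a plain-variance variant can be computed on raw values if
desired.

## PERMANOVA

Euclidean distances are computed after an element-specific transform:
absolute value for carbon (all δ¹³C are negative in practice, so this
mirrors the data and cannot change distances between all-negative
profiles — a test documents the equivalence to a sign flip), and a
positive constant shift (−min + 1) for nitrogen. Euclidean distance is
translation-invariant, so the nitrogen shift is exactly a no-op; this
is asserted by test rather than assumed, since the convention exists
only to satisfy the expectations of other software.

The distance matrix is Gower-centered (G = −½·J D² J) and partitioned by
sequential (Type I) hat-matrix projections over the model terms in the
order fraction, treatment, fraction × treatment (McArdle–Anderson), so
the sums of squares are exact: terms + residual = total to machine
precision. Pseudo-F per term is (SS/df)/(SS_res/df_res). Significance
comes from free permutation of observations: `p = (#{F* ≥ F} + 1)/(n_perm + 1)`
with 999 permutations by default and a mandatory seed; for n ≤ 8 an
exact mode enumerates all n! permutations and reports
`p = #{F* ≥ F}/n!`. With a single factor and univariate input the
pseudo-F equals the classical one-way ANOVA F exactly (tested against a
closed-form oracle, and against scikit-bio's single-factor
implementation for multivariate input).

## PCA, ellipses, per-AA linear models

PCA operates on the correlation matrix of the (centered, unit-scaled)
variables; scores are the scaled data projected on the eigenvectors, so
scores × loadingsᵀ reconstructs the scaled data exactly. Component
signs are fixed by making the largest-magnitude loading positive.
Correlation vectors are the Pearson correlations of each variable with
the first two components, flagged significant at α = 0.05 by the
correlation t-test, uncorrected — the convention of the biplot displays
this mirrors.

Group ellipses come from the 2-D covariance eigenstructure of a group's
ordination scores, with semi-axes √(eigenvalue · χ²₂(level)); the level
(0.90 "SD ellipse" or 0.95 "confidence ellipse" in common figure
captions) is a parameter of the one routine, since the two conventions
differ only in the quantile. Empirical coverage at level 0.90 is
verified by Monte-Carlo to within 1 %.

Per-amino-acid scalar responses are analysed with a fixed-effects
linear model `value ~ fraction + treatment` (no interaction, matching
the conventional reported term list) via statsmodels OLS/anova_lm, with
Tukey HSD pairwise treatment contrasts as the post hoc procedure. A
simulation test confirms the type-I error rate is calibrated at α = 0.05
under the null.

## Linear discriminant classification

Discriminant scalings solve the generalized eigenproblem B·v = λ·W·v
with W the pooled unbiased within-class covariance and B the
class-size-weighted between-class covariance, normalized so pooled
within-class variance is unit along each discriminant — the scaling
convention of the classical R implementation, so `scalings`,
`proportion_of_trace` and class means are directly comparable to that
output. Directions are defined up to sign; all quantities used
downstream (classifications, posteriors, proportion of trace) are
sign-invariant. Priors default to class-proportional; uniform or
explicit priors are options.

Mean-normalized fingerprints carry an exact sum-to-zero constraint per
row, making W singular by construction. For fingerprint input the
solver therefore works in the non-null eigen-subspace of W (relative
tolerance 10⁻⁹); for raw input a singular W is an error, with two
explicit escapes: a ridge (λ·trace(W)/p added to the diagonal) or an
explicit subspace tolerance. Prediction uses the Gaussian
equal-covariance posterior with a pseudo-inverse of W, which is
consistent with the subspace construction because class means lie in
the same subspace. Leave-one-out cross-validation refits the model per
fold and reports per-class and overall success plus the full confusion
table; a fold in which a class vanishes is an error rather than a
silent skip. Predictions agree with scikit-learn's LDA on
full-rank input (tested), but scikit-learn is never used as the
implementation because its scaling convention differs.

## Synthetic data: what it emulates, and what it does not

The generator fixes latent per-amino-acid mean profiles per group
(host, symbiont, plankton) and draws independent Gaussian replicate
injections around them. The preset encodes the study conditions of a
host/symbiont/plankton feeding experiment:

* host δ¹³C means spanning −21.5 to −8.5 ‰ (within the −24.3 to −8.1 ‰
  range typical of shallow coral hosts);
* symbiont δ¹³C offsets averaging −0.9 ‰ with essential amino acids
  nearly identical to the host (the largest deviations are in the
  nonessential Gly and Glx);
* plankton δ¹³C offsets averaging −5.5 ‰ but amino-acid-specific
  (strongest in Ile, Lys, Thr). This matters: a *constant* offset would
  vanish under mean-normalization and leave fingerprints with no group
  signal, so the pattern — not the average — is what makes the
  plankton fingerprint separable;
* plankton δ¹⁵N offsets of +2.5 ‰, with the Glx mean then overwritten
  from the group's target trophic position
  (Glx = Phe + β + (TP − 1)·Δ): host/symbiont TP 1.0, plankton TP 2.0;
* symbiont δ¹⁵N deviations from the host (Leu, Pro, Asp slightly lower;
  Gly, Thr, Tyr higher) so the host/symbiont fraction effect that
  nitrogen PERMANOVA should detect exists in the generator;
* design of 2 genets × 3 treatments (L-NF, L-F, D-F) × 2 fractions plus
  one plankton sample, triplicate injections with 0.3 ‰ analytical SD.
  Treatment effect sizes default to zero (the regime the experiment
  actually found). All counts and effects are configurable; analyses
  that train a classifier use `n_plankton=6`, emulating the pooled
  multi-study heterotrophic training set that such classifiers are fit
  on in practice, since a single end-member sample cannot form a class.

Limitations, hence what passing tests do and do not show: noise is
independent Gaussian per amino acid per replicate with no amino-acid
covariance and, by default, no between-sample biological variance
beyond the optional per-sample baseline shift (common to all amino
acids of a sample, default off, used by tests to demonstrate that
mean-normalization removes exactly this kind of variation). Real data
have colony-level biological scatter and correlated amino-acid
deviations, so synthetic group separations are cleaner than field
data's; recovery and power results on the preset are upper bounds, not
field predictions. The generator targets statistical structure only —
no isotope-fractionation chemistry or host–symbiont nitrogen recycling
is simulated. The exact latent means, TP targets, effects and seed are
serialized as JSON ground truth next to every dataset so recovery tests
never re-derive them.

## Pipeline and reproducibility

`run_pipeline` executes, in order: validation → per-sample TP with
uncertainty → heterotrophy scenario grid (host samples) → ∑V and
weighted means → carbon and nitrogen PERMANOVA (host/symbiont, full
factorial terms) → PCA of both elements (all samples) → fingerprint LDA
(train on nutrition-source classes, LOOCV, predict hosts, map to
autotrophy/heterotrophy coarse groups). Any stage failure aborts with
the stage name. Every output table carries the resolved seed and
package version; the resolved config is echoed as YAML into the output
directory, and a rerun from the same config and inputs is
byte-identical (asserted by test). One seed drives the generator, the
PERMANOVA permutations and everything else stochastic.

Problem sizes used by the test suite and acceptance script — 10⁶ draws
for Monte-Carlo propagation oracles, 10⁵ points for ellipse coverage,
200 replicate simulations at 199 permutations for PERMANOVA power,
400 replicates for ANOVA type-I calibration, full 6! enumeration for
exact permutation checks — were chosen so each oracle's sampling error
is several times smaller than the tolerance it guards.
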