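# Methods

## Scoring model

A policy is evaluated against a schema of primary variables, each owning
`T_i` binary secondary indicators. Indicator coding is strictly binary: a
policy text either matches an indicator's criterion (1) or it does not (0).
(Schema notation sometimes writes the assignment range as a distribution on
[0, 1]; the operative rule here is the binary count — values are restricted
to {0, 1}.) The primary score is the unweighted mean of its block,
`X_i = Σ_j X_ij / T_i`, and the PMC index is the plain sum `PMC = Σ_i X_i`,
so every secondary indicator carries equal importance and weight and the
index ranges from 0 to the number of primaries. No weighted variant is
provided; equal weighting is part of the method's definition.

**Direct-scored primaries.** A primary with no secondaries (X10, policy
disclosure, in the default schema) is treated as owning one implicit
indicator with `T = 1`: the policy is coded 0/1 on the primary itself and
the mean formula applies uniformly. This reconstruction keeps the scoring
rule single-cased; it is why the default coding matrix has 45 columns while
the schema counts 44 explicit secondaries.

**Grade bands.** The consistency scale is printed with 2-dp band edges
(e.g. "7~8.99"), which cannot partition a real-valued index. Bands are
therefore implemented left-closed/right-open — `[9, 10]`, `[7, 9)`,
`[5, 7)`, `[0, 5)` — with the top band closed at the maximum attainable
index. Grading always uses the unrounded index value: rounding to the 3-dp
display precision before banding could flip a grade at a boundary. Validation
rejects any custom scale whose bands overlap, leave gaps, or fail to cover
`[0, n_primaries]`.

**Precision.** All computation is full precision; 3-dp rounding (matching
the published tables) is applied only on output. When scoring starts from a
published primary-score table rather than raw 0/1 codes, the 3-dp inputs
propagate up to ±0.002 of rounding error into a 10-term sum, which is the
tolerance used whenever reproduced sums are compared with printed values.

## The packaged cohort

The indicator-level 0/1 sheet of the 37 Sichuan pilot-area HPPs was never
released; what is published are the per-primary scores, the PMC row, the
ranks, and the expert field totals. The fixture therefore ships as a
37×10 primary-score table plus a 37-element expert vector, and the scoring
entry point accepts either a coding matrix or a primary-score table. Pairing
of policies to pilot areas is positional (policy Pk ↔ area k). Whether the
expert totals are correlated on the raw 1000-point or the percentage scale is
immaterial: Pearson r is invariant under positive affine rescaling.

## Surface matrices

The 3×3 surface drops X10, both for squareness and because disclosure is 1
for every openly published policy, carrying no contrast. Matrix row `r`,
column `c` maps to plot coordinates `y = r+1`, `x = c+1`. Rendering
bilinearly refines the nine points for visual smoothness but always overlays
the raw values; the z-axis is fixed to [0, 1] so depressions are comparable
across policies, and the viewpoint is fixed so renders are deterministic.
A numeric "depression index" is deliberately not defined.

## Concordance

The formulation–implementation association is the Pearson product-moment
coefficient with the exact two-tailed t-test (`n−2` df), computed via
`scipy.stats.pearsonr` and cross-checked in the tests against an independent
hand-written implementation of the formula. Normality is not pre-tested; the
coefficient is computed unconditionally and reported with its p-value, which
is the transparent thing to do for a fixed published cohort. Inputs must be
paired, non-constant, and of length ≥ 3.

## Text mining

The co-word stage is a generic reconstruction of the usual
term-frequency/co-occurrence workflow: tokens are maximal alphanumeric runs,
optionally lowercased, with stopwords removed after case folding;
co-occurrence is presence-based (counted once per document, or per sliding
window of a chosen size), giving a symmetric matrix whose diagonal is the
document (or window) frequency. No fidelity to any proprietary segmentation
tool is claimed; corpora in languages that need real word segmentation
(Chinese in particular) must be tokenized upstream and passed in
pre-tokenized. Stopword policy and the "high-frequency" cutoff are exposed
as options because no canonical values exist.

## Synthetic-data generator

The generator reproduces the statistical shape the analysis assumes, so the
pipeline and the concordance test can be exercised end to end:

* **Coding**: independent Bernoulli(p_j) draws per policy and indicator.
  Real indicator codes are surely dependent within a policy; as a documented
  simplification the default is independence, with an optional shared latent
  "policy quality" shift (per-policy u ~ Uniform(−δ, δ) added to all p_j,
  clipped to [0, 1]) to induce positive within-policy correlation.
* **Expert totals**: `a + b·PMC + ε`, `ε ~ Normal(0, σ²)`, clamped to the
  percentage range [0, 100] because field totals are bounded percentages.

Defaults are fixed to the observed cohort's conditions: 37 policies;
per-indicator p equal to the cohort's per-primary mean scores (computed from
the packaged fixture at call time, so E[X_i] matches the cohort by
construction); expert model a = 72.0, b = 2.25, σ = 5.0, rounded from the
least-squares fit of the published expert totals on the published indices
(intercept 72.13, slope 2.246, residual sd 4.99). Under this model the
implied correlation `r = b·sd(PMC)/√(b²·Var(PMC) + σ²)` with
`Var(PMC) = Σ_i Σ_j p_j(1−p_j)/T_i²` is about 0.25 — lower than the observed
0.41 because independent indicators understate the between-policy variance
of the index; the latent-shift option closes that gap if desired. The
clamp is ignored by the plug-in formula, so it is accurate only while the
line stays inside the score range.

All randomness flows from one integer seed through numpy `SeedSequence`;
coding and expert noise use separate spawned streams, and replicate seeds in
the recovery experiment are spawned from the master seed, so identical
spec + seed gives bit-identical output.

**What passing synthetic tests shows — and does not.** Recovery of Bernoulli
means, agreement of empirical with plug-in r, and a ~5% null rejection rate
validate the arithmetic of scoring, banding and testing. They say nothing
about coder reliability, indicator dependence in real policy texts, or the
validity of the expert rubric, none of which the generator models.

## Problem sizes

The packaged analyses are desk-scale (37 policies) and run in seconds. The
statistical test batteries use 1 000 random matrices for the scoring oracle
check, 200 replicates for mean recovery, and 500 seeded cohorts for the null
calibration of the concordance test — sizes at which Monte-Carlo standard
errors are small enough for 2–3 SE assertions to be meaningful while the
whole suite stays fast.

## Known limitations

* The fixture carries 3-dp rounding; indicator-level reanalysis of the
  original cohort is impossible without the unreleased coding sheet.
* The surface is defined only for the 10-primary layout.
* The generator's independence default understates index variance (above).
* Grade letters beyond the default A–D are supported via custom scales, but
  cohort summaries order groups lexicographically.
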