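# Methods

## Distribution family and links

Each region is modelled with a three-parameter generalized gamma
distribution in location–scale–shape form.  With θ = 1/(σ²ν²) and
z = (y/μ)^ν the log density is

    log f(y) = log|ν| + θ log θ + θν(log y − log μ) − θz − log Γ(θ) − log y,

the CDF is the regularized lower incomplete gamma P(θ, θz) for ν > 0 and
its complement for ν < 0, and ν → 0 recovers the lognormal with log-scale
σ.  The family nests the gamma (ν = 1) and lognormal limits that positive
morphometric measures are usually fitted with, and σ is approximately the
coefficient of variation, which makes fitted scales directly
interpretable (≈6% for thickness, ≈12% for subcortical volume in the
synthetic defaults).

θ grows like ν⁻², so the textbook formula destroys all precision near
ν = 0.  Everything is therefore computed through the equivalent form
log|ν| + A(θ) − θ·(expm1(νt) − νt) − log y with t = log y − log μ and
A(θ) = θ log θ − θ − log Γ(θ); A switches to a Stirling tail above
θ = 10⁶, and below |ν| = 10⁻⁴ an explicit lognormal series (with the
first-order skew correction) takes over.  Score functions are analytic in
both branches; the ν-score limit −t³/(6σ²) is used in the small-ν branch.
Unit tests pin the gamma special case, quadrature normalization, a
10⁶-draw Monte-Carlo CDF comparison, and continuity across the branch
switch at 10⁻⁶.

## Covariate basis

Age enters through t = log(age + c) with c = 0.75 years, so the basis is
defined from birth and compresses the fast early-life changes onto an
approximately linear scale.  Fractional-polynomial terms t^p with powers
from {−2, −1, −½, 0 → log t, ½, 1, 2, 3} form the age trend: up to three
terms for log μ, two for log σ, and a constant (optionally one term) for
ν.  The location predictor always contains an intercept and a male
indicator; volume regions additionally carry log eTIV centred at
log 1.5·10⁶ mm³ (a typical adult intracranial volume), entering μ only —
head size scales volumes but there is no comparable rationale for a scale
effect, and σ would be weakly identified against it.  Log and fractional
powers require t > 0 (age > 0.25 y) and are rejected otherwise; the
default generator and fits use powers (1, 2), which are valid from birth.

Per-region powers are chosen by BIC over an enumerated candidate list,
deterministic tie-break to fewer terms then lexicographically smaller
powers.  This realizes region-specific smoothness selection with a
criterion that is reproducible and testable (selection consistency is
asserted at n = 5,000 against a refit with the generative powers).

## Reference fit with batch offsets

Scanner site × software version defines a batch.  Batches shift the μ and
σ links additively; shape is batch-free in the reference fit because a
per-batch skew parameter is weakly identified even at thousands of scans
per batch.  The objective is the penalized log likelihood

    Σᵢ log f(yᵢ) − Σ_b δμ_b²/(2τμ²) − Σ_b δσ_b²/(2τσ²),

maximized by L-BFGS-B on link-scale parameters with analytic gradients.
Non-intercept design columns are z-scored internally for conditioning and
coefficients mapped back afterwards.  Three deterministic starts
(lognormal OLS with ν = 1, ν ≈ 0, and a perturbed negative-skew start)
are ranked by 40-iteration pre-solves, and the winner is polished; fixed
start order keeps fits bit-reproducible.  τ² is updated by the
empirical-Bayes fixed point τ² ← mean(δ²); alternating with the inner
maximization is block coordinate ascent on the joint objective including
the −(B/2) log τ² terms, so the monitored objective never decreases (a
test asserts this to 10⁻⁶).  Numerical tolerances: inner ftol 10⁻¹²/gtol
10⁻⁸, outer stop when τ² moves < 1% (far below its sampling error with
~4 batches) or the joint objective moves < 10⁻⁴; τ² has a floor of 10⁻⁶,
and reaching it means "no batch effect" and counts as convergence.  A
warm restart whose line search cannot improve the objective at machine
precision is likewise converged.  Non-converged regions are flagged and
excluded from scoring, never silently used.

With a single batch the offsets are pinned at zero.  With penalized
offsets the model is identified only up to the sample mean of the batch
offsets (absorbed into the intercept); this matters when interpreting
out-of-sample offsets against a generative truth and is handled in the
recovery experiments by simulating the reference with zero batch offsets.

Asymptotic coefficient SEs come from the observed information (central
finite differences of the analytic score, offsets held fixed),
transformed back through the standardization map.

## Out-of-sample calibration and scoring

A new study is aligned by maximizing the frozen-coefficient likelihood
over one (δμ, δσ, δν) triple per region, started at zero, using only that
study's cognitively normal controls (mixed-batch or cognitively abnormal
control sets are rejected).  δν carries a ridge penalty ½·w·δν² with
w = 200 by default: at the recommended ~100 controls a free skew shift is
not meaningfully estimable, so the default keeps δν ≈ 0 unless the
controls strongly demand otherwise; setting w ≈ 0 frees it.  Below 100
controls the result carries a low-sample warning; below 10 calibration is
refused.  Centiles are 100·F(y | adjusted parameters), clamped to
[0.01, 99.99] so downstream rank statistics never see 0/100 artifacts.
Replicate experiments show δμ recovery RMSE of ~0.026 at 25 controls
falling to ~0.012 at 100–200, the empirical content of the ~100-controls
guidance; the residual floor is the reference model's own estimation
error.

## Synthetic study system

The generator draws from the same family and basis the model fits
(recovery tests are then well-posed); a lognormal toggle provides a
misspecification check.  Defaults, chosen to mimic adult morphometry:
thickness trajectories log μ = c₀ − k(t−2)² with peak near age 6 and
k ∈ [0.02, 0.05], parcel medians 2–3 mm, CV 5–8%, ν ∈ [0.6, 1.4]; volume
trajectories peak near age 19 with hippocampus ≈ 4,200 mm³ and amygdala
≈ 1,750 mm³ at the reference head size, eTIV elasticity 0.6–0.9, CV
10–15%.  eTIV is lognormal with a ~10% male shift.  Batch offsets are
mean-zero Gaussian with τμ = 0.02 and τσ = 0.05 on the links.  Ages are
uniform over the configured range — even coverage of the curve support,
not a real age pyramid.

Disease patterns are fixed per-region downward shifts on log μ, scaled
per case by a lognormal severity (SD 0.3) and by a configurable
`effect_scale`: AD is temporo-limbic (hippocampus −0.20, amygdala −0.18,
entorhinal −0.15, inferior/middle temporal −0.10, precuneus and inferior
parietal −0.08); bvFTD is frontal/insular (orbitofrontal −0.20, superior
and rostral-middle frontal −0.18, milder temporo-limbic involvement);
PPA-SV is left-dominant anterior temporal; PPA-PNFA is confined to left
frontal regions (pars triangularis, precentral, caudal middle frontal,
pars opercularis).  Cases are sampled older than controls so the matching
step has work to do.  MMSE is Binomial(30, p) with p linear in the mean
signature-region centile (calibrated so healthy scans sit near 29/30 and
strongly affected cases near 24/30); tau SUVR is lognormal with a
negative loading on the region's own centile in temporal/amygdala regions
and none elsewhere, generated only for the PET-available subset (88%).
The Euler index is lognormal with 5% of subjects inflated ×8 to give the
MAD filter something to remove.  The joint distribution of cognition, tau
and atrophy in real cohorts is unknown; these linkages are modelling
choices for testability — passing tests demonstrate the pipeline's
statistical machinery and sign conventions, not cohort-level effect
sizes, which is also why synthetic AUCs run higher than any real study's.

## Cohort statistics

Spearman correlations use midranks; BH correction runs within each
analysis family only — 72 regions for cognition, 70 for tau, where the
hippocampi are excluded because hippocampal flortaucipir signal is
contaminated by choroid-plexus off-target binding (region-wise pairing:
each region's SUVR against its own centile).  Propensity matching fits an
age+sex logistic model and matches greedily 1:1 without replacement or
caliper, cases in descending propensity order, seeded shuffle breaking
exact-distance ties; balance is reported as age SMD, chi-squared for sex
and Mann–Whitney for age, pre and post.  Discrimination fits unpenalized
logistic models per ROI and for the 14-predictor combined signature set
(left/right entered separately); AUCs are computed on fitted
probabilities with DeLong placement-variance CIs, and paired model
comparison uses the midrank DeLong test.  Youden cut-points scan all
observed score values with "positive = centile ≤ t", tie-break to the
lowest threshold, and also report a fixed grid down to the 1st centile.
Cross-validation is stratified 10-fold, repeated 10 times by default with
out-of-fold probabilities pooled per repeat and sensitivity/specificity
taken at probability 0.5.  The Euler MAD filter keeps subjects with
index ≤ median + 2·MAD using the unscaled MAD and an inclusive boundary —
a strict "<" degenerates to excluding everyone when MAD = 0 — with both
choices toggleable.

## Determinism and I/O

Every stochastic step takes an explicit seed (numpy Generator seeded via
SeedSequence); fits use fixed start orders; the pipeline manifest hashes
every artifact and embeds no wall-clock time, so identical configs
reproduce identical bytes.  Models and offsets serialize to versioned
JSON with a SHA-256 checksum over the canonical payload; loading verifies
both.  FreeSurfer stats files are parsed by column *name* from the
`# ColHeaders` line (permutation-proof), eTIV from the
`EstimatedTotalIntraCranialVol` measure line; unknown rows are skipped
with a notice, missing required rows are hard errors naming the file and
structure.

## Problem sizes

The acceptance checks use a 20,000-scan, 4-batch reference with 10,000
held-out scans for decile calibration; 100 calibration replicates at each
of 25/50/100/200 controls; 50 seeded case–control studies (120 cases /
360 controls, effect scale 0.6) for the centile-vs-raw comparison plus
one larger study (250/500) with a widened age range for the DeLong check;
and cohorts of 120 cases for the sign-structure and pattern-separation
analyses.  These sizes make every Monte-Carlo tolerance comfortably
larger than its sampling noise while the whole suite completes on a
single CPU in minutes.

## Known limitations

Cross-sectional only — no longitudinal within-subject modelling.  One
offset triple per study (no age-dependent batch effects).  ν is modelled
as a constant per region by default.  The synthetic generator shares the
model's family and basis, so calibration results on it bound what
correct-specification performance looks like; the lognormal toggle probes
misspecification but real-data deviations (heavy tails, segmentation
failures, site-by-age interactions) are out of scope.  Subjects missing
any region are excluded from reference fitting but can still be scored
for the regions they have.
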