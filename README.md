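# regionchart

Regional lifespan normative brain charts: per-region distributional
regression models that convert a single structural MRI measurement —
cortical thickness of a Desikan-Killiany parcel, or hippocampal/amygdala
volume — into an age-, sex- and head-size-adjusted **centile score**, plus
the cohort-level statistics used to evaluate such scores in dementia
research (case–control discrimination, cognition and tau-PET correlations,
quality filtering, cut-point selection).

It is written for neuroimaging statisticians and dementia researchers who
want a growth-chart-style reference frame for FreeSurfer morphometry:
72 regions (34 Desikan-Killiany parcels × 2 hemispheres as thickness, plus
bilateral hippocampus and amygdala as eTIV-adjusted volume), each modelled
independently across the lifespan, with out-of-sample calibration so that
scans from a *new* scanner can be scored against the same reference.
Because real multi-site reference cohorts are access-controlled, the
package ships a first-class synthetic-data module that generates reference
populations and clinical study cohorts with known ground truth; every
stage of the pipeline is tested against that truth.

## The model

Each region's measurement *y* > 0 follows a generalized gamma distribution
with location μ, scale σ and shape ν (GAMLSS-style distributional
regression; ν = 1 gives the gamma, ν → 0 the lognormal):

    log μ = β₀ + Σₖ βₖ t^{pₖ} + β_sex·male [+ β_eTIV·(log eTIV − c̄)]   (volumes only)
    log σ = γ₀ + Σₖ γₖ t^{qₖ}
        ν = δ₀

with t = log(age + 0.75) and fractional-polynomial powers p, q chosen per
region by BIC from {−2, −1, −½, 0(log), ½, 1, 2, 3}.  Scanner/study
batches enter as penalized offsets on the μ and σ links; the offset
variances are updated by an empirical-Bayes fixed point, so offsets are
shrunk toward zero exactly as random effects would be.

A new study is calibrated by maximum likelihood: with the reference
coefficients frozen, one offset triple (δμ, δσ, δν) per region is
estimated from that study's cognitively normal controls (≈100 controls
per scanner are recommended; fewer raises a warning).  A subject's centile
is then 100·F(y | offset-adjusted μ, σ, ν), clamped to [0.01, 99.99].

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
cohorts and write tidy tables under `results/`:

```
python analysis/01_simulate_cohorts.py      # reference (10,000 scans, 4 batches) + AD/bvFTD/PPA studies
python analysis/02_fit_reference_model.py   # 72 normative fits + held-out calibration check
python analysis/03_calibrate_and_score.py   # study offsets + centile tables
python analysis/04_ad_cohort_analysis.py    # correlations, matching, AUCs, cut-points, CV
python analysis/05_ftld_patterns.py         # FTLD phenotype patterns, bvFTD-vs-AD ranking
python analysis/06_individual_reports.py    # lobe-grouped individual reports
```

Output from a run of steps 02 and 04:

```
fitted 72 regions on 7500 subjects; 72 converged
max decile error: 0.11 pp on 2500 held-out subjects

MMSE vs centile in signature regions: rho 0.37..0.57, all BH-significant: True
tau vs centile: 20 regions with significant negative rho (strongest -0.94)
Euler filter: kept 467, excluded 83 (threshold 98)
matched 150 pairs; age SMD 0.91 -> 0.09
combined AUC: centile 1.000 vs raw 0.997 (DeLong Z 1.70, p 0.09)
optimal centile cut-points: median 17 (range 8-30)
10x10 CV: mean AUC 0.995, sens 0.96, spec 0.96
```

Reading these numbers: held-out subjects from the reference batches score
uniform centiles (every decile within 0.11 percentage points of nominal),
i.e. the charts are calibrated.  In the synthetic AD study, lower
signature-region centiles go with lower MMSE and higher regional tau
SUVR; propensity matching removes the designed age imbalance between
cases and controls (standardized mean difference 0.91 → 0.09); and
centile scores discriminate cases from matched controls at least as well
as raw values.  Because these cohorts are synthetic with configurable
effect sizes, the *magnitudes* (near-perfect AUCs under the default
atrophy shifts) are properties of the generator, not claims about real
cohorts — the directions and orderings are what the pipeline asserts.

A `regionchart` command-line interface wraps the same steps
(`simulate | fit | calibrate | score | analyze | report | run`); `run`
executes a configured multi-stage pipeline and writes a hash manifest so
that identical configs reproduce identical artifacts.

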