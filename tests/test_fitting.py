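import numpy as np
import pandas as pd
import pytest

from regionchart.basis import BasisSpec
from regionchart.distributions import gg_log_density, gg_ppf, gg_rvs
from regionchart.fitting import (fit_reference_model, fit_region, select_by_bic,
                                 select_fp_powers)
from regionchart.synthetic import (SimulationConfig,
                                   generate_reference_population, make_truth)
from regionchart.tables import CohortTable


def _flat_cohort(n, age, value_fn, rng, region="lh_precuneus", batches=1):
    ages = np.full(n, age) if np.isscalar(age) else age
    meta = pd.DataFrame({
        "age": ages,
        "sex": ["F"] * n,
        "batch": [f"b{i % batches}" for i in range(n)],
        "etiv": np.full(n, 1.5e6),
    }, index=pd.Index([f"s{i}" for i in range(n)], name="subject"))
    values = pd.DataFrame({region: value_fn(ages)}, index=meta.index)
    return CohortTable(meta=meta, values=values)


def test_intercept_only_fit_matches_grid_search_mle(rng):
    """On constant covariates the fit equals a brute-force 3-parameter MLE."""
    mu0, sig0, nu0 = 3.0, 0.2, 0.8
    y = gg_rvs(mu0, sig0, nu0, size=500, rng=rng)
    spec = BasisSpec(mu_powers=(), sigma_powers=(), nu_powers=())
    m = fit_region(y, np.full(500, 50.0), np.zeros(500), np.full(500, 1.5e6),
                   np.array(["b0"] * 500), spec, compute_se=False)

    # independent oracle: iteratively refined grid search on the link scales
    center = np.array([np.log(np.mean(y)), np.log(0.3), 0.0])
    width = np.array([0.3, 1.0, 2.0])
    for _ in range(6):
        axes = [np.linspace(c - w, c + w, 21) for c, w in zip(center, width)]
        G = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        ll = np.array([
            np.sum(gg_log_density(y, np.exp(g[0]), np.exp(g[1]), g[2])) for g in G
        ])
        center = G[np.argmax(ll)]
        width = width / 5.0
    assert m.beta_mu[0] == pytest.approx(center[0], abs=1e-3)
    assert m.beta_sigma[0] == pytest.approx(center[1], abs=1e-3)
    assert m.beta_nu[0] == pytest.approx(center[2], abs=1e-3)


def test_known_coefficients_recovered_within_three_ses():
    """n=5,000 single-region fit recovers every generative coefficient."""
    truth = make_truth(n_batches=1, seed=5)
    cfg = SimulationConfig(n_batches=1, subjects_per_batch=5000, seed=5)
    cohort, truth = generate_reference_population(cfg, truth=truth)
    region = "Left-Hippocampus"
    model = fit_reference_model(cohort, regions=[region], min_n=100,
                                compute_se=True)
    m = model[region]
    assert m.converged
    for hat, true, se in [
        (m.beta_mu, truth.beta_mu[region], m.se_mu),
        (m.beta_sigma, truth.beta_sigma[region], m.se_sigma),
        (m.beta_nu, np.array([truth.nu[region]]), m.se_nu),
    ]:
        np.testing.assert_array_less(np.abs(hat - true), 3.0 * se)


def test_single_batch_pins_offsets_at_zero(small_model):
    # the conftest model has 3 batches; refit one region on one batch
    truth = make_truth(n_batches=1, seed=9)
    cfg = SimulationConfig(n_batches=1, subjects_per_batch=800, seed=9)
    cohort, _ = generate_reference_population(cfg, truth=truth)
    model = fit_reference_model(cohort, regions=["lh_cuneus"], min_n=100)
    m = model["lh_cuneus"]
    assert np.all(m.delta_mu == 0.0) and np.all(m.delta_sigma == 0.0)
    assert m.tau2_mu == 0.0


def test_zero_offset_batches_recover_null_offsets():
    """Multi-batch data generated with zero offsets: tau2 < 1e-4, offsets ~ 0."""
    truth = make_truth(n_batches=3, seed=11, zero_offsets=True)
    cfg = SimulationConfig(n_batches=3, subjects_per_batch=700, seed=11)
    cohort, _ = generate_reference_population(cfg, truth=truth)
    model = fit_reference_model(cohort, regions=["lh_fusiform"], min_n=100)
    m = model["lh_fusiform"]
    assert m.tau2_mu < 1e-4 and m.tau2_sigma < 1e-4
    assert np.max(np.abs(m.delta_mu)) < 0.01


def test_joint_objective_never_decreases(small_ref):
    cohort, _ = small_ref
    from regionchart.fitting import _cohort_arrays, default_spec_for

    y, age, male, etiv, batch = _cohort_arrays(cohort, "rh_superiorfrontal")
    mon = []
    fit_region(y, age, male, etiv, batch, default_spec_for("rh_superiorfrontal"),
               monitor=mon, compute_se=False)
    diffs = np.diff(np.array(mon))
    assert np.all(diffs > -1e-6)


def test_offset_shrinkage_limits():
    """tau2 -> 0 pins offsets; tau2 -> inf recovers per-batch fits."""
    truth = make_truth(n_batches=3, seed=13)
    cfg = SimulationConfig(n_batches=3, subjects_per_batch=400, seed=13)
    cohort, _ = generate_reference_population(cfg, truth=truth)
    from regionchart.fitting import _cohort_arrays, default_spec_for

    region = "lh_lingual"
    spec = default_spec_for(region)
    y, age, male, etiv, batch = _cohort_arrays(cohort, region)

    tight = fit_region(y, age, male, etiv, batch, spec,
                       fix_tau2=(1e-10, 1e-10), compute_se=False)
    assert np.max(np.abs(tight.delta_mu)) < 1e-3

    loose = fit_region(y, age, male, etiv, batch, spec,
                       fix_tau2=(1e6, 1e6), compute_se=False)
    # oracle: with the coefficients frozen at the joint estimates, each
    # batch's unpenalized offset MLE (independent 2-parameter optimization)
    # must coincide with the fitted offsets when the penalty vanishes
    from regionchart.basis import build_design_basis
    from regionchart.calibration import _region_offset_fit

    X = build_design_basis(age, male, etiv, spec)
    eta_mu = X["mu"] @ loose.beta_mu
    eta_s = X["sigma"] @ loose.beta_sigma
    nu0 = X["nu"] @ loose.beta_nu
    for b, label in enumerate(sorted(set(batch))):
        mask = batch == label
        d, ok = _region_offset_fit(np.log(y[mask]), eta_mu[mask], eta_s[mask],
                                   nu0[mask], nu_ridge=1e12)
        assert ok
        assert loose.delta_mu[b] == pytest.approx(d[0], abs=2e-3)
        assert loose.delta_sigma[b] == pytest.approx(d[1], abs=2e-3)


def test_etiv_changes_location_but_not_quantile_centile(small_model):
    """Same conditional quantile -> same centile, despite different eTIV."""
    m = small_model["Left-Hippocampus"]
    from regionchart.distributions import gg_cdf

    mus, sigmas, nus = [], [], []
    for etiv in (1.3e6, 1.7e6):
        mu, sigma, nu = m.params_for([70.0], [1.0], [etiv])
        mus.append(mu[0]); sigmas.append(sigma[0]); nus.append(nu[0])
    assert mus[0] != pytest.approx(mus[1], rel=1e-3)
    for q in (0.1, 0.5, 0.9):
        y0 = gg_ppf(q, mus[0], sigmas[0], nus[0])
        y1 = gg_ppf(q, mus[1], sigmas[1], nus[1])
        assert gg_cdf(y0, mus[0], sigmas[0], nus[0]) == pytest.approx(
            gg_cdf(y1, mus[1], sigmas[1], nus[1]), abs=1e-10
        )


def test_min_n_guard_names_the_region(small_ref):
    cohort, _ = small_ref
    with pytest.raises(ValueError, match="lh_cuneus"):
        fit_reference_model(cohort, regions=["lh_cuneus"], min_n=10**6)


# ----------------------------------------------------------------------
# FP power selection


def test_bic_tie_breaks_to_fewer_terms_then_lexicographic():
    assert select_by_bic([(1.0,), (1.0, 2.0)], [100.0, 100.0]) == (1.0,)
    assert select_by_bic([(2.0,), (1.0,)], [50.0, 50.0]) == (1.0,)
    assert select_by_bic([(1.0,), (1.0, 2.0)], [100.0, 90.0]) == (1.0, 2.0)


def test_single_candidate_returned_unchanged(small_ref):
    cohort, _ = small_ref
    spec = select_fp_powers(cohort, "lh_precuneus", candidates=[(1.0, 2.0)])
    assert spec.mu_powers == (1.0, 2.0)


def test_selected_powers_fit_at_least_as_well_as_truth():
    """BIC of the selected set is within 2 of refitting the true powers."""
    truth = make_truth(n_batches=1, seed=17)   # generative mu powers are (1, 2)
    cfg = SimulationConfig(n_batches=1, subjects_per_batch=5000, seed=17)
    cohort, _ = generate_reference_population(cfg, truth=truth)
    region = "rh_inferiorparietal"
    candidates = [(1.0,), (2.0,), (1.0, 2.0), (0.5, 1.0)]
    chosen = select_fp_powers(cohort, region, candidates=candidates)

    from regionchart.fitting import _cohort_arrays, default_spec_for

    y, age, male, etiv, batch = _cohort_arrays(cohort, region)
    bics = {}
    for powers in [(1.0, 2.0), chosen.mu_powers]:
        spec = BasisSpec(mu_powers=powers)
        bics[powers] = fit_region(y, age, male, etiv, batch, spec,
                                  compute_se=False).bic
    assert bics[chosen.mu_powers] <= bics[(1.0, 2.0)] + 2.0


def test_no_converging_candidate_is_an_error(rng):
    cohort = _flat_cohort(
        150, rng.uniform(0.0, 0.2, 150), lambda a: rng.uniform(2.0, 3.0, 150), rng
    )
    # fractional power requires log(age + c) > 0, impossible for these ages
    with pytest.raises(RuntimeError, match="no candidate"):
        select_fp_powers(cohort, "lh_precuneus", candidates=[(0.5,)], min_n=50)
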