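import numpy as np
import pandas as pd
import pytest
from scipy import stats

from regionchart.catalog import CATALOG
from regionchart.distributions import gg_cdf, gg_median
from regionchart.synthetic import (
    SimulationConfig, generate_clinical_study, generate_reference_population,
    make_truth,
)


def _study(truth, **kw):
    defaults = dict(disease_pattern="AD", n_cases=150, n_controls=150, seed=5)
    defaults.update(kw)
    return generate_clinical_study(truth, SimulationConfig(**defaults))


def test_same_config_and_seed_is_byte_identical(tmp_path):
    cfg = SimulationConfig(n_batches=2, subjects_per_batch=50, seed=9)
    a, _ = generate_reference_population(cfg)
    b, _ = generate_reference_population(cfg)
    pa = a.to_csv(tmp_path / "a")
    pb = b.to_csv(tmp_path / "b")
    for key in pa:
        assert open(pa[key], "rb").read() == open(pb[key], "rb").read()


def test_empirical_median_matches_generative_median_curve():
    """y_i / median(mu_i, sigma_i, nu_i) has empirical median 1 at n=20,000."""
    truth = make_truth(n_batches=1, seed=21)
    cfg = SimulationConfig(n_batches=1, subjects_per_batch=20_000, seed=21)
    cohort, truth = generate_reference_population(cfg, truth=truth)
    meta = cohort.meta
    male = (meta["sex"] == "M").to_numpy(float)
    for region in ("lh_superiorfrontal", "Left-Hippocampus"):
        mu, sigma, nu = truth.region_params(
            region, meta["age"].to_numpy(), male, meta["etiv"].to_numpy(),
            batch=cohort.batches[0],
        )
        ratio = cohort.values[region].to_numpy() / gg_median(mu, sigma, nu)
        assert np.median(ratio) == pytest.approx(1.0, abs=0.01)


def test_sex_proportion_within_three_binomial_sds():
    cfg = SimulationConfig(n_batches=1, subjects_per_batch=10_000,
                           sex_proportion_female=0.5, seed=4)
    cohort, _ = generate_reference_population(cfg)
    frac = (cohort.meta["sex"] == "F").mean()
    assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / 10_000)


def test_all_values_positive_and_finite(small_ref):
    cohort, _ = small_ref
    v = cohort.values.to_numpy()
    assert np.all(np.isfinite(v)) and np.all(v > 0)


def test_zero_offset_batches_are_exchangeable():
    """Two-sample KS between batches is non-significant (alpha=0.01) in
    >= 95% of (seed, region) draws when offsets and disease are absent."""
    n_ok = n_tot = 0
    for seed in range(12):
        truth = make_truth(n_batches=2, seed=seed, zero_offsets=True)
        cfg = SimulationConfig(n_batches=2, subjects_per_batch=1000, seed=seed)
        cohort, _ = generate_reference_population(cfg, truth=truth)
        b0, b1 = cohort.batches
        g0 = cohort.values[cohort.meta["batch"] == b0]
        g1 = cohort.values[cohort.meta["batch"] == b1]
        for region in CATALOG.names[::12]:
            p = stats.ks_2samp(g0[region], g1[region]).pvalue
            n_ok += p > 0.01
            n_tot += 1
    assert n_ok / n_tot >= 0.95


def test_volumes_track_etiv_but_thickness_does_not(small_ref):
    cohort, truth = small_ref
    etiv = cohort.meta["etiv"]
    r_vol = stats.spearmanr(etiv, cohort.values["Left-Hippocampus"]).statistic
    assert r_vol > 0.3
    assert not truth.specs["lh_precuneus"].include_etiv
    assert truth.specs["Left-Hippocampus"].include_etiv


def test_pure_control_study_has_no_cases():
    truth = make_truth(seed=1)
    study = _study(truth, disease_pattern="none", n_cases=0, n_controls=80)
    assert (study.meta["diagnosis"] == "CN").all()
    assert study.n == 80


def test_ad_cases_have_lower_hippocampal_volume():
    truth = make_truth(seed=1)
    truth.disease_patterns["AD"]["Left-Hippocampus"] = -0.30
    study = _study(truth, n_cases=200, n_controls=200)
    case = study.meta["diagnosis"] != "CN"
    med_case = study.values.loc[case, "Left-Hippocampus"].median()
    med_ctrl = study.values.loc[~case, "Left-Hippocampus"].median()
    assert med_case < med_ctrl


def test_ppa_pnfa_pattern_is_confined_to_left_frontal():
    truth = make_truth(seed=1)
    pattern = truth.disease_patterns["PPA-PNFA"]
    for required in ("lh_parstriangularis", "lh_precentral", "lh_caudalmiddlefrontal"):
        assert pattern[required] < 0
    for region, shift in pattern.items():
        assert region.startswith("lh_")
        assert CATALOG.lobe(region) == "frontal"
        assert shift <= 0


def test_cases_sampled_older_than_controls():
    truth = make_truth(seed=1)
    study = _study(truth, n_cases=300, n_controls=300)
    case = study.meta["diagnosis"] != "CN"
    assert study.meta.loc[case, "age"].mean() > study.meta.loc[~case, "age"].mean()


def test_mmse_and_tau_linkages_have_the_configured_signs():
    """rho(MMSE, signature centile) > 0 and rho(tau, temporal centile) < 0."""
    truth = make_truth(seed=2)
    study = _study(truth, n_cases=150, n_controls=150, with_tau=True, seed=8)
    meta = study.meta
    male = (meta["sex"] == "M").to_numpy(float)
    extra = tuple(study.provenance["study_offsets"])

    sig = [r for r in truth.disease_patterns["AD"]]
    cents = {}
    for region in sig + ["lh_middletemporal"]:
        mu, sigma, nu = truth.region_params(
            region, meta["age"].to_numpy(), male, meta["etiv"].to_numpy(),
            extra=extra,
        )
        cents[region] = 100.0 * gg_cdf(study.values[region].to_numpy(), mu, sigma, nu)
    mean_sig = np.column_stack([cents[r] for r in sig]).mean(axis=1)
    assert stats.spearmanr(meta["mmse"], mean_sig).statistic > 0

    tau = study.tau["lh_middletemporal"]
    avail = tau.notna().to_numpy()
    rho_tau = stats.spearmanr(
        tau[avail], cents["lh_middletemporal"][avail]
    ).statistic
    assert rho_tau < 0


def test_euler_index_has_occasional_gross_outliers():
    truth = make_truth(seed=3)
    study = _study(truth, n_cases=0, n_controls=2000, disease_pattern="none")
    euler = study.meta["euler"]
    frac_outlier = (euler > 4 * euler.median()).mean()
    assert 0.02 < frac_outlier < 0.09


@pytest.mark.parametrize("field,value,msg", [
    ("n_batches", 0, "n_batches"),
    ("subjects_per_batch", 0, "subjects_per_batch"),
    ("age_range", (50.0, 40.0), "age_range"),
    ("sex_proportion_female", 1.5, "sex_proportion_female"),
    ("family", "weibull", "family"),
])
def test_invalid_reference_config_names_offending_field(field, value, msg):
    cfg = SimulationConfig(**{field: value})
    with pytest.raises(ValueError, match=msg):
        cfg.validate(clinical=False)


def test_unknown_disease_pattern_rejected():
    truth = make_truth(seed=1)
    cfg = SimulationConfig(disease_pattern="CJD", n_cases=10, n_controls=10)
    with pytest.raises(ValueError, match="CJD"):
        generate_clinical_study(truth, cfg)


def test_reference_config_rejects_disease_pattern():
    cfg = SimulationConfig(disease_pattern="AD")
    with pytest.raises(ValueError, match="disease_pattern"):
        generate_reference_population(cfg)


def test_truth_round_trips_through_json(tmp_path):
    from regionchart.synthetic import GenerativeTruth

    truth = make_truth(n_batches=2, seed=6)
    truth.to_json(tmp_path / "truth.json")
    back = GenerativeTruth.from_json(tmp_path / "truth.json")
    np.testing.assert_array_equal(
        back.beta_mu["lh_cuneus"], truth.beta_mu["lh_cuneus"]
    )
    pd.testing.assert_frame_equal(
        back.batch_dmu[truth.batch_dmu.columns], truth.batch_dmu
    )
    assert back.nu["Left-Amygdala"] == truth.nu["Left-Amygdala"]
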