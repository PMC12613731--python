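"""Synthetic reference populations and clinical study cohorts.

The generator emulates the statistical structure the analysis assumes:
lifespan age trajectories of cortical thickness and subcortical volume,
sex differences, eTIV scaling of volumes, study-batch offsets on the
mu/sigma links, disease-specific regional atrophy patterns, an MMSE score
linked to signature-region centiles, optional regional tau SUVR with
negative linkage to temporal/amygdala centiles, and a surface-quality
Euler index with occasional gross outliers.  All ground-truth parameters
are retained in :class:`GenerativeTruth` so parameter- and
offset-recovery tests are well-posed.

By default the generative family equals the modelling family (generalized
gamma on the same link-scale bases), so recovery is exact in expectation;
a lognormal toggle provides a model-misspecification robustness check.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .basis import BasisSpec, build_design_basis
from .catalog import (
    AD_SIGNATURE_REGIONS, CATALOG, HEMIS, RegionCatalog, THICKNESS, VOLUME,
)
from .distributions import gg_cdf, gg_rvs
from .tables import CohortTable

#: clinical atrophy patterns: region -> downward shift on the log-mu link.
#: AD follows the temporo-limbic signature (hippocampus, amygdala,
#: entorhinal, inferior/middle temporal, precuneus, inferior parietal);
#: bvFTD is predominantly frontal/insular with milder temporo-limbic
#: involvement; PPA-SV is left-dominant anterior temporal; PPA-PNFA is
#: confined to left frontal regions (pars triangularis/opercularis,
#: precentral, caudal middle frontal).
DISEASE_PATTERNS: dict[str, dict[str, float]] = {}


def _bilateral(parcel: str, shift: float) -> dict[str, float]:
    return {f"{h}_{parcel}": shift for h in HEMIS}


def _build_patterns() -> None:
    ad: dict[str, float] = {}
    for parcel, shift in [("entorhinal", -0.15), ("inferiortemporal", -0.10),
                          ("middletemporal", -0.10), ("precuneus", -0.08),
                          ("inferiorparietal", -0.08)]:
        ad.update(_bilateral(parcel, shift))
    ad.update({"Left-Hippocampus": -0.20, "Right-Hippocampus": -0.20,
               "Left-Amygdala": -0.18, "Right-Amygdala": -0.18})

    bvftd: dict[str, float] = {}
    for parcel, shift in [("superiorfrontal", -0.18), ("caudalmiddlefrontal", -0.16),
                          ("parsopercularis", -0.14), ("lateralorbitofrontal", -0.20),
                          ("rostralmiddlefrontal", -0.18), ("parsorbitalis", -0.16),
                          ("parstriangularis", -0.14), ("medialorbitofrontal", -0.20),
                          ("frontalpole", -0.16), ("insula", -0.12),
                          ("middletemporal", -0.06)]:
        bvftd.update(_bilateral(parcel, shift))
    bvftd.update({"Left-Hippocampus": -0.08, "Right-Hippocampus": -0.08,
                  "Left-Amygdala": -0.10, "Right-Amygdala": -0.10})

    ppa_sv = {
        "lh_temporalpole": -0.28, "lh_entorhinal": -0.22,
        "lh_inferiortemporal": -0.15, "lh_middletemporal": -0.15,
        "lh_fusiform": -0.12, "lh_superiortemporal": -0.10,
        "rh_temporalpole": -0.10,
        "Left-Amygdala": -0.20, "Left-Hippocampus": -0.15,
        "Right-Amygdala": -0.08,
    }
    ppa_pnfa = {
        "lh_parstriangularis": -0.18, "lh_precentral": -0.15,
        "lh_caudalmiddlefrontal": -0.15, "lh_parsopercularis": -0.12,
    }
    DISEASE_PATTERNS.update(
        {"AD": ad, "bvFTD": bvftd, "PPA-SV": ppa_sv, "PPA-PNFA": ppa_pnfa}
    )


_build_patterns()

KNOWN_PATTERNS = ("none",) + tuple(DISEASE_PATTERNS)

#: temporal + amygdala regions carrying a (negative) tau linkage
TAU_LINKED_REGIONS: tuple[str, ...] = tuple(
    n for n in CATALOG.names
    if CATALOG.lobe(n) == "temporal"
) + ("Left-Amygdala", "Right-Amygdala")


@dataclass
class SimulationConfig:
    """Sampling plan for one generated cohort."""

    n_batches: int = 4
    subjects_per_batch: int = 1000
    age_range: tuple[float, float] = (5.0, 95.0)
    sex_proportion_female: float = 0.5
    disease_pattern: str | None = None
    n_cases: int = 0
    n_controls: int = 0
    seed: int = 0
    # clinical-study extras
    study_id: str = "new_study"
    case_age_range: tuple[float, float] = (65.0, 90.0)
    control_age_range: tuple[float, float] = (55.0, 85.0)
    study_offsets: tuple[float, float, float] | None = None
    effect_scale: float = 1.0          # multiplies the pattern's atrophy shifts
    with_mmse: bool = True
    with_tau: bool = False
    pet_fraction: float = 0.88
    with_euler: bool = True
    family: str = "gg"   # or "lognormal" (misspecification toggle)

    def validate(self, clinical: bool = False) -> None:
        if self.n_batches < 1:
            raise ValueError("n_batches must be positive")
        if not clinical and self.subjects_per_batch < 1:
            raise ValueError("subjects_per_batch must be positive")
        for name, rng in (("age_range", self.age_range),
                          ("case_age_range", self.case_age_range),
                          ("control_age_range", self.control_age_range)):
            lo, hi = rng
            if not (0.0 <= lo < hi <= 100.0):
                raise ValueError(f"{name} must satisfy 0 <= lo < hi <= 100, got {rng}")
        if not (0.0 <= self.sex_proportion_female <= 1.0):
            raise ValueError(
                f"sex_proportion_female must lie in [0, 1], got {self.sex_proportion_female}"
            )
        if self.family not in ("gg", "lognormal"):
            raise ValueError(f"family must be 'gg' or 'lognormal', got {self.family!r}")
        if self.effect_scale < 0:
            raise ValueError(f"effect_scale must be >= 0, got {self.effect_scale}")
        if clinical:
            pattern = self.disease_pattern or "none"
            if pattern not in KNOWN_PATTERNS:
                raise ValueError(
                    f"unknown disease_pattern {pattern!r}; known: {KNOWN_PATTERNS}"
                )
            if self.n_cases < 0 or self.n_controls < 0:
                raise ValueError("n_cases and n_controls must be non-negative")
            if self.n_cases + self.n_controls == 0:
                raise ValueError("a clinical study needs n_cases + n_controls > 0")
        elif self.disease_pattern not in (None, "none"):
            raise ValueError(
                "disease_pattern must be unset for a reference population"
            )


@dataclass
class GenerativeTruth:
    """Every parameter used to generate data, retained for recovery tests."""

    specs: dict[str, BasisSpec]            # region -> basis
    beta_mu: dict[str, np.ndarray]
    beta_sigma: dict[str, np.ndarray]
    nu: dict[str, float]
    batch_dmu: pd.DataFrame                # batch x region
    batch_dsigma: pd.DataFrame
    tau_mu: float
    tau_sigma: float
    disease_patterns: dict[str, dict[str, float]]
    mmse_base: float
    mmse_slope: float
    tau_slopes: dict[str, float]           # <= 0; 0 outside temporal/amygdala
    euler_log_mean: float
    euler_log_sd: float
    euler_outlier_frac: float
    euler_outlier_mult: float
    seed: int
    family: str = "gg"

    def __post_init__(self) -> None:
        for name, pattern in self.disease_patterns.items():
            for region, shift in pattern.items():
                if shift > 0:
                    raise ValueError(
                        f"pattern {name!r}: atrophy shift for {region} must be <= 0"
                    )
        for region, slope in self.tau_slopes.items():
            if region in TAU_LINKED_REGIONS and slope > 0:
                raise ValueError(f"tau slope for {region} must be <= 0")

    @property
    def batches(self) -> list[str]:
        return list(self.batch_dmu.index)

    def region_params(self, region: str, age, male, etiv,
                      batch: str | None = None,
                      log_mu_shift=0.0,
                      extra=(0.0, 0.0, 0.0)):
        """True conditional (mu, sigma, nu) for given covariates."""
        spec = self.specs[region]
        X = build_design_basis(age, male, etiv, spec)
        dmu = dsig = 0.0
        if batch is not None and batch in self.batch_dmu.index:
            dmu = float(self.batch_dmu.loc[batch, region])
            dsig = float(self.batch_dsigma.loc[batch, region])
        emu, esig, enu = extra
        mu = np.exp(X["mu"] @ self.beta_mu[region] + dmu + emu + log_mu_shift)
        sigma = np.exp(X["sigma"] @ self.beta_sigma[region] + dsig + esig)
        nu_val = self.nu[region] + enu
        nu = np.full(mu.shape, 0.0 if self.family == "lognormal" else nu_val)
        return mu, sigma, nu

    # -- serialization ------------------------------------------------
    def to_json(self, path) -> None:
        doc = {
            "seed": self.seed, "family": self.family,
            "tau_mu": self.tau_mu, "tau_sigma": self.tau_sigma,
            "mmse_base": self.mmse_base, "mmse_slope": self.mmse_slope,
            "euler": [self.euler_log_mean, self.euler_log_sd,
                      self.euler_outlier_frac, self.euler_outlier_mult],
            "specs": {r: s.to_dict() for r, s in self.specs.items()},
            "beta_mu": {r: list(map(float, b)) for r, b in self.beta_mu.items()},
            "beta_sigma": {r: list(map(float, b)) for r, b in self.beta_sigma.items()},
            "nu": {r: float(v) for r, v in self.nu.items()},
            "batch_dmu": self.batch_dmu.to_dict(orient="index"),
            "batch_dsigma": self.batch_dsigma.to_dict(orient="index"),
            "disease_patterns": self.disease_patterns,
            "tau_slopes": self.tau_slopes,
        }
        Path(path).write_text(json.dumps(doc, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "GenerativeTruth":
        doc = json.loads(Path(path).read_text())
        eu = doc["euler"]
        return cls(
            specs={r: BasisSpec.from_dict(d) for r, d in doc["specs"].items()},
            beta_mu={r: np.asarray(b) for r, b in doc["beta_mu"].items()},
            beta_sigma={r: np.asarray(b) for r, b in doc["beta_sigma"].items()},
            nu=doc["nu"],
            batch_dmu=pd.DataFrame.from_dict(doc["batch_dmu"], orient="index"),
            batch_dsigma=pd.DataFrame.from_dict(doc["batch_dsigma"], orient="index"),
            tau_mu=doc["tau_mu"], tau_sigma=doc["tau_sigma"],
            disease_patterns=doc["disease_patterns"],
            mmse_base=doc["mmse_base"], mmse_slope=doc["mmse_slope"],
            tau_slopes=doc["tau_slopes"],
            euler_log_mean=eu[0], euler_log_sd=eu[1],
            euler_outlier_frac=eu[2], euler_outlier_mult=eu[3],
            seed=doc["seed"], family=doc["family"],
        )


# ----------------------------------------------------------------------


def _batch_labels(n_batches: int) -> list[str]:
    # site x FreeSurfer-version labels, mimicking the reference batch design
    return [f"site{b:02d}_fs{'6.0' if b % 2 == 0 else '7.1'}" for b in range(n_batches)]


def make_truth(
    n_batches: int = 4,
    seed: int = 0,
    tau_mu: float = 0.02,
    tau_sigma: float = 0.05,
    zero_offsets: bool = False,
    family: str = "gg",
    catalog: RegionCatalog = CATALOG,
) -> GenerativeTruth:
    """Draw a full set of ground-truth parameters.

    Thickness trajectories peak in childhood and decline on the log-age
    scale; volumes peak in late adolescence, scale with log eTIV and are
    noisier (CV ~12% vs ~6%).  Batch offsets are mean-zero Gaussian on
    the mu and sigma links with SDs ``tau_mu`` / ``tau_sigma``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    specs: dict[str, BasisSpec] = {}
    beta_mu: dict[str, np.ndarray] = {}
    beta_sigma: dict[str, np.ndarray] = {}
    nu: dict[str, float] = {}
    for region in catalog.names:
        metric = catalog.metric(region)
        spec = BasisSpec(include_etiv=(metric == VOLUME))
        specs[region] = spec
        if metric == THICKNESS:
            # log mu = c0 - k (t - 2)^2 : peak near age ~6, gentle decline
            k = rng.uniform(0.02, 0.05)
            c0 = np.log(rng.uniform(2.0, 3.0))
            bm = [c0 - 4.0 * k, 4.0 * k, -k, rng.uniform(-0.01, 0.02)]
            bs = [np.log(rng.uniform(0.05, 0.08)), rng.uniform(0.0, 0.02)]
            nu[region] = rng.uniform(0.6, 1.4)
        else:
            base = 4200.0 if "Hippocampus" in region else 1750.0
            k = rng.uniform(0.05, 0.10)
            c0 = np.log(base) + rng.normal(0.0, 0.03)
            # peak at t = 3 (age ~19); eTIV elasticity ~0.6-0.9
            bm = [c0 - 9.0 * k, 6.0 * k, -k, rng.uniform(-0.02, 0.02),
                  rng.uniform(0.6, 0.9)]
            bs = [np.log(rng.uniform(0.10, 0.15)), rng.uniform(0.0, 0.015)]
            nu[region] = rng.uniform(0.5, 1.2)
        beta_mu[region] = np.asarray(bm)
        beta_sigma[region] = np.asarray(bs)

    batches = _batch_labels(n_batches)
    shape = (n_batches, len(catalog))
    if zero_offsets or n_batches == 1:
        dmu = np.zeros(shape)
        dsig = np.zeros(shape)
    else:
        dmu = rng.normal(0.0, tau_mu, size=shape)
        dsig = rng.normal(0.0, tau_sigma, size=shape)

    tau_slopes = {
        r: (-rng.uniform(0.4, 0.7) if r in TAU_LINKED_REGIONS else 0.0)
        for r in catalog.names
    }
    return GenerativeTruth(
        specs=specs, beta_mu=beta_mu, beta_sigma=beta_sigma, nu=nu,
        batch_dmu=pd.DataFrame(dmu, index=batches, columns=catalog.names),
        batch_dsigma=pd.DataFrame(dsig, index=batches, columns=catalog.names),
        tau_mu=tau_mu, tau_sigma=tau_sigma,
        disease_patterns={k: dict(v) for k, v in DISEASE_PATTERNS.items()},
        mmse_base=0.758, mmse_slope=0.417,
        tau_slopes=tau_slopes,
        euler_log_mean=float(np.log(60.0)), euler_log_sd=0.4,
        euler_outlier_frac=0.05, euler_outlier_mult=8.0,
        seed=seed, family=family,
    )


def _draw_demographics(rng, n, age_range, p_female):
    age = rng.uniform(age_range[0], age_range[1], size=n)
    female = rng.random(n) < p_female
    sex = np.where(female, "F", "M")
    male = (~female).astype(float)
    log_etiv = rng.normal(np.log(1.40e6) + 0.10 * male, 0.06)
    return age, sex, male, np.exp(log_etiv)


def _sample_values(truth, rng, region, age, male, etiv, batch_label,
                   log_mu_shift=0.0, extra=(0.0, 0.0, 0.0)):
    mu, sigma, nu = truth.region_params(
        region, age, male, etiv, batch=batch_label,
        log_mu_shift=log_mu_shift, extra=extra,
    )
    return gg_rvs(mu, sigma, nu, rng=rng)


def generate_reference_population(
    config: SimulationConfig,
    truth: GenerativeTruth | None = None,
    catalog: RegionCatalog = CATALOG,
) -> tuple[CohortTable, GenerativeTruth]:
    """Generate a healthy multi-batch reference cohort plus its truth."""
    config.validate(clinical=False)
    if truth is None:
        truth = make_truth(config.n_batches, seed=config.seed, family=config.family)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))

    frames = []
    values = {}
    offset = 0
    all_ids, all_age, all_sex, all_male, all_etiv, all_batch = [], [], [], [], [], []
    for b, label in enumerate(truth.batches[: config.n_batches]):
        n = config.subjects_per_batch
        age, sex, male, etiv = _draw_demographics(
            rng, n, config.age_range, config.sex_proportion_female
        )
        ids = [f"ref{offset + i:06d}" for i in range(n)]
        offset += n
        all_ids += ids
        all_age.append(age); all_sex.append(sex)
        all_male.append(male); all_etiv.append(etiv)
        all_batch += [label] * n

    age = np.concatenate(all_age)
    sex = np.concatenate(all_sex)
    male = np.concatenate(all_male)
    etiv = np.concatenate(all_etiv)
    batch = np.asarray(all_batch)

    for region in catalog.names:
        col = np.empty(len(all_ids))
        for label in truth.batches[: config.n_batches]:
            m = batch == label
            col[m] = _sample_values(truth, rng, region, age[m], male[m],
                                    etiv[m], label)
        values[region] = col

    meta = pd.DataFrame(
        {"age": age, "sex": sex, "batch": batch, "etiv": etiv},
        index=pd.Index(all_ids, name="subject"),
    )
    cohort = CohortTable(
        meta=meta,
        values=pd.DataFrame(values, index=meta.index),
        provenance={"source": "synthetic-reference", "seed": config.seed},
    )
    return cohort, truth


def generate_clinical_study(
    truth: GenerativeTruth,
    config: SimulationConfig,
    catalog: RegionCatalog = CATALOG,
) -> CohortTable:
    """Generate a case/control study on a new scanner batch.

    Cases receive pattern-specific downward log-mu shifts scaled by a
    per-subject severity factor and are sampled older than controls;
    MMSE rises with mean signature-region centile; optional tau SUVR
    falls with temporal/amygdala centiles; an Euler index with occasional
    gross outliers exercises the QC filter.
    """
    config.validate(clinical=True)
    pattern_name = config.disease_pattern or "none"
    pattern = truth.disease_patterns.get(pattern_name, {}) if pattern_name != "none" else {}

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    if config.study_offsets is not None:
        extra = tuple(float(v) for v in config.study_offsets)
    else:
        extra = (float(rng.normal(0.0, truth.tau_mu)),
                 float(rng.normal(0.0, truth.tau_sigma)), 0.0)

    n_ca, n_co = config.n_cases, config.n_controls
    age_ca, sex_ca, male_ca, etiv_ca = _draw_demographics(
        rng, n_ca, config.case_age_range, config.sex_proportion_female
    )
    age_co, sex_co, male_co, etiv_co = _draw_demographics(
        rng, n_co, config.control_age_range, config.sex_proportion_female
    )
    age = np.concatenate([age_ca, age_co])
    sex = np.concatenate([sex_ca, sex_co])
    male = np.concatenate([male_ca, male_co])
    etiv = np.concatenate([etiv_ca, etiv_co])
    is_case = np.concatenate([np.ones(n_ca, bool), np.zeros(n_co, bool)])
    n = n_ca + n_co
    ids = [f"{'case' if c else 'ctrl'}{i:05d}" for i, c in enumerate(is_case)]

    severity = np.where(is_case, np.exp(rng.normal(0.0, 0.3, size=n)), 0.0)

    values = {}
    centiles = {}
    for region in catalog.names:
        shift = pattern.get(region, 0.0) * severity * config.effect_scale
        mu0, sigma0, nu0 = truth.region_params(
            region, age, male, etiv, batch=None, extra=extra
        )
        y = gg_rvs(mu0 * np.exp(shift), sigma0, nu0, rng=rng)
        values[region] = y
        # centile against the healthy (shift-free) study distribution
        centiles[region] = 100.0 * gg_cdf(y, mu0, sigma0, nu0)

    meta = pd.DataFrame(
        {
            "age": age, "sex": sex, "batch": config.study_id, "etiv": etiv,
            "diagnosis": np.where(is_case, pattern_name if pattern_name != "none" else "case", "CN"),
        },
        index=pd.Index(ids, name="subject"),
    )

    signature = [r for r in (pattern or dict.fromkeys(AD_SIGNATURE_REGIONS))
                 if r in catalog.names]
    sig_centile = np.column_stack([centiles[r] for r in signature]).mean(axis=1)

    if config.with_mmse:
        p = np.clip(truth.mmse_base + truth.mmse_slope * sig_centile / 100.0,
                    0.02, 0.999)
        meta["mmse"] = rng.binomial(30, p)
    if config.with_euler:
        euler = np.round(np.exp(rng.normal(truth.euler_log_mean,
                                           truth.euler_log_sd, size=n)))
        outlier = rng.random(n) < truth.euler_outlier_frac
        euler[outlier] *= truth.euler_outlier_mult
        meta["euler"] = euler.astype(int)

    tau = None
    if config.with_tau:
        pet = rng.random(n) < config.pet_fraction
        meta["pet_available"] = pet
        cols = {}
        for region in catalog.names:
            slope = truth.tau_slopes.get(region, 0.0)
            base = np.log(1.2) if slope != 0.0 else np.log(1.1)
            log_tau = base + slope * (centiles[region] / 100.0 - 0.5) \
                + rng.normal(0.0, 0.08, size=n)
            col = np.exp(log_tau)
            col[~pet] = np.nan
            cols[region] = col
        tau = pd.DataFrame(cols, index=meta.index)

    return CohortTable(
        meta=meta,
        values=pd.DataFrame(values, index=meta.index),
        tau=tau,
        provenance={
            "source": "synthetic-clinical", "pattern": pattern_name,
            "seed": config.seed, "study_offsets": list(extra),
        },
    )
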