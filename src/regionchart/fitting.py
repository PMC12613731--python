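"""Per-region normative model fitting.

Each region is fitted independently: a generalized-gamma likelihood with
log-linked location mu and scale sigma and identity-linked shape nu, each
a linear predictor over a fractional-polynomial age basis (plus sex, plus
centred log eTIV for volumes).  Study/scanner batches enter as penalized
additive offsets on the mu and sigma links,

    maximize  sum_i log f(y_i | mu_i, sigma_i, nu)
              - sum_b d_mu_b^2 / (2 tau_mu^2) - sum_b d_sig_b^2 / (2 tau_sig^2),

with the offset variances tau^2 updated by a fixed-point (empirical
Bayes) step tau^2 <- mean(d^2); alternating the inner quasi-Newton
maximization with the tau update is block coordinate ascent on the joint
objective including the -(B/2) log tau^2 terms, so the monitored joint
objective is non-decreasing.  Shape is batch-free in the reference fit
(study-level shape offsets appear only in out-of-sample calibration).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .basis import BasisSpec, build_design_basis, candidate_mu_power_sets
from .catalog import CATALOG, VOLUME, RegionCatalog
from .distributions import NU_SMALL, loglik_gradients, _stable_A
from .tables import CohortTable

logger = logging.getLogger(__name__)

#: variance floor for the offset fixed point; reaching it means "no batch
#: effect" (offsets shrunk to ~0) and counts as convergence
TAU2_FLOOR = 1e-6
#: default convergence tolerances
REL_LL_TOL = 1e-8
ABS_LL_TOL = 1e-4
MAX_OUTER = 50


def _loglik_kernel(t, sigma, nu):
    """Per-observation log density *excluding* the -log y Jacobian term."""
    out = np.empty(t.shape)
    small = np.abs(nu) < NU_SMALL
    if np.any(small):
        ts, ss, ns = t[small], sigma[small], nu[small]
        quad = ts * ts / (2.0 * ss * ss)
        out[small] = -np.log(ss) - 0.5 * np.log(2.0 * np.pi) - quad * (1.0 + ns * ts / 3.0)
    big = ~small
    if np.any(big):
        tg, sg, ng = t[big], sigma[big], nu[big]
        theta = 1.0 / (sg * sg * ng * ng)
        nt = ng * tg
        w = np.expm1(nt) - nt
        out[big] = np.log(np.abs(ng)) + _stable_A(theta) - theta * w
    return out


@dataclass
class RegionModel:
    """Fitted normative model for one region."""

    region: str
    spec: BasisSpec
    beta_mu: np.ndarray
    beta_sigma: np.ndarray
    beta_nu: np.ndarray
    batch_labels: list[str]
    delta_mu: np.ndarray
    delta_sigma: np.ndarray
    tau2_mu: float
    tau2_sigma: float
    loglik: float
    bic: float
    converged: bool
    n_obs: int
    n_iter: int
    se_mu: np.ndarray | None = None
    se_sigma: np.ndarray | None = None
    se_nu: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.beta_mu) != len(self.spec.mu_columns):
            raise ValueError("beta_mu length does not match basis spec")
        if len(self.beta_sigma) != len(self.spec.sigma_columns):
            raise ValueError("beta_sigma length does not match basis spec")
        if self.tau2_mu < 0 or self.tau2_sigma < 0:
            raise ValueError("offset variances must be non-negative")

    def batch_offsets(self, batch: str | None) -> tuple[float, float]:
        if batch is None:
            return 0.0, 0.0
        try:
            b = self.batch_labels.index(batch)
        except ValueError:
            raise KeyError(
                f"batch {batch!r} was not in the reference fit for {self.region}"
            ) from None
        return float(self.delta_mu[b]), float(self.delta_sigma[b])

    def params_for(self, age, sex_male, etiv, batch: str | None = None,
                   extra_offsets: tuple[float, float, float] = (0.0, 0.0, 0.0)):
        """Conditional (mu, sigma, nu) for given covariates.

        ``batch`` selects a fitted reference-batch offset; ``extra_offsets``
        adds an out-of-sample (d_mu, d_sigma, d_nu) triple on the links.
        """
        X = build_design_basis(age, sex_male, etiv, self.spec)
        dmu_b, dsig_b = self.batch_offsets(batch)
        dmu, dsig, dnu = extra_offsets
        mu = np.exp(X["mu"] @ self.beta_mu + dmu_b + dmu)
        sigma = np.exp(X["sigma"] @ self.beta_sigma + dsig_b + dsig)
        nu = X["nu"] @ self.beta_nu + dnu
        return mu, sigma, nu


@dataclass
class ReferenceModelSet:
    """One fitted RegionModel per catalog region, plus provenance."""

    models: dict[str, RegionModel]
    catalog: RegionCatalog = field(default_factory=lambda: CATALOG)
    provenance: dict = field(default_factory=dict)

    def __getitem__(self, region: str) -> RegionModel:
        return self.models[region]

    def __contains__(self, region: str) -> bool:
        return region in self.models

    @property
    def regions(self) -> list[str]:
        return list(self.models)

    def converged_regions(self) -> list[str]:
        return [r for r, m in self.models.items() if m.converged]


def default_spec_for(region: str, catalog: RegionCatalog = CATALOG) -> BasisSpec:
    return BasisSpec(include_etiv=catalog.metric(region) == VOLUME)


# ----------------------------------------------------------------------
# single-region fit


def _standardize(X: np.ndarray):
    """Z-score non-intercept columns; returns (X_std, (means, scales))."""
    m = X.mean(axis=0)
    s = X.std(axis=0)
    m[0], s[0] = 0.0, 1.0
    s[s < 1e-12] = 1.0
    return (X - m) / s, (m, s)


def _affine_T(m: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Map standardized-basis coefficients back to the raw basis."""
    p = len(m)
    T = np.zeros((p, p))
    T[0, 0] = 1.0
    for j in range(1, p):
        T[j, j] = 1.0 / s[j]
        T[0, j] = -m[j] / s[j]
    return T


def _pack(beta_mu, beta_sigma, beta_nu, dmu, dsig, free_offsets):
    parts = [beta_mu, beta_sigma, beta_nu]
    if free_offsets:
        parts += [dmu, dsig]
    return np.concatenate(parts)


def _make_objective(logy, Xmu, Xs, Xnu, codes, n_batches, free_offsets):
    pm, ps, pn = Xmu.shape[1], Xs.shape[1], Xnu.shape[1]
    B = n_batches

    def unpack(params):
        i = 0
        bm = params[i:i + pm]; i += pm
        bs = params[i:i + ps]; i += ps
        bn = params[i:i + pn]; i += pn
        if free_offsets:
            dmu = params[i:i + B]; i += B
            dsig = params[i:i + B]; i += B
        else:
            dmu = np.zeros(B)
            dsig = np.zeros(B)
        return bm, bs, bn, dmu, dsig

    def neg_penalized(params, tau2_mu, tau2_sig):
        bm, bs, bn, dmu, dsig = unpack(params)
        t = logy - (Xmu @ bm + dmu[codes])
        sigma = np.exp(np.clip(Xs @ bs + dsig[codes], -12.0, 6.0))
        nu = Xnu @ bn
        ll = float(np.sum(_loglik_kernel(t, sigma, nu)))
        pen = 0.0
        if free_offsets:
            pen = 0.5 * float(dmu @ dmu) / tau2_mu + 0.5 * float(dsig @ dsig) / tau2_sig
        g_mu, g_sig, g_nu = loglik_gradients(t, sigma, nu)
        grads = [Xmu.T @ g_mu, Xs.T @ g_sig, Xnu.T @ g_nu]
        if free_offsets:
            grads.append(np.bincount(codes, weights=g_mu, minlength=B) - dmu / tau2_mu)
            grads.append(np.bincount(codes, weights=g_sig, minlength=B) - dsig / tau2_sig)
        grad = np.concatenate(grads)
        return -(ll - pen), -grad

    return neg_penalized, unpack


def _starts(logy, Xmu, Xs, Xnu, n_batches, free_offsets):
    """Three deterministic starts: moments-style, lognormal, perturbed."""
    bm0, *_ = np.linalg.lstsq(Xmu, logy, rcond=None)
    resid = logy - Xmu @ bm0
    s0 = float(np.log(max(np.std(resid), 1e-6)))
    bs0 = np.zeros(Xs.shape[1]); bs0[0] = s0
    starts = []
    for nu0, bump in ((1.0, 0.0), (0.05, 0.0), (-0.5, 0.05)):
        bn = np.zeros(Xnu.shape[1]); bn[0] = nu0
        bm = bm0.copy(); bm[0] += bump
        starts.append(_pack(bm, bs0.copy(), bn,
                            np.zeros(n_batches), np.zeros(n_batches), free_offsets))
    return starts


def fit_region(
    y: np.ndarray,
    age: np.ndarray,
    sex_male: np.ndarray,
    etiv: np.ndarray,
    batch: np.ndarray,
    spec: BasisSpec,
    region: str = "region",
    tau2_init: float = 1e-2,
    max_outer: int = MAX_OUTER,
    rel_tol: float = REL_LL_TOL,
    compute_se: bool = True,
    pin_offsets: bool = False,
    fix_tau2: tuple[float, float] | None = None,
    monitor: list | None = None,
) -> RegionModel:
    """Fit one region's normative model.

    ``monitor``, if given, collects the joint objective after every block
    update (used to verify monotone ascent).  ``fix_tau2`` freezes the
    offset variances (no fixed-point updates), which exposes the
    shrinkage behaviour: tau2 -> 0 pins offsets at zero, tau2 -> inf
    recovers per-batch unpenalized estimates.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0) or not np.all(np.isfinite(y)):
        raise ValueError(f"{region}: phenotype values must be positive and finite")
    logy = np.log(y)
    n = len(y)
    X = build_design_basis(age, sex_male, etiv, spec)
    # standardize non-intercept columns for optimizer conditioning;
    # coefficients are mapped back to the raw basis at the end
    Xmu, mu_ms = _standardize(X["mu"])
    Xs, s_ms = _standardize(X["sigma"])
    Xnu, nu_ms = _standardize(X["nu"])

    batch = np.asarray(batch)
    labels, codes = np.unique(batch, return_inverse=True)
    B = len(labels)
    free_offsets = (B > 1) and not pin_offsets

    neg_pen, unpack = _make_objective(logy, Xmu, Xs, Xnu, codes, B, free_offsets)
    sum_logy = float(np.sum(logy))

    # nu intercept bounded to keep theta representable
    npar = Xmu.shape[1] + Xs.shape[1] + Xnu.shape[1] + (2 * B if free_offsets else 0)
    bounds = [(None, None)] * npar
    bounds[Xmu.shape[1] + Xs.shape[1]] = (-8.0, 8.0)

    if fix_tau2 is not None:
        tau2_mu, tau2_sig = (float(v) for v in fix_tau2)
    else:
        tau2_mu = tau2_sig = float(tau2_init)

    def solve(x0, maxiter=300):
        return optimize.minimize(
            neg_pen, x0, args=(tau2_mu, tau2_sig), jac=True,
            method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-8},
        )

    # short pre-solves rank the three deterministic starts; the winner is
    # then polished to tolerance (fixed order keeps the fit deterministic)
    best = None
    for x0 in _starts(logy, Xmu, Xs, Xnu, B, free_offsets):
        res = solve(x0, maxiter=40)
        if best is None or res.fun < best.fun:
            best = res
    best = solve(best.x)

    def joint(res_fun, dmu, dsig):
        # penalized loglik plus the tau normalization terms (block ascent target)
        j = -res_fun
        if free_offsets:
            j -= 0.5 * B * (np.log(tau2_mu) + np.log(tau2_sig))
        return j

    converged = bool(best.success)
    n_iter = int(best.nit)
    if free_offsets and fix_tau2 is None:
        prev_j: float | None = None
        for outer in range(max_outer):
            bm, bs, bn, dmu, dsig = unpack(best.x)
            old_t2 = (tau2_mu, tau2_sig)
            tau2_mu = max(float(np.mean(dmu ** 2)), TAU2_FLOOR)
            tau2_sig = max(float(np.mean(dsig ** 2)), TAU2_FLOOR)
            f, _ = neg_pen(best.x, tau2_mu, tau2_sig)
            j = joint(f, dmu, dsig)
            if monitor is not None:
                monitor.append(j)
            res = solve(best.x)
            n_iter += int(res.nit)
            best = res
            j2 = joint(res.fun, *unpack(best.x)[3:5])
            if monitor is not None:
                monitor.append(j2)
            # tau2 from 4-ish batches carries tens-of-percent sampling error;
            # 1% fixed-point precision is far below that noise
            tau_settled = all(
                abs(new - old) <= 1e-2 * old
                for new, old in zip((tau2_mu, tau2_sig), old_t2)
            )
            j_settled = prev_j is not None and abs(j2 - prev_j) <= max(
                rel_tol * (abs(prev_j) + 1.0), ABS_LL_TOL
            )
            if tau_settled or j_settled:
                # a warm restart that cannot improve (line search exhausted
                # at machine precision) counts as converged
                converged = bool(res.success) or abs(j2 - j) <= ABS_LL_TOL
                break
            prev_j = j2
        else:
            converged = False

    bm_s, bs_s, bn_s, dmu, dsig = unpack(best.x)
    t = logy - (Xmu @ bm_s + dmu[codes])
    sigma = np.exp(Xs @ bs_s + dsig[codes])
    nu = Xnu @ bn_s
    ll = float(np.sum(_loglik_kernel(t, sigma, nu))) - sum_logy
    k = Xmu.shape[1] + Xs.shape[1] + Xnu.shape[1] + (2 * B if free_offsets else 0)
    bic = -2.0 * ll + k * np.log(n)

    # back to the raw basis
    Tm, Ts_, Tn = _affine_T(*mu_ms), _affine_T(*s_ms), _affine_T(*nu_ms)
    bm, bs, bn = Tm @ bm_s, Ts_ @ bs_s, Tn @ bn_s

    se_mu = se_sigma = se_nu = None
    if compute_se:
        try:
            cov = _coef_cov(logy, Xmu, Xs, Xnu, codes, bm_s, bs_s, bn_s, dmu, dsig)
            from scipy.linalg import block_diag
            T = block_diag(Tm, Ts_, Tn)
            se = np.sqrt(np.clip(np.diag(T @ cov @ T.T), 0.0, None))
            pm, ps = Xmu.shape[1], Xs.shape[1]
            se_mu, se_sigma, se_nu = se[:pm], se[pm:pm + ps], se[pm + ps:]
        except np.linalg.LinAlgError:  # pragma: no cover - degenerate design
            logger.warning("%s: singular information matrix; SEs unavailable", region)

    if not converged:
        logger.warning("%s: fit did not converge (flagged)", region)

    return RegionModel(
        region=region, spec=spec,
        beta_mu=bm.copy(), beta_sigma=bs.copy(), beta_nu=bn.copy(),
        batch_labels=[str(b) for b in labels],
        delta_mu=dmu.copy(), delta_sigma=dsig.copy(),
        tau2_mu=(tau2_mu if free_offsets else 0.0),
        tau2_sigma=(tau2_sig if free_offsets else 0.0),
        loglik=ll, bic=float(bic), converged=converged,
        n_obs=n, n_iter=n_iter,
        se_mu=se_mu, se_sigma=se_sigma, se_nu=se_nu,
    )


def _coef_cov(logy, Xmu, Xs, Xnu, codes, bm, bs, bn, dmu, dsig):
    """Asymptotic covariance from the observed information of the coefficients.

    Offsets are held at their fitted values; the Hessian is a central
    finite difference of the analytic score.
    """
    theta0 = np.concatenate([bm, bs, bn])
    pm, ps = len(bm), len(bs)

    def score(theta):
        a = theta[:pm]; b = theta[pm:pm + ps]; c = theta[pm + ps:]
        t = logy - (Xmu @ a + dmu[codes])
        sigma = np.exp(Xs @ b + dsig[codes])
        nu = Xnu @ c
        g_mu, g_sig, g_nu = loglik_gradients(t, sigma, nu)
        return np.concatenate([Xmu.T @ g_mu, Xs.T @ g_sig, Xnu.T @ g_nu])

    p = len(theta0)
    H = np.empty((p, p))
    eps = 1e-5 * np.maximum(np.abs(theta0), 1.0)
    for j in range(p):
        tp = theta0.copy(); tp[j] += eps[j]
        tm = theta0.copy(); tm[j] -= eps[j]
        H[:, j] = (score(tp) - score(tm)) / (2 * eps[j])
    H = 0.5 * (H + H.T)
    return np.linalg.inv(-H)


# ----------------------------------------------------------------------
# cohort-level fitting


def _cohort_arrays(cohort: CohortTable, region: str):
    sub = cohort.complete_subjects([region])
    meta = cohort.meta.loc[sub]
    y = cohort.values.loc[sub, region].to_numpy(dtype=float)
    age = meta["age"].to_numpy(dtype=float)
    male = (meta["sex"] == "M").to_numpy(dtype=float)
    etiv = meta["etiv"].to_numpy(dtype=float)
    batch = meta["batch"].to_numpy()
    return y, age, male, etiv, batch


def cohort_data_hash(cohort: CohortTable) -> str:
    h = hashlib.sha256()
    h.update(pd.util.hash_pandas_object(cohort.values, index=True).values.tobytes())
    h.update(pd.util.hash_pandas_object(
        cohort.meta[["age", "sex", "batch", "etiv"]], index=True).values.tobytes())
    return h.hexdigest()[:16]


def fit_reference_model(
    cohort: CohortTable,
    specs: dict[str, BasisSpec] | None = None,
    regions: list[str] | None = None,
    min_n: int = 500,
    compute_se: bool = False,
    catalog: RegionCatalog = CATALOG,
) -> ReferenceModelSet:
    """Fit every requested region independently on the reference cohort.

    ``specs`` overrides the default basis per region; regions with fewer
    than ``min_n`` complete observations are rejected.  Non-converged
    regions are kept but flagged and excluded by downstream scoring.
    """
    regions = list(regions) if regions is not None else catalog.names
    models: dict[str, RegionModel] = {}
    for region in regions:
        spec = (specs or {}).get(region) or default_spec_for(region, catalog)
        y, age, male, etiv, batch = _cohort_arrays(cohort, region)
        if len(y) < min_n:
            raise ValueError(
                f"region {region!r}: {len(y)} observations < minimum {min_n}"
            )
        models[region] = fit_region(
            y, age, male, etiv, batch, spec, region=region, compute_se=compute_se
        )
    from . import __version__

    return ReferenceModelSet(
        models=models,
        catalog=catalog,
        provenance={
            "data_hash": cohort_data_hash(cohort),
            "software": f"regionchart {__version__}",
            "n_subjects": cohort.n,
            "n_batches": len(cohort.batches),
        },
    )


# ----------------------------------------------------------------------
# fractional-polynomial power selection


def select_by_bic(candidates: list[tuple[float, ...]], bics: list[float],
                  tol: float = 1e-9) -> tuple[float, ...]:
    """Pick the BIC-minimizing power set; ties go to fewer terms, then
    lexicographically smaller powers."""
    order = sorted(
        range(len(candidates)), key=lambda i: (len(candidates[i]), candidates[i])
    )
    best_i = order[0]
    for i in order[1:]:
        if bics[i] < bics[best_i] - tol:
            best_i = i
    return candidates[best_i]


def select_fp_powers(
    cohort: CohortTable,
    region: str,
    candidates: list[tuple[float, ...]] | None = None,
    base_spec: BasisSpec | None = None,
    min_n: int = 100,
) -> BasisSpec:
    """Choose the location-predictor FP powers for one region by BIC."""
    base = base_spec or default_spec_for(region)
    if candidates is None:
        candidates = candidate_mu_power_sets(max_degree=2)
    y, age, male, etiv, batch = _cohort_arrays(cohort, region)
    if len(y) < min_n:
        raise ValueError(f"region {region!r}: too few observations to select powers")

    kept: list[tuple[float, ...]] = []
    bics: list[float] = []
    for powers in candidates:
        spec = BasisSpec(
            mu_powers=tuple(powers), sigma_powers=base.sigma_powers,
            nu_powers=base.nu_powers, include_etiv=base.include_etiv,
            age_offset=base.age_offset, etiv_center=base.etiv_center,
        )
        try:
            m = fit_region(y, age, male, etiv, batch, spec,
                           region=region, compute_se=False)
        except (ValueError, FloatingPointError):  # basis invalid for this age range
            continue
        if not m.converged:
            continue
        kept.append(tuple(powers))
        bics.append(m.bic)
    if not kept:
        raise RuntimeError(f"region {region!r}: no candidate power set converged")
    chosen = select_by_bic(kept, bics)
    return BasisSpec(
        mu_powers=chosen, sigma_powers=base.sigma_powers,
        nu_powers=base.nu_powers, include_etiv=base.include_etiv,
        age_offset=base.age_offset, etiv_center=base.etiv_center,
    )
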