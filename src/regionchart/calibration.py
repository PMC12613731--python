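"""Out-of-sample study calibration and centile scoring.

A new study is aligned to the frozen reference model by maximum-likelihood
estimation of one offset triple (d_mu, d_sigma, d_nu) per region on the
link scales, using only that study's cognitively normal controls.  A mild
ridge on d_nu keeps the weakly identified shape shift near zero unless the
controls strongly demand otherwise.  Centile scores are then
100 * F(y | offset-adjusted parameters), clamped to [0.01, 99.99].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .catalog import CATALOG
from .distributions import gg_cdf, loglik_gradients
from .fitting import ReferenceModelSet, _loglik_kernel
from .basis import build_design_basis
from .tables import CohortTable

logger = logging.getLogger(__name__)

#: below this many controls calibration refuses to run
HARD_FLOOR = 10
#: below this many controls a low-sample warning is attached
WARN_THRESHOLD = 100
#: default ridge weight on the shape offset (penalty = 0.5 * w * d_nu^2)
NU_RIDGE = 200.0

CENTILE_CLAMP = (0.01, 99.99)


@dataclass
class StudyOffsets:
    """Per-region calibration offsets for one study."""

    study: str
    offsets: pd.DataFrame        # index region; columns d_mu, d_sigma, d_nu
    converged: pd.Series         # bool per region
    n_controls: int
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        required = {"d_mu", "d_sigma", "d_nu"}
        if not required <= set(self.offsets.columns):
            raise ValueError(f"offsets frame must carry columns {required}")
        if not np.all(np.isfinite(self.offsets.to_numpy(dtype=float))):
            raise ValueError("offsets must be finite")

    def triple(self, region: str) -> tuple[float, float, float]:
        row = self.offsets.loc[region]
        return float(row["d_mu"]), float(row["d_sigma"]), float(row["d_nu"])

    @property
    def low_sample(self) -> bool:
        return any("low-sample" in w for w in self.warnings)


@dataclass
class CentileTable:
    """Subject x region centile scores in (0, 100), long format."""

    table: pd.DataFrame          # columns subject, region, centile, age, sex, etiv
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        c = self.table["centile"].to_numpy(dtype=float)
        if np.any((c <= 0) | (c >= 100)):
            raise ValueError("centiles must lie strictly inside (0, 100)")

    def wide(self) -> pd.DataFrame:
        w = self.table.pivot(index="subject", columns="region", values="centile")
        w.columns.name = None
        return w

    def for_subject(self, subject: str) -> pd.Series:
        sub = self.table[self.table["subject"] == subject]
        if sub.empty:
            raise KeyError(f"subject {subject!r} not in centile table")
        return sub.set_index("region")["centile"]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CentileTable":
        t = pd.read_csv(path, dtype={"subject": str})
        return cls(table=t, provenance={"source": str(path)})


def _region_offset_fit(logy, Xmu_beta, Xs_beta, nu0, nu_ridge):
    """Maximize the frozen-coefficient likelihood over (d_mu, d_sig, d_nu)."""

    def neg(d):
        dmu, dsig, dnu = d
        t = logy - (Xmu_beta + dmu)
        sigma = np.exp(np.clip(Xs_beta + dsig, -12.0, 6.0))
        nu = nu0 + dnu
        ll = float(np.sum(_loglik_kernel(t, sigma, nu)))
        g_mu, g_sig, g_nu = loglik_gradients(t, sigma, nu)
        grad = np.array([np.sum(g_mu), np.sum(g_sig), np.sum(g_nu) - nu_ridge * dnu])
        return -(ll - 0.5 * nu_ridge * dnu * dnu), -grad

    res = optimize.minimize(
        neg, np.zeros(3), jac=True, method="L-BFGS-B",
        bounds=[(-3.0, 3.0), (-3.0, 3.0), (-4.0, 4.0)],
        options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-8},
    )
    # a line-search abort with a vanished score is a converged optimum;
    # the tolerance scales with n (per-observation score < 1e-5)
    ok = bool(res.success) or float(np.max(np.abs(res.jac))) < 1e-5 * max(len(logy), 100)
    return res.x, ok


def estimate_study_offsets(
    model: ReferenceModelSet,
    controls: CohortTable,
    nu_ridge: float = NU_RIDGE,
    hard_floor: int = HARD_FLOOR,
    regions: list[str] | None = None,
) -> StudyOffsets:
    """Calibrate a new study from its cognitively normal controls.

    All controls must share one batch id (the study label).  Offsets start
    at zero and reference coefficients stay frozen.  Roughly 100 controls
    are needed for stable calibration; fewer attaches a warning, and below
    ``hard_floor`` the estimation is refused.
    """
    batches = controls.meta["batch"].unique()
    if len(batches) != 1:
        raise ValueError(
            f"controls must share a single batch id, found {sorted(batches)}"
        )
    study = str(batches[0])
    if "diagnosis" in controls.meta.columns:
        dx = controls.meta["diagnosis"].dropna().unique()
        abnormal = [d for d in dx if str(d) not in ("CN", "control", "normal")]
        if abnormal:
            raise ValueError(
                f"calibration controls must be cognitively normal; found {abnormal}"
            )
    n = controls.n
    if n < hard_floor:
        raise ValueError(
            f"{n} controls below the hard floor of {hard_floor}; cannot calibrate"
        )
    warnings: list[str] = []
    if n < WARN_THRESHOLD:
        warnings.append(
            f"low-sample calibration: {n} controls < {WARN_THRESHOLD} recommended"
        )

    regions = regions or [r for r in model.regions if model[r].converged]
    rows = {}
    conv = {}
    meta = controls.meta
    age = meta["age"].to_numpy(dtype=float)
    male = (meta["sex"] == "M").to_numpy(dtype=float)
    etiv = meta["etiv"].to_numpy(dtype=float)
    for region in regions:
        rm = model[region]
        avail = controls.values[region].notna().to_numpy()
        if avail.sum() < hard_floor:
            conv[region] = False
            rows[region] = (0.0, 0.0, 0.0)
            warnings.append(f"{region}: too few control values; offsets unset")
            continue
        y = controls.values.loc[avail, region].to_numpy(dtype=float)
        X = build_design_basis(age[avail], male[avail], etiv[avail], rm.spec)
        Xmu_beta = X["mu"] @ rm.beta_mu
        Xs_beta = X["sigma"] @ rm.beta_sigma
        nu0 = X["nu"] @ rm.beta_nu
        d, ok = _region_offset_fit(np.log(y), Xmu_beta, Xs_beta, nu0, nu_ridge)
        rows[region] = tuple(d)
        conv[region] = ok
        if not ok:
            logger.warning("%s: offset estimation did not converge", region)

    offsets = pd.DataFrame.from_dict(rows, orient="index",
                                     columns=["d_mu", "d_sigma", "d_nu"])
    return StudyOffsets(
        study=study, offsets=offsets,
        converged=pd.Series(conv), n_controls=n, warnings=warnings,
    )


def score_centiles(
    model: ReferenceModelSet,
    offsets: StudyOffsets,
    subjects: CohortTable,
    clamp: tuple[float, float] = CENTILE_CLAMP,
) -> CentileTable:
    """Centile-score every available subject-region of a calibrated study.

    Subjects' batch id must equal the offsets' study id (scoring with the
    wrong calibration is refused).  Regions whose offsets failed to
    converge are omitted, never silently scored.
    """
    batches = set(subjects.meta["batch"].unique())
    if batches != {offsets.study}:
        raise ValueError(
            f"subject batches {sorted(batches)} do not match calibrated study "
            f"{offsets.study!r}"
        )
    usable = [r for r in offsets.offsets.index
              if r in model.models and model[r].converged
              and bool(offsets.converged.get(r, False))]
    skipped = [r for r in offsets.offsets.index if r not in usable]
    if skipped:
        logger.warning("regions skipped (failed calibration or fit): %s", skipped)

    meta = subjects.meta
    age = meta["age"].to_numpy(dtype=float)
    male = (meta["sex"] == "M").to_numpy(dtype=float)
    etiv = meta["etiv"].to_numpy(dtype=float)
    records = []
    for region in usable:
        rm = model[region]
        avail = subjects.values[region].notna().to_numpy()
        if not avail.any():
            continue
        y = subjects.values.loc[avail, region].to_numpy(dtype=float)
        mu, sigma, nu = rm.params_for(
            age[avail], male[avail], etiv[avail],
            batch=None, extra_offsets=offsets.triple(region),
        )
        cent = 100.0 * gg_cdf(y, mu, sigma, nu)
        cent = np.clip(cent, clamp[0], clamp[1])
        idx = meta.index[avail]
        for s, a, sx, e, c in zip(idx, age[avail], meta.loc[idx, "sex"],
                                  etiv[avail], cent):
            records.append((s, region, c, a, sx, e))

    table = pd.DataFrame(
        records, columns=["subject", "region", "centile", "age", "sex", "etiv"]
    )
    return CentileTable(
        table=table,
        provenance={
            "study": offsets.study,
            "model_hash": model.provenance.get("data_hash", ""),
            "n_controls": offsets.n_controls,
        },
    )


def score_reference_centiles(
    model: ReferenceModelSet,
    subjects: CohortTable,
    clamp: tuple[float, float] = CENTILE_CLAMP,
) -> CentileTable:
    """Score subjects from the *reference* batches with their fitted offsets.

    Used for held-out calibration checks; each subject's batch must appear
    in the reference fit.
    """
    meta = subjects.meta
    age = meta["age"].to_numpy(dtype=float)
    male = (meta["sex"] == "M").to_numpy(dtype=float)
    etiv = meta["etiv"].to_numpy(dtype=float)
    batch = meta["batch"].astype(str).to_numpy()
    records = []
    for region in model.regions:
        rm = model[region]
        if not rm.converged:
            continue
        avail = subjects.values[region].notna().to_numpy()
        if not avail.any():
            continue
        y = subjects.values.loc[avail, region].to_numpy(dtype=float)
        X = build_design_basis(age[avail], male[avail], etiv[avail], rm.spec)
        unknown = sorted(set(batch[avail]) - set(rm.batch_labels))
        if unknown:
            raise ValueError(
                f"{region}: batches {unknown} were not in the reference fit; "
                "new studies must be calibrated with estimate_study_offsets"
            )
        code = np.array([rm.batch_labels.index(b) for b in batch[avail]])
        mu = np.exp(X["mu"] @ rm.beta_mu + rm.delta_mu[code])
        sigma = np.exp(X["sigma"] @ rm.beta_sigma + rm.delta_sigma[code])
        nu = X["nu"] @ rm.beta_nu
        cent = np.clip(100.0 * gg_cdf(y, mu, sigma, nu), clamp[0], clamp[1])
        idx = meta.index[avail]
        for s, a, sx, e, c in zip(idx, age[avail], meta.loc[idx, "sex"],
                                  etiv[avail], cent):
            records.append((s, region, c, a, sx, e))
    table = pd.DataFrame(
        records, columns=["subject", "region", "centile", "age", "sex", "etiv"]
    )
    return CentileTable(
        table=table,
        provenance={"study": "reference",
                    "model_hash": model.provenance.get("data_hash", "")},
    )
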