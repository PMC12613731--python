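"""Cohort-level statistics over centile tables.

Spearman correlations with Benjamini-Hochberg correction across the
analyzed regions, nearest-neighbour propensity matching on age and sex,
per-ROI and combined logistic discrimination with DeLong confidence
intervals and paired DeLong comparison, Youden-index cut-points,
stratified repeated cross-validation, and the Euler-index MAD quality
filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from statsmodels.stats.multitest import multipletests

from .tables import CohortTable

# ----------------------------------------------------------------------
# Spearman + BH


def spearman_fdr(
    centiles: pd.DataFrame,
    outcome: pd.Series,
    regions: list[str] | None = None,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Spearman rank correlation of each region's centiles with an outcome.

    ``centiles`` is wide (subjects x regions).  BH step-up runs across
    exactly the analyzed regions (72 for MMSE-style analyses, 70 for tau
    where hippocampus is excluded upstream).  Returns a frame sorted by
    adjusted p with columns region, rho, p, p_adj, n.
    """
    regions = list(regions) if regions is not None else list(centiles.columns)
    joined = centiles[regions].join(outcome.rename("__outcome__"), how="inner")
    out_vals = joined["__outcome__"]
    if out_vals.dropna().nunique() <= 1:
        raise ValueError(f"outcome {outcome.name!r} is constant; correlation undefined")

    rows = []
    for region in regions:
        pair = joined[[region, "__outcome__"]].dropna()
        if len(pair) < min_pairs:
            raise ValueError(f"region {region!r}: fewer than {min_pairs} complete pairs")
        rho, p = stats.spearmanr(pair[region], pair["__outcome__"])
        rows.append((region, rho, p, len(pair)))
    frame = pd.DataFrame(rows, columns=["region", "rho", "p", "n"])
    frame["p_adj"] = multipletests(frame["p"].to_numpy(), method="fdr_bh")[1]
    frame = frame[["region", "rho", "p", "p_adj", "n"]]
    return frame.sort_values(["p_adj", "p", "region"], kind="stable").reset_index(drop=True)


def regionwise_spearman_fdr(
    centiles: pd.DataFrame,
    outcomes: pd.DataFrame,
    regions: list[str] | None = None,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Column-wise Spearman: each region's centile against that region's
    own outcome column (e.g. regional tau SUVR), BH across the regions.

    Hippocampus is excluded upstream for tau (70-region family).
    """
    regions = list(regions) if regions is not None else [
        r for r in centiles.columns if r in outcomes.columns
    ]
    rows = []
    for region in regions:
        pair = pd.concat(
            [centiles[region], outcomes[region]], axis=1, join="inner", keys=["c", "o"]
        ).dropna()
        if len(pair) < min_pairs:
            raise ValueError(f"region {region!r}: fewer than {min_pairs} complete pairs")
        rho, p = stats.spearmanr(pair["c"], pair["o"])
        rows.append((region, rho, p, len(pair)))
    frame = pd.DataFrame(rows, columns=["region", "rho", "p", "n"])
    frame["p_adj"] = multipletests(frame["p"].to_numpy(), method="fdr_bh")[1]
    frame = frame[["region", "rho", "p", "p_adj", "n"]]
    return frame.sort_values(["p_adj", "p", "region"], kind="stable").reset_index(drop=True)


# ----------------------------------------------------------------------
# propensity matching


@dataclass
class MatchResult:
    pairs: pd.DataFrame                 # columns case, control
    smd_age_pre: float
    smd_age_post: float
    sex_female_pre: tuple[float, float]   # (cases, controls)
    sex_female_post: tuple[float, float]
    chi2_sex_pre: tuple[float, float]     # (statistic, p)
    chi2_sex_post: tuple[float, float]
    mwu_age_pre: tuple[float, float]
    mwu_age_post: tuple[float, float]
    n_unmatched_cases: int = 0


def _smd(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 2 or len(b) < 2:
        return 0.0
    sd = np.sqrt((np.var(a, ddof=1) + np.var(b, ddof=1)) / 2.0)
    return float((np.mean(a) - np.mean(b)) / sd) if sd > 0 else 0.0


def _balance(cases: pd.DataFrame, controls: pd.DataFrame):
    age_c = cases["age"].to_numpy(float)
    age_k = controls["age"].to_numpy(float)
    fem_c = (cases["sex"] == "F").to_numpy()
    fem_k = (controls["sex"] == "F").to_numpy()
    table = np.array([[fem_c.sum(), (~fem_c).sum()],
                      [fem_k.sum(), (~fem_k).sum()]])
    if np.all(table.sum(axis=0) > 0):
        chi2 = stats.chi2_contingency(table, correction=False)
        chi2_stat = (float(chi2.statistic), float(chi2.pvalue))
    else:
        chi2_stat = (0.0, 1.0)
    mwu = stats.mannwhitneyu(age_c, age_k, alternative="two-sided")
    return (_smd(age_c, age_k), (float(fem_c.mean()), float(fem_k.mean())),
            chi2_stat, (float(mwu.statistic), float(mwu.pvalue)))


def propensity_match(
    cases: pd.DataFrame,
    controls: pd.DataFrame,
    seed: int = 0,
) -> MatchResult:
    """Greedy 1:1 nearest-neighbour matching on the age+sex propensity score.

    Cases are processed in descending propensity order; each control is
    used at most once; ties among equidistant controls are broken by a
    seeded shuffle.  If controls run short, the remaining cases are left
    unmatched and reported.
    """
    if cases.empty or controls.empty:
        raise ValueError("both cases and controls must be non-empty")
    for frame, label in ((cases, "cases"), (controls, "controls")):
        if frame[["age", "sex"]].isna().any().any():
            raise ValueError(f"{label}: age/sex covariates must be complete")

    X = np.column_stack([
        np.concatenate([cases["age"], controls["age"]]).astype(float),
        np.concatenate([(cases["sex"] == "M"), (controls["sex"] == "M")]).astype(float),
    ])
    ylab = np.r_[np.ones(len(cases)), np.zeros(len(controls))]
    lr = LogisticRegression(C=np.inf, max_iter=2000)
    lr.fit(X, ylab)
    ps = lr.predict_proba(X)[:, 1]
    ps_cases = pd.Series(ps[: len(cases)], index=cases.index)
    ps_controls = pd.Series(ps[len(cases):], index=controls.index)

    rng = np.random.default_rng(seed)
    ctrl_order = rng.permutation(len(ps_controls))
    ctrl_ids = ps_controls.index.to_numpy()[ctrl_order]
    ctrl_ps = ps_controls.to_numpy()[ctrl_order]
    available = np.ones(len(ctrl_ids), dtype=bool)

    pairs = []
    for case_id in ps_cases.sort_values(ascending=False).index:
        if not available.any():
            break
        d = np.abs(ctrl_ps - ps_cases[case_id])
        d[~available] = np.inf
        j = int(np.argmin(d))          # first minimum in shuffled order
        pairs.append((case_id, ctrl_ids[j]))
        available[j] = False

    pairs_df = pd.DataFrame(pairs, columns=["case", "control"])
    matched_cases = cases.loc[pairs_df["case"]]
    matched_controls = controls.loc[pairs_df["control"]]

    smd_pre, fem_pre, chi2_pre, mwu_pre = _balance(cases, controls)
    smd_post, fem_post, chi2_post, mwu_post = _balance(matched_cases, matched_controls)
    return MatchResult(
        pairs=pairs_df,
        smd_age_pre=smd_pre, smd_age_post=smd_post,
        sex_female_pre=fem_pre, sex_female_post=fem_post,
        chi2_sex_pre=chi2_pre, chi2_sex_post=chi2_post,
        mwu_age_pre=mwu_pre, mwu_age_post=mwu_post,
        n_unmatched_cases=len(cases) - len(pairs_df),
    )


# ----------------------------------------------------------------------
# discrimination


@dataclass
class DiscriminationResult:
    roi_set: list[str]
    per_roi: pd.DataFrame                 # region, auc, ci_lo, ci_hi
    combined_auc: float | None = None
    combined_ci: tuple[float, float] | None = None
    combined_coef: dict[str, float] | None = None
    combined_loglik: float | None = None
    per_roi_loglik: dict[str, float] = field(default_factory=dict)
    nonconverged: list[str] = field(default_factory=list)
    scores: pd.Series | None = None       # combined-model probabilities


def _fit_logistic(X: np.ndarray, y: np.ndarray):
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        lr = LogisticRegression(C=np.inf, max_iter=500)
        try:
            lr.fit(X, y)
        except ConvergenceWarning:
            converged = False
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                lr = LogisticRegression(C=np.inf, max_iter=5000)
                lr.fit(X, y)
    p = np.clip(lr.predict_proba(X)[:, 1], 1e-12, 1 - 1e-12)
    ll = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
    return lr, p, ll, converged


def auc_with_ci(scores, labels, alpha: float = 0.05):
    """AUC with a DeLong (placement-variance) confidence interval."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    auc, var = _delong_single(scores, labels)
    se = np.sqrt(var)
    zq = stats.norm.ppf(1 - alpha / 2)
    return auc, (max(0.0, auc - zq * se), min(1.0, auc + zq * se))


def discriminate(
    features: pd.DataFrame,
    labels: pd.Series,
    roi_set: list[str] | None = None,
    mode: str = "both",
) -> DiscriminationResult:
    """Logistic discrimination per ROI and for all ROIs combined.

    AUCs are computed on the fitted probabilities; a single-feature AUC
    is therefore invariant to monotone transforms of that feature.
    """
    roi_set = list(roi_set) if roi_set is not None else list(features.columns)
    y = labels.loc[features.index].to_numpy().astype(int)
    if len(np.unique(y)) != 2:
        raise ValueError("labels must contain exactly two classes")
    sub = features[roi_set].dropna()
    y = labels.loc[sub.index].to_numpy().astype(int)

    per_rows = []
    per_ll: dict[str, float] = {}
    bad: list[str] = []
    if mode in ("per-roi", "both"):
        for roi in roi_set:
            x = sub[[roi]].to_numpy(dtype=float)
            _, p, ll, ok = _fit_logistic(x, y)
            if not ok:
                bad.append(roi)
            auc, ci = auc_with_ci(p, y)
            per_rows.append((roi, auc, ci[0], ci[1]))
            per_ll[roi] = ll
    per_roi = pd.DataFrame(per_rows, columns=["region", "auc", "ci_lo", "ci_hi"])

    combined_auc = combined_ci = combined_coef = combined_ll = None
    scores = None
    if mode in ("combined", "both"):
        X = sub.to_numpy(dtype=float)
        lr, p, combined_ll, ok = _fit_logistic(X, y)
        if not ok:
            bad.append("__combined__")
        combined_auc, combined_ci = auc_with_ci(p, y)
        combined_coef = dict(zip(roi_set, lr.coef_.ravel().tolist()))
        combined_coef["intercept"] = float(lr.intercept_[0])
        scores = pd.Series(p, index=sub.index, name="combined_prob")

    return DiscriminationResult(
        roi_set=roi_set, per_roi=per_roi,
        combined_auc=combined_auc, combined_ci=combined_ci,
        combined_coef=combined_coef, combined_loglik=combined_ll,
        per_roi_loglik=per_ll, nonconverged=bad, scores=scores,
    )


# ----------------------------------------------------------------------
# DeLong machinery


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_placements(scores: np.ndarray, labels: np.ndarray):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    all_r = _midrank(np.concatenate([pos, neg]))
    r_pos = _midrank(pos)
    r_neg = _midrank(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (all_r[:m] - r_pos) / n            # placements of positives
    v10 = 1.0 - (all_r[m:] - r_neg) / m      # placements of negatives
    return auc, v01, v10


def _delong_single(scores, labels):
    auc, v01, v10 = _delong_placements(scores, labels)
    var = np.var(v01, ddof=1) / len(v01) + np.var(v10, ddof=1) / len(v10)
    return float(auc), float(var)


@dataclass
class DeLongResult:
    auc_a: float
    auc_b: float
    delta: float
    z: float
    p: float
    ci: tuple[float, float]


def delong_compare(scores_a, scores_b, labels, alpha: float = 0.05) -> DeLongResult:
    """Paired DeLong test for AUC(a) - AUC(b) on the same subjects."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels).astype(int)
    if not (len(scores_a) == len(scores_b) == len(labels)):
        raise ValueError("paired comparison requires equal-length score vectors")

    auc_a, va01, va10 = _delong_placements(scores_a, labels)
    auc_b, vb01, vb10 = _delong_placements(scores_b, labels)
    m, n = len(va01), len(va10)
    s01 = np.cov(np.stack([va01, vb01]), ddof=1)
    s10 = np.cov(np.stack([va10, vb10]), ddof=1)
    cov = s01 / m + s10 / n
    delta = auc_a - auc_b
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    se = float(np.sqrt(max(var, 0.0)))
    if se == 0.0:
        z, p = 0.0, 1.0
    else:
        z = delta / se
        p = float(2 * stats.norm.sf(abs(z)))
    zq = stats.norm.ppf(1 - alpha / 2)
    return DeLongResult(
        auc_a=float(auc_a), auc_b=float(auc_b), delta=float(delta),
        z=float(z), p=p, ci=(delta - zq * se, delta + zq * se),
    )


# ----------------------------------------------------------------------
# Youden cut-points


@dataclass
class CutpointResult:
    cutpoint: float
    sensitivity: float
    specificity: float
    youden_j: float
    grid: pd.DataFrame       # threshold, sensitivity, specificity


DEFAULT_CENTILE_GRID = (1.0, 5.0, 10.0, 20.0, 30.0, 40.0, 50.0)


def _sens_spec_at(scores, labels, t, positive_direction):
    if positive_direction == "low":
        pred = scores <= t
    else:
        pred = scores >= t
    tp = np.sum(pred & (labels == 1))
    fn = np.sum(~pred & (labels == 1))
    tn = np.sum(~pred & (labels == 0))
    fp = np.sum(pred & (labels == 0))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return float(sens), float(spec)


def youden_cutpoint(
    scores,
    labels,
    positive_direction: str = "low",
    grid: tuple[float, ...] = DEFAULT_CENTILE_GRID,
) -> CutpointResult:
    """Optimal threshold by Youden's J = sensitivity + specificity - 1.

    With ``positive_direction='low'`` a subject is called positive when
    its score (centile) is <= t, matching the convention that disease
    sits at low centiles.  All observed score values are scanned; ties
    break toward the lowest threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) != 2:
        raise ValueError("both classes must be present to choose a cut-point")
    best_t, best_j, best_ss = None, -np.inf, (0.0, 0.0)
    for t in np.sort(np.unique(scores)):
        sens, spec = _sens_spec_at(scores, labels, t, positive_direction)
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_t, best_j, best_ss = float(t), j, (sens, spec)
    grid_rows = [
        (t, *_sens_spec_at(scores, labels, t, positive_direction)) for t in grid
    ]
    return CutpointResult(
        cutpoint=best_t, sensitivity=best_ss[0], specificity=best_ss[1],
        youden_j=float(best_j),
        grid=pd.DataFrame(grid_rows, columns=["threshold", "sensitivity", "specificity"]),
    )


# ----------------------------------------------------------------------
# repeated cross-validation


@dataclass
class CVResult:
    k: int
    repeats: int
    seed: int
    auc_per_repeat: list[float]
    mean_auc: float
    mean_sensitivity: float
    mean_specificity: float


def repeated_cv(
    features: pd.DataFrame,
    labels: pd.Series,
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold cross-validation repeated over independent shuffles.

    Out-of-fold probabilities are pooled within each repeat for one AUC
    per repeat; sensitivity/specificity use the 0.5 probability
    threshold.  Fully determined by ``seed``.
    """
    X = features.to_numpy(dtype=float)
    y = labels.loc[features.index].to_numpy().astype(int)
    n = len(y)
    if n < 2 * k:
        raise ValueError(f"need at least 2k={2 * k} subjects for {k}-fold CV")
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError("each class needs at least k members for stratified folds")

    aucs, senss, specs = [], [], []
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + r)
        oof = np.empty(n)
        for train, test in skf.split(X, y):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                lr = LogisticRegression(C=np.inf, max_iter=2000)
                lr.fit(X[train], y[train])
            oof[test] = lr.predict_proba(X[test])[:, 1]
        aucs.append(float(roc_auc_score(y, oof)))
        pred = oof >= 0.5
        senss.append(float(np.mean(pred[y == 1])))
        specs.append(float(np.mean(~pred[y == 0])))
    return CVResult(
        k=k, repeats=repeats, seed=seed, auc_per_repeat=aucs,
        mean_auc=float(np.mean(aucs)),
        mean_sensitivity=float(np.mean(senss)),
        mean_specificity=float(np.mean(specs)),
    )


# ----------------------------------------------------------------------
# Euler MAD quality filter


def euler_mad_filter(
    cohort: CohortTable, n_mads: float = 2.0, inclusive: bool = True
) -> tuple[CohortTable, dict]:
    """Drop subjects whose Euler index exceeds median + n_mads * MAD.

    The MAD is unscaled (no normal-consistency factor) and the boundary
    is inclusive by default, so an all-equal cohort (MAD = 0) keeps every
    subject rather than excluding all of them.
    """
    if "euler" not in cohort.meta.columns:
        raise ValueError("cohort has no 'euler' column")
    euler = cohort.meta["euler"]
    missing = list(cohort.meta.index[euler.isna()])
    if missing:
        raise ValueError(f"missing Euler values for subjects: {missing}")
    e = euler.to_numpy(dtype=float)
    med = float(np.median(e))
    mad = float(np.median(np.abs(e - med)))
    threshold = med + n_mads * mad
    keep = e <= threshold if inclusive else e < threshold
    excluded = list(cohort.meta.index[~keep])
    report = {
        "median": med, "mad": mad, "threshold": threshold,
        "n_kept": int(keep.sum()), "n_excluded": len(excluded),
        "excluded": excluded,
    }
    return cohort.subset(list(cohort.meta.index[keep])), report
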