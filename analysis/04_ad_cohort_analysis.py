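"""The AD-cohort statistical stack: MMSE and tau correlations, Euler QC
sensitivity, propensity matching, ROI and combined discrimination
(centile vs raw), DeLong comparison, Youden cut-points, and repeated
cross-validation.

Reads results/centiles_ad.csv + results/cohorts/ad; writes tidy tables
under results/ad/.  Run 01-03 first.
"""

from pathlib import Path

import pandas as pd

from regionchart import analysis as an
from regionchart.calibration import CentileTable
from regionchart.catalog import AD_SIGNATURE_REGIONS, TAU_REGIONS
from regionchart.tables import CohortTable

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "ad"
SEED = 11


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    study = CohortTable.from_csv(ROOT / "cohorts" / "ad")
    wide = CentileTable.from_csv(ROOT / "centiles_ad.csv").wide()
    meta = study.meta.loc[wide.index]
    labels = (meta["diagnosis"] != "CN").astype(int)
    rois = list(AD_SIGNATURE_REGIONS)

    # cognition: Spearman rho per region, BH across the 72 regions
    corr = an.spearman_fdr(wide, meta["mmse"])
    corr.to_csv(OUT / "mmse_correlations.csv", index=False)
    sig = corr[corr["region"].isin(rois)]
    print(f"MMSE vs centile in signature regions: rho "
          f"{sig['rho'].min():.2f}..{sig['rho'].max():.2f}, "
          f"all BH-significant: {(sig['p_adj'] < 0.05).all()}")

    # tau: region-wise SUVR vs own centile, 70-region BH family
    tau = an.regionwise_spearman_fdr(wide, study.tau.loc[wide.index],
                                     regions=list(TAU_REGIONS))
    tau.to_csv(OUT / "tau_correlations.csv", index=False)
    hits = tau[(tau["p_adj"] < 0.05) & (tau["rho"] < 0)]
    print(f"tau vs centile: {len(hits)} regions with significant negative rho "
          f"(strongest {tau['rho'].min():.2f})")

    # Euler QC sensitivity: repeat discrimination on the MAD-filtered cohort
    kept, qc = an.euler_mad_filter(study)
    pd.Series(qc["excluded"]).to_csv(OUT / "euler_excluded.csv", index=False)
    print(f"Euler filter: kept {qc['n_kept']}, excluded {qc['n_excluded']} "
          f"(threshold {qc['threshold']:.0f})")

    # propensity matching, then centile vs raw discrimination
    match = an.propensity_match(meta[labels == 1][["age", "sex"]],
                                meta[labels == 0][["age", "sex"]], seed=SEED)
    ids = list(match.pairs["case"]) + list(match.pairs["control"])
    print(f"matched {len(match.pairs)} pairs; age SMD "
          f"{match.smd_age_pre:.2f} -> {match.smd_age_post:.2f}")

    disc_c = an.discriminate(wide.loc[ids, rois], labels.loc[ids])
    disc_r = an.discriminate(study.values.loc[ids, rois], labels.loc[ids])
    disc_c.per_roi.assign(kind="centile").pipe(
        lambda a: pd.concat([a, disc_r.per_roi.assign(kind="raw")])
    ).to_csv(OUT / "roi_aucs.csv", index=False)
    dl = an.delong_compare(disc_c.scores.loc[ids], disc_r.scores.loc[ids],
                           labels.loc[ids])
    print(f"combined AUC: centile {disc_c.combined_auc:.3f} vs raw "
          f"{disc_r.combined_auc:.3f} (DeLong Z {dl.z:.2f}, p {dl.p:.2g})")

    # Youden cut-points per signature ROI
    cuts = []
    for roi in rois:
        cp = an.youden_cutpoint(wide.loc[ids, roi].to_numpy(),
                                labels.loc[ids].to_numpy())
        cuts.append((roi, cp.cutpoint, cp.sensitivity, cp.specificity))
    cuts = pd.DataFrame(cuts, columns=["region", "cutpoint", "sensitivity",
                                       "specificity"])
    cuts.to_csv(OUT / "youden_cutpoints.csv", index=False)
    print(f"optimal centile cut-points: median {cuts['cutpoint'].median():.0f} "
          f"(range {cuts['cutpoint'].min():.0f}-{cuts['cutpoint'].max():.0f})")

    # tenfold repeated CV of the combined centile model
    cv = an.repeated_cv(wide.loc[ids, rois], labels.loc[ids], k=10,
                        repeats=10, seed=SEED)
    pd.DataFrame({"repeat": range(cv.repeats), "auc": cv.auc_per_repeat}).to_csv(
        OUT / "cv_aucs.csv", index=False)
    print(f"10x10 CV: mean AUC {cv.mean_auc:.3f}, sens {cv.mean_sensitivity:.2f}, "
          f"spec {cv.mean_specificity:.2f}")


if __name__ == "__main__":
    main()
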