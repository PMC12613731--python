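"""FTLD phenotypes: regional centile medians per pattern and the regions
that best separate bvFTD from AD.

The bvFTD-vs-AD ranking exercises the common-reference-frame idea: both
cohorts are scored against the same normative model, so their centiles
are directly comparable.  Writes results/ftld/.  Run 01-03 first.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from regionchart import analysis as an
from regionchart.calibration import CentileTable
from regionchart.catalog import CATALOG
from regionchart.tables import CohortTable

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "ftld"


def _cases(name):
    study = CohortTable.from_csv(ROOT / "cohorts" / name)
    wide = CentileTable.from_csv(ROOT / f"centiles_{name}.csv").wide()
    case_ids = study.meta.index[study.meta["diagnosis"] != "CN"]
    return wide.loc[wide.index.intersection(case_ids)]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    medians = {}
    for name in ("ad", "bvftd", "ppa_sv", "ppa_pnfa"):
        medians[name] = _cases(name).median()
    med = pd.DataFrame(medians)
    med.insert(0, "lobe", [CATALOG.lobe(r) for r in med.index])
    med.to_csv(OUT / "median_centiles_by_pattern.csv", index_label="region")
    by_lobe = med.groupby("lobe").median(numeric_only=True).round(1)
    print("median centile by lobe and pattern:")
    print(by_lobe.to_string())

    # bvFTD vs AD: per-region discrimination on the shared centile scale
    ftd, ad = _cases("bvftd"), _cases("ad")
    feats = pd.concat([ftd, ad])
    labels = np.r_[np.ones(len(ftd)), np.zeros(len(ad))]
    rows = []
    for region in CATALOG.names:
        auc, _ = an.auc_with_ci(feats[region].to_numpy(), labels)
        rows.append((region, CATALOG.lobe(region), max(auc, 1 - auc)))
    rank = pd.DataFrame(rows, columns=["region", "lobe", "auc"]) \
        .sort_values("auc", ascending=False).reset_index(drop=True)
    rank.to_csv(OUT / "bvftd_vs_ad_region_ranking.csv", index=False)
    print("\ntop regions separating bvFTD from AD:")
    print(rank.head(10).to_string(index=False))


if __name__ == "__main__":
    main()
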