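"""Individual-level reports: lobe-grouped centile tables with low-centile
flags for a typical AD case and a cognitively normal control.

Writes text + CSV reports under results/reports/.  Run 01-03 first.
"""

from pathlib import Path

from regionchart.calibration import CentileTable
from regionchart.reporting import render_individual_report, write_report
from regionchart.tables import CohortTable

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    study = CohortTable.from_csv(ROOT / "cohorts" / "ad")
    cent = CentileTable.from_csv(ROOT / "centiles_ad.csv")
    wide = cent.wide()

    case_ids = study.meta.index[study.meta["diagnosis"] != "CN"]
    # the case with the lowest mean signature centile = most affected scan
    worst_case = wide.loc[wide.index.intersection(case_ids)].mean(axis=1).idxmin()
    a_control = study.meta.index[study.meta["diagnosis"] == "CN"][0]

    for subject in (worst_case, a_control):
        rep = render_individual_report(cent, subject)
        paths = write_report(rep, ROOT / "reports")
        print(f"{subject}: {len(rep.flagged)} regions flagged "
              f"below the {rep.flag_threshold:g}th centile -> {paths['text']}")
    print("\nexcerpt of the case report:")
    print("\n".join(render_individual_report(cent, worst_case)
                    .to_text().splitlines()[:18]))


if __name__ == "__main__":
    main()
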