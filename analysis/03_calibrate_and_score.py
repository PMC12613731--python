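"""Calibrate each clinical study against the frozen reference model and
score every scan as age/sex/eTIV-adjusted centiles.

Calibration uses only each study's cognitively normal controls (the
~100-controls-per-scanner guidance).  Writes offsets and centile tables
per study under results/.  Run 01 and 02 first.
"""

from pathlib import Path

from regionchart.calibration import estimate_study_offsets, score_centiles
from regionchart.model_io import load_model_set, save_study_offsets
from regionchart.tables import CohortTable

ROOT = Path(__file__).resolve().parents[1] / "results"
STUDIES = ("ad", "bvftd", "ppa_sv", "ppa_pnfa")


def main() -> None:
    model = load_model_set(ROOT / "model.json")
    for name in STUDIES:
        study = CohortTable.from_csv(ROOT / "cohorts" / name)
        controls = study.subset(study.meta.index[study.meta["diagnosis"] == "CN"])
        offsets = estimate_study_offsets(model, controls)
        save_study_offsets(offsets, ROOT / f"offsets_{name}.json")
        cent = score_centiles(model, offsets, study)
        cent.to_csv(ROOT / f"centiles_{name}.csv")
        d = offsets.offsets
        print(f"{name}: {offsets.n_controls} controls; "
              f"median |d_mu| {d['d_mu'].abs().median():.3f}, "
              f"median |d_sigma| {d['d_sigma'].abs().median():.3f}; "
              f"{len(cent.table)} subject-region centiles")
        for w in offsets.warnings:
            print(f"  warning: {w}")


if __name__ == "__main__":
    main()
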