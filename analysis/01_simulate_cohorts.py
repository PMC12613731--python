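"""Generate the synthetic study system: a 4-batch lifespan reference
population plus AD / bvFTD / PPA clinical studies on new scanners.

Writes the cohorts, the retained generative truth, and a summary of the
cohort structure under results/cohorts/.
"""

from pathlib import Path

import pandas as pd

from regionchart.synthetic import (SimulationConfig, generate_clinical_study,
                                   generate_reference_population)

OUT = Path(__file__).resolve().parents[1] / "results" / "cohorts"
SEED = 7


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    ref_cfg = SimulationConfig(n_batches=4, subjects_per_batch=2500, seed=SEED)
    reference, truth = generate_reference_population(ref_cfg)
    reference.to_csv(OUT / "reference")
    truth.to_json(OUT / "truth.json")
    print(f"reference: {reference.n} subjects, {len(reference.batches)} batches, "
          f"ages {reference.meta['age'].min():.1f}-{reference.meta['age'].max():.1f}")

    studies = {
        "ad": dict(disease_pattern="AD", n_cases=150, n_controls=400,
                   with_tau=True, seed=SEED + 1),
        "bvftd": dict(disease_pattern="bvFTD", n_cases=100, n_controls=200,
                      seed=SEED + 2),
        "ppa_sv": dict(disease_pattern="PPA-SV", n_cases=60, n_controls=150,
                       seed=SEED + 3),
        "ppa_pnfa": dict(disease_pattern="PPA-PNFA", n_cases=60, n_controls=150,
                         seed=SEED + 4),
    }
    rows = []
    for name, kw in studies.items():
        study = generate_clinical_study(truth, SimulationConfig(
            study_id=f"study_{name}", **kw))
        study.to_csv(OUT / name)
        case = study.meta["diagnosis"] != "CN"
        rows.append({
            "study": name, "n_cases": int(case.sum()),
            "n_controls": int((~case).sum()),
            "case_median_age": study.meta.loc[case, "age"].median(),
            "control_median_age": study.meta.loc[~case, "age"].median(),
            "case_median_mmse": study.meta.loc[case, "mmse"].median(),
        })
    summary = pd.DataFrame(rows)
    summary.to_csv(OUT / "study_summary.csv", index=False)
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
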