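"""End-to-end pipeline driver: simulate -> fit -> calibrate -> score ->
analyze -> report.

A pipeline run is described by a plain config dict (YAML-friendly),
validated up front; stages execute in order, every artifact is written
under the output directory, and a manifest records the SHA-256 of each
file plus the config hash.  All randomness flows from the config seed,
and no artifact embeds wall-clock time, so re-running an identical
config reproduces identical hashes.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import analysis as an
from .calibration import estimate_study_offsets, score_centiles
from .catalog import AD_SIGNATURE_REGIONS
from .fitting import fit_reference_model
from .model_io import (load_model_set, load_study_offsets, save_model_set,
                       save_study_offsets)
from .reporting import render_individual_report, write_report
from .synthetic import (SimulationConfig, generate_clinical_study,
                        generate_reference_population)

STAGES = ("simulate", "fit", "calibrate", "score", "analyze", "report")

#: stages that must have run earlier in the same pipeline
_REQUIRES = {
    "fit": ("simulate",),
    "calibrate": ("simulate", "fit"),
    "score": ("simulate", "fit", "calibrate"),
    "analyze": ("score",),
    "report": ("score",),
}


class ConfigError(ValueError):
    pass


def validate_config(config: dict) -> dict:
    """Check stage ordering and fill defaults; raises ConfigError."""
    cfg = dict(config)
    stages = cfg.get("stages")
    if not stages:
        raise ConfigError("config must name at least one stage under 'stages'")
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ConfigError(f"unknown stages: {unknown}; known: {list(STAGES)}")
    seen: set[str] = set()
    for s in stages:
        missing = [r for r in _REQUIRES.get(s, ()) if r not in seen]
        if missing:
            raise ConfigError(
                f"stage {s!r} requires earlier stage(s) {missing} in this pipeline"
            )
        seen.add(s)
    cfg.setdefault("seed", 0)
    cfg.setdefault("reference", {})
    cfg.setdefault("study", {})
    cfg.setdefault("analysis", {})
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(config: dict, outdir) -> dict:
    """Execute the configured stages; returns the artifact manifest."""
    cfg = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    cfg_hash = _config_hash(cfg)
    artifacts: dict[str, str] = {}
    state: dict = {}

    def emit(name: str, path: Path) -> None:
        artifacts[name] = str(path)

    for stage in cfg["stages"]:
        try:
            if stage == "simulate":
                ref_cfg = SimulationConfig(
                    n_batches=int(cfg["reference"].get("n_batches", 4)),
                    subjects_per_batch=int(cfg["reference"].get("subjects_per_batch", 300)),
                    seed=seed,
                )
                ref, truth = generate_reference_population(ref_cfg)
                st_cfg = SimulationConfig(
                    disease_pattern=cfg["study"].get("pattern", "AD"),
                    n_cases=int(cfg["study"].get("n_cases", 60)),
                    n_controls=int(cfg["study"].get("n_controls", 150)),
                    with_tau=bool(cfg["study"].get("with_tau", True)),
                    seed=seed + 1,
                )
                study = generate_clinical_study(truth, st_cfg)
                for name, path in ref.to_csv(outdir / "reference").items():
                    emit(f"reference_{name}", Path(path))
                for name, path in study.to_csv(outdir / "study").items():
                    emit(f"study_{name}", Path(path))
                truth.to_json(outdir / "truth.json")
                emit("truth", outdir / "truth.json")
                state.update(reference=ref, study=study, truth=truth)
            elif stage == "fit":
                model = fit_reference_model(
                    state["reference"],
                    min_n=int(cfg["reference"].get("min_n", 100)),
                )
                save_model_set(model, outdir / "model.json")
                emit("model", outdir / "model.json")
                state["model"] = model
            elif stage == "calibrate":
                study = state["study"]
                controls = study.subset(
                    study.meta.index[study.meta["diagnosis"] == "CN"]
                )
                offsets = estimate_study_offsets(
                    load_model_set(outdir / "model.json"), controls
                )
                save_study_offsets(offsets, outdir / "offsets.json")
                emit("offsets", outdir / "offsets.json")
                state["offsets"] = offsets
            elif stage == "score":
                cent = score_centiles(
                    state["model"], load_study_offsets(outdir / "offsets.json"),
                    state["study"],
                )
                cent.to_csv(outdir / "centiles.csv")
                emit("centiles", outdir / "centiles.csv")
                state["centiles"] = cent
            elif stage == "analyze":
                _run_analysis(state, cfg, outdir, emit, seed)
            elif stage == "report":
                cent = state["centiles"]
                subject = cfg.get("report_subject") or cent.table["subject"].iloc[0]
                rep = render_individual_report(cent, subject)
                for name, path in write_report(rep, outdir / "reports").items():
                    emit(f"report_{name}", Path(path))
        except (ConfigError,):
            raise
        except Exception as e:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    manifest = {
        "config_hash": cfg_hash,
        "seed": seed,
        "stages": list(cfg["stages"]),
        "artifacts": {
            name: {"path": p, "sha256": _sha256(Path(p))}
            for name, p in artifacts.items()
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _run_analysis(state, cfg, outdir, emit, seed) -> None:
    cent = state["centiles"]
    study = state["study"]
    wide = cent.wide()
    meta = study.meta.loc[wide.index]
    labels = (meta["diagnosis"] != "CN").astype(int)

    adir = outdir / "analysis"
    adir.mkdir(parents=True, exist_ok=True)

    corr = an.spearman_fdr(wide, meta["mmse"])
    corr.to_csv(adir / "mmse_correlations.csv", index=False)
    emit("analysis_mmse_correlations", adir / "mmse_correlations.csv")

    rois = [r for r in AD_SIGNATURE_REGIONS if r in wide.columns]
    match = an.propensity_match(
        meta[labels == 1][["age", "sex"]], meta[labels == 0][["age", "sex"]],
        seed=seed,
    )
    matched = list(match.pairs["case"]) + list(match.pairs["control"])
    disc = an.discriminate(wide.loc[matched, rois], labels.loc[matched])
    disc.per_roi.assign(combined_auc=disc.combined_auc).to_csv(
        adir / "discrimination.csv", index=False
    )
    emit("analysis_discrimination", adir / "discrimination.csv")

    cuts = []
    for roi in rois:
        cp = an.youden_cutpoint(
            wide.loc[matched, roi].to_numpy(), labels.loc[matched].to_numpy()
        )
        cuts.append((roi, cp.cutpoint, cp.sensitivity, cp.specificity))
    pd.DataFrame(
        cuts, columns=["region", "cutpoint", "sensitivity", "specificity"]
    ).to_csv(adir / "cutpoints.csv", index=False)
    emit("analysis_cutpoints", adir / "cutpoints.csv")
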