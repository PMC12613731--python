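"""Versioned JSON persistence for fitted models and study offsets.

Documents carry a schema version and a SHA-256 checksum over the
canonical (sorted-keys) JSON payload; loading verifies both, so a
truncated or hand-edited document fails loudly rather than silently
producing wrong centiles.  Floats round-trip exactly (repr-level
precision).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .basis import BasisSpec
from .calibration import StudyOffsets
from .catalog import CATALOG
from .fitting import ReferenceModelSet, RegionModel

SCHEMA_VERSION = "regionchart-model/1"


class ModelIOError(ValueError):
    pass


def _checksum(payload: dict) -> str:
    canon = json.dumps(payload, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()


def _wrap(kind: str, payload: dict) -> str:
    return json.dumps(
        {"schema": SCHEMA_VERSION, "kind": kind, "payload": payload,
         "checksum": _checksum(payload)},
        sort_keys=True,
    )


def _unwrap(text: str, kind: str) -> dict:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as e:
        raise ModelIOError(f"document is not valid JSON: {e}") from e
    if doc.get("schema") != SCHEMA_VERSION:
        raise ModelIOError(
            f"unknown schema version {doc.get('schema')!r}; expected {SCHEMA_VERSION}"
        )
    if doc.get("kind") != kind:
        raise ModelIOError(f"document kind {doc.get('kind')!r}; expected {kind!r}")
    payload = doc.get("payload", {})
    if _checksum(payload) != doc.get("checksum"):
        raise ModelIOError("checksum mismatch: document corrupted or edited")
    return payload


def _floats(a) -> list[float]:
    return [float(v) for v in np.asarray(a).ravel()]


def _model_dict(m: RegionModel) -> dict:
    return {
        "region": m.region,
        "spec": m.spec.to_dict(),
        "beta_mu": _floats(m.beta_mu),
        "beta_sigma": _floats(m.beta_sigma),
        "beta_nu": _floats(m.beta_nu),
        "batch_labels": list(m.batch_labels),
        "delta_mu": _floats(m.delta_mu),
        "delta_sigma": _floats(m.delta_sigma),
        "tau2_mu": float(m.tau2_mu),
        "tau2_sigma": float(m.tau2_sigma),
        "loglik": float(m.loglik),
        "bic": float(m.bic),
        "converged": bool(m.converged),
        "n_obs": int(m.n_obs),
        "n_iter": int(m.n_iter),
    }


def _model_from_dict(d: dict) -> RegionModel:
    return RegionModel(
        region=d["region"],
        spec=BasisSpec.from_dict(d["spec"]),
        beta_mu=np.asarray(d["beta_mu"]),
        beta_sigma=np.asarray(d["beta_sigma"]),
        beta_nu=np.asarray(d["beta_nu"]),
        batch_labels=list(d["batch_labels"]),
        delta_mu=np.asarray(d["delta_mu"]),
        delta_sigma=np.asarray(d["delta_sigma"]),
        tau2_mu=d["tau2_mu"], tau2_sigma=d["tau2_sigma"],
        loglik=d["loglik"], bic=d["bic"], converged=d["converged"],
        n_obs=d["n_obs"], n_iter=d["n_iter"],
    )


def save_model_set(model: ReferenceModelSet, path) -> None:
    payload = {
        "provenance": model.provenance,
        "regions": {r: _model_dict(m) for r, m in model.models.items()},
    }
    Path(path).write_text(_wrap("reference-model-set", payload))


def load_model_set(path) -> ReferenceModelSet:
    payload = _unwrap(Path(path).read_text(), "reference-model-set")
    models = {r: _model_from_dict(d) for r, d in payload["regions"].items()}
    return ReferenceModelSet(models=models, catalog=CATALOG,
                             provenance=payload.get("provenance", {}))


def save_study_offsets(offsets: StudyOffsets, path) -> None:
    payload = {
        "study": offsets.study,
        "n_controls": int(offsets.n_controls),
        "warnings": list(offsets.warnings),
        "offsets": {
            r: {"d_mu": float(row["d_mu"]), "d_sigma": float(row["d_sigma"]),
                "d_nu": float(row["d_nu"]),
                "converged": bool(offsets.converged.get(r, False))}
            for r, row in offsets.offsets.iterrows()
        },
    }
    Path(path).write_text(_wrap("study-offsets", payload))


def load_study_offsets(path) -> StudyOffsets:
    payload = _unwrap(Path(path).read_text(), "study-offsets")
    rows = payload["offsets"]
    frame = pd.DataFrame.from_dict(
        {r: {k: d[k] for k in ("d_mu", "d_sigma", "d_nu")} for r, d in rows.items()},
        orient="index",
    )
    conv = pd.Series({r: d["converged"] for r, d in rows.items()})
    return StudyOffsets(
        study=payload["study"], offsets=frame, converged=conv,
        n_controls=payload["n_controls"], warnings=list(payload["warnings"]),
    )
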