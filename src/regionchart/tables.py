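"""In-memory cohort model and CSV interchange.

A cohort is a pair of aligned pandas frames: ``meta`` (one row per
subject-scan: age, sex, batch, eTIV and optional clinical fields) and
``values`` (one column per catalog region).  Long-format CSV
(subject, batch, age, sex, eTIV, region, metric, value) plus a wide
metadata CSV is the on-disk interchange.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import CATALOG, RegionCatalog

logger = logging.getLogger(__name__)

SEXES = ("F", "M")

#: metadata columns always present
META_REQUIRED = ("age", "sex", "batch", "etiv")
#: optional clinical / QC columns
META_OPTIONAL = ("diagnosis", "mmse", "euler", "pet_available")


@dataclass
class PhenotypeRecord:
    """One subject-scan: demographics, batch, eTIV and regional measurements.

    ``measurements`` maps region name -> value (mm for thickness regions,
    mm^3 for volume regions).  Records parsed from stats files alone are
    *partial* (no age/sex/batch) until joined with metadata.
    """

    subject: str | None = None
    batch: str | None = None
    age: float | None = None
    sex: str | None = None
    etiv: float | None = None
    measurements: dict[str, float] = field(default_factory=dict)
    diagnosis: str | None = None
    mmse: int | None = None
    euler: int | None = None
    tau: dict[str, float] = field(default_factory=dict)

    def validate(self, catalog: RegionCatalog = CATALOG) -> None:
        for region, value in self.measurements.items():
            if region not in catalog:
                raise ValueError(f"unknown region {region!r}")
            if not (np.isfinite(value) and value > 0):
                raise ValueError(
                    f"non-positive value {value!r} for region {region!r}"
                )
        if self.age is not None and not (0.0 <= self.age <= 100.0):
            raise ValueError(f"age {self.age} outside [0, 100]")
        if self.sex is not None and self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.etiv is not None and not self.etiv > 0:
            raise ValueError(f"eTIV must be positive, got {self.etiv}")
        if self.mmse is not None and not (0 <= int(self.mmse) <= 30):
            raise ValueError(f"MMSE {self.mmse} outside [0, 30]")


@dataclass
class CohortTable:
    """Aligned metadata and regional-value frames for one cohort."""

    meta: pd.DataFrame
    values: pd.DataFrame
    tau: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.meta.index.equals(self.values.index):
            self.values = self.values.reindex(self.meta.index)
        self.validate()

    def validate(self) -> None:
        if self.meta.index.has_duplicates:
            dupes = self.meta.index[self.meta.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate subject ids: {dupes}")
        missing = [c for c in META_REQUIRED if c not in self.meta.columns]
        if missing:
            raise ValueError(f"metadata missing required columns: {missing}")
        ages = self.meta["age"].to_numpy(dtype=float)
        if np.any((ages < 0) | (ages > 100)):
            bad = self.meta.index[(ages < 0) | (ages > 100)].tolist()
            raise ValueError(f"ages outside [0, 100] for subjects: {bad[:5]}")
        if not set(self.meta["sex"].unique()) <= set(SEXES):
            raise ValueError("sex column must contain only 'F'/'M'")
        if np.any(self.meta["etiv"].to_numpy(dtype=float) <= 0):
            raise ValueError("eTIV must be strictly positive")
        unknown = [c for c in self.values.columns if c not in CATALOG]
        if unknown:
            raise ValueError(f"unknown regions in value table: {unknown}")
        if "mmse" in self.meta.columns:
            mm = self.meta["mmse"].dropna()
            if len(mm) and ((mm < 0) | (mm > 30)).any():
                raise ValueError("MMSE values outside [0, 30]")

    # ------------------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.meta)

    @property
    def subjects(self) -> list[str]:
        return list(self.meta.index)

    @property
    def batches(self) -> list[str]:
        return sorted(self.meta["batch"].unique())

    def subset(self, subjects) -> "CohortTable":
        subjects = list(subjects)
        return CohortTable(
            meta=self.meta.loc[subjects].copy(),
            values=self.values.loc[subjects].copy(),
            tau=None if self.tau is None else self.tau.loc[
                self.tau.index.intersection(subjects)
            ].copy(),
            provenance=dict(self.provenance),
        )

    def complete_subjects(self, regions=None) -> list[str]:
        """Subjects with every requested region present and finite."""
        cols = list(regions) if regions is not None else list(self.values.columns)
        ok = self.values[cols].notna().all(axis=1)
        return list(self.meta.index[ok])

    # ------------------------------------------------------------------
    def to_csv(self, directory) -> dict[str, str]:
        """Write long values CSV + wide metadata CSV; returns path map."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        long = self.values.reset_index(names="subject").melt(
            id_vars="subject", var_name="region", value_name="value"
        ).dropna(subset=["value"])
        long["metric"] = [CATALOG.metric(r) for r in long["region"]]
        join = self.meta[["batch", "age", "sex", "etiv"]].reset_index(names="subject")
        long = long.merge(join, on="subject")
        long = long[["subject", "batch", "age", "sex", "etiv", "region", "metric", "value"]]
        long = long.sort_values(["subject", "region"], kind="stable")
        values_path = directory / "values.csv"
        meta_path = directory / "metadata.csv"
        long.to_csv(values_path, index=False)
        self.meta.to_csv(meta_path, index_label="subject")
        paths = {"values": str(values_path), "metadata": str(meta_path)}
        if self.tau is not None:
            tau_path = directory / "tau.csv"
            self.tau.to_csv(tau_path, index_label="subject")
            paths["tau"] = str(tau_path)
        return paths

    @classmethod
    def from_csv(cls, directory) -> "CohortTable":
        directory = Path(directory)
        long = pd.read_csv(directory / "values.csv")
        meta = pd.read_csv(directory / "metadata.csv", index_col="subject")
        meta.index = meta.index.astype(str)
        values = long.pivot(index="subject", columns="region", values="value")
        values.index = values.index.astype(str)
        values.columns.name = None
        tau = None
        if (directory / "tau.csv").exists():
            tau = pd.read_csv(directory / "tau.csv", index_col="subject")
            tau.index = tau.index.astype(str)
        return cls(meta=meta, values=values.reindex(meta.index), tau=tau,
                   provenance={"source": str(directory)})


def assemble_cohort_table(records, metadata: pd.DataFrame) -> CohortTable:
    """Inner-join stats records with a subject-keyed metadata table.

    Orphans on either side are reported via logging; duplicate subject ids
    and out-of-range clinical values are rejected.
    """
    if metadata.index.name != "subject":
        if "subject" in metadata.columns:
            metadata = metadata.set_index("subject")
    metadata.index = metadata.index.astype(str)
    if metadata.index.has_duplicates:
        dupes = metadata.index[metadata.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate subject ids in metadata: {dupes}")

    by_subject: dict[str, PhenotypeRecord] = {}
    for rec in records:
        rec.validate()
        if rec.subject is None:
            raise ValueError("record without subject id cannot be joined")
        if rec.subject in by_subject:
            raise ValueError(f"duplicate subject id in records: {rec.subject!r}")
        by_subject[rec.subject] = rec

    matched = [s for s in metadata.index if s in by_subject]
    orphan_meta = [s for s in metadata.index if s not in by_subject]
    orphan_recs = [s for s in by_subject if s not in set(metadata.index)]
    if orphan_meta:
        logger.warning("metadata rows without stats records: %s", orphan_meta)
    if orphan_recs:
        logger.warning("stats records without metadata: %s", orphan_recs)

    values = pd.DataFrame.from_dict(
        {s: by_subject[s].measurements for s in matched}, orient="index"
    )
    meta = metadata.loc[matched].copy()
    if "etiv" not in meta.columns:
        meta["etiv"] = [by_subject[s].etiv for s in matched]
    return CohortTable(meta=meta, values=values,
                       provenance={"source": "assembled", "n_records": len(matched)})
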