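"""FreeSurfer ``aparc.stats`` / ``aseg.stats`` text-dialect I/O.

The dialect: comment/header lines start with ``#``; a ``# ColHeaders``
line names the whitespace-delimited table columns; ``# Measure`` lines
carry scalar measures (eTIV lives in the aseg
``EstimatedTotalIntraCranialVol`` measure).  Columns are located by
header name, never by position, so permuted files parse identically.
Thickness comes from the ``ThickAvg`` column of the two aparc files and
subcortical volumes from ``Volume_mm3`` of aseg.
"""

from __future__ import annotations

import logging
from pathlib import Path

from .catalog import ASEG_REGIONS, CATALOG, DK_PARCELS, RegionCatalog
from .tables import CohortTable, PhenotypeRecord

logger = logging.getLogger(__name__)

_APARC_COLS = ("StructName", "NumVert", "SurfArea", "GrayVol", "ThickAvg",
               "ThickStd", "MeanCurv", "GausCurv", "FoldInd", "CurvInd")
_ASEG_COLS = ("Index", "SegId", "NVoxels", "Volume_mm3", "StructName",
              "normMean", "normStdDev", "normMin", "normMax", "normRange")

#: aseg SegId by structure, as in standard FreeSurfer color tables
_SEG_IDS = {"Left-Hippocampus": 17, "Left-Amygdala": 18,
            "Right-Hippocampus": 53, "Right-Amygdala": 54}


def _parse_stats_table(path: Path) -> tuple[list[dict[str, str]], dict[str, str]]:
    """Return (data rows keyed by column name, measure name -> value)."""
    headers: list[str] | None = None
    rows: list[dict[str, str]] = []
    measures: dict[str, str] = {}
    for line in path.read_text().splitlines():
        line = line.rstrip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("ColHeaders"):
                headers = body.split()[1:]
            elif body.startswith("Measure"):
                parts = [p.strip() for p in body[len("Measure"):].split(",")]
                if len(parts) >= 4:
                    measures[parts[0]] = parts[-2]
            continue
        fields = line.split()
        if headers is None:
            raise ValueError(f"{path}: data row before '# ColHeaders' line")
        if len(fields) != len(headers):
            raise ValueError(f"{path}: row has {len(fields)} fields, "
                             f"expected {len(headers)}: {line!r}")
        rows.append(dict(zip(headers, fields)))
    return rows, measures


def _hemi_thickness(path: Path, hemi: str) -> dict[str, float]:
    rows, _ = _parse_stats_table(path)
    out: dict[str, float] = {}
    for row in rows:
        if "StructName" not in row or "ThickAvg" not in row:
            raise ValueError(f"{path}: missing StructName/ThickAvg columns")
        parcel = row["StructName"]
        if parcel not in DK_PARCELS:
            logger.info("%s: ignoring unknown parcel row %r", path, parcel)
            continue
        value = float(row["ThickAvg"])
        if value <= 0:
            raise ValueError(f"{path}: non-positive ThickAvg for {parcel!r}")
        out[f"{hemi}_{parcel}"] = value
    missing = [p for p in DK_PARCELS if f"{hemi}_{p}" not in out]
    if missing:
        raise ValueError(f"{path}: missing parcel rows: {missing}")
    return out


def read_freesurfer_stats(
    lh_aparc, rh_aparc, aseg, subject: str | None = None,
    catalog: RegionCatalog = CATALOG,
) -> PhenotypeRecord:
    """Parse one subject's three stats files into a partial record.

    Returns 68 thickness values, 4 subcortical volumes and eTIV; the
    record still lacks age/sex/batch until joined with metadata.
    """
    measurements: dict[str, float] = {}
    measurements.update(_hemi_thickness(Path(lh_aparc), "lh"))
    measurements.update(_hemi_thickness(Path(rh_aparc), "rh"))

    aseg = Path(aseg)
    rows, measures = _parse_stats_table(aseg)
    if "EstimatedTotalIntraCranialVol" not in measures:
        raise ValueError(f"{aseg}: missing EstimatedTotalIntraCranialVol measure line")
    etiv = float(measures["EstimatedTotalIntraCranialVol"])
    if etiv <= 0:
        raise ValueError(f"{aseg}: non-positive eTIV {etiv}")

    seen = set()
    for row in rows:
        name = row.get("StructName", "")
        if name not in ASEG_REGIONS:
            logger.info("%s: ignoring unknown segmentation row %r", aseg, name)
            continue
        value = float(row["Volume_mm3"])
        if value <= 0:
            raise ValueError(f"{aseg}: non-positive Volume_mm3 for {name!r}")
        measurements[name] = value
        seen.add(name)
    missing = [r for r in ASEG_REGIONS if r not in seen]
    if missing:
        raise ValueError(f"{aseg}: missing segmentation rows: {missing}")

    rec = PhenotypeRecord(subject=subject, etiv=etiv, measurements=measurements)
    rec.validate(catalog)
    return rec


# ----------------------------------------------------------------------
# fixture writing


def _write_aparc(path: Path, subject: str, hemi: str,
                 thickness: dict[str, float]) -> None:
    lines = [
        "# Table of FreeSurfer cortical parcellation anatomical statistics",
        f"# subjectname {subject}",
        f"# hemi {hemi}",
        "# ColHeaders " + " ".join(_APARC_COLS),
    ]
    for parcel in DK_PARCELS:
        th = thickness[f"{hemi}_{parcel}"]
        lines.append(
            f"{parcel} 1500 1000 2500 {th:.6f} 0.450 0.120 0.025 12 1.2"
        )
    path.write_text("\n".join(lines) + "\n")


def _write_aseg(path: Path, subject: str, volumes: dict[str, float],
                etiv: float) -> None:
    lines = [
        "# Title Segmentation Statistics",
        f"# subjectname {subject}",
        "# Measure EstimatedTotalIntraCranialVol, eTIV, "
        f"Estimated Total Intracranial Volume, {etiv:.6f}, mm^3",
        "# ColHeaders " + " ".join(_ASEG_COLS),
    ]
    for i, name in enumerate(ASEG_REGIONS, start=1):
        vol = volumes[name]
        lines.append(
            f"{i} {_SEG_IDS[name]} {int(round(vol / 1.1))} {vol:.4f} {name} "
            "80.0 7.0 50.0 110.0 60.0"
        )
    # an extra structure the pipeline does not analyze (readers must skip it)
    lines.append(f"{len(ASEG_REGIONS) + 1} 16 20000 21000.0000 Brain-Stem "
                 "80.0 7.0 50.0 110.0 60.0")
    path.write_text("\n".join(lines) + "\n")


def write_freesurfer_fixtures(cohort: CohortTable, directory) -> dict[str, dict[str, str]]:
    """Write per-subject lh/rh aparc.stats and aseg.stats files.

    Thickness is written at 1e-6 mm and volumes at 1e-4 mm^3, so the
    round trip through :func:`read_freesurfer_stats` reproduces values at
    the written precision.  Returns a manifest subject -> file paths.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict[str, str]] = {}
    for subject in cohort.subjects:
        row = cohort.values.loc[subject]
        missing = [r for r in CATALOG.names if not (r in row and row[r] == row[r])]
        if missing:
            raise ValueError(
                f"subject {subject!r} missing regions {missing}; cannot write fixtures"
            )
        sdir = directory / subject / "stats"
        sdir.mkdir(parents=True, exist_ok=True)
        thickness = {r: float(row[r]) for r in CATALOG.thickness_names}
        volumes = {r: float(row[r]) for r in CATALOG.volume_names}
        paths = {
            "lh_aparc": sdir / "lh.aparc.stats",
            "rh_aparc": sdir / "rh.aparc.stats",
            "aseg": sdir / "aseg.stats",
        }
        _write_aparc(paths["lh_aparc"], subject, "lh", thickness)
        _write_aparc(paths["rh_aparc"], subject, "rh", thickness)
        _write_aseg(paths["aseg"], subject, volumes,
                    float(cohort.meta.loc[subject, "etiv"]))
        manifest[subject] = {k: str(v) for k, v in paths.items()}
    return manifest
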