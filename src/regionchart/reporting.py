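"""Individual-level centile reports.

Lobe-grouped tabular reports for one subject-scan, with low-centile
flags (default: flag below the 5th centile, highlight below the 1st).
These thresholds are screening defaults, not clinical cut-offs, and are
configurable.  Output is text + CSV only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .calibration import CentileTable
from .catalog import CATALOG, RegionCatalog

LOBE_ORDER = ("frontal", "temporal", "parietal", "occipital",
              "cingulate", "insula", "subcortical")


@dataclass
class IndividualReport:
    subject: str
    age: float
    sex: str
    table: pd.DataFrame        # region, lobe, metric, centile, flag
    flag_threshold: float
    highlight_threshold: float
    provenance: dict = field(default_factory=dict)

    @property
    def flagged(self) -> list[str]:
        return list(self.table.loc[self.table["flag"] != "", "region"])

    def to_text(self) -> str:
        lines = [
            f"Regional centile report — subject {self.subject}",
            f"age {self.age:.1f} y, sex {self.sex}",
            f"flag: centile < {self.flag_threshold:g}   "
            f"highlight (**): centile < {self.highlight_threshold:g}",
            "",
        ]
        for lobe in LOBE_ORDER:
            block = self.table[self.table["lobe"] == lobe]
            if block.empty:
                continue
            lines.append(lobe.upper())
            for _, row in block.iterrows():
                cent = ("   n/a" if pd.isna(row["centile"])
                        else f"{row['centile']:6.1f}")
                lines.append(f"  {row['region']:<28s} {cent}  {row['flag']}")
            lines.append("")
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def render_individual_report(
    centiles: CentileTable,
    subject: str,
    flag_threshold: float = 5.0,
    highlight_threshold: float = 1.0,
    catalog: RegionCatalog = CATALOG,
) -> IndividualReport:
    """Build a lobe-grouped report for one subject.

    Every catalog region appears; regions without a centile are marked
    unavailable (NaN) rather than dropped.
    """
    per = centiles.for_subject(subject)      # raises KeyError if unknown
    meta = centiles.table[centiles.table["subject"] == subject].iloc[0]

    rows = []
    for lobe in LOBE_ORDER:
        for region in catalog.by_lobe().get(lobe, []):
            cent = float(per[region]) if region in per.index else float("nan")
            if cent == cent and cent < highlight_threshold:
                flag = "**"
            elif cent == cent and cent < flag_threshold:
                flag = "*"
            else:
                flag = ""
            rows.append((region, lobe, catalog.metric(region), cent, flag))
    table = pd.DataFrame(rows, columns=["region", "lobe", "metric", "centile", "flag"])
    return IndividualReport(
        subject=subject, age=float(meta["age"]), sex=str(meta["sex"]),
        table=table, flag_threshold=flag_threshold,
        highlight_threshold=highlight_threshold,
        provenance=dict(centiles.provenance),
    )


def write_report(report: IndividualReport, directory) -> dict[str, str]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    txt = directory / f"report_{report.subject}.txt"
    csv = directory / f"report_{report.subject}.csv"
    txt.write_text(report.to_text())
    report.to_csv(csv)
    return {"text": str(txt), "csv": str(csv)}
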