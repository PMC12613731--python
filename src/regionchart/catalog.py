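"""The fixed 72-region catalog.

68 cortical thickness parcels (34 Desikan-Killiany parcels per hemisphere)
plus bilateral hippocampus and amygdala volumes.  Every table in the
pipeline is keyed by these names; cortical parcels are ``<hemi>_<parcel>``
and subcortical structures keep their FreeSurfer aseg names.
"""

from __future__ import annotations

from dataclasses import dataclass

# Desikan-Killiany parcels grouped by cortical lobe.
_DK_LOBES: dict[str, tuple[str, ...]] = {
    "frontal": (
        "caudalmiddlefrontal", "frontalpole", "lateralorbitofrontal",
        "medialorbitofrontal", "paracentral", "parsopercularis",
        "parsorbitalis", "parstriangularis", "precentral",
        "rostralmiddlefrontal", "superiorfrontal",
    ),
    "temporal": (
        "bankssts", "entorhinal", "fusiform", "inferiortemporal",
        "middletemporal", "parahippocampal", "superiortemporal",
        "temporalpole", "transversetemporal",
    ),
    "parietal": (
        "inferiorparietal", "postcentral", "precuneus",
        "superiorparietal", "supramarginal",
    ),
    "occipital": ("cuneus", "lateraloccipital", "lingual", "pericalcarine"),
    "cingulate": (
        "caudalanteriorcingulate", "isthmuscingulate",
        "posteriorcingulate", "rostralanteriorcingulate",
    ),
    "insula": ("insula",),
}

DK_PARCELS: tuple[str, ...] = tuple(
    p for parcels in _DK_LOBES.values() for p in parcels
)
assert len(DK_PARCELS) == 34

HEMIS = ("lh", "rh")

#: aseg structure names for the four subcortical volumes.
ASEG_REGIONS: tuple[str, ...] = (
    "Left-Hippocampus", "Right-Hippocampus",
    "Left-Amygdala", "Right-Amygdala",
)

THICKNESS = "thickness"
VOLUME = "volume"


@dataclass(frozen=True)
class Region:
    """One catalog entry: a named measurement with its metric kind and lobe."""

    name: str
    metric: str   # THICKNESS (mm) or VOLUME (mm^3)
    lobe: str
    hemi: str
    parcel: str   # DK parcel or aseg structure stem


def _build_regions() -> tuple[Region, ...]:
    regions: list[Region] = []
    for hemi in HEMIS:
        for lobe, parcels in _DK_LOBES.items():
            for parcel in parcels:
                regions.append(
                    Region(f"{hemi}_{parcel}", THICKNESS, lobe, hemi, parcel)
                )
    for name in ASEG_REGIONS:
        hemi = "lh" if name.startswith("Left") else "rh"
        parcel = name.split("-", 1)[1].lower()
        regions.append(Region(name, VOLUME, "subcortical", hemi, parcel))
    return tuple(regions)


class RegionCatalog:
    """The 72 analyzed regions, with per-region metric kind and lobe label."""

    def __init__(self) -> None:
        self.regions = _build_regions()
        self._by_name = {r.name: r for r in self.regions}
        if len(self._by_name) != 72:
            raise RuntimeError("catalog must contain exactly 72 unique regions")

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.regions]

    @property
    def thickness_names(self) -> list[str]:
        return [r.name for r in self.regions if r.metric == THICKNESS]

    @property
    def volume_names(self) -> list[str]:
        return [r.name for r in self.regions if r.metric == VOLUME]

    def __len__(self) -> int:
        return len(self.regions)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> Region:
        return self._by_name[name]

    def metric(self, name: str) -> str:
        return self._by_name[name].metric

    def lobe(self, name: str) -> str:
        return self._by_name[name].lobe

    def by_lobe(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for r in self.regions:
            out.setdefault(r.lobe, []).append(r.name)
        return out


#: Module-level singleton; the catalog is immutable so sharing is safe.
CATALOG = RegionCatalog()

#: A-priori AD signature set: bilateral amygdala + hippocampal volume and
#: five temporo-parietal thickness parcels, entered per hemisphere
#: (14 predictors in the combined discrimination model).
AD_SIGNATURE_PARCELS = (
    "entorhinal", "inferiortemporal", "middletemporal",
    "precuneus", "inferiorparietal",
)
AD_SIGNATURE_REGIONS: tuple[str, ...] = tuple(
    f"{h}_{p}" for p in AD_SIGNATURE_PARCELS for h in HEMIS
) + ASEG_REGIONS

#: Regions excluded from tau correlation analyses: hippocampal tau PET is
#: unreliable (off-target choroid-plexus binding), leaving 70 regions.
TAU_EXCLUDED_REGIONS: tuple[str, ...] = ("Left-Hippocampus", "Right-Hippocampus")
TAU_REGIONS: tuple[str, ...] = tuple(
    n for n in CATALOG.names if n not in TAU_EXCLUDED_REGIONS
)
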