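"""Feature registry for FreeSurfer-derived morphometry tables.

The analysis operates on 153 raw measures (left/right subcortical volumes,
lateral ventricles, Desikan-Killiany cortical thickness and surface area,
plus total intracranial volume) and on the 77-column matrix obtained by
averaging the two hemispheres of every paired measure.

Column naming convention:

* raw:       ``L_hippocampus_vol``, ``R_insula_thickavg``,
             ``L_superiorfrontal_surfarea``, ``ICV``
* averaged:  ``hippocampus_vol``, ``insula_thickavg``, ``ICV``
"""

from __future__ import annotations

# modality tags
SUBCORTICAL_VOLUME = "subcortical_volume"
VENTRICLE = "ventricle"
THICKNESS = "thickness"
SURFACE_AREA = "surface_area"
ICV = "icv"

MODALITIES = (SUBCORTICAL_VOLUME, VENTRICLE, THICKNESS, SURFACE_AREA, ICV)

#: 7 bilateral subcortical gray-matter structures
SUBCORTICAL_REGIONS = (
    "accumbens",
    "amygdala",
    "caudate",
    "hippocampus",
    "pallidum",
    "putamen",
    "thalamus",
)

#: 34 Desikan-Killiany cortical parcels
DK_REGIONS = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "frontalpole",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "insula",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "paracentral",
    "parahippocampal",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "temporalpole",
    "transversetemporal",
)

ICV_COLUMN = "ICV"

#: thickness parcels whose cross-sectional age slope is positive
#: (all other thickness parcels thin with age)
POSITIVE_SLOPE_THICKNESS = ("entorhinal", "temporalpole")


def _paired_specs():
    """Yield (averaged_name, modality) for the 76 paired measures, in
    registry order: subcortical volumes, ventricle, thickness, area."""
    for r in SUBCORTICAL_REGIONS:
        yield f"{r}_vol", SUBCORTICAL_VOLUME
    yield "lateralventricle_vol", VENTRICLE
    for r in DK_REGIONS:
        yield f"{r}_thickavg", THICKNESS
    for r in DK_REGIONS:
        yield f"{r}_surfarea", SURFACE_AREA


def averaged_columns() -> list[str]:
    """The 77 analysis features in canonical order (ICV last)."""
    return [name for name, _ in _paired_specs()] + [ICV_COLUMN]


def raw_columns() -> list[str]:
    """The 153 raw measures: L/R for every paired feature, then ICV."""
    cols: list[str] = []
    for name, _ in _paired_specs():
        cols.append(f"L_{name}")
        cols.append(f"R_{name}")
    cols.append(ICV_COLUMN)
    return cols


def hemisphere_pairs() -> dict[str, tuple[str, str]]:
    """Map averaged feature name -> (left column, right column)."""
    return {name: (f"L_{name}", f"R_{name}") for name, _ in _paired_specs()}


def modality_map() -> dict[str, str]:
    """Map averaged feature name -> modality tag."""
    m = {name: mod for name, mod in _paired_specs()}
    m[ICV_COLUMN] = ICV
    return m


def features_of_modality(modality: str) -> list[str]:
    """Averaged feature names belonging to ``modality``."""
    if modality not in MODALITIES:
        raise ValueError(
            f"unknown modality {modality!r}; valid tags: {', '.join(MODALITIES)}"
        )
    return [f for f, m in modality_map().items() if m == modality]
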