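"""Feature panels: which per-cell measurements become profile features.

Two bundled panels mirror the two profiling depths used in practice:

* ``core``: 21 features drawn from 12 cellular markers (nucleus, ER, lysosome,
  membrane stain, membrane-permeability dye, p53, caspase-9, mitochondria,
  cytochrome c, NF-kB, actin, tubulin), one feature per major phenotypic
  attribute. This is the heat-map panel.
* ``full``: a high-resolution panel (>=130 features) that augments the marker
  set with per-well distributional statistics (median, dispersion) of the same
  per-cell measurements, used for reference-library matching.

Markers are imaged in four staining panels (P1-P4); each feature belongs to
the staining panel its marker is imaged in, so aggregation only consumes wells
stained with the right panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: profiled fluorescence channels beyond the nuclear (DNA) stain
PROFILED_MARKERS = (
    "er",
    "lysosome",
    "membrane",
    "permeability",
    "p53",
    "caspase9",
    "mitochondria",
    "cytochrome_c",
    "nfkb",
    "actin",
    "tubulin",
)

#: endpoint-assay channels carried in cell tables but not in the core panel
ASSAY_MARKERS = ("mitosox", "h2ax")

ALL_MARKERS = PROFILED_MARKERS + ASSAY_MARKERS

#: staining panel of each marker (nucleus is imaged on P2/P3/P4; its derived
#: features are aggregated from P2 wells)
MARKER_PANEL = {
    "er": "P1",
    "lysosome": "P1",
    "membrane": "P1",
    "permeability": "P1",
    "nucleus": "P2",
    "p53": "P2",
    "caspase9": "P2",
    "h2ax": "P2",
    "mitochondria": "P3",
    "cytochrome_c": "P3",
    "nfkb": "P3",
    "mitosox": "P3",
    "actin": "P4",
    "tubulin": "P4",
}


@dataclass(frozen=True)
class Feature:
    """One profile feature.

    ``source`` names the per-cell quantity: ``{marker}:{compartment}:{mean|total}``
    for marker intensities, or one of the specials ``count`` (valid objects per
    well), ``area`` (nuclear area), ``dna`` (integrated nuclear DNA intensity).
    ``stat`` is the across-cell aggregation within a well.
    """

    feature_id: str
    marker: str
    compartment: str  # nuc | ring | well
    source: str
    stat: str  # mean | median | std | count
    attribute: str
    panel: str  # staining panel P1..P4


def _intensity(fid, marker, comp, kind, attribute):
    return Feature(
        feature_id=fid,
        marker=marker,
        compartment=comp,
        source=f"{marker}:{comp}:{kind}",
        stat="mean",
        attribute=attribute,
        panel=MARKER_PANEL[marker],
    )


def core_panel() -> "FeaturePanel":
    """The bundled 21-feature / 12-marker core panel."""
    f = [
        Feature("cell_count", "nucleus", "well", "count", "count", "proliferation", "P2"),
        Feature("nuclear_area", "nucleus", "nuc", "area", "mean", "nuclear morphology", "P2"),
        Feature("dna_total", "nucleus", "nuc", "dna", "mean", "nuclear intensity", "P2"),
        _intensity("er_mean", "er", "ring", "mean", "endoplasmic reticulum"),
        _intensity("er_total", "er", "ring", "total", "endoplasmic reticulum"),
        _intensity("lysosome_mean", "lysosome", "ring", "mean", "lysosomes"),
        _intensity("lysosome_total", "lysosome", "ring", "total", "lysosomes"),
        _intensity("membrane_mean", "membrane", "ring", "mean", "membrane"),
        _intensity("permeability_mean", "permeability", "ring", "mean", "membrane permeability"),
        _intensity("p53_nuc_mean", "p53", "nuc", "mean", "p53"),
        _intensity("p53_nuc_total", "p53", "nuc", "total", "p53"),
        _intensity("caspase9_mean", "caspase9", "ring", "mean", "apoptosis"),
        _intensity("mito_mean", "mitochondria", "ring", "mean", "mitochondria"),
        _intensity("mito_total", "mitochondria", "ring", "total", "mitochondria"),
        _intensity("cytc_ring_mean", "cytochrome_c", "ring", "mean", "cytochrome c"),
        _intensity("cytc_nuc_mean", "cytochrome_c", "nuc", "mean", "cytochrome c release"),
        _intensity("nfkb_nuc_mean", "nfkb", "nuc", "mean", "NF-kB translocation"),
        _intensity("nfkb_ring_mean", "nfkb", "ring", "mean", "NF-kB"),
        _intensity("actin_mean", "actin", "ring", "mean", "actin"),
        _intensity("tubulin_mean", "tubulin", "ring", "mean", "tubulin"),
        _intensity("tubulin_total", "tubulin", "ring", "total", "tubulin"),
    ]
    return FeaturePanel("core", f)


def full_panel() -> "FeaturePanel":
    """High-resolution panel: every marker x compartment x per-cell kind,
    aggregated by mean/median/dispersion, plus nuclear morphology stats."""
    feats = []
    for stat in ("mean", "median", "std"):
        suffix = "" if stat == "mean" else f"_{stat}"
        feats.append(
            Feature(f"nuclear_area{suffix}", "nucleus", "nuc", "area", stat, "nuclear morphology", "P2")
        )
        feats.append(
            Feature(f"dna_total{suffix}", "nucleus", "nuc", "dna", stat, "nuclear intensity", "P2")
        )
    feats.append(Feature("cell_count", "nucleus", "well", "count", "count", "proliferation", "P2"))
    for marker in PROFILED_MARKERS:
        for comp in ("nuc", "ring"):
            for kind in ("mean", "total"):
                for stat in ("mean", "median", "std"):
                    fid = f"{marker}_{comp}_{kind}" + ("" if stat == "mean" else f"_{stat}")
                    feats.append(
                        Feature(fid, marker, comp, f"{marker}:{comp}:{kind}", stat, marker, MARKER_PANEL[marker])
                    )
    return FeaturePanel("full", feats)


class FeaturePanel:
    """Ordered collection of :class:`Feature` with uniqueness checks."""

    def __init__(self, name: str, features: list[Feature]):
        ids = [f.feature_id for f in features]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate feature ids in panel")
        self.name = name
        self.features = list(features)

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)

    @property
    def feature_ids(self) -> list[str]:
        return [f.feature_id for f in self.features]

    @property
    def markers(self) -> list[str]:
        return sorted({f.marker for f in self.features})

    def features_for_panel(self, staining_panel: str) -> list[Feature]:
        return [f for f in self.features if f.panel == staining_panel]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "feature_id": f.feature_id,
                    "marker": f.marker,
                    "compartment": f.compartment,
                    "source": f.source,
                    "stat": f.stat,
                    "attribute": f.attribute,
                    "panel": f.panel,
                }
                for f in self.features
            ]
        )


def get_panel(name: str) -> FeaturePanel:
    if name == "core":
        return core_panel()
    if name == "full":
        return full_panel()
    raise ValueError(f"unknown panel {name!r} (expected 'core' or 'full')")


def percell_values(cells: pd.DataFrame, feature: Feature) -> np.ndarray:
    """Map a feature's per-cell source onto a cell table, one value per cell."""
    src = feature.source
    if src == "count":
        raise ValueError("count features are well-level; aggregate_well handles them")
    if src == "area":
        return cells["nuclear_area"].to_numpy(float)
    if src == "dna":
        return cells["dna_content"].to_numpy(float)
    marker, comp, kind = src.split(":")
    mean_col = f"{marker}_{comp}_mean"
    if mean_col not in cells.columns:
        raise KeyError(f"cell table lacks column {mean_col} for feature {feature.feature_id}")
    vals = cells[mean_col].to_numpy(float)
    if kind == "total":
        area_col = "nuclear_area" if comp == "nuc" else "ring_area"
        vals = vals * cells[area_col].to_numpy(float)
    return vals
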