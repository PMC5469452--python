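"""Configuration dataclasses and YAML (de)serialization for screens and runs."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

DEFAULT_DOSES = (0.0, 1.56, 3.12, 6.25, 12.5, 25.0, 50.0)  # ug/ml


@dataclass
class ScreenConfig:
    """Design and generative parameters of one synthetic screen.

    The defaults reproduce the screen the pipeline is modelled on: 3 plants x
    28 SPE fractions each, a 7-point dose ladder in ug/ml, quadruplicate
    treated wells, 4 staining panels, untreated in-plate controls, and
    384-well plates seeded at 2,000 cells per well.
    """

    n_plants: int = 3
    n_fractions_per_plant: int = 28
    doses: tuple = DEFAULT_DOSES
    n_replicates: int = 4
    panels: tuple = ("P1", "P2", "P3", "P4")
    controls_per_plate: int = 16
    timepoints_h: tuple = (24,)

    # population model
    baseline_cells: int = 2000
    dna_scale: float = 500.0        # intensity units per 1N of DNA
    dna_peak_sd: float = 0.16       # peak spread of the 2N/4N components, N units
    cycle_tolerance: float = 0.5    # tau: half-width of the ~2N / ~4N windows, N units
    intensity_cv: float = 0.25      # per-cell lognormal CV of marker intensities
    area_base: float = 80.0         # median nuclear area at 2N, px
    area_cv: float = 0.15
    ring_area_factor: float = 1.5
    fraction_active: float = 0.7    # share of fractions drawn from a non-inert class

    def validate(self) -> None:
        if self.n_plants < 1 or self.n_fractions_per_plant < 1:
            raise ValueError("n_plants and n_fractions_per_plant must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("replicate count must be >= 1")
        if len(self.doses) == 0:
            raise ValueError("dose ladder must not be empty")
        if self.controls_per_plate < 1:
            raise ValueError("need >= 1 control well per plate")
        if not (0 < self.cycle_tolerance < 1):
            raise ValueError("cycle_tolerance must lie in (0, 1)")

    @property
    def n_samples(self) -> int:
        return self.n_plants * self.n_fractions_per_plant


@dataclass
class ReferenceConfig:
    """Reference-compound library generation parameters."""

    n_compounds: int = 735
    n_moa_classes: int = 10
    noise_sd: float = 0.15          # per-feature noise around the class signature
    max_class_correlation: float = 0.5  # separability: max pairwise |r| of class signatures
    panel: str = "core"

    def validate(self) -> None:
        if self.n_moa_classes > self.n_compounds:
            raise ValueError("n_moa_classes cannot exceed n_compounds")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


@dataclass
class SegmentationParams:
    """Nuclei segmentation and validity-filter parameters (pixels)."""

    min_area: int = 25
    max_area: int = 4000
    ring_width: int = 4
    watershed_min_distance: int = 7
    exclude_border: bool = True


@dataclass
class RunConfig:
    """Full pipeline run: design + analysis settings, serialized with outputs."""

    seed: int = 0
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    reference: ReferenceConfig = field(default_factory=ReferenceConfig)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    panel: str = "core"             # core | full
    normalization: str = "screen-max"  # screen-max | robust-z-tanh
    normalization_scope: str = "screen"  # screen | plate
    linkage: str = "average"
    cut_height: float = 0.3         # 1 - r; 0.3 keeps clusters at r >= 0.7
    qc_min_valid_objects: int = 500
    alpha: float = 0.05
    moa_dose: float = 12.5          # dose (ug/ml) whose profiles feed clustering;
                                    # mid-ladder, sub-cytotoxic for most classes
    render_images: bool = False
    cells_per_well: int | None = None  # override baseline_cells for quick runs


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, tuple):
        return list(obj)
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    return obj


def config_to_dict(cfg) -> dict:
    return _to_plain(cfg)


def config_digest(cfg) -> str:
    """Stable digest of a config, recorded in ground truth and manifests."""
    blob = json.dumps(config_to_dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


_TUPLE_FIELDS = {"doses", "panels", "timepoints_h", "suppressive"}


def _from_dict(cls, d: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in d:
            continue
        v = d[f.name]
        if dataclasses.is_dataclass(f.type) if isinstance(f.type, type) else False:
            v = _from_dict(f.type, v)
        elif f.name in ("screen",):
            v = _from_dict(ScreenConfig, v)
        elif f.name in ("reference",):
            v = _from_dict(ReferenceConfig, v)
        elif f.name in ("segmentation",):
            v = _from_dict(SegmentationParams, v)
        elif f.name in _TUPLE_FIELDS and isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _from_dict(RunConfig, data)


def save_run_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=True)
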