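"""384-well plate geometry, layouts and layout I/O.

A screen is laid out on 16x24 (rows A-P, columns 1-24) plates. Every plate
carries untreated in-plate control wells (pure medium, no treatment) that all
normalization downstream refers to. Well addresses are 1-based in files
("A1".."P24"); internal coordinates are 0-based (row, col).
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import pandas as pd

N_ROWS = 16
N_COLS = 24
ROW_LETTERS = string.ascii_uppercase[:N_ROWS]  # A..P

CONTROL_SAMPLE = "CONTROL"

LAYOUT_COLUMNS = [
    "plate_id",
    "well",
    "panel",
    "sample_id",
    "dose_ugml",
    "replicate",
    "is_control",
]


def well_name(row: int, col: int) -> str:
    """0-based (row, col) -> address like 'B7'."""
    if not (0 <= row < N_ROWS and 0 <= col < N_COLS):
        raise ValueError(f"well ({row}, {col}) outside the {N_ROWS}x{N_COLS} grid")
    return f"{ROW_LETTERS[row]}{col + 1}"


def parse_well(name: str) -> tuple[int, int]:
    """Address like 'B7' -> 0-based (row, col); raises on off-grid addresses."""
    name = name.strip().upper()
    if len(name) < 2 or name[0] not in ROW_LETTERS or not name[1:].isdigit():
        raise ValueError(f"invalid well address {name!r} (grid is A-P x 1-24)")
    row = ROW_LETTERS.index(name[0])
    col = int(name[1:]) - 1
    if not (0 <= col < N_COLS):
        raise ValueError(f"invalid well address {name!r} (grid is A-P x 1-24)")
    return row, col


@dataclass(frozen=True)
class WellSpec:
    """One well of a plate: who sits in it and at what dose."""

    well: str
    panel: str
    sample_id: str
    dose_ugml: float
    replicate: int

    @property
    def is_control(self) -> bool:
        return self.sample_id == CONTROL_SAMPLE


@dataclass
class PlateLayout:
    """A single 384-well plate: one staining panel, treated + control wells."""

    plate_id: str
    panel_id: str
    wells: list[WellSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[str] = set()
        n_controls = 0
        for w in self.wells:
            parse_well(w.well)  # raises if off-grid
            if w.well in seen:
                raise ValueError(f"duplicate well {w.well} on plate {self.plate_id}")
            seen.add(w.well)
            if w.replicate < 1:
                raise ValueError(f"replicate index < 1 in well {w.well}")
            n_controls += w.is_control
        if self.wells and n_controls == 0:
            raise ValueError(f"plate {self.plate_id} has no control wells")

    @property
    def control_wells(self) -> list[WellSpec]:
        return [w for w in self.wells if w.is_control]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "plate_id": self.plate_id,
                "well": w.well,
                "panel": self.panel_id,
                "sample_id": w.sample_id,
                "dose_ugml": w.dose_ugml,
                "replicate": w.replicate,
                "is_control": int(w.is_control),
            }
            for w in self.wells
        ]
        return pd.DataFrame(rows, columns=LAYOUT_COLUMNS)


def layouts_to_frame(layouts: list[PlateLayout]) -> pd.DataFrame:
    if not layouts:
        return pd.DataFrame(columns=LAYOUT_COLUMNS)
    return pd.concat([p.to_frame() for p in layouts], ignore_index=True)


def frame_to_layouts(df: pd.DataFrame) -> list[PlateLayout]:
    layouts = []
    for (plate_id, panel), sub in df.groupby(["plate_id", "panel"], sort=False):
        wells = [
            WellSpec(
                well=r.well,
                panel=panel,
                sample_id=r.sample_id,
                dose_ugml=float(r.dose_ugml),
                replicate=int(r.replicate),
            )
            for r in sub.itertuples()
        ]
        layouts.append(PlateLayout(plate_id=plate_id, panel_id=panel, wells=wells))
    return layouts


def write_layout(layouts: list[PlateLayout], path) -> None:
    layouts_to_frame(layouts).to_csv(path, sep="\t", index=False)


def read_layout(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"plate_id": str, "well": str, "panel": str, "sample_id": str})
    missing = set(LAYOUT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"layout file {path} missing columns: {sorted(missing)}")
    return df
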