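"""Phenotype signatures: the simulator's ground-truth vocabulary.

A :class:`PhenotypeSignature` encodes everything a treatment class does to a
cell population as dose rises: a Hill-shaped kill curve (cytotoxicity), a
shift of the cell-cycle phase mixture (DNA-content distribution), per-channel
intensity effects on the profiled markers, and saturating fold-changes on the
five endpoint assays (MitoSOX, membrane permeability, caspase-9, p53, gH2AX).

Dose -> effect strength uses the same Hill family as the kill curve with its
own midpoint, so a single pair (ec50, hill) per axis governs the whole dose
ladder. ``w(dose)`` runs from 0 (untreated) to 1 (saturation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

#: cell-cycle phase keys, in ascending DNA-content order
PHASES = ("low", "g0g1", "s", "g2m", "high")

#: DNA content (in N units) at the centre of each phase component
PHASE_DNA_CENTER = {"low": 1.2, "g0g1": 2.0, "s": 3.0, "g2m": 4.0, "high": 5.5}

#: untreated HeLa-like phase mixture
CONTROL_CYCLE = {"low": 0.02, "g0g1": 0.60, "s": 0.20, "g2m": 0.16, "high": 0.02}

#: endpoint assay -> per-cell channel (marker_compartment) it reads
ASSAY_CHANNELS = {
    "mitosox": "mitosox_ring",
    "permeability": "permeability_ring",
    "caspase9": "caspase9_ring",
    "p53": "p53_nuc",
    "h2ax": "h2ax_nuc",
}

ASSAYS = tuple(ASSAY_CHANNELS)


def hill_response(dose: float, ec50: float, hill: float) -> float:
    """Saturating Hill response in [0, 1): 0 at dose 0, 1/2 at ec50."""
    if dose <= 0:
        return 0.0
    if math.isinf(ec50):
        return 0.0
    return 1.0 / (1.0 + (ec50 / dose) ** hill)


def hill_survival(dose: float, ec50: float, hill: float) -> float:
    """Surviving fraction under a Hill kill curve: 1 at dose 0, 1/2 at ec50."""
    if dose <= 0 or math.isinf(ec50):
        return 1.0
    return 1.0 / (1.0 + (dose / ec50) ** hill)


@dataclass(frozen=True)
class PhenotypeSignature:
    """Ground-truth phenotype of one treatment class."""

    moa_label: str
    effect: dict[str, float] = field(default_factory=dict)  # channel -> shift at saturation
    kill_ec50: float = math.inf  # ug/ml
    kill_hill: float = 1.5
    effect_ec50: float = 5.0  # ug/ml, midpoint of the marker/cycle response
    effect_hill: float = 2.0
    cycle_shift: dict[str, float] = field(default_factory=lambda: dict(CONTROL_CYCLE))
    induction: dict[str, float] = field(default_factory=lambda: {a: 1.0 for a in ASSAYS})
    suppressive: tuple[str, ...] = ()  # assays allowed to have induction < 1
    area_effect: float = 0.0  # relative nuclear-area shift at saturation

    def __post_init__(self) -> None:
        probs = np.array([self.cycle_shift.get(p, 0.0) for p in PHASES])
        if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(f"cycle_shift of {self.moa_label} must be >=0 and sum to 1")
        if not (self.kill_ec50 > 0 and self.kill_hill > 0):
            raise ValueError("kill_ec50 and kill_hill must be positive")
        for assay, fc in self.induction.items():
            if fc <= 0:
                raise ValueError(f"induction for {assay} must be positive")
            if fc < 1.0 and assay not in self.suppressive:
                raise ValueError(
                    f"induction {fc} < 1 for {assay} of {self.moa_label}: "
                    "mark the assay as suppressive explicitly"
                )

    # ---- dose response -------------------------------------------------

    def effect_weight(self, dose: float) -> float:
        return hill_response(dose, self.effect_ec50, self.effect_hill)

    def survival(self, dose: float) -> float:
        return hill_survival(dose, self.kill_ec50, self.kill_hill)

    def phase_probs(self, dose: float) -> np.ndarray:
        """Phase mixture at a dose: control mixture pulled toward cycle_shift."""
        w = self.effect_weight(dose)
        ctrl = np.array([CONTROL_CYCLE[p] for p in PHASES])
        tgt = np.array([self.cycle_shift.get(p, 0.0) for p in PHASES])
        return (1 - w) * ctrl + w * tgt

    def channel_effects(self) -> dict[str, float]:
        """Saturation-level relative shift per channel, assays folded in."""
        eff = dict(self.effect)
        for assay, fc in self.induction.items():
            eff[ASSAY_CHANNELS[assay]] = fc - 1.0
        return eff

    def with_label(self, label: str) -> "PhenotypeSignature":
        return replace(self, moa_label=label)


# ---- bundled treatment classes ----------------------------------------

def inert_signature() -> PhenotypeSignature:
    """No effect anywhere: the class control wells are drawn from."""
    return PhenotypeSignature(moa_label="inert")


def builtin_signatures() -> dict[str, PhenotypeSignature]:
    """A small library of canonical mode-of-action classes.

    Effects are relative shifts at saturation on ``{marker}_{nuc|ring}``
    channels; magnitudes are in the 0.3-1.5 range so that well-replicated
    screens separate classes while single wells stay noisy.
    """
    sigs = [
        inert_signature(),
        PhenotypeSignature(
            moa_label="topoisomerase_inhibitor",
            effect={"p53_nuc": 1.2, "nfkb_nuc": 0.4, "mitochondria_ring": -0.3},
            kill_ec50=9.0,
            cycle_shift={"low": 0.06, "g0g1": 0.18, "s": 0.30, "g2m": 0.40, "high": 0.06},
            induction={"mitosox": 1.4, "permeability": 1.2, "caspase9": 2.0, "p53": 2.2, "h2ax": 3.5},
            area_effect=0.25,
        ),
        PhenotypeSignature(
            moa_label="tubulin_binder",
            effect={"tubulin_ring": -0.8, "actin_ring": -0.2, "nfkb_nuc": 0.2},
            kill_ec50=12.0,
            cycle_shift={"low": 0.05, "g0g1": 0.10, "s": 0.12, "g2m": 0.63, "high": 0.10},
            induction={"mitosox": 1.2, "permeability": 1.1, "caspase9": 1.5, "p53": 1.4, "h2ax": 1.3},
        ),
        PhenotypeSignature(
            moa_label="mitochondrial_toxin",
            effect={
                "mitochondria_ring": -0.7,
                "cytochrome_c_ring": -0.5,
                "cytochrome_c_nuc": 0.6,
                "er_ring": -0.2,
            },
            kill_ec50=15.0,
            cycle_shift={"low": 0.10, "g0g1": 0.60, "s": 0.14, "g2m": 0.12, "high": 0.04},
            induction={"mitosox": 3.0, "permeability": 1.6, "caspase9": 2.5, "p53": 1.3, "h2ax": 1.2},
        ),
        PhenotypeSignature(
            moa_label="er_stressor",
            effect={"er_ring": 0.9, "lysosome_ring": 0.4, "membrane_ring": -0.2},
            kill_ec50=25.0,
            cycle_shift={"low": 0.04, "g0g1": 0.70, "s": 0.12, "g2m": 0.12, "high": 0.02},
            induction={"mitosox": 1.3, "permeability": 1.1, "caspase9": 1.4, "p53": 1.2, "h2ax": 1.1},
        ),
        PhenotypeSignature(
            moa_label="lysosomotropic",
            effect={"lysosome_ring": 1.4, "membrane_ring": 0.3, "er_ring": 0.2},
            kill_ec50=35.0,
            induction={"mitosox": 1.1, "permeability": 1.3, "caspase9": 1.1, "p53": 1.0, "h2ax": 1.0},
        ),
        PhenotypeSignature(
            moa_label="actin_disruptor",
            effect={"actin_ring": -1.0, "tubulin_ring": 0.3, "nfkb_ring": 0.2},
            kill_ec50=40.0,
            area_effect=-0.15,
            induction={"mitosox": 1.1, "permeability": 1.2, "caspase9": 1.1, "p53": 1.0, "h2ax": 1.0},
        ),
        PhenotypeSignature(
            moa_label="dna_synthesis_inhibitor",
            effect={"er_ring": 0.5, "mitochondria_ring": 0.35, "lysosome_ring": -0.3},
            kill_ec50=30.0,
            cycle_shift={"low": 0.04, "g0g1": 0.26, "s": 0.58, "g2m": 0.08, "high": 0.04},
            induction={"mitosox": 1.1, "permeability": 1.0, "caspase9": 1.2, "p53": 1.6, "h2ax": 1.5},
        ),
        PhenotypeSignature(
            moa_label="nfkb_activator",
            effect={"nfkb_nuc": 1.1, "nfkb_ring": -0.4},
            kill_ec50=60.0,
            induction={"mitosox": 1.1, "permeability": 1.0, "caspase9": 1.0, "p53": 1.1, "h2ax": 1.0},
        ),
        PhenotypeSignature(
            moa_label="membrane_permeabilizer",
            effect={"membrane_ring": -0.7, "lysosome_ring": -0.3},
            kill_ec50=18.0,
            cycle_shift={"low": 0.12, "g0g1": 0.56, "s": 0.16, "g2m": 0.12, "high": 0.04},
            induction={"mitosox": 1.4, "permeability": 2.8, "caspase9": 1.3, "p53": 1.1, "h2ax": 1.1},
        ),
    ]
    return {s.moa_label: s for s in sigs}
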