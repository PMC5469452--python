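"""Seeded synthetic high-content screens.

Generates everything the downstream analysis consumes: 384-well plate
layouts with in-plate untreated controls, a ground-truth record per well,
per-cell feature tables with the statistical structure the profiling and
endpoint modules assume, reference-compound libraries with known
mode-of-action labels, and (optionally) rendered fluorescence field images.

The generative model per well:

* cell count ~ Poisson(baseline x survival(dose)), survival a Hill kill curve;
* DNA content per cell drawn from a 5-component mixture (sub-2N "low", 2N
  G0/G1 peak, S plateau between the 2N and 4N windows, 4N G2/M peak,
  super-4N "high") whose weights shift with dose toward the signature's
  target mixture;
* nuclear area scales with DNA content (volume-like 2/3 power);
* marker intensities are control mean x (1 + w(dose) x effect), with per-cell
  lognormal noise.
"""

from __future__ import annotations

import dataclasses
import hashlib
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import ReferenceConfig, ScreenConfig, config_digest
from .panels import ALL_MARKERS, FeaturePanel, core_panel
from .plates import (
    CONTROL_SAMPLE,
    N_COLS,
    N_ROWS,
    PlateLayout,
    WellSpec,
    layouts_to_frame,
    read_layout,
    well_name,
    write_layout,
)
from .signatures import (
    CONTROL_CYCLE,
    PHASE_DNA_CENTER,
    PHASES,
    PhenotypeSignature,
    builtin_signatures,
    inert_signature,
)

#: control-condition mean intensity per channel (arbitrary fluorescence units)
BASE_INTENSITY = {
    "er": {"nuc": 60.0, "ring": 140.0},
    "lysosome": {"nuc": 40.0, "ring": 120.0},
    "membrane": {"nuc": 30.0, "ring": 150.0},
    "permeability": {"nuc": 50.0, "ring": 90.0},
    "p53": {"nuc": 110.0, "ring": 60.0},
    "caspase9": {"nuc": 70.0, "ring": 100.0},
    "mitochondria": {"nuc": 50.0, "ring": 160.0},
    "cytochrome_c": {"nuc": 55.0, "ring": 130.0},
    "nfkb": {"nuc": 80.0, "ring": 110.0},
    "actin": {"nuc": 45.0, "ring": 170.0},
    "tubulin": {"nuc": 50.0, "ring": 160.0},
    "mitosox": {"nuc": 30.0, "ring": 80.0},
    "h2ax": {"nuc": 60.0, "ring": 25.0},
}

CHANNEL_COLUMNS = [f"{m}_{c}_mean" for m in ALL_MARKERS for c in ("nuc", "ring")]

CELL_TABLE_COLUMNS = (
    ["plate_id", "well", "cell_id", "x", "y", "nuclear_area", "dna_content", "ring_area", "true_phase"]
    + CHANNEL_COLUMNS
)


def stable_seed(*parts) -> int:
    """Deterministic 31-bit seed derived from arbitrary string parts."""
    blob = "|".join(str(p) for p in parts).encode()
    return int.from_bytes(hashlib.sha256(blob).digest()[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# study design

@dataclass
class WellTruth:
    """Ground truth for one generated well."""

    sample_id: str
    dose: float
    moa_label: str
    timepoint_h: float
    expected_count: float
    phase_probs: dict
    channel_means: dict


@dataclass
class GroundTruth:
    """Everything the generator knew: per-well truth plus provenance."""

    seed: int
    config_digest: str
    sample_moa: dict = field(default_factory=dict)
    signatures: dict = field(default_factory=dict)  # label -> PhenotypeSignature
    wells: dict = field(default_factory=dict)       # (plate_id, well) -> WellTruth

    def signature_for(self, sample_id: str) -> PhenotypeSignature:
        if sample_id == CONTROL_SAMPLE:
            return self.signatures["inert"]
        return self.signatures[self.sample_moa[sample_id]]


def expected_channel_means(sig: PhenotypeSignature, dose: float) -> dict:
    """Expected per-cell mean intensity per channel at a dose."""
    w = sig.effect_weight(dose)
    eff = sig.channel_effects()
    out = {}
    for marker in ALL_MARKERS:
        for comp in ("nuc", "ring"):
            chan = f"{marker}_{comp}"
            base = BASE_INTENSITY[marker][comp]
            out[chan] = max(base * (1.0 + w * eff.get(chan, 0.0)), 0.0)
    return out


def generate_study_design(
    config: ScreenConfig, seed: int = 0
) -> tuple[list[PlateLayout], GroundTruth]:
    """Lay out the whole screen on 384-well plates and fix its ground truth.

    Deterministic for a fixed (config, seed). Samples are named
    ``plant{i}_f{j}``; each is assigned a mode-of-action signature (inert with
    probability ``1 - fraction_active``). Treated wells for one staining panel
    are enumerated column-major onto as many plates as needed; the first
    ``controls_per_plate`` wells of every plate are untreated controls.
    """
    config.validate()
    rng = np.random.default_rng(stable_seed(seed, "design"))
    sigs = builtin_signatures()
    active_labels = [l for l in sigs if l != "inert"]

    samples = [
        f"plant{p + 1}_f{f + 1:02d}"
        for p in range(config.n_plants)
        for f in range(config.n_fractions_per_plant)
    ]
    sample_moa = {}
    for s in samples:
        if rng.random() < config.fraction_active:
            sample_moa[s] = active_labels[rng.integers(len(active_labels))]
        else:
            sample_moa[s] = "inert"

    truth = GroundTruth(
        seed=seed,
        config_digest=config_digest(config),
        sample_moa=sample_moa,
        signatures=sigs,
    )

    capacity = N_ROWS * N_COLS - config.controls_per_plate
    if capacity < 1:
        raise ValueError("controls_per_plate leaves no treated wells on a plate")
    all_wells = [well_name(r, c) for c in range(N_COLS) for r in range(N_ROWS)]

    layouts = []
    for timepoint in config.timepoints_h:
        tp_tag = f"t{int(timepoint)}" if len(config.timepoints_h) > 1 else None
        for panel in config.panels:
            slots = [
                (s, d, rep)
                for s in samples
                for d in config.doses
                for rep in range(1, config.n_replicates + 1)
            ]
            n_plates = math.ceil(len(slots) / capacity)
            k = 0
            for p_idx in range(n_plates):
                parts = [panel] + ([tp_tag] if tp_tag else []) + [f"{p_idx + 1:02d}"]
                plate_id = "-".join(parts)
                wells = []
                for i in range(config.controls_per_plate):
                    wells.append(
                        WellSpec(all_wells[i], panel, CONTROL_SAMPLE, 0.0, i + 1)
                    )
                for addr in all_wells[config.controls_per_plate:]:
                    if k >= len(slots):
                        break
                    s, d, rep = slots[k]
                    k += 1
                    wells.append(WellSpec(addr, panel, s, d, rep))
                plate = PlateLayout(plate_id=plate_id, panel_id=panel, wells=wells)
                layouts.append(plate)
                for w in plate.wells:
                    sig = truth.signature_for(w.sample_id)
                    truth.wells[(plate_id, w.well)] = WellTruth(
                        sample_id=w.sample_id,
                        dose=w.dose_ugml,
                        moa_label=sig.moa_label,
                        timepoint_h=float(timepoint),
                        expected_count=config.baseline_cells * sig.survival(w.dose_ugml),
                        phase_probs={
                            ph: float(v)
                            for ph, v in zip(PHASES, sig.phase_probs(w.dose_ugml))
                        },
                        channel_means=expected_channel_means(sig, w.dose_ugml),
                    )
    return layouts, truth


# ---------------------------------------------------------------------------
# per-cell simulation

def _lognormal_factor(rng, cv: float, n: int) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with the given CV."""
    if cv <= 0:
        return np.ones(n)
    s = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(-0.5 * s * s, s, size=n)


def draw_dna_content_n(
    rng, phases: np.ndarray, peak_sd: float, tolerance: float
) -> np.ndarray:
    """DNA content in N units given each cell's phase.

    G0/G1 and G2/M are Gaussian peaks at 2N and 4N; S-phase cells fill the
    band between the ~2N and ~4N windows uniformly; sub-2N ("low") and
    super-4N ("high") populations sit below/above the classified range.
    """
    n = len(phases)
    out = np.empty(n)
    for ph, (lo_or_mu, kind) in {
        "low": (1.2, "norm"),
        "g0g1": (2.0, "norm"),
        "s": (None, "unif"),
        "g2m": (4.0, "norm"),
        "high": (5.5, "norm_wide"),
    }.items():
        idx = phases == ph
        m = int(idx.sum())
        if m == 0:
            continue
        if kind == "unif":
            out[idx] = rng.uniform(2.0 + tolerance, 4.0 - tolerance, size=m)
        elif kind == "norm_wide":
            out[idx] = rng.normal(lo_or_mu, 0.3, size=m)
        else:
            out[idx] = rng.normal(lo_or_mu, peak_sd, size=m)
    return np.clip(out, 0.05, None)


def simulate_cell_population(
    well_spec,
    signature: PhenotypeSignature,
    dose: float,
    rng,
    config: ScreenConfig | None = None,
    baseline_cells: int | None = None,
    field_shape: tuple[int, int] = (1000, 1000),
) -> pd.DataFrame:
    """Simulate the segmented-cell table of one well.

    ``well_spec`` may be a :class:`WellSpec` or a ``(plate_id, well)`` pair.
    Dose 0 returns a control-like population (survival 1, no marker effect).
    """
    if dose < 0:
        raise ValueError("dose must be >= 0")
    cfg = config or ScreenConfig()
    if isinstance(well_spec, WellSpec):
        plate_id, well = "plate1", well_spec.well
    else:
        plate_id, well = well_spec
    baseline = baseline_cells if baseline_cells is not None else cfg.baseline_cells

    n = int(rng.poisson(baseline * signature.survival(dose)))
    probs = signature.phase_probs(dose)
    phases = rng.choice(np.array(PHASES), size=n, p=probs / probs.sum())
    dna_n = draw_dna_content_n(rng, phases, cfg.dna_peak_sd, cfg.cycle_tolerance)
    dna_content = dna_n * cfg.dna_scale

    area = (
        cfg.area_base
        * (dna_n / 2.0) ** (2.0 / 3.0)
        * (1.0 + signature.effect_weight(dose) * signature.area_effect)
        * _lognormal_factor(rng, cfg.area_cv, n)
    )
    ring_area = cfg.ring_area_factor * area

    margin = 16
    h, w = field_shape
    data = {
        "plate_id": plate_id,
        "well": well,
        "cell_id": np.arange(1, n + 1),
        "x": rng.uniform(margin, w - margin, size=n),
        "y": rng.uniform(margin, h - margin, size=n),
        "nuclear_area": area,
        "dna_content": dna_content,
        "ring_area": ring_area,
        "true_phase": phases,
    }
    means = expected_channel_means(signature, dose)
    for marker in ALL_MARKERS:
        for comp in ("nuc", "ring"):
            col = f"{marker}_{comp}_mean"
            data[col] = means[f"{marker}_{comp}"] * _lognormal_factor(rng, cfg.intensity_cv, n)
    return pd.DataFrame(data, columns=CELL_TABLE_COLUMNS)


def simulate_screen_cells(
    layouts: list[PlateLayout],
    truth: GroundTruth,
    config: ScreenConfig,
    seed: int,
    cells_per_well: int | None = None,
) -> pd.DataFrame:
    """Per-cell tables for every well of a designed screen.

    Each well gets an independent stream seeded from (seed, plate, well), so
    regeneration of any single well reproduces its cells exactly.
    """
    frames = []
    baseline = cells_per_well if cells_per_well is not None else config.baseline_cells
    for plate in layouts:
        for w in plate.wells:
            sig = truth.signature_for(w.sample_id)
            rng = np.random.default_rng(stable_seed(seed, "cells", plate.plate_id, w.well))
            frames.append(
                simulate_cell_population(
                    (plate.plate_id, w.well), sig, w.dose_ugml, rng,
                    config=config, baseline_cells=baseline,
                )
            )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# reference library

def _separable_class_signatures(
    rng, n_classes: int, n_features: int, max_r: float, max_tries: int = 2000
) -> np.ndarray:
    sigs: list[np.ndarray] = []
    for _ in range(max_tries):
        cand = rng.uniform(-1.0, 1.0, size=n_features)
        ok = True
        for s in sigs:
            r = np.corrcoef(cand, s)[0, 1]
            if abs(r) > max_r:
                ok = False
                break
        if ok:
            sigs.append(cand)
            if len(sigs) == n_classes:
                return np.vstack(sigs)
    raise RuntimeError(
        f"could not draw {n_classes} class signatures with pairwise |r| <= {max_r}"
    )


def generate_reference_library(
    config: ReferenceConfig,
    seed: int = 0,
    panel: FeaturePanel | None = None,
    class_signatures: np.ndarray | None = None,
    class_labels: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Reference compounds with known MoA labels and profile vectors.

    Each compound's profile is its class signature plus independent Gaussian
    noise, clipped to [-1, 1]. Class signatures are drawn mutually separable
    (pairwise |r| below ``max_class_correlation``) unless provided explicitly.

    Returns ``(profiles, labels, class_signatures)``: profiles is a
    compounds x features DataFrame indexed by compound_id; labels maps
    compound_id -> moa_label.
    """
    config.validate()
    pan = panel or core_panel()
    rng = np.random.default_rng(stable_seed(seed, "references"))
    n_feat = len(pan)

    if class_signatures is None:
        class_signatures = _separable_class_signatures(
            rng, config.n_moa_classes, n_feat, config.max_class_correlation
        )
    class_signatures = np.asarray(class_signatures, float)
    n_classes = class_signatures.shape[0]
    if class_signatures.shape[1] != n_feat:
        raise ValueError("class signature length does not match the panel")

    if class_labels is None:
        builtin = [l for l in builtin_signatures() if l != "inert"]
        class_labels = [
            builtin[i] if i < len(builtin) else f"moa_class_{i + 1:02d}"
            for i in range(n_classes)
        ]

    assignments = np.arange(config.n_compounds) % n_classes
    noise = rng.normal(0.0, config.noise_sd, size=(config.n_compounds, n_feat))
    profiles = np.clip(class_signatures[assignments] + noise, -1.0, 1.0)

    ids = [f"ref_{i + 1:04d}" for i in range(config.n_compounds)]
    prof_df = pd.DataFrame(profiles, index=pd.Index(ids, name="sample_id"), columns=pan.feature_ids)
    labels_df = pd.DataFrame(
        {"compound_id": ids, "moa_label": [class_labels[a] for a in assignments]}
    )
    return prof_df, labels_df, class_signatures


def signature_feature_effects(
    sig: PhenotypeSignature,
    panel: FeaturePanel,
    config: ScreenConfig | None = None,
    ref_dose: float = 25.0,
    normalize: bool = True,
) -> np.ndarray:
    """Expected relative feature shifts of a signature at a reference dose.

    Used to express a simulator signature in profile-feature space (e.g. to
    build reference-library entries consistent with simulated fractions).
    With ``normalize`` the largest absolute entry is scaled to 1; otherwise
    raw relative shifts (fraction of the control mean) are returned.
    """
    cfg = config or ScreenConfig()
    w = sig.effect_weight(ref_dose)
    eff = sig.channel_effects()

    def phase_mean(fn, dose):
        p = sig.phase_probs(dose)
        return float(sum(pi * fn(PHASE_DNA_CENTER[ph]) for pi, ph in zip(p, PHASES)))

    dna_shift = phase_mean(lambda n: n, ref_dose) / phase_mean(lambda n: n, 0.0) - 1.0
    area_ratio = phase_mean(lambda n: (n / 2.0) ** (2.0 / 3.0), ref_dose) / phase_mean(
        lambda n: (n / 2.0) ** (2.0 / 3.0), 0.0
    )
    area_shift = (1.0 + w * sig.area_effect) * area_ratio - 1.0

    out = np.zeros(len(panel))
    for i, f in enumerate(panel):
        if f.source == "count":
            out[i] = sig.survival(ref_dose) - 1.0
        elif f.source == "area":
            out[i] = area_shift
        elif f.source == "dna":
            out[i] = dna_shift
        else:
            marker, comp, kind = f.source.split(":")
            mean_shift = w * eff.get(f"{marker}_{comp}", 0.0)
            if kind == "total":
                out[i] = (1.0 + mean_shift) * (1.0 + area_shift) - 1.0
            else:
                out[i] = mean_shift
    if not normalize:
        return out
    peak = np.abs(out).max()
    return out / peak if peak > 0 else out


def signature_score_space(
    sig: PhenotypeSignature,
    panel: FeaturePanel,
    control_means,
    denominators,
    config: ScreenConfig | None = None,
    ref_dose: float = 25.0,
) -> np.ndarray:
    """A signature's expected profile in a screen's normalized score space.

    Converts relative feature shifts to raw deltas via the screen's control
    feature means, then applies the same per-feature normalization scale the
    screen's profiles were scored with (clipped to [-1, 1]). This is how a
    reference compound screened alongside the fractions would score.
    """
    rel = signature_feature_effects(sig, panel, config, ref_dose=ref_dose, normalize=False)
    ctrl = np.asarray([control_means[f] for f in panel.feature_ids], float)
    den = np.asarray([denominators[f] for f in panel.feature_ids], float)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(den > 0, rel * ctrl / den, 0.0)
    return np.clip(scores, -1.0, 1.0)


# ---------------------------------------------------------------------------
# image rendering

def render_field_images(
    cells: pd.DataFrame,
    channels: list[str],
    image_shape: tuple[int, int] = (512, 512),
    rng=None,
    gain: float = 1.0,
    background: float = 100.0,
    noise: bool = True,
    min_spacing: float = 12.0,
) -> tuple[dict, np.ndarray]:
    """Render one field as 16-bit images, one per requested channel.

    Nuclei are flat-top radial spots (super-Gaussian, near-uniform interior
    with a soft edge, like a stained nucleus) whose integrated intensity
    equals ``dna_content x gain`` in the nuclear ('dna') channel; marker
    channels add a dimmer Gaussian cytoplasmic halo. Returns
    ``(images, centroids)`` where centroids is the ground-truth (row, col)
    array.
    """
    h, w = image_shape
    n = len(cells)
    if n * min_spacing**2 > h * w:
        raise ValueError(
            f"image {image_shape} too small for {n} cells at spacing {min_spacing}"
        )
    ys = cells["y"].to_numpy(float)
    xs = cells["x"].to_numpy(float)
    if n and (ys.min() < 0 or ys.max() >= h or xs.min() < 0 or xs.max() >= w):
        raise ValueError("cell positions fall outside the image bounds")

    # super-Gaussian exp(-(d/rho)^8): integral = 2*pi*rho^2 * Gamma(1/4)/8
    _SG_NORM = 2 * np.pi * math.gamma(0.25) / 8.0
    radius_n = np.sqrt(cells["nuclear_area"].to_numpy(float) / np.pi) if n else np.array([])
    images = {}
    for chan in channels:
        img = np.full((h, w), float(background))
        for i in range(n):
            rho = radius_n[i]
            if chan == "dna":
                comps = [(cells["dna_content"].iat[i] * gain, rho, "nuc")]
            else:
                nuc_tot = cells[f"{chan}_nuc_mean"].iat[i] * cells["nuclear_area"].iat[i]
                ring_tot = cells[f"{chan}_ring_mean"].iat[i] * cells["ring_area"].iat[i]
                comps = [(nuc_tot * gain, rho, "nuc"), (ring_tot * gain, 1.2 * rho, "halo")]
            for total, scale, kind in comps:
                rad = int(math.ceil(2.0 * scale)) if kind == "nuc" else int(math.ceil(4.0 * scale))
                r0, r1 = int(ys[i]) - rad, int(ys[i]) + rad + 1
                c0, c1 = int(xs[i]) - rad, int(xs[i]) + rad + 1
                rr = np.arange(max(r0, 0), min(r1, h))
                cc = np.arange(max(c0, 0), min(c1, w))
                if len(rr) == 0 or len(cc) == 0:
                    continue
                d2 = ((rr - ys[i]) ** 2)[:, None] + ((cc - xs[i]) ** 2)[None, :]
                if kind == "nuc":
                    amp = total / (_SG_NORM * scale**2)
                    img[np.ix_(rr, cc)] += amp * np.exp(-((d2 / scale**2) ** 4))
                else:
                    amp = total / (2 * np.pi * scale**2)
                    img[np.ix_(rr, cc)] += amp * np.exp(-d2 / (2 * scale**2))
        if noise:
            if rng is None:
                raise ValueError("rng required when noise=True")
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
        images[chan] = np.clip(img, 0, 65535).astype(np.uint16)
    centroids = np.column_stack([ys, xs]) if n else np.empty((0, 2))
    return images, centroids


# ---------------------------------------------------------------------------
# screen I/O

def _truth_to_plain(truth: GroundTruth) -> dict:
    def sig_plain(s: PhenotypeSignature):
        d = dataclasses.asdict(s)
        d["suppressive"] = list(d["suppressive"])
        d["kill_ec50"] = "inf" if math.isinf(s.kill_ec50) else s.kill_ec50
        return d

    return {
        "seed": truth.seed,
        "config_digest": truth.config_digest,
        "sample_moa": dict(truth.sample_moa),
        "signatures": {k: sig_plain(v) for k, v in truth.signatures.items()},
        "wells": {
            f"{p}:{w}": dataclasses.asdict(t) for (p, w), t in truth.wells.items()
        },
    }


def _truth_from_plain(d: dict) -> GroundTruth:
    sigs = {}
    for label, sd in d.get("signatures", {}).items():
        sd = dict(sd)
        if sd.get("kill_ec50") == "inf":
            sd["kill_ec50"] = math.inf
        sd["suppressive"] = tuple(sd.get("suppressive", ()))
        sigs[label] = PhenotypeSignature(**sd)
    wells = {}
    for key, wt in d.get("wells", {}).items():
        plate, well = key.split(":", 1)
        wells[(plate, well)] = WellTruth(**wt)
    return GroundTruth(
        seed=d["seed"],
        config_digest=d["config_digest"],
        sample_moa=d.get("sample_moa", {}),
        signatures=sigs,
        wells=wells,
    )


def write_screen(
    out_dir,
    layouts: list[PlateLayout],
    cells: pd.DataFrame | None = None,
    truth: GroundTruth | None = None,
    images: dict | None = None,
) -> Path:
    """Write a screen under a documented directory schema.

    ``out_dir/layout.tsv``, ``out_dir/cells.tsv``, ``out_dir/ground_truth.yaml``
    and, only when images are passed, ``out_dir/images/{plate}_{well}_{field}_{channel}.tif``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_layout(layouts, out / "layout.tsv")
    if cells is not None:
        cells.to_csv(out / "cells.tsv", sep="\t", index=False)
    if truth is not None:
        with open(out / "ground_truth.yaml", "w") as fh:
            yaml.safe_dump(_truth_to_plain(truth), fh, sort_keys=True)
    if images:
        import tifffile

        img_dir = out / "images"
        img_dir.mkdir(exist_ok=True)
        for (plate, well, fld), chans in images.items():
            for chan, img in chans.items():
                tifffile.imwrite(img_dir / f"{plate}_{well}_{fld}_{chan}.tif", img)
    return out


def read_screen(in_dir) -> tuple[pd.DataFrame, pd.DataFrame | None, GroundTruth | None]:
    """Read back (layout, cells, truth); cells/truth may be absent."""
    src = Path(in_dir)
    layout = read_layout(src / "layout.tsv")
    cells = None
    if (src / "cells.tsv").exists():
        cells = pd.read_csv(src / "cells.tsv", sep="\t", dtype={"plate_id": str, "well": str})
    truth = None
    if (src / "ground_truth.yaml").exists():
        with open(src / "ground_truth.yaml") as fh:
            truth = _truth_from_plain(yaml.safe_load(fh))
    return layout, cells, truth
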