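"""End-to-end orchestration: simulate -> (imaging) -> profile -> MoA -> endpoints.

One :func:`run_pipeline` call executes every stage on a seeded synthetic
screen, writes all tables under the output directory, and records a manifest
with per-file checksums so two runs with the same config and seed are
byte-comparable. Stage seeds are derived from the master seed by hashing the
stage name, so any stage is independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import endpoints as ep
from . import moa as moa_mod
from .config import RunConfig, config_digest, save_run_config
from .panels import MARKER_PANEL, get_panel
from .plates import parse_well, read_layout
from .profiling import (
    aggregate_wells,
    build_profile_matrix,
    compute_feature_scores,
    drop_incomplete_profiles,
    write_profile_matrix,
)
from .synthdata import (
    generate_reference_library,
    generate_study_design,
    render_field_images,
    signature_score_space,
    simulate_screen_cells,
    stable_seed,
    write_screen,
)
from .signatures import builtin_signatures

log = logging.getLogger("cytoprofile")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run every stage on a synthetic screen; returns the report dict.

    Outputs under ``out_dir``: layout.tsv, cells.tsv, ground_truth.yaml,
    profiles.tsv(+.json), references.tsv, references_moa.tsv, calls.tsv,
    tree.nwk, ordered_matrix.tsv, heatmap.png, endpoints.tsv, phases.tsv,
    qc.tsv, config.yaml, manifest.json, report.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    panel = get_panel(config.panel)
    log.info(
        "run: panel=%s normalization=%s linkage=%s cut_height=%s tau=%s alpha=%s qc_min=%s",
        config.panel, config.normalization, config.linkage, config.cut_height,
        config.screen.cycle_tolerance, config.alpha, config.qc_min_valid_objects,
    )
    manifest: dict = {"config_digest": config_digest(config), "seed": seed, "stages": {}}
    save_run_config(config, out / "config.yaml")

    def _fail(stage: str, ident: str, err: Exception):
        raise RuntimeError(f"stage {stage!r} failed on {ident}: {err}") from err

    # --- simulate ---------------------------------------------------------
    stage = "simulate"
    try:
        layouts, truth = generate_study_design(config.screen, seed=stable_seed(seed, stage))
        cells = simulate_screen_cells(
            layouts, truth, config.screen, seed=stable_seed(seed, stage),
            cells_per_well=config.cells_per_well,
        )
        write_screen(out, layouts, cells=cells, truth=truth)
    except Exception as e:  # noqa: BLE001
        _fail(stage, "screen design/simulation", e)
    manifest["stages"][stage] = {f: _sha256(out / f) for f in ("layout.tsv", "cells.tsv")}
    layout = read_layout(out / "layout.tsv")

    # --- imaging (optional) ----------------------------------------------
    if config.render_images:
        stage = "imaging"
        try:
            cells = _imaging_roundtrip(cells, layout, config, seed)
            cells.to_csv(out / "cells_extracted.tsv", sep="\t", index=False)
        except Exception as e:  # noqa: BLE001
            _fail(stage, "field rendering/extraction", e)
        manifest["stages"][stage] = {"cells_extracted.tsv": _sha256(out / "cells_extracted.tsv")}

    # --- profiling --------------------------------------------------------
    stage = "profile"
    try:
        well_means, qc = aggregate_wells(
            cells, layout, panel, min_valid_objects=config.qc_min_valid_objects
        )
        qc.to_csv(out / "qc.tsv", sep="\t", index=False)
        profiles = compute_feature_scores(
            well_means, panel, method=config.normalization, scope=config.normalization_scope, qc=qc
        )
        doses = profiles.scores.index.get_level_values("dose_ugml").unique()
        moa_dose = min((d for d in doses if d > 0), key=lambda d: abs(d - config.moa_dose))
        if moa_dose != config.moa_dose:
            log.info("profiling dose %s not in ladder; using nearest dose %s", config.moa_dose, moa_dose)
        matrix = build_profile_matrix(profiles, panel, dose=moa_dose)
        matrix = drop_incomplete_profiles(matrix)
        write_profile_matrix(
            matrix, out / "profiles.tsv", panel_name=panel.name,
            method=config.normalization, seed=seed,
        )
    except Exception as e:  # noqa: BLE001
        _fail(stage, "well aggregation/scoring", e)
    manifest["stages"][stage] = {
        f: _sha256(out / f) for f in ("qc.tsv", "profiles.tsv")
    }

    # --- moa --------------------------------------------------------------
    stage = "moa"
    try:
        sigs = {k: v for k, v in builtin_signatures().items() if k != "inert"}
        class_mat = np.vstack(
            [
                signature_score_space(
                    s, panel, profiles.control_means, profiles.denominators,
                    config.screen, ref_dose=moa_dose,
                )
                for s in sigs.values()
            ]
        )
        refs, ref_labels, _ = generate_reference_library(
            config.reference, seed=stable_seed(seed, stage), panel=panel,
            class_signatures=class_mat, class_labels=list(sigs),
        )
        refs.to_csv(out / "references.tsv", sep="\t")
        ref_labels.to_csv(out / "references_moa.tsv", sep="\t", index=False)
        joint = pd.concat([matrix.dropna(), refs])
        dist = moa_mod.pearson_distance_matrix(joint)
        tree = moa_mod.hierarchical_cluster(dist, linkage=config.linkage)
        calls = moa_mod.assign_moa(tree, ref_labels, joint, cut_height=config.cut_height)
        calls.to_csv(out / "calls.tsv", sep="\t", index=False)
        (out / "tree.nwk").write_text(moa_mod.export_newick(tree))
        moa_mod.render_heatmap(joint, tree, out_png=out / "heatmap.png",
                               out_tsv=out / "ordered_matrix.tsv")
    except Exception as e:  # noqa: BLE001
        _fail(stage, "reference clustering/assignment", e)
    manifest["stages"][stage] = {
        f: _sha256(out / f) for f in ("calls.tsv", "tree.nwk", "ordered_matrix.tsv")
    }

    # --- endpoints --------------------------------------------------------
    stage = "endpoints"
    try:
        wv = ep.well_endpoint_values(cells, layout)
        available = [
            n for n in ep.ENDPOINT_NAMES
            if n == "cell_loss_pct" or n.removesuffix("_fc") in wv.columns
        ]
        tables = [
            ep.dose_response_table(wv, name, alpha=config.alpha,
                                   timepoint_h=config.screen.timepoints_h[0])
            for name in available
        ]
        endpoint_table = pd.concat(tables, ignore_index=True)
        endpoint_table.to_csv(out / "endpoints.tsv", sep="\t", index=False)
        phases = ep.phase_fraction_table(
            cells, layout, tolerance=config.screen.cycle_tolerance,
            min_control_cells=min(200, max(20, (config.cells_per_well or 200) // 2)),
            timepoint_h=config.screen.timepoints_h[0],
        )
        phases.to_csv(out / "phases.tsv", sep="\t", index=False)
    except Exception as e:  # noqa: BLE001
        _fail(stage, "endpoint tables", e)
    manifest["stages"][stage] = {
        f: _sha256(out / f) for f in ("endpoints.tsv", "phases.tsv")
    }

    # --- report -----------------------------------------------------------
    qc_failures = qc[~qc["qc_pass"]]
    significant = endpoint_table[endpoint_table["significant"]]
    report = {
        "seed": seed,
        "config_digest": manifest["config_digest"],
        "n_samples": int(layout.loc[~layout["is_control"].astype(bool), "sample_id"].nunique()),
        "n_wells": int(len(layout)),
        "qc_failed_wells": qc_failures[["plate_id", "well"]].to_dict("records"),
        "moa_calls": calls[["sample_id", "predicted_moa", "support", "nearest_reference", "nearest_r"]]
        .to_dict("records"),
        "significant_endpoints": significant[
            ["sample_id", "dose_ugml", "endpoint", "mean", "p", "stars"]
        ].to_dict("records"),
        "true_moa": dict(truth.sample_moa),
    }
    (out / "report.json").write_text(json.dumps(report, indent=1, default=str))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return report


def _imaging_roundtrip(cells: pd.DataFrame, layout: pd.DataFrame, config: RunConfig, seed: int) -> pd.DataFrame:
    """Render each well as one field and re-extract features from the pixels."""
    from .imaging import correct_background, extract_cell_features, segment_nuclei

    out_frames = []
    shape = (512, 512)
    for (plate, well), sub in cells.groupby(["plate_id", "well"], sort=False):
        meta = layout[(layout["plate_id"] == plate) & (layout["well"] == well)]
        panel_id = meta["panel"].iloc[0]
        markers = [m for m, p in MARKER_PANEL.items() if p == panel_id and m != "nucleus"]
        sub = sub.copy()
        # re-place cells inside the render frame
        rng = np.random.default_rng(stable_seed(seed, "imaging", plate, well))
        sub["x"] = rng.uniform(20, shape[1] - 20, size=len(sub))
        sub["y"] = rng.uniform(20, shape[0] - 20, size=len(sub))
        images, _ = render_field_images(sub, ["dna"] + markers, image_shape=shape,
                                        rng=rng, min_spacing=4.0)
        corrected = {c: correct_background(img) for c, img in images.items()}
        seg = segment_nuclei(corrected["dna"], config.segmentation)
        feats = extract_cell_features(
            seg, corrected, ring_width=config.segmentation.ring_width,
            plate_id=plate, well=well,
        )
        out_frames.append(feats)
    return pd.concat(out_frames, ignore_index=True)


# ---------------------------------------------------------------------------
# input validation

def validate_inputs(
    layout_path=None, cells_path=None, profiles_path=None
) -> list[dict]:
    """Schema checks with line-numbered errors; reports rather than raises."""
    errors: list[dict] = []

    def err(file, line, message):
        errors.append({"file": str(file), "line": line, "error": message})

    if layout_path is not None:
        try:
            df = pd.read_csv(layout_path, sep="\t")
        except Exception as e:  # noqa: BLE001
            err(layout_path, 0, f"unreadable: {e}")
            df = None
        if df is not None:
            from .plates import LAYOUT_COLUMNS

            for col in LAYOUT_COLUMNS:
                if col not in df.columns:
                    err(layout_path, 1, f"missing column {col!r}")
            if "well" in df.columns:
                for i, w in enumerate(df["well"]):
                    try:
                        parse_well(str(w))
                    except ValueError as e:
                        err(layout_path, i + 2, str(e))
            if {"plate_id", "well"} <= set(df.columns):
                dup = df.duplicated(subset=["plate_id", "well"])
                for i in np.flatnonzero(dup.to_numpy()):
                    err(layout_path, int(i) + 2,
                        f"duplicate (plate, well) = ({df['plate_id'].iat[i]}, {df['well'].iat[i]})")
            if "dose_ugml" in df.columns:
                bad = ~(pd.to_numeric(df["dose_ugml"], errors="coerce") >= 0)
                for i in np.flatnonzero(bad.to_numpy()):
                    err(layout_path, int(i) + 2, f"invalid dose {df['dose_ugml'].iat[i]!r}")
            if "replicate" in df.columns:
                bad = ~(pd.to_numeric(df["replicate"], errors="coerce") >= 1)
                for i in np.flatnonzero(bad.to_numpy()):
                    err(layout_path, int(i) + 2, f"replicate index < 1")

    if cells_path is not None:
        try:
            df = pd.read_csv(cells_path, sep="\t", nrows=100000)
        except Exception as e:  # noqa: BLE001
            err(cells_path, 0, f"unreadable: {e}")
            df = None
        if df is not None:
            for col in ("plate_id", "well", "cell_id", "nuclear_area", "dna_content"):
                if col not in df.columns:
                    err(cells_path, 1, f"missing column {col!r}")
            for col in ("nuclear_area", "dna_content"):
                if col in df.columns:
                    bad = ~(pd.to_numeric(df[col], errors="coerce") >= 0)
                    for i in np.flatnonzero(bad.to_numpy()):
                        err(cells_path, int(i) + 2, f"negative or non-numeric {col}")

    if profiles_path is not None:
        try:
            df = pd.read_csv(profiles_path, sep="\t")
        except Exception as e:  # noqa: BLE001
            err(profiles_path, 0, f"unreadable: {e}")
            df = None
        if df is not None:
            if df.columns[0] != "sample_id":
                err(profiles_path, 1, "first column must be sample_id")
            feat_cols = [c for c in df.columns if c != "sample_id"]
            vals = df[feat_cols].apply(pd.to_numeric, errors="coerce")
            out_of_range = (vals.abs() > 1 + 1e-9).any(axis=1)
            for i in np.flatnonzero(out_of_range.to_numpy()):
                err(profiles_path, int(i) + 2, "score outside [-1, 1]")
    return errors
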