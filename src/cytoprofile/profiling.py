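"""Per-well aggregation and control-normalized cytological profiles.

Wells that passed QC are collapsed to per-well feature values (a statistic
over valid cells), wells are averaged within a (sample, dose) replicate
group, the in-plate untreated-control mean is subtracted, and the resulting
deltas are normalized to scores in [-1, 1].

Two normalizations are provided:

* ``screen-max`` (default): score = delta / max over the screen of |delta|
  for that feature, clipped to [-1, 1]. Parameter-free; by construction the
  strongest sample per feature scores exactly +/-1.
* ``robust-z-tanh``: score = tanh(z / 3) with z the delta over the robust
  (MAD-based) spread of control wells; bounded without clipping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .panels import FeaturePanel, get_panel, percell_values
from .plates import LAYOUT_COLUMNS

_META_COLS = ["plate_id", "well", "panel", "sample_id", "dose_ugml", "replicate", "is_control"]


def aggregate_well(cell_records: pd.DataFrame, panel: FeaturePanel, staining_panel: str | None = None) -> pd.Series:
    """Collapse one well's cell table to per-feature values.

    Only features imaged in the well's staining panel are computed (all of
    them when ``staining_panel`` is None). Raises on zero valid cells — such
    wells must be QC-excluded before aggregation.
    """
    cells = cell_records
    if "valid" in cells.columns:
        cells = cells[cells["valid"].astype(bool)]
    if len(cells) == 0:
        raise ValueError("aggregate_well called on a well with zero valid cells")
    feats = panel.features if staining_panel is None else panel.features_for_panel(staining_panel)
    out = {}
    for f in feats:
        if f.source == "count":
            out[f.feature_id] = float(len(cells))
            continue
        vals = percell_values(cells, f)
        if f.stat == "mean":
            out[f.feature_id] = float(np.mean(vals))
        elif f.stat == "median":
            out[f.feature_id] = float(np.median(vals))
        elif f.stat == "std":
            out[f.feature_id] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        else:
            raise ValueError(f"unknown feature statistic {f.stat!r}")
    return pd.Series(out)


def aggregate_wells(
    cells: pd.DataFrame,
    layout: pd.DataFrame,
    panel: FeaturePanel,
    min_valid_objects: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vectorized per-well aggregation over a whole screen.

    Returns ``(well_means, qc)``: one row per passing well with layout
    metadata plus feature columns (NaN for features outside the well's
    staining panel), and a QC table with per-well valid-object counts and
    pass/fail flags.
    """
    work = cells
    if "valid" in work.columns:
        work = work[work["valid"].astype(bool)]
    counts = (
        work.groupby(["plate_id", "well"], sort=False).size().rename("n_valid").reset_index()
    )
    qc = layout.merge(counts, on=["plate_id", "well"], how="left")
    qc["n_valid"] = qc["n_valid"].fillna(0).astype(int)
    qc["qc_pass"] = qc["n_valid"] >= min_valid_objects

    passing = qc[qc["qc_pass"]][_META_COLS + ["n_valid"]]
    keyed = work.merge(
        passing[["plate_id", "well", "panel"]], on=["plate_id", "well"], how="inner"
    )

    per_panel = []
    for staining_panel, sub in keyed.groupby("panel", sort=False):
        feats = panel.features_for_panel(staining_panel)
        if not feats:
            continue
        vals = {}
        aggspec = {}
        for f in feats:
            if f.source == "count":
                continue
            vals[f.feature_id] = percell_values(sub, f)
            aggspec[f.feature_id] = (f.feature_id, f.stat)
        fdf = pd.DataFrame(vals)
        fdf["plate_id"] = sub["plate_id"].to_numpy()
        fdf["well"] = sub["well"].to_numpy()
        g = fdf.groupby(["plate_id", "well"], sort=False)
        agg = g.agg(**aggspec) if aggspec else pd.DataFrame(index=g.size().index)
        for f in feats:
            if f.source == "count":
                agg[f.feature_id] = g.size()
        per_panel.append(agg.reset_index())

    if per_panel:
        feat_wide = pd.concat(per_panel, ignore_index=True)
        feat_wide = feat_wide.groupby(["plate_id", "well"], sort=False).first().reset_index()
        well_means = passing.merge(feat_wide, on=["plate_id", "well"], how="left")
    else:
        well_means = passing.copy()
    for fid in panel.feature_ids:
        if fid not in well_means.columns:
            well_means[fid] = np.nan
    return well_means, qc


@dataclass
class ProfileSet:
    """Scored cytological profiles of one screen.

    ``denominators`` holds the per-feature normalization scale actually used
    (screen-max |delta|, or the robust control sigma), so externally supplied
    profiles — e.g. reference-library signatures — can be expressed in the
    same score space.
    """

    scores: pd.DataFrame  # index (sample_id, dose_ugml), columns = panel features
    meta: pd.DataFrame    # per profile: n_wells_used, qc_excluded
    panel_name: str
    method: str
    denominators: pd.Series | None = None
    control_means: pd.Series | None = None


def compute_feature_scores(
    well_means: pd.DataFrame,
    panel: FeaturePanel,
    method: str = "screen-max",
    scope: str = "screen",
    qc: pd.DataFrame | None = None,
    tanh_scale: float = 3.0,
) -> ProfileSet:
    """Control-normalize per-well feature values into [-1, 1] scores.

    Per feature and (sample, dose): delta = mean over replicate wells of
    (well value - in-plate control mean). ``screen-max`` divides by the
    screen-wide max |delta| of the feature; ``robust-z-tanh`` squashes the
    robust z-score against control spread through tanh. Features whose
    deltas are all zero score 0 everywhere.
    """
    if method not in ("screen-max", "robust-z-tanh"):
        raise ValueError(f"unknown normalization method {method!r}")
    if scope not in ("screen", "plate"):
        raise ValueError(f"unknown normalization scope {scope!r}")
    fids = [f for f in panel.feature_ids if f in well_means.columns]
    ctrl = well_means[well_means["is_control"].astype(bool)]
    if len(ctrl) == 0:
        raise ValueError("no control wells available for normalization")
    treated = well_means[~well_means["is_control"].astype(bool)].copy()

    ctrl_mean = ctrl.groupby("plate_id")[fids].mean()
    deltas_w = treated[fids].to_numpy(float) - ctrl_mean.reindex(treated["plate_id"]).to_numpy(float)
    dw = pd.DataFrame(deltas_w, columns=fids)
    dw["sample_id"] = treated["sample_id"].to_numpy()
    dw["dose_ugml"] = treated["dose_ugml"].to_numpy()
    dw["plate_id"] = treated["plate_id"].to_numpy()

    keys = ["sample_id", "dose_ugml"] + (["plate_id"] if scope == "plate" else [])
    grouped = dw.groupby(keys, sort=True)
    delta = grouped[fids].mean()
    n_wells = grouped.size().rename("n_wells_used")

    denom_out = None
    if method == "screen-max":
        if scope == "plate":
            denom = delta.abs().groupby(level="plate_id").max()
            scores = delta / denom.reindex(delta.index.get_level_values("plate_id")).to_numpy()
        else:
            denom = delta.abs().max(axis=0)
            denom_out = denom
            scores = delta / denom
        scores = scores.where(np.isfinite(scores), 0.0).clip(-1.0, 1.0)
    else:
        med = ctrl[fids].median()
        mad = (ctrl[fids] - med).abs().median()
        sigma = 1.4826 * mad
        denom_out = sigma * tanh_scale
        z = delta / sigma.replace(0.0, np.nan)
        scores = np.tanh(z / tanh_scale).fillna(0.0)

    if scope == "plate":
        scores = scores.groupby(level=["sample_id", "dose_ugml"]).mean()
        n_wells = n_wells.groupby(level=["sample_id", "dose_ugml"]).sum()

    meta = n_wells.to_frame()
    if qc is not None:
        excl = (
            qc[(~qc["is_control"].astype(bool)) & (~qc["qc_pass"])]
            .groupby(["sample_id", "dose_ugml"])
            .size()
            .rename("qc_excluded")
        )
        meta = meta.join(excl, how="left")
        meta["qc_excluded"] = meta["qc_excluded"].fillna(0).astype(int)
    else:
        meta["qc_excluded"] = 0
    return ProfileSet(
        scores=scores,
        meta=meta,
        panel_name=panel.name,
        method=method,
        denominators=denom_out,
        control_means=ctrl[fids].mean(),
    )


def build_profile_matrix(
    profiles: ProfileSet | pd.DataFrame,
    panel: FeaturePanel,
    dose: float | None = None,
) -> pd.DataFrame:
    """Samples x features matrix in panel column order.

    With ``dose`` given, one row per sample at that dose; otherwise rows are
    labelled ``sample@dose``. Missing (QC-excluded) entries stay NaN.
    """
    scores = profiles.scores if isinstance(profiles, ProfileSet) else profiles
    if isinstance(profiles, ProfileSet) and profiles.panel_name != panel.name:
        raise ValueError(
            f"profiles were scored on panel {profiles.panel_name!r}, not {panel.name!r}"
        )
    missing = set(panel.feature_ids) - set(scores.columns)
    if missing:
        raise ValueError(f"profiles lack panel features: {sorted(missing)[:5]} ...")
    mat = scores[panel.feature_ids].copy()
    if isinstance(mat.index, pd.MultiIndex):
        if dose is not None:
            mat = mat.xs(dose, level="dose_ugml")
        else:
            mat.index = [f"{s}@{d:g}" for s, d in mat.index]
    mat.index.name = "sample_id"
    return mat


def write_profile_matrix(matrix: pd.DataFrame, path, panel_name: str = "core",
                         method: str = "screen-max", seed: int | None = None) -> None:
    path = Path(path)
    matrix.to_csv(path, sep="\t", index=True)
    sidecar = {
        "panel": panel_name,
        "n_features": int(matrix.shape[1]),
        "method": method,
        "seed": seed,
        "feature_order": list(matrix.columns),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_profile_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def drop_incomplete_profiles(matrix: pd.DataFrame, max_missing: float = 0.25) -> pd.DataFrame:
    """Drop samples missing more than ``max_missing`` of their features
    (clustering needs near-complete vectors)."""
    frac_missing = matrix.isna().mean(axis=1)
    return matrix[frac_missing <= max_missing]


__all__ = [
    "ProfileSet",
    "aggregate_well",
    "aggregate_wells",
    "build_profile_matrix",
    "compute_feature_scores",
    "drop_incomplete_profiles",
    "get_panel",
    "read_profile_matrix",
    "write_profile_matrix",
]
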