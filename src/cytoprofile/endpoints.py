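"""Quantitative screen endpoints.

Implements the dose-response endpoints reported alongside cytological
profiles: percent-of-control optical density (and the companion cell-loss
percentage), DNA-content cell-cycle classification against a control-
calibrated 2N anchor, in-plate-normalized fold-change assays (MitoSOX,
membrane permeability, caspase-9, p53, gamma-H2AX), and two-tailed pooled-
variance Student's t-tests with star annotations.

Cell-cycle rule: with DNA content in N units and a tolerance tau (default
0.5N), cells near 2N are G0/G1, cells near 4N are G2/M, cells strictly
between the windows are S; below-2N cells are damaged/apoptotic ("low") and
above-4N cells are clumped/high-ploidy ("high").
"""

from __future__ import annotations

from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from .signatures import ASSAY_CHANNELS, PHASES

ALPHA_DEFAULT = 0.05

#: star annotation tiers, strongest first
STAR_TIERS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


class CellCyclePhase(str, Enum):
    LOW = "low"
    G0G1 = "g0g1"
    S = "s"
    G2M = "g2m"
    HIGH = "high"


def percent_of_control(od_treated: float, od_control: float) -> float:
    """Treated signal as a percentage of the untreated in-plate control:
    OD_treated / OD_control x 100."""
    if od_control <= 0:
        raise ValueError("control OD must be positive")
    if od_treated < 0:
        raise ValueError("treated OD must be >= 0")
    return od_treated / od_control * 100.0


def cell_loss_pct(od_treated: float, od_control: float) -> float:
    """Percentage of signal lost relative to control: 100 - percent_of_control."""
    return 100.0 - percent_of_control(od_treated, od_control)


def calibrate_dna_scale(
    control_dna_contents: np.ndarray, min_cells: int = 200, grid_size: int = 1024
) -> float:
    """Intensity units per 1N, anchored on the control G1 (2N) peak.

    The anchor is the mode of a kernel-smoothed histogram of control DNA
    contents; when the density is multimodal the lower major mode is taken
    (G1 dominates untreated populations). Returns anchor / 2.
    """
    x = np.asarray(control_dna_contents, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < min_cells:
        raise ValueError(f"need >= {min_cells} control cells to calibrate, got {len(x)}")
    if x.std() == 0:
        return float(x[0]) / 2.0
    kde = stats.gaussian_kde(x)
    grid = np.linspace(0.0, np.quantile(x, 0.995), grid_size)
    dens = kde(grid)
    # local maxima; keep "major" ones within 2x of the global peak
    interior = (dens[1:-1] >= dens[:-2]) & (dens[1:-1] >= dens[2:])
    peaks = np.flatnonzero(interior) + 1
    if len(peaks) == 0:
        anchor = grid[int(np.argmax(dens))]
    else:
        major = peaks[dens[peaks] >= 0.5 * dens[peaks].max()]
        anchor = grid[major.min()]
    return float(anchor) / 2.0


def classify_cell_cycle(dna_content_n, tolerance: float = 0.5):
    """Map calibrated DNA content (N units) to a cell-cycle phase.

    Windows: low < 2-tau; G0/G1 in [2-tau, 2+tau]; S in (2+tau, 4-tau);
    G2/M in [4-tau, 4+tau]; high > 4+tau. The five intervals partition
    [0, inf) for every tau in (0, 1). Accepts scalars or arrays.
    """
    if not (0 < tolerance < 1):
        raise ValueError("tolerance must lie in (0, 1)")
    x = np.asarray(dna_content_n, dtype=float)
    if (x < 0).any():
        raise ValueError("DNA content must be non-negative")
    out = np.empty(x.shape, dtype=object)
    out[x < 2 - tolerance] = CellCyclePhase.LOW
    out[(x >= 2 - tolerance) & (x <= 2 + tolerance)] = CellCyclePhase.G0G1
    out[(x > 2 + tolerance) & (x < 4 - tolerance)] = CellCyclePhase.S
    out[(x >= 4 - tolerance) & (x <= 4 + tolerance)] = CellCyclePhase.G2M
    out[x > 4 + tolerance] = CellCyclePhase.HIGH
    if np.isscalar(dna_content_n) or np.ndim(dna_content_n) == 0:
        return out.item()
    return out


def phase_distribution(phases) -> pd.Series:
    """Empirical phase frequencies over the five phases; sums to 1."""
    seq = list(phases)
    if len(seq) == 0:
        raise ValueError("phase_distribution needs at least one cell")
    vals = [p.value if isinstance(p, CellCyclePhase) else str(p) for p in seq]
    counts = pd.Series(vals).value_counts()
    return pd.Series(
        [counts.get(p, 0) / len(vals) for p in PHASES], index=list(PHASES), name="fraction"
    )


def fold_change_assay(treated_intensities, control_intensities) -> float:
    """mean(treated) / mean(control), the in-plate-normalized fold change."""
    t = np.asarray(treated_intensities, dtype=float)
    c = np.asarray(control_intensities, dtype=float)
    cm = c.mean()
    if cm <= 0:
        raise ValueError("control mean must be positive")
    return float(t.mean() / cm)


def two_tailed_t(group_a, group_b) -> tuple[float, float]:
    """Classical pooled-variance (Student's) two-tailed t-test.

    t = (mean_a - mean_b) / (s_p * sqrt(1/n_a + 1/n_b)) with the pooled
    variance s_p^2 on n_a + n_b - 2 degrees of freedom. Degenerate zero-
    variance input: equal means give (0, 1); unequal means are an error.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    diff = a.mean() - b.mean()
    if pooled == 0:
        if diff == 0:
            return 0.0, 1.0
        raise ValueError("zero pooled variance with unequal means: t undefined")
    t = diff / np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    p = 2.0 * stats.t.sf(abs(t), df=na + nb - 2)
    return float(t), float(p)


def welch_t(group_a, group_b) -> tuple[float, float]:
    """Welch's unequal-variance alternative, behind its own name."""
    t, p = stats.ttest_ind(group_a, group_b, equal_var=False)
    return float(t), float(p)


def significance_stars(p: float) -> str:
    for cutoff, stars in STAR_TIERS:
        if p <= cutoff:
            return stars
    return ""


# ---------------------------------------------------------------------------
# well-level endpoint extraction and dose-response tables

ENDPOINT_NAMES = ("cell_loss_pct",) + tuple(f"{a}_fc" for a in ASSAY_CHANNELS)


def well_endpoint_values(cells: pd.DataFrame, layout: pd.DataFrame) -> pd.DataFrame:
    """Per-well raw endpoint readouts from a cell table.

    The optical-density proxy is the well's integrated nuclear DNA stain;
    each assay readout is the well mean of its channel. Returns one row per
    well with layout metadata plus ``od`` and per-assay columns.
    """
    work = cells
    if "valid" in work.columns:
        work = work[work["valid"].astype(bool)]
    g = work.groupby(["plate_id", "well"], sort=False)
    aggspec = {
        assay: (f"{chan}_mean", "mean")
        for assay, chan in ASSAY_CHANNELS.items()
        if f"{chan}_mean" in work.columns  # imaging mode may carry fewer channels
    }
    vals = g.agg(od=("dna_content", "sum"), n_cells=("dna_content", "size"), **aggspec).reset_index()
    return layout.merge(vals, on=["plate_id", "well"], how="inner")


def dose_response_table(
    well_values: pd.DataFrame,
    endpoint: str,
    alpha: float = ALPHA_DEFAULT,
    timepoint_h: float = 24.0,
) -> pd.DataFrame:
    """Per (sample, dose) endpoint summary with a t-test against dose 0.

    ``endpoint`` is ``cell_loss_pct`` or ``{assay}_fc``. Untreated in-plate
    control wells provide both the normalization baseline and the dose-0
    comparison group. Rows report mean +/- SD over replicate wells, the
    pooled-variance t and two-tailed p versus dose 0, and star annotations.
    """
    if endpoint == "cell_loss_pct":
        raw_col, transform = "od", "percent"
    else:
        assay = endpoint.removesuffix("_fc")
        if assay not in ASSAY_CHANNELS:
            raise ValueError(f"unknown endpoint {endpoint!r}")
        raw_col, transform = assay, "fold"

    ctrl = well_values[well_values["is_control"].astype(bool)]
    if len(ctrl) == 0:
        raise ValueError("missing dose-0 (control) group")

    rows = []
    for sample_id, sub in well_values[~well_values["is_control"].astype(bool)].groupby(
        "sample_id", sort=True
    ):
        for dose, grp in sub.groupby("dose_ugml", sort=True):
            plates = grp["plate_id"].unique()
            base = ctrl[ctrl["plate_id"].isin(plates)]
            if len(base) == 0:
                raise ValueError(f"no in-plate controls for sample {sample_id} dose {dose}")
            cmean = base[raw_col].mean()
            if transform == "percent":
                vals = 100.0 - grp[raw_col].to_numpy(float) / cmean * 100.0
                ctrl_vals = 100.0 - base[raw_col].to_numpy(float) / cmean * 100.0
            else:
                vals = grp[raw_col].to_numpy(float) / cmean
                ctrl_vals = base[raw_col].to_numpy(float) / cmean
            if len(vals) >= 2 and len(ctrl_vals) >= 2:
                t, p = two_tailed_t(vals, ctrl_vals)
            else:
                t, p = np.nan, np.nan
            rows.append(
                {
                    "sample_id": sample_id,
                    "dose_ugml": dose,
                    "timepoint_h": timepoint_h,
                    "endpoint": endpoint,
                    "mean": float(np.mean(vals)),
                    "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                    "n": len(vals),
                    "control_mean": float(cmean),
                    "t": t,
                    "p": p,
                    "significant": bool(p <= alpha) if np.isfinite(p) else False,
                    "stars": significance_stars(p) if np.isfinite(p) else "",
                }
            )
    return pd.DataFrame(rows)


def phase_fraction_table(
    cells: pd.DataFrame,
    layout: pd.DataFrame,
    tolerance: float = 0.5,
    min_control_cells: int = 200,
    timepoint_h: float = 24.0,
) -> pd.DataFrame:
    """Per (sample, dose) cell-cycle phase fractions.

    The DNA scale is calibrated per plate on pooled control cells; every
    cell is classified and fractions are averaged over replicate wells.
    """
    keyed = cells.merge(
        layout[["plate_id", "well", "sample_id", "dose_ugml", "is_control"]],
        on=["plate_id", "well"],
        how="inner",
    )
    scales = {}
    for plate, sub in keyed[keyed["is_control"].astype(bool)].groupby("plate_id"):
        scales[plate] = calibrate_dna_scale(
            sub["dna_content"].to_numpy(), min_cells=min_control_cells
        )
    rows = []
    for (sample_id, dose), grp in keyed[~keyed["is_control"].astype(bool)].groupby(
        ["sample_id", "dose_ugml"], sort=True
    ):
        per_well = []
        for (plate, _well), wgrp in grp.groupby(["plate_id", "well"], sort=False):
            if plate not in scales:
                raise ValueError(f"plate {plate} has no calibrated controls")
            n_units = wgrp["dna_content"].to_numpy(float) / scales[plate]
            per_well.append(phase_distribution(classify_cell_cycle(n_units, tolerance)))
        frac = pd.concat(per_well, axis=1).mean(axis=1)
        row = {"sample_id": sample_id, "dose_ugml": dose, "timepoint_h": timepoint_h,
               "n": len(per_well)}
        row.update({f"frac_{p}": float(frac[p]) for p in PHASES})
        rows.append(row)
    return pd.DataFrame(rows)
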