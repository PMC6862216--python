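"""mRNA half-life estimation from transcription-shutoff chase time courses.

After transcription is blocked (actinomycin D), residual mRNA decays
roughly exponentially.  Per gene and condition, expression values at the
chase time points (default 0, 4, 8 h) are normalized to the 0 h value,
log-transformed (natural log), and fit by ordinary least squares against
time.  The half-life is computed from the fitted line as

    t_half = ln(0.5 / e^intercept) / slope = (ln 0.5 - intercept) / slope

i.e. the time at which the fitted line crosses relative expression 0.5.
Because values are pre-normalized to t=0 the intercept is near zero, but
the regression is not forced through the origin, and the intercept enters
the half-life exactly as written above.  The alternative "time for the
fitted curve to fall to half of its own fitted t=0 value" (ln 0.5 / slope)
is also reported for diagnostics but is not the canonical estimate.

Fits with half-life below 0 h (positive slope) or above 50 h (too slow to
measure over an 8 h chase), or from genes below the 0.1 FPKM expression
floor at t=0, are excluded.  A knockout/control half-life ratio above 2.0
calls a gene stabilized; below 0.5, destabilized (strict inequalities).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import linregress

__all__ = [
    "ChaseSeries",
    "DecayFit",
    "StabilityCall",
    "fit_decay",
    "fit_decay_table",
    "filter_half_lives",
    "classify_stability",
    "stability_table",
    "HL_MIN_H",
    "HL_MAX_H",
    "STABILIZED_RATIO",
    "DESTABILIZED_RATIO",
]

HL_MIN_H = 0.0
HL_MAX_H = 50.0
STABILIZED_RATIO = 2.0
DESTABILIZED_RATIO = 0.5

LN_HALF = math.log(0.5)


@dataclass
class ChaseSeries:
    """Replicate-averaged expression along one gene's chase, one condition."""

    gene_id: str
    condition: str
    time_points_h: list[float]
    expr_values: list[float]

    def __post_init__(self) -> None:
        t = self.time_points_h
        if len(t) != len(self.expr_values):
            raise ValueError("time points and expression values differ in length")
        if sorted(t) != list(t) or len(set(t)) != len(t):
            raise ValueError("time points must be strictly increasing")
        if t and t[0] != 0:
            raise ValueError("chase series must start at t=0")

    @property
    def rel_values(self) -> list[float]:
        e0 = self.expr_values[0]
        if e0 <= 0:
            return [float("nan")] * len(self.expr_values)
        return [v / e0 for v in self.expr_values]


@dataclass
class DecayFit:
    gene_id: str
    condition: str
    intercept: float = float("nan")  # ln relative expression at t=0
    slope: float = float("nan")  # 1/h
    half_life_h: float = float("nan")
    time_to_half_h: float = float("nan")  # ln 0.5 / slope, diagnostic only
    n_points: int = 0
    excluded: bool = False
    reason: str = ""


def half_life_from_fit(intercept: float, slope: float) -> float:
    """(ln 0.5 - intercept) / slope — where the fitted line crosses 0.5."""
    return (LN_HALF - intercept) / slope


def fit_decay(series: ChaseSeries) -> DecayFit:
    """OLS of ln(relative expression) on chase time; half-life from the line.

    Time points with non-positive expression are dropped (log undefined);
    fewer than two usable points, or a flat/rising series, yields an
    excluded fit with a reason.
    """
    t = np.asarray(series.time_points_h, dtype=float)
    y = np.asarray(series.expr_values, dtype=float)
    usable = y > 0
    if series.expr_values and series.expr_values[0] <= 0:
        return DecayFit(
            series.gene_id, series.condition, excluded=True, reason="zero at t=0"
        )
    t, y = t[usable], y[usable]
    if len(t) < 2:
        return DecayFit(
            series.gene_id,
            series.condition,
            n_points=len(t),
            excluded=True,
            reason="insufficient points",
        )
    rel = y / y[0]
    fit = linregress(t, np.log(rel))
    if fit.slope == 0 or not np.isfinite(fit.slope):
        return DecayFit(
            series.gene_id,
            series.condition,
            intercept=float(fit.intercept),
            slope=float(fit.slope),
            n_points=len(t),
            excluded=True,
            reason="no decay (zero slope)",
        )
    return DecayFit(
        series.gene_id,
        series.condition,
        intercept=float(fit.intercept),
        slope=float(fit.slope),
        half_life_h=half_life_from_fit(fit.intercept, fit.slope),
        time_to_half_h=LN_HALF / float(fit.slope),
        n_points=len(t),
    )


def fit_decay_table(
    expr: pd.DataFrame,
    samples: pd.DataFrame,
    value: str = "norm_expr",
    per_replicate: bool = False,
) -> pd.DataFrame:
    """Fit every (gene, condition) chase series in a long expression table.

    ``samples`` must carry time_point_h for the chase samples.  By default
    replicates are averaged at each time point before fitting; with
    ``per_replicate`` each replicate is fit separately and half-lives
    averaged across retained replicate fits.
    """
    chase_samples = samples[samples["time_point_h"].notna()]
    merged = expr.merge(
        chase_samples[["sample_id", "condition", "replicate", "time_point_h"]],
        on="sample_id",
    )
    fits: list[DecayFit] = []
    if not per_replicate:
        mean = (
            merged.groupby(["gene_id", "condition", "time_point_h"])[value]
            .mean()
            .reset_index()
            .sort_values("time_point_h")
        )
        for (gid, cond), grp in mean.groupby(["gene_id", "condition"]):
            fits.append(
                fit_decay(
                    ChaseSeries(
                        gid, cond, list(grp["time_point_h"]), list(grp[value])
                    )
                )
            )
    else:
        merged = merged.sort_values("time_point_h")
        for (gid, cond), grp in merged.groupby(["gene_id", "condition"]):
            reps = []
            for _, rep_grp in grp.groupby("replicate"):
                f = fit_decay(
                    ChaseSeries(
                        gid,
                        cond,
                        list(rep_grp["time_point_h"]),
                        list(rep_grp[value]),
                    )
                )
                if not f.excluded:
                    reps.append(f)
            if reps:
                fits.append(
                    DecayFit(
                        gid,
                        cond,
                        intercept=float(np.mean([f.intercept for f in reps])),
                        slope=float(np.mean([f.slope for f in reps])),
                        half_life_h=float(np.mean([f.half_life_h for f in reps])),
                        time_to_half_h=float(
                            np.mean([f.time_to_half_h for f in reps])
                        ),
                        n_points=int(np.mean([f.n_points for f in reps])),
                    )
                )
            else:
                fits.append(
                    DecayFit(gid, cond, excluded=True, reason="no replicate fit")
                )
    return pd.DataFrame([vars(f) for f in fits])


def filter_half_lives(
    fits: pd.DataFrame,
    fpkm_t0: dict[str, float] | pd.Series | None = None,
    min_fpkm: float = 0.1,
    hl_min: float = HL_MIN_H,
    hl_max: float = HL_MAX_H,
) -> pd.DataFrame:
    """Exclude fits with half-life < 0 h or > 50 h, or gene FPKM below 0.1.

    ``fpkm_t0`` maps gene_id to the t=0 condition-mean FPKM.  Boundaries:
    exactly 0 and exactly 50 h are retained ("less than 0" / "longer than
    50" excluded).
    """
    out = fits.copy()
    hl = out["half_life_h"]
    low = (~out["excluded"]) & (hl < hl_min)
    high = (~out["excluded"]) & (hl > hl_max)
    out.loc[low, ["excluded", "reason"]] = [True, "half-life < 0 h"]
    out.loc[high, ["excluded", "reason"]] = [True, f"half-life > {hl_max:g} h"]
    if fpkm_t0 is not None:
        fp = out["gene_id"].map(fpkm_t0)
        dim = (~out["excluded"]) & ((fp < min_fpkm) | fp.isna())
        out.loc[dim, ["excluded", "reason"]] = [True, f"FPKM < {min_fpkm:g}"]
    return out


@dataclass
class StabilityCall:
    gene_id: str
    hl_control: float
    hl_ko: float
    ratio: float
    klass: str  # stabilized | destabilized | unchanged


def classify_stability(
    fit_control: DecayFit,
    fit_ko: DecayFit,
    stabilized_ratio: float = STABILIZED_RATIO,
    destabilized_ratio: float = DESTABILIZED_RATIO,
) -> StabilityCall | None:
    """Call stabilized/destabilized from the KO/control half-life ratio.

    Returns None when either fit is excluded (no call, never "unchanged").
    """
    if fit_control.excluded or fit_ko.excluded:
        return None
    ratio = fit_ko.half_life_h / fit_control.half_life_h
    if ratio > stabilized_ratio:
        klass = "stabilized"
    elif ratio < destabilized_ratio:
        klass = "destabilized"
    else:
        klass = "unchanged"
    return StabilityCall(
        fit_control.gene_id,
        fit_control.half_life_h,
        fit_ko.half_life_h,
        ratio,
        klass,
    )


def stability_table(
    fits: pd.DataFrame,
    control: str = "control",
    ko: str = "KO",
    stabilized_ratio: float = STABILIZED_RATIO,
    destabilized_ratio: float = DESTABILIZED_RATIO,
) -> pd.DataFrame:
    """Pair retained control/KO fits per gene into stability calls."""
    kept = fits[~fits["excluded"]]
    ctrl = kept[kept["condition"] == control].set_index("gene_id")
    kod = kept[kept["condition"] == ko].set_index("gene_id")
    rows = []
    for gid in sorted(set(ctrl.index) & set(kod.index)):
        ratio = kod.loc[gid, "half_life_h"] / ctrl.loc[gid, "half_life_h"]
        if ratio > stabilized_ratio:
            klass = "stabilized"
        elif ratio < destabilized_ratio:
            klass = "destabilized"
        else:
            klass = "unchanged"
        rows.append(
            {
                "gene_id": gid,
                "hl_control": ctrl.loc[gid, "half_life_h"],
                "hl_ko": kod.loc[gid, "half_life_h"],
                "ratio": ratio,
                "klass": klass,
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "hl_control", "hl_ko", "ratio", "klass"]
    )
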