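"""Phenotype statistics: drug effects on growth and scratch-wound migration.

Growth: treated confluence curves are normalized pointwise to the untreated
control mean curve, summarized per replicate as the trapezoidal area under
the normalized curve, and compared with a two-sided Welch t-test.

Migration: the scratch width measured at 0 and 12 h gives the closed
distance; rate = closed / 12 h (um/h), reported also as a fraction of the
control mean rate, with a Welch t-test against control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError

MIGRATION_HOURS = 12.0


@dataclass
class GrowthComparison:
    condition: str
    auc_treated: np.ndarray       # normalized-confluence hours, per replicate
    auc_control: np.ndarray
    welch_t: float
    p: float


def _replicate_curves(table: pd.DataFrame) -> dict:
    curves = {}
    for rep, grp in table.groupby("replicate", sort=True):
        grp = grp.sort_values("hour")
        hours = grp["hour"].to_numpy(dtype=float)
        if len(hours) < 2:
            raise ConfigurationError(f"replicate {rep!r}: need >= 2 timepoints")
        if np.any(np.diff(hours) <= 0):
            raise ConfigurationError(f"replicate {rep!r}: hours must be strictly increasing")
        curves[rep] = (hours, grp["confluence"].to_numpy(dtype=float))
    return curves


def growth_auc_test(treated: pd.DataFrame, control: pd.DataFrame) -> GrowthComparison:
    """Welch t-test of control-normalized growth AUCs, treated vs control.

    Every curve is interpolated to the control time grid, divided pointwise
    by the control mean curve, and integrated by the trapezoid rule. The
    control replicates themselves, normalized the same way, are the
    comparison group (their AUCs equal the time span up to replicate noise).
    """
    ctrl_curves = _replicate_curves(control)
    trt_curves = _replicate_curves(treated)
    if len(ctrl_curves) < 2 or len(trt_curves) < 2:
        raise ConfigurationError("need >= 2 replicates per group")
    grid = next(iter(ctrl_curves.values()))[0]
    ctrl_mat = np.vstack([np.interp(grid, h, c) for h, c in ctrl_curves.values()])
    ctrl_mean = ctrl_mat.mean(axis=0)
    if np.any(ctrl_mean <= 0):
        raise ConfigurationError("control mean confluence is zero at a timepoint")

    def aucs(curves):
        out = []
        for hours, conf in curves.values():
            norm = np.interp(grid, hours, conf) / ctrl_mean
            out.append(np.trapezoid(norm, grid))
        return np.array(out)

    auc_t, auc_c = aucs(trt_curves), aucs(ctrl_curves)
    t, p = stats.ttest_ind(auc_t, auc_c, equal_var=False)
    cond = treated["condition"].iloc[0] if "condition" in treated.columns else "treated"
    return GrowthComparison(str(cond), auc_t, auc_c, float(t), float(p))


def migration_rate(records: pd.DataFrame, control: str) -> pd.DataFrame:
    """Closed distance, migration rate and control-normalized rate per well.

    ``records`` needs columns condition, replicate, width_0h_um, width_12h_um.
    Returns per-well records with closed_um, rate_um_per_h, normalized_rate
    (fraction of the control mean rate) plus per-condition Welch t and p
    against control. Negative closure (scratch widening) is kept but flagged.
    """
    required = {"condition", "replicate", "width_0h_um", "width_12h_um"}
    missing = required - set(records.columns)
    if missing:
        raise ConfigurationError(f"migration table missing columns {sorted(missing)}")
    if control not in set(records["condition"]):
        raise ConfigurationError(f"control condition {control!r} not present")
    out = records.copy()
    out["closed_um"] = out["width_0h_um"] - out["width_12h_um"]
    if (out["closed_um"] < 0).any():
        warnings.warn(
            f"{int((out['closed_um'] < 0).sum())} wells with negative closure "
            "(scratch widened)",
            stacklevel=2,
        )
    out["rate_um_per_h"] = out["closed_um"] / MIGRATION_HOURS
    ctrl_rates = out.loc[out["condition"] == control, "rate_um_per_h"].to_numpy()
    out["normalized_rate"] = out["rate_um_per_h"] / ctrl_rates.mean()
    t_col, p_col = {}, {}
    for cond, grp in out.groupby("condition"):
        if cond == control or len(grp) < 2 or len(ctrl_rates) < 2:
            t_col[cond], p_col[cond] = np.nan, np.nan
            continue
        t, p = stats.ttest_ind(
            grp["rate_um_per_h"].to_numpy(), ctrl_rates, equal_var=False
        )
        t_col[cond], p_col[cond] = float(t), float(p)
    out["welch_t"] = out["condition"].map(t_col)
    out["p"] = out["condition"].map(p_col)
    return out
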