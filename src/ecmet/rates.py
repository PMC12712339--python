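"""Uptake/secretion rate estimation from timed supernatant measurements.

Supernatant ion intensities sampled at 0, 2, 22 and 24 h after each medium
exchange are normalized to the t = 0 value within each (ion, condition,
replicate) series; the slope of an ordinary least squares fit of normalized
intensity on time is the exchange rate in normalized intensity per hour.
Negative rates mean uptake from the medium, positive rates secretion.
Because absolute rates depend on each compound's starting abundance in the
medium, cross-condition comparisons use the per-ion z-score of rates.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError

RATE_COLUMNS = ["ion_id", "condition", "rate", "intercept", "r2",
                "direction", "n_points"]


def normalize_to_t0(table: pd.DataFrame) -> pd.DataFrame:
    """Divide each (ion, condition, replicate) series by its t = 0 intensity.

    Series with a missing or non-positive t = 0 measurement are excluded
    with a warning; t = 0 entries of surviving series become exactly 1.
    Idempotent on its own output.
    """
    required = {"ion_id", "condition", "replicate", "hour", "intensity"}
    missing = required - set(table.columns)
    if missing:
        raise ConfigurationError(f"supernatant table missing columns {sorted(missing)}")
    keys = ["ion_id", "condition", "replicate"]
    out = []
    n_dropped = 0
    for key, grp in table.groupby(keys, sort=False):
        t0 = grp.loc[grp["hour"] == 0, "intensity"]
        if t0.empty or not np.isfinite(t0.iloc[0]) or t0.iloc[0] <= 0:
            n_dropped += 1
            continue
        g = grp.copy()
        g["intensity"] = g["intensity"] / float(t0.iloc[0])
        out.append(g)
    if n_dropped:
        warnings.warn(
            f"excluded {n_dropped} series with missing or zero t=0 intensity",
            stacklevel=2,
        )
    if not out:
        return table.iloc[0:0].copy()
    return pd.concat(out, ignore_index=True)


def fit_rate(table: pd.DataFrame, pool_replicates: bool = True) -> pd.DataFrame:
    """OLS slope of t0-normalized intensity vs time per (ion, condition).

    Replicate series are pooled into one regression by default (one slope
    from all points); ``pool_replicates=False`` fits each replicate and
    reports the mean slope with its SD. Fewer than 3 points yields an NA
    record. Direction is uptake (rate < 0), secretion (rate > 0) or none.
    """
    keys = ["ion_id", "condition"] if pool_replicates else ["ion_id", "condition", "replicate"]
    rows = []
    for key, grp in table.groupby(keys, sort=False):
        x = grp["hour"].to_numpy(dtype=float)
        y = grp["intensity"].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        rec = dict(zip(keys, key))
        rec["n_points"] = int(ok.sum())
        if len(x) < 3 or np.ptp(x) == 0:
            rec.update(rate=np.nan, intercept=np.nan, r2=np.nan, direction="NA")
        else:
            res = stats.linregress(x, y)
            rate = float(res.slope)
            rec.update(
                rate=rate,
                intercept=float(res.intercept),
                r2=float(res.rvalue**2),
                direction="uptake" if rate < 0 else "secretion" if rate > 0 else "none",
            )
        rows.append(rec)
    out = pd.DataFrame(rows)
    if not pool_replicates and len(out):
        agg = (
            out.dropna(subset=["rate"])
            .groupby(["ion_id", "condition"], sort=False)["rate"]
            .agg(rate="mean", rate_sd="std", n_replicates="count")
            .reset_index()
        )
        agg["direction"] = np.select(
            [agg["rate"] < 0, agg["rate"] > 0], ["uptake", "secretion"], "none"
        )
        return agg
    return out[RATE_COLUMNS]


def rate_zscore_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per-ion z-scores of rates across conditions (ions x conditions).

    Each ion's rates across all conditions (cell line x state) are z-scored
    with ddof = 1 to highlight relative differences between conditions.
    Ions with constant rates (or < 2 conditions) become all-NA rows with a
    warning.
    """
    wide = records.pivot_table(index="ion_id", columns="condition",
                               values="rate", aggfunc="mean")
    mean = wide.mean(axis=1, skipna=True)
    sd = wide.std(axis=1, ddof=1, skipna=True)
    degenerate = (sd == 0) | sd.isna() | (wide.notna().sum(axis=1) < 2)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} ions with constant or single rates "
            "z-scored to NA",
            stacklevel=2,
        )
    sd = sd.mask(degenerate)
    return wide.sub(mean, axis=0).div(sd, axis=0)
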