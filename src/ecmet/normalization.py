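"""Intensity normalization: injection-order drift removal, cell-number
correction and z-scoring.

Flow-injection instruments drift slowly in sensitivity over an acquisition
sequence. Because injection order is randomized with respect to the design,
the drift can be estimated from the per-sample median intensity over all
ions (robust to the minority of truly changing metabolites) and divided out
with a centered moving median over acquisition order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import OmicsMatrix, SampleAnnotation


@dataclass
class DriftModel:
    """Fitted drift correction: per-sample multiplicative scale factors."""

    window: int
    scale_factors: pd.Series  # indexed by sample id, all > 0
    reference_level: float  # global median of per-sample medians


def moving_median_drift_correct(
    m: OmicsMatrix,
    order: pd.Series | dict,
    window: int = 15,
    per_ion: bool = False,
) -> tuple[OmicsMatrix, DriftModel]:
    """Remove temporal drift by moving-median scaling over acquisition order.

    For each sample the local instrument response level is the median of
    per-sample median intensities within a centered window of ``window``
    consecutive acquisitions (slid inward at the sequence edges so it always
    spans ``window`` acquisitions). Each sample
    is rescaled by reference_level / local_level, where reference_level is
    the global median of per-sample medians, so the overall intensity scale
    is preserved.

    ``per_ion=True`` applies the same windowed-median correction per ion
    trace instead of per-sample medians.
    """
    if window < 1 or window % 2 == 0:
        raise ConfigurationError("window must be an odd count >= 1")
    order = pd.Series(order)
    missing = [s for s in m.sample_ids if s not in order.index]
    if missing:
        raise ConfigurationError(f"samples missing acquisition index: {missing}")
    if window > len(m.sample_ids):
        raise ConfigurationError("window larger than the number of samples")

    seq = order.loc[m.sample_ids].sort_values().index  # samples in run order
    half = window // 2
    n = len(seq)

    if per_ion:
        values = m.data[seq].to_numpy(dtype=float)
        corrected = values.copy()
        ref = np.nanmedian(values, axis=1)
        for j in range(n):
            lo = min(max(0, j - half), n - window)
            hi = lo + window
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                local = np.nanmedian(values[:, lo:hi], axis=1)
            local = np.where((local > 0) & np.isfinite(local), local, ref)
            corrected[:, j] = values[:, j] * np.where(local > 0, ref / local, 1.0)
        out = m.data.copy()
        out[seq] = corrected
        factors = pd.Series(1.0, index=seq)  # per-ion mode has no single factor
        return OmicsMatrix(out), DriftModel(window, factors.loc[m.sample_ids],
                                            float(np.nanmedian(ref)))

    medians = m.data[seq].median(axis=0, skipna=True)  # per-sample medians, run order
    reference = float(np.median(medians.to_numpy()))
    local = np.empty(n)
    med = medians.to_numpy()
    for j in range(n):
        # centered window; at the edges it slides inward so it always spans
        # `window` acquisitions (window = n_samples degenerates to a single
        # global median scaling)
        lo = min(max(0, j - half), n - window)
        local[j] = np.median(med[lo:lo + window])
    factors = pd.Series(reference / local, index=seq)
    out = m.data.copy()
    out[seq] = m.data[seq] * factors
    return OmicsMatrix(out), DriftModel(window, factors.loc[m.sample_ids], reference)


def celltype_mean_normalize(m: OmicsMatrix, ann: SampleAnnotation) -> OmicsMatrix:
    """Equalize mean ion intensity across samples within each cell type.

    Differences in cell number at extraction scale all ions of a sample
    together; within a cell type each sample is rescaled so its mean ion
    intensity equals the cell-type grand mean (mean of per-sample means),
    preserving the total signal per cell type.
    """
    missing = [s for s in m.sample_ids if s not in ann.table.index]
    if missing:
        raise ConfigurationError(f"samples missing cell_type annotation: {missing}")
    out = m.data.copy()
    cell_types = ann.table.loc[m.sample_ids, "cell_type"]
    for _, samples in cell_types.groupby(cell_types).groups.items():
        samples = list(samples)
        means = m.data[samples].mean(axis=0, skipna=True)
        target = float(means.mean())
        out[samples] = m.data[samples] * (target / means)
    return OmicsMatrix(out)


def zscore(values, axis: str = "features"):
    """Z-score a matrix along ``features`` (rows) or ``samples`` (columns).

    Uses the sample standard deviation (ddof=1); missing values propagate.
    Vectors with zero variance (or < 2 observed values) come back all-missing
    with a warning.
    """
    if axis not in ("features", "samples"):
        raise ConfigurationError("axis must be 'features' or 'samples'")
    df = values.data if isinstance(values, OmicsMatrix) else pd.DataFrame(values)
    ax = 1 if axis == "features" else 0
    mean = df.mean(axis=ax, skipna=True)
    sd = df.std(axis=ax, ddof=1, skipna=True)
    n_obs = df.notna().sum(axis=ax)
    degenerate = (sd == 0) | (n_obs < 2) | sd.isna()
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} constant or underpopulated vectors "
            "z-scored to missing",
            stacklevel=2,
        )
    sd = sd.mask(degenerate)
    z = df.sub(mean, axis=1 - ax).div(sd, axis=1 - ax)
    return z
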