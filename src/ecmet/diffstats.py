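"""Two-group differential analysis with Storey q-value or Benjamini-Hochberg
false-discovery-rate control.

The canonical contrast is quiescence (day 5, contact-inhibited) versus
proliferation (day 2). Tests run on log2-transformed intensities; fold
changes are differences of group means on the log2 scale, oriented
quiescent / proliferating. Proteomics-style calls use Storey q < 0.05 with
|log2FC| > 0.5; metabolomics-style calls use BH-adjusted p with the same
fold-change cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import interpolate, stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError
from .io import OmicsMatrix
from .normalization import zscore


@dataclass
class QvalueModel:
    """Storey pi0 estimate with its lambda profile."""

    pi0: float
    lambda_grid: np.ndarray
    pi0_by_lambda: np.ndarray


def two_group_test(
    m: OmicsMatrix,
    group_a: list[str],
    group_b: list[str],
    variant: str = "welch",
    already_log2: bool = False,
) -> pd.DataFrame:
    """Per-feature two-sided t-test of group A (quiescent) vs B (proliferating).

    Intensities are log2-transformed unless ``already_log2``. Missing values
    are dropped pairwise per feature; features with fewer than two observed
    values in either group get NaN results. Returns a DataFrame indexed by
    feature id with columns log2fc, t_stat, p, n_a, n_b.
    """
    if variant not in ("student", "welch"):
        raise ConfigurationError(f"unknown t-test variant {variant!r}")
    if not group_a or not group_b:
        raise ConfigurationError("both groups must be non-empty")
    a = m.data[list(group_a)].to_numpy(dtype=float)
    b = m.data[list(group_b)].to_numpy(dtype=float)
    if not already_log2:
        with np.errstate(divide="ignore"):
            a, b = np.log2(a), np.log2(b)
        a[~np.isfinite(a)] = np.nan
        b[~np.isfinite(b)] = np.nan
    n_a = np.sum(~np.isnan(a), axis=1)
    n_b = np.sum(~np.isnan(b), axis=1)
    ok = (n_a >= 2) & (n_b >= 2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(
            a, b, axis=1, equal_var=(variant == "student"), nan_policy="omit"
        )
        log2fc = np.nanmean(a, axis=1) - np.nanmean(b, axis=1)
    t_stat = np.where(ok, res.statistic, np.nan)
    p = np.where(ok, res.pvalue, np.nan)
    log2fc = np.where((n_a >= 1) & (n_b >= 1), log2fc, np.nan)
    return pd.DataFrame(
        {"log2fc": log2fc, "t_stat": t_stat, "p": p, "n_a": n_a, "n_b": n_b},
        index=m.data.index,
    )


def storey_qvalues(p) -> tuple[np.ndarray, QvalueModel]:
    """Storey-Tibshirani q-values.

    pi0 is estimated from the p-value histogram tail: pi0(lambda) =
    #{p > lambda} / (m (1 - lambda)) on lambda = 0.05, 0.10, ..., 0.95, then
    smoothed with a cubic smoothing spline and evaluated at lambda = 0.95,
    clipped into (0, 1]. q(p_(i)) = min_{t >= p_(i)} pi0 * m * t / #{p <= t}.
    With fewer than 20 p-values the spline is unstable and pi0 falls back
    to 1 (equivalent to BH).
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ConfigurationError("p must be one-dimensional")
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ConfigurationError("p-values must lie in [0, 1]")
    m = p.size
    if m < 20:
        lam = np.array([])
        pi0s = np.array([])
        pi0 = 1.0
    else:
        lam = np.arange(0.05, 0.96, 0.05)
        pi0s = np.array([np.mean(p > l) / (1.0 - l) for l in lam])
        spline = interpolate.UnivariateSpline(lam, pi0s, k=3)
        pi0 = float(np.clip(spline(lam[-1]), 1.0 / m, 1.0))
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * p_sorted / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, QvalueModel(pi0, lam, pi0s)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ConfigurationError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def add_fdr(records: pd.DataFrame, correction: str = "storey") -> pd.DataFrame:
    """Attach a 'q' (Storey) or 'adj_p' (BH) column, ignoring NaN tests.

    Features whose test failed the >= 2 observations rule are excluded from
    the multiplicity denominator and keep NaN.
    """
    if correction not in ("storey", "bh"):
        raise ConfigurationError(f"unknown correction {correction!r}")
    out = records.copy()
    valid = out["p"].notna()
    col = "q" if correction == "storey" else "adj_p"
    vals = np.full(len(out), np.nan)
    if valid.any():
        if correction == "storey":
            vals[valid.to_numpy()], model = storey_qvalues(out.loc[valid, "p"])
            out.attrs["qvalue_model"] = model
        else:
            vals[valid.to_numpy()] = bh_adjust(out.loc[valid, "p"])
    out[col] = vals
    return out


def filter_significant(
    records: pd.DataFrame,
    fc_cutoff: float = 0.5,
    alpha: float = 0.05,
    correction: str = "storey",
) -> pd.DataFrame:
    """Apply the significance call: |log2fc| > fc_cutoff AND q (or adj_p) < alpha.

    Both inequalities are strict. Returns the records with a boolean
    'significant' column added (computing the FDR column if absent).
    """
    col = "q" if correction == "storey" else "adj_p"
    out = records if col in records.columns else add_fdr(records, correction)
    out = out.copy()
    out["significant"] = (
        (out["log2fc"].abs() > fc_cutoff) & (out[col] < alpha)
    ).fillna(False)
    return out


def core_signature(
    per_cell_line_records: dict[str, pd.DataFrame],
    fc_cutoff: float = 1.0,
    alpha: float = 0.01,
    correction: str = "storey",
) -> set[str]:
    """Features significant in every cell line (default |log2fc| > 1, q < 0.01).

    The intersection over cell lines of the per-line significant sets —
    the state signature conserved across all endothelial cell types.
    """
    if not per_cell_line_records:
        raise ConfigurationError("need records for at least one cell line")
    sets = []
    for records in per_cell_line_records.values():
        filt = filter_significant(records, fc_cutoff, alpha, correction)
        sets.append(set(filt.index[filt["significant"]]))
    return set.intersection(*sets)


def ordination_and_correlation(m: OmicsMatrix, n_components: int = 2):
    """PCA scores on z-scored features plus a sample-sample Spearman matrix.

    Constant features are dropped with a warning before z-scoring. Returns
    (scores DataFrame [samples x PCs], explained variance fractions,
    Spearman rho DataFrame [samples x samples]).
    """
    from sklearn.decomposition import PCA

    if len(m.sample_ids) < 2:
        raise ConfigurationError("need at least 2 samples")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        z = zscore(m, axis="features")
    z = z.dropna(axis=0, how="any")
    dropped = m.shape[0] - z.shape[0]
    if dropped:
        warnings.warn(f"dropped {dropped} constant or incomplete features",
                      stacklevel=2)
    n_components = min(n_components, min(z.shape) - 1) or 1
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(z.to_numpy().T)
    scores = pd.DataFrame(
        scores, index=z.columns, columns=[f"PC{i+1}" for i in range(n_components)]
    )
    rho, _ = stats.spearmanr(z.to_numpy())
    rho = np.atleast_2d(rho)
    rho_df = pd.DataFrame(rho, index=z.columns, columns=z.columns)
    return scores, pca.explained_variance_ratio_, rho_df
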