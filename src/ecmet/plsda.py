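"""PLS-DA marker discovery for vascular-bed identity.

A two-class partial least squares discriminant analysis (lymphatic vs blood
endothelial cells, encoded +1 / -1) is fit on autoscaled intensities; the
first latent variable (LV1) carries the class-discriminating information
and each feature's LV1 weight measures its contribution. Marker selection
is stabilized by bootstrap: samples are resampled with replacement within
each class, the model refit, the component sign aligned to the full-data
fit, and a feature is called LEC-associated if it falls in the top
``tail_fraction`` of LV1 weights (90th percentile by default) in at least a
``consensus`` fraction of replicates — BEC-associated symmetrically in the
bottom tail. A permutation test on the class labels yields a null
distribution for the selected-feature counts.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

from .errors import ConfigurationError
from .io import OmicsMatrix

CLASS_ENCODING = {"LEC": 1.0, "BEC": -1.0}


@dataclass
class PlsdaModel:
    n_components: int
    weights: pd.DataFrame       # feature x component, unit-norm columns
    scores: pd.DataFrame        # sample x component
    loadings: pd.DataFrame      # feature x component
    class_encoding: dict[str, float]
    dropped_features: list[str]  # constant under autoscaling


@dataclass
class BootstrapSelection:
    B: int
    tail_fraction: float
    consensus: float
    lec_features: set[str]
    bec_features: set[str]
    top_frequency: pd.Series     # per-feature fraction of replicates in top tail
    bottom_frequency: pd.Series
    mode: str = "consensus"


@dataclass
class PermutationResult:
    n_permutations: int
    null_counts_top: np.ndarray
    null_counts_bottom: np.ndarray
    null_counts_combined: np.ndarray
    observed_top: int
    observed_bottom: int
    observed_combined: int
    p_top: float
    p_bottom: float
    p_combined: float
    exhaustive: bool = False
    warnings: list[str] = field(default_factory=list)


def _autoscale(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column z-scores (ddof=1); returns (scaled X, keep mask for non-constant)."""
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    Xs = (X[:, keep] - mean[keep]) / sd[keep]
    return Xs, keep


def _encode_classes(sample_ids, classes) -> np.ndarray:
    y = []
    for s in sample_ids:
        label = classes[s]
        if label not in CLASS_ENCODING:
            raise ConfigurationError(f"sample {s!r}: unknown class {label!r}")
        y.append(CLASS_ENCODING[label])
    y = np.asarray(y)
    if len(set(y)) < 2:
        raise ConfigurationError("both LEC and BEC classes must be present")
    return y


def fit_plsda(
    m: OmicsMatrix, classes: dict[str, str] | pd.Series, n_components: int = 2
) -> PlsdaModel:
    """Fit a two-class PLS-DA (NIPALS PLS1 on y in {+1, -1}, autoscaled X).

    The fit is deterministic. Component 1 is oriented so LEC samples score
    positive, hence positive LV1 weights indicate LEC association. Constant
    features are dropped and reported on the model.
    """
    if n_components < 1:
        raise ConfigurationError("n_components must be >= 1")
    X = m.data.to_numpy(dtype=float).T  # samples x features
    if np.isnan(X).any():
        raise ConfigurationError("PLS-DA requires a complete matrix (no missing)")
    y = _encode_classes(m.sample_ids, classes)
    Xs, keep = _autoscale(X)
    rank = np.linalg.matrix_rank(Xs)
    if n_components > rank:
        raise ConfigurationError(
            f"n_components={n_components} exceeds matrix rank {rank}"
        )
    pls = PLSRegression(n_components=n_components, scale=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pls.fit(Xs, y - y.mean())
    W = pls.x_weights_.copy()     # unit-norm columns
    T = pls.x_scores_.copy()
    P = pls.x_loadings_.copy()
    # orient LV1 so the +1 (LEC) class scores positive
    if T[y > 0, 0].mean() < T[y < 0, 0].mean():
        W[:, 0] *= -1.0
        T[:, 0] *= -1.0
        P[:, 0] *= -1.0
    kept = [f for f, k in zip(m.feature_ids, keep) if k]
    dropped = [f for f, k in zip(m.feature_ids, keep) if not k]
    comps = [f"LV{i+1}" for i in range(n_components)]
    return PlsdaModel(
        n_components=n_components,
        weights=pd.DataFrame(W, index=kept, columns=comps),
        scores=pd.DataFrame(T, index=m.sample_ids, columns=comps),
        loadings=pd.DataFrame(P, index=kept, columns=comps),
        class_encoding=dict(CLASS_ENCODING),
        dropped_features=dropped,
    )


def _lv1_weights(X: np.ndarray, y: np.ndarray, feature_ids) -> pd.Series:
    """LV1 weight vector over all features; NaN where a feature is constant."""
    Xs, keep = _autoscale(X)
    if Xs.shape[1] == 0:
        return pd.Series(np.nan, index=feature_ids)
    pls = PLSRegression(n_components=1, scale=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pls.fit(Xs, y - y.mean())
    w = np.full(len(feature_ids), np.nan)
    w[keep] = pls.x_weights_[:, 0]
    t1 = Xs @ pls.x_weights_[:, 0]
    if t1[y > 0].mean() < t1[y < 0].mean():
        w = -w
    return pd.Series(w, index=feature_ids)


def bootstrap_select(
    m: OmicsMatrix,
    classes: dict[str, str] | pd.Series,
    B: int = 1000,
    tail_fraction: float = 0.10,
    consensus: float = 0.9,
    seed: int = 0,
    mode: str = "consensus",
) -> BootstrapSelection:
    """Bootstrap-stabilized selection of LEC/BEC-associated features.

    ``consensus`` mode (default): per replicate, the top/bottom
    ``tail_fraction`` quantiles of LV1 weights define the tails; a feature
    is selected for a class when its tail frequency reaches ``consensus``.
    ``ci`` mode: a feature is selected when its bootstrap weight
    distribution's [tail_fraction, 1 - tail_fraction] percentile interval
    excludes zero, classed by the sign of its mean weight.
    """
    if not 0.0 < tail_fraction < 0.5:
        raise ConfigurationError("tail_fraction must lie in (0, 0.5)")
    if B < 1:
        raise ConfigurationError("B must be >= 1")
    if mode not in ("consensus", "ci"):
        raise ConfigurationError(f"unknown selection mode {mode!r}")
    X = m.data.to_numpy(dtype=float).T
    y = _encode_classes(m.sample_ids, classes)
    feature_ids = pd.Index(m.feature_ids)
    full_w = _lv1_weights(X, y, feature_ids)

    rng = np.random.default_rng(seed)
    # strata ordered by sample position, not by class label, so that swapping
    # LEC/BEC labels reproduces the same resamples and exactly swaps the lists
    strata = sorted(
        [np.flatnonzero(y > 0), np.flatnonzero(y < 0)], key=lambda idx: idx.min()
    )
    n_feat = len(feature_ids)
    top_counts = np.zeros(n_feat)
    bottom_counts = np.zeros(n_feat)
    all_w = np.empty((B, n_feat)) if mode == "ci" else None

    full_vals = full_w.to_numpy()
    for b in range(B):
        take = np.concatenate(
            [rng.choice(g, size=g.size, replace=True) for g in strata]
        )
        w = _lv1_weights(X[take], y[take], feature_ids).to_numpy()
        # sign-align to the full-data LV1 (component signs are arbitrary)
        both = ~np.isnan(w) & ~np.isnan(full_vals)
        if both.sum() >= 2 and np.corrcoef(w[both], full_vals[both])[0, 1] < 0:
            w = -w
        if mode == "ci":
            all_w[b] = w
        observed = ~np.isnan(w)
        if observed.any():
            hi = np.nanquantile(w, 1.0 - tail_fraction)
            lo = np.nanquantile(w, tail_fraction)
            top_counts[observed & (w >= hi)] += 1
            bottom_counts[observed & (w <= lo)] += 1

    top_freq = pd.Series(top_counts / B, index=feature_ids)
    bottom_freq = pd.Series(bottom_counts / B, index=feature_ids)
    if mode == "consensus":
        lec_mask = top_freq >= consensus
        bec_mask = bottom_freq >= consensus
        clash = lec_mask & bec_mask
        if clash.any():  # only reachable at consensus <= 0.5; break by frequency
            prefer_top = top_freq >= bottom_freq
            lec_mask &= ~clash | prefer_top
            bec_mask &= ~clash | ~prefer_top
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            lo_q = np.nanquantile(all_w, tail_fraction, axis=0)
            hi_q = np.nanquantile(all_w, 1.0 - tail_fraction, axis=0)
            mean_w = np.nanmean(all_w, axis=0)
        excludes_zero = (lo_q > 0) | (hi_q < 0)
        lec_mask = pd.Series(excludes_zero & (mean_w > 0), index=feature_ids)
        bec_mask = pd.Series(excludes_zero & (mean_w < 0), index=feature_ids)
    return BootstrapSelection(
        B=B,
        tail_fraction=tail_fraction,
        consensus=consensus,
        lec_features=set(feature_ids[lec_mask]),
        bec_features=set(feature_ids[bec_mask]),
        top_frequency=top_freq,
        bottom_frequency=bottom_freq,
        mode=mode,
    )


def _celltype_assignments(cell_types: pd.Series, n_lec: int):
    """All ways to assign n_lec of the distinct cell types to the LEC bed."""
    distinct = sorted(cell_types.unique())
    for combo in itertools.combinations(distinct, n_lec):
        yield {ct: ("LEC" if ct in combo else "BEC") for ct in distinct}


def permutation_null(
    m: OmicsMatrix,
    classes: dict[str, str] | pd.Series,
    n_permutations: int = 999,
    tail_fraction: float = 0.10,
    consensus: float = 0.9,
    B_inner: int = 100,
    seed: int = 0,
    level: str = "sample",
    cell_types: pd.Series | None = None,
) -> PermutationResult:
    """Permutation null for the number of features passing the LV1 selection.

    ``level='sample'`` shuffles bed labels across samples; ``level='celltype'``
    permutes at the cell-type level (all samples of a cell type share a bed),
    falling back to exhaustive enumeration of the alternative assignments
    when fewer distinct permutations exist than requested. One-sided p-values
    use (1 + #{null >= observed}) / (1 + n_used).
    """
    if level not in ("sample", "celltype"):
        raise ConfigurationError(f"unknown permutation level {level!r}")
    classes = pd.Series({s: classes[s] for s in m.sample_ids})
    rng = np.random.default_rng(seed)
    notes: list[str] = []

    observed = bootstrap_select(
        m, classes, B=B_inner, tail_fraction=tail_fraction,
        consensus=consensus, seed=int(rng.integers(2**31)),
    )
    obs_top, obs_bottom = len(observed.lec_features), len(observed.bec_features)
    obs_comb = obs_top + obs_bottom

    null_labelings: list[pd.Series] = []
    exhaustive = False
    if level == "celltype":
        if cell_types is None:
            raise ConfigurationError("celltype-level permutation needs cell_types")
        cell_types = pd.Series({s: cell_types[s] for s in m.sample_ids})
        bed_of = classes.groupby(cell_types).first()
        n_lec = int((bed_of == "LEC").sum())
        swap = {"LEC": "BEC", "BEC": "LEC"}
        # the complement assignment is the observed one with classes swapped:
        # selection lists merely exchange, so it is not a genuine null point
        assignments = [
            a for a in _celltype_assignments(cell_types, n_lec)
            if any(a[ct] != bed_of[ct] for ct in a)
            and any(a[ct] != swap[bed_of[ct]] for ct in a)
        ]
        if len(assignments) < n_permutations:
            exhaustive = True
            notes.append(
                f"only {len(assignments)} distinct cell-type assignments; "
                "running exhaustive enumeration"
            )
            chosen = assignments
        else:
            chosen = [assignments[i] for i in
                      rng.choice(len(assignments), n_permutations, replace=False)]
        for a in chosen:
            null_labelings.append(cell_types.map(a))
    else:
        labels = classes.to_numpy()
        for _ in range(n_permutations):
            null_labelings.append(
                pd.Series(rng.permutation(labels), index=classes.index)
            )

    n_top, n_bottom, n_comb = [], [], []
    for perm in null_labelings:
        sel = bootstrap_select(
            m, perm, B=B_inner, tail_fraction=tail_fraction,
            consensus=consensus, seed=int(rng.integers(2**31)),
        )
        n_top.append(len(sel.lec_features))
        n_bottom.append(len(sel.bec_features))
        n_comb.append(len(sel.lec_features) + len(sel.bec_features))
    n_top, n_bottom, n_comb = map(np.asarray, (n_top, n_bottom, n_comb))
    n_used = len(null_labelings)

    def pval(null, obs):
        return float((1 + np.sum(null >= obs)) / (1 + n_used))

    if notes:
        for note in notes:
            warnings.warn(note, stacklevel=2)
    return PermutationResult(
        n_permutations=n_used,
        null_counts_top=n_top,
        null_counts_bottom=n_bottom,
        null_counts_combined=n_comb,
        observed_top=obs_top,
        observed_bottom=obs_bottom,
        observed_combined=obs_comb,
        p_top=pval(n_top, obs_top),
        p_bottom=pval(n_bottom, obs_bottom),
        p_combined=pval(n_comb, obs_comb),
        exhaustive=exhaustive,
        warnings=notes,
    )
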