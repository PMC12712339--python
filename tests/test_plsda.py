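import numpy as np
import pandas as pd
import pytest

from ecmet import io, plsda
from ecmet.errors import ConfigurationError
from ecmet.plsda import bootstrap_select, fit_plsda, permutation_null
from ecmet.synthetic import SimulationConfig, gen_omics_matrix


def matrix_from(values, samples=None, features=None):
    values = np.asarray(values, dtype=float)
    features = features or [f"f{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return io.OmicsMatrix(pd.DataFrame(values, index=features, columns=samples))


def nipals_pls1_oracle(X, y, n_components):
    """Independent PLS1 reference: w = X'y / ||X'y||, standard deflation."""
    X = X.copy()
    y = y - y.mean()
    W, T, P = [], [], []
    for _ in range(n_components):
        w = X.T @ y
        w = w / np.linalg.norm(w)
        t = X @ w
        p = X.T @ t / (t @ t)
        X = X - np.outer(t, p)
        W.append(w)
        T.append(t)
        P.append(p)
    return np.column_stack(W), np.column_stack(T), np.column_stack(P)


@pytest.fixture(scope="module")
def bed_dataset():
    cfg = SimulationConfig(
        n_features=400, days=(2, 5), frac_state_markers=0.0,
        frac_bed_markers=0.1, effect_size_log2=2.0, noise_sd_log2=0.3, seed=7,
    )
    m, ann, truth = gen_omics_matrix(cfg)
    return m, ann.table["vascular_bed"], truth


class TestFitPlsda:
    def test_separates_planted_classes_by_lv1_sign(self, bed_dataset):
        m, classes, _ = bed_dataset
        model = fit_plsda(m, classes, n_components=2)
        lv1 = model.scores["LV1"]
        lec = classes[classes == "LEC"].index
        bec = classes[classes == "BEC"].index
        assert (lv1.loc[lec] > 0).all()
        assert (lv1.loc[bec] < 0).all()

    def test_single_class_rejected(self, bed_dataset):
        m, classes, _ = bed_dataset
        with pytest.raises(ConfigurationError, match="both"):
            fit_plsda(m, pd.Series("LEC", index=classes.index), 1)

    def test_components_beyond_rank_rejected(self, rng):
        m = matrix_from(rng.normal(10, 1, size=(20, 4)) ** 2)
        classes = pd.Series(["LEC", "LEC", "BEC", "BEC"], index=m.sample_ids)
        with pytest.raises(ConfigurationError, match="rank"):
            fit_plsda(m, classes, n_components=10)

    def test_weight_columns_unit_norm(self, bed_dataset):
        m, classes, _ = bed_dataset
        model = fit_plsda(m, classes, n_components=2)
        norms = np.linalg.norm(model.weights.to_numpy(), axis=0)
        assert np.allclose(norms, 1.0, atol=1e-10)

    def test_matches_independent_nipals_oracle(self, rng):
        X = rng.normal(size=(8, 6))
        y = np.array([1.0, 1.0, 1.0, 1.0, -1.0, -1.0, -1.0, -1.0])
        # positive intensities; the oracle autoscales the same way the fit does
        m = matrix_from(np.exp(X.T / 4))
        classes = pd.Series(np.where(y > 0, "LEC", "BEC"), index=m.sample_ids)
        model = fit_plsda(m, classes, n_components=2)
        Xin = m.data.to_numpy().T
        Xin = (Xin - Xin.mean(0)) / Xin.std(0, ddof=1)
        W, T, P = nipals_pls1_oracle(Xin, y, 2)
        for comp in range(2):
            w_fit = model.weights.iloc[:, comp].to_numpy()
            w_ref = W[:, comp]
            sign = np.sign(w_fit @ w_ref)
            assert np.allclose(w_fit, sign * w_ref, atol=1e-8)
            assert np.allclose(
                model.scores.iloc[:, comp].to_numpy(), sign * T[:, comp], atol=1e-8
            )

    def test_duplicated_feature_block_splits_weights_evenly(self, rng):
        base = rng.normal(10, 1, size=(5, 6)) ** 2
        m1 = matrix_from(base)
        m2 = matrix_from(
            np.vstack([base, base]),
            features=[f"f{i}" for i in range(5)] + [f"g{i}" for i in range(5)],
        )
        classes = pd.Series(["LEC"] * 3 + ["BEC"] * 3, index=m1.sample_ids)
        a = fit_plsda(m1, classes, 1)
        b = fit_plsda(m2, classes, 1)
        wa = a.weights["LV1"].to_numpy()
        wb = b.weights["LV1"].to_numpy()
        # duplicated block halves the weight mass per copy (norm preserved)
        assert np.allclose(wb[:5], wb[5:], atol=1e-10)
        assert np.allclose(wb[:5] * np.sqrt(2), wa, atol=1e-8)
        # scores identical up to the common scale factor
        ta, tb = a.scores["LV1"].to_numpy(), b.scores["LV1"].to_numpy()
        assert np.allclose(tb / np.linalg.norm(tb), ta / np.linalg.norm(ta), atol=1e-8)


class TestBootstrapSelect:
    def test_recovers_planted_bed_markers(self, bed_dataset):
        m, classes, truth = bed_dataset
        sel = bootstrap_select(m, classes, B=100, tail_fraction=0.10,
                               consensus=0.9, seed=5)
        lec_true = {f for f, c in truth.bed_marker_class.items() if c == "LEC"}
        bec_true = truth.bed_marker_ids - lec_true
        recovered = len(sel.lec_features & lec_true) + len(sel.bec_features & bec_true)
        assert recovered >= 0.9 * len(truth.bed_marker_ids)
        assert not sel.lec_features & bec_true
        assert not sel.bec_features & lec_true

    def test_lists_disjoint(self, bed_dataset):
        m, classes, _ = bed_dataset
        sel = bootstrap_select(m, classes, B=50, seed=1)
        assert not sel.lec_features & sel.bec_features

    def test_selection_monotone_in_consensus(self, bed_dataset):
        m, classes, _ = bed_dataset
        loose = bootstrap_select(m, classes, B=50, consensus=0.5, seed=2)
        strict = bootstrap_select(m, classes, B=50, consensus=1.0, seed=2)
        assert strict.lec_features <= loose.lec_features
        assert strict.bec_features <= loose.bec_features

    def test_reproducible_given_seed(self, bed_dataset):
        m, classes, _ = bed_dataset
        a = bootstrap_select(m, classes, B=30, seed=9)
        b = bootstrap_select(m, classes, B=30, seed=9)
        assert a.lec_features == b.lec_features
        assert a.bec_features == b.bec_features

    def test_swapping_class_labels_swaps_lists(self, bed_dataset):
        m, classes, _ = bed_dataset
        swapped = classes.map({"LEC": "BEC", "BEC": "LEC"})
        a = bootstrap_select(m, classes, B=40, seed=4)
        b = bootstrap_select(m, swapped, B=40, seed=4)
        assert a.lec_features == b.bec_features
        assert a.bec_features == b.lec_features

    def test_ci_mode_also_recovers_markers(self, bed_dataset):
        m, classes, truth = bed_dataset
        sel = bootstrap_select(m, classes, B=100, tail_fraction=0.10,
                               seed=5, mode="ci")
        lec_true = {f for f, c in truth.bed_marker_class.items() if c == "LEC"}
        assert lec_true <= sel.lec_features
        assert not sel.bec_features & lec_true

    @pytest.mark.parametrize("bad", [0.0, 0.5, 0.7])
    def test_tail_fraction_range_enforced(self, bed_dataset, bad):
        m, classes, _ = bed_dataset
        with pytest.raises(ConfigurationError):
            bootstrap_select(m, classes, B=10, tail_fraction=bad)


@pytest.fixture(scope="module")
def small_dataset():
    cfg = SimulationConfig(
        n_features=150, days=(2, 5), frac_state_markers=0.0,
        frac_bed_markers=0.1, effect_size_log2=2.0, seed=3,
    )
    m, ann, _ = gen_omics_matrix(cfg)
    return m, ann


class TestPermutationNull:
    def test_celltype_level_is_exhaustive_for_four_types(self, small_dataset):
        m, ann = small_dataset
        with pytest.warns(UserWarning, match="exhaustive"):
            res = permutation_null(
                m, ann.table["vascular_bed"], n_permutations=99, B_inner=20,
                seed=11, level="celltype", cell_types=ann.table["cell_type"],
            )
        # 6 assignments minus observed and its class-swapped complement
        assert res.exhaustive
        assert res.n_permutations == 4

    def test_planted_markers_reach_the_enumeration_floor(self, small_dataset):
        m, ann = small_dataset
        res = permutation_null(
            m, ann.table["vascular_bed"], n_permutations=99, B_inner=30,
            seed=13, level="celltype", cell_types=ann.table["cell_type"],
        )
        assert res.p_combined == pytest.approx(1 / 5)

    def test_p_values_match_their_definition(self, small_dataset):
        m, ann = small_dataset
        res = permutation_null(
            m, ann.table["vascular_bed"], n_permutations=99, B_inner=20,
            seed=17, level="celltype", cell_types=ann.table["cell_type"],
        )
        for null, obs, p in [
            (res.null_counts_top, res.observed_top, res.p_top),
            (res.null_counts_bottom, res.observed_bottom, res.p_bottom),
            (res.null_counts_combined, res.observed_combined, res.p_combined),
        ]:
            assert p == pytest.approx(
                (1 + np.sum(null >= obs)) / (1 + res.n_permutations)
            )

    def test_sample_level_gives_small_p_for_planted_markers(self, small_dataset):
        m, ann = small_dataset
        res = permutation_null(
            m, ann.table["vascular_bed"], n_permutations=19, B_inner=20,
            seed=19, level="sample",
        )
        assert res.p_combined == pytest.approx(1 / 20)
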