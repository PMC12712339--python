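import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ecmet import diffstats, io
from ecmet.diffstats import (
    add_fdr,
    bh_adjust,
    core_signature,
    filter_significant,
    ordination_and_correlation,
    storey_qvalues,
    two_group_test,
)
from ecmet.errors import ConfigurationError
from ecmet.synthetic import SimulationConfig, gen_omics_matrix


def matrix_from(values, samples=None):
    values = np.asarray(values, dtype=float)
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    idx = [f"f{i}" for i in range(values.shape[0])]
    return io.OmicsMatrix(pd.DataFrame(values, index=idx, columns=samples))


class TestTwoGroupTest:
    def test_identical_groups_give_zero_fc_and_p_one(self):
        m = matrix_from([[2.0, 4.0, 8.0, 2.0, 4.0, 8.0]])
        rec = two_group_test(m, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert rec["log2fc"].iloc[0] == pytest.approx(0.0)
        assert rec["p"].iloc[0] == pytest.approx(1.0)

    def test_student_variant_matches_pooled_variance_closed_form(self):
        a, b = np.array([2.0, 4.0, 6.0]), np.array([1.0, 2.0, 3.0])
        m = matrix_from([np.concatenate([a, b])])
        rec = two_group_test(
            m, ["s0", "s1", "s2"], ["s3", "s4", "s5"],
            variant="student", already_log2=True,
        )
        sp2 = (a.var(ddof=1) + b.var(ddof=1)) / 2
        t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (2 / 3))
        p_hand = 2 * stats.t.sf(abs(t_hand), df=4)
        assert rec["t_stat"].iloc[0] == pytest.approx(t_hand)
        assert rec["p"].iloc[0] == pytest.approx(p_hand)
        assert rec["log2fc"].iloc[0] == pytest.approx(a.mean() - b.mean())

    def test_null_pvalues_uniform(self):
        cfg = SimulationConfig(
            n_features=1000, n_cell_types=1, days=(2, 5),
            frac_state_markers=0, frac_bed_markers=0, seed=17,
        )
        m, ann, _ = gen_omics_matrix(cfg)
        rec = two_group_test(
            m, ann.samples_where(state="quiescent"),
            ann.samples_where(state="proliferating"), variant="student",
        )
        assert stats.kstest(rec["p"], "uniform").pvalue > 0.01

    def test_empty_group_rejected(self, toy_matrix):
        with pytest.raises(ConfigurationError):
            two_group_test(toy_matrix, [], ["s1"])

    def test_too_few_observations_yield_missing(self):
        m = matrix_from([[1.0, np.nan, 4.0, 8.0]])
        rec = two_group_test(m, ["s0", "s1"], ["s2", "s3"])
        assert np.isnan(rec["p"].iloc[0])
        assert np.isnan(rec["t_stat"].iloc[0])

    def test_invariant_to_permutation_within_groups(self, rng):
        m = matrix_from(rng.lognormal(3, 1, size=(20, 8)))
        a, b = ["s0", "s1", "s2", "s3"], ["s4", "s5", "s6", "s7"]
        rec1 = two_group_test(m, a, b)
        rec2 = two_group_test(m, a[::-1], list(reversed(b)))
        pd.testing.assert_frame_equal(rec1, rec2)


class TestStoreyQvalues:
    def test_all_p_one_gives_pi0_one_and_q_one(self):
        q, model = storey_qvalues(np.ones(100))
        assert model.pi0 == pytest.approx(1.0)
        assert np.allclose(q, 1.0)

    def test_uniform_null_pi0_near_one_and_no_calls(self, rng):
        p = rng.uniform(size=2000)
        q, model = storey_qvalues(p)
        assert 0.9 <= model.pi0 <= 1.0
        assert (q < 0.05).sum() == 0

    def test_small_m_falls_back_to_bh(self):
        p = np.array([0.01, 0.2, 0.5])
        q, model = storey_qvalues(p)
        assert model.pi0 == 1.0
        assert np.allclose(q, bh_adjust(p))

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError):
            storey_qvalues(np.array([0.5, 1.5]))

    def test_q_monotone_in_p(self, rng):
        p = rng.uniform(size=500)
        q, _ = storey_qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_empirical_fdr_controlled_with_planted_effects(self):
        """20% planted alternatives at 1.5 log2, n=3/group: FDR(q<0.05) <= 0.10."""
        fdrs = []
        for seed in range(50):
            cfg = SimulationConfig(
                n_features=400, n_cell_types=1, days=(2, 5),
                frac_state_markers=0.2, frac_bed_markers=0,
                effect_size_log2=1.5, seed=1000 + seed,
            )
            m, ann, truth = gen_omics_matrix(cfg)
            rec = two_group_test(
                m, ann.samples_where(state="quiescent"),
                ann.samples_where(state="proliferating"),
            )
            q, _ = storey_qvalues(rec["p"].to_numpy())
            calls = set(rec.index[q < 0.05])
            fdrs.append(
                len(calls - truth.state_marker_ids) / len(calls) if calls else 0.0
            )
        assert np.mean(fdrs) <= 0.10


class TestBhAdjust:
    def test_closed_form_triplet(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_matches_brute_force_definition(self, rng):
        for _ in range(100):
            p = rng.uniform(size=rng.integers(1, 40))
            m = p.size
            order = np.argsort(p)
            brute = np.empty(m)
            for rank_idx, i in enumerate(order):
                later = order[rank_idx:]
                brute[i] = min(
                    min(m * p[j] / (np.searchsorted(p[order], p[j], side="right"))
                        for j in later),
                    1.0,
                )
            assert np.allclose(bh_adjust(p), brute)


class TestFilters:
    def _records(self, rows):
        return pd.DataFrame(rows, index=[f"f{i}" for i in range(len(rows))])

    def test_paper_thresholds(self):
        rec = self._records([{"log2fc": 0.6, "p": 0.001, "q": 0.04}])
        out = filter_significant(rec, fc_cutoff=0.5, alpha=0.05)
        assert out["significant"].iloc[0]

    @pytest.mark.parametrize("log2fc, q, expect", [
        (0.5, 0.04, False),   # fc boundary is strict
        (0.6, 0.05, False),   # alpha boundary is strict
        (-0.6, 0.04, True),   # absolute fold change
    ])
    def test_strict_inequalities(self, log2fc, q, expect):
        rec = self._records([{"log2fc": log2fc, "p": 0.001, "q": q}])
        assert filter_significant(rec)["significant"].iloc[0] == expect

    def test_empty_input(self):
        out = filter_significant(pd.DataFrame(columns=["log2fc", "p", "q"]))
        assert out.empty

    def test_core_signature_requires_all_cell_lines(self):
        passing = self._records([{"log2fc": 2.0, "p": 1e-6, "q": 1e-4}])
        failing = self._records([{"log2fc": 0.2, "p": 0.5, "q": 0.9}])
        per_line = {"A": passing, "B": passing, "C": passing, "D": failing}
        assert core_signature(per_line) == set()
        per_line["D"] = passing
        assert core_signature(per_line) == {"f0"}

    def test_core_signature_single_line_equals_filter(self):
        rec = self._records(
            [{"log2fc": 1.5, "p": 1e-6, "q": 1e-3},
             {"log2fc": 0.8, "p": 0.001, "q": 0.005}]
        )
        assert core_signature({"only": rec}) == {"f0"}

    def test_core_signature_recovers_planted_universal_markers(self):
        recovered, planted = 0, 0
        per_line = {}
        # pool the proliferative (1-2) and quiescent (5-7) day range per line
        cfg = SimulationConfig(
            n_features=300, days=(1, 2, 5, 6, 7), frac_state_markers=0.1,
            frac_bed_markers=0, effect_size_log2=2.0, seed=31,
        )
        m, ann, truth = gen_omics_matrix(cfg)
        for ct in ann.table["cell_type"].unique():
            samples = ann.samples_where(cell_type=ct)
            q = [s for s in samples if ann.table.loc[s, "state"] == "quiescent"]
            p = [s for s in samples if ann.table.loc[s, "state"] == "proliferating"]
            rec = add_fdr(two_group_test(m, q, p), "storey")
            per_line[ct] = rec
        core = core_signature(per_line)
        assert len(core & truth.state_marker_ids) >= 0.9 * len(truth.state_marker_ids)
        assert not core - truth.state_marker_ids  # no false universal markers


class TestOrdination:
    def test_duplicate_samples_identical_scores_and_rho_one(self, rng):
        base = rng.lognormal(3, 1, size=(40, 3))
        m = matrix_from(np.hstack([base, base]),
                        samples=["a1", "a2", "a3", "b1", "b2", "b3"])
        scores, evr, rho = ordination_and_correlation(m)
        assert np.allclose(scores.loc["a1"], scores.loc["b1"], atol=1e-8)
        assert rho.loc["a1", "b1"] == pytest.approx(1.0)
        assert np.allclose(np.diag(rho), 1.0)

    def test_explained_variance_fractions_sum_below_one(self, rng):
        m = matrix_from(rng.lognormal(3, 1, size=(30, 10)))
        _, evr, _ = ordination_and_correlation(m, n_components=4)
        assert evr.sum() <= 1.0 + 1e-12

    def test_spearman_equals_rank_then_pearson(self, rng):
        m = matrix_from(rng.lognormal(2, 1, size=(10, 10)))
        _, _, rho = ordination_and_correlation(m)
        from ecmet.normalization import zscore
        z = zscore(m, axis="features")
        ranks = z.rank(axis=0)
        oracle = np.corrcoef(ranks.to_numpy().T)
        assert np.allclose(rho.to_numpy(), oracle, atol=1e-12)


@settings(deadline=None, max_examples=30)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60))
def test_bh_is_monotone_and_bounded(p):
    adj = bh_adjust(np.array(p))
    assert ((adj >= np.array(p) - 1e-12) | np.isclose(adj, p)).all()
    assert (adj <= 1.0 + 1e-12).all()
    order = np.argsort(p)
    assert (np.diff(adj[order]) >= -1e-12).all()
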