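import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from rdpa import (
    ImputationParams,
    call_rdpa,
    filter_valid_values,
    impute_downshifted,
    permutation_fdr,
    s0_statistic,
)
from rdpa.discovery import _null_assignments
from rdpa.simulate import PulldownConfig, generate_pulldown_experiment

from conftest import make_matrix
from oracles import pooled_t_oracle


class TestFilterValidValues:
    def test_complete_group_retained(self):
        m = make_matrix(
            [[25, 25, 25, np.nan, np.nan, np.nan]], ["A"] * 3 + ["B"] * 3
        )
        assert filter_valid_values(m).protein_ids == ["P1"]

    def test_no_complete_group_removed(self):
        m = make_matrix(
            [[25, 25, np.nan, 20, 20, np.nan]], ["A"] * 3 + ["B"] * 3
        )
        with pytest.warns(UserWarning, match="no rows pass"):
            out = filter_valid_values(m)
        assert out.protein_ids == []

    def test_fully_observed_retained(self):
        m = make_matrix([[1, 2, 3, 4]], ["A", "A", "B", "B"])
        assert filter_valid_values(m).protein_ids == ["P1"]


class TestImputation:
    def test_no_missing_is_identity(self):
        m = make_matrix([[25.0, 26.0], [24.0, 23.0], [22.0, 21.0]], ["A", "B"])
        out = impute_downshifted(m, ImputationParams(seed=0))
        assert np.array_equal(out.data.to_numpy(), m.data.to_numpy())

    def test_same_seed_bit_identical(self, rng):
        v = rng.normal(25, 2, (50, 4))
        v[rng.random((50, 4)) < 0.3] = np.nan
        m = make_matrix(v, ["A", "A", "B", "B"])
        a = impute_downshifted(m, ImputationParams(seed=42))
        b = impute_downshifted(m, ImputationParams(seed=42))
        assert np.array_equal(a.data.to_numpy(), b.data.to_numpy())

    def test_observed_cells_untouched(self, rng):
        v = rng.normal(25, 2, (50, 4))
        mask = rng.random((50, 4)) < 0.3
        v[mask] = np.nan
        m = make_matrix(v, ["A", "A", "B", "B"])
        out = impute_downshifted(m, ImputationParams(seed=1)).data.to_numpy()
        assert np.array_equal(out[~mask], np.asarray(v)[~mask])

    def test_downshifted_moments(self):
        # observed column values engineered to mean 25, SD 2 exactly
        z = np.arange(100, dtype=float)
        obs = 25 + 2 * (z - z.mean()) / z.std(ddof=1)
        col = np.concatenate([obs, np.full(10_000, np.nan)])
        m = make_matrix(col[:, None], ["A"])
        out = impute_downshifted(m, ImputationParams(seed=7)).data.to_numpy()[:, 0]
        imputed = out[100:]
        assert abs(imputed.mean() - (25 - 1.8 * 2)) < 0.05
        assert abs(imputed.std(ddof=1) - 0.3 * 2) < 0.05

    def test_imputed_distribution_matches_target_normal(self):
        # Kolmogorov-Smirnov against the analytic target in >= 9/10 seeds
        z = np.arange(200, dtype=float)
        obs = 25 + 2 * (z - z.mean()) / z.std(ddof=1)
        col = np.concatenate([obs, np.full(10_000, np.nan)])
        m = make_matrix(col[:, None], ["A"])
        passed = 0
        for seed in range(10):
            out = impute_downshifted(m, ImputationParams(seed=seed))
            imputed = out.data.to_numpy()[200:, 0]
            p = stats.kstest(imputed, "norm", args=(25 - 3.6, 0.6)).pvalue
            passed += p > 0.01
        assert passed >= 9

    def test_too_few_observed_values(self):
        m = make_matrix([[25.0], [np.nan], [np.nan]], ["A"])
        with pytest.raises(ValueError, match="S1"):
            impute_downshifted(m, ImputationParams(seed=0))


class TestS0Statistic:
    def test_identical_groups_zero(self):
        assert s0_statistic([1, 2, 3], [1, 2, 3], s0=0.2) == 0.0

    def test_zero_variance_groups(self):
        assert s0_statistic([2, 2, 2], [1, 1, 1], s0=0.2) == pytest.approx(5.0)

    def test_s0_zero_equals_classical_t(self, rng):
        for _ in range(50):
            a = rng.normal(0, 1, rng.integers(2, 8))
            b = rng.normal(0.5, 2, rng.integers(2, 8))
            d = s0_statistic(a, b, s0=0.0)
            assert d == pytest.approx(pooled_t_oracle(a, b), abs=1e-12)
            t_scipy = stats.ttest_ind(a, b, equal_var=True).statistic
            assert d == pytest.approx(t_scipy, abs=1e-10)

    def test_group_too_small(self):
        with pytest.raises(ValueError):
            s0_statistic([1.0], [1.0, 2.0], s0=0.2)

    @given(
        a=st.lists(st.floats(-50, 50), min_size=2, max_size=6),
        b=st.lists(st.floats(-50, 50), min_size=2, max_size=6),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_antisymmetry_under_group_swap(self, a, b):
        assert s0_statistic(a, b, 0.2) == pytest.approx(
            -s0_statistic(b, a, 0.2), abs=1e-9
        )

    @given(
        a=st.lists(st.floats(-50, 50), min_size=2, max_size=6),
        b=st.lists(st.floats(-50, 50), min_size=2, max_size=6),
        s0_pair=st.tuples(st.floats(1e-3, 2), st.floats(1e-3, 2)),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_monotone_shrinkage_in_s0(self, a, b, s0_pair):
        lo, hi = sorted(s0_pair)
        assert abs(s0_statistic(a, b, hi)) <= abs(s0_statistic(a, b, lo)) + 1e-12


class TestPermutationFdr:
    def test_exact_enumeration_when_n_perm_large(self):
        # 3v3 one-sided: 19 distinct non-identity relabelings; asking for
        # more must fall back to exact enumeration
        assert len(_null_assignments(3, 3, 10_000, False, np.random.default_rng(0))) == 19
        assert len(_null_assignments(3, 3, 10_000, True, np.random.default_rng(0))) == 9

    def test_n_perm_too_small(self, rng):
        m = make_matrix(rng.normal(25, 1, (20, 6)), ["A"] * 3 + ["B"] * 3)
        with pytest.raises(ValueError, match="n_perm"):
            permutation_fdr(m, "A", "B", n_perm=5)

    def test_missing_values_rejected(self):
        m = make_matrix([[1, np.nan, 3, 4, 5, 6]], ["A"] * 3 + ["B"] * 3)
        with pytest.raises(ValueError, match="missing"):
            permutation_fdr(m, "A", "B")

    def test_identical_group_labels_rejected(self, rng):
        m = make_matrix(rng.normal(25, 1, (20, 6)), ["A"] * 6)
        with pytest.raises(ValueError):
            permutation_fdr(m, "A", "A")

    def test_planted_shift_detected(self, rng):
        X = rng.normal(25, 0.3, (300, 6))
        X[:30, :3] += 2.0  # 10% of rows shifted up in group A
        m = make_matrix(X, ["A"] * 3 + ["B"] * 3)
        res = permutation_fdr(m, "A", "B", alternative="one_sided", seed=0)
        shifted = res.iloc[:30]
        assert shifted.significant.mean() >= 0.95
        assert res.q_value.between(0, 1).all()

    def test_null_matrix_mostly_non_significant(self):
        n_sig = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            m = make_matrix(rng.normal(25, 1, (200, 6)), ["A"] * 3 + ["B"] * 3)
            res = permutation_fdr(m, "A", "B", alternative="one_sided", seed=seed)
            n_sig += res.significant.sum()
        assert n_sig <= 0.02 * 5 * 200


class TestCallRdpa:
    def test_two_step_logic_and_invariants(self):
        m, truth = generate_pulldown_experiment(PulldownConfig(n_proteins=400,
                                                n_pip2=60, n_dsrna_plus=40,
                                                n_dsrna_minus=5), seed=0)
        call = call_rdpa(m, m, seed=0)
        assert call.dsrna_plus <= call.pip2_associated
        assert call.dsrna_minus <= call.pip2_associated
        assert not call.dsrna_plus & call.dsrna_minus
        # direction: dsRNA+ proteins are lower after RNase III
        for pid in call.dsrna_plus:
            assert call.step2.loc[pid, "mean_diff"] > 0

    def test_step1_significant_but_rnase_inert_protein(self):
        # planted PIP2-associated proteins with no RNase effect end up in
        # pip2_associated but in neither dsRNA set
        cfg = PulldownConfig(n_proteins=300, n_pip2=40, n_dsrna_plus=0,
                             n_dsrna_minus=0, mcar_rate=0.0)
        m, truth = generate_pulldown_experiment(cfg, seed=1)
        call = call_rdpa(m, m, seed=1)
        found = call.pip2_associated & truth.pip2_associated
        assert len(found) >= 30
        assert not call.dsrna_plus and not call.dsrna_minus

    def test_step2_restricted_to_step1(self):
        m, truth = generate_pulldown_experiment(
            PulldownConfig(n_proteins=300, n_pip2=40, n_dsrna_plus=20,
                           n_dsrna_minus=5), seed=2)
        call = call_rdpa(m, m, seed=2)
        assert set(call.step2.index) <= call.pip2_associated
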