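import numpy as np
import pandas as pd
import pytest
from scipy.stats import ttest_ind_from_stats

from diogene.edi import EdiUndefinedError
from diogene.optimizer import (
    MseEdiProfile,
    build_profiles,
    interpolate_null,
    optimize_gene,
    select_alpha_min_mse,
    select_alpha_opt,
    student_statistic,
)
from diogene.prior_weights import default_grid


def make_profile(target, kind, alphas, mu_mse, sigma_mse, mu_edi, n=10):
    table = pd.DataFrame(
        {
            "mu_mse": mu_mse,
            "sigma_mse": sigma_mse,
            "mu_edi": mu_edi,
            "n_reps": n,
        },
        index=pd.Index(alphas, name="alpha"),
    )
    return MseEdiProfile(target, kind, table)


class TestStudentStatistic:
    def test_worked_example(self):
        t = student_statistic(0.8, 0.1, 1.0, 0.1, 50)
        assert t == pytest.approx(-10.0)

    def test_equal_means_give_zero(self):
        assert student_statistic(0.5, 0.2, 0.5, 0.1, 10) == 0.0

    def test_doubling_n_scales_by_sqrt2(self):
        t1 = student_statistic(0.7, 0.15, 1.0, 0.2, 25)
        t2 = student_statistic(0.7, 0.15, 1.0, 0.2, 50)
        assert t2 == pytest.approx(np.sqrt(2) * t1)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            student_statistic(0.5, 0.0, 0.6, 0.0, 10)

    def test_matches_two_sample_t_oracle(self):
        """Equal-N pooled two-sample t from scipy agrees with the formula."""
        rng = np.random.default_rng(0)
        for _ in range(1000):
            mu, mu0 = rng.normal(1, 0.3, 2)
            s, s0 = rng.uniform(0.05, 0.5, 2)
            n = int(rng.integers(2, 200))
            ours = student_statistic(mu, s, mu0, s0, n)
            ref = ttest_ind_from_stats(mu, s, n, mu0, s0, n, equal_var=True)
            assert ours == pytest.approx(ref.statistic, rel=1e-9)


class TestInterpolateNull:
    def test_query_at_knot_returns_knot(self):
        prof = make_profile(
            "t", "null", [0.0, 0.5, 1.0], [1.0, 1.5, 2.0], [0.1, 0.2, 0.3], [1.0, 2.0, 3.0]
        )
        assert interpolate_null(prof, 2.0) == (1.5, 0.2)

    def test_linear_midpoint(self):
        prof = make_profile("t", "null", [0.0, 1.0], [1.0, 2.0], [0.1, 0.3], [1.0, 3.0])
        mu0, s0 = interpolate_null(prof, 2.0)
        assert mu0 == pytest.approx(1.5)
        assert s0 == pytest.approx(0.2)

    def test_clamped_outside_range(self):
        prof = make_profile("t", "null", [0.0, 1.0], [1.0, 2.0], [0.1, 0.3], [2.0, 4.0])
        assert interpolate_null(prof, 0.5) == (1.0, 0.1)
        assert interpolate_null(prof, 9.0) == (2.0, 0.3)

    def test_degenerate_null_warns_and_returns_point(self):
        prof = make_profile("t", "null", [0.0, 1.0], [1.0, 1.2], [0.1, 0.2], [2.0, 2.0])
        with pytest.warns(UserWarning, match="degenerate"):
            mu0, s0 = interpolate_null(prof, 3.0)
        assert mu0 == pytest.approx(1.1)


class TestAlphaSelection:
    alphas = [0.0, 0.5, 1.0]

    def _profiles(self, mu_true):
        true = make_profile("g", "true", self.alphas, mu_true, [0.1] * 3, [2.0, 3.0, 4.0])
        null = make_profile(
            "g", "null", self.alphas, [1.0, 1.1, 1.2], [0.1] * 3, [2.0, 3.0, 4.0]
        )
        return true, null

    def test_significant_improvement_selects_best_alpha(self):
        true, null = self._profiles([1.0, 0.6, 0.9])
        opt = select_alpha_opt(true, null)
        assert opt.alpha_opt == 0.5
        assert opt.reason == "optimized"

    def test_no_significance_sets_zero(self):
        true, null = self._profiles([1.0, 1.1, 1.2])  # identical to null
        opt = select_alpha_opt(true, null)
        assert opt.alpha_opt == 0.0
        assert opt.reason == "not_significant"
        assert (opt.table["p_adj"] > 0.05).all()

    def test_one_sided_ignores_deterioration(self):
        # much WORSE than null everywhere: lower-tail test must not fire
        true, null = self._profiles([2.0, 2.1, 2.2])
        opt = select_alpha_opt(true, null)
        assert opt.alpha_opt == 0.0
        two = select_alpha_opt(true, null, two_sided=True)
        assert two.reason == "optimized"  # flag flips the behavior

    def test_min_mse_baseline_with_tie_toward_smaller_alpha(self):
        prof = make_profile(
            "g", "true", [0.0, 0.3, 0.4, 1.0], [0.9, 0.5, 0.5, 0.8], [0.1] * 4, [2] * 4
        )
        assert select_alpha_min_mse(prof) == 0.3

    def test_min_mse_monotone_profiles(self):
        up = make_profile("g", "true", self.alphas, [0.5, 0.7, 0.9], [0.1] * 3, [2] * 3)
        down = make_profile("g", "true", self.alphas, [0.9, 0.7, 0.5], [0.1] * 3, [2] * 3)
        assert select_alpha_min_mse(up) == 0.0
        assert select_alpha_min_mse(down) == 1.0

    def test_min_mse_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            k = int(rng.integers(2, 8))
            alphas = np.sort(rng.choice(np.round(np.linspace(0, 1, 11), 10), k, replace=False))
            alphas[0], alphas[-1] = 0.0, 1.0
            alphas = np.unique(alphas)
            mu = rng.choice([0.4, 0.5, 0.6, 0.7], len(alphas))  # force ties
            prof = make_profile("g", "true", alphas, mu, [0.1] * len(alphas), [2] * len(alphas))
            expected = min(zip(mu, alphas))[1]  # smallest mse, then smallest alpha
            assert select_alpha_min_mse(prof) == expected


class TestGenePipeline:
    def test_profiles_bookkeeping(self, tiny_system):
        grid = default_grid(1.0)  # alphas {0, 1}
        true, null = build_profiles(
            "T001", "weightedLASSO", tiny_system.data, tiny_system.prior,
            grid=grid, N=2, seed=5,
        )
        for prof in (true, null):
            assert list(prof.table.index) == [0.0, 1.0]
            assert (prof.table["n_reps"] == 2).all()
        assert set(true.importances) == {0.0, 1.0}

    def test_no_motif_gene_short_circuits(self, tiny_system):
        import pandas as pd

        from diogene.data_model import PriorMatrix

        zero_prior = PriorMatrix(
            pi=pd.DataFrame(
                0.0,
                index=tiny_system.prior.pi.index,
                columns=tiny_system.prior.pi.columns,
            )
        )
        opt, true, null = optimize_gene(
            "T001", "weightedLASSO", tiny_system.data, zero_prior, N=2, seed=1
        )
        assert opt.reason == "no_motif"
        assert opt.alpha_opt == 0.0
        assert null is None
        assert list(true.table.index) == [0.0]
        with pytest.raises(EdiUndefinedError):
            build_profiles(
                "T001", "weightedLASSO", tiny_system.data, zero_prior, N=2, seed=1
            )
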