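"""Detection-conditional binomial model: PMF, fitting, model selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oligotrace.steps import StepCountTable
from oligotrace.stoichiometry import (
    BinomialModel,
    conditional_binomial_pmf,
    fit_mixture,
    fit_p,
    goodness_of_fit,
    select_model,
)
from tests.conftest import enumeration_pmf, grid_search_p


class TestConditionalPmf:
    def test_visible_monomer_always_shows_one_step(self):
        assert conditional_binomial_pmf(1, 0.3, 1) == pytest.approx(1.0)

    def test_dimer_half_p_values(self):
        assert conditional_binomial_pmf(2, 0.5, 1) == pytest.approx(2 / 3)
        assert conditional_binomial_pmf(2, 0.5, 2) == pytest.approx(1 / 3)

    def test_tetramer_at_typical_maturation(self):
        # frozen from the 2^4 enumeration oracle at p = 0.67
        assert conditional_binomial_pmf(4, 0.67, 4) == pytest.approx(0.20393, abs=5e-6)
        pmf = conditional_binomial_pmf(4, 0.67, np.arange(1, 5))
        assert np.argmax(pmf) == 2  # mode at k = 3
        assert pmf[2] == pytest.approx(0.40177, abs=5e-6)

    @pytest.mark.parametrize("n", range(1, 7))
    def test_matches_exhaustive_enumeration(self, n):
        for p in np.linspace(0.05, 0.95, 19):
            for k in range(1, n + 1):
                assert abs(conditional_binomial_pmf(n, p, k) - enumeration_pmf(n, p, k)) < 1e-12

    @given(n=st.integers(1, 6), p=st.floats(0.01, 1.0))
    @settings(deadline=None, max_examples=60)
    def test_normalizes_over_visible_counts(self, n, p):
        total = sum(conditional_binomial_pmf(n, p, k) for k in range(1, n + 1))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            conditional_binomial_pmf(2, 0.5, 3)
        with pytest.raises(ValueError):
            conditional_binomial_pmf(2, 0.0, 1)


class TestFitP:
    def test_recovers_p_from_exact_tetramer_table(self):
        pmf = conditional_binomial_pmf(4, 0.67, np.arange(1, 5))
        table = StepCountTable.from_counts(
            {k: int(round(10_000 * pmf[k - 1])) for k in range(1, 5)}
        )
        fit = fit_p(table, 4)
        assert fit.model.p == pytest.approx(0.67, abs=1e-3)
        assert fit.p_ci[0] < 0.67 < fit.p_ci[1]
        # independent dense grid-search oracle agrees
        assert abs(fit.model.p - grid_search_p(table, 4)) < 1e-3

    def test_dimer_table_inverts_to_half(self):
        fit = fit_p(StepCountTable.from_counts({1: 667, 2: 333}), 2)
        assert fit.model.p == pytest.approx(0.5, abs=1e-3)

    def test_monomer_likelihood_is_flat_in_p(self):
        fit = fit_p(StepCountTable.from_counts({1: 500}), 1)
        assert fit.flat_likelihood
        assert fit.model.p == 1.0
        assert fit.log_likelihood == 0.0

    def test_impossible_counts_flagged_not_fatal(self):
        fit = fit_p(StepCountTable.from_counts({1: 100, 2: 50}), 1, warn=False)
        assert fit.lack_of_fit

    def test_matches_grid_oracle_on_random_tables(self):
        rng = np.random.default_rng(2024)
        for _ in range(20):
            n = int(rng.integers(2, 5))
            p_true = float(rng.uniform(0.2, 0.95))
            pmf = conditional_binomial_pmf(n, p_true, np.arange(1, n + 1))
            counts = rng.multinomial(400, pmf)
            table = StepCountTable.from_counts(
                {k + 1: int(c) for k, c in enumerate(counts) if c}
            )
            fit = fit_p(table, n)
            assert abs(fit.model.p - grid_search_p(table, n)) < 1e-3


class TestSelectModel:
    def test_pure_one_step_table_selects_monomer_by_parsimony(self):
        sel = select_model(StepCountTable.from_counts({1: 5000}))
        assert sel.selected_n == 1

    def test_near_equal_split_selects_dimer(self):
        sel = select_model(StepCountTable.from_counts({1: 248, 2: 252}))
        assert sel.selected_n == 2

    def test_tetramer_table_selects_four(self):
        pmf = conditional_binomial_pmf(4, 0.67, np.arange(1, 5))
        table = StepCountTable.from_counts({k: int(round(1000 * pmf[k - 1])) for k in range(1, 5)})
        sel = select_model(table)
        assert sel.selected_n == 4
        assert sel.selection_margin > 0


class TestMixture:
    def test_pure_dimer_table_gets_full_dimer_weight(self):
        fit = fit_mixture(StepCountTable.from_counts({1: 496, 2: 504}), p_fixed=0.67)
        weights = dict(fit.components)
        assert weights[2] == pytest.approx(1.0, abs=1e-3)

    def test_pure_monomer_table_gets_full_monomer_weight(self):
        fit = fit_mixture(StepCountTable.from_counts({1: 1000}), p_fixed=0.67)
        weights = dict(fit.components)
        assert weights[1] == pytest.approx(1.0, abs=1e-3)
        assert fit.boundary

    def test_weights_sum_to_one(self):
        fit = fit_mixture(StepCountTable.from_counts({1: 300, 2: 200}))
        assert sum(w for _, w in fit.components) == pytest.approx(1.0, abs=1e-9)


class TestGoodnessOfFit:
    def test_exact_table_gives_zero_statistic(self):
        model = BinomialModel(n=2, p=0.5)
        table = StepCountTable.from_counts({1: 400, 2: 200})  # exactly 2:1
        stat, df, pval = goodness_of_fit(table, model)
        assert stat == pytest.approx(0.0, abs=1e-20)

    def test_near_dimer_table_statistic_frozen_value(self):
        # oracle: expected counts 500 x (0.496241, 0.503759) from enumeration
        stat, df, _ = goodness_of_fit(
            StepCountTable.from_counts({1: 248, 2: 252}), BinomialModel(n=2, p=0.67)
        )
        assert stat == pytest.approx(1.1578e-4, rel=1e-3)
        assert df == 1

    def test_impossible_cells_pooled_with_warning(self, caplog):
        import logging

        # a 2-step count is impossible under a monomer: pooled with a warning,
        # after which a single cell remains and the defined error is raised
        with caplog.at_level(logging.WARNING, logger="oligotrace.stoichiometry"):
            with pytest.raises(ValueError, match="usable cells"):
                goodness_of_fit(
                    StepCountTable.from_counts({1: 90, 2: 10}), BinomialModel(n=1, p=1.0)
                )
        assert "pooled" in caplog.text
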