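"""Logistic association testing: eligibility, fits, Wald tests and FDR."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from funkfams.association import (
    bh_fdr,
    fit_logistic,
    phenotype_eligible,
    run_association,
    wald_tests,
)
from funkfams.synthetic_data import simulate_presence


class TestEligibility:
    def test_two_levels_of_five_eligible(self):
        values = ["A"] * 5 + ["B"] * 5
        assert phenotype_eligible(values).eligible

    def test_four_observations_is_not_more_than_four(self):
        values = ["A"] * 5 + ["B"] * 4
        assert not phenotype_eligible(values).eligible

    def test_single_level_ineligible(self):
        assert not phenotype_eligible(["A"] * 10).eligible

    def test_missing_values_dropped_first(self):
        values = ["A"] * 5 + ["B"] * 5 + [None] * 3
        elig = phenotype_eligible(values)
        assert elig.eligible and None not in elig.level_counts

    def test_continuous_covariate_uses_total_observation_budget(self):
        rng = np.random.default_rng(0)
        assert phenotype_eligible(rng.normal(size=10)).eligible
        assert not phenotype_eligible(rng.normal(size=9)).eligible
        assert not phenotype_eligible([1.5] * 20).eligible  # constant


def design_with_x(x: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(x), x])


class TestFitLogistic:
    def test_two_by_two_table_recovers_log_odds_ratio(self):
        # cells (a, b, c, d) = (10, 5, 5, 10): saturated model slope = ln(ad/bc)
        y = np.array([1] * 10 + [0] * 5 + [1] * 5 + [0] * 10)
        x = np.array([1] * 15 + [0] * 15, dtype=float)
        fit = fit_logistic(y, design_with_x(x), ["intercept", "x"])
        assert fit.converged and not fit.separation_flag
        assert fit.coefficients["x"] == pytest.approx(math.log(4), abs=1e-4)

    def test_matches_grid_search_mle(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=60)
        y = (rng.random(60) < 1 / (1 + np.exp(-(0.3 + 0.8 * x)))).astype(float)
        fit = fit_logistic(y, design_with_x(x), ["intercept", "x"])

        def nll(b0, b1):
            eta = b0 + b1 * x
            return float(np.sum(np.log1p(np.exp(eta)) - y * eta))

        grid = np.arange(-3, 3, 0.001)
        b0_hat = fit.coefficients["intercept"]
        best_b1 = min(grid, key=lambda b1: nll(b0_hat, b1))
        best_b0 = min(grid, key=lambda b0: nll(b0, fit.coefficients["x"]))
        assert fit.coefficients["x"] == pytest.approx(best_b1, abs=1e-3)
        assert fit.coefficients["intercept"] == pytest.approx(best_b0, abs=1e-3)

    def test_symmetric_balanced_data_gives_zero_coefficient(self):
        # identical outcome mix in both covariate groups: slope must be 0
        y = np.array([1, 0, 1, 0, 1, 0, 1, 0], dtype=float)
        x = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=float)
        fit = fit_logistic(y, design_with_x(x), ["intercept", "x"])
        assert fit.coefficients["x"] == pytest.approx(0.0, abs=1e-8)

    def test_single_class_response_rejected(self):
        y = np.ones(10)
        x = np.arange(10, dtype=float)
        with pytest.raises(ValueError, match="single-class"):
            fit_logistic(y, design_with_x(x), ["intercept", "x"])

    def test_rank_deficient_design_names_collinear_term(self):
        y = np.array([0, 1] * 10, dtype=float)
        x = np.arange(20, dtype=float)
        design = np.column_stack([np.ones(20), x, 2 * x])
        with pytest.raises(ValueError, match=r"collinear.*x"):
            fit_logistic(y, design, ["intercept", "x", "x_copy"])

    def test_perfect_separation_flagged(self):
        x = np.array([-2, -1.5, -1, -0.5, 0.5, 1, 1.5, 2], dtype=float)
        y = (x > 0).astype(float)
        fit = fit_logistic(y, design_with_x(x), ["intercept", "x"])
        assert fit.separation_flag


class TestWaldTests:
    def _fit(self, coef, se, n_obs=12, n_terms=2):
        from funkfams.association import LogisticFit

        names = [f"b{i}" for i in range(n_terms)]
        return LogisticFit(
            coefficients={names[0]: coef, **{n: 0.5 for n in names[1:]}},
            std_errors={n: se for n in names},
            converged=True,
            separation_flag=False,
            n_obs=n_obs,
        )

    def test_zero_coefficient_gives_p_one(self):
        tests = wald_tests(self._fit(0.0, 1.0))
        t, p = tests["b0"]
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_t_two_with_ten_df(self):
        tests = wald_tests(self._fit(2.0, 1.0, n_obs=12, n_terms=2))
        t, p = tests["b0"]
        assert t == pytest.approx(2.0)
        assert p == pytest.approx(2 * stats.t.sf(2.0, 10), abs=1e-10)
        assert p == pytest.approx(0.0734, abs=5e-4)

    def test_sign_flip_preserves_p(self):
        p_pos = wald_tests(self._fit(2.0, 1.0))["b0"][1]
        p_neg = wald_tests(self._fit(-2.0, 1.0))["b0"][1]
        assert p_pos == pytest.approx(p_neg)

    def test_zero_standard_error_rejected(self):
        with pytest.raises(ValueError):
            wald_tests(self._fit(1.0, 0.0))


def step_up_reference(p: np.ndarray) -> np.ndarray:
    """Textbook BH step-up, written independently of the implementation."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running = min(running, m * p[idx] / rank_from_top)
        q[idx] = min(running, 1.0)
    return q


class TestBhFdr:
    def test_hand_computed_vector(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_passes_through(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_all_ones_stay_one(self):
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=200, deadline=None)
    def test_agrees_with_step_up_reference(self, ps):
        p = np.array(ps)
        assert np.allclose(bh_fdr(p), step_up_reference(p), atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_q_at_least_p_and_monotone_when_sorted(self, ps):
        p = np.sort(np.array(ps))
        q = bh_fdr(p)
        assert (q >= p - 1e-12).all()
        assert (np.diff(q) >= -1e-12).all()


def make_samples(n_per_env=50, envs=("ENV_A", "ENV_B"), rng=None):
    rng = rng or np.random.default_rng(0)
    rows = []
    for env in envs:
        for i in range(n_per_env):
            rows.append(
                {
                    "sample_id": f"{env}_{i:03d}",
                    "environment": env,
                    "pheno_cat": "X1" if i % 2 else "X0",
                    "pheno_num": float(rng.normal()),
                }
            )
    return pd.DataFrame(rows).set_index("sample_id")


class TestRunAssociation:
    def test_planted_effect_is_unique_discovery(self):
        rng = np.random.default_rng(7)
        samples = make_samples(n_per_env=60, rng=rng)
        fam_ids = [f"f{i}" for i in range(12)]
        presence = simulate_presence(
            fam_ids, samples, [("f0", "pheno_cat", "ENV_A", 3.0)], -1.0, rng
        )
        results = run_association(
            presence, samples, covariates=["pheno_cat"], stratum_var="environment"
        )
        hits = [
            (r.family_id, r.stratum)
            for r in results
            if r.status == "OK" and r.q_value < 0.05
        ]
        assert hits == [("f0", "ENV_A")]
        planted = [r for r in results if r.family_id == "f0" and r.stratum == "ENV_A"][0]
        assert planted.coefficient > 0

    def test_ineligible_covariate_skips_every_family(self):
        samples = make_samples(n_per_env=20)
        samples["lopsided"] = ["L0"] * 39 + ["L1"]  # second level has one obs
        presence = pd.DataFrame(
            np.random.default_rng(0).random((4, 40)) < 0.5,
            index=[f"f{i}" for i in range(4)],
            columns=samples.index,
        )
        results = run_association(
            presence, samples, covariates=["lopsided"], stratum_var="environment"
        )
        assert results and all(r.status == "SKIPPED_INELIGIBLE" for r in results)

    def test_constant_presence_family_skipped(self):
        samples = make_samples(n_per_env=20)
        presence = pd.DataFrame(
            True, index=["f_const"], columns=samples.index
        )
        results = run_association(
            presence, samples, covariates=["pheno_cat"], stratum_var="environment"
        )
        assert all(r.status == "SKIPPED_INELIGIBLE" for r in results)

    def test_unknown_variable_rejected(self):
        samples = make_samples(n_per_env=10)
        presence = pd.DataFrame(True, index=["f"], columns=samples.index)
        with pytest.raises(Exception, match="no_such"):
            run_association(presence, samples, covariates=["no_such"])

    def test_global_pooling_changes_only_q(self):
        rng = np.random.default_rng(3)
        samples = make_samples(n_per_env=40, rng=rng)
        fam_ids = [f"f{i}" for i in range(6)]
        presence = simulate_presence(fam_ids, samples, [], 0.0, rng)
        per = run_association(presence, samples, ["pheno_cat"], fdr_pool="per_stratum_covariate")
        glob = run_association(presence, samples, ["pheno_cat"], fdr_pool="global")
        per_ok = [(r.family_id, r.stratum, r.p_value) for r in per if r.status == "OK"]
        glob_ok = [(r.family_id, r.stratum, r.p_value) for r in glob if r.status == "OK"]
        assert per_ok == glob_ok
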