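"""Covariate correction, regimen pooling and Monte Carlo survival tables."""

import math

import numpy as np
import pytest

from survmeta.hazards import (
    CovariateModel,
    CovariateTerm,
    HazardModelSpec,
    apply_covariates,
)
from survmeta.nlme import PopulationParams
from survmeta.propmeta import dersimonian_laird
from survmeta.subgroups import (
    CorrectedArm,
    covariate_correct,
    pool_all_regimens,
    pool_regimen,
    regimen_table,
    simulate_typical_os,
    subgroup_table,
)

PUBLISHED = PopulationParams(
    spec=HazardModelSpec("constant", 0.098),
    cov_model=CovariateModel(
        (CovariateTerm("age", 0.017, 72.5), CovariateTerm("ps2_pct", 0.004, 14.0))
    ),
)


class TestCovariateCorrect:
    def test_round_trip_restores_individual_beta(
        self, paper_scale_fit, paper_scale_dataset
    ):
        """corrected beta times the covariate multiplier equals the arm's
        individual beta at machine precision."""
        dataset, _ = paper_scale_dataset
        fit = paper_scale_fit
        corrected = covariate_correct(fit, dataset)
        p = fit.params
        for arm in dataset.arms:
            individual = apply_covariates(
                p.spec.beta0, p.cov_model, arm.covariates(),
                fit.eta_hat[arm.arm_id],
            )
            multiplier = p.cov_model.multiplier(arm.covariates())
            assert corrected[arm.arm_id].beta * multiplier == pytest.approx(
                individual, rel=1e-12
            )

    def test_reference_arm_is_unchanged(self, paper_scale_fit,
                                        paper_scale_dataset):
        dataset, _ = paper_scale_dataset
        fit = paper_scale_fit
        corrected = covariate_correct(fit, dataset)
        # geometric mean of corrections equals beta_typical when mean eta = 0
        etas = np.array([fit.eta_hat[a] for a in dataset.arm_ids])
        log_betas = np.array([corrected[a].log_beta for a in dataset.arm_ids])
        assert np.mean(log_betas) == pytest.approx(
            math.log(fit.params.spec.beta0) + np.mean(etas), abs=1e-12
        )


class TestPooling:
    def test_identical_arms_pool_to_their_value(self):
        arms = [CorrectedArm(f"A{i}", "GV", 0.1, math.log(0.1), 0.05)
                for i in range(3)]
        pooled = pool_regimen(arms)
        assert pooled.beta == pytest.approx(0.1)
        assert pooled.tau2 == 0.0

    def test_matches_hand_computed_dersimonian_laird(self):
        """3-arm toy reproduced against the textbook DL arithmetic."""
        y = np.array([-2.3, -2.2, -2.4])
        v = np.full(3, 0.05**2)
        w = 1.0 / v
        ybar = np.sum(w * y) / np.sum(w)
        Q = float(np.sum(w * (y - ybar) ** 2))
        c = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (Q - 2.0) / c)
        wstar = 1.0 / (v + tau2)
        mu = float(np.sum(wstar * y) / np.sum(wstar))
        se = 1.0 / math.sqrt(np.sum(wstar))
        got = dersimonian_laird(y, v)
        assert got[0] == pytest.approx(mu, abs=1e-10)
        assert got[1] == pytest.approx(se, abs=1e-10)
        assert got[2] == pytest.approx(tau2, abs=1e-10)
        arms = [CorrectedArm(f"A{i}", "G", math.exp(yi), yi, 0.05)
                for i, yi in enumerate(y)]
        pooled = pool_regimen(arms)
        assert pooled.log_beta == pytest.approx(mu, abs=1e-10)

    def test_regimens_overlap_under_common_truth(self, paper_scale_fit,
                                                 paper_scale_dataset):
        """All regimens share one generating beta: pooled CIs overlap."""
        dataset, _ = paper_scale_dataset
        pooled = pool_all_regimens(paper_scale_fit, dataset)
        assert set(pooled) == {"GV", "GD", "G"}
        los = [p.ci_log[0] for p in pooled.values()]
        his = [p.ci_log[1] for p in pooled.values()]
        assert max(los) < min(his)  # a common value is inside every interval


class TestSimulateTypicalOS:
    def test_zero_uncertainty_matches_analytic_curve(self):
        """Point parameters: MST is ln2/h and survival is exp(-h t) exactly."""
        summary = simulate_typical_os(
            PUBLISHED, {"age": 80.0, "ps2_pct": 14.0}, n_draws=100, seed=0
        )
        h = 0.098 * math.exp((80 - 72.5) * 0.017)
        assert summary.mst == pytest.approx(math.log(2) / h, rel=1e-12)
        assert summary.surv_pct[24.0] == pytest.approx(
            100 * math.exp(-24 * h), rel=1e-12
        )
        assert summary.mst_ci is None

    def test_age80_row_matches_published_table(self):
        summary = simulate_typical_os(PUBLISHED, {"age": 80.0, "ps2_pct": 14.0})
        assert round(summary.mst, 1) == 6.2
        assert round(summary.surv_pct[24.0], 1) == 6.9

    def test_intervals_widen_with_parameter_variance(self, paper_scale_fit):
        widths = []
        for scale in (0.25, 1.0, 4.0):
            fit = paper_scale_fit
            scaled = type(fit)(**{**fit.__dict__,
                                  "covariance": fit.covariance * scale})
            s = simulate_typical_os(scaled, {"age": 72.5, "ps2_pct": 14.0},
                                    n_draws=4000, seed=5)
            widths.append(s.mst_ci[1] - s.mst_ci[0])
        assert widths[0] < widths[1] < widths[2]

    def test_deterministic_given_seed(self, paper_scale_fit):
        a = simulate_typical_os(paper_scale_fit, n_draws=500, seed=9)
        b = simulate_typical_os(paper_scale_fit, n_draws=500, seed=9)
        assert a == b


class TestTables:
    def test_subgroup_table_monotone_in_age_and_ps(self):
        table = subgroup_table(PUBLISHED, n_draws=10)
        table = table.set_index("label")
        assert (table.loc["age 60", "mst_months"]
                > table.loc["age 70", "mst_months"]
                > table.loc["age 80", "mst_months"])
        assert (table.loc["PS 0-1", "mst_months"]
                > table.loc["PS 2", "mst_months"])

    def test_ps_gap_close_to_published_difference(self):
        """PS0-1 vs PS2 at point estimates: roughly 2.5 months apart."""
        table = subgroup_table(PUBLISHED, n_draws=10).set_index("label")
        gap = table.loc["PS 0-1", "mst_months"] - table.loc["PS 2", "mst_months"]
        assert gap == pytest.approx(2.5, abs=0.3)

    def test_regimen_table_shape(self, paper_scale_fit, paper_scale_dataset):
        dataset, _ = paper_scale_dataset
        table = regimen_table(paper_scale_fit, dataset, n_draws=500, seed=3)
        assert set(table["label"]) == {"GV", "GD", "G"}
        assert {"mst_months", "mst_lo", "mst_hi"} <= set(table.columns)
        assert (table["mst_lo"] <= table["mst_months"]).all()
        assert (table["mst_months"] <= table["mst_hi"]).all()
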