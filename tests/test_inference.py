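import numpy as np
import pytest
from scipy import stats

from narrecall.inference import (
    CATEGORICAL_LEVELS,
    CoefEstimate,
    DegenerateOutcomeError,
    ModelFit,
    ModelSpec,
    build_design,
    clopper_pearson,
    fit_glmm,
    pearson_cor,
    power_simulation,
    simple_slopes,
    type3_wald,
)
from narrecall.synthetic import SyntheticConfig, simulate_table

RECALL_SPEC = ModelSpec(
    family="binomial",
    response="recalled",
    fixed_terms=("group", "centrality_z", "group:centrality_z"),
)


def _make_fit(names, estimates, cov, terms):
    params = {}
    for i, n in enumerate(names):
        se = float(np.sqrt(cov[i, i]))
        params[n] = CoefEstimate(
            estimate=estimates[i], se=se, z=estimates[i] / se,
            p=float(2 * stats.norm.sf(abs(estimates[i] / se))),
            ci_low=estimates[i] - 1.96 * se, ci_high=estimates[i] + 1.96 * se,
        )
    return ModelFit(
        spec=RECALL_SPEC, names=tuple(names), params=params, cov=np.asarray(cov),
        terms=terms, sigmas={}, scale=None, loglik=0.0, converged=True, n_obs=100,
    )


class TestDesign:
    def test_treatment_coding_and_reference_levels(self, tiny_cfg):
        df = simulate_table(tiny_cfg)
        X, names, terms = build_design(df, ("group", "session", "centrality_z"))
        assert names[0] == "(Intercept)"
        assert "group[older]" in names
        assert "session[day2]" in names and "session[day8]" in names
        assert "group[young]" not in names  # reference absorbed
        assert terms["session"] == tuple(
            names.index(n) for n in ("session[day2]", "session[day8]")
        )

    def test_interaction_columns_are_products(self, tiny_cfg):
        df = simulate_table(tiny_cfg)
        X, names, terms = build_design(df, ("group", "centrality_z", "group:centrality_z"))
        i_g = names.index("group[older]")
        i_c = names.index("centrality_z")
        i_i = names.index("group[older]:centrality_z")
        np.testing.assert_allclose(X[:, i_i], X[:, i_g] * X[:, i_c])

    def test_unknown_term_rejected(self, tiny_cfg):
        df = simulate_table(tiny_cfg)
        with pytest.raises(ValueError, match="no_such"):
            build_design(df, ("no_such",))


class TestFitGlmm:
    def test_zero_variance_data_matches_glm_oracle(self):
        sm = pytest.importorskip("statsmodels.api")
        cfg = SyntheticConfig(
            seed=0, sigma_participant=0.0, sigma_video=0.0,
            n_per_group=20, n_videos=6, events_min=10, events_max=12,
        )
        df = simulate_table(cfg)
        sub = df[df["session"] == "day1"].reset_index(drop=True)
        fit = fit_glmm(sub, RECALL_SPEC)
        X, names, _ = build_design(sub, RECALL_SPEC.fixed_terms)
        glm = sm.GLM(sub["recalled"], X, family=sm.families.Binomial()).fit()
        mine = np.array([fit.params[n].estimate for n in names])
        assert np.abs(mine - glm.params.values).max() < 1e-3

    def test_poisson_zero_variance_matches_glm_oracle(self):
        sm = pytest.importorskip("statsmodels.api")
        cfg = SyntheticConfig(
            seed=1, sigma_participant=0.0, sigma_video=0.0,
            n_per_group=20, n_videos=6, events_min=10, events_max=12,
        )
        df = simulate_table(cfg)
        sub = df[(df["session"] == "day1") & (df["recalled"] == 1)].reset_index(drop=True)
        spec = ModelSpec(family="poisson", response="n_central",
                         fixed_terms=("group", "centrality_z"))
        fit = fit_glmm(sub, spec)
        X, names, _ = build_design(sub, spec.fixed_terms)
        glm = sm.GLM(sub["n_central"], X, family=sm.families.Poisson()).fit()
        mine = np.array([fit.params[n].estimate for n in names])
        assert np.abs(mine - glm.params.values).max() < 1e-3

    def test_gaussian_family_recovers_group_difference(self, rng):
        import pandas as pd

        n_p, n_v = 20, 6
        pids = [f"p{i}" for i in range(n_p)]
        u = rng.normal(0, 0.4, n_p)
        w = rng.normal(0, 0.3, n_v)
        rows = []
        for i, pid in enumerate(pids):
            g = "older" if i % 2 else "young"
            for v in range(n_v):
                y = 3.0 + 0.5 * (g == "older") + u[i] + w[v] + rng.normal(0, 0.5)
                rows.append({"participant_id": pid, "group": g,
                             "video_id": f"v{v}", "vividness": y})
        df = pd.DataFrame(rows)
        spec = ModelSpec(family="gaussian", response="vividness", fixed_terms=("group",))
        fit = fit_glmm(df, spec)
        assert fit.params["group[older]"].estimate == pytest.approx(0.5, abs=0.3)
        assert fit.scale == pytest.approx(0.5, abs=0.15)

    def test_constant_response_degenerate(self, tiny_cfg):
        df = simulate_table(tiny_cfg).copy()
        df["recalled"] = 1
        with pytest.raises(DegenerateOutcomeError, match="degenerate"):
            fit_glmm(df, RECALL_SPEC)

    def test_recovers_variance_components(self):
        cfg = SyntheticConfig(seed=30, n_per_group=28, events_min=14, events_max=16)
        df = simulate_table(cfg)
        fit = fit_glmm(df[df["session"] == "day8"], ModelSpec(
            family="binomial", response="recalled",
            fixed_terms=("group", "centrality_z", "recall_type"),
        ))
        assert 0.2 < fit.sigmas["participant"] < 0.9  # true 0.5
        assert fit.converged

    def test_ci_equals_beta_pm_1p96_se(self, tiny_cfg):
        df = simulate_table(tiny_cfg)
        fit = fit_glmm(df[df["session"] == "day1"], RECALL_SPEC)
        for c in fit.params.values():
            assert c.ci_low == pytest.approx(c.estimate - 1.96 * c.se, abs=2e-4 * max(c.se, 1))
            assert c.ci_high == pytest.approx(c.estimate + 1.96 * c.se, abs=2e-4 * max(c.se, 1))


class TestWald:
    def test_single_coefficient_identity(self, tiny_cfg):
        df = simulate_table(tiny_cfg)
        fit = fit_glmm(df[df["session"] == "day1"], RECALL_SPEC)
        chi2, dof, p = type3_wald(fit, "centrality_z")
        c = fit.params["centrality_z"]
        assert dof == 1
        assert chi2 == pytest.approx((c.estimate / c.se) ** 2, rel=1e-10)

    def test_chi2_tail_closed_form(self):
        assert stats.chi2.sf(3.841, 1) == pytest.approx(0.0500, abs=2e-4)

    def test_two_coefficient_diagonal_block(self):
        names = ["(Intercept)", "a", "b"]
        cov = np.diag([1.0, 0.04, 0.09])
        fit = _make_fit(names, [0.0, 0.4, 0.6], cov, {"ab": (1, 2)})
        chi2, dof, p = type3_wald(fit, "ab")
        assert dof == 2
        assert chi2 == pytest.approx((0.4 / 0.2) ** 2 + (0.6 / 0.3) ** 2)

    def test_missing_term(self, tiny_cfg):
        df = simulate_table(tiny_cfg)
        fit = fit_glmm(df[df["session"] == "day1"], RECALL_SPEC)
        with pytest.raises(ValueError, match="not in model"):
            type3_wald(fit, "session")


class TestSimpleSlopes:
    NAMES = ["(Intercept)", "group[older]", "centrality_z", "group[older]:centrality_z"]
    TERMS = {
        "(Intercept)": (0,), "group": (1,), "centrality_z": (2,),
        "group:centrality_z": (3,),
    }

    def test_zero_interaction_equal_slopes(self):
        fit = _make_fit(self.NAMES, [0.1, 0.0, 0.25, 0.0], np.eye(4) * 0.01, self.TERMS)
        slopes = simple_slopes(fit)
        assert slopes["young"].estimate == pytest.approx(slopes["older"].estimate)

    def test_reference_slope_is_main_effect(self):
        fit = _make_fit(self.NAMES, [0.1, 0.2, 0.25, -0.1], np.eye(4) * 0.01, self.TERMS)
        assert simple_slopes(fit)["young"].estimate == pytest.approx(0.25)

    def test_constructed_day1_pattern(self):
        # beta_c = 0.10, beta_int = -0.097 -> non-reference slope 0.003
        fit = _make_fit(self.NAMES, [0.0, 0.0, 0.10, -0.097], np.eye(4) * 0.0009, self.TERMS)
        slopes = simple_slopes(fit)
        assert slopes["young"].estimate == pytest.approx(0.10)
        assert slopes["older"].estimate == pytest.approx(0.003)

    def test_delta_rule_se_uses_covariance(self):
        cov = np.eye(4) * 0.01
        cov[2, 3] = cov[3, 2] = -0.005
        fit = _make_fit(self.NAMES, [0.0, 0.0, 0.1, 0.1], cov, self.TERMS)
        s = simple_slopes(fit)["older"]
        assert s.se == pytest.approx(np.sqrt(0.01 + 0.01 + 2 * -0.005))

    def test_missing_interaction_rejected(self, tiny_cfg):
        df = simulate_table(tiny_cfg)
        fit = fit_glmm(df[df["session"] == "day1"], ModelSpec(
            family="binomial", response="recalled", fixed_terms=("group", "centrality_z"),
        ))
        with pytest.raises(ValueError, match="interaction"):
            simple_slopes(fit)


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        res = pearson_cor(x, 2 * x + 1)
        assert res["r"] == pytest.approx(1.0)

    def test_worked_value(self):
        res = pearson_cor([1, 2, 3], [1, 2, 4])
        assert res["r"] == pytest.approx(0.9820, abs=1e-4)
        assert res["df"] == 1

    def test_fisher_ci_brackets_r(self, rng):
        x = rng.normal(size=50)
        y = x + rng.normal(size=50)
        res = pearson_cor(x, y)
        assert res["ci_low"] < res["r"] < res["ci_high"]

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_cor([1, 1, 1], [1, 2, 3])

    def test_null_rejection_rate(self, rng):
        reps, n, rej = 1000, 111, 0
        for _ in range(reps):
            if pearson_cor(rng.normal(size=n), rng.normal(size=n))["p"] < 0.05:
                rej += 1
        assert 0.03 <= rej / reps <= 0.07


class TestClopperPearson:
    def test_zero_successes_upper_bound_closed_form(self):
        lo, hi = clopper_pearson(0, 1000)
        assert lo == 0.0
        assert hi == pytest.approx(1 - 0.025 ** (1 / 1000), rel=1e-10)
        assert round(hi * 100, 2) == 0.37

    def test_all_successes(self):
        lo, hi = clopper_pearson(10, 10)
        assert hi == 1.0
        assert lo == pytest.approx(0.025 ** (1 / 10), rel=1e-10)

    def test_interval_brackets_point_estimate(self):
        lo, hi = clopper_pearson(30, 100)
        assert lo < 0.3 < hi

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            clopper_pearson(5, 4)


class TestPowerSimulation:
    TEMPLATE = SyntheticConfig(
        seed=0, n_per_group=6, n_videos=4, events_min=5, events_max=7
    )

    def test_deterministic_given_seed(self):
        a = power_simulation(self.TEMPLATE, effect=0.5, nsim=4, seed=99)
        b = power_simulation(self.TEMPLATE, effect=0.5, nsim=4, seed=99)
        assert a == b

    def test_power_is_fraction_with_cp_interval(self):
        res = power_simulation(self.TEMPLATE, effect=1.5, nsim=5, seed=1)
        assert res.power == res.n_significant / res.nsim
        assert res.ci_low <= res.power <= res.ci_high

    def test_seed_required(self):
        with pytest.raises(ValueError, match="seed"):
            power_simulation(self.TEMPLATE, effect=0.5, nsim=2)
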