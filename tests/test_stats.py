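"""Common-gradient screen contracts: normal-equation oracle equivalence,
model choice behaviour, percent change, classification and the
permutation / type-I properties of the gradient test."""

import numpy as np
import pytest
from scipy import stats as sps

from threetau.stats import (DegenerateDesignError, ModelFit, ObservationTable,
                            benjamini_hochberg, classify, compare_models,
                            fit_common_gradient, percent_change,
                            screen_quantity)

GROUPS3 = np.array(["4T1", "FARN", "TSA"], dtype=object)


def _random_table(rng, n_per=10, beta=-0.1, offsets=(0.0, 0.0, 0.0), sd=1.0,
                  alpha=10.0):
    groups, cs, ys = [], [], []
    for g, off in zip(GROUPS3, offsets):
        c = rng.uniform(0, 83, n_per)
        y = alpha + off + beta * c + sd * rng.standard_normal(n_per)
        groups.extend([g] * n_per)
        cs.extend(c)
        ys.extend(y)
    return ObservationTable(np.array(groups, dtype=object), np.array(cs),
                            np.array(ys), quantity_name="toy")


def _brute_force_ols(table, kind):
    """Independent oracle: explicit design matrix + normal equations."""
    n = table.n
    c = table.c
    if kind == "parallel":
        present = sorted(set(table.group), key=list(GROUPS3).index)
        X = np.zeros((n, len(present) + 1))
        for j, g in enumerate(present):
            X[:, j] = (table.group == g).astype(float)
        X[:, -1] = c
        p_extra = len(present)  # coefficients beyond one grand intercept: k-1 dummies + slope
    else:
        X = np.column_stack([np.ones(n), c])
        p_extra = 1
    coef = np.linalg.solve(X.T @ X, X.T @ table.y)
    resid = table.y - X @ coef
    rss = float(resid @ resid)
    dof = n - X.shape[1]
    sigma2 = rss / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    beta = coef[-1]
    se = np.sqrt(cov[-1, -1])
    p = 2.0 * sps.t.sf(abs(beta / se), dof)
    tss = float(np.sum((table.y - table.y.mean()) ** 2))
    r2 = 1.0 - rss / tss
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 1 - p_extra)
    return beta, se, p, adj, rss


class TestOLSOracle:
    @pytest.mark.parametrize("kind", ["parallel", "coincident"])
    def test_matches_normal_equations_on_random_tables(self, kind):
        rng = np.random.default_rng(11)
        for _ in range(20):
            table = _random_table(rng, n_per=10,
                                  beta=rng.normal(scale=0.2),
                                  offsets=rng.normal(scale=2.0, size=3),
                                  sd=rng.uniform(0.5, 3.0))
            fit = fit_common_gradient(table, kind)
            beta, se, p, adj, rss = _brute_force_ols(table, kind)
            assert fit.beta == pytest.approx(beta, rel=1e-10)
            assert fit.beta_se == pytest.approx(se, rel=1e-10)
            assert fit.beta_p_value == pytest.approx(p, rel=1e-8, abs=1e-300)
            assert fit.adjusted_r2 == pytest.approx(adj, rel=1e-10)
            assert fit.rss == pytest.approx(rss, rel=1e-10)

    def test_exact_line_recovered(self):
        c = np.tile(np.linspace(0, 80, 10), 3)
        g = np.repeat(GROUPS3, 10)
        y = 2.0 + 0.5 * c
        table = ObservationTable(g, c, y)
        fit = fit_common_gradient(table, "coincident")
        assert fit.intercepts["all"] == pytest.approx(2.0, abs=1e-10)
        assert fit.beta == pytest.approx(0.5, rel=1e-12)
        assert fit.adjusted_r2 == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(fit.residuals, 0.0, atol=1e-10)

    def test_parallel_never_worse_than_coincident(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            table = _random_table(rng, offsets=rng.normal(scale=1.0, size=3))
            rss_p = fit_common_gradient(table, "parallel").rss
            rss_c = fit_common_gradient(table, "coincident").rss
            assert rss_p <= rss_c * (1 + 1e-12)

    def test_degenerate_designs_raise(self):
        g = np.repeat(GROUPS3, 4)
        c = np.full(12, 50.0)
        with pytest.raises(DegenerateDesignError):
            fit_common_gradient(ObservationTable(g, c, np.ones(12)), "coincident")


class TestModelChoice:
    def test_identical_intercepts_prefer_coincident(self):
        rng = np.random.default_rng(5)
        chosen = []
        for _ in range(500):
            table = _random_table(rng, n_per=10, beta=-0.1,
                                  offsets=(0.0, 0.0, 0.0), sd=1.0)
            kind, _, _ = compare_models(fit_common_gradient(table, "parallel"),
                                        fit_common_gradient(table, "coincident"))
            chosen.append(kind)
        assert np.mean([k == "coincident" for k in chosen]) >= 0.90

    def test_separated_intercepts_prefer_parallel(self):
        rng = np.random.default_rng(6)
        chosen = []
        for _ in range(500):
            table = _random_table(rng, n_per=10, beta=-0.1,
                                  offsets=(10.0, 0.0, -10.0), sd=1.0)
            kind, _, _ = compare_models(fit_common_gradient(table, "parallel"),
                                        fit_common_gradient(table, "coincident"))
            chosen.append(kind)
        assert np.mean([k == "parallel" for k in chosen]) >= 0.99

    def test_equal_rss_gives_f_zero_and_coincident(self):
        c = np.tile(np.linspace(0, 80, 10), 3)
        g = np.repeat(GROUPS3, 10)
        rng = np.random.default_rng(7)
        y = 5.0 - 0.2 * c + rng.standard_normal(30)
        fit_p = fit_common_gradient(ObservationTable(g, c, y), "parallel")
        fit_c = fit_common_gradient(ObservationTable(g, c, y), "coincident")
        forced = ModelFit("parallel", fit_p.intercepts, fit_p.beta,
                          fit_p.beta_se, fit_p.beta_p_value, fit_p.adjusted_r2,
                          fit_c.rss, fit_c.residuals, fit_c.n)
        kind, f_stat, p = compare_models(forced, fit_c)
        assert f_stat == 0.0
        assert kind == "coincident"


class TestPercentChange:
    def test_study_value(self):
        """alpha = 29.51, beta = -0.121 gives the printed -41% change."""
        fit = ModelFit("coincident", {"all": 29.512195}, -0.121, 0.01, 1e-12,
                       0.8, 1.0, np.zeros(32), 32)
        assert percent_change(fit) == pytest.approx(-41.0, abs=0.05)

    def test_flat_line_and_scale_invariance(self):
        flat = ModelFit("coincident", {"all": 10.0}, 0.0, 0.01, 0.9, 0.0,
                        1.0, np.zeros(10), 10)
        assert percent_change(flat) == 0.0
        a = ModelFit("coincident", {"all": 7.0}, -0.02, 0.01, 0.01, 0.5,
                     1.0, np.zeros(10), 10)
        b = ModelFit("coincident", {"all": 14.0}, -0.04, 0.01, 0.01, 0.5,
                     1.0, np.zeros(10), 10)
        assert percent_change(a) == pytest.approx(percent_change(b))

    def test_parallel_uses_group_weighted_intercepts(self):
        fit = ModelFit("parallel", {"4T1": 10.0, "FARN": 20.0, "TSA": 40.0},
                       -0.05, 0.01, 0.01, 0.6, 1.0, np.zeros(32), 32)
        sizes = {"4T1": 11, "FARN": 11, "TSA": 10}
        y0 = (10 * 11 + 20 * 11 + 40 * 10) / 32
        assert percent_change(fit, sizes) == pytest.approx(100 * -5.0 / y0)

    def test_zero_intercept_raises(self):
        fit = ModelFit("coincident", {"all": 0.0}, -0.05, 0.01, 0.01, 0.6,
                       1.0, np.zeros(10), 10)
        with pytest.raises(ZeroDivisionError):
            percent_change(fit)


class TestClassification:
    @pytest.mark.parametrize("p,r2,expected", [
        (1.3e-8, 0.757, "biomarker"),            # the bulk-time outcome
        (1.59e-4, 0.363, "significant-but-weak"),  # the desorption-time outcome
        (0.471, 0.33, "none-suitable"),           # non-significant gradient
        (4.67e-6, 0.069, "none-suitable"),        # significant but tiny R^2
        (0.04999, 0.5, "biomarker"),
        (0.05, 0.9, "none-suitable"),             # boundary: p not < 0.05
        (0.01, 0.2, "significant-but-weak"),
        (0.01, 0.1999, "none-suitable"),
    ])
    def test_decision_rule(self, p, r2, expected):
        assert classify(p, r2) == expected


class TestScreenProperties:
    def test_permuting_y_destroys_significance(self):
        rng = np.random.default_rng(12)
        table = _random_table(rng, beta=-0.1, sd=0.5)
        base = screen_quantity(table)
        assert base.p_value < 1e-4
        pvals = []
        for _ in range(100):
            perm = ObservationTable(table.group, table.c,
                                    rng.permutation(table.y))
            pvals.append(fit_common_gradient(perm, "coincident").beta_p_value)
        assert np.median(pvals) > 0.3

    def test_type_one_error_near_nominal(self):
        """Null gradient: rejection rate of the beta t-test ~ 5%."""
        rng = np.random.default_rng(13)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            table = _random_table(rng, beta=0.0, sd=1.0)
            fit = fit_common_gradient(table, "coincident")
            rejections += fit.beta_p_value < 0.05
        assert rejections / n_rep == pytest.approx(0.05, abs=0.025)

    def test_benjamini_hochberg_monotone_and_bounded(self):
        p = np.array([0.001, 0.01, 0.02, 0.3, 0.9])
        adj = benjamini_hochberg(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)
        assert adj[0] == pytest.approx(0.005)
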