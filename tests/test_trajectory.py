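"""Spline basis algebra, coefficient recovery, cluster-robust covariance
properties, Wald tests and per-day t-tests."""

import numpy as np
import pandas as pd
import pytest

from ramanremodel import (
    ModelSpec,
    RCSTrajectoryModel,
    cluster_robust_cov,
    fit_trajectory,
    localize_jump,
    rcs_basis,
    ttest_by_day,
)
from ramanremodel.trajectory import build_design, default_knots

KNOTS = np.array([4.0, 13.0, 19.0])
DAYS = {"WT": [0, 4, 12, 15, 18, 19], "KO": [0, 4, 12, 15, 19, 20]}


def make_table(n_mice=6, obs=4, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for g, days in DAYS.items():
        for d in days:
            for m in range(n_mice):
                for _ in range(obs):
                    rows.append(dict(mouse_id=f"{g}{d}m{m}", genotype=g,
                                     gestation_day=str(d) if d else "NG",
                                     i1440=rng.uniform(200, 800)))
    return pd.DataFrame(rows), rng


def simulate_response(tbl, rng, coefs=None, sigma=0.0, icc_sd=0.0, zero=()):
    spec = ModelSpec(response="y", knots=KNOTS)
    X, _ = build_design(tbl, spec)
    if coefs is None:
        coefs = rng.normal(0, 1, X.shape[1])
        coefs[list(X.columns).index("intensity")] = 0.002
    coefs = np.asarray(coefs, float).copy()
    for i, t in enumerate(X.columns):
        if any(z in t for z in zero):
            coefs[i] = 0.0
    y = X.to_numpy() @ coefs
    if icc_sd:
        mice = tbl.mouse_id.unique()
        re = dict(zip(mice, icc_sd * rng.standard_normal(len(mice))))
        y = y + tbl.mouse_id.map(re).to_numpy()
    if sigma:
        y = y + sigma * rng.standard_normal(len(tbl))
    out = tbl.copy()
    out["y"] = y
    return out, coefs, spec


class TestBasis:
    def test_nonlinear_term_zero_at_and_below_first_knot(self):
        x = np.array([-3.0, 0.0, 4.0])
        assert np.allclose(rcs_basis(x, KNOTS)[:, 1], 0.0)

    def test_linear_beyond_boundary_knot(self):
        # numerical second derivative vanishes past the last knot
        for x0 in (19.5, 21.0, 30.0):
            h = 1e-3
            s = rcs_basis(np.array([x0 - h, x0, x0 + h]), KNOTS)[:, 1]
            d2 = (s[0] - 2 * s[1] + s[2]) / h**2
            assert abs(d2) < 1e-6

    def test_curved_between_knots(self):
        h = 1e-3
        s = rcs_basis(np.array([10 - h, 10.0, 10 + h]), KNOTS)[:, 1]
        assert abs((s[0] - 2 * s[1] + s[2]) / h**2) > 1e-3

    def test_duplicate_knots_rejected(self):
        with pytest.raises(ValueError):
            rcs_basis(np.array([1.0]), np.array([4.0, 4.0, 19.0]))

    def test_default_knots_are_quantiles(self):
        days = np.concatenate([np.full(10, d) for d in (0, 4, 12, 15, 18, 19)])
        q = default_knots(days)
        assert (np.diff(q) > 0).all()
        assert q[0] >= 0 and q[-1] <= 19


class TestFit:
    def test_noiseless_coefficient_recovery(self):
        tbl, rng = make_table()
        data, coefs, spec = simulate_response(tbl, rng)
        model = RCSTrajectoryModel(spec=spec).fit(data)
        assert np.abs(model.coef_.to_numpy() - coefs).max() < 1e-6

    def test_fitted_curve_smooth_across_knots(self):
        tbl, rng = make_table()
        data, _, spec = simulate_response(tbl, rng)
        model = RCSTrajectoryModel(spec=spec).fit(data)
        # grid stops short of the last-day indicator (a planted discontinuity)
        grid = np.linspace(0.0, 18.5, 1851)
        curve = model.predict_trajectory("WT", grid)
        d2 = np.diff(curve, 2)
        # continuous first/second differences: no isolated spikes at the knots
        assert np.max(np.abs(np.diff(d2))) < 1e-2 * max(np.abs(curve).max(), 1.0)

    def test_rank_deficient_design_names_columns(self):
        tbl, rng = make_table(n_mice=2, obs=1)
        data, _, spec = simulate_response(tbl, rng)
        data["i1440"] = 1.0  # constant intensity aliases the intercept
        with pytest.raises(ValueError, match="aliased"):
            RCSTrajectoryModel(spec=spec).fit(data)

    def test_planted_jump_detected_on_correct_side(self):
        tbl, rng = make_table(n_mice=8, obs=4, seed=2)
        data, _, spec = simulate_response(tbl, rng, sigma=0.3)
        # overwrite: jump only in WT at day 19
        day = data.gestation_day.map(lambda v: 0.0 if v == "NG" else float(v))
        data["y"] = 0.001 * data["i1440"] + 0.3 * day \
            - 4.0 * ((data.genotype == "WT") & (day == 19)) \
            + 0.3 * rng.standard_normal(len(data))
        m = RCSTrajectoryModel(spec=spec).fit(data)
        z_wt = abs(m.z_value("lastday_WT"))
        z_ko = abs(m.z_value("lastday_KO"))
        assert z_wt > 5 and z_wt > z_ko
        # swapping genotype labels (indicator days travel with the labels,
        # since each genotype's sampling days are design-specific) swaps the
        # significant indicator
        sw = data.copy()
        sw["genotype"] = sw.genotype.map({"WT": "KO", "KO": "WT"})
        spec_sw = ModelSpec(response="y", knots=KNOTS,
                            jump_days={"WT": 20, "KO": 19})
        m2 = RCSTrajectoryModel(spec=spec_sw).fit(sw)
        assert abs(m2.z_value("lastday_KO")) > 5
        assert abs(m2.z_value("lastday_KO")) > abs(m2.z_value("lastday_WT"))

    def test_wald_untestable_when_covariance_singular(self):
        tbl, rng = make_table(n_mice=4, obs=2)
        data, _, spec = simulate_response(tbl, rng, sigma=0.4)
        m = RCSTrajectoryModel(spec=spec).fit(data)
        # force a degenerate sub-block: duplicated row/column
        m.cov_.loc["geno_KO:day_cub", :] = m.cov_.loc["geno_KO:day", :]
        m.cov_.loc[:, "geno_KO:day_cub"] = m.cov_.loc[:, "geno_KO:day"]
        res = m.wald_test(["geno_KO:day", "geno_KO:day_cub"])
        assert not res["testable"]
        assert np.isnan(res["p"])


class TestRobustCovariance:
    def test_single_cluster_rejected(self):
        X = np.ones((5, 1))
        with pytest.raises(ValueError):
            cluster_robust_cov(X, np.ones(5), np.zeros(5))

    def test_agrees_with_classical_under_independence(self):
        rng = np.random.default_rng(1)
        n = 1000
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ [1.0, 2.0] + rng.normal(size=n)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        vr = cluster_robust_cov(X, resid, np.arange(n))  # singleton clusters
        vc = resid @ resid / (n - 2) * np.linalg.inv(X.T @ X)
        assert np.sqrt(np.diag(vr)) == pytest.approx(np.sqrt(np.diag(vc)), rel=0.10)

    def test_duplicating_within_cluster_leaves_robust_se_unchanged(self):
        rng = np.random.default_rng(2)
        n = 200
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ [1.0, 2.0] + rng.normal(size=n)
        clusters = np.arange(n)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        v1 = cluster_robust_cov(X, resid, clusters)
        X2 = np.vstack([X, X])
        y2 = np.concatenate([y, y])
        c2 = np.concatenate([clusters, clusters])
        beta2, *_ = np.linalg.lstsq(X2, y2, rcond=None)
        resid2 = y2 - X2 @ beta2
        v2 = cluster_robust_cov(X2, resid2, c2)
        # (2X'X)^-1 (4 meat) (2X'X)^-1 = V: robust SEs are duplication-invariant
        assert np.allclose(v2, v1, rtol=1e-6)
        # classical SEs would shrink by sqrt(~2) under duplication
        vc1 = resid @ resid / (n - 2) * np.linalg.inv(X.T @ X)
        vc2 = resid2 @ resid2 / (2 * n - 2) * np.linalg.inv(X2.T @ X2)
        assert np.sqrt(vc2[1, 1]) < 0.8 * np.sqrt(vc1[1, 1])

    def test_intra_cluster_correlation_inflates_robust_se(self):
        rng = np.random.default_rng(3)
        G, size = 60, 8
        cluster = np.repeat(np.arange(G), size)
        x = np.repeat(rng.normal(size=G), size)  # cluster-constant covariate
        X = np.column_stack([np.ones(G * size), x])
        re = np.repeat(rng.normal(scale=2.0, size=G), size)  # ICC ~ 0.8
        y = 1.0 + 0.5 * x + re + rng.normal(size=G * size)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        vr = cluster_robust_cov(X, resid, cluster)
        vc = resid @ resid / (len(y) - 2) * np.linalg.inv(X.T @ X)
        assert np.sqrt(vr[1, 1]) > np.sqrt(vc[1, 1])

    def test_matches_statsmodels_up_to_correction_factor(self):
        import statsmodels.api as sm

        tbl, rng = make_table(n_mice=4, obs=3)
        data, _, spec = simulate_response(tbl, rng, sigma=0.5, icc_sd=0.5)
        model = RCSTrajectoryModel(spec=spec).fit(data)
        X, _ = build_design(data, spec)
        codes, _ = pd.factorize(data.mouse_id)
        fit = sm.OLS(data.y.to_numpy(), X.to_numpy()).fit(
            cov_type="cluster", cov_kwds={"groups": codes}
        )
        G, N, K = model.n_clusters_, model.n_obs_, X.shape[1]
        factor = (N - 1) / (N - K)  # statsmodels' extra df correction
        assert np.allclose(
            model.cov_.to_numpy() * factor, fit.cov_params(), rtol=1e-8
        )


class TestWald:
    def test_one_df_group_equals_squared_z(self):
        tbl, rng = make_table()
        data, _, spec = simulate_response(tbl, rng, sigma=0.4, icc_sd=0.2)
        m = RCSTrajectoryModel(spec=spec).fit(data)
        res = m.wald_test(["lastday_WT"])
        assert res["stat"] == pytest.approx(m.z_value("lastday_WT") ** 2, rel=1e-10)

    def test_zero_coefficients_give_zero_statistic(self):
        tbl, rng = make_table(n_mice=6, obs=3)
        data, _, spec = simulate_response(tbl, rng, sigma=0.5)
        m = RCSTrajectoryModel(spec=spec).fit(data)
        m.coef_["geno_KO:day"] = 0.0
        m.coef_["geno_KO:day_cub"] = 0.0
        res = m.wald_test(["geno_KO:day", "geno_KO:day_cub"])
        assert res["stat"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_power_increases_with_interaction_size(self):
        ps = []
        for size in (0.02, 0.1, 0.5):
            tbl, rng = make_table(n_mice=8, obs=3, seed=7)
            data, coefs, spec = simulate_response(tbl, rng, sigma=1.0, zero=(":day",))
            X, _ = build_design(data, spec)
            data["y"] = data["y"] + size * X["geno_KO:day"].to_numpy()
            m = RCSTrajectoryModel(spec=spec).fit(data)
            a = m.wald_anova()
            ps.append(a.loc[a.effect == "genotype:gestation", "p"].iloc[0])
        assert ps[0] > ps[1] > ps[2]


class TestJumpLocalization:
    def test_localizes_planted_jump_days(self):
        tbl, rng = make_table(n_mice=8, obs=4, seed=11)
        day = tbl.gestation_day.map(lambda v: 0.0 if v == "NG" else float(v))
        jump = -3.0 * (((tbl.genotype == "WT") & (day >= 19))
                       | ((tbl.genotype == "KO") & (day >= 20)))
        tbl["y"] = 0.2 * day + jump + 0.001 * tbl.i1440 \
            + 0.3 * rng.standard_normal(len(tbl))
        best = localize_jump(tbl, "y", {"WT": [15, 18, 19], "KO": [15, 19, 20]},
                             ModelSpec(response="y", knots=KNOTS))
        assert best == {"WT": 19, "KO": 20}


class TestTTests:
    def _per_mouse(self, deltas, n=8, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for day, delta in deltas.items():
            for g, shift in (("WT", 0.0), ("KO", delta)):
                for m in range(n):
                    rows.append(dict(mouse_id=f"{g}{day}{m}", genotype=g,
                                     gestation_day=day,
                                     r=shift + rng.standard_normal()))
        return pd.DataFrame(rows)

    def test_identical_groups_p_one(self):
        pm = self._per_mouse({"12": 0.0})
        pm.loc[pm.genotype == "KO", "r"] = pm.loc[pm.genotype == "WT", "r"].to_numpy()
        out = ttest_by_day(pm, "r")
        assert out["p"].iloc[0] == pytest.approx(1.0)
        assert out["t"].iloc[0] == pytest.approx(0.0)

    def test_label_swap_symmetry(self):
        pm = self._per_mouse({"12": 1.0})
        out1 = ttest_by_day(pm, "r")
        sw = pm.copy()
        sw["genotype"] = sw.genotype.map({"WT": "KO", "KO": "WT"})
        out2 = ttest_by_day(sw, "r")
        assert out1["p"].iloc[0] == pytest.approx(out2["p"].iloc[0])

    def test_power_at_five_sigma_separation(self):
        hits = 0
        for seed in range(200):
            pm = self._per_mouse({"19": 5.0}, n=8, seed=seed)
            out = ttest_by_day(pm, "r")
            hits += bool(out["significant"].iloc[0])
        assert hits >= 198  # >= 99% of 200 seeds

    def test_small_group_skipped_with_warning(self):
        pm = self._per_mouse({"12": 1.0}, n=1)
        with pytest.warns(UserWarning, match="skipped"):
            out = ttest_by_day(pm, "r")
        assert out.empty
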