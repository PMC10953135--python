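"""REML machinery against dense GLS, ANOVA closed forms and grid oracles."""

import numpy as np
import pandas as pd
import pytest

from layres import animal_model as am
from layres.pedigree import PedigreeRelationship, build_A
from tests.test_pedigree import random_pedigree


def half_sib_data(s=30, n=15, s2a=0.4, s2e=0.6, mu=2.0, seed=5):
    """Balanced paternal half-sib families, dams unknown."""
    rng = np.random.default_rng(seed)
    rows = [(i, 0, 0) for i in range(1, s + 1)]
    prog = []
    aid = s + 1
    for i in range(1, s + 1):
        for _ in range(n):
            rows.append((aid, i, 0))
            prog.append(aid)
            aid += 1
    ped = pd.DataFrame(rows, columns=["animal", "sire", "dam"])
    u_s = rng.normal(0, np.sqrt(s2a), s)
    y = []
    for i in range(s):
        for _ in range(n):
            a = 0.5 * u_s[i] + rng.normal(0, np.sqrt(0.75 * s2a))
            y.append(mu + a + rng.normal(0, np.sqrt(s2e)))
    return ped, pd.DataFrame({"animal": prog, "y": y})


class TestMME:
    def test_solution_matches_dense_gls(self):
        """Ten-record toy system vs a dense GLS oracle."""
        ped = random_pedigree(14, seed=2, n_founders=6)
        rel = PedigreeRelationship.from_pedigree(ped)
        rng = np.random.default_rng(3)
        animals = np.arange(5, 15)
        data = pd.DataFrame({
            "animal": animals,
            "grp": ["a", "b"] * 5,
            "y": rng.normal(1.0, 1.0, 10),
        })
        s2a, s2e = 0.5, 0.8
        spec = am.ModelSpec(response="y", fixed=("grp",))
        C, rhs, parts = am.build_mme(spec, data, rel,
                                     {"sigma2_a": s2a, "sigma2_e": s2e})
        sol = am.solve_mme(C, rhs)
        X = parts.X.toarray()
        Z = parts.Za.toarray()
        A = build_A(ped)
        V = s2a * Z @ A @ Z.T + s2e * np.eye(10)
        Vi = np.linalg.inv(V)
        b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ data["y"])
        u = s2a * A @ Z.T @ Vi @ (data["y"] - X @ b)
        assert np.abs(sol[: len(b)] - b).max() < 1e-8
        assert np.abs(sol[len(b):] - u).max() < 1e-8

    def test_vanishing_genetic_variance_recovers_ols_cell_means(self):
        rng = np.random.default_rng(4)
        ped = random_pedigree(12, seed=4, n_founders=6)
        rel = PedigreeRelationship.from_pedigree(ped)
        data = pd.DataFrame({
            "animal": np.arange(1, 13),
            "grp": ["a"] * 6 + ["b"] * 6,
            "y": rng.normal(0, 1, 12),
        })
        spec = am.ModelSpec(response="y", fixed=("grp",))
        C, rhs, parts = am.build_mme(spec, data, rel,
                                     {"sigma2_a": 1e-12, "sigma2_e": 1.0})
        sol = am.solve_mme(C, rhs)
        means = data.groupby("grp")["y"].mean()
        # intercept = mean(a); contrast = mean(b) - mean(a)
        assert sol[0] == pytest.approx(means["a"], abs=1e-6)
        assert sol[1] == pytest.approx(means["b"] - means["a"], abs=1e-6)

    def test_strict_mode_names_confounded_factors(self):
        data = pd.DataFrame({
            "animal": [1, 2, 3, 4],
            "f1": ["a", "a", "b", "b"],
            "f2": ["x", "x", "y", "y"],   # identical partition -> confounded
            "y": [1.0, 2.0, 3.0, 4.0],
        })
        spec = am.ModelSpec(response="y", fixed=("f1", "f2"))
        with pytest.raises(am.ModelError, match="f2"):
            am.build_fixed_design(spec, data, strict=True)
        X, names, rank = am.build_fixed_design(spec, data)
        assert X.shape[1] == 2  # intercept + one usable contrast


class TestUnivariateREML:
    def test_half_sib_matches_anova_closed_form(self):
        ped, data = half_sib_data(s=40, n=20, seed=7)
        rel = PedigreeRelationship.from_pedigree(ped)
        Y = data["y"].to_numpy().reshape(40, 20)
        msb = 20 * np.var(Y.mean(axis=1), ddof=1)
        msw = np.mean(np.var(Y, axis=1, ddof=1))
        s2a_hat = 4 * (msb - msw) / 20
        s2e_hat = msw - 3 * (msb - msw) / 20
        assert s2a_hat > 0  # interior case
        fit = am.reml_fit(am.ModelSpec(response="y"), data, rel,
                          nm_options={"xatol": 1e-9}, compute_se=False)
        assert fit.sigma2_a == pytest.approx(s2a_hat, rel=1e-4)
        assert fit.sigma2_e == pytest.approx(s2e_hat, rel=1e-4)

    def test_em_direct_agreement_and_em_monotone(self):
        ped, data = half_sib_data(s=15, n=10, seed=8)
        rel = PedigreeRelationship.from_pedigree(ped)
        spec = am.ModelSpec(response="y")
        em = am.reml_fit(spec, data, rel, method="em", max_iter=5000,
                         tol_ll=1e-12, tol_par=1e-8, compute_se=False)
        direct = am.reml_fit(spec, data, rel, compute_se=False)
        hist = np.array(em.loglik_history)
        assert np.all(np.diff(hist) >= -1e-7)
        assert em.sigma2_a == pytest.approx(direct.sigma2_a, rel=2e-2)
        assert em.loglik == pytest.approx(direct.loglik, abs=1e-3)

    def test_identity_relationship_matches_grid_oracle(self):
        """A = I repeated-records random-intercept toy vs a dense
        restricted-likelihood grid + golden-section oracle."""
        rng = np.random.default_rng(9)
        n_id, reps = 40, 5
        ids = np.repeat(np.arange(1, n_id + 1), reps)
        u = rng.normal(0, np.sqrt(0.5), n_id)
        y = 1.0 + u[ids - 1] + rng.normal(0, 1.0, len(ids))
        ped = pd.DataFrame({"animal": np.arange(1, n_id + 1),
                            "sire": 0, "dam": 0})
        rel = PedigreeRelationship.from_pedigree(ped)
        data = pd.DataFrame({"animal": ids, "y": y})
        fit = am.reml_fit(am.ModelSpec(response="y"), data, rel,
                          compute_se=False, nm_options={"xatol": 1e-9})

        Z = np.zeros((len(ids), n_id))
        Z[np.arange(len(ids)), ids - 1] = 1.0
        X = np.ones((len(ids), 1))

        def m2ll(lam):
            V = lam * Z @ Z.T + np.eye(len(ids))
            Vi = np.linalg.inv(V)
            b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
            r = y - X @ b
            T = r @ Vi @ r
            s2e = T / (len(ids) - 1)
            _, ldV = np.linalg.slogdet(V)
            ldX = np.log((X.T @ Vi @ X)[0, 0])
            return (len(ids) - 1) * np.log(s2e) + ldV + ldX, s2e

        grid = np.exp(np.linspace(np.log(1e-4), np.log(50), 60))
        vals = [m2ll(l)[0] for l in grid]
        k = int(np.argmin(vals))
        from scipy.optimize import minimize_scalar
        res = minimize_scalar(lambda u_: m2ll(np.exp(u_))[0],
                              bounds=(np.log(grid[max(k - 1, 0)]),
                                      np.log(grid[min(k + 1, 59)])),
                              method="bounded", options={"xatol": 1e-10})
        lam_star = np.exp(res.x)
        s2e_star = m2ll(lam_star)[1]
        assert fit.sigma2_a == pytest.approx(lam_star * s2e_star, rel=0.01)
        assert fit.sigma2_e == pytest.approx(s2e_star, rel=0.01)

    def test_estimates_invariant_to_record_order_and_level_labels(self):
        ped, data = half_sib_data(s=12, n=8, seed=10)
        rel = PedigreeRelationship.from_pedigree(ped)
        data = data.assign(grp=np.tile(["u", "v"], len(data) // 2))
        spec = am.ModelSpec(response="y", fixed=("grp",))
        fit1 = am.reml_fit(spec, data, rel, compute_se=False)
        shuffled = data.sample(frac=1.0, random_state=1).reset_index(drop=True)
        shuffled["grp"] = shuffled["grp"].map({"u": "zz", "v": "aa"})
        fit2 = am.reml_fit(spec, shuffled, rel, compute_se=False)
        assert fit1.sigma2_a == pytest.approx(fit2.sigma2_a, rel=1e-5)
        assert fit1.sigma2_e == pytest.approx(fit2.sigma2_e, rel=1e-5)

    def test_zero_true_additive_variance_rarely_significant(self):
        """With sigma2_a = 0 in truth, the additive LRT should declare
        'not significantly different from zero' in >= 90% of replicates."""
        from layres import genparams as gp

        hits = 0
        reps = 20
        for r in range(reps):
            rng = np.random.default_rng(100 + r)
            ped = random_pedigree(160, seed=100 + r, n_founders=40)
            rel = PedigreeRelationship.from_pedigree(ped)
            data = pd.DataFrame({"animal": np.arange(41, 161),
                                 "y": rng.normal(0, 1, 120)})
            res = gp.analyze_trait("y", data, rel, fixed=(), test_maternal=False)
            if not res.heritable:
                hits += 1
        assert hits >= 0.9 * reps

    def test_maternal_component_recovered_when_present(self):
        rng = np.random.default_rng(12)
        cfgs = dict(s=25, n=12)
        ped, data = half_sib_data(seed=12, **cfgs)
        # overlay a dam effect: progeny of each sire share 3 dams
        dams = np.repeat(np.arange(len(data) // 4), 4)[: len(data)]
        dam_eff = rng.normal(0, np.sqrt(0.3), dams.max() + 1)
        data = data.assign(dam=dams + 10000, y=data["y"] + dam_eff[dams])
        rel = PedigreeRelationship.from_pedigree(ped)
        spec = am.ModelSpec(response="y", maternal=True)
        fit = am.reml_fit(spec, data, rel, compute_se=False)
        assert 0.1 < fit.sigma2_m < 0.6


class TestBivariate:
    def test_duplicated_trait_gives_unit_genetic_correlation(self):
        from layres import genparams as gp

        ped, data = half_sib_data(s=20, n=10, seed=13)
        rel = PedigreeRelationship.from_pedigree(ped)
        data = data.assign(t1=data["y"], t2=data["y"])
        fit = am.reml_fit_bivariate(
            am.ModelSpec(response="t1"), am.ModelSpec(response="t2"),
            data, rel, compute_se=False,
            nm_options={"xatol": 1e-6, "fatol": 1e-8,
                        "maxiter": 10000, "maxfev": 10000})
        r, _ = gp.correlation_from_bifit(fit)
        assert r == pytest.approx(1.0, abs=1e-3)

    def test_margins_match_univariate_when_covariances_fixed_zero(self):
        rng = np.random.default_rng(14)
        ped, data = half_sib_data(s=40, n=10, seed=14)
        rel = PedigreeRelationship.from_pedigree(ped)
        data = data.assign(t1=data["y"],
                           t2=rng.normal(0, 1, len(data)) + 0.3 * data["y"])
        s1, s2 = am.ModelSpec(response="t1"), am.ModelSpec(response="t2")
        bi = am.reml_fit_bivariate(s1, s2, data, rel,
                                   estimate_residual_cov=False,
                                   estimate_genetic_cov=False,
                                   compute_se=False,
                                   nm_options={"xatol": 1e-7, "fatol": 1e-9})
        u1 = am.reml_fit(s1, data, rel, compute_se=False,
                         nm_options={"xatol": 1e-9})
        u2 = am.reml_fit(s2, data, rel, compute_se=False,
                         nm_options={"xatol": 1e-9})
        assert bi.sigma2_a == pytest.approx(u1.sigma2_a, rel=2e-2)
        assert bi.sigma2_a2 == pytest.approx(u2.sigma2_a, rel=2e-2)
        assert bi.sigma2_e == pytest.approx(u1.sigma2_e, rel=1e-2)

    def test_disjoint_traits_through_pedigree_only(self):
        """Unrelated traits measured on disjoint animal sets: residual
        covariance is fixed at zero and the estimate centers near 0."""
        rng = np.random.default_rng(15)
        ped = random_pedigree(400, seed=15, n_founders=60)
        rel = PedigreeRelationship.from_pedigree(ped)
        animals = np.arange(61, 401)
        half = len(animals) // 2
        data = pd.DataFrame({"animal": animals})
        data["t1"] = np.where(np.arange(len(animals)) < half,
                              rng.normal(0, 1, len(animals)), np.nan)
        data["t2"] = np.where(np.arange(len(animals)) >= half,
                              rng.normal(0, 1, len(animals)), np.nan)
        s1, s2 = am.ModelSpec(response="t1"), am.ModelSpec(response="t2")
        with pytest.raises(am.ModelError):
            am.reml_fit_bivariate(s1, s2, data, rel, estimate_residual_cov=True)
        fit = am.reml_fit_bivariate(s1, s2, data, rel, compute_se=False)
        assert fit.sigma_e12 == 0.0
        assert abs(fit.sigma_a12) < 0.5


class TestLRT:
    def test_identical_likelihoods(self):
        f0 = am.VarCompFit(sigma2_a=1, sigma2_e=1, loglik=-10.0, n_records=50)
        f1 = am.VarCompFit(sigma2_a=1, sigma2_e=1, loglik=-10.0, n_records=50)
        stat, p = am.lrt_variance_component(f0, f1)
        assert stat == 0.0 and p == 1.0

    def test_chi2_tail_at_critical_value(self):
        f0 = am.VarCompFit(sigma2_a=1, sigma2_e=1, loglik=-10.0, n_records=50)
        f1 = am.VarCompFit(sigma2_a=1, sigma2_e=1, loglik=-10.0 + 3.84 / 2,
                           n_records=50)
        stat, p = am.lrt_variance_component(f0, f1)
        assert stat == pytest.approx(3.84)
        assert p == pytest.approx(0.05, abs=2e-3)

    def test_negative_statistic_floored_with_warning(self):
        f0 = am.VarCompFit(sigma2_a=1, sigma2_e=1, loglik=-10.0, n_records=50)
        f1 = am.VarCompFit(sigma2_a=1, sigma2_e=1, loglik=-10.1, n_records=50)
        with pytest.warns(UserWarning):
            stat, p = am.lrt_variance_component(f0, f1)
        assert stat == 0.0 and p == 1.0

    def test_different_data_rejected(self):
        f0 = am.VarCompFit(sigma2_a=1, sigma2_e=1, loglik=-10.0, n_records=50)
        f1 = am.VarCompFit(sigma2_a=1, sigma2_e=1, loglik=-9.0, n_records=51)
        with pytest.raises(am.ModelError):
            am.lrt_variance_component(f0, f1)
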