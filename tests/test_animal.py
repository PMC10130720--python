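"""Animal model: design bundling, Gibbs recovery, REML oracle, DIC, r_G."""

import numpy as np
import pandas as pd
import pytest
from scipy import linalg, optimize

from wildqg.animal import (
    AnimalModel,
    GibbsPriors,
    TraitModelSpec,
    build_model_matrices,
    compare_naive_full,
    evolvability,
    heritability,
)
from wildqg.genotypes import impute_missing
from wildqg.relatedness import stabilize_for_inversion, vanraden_grm
from wildqg.simulate import (
    FamilyStructure,
    SimulationConfig,
    TraitParams,
    simulate_genotypes,
    simulate_phenotypes,
)

CHAIN = dict(n_iter=1500, burnin=400, thin=1)


def _tiny_dataset():
    return pd.DataFrame(
        {
            "plant_id": ["p1", "p1", "p2", "p2"],
            "site": ["s1"] * 4,
            "elevation_m": [100.0] * 4,
            "flower_idx": [1, 2, 1, 2],
            "y": [1.0, 1.2, 0.8, 0.9],
        }
    )


def _identity_grm(ids):
    from wildqg.relatedness import RelatednessMatrix

    return RelatednessMatrix(list(ids), np.eye(len(ids)), n_loci_used=100)


class TestDesignBundle:
    def test_dimensions(self):
        data = _tiny_dataset()
        bundle = build_model_matrices(
            data, TraitModelSpec(("y",)), _identity_grm(["p1", "p2"])
        )
        assert bundle.Z1.shape == (4, 2)
        assert bundle.Z3.shape == (4, 2)
        assert bundle.Z2.shape == (4, 1)
        # constant elevation (single site) is dropped from the fixed part
        assert bundle.X.shape == (4, 1)

    def test_naive_spec(self):
        data = _tiny_dataset()
        bundle = build_model_matrices(
            data, TraitModelSpec(("y",), naive=True), _identity_grm(["p1", "p2"])
        )
        assert bundle.X.shape == (4, 1)  # intercept only
        assert bundle.Z2 is None

    def test_missing_plant_listed(self):
        data = _tiny_dataset()
        with pytest.raises(KeyError, match="p2"):
            build_model_matrices(
                data, TraitModelSpec(("y",)), _identity_grm(["p1"])
            )

    def test_single_replicate_warns(self):
        data = _tiny_dataset().iloc[[0, 1, 2]]
        with pytest.warns(UserWarning, match="single replicate"):
            build_model_matrices(
                data, TraitModelSpec(("y",)), _identity_grm(["p1", "p2"])
            )


class TestDerivedQuantities:
    def test_h2_arithmetic(self):
        draws = pd.DataFrame(
            {"V_a": [1.0], "V_s": [1.0], "V_i": [1.0], "V_error": [1.0]}
        )
        assert heritability(draws).draws[0] == pytest.approx(0.25)

    def test_h2_zero_additive(self):
        draws = pd.DataFrame(
            {"V_a": [0.0, 0.0], "V_s": [1.0, 2.0], "V_i": [1.0, 1.0],
             "V_error": [1.0, 0.5]}
        )
        assert (heritability(draws).draws == 0).all()

    def test_h2_naive_without_site_column(self):
        draws = pd.DataFrame({"V_a": [1.0], "V_i": [1.0], "V_error": [2.0]})
        assert heritability(draws).draws[0] == pytest.approx(0.25)

    def test_evolvability_arithmetic(self):
        draws = pd.DataFrame({"V_a": [0.04]})
        assert evolvability(draws, 2.0).draws[0] == pytest.approx(1.0)  # 1%
        assert evolvability(pd.DataFrame({"V_a": [0.0]}), 3.0).draws[0] == 0.0

    def test_evolvability_requires_positive_mean(self):
        with pytest.raises(ValueError, match="positive"):
            evolvability(pd.DataFrame({"V_a": [1.0]}), 0.0)


def reml_fit(y, X, covs):
    """Direct REML maximization over variance components (oracle).

    ``covs`` maps component name -> n x n covariance kernel; an "e" identity
    term is appended automatically.
    """
    n = y.size
    p = X.shape[1]
    names = list(covs)

    def negloglik(log_v):
        v = np.exp(log_v)
        V = v[-1] * np.eye(n)
        for k, name in enumerate(names):
            V += v[k] * covs[name]
        try:
            cf = linalg.cho_factor(V)
        except linalg.LinAlgError:
            return 1e10
        logdet_v = 2.0 * np.sum(np.log(np.diag(cf[0])))
        Vi_X = linalg.cho_solve(cf, X)
        XtViX = X.T @ Vi_X
        Vi_y = linalg.cho_solve(cf, y)
        beta = np.linalg.solve(XtViX, X.T @ Vi_y)
        r = y - X @ beta
        Vi_r = linalg.cho_solve(cf, r)
        _, logdet_x = np.linalg.slogdet(XtViX)
        return 0.5 * (logdet_v + logdet_x + r @ Vi_r)

    x0 = np.log(np.full(len(names) + 1, y.var() / (len(names) + 1)))
    res = optimize.minimize(negloglik, x0, method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-8,
                                     "maxiter": 4000})
    v = np.exp(res.x)
    return dict(zip(names + ["e"], v))


@pytest.fixture(scope="module")
def sib_design():
    """Strong sibship design: 20 full-sib families of 4, high h2."""
    cfg = SimulationConfig(
        seed=515,
        n_sites=1,
        plants_per_site=80,
        flowers_per_plant=4,
        n_loci=600,
        elevation_per_site=(100.0,),
        family_structure=FamilyStructure(
            mean_sibship=4.0, migration=0.0, founders_per_site=40
        ),
    )
    cfg.traits = {
        "y": TraitParams(mean=10.0, v_a=2.0, v_s=0.0, v_i=1.0, v_error=1.0)
    }
    g = simulate_genotypes(cfg)
    phen, _, truth = simulate_phenotypes(g, cfg)
    grm = vanraden_grm(impute_missing(g))
    return phen, grm, truth


@pytest.fixture(scope="module")
def tiny_instance():
    """16 plants x 3 flowers, strong sibships: small enough for an exact
    posterior by quadrature."""
    cfg = SimulationConfig(
        seed=515, n_sites=1, plants_per_site=16, flowers_per_plant=3,
        n_loci=500, elevation_per_site=(100.0,),
        family_structure=FamilyStructure(
            mean_sibship=4.0, migration=0.0, founders_per_site=10
        ),
    )
    cfg.traits = {
        "y": TraitParams(mean=10.0, v_a=2.0, v_s=0.0, v_i=1.0, v_error=1.0)
    }
    g = simulate_genotypes(cfg)
    phen, _, _ = simulate_phenotypes(g, cfg)
    grm = vanraden_grm(impute_missing(g))
    bundle = build_model_matrices(phen, TraitModelSpec(("y",), naive=True), grm)
    G = stabilize_for_inversion(grm.subset(bundle.plant_ids)).values
    kernels = {
        "a": bundle.Z1 @ G @ bundle.Z1.T,
        "i": bundle.Z3 @ bundle.Z3.T,
    }
    return phen, grm, bundle, kernels


def exact_posterior_means(y, X, kernels, nu, s2, n_grid=36):
    """Posterior means of (V_a, V_i, V_e) by brute-force grid quadrature.

    Location effects are marginalized analytically (REML-style marginal
    likelihood); the same scaled-inverse-chi-squared priors as the sampler
    are applied on a log-spaced 3-D grid.
    """
    n = y.size
    vy = y.var(ddof=1)
    grid = np.exp(np.linspace(np.log(0.02 * vy), np.log(3.0 * vy), n_grid))
    K1, K2 = kernels["a"], kernels["i"]
    lw = np.empty((n_grid,) * 3)
    eye = np.eye(n)
    for i, va in enumerate(grid):
        for j, vi in enumerate(grid):
            for k, ve in enumerate(grid):
                V = va * K1 + vi * K2 + ve * eye
                cf = linalg.cho_factor(V)
                ld = 2.0 * np.sum(np.log(np.diag(cf[0])))
                ViX = linalg.cho_solve(cf, X)
                XtViX = X.T @ ViX
                beta = np.linalg.solve(XtViX, X.T @ linalg.cho_solve(cf, y))
                r = y - X @ beta
                _, ldx = np.linalg.slogdet(XtViX)
                ll = -0.5 * (ld + ldx + r @ linalg.cho_solve(cf, r))
                lp = sum(
                    -(nu / 2 + 1) * np.log(v) - nu * s2 / (2 * v)
                    for v in (va, vi, ve)
                )
                lw[i, j, k] = ll + lp
    lw -= lw.max()
    w = np.exp(lw) * np.multiply.outer(np.multiply.outer(grid, grid), grid)
    w /= w.sum()
    return {
        "a": float((w.sum(axis=(1, 2)) * grid).sum()),
        "i": float((w.sum(axis=(0, 2)) * grid).sum()),
        "e": float((w.sum(axis=(0, 1)) * grid).sum()),
    }


class TestUnivariateSampler:
    def test_exact_posterior_oracle(self, tiny_instance):
        """Gibbs posterior means match brute-force quadrature posterior means.

        Seed-averaged chains against an independent evaluation of the same
        posterior (location effects integrated analytically, variances on a
        log grid) — the definitive correctness check for the sampler.
        """
        phen, grm, bundle, kernels = tiny_instance
        vy = bundle.y[:, 0].var(ddof=1)
        oracle = exact_posterior_means(
            bundle.y[:, 0], bundle.X, kernels, nu=0.002, s2=vy / 4
        )
        pts = []
        for seed in (3, 4, 5):
            res = AnimalModel(phen, grm, "y", naive=True).fit(
                n_iter=8000, burnin=1500, seed=seed
            )
            pts.append(res.point[["V_a", "V_i", "V_error"]])
        avg = pd.concat(pts, axis=1).mean(axis=1)
        assert avg["V_a"] == pytest.approx(oracle["a"], rel=0.15)
        assert avg["V_i"] == pytest.approx(oracle["i"], rel=0.15)
        assert avg["V_error"] == pytest.approx(oracle["e"], rel=0.05)

    def test_reml_point_inside_posterior_interval(self, tiny_instance):
        """An independent REML fit falls inside the Gibbs 95% intervals."""
        phen, grm, bundle, kernels = tiny_instance
        oracle = reml_fit(bundle.y[:, 0], bundle.X, kernels)
        res = AnimalModel(phen, grm, "y", naive=True).fit(
            n_iter=6000, burnin=1000, seed=6
        )
        ci = res.ci95
        for comp, col in (("a", "V_a"), ("i", "V_i"), ("e", "V_error")):
            assert ci.loc[col, "lower"] <= oracle[comp] <= ci.loc[col, "upper"]

    def test_null_additive_variance(self, grm, study):
        """True V_a = 0: h2 posterior concentrates near zero."""
        cfg = SimulationConfig(seed=616, n_loci=400)
        cfg.traits = {
            "y": TraitParams(mean=20.0, v_a=0.0, v_s=5.0, v_i=3.0, v_error=2.0)
        }
        g = simulate_genotypes(cfg)
        phen, _, _ = simulate_phenotypes(g, cfg)
        res = AnimalModel(phen, vanraden_grm(g), "y", px=True).fit(
            seed=4, **CHAIN
        )
        lo, _ = res.heritability().ci95
        assert lo < 0.05

    def test_determinism_same_seed(self, sib_design):
        phen, grm, _ = sib_design
        a = AnimalModel(phen, grm, "y").fit(n_iter=300, burnin=100, seed=9)
        b = AnimalModel(phen, grm, "y").fit(n_iter=300, burnin=100, seed=9)
        pd.testing.assert_frame_equal(a.draws, b.draws)

    def test_row_shuffle_equivariance(self, sib_design):
        phen, grm, _ = sib_design
        shuffled = phen.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = AnimalModel(phen, grm, "y").fit(seed=11, **CHAIN)
        b = AnimalModel(shuffled, grm, "y").fit(seed=11, **CHAIN)
        assert a.heritability().mean == pytest.approx(
            b.heritability().mean, abs=0.06
        )

    def test_chain_invariance_across_seeds(self, study, grm):
        """Two chains with different seeds agree on the h2 posterior mean."""
        m = AnimalModel(study.phenotypes, grm, "flower_weight_mg")
        a = m.fit(n_iter=4000, burnin=800, seed=21)
        b = m.fit(n_iter=4000, burnin=800, seed=22)
        assert abs(a.heritability().mean - b.heritability().mean) < 0.02

    def test_draw_invariants(self, study, grm):
        res = AnimalModel(study.phenotypes, grm, "flower_weight_mg").fit(
            seed=5, **CHAIN
        )
        d = res.draws
        assert (d[["V_a", "V_s", "V_i", "V_error"]] >= 0).all().all()
        assert d["h2"].between(0, 1).all()
        assert res.ci95.loc["h2", "lower"] <= res.point["h2"] <= res.ci95.loc["h2", "upper"]

    def test_invalid_chain_settings(self, study, grm):
        m = AnimalModel(study.phenotypes, grm, "flower_weight_mg")
        with pytest.raises(ValueError):
            m.fit(n_iter=100, burnin=200)


@pytest.fixture(scope="module")
def bivariate_design():
    def make(rg, seed):
        cfg = SimulationConfig(
            seed=seed,
            plants_per_site=25,
            flowers_per_plant=3,
            n_loci=600,
            genetic_corr=rg,
            env_corr=0.3,
            family_structure=FamilyStructure(
                mean_sibship=4.0, migration=0.02, founders_per_site=20
            ),
        )
        cfg.traits = {
            "tA": TraitParams(mean=10.0, v_a=4.0, v_s=0.5, v_i=2.0, v_error=3.5),
            "tB": TraitParams(mean=20.0, v_a=4.0, v_s=0.5, v_i=2.0, v_error=3.5),
        }
        g = simulate_genotypes(cfg)
        phen, _, truth = simulate_phenotypes(g, cfg)
        return phen, vanraden_grm(g), truth

    return make


class TestBivariateSampler:
    def test_rg_recovery(self, bivariate_design):
        phen, grm, truth = bivariate_design(0.8, 881)
        res = AnimalModel(phen, grm, ("tA", "tB")).fit(
            n_iter=1200, burnin=300, seed=7
        )
        rg = res.genetic_correlation()
        assert rg.mean == pytest.approx(truth["realized_genetic_corr"], abs=0.15)
        assert (np.abs(res.draws["r_G"]) <= 1).all()

    def test_null_genetic_correlation(self, bivariate_design):
        phen, grm, _ = bivariate_design(0.0, 882)
        res = AnimalModel(phen, grm, ("tA", "tB")).fit(
            n_iter=1000, burnin=300, seed=8
        )
        lo, hi = res.genetic_correlation().ci95
        assert lo < 0.0 < hi

    def test_h2_per_trait_draws(self, bivariate_design):
        phen, grm, _ = bivariate_design(0.0, 882)
        res = AnimalModel(phen, grm, ("tA", "tB")).fit(
            n_iter=600, burnin=200, seed=9
        )
        assert res.draws["t1_h2"].between(0, 1).all()
        h2a = res.heritability("tA")
        assert 0 <= h2a.mean <= 1
        with pytest.raises(ValueError, match="specify"):
            res.heritability()

    def test_zero_variance_trait_rejected(self, grm, study):
        phen = study.phenotypes.copy()
        phen["flat"] = 1.0
        with pytest.raises(ValueError, match="zero variance"):
            AnimalModel(phen, grm, ("flower_weight_mg", "flat")).fit(
                n_iter=200, burnin=50
            )


class TestModelComparison:
    def test_identical_specs_small_delta(self, study, grm):
        m = AnimalModel(study.phenotypes, grm, "flower_weight_mg")
        a = m.fit(seed=31, **CHAIN)
        b = m.fit(seed=32, **CHAIN)
        assert abs(a.dic - b.dic) < 20  # Monte Carlo error only

    def test_no_site_effects_small_delta(self):
        cfg = SimulationConfig(seed=909, n_loci=300)
        cfg.traits = {
            "y": TraitParams(mean=15.0, v_a=2.0, v_s=0.0, v_i=2.0,
                             v_error=2.0, elevation_slope=0.0)
        }
        g = simulate_genotypes(cfg)
        phen, _, _ = simulate_phenotypes(g, cfg)
        cmp = compare_naive_full(
            phen, vanraden_grm(g), "y", seed=12, **CHAIN
        )
        assert abs(cmp["delta_dic"]) < 25

    def test_summary_renders(self, study, grm):
        res = AnimalModel(study.phenotypes, grm, "flower_weight_mg").fit(
            n_iter=400, burnin=100, seed=2
        )
        text = res.summary()
        assert "V_a" in text and "h2[" in text and "DIC" in text
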