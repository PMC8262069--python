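import numpy as np
import pytest

from epiblup.kernels import Kernel, KernelSet, build_kernel_set
from epiblup.reml import (
    MixedModelSpec,
    aic,
    fit_reml,
    predict_unphenotyped,
    restricted_loglik,
    variance_proportions,
)
from epiblup import simulate_effects, simulate_genotypes, simulate_phenotypes


def random_kernel(n, n_snps, seed, name="A"):
    rng = np.random.default_rng(seed)
    W = rng.standard_normal((n, n_snps))
    K = W @ W.T
    return Kernel(name, K * n / np.trace(K), [f"a{i}" for i in range(n)])


def random_instance(n, n_kernels, seed, h2=0.5):
    rng = np.random.default_rng(seed)
    kernels = KernelSet(
        {
            nm: random_kernel(n, n + 5, seed + 13 * i, nm)
            for i, nm in enumerate(["A", "AA"][:n_kernels])
        }
    )
    y = rng.standard_normal(n) * np.sqrt(1 - h2)
    for k in kernels.values():
        L = np.linalg.cholesky(k.matrix + 1e-10 * np.eye(n))
        y = y + np.sqrt(h2 / n_kernels) * (L @ rng.standard_normal(n))
    X = np.column_stack([np.ones(n), rng.standard_normal(n)])
    return MixedModelSpec(y=y, X=X, kernels=kernels, obs_indices=np.arange(n))


class TestRestrictedLoglik:
    def test_null_model_closed_form(self):
        rng = np.random.default_rng(2)
        y = rng.standard_normal(25) * 1.7 + 3.0
        spec = MixedModelSpec(
            y=y, X=np.ones((25, 1)), kernels=KernelSet(), obs_indices=np.arange(25)
        )
        fit = fit_reml(spec)
        assert fit.varcomps["residual"][0] == pytest.approx(
            y.var(ddof=1), rel=1e-6
        )

    def test_translation_invariance(self):
        spec = random_instance(15, 1, seed=3)
        ll1 = restricted_loglik(spec, [0.4, 0.6])
        shifted = MixedModelSpec(
            y=spec.y + 100.0,
            X=spec.X,
            kernels=spec.kernels,
            obs_indices=spec.obs_indices,
        )
        ll2 = restricted_loglik(shifted, [0.4, 0.6])
        assert ll1 == pytest.approx(ll2, abs=1e-8)

    def test_grid_oracle_single_kernel(self):
        spec = random_instance(12, 1, seed=5)
        fit = fit_reml(spec)
        grid = np.linspace(0.01, 4.0, 100)
        best = max(
            restricted_loglik(spec, [a, e]) for a in grid for e in grid
        )
        assert fit.loglik_restricted >= best - 1e-4

    def test_wrong_sigma_count_rejected(self):
        spec = random_instance(10, 1, seed=6)
        with pytest.raises(ValueError, match="variance components"):
            restricted_loglik(spec, [1.0])

    def test_negative_sigma_rejected(self):
        spec = random_instance(10, 1, seed=6)
        with pytest.raises(ValueError):
            restricted_loglik(spec, [-0.1, 1.0])

    def test_rank_deficient_design_rejected(self):
        n = 10
        X = np.column_stack([np.ones(n), np.ones(n)])
        with pytest.raises(ValueError, match="rank"):
            MixedModelSpec(
                y=np.zeros(n), X=X, kernels=KernelSet(), obs_indices=np.arange(n)
            )


class TestFitReml:
    def test_parameter_recovery_small(self):
        # truth {A: 0.45, AA: 0.15, E: 0.40}; modest n, a few seeds
        props = []
        for seed in range(3):
            g = simulate_genotypes(25, 30, 1200, seed=seed + 60, full_sibs=True)
            eff = simulate_effects(
                g, {"A": 0.45, "AA": 0.15}, seed=seed, aa_mode="mvn_kernel"
            )
            ph = simulate_phenotypes(g, eff, residual_fraction=0.4, seed=seed)
            ks = build_kernel_set(g, which=("A", "AA"))
            spec = MixedModelSpec(
                y=ph["trait_value"].to_numpy(),
                X=np.ones((g.n_animals, 1)),
                kernels=ks,
                obs_indices=np.arange(g.n_animals),
            )
            fit = fit_reml(spec)
            assert fit.converged
            p = variance_proportions(fit)
            props.append([p["A"][0], p["AA"][0]])
        mean = np.mean(props, axis=0)
        assert mean[0] == pytest.approx(0.45, abs=0.12)
        assert mean[1] == pytest.approx(0.15, abs=0.12)

    def test_pure_noise_gives_null_additive_share(self, halfsib_g):
        # under the null the non-negativity constraint piles estimates at 0;
        # with an informative family kernel the mean share stays near zero
        ks = build_kernel_set(halfsib_g, which=("A",))
        n = halfsib_g.n_animals
        shares = []
        for seed in range(20):
            rng = np.random.default_rng(seed + 500)
            y = rng.standard_normal(n)
            spec = MixedModelSpec(
                y=y, X=np.ones((n, 1)), kernels=ks, obs_indices=np.arange(n)
            )
            fit = fit_reml(spec)
            shares.append(fit.varcomps["A"][0] / fit.total_variance())
        shares = np.asarray(shares)
        mc_se = shares.std(ddof=1) / np.sqrt(len(shares))
        assert shares.mean() < 2 * mc_se + 0.02

    def test_exchangeability_under_permutation(self):
        spec = random_instance(30, 2, seed=8)
        fit = fit_reml(spec)
        rng = np.random.default_rng(0)
        perm = rng.permutation(30)
        kernels = KernelSet(
            {
                nm: Kernel(
                    nm,
                    k.matrix[np.ix_(perm, perm)],
                    [k.animal_ids[i] for i in perm],
                )
                for nm, k in spec.kernels.items()
            }
        )
        inv = np.argsort(perm)
        spec_p = MixedModelSpec(
            y=spec.y[perm],
            X=spec.X[perm],
            kernels=kernels,
            obs_indices=inv[spec.obs_indices][perm],
        )
        fit_p = fit_reml(spec_p)
        for nm in fit.varcomps:
            assert fit_p.varcomps[nm][0] == pytest.approx(
                fit.varcomps[nm][0], abs=1e-6
            )
        for nm in fit.blups:
            assert np.allclose(fit_p.blups[nm], fit.blups[nm][perm], atol=1e-6)

    def test_residual_identity(self):
        spec = random_instance(25, 1, seed=9)
        fit = fit_reml(spec)
        recon = spec.X @ fit.beta + fit.blups["A"][spec.obs_indices] + fit.residuals
        assert np.allclose(recon, spec.y, atol=1e-10)

    def test_nonconvergence_flagged(self):
        spec = random_instance(40, 2, seed=10)
        fit = fit_reml(spec, max_iter=1)
        assert fit.n_iter == 1
        assert fit.final_gradient_norm >= 0.0
        full = fit_reml(spec)
        assert full.converged

    def test_independent_copy_duplication_consistency(self):
        # appending an independent replicate of the population leaves the
        # variance-component estimates nearly unchanged (tolerance from a
        # numerical oracle run of the same construction)
        rng = np.random.default_rng(7)
        n = 50
        k = random_kernel(n, 80, 77)
        L = np.linalg.cholesky(k.matrix + 1e-10 * np.eye(n))
        y = 0.5 + 0.8 * (L @ rng.standard_normal(n)) + 0.7 * rng.standard_normal(n)
        spec = MixedModelSpec(
            y=y,
            X=np.ones((n, 1)),
            kernels=KernelSet({"A": k}),
            obs_indices=np.arange(n),
        )
        fit0 = fit_reml(spec)
        K2 = np.block(
            [[k.matrix, np.zeros((n, n))], [np.zeros((n, n)), k.matrix]]
        )
        ids2 = k.animal_ids + [f"b{i}" for i in range(n)]
        spec2 = MixedModelSpec(
            y=np.concatenate([y, y]),
            X=np.ones((2 * n, 1)),
            kernels=KernelSet({"A": Kernel("A", K2, ids2)}),
            obs_indices=np.arange(2 * n),
        )
        fit2 = fit_reml(spec2)
        for nm in ("A", "residual"):
            assert fit2.varcomps[nm][0] == pytest.approx(
                fit0.varcomps[nm][0], abs=0.02
            )

    def test_boundary_component_flagged_with_nan_se(self):
        rng = np.random.default_rng(11)
        n = 60
        y = rng.standard_normal(n)  # no genetic signal at all
        k = random_kernel(n, 100, 123)
        spec = MixedModelSpec(
            y=y,
            X=np.ones((n, 1)),
            kernels=KernelSet({"A": k}),
            obs_indices=np.arange(n),
        )
        fit = fit_reml(spec)
        if fit.boundary["A"]:
            assert np.isnan(fit.varcomps["A"][1])


class TestAic:
    def test_arithmetic(self):
        spec = random_instance(20, 1, seed=12)
        fit = fit_reml(spec)
        assert aic(fit) == pytest.approx(-2 * fit.loglik_restricted + 2 * 2)

    def test_loglik_monotone_in_nesting(self):
        spec2 = random_instance(30, 2, seed=13)
        spec1 = MixedModelSpec(
            y=spec2.y,
            X=spec2.X,
            kernels=KernelSet({"A": spec2.kernels["A"]}),
            obs_indices=spec2.obs_indices,
        )
        ll1 = fit_reml(spec1).loglik_restricted
        ll2 = fit_reml(spec2).loglik_restricted
        assert ll2 >= ll1 - 1e-3

    def test_aic_ranking_on_additive_architecture(self):
        # with purely additive truth, AIC should favour the single-kernel
        # model over the two-kernel model in the majority of seeds
        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            g = simulate_genotypes(10, 25, 600, seed=seed + 700)
            eff = simulate_effects(g, {"A": 0.4}, seed=seed)
            ph = simulate_phenotypes(g, eff, residual_fraction=0.6, seed=seed)
            ks = build_kernel_set(g, which=("A", "AA"))
            y = ph["trait_value"].to_numpy()
            X = np.ones((g.n_animals, 1))
            ix = np.arange(g.n_animals)
            fit_a = fit_reml(
                MixedModelSpec(
                    y=y, X=X, kernels=KernelSet({"A": ks["A"]}), obs_indices=ix
                )
            )
            fit_aa = fit_reml(
                MixedModelSpec(y=y, X=X, kernels=ks, obs_indices=ix)
            )
            if fit_a.aic <= fit_aa.aic:
                wins += 1
        assert wins > n_seeds / 2


class TestVarianceProportions:
    def test_sum_to_one(self):
        fit = fit_reml(random_instance(25, 2, seed=14))
        props = variance_proportions(fit)
        assert sum(p for p, _ in props.values()) == pytest.approx(1.0, abs=1e-12)

    def test_single_kernel_formula(self):
        fit = fit_reml(random_instance(25, 1, seed=15))
        props = variance_proportions(fit)
        sa = fit.varcomps["A"][0]
        se = fit.varcomps["residual"][0]
        assert props["A"][0] == pytest.approx(sa / (sa + se), rel=1e-12)

    def test_delta_se_close_to_parametric_bootstrap(self):
        # oracle: refit on data re-simulated from the fitted model
        n = 500
        g = simulate_genotypes(25, 20, 800, seed=42)
        ks = build_kernel_set(g, which=("A",))
        K = ks["A"].matrix
        rng = np.random.default_rng(43)
        L = np.linalg.cholesky(K + 1e-10 * np.eye(n))
        sa_true, se_true = 0.5, 0.5
        y = np.sqrt(sa_true) * (L @ rng.standard_normal(n)) + np.sqrt(
            se_true
        ) * rng.standard_normal(n)
        X = np.ones((n, 1))
        ix = np.arange(n)
        fit = fit_reml(MixedModelSpec(y=y, X=X, kernels=ks, obs_indices=ix))
        p_hat = variance_proportions(fit)["A"]
        sa, se_ = fit.varcomps["A"][0], fit.varcomps["residual"][0]
        boots = []
        for b in range(120):
            yb = np.sqrt(sa) * (L @ rng.standard_normal(n)) + np.sqrt(
                se_
            ) * rng.standard_normal(n)
            fb = fit_reml(
                MixedModelSpec(y=yb, X=X, kernels=ks, obs_indices=ix)
            )
            boots.append(variance_proportions(fb)["A"][0])
        boot_se = np.std(boots, ddof=1)
        assert p_hat[1] == pytest.approx(boot_se, rel=0.3)


class TestPredictUnphenotyped:
    def test_phenotyped_target_matches_in_fit_blup(self):
        spec = random_instance(20, 1, seed=16)
        fit = fit_reml(spec)
        target = spec.kernels.animal_ids[3]
        pred = predict_unphenotyped(fit, [target])
        assert pred["A"][0] == pytest.approx(fit.blups["A"][3], abs=1e-12)

    def test_zero_covariance_target_predicts_zero(self):
        n = 12
        K = np.eye(n + 1)
        K[:n, :n] = random_kernel(n, 30, seed=17).matrix
        K = K * (n + 1) / np.trace(K)
        ids = [f"a{i}" for i in range(n + 1)]
        kernels = KernelSet({"A": Kernel("A", K, ids)})
        rng = np.random.default_rng(18)
        spec = MixedModelSpec(
            y=rng.standard_normal(n),
            X=np.ones((n, 1)),
            kernels=kernels,
            obs_indices=np.arange(n),
        )
        fit = fit_reml(spec)
        pred = predict_unphenotyped(fit, [ids[-1]])
        assert pred["A"][0] == pytest.approx(0.0, abs=1e-12)
        assert pred["total"][0] == pytest.approx(0.0, abs=1e-12)

    def test_missing_target_named(self):
        fit = fit_reml(random_instance(10, 1, seed=19))
        with pytest.raises(KeyError, match="nope"):
            predict_unphenotyped(fit, ["nope"])

    def test_agrees_with_mixed_model_equations(self):
        # Henderson's MME as an independent oracle on a 40-animal instance
        n, n_unobs = 40, 8
        rng = np.random.default_rng(20)
        W = rng.standard_normal((n, 60))
        K = W @ W.T + 0.05 * np.eye(n)  # full rank so K^-1 exists
        K = K * n / np.trace(K)
        ids = [f"a{i}" for i in range(n)]
        kernels = KernelSet({"A": Kernel("A", K, ids)})
        obs = np.arange(n - n_unobs)
        L = np.linalg.cholesky(K)
        u = L @ rng.standard_normal(n)
        y = 1.0 + u[obs] + rng.standard_normal(obs.size)
        X = np.ones((obs.size, 1))
        spec = MixedModelSpec(y=y, X=X, kernels=kernels, obs_indices=obs)
        fit = fit_reml(spec)
        sa, se = fit.varcomps["A"][0], fit.varcomps["residual"][0]
        Z = np.zeros((obs.size, n))
        Z[np.arange(obs.size), obs] = 1.0
        lam = se / sa
        lhs = np.block(
            [
                [X.T @ X, X.T @ Z],
                [Z.T @ X, Z.T @ Z + lam * np.linalg.inv(K)],
            ]
        )
        rhs = np.concatenate([X.T @ y, Z.T @ y])
        sol = np.linalg.solve(lhs, rhs)
        u_mme = sol[1:]
        pred = predict_unphenotyped(fit, ids)
        assert np.allclose(pred["A"], u_mme, atol=1e-8)
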