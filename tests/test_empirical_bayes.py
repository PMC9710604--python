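import numpy as np
import pytest

from recombat import (
    DesignSpec,
    ExpressionMatrix,
    RegularizationConfig,
    SampleMetadata,
    SimulationConfig,
    adjust,
    encode_design,
    estimate_batch_effects,
    estimate_prior_hyperparameters,
    fit_linear_model,
    recombat,
    simulate,
    standardize,
)
from recombat.empirical_bayes import PriorHyperparams, StandardizedData

from combat_reference import combat_reference


def _two_batch_design(n_per_batch, n_genes, seed=0):
    n = 2 * n_per_batch
    meta = SampleMetadata(
        sample_ids=[f"s{i}" for i in range(n)],
        columns={"batch": ["b1"] * n_per_batch + ["b2"] * n_per_batch},
        batch_column="batch",
    )
    d = encode_design(meta, DesignSpec(batch_column="batch"))
    return meta, d


def _numeric_spec(ds):
    """Declare the simulator's binary features numeric -> full-rank design."""
    cols = [f"f{i}" for i in range(ds.config.n_design_features)]
    return DesignSpec(batch_column="batch", desired_columns=cols, numeric_columns=cols)


def _fit_on(ds, lam1=0.0, lam2=1e-9, numeric=False):
    spec = _numeric_spec(ds) if numeric else ds.design_spec()
    d = encode_design(ds.metadata, spec)
    fit = fit_linear_model(ds.observed, d, RegularizationConfig(lam1, lam2))
    return d, fit


class TestStandardize:
    def test_noiseless_data_hits_zero_variance_error(self):
        # batch-means-only model fits noiseless data exactly: residuals 0
        meta, d = _two_batch_design(5, 10)
        Y = ExpressionMatrix(
            np.tile(np.arange(10.0), (10, 1)), meta.sample_ids,
            [f"g{k}" for k in range(10)],
        )
        fit = fit_linear_model(Y, d, RegularizationConfig(0.0, 0.0))
        with pytest.raises(ValueError, match="zero residual variance"):
            standardize(Y, fit, d)

    def test_pooled_moments_near_standard_on_pure_noise(self):
        # gamma = 0, delta^2 = 1: Z estimates plain standard noise
        ds = simulate(
            SimulationConfig(
                n_samples=500, n_batches=5, n_zero_hops=8, n_genes=50,
                additive_batch_sd=0.0, multiplicative_scale=0.0, seed=3,
            )
        )
        d, fit = _fit_on(ds, 0.0, 0.0, numeric=True)
        s = standardize(ds.observed, fit, d)
        assert np.abs(s.Z.mean(axis=0)).max() < 0.2
        assert np.abs(s.Z.var(axis=0) - 1.0).max() < 0.3

    def test_scale_equivariance(self, sim_small):
        ds = sim_small
        d = encode_design(ds.metadata, _numeric_spec(ds))
        fit1 = fit_linear_model(ds.observed, d, RegularizationConfig(0.0, 0.0))
        doubled = ExpressionMatrix(
            2.0 * ds.observed.values, ds.observed.sample_ids, ds.observed.gene_ids
        )
        fit2 = fit_linear_model(doubled, d, RegularizationConfig(0.0, 0.0))
        s1 = standardize(ds.observed, fit1, d)
        s2 = standardize(doubled, fit2, d)
        np.testing.assert_allclose(s2.sigma_hat, 2.0 * s1.sigma_hat, rtol=1e-10)
        np.testing.assert_allclose(s2.Z, s1.Z, atol=1e-10)


class TestPriorEstimation:
    def _standardized(self, Z, d):
        return StandardizedData(
            Z=Z,
            sigma_hat=np.ones(Z.shape[1]),
            retained=np.ones(Z.shape[1], dtype=bool),
            gene_ids=[f"g{k}" for k in range(Z.shape[1])],
            fit_fingerprint=d.fingerprint(),
        )

    def test_moment_matching_recovers_simulated_priors(self):
        """Batch means ~ N(2, 0.25) and variances ~ InvGamma(3, 2) are
        recovered by the moment-matched hyperparameters (frozen seed)."""
        rng = np.random.default_rng(21)
        g = 5000
        v = 2.0 / rng.gamma(3.0, 1.0, size=g)          # InvGamma(3, 2)
        gam = rng.normal(2.0, 0.5, size=2000)
        # batch b1: 2 samples per gene with exact mean gam_k, variance v_k
        half = np.sqrt(v[:2000] / 2.0)
        z_b1 = np.stack([gam + half[:2000], gam - half[:2000]])
        meta, d = _two_batch_design(2, 2000)
        Z = np.vstack([z_b1, rng.normal(size=(2, 2000))])
        priors = estimate_prior_hyperparameters(self._standardized(Z, d), d)
        assert priors.gamma_bar[0] == pytest.approx(1.9936, abs=0.034)
        assert priors.tau_sq[0] == pytest.approx(0.2518, abs=0.03)
        # inverse-gamma matching on the full 5000 draws, checked directly
        vbar, s2 = v.mean(), v.var(ddof=1)
        assert (vbar**2 + 2 * s2) / s2 == pytest.approx(3.0, rel=0.25)
        assert (vbar**3 + vbar * s2) / s2 == pytest.approx(2.0, rel=0.25)

    def test_constant_batch_means_give_zero_tau(self):
        rng = np.random.default_rng(1)
        meta, d = _two_batch_design(3, 20)
        base = rng.normal(size=(6, 20))
        Z = base - base[:3].mean(axis=0) + 2.5  # batch-b1 means all exactly 2.5
        Z[3:] = rng.normal(size=(3, 20))
        priors = estimate_prior_hyperparameters(self._standardized(Z, d), d)
        assert priors.gamma_bar[0] == pytest.approx(2.5, abs=1e-10)
        assert priors.tau_sq[0] == pytest.approx(0.0, abs=1e-20)

    def test_singleton_batch_rejected_with_guidance(self):
        meta = SampleMetadata(
            sample_ids=["s0", "s1", "s2"],
            columns={"batch": ["b1", "b1", "b2"]},
            batch_column="batch",
        )
        d = encode_design(meta, DesignSpec(batch_column="batch"))
        Z = np.random.default_rng(0).normal(size=(3, 5))
        with pytest.raises(ValueError, match="at least 2"):
            estimate_prior_hyperparameters(self._standardized(Z, d), d)


class TestBatchEffectEstimates:
    def _setup(self, seed=2, n_per_batch=4, g=6):
        rng = np.random.default_rng(seed)
        meta, d = _two_batch_design(n_per_batch, g)
        Z = rng.normal(size=(2 * n_per_batch, g)) + 1.0
        s = StandardizedData(
            Z=Z, sigma_hat=np.ones(g), retained=np.ones(g, dtype=bool),
            gene_ids=[f"g{k}" for k in range(g)], fit_fingerprint=d.fingerprint(),
        )
        priors = estimate_prior_hyperparameters(s, d)
        return s, d, priors

    def test_infinite_tau_keeps_naive_estimates(self):
        s, d, priors = self._setup()
        priors.tau_sq[:] = 1e12
        est = estimate_batch_effects(s, d, priors)
        np.testing.assert_allclose(est.gamma_star, priors.gamma_hat, atol=1e-4)

    def test_zero_tau_collapses_to_prior_mean(self):
        s, d, priors = self._setup()
        priors.tau_sq[:] = 0.0
        est = estimate_batch_effects(s, d, priors)
        for i in range(2):
            np.testing.assert_array_equal(
                est.gamma_star[i], np.full(6, priors.gamma_bar[i])
            )

    def test_fixed_point_matches_brute_force_iteration(self):
        """The vectorized solver lands on the same fixed point as a plain
        scalar-loop alternating iteration run to 10 000 steps."""
        s, d, priors = self._setup(seed=5, n_per_batch=4, g=3)
        est = estimate_batch_effects(s, d, priors, tol=1e-12, max_iter=10_000)
        idx = d.batch_index
        for i in range(2):
            Zi = s.Z[idx == i]
            ni = Zi.shape[0]
            for k in range(3):
                g_star = priors.gamma_hat[i, k]
                d_star = priors.batch_var[i, k]
                for _ in range(10_000):
                    g_star = (
                        ni * priors.tau_sq[i] * priors.gamma_hat[i, k]
                        + d_star * priors.gamma_bar[i]
                    ) / (ni * priors.tau_sq[i] + d_star)
                    d_star = (
                        priors.theta_bar[i] + 0.5 * ((Zi[:, k] - g_star) ** 2).sum()
                    ) / (ni / 2.0 + priors.lambda_bar[i] - 1.0)
                assert est.gamma_star[i, k] == pytest.approx(g_star, abs=1e-9)
                assert est.delta_sq_star[i, k] == pytest.approx(d_star, rel=1e-9)

    def test_posterior_variance_positive_and_converged(self, sim_small):
        ds = sim_small
        d, fit = _fit_on(ds)
        s = standardize(ds.observed, fit, d)
        priors = estimate_prior_hyperparameters(s, d)
        est = estimate_batch_effects(s, d, priors)
        assert (est.delta_sq_star > 0).all()
        assert all(est.converged.values())

    def test_shrinkage_brackets_naive_and_prior_mean(self, sim_small):
        ds = sim_small
        d, fit = _fit_on(ds)
        s = standardize(ds.observed, fit, d)
        priors = estimate_prior_hyperparameters(s, d)
        est = estimate_batch_effects(s, d, priors)
        lo = np.minimum(priors.gamma_hat, priors.gamma_bar[:, None])
        hi = np.maximum(priors.gamma_hat, priors.gamma_bar[:, None])
        assert (est.gamma_star >= lo - 1e-10).all()
        assert (est.gamma_star <= hi + 1e-10).all()


class TestAdjust:
    def test_identity_when_no_batch_effect_estimated(self, sim_small):
        ds = sim_small
        d, fit = _fit_on(ds)
        s = standardize(ds.observed, fit, d)
        priors = estimate_prior_hyperparameters(s, d)
        est = estimate_batch_effects(s, d, priors)
        est.gamma_star[:] = 0.0
        est.delta_sq_star[:] = 1.0
        out = adjust(ds.observed, s, est, fit, d)
        np.testing.assert_allclose(out.values, ds.observed.values, atol=1e-10)

    def test_additive_offset_removed(self):
        """A +3 shift on batch 2 collapses to near zero after correction."""
        rng = np.random.default_rng(17)
        n, g = 200, 100
        meta = SampleMetadata(
            sample_ids=[f"s{i}" for i in range(n)],
            columns={"batch": ["b1"] * 100 + ["b2"] * 100},
            batch_column="batch",
        )
        spec = DesignSpec(batch_column="batch")
        vals = rng.normal(size=(n, g))
        vals[100:] += 3.0
        Y = ExpressionMatrix(vals, meta.sample_ids, [f"g{k}" for k in range(g)])
        out = recombat(Y, meta, spec, RegularizationConfig(0.0, 1e-9))
        diff = out.values[100:].mean(axis=0) - out.values[:100].mean(axis=0)
        before = vals[100:].mean(axis=0) - vals[:100].mean(axis=0)
        assert np.abs(before).mean() > 2.5
        assert np.abs(diff).mean() < 0.1
        assert np.abs(diff).max() < 0.5


class TestRecombatPipeline:
    def test_matches_independent_classic_combat_on_full_rank_design(self):
        """With no regularization on a full-rank design the whole pipeline
        equals an independently coded OLS + parametric-EB reference."""
        ds = simulate(
            SimulationConfig(
                n_samples=120, n_batches=3, n_design_features=2, n_zero_hops=4,
                n_genes=40, seed=29,
            )
        )
        spec = DesignSpec(
            batch_column="batch",
            desired_columns=["f0", "f1"],
            numeric_columns=["f0", "f1"],
        )
        out = recombat(
            ds.observed, ds.metadata, spec, RegularizationConfig(0.0, 0.0),
            eb_tol=1e-10,
        )
        d = encode_design(ds.metadata, spec)
        ref = combat_reference(
            ds.observed.values,
            d.matrix,
            d.batch_index,
            d.n_batches,
            d.columns_with_role("batch"),
            d.columns_with_role("desired"),
            eb_tol=1e-12,
        )
        np.testing.assert_allclose(out.values, ref, rtol=1e-6, atol=1e-8)

    def test_permutation_equivariance(self, sim_small):
        ds = sim_small
        spec = ds.design_spec()
        out = recombat(ds.observed, ds.metadata, spec)
        rng = np.random.default_rng(4)
        perm = rng.permutation(ds.observed.n_samples)
        ids_p = [ds.observed.sample_ids[i] for i in perm]
        Yp = ExpressionMatrix(
            ds.observed.values[perm], ids_p, list(ds.observed.gene_ids)
        )
        out_p = recombat(Yp, ds.metadata.subset(ids_p), spec)
        np.testing.assert_allclose(out_p.values, out.values[perm], atol=1e-8)

    def test_unwanted_covariate_restored_by_default_dropped_on_request(self):
        rng = np.random.default_rng(31)
        n, g = 120, 30
        lab = ["L1"] * 60 + ["L2"] * 60
        meta = SampleMetadata(
            sample_ids=[f"s{i}" for i in range(n)],
            columns={
                "batch": (["b1"] * 30 + ["b2"] * 30) * 2,
                "lab": lab,
                "cond": [float(i % 2) for i in range(n)],
            },
            batch_column="batch",
        )
        spec = DesignSpec(
            batch_column="batch",
            desired_columns=["cond"],
            unwanted_columns=["lab"],
            numeric_columns=["cond"],
        )
        vals = rng.normal(size=(n, g))
        vals[np.array(lab) == "L2"] += 2.0
        Y = ExpressionMatrix(vals, meta.sample_ids, [f"g{k}" for k in range(g)])
        kept = recombat(Y, meta, spec, RegularizationConfig(0.0, 1e-9))
        dropped = recombat(
            Y, meta, spec, RegularizationConfig(0.0, 1e-9), drop_unwanted=True
        )
        sel = np.array(lab) == "L2"
        gap_kept = kept.values[sel].mean() - kept.values[~sel].mean()
        gap_dropped = dropped.values[sel].mean() - dropped.values[~sel].mean()
        assert gap_kept > 1.5  # lab effect restored
        assert abs(gap_dropped) < 0.3  # lab effect regressed out

    def test_stage_name_prepended_on_failure(self):
        meta = SampleMetadata(
            sample_ids=["s0", "s1", "s2"],
            columns={"batch": ["b1", "b1", "b2"]},
            batch_column="batch",
        )
        Y = ExpressionMatrix(
            np.zeros((3, 4)), ["s0", "s1", "s2"], list("abcd")
        )
        with pytest.raises(ValueError, match=r"\[standardize\]"):
            recombat(Y, meta, DesignSpec(batch_column="batch"))


@pytest.mark.parametrize("n_genes", [1])
def test_single_gene_degenerate_priors_pass_through(n_genes):
    """With one gene there is no across-gene pooling: priors are degenerate
    and the naive estimates are used unshrunk, still finite."""
    ds = simulate(
        SimulationConfig(
            n_samples=60, n_batches=3, n_zero_hops=4, n_genes=n_genes, seed=7
        )
    )
    with pytest.warns(UserWarning, match="degenerate"):
        out = recombat(ds.observed, ds.metadata, ds.design_spec())
    assert np.isfinite(out.values).all()
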