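"""Parametric empirical-Bayes batch-effect estimation and adjustment.

After the location model is fitted, the algorithm proceeds in three steps:

1. **Standardize.**  Z = (Y - alpha - X beta_x - C beta_c) / sigma, where
   sigma_k is the per-gene standard deviation of the *full*-model residuals
   (batch term included), pooled over all N samples with divisor N.  Z then
   carries only the batch effects plus unit-scale noise.

2. **Shrink.**  Per batch i and gene k, the naive estimates are the batch
   mean gamma_hat_ik of Z and the batch sample variance.  Pooling across
   genes, the additive effects are given a Normal(gamma_bar_i, tau2_i)
   prior and the variances an InverseGamma(lambda_i, theta_i) prior, both
   moment-matched.  The posterior estimates (gamma*, delta2*) are the fixed
   point of the conditional-posterior-mean iteration

       gamma*  = (n_i tau2 gamma_hat + delta2* gamma_bar) / (n_i tau2 + delta2*)
       delta2* = (theta + 0.5 sum_j (Z_jk - gamma*)^2) / (n_i/2 + lambda - 1).

3. **Adjust.**  Y~ = sigma/delta* (Z - gamma*) + alpha + X beta_x [+ C beta_c];
   the biological design is restored, the batch terms are removed.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_io import ExpressionMatrix, SampleMetadata, align
from .design import DesignSpec, EncodedDesign, encode_design, rank_diagnostics
from .regression import (
    LinearModelFit,
    RegularizationConfig,
    fit_linear_model,
    predict_mean,
)

__all__ = [
    "StandardizedData",
    "PriorHyperparams",
    "BatchEffectEstimates",
    "standardize",
    "estimate_prior_hyperparameters",
    "estimate_batch_effects",
    "adjust",
    "recombat",
]

logger = logging.getLogger(__name__)

_ZERO_VAR_TOL = 1e-12


@dataclass
class StandardizedData:
    """Residual-scaled data restricted to genes with positive residual variance.

    ``retained`` is a boolean mask over the original gene axis; ``Z`` and
    ``sigma_hat`` cover only retained genes.
    """

    Z: np.ndarray
    sigma_hat: np.ndarray
    retained: np.ndarray
    gene_ids: list[str]
    fit_fingerprint: tuple

    @property
    def excluded_gene_ids(self) -> list[str]:
        return [g for g, keep in zip(self.gene_ids, self.retained) if not keep]


@dataclass
class PriorHyperparams:
    """Moment-matched prior parameters, one entry per batch.

    gamma_bar/tau_sq parameterize the normal prior on additive effects;
    lambda_bar/theta_bar the inverse-gamma prior (shape/scale) on
    multiplicative effects.  ``gamma_hat`` and ``batch_var`` keep the raw
    per-batch, per-gene moments the priors were matched to; ``degenerate``
    flags batches whose per-gene variances had zero spread, for which no
    variance shrinkage is possible.
    """

    batch_names: list[str]
    gamma_bar: np.ndarray
    tau_sq: np.ndarray
    lambda_bar: np.ndarray
    theta_bar: np.ndarray
    gamma_hat: np.ndarray
    batch_var: np.ndarray
    degenerate: np.ndarray


@dataclass
class BatchEffectEstimates:
    gamma_star: np.ndarray
    delta_sq_star: np.ndarray
    priors: PriorHyperparams
    n_iterations: dict[str, int]
    converged: dict[str, bool] = field(default_factory=dict)


def standardize(
    Y: ExpressionMatrix, fit: LinearModelFit, d: EncodedDesign
) -> StandardizedData:
    """Center by the batch-free mean and scale by pooled residual SD."""
    if fit.design_fingerprint != d.fingerprint():
        raise ValueError("fit was produced from a different design")
    if list(Y.gene_ids) != fit.gene_ids:
        raise ValueError("fit was produced from a different expression matrix")
    mean = predict_mean(fit, d)
    full = mean + fit.gamma_hat[d.batch_index]
    resid = Y.values - full
    sigma = np.sqrt(np.mean(resid**2, axis=0))  # divisor N
    retained = sigma > _ZERO_VAR_TOL
    if not retained.any():
        raise ValueError(
            "all genes have zero residual variance; nothing to standardize"
        )
    if not retained.all():
        warnings.warn(
            f"excluding {int((~retained).sum())} zero-variance genes from "
            "standardization; they will pass through the adjustment unchanged",
            stacklevel=2,
        )
    Z = (Y.values[:, retained] - mean[:, retained]) / sigma[retained]
    return StandardizedData(
        Z=Z,
        sigma_hat=sigma[retained],
        retained=retained,
        gene_ids=list(Y.gene_ids),
        fit_fingerprint=fit.design_fingerprint,
    )


def estimate_prior_hyperparameters(
    s: StandardizedData, d: EncodedDesign
) -> PriorHyperparams:
    """Method-of-moments priors pooled across genes, per batch.

    Normal prior: gamma_bar = mean over genes of the per-gene batch means of
    Z, tau_sq their variance.  Inverse-gamma prior: with Vbar and S the mean
    and variance over genes of the per-gene batch sample variances,
    shape = (Vbar^2 + 2 S) / S and scale = (Vbar^3 + Vbar S) / S.
    """
    idx = d.batch_index
    nb = d.n_batches
    g = s.Z.shape[1]
    gamma_hat = np.empty((nb, g))
    batch_var = np.empty((nb, g))
    for i, name in enumerate(d.batch_names):
        rows = s.Z[idx == i]
        if rows.shape[0] < 2:
            raise ValueError(
                f"batch {name!r} has {rows.shape[0]} sample(s); at least 2 are "
                "required to estimate a batch variance. Merge or drop "
                "singleton batches before correcting."
            )
        gamma_hat[i] = rows.mean(axis=0)
        batch_var[i] = rows.var(axis=0, ddof=1)

    gamma_bar = gamma_hat.mean(axis=1)
    tau_sq = gamma_hat.var(axis=1, ddof=1) if g > 1 else np.zeros(nb)
    v_bar = batch_var.mean(axis=1)
    s_var = batch_var.var(axis=1, ddof=1) if g > 1 else np.zeros(nb)
    degenerate = s_var <= 0
    lambda_bar = np.full(nb, np.nan)
    theta_bar = np.full(nb, np.nan)
    ok = ~degenerate
    lambda_bar[ok] = (v_bar[ok] ** 2 + 2 * s_var[ok]) / s_var[ok]
    theta_bar[ok] = (v_bar[ok] ** 3 + v_bar[ok] * s_var[ok]) / s_var[ok]
    if degenerate.any():
        names = [n for n, dg in zip(d.batch_names, degenerate) if dg]
        warnings.warn(
            f"batches with degenerate variance priors (no spread across "
            f"genes): {names}; their batch effects will not be shrunk",
            stacklevel=2,
        )
    return PriorHyperparams(
        batch_names=list(d.batch_names),
        gamma_bar=gamma_bar,
        tau_sq=tau_sq,
        lambda_bar=lambda_bar,
        theta_bar=theta_bar,
        gamma_hat=gamma_hat,
        batch_var=batch_var,
        degenerate=degenerate,
    )


def estimate_batch_effects(
    s: StandardizedData,
    d: EncodedDesign,
    priors: PriorHyperparams,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> BatchEffectEstimates:
    """Iterate the conditional posterior means to their fixed point.

    Initialized at the naive estimates; converged when the largest absolute
    change of both arrays drops below ``tol``.  Degenerate batches keep
    their naive estimates unshrunk.
    """
    idx = d.batch_index
    gamma_star = priors.gamma_hat.copy()
    delta_sq_star = priors.batch_var.copy()
    n_iterations: dict[str, int] = {}
    converged: dict[str, bool] = {}
    for i, name in enumerate(priors.batch_names):
        if priors.degenerate[i]:
            n_iterations[name] = 0
            converged[name] = True
            continue
        Zi = s.Z[idx == i]
        n_i = Zi.shape[0]
        tau2 = priors.tau_sq[i]
        gbar = priors.gamma_bar[i]
        lam = priors.lambda_bar[i]
        theta = priors.theta_bar[i]
        g_old = priors.gamma_hat[i].copy()
        d_old = priors.batch_var[i].copy()
        ok = False
        it = 0
        for it in range(1, max_iter + 1):
            g_new = (n_i * tau2 * priors.gamma_hat[i] + d_old * gbar) / (
                n_i * tau2 + d_old
            )
            sum_sq = ((Zi - g_new[None, :]) ** 2).sum(axis=0)
            d_new = (theta + 0.5 * sum_sq) / (n_i / 2.0 + lam - 1.0)
            change = max(
                float(np.abs(g_new - g_old).max()), float(np.abs(d_new - d_old).max())
            )
            g_old, d_old = g_new, d_new
            if change < tol:
                ok = True
                break
        if not ok:
            warnings.warn(
                f"empirical-Bayes iteration for batch {name!r} did not converge "
                f"in {max_iter} iterations",
                stacklevel=2,
            )
        gamma_star[i] = g_old
        delta_sq_star[i] = d_old
        n_iterations[name] = it
        converged[name] = ok
    return BatchEffectEstimates(
        gamma_star=gamma_star,
        delta_sq_star=delta_sq_star,
        priors=priors,
        n_iterations=n_iterations,
        converged=converged,
    )


def adjust(
    Y: ExpressionMatrix,
    s: StandardizedData,
    est: BatchEffectEstimates,
    fit: LinearModelFit,
    d: EncodedDesign,
    drop_unwanted: bool = False,
) -> ExpressionMatrix:
    """Remove the estimated batch effects and restore the modeled means.

    Y~ = sigma/delta* (Z - gamma*) + alpha + X beta_x + C beta_c.  By
    default the unwanted-covariate term C beta_c is restored too (only
    batch effects are corrected); ``drop_unwanted=True`` omits it so known
    nuisance covariates are regressed out of the output as well.
    Zero-variance genes excluded from standardization pass through
    unchanged.
    """
    if s.fit_fingerprint != fit.design_fingerprint or fit.design_fingerprint != d.fingerprint():
        raise ValueError("inconsistent provenance of fit/standardization/design")
    if Y.values.shape != (d.n, len(s.gene_ids)):
        raise ValueError("expression matrix shape does not match design/fit")
    idx = d.batch_index
    delta_star = np.sqrt(est.delta_sq_star)
    corrected_z = (s.Z - est.gamma_star[idx]) / delta_star[idx]
    mean = np.tile(fit.alpha_hat, (d.n, 1))
    Xd = d.matrix[:, d.columns_with_role("desired")]
    if Xd.shape[1]:
        mean += Xd @ fit.beta_x
    if not drop_unwanted:
        Xu = d.matrix[:, d.columns_with_role("unwanted")]
        if Xu.shape[1]:
            mean += Xu @ fit.beta_c
    out = Y.values.copy()
    out[:, s.retained] = corrected_z * s.sigma_hat + mean[:, s.retained]
    if not s.retained.all():
        warnings.warn(
            f"{int((~s.retained).sum())} zero-variance genes passed through "
            "uncorrected",
            stacklevel=2,
        )
    return ExpressionMatrix(out, list(Y.sample_ids), list(Y.gene_ids))


def recombat(
    Y: ExpressionMatrix,
    meta: SampleMetadata,
    spec: DesignSpec,
    reg: RegularizationConfig | None = None,
    drop_unwanted: bool = False,
    eb_tol: float = 1e-6,
    eb_max_iter: int = 1000,
) -> ExpressionMatrix:
    """One-call batch correction: encode, fit, standardize, shrink, adjust.

    Inputs are aligned on their common samples first.  Stage failures are
    re-raised with the stage name prepended; rank diagnostics and per-stage
    timings are logged at INFO level.
    """
    Y, meta = align(Y, meta)
    stages: list[tuple[str, float]] = []

    def _run(stage, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except Exception as e:
            e.args = (f"[{stage}] {e.args[0] if e.args else ''}",) + e.args[1:]
            raise
        stages.append((stage, time.perf_counter() - t0))
        return out

    d = _run("encode_design", lambda: encode_design(meta, spec))
    logger.info("%s", rank_diagnostics(d))
    fit = _run("fit_linear_model", lambda: fit_linear_model(Y, d, reg))
    s = _run("standardize", lambda: standardize(Y, fit, d))
    priors = _run(
        "estimate_prior_hyperparameters",
        lambda: estimate_prior_hyperparameters(s, d),
    )
    est = _run(
        "estimate_batch_effects",
        lambda: estimate_batch_effects(s, d, priors, tol=eb_tol, max_iter=eb_max_iter),
    )
    out = _run("adjust", lambda: adjust(Y, s, est, fit, d, drop_unwanted=drop_unwanted))
    for stage, dt in stages:
        logger.info("stage %-28s %.3fs", stage, dt)
    return out
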