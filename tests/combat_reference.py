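"""Independent classic-ComBat reference path, used only as a test oracle.

Deliberately written from the published location-scale formulas with plain
per-gene / per-batch loops and pseudo-inverse OLS, sharing no code with the
package implementation.  Valid only on full-rank designs.
"""

from __future__ import annotations

import numpy as np


def combat_reference(
    Y: np.ndarray,
    design: np.ndarray,
    batch_index: np.ndarray,
    n_batches: int,
    batch_cols: np.ndarray,
    covariate_cols: np.ndarray,
    eb_tol: float = 1e-8,
    eb_max_iter: int = 5000,
) -> np.ndarray:
    """Classic OLS + parametric empirical-Bayes batch correction.

    ``design`` is the full model matrix (batch one-hots plus covariates),
    ``batch_cols``/``covariate_cols`` index its columns, and
    ``batch_index[j]`` maps sample j to the batch whose one-hot sits at
    ``batch_cols[batch_index[j]]``.
    """
    n, g = Y.shape
    sizes = np.array([(batch_index == i).sum() for i in range(n_batches)], dtype=float)

    # per-gene OLS via pseudo-inverse
    pinv = np.linalg.pinv(design)
    B = np.empty((design.shape[1], g))
    for k in range(g):
        B[:, k] = pinv @ Y[:, k]

    # intercept from the weighted-mean constraint on batch coefficients
    alpha = np.zeros(g)
    for k in range(g):
        alpha[k] = sum(
            sizes[i] / n * B[batch_cols[i], k] for i in range(n_batches)
        )
    gamma_reg = np.empty((n_batches, g))
    for i in range(n_batches):
        gamma_reg[i] = B[batch_cols[i]] - alpha

    # standardize against the batch-free mean, pooled full-model residual SD
    fitted = design @ B
    sigma = np.empty(g)
    for k in range(g):
        sigma[k] = np.sqrt(np.mean((Y[:, k] - fitted[:, k]) ** 2))
    stand_mean = np.tile(alpha, (n, 1))
    for c in covariate_cols:
        stand_mean += np.outer(design[:, c], B[c])
    Z = (Y - stand_mean) / sigma

    # moment-matched priors
    gamma_hat = np.empty((n_batches, g))
    v_hat = np.empty((n_batches, g))
    for i in range(n_batches):
        rows = Z[batch_index == i]
        for k in range(g):
            gamma_hat[i, k] = rows[:, k].mean()
            v_hat[i, k] = rows[:, k].var(ddof=1)
    out = Y.copy()
    for i in range(n_batches):
        gbar = gamma_hat[i].mean()
        t2 = gamma_hat[i].var(ddof=1)
        vbar = v_hat[i].mean()
        s2 = v_hat[i].var(ddof=1)
        a = (vbar**2 + 2 * s2) / s2
        b = (vbar**3 + vbar * s2) / s2

        rows = Z[batch_index == i]
        ni = rows.shape[0]
        g_star = gamma_hat[i].copy()
        d_star = v_hat[i].copy()
        for _ in range(eb_max_iter):
            g_new = np.empty(g)
            d_new = np.empty(g)
            for k in range(g):
                g_new[k] = (ni * t2 * gamma_hat[i, k] + d_star[k] * gbar) / (
                    ni * t2 + d_star[k]
                )
                ss = ((rows[:, k] - g_new[k]) ** 2).sum()
                d_new[k] = (b + 0.5 * ss) / (ni / 2.0 + a - 1.0)
            if (
                np.abs(g_new - g_star).max() < eb_tol
                and np.abs(d_new - d_star).max() < eb_tol
            ):
                g_star, d_star = g_new, d_new
                break
            g_star, d_star = g_new, d_new

        sel = batch_index == i
        for k in range(g):
            out[sel, k] = (
                sigma[k] / np.sqrt(d_star[k]) * (Z[sel, k] - g_star[k])
                + stand_mean[sel, k]
            )
    return out
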