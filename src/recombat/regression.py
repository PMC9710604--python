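"""Location-model fitting: elastic net with an unpenalized batch block.

Per gene k the model is  Y_k = X~ b_k + noise  with X~ = [batch one-hots |
desired covariates X | unwanted covariates C].  The objective minimized is

    ||Y_k - X~ b_k||^2  +  lambda1 * ||b_pen||_1  +  lambda2 * ||b_pen||_2^2

where b_pen covers only the covariate coefficients (beta_x, beta_c): batch
coefficients are never penalized, since shrinking them would bias the
additive batch-effect estimates that the empirical-Bayes step shrinks
properly.  With lambda1 = lambda2 = 0 this is ordinary least squares and
requires a full-rank design; any positive lambda2 makes the problem strictly
convex even on singular designs, which is the whole point.

After fitting, the per-gene intercept is recovered from the batch block via
the constraint that the sample-size-weighted mean of the per-batch additive
coefficients vanishes: alpha_k = sum_i (n_i / N) b_ik, which is subtracted
from the batch coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .data_io import ExpressionMatrix
from .design import EncodedDesign, rank_diagnostics

__all__ = [
    "RegularizationConfig",
    "LinearModelFit",
    "SingularDesignError",
    "ConvergenceError",
    "fit_linear_model",
    "predict_mean",
]


class SingularDesignError(np.linalg.LinAlgError):
    """Unregularized fit requested on a rank-deficient design."""


class ConvergenceError(RuntimeError):
    """Coordinate descent failed to converge within max_iter."""


@dataclass
class RegularizationConfig:
    """Elastic-net penalties for the location model.

    lambda1 is the LASSO (l1) penalty, lambda2 the ridge (l2) penalty, both
    applied to covariate coefficients only.  (0, 0) selects the exact OLS
    path.  The default (0, 1e-9) is a vanishing ridge: it leaves
    well-conditioned fits numerically unchanged while making singular
    designs solvable.
    """

    lambda1: float = 0.0
    lambda2: float = 1e-9
    max_iter: int = 10_000
    tol: float = 1e-7

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("penalties must be non-negative")


@dataclass
class LinearModelFit:
    """Fitted location model, with the intercept split out of the batch block.

    ``gamma_hat`` holds the centered per-batch additive coefficients
    (n_batches x genes); for every gene the n_i-weighted mean of its batch
    coefficients is zero by construction.
    """

    beta_x: np.ndarray
    beta_c: np.ndarray
    gamma_hat: np.ndarray
    alpha_hat: np.ndarray
    regularization: RegularizationConfig
    design_fingerprint: tuple
    gene_ids: list[str]
    n_iterations: int = 0
    objective_history: list[float] = field(default_factory=list)

    @property
    def n_genes(self) -> int:
        return self.alpha_hat.shape[0]


def _soft_threshold(x: np.ndarray, t: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


def _coordinate_descent(
    X: np.ndarray,
    Y: np.ndarray,
    reg: RegularizationConfig,
) -> tuple[np.ndarray, int, list[float]]:
    """Cyclic coordinate descent on the projected, all-penalized subproblem.

    Each coordinate update is the exact minimizer of the objective in that
    coordinate (soft-thresholding), so the penalized objective is
    non-increasing across sweeps.  Convergence is declared when either the
    largest raw coefficient update falls below ``tol``, or — the criterion
    glmnet uses — the largest deviance-scale impact of an update,
    max_j ||x_j||^2 (delta b_j)^2, falls below ``tol * mean_k ||y_k||^2``.
    The second criterion is essential on singular designs, where directions
    in the design null space have curvature equal to lambda2 only and raw
    coefficient changes decay too slowly to ever cross an absolute
    threshold.
    """
    n, m = X.shape
    g = Y.shape[1]
    B = np.zeros((m, g))
    R = Y.copy()
    col_sq = np.einsum("ij,ij->j", X, X)
    lam1, lam2 = reg.lambda1, reg.lambda2
    y_scale = float(np.einsum("ij,ij->", Y, Y)) / max(g, 1)
    dev_tol = reg.tol * max(y_scale, 1e-30)
    history: list[float] = []
    for it in range(reg.max_iter):
        max_delta = 0.0
        max_dev = 0.0
        for j in range(m):
            if col_sq[j] < 1e-12:
                continue
            xj = X[:, j]
            rho = xj @ R + col_sq[j] * B[j]
            new = _soft_threshold(rho, lam1 / 2.0) / (col_sq[j] + lam2)
            delta = new - B[j]
            nz = delta != 0.0
            if nz.any():
                R[:, nz] -= np.outer(xj, delta[nz])
                B[j] = new
                dmax = float(np.abs(delta).max())
                max_delta = max(max_delta, dmax)
                max_dev = max(max_dev, col_sq[j] * dmax**2)
        obj = (
            float(np.einsum("ij,ij->", R, R))
            + lam1 * float(np.abs(B).sum())
            + lam2 * float((B**2).sum())
        )
        history.append(obj)
        if max_delta < reg.tol or max_dev < dev_tol:
            return B, it + 1, history
    raise ConvergenceError(
        f"coordinate descent did not converge in {reg.max_iter} iterations "
        f"(last max coefficient change {max_delta:.3e}, tol {reg.tol:.0e}; "
        f"objective change over last step "
        f"{history[-2] - history[-1] if len(history) > 1 else float('nan'):.3e}). "
        "Larger lambda1/lambda2 usually stabilizes the fit."
    )


def fit_linear_model(
    Y: ExpressionMatrix, d: EncodedDesign, reg: RegularizationConfig | None = None
) -> LinearModelFit:
    """Fit the location model for every gene.

    Paths
    -----
    * lambda1 = lambda2 = 0: exact OLS via the normal equations; raises
      :class:`SingularDesignError` on a rank-deficient design.
    * lambda1 = 0, lambda2 > 0: closed-form generalized ridge, one symmetric
      solve shared by all genes (the penalty matrix is diagonal with zeros
      on the batch block).
    * lambda1 > 0: cyclic coordinate descent, vectorized across genes.
    """
    if reg is None:
        reg = RegularizationConfig()
    if Y.n_samples != d.n:
        raise ValueError(
            f"expression matrix has {Y.n_samples} samples but design has {d.n}"
        )
    if d.n_batches < 2:
        raise ValueError(f"need at least 2 batches, got {d.n_batches}")

    X = d.matrix
    n, m = X.shape
    roles = np.array(d.column_roles)
    penalized = roles != "batch"
    batch_cols = d.columns_with_role("batch")
    desired_cols = d.columns_with_role("desired")
    unwanted_cols = d.columns_with_role("unwanted")

    n_iter = 0
    history: list[float] = []
    if reg.lambda1 == 0.0:
        A = X.T @ X
        XtY = X.T @ Y.values
        if reg.lambda2 == 0.0:
            report = rank_diagnostics(d)
            if report.is_singular:
                raise SingularDesignError(
                    "ordinary least squares requested on a singular design: "
                    f"{report}. Set lambda2 > 0 (e.g. 1e-9) to obtain a "
                    "unique regularized solution."
                )
            B = scipy.linalg.solve(A, XtY, assume_a="sym")
        else:
            A = A + reg.lambda2 * np.diag(penalized.astype(float))
            try:
                B = scipy.linalg.solve(A, XtY, assume_a="sym")
            except scipy.linalg.LinAlgError:
                B, *_ = np.linalg.lstsq(A, XtY, rcond=None)
    else:
        # Profile out the unpenalized batch block exactly (Frisch-Waugh):
        # its one-hot columns are orthogonal, so projecting onto their
        # complement is per-batch mean-centering.  Coordinate descent then
        # runs on the projected, all-penalized subproblem, and the batch
        # coefficients are recovered as per-batch means of the partial
        # residuals.
        idx = d.batch_index
        Xp = X[:, penalized].copy()
        Yp = Y.values.copy()
        for i in range(d.n_batches):
            rows = idx == i
            Xp[rows] -= Xp[rows].mean(axis=0)
            Yp[rows] -= Yp[rows].mean(axis=0)
        B_pen, n_iter, history = _coordinate_descent(Xp, Yp, reg)
        partial = Y.values - X[:, penalized] @ B_pen
        B = np.zeros((m, Y.n_genes))
        B[np.flatnonzero(penalized)] = B_pen
        for i, c in enumerate(batch_cols):
            B[c] = partial[idx == i].mean(axis=0)

    batch_coef = B[batch_cols, :]
    sizes = np.array([d.batch_sizes[b] for b in d.batch_names], dtype=float)
    weights = sizes / sizes.sum()
    alpha_hat = weights @ batch_coef
    gamma_hat = batch_coef - alpha_hat[None, :]

    return LinearModelFit(
        beta_x=B[desired_cols, :],
        beta_c=B[unwanted_cols, :],
        gamma_hat=gamma_hat,
        alpha_hat=alpha_hat,
        regularization=reg,
        design_fingerprint=d.fingerprint(),
        gene_ids=list(Y.gene_ids),
        n_iterations=n_iter,
        objective_history=history,
    )


def predict_mean(fit: LinearModelFit, d: EncodedDesign) -> np.ndarray:
    """Batch-free fitted mean  alpha + X beta_x + C beta_c  (n x genes).

    The batch block is excluded; adding ``fit.gamma_hat`` for each sample's
    batch reproduces the full regression prediction.
    """
    if fit.design_fingerprint != d.fingerprint():
        raise ValueError("fit was produced from a different design")
    Xd = d.matrix[:, d.columns_with_role("desired")]
    Xu = d.matrix[:, d.columns_with_role("unwanted")]
    out = np.tile(fit.alpha_hat, (d.n, 1))
    if Xd.shape[1]:
        out += Xd @ fit.beta_x
    if Xu.shape[1]:
        out += Xu @ fit.beta_c
    return out
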