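"""Covariate-adjusted logistic-regression score test for a single variant.

The phenotype follows logit P(Y=1 | Z, G) = Z'a + G*b and the null H0: b = 0
is tested with the score statistic

    S = G~' (Y - mu),   G~ = G - Z (Z'VZ)^{-1} Z'V G,   V = diag{mu(1-mu)},

where mu are the fitted probabilities of the covariate-only model. Under H0,
E(S) = 0 and Var(S) = sum_i G~_i^2 mu_i (1 - mu_i), and T = S^2/Var(S) is
asymptotically chi-square with one degree of freedom.

The null model depends only on (Y, Z), so it is fitted once and reused
across all variants of a scan; every function here accepts either a single
genotype vector or an (n, n_variants) matrix and vectorizes over columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats
from scipy.special import expit

__all__ = ["NullModel", "ScoreResult", "fit_null", "adjust_genotype", "score_test"]

MU_CLIP = 1e-12


class NullModelError(RuntimeError):
    """Raised when the covariate-only logistic fit is unusable."""


@dataclass
class NullModel:
    """Covariate-only logistic fit reused across variants.

    Holds the MLE coefficients, fitted probabilities ``mu_hat`` (clipped away
    from 0/1), the IRLS weights ``V = mu(1-mu)``, the phenotype and design it
    was fitted to, and a Cholesky factorization of Z'VZ for the projection.
    """

    alpha_hat: np.ndarray
    mu_hat: np.ndarray
    V: np.ndarray
    converged: bool
    Y: np.ndarray
    Z: np.ndarray
    projection_cache: tuple = field(repr=False, default=None)

    @property
    def residuals(self) -> np.ndarray:
        return self.Y - self.mu_hat

    @property
    def n(self) -> int:
        return len(self.Y)

    @property
    def case_fraction(self) -> float:
        return float(self.Y.mean())


def _with_intercept(Z: np.ndarray | None, n: int) -> np.ndarray:
    if Z is None:
        return np.ones((n, 1))
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[0] != n:
        Z = Z.T
    # prepend an intercept column unless one is already present
    has_const = np.any(np.all(Z == Z[0:1, :], axis=0) & (Z[0, :] != 0))
    return Z if has_const else np.column_stack([np.ones(n), Z])


def fit_null(
    Y: np.ndarray,
    Z: np.ndarray | None = None,
    max_iter: int = 50,
    tol: float = 1e-8,
    add_intercept: bool = True,
) -> NullModel:
    """Fit the covariate-only logistic model by iteratively reweighted least squares.

    Convergence is declared when the largest coefficient change drops below
    ``tol``; fitted probabilities are clipped to [1e-12, 1-1e-12] so the
    downstream cumulant-generating function stays finite. ``Z`` excludes the
    intercept unless ``add_intercept`` is False.
    """
    Y = np.asarray(Y, dtype=float)
    n = len(Y)
    if len(np.unique(Y)) < 2:
        raise NullModelError("phenotype has a single class; cannot fit the null model")
    Zd = _with_intercept(Z, n) if add_intercept else np.atleast_2d(np.asarray(Z, dtype=float))
    q = Zd.shape[1]
    if np.linalg.matrix_rank(Zd) < q:
        raise NullModelError("covariate design is rank deficient")

    beta = np.zeros(q)
    ybar = Y.mean()
    beta[0] = np.log(ybar / (1.0 - ybar))  # intercept start at marginal logit
    converged = False
    for _ in range(max_iter):
        mu = np.clip(expit(Zd @ beta), MU_CLIP, 1.0 - MU_CLIP)
        v = mu * (1.0 - mu)
        h = (Zd * v[:, None]).T @ Zd
        grad = Zd.T @ (Y - mu)
        try:
            step = np.linalg.solve(h, grad)
        except np.linalg.LinAlgError as err:  # pragma: no cover - separation guard
            raise NullModelError("singular information matrix in IRLS") from err
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    mu = np.clip(expit(Zd @ beta), MU_CLIP, 1.0 - MU_CLIP)
    v = mu * (1.0 - mu)
    ztvz = (Zd * v[:, None]).T @ Zd
    cache = linalg.cho_factor(ztvz)
    return NullModel(beta, mu, v, converged, Y.copy(), Zd, cache)


def adjust_genotype(G: np.ndarray, null: NullModel, Z: np.ndarray | None = None) -> np.ndarray:
    """V-weighted projection residual of G on the covariate column space.

    ``G`` may be a vector or an (n, n_variants) matrix. ``Z`` defaults to the
    design the null model was fitted with (the usual case); passing a
    different design is rejected if it is collinear.
    """
    if not null.converged:
        raise NullModelError("null model did not converge; refusing to adjust genotypes")
    Zd = null.Z if Z is None else _with_intercept(np.asarray(Z, dtype=float), null.n)
    G = np.asarray(G, dtype=float)
    vec = G.ndim == 1
    Gm = G[:, None] if vec else G
    if Z is None:
        coef = linalg.cho_solve(null.projection_cache, (Zd * null.V[:, None]).T @ Gm)
    else:
        ztvz = (Zd * null.V[:, None]).T @ Zd
        if np.linalg.matrix_rank(Zd) < Zd.shape[1]:
            raise NullModelError("collinear covariate columns in projection design")
        coef = np.linalg.solve(ztvz, (Zd * null.V[:, None]).T @ Gm)
    gt = Gm - Zd @ coef
    return gt[:, 0] if vec else gt


@dataclass
class ScoreResult:
    """Score statistic, its variance, and the asymptotic chi-square p-value."""

    S: float
    var_S: float
    G_tilde: np.ndarray
    T: float
    p_value: float
    route: str = "asymptotic"


def score_components(
    G: np.ndarray, null: NullModel
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized (S, Var(S), G~) for one or many genotype columns."""
    gt = adjust_genotype(G, null)
    gm = gt[:, None] if gt.ndim == 1 else gt
    s = gm.T @ null.residuals
    var_s = null.V @ (gm * gm)
    if gt.ndim == 1:
        return float(s[0]), float(var_s[0]), gt
    return s, var_s, gt


def score_test(G: np.ndarray, null: NullModel) -> ScoreResult:
    """Asymptotic chi-square(1) score test for one variant.

    A variant that is monomorphic after covariate adjustment (Var(S) = 0)
    yields p = 1 rather than an error.
    """
    s, var_s, gt = score_components(np.asarray(G, dtype=float), null)
    if var_s <= 0.0 or not np.isfinite(var_s):
        return ScoreResult(s, max(var_s, 0.0), gt, 0.0, 1.0, route="asymptotic")
    t = s * s / var_s
    return ScoreResult(s, var_s, gt, t, float(stats.chi2.sf(t, df=1)), route="asymptotic")
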