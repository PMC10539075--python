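"""Weighted-GEE logistic estimation and association tests.

For a binary outcome with independent subjects and an identity working
correlation, the GEE quasi-score collapses to the weighted logistic score

    U(theta) = sum_i  x_i * w_i * (y_i - mu_i(theta)),    mu = expit(x' theta),

so the estimator is a weighted logistic regression solved by Fisher scoring
(IRLS).  The weights here are *analysis* weights derived from the confidence
of imputed disease labels (1 for observed cases/controls, max(p, 1-p) for
imputed subjects), not frequency weights, which is why the robust sandwich
covariance is the default for inference on weighted cohorts.

Three analysis methods share this single code path and differ only in the
(subset, weight) inputs:

* ``LR``  -- labeled subjects only, all weights 1 (ordinary logistic regression);
* ``IP``  -- labeled + imputed subjects, all weights 1;
* ``WIP`` -- labeled + imputed subjects, probability-derived weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

__all__ = [
    "CohortData",
    "WGEEFit",
    "TestResult",
    "SeparationError",
    "ConvergenceError",
    "fit_wgee",
    "wald_test",
    "score_test",
]


class SeparationError(RuntimeError):
    """Raised when a design column perfectly separates the outcome."""


class ConvergenceError(RuntimeError):
    """Raised when a test is requested on a non-converged fit."""


def _expit(eta: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-eta))


@dataclass
class CohortData:
    """Aligned per-subject arrays for one association analysis.

    Parameters
    ----------
    y : array of 0/1 outcomes (observed or imputed disease status).
    Z : covariate matrix with an explicit leading intercept column of ones,
        shape ``(n, q+1)``.
    G : genotype column(s), additive minor-allele dosage; shape ``(n,)`` or
        ``(n, m)``.
    w : strictly positive analysis weights in ``(0, 1]``.
    """

    y: np.ndarray
    Z: np.ndarray
    G: np.ndarray
    w: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        self.G = np.asarray(self.G, dtype=float)
        if self.G.ndim == 1:
            self.G = self.G[:, None]
        n = self.y.shape[0]
        if self.w is None:
            self.w = np.ones(n)
        self.w = np.asarray(self.w, dtype=float)
        if not (self.Z.shape[0] == n and self.G.shape[0] == n and self.w.shape[0] == n):
            raise ValueError(
                f"row mismatch: y={n}, Z={self.Z.shape[0]}, "
                f"G={self.G.shape[0]}, w={self.w.shape[0]}"
            )
        if np.any(self.w <= 0):
            raise ValueError("analysis weights must be strictly positive")
        if not np.allclose(self.Z[:, 0], 1.0):
            raise ValueError("Z must carry a leading intercept column of ones")
        if not np.isin(self.y, (0.0, 1.0)).all():
            raise ValueError("y must be binary 0/1")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def n_geno(self) -> int:
        return self.G.shape[1]

    @classmethod
    def for_method(
        cls,
        method: str,
        y: np.ndarray,
        p: np.ndarray,
        Z: np.ndarray,
        G: np.ndarray,
        labeled: np.ndarray,
    ) -> "CohortData":
        """Assemble the cohort for one of the three analysis methods.

        ``y`` holds observed status for labeled subjects (ignored for the
        rest), ``p`` the affection probability for unlabeled subjects,
        ``labeled`` is a boolean mask.  ``lr`` keeps labeled subjects with
        unit weights; ``ip`` adds imputed subjects with unit weights; ``wip``
        adds them with weights ``max(p, 1-p)``.
        """
        from .weights import impute_and_weight  # local import to avoid a cycle

        method = method.lower()
        y = np.asarray(y, dtype=float)
        p = np.asarray(p, dtype=float)
        labeled = np.asarray(labeled, dtype=bool)
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        G = np.asarray(G, dtype=float)
        if method == "lr":
            return cls(y[labeled], Z[labeled], G[labeled], None)
        if method not in ("ip", "wip"):
            raise ValueError(f"unknown method {method!r}; expected lr, ip or wip")
        y_imp, w_imp = impute_and_weight(p[~labeled])
        y_all = np.concatenate([y[labeled], y_imp.astype(float)])
        Z_all = np.concatenate([Z[labeled], Z[~labeled]])
        G_all = np.concatenate([G[labeled], G[~labeled]])
        if method == "ip":
            w_all = None
        else:
            w_all = np.concatenate([np.ones(labeled.sum()), w_imp])
        return cls(y_all, Z_all, G_all, w_all)


@dataclass
class WGEEFit:
    """Solution of the weighted quasi-score equations."""

    params: np.ndarray
    cov_model: np.ndarray
    cov_robust: np.ndarray
    n_iter: int
    converged: bool
    score_norm: float
    geno_idx: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    n_obs: int = 0

    @property
    def alpha(self) -> np.ndarray:
        mask = np.ones(len(self.params), dtype=bool)
        mask[self.geno_idx] = False
        return self.params[mask]

    @property
    def beta(self) -> np.ndarray:
        return self.params[self.geno_idx]

    def bse(self, cov: str = "robust") -> np.ndarray:
        c = self.cov_robust if cov == "robust" else self.cov_model
        return np.sqrt(np.diag(c))


@dataclass
class TestResult:
    statistic: float
    df: int
    pvalue: float
    kind: str           # "wald" | "score"
    cov_type: str       # "robust" | "model"
    method: str | None = None


def _check_separation(X: np.ndarray, y: np.ndarray) -> None:
    # A column whose case values all lie strictly above (or below) every
    # control value separates the data perfectly; the MLE diverges.
    cases = y == 1
    if cases.all() or (~cases).all():
        return
    for j in range(X.shape[1]):
        col = X[:, j]
        if np.ptp(col) == 0:
            continue
        if col[cases].min() > col[~cases].max() or col[cases].max() < col[~cases].min():
            raise SeparationError(f"column {j} perfectly separates the outcome")


def _weighted_loglik(y: np.ndarray, w: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    return float(np.sum(w * (y * np.log(mu) + (1 - y) * np.log(1 - mu))))


def fit_wgee(
    data: CohortData,
    include_genotype: bool = True,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> WGEEFit:
    """Fisher-scoring solution of ``U(theta) = X' diag(w) (y - mu) = 0``.

    Returns both the model-based covariance (inverse weighted expected
    information) and the robust sandwich covariance
    ``I_w^{-1} [sum_i w_i^2 (y_i-mu_i)^2 x_i x_i'] I_w^{-1}``.

    Non-convergence is flagged on the result rather than raised; tests refuse
    to run on flagged fits.  Perfect separation raises ``SeparationError``.
    """
    if include_genotype:
        X = np.hstack([data.Z, data.G])
        geno_idx = np.arange(data.Z.shape[1], X.shape[1])
    else:
        X = data.Z
        geno_idx = np.array([], dtype=int)
    y, w = data.y, data.w
    _check_separation(X, y)

    beta = np.zeros(X.shape[1])
    mu = _expit(X @ beta)
    ll = _weighted_loglik(y, w, mu)
    converged = False
    it = 0
    score_norm = np.inf
    for it in range(1, max_iter + 1):
        score = X.T @ (w * (y - mu))
        score_norm = float(np.max(np.abs(score)))
        if score_norm <= tol:
            converged = True
            break
        info = (X * (w * mu * (1 - mu))[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(f"singular weighted information: {exc}") from exc
        # step-halving on the weighted quasi-likelihood
        for _ in range(30):
            cand = beta + step
            mu_c = _expit(X @ cand)
            ll_c = _weighted_loglik(y, w, mu_c)
            if ll_c >= ll - 1e-12:
                beta, mu, ll = cand, mu_c, ll_c
                break
            step = step / 2.0
        else:  # pragma: no cover - pathological
            break

    mu = _expit(X @ beta)
    v = w * mu * (1 - mu)
    info = (X * v[:, None]).T @ X
    bread = np.linalg.inv(info)
    resid = w * (y - mu)
    meat = (X * (resid**2)[:, None]).T @ X
    sandwich = bread @ meat @ bread
    return WGEEFit(
        params=beta,
        cov_model=bread,
        cov_robust=sandwich,
        n_iter=it,
        converged=converged,
        score_norm=score_norm,
        geno_idx=geno_idx,
        n_obs=data.n,
    )


def wald_test(
    fit: WGEEFit,
    which: np.ndarray | list[int] | None = None,
    cov: str = "robust",
    method: str | None = None,
) -> TestResult:
    """Wald test ``beta' cov(beta)^{-1} beta ~ chi2_df`` on the genotype block.

    ``which`` selects genotype coefficients (default: all of them); ``cov``
    picks the covariance flavor ("robust" sandwich or "model" based).
    """
    if not fit.converged:
        raise ConvergenceError("Wald test requested on a non-converged fit")
    idx = fit.geno_idx if which is None else fit.geno_idx[np.asarray(which)]
    if idx.size == 0:
        raise ValueError("fit carries no genotype coefficients")
    C = fit.cov_robust if cov == "robust" else fit.cov_model
    b = fit.params[idx]
    V = C[np.ix_(idx, idx)]
    try:
        stat = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular covariance in Wald test: {exc}") from exc
    df = idx.size
    return TestResult(stat, df, float(chi2.sf(stat, df)), "wald", cov, method)


def score_test(data: CohortData, cov: str = "model", method: str | None = None) -> TestResult:
    """Generalized score test of H0: beta = 0 for the genotype block.

    The nuisance coefficients are fit under the null (covariates only, same
    weights); the quasi-score for beta is evaluated at that null fit,

        U_P = sum_i G_i w_i (y_i - mu_i(alpha0)),

    and the statistic is ``T = U_P' var(U_P)^{-1} U_P ~ chi2_df``.

    cov="model" uses the weighted expected information with the nuisance
    block projected out (the Schur complement ``I_GG - I_GZ I_ZZ^{-1} I_ZG``);
    at unit weights this is the classical Rao score test.  cov="robust" uses
    the empirical outer product of the per-subject effective scores
    ``e_i = w_i (y_i - mu_i) (G_i - I_GZ I_ZZ^{-1} Z_i)``.
    """
    null_fit = fit_wgee(data, include_genotype=False)
    if not null_fit.converged:
        raise ConvergenceError("null model did not converge; cannot form score test")
    Z, G, y, w = data.Z, data.G, data.y, data.w
    mu = _expit(Z @ null_fit.params)
    resid = w * (y - mu)
    U = G.T @ resid
    v = w * mu * (1 - mu)
    I_zz = (Z * v[:, None]).T @ Z
    I_gz = (G * v[:, None]).T @ Z
    I_gg = (G * v[:, None]).T @ G
    A = np.linalg.solve(I_zz, I_gz.T).T          # I_gz I_zz^{-1}
    if cov == "model":
        V = I_gg - A @ I_gz.T
    elif cov == "robust":
        E = (G - Z @ A.T) * resid[:, None]       # effective score contributions
        V = E.T @ E
    else:
        raise ValueError(f"unknown covariance flavor {cov!r}")
    df = G.shape[1]
    if np.allclose(V, 0):
        # degenerate direction (e.g. constant genotype): no information, T = 0
        return TestResult(0.0, df, 1.0, "score", cov, method)
    stat = float(U @ np.linalg.solve(V, U))
    return TestResult(stat, df, float(chi2.sf(stat, df)), "score", cov, method)
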