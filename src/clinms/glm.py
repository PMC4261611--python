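"""Logistic regression by IRLS, with offsets, and ridge-penalized IRLS.

Two estimators live here:

* :func:`fit_logistic` — maximum-likelihood logistic regression on a
  low-dimensional design (the clinical block), solved by iteratively
  reweighted least squares with an optional fixed offset in the linear
  predictor.  Step-halving guards against likelihood decreases near
  separation.

* :func:`ridge_irls` — the ridge-penalized IRLS iteration on the
  high-dimensional feature block X,

      beta^{h+1} = (X' W^h X + lambda * Sigma2)^{-1} X' W^h ytilde^h,

  which exists for p >> n and yields, at convergence, the pseudo-response
  ytilde* and weight diagonal W* that the PLS-based classifiers consume.
  When an offset (a fitted clinical predictor) is supplied it enters the
  linear predictor eta^h = offset + X beta^{h-1} but is *excluded* from the
  pseudo-response ytilde^h = X beta^{h-1} + (y - pi^h)/W^h, making ytilde*
  the offset-adjusted working response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = ["LogisticFit", "PseudoResponse", "fit_logistic", "ridge_irls"]

_W_FLOOR = 1e-10


def binomial_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    """Binomial log-likelihood sum_i (y_i eta_i - log(1 + exp(eta_i)))."""
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


@dataclass
class LogisticFit:
    """A fitted logistic regression.

    ``coefficients`` holds the intercept first (when present) followed by
    one coefficient per design column.  ``linear_predictor`` is the fitted
    eta on the training samples, including any offset.
    """

    coefficients: np.ndarray
    linear_predictor: np.ndarray
    converged: bool
    n_iterations: int
    add_intercept: bool
    log_likelihood: float
    loglik_path: np.ndarray = field(default_factory=lambda: np.empty(0))
    offset_used: np.ndarray | None = None

    def _design(self, design: np.ndarray) -> np.ndarray:
        design = np.atleast_2d(np.asarray(design, dtype=float))
        if self.add_intercept:
            design = np.column_stack([np.ones(design.shape[0]), design])
        if design.shape[1] != self.coefficients.size:
            raise ValueError(
                f"design has {design.shape[1]} columns (incl. intercept), "
                f"fit expects {self.coefficients.size}"
            )
        return design

    def predict_linear(
        self, design: np.ndarray, offset: np.ndarray | float = 0.0
    ) -> np.ndarray:
        return self._design(design) @ self.coefficients + offset

    def predict_proba(
        self, design: np.ndarray, offset: np.ndarray | float = 0.0
    ) -> np.ndarray:
        return expit(self.predict_linear(design, offset))

    def to_table(self, names: list[str] | None = None):
        """Plain-text serializable (term, estimate) table."""
        import pandas as pd

        k = self.coefficients.size - (1 if self.add_intercept else 0)
        if names is None:
            names = [f"z{j + 1}" for j in range(k)]
        terms = (["(intercept)"] if self.add_intercept else []) + list(names)
        return pd.DataFrame({"term": terms, "estimate": self.coefficients})


def fit_logistic(
    design: np.ndarray,
    y: np.ndarray,
    offset: np.ndarray | None = None,
    *,
    add_intercept: bool = True,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> LogisticFit:
    """Maximum-likelihood logistic regression by IRLS.

    Each step is a weighted least-squares regression of the pseudo-response
    ytilde^h = D gamma^h + (y - pi^h)/W^h on the design D, weighted by
    W^h = diag(pi^h (1 - pi^h)).  Step-halving is applied whenever the raw
    Newton step would decrease the log-likelihood.  Near-separation shows up
    as ``converged=False`` rather than an exception; an exactly singular
    weighted normal-equation matrix raises ``numpy.linalg.LinAlgError``.
    """
    y = np.asarray(y, dtype=float).ravel()
    design = np.atleast_2d(np.asarray(design, dtype=float))
    if design.shape[0] != y.size:
        raise ValueError("design and y have different numbers of rows")
    if np.unique(y).size < 2:
        raise ValueError("y must contain both classes")
    D = (
        np.column_stack([np.ones(y.size), design])
        if add_intercept
        else design
    )
    if D.shape[1] >= y.size:
        raise ValueError(
            f"needs fewer coefficients ({D.shape[1]}) than samples ({y.size})"
        )
    off = np.zeros(y.size) if offset is None else np.asarray(offset, dtype=float)

    # all-zero columns carry no information: coefficient pinned at 0 so an
    # uninformative clinical block degrades to the intercept-only model
    live = np.any(D != 0.0, axis=0)
    D_full, D = D, D[:, live]

    gamma = np.zeros(D.shape[1])
    eta = off + D @ gamma
    ll = binomial_loglik(y, eta)
    ll_path = [ll]
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        pi = expit(eta)
        w = np.clip(pi * (1.0 - pi), _W_FLOOR, None)
        ytilde = D @ gamma + (y - pi) / w
        A = D.T @ (w[:, None] * D)
        b = D.T @ (w * ytilde)
        try:
            gamma_new = np.linalg.solve(A, b)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "singular weighted normal equations in IRLS "
                "(collinear design or degenerate weights)"
            ) from exc
        # step-halving toward the current iterate if the likelihood drops
        step = gamma_new - gamma
        scale = 1.0
        for _ in range(30):
            cand = gamma + scale * step
            ll_new = binomial_loglik(y, off + D @ cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            scale /= 2.0
        else:
            break  # no acceptable step: stop, flagged unconverged
        delta = np.max(np.abs(scale * step))
        gamma = cand
        eta = off + D @ gamma
        ll = ll_new
        ll_path.append(ll)
        if delta < tol * (1.0 + np.max(np.abs(gamma))):
            converged = True
            break
    full_gamma = np.zeros(D_full.shape[1])
    full_gamma[live] = gamma
    return LogisticFit(
        coefficients=full_gamma,
        linear_predictor=eta,
        converged=converged,
        n_iterations=n_iter,
        add_intercept=add_intercept,
        log_likelihood=ll,
        loglik_path=np.asarray(ll_path),
        offset_used=None if offset is None else off,
    )


@dataclass
class PseudoResponse:
    """Converged state of the (possibly offset) ridge-IRLS iteration.

    ``y_tilde_star`` excludes the offset: it is the offset-adjusted working
    response X beta + (y - pi)/W at convergence.  ``w_star`` is the diagonal
    of W*.
    """

    y_tilde_star: np.ndarray
    w_star: np.ndarray
    beta_ridge: np.ndarray
    lam: float
    offset_used: np.ndarray
    converged: bool
    n_iterations: int


def ridge_irls(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    sigma2: np.ndarray | None = None,
    offset: np.ndarray | None = None,
    *,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> PseudoResponse:
    """Ridge-penalized IRLS on a (possibly p >> n) feature matrix.

    Iterates, starting from beta = 0:

        eta^h    = offset + X beta^{h-1}
        pi^h     = 1 / (1 + exp(-eta^h))
        W^h      = diag(pi^h (1 - pi^h))
        ytilde^h = X beta^{h-1} + (y - pi^h) / W^h
        beta^h   = (X' W^h X + lam * diag(sigma2))^{-1} X' W^h ytilde^h

    ``sigma2`` defaults to the identity diagonal (standard ridge).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if lam <= 0:
        raise ValueError(f"lambda must be > 0, got {lam}")
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y have different numbers of rows")
    s2 = np.ones(p) if sigma2 is None else np.asarray(sigma2, dtype=float)
    if s2.shape != (p,):
        raise ValueError("sigma2 must be a p-length diagonal")
    off = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)

    beta = np.zeros(p)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        xb = X @ beta
        pi = expit(off + xb)
        w = np.clip(pi * (1.0 - pi), _W_FLOOR, None)
        ytilde = xb + (y - pi) / w
        A = X.T @ (w[:, None] * X)
        A[np.diag_indices_from(A)] += lam * s2
        beta_new = np.linalg.solve(A, X.T @ (w * ytilde))
        delta = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if delta < tol * (1.0 + np.max(np.abs(beta))):
            converged = True
            break
    # converged state evaluated at the final beta
    xb = X @ beta
    pi = expit(off + xb)
    w = np.clip(pi * (1.0 - pi), _W_FLOOR, None)
    ytilde = xb + (y - pi) / w
    return PseudoResponse(
        y_tilde_star=ytilde,
        w_star=w,
        beta_ridge=beta,
        lam=float(lam),
        offset_used=off,
        converged=converged,
        n_iterations=n_iter,
    )
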