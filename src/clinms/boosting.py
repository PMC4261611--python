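"""Component-wise linear least-squares boosting for a binary response.

The loss is the binomial negative log-likelihood written on the half-logit
scale, rho(y, f) = log(1 + exp(-2 yhat f)) with yhat = 2y - 1 in {-1, +1}
and f = log(pi / (1 - pi)) / 2.  Each iteration fits the negative gradient
u_i = 2 (y_i - pi_i) by simple least squares on every (centered) feature
column, keeps the single best column, and adds a nu-shrunken copy of that
fit to the current predictor.

Stopping uses AIC(h) = -2 loglik(h) + 2 df(h), where df(h) is the trace of
the accumulated boosting hat operator

    B_h = B_{h-1} + nu * H_{s_h} (I - B_{h-1}),   H_j = x_j x_j' / (x_j'x_j),

the standard degrees-of-freedom measure for component-wise boosting.

A fitted clinical predictor can be supplied as a fixed offset: it enters the
initial predictor as offset/2 (f lives on the half-logit scale) together
with a one-parameter maximum-likelihood intercept, and is never updated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = ["BoostFit", "fit_boost", "aic_stop", "predict_boost"]


def _boost_loglik(y: np.ndarray, f: np.ndarray) -> float:
    """Binomial log-likelihood at the half-logit predictor f (eta = 2f)."""
    eta = 2.0 * f
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _mle_intercept(y: np.ndarray, base: np.ndarray) -> float:
    """One-parameter MLE constant c maximizing loglik at f = base + c.

    Reduces to log(pibar/(1-pibar))/2 when base == 0.
    """
    c = 0.0
    for _ in range(50):
        pi = expit(2.0 * (base + c))
        grad = 2.0 * np.sum(y - pi)  # d loglik / dc
        hess = -4.0 * np.sum(pi * (1.0 - pi))
        step = -grad / hess if hess < 0 else 0.0
        c += step
        if abs(step) < 1e-12:
            break
    return c


@dataclass
class BoostFit:
    """State of a boosting run, sufficient to evaluate f-hat at any h."""

    nu: float
    h_max: int
    h_stop: int
    f0: float
    selected_sequence: np.ndarray  # (h_max,) chosen column per step
    step_coefs: np.ndarray  # (h_max,) per-step component coefficients
    x_mean: np.ndarray  # centering constants, (p,)
    loglik_path: np.ndarray  # (h_max + 1,)
    df_path: np.ndarray  # (h_max + 1,)
    aic_path: np.ndarray  # (h_max + 1,)
    offset_used: np.ndarray | None = None
    p: int = 0

    @property
    def beta_hat(self) -> np.ndarray:
        """Coefficients (half-logit scale) at the stopping iteration."""
        return self.beta_at(self.h_stop)

    def beta_at(self, h: int) -> np.ndarray:
        beta = np.zeros(self.p)
        np.add.at(
            beta,
            self.selected_sequence[:h],
            self.nu * self.step_coefs[:h],
        )
        return beta

    def selected_set(self, h: int | None = None) -> np.ndarray:
        """Support of beta-hat at iteration h (default: h_stop)."""
        h = self.h_stop if h is None else h
        return np.flatnonzero(self.beta_at(h))

    def f_hat(
        self,
        X: np.ndarray,
        offset: np.ndarray | float | None = None,
        h: int | None = None,
    ) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.p:
            raise ValueError(f"X has {X.shape[1]} columns, fit expects {self.p}")
        h = self.h_stop if h is None else h
        if self.offset_used is not None and offset is None:
            raise ValueError("fit used an offset; supply offset for prediction")
        base = 0.0 if offset is None else np.asarray(offset, dtype=float) / 2.0
        beta = self.beta_at(h)
        return base + self.f0 + (X - self.x_mean) @ beta

    def linear_predictor(
        self,
        X: np.ndarray,
        offset: np.ndarray | float | None = None,
        h: int | None = None,
    ) -> np.ndarray:
        """Predictor on the logit scale, eta = 2 f-hat."""
        return 2.0 * self.f_hat(X, offset=offset, h=h)

    def to_table(self, names: list[str] | None = None):
        """Two-column (feature, beta-hat) coefficient table."""
        import pandas as pd

        if names is None:
            names = [f"m{j + 1}" for j in range(self.p)]
        return pd.DataFrame({"feature": names, "beta_hat": self.beta_hat})


def fit_boost(
    X: np.ndarray,
    y: np.ndarray,
    nu: float = 0.1,
    h_max: int = 1000,
    offset: np.ndarray | None = None,
    *,
    compute_df: bool = True,
) -> BoostFit:
    """Run component-wise boosting to ``h_max`` and pick h_stop by AIC.

    Zero-variance columns get a per-component coefficient of 0 and are never
    selected.  ``compute_df=False`` skips the hat-operator trace (then AIC is
    unavailable and h_stop = h_max).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y have different numbers of rows")
    if not (0.0 < nu <= 1.0):
        raise ValueError(f"nu must be in (0, 1], got {nu}")
    if np.unique(y).size < 2:
        raise ValueError("y must contain both classes")

    x_mean = X.mean(axis=0)
    Xc = X - x_mean
    colsq = np.einsum("ij,ij->j", Xc, Xc)
    degenerate = colsq <= 0.0
    safe_colsq = np.where(degenerate, 1.0, colsq)

    off = None if offset is None else np.asarray(offset, dtype=float)
    base = np.zeros(n) if off is None else off / 2.0
    f0 = _mle_intercept(y, base)
    f = base + f0

    selected = np.zeros(h_max, dtype=int)
    step_coefs = np.zeros(h_max)
    loglik = np.zeros(h_max + 1)
    df = np.zeros(h_max + 1)
    loglik[0] = _boost_loglik(y, f)

    B = np.zeros((n, n)) if compute_df else None
    trace = 0.0
    for h in range(1, h_max + 1):
        pi = expit(2.0 * f)
        u = 2.0 * (y - pi)
        bj = (Xc.T @ u) / safe_colsq
        # SSE_j = u'u - bj_j^2 * colsq_j, so argmin SSE = argmax bj^2 * colsq
        score = bj * bj * colsq
        score[degenerate] = -np.inf
        s = int(np.argmax(score))  # ties: smallest index
        b = bj[s]
        f = f + nu * b * Xc[:, s]
        selected[h - 1] = s
        step_coefs[h - 1] = b
        loglik[h] = _boost_loglik(y, f)
        if compute_df:
            x = Xc[:, s]
            v = x - B.T @ x  # (I - B)' x
            scale = nu / colsq[s]
            B += scale * np.outer(x, v)
            trace += scale * float(x @ v)
            df[h] = trace

    if compute_df:
        aic = -2.0 * loglik + 2.0 * df
        h_stop = aic_stop(aic)
    else:
        aic = np.full(h_max + 1, np.nan)
        h_stop = h_max
    return BoostFit(
        nu=nu,
        h_max=h_max,
        h_stop=h_stop,
        f0=f0,
        selected_sequence=selected,
        step_coefs=step_coefs,
        x_mean=x_mean,
        loglik_path=loglik,
        df_path=df,
        aic_path=aic,
        offset_used=off,
        p=p,
    )


def aic_stop(aic_path: np.ndarray) -> int:
    """Stopping iteration: argmin over h of AIC(h); ties -> smallest h."""
    aic_path = np.asarray(aic_path, dtype=float)
    if aic_path.ndim != 1 or aic_path.size == 0:
        raise ValueError("aic_path must be a non-empty 1-d array")
    return int(np.argmin(aic_path))


def predict_boost(
    fit: BoostFit,
    X_new: np.ndarray,
    offset_new: np.ndarray | float | None = None,
    h: int | None = None,
) -> np.ndarray:
    """Class-1 probabilities pi-hat = 1 / (1 + exp(-2 f-hat))."""
    return expit(2.0 * fit.f_hat(X_new, offset=offset_new, h=h))
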