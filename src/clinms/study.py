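"""Metrics, cross-validated tuning, the method registry, and the study driver.

The comparison covers eleven classifiers of a binary outcome from a clinical
block Z and a high-dimensional feature block X:

* Clin — logistic regression on Z only.
* Boost, SGPLS, RPLS — feature-only fits (boosting, sparse generalized PLS,
  ridge PLS).
* BoostOffClin, SGPLSOffClin, RPLSOffClin — two-step: logistic regression on
  Z first, then the feature method with the clinical predictor as a fixed
  offset.
* ClinOffBoost, ClinOffSGPLS, ClinOffRPLS — reversed: feature fit first,
  then logistic regression on Z with the feature predictor as offset.
* Oracle — logistic regression on Z plus only the truly active feature
  columns (requires simulation ground truth).

Performance is summarized by the test-set misclassification rate
MCR = card(yhat != y) / card(y) * 100 at the 0.5 probability threshold,
true/false positives of the selecting methods, and

    cbar = ||(I - P_Z) eta|| / ||eta||,

the fraction of a fitted predictor's norm orthogonal to the clinical span
(computed on test samples, intercept included in Z's span).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .boosting import BoostFit, fit_boost
from .glm import LogisticFit, fit_logistic
from .pls import RPLSFit, fit_rpls
from .sgpls import SGPLSFit, fit_sgpls
from .synthetic import Dataset, SimulationConfig, make_split, simulate_dataset

logger = logging.getLogger(__name__)

__all__ = [
    "MethodSpec",
    "METHODS",
    "FittedClassifier",
    "StudyConfig",
    "StudyResult",
    "mcr",
    "tp_fp",
    "cbar",
    "cv_error",
    "tune_by_cv",
    "fit_method",
    "run_study",
]


# ---------------------------------------------------------------------------
# metrics


def mcr(y_pred: np.ndarray, y_true: np.ndarray) -> float:
    """Misclassification rate in percent: card(yhat != y) / card(y) * 100."""
    y_pred = np.asarray(y_pred).ravel()
    y_true = np.asarray(y_true).ravel()
    if y_pred.size != y_true.size:
        raise ValueError(
            f"length mismatch: {y_pred.size} predictions vs {y_true.size} labels"
        )
    if y_true.size == 0:
        raise ValueError("empty vectors")
    return float(np.mean(y_pred != y_true) * 100.0)


def tp_fp(selected, active) -> tuple[int, int]:
    """True/false positive counts of a selected variable set.

    TP = |selected ∩ active|, FP = |selected \\ active|.
    """
    sel = set(np.asarray(list(selected), dtype=int).tolist())
    act = set(np.asarray(list(active), dtype=int).tolist())
    return len(sel & act), len(sel - act)


def cbar(eta: np.ndarray, Z: np.ndarray, add_intercept: bool = True) -> float:
    """Fraction of eta's norm orthogonal to the clinical span.

    P_Z is the orthogonal projector onto span([1, Z]) (intercept included by
    default); returns ||(I - P_Z) eta|| / ||eta||.
    """
    eta = np.asarray(eta, dtype=float).ravel()
    norm = np.linalg.norm(eta)
    if norm <= 0:
        raise ValueError("eta has zero norm; cbar undefined")
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[0] != eta.size:
        raise ValueError("eta and Z have different numbers of rows")
    D = np.column_stack([np.ones(eta.size), Z]) if add_intercept else Z
    Q, _ = np.linalg.qr(D)
    resid = eta - Q @ (Q.T @ eta)
    return float(np.linalg.norm(resid) / norm)


# ---------------------------------------------------------------------------
# method registry


@dataclass(frozen=True)
class MethodSpec:
    """A named method with its tuning grid and data requirements."""

    name: str
    uses_clinical: bool
    uses_ms: bool
    selects: bool = False
    tuning_grid: tuple = ()
    needs_ground_truth: bool = False


_RPLS_GRID = tuple(
    {"lam": float(lam), "r": r}
    for lam in range(80, 201, 10)
    for r in range(1, 6)
)
_SGPLS_GRID = tuple(
    {"r": r, "delta": round(0.1 * d, 1)}
    for r in range(1, 6)
    for d in range(1, 10)
)

METHODS: dict[str, MethodSpec] = {
    spec.name: spec
    for spec in [
        MethodSpec("Clin", True, False),
        MethodSpec("Boost", False, True, selects=True),
        MethodSpec("BoostOffClin", True, True, selects=True),
        MethodSpec("ClinOffBoost", True, True),
        MethodSpec("SGPLS", False, True, selects=True, tuning_grid=_SGPLS_GRID),
        MethodSpec(
            "SGPLSOffClin", True, True, selects=True, tuning_grid=_SGPLS_GRID
        ),
        MethodSpec("ClinOffSGPLS", True, True, tuning_grid=_SGPLS_GRID),
        MethodSpec("RPLS", False, True, tuning_grid=_RPLS_GRID),
        MethodSpec("RPLSOffClin", True, True, tuning_grid=_RPLS_GRID),
        MethodSpec("ClinOffRPLS", True, True, tuning_grid=_RPLS_GRID),
        MethodSpec("Oracle", True, True, needs_ground_truth=True),
    ]
}


def _resolve(method: "MethodSpec | str") -> MethodSpec:
    if isinstance(method, MethodSpec):
        return method
    try:
        return METHODS[method]
    except KeyError:
        raise ValueError(
            f"unknown method {method!r}; valid names: {sorted(METHODS)}"
        ) from None


# ---------------------------------------------------------------------------
# fitted-classifier wrapper


@dataclass
class FittedClassifier:
    """Uniform wrapper around any fitted method.

    ``selected`` is the selected-variable index set for selecting methods
    (support of the boosting coefficients, SGPLS active set), else None.
    """

    name: str
    params: dict
    selected: np.ndarray | None = None
    _predict_linear: callable = None
    clinical: LogisticFit | None = None
    model: object = None

    def linear_predictor(
        self, X: np.ndarray | None = None, Z: np.ndarray | None = None
    ) -> np.ndarray:
        return self._predict_linear(X, Z)

    def predict_proba(
        self, X: np.ndarray | None = None, Z: np.ndarray | None = None
    ) -> np.ndarray:
        from scipy.special import expit

        return expit(self.linear_predictor(X, Z))

    def predict(
        self, X: np.ndarray | None = None, Z: np.ndarray | None = None
    ) -> np.ndarray:
        """Hard 0/1 classification at the 0.5 probability threshold."""
        return (self.predict_proba(X, Z) > 0.5).astype(int)


def _fit_ms_only(name: str, X, y, params, boost_opts):
    """Feature-block fit used both standalone and inside ClinOffX."""
    if name.endswith("Boost"):
        fit = fit_boost(X, y, **boost_opts)
        return fit, (lambda Xn: fit.linear_predictor(Xn)), fit.selected_set()
    if name.endswith("SGPLS"):
        fit = fit_sgpls(X, y, delta=params["delta"], r=params["r"])
        return fit, (lambda Xn: fit.linear_predictor(Xn)), fit.active_set
    if name.endswith("RPLS"):
        fit = fit_rpls(X, y, lam=params["lam"], r=params["r"])
        return fit, (lambda Xn: fit.linear_predictor(Xn)), None
    raise ValueError(f"no feature-only fit for {name!r}")


def fit_method(
    method: "MethodSpec | str",
    train: Dataset,
    params: dict | None = None,
    boost_opts: dict | None = None,
) -> FittedClassifier:
    """Fit one registered method on a training dataset.

    ``params`` are the tuning values (from :func:`tune_by_cv` or fixed);
    ``boost_opts`` forwards nu/h_max to the boosting fits.
    """
    spec = _resolve(method)
    params = dict(params or {})
    boost_opts = dict(boost_opts or {})
    X, Z, y = train.X, train.Z, train.y

    if spec.name == "Clin":
        fit = fit_logistic(Z, y)
        return FittedClassifier(
            spec.name,
            params,
            _predict_linear=lambda Xn, Zn: fit.predict_linear(Zn),
            clinical=fit,
            model=fit,
        )

    if spec.name == "Oracle":
        if train.active_set is None:
            raise ValueError("Oracle requires ground-truth active_set")
        active = np.asarray(train.active_set, dtype=int)
        design = np.column_stack([Z, X[:, active]])
        fit = fit_logistic(design, y)
        return FittedClassifier(
            spec.name,
            params,
            _predict_linear=lambda Xn, Zn: fit.predict_linear(
                np.column_stack([Zn, np.asarray(Xn)[:, active]])
            ),
            model=fit,
        )

    if spec.name in ("Boost", "SGPLS", "RPLS"):
        model, lp, selected = _fit_ms_only(spec.name, X, y, params, boost_opts)
        return FittedClassifier(
            spec.name,
            params,
            selected=selected,
            _predict_linear=lambda Xn, Zn=None: lp(Xn),
            model=model,
        )

    if spec.name == "BoostOffClin":
        clin = fit_logistic(Z, y)
        fit = fit_boost(X, y, offset=clin.linear_predictor, **boost_opts)
        return FittedClassifier(
            spec.name,
            params,
            selected=fit.selected_set(),
            _predict_linear=lambda Xn, Zn: fit.linear_predictor(
                Xn, offset=clin.predict_linear(Zn)
            ),
            clinical=clin,
            model=fit,
        )

    if spec.name == "SGPLSOffClin":
        fit = fit_sgpls(
            X, y, delta=params["delta"], r=params["r"], clinical_design=Z
        )
        return FittedClassifier(
            spec.name,
            params,
            selected=fit.active_set,
            _predict_linear=lambda Xn, Zn: fit.linear_predictor(Xn, Zn),
            clinical=fit.clinical,
            model=fit,
        )

    if spec.name == "RPLSOffClin":
        fit = fit_rpls(X, y, lam=params["lam"], r=params["r"], clinical_design=Z)
        return FittedClassifier(
            spec.name,
            params,
            _predict_linear=lambda Xn, Zn: fit.linear_predictor(Xn, Zn),
            clinical=fit.clinical,
            model=fit,
        )

    if spec.name in ("ClinOffBoost", "ClinOffSGPLS", "ClinOffRPLS"):
        model, lp, selected = _fit_ms_only(spec.name, X, y, params, boost_opts)
        clin = fit_logistic(Z, y, offset=lp(X))
        return FittedClassifier(
            spec.name,
            params,
            selected=selected,
            _predict_linear=lambda Xn, Zn: clin.predict_linear(Zn, offset=lp(Xn)),
            clinical=clin,
            model=model,
        )

    raise ValueError(f"unhandled method {spec.name!r}")


# ---------------------------------------------------------------------------
# cross-validated tuning


def cv_error(
    method: "MethodSpec | str",
    train: Dataset,
    params: dict,
    folds: int = 5,
    seed: int | None = None,
    boost_opts: dict | None = None,
    max_reshuffles: int = 20,
) -> float:
    """Mean CV misclassification fraction of one grid point.

    A fold assignment giving any single-class training part is reshuffled
    with the next seed (logged).
    """
    y = train.y
    base = 0 if seed is None else int(seed)
    for shift in range(max_reshuffles):
        kf = KFold(n_splits=folds, shuffle=True, random_state=base + shift)
        splits = list(kf.split(y))
        if all(np.unique(y[tr]).size == 2 for tr, _ in splits):
            if shift:
                logger.info("reshuffled CV folds %d time(s)", shift)
            break
    else:
        raise ValueError("could not build CV folds with two classes per fold")
    errors = 0
    total = 0
    for tr, va in splits:
        fit = fit_method(method, train.subset(tr), params, boost_opts=boost_opts)
        pred = fit.predict(train.X[va], train.Z[va])
        errors += int(np.sum(pred != y[va]))
        total += va.size
    return errors / total


def tune_by_cv(
    method: "MethodSpec | str",
    train: Dataset,
    folds: int = 5,
    seed: int | None = None,
    grid: tuple | list | None = None,
    boost_opts: dict | None = None,
) -> dict:
    """Grid point minimizing mean CV misclassification; ties -> first point."""
    spec = _resolve(method)
    grid = tuple(spec.tuning_grid if grid is None else grid)
    if len(grid) == 0:
        return {}
    if len(grid) == 1:
        return dict(grid[0])
    if folds < 2:
        raise ValueError("folds must be >= 2")
    best, best_err = None, np.inf
    for point in grid:
        err = cv_error(spec, train, dict(point), folds, seed, boost_opts)
        if err < best_err:
            best, best_err = dict(point), err
    return best


# ---------------------------------------------------------------------------
# study driver


@dataclass(frozen=True)
class StudyConfig:
    """Settings for one simulation study run."""

    n_values: tuple = (100, 200, 500)
    p: int = 500
    mu_values: tuple = (0.5, 2.0)
    replicates: int = 50
    methods: tuple = tuple(METHODS)
    seed: int = 0
    q: int = 5
    p_star: int = 20
    gamma_value: float = 1.5
    train_fraction: float = 0.8
    cv_folds: int = 5
    boost_nu: float = 0.1
    boost_h_max: int = 1000


@dataclass
class StudyResult:
    """Per-replicate records plus aggregation helpers."""

    records: pd.DataFrame
    failures: pd.DataFrame
    config: StudyConfig

    def aggregate(self) -> pd.DataFrame:
        """Mean and sd of the MCR by (mu, method, n)."""
        agg = (
            self.records.groupby(["mu", "method", "n"])["mcr"]
            .agg(["mean", "std", "count"])
            .reset_index()
            .rename(columns={"mean": "mcr_mean", "std": "mcr_sd"})
        )
        return agg

    def table(self, mu: float) -> pd.DataFrame:
        """Mean (sd) MCR table for one regime, methods x sample sizes."""
        agg = self.aggregate()
        agg = agg[agg["mu"] == mu]
        out = {}
        for n in sorted(agg["n"].unique()):
            sub = agg[agg["n"] == n].set_index("method")
            out[f"n={n}"] = {
                m: f"{row.mcr_mean:.0f} ({row.mcr_sd:.0f})"
                for m, row in sub.iterrows()
            }
        order = [m for m in self.config.methods if m in set(agg["method"])]
        return pd.DataFrame(out).reindex(order)

    def selection_summary(self) -> pd.DataFrame:
        """Mean TP / FP by (mu, method, n) for the selecting methods."""
        sel = self.records.dropna(subset=["tp"])
        if sel.empty:
            return pd.DataFrame(columns=["mu", "method", "n", "tp_mean", "fp_mean"])
        return (
            sel.groupby(["mu", "method", "n"])[["tp", "fp"]]
            .mean()
            .reset_index()
            .rename(columns={"tp": "tp_mean", "fp": "fp_mean"})
        )

    def cbar_summary(self) -> pd.DataFrame:
        """Mean cbar by (mu, method, n) for the combined methods."""
        cb = self.records.dropna(subset=["cbar"])
        if cb.empty:
            return pd.DataFrame(columns=["mu", "method", "n", "cbar_mean"])
        return (
            cb.groupby(["mu", "method", "n"])["cbar"]
            .mean()
            .reset_index()
            .rename(columns={"cbar": "cbar_mean"})
        )


def _replicate_seeds(master_seed: int, count: int) -> np.ndarray:
    """Deterministic independent per-replicate integer seeds."""
    state = np.random.SeedSequence(master_seed).generate_state(count, dtype=np.uint64)
    return (state % (2**31)).astype(np.int64)


def run_study(config: StudyConfig) -> StudyResult:
    """Run the full simulate / split / tune / fit / evaluate loop.

    For each (mu, n) cell and replicate: simulate a dataset, split it
    80/20, tune each method by CV on the training part, fit, and record the
    test MCR; TP/FP for selecting methods; cbar of the test-set predictor
    for methods combining both blocks.  Per-method failures are recorded and
    excluded from aggregation, never silently dropped.
    """
    rows = []
    failures = []
    cells = [(mu, n) for mu in config.mu_values for n in config.n_values]
    seeds = _replicate_seeds(config.seed, 2 * len(cells) * config.replicates)
    boost_opts = {"nu": config.boost_nu, "h_max": config.boost_h_max}
    k = 0
    for mu, n in cells:
        for rep in range(config.replicates):
            sim_seed = int(seeds[k])
            cv_seed = int(seeds[k + 1])
            k += 2
            ds = simulate_dataset(
                SimulationConfig(
                    n=n,
                    p=config.p,
                    q=config.q,
                    p_star=config.p_star,
                    gamma_value=config.gamma_value,
                    mu=mu,
                    seed=sim_seed,
                )
            )
            plan = make_split(n, config.train_fraction, seed=sim_seed)
            train = ds.subset(plan.train_indices)
            test = ds.subset(plan.test_indices)
            for name in config.methods:
                spec = _resolve(name)
                try:
                    params = tune_by_cv(
                        spec,
                        train,
                        folds=config.cv_folds,
                        seed=cv_seed,
                        boost_opts=boost_opts,
                    )
                    fit = fit_method(spec, train, params, boost_opts=boost_opts)
                    pred = fit.predict(test.X, test.Z)
                    rec = {
                        "mu": mu,
                        "n": n,
                        "p": config.p,
                        "method": spec.name,
                        "replicate": rep,
                        "mcr": mcr(pred, test.y),
                        "tp": np.nan,
                        "fp": np.nan,
                        "cbar": np.nan,
                        "params": repr(params) if params else "",
                    }
                    if spec.selects and ds.active_set is not None:
                        tp, fp = tp_fp(fit.selected, ds.active_set)
                        rec["tp"], rec["fp"] = tp, fp
                    if spec.uses_clinical and spec.uses_ms:
                        eta_test = fit.linear_predictor(test.X, test.Z)
                        if np.linalg.norm(eta_test) > 0:
                            rec["cbar"] = cbar(eta_test, test.Z)
                    rows.append(rec)
                except Exception as exc:  # recorded, not silently dropped
                    logger.warning(
                        "replicate %d method %s failed: %s", rep, spec.name, exc
                    )
                    failures.append(
                        {
                            "mu": mu,
                            "n": n,
                            "method": spec.name,
                            "replicate": rep,
                            "error": str(exc),
                        }
                    )
    columns = [
        "mu", "n", "p", "method", "replicate", "mcr", "tp", "fp", "cbar", "params",
    ]
    records = pd.DataFrame(rows, columns=columns)
    fail_df = pd.DataFrame(failures, columns=["mu", "n", "method", "replicate", "error"])
    return StudyResult(records=records, failures=fail_df, config=config)
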