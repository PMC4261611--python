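"""Simulated clinical + mass-spectrometry datasets.

The simulation design used throughout the package: an n x q clinical block Z
and an n x p high-dimensional feature block X, both with i.i.d. standard
normal entries, a linear predictor

    eta = Z @ gamma + X @ beta,

with a common clinical coefficient gamma_j = ``gamma_value`` and a sparse
feature coefficient vector beta whose first ``p_star`` entries equal
``mu * gamma_value`` (the rest are zero).  ``mu`` controls the relative
importance of the high-dimensional features over the clinical covariates
(mu = 0.5: clinical information dominates; mu = 2: the features dominate).
The binary response is Bernoulli(logistic(eta)).

Datasets round-trip to plain delimited text plus a JSON metadata sidecar,
and :func:`make_split` performs the random train/test partition used by the
evaluation study (80/20 by default).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "Dataset",
    "SplitPlan",
    "simulate_dataset",
    "make_split",
    "save_dataset",
    "load_dataset",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the simulated study design.

    Defaults (q=5, p_star=20, gamma_value=1.5) reproduce the reference
    simulation design; ``mu`` selects the regime.
    """

    n: int
    p: int
    q: int = 5
    p_star: int = 20
    gamma_value: float = 1.5
    mu: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"invalid config: n must be >= 2, got n={self.n}")
        if not (1 <= self.p_star <= self.p):
            raise ValueError(
                "invalid config: requires 1 <= p_star <= p, got "
                f"p_star={self.p_star}, p={self.p}"
            )
        if self.q < 1:
            raise ValueError(f"invalid config: q must be >= 1, got q={self.q}")


@dataclass
class Dataset:
    """A paired (X, Z, y) dataset with optional simulation ground truth."""

    X: np.ndarray
    Z: np.ndarray
    y: np.ndarray
    gamma_true: np.ndarray | None = None
    beta_true: np.ndarray | None = None
    active_set: np.ndarray | None = None
    config: SimulationConfig | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Z = np.asarray(self.Z, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2 or self.Z.ndim != 2:
            raise ValueError("X and Z must be 2-dimensional")
        n = self.X.shape[0]
        if self.Z.shape[0] != n or self.y.shape[0] != n:
            raise ValueError(
                "row counts of X, Z, y must agree; got "
                f"{self.X.shape[0]}, {self.Z.shape[0]}, {self.y.shape[0]}"
            )
        if not np.isin(self.y, [0, 1]).all():
            raise ValueError("y must contain only 0/1 values")
        self.y = self.y.astype(int)
        if self.beta_true is not None:
            self.beta_true = np.asarray(self.beta_true, dtype=float)
            support = np.flatnonzero(self.beta_true)
            if self.active_set is None:
                self.active_set = support
            else:
                self.active_set = np.asarray(self.active_set, dtype=int)
                if not np.array_equal(np.sort(self.active_set), support):
                    raise ValueError(
                        "active_set must equal the nonzero support of beta_true"
                    )

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def q(self) -> int:
        return self.Z.shape[1]

    def subset(self, indices: np.ndarray) -> "Dataset":
        """Row-subset (e.g. the train or test part of a split)."""
        idx = np.asarray(indices, dtype=int)
        return Dataset(
            X=self.X[idx],
            Z=self.Z[idx],
            y=self.y[idx],
            gamma_true=self.gamma_true,
            beta_true=self.beta_true,
            active_set=self.active_set,
            config=self.config,
        )


@dataclass(frozen=True)
class SplitPlan:
    """A disjoint train/test partition of sample indices."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    train_fraction: float
    seed: int | None = None

    def __post_init__(self) -> None:
        train = np.asarray(self.train_indices, dtype=int)
        test = np.asarray(self.test_indices, dtype=int)
        object.__setattr__(self, "train_indices", train)
        object.__setattr__(self, "test_indices", test)
        n = train.size + test.size
        combined = np.sort(np.concatenate([train, test]))
        if not np.array_equal(combined, np.arange(n)):
            raise ValueError(
                "train and test indices must partition 0..n-1 exactly once"
            )


def simulate_dataset(config: SimulationConfig, max_redraws: int = 100) -> Dataset:
    """Draw one dataset from the simulation design.

    Z and X entries are i.i.d. N(0,1); gamma_j = gamma_value for all j;
    beta_k = mu * gamma_value for k < p_star and 0 otherwise;
    y_i ~ Bernoulli(1 / (1 + exp(-eta_i))).

    A replicate whose response is single-class (possible at small n) is
    redrawn from the continuation of the same random stream, since none of
    the classifiers in the comparison is defined for a single class.
    """
    rng = np.random.default_rng(config.seed)
    gamma = np.full(config.q, config.gamma_value, dtype=float)
    beta = np.zeros(config.p, dtype=float)
    beta[: config.p_star] = config.mu * config.gamma_value

    for attempt in range(max_redraws):
        Z = rng.standard_normal((config.n, config.q))
        X = rng.standard_normal((config.n, config.p))
        eta = Z @ gamma + X @ beta
        pi = expit(eta)
        y = rng.binomial(1, pi)
        if 0 < y.sum() < config.n:
            if attempt > 0:
                logger.info(
                    "redrew %d degenerate (single-class) replicate(s) for seed=%r",
                    attempt,
                    config.seed,
                )
            return Dataset(
                X=X,
                Z=Z,
                y=y,
                gamma_true=gamma,
                beta_true=beta,
                config=config,
            )
    raise RuntimeError(
        f"could not draw a two-class response in {max_redraws} attempts "
        "(linear predictor too extreme?)"
    )


def make_split(
    n: int,
    train_fraction: float = 0.8,
    seed: int | None = None,
    y: np.ndarray | None = None,
    stratify: bool = False,
) -> SplitPlan:
    """Uniformly random train/test partition of ``n`` samples.

    ``|train| = round(train_fraction * n)``.  When ``stratify`` is set the
    split is drawn within each class of ``y`` (off by default).
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    if n < 2:
        raise ValueError(f"need n >= 2 samples to split, got {n}")
    n_train = int(round(train_fraction * n))
    if n_train == 0 or n_train == n:
        raise ValueError(
            f"train_fraction={train_fraction} with n={n} leaves an empty part"
        )
    rng = np.random.default_rng(seed)
    if stratify:
        if y is None:
            raise ValueError("stratify=True requires the labels y")
        y = np.asarray(y)
        train_parts = []
        for cls in np.unique(y):
            cls_idx = np.flatnonzero(y == cls)
            perm = rng.permutation(cls_idx)
            k = int(round(train_fraction * cls_idx.size))
            train_parts.append(perm[:k])
        train = np.sort(np.concatenate(train_parts))
        test = np.setdiff1d(np.arange(n), train)
        if train.size == 0 or test.size == 0:
            raise ValueError("stratified split produced an empty part")
    else:
        perm = rng.permutation(n)
        train = np.sort(perm[:n_train])
        test = np.sort(perm[n_train:])
    return SplitPlan(
        train_indices=train,
        test_indices=test,
        train_fraction=train_fraction,
        seed=seed,
    )


def save_dataset(dataset: Dataset, prefix: str | Path) -> None:
    """Write a dataset as delimited text tables plus a JSON metadata sidecar.

    Produces ``<prefix>_features.tsv`` (columns m1..mp),
    ``<prefix>_clinical.tsv`` (columns z1..zq), ``<prefix>_response.tsv``
    (column y) and ``<prefix>_meta.json`` (config + ground truth).
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    feat = pd.DataFrame(
        dataset.X, columns=[f"m{j + 1}" for j in range(dataset.p)]
    )
    clin = pd.DataFrame(
        dataset.Z, columns=[f"z{k + 1}" for k in range(dataset.q)]
    )
    resp = pd.DataFrame({"y": dataset.y})
    feat.to_csv(f"{prefix}_features.tsv", sep="\t", index=False)
    clin.to_csv(f"{prefix}_clinical.tsv", sep="\t", index=False)
    resp.to_csv(f"{prefix}_response.tsv", sep="\t", index=False)
    meta: dict = {}
    if dataset.config is not None:
        meta["config"] = {
            "n": dataset.config.n,
            "p": dataset.config.p,
            "q": dataset.config.q,
            "p_star": dataset.config.p_star,
            "gamma_value": dataset.config.gamma_value,
            "mu": dataset.config.mu,
            "seed": dataset.config.seed,
        }
    if dataset.gamma_true is not None:
        meta["gamma_true"] = dataset.gamma_true.tolist()
    if dataset.beta_true is not None:
        meta["beta_true"] = dataset.beta_true.tolist()
    if dataset.active_set is not None:
        meta["active_set"] = np.asarray(dataset.active_set).tolist()
    with open(f"{prefix}_meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)


def load_dataset(prefix: str | Path) -> Dataset:
    """Read back a dataset written by :func:`save_dataset`."""
    X = pd.read_csv(f"{prefix}_features.tsv", sep="\t").to_numpy(dtype=float)
    Z = pd.read_csv(f"{prefix}_clinical.tsv", sep="\t").to_numpy(dtype=float)
    y = pd.read_csv(f"{prefix}_response.tsv", sep="\t")["y"].to_numpy()
    meta_path = Path(f"{prefix}_meta.json")
    gamma_true = beta_true = active_set = config = None
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        if "gamma_true" in meta:
            gamma_true = np.asarray(meta["gamma_true"], dtype=float)
        if "beta_true" in meta:
            beta_true = np.asarray(meta["beta_true"], dtype=float)
        if "active_set" in meta:
            active_set = np.asarray(meta["active_set"], dtype=int)
        if "config" in meta:
            config = SimulationConfig(**meta["config"])
    return Dataset(
        X=X,
        Z=Z,
        y=y,
        gamma_true=gamma_true,
        beta_true=beta_true,
        active_set=active_set,
        config=config,
    )
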