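"""Nonlinear regression linking per-subject connectivity summaries to DDM
parameters, scored by 10-fold cross-validated normalized error.

For each frequency band and gating process, a one-hidden-layer feedforward
network maps the per-subject [mean linear connectivity, mean nonlinear
connectivity] features to one DDM parameter at a time.  The goodness of fit
is the mean CV mean-squared prediction error divided by the mean absolute
value of the target parameter ("normalized error"), with a 95% t-interval
over fold errors; non-overlapping intervals between two runs are read as a
significant difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor
from sklearn.preprocessing import StandardScaler

__all__ = ["RegressionResult", "fit_predict_cv", "compare_conditions"]


@dataclass
class RegressionResult:
    target: str  # "a" | "v" | "t0" (free-form label)
    band: str | None
    process: str | None
    normalized_error: float
    ci95: tuple[float, float]
    fold_errors: list[float]  # normalized per-fold errors


def fit_predict_cv(
    X: np.ndarray,
    y: np.ndarray,
    hidden_units: int = 8,
    folds: int = 10,
    seed: int = 0,
    target: str = "y",
    band: str | None = None,
    process: str | None = None,
    alpha: float = 1e-1,
    max_iter: int = 2000,
) -> RegressionResult:
    """Cross-validated nonlinear regression of one DDM parameter.

    The per-fold test MSE is divided by mean |y| (so errors of parameters
    on different scales are comparable); the summary is the mean of the
    normalized fold errors with its 95% t-interval.  Fold assignment is a
    seeded shuffle, so results do not depend on subject ordering.  The
    network is a single tanh hidden layer trained by L-BFGS with a ridge
    penalty ``alpha`` as the capacity control, which is what a sample of a
    few dozen subjects supports.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim == 1:
        X = X[:, None]
    n = y.size
    if n < folds:
        raise ValueError(f"need at least {folds} subjects for {folds}-fold CV")
    scale = float(np.mean(np.abs(y)))
    if scale == 0.0:
        raise ValueError("target has zero mean absolute value")

    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_errors = []
    for tr, te in kf.split(X):
        scaler = StandardScaler().fit(X[tr])
        net = MLPRegressor(
            hidden_layer_sizes=(hidden_units,),
            activation="tanh",
            solver="lbfgs",
            alpha=alpha,
            max_iter=max_iter,
            random_state=seed,
        )
        net.fit(scaler.transform(X[tr]), y[tr])
        pred = net.predict(scaler.transform(X[te]))
        fold_errors.append(float(np.mean((pred - y[te]) ** 2) / scale))

    fe = np.asarray(fold_errors)
    mean = float(fe.mean())
    se = float(fe.std(ddof=1) / np.sqrt(folds))
    tq = float(stats.t.ppf(0.975, folds - 1))
    return RegressionResult(
        target=target,
        band=band,
        process=process,
        normalized_error=mean,
        ci95=(mean - tq * se, mean + tq * se),
        fold_errors=fold_errors,
    )


def compare_conditions(a: RegressionResult, b: RegressionResult) -> bool:
    """Significance by 95% CI non-overlap of the normalized errors."""
    if a.target != b.target:
        raise ValueError("results target different parameters")
    lo_a, hi_a = a.ci95
    lo_b, hi_b = b.ci95
    return hi_a < lo_b or hi_b < lo_a
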