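"""Nonlinear-MVAR effective connectivity estimated with an artificial neural
network (nCREANN-style).

Each node's current sample is modeled as f(xp) + noise, where xp stacks the
p past samples of all M nodes and f splits into an explicit linear path and
a one-hidden-layer tanh path:

    x_j(n) = sum_{i,k} W_lin[(k,i), j] * x_i(n-k)  +  fNonLin_j(xp) + e_j(n)

The split between fLin and fNonLin is not identifiable from the loss alone:
tanh is locally linear, so the hidden path can silently absorb linear
structure.  After training, the model is therefore re-centered: the hidden
path's best linear approximation over the training trajectory (ordinary
least squares of its output on the embedded inputs) is folded into the
linear weights, leaving a purely nonlinear residual path.  Predictions are
unchanged by this reparameterization.

Directed connectivity is read off the re-centered model: linear
connectivity lC[i -> j] is the mean absolute linear weight from node i's
lags to node j; nonlinear connectivity NC[i -> j] is the mean absolute
partial derivative of the residual nonlinear path of node j with respect to
x_i(n-k), evaluated along the observed trajectory (sensitivity
attribution).  Both reduce correctly in the limiting cases: on purely
linear data the residual path has near-zero sensitivity, and with the
hidden layer removed the model is an ordinary VAR.

Connectivity matrices here use rows = source, columns = target:
``lC[i, j]`` is the influence of node i on node j.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "NMVARModel",
    "ConnectivityMatrix",
    "embed_lags",
    "train_ncreann",
    "linear_connectivity",
    "nonlinear_connectivity",
    "predict",
    "select_order",
    "OrderSelection",
    "normalize_connectivity",
    "average_nonself",
]


@dataclass
class NMVARModel:
    M: int
    p: int
    W_lin: np.ndarray  # (M*p, M); row (k-1)*M + i = lag k of node i
    W_h: np.ndarray  # (M*p, H)
    b_h: np.ndarray  # (H,)
    W_o: np.ndarray  # (H, M)
    b_o: np.ndarray  # (M,)
    sigma: np.ndarray  # (M,) residual SDs on training data
    loss: float
    seed: int
    n_iter: int
    converged: bool
    # linear component of the hidden path on the training trajectory,
    # already folded into W_lin/b_o; the residual nonlinear path is
    # tanh(X W_h + b_h) W_o - X nl_lin - nl_c
    nl_lin: np.ndarray | None = None  # (M*p, M)
    nl_c: np.ndarray | None = None  # (M,)
    #: False when validation showed no gain from the hidden path and it was
    #: pruned (the model is then exactly the least-squares VAR)
    nonlinear_retained: bool = True

    def __post_init__(self) -> None:
        if self.nl_lin is None:
            self.nl_lin = np.zeros_like(self.W_lin)
        if self.nl_c is None:
            self.nl_c = np.zeros_like(self.b_o)


@dataclass
class ConnectivityMatrix:
    lC: np.ndarray  # (M, M), [source, target], nonnegative
    NC: np.ndarray  # (M, M), [source, target], nonnegative
    band: str | None = None
    process: str | None = None
    normalized: bool = False


def embed_lags(ts: np.ndarray | list, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Lag-embed one or more trials into regression matrices.

    ``ts`` is (M, L) for a single trial or (n_trials, M, L); trials are
    embedded separately so no regression row spans a concatenation joint.
    Returns X (N, M*p) with column (k-1)*M + i holding x_i(n-k), and
    Y (N, M).
    """
    arr = np.asarray(ts, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError("ts must be (M, L) or (n_trials, M, L)")
    n_trials, M, L = arr.shape
    if L <= p:
        raise ValueError(f"series length {L} must exceed order {p}")
    Xs, Ys = [], []
    for tr in arr:
        rows = []
        for k in range(1, p + 1):
            rows.append(tr[:, p - k : L - k].T)  # x_i(n-k), n = p..L-1
        Xs.append(np.hstack(rows))
        Ys.append(tr[:, p:].T)
    return np.vstack(Xs), np.vstack(Ys)


def _unpack(theta, M, p, H):
    d = M * p
    i = 0
    W_lin = theta[i : i + d * M].reshape(d, M); i += d * M
    W_h = theta[i : i + d * H].reshape(d, H); i += d * H
    b_h = theta[i : i + H]; i += H
    W_o = theta[i : i + H * M].reshape(H, M); i += H * M
    b_o = theta[i : i + M]
    return W_lin, W_h, b_h, W_o, b_o


def _loss_grad(theta, X, Y, M, p, H, wd):
    W_lin, W_h, b_h, W_o, b_o = _unpack(theta, M, p, H)
    N = X.shape[0]
    Hact = np.tanh(X @ W_h + b_h)
    E = X @ W_lin + Hact @ W_o + b_o - Y
    loss = 0.5 * np.sum(E * E) / N + 0.5 * wd * (np.sum(W_h * W_h) + np.sum(W_o * W_o))
    gE = E / N
    g_Wlin = X.T @ gE
    g_bo = gE.sum(axis=0)
    g_Wo = Hact.T @ gE + wd * W_o
    dH = (gE @ W_o.T) * (1.0 - Hact * Hact)
    g_Wh = X.T @ dH + wd * W_h
    g_bh = dH.sum(axis=0)
    grad = np.concatenate(
        [g_Wlin.ravel(), g_Wh.ravel(), g_bh.ravel(), g_Wo.ravel(), g_bo.ravel()]
    )
    return loss, grad


def train_ncreann(
    ts: np.ndarray | list,
    p: int = 10,
    hidden_units: int | None = None,
    max_iter: int = 1000,
    weight_decay: float = 1e-2,
    restarts: int = 3,
    seed: int = 0,
    init_scale: float = 1.0,
) -> NMVARModel:
    """Jointly fit the linear and nonlinear paths by one-step-ahead least
    squares (full-batch L-BFGS), deterministic given the seed.

    The linear path is initialized at the ordinary-VAR least-squares
    solution and left unpenalized; the hidden path carries the
    ``weight_decay`` penalty.  Capacity control is validation-based: a
    seeded 10% row holdout scores each restart, and if the best network
    does not beat the plain least-squares VAR on held-out error the hidden
    path is pruned, leaving exactly the VAR (NC identically 0).  Kept
    networks are re-centered (the hidden path's linear component on the
    training trajectory is folded into the linear weights) so the
    linear/nonlinear split is identifiable.  Hidden layer defaults to
    2*M*p tanh units.
    """
    X_all, Y_all = embed_lags(ts, p)
    N_all, d = X_all.shape
    M = Y_all.shape[1]
    H = hidden_units if hidden_units is not None else 2 * M * p
    n_params = d * M + d * H + H + H * M + M
    if N_all < 10 * n_params:
        import warnings

        warnings.warn(
            f"{N_all} embedded samples for {n_params} parameters (< 10x); "
            "estimates may be unstable"
        )
    root = np.random.SeedSequence(seed)
    split_rng = np.random.default_rng(root.spawn(1)[0])
    perm = split_rng.permutation(N_all)
    n_val = max(1, N_all // 10)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    X, Y = X_all[tr_idx], Y_all[tr_idx]
    Xv, Yv = X_all[val_idx], Y_all[val_idx]
    N = X.shape[0]

    Xc1 = np.hstack([X, np.ones((N, 1))])
    Bc_ols, *_ = np.linalg.lstsq(Xc1, Y, rcond=None)
    W_ols, b_ols = Bc_ols[:-1], Bc_ols[-1]
    val_lin = float(np.mean((Xv @ W_ols + b_ols - Yv) ** 2))

    best = None
    best_val = np.inf
    for r, sseq in enumerate(root.spawn(restarts + 1)[1:]):
        rng = np.random.default_rng(sseq)
        W_h0 = rng.standard_normal((d, H)) * (init_scale / np.sqrt(d))
        W_o0 = rng.standard_normal((H, M)) * (init_scale * 0.3 / np.sqrt(H))
        theta0 = np.concatenate(
            [W_ols.ravel(), W_h0.ravel(), rng.standard_normal(H) * 0.01,
             W_o0.ravel(), b_ols]
        )
        res = minimize(
            _loss_grad,
            theta0,
            args=(X, Y, M, p, H, weight_decay),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": max_iter, "ftol": 1e-10, "gtol": 1e-8},
        )
        Wl, Wh, bh, Wo, bo = _unpack(res.x, M, p, H)
        val = float(
            np.mean((Xv @ Wl + np.tanh(Xv @ Wh + bh) @ Wo + bo - Yv) ** 2)
        )
        if val < best_val:
            best, best_val = res, val

    if best_val >= val_lin:
        # hidden path does not generalize: prune to the plain VAR
        resid = Xc1 @ Bc_ols - Y
        return NMVARModel(
            M=M,
            p=p,
            W_lin=W_ols,
            W_h=np.zeros((d, H)),
            b_h=np.zeros(H),
            W_o=np.zeros((H, M)),
            b_o=b_ols,
            sigma=resid.std(axis=0, ddof=1),
            loss=float(0.5 * np.mean(np.sum(resid**2, axis=1))),
            seed=seed,
            n_iter=0,
            converged=True,
            nonlinear_retained=False,
        )

    W_lin, W_h, b_h, W_o, b_o = _unpack(best.x, M, p, H)

    # re-center: fold the hidden path's linear component (OLS on the
    # training trajectory) into the linear weights so fNonLin is purely
    # nonlinear; predictions are unchanged
    F = np.tanh(X @ W_h + b_h) @ W_o
    Bc, *_ = np.linalg.lstsq(Xc1, F, rcond=None)
    nl_lin, nl_c = Bc[:-1], Bc[-1]

    resid = X @ W_lin + F + b_o - Y
    return NMVARModel(
        M=M,
        p=p,
        W_lin=W_lin + nl_lin,
        W_h=W_h,
        b_h=b_h,
        W_o=W_o,
        b_o=b_o + nl_c,
        sigma=resid.std(axis=0, ddof=1),
        loss=float(best.fun),
        seed=seed,
        n_iter=int(best.nit),
        converged=bool(best.success or best.nit >= max_iter),
        nl_lin=nl_lin,
        nl_c=nl_c,
        nonlinear_retained=True,
    )


def predict(model: NMVARModel, X: np.ndarray, linear_only: bool = False) -> np.ndarray:
    """One-step-ahead prediction from embedded inputs.

    ``linear_only`` evaluates just the (re-centered) linear path fLin."""
    lin = X @ model.W_lin + model.b_o
    if linear_only:
        return lin
    nonlin = np.tanh(X @ model.W_h + model.b_h) @ model.W_o - X @ model.nl_lin - model.nl_c
    return lin + nonlin


def linear_connectivity(model: NMVARModel) -> np.ndarray:
    """lC[i, j] = mean over lags of |linear weight (j <- i, lag k)|."""
    W = model.W_lin.reshape(model.p, model.M, model.M)  # (lag, source, target)
    return np.abs(W).mean(axis=0)


def nonlinear_connectivity(
    model: NMVARModel, ts: np.ndarray | list, chunk: int = 2048
) -> np.ndarray:
    """NC[i, j]: trajectory-mean absolute sensitivity of fNonLin_j to x_i(n-k).

    The partial derivative of the residual nonlinear path is
    W_h[(k,i), :] * (1 - tanh^2) * W_o[:, j] summed over hidden units minus
    the folded-out linear component, evaluated at every observed embedded
    sample; NC averages its absolute value over samples and lags.
    """
    X, _ = embed_lags(ts, model.p)
    d = model.M * model.p
    acc = np.zeros((d, model.M))
    n = 0
    for start in range(0, X.shape[0], chunk):
        Xc = X[start : start + chunk]
        D = 1.0 - np.tanh(Xc @ model.W_h + model.b_h) ** 2  # (n, H)
        # J[n, c, j] = sum_h W_h[c,h] D[n,h] W_o[h,j] - nl_lin[c,j]
        J = np.einsum("ch,nh,hj->ncj", model.W_h, D, model.W_o, optimize=True)
        J -= model.nl_lin[None, :, :]
        acc += np.abs(J).sum(axis=0)
        n += Xc.shape[0]
    sens = (acc / n).reshape(model.p, model.M, model.M)  # (lag, source, target)
    return sens.mean(axis=0)


@dataclass
class OrderSelection:
    aic_order: int
    bic_order: int
    recommended: int
    aic: dict
    bic: dict


def select_order(ts: np.ndarray | list, p_max: int = 20) -> OrderSelection:
    """Akaike and Schwarz order selection on the linear VAR backbone.

    For each candidate order the VAR is fitted by least squares on the
    trial-respecting lag embedding; the criteria penalize log det of the
    residual covariance by the parameter count.  The recommendation is the
    BIC minimizer (the stronger penalty).
    """
    aic, bic = {}, {}
    for p in range(1, p_max + 1):
        X, Y = embed_lags(ts, p)
        N, _ = X.shape
        M = Y.shape[1]
        Xc = np.hstack([X, np.ones((N, 1))])
        B, *_ = np.linalg.lstsq(Xc, Y, rcond=None)
        E = Y - Xc @ B
        S = (E.T @ E) / N
        sign, logdet = np.linalg.slogdet(S)
        if sign <= 0:
            logdet = -np.inf
        k = p * M * M
        aic[p] = float(logdet + 2.0 * k / N)
        bic[p] = float(logdet + np.log(N) * k / N)
    a = min(aic, key=aic.get)
    b = min(bic, key=bic.get)
    return OrderSelection(aic_order=a, bic_order=b, recommended=b, aic=aic, bic=bic)


def normalize_connectivity(matrices: dict) -> dict:
    """Normalize a subject's band x condition set of connectivity matrices.

    Every lC is divided by the maximum lC entry across the whole set, and
    independently every NC by the maximum NC, so each measure lies in [0, 1]
    with at least one entry exactly 1.  Idempotent.
    """
    if not matrices:
        raise ValueError("empty connectivity set")
    max_l = max(float(np.max(m.lC)) for m in matrices.values())
    max_n = max(float(np.max(m.NC)) for m in matrices.values())
    if max_l <= 0 and max_n <= 0:
        raise ValueError("all-zero connectivity set")
    out = {}
    for key, m in matrices.items():
        out[key] = ConnectivityMatrix(
            lC=m.lC / max_l if max_l > 0 else m.lC.copy(),
            NC=m.NC / max_n if max_n > 0 else m.NC.copy(),
            band=m.band,
            process=m.process,
            normalized=True,
        )
    return out


def average_nonself(conn: ConnectivityMatrix) -> tuple[float, float]:
    """Mean of the off-diagonal entries, per measure (lC, NC)."""
    M = conn.lC.shape[0]
    if M < 2:
        raise ValueError("need at least 2 nodes for non-self averages")
    mask = ~np.eye(M, dtype=bool)
    return float(conn.lC[mask].mean()), float(conn.NC[mask].mean())
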