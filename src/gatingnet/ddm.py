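"""Drift-diffusion model: simulation, first-passage densities, ML fitting.

The model is the standard two-boundary Wiener diffusion with unit diffusion
coefficient: evidence starts at ``zr * a``, drifts with rate ``v`` and is
absorbed at 0 (the "mismatch" response) or at ``a`` (the "match" response).
Observed response time is first-passage time plus the non-decision time
``t0``.  Relative start ``zr`` is fixed at 0.5 and the inter-trial
variability parameters are fixed at zero, so only (a, v, t0) are free.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = ["DDMParams", "DDMFit", "simulate_ddm", "wfpt_density", "prob_upper", "fit_ddm"]

UPPER = "match"
LOWER = "mismatch"

# box constraints for the optimizer; t0 is additionally capped at min observed rt
BOUNDS_A = (0.3, 3.0)
BOUNDS_V = (-5.0, 5.0)


@dataclass(frozen=True)
class DDMParams:
    a: float  # boundary separation
    v: float  # drift rate (positive drives toward the upper/"match" boundary)
    t0: float  # non-decision time, seconds
    zr: float = 0.5  # relative start point, fixed
    szr: float = 0.0
    sv: float = 0.0
    p_contaminant: float = 0.0

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError("boundary separation a must be > 0")
        if not 0 < self.zr < 1:
            raise ValueError("relative start zr must lie in (0, 1)")
        if self.t0 < 0:
            raise ValueError("non-decision time t0 must be >= 0")
        if self.szr != 0 or self.sv != 0 or self.p_contaminant != 0:
            raise ValueError("inter-trial variability parameters are fixed at 0")


@dataclass
class DDMFit:
    """ML estimates per condition cell."""

    params: dict  # cell label -> DDMParams
    loglik: dict  # cell label -> float
    n_trials: dict  # cell label -> int
    converged: dict  # cell label -> bool


def prob_upper(params: DDMParams) -> float:
    """Closed-form probability of absorption at the upper boundary."""
    a, v, zr = params.a, params.v, params.zr
    if v == 0.0:
        return zr
    return float(np.expm1(-2.0 * v * a * zr) / np.expm1(-2.0 * v * a))


def simulate_ddm(
    params: DDMParams,
    n: int,
    dt: float = 1e-4,
    seed: int | np.random.Generator = 0,
    max_t: float = 20.0,
) -> pd.DataFrame:
    """Simulate ``n`` trials by an Euler-Maruyama random walk.

    Returns a DataFrame with columns ``response`` ("match" for upper-boundary
    absorption, "mismatch" for lower) and ``rt_s``.  Trials not absorbed
    within ``max_t`` seconds of decision time are resampled; the count is in
    ``df.attrs["n_resampled"]``.
    """
    if dt > 1e-3:
        raise ValueError("dt must be <= 1e-3 s for an accurate walk")
    rng = np.random.default_rng(seed)
    max_steps = int(np.ceil(max_t / dt))
    sqdt = np.sqrt(dt)

    rts = np.empty(n)
    upper = np.empty(n, dtype=bool)
    pending = np.arange(n)
    n_resampled = 0
    while pending.size:
        x = np.full(pending.size, params.zr * params.a)
        t_steps = np.zeros(pending.size, dtype=np.int64)
        alive = np.ones(pending.size, dtype=bool)
        hit_up = np.zeros(pending.size, dtype=bool)
        for step in range(1, max_steps + 1):
            idx = np.flatnonzero(alive)
            if idx.size == 0:
                break
            x[idx] += params.v * dt + sqdt * rng.standard_normal(idx.size)
            crossed_up = x[idx] >= params.a
            crossed_lo = x[idx] <= 0.0
            done = crossed_up | crossed_lo
            fin = idx[done]
            hit_up[fin] = crossed_up[done]
            t_steps[fin] = step
            alive[fin] = False
        finished = ~alive
        tgt = pending[finished]
        rts[tgt] = t_steps[finished] * dt + params.t0
        upper[tgt] = hit_up[finished]
        n_resampled += int(np.count_nonzero(alive))
        pending = pending[alive]

    df = pd.DataFrame(
        {"response": np.where(upper, UPPER, LOWER), "rt_s": rts}
    )
    df.attrs["n_resampled"] = n_resampled
    return df


def _f0(tau: np.ndarray, w: float, eps: float) -> np.ndarray:
    """Density of first passage through 0 for a zero-drift unit diffusion
    started at relative position ``w`` on [0, 1], at scaled times ``tau``.

    Uses the small-time and large-time series, each truncated at the number
    of terms that bounds the absolute error by ``eps`` (per-time switch).
    """
    tau = np.asarray(tau, dtype=float)
    out = np.zeros_like(tau)
    pos = tau > 0
    if not np.any(pos):
        return out
    t = tau[pos]

    # terms needed by each expansion (error bounds of the standard series)
    with np.errstate(invalid="ignore", divide="ignore"):
        arg_s = 2.0 * np.sqrt(2.0 * np.pi * t) * eps
        ks = np.where(
            arg_s < 1.0,
            2.0 + np.sqrt(np.maximum(-2.0 * t * np.log(np.maximum(arg_s, 1e-300)), 0.0)),
            2.0,
        )
        ks = np.maximum(ks, np.sqrt(t) + 1.0)
        arg_l = np.pi * t * eps
        kl = np.where(
            arg_l < 1.0,
            np.sqrt(np.maximum(-2.0 * np.log(np.maximum(arg_l, 1e-300)), 0.0) / (np.pi**2 * t)),
            1.0 / (np.pi * np.sqrt(t)),
        )
        kl = np.maximum(kl, 1.0 / (np.pi * np.sqrt(t)))

    use_small = ks < kl
    val = np.empty_like(t)

    if np.any(use_small):
        ts = t[use_small]
        K = int(np.ceil(np.max(ks[use_small])))
        # K consecutive image terms centered on 0
        ks_range = np.arange(-((K - 1) // 2), K // 2 + 1)
        terms = (w + 2.0 * ks_range[:, None]) * np.exp(
            -((w + 2.0 * ks_range[:, None]) ** 2) / (2.0 * ts[None, :])
        )
        val[use_small] = terms.sum(axis=0) / np.sqrt(2.0 * np.pi * ts**3)

    if np.any(~use_small):
        tl = t[~use_small]
        K = int(np.ceil(np.max(kl[~use_small])))
        k_range = np.arange(1, K + 1)
        terms = (
            k_range[:, None]
            * np.exp(-(k_range[:, None] ** 2) * np.pi**2 * tl[None, :] / 2.0)
            * np.sin(k_range[:, None] * np.pi * w)
        )
        val[~use_small] = np.pi * terms.sum(axis=0)

    out[pos] = np.maximum(val, 0.0)
    return out


def wfpt_density(
    t: np.ndarray | float,
    params: DDMParams,
    boundary: str = UPPER,
    eps: float = 1e-4,
) -> np.ndarray:
    """Wiener first-passage-time density at observed times ``t`` (seconds).

    ``boundary`` selects absorption at the upper ("match") or lower
    ("mismatch") boundary; the density is defective and the two boundaries
    together integrate to 1.  Times at or below ``t0`` get density 0.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    a, v, zr = params.a, params.v, params.zr
    if boundary == UPPER:
        v, zr = -v, 1.0 - zr
    elif boundary != LOWER:
        raise ValueError(f"unknown boundary {boundary!r}")
    td = t - params.t0
    tau = np.where(td > 0, td, np.nan) / a**2
    dens = np.zeros_like(t)
    ok = td > 0
    if np.any(ok):
        # map the eps on the physical-time density to the scaled series
        f0 = _f0(tau[ok], zr, eps * a**2)
        dens[ok] = (
            np.exp(-v * a * zr - v**2 * td[ok] / 2.0) / a**2 * f0
        )
    return dens


def _negloglik(theta: np.ndarray, rt: np.ndarray, is_upper: np.ndarray, eps: float) -> float:
    a, v, t0 = theta
    if not (BOUNDS_A[0] < a < BOUNDS_A[1] and BOUNDS_V[0] < v < BOUNDS_V[1]):
        return 1e10
    if not (0.0 < t0 < rt.min()):
        return 1e10
    params = DDMParams(a=a, v=v, t0=t0)
    dens = np.empty_like(rt)
    dens[is_upper] = wfpt_density(rt[is_upper], params, UPPER, eps)
    dens[~is_upper] = wfpt_density(rt[~is_upper], params, LOWER, eps)
    if np.any(dens <= 0.0):
        return 1e10
    return float(-np.sum(np.log(dens)))


def _fit_cell(
    rt: np.ndarray,
    is_upper: np.ndarray,
    seed: int,
    n_restarts: int = 5,
    eps: float = 1e-4,
) -> tuple[DDMParams, float, bool]:
    rng = np.random.default_rng(seed)
    rt_min = float(rt.min())
    p_up = float(np.mean(is_upper))
    best = None
    for r in range(n_restarts):
        a0 = float(np.clip(1.0 * np.exp(0.3 * rng.standard_normal()), 0.4, 2.5)) if r else 1.0
        # crude drift guess from the choice fraction, jittered on restarts
        v0 = 2.0 * (p_up - 0.5) + (0.4 * rng.standard_normal() if r else 0.0)
        t00 = rt_min * (0.85 if r == 0 else float(rng.uniform(0.5, 0.95)))
        res = minimize(
            _negloglik,
            np.array([a0, v0, t00]),
            args=(rt, is_upper, eps),
            method="Nelder-Mead",
            options={"xatol": 1e-5, "fatol": 1e-7, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    a, v, t0 = best.x
    params = DDMParams(a=float(a), v=float(v), t0=float(t0))
    return params, -float(best.fun), bool(best.fun < 1e9)


def fit_ddm(
    trials: pd.DataFrame,
    seed: int = 0,
    min_trials: int = 20,
    correct_only: bool = True,
    n_restarts: int = 5,
    eps: float = 1e-4,
) -> DDMFit:
    """Per-cell maximum-likelihood fit of (a, v, t0).

    ``trials`` needs columns ``response`` and ``rt_s``; if ``switching`` and
    ``trial_type`` columns exist the fit is done per Switching x TrialType
    cell, otherwise a single cell named "all" is fitted.  With
    ``correct_only`` (the default) only rows with ``correct == 1`` enter the
    likelihood; responses are boundary-coded ("match" -> upper, "mismatch"
    -> lower).  Cells with fewer than ``min_trials`` usable trials are
    reported as missing (no entry in ``params``).
    """
    df = trials
    if correct_only and "correct" in df.columns:
        df = df[df["correct"] == 1]
    if {"switching", "trial_type"}.issubset(df.columns):
        groups = df.groupby(
            df["switching"].astype(str) + "-" + df["trial_type"].astype(str)
        )
    else:
        groups = [("all", df)]

    fit = DDMFit(params={}, loglik={}, n_trials={}, converged={})
    for cell, sub in groups:
        fit.n_trials[cell] = len(sub)
        if len(sub) < min_trials:
            fit.converged[cell] = False
            continue
        rt = sub["rt_s"].to_numpy(dtype=float)
        is_upper = (sub["response"] == UPPER).to_numpy()
        params, ll, conv = _fit_cell(rt, is_upper, seed=seed, n_restarts=n_restarts, eps=eps)
        fit.params[cell] = params
        fit.loglik[cell] = ll
        fit.converged[cell] = conv
    return fit
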