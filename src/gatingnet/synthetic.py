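"""Synthetic behavioral cohorts and coupled neural sources with known ground truth.

Everything downstream (behavioral statistics, DDM fitting, beamforming,
connectivity estimation, brain-behavior regression) is exercised on data from
this module, so each generator records the ground truth it used.

Randomness: every public generator takes a single seed and derives independent
substreams (per subject, per trial batch) through ``numpy.random.SeedSequence``
spawning, so runs are reproducible and subjects are statistically independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import firwin, lfilter

from gatingnet.containers import CONDITIONS, EpochArray, Leadfield
from gatingnet.ddm import DDMParams, simulate_ddm

__all__ = [
    "CohortSpec",
    "CouplingSpec",
    "gen_behavior",
    "gen_coupled_sources",
    "gen_sensor_epochs",
    "make_leadfield",
    "random_stable_var",
]

#: Cell-mean DDM parameters of the reference-back task used as generator
#: defaults: boundary separation and non-decision time carry the switch cost
#: (switch > nonswitch), drift is larger on switch trials.
DEFAULT_DDM_PARAMS = {
    "switch-reference": DDMParams(a=0.93, v=0.09, t0=0.356),
    "nonswitch-reference": DDMParams(a=0.86, v=0.01, t0=0.332),
    "switch-comparison": DDMParams(a=0.93, v=0.09, t0=0.356),
    "nonswitch-comparison": DDMParams(a=0.86, v=0.01, t0=0.332),
}

OVERFLOW_GUARD = 1e6


@dataclass
class CohortSpec:
    """Study-condition description for a synthetic behavioral cohort."""

    n_subjects: int = 20
    trials_per_condition: int = 100
    ddm_params_by_condition: dict = field(
        default_factory=lambda: dict(DEFAULT_DDM_PARAMS)
    )
    p_match: float = 0.5
    p_reference: float = 0.5  # trial-type ratio; the task's is a free parameter
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trials_per_condition < 1:
            raise ValueError("trials_per_condition must be >= 1")
        if not 0 < self.p_match < 1:
            raise ValueError("p_match must lie in (0, 1)")
        if set(self.ddm_params_by_condition) != set(CONDITIONS):
            raise ValueError(f"need DDM parameters for all cells {CONDITIONS}")
        for cond, p in self.ddm_params_by_condition.items():
            if not isinstance(p, DDMParams):
                self.ddm_params_by_condition[cond] = DDMParams(*p)


def gen_behavior(spec: CohortSpec, dt: float = 1e-3) -> pd.DataFrame:
    """Generate a per-trial behavioral table for the reference-back task.

    Frame colors (reference/comparison) are drawn i.i.d. with
    ``p_reference``; the switch/nonswitch label follows from the previous
    trial's frame, so the first trial of each subject is unlabeled and
    dropped.  Match/mismatch ground truth is i.i.d. with ``p_match``.  Choice
    and RT come from the DDM simulator with the cell's parameters; the drift
    is stimulus-coded (sign of v points to the correct boundary), and
    ``correct`` marks trials absorbed at the correct boundary.

    Trials are generated until every Switching x TrialType cell holds exactly
    ``trials_per_condition`` trials, so the output has
    ``n_subjects * 4 * trials_per_condition`` rows.
    """
    root = np.random.SeedSequence(spec.seed)
    subject_seeds = root.spawn(spec.n_subjects)
    rows = []
    tpc = spec.trials_per_condition
    for subj, sseq in enumerate(subject_seeds):
        rng = np.random.default_rng(sseq)
        counts = {c: 0 for c in CONDITIONS}
        kept = []  # (trial_index, condition, matching)
        prev_type = "reference" if rng.random() < spec.p_reference else "comparison"
        trial_idx = 0
        while min(counts.values()) < tpc:
            ttype = "reference" if rng.random() < spec.p_reference else "comparison"
            switching = "nonswitch" if ttype == prev_type else "switch"
            prev_type = ttype
            cond = f"{switching}-{ttype}"
            trial_idx += 1
            if counts[cond] >= tpc:
                continue
            counts[cond] += 1
            matching = "match" if rng.random() < spec.p_match else "mismatch"
            kept.append((trial_idx, switching, ttype, matching))

        # simulate RTs in batches per (cell, matching) for speed
        kept_df = pd.DataFrame(
            kept, columns=["trial", "switching", "trial_type", "matching"]
        )
        kept_df["subject"] = subj
        kept_df["response"] = ""
        kept_df["rt_s"] = np.nan
        for (sw, tt, m), grp in kept_df.groupby(["switching", "trial_type", "matching"]):
            base = spec.ddm_params_by_condition[f"{sw}-{tt}"]
            # stimulus coding: drift toward the correct boundary
            v = base.v if m == "match" else -base.v
            sim = simulate_ddm(
                DDMParams(a=base.a, v=v, t0=base.t0),
                n=len(grp),
                dt=dt,
                seed=np.random.default_rng(rng.integers(2**31)),
            )
            kept_df.loc[grp.index, "response"] = sim["response"].to_numpy()
            kept_df.loc[grp.index, "rt_s"] = sim["rt_s"].to_numpy()
        kept_df["correct"] = (kept_df["response"] == kept_df["matching"]).astype(int)
        rows.append(kept_df)

    out = pd.concat(rows, ignore_index=True)
    return out[
        ["subject", "trial", "trial_type", "switching", "matching", "response", "correct", "rt_s"]
    ]


@dataclass
class CouplingSpec:
    """Ground-truth coupling for a nonlinear MVAR source system.

    ``linear_coeffs`` has shape (p, M, M) with entry ``[k, j, i]`` the effect
    of node i at lag k+1 on node j.  ``nonlinear_terms`` is a list of
    ``(source, target, lag, tag, gain)`` with tag in {"square", "tanh",
    "product"}; "product" multiplies the source's lag-k and lag-(k+1) samples.
    """

    n_nodes: int
    order: int
    linear_coeffs: np.ndarray
    nonlinear_terms: list = field(default_factory=list)
    noise_sd: np.ndarray | float = 1.0
    band: tuple[float, float] | None = None  # narrowband innovations if set
    sfreq_hz: float = 256.0

    def __post_init__(self) -> None:
        self.linear_coeffs = np.asarray(self.linear_coeffs, dtype=float)
        if self.linear_coeffs.shape != (self.order, self.n_nodes, self.n_nodes):
            raise ValueError("linear_coeffs must have shape (p, M, M)")
        self.noise_sd = np.broadcast_to(
            np.asarray(self.noise_sd, dtype=float), (self.n_nodes,)
        ).copy()
        if np.any(self.noise_sd <= 0):
            raise ValueError("noise_sd must be > 0")
        rho = self.spectral_radius()
        if rho >= 1.0:
            raise ValueError(f"linear part is non-stationary (spectral radius {rho:.3f})")
        for src, tgt, lag, tag, gain in self.nonlinear_terms:
            if tag not in ("square", "tanh", "product"):
                raise ValueError(f"unknown nonlinear tag {tag!r}")
            if not (1 <= lag <= self.order):
                raise ValueError("nonlinear lag must lie in 1..p")

    def spectral_radius(self) -> float:
        M, p = self.n_nodes, self.order
        comp = np.zeros((M * p, M * p))
        for k in range(p):
            comp[:M, k * M : (k + 1) * M] = self.linear_coeffs[k]
        if p > 1:
            comp[M:, :-M] = np.eye(M * (p - 1))
        return float(np.max(np.abs(np.linalg.eigvals(comp))))

    def ground_truth_adjacency(self) -> dict:
        """JSON-serializable ground truth for recovery scoring."""
        lin = np.any(self.linear_coeffs != 0.0, axis=0).astype(int)
        nl = np.zeros((self.n_nodes, self.n_nodes), dtype=int)
        for src, tgt, _, _, gain in self.nonlinear_terms:
            if gain != 0:
                nl[tgt, src] = 1
        return {
            "n_nodes": self.n_nodes,
            "order": self.order,
            "linear_adjacency": lin.tolist(),  # [target][source]
            "nonlinear_adjacency": nl.tolist(),
            "linear_coeffs": self.linear_coeffs.tolist(),
            "nonlinear_terms": [list(t) for t in self.nonlinear_terms],
        }


def _innovations(
    rng: np.random.Generator,
    n_nodes: int,
    n_samples: int,
    noise_sd: np.ndarray,
    band: tuple[float, float] | None,
    sfreq: float,
) -> np.ndarray:
    eps = rng.standard_normal((n_nodes, n_samples)) * noise_sd[:, None]
    if band is not None:
        lo, hi = band
        taps = firwin(129, [lo, hi], pass_zero=False, fs=sfreq, window="hamming")
        eps = lfilter(taps, 1.0, eps, axis=1)
        # restore the requested innovation scale after filtering
        eps *= noise_sd[:, None] / np.maximum(eps.std(axis=1, keepdims=True), 1e-12)
    return eps


def gen_coupled_sources(
    spec: CouplingSpec,
    n_trials: int,
    trial_len: int,
    seed: int = 0,
    burn_in: int = 200,
) -> tuple[np.ndarray, dict]:
    """Simulate per-trial node time series from the nonlinear MVAR recursion.

    Each node's sample is the linear combination of the p past samples of all
    nodes, plus the configured nonlinear terms, plus innovation noise.
    Returns ``(data, ground_truth)`` with data shaped
    (n_trials, n_nodes, trial_len); the burn-in is discarded.
    """
    M, p = spec.n_nodes, spec.order
    root = np.random.SeedSequence(seed)
    data = np.zeros((n_trials, M, trial_len))
    for trial, sseq in enumerate(root.spawn(n_trials)):
        rng = np.random.default_rng(sseq)
        total = trial_len + burn_in + p
        eps = _innovations(rng, M, total, spec.noise_sd, spec.band, spec.sfreq_hz)
        x = np.zeros((M, total))
        x[:, :p] = eps[:, :p]
        for n in range(p, total):
            acc = eps[:, n].copy()
            for k in range(p):
                acc += spec.linear_coeffs[k] @ x[:, n - k - 1]
            for src, tgt, lag, tag, gain in spec.nonlinear_terms:
                if gain == 0.0:
                    continue
                xs = x[src, n - lag]
                if tag == "square":
                    acc[tgt] += gain * xs * xs
                elif tag == "tanh":
                    acc[tgt] += gain * np.tanh(xs)
                else:  # product of consecutive lags of the source
                    acc[tgt] += gain * xs * x[src, n - lag - 1]
            if np.any(np.abs(acc) > OVERFLOW_GUARD):
                raise FloatingPointError(
                    f"nMVAR simulation diverged at trial {trial}, sample {n} "
                    f"(|x| > {OVERFLOW_GUARD:g}); reduce coupling gains"
                )
            x[:, n] = acc
        data[trial] = x[:, p + burn_in :]
    return data, spec.ground_truth_adjacency()


def random_stable_var(
    n_nodes: int = 5,
    order: int = 2,
    density: float = 0.3,
    seed: int = 0,
    coeff_range: tuple[float, float] = (0.2, 0.6),
) -> CouplingSpec:
    """Random sparse stationary linear VAR for recovery benchmarks.

    Off-diagonal couplings appear with probability ``density`` and random
    sign; moderate self-decay sits on the diagonal.  Seeds are advanced
    until the companion matrix is stable.
    """
    attempt = seed
    while True:
        r = np.random.default_rng(attempt)
        A = np.zeros((order, n_nodes, n_nodes))
        for k in range(order):
            mask = r.random((n_nodes, n_nodes)) < density
            A[k][mask] = r.uniform(*coeff_range, mask.sum()) * r.choice([-1, 1], mask.sum())
            np.fill_diagonal(A[k], r.uniform(0.1, 0.3, n_nodes) * (1.0 if k == 0 else 0.3))
        try:
            return CouplingSpec(n_nodes=n_nodes, order=order, linear_coeffs=A, noise_sd=1.0)
        except ValueError:
            attempt += 7919  # jump to a fresh stream and retry


def make_leadfield(n_voxels: int, n_channels: int, seed: int = 0) -> Leadfield:
    """Synthetic distance-decaying leadfield on a regular 3-D voxel grid.

    Voxels sit on a unit-spaced grid; channels sit on a sphere enclosing the
    grid (a jittered Fibonacci lattice), which gives the montage sensitivity
    to source depth in every direction.  Gain from voxel to channel is
    ``1 / (1 + d^2)`` with d the Euclidean distance, so each voxel's
    strongest channel is its nearest channel.
    """
    if n_voxels < 2 or n_channels < 2:
        raise ValueError("need at least 2 voxels and 2 channels")
    side = int(np.ceil(n_voxels ** (1.0 / 3.0)))
    grid = np.array(
        [(x, y, z) for z in range(side) for y in range(side) for x in range(side)],
        dtype=float,
    )[:n_voxels]

    rng = np.random.default_rng(seed)
    center = grid.mean(axis=0)
    radius = 0.5 * side * np.sqrt(3.0) + 1.0
    i = np.arange(n_channels, dtype=float)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n_channels
    r_xy = np.sqrt(1.0 - z**2)
    theta = golden * i + rng.uniform(0.0, 0.05, n_channels)
    unit = np.column_stack([r_xy * np.cos(theta), r_xy * np.sin(theta), z])
    ch_pos = center + radius * unit

    d2 = ((grid[:, None, :] - ch_pos[None, :, :]) ** 2).sum(axis=2)
    gain = 1.0 / (1.0 + d2)
    names = [f"CH{i:02d}" for i in range(n_channels)]
    return Leadfield(gain=gain, voxel_positions=grid, channel_names=names, channel_positions=ch_pos)


def gen_sensor_epochs(
    sources: np.ndarray,
    leadfield: Leadfield,
    source_voxels: np.ndarray | list[int],
    sensor_noise_sd: float = 1.0,
    seed: int = 0,
    sfreq_hz: float = 256.0,
    tmin_s: float = -2.0,
    tmax_s: float = 2.0,
    condition_labels: np.ndarray | None = None,
) -> EpochArray:
    """Project source trials to sensors through the leadfield and add noise.

    ``sources`` is (n_trials, n_sources, n_times); each source is placed at
    the corresponding entry of ``source_voxels``.  The epoch window runs from
    ``tmin_s`` to ``tmax_s`` inclusive of both endpoints (1025 samples for
    the default -2...+2 s at 256 Hz), with stimulus onset at t = 0.
    """
    sources = np.asarray(sources, dtype=float)
    source_voxels = np.asarray(source_voxels, dtype=int)
    if sources.ndim != 3 or sources.shape[1] != source_voxels.size:
        raise ValueError("sources must be (n_trials, n_sources, n_times) matching source_voxels")
    n_times = int(round((tmax_s - tmin_s) * sfreq_hz)) + 1  # inclusive endpoints
    if sources.shape[2] != n_times:
        raise ValueError(
            f"sources have {sources.shape[2]} samples; epoch window needs {n_times}"
        )
    times = tmin_s + np.arange(n_times) / sfreq_hz
    rng = np.random.default_rng(seed)
    G = leadfield.gain[source_voxels]  # (n_sources, n_channels)
    data = np.einsum("tsn,sc->tcn", sources, G)
    if sensor_noise_sd > 0:
        data = data + sensor_noise_sd * rng.standard_normal(data.shape)
    return EpochArray(
        data=data,
        times_s=times,
        sfreq_hz=sfreq_hz,
        channel_names=list(leadfield.channel_names),
        condition_labels=condition_labels,
        channel_positions=leadfield.channel_positions,
    )
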