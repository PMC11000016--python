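"""LCMV beamforming, source-level gating contrast, voxel selection, DBSCAN
clustering, and cluster signal extraction.

The beamformer is the scalar (fixed-orientation) linearly constrained
minimum-variance filter: for voxel leadfield row g and regularized sensor
covariance C, the weights are w = (g C^-1 g^T)^-1 g C^-1, which pass the
voxel's own activity with unit gain while minimizing output variance.  A
single common filter is computed from all relevant conditions so that
condition contrasts are not biased by filter differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import filtfilt, firwin
from sklearn.cluster import DBSCAN

from gatingnet.containers import BANDS, EpochArray, Leadfield, SourceSignal

__all__ = [
    "SpatialFilter",
    "SourceCluster",
    "bandpass_fir",
    "lcmv_common_filter",
    "apply_filter",
    "source_gating_contrast",
    "select_top_voxels",
    "dbscan_cluster",
    "extract_cluster_signals",
]


@dataclass
class SpatialFilter:
    weights: np.ndarray  # (n_voxels, n_channels)
    regularization: float
    covariance_condition: float  # condition number of the regularized covariance


@dataclass
class SourceCluster:
    cluster_id: int
    voxels: np.ndarray  # global voxel indices, >= 2 of them
    centroid: np.ndarray  # (3,)
    band: str | None = None
    process: str | None = None


def bandpass_fir(
    epochs: EpochArray,
    band: str | tuple[float, float],
    transition_hz: float = 2.0,
) -> EpochArray:
    """Zero-phase Hamming-windowed sinc FIR band-pass along the time axis.

    Filter order follows the Hamming transition-width rule
    (3.3 / normalized transition width); forward-backward application makes
    the net response zero-phase (and squares the magnitude response).
    """
    lo, hi = BANDS[band] if isinstance(band, str) else band
    nyq = epochs.sfreq_hz / 2.0
    if hi >= nyq:
        raise ValueError(f"band edge {hi} Hz at or above Nyquist ({nyq} Hz)")
    numtaps = int(np.ceil(3.3 * epochs.sfreq_hz / transition_hz))
    numtaps += 1 - numtaps % 2  # odd length, linear phase type I
    taps = firwin(numtaps, [lo, hi], pass_zero=False, fs=epochs.sfreq_hz, window="hamming")
    padlen = min(3 * (numtaps - 1), epochs.data.shape[2] - 1)
    filtered = filtfilt(taps, 1.0, epochs.data, axis=2, padlen=padlen)
    return EpochArray(
        data=filtered,
        times_s=epochs.times_s,
        sfreq_hz=epochs.sfreq_hz,
        channel_names=list(epochs.channel_names),
        condition_labels=epochs.condition_labels,
        channel_positions=epochs.channel_positions,
    )


def _sensor_covariance(epochs_list: list[EpochArray], mode: str) -> np.ndarray:
    if mode == "trials":
        # average of single-trial covariances across appended conditions
        covs = []
        for ep in epochs_list:
            X = ep.data - ep.data.mean(axis=2, keepdims=True)
            covs.append(np.einsum("tcn,tdn->cd", X, X) / (X.shape[0] * (X.shape[2] - 1)))
        return np.mean(covs, axis=0)
    if mode == "average":
        # covariance of the trial-averaged (evoked) data
        avg = np.mean([ep.data.mean(axis=0) for ep in epochs_list], axis=0)
        avg = avg - avg.mean(axis=1, keepdims=True)
        return (avg @ avg.T) / (avg.shape[1] - 1)
    raise ValueError(f"unknown covariance mode {mode!r}")


def lcmv_common_filter(
    epochs_all_conditions: list[EpochArray] | EpochArray,
    leadfield: Leadfield,
    reg: float = 0.05,
    cov_mode: str = "trials",
) -> SpatialFilter:
    """Common LCMV spatial filter from the appended conditions.

    ``reg`` adds that fraction of the mean sensor variance to the diagonal.
    ``cov_mode="trials"`` (default) averages single-trial covariances;
    ``"average"`` uses the covariance of the trial-averaged data.
    """
    if isinstance(epochs_all_conditions, EpochArray):
        epochs_all_conditions = [epochs_all_conditions]
    C = _sensor_covariance(epochs_all_conditions, cov_mode)
    n_ch = C.shape[0]
    if leadfield.n_channels != n_ch:
        raise ValueError("leadfield/sensor channel count mismatch")
    C = C + reg * (np.trace(C) / n_ch) * np.eye(n_ch)
    cond = float(np.linalg.cond(C))
    Cinv = np.linalg.inv(C)
    GC = leadfield.gain @ Cinv  # (voxels, channels)
    denom = np.einsum("vc,vc->v", GC, leadfield.gain)
    if np.any(denom <= 0):
        raise np.linalg.LinAlgError("covariance not positive definite for some voxel")
    W = GC / denom[:, None]
    return SpatialFilter(weights=W, regularization=reg, covariance_condition=cond)


def apply_filter(filt: SpatialFilter, epochs: EpochArray) -> np.ndarray:
    """Reconstruct voxel time series: (n_trials, n_voxels, n_times)."""
    return np.einsum("vc,tcn->tvn", filt.weights, epochs.data)


def source_gating_contrast(
    switch_sources: np.ndarray, nonswitch_sources: np.ndarray
) -> np.ndarray:
    """Per-voxel switch minus nonswitch source power (variance over time,
    averaged over trials)."""
    sw = np.asarray(switch_sources, dtype=float)
    ns = np.asarray(nonswitch_sources, dtype=float)
    if sw.shape[1] != ns.shape[1]:
        raise ValueError("voxel grids do not match")
    return sw.var(axis=2).mean(axis=0) - ns.var(axis=2).mean(axis=0)


def select_top_voxels(effect_map: np.ndarray, pct: float = 1.0) -> np.ndarray:
    """Indices of the ceil(pct% of n) voxels with largest absolute effect.

    Absolute value is used so suppression effects are selectable; ties are
    broken by voxel index (stable sort).
    """
    effect = np.asarray(effect_map, dtype=float)
    if effect.size == 0:
        raise ValueError("empty effect map")
    k = int(np.ceil(pct / 100.0 * effect.size))
    order = np.argsort(-np.abs(effect), kind="stable")
    return np.sort(order[:k])


def dbscan_cluster(
    voxel_positions: np.ndarray,
    eps: float,
    min_pts: int = 2,
    voxel_indices: np.ndarray | None = None,
    band: str | None = None,
    process: str | None = None,
) -> list[SourceCluster]:
    """DBSCAN on selected-voxel coordinates; noise voxels are discarded.

    ``voxel_indices`` maps the rows of ``voxel_positions`` back to global
    voxel indices (defaults to 0..n-1).
    """
    if eps <= 0:
        raise ValueError("eps must be > 0")
    pos = np.asarray(voxel_positions, dtype=float)
    idx = np.arange(pos.shape[0]) if voxel_indices is None else np.asarray(voxel_indices)
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(pos)
    clusters = []
    for cid in sorted(set(labels) - {-1}):
        mask = labels == cid
        clusters.append(
            SourceCluster(
                cluster_id=int(cid),
                voxels=idx[mask],
                centroid=pos[mask].mean(axis=0),
                band=band,
                process=process,
            )
        )
    return clusters


def extract_cluster_signals(
    switch_voxel_ts: np.ndarray,
    clusters: list[SourceCluster],
    nonswitch_mean: np.ndarray,
    times_s: np.ndarray,
    window: tuple[float, float] = (-0.5, 1.5),
) -> list[SourceSignal]:
    """Baseline-subtracted, cluster-averaged single-trial source signals.

    Each switch trial has the mean nonswitch signal subtracted per voxel
    before averaging over the cluster's voxels; the result is cropped to the
    half-open window [start, stop) — 512 samples for -500...1500 ms at
    256 Hz.
    """
    ts = np.asarray(switch_voxel_ts, dtype=float)
    base = np.asarray(nonswitch_mean, dtype=float)
    times = np.asarray(times_s, dtype=float)
    n_vox = ts.shape[1]
    if base.shape[0] != n_vox:
        raise ValueError("baseline voxel count mismatch")
    sel = (times >= window[0]) & (times < window[1])
    out = []
    for cl in clusters:
        if np.any(cl.voxels >= n_vox) or np.any(cl.voxels < 0):
            raise IndexError(f"cluster {cl.cluster_id} references unavailable voxel")
        diff = ts[:, cl.voxels, :] - base[cl.voxels][None, :, :]
        sig = diff.mean(axis=1)[:, sel]
        out.append(
            SourceSignal(
                data=sig,
                times_s=times[sel],
                cluster_id=cl.cluster_id,
                band=cl.band,
                process=cl.process,
            )
        )
    return out
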