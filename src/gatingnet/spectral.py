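"""Morlet time-frequency decomposition, decibel baseline normalization, band
averaging, and the cluster-based permutation test.

Wavelet conventions: "width" is the number of cycles (the Gaussian envelope
SD in time is width / (2*pi*f)), and the wavelet support extends
``gauss_len`` SDs on each side of the center.  Samples at epoch edges where
the wavelet overruns the data are masked as missing (NaN).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse, stats
from scipy.signal import fftconvolve
from scipy.sparse.csgraph import connected_components

from gatingnet.containers import BANDS, EpochArray

__all__ = [
    "TFR",
    "ClusterResult",
    "morlet_tfr",
    "db_baseline",
    "band_average",
    "channel_adjacency",
    "cluster_perm_test",
]


@dataclass
class TFR:
    """Condition-averaged time-frequency power.

    ``power`` has shape (n_conditions, n_channels, n_freqs, n_times); edge
    samples contaminated by wavelet overrun are NaN.
    """

    power: np.ndarray
    freqs: np.ndarray
    times_s: np.ndarray
    conditions: list[str]
    channel_names: list[str]
    is_db: bool = False
    baseline_window: tuple[float, float] | None = None


@dataclass
class Cluster:
    points: np.ndarray  # (n_points, 2) array of (channel, time) indices
    stat: float  # summed t within the cluster
    p: float
    polarity: int  # +1 / -1


@dataclass
class ClusterResult:
    clusters: list  # significant and non-significant, sorted by |stat|
    t_map: np.ndarray  # (n_channels, n_times) pointwise paired t
    threshold: float
    n_perm: int

    @property
    def significant(self) -> list:
        return [c for c in self.clusters if c.p <= 0.05]

    @property
    def min_p(self) -> float:
        return min((c.p for c in self.clusters), default=1.0)


def _morlet(freq: float, sfreq: float, width: float, gauss_len: float) -> np.ndarray:
    sigma_t = width / (2.0 * np.pi * freq)
    half = int(np.round(gauss_len * sigma_t * sfreq))
    t = np.arange(-half, half + 1) / sfreq
    w = np.exp(2j * np.pi * freq * t) * np.exp(-(t**2) / (2.0 * sigma_t**2))
    return w / np.linalg.norm(w)


def morlet_tfr(
    epochs: EpochArray,
    freqs: np.ndarray | None = None,
    width: float = 5.5,
    gauss_len: float = 3.0,
) -> TFR:
    """Per-trial Morlet convolution power, averaged within condition.

    Default frequency grid is 1-30 Hz in 0.5 Hz steps.  Frequencies whose
    wavelet is longer than the epoch are fully masked with a warning.
    """
    if freqs is None:
        freqs = np.arange(1.0, 30.0 + 0.25, 0.5)
    freqs = np.asarray(freqs, dtype=float)
    if epochs.sfreq_hz < 2.0 * freqs.max():
        raise ValueError("sampling rate below Nyquist for requested frequencies")
    if epochs.condition_labels is None:
        conditions = ["all"]
        cond_masks = [np.ones(epochs.n_trials, dtype=bool)]
    else:
        conditions = sorted(set(map(str, epochs.condition_labels)))
        cond_masks = [epochs.condition_labels.astype(str) == c for c in conditions]

    n_times = epochs.times_s.size
    power = np.full((len(conditions), epochs.n_channels, freqs.size, n_times), np.nan)
    for fi, f in enumerate(freqs):
        w = _morlet(f, epochs.sfreq_hz, width, gauss_len)
        half = (w.size - 1) // 2
        if w.size > n_times:
            warnings.warn(
                f"wavelet at {f:g} Hz longer than the epoch; frequency fully masked"
            )
            continue
        conv = fftconvolve(epochs.data, w[None, None, :], mode="same", axes=2)
        p = np.abs(conv) ** 2
        p[..., :half] = np.nan
        if half > 0:
            p[..., -half:] = np.nan
        for ci, mask in enumerate(cond_masks):
            power[ci, :, fi, :] = p[mask].mean(axis=0)
    return TFR(
        power=power,
        freqs=freqs,
        times_s=epochs.times_s.copy(),
        conditions=conditions,
        channel_names=list(epochs.channel_names),
    )


def db_baseline(tfr: TFR, window: tuple[float, float] = (-0.2, 0.0)) -> TFR:
    """Decibel normalization: 10*log10(power / mean baseline power).

    The baseline mean is taken per condition, channel and frequency over the
    window (inclusive endpoints).  Masked or zero baseline power raises.
    """
    if tfr.is_db:
        raise ValueError("TFR already decibel-normalized")
    sel = (tfr.times_s >= window[0]) & (tfr.times_s <= window[1])
    if not np.any(sel):
        raise ValueError("baseline window outside epoch")
    base = tfr.power[..., sel]
    with warnings.catch_warnings():
        # frequencies fully masked by edge effects stay NaN after division
        warnings.simplefilter("ignore", category=RuntimeWarning)
        bmean = np.nanmean(base, axis=-1, keepdims=True)
    if np.any(bmean[np.isfinite(bmean)] <= 0.0):
        raise ValueError("zero baseline power")
    with np.errstate(invalid="ignore", divide="ignore"):
        normed = 10.0 * np.log10(tfr.power / bmean)
    return TFR(
        power=normed,
        freqs=tfr.freqs,
        times_s=tfr.times_s,
        conditions=tfr.conditions,
        channel_names=tfr.channel_names,
        is_db=True,
        baseline_window=window,
    )


def band_average(tfr: TFR, band: str | tuple[float, float]) -> np.ndarray:
    """Mean power over the band's frequency bins (inclusive edges).

    Returns an array (n_conditions, n_channels, n_times).
    """
    lo, hi = BANDS[band] if isinstance(band, str) else band
    sel = (tfr.freqs >= lo) & (tfr.freqs <= hi)
    if not np.any(sel):
        raise ValueError(f"no frequency bins in band {band}")
    return tfr.power[:, :, sel, :].mean(axis=2)


def channel_adjacency(positions: np.ndarray, factor: float = 1.5) -> np.ndarray:
    """Boolean channel adjacency from sensor positions.

    Channels closer than ``factor`` times the median nearest-neighbor
    distance are neighbors.
    """
    pos = np.asarray(positions, dtype=float)
    d = np.sqrt(((pos[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2))
    np.fill_diagonal(d, np.inf)
    thresh = factor * np.median(d.min(axis=1))
    adj = d <= thresh
    return adj


class _GridGraph:
    """Edge lists of the (channel, time) lattice given channel adjacency."""

    def __init__(self, ch_adj: np.ndarray, n_times: int):
        n_ch = ch_adj.shape[0]
        self.n_nodes = n_ch * n_times
        e0, e1 = [], []
        idx = np.arange(self.n_nodes).reshape(n_ch, n_times)
        # time neighbors within each channel
        e0.append(idx[:, :-1].ravel())
        e1.append(idx[:, 1:].ravel())
        # channel neighbors at identical time points
        ci, cj = np.nonzero(np.triu(ch_adj, k=1))
        if ci.size:
            e0.append(idx[ci].ravel())
            e1.append(idx[cj].ravel())
        self.e0 = np.concatenate(e0)
        self.e1 = np.concatenate(e1)

    def clusters(self, mask: np.ndarray) -> list[np.ndarray]:
        """Connected components of the masked subgraph (mask is flat boolean)."""
        nodes = np.flatnonzero(mask)
        if nodes.size == 0:
            return []
        relabel = -np.ones(self.n_nodes, dtype=np.int64)
        relabel[nodes] = np.arange(nodes.size)
        keep = mask[self.e0] & mask[self.e1]
        r0, r1 = relabel[self.e0[keep]], relabel[self.e1[keep]]
        g = sparse.coo_matrix(
            (np.ones(r0.size), (r0, r1)), shape=(nodes.size, nodes.size)
        )
        n_comp, labels = connected_components(g, directed=False)
        return [nodes[labels == c] for c in range(n_comp)]


def _max_cluster_stat(tmap_flat: np.ndarray, thr: float, graph: _GridGraph) -> float:
    best = 0.0
    for sign in (1.0, -1.0):
        mask = sign * tmap_flat > thr
        for comp in graph.clusters(mask):
            s = abs(float(tmap_flat[comp].sum()))
            if s > best:
                best = s
    return best


def cluster_perm_test(
    condA: np.ndarray,
    condB: np.ndarray,
    ch_adjacency: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> ClusterResult:
    """Cluster-based sign-flip permutation test for paired condition data.

    ``condA`` and ``condB`` are (n_subjects, n_channels, n_times) arrays of
    within-subject condition means.  A pointwise paired t is thresholded
    two-sided at ``alpha``; suprathreshold neighbors (adjacent in time, or
    adjacent channels at the same time point) of equal sign form clusters
    scored by their summed t.  The null distribution is the maximal absolute
    cluster sum under random within-subject sign flips, giving a familywise-
    corrected two-sided Monte-Carlo p per cluster.
    """
    A = np.asarray(condA, dtype=float)
    B = np.asarray(condB, dtype=float)
    if A.shape != B.shape or A.ndim != 3:
        raise ValueError("condA/condB must be (n_subjects, n_channels, n_times)")
    n_subj, n_ch, n_time = A.shape
    if n_subj < 6:
        raise ValueError("need at least 6 subjects")
    D = A - B  # (subj, ch, time)
    df = n_subj - 1
    thr = float(stats.t.ppf(1.0 - alpha / 2.0, df))

    Df = D.reshape(n_subj, -1)
    sum_sq = (Df**2).sum(axis=0)

    def tmap_for(signs: np.ndarray) -> np.ndarray:
        m = signs @ Df / n_subj
        var = (sum_sq - n_subj * m**2) / df
        var = np.maximum(var, 1e-300)
        return m / np.sqrt(var / n_subj)

    graph = _GridGraph(np.asarray(ch_adjacency, dtype=bool), n_time)
    t_obs = tmap_for(np.ones(n_subj))

    obs_clusters = []
    for sign in (1, -1):
        mask = sign * t_obs > thr
        for comp in graph.clusters(mask):
            obs_clusters.append((comp, float(t_obs[comp].sum()), sign))

    rng = np.random.default_rng(seed)
    if obs_clusters:
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n_subj))
        null = np.empty(n_perm)
        for i in range(n_perm):
            null[i] = _max_cluster_stat(tmap_for(signs[i]), thr, graph)
        clusters = []
        for comp, s, sign in obs_clusters:
            p = (1.0 + np.count_nonzero(null >= abs(s))) / (n_perm + 1.0)
            pts = np.column_stack(np.unravel_index(comp, (n_ch, n_time)))
            clusters.append(Cluster(points=pts, stat=s, p=float(p), polarity=sign))
        clusters.sort(key=lambda c: -abs(c.stat))
    else:
        clusters = []
    return ClusterResult(
        clusters=clusters,
        t_map=t_obs.reshape(n_ch, n_time),
        threshold=thr,
        n_perm=n_perm,
    )
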