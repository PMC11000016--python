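"""End-to-end orchestration of the synthetic working-memory gating analysis.

Stages: simulate -> behavior -> ddm -> tfr -> permtest -> source ->
connectivity -> regress.  Every artifact is stamped with the config hash and
master seed; per-stage seeds are derived from the master seed so stages are
independently reproducible.  A completed stage's outputs can be reused
(``resume=True``) instead of recomputed.

The synthetic cohort couples neurophysiology to behavior by construction:
each subject has a connectivity gain factor that scales the source coupling
and shifts the subject's boundary-separation parameter, so the regress stage
has a real signal for ``a`` (and none for ``v``).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from gatingnet import io as gio
from gatingnet import ncreann
from gatingnet.behavior import filter_outliers, gating_contrast, rm_anova, summarize
from gatingnet.containers import CONDITIONS, EpochArray
from gatingnet.ddm import DDMParams, fit_ddm
from gatingnet.brain_behavior import fit_predict_cv
from gatingnet.source import (
    apply_filter,
    bandpass_fir,
    dbscan_cluster,
    extract_cluster_signals,
    lcmv_common_filter,
    select_top_voxels,
    source_gating_contrast,
)
from gatingnet.spectral import band_average, channel_adjacency, cluster_perm_test, db_baseline, morlet_tfr
from gatingnet.synthetic import (
    CohortSpec,
    CouplingSpec,
    gen_behavior,
    gen_coupled_sources,
    gen_sensor_epochs,
    make_leadfield,
)

__all__ = ["PipelineConfig", "run_pipeline", "STAGES", "STAGE_DEPS"]

log = logging.getLogger("gatingnet.pipeline")

STAGES = ["simulate", "behavior", "ddm", "tfr", "permtest", "source", "connectivity", "regress"]
STAGE_DEPS = {
    "simulate": [],
    "behavior": ["simulate"],
    "ddm": ["simulate"],
    "tfr": ["simulate"],
    "permtest": ["tfr"],
    "source": ["simulate"],
    "connectivity": ["source"],
    "regress": ["connectivity", "ddm"],
}


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "gatingnet_out"
    stages: list = field(default_factory=lambda: list(STAGES))
    # cohort / behavior
    n_subjects: int = 10
    trials_per_condition: int = 40
    outlier_k: float = 2.0
    # ddm
    ddm_min_trials: int = 20
    ddm_restarts: int = 3
    ddm_dt: float = 1e-3
    # neural simulation
    n_neural_trials: int = 20
    n_voxels: int = 64
    n_channels: int = 25
    source_amp: float = 30.0
    sensor_noise_sd: float = 1.0
    band: str = "beta"
    # tfr / permtest
    tfr_fmin: float = 2.0
    tfr_fmax: float = 30.0
    tfr_fstep: float = 1.0
    n_perm: int = 500
    cluster_alpha: float = 0.05
    # source
    select_pct: float = 10.0
    dbscan_eps: float = 1.5
    lcmv_reg: float = 0.05
    # connectivity
    var_order: int = 3
    hidden_units: int = 16
    train_max_iter: int = 300
    train_restarts: int = 2
    # regress
    cv_folds: int = 5
    regress_hidden: int = 8

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for s in self.stages:
            missing = [d for d in STAGE_DEPS[s] if d not in self.stages]
            if missing:
                raise ValueError(f"stage {s!r} requires disabled stage(s) {missing}")
        if self.n_subjects < 2 or self.trials_per_condition < 1:
            raise ValueError("cohort too small")
        if "regress" in self.stages and self.cv_folds > self.n_subjects:
            raise ValueError("cv_folds exceeds n_subjects")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("out_dir")  # artifact location does not change the analysis
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _stage_seed(cfg: PipelineConfig, stage: str) -> int:
    h = hashlib.sha256(f"{cfg.seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _header(cfg: PipelineConfig) -> dict:
    return {"config_hash": cfg.config_hash(), "seed": cfg.seed}


def _subject_profiles(cfg: PipelineConfig) -> pd.DataFrame:
    """Per-subject coupling gains and DDM cell parameters.

    The coupling gain g (uniform 0.4...1.6) scales the source-level linear
    coupling; boundary separation rises with g (0.06 per unit) on top of the
    condition means, so connectivity predicts a but not v.
    """
    rng = np.random.default_rng(_stage_seed(cfg, "profiles"))
    g = rng.uniform(0.4, 1.6, cfg.n_subjects)
    rows = []
    for s in range(cfg.n_subjects):
        da = 0.06 * (g[s] - 1.0) + 0.02 * rng.standard_normal()
        rows.append({"subject": s, "gain": g[s], "delta_a": da})
    return pd.DataFrame(rows)


def _stage_simulate(cfg: PipelineConfig, out: Path) -> None:
    profiles = _subject_profiles(cfg)
    base = {
        "switch-reference": DDMParams(a=0.93, v=0.09, t0=0.356),
        "nonswitch-reference": DDMParams(a=0.86, v=0.01, t0=0.332),
        "switch-comparison": DDMParams(a=0.95, v=0.09, t0=0.367),
        "nonswitch-comparison": DDMParams(a=0.86, v=0.01, t0=0.332),
    }
    seed0 = _stage_seed(cfg, "simulate")
    frames = []
    for _, row in profiles.iterrows():
        params = {
            c: DDMParams(a=p.a + row.delta_a, v=p.v, t0=p.t0) for c, p in base.items()
        }
        spec = CohortSpec(
            n_subjects=1,
            trials_per_condition=cfg.trials_per_condition,
            ddm_params_by_condition=params,
            seed=seed0 + int(row.subject),
        )
        tr = gen_behavior(spec, dt=cfg.ddm_dt)
        tr["subject"] = int(row.subject)
        frames.append(tr)
    trials = pd.concat(frames, ignore_index=True)
    gio.write_trials(trials, out / "trials.tsv", _header(cfg))
    profiles.to_json(out / "subject_profiles.json", orient="records", indent=2)

    # neural data: two coupled band-limited sources per subject, projected
    # through a common leadfield; switch trials carry the sources,
    # nonswitch trials are sensor noise only
    lf = make_leadfield(cfg.n_voxels, cfg.n_channels, seed=seed0)
    gio.write_leadfield(lf, out / "leadfield.h5")
    v_src = [0, cfg.n_voxels - 1]
    n_t = 1025
    gt_all = {}
    for _, row in profiles.iterrows():
        s = int(row.subject)
        A = np.zeros((cfg.var_order, 2, 2))
        A[0] = [[0.3, 0.0], [0.35 * row.gain, 0.3]]
        spec = CouplingSpec(
            n_nodes=2, order=cfg.var_order, linear_coeffs=A, noise_sd=1.0,
            band=None,
        )
        src, gt = gen_coupled_sources(spec, cfg.n_neural_trials, n_t, seed=seed0 + 100 + s)
        sw = gen_sensor_epochs(
            cfg.source_amp * src, lf, v_src, cfg.sensor_noise_sd, seed=seed0 + 200 + s,
            condition_labels=np.array(["switch"] * cfg.n_neural_trials),
        )
        ns = gen_sensor_epochs(
            np.zeros_like(src), lf, v_src, cfg.sensor_noise_sd, seed=seed0 + 300 + s,
            condition_labels=np.array(["nonswitch"] * cfg.n_neural_trials),
        )
        both = EpochArray(
            np.concatenate([sw.data, ns.data]),
            sw.times_s,
            sw.sfreq_hz,
            sw.channel_names,
            np.concatenate([sw.condition_labels, ns.condition_labels]),
            sw.channel_positions,
        )
        gio.write_epochs(both, out / f"epochs_s{s:02d}.h5", _header(cfg))
        gt_all[str(s)] = gt
    gio.write_report({"source_voxels": v_src, "ground_truth": gt_all}, out / "neural_truth.json")


def _stage_behavior(cfg: PipelineConfig, out: Path) -> None:
    trials = gio.read_trials(out / "trials.tsv")
    rep = filter_outliers(trials, k=cfg.outlier_k)
    summ = summarize(rep.trials)
    summ.to_csv(out / "condition_summary.tsv", sep="\t", index=False)

    cells = summ.pivot_table(
        index="subject", columns=["switching", "trial_type"], values="mean_rt_s"
    )
    order = [("switch", "reference"), ("nonswitch", "reference"),
             ("switch", "comparison"), ("nonswitch", "comparison")]
    mat = cells[[("switch", "reference"), ("switch", "comparison"),
                 ("nonswitch", "reference"), ("nonswitch", "comparison")]].to_numpy()
    rows = rm_anova(mat, ["Switching", "TrialType"])
    anova = pd.DataFrame([dataclasses.asdict(r) for r in rows])
    anova.to_csv(out / "rt_anova.tsv", sep="\t", index=False)

    per_subj = {}
    for s, sub in summ.groupby("subject"):
        c = {f"{r.switching}-{r.trial_type}": r.mean_rt_s for r in sub.itertuples()}
        gs = gating_contrast(c, measure="rt_s")
        per_subj[int(s)] = {"opening": gs.opening, "closing": gs.closing}
    gio.write_report(
        {
            "config_hash": cfg.config_hash(),
            "flagged_subjects": rep.flagged_subjects,
            "n_removed": rep.n_removed_per_subject,
            "rt_gating_by_subject": per_subj,
        },
        out / "behavior_report.json",
    )


def _stage_ddm(cfg: PipelineConfig, out: Path) -> None:
    trials = gio.read_trials(out / "trials.tsv")
    seed = _stage_seed(cfg, "ddm")
    rows = []
    for s, sub in trials.groupby("subject"):
        fit = fit_ddm(
            sub, seed=seed + int(s), min_trials=cfg.ddm_min_trials,
            n_restarts=cfg.ddm_restarts,
        )
        for cell, p in fit.params.items():
            rows.append(
                {
                    "subject": int(s),
                    "condition": cell,
                    "a": p.a,
                    "v": p.v,
                    "t0": p.t0,
                    "loglik": fit.loglik[cell],
                    "n_trials": fit.n_trials[cell],
                    "converged": int(fit.converged[cell]),
                }
            )
    pd.DataFrame(rows).to_csv(out / "ddm_fits.tsv", sep="\t", index=False)


def _stage_tfr(cfg: PipelineConfig, out: Path) -> None:
    freqs = np.arange(cfg.tfr_fmin, cfg.tfr_fmax + cfg.tfr_fstep / 2, cfg.tfr_fstep)
    band_maps = {"switch": [], "nonswitch": []}
    ch_pos = None
    for s in range(cfg.n_subjects):
        ep = gio.read_epochs(out / f"epochs_s{s:02d}.h5")
        ch_pos = ep.channel_positions
        tfr = db_baseline(morlet_tfr(ep, freqs=freqs))
        ba = band_average(tfr, cfg.band)  # (cond, ch, time)
        for ci, cond in enumerate(tfr.conditions):
            band_maps[cond].append(ba[ci])
    np.savez(
        out / "band_power.npz",
        switch=np.array(band_maps["switch"]),
        nonswitch=np.array(band_maps["nonswitch"]),
        channel_positions=ch_pos,
    )


def _stage_permtest(cfg: PipelineConfig, out: Path) -> None:
    z = np.load(out / "band_power.npz")
    sw, ns = z["switch"], z["nonswitch"]
    # restrict to samples valid at all band frequencies (edge-effect masking)
    valid = ~np.isnan(sw).any(axis=(0, 1)) & ~np.isnan(ns).any(axis=(0, 1))
    adj = channel_adjacency(z["channel_positions"])
    res = cluster_perm_test(
        sw[:, :, valid], ns[:, :, valid], adj,
        n_perm=cfg.n_perm, alpha=cfg.cluster_alpha,
        seed=_stage_seed(cfg, "permtest"),
    )
    gio.write_report(
        {
            "config_hash": cfg.config_hash(),
            "band": cfg.band,
            "n_clusters": len(res.clusters),
            "clusters": [
                {"stat": c.stat, "p": c.p, "polarity": c.polarity, "n_points": len(c.points)}
                for c in res.clusters
            ],
        },
        out / "permtest_report.json",
    )


def _stage_source(cfg: PipelineConfig, out: Path) -> None:
    lf = gio.read_leadfield(out / "leadfield.h5")
    effects = []
    per_subject = []
    for s in range(cfg.n_subjects):
        ep = gio.read_epochs(out / f"epochs_s{s:02d}.h5")
        ep = bandpass_fir(ep, cfg.band)
        filt = lcmv_common_filter(ep, lf, reg=cfg.lcmv_reg)
        sw = ep.select("switch")
        ns = ep.select("nonswitch")
        vs = apply_filter(filt, sw)
        vn = apply_filter(filt, ns)
        effects.append(source_gating_contrast(vs, vn))
        per_subject.append((vs, vn, ep.times_s))
    effect = np.mean(effects, axis=0)
    top = select_top_voxels(effect, pct=cfg.select_pct)
    clusters = dbscan_cluster(
        lf.voxel_positions[top], eps=cfg.dbscan_eps, voxel_indices=top,
        band=cfg.band, process="opening",
    )
    rows = [
        {
            "cluster_id": c.cluster_id,
            "voxel_count": len(c.voxels),
            "centroid_x": c.centroid[0],
            "centroid_y": c.centroid[1],
            "centroid_z": c.centroid[2],
            "band": c.band,
            "process": c.process,
        }
        for c in clusters
    ]
    pd.DataFrame(rows).to_csv(out / "source_clusters.tsv", sep="\t", index=False)

    # per-subject cluster signals (baseline = mean nonswitch per voxel)
    sig_all = {}
    for s, (vs, vn, times) in enumerate(per_subject):
        sigs = extract_cluster_signals(vs, clusters, vn.mean(axis=0), times)
        sig_all[str(s)] = np.array([sg.data for sg in sigs])  # (cluster, trial, time)
    np.savez(out / "cluster_signals.npz", **sig_all)
    gio.write_report(
        {"config_hash": cfg.config_hash(), "selected_voxels": top, "effect_map": effect},
        out / "source_report.json",
    )


def _stage_connectivity(cfg: PipelineConfig, out: Path) -> None:
    z = np.load(out / "cluster_signals.npz")
    seed = _stage_seed(cfg, "connectivity")
    rows = []
    for s in range(cfg.n_subjects):
        sig = z[str(s)]  # (n_clusters, n_trials, n_times)
        if sig.shape[0] < 2:
            log.warning("subject %d: fewer than 2 clusters, skipped", s)
            continue
        trials = np.transpose(sig, (1, 0, 2))  # (trial, node, time)
        model = ncreann.train_ncreann(
            trials,
            p=cfg.var_order,
            hidden_units=cfg.hidden_units,
            max_iter=cfg.train_max_iter,
            restarts=cfg.train_restarts,
            seed=seed + s,
        )
        lC = ncreann.linear_connectivity(model)
        NC = ncreann.nonlinear_connectivity(model, trials)
        conn = {("band", "proc"): ncreann.ConnectivityMatrix(lC=lC, NC=NC, band=cfg.band)}
        norm = ncreann.normalize_connectivity(conn)[("band", "proc")]
        ml, mn = ncreann.average_nonself(norm)
        for i in range(lC.shape[0]):
            for j in range(lC.shape[1]):
                rows.append(
                    {
                        "subject": s, "source": i, "target": j,
                        "lC": norm.lC[i, j], "NC": norm.NC[i, j],
                        "band": cfg.band, "process": "opening", "normalized": 1,
                    }
                )
        rows.append(
            {
                "subject": s, "source": -1, "target": -1,
                "lC": ml, "NC": mn, "band": cfg.band,
                "process": "opening", "normalized": 1,
            }
        )
    pd.DataFrame(rows).to_csv(out / "connectivity.tsv", sep="\t", index=False)


def _stage_regress(cfg: PipelineConfig, out: Path) -> None:
    conn = pd.read_csv(out / "connectivity.tsv", sep="\t")
    ddm = pd.read_csv(out / "ddm_fits.tsv", sep="\t")
    means = conn[conn["source"] == -1].set_index("subject")
    # subject-level DDM parameters: mean over cells
    by_subj = ddm.groupby("subject")[["a", "v", "t0"]].mean()
    common = sorted(set(means.index) & set(by_subj.index))
    X = means.loc[common, ["lC", "NC"]].to_numpy()
    seed = _stage_seed(cfg, "regress")
    results = []
    for target in ("a", "v", "t0"):
        y = by_subj.loc[common, target].to_numpy()
        r = fit_predict_cv(
            X, y, hidden_units=cfg.regress_hidden, folds=cfg.cv_folds,
            seed=seed, target=target, band=cfg.band, process="opening",
        )
        results.append(
            {
                "parameter": target, "band": r.band, "process": r.process,
                "normalized_error": r.normalized_error,
                "ci_lo": r.ci95[0], "ci_hi": r.ci95[1],
            }
        )
    pd.DataFrame(results).to_csv(out / "regression.tsv", sep="\t", index=False)


_STAGE_FN = {
    "simulate": _stage_simulate,
    "behavior": _stage_behavior,
    "ddm": _stage_ddm,
    "tfr": _stage_tfr,
    "permtest": _stage_permtest,
    "source": _stage_source,
    "connectivity": _stage_connectivity,
    "regress": _stage_regress,
}

_STAGE_OUTPUTS = {
    "simulate": ["trials.tsv", "leadfield.h5"],
    "behavior": ["condition_summary.tsv", "rt_anova.tsv", "behavior_report.json"],
    "ddm": ["ddm_fits.tsv"],
    "tfr": ["band_power.npz"],
    "permtest": ["permtest_report.json"],
    "source": ["source_clusters.tsv", "cluster_signals.npz"],
    "connectivity": ["connectivity.tsv"],
    "regress": ["regression.tsv"],
}


def run_pipeline(config: PipelineConfig, resume: bool = False) -> dict:
    """Run the enabled stages in order; returns a manifest of artifacts.

    With ``resume=True`` a stage whose outputs all exist is skipped.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": config.config_hash(), "seed": config.seed, "stages": {}}
    for stage in STAGES:
        if stage not in config.stages:
            continue
        outputs = [out / f for f in _STAGE_OUTPUTS[stage]]
        if resume and all(p.exists() for p in outputs):
            log.info("stage %s: resumed from existing outputs", stage)
            manifest["stages"][stage] = {"status": "resumed"}
            continue
        t0 = time.time()
        try:
            _STAGE_FN[stage](config, out)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = {
            "status": "done",
            "seconds": round(time.time() - t0, 2),
            "outputs": [str(p) for p in outputs],
        }
        log.info("stage %s done in %.1fs", stage, time.time() - t0)
    gio.write_report(manifest, out / "manifest.json")
    return manifest
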