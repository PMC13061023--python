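"""End-to-end orchestration: simulate -> segment -> posture -> states -> emg -> perturb.

A single YAML-able config drives the full analysis on a synthetic cohort
(or on pose tables read from disk), with one root seed feeding named
substreams per stage.  Every stage writes plain CSV/JSON artifacts into
the output directory and registers them in a manifest; a stage failure is
recorded and aborts the stages downstream of it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import emg as emg_mod
from . import kinematics as kin
from . import posture as post_mod
from . import states as states_mod
from . import perturb as pert_mod
from .records import StimEpoch
from .synth import SynthConfig, apply_stim_effect, generate_cohort

log = logging.getLogger("gapcross.pipeline")

STAGES = ("simulate", "segment", "posture", "states", "emg", "perturb", "report")


@dataclass
class AnalysisConfig:
    """Parameters for the full pipeline; defaults reproduce the standard run."""

    seed: int = 0
    out_dir: str = "gapcross_out"
    stages: tuple[str, ...] = STAGES
    synth: dict = field(default_factory=dict)
    n_animals: int = 6
    trials_per_condition: int = 2
    input_dir: str | None = None  # read pose tables instead of simulating
    segmentation: dict = field(default_factory=dict)
    bin_ms: float = 2.0
    pca_components: int | None = None
    variance_target: float = 0.90
    clustering: dict = field(default_factory=dict)
    arhmm: dict = field(default_factory=dict)
    run_arhmm: bool = True
    emg_window_ms: float = 20.0
    run_emg: bool = True
    stim: dict = field(default_factory=lambda: {
        "enabled": True, "mode": "suppress", "onset_ms": -35.0,
        "duration_ms": 50.0, "phase_label": "propulsion",
    })
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def synth_config(self) -> SynthConfig:
        return SynthConfig(**self.synth)


class _Manifest:
    def __init__(self, out: Path, seed: int):
        self.out = out
        self.data = {
            "seed": seed, "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "stages": {}, "artifacts": {},
        }

    def stage(self, name: str, status: str, **info) -> None:
        self.data["stages"][name] = {"status": status, **info}

    def artifact(self, name: str, path: Path, **params) -> None:
        self.data["artifacts"][name] = {
            "path": str(path.relative_to(self.out)), "params": params,
        }

    def write(self) -> Path:
        p = self.out / "manifest.json"
        p.write_text(json.dumps(self.data, indent=2, default=str))
        return p


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Run the configured stages; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
    manifest = _Manifest(out, config.seed)
    ctx: dict = {}
    failed = False
    for stage in STAGES:
        if stage not in config.stages and stage != "report":
            manifest.stage(stage, "skipped", reason="not requested")
            continue
        if failed and stage != "report":
            manifest.stage(stage, "aborted", reason="upstream failure")
            continue
        t0 = time.time()
        try:
            _RUNNERS[stage](config, ctx, out, manifest)
            if stage not in manifest.data["stages"]:  # runner may mark skipped
                manifest.stage(stage, "ok", seconds=round(time.time() - t0, 2))
            log.info("stage %s finished in %.2fs", stage, time.time() - t0)
        except Exception as err:  # recorded, downstream aborted
            manifest.stage(stage, "failed", error=f"{type(err).__name__}: {err}")
            log.error("stage %s failed: %s", stage, err)
            failed = True
    manifest.write()
    return manifest.data


# ---------------------------------------------------------------------------
# stage runners


def _stage_simulate(cfg: AnalysisConfig, ctx, out: Path, man: _Manifest) -> None:
    scfg = cfg.synth_config()
    cohort = generate_cohort(
        scfg, n_animals=cfg.n_animals,
        trials_per_condition=cfg.trials_per_condition,
        seed=cfg.seed, include_emg=cfg.run_emg,
    )
    ctx["cohort"] = cohort
    ctx["synth_cfg"] = scfg
    path = out / "cohort_manifest.csv"
    cohort.manifest().to_csv(path, index=False)
    man.artifact("cohort_manifest", path,
                 n_animals=cfg.n_animals,
                 trials_per_condition=cfg.trials_per_condition, seed=cfg.seed)


def _stage_segment(cfg: AnalysisConfig, ctx, out: Path, man: _Manifest) -> None:
    cohort = ctx["cohort"]
    rows, segs = [], []
    for trial in cohort.trials:
        accel = kin.compute_acceleration(trial, "hindpaw")
        seg = kin.segment_phases(accel, trial.frame_rate, **cfg.segmentation)
        segs.append(seg)
        durs = kin.phase_durations(seg, trial.frame_rate)
        rows.append({
            "trial_id": trial.trial_id, "animal_id": trial.animal_id,
            "gap_distance": trial.gap_distance,
            "b1": seg.boundaries[0], "takeoff": seg.boundaries[1],
            "b3": seg.boundaries[2], **{f"{k}_ms": v for k, v in durs.items()},
        })
    ctx["segmentations"] = segs
    path = out / "segmentation.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    man.artifact("segmentation", path, **cfg.segmentation)

    # flight-duration task-demand contrast
    df = pd.DataFrame(rows)
    groups = {
        str(d): sub["flight_ms"].to_numpy()
        for d, sub in df.groupby("gap_distance")
    }
    if len(groups) >= 2 and all(v.size >= 2 for v in groups.values()):
        anova = pert_mod.oneway_anova_tukey(groups)
        apath = out / "flight_duration_anova.json"
        apath.write_text(json.dumps(
            {k: (v if not isinstance(v, dict)
                 else {f"{a} vs {b}": p for (a, b), p in v.items()})
             for k, v in anova.items()}, indent=2))
        man.artifact("flight_duration_anova", apath)
        ctx["flight_anova"] = anova


def _stage_posture(cfg: AnalysisConfig, ctx, out: Path, man: _Manifest) -> None:
    cohort = ctx["cohort"]
    matrices = [post_mod.build_posture_matrix(t) for t in cohort.trials]
    model = post_mod.fit_pca(matrices, k=cfg.pca_components,
                             variance_target=cfg.variance_target)
    embeddings = [post_mod.embed(m, model) for m in matrices]
    ctx["pca"] = model
    ctx["embeddings"] = embeddings

    mpath = out / "pca_model.json"
    mpath.write_text(json.dumps({
        "mean": model.mean_.tolist(),
        "components": model.components_.tolist(),
        "explained_variance_ratio": model.explained_variance_ratio_.tolist(),
        "k": model.k_,
    }))
    man.artifact("pca_model", mpath, variance_target=cfg.variance_target)

    disp = post_mod.dispersion_profile(embeddings, bin_ms=cfg.bin_ms)
    dpath = out / "dispersion.csv"
    pd.DataFrame({
        "time_ms": disp.time_bins_ms, "median": disp.median, "iqr": disp.iqr,
    }).to_csv(dpath, index=False)
    man.artifact("dispersion", dpath, bin_ms=cfg.bin_ms)
    ctx["dispersion"] = disp

    sim = post_mod.similarity_matrix(embeddings, bin_ms=cfg.bin_ms)
    spath = out / "similarity.csv"
    pd.DataFrame(sim.distance, index=sim.time_bins_ms,
                 columns=sim.time_bins_ms).to_csv(spath)
    man.artifact("similarity", spath, bin_ms=cfg.bin_ms)
    ctx["similarity"] = sim

    bounds = post_mod.detect_segments(sim, n_segments=4)
    bpath = out / "similarity_segments.json"
    bpath.write_text(json.dumps({
        "boundary_bins": [int(b) for b in bounds],
        "boundary_times_ms": [float(sim.time_bins_ms[b]) for b in bounds],
    }))
    man.artifact("similarity_segments", bpath, n_segments=4)


def _stage_states(cfg: AnalysisConfig, ctx, out: Path, man: _Manifest) -> None:
    embeddings = ctx["embeddings"]
    pooled = np.vstack([e.scores for e in embeddings])
    times = np.concatenate([e.relative_time_ms for e in embeddings])
    clus = states_mod.cluster_postures(
        pooled, seed=cfg.seed, **cfg.clustering
    )
    ctx["clusters"] = clus
    occ = states_mod.occupancy_over_time(clus.labels_, times, bin_ms=cfg.bin_ms)
    opath = out / "cluster_occupancy.csv"
    pd.DataFrame(occ.occupancy, columns=occ.time_bins_ms).to_csv(opath)
    man.artifact("cluster_occupancy", opath,
                 n_clusters=clus.n_clusters_, **cfg.clustering)
    ctx["occupancy"] = occ

    if cfg.run_arhmm:
        model, posts = states_mod.fit_arhmm(
            embeddings, seed=cfg.seed, **cfg.arhmm
        )
        centers, profile = states_mod.state_probability_profile(
            posts, bin_ms=cfg.bin_ms
        )
        ppath = out / "state_probabilities.csv"
        pd.DataFrame(profile, columns=centers).to_csv(ppath)
        man.artifact("state_probabilities", ppath,
                     n_states=model.n_states, log_likelihood=model.log_likelihood_)
        ctx["arhmm"] = model
        ctx["state_profile"] = (centers, profile)


def _stage_emg(cfg: AnalysisConfig, ctx, out: Path, man: _Manifest) -> None:
    if not cfg.run_emg:
        man.stage("emg", "skipped", reason="run_emg disabled")
        return
    cohort = ctx["cohort"]
    segs = ctx.get("segmentations")
    rows = []
    for i, (trial, chans) in enumerate(zip(cohort.trials, cohort.emg)):
        if not chans:
            continue
        seg = segs[i] if segs else None
        b1, b2, b3 = cohort.truths[i].phase_boundaries
        if seg is None:
            seg = kin.PhaseSegmentation(boundaries=(b1, b2, b3),
                                        n_frames=trial.n_frames)
        for rec in chans:
            env = emg_mod.rms_envelope(rec, cfg.emg_window_ms)
            phase = "flight" if rec.role == "flexor" else "propulsion"
            burst = emg_mod.phase_peak(env, seg, phase, rec.role,
                                       trial.frame_rate)
            rows.append({
                "trial_id": trial.trial_id, "animal_id": trial.animal_id,
                "gap_distance": trial.gap_distance, "muscle": rec.muscle,
                "role": rec.role, "phase": phase, "peak": burst.peak,
                "peak_time_ms": burst.peak_time_ms,
            })
    bursts = pd.DataFrame(rows)
    bpath = out / "burst_stats.csv"
    bursts.to_csv(bpath, index=False)
    man.artifact("burst_stats", bpath, window_ms=cfg.emg_window_ms)

    ext = bursts[bursts.role != "flexor"].dropna(subset=["peak"])
    if not ext.empty and ext.gap_distance.nunique() >= 2:
        fit = emg_mod.distance_modulation_fit(
            ext.peak.to_numpy(), ext.gap_distance.to_numpy(),
            ext.animal_id.to_numpy(),
        )
        fpath = out / "distance_modulation.json"
        fpath.write_text(json.dumps(dataclasses.asdict(fit), indent=2))
        man.artifact("distance_modulation", fpath)
        ctx["distance_fit"] = fit


def _stage_perturb(cfg: AnalysisConfig, ctx, out: Path, man: _Manifest) -> None:
    if not cfg.stim.get("enabled", True):
        man.stage("perturb", "skipped", reason="stim disabled")
        return
    cohort = ctx["cohort"]
    epoch = StimEpoch(
        onset_ms=cfg.stim.get("onset_ms", -35.0),
        duration_ms=cfg.stim.get("duration_ms", 50.0),
        phase_label=cfg.stim.get("phase_label", "propulsion"),
    )
    mode = cfg.stim.get("mode", "suppress")
    results = {}
    if mode == "suppress" and cfg.run_emg:
        sis = []
        for trial, chans in zip(cohort.trials, cohort.emg):
            if not chans:
                continue
            _, stim_emg = apply_stim_effect(trial, chans, epoch, "suppress")
            for rec, orig in zip(stim_emg, chans):
                env = emg_mod.rms_envelope(rec, cfg.emg_window_ms)
                env_orig = emg_mod.rms_envelope(orig, cfg.emg_window_ms)
                # suppression relative to the same window of the
                # unstimulated recording
                ctrl = env_orig.window_mean(epoch.onset_ms, epoch.offset_ms)
                if ctrl == 0:
                    continue
                si = 1.0 - env.window_mean(epoch.onset_ms, epoch.offset_ms) / ctrl
                sis.append({"trial_id": trial.trial_id, "muscle": rec.muscle,
                            "suppression_index": si})
        df = pd.DataFrame(sis)
        spath = out / "suppression_index.csv"
        df.to_csv(spath, index=False)
        man.artifact("suppression_index", spath, mode=mode,
                     onset_ms=epoch.onset_ms)
        results["mean_suppression_index"] = float(df.suppression_index.mean())
    elif mode == "flex_drive":
        lat_rows = []
        for trial in cohort.trials:
            stim_trial, _ = apply_stim_effect(
                trial, [], epoch, "flex_drive",
                latency_ms=cfg.stim.get("latency_ms", 10.0),
            )
            angles = kin.compute_joint_angles(stim_trial)
            hip = next(a for a in angles if a.joint == "hip")
            lat = pert_mod.movement_latency(
                hip.angle_deg, stim_trial.relative_time_ms, epoch
            )
            pre, post = pert_mod.prepost_angles(
                hip, stim_trial.relative_time_ms, epoch,
                pre_ms=min(100.0, epoch.onset_ms - stim_trial.relative_time_ms[0]),
                post_ms=50.0,
            )
            lat_rows.append({
                "trial_id": trial.trial_id,
                "onset_latency_ms": lat.onset_latency_ms,
                "max_latency_ms": lat.max_latency_ms,
                "hip_pre": pre, "hip_post": post,
            })
        df = pd.DataFrame(lat_rows)
        lpath = out / "flex_drive_latency.csv"
        df.to_csv(lpath, index=False)
        man.artifact("flex_drive_latency", lpath, mode=mode)
        results["median_onset_latency_ms"] = float(df.onset_latency_ms.median())
    ctx["perturb_results"] = results


def _stage_report(cfg: AnalysisConfig, ctx, out: Path, man: _Manifest) -> None:
    summary = {"seed": cfg.seed}
    if "segmentations" in ctx:
        summary["n_trials_segmented"] = len(ctx["segmentations"])
        summary["phase_count"] = 4
    if "pca" in ctx:
        summary["pca_k"] = ctx["pca"].k_
        summary["explained_variance_ratio"] = (
            ctx["pca"].explained_variance_ratio_.tolist()
        )
    if "clusters" in ctx:
        summary["n_clusters"] = ctx["clusters"].n_clusters_
    if "arhmm" in ctx:
        summary["arhmm_log_likelihood"] = ctx["arhmm"].log_likelihood_
    if "distance_fit" in ctx:
        summary["extensor_distance_slope"] = ctx["distance_fit"].beta1
        summary["extensor_distance_p"] = ctx["distance_fit"].p_value
    if "flight_anova" in ctx:
        summary["flight_duration_F"] = ctx["flight_anova"]["F"]
    if "perturb_results" in ctx:
        summary.update(ctx["perturb_results"])
    spath = out / "summary.json"
    spath.write_text(json.dumps(summary, indent=2))
    man.artifact("summary", spath)


_RUNNERS = {
    "simulate": _stage_simulate,
    "segment": _stage_segment,
    "posture": _stage_posture,
    "states": _stage_states,
    "emg": _stage_emg,
    "perturb": _stage_perturb,
    "report": _stage_report,
}
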