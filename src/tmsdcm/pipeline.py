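"""End-to-end orchestration of the analysis pipeline.

Binds the stages into the study's flow: simulate a cohort -> preprocess ->
individualized target selection -> seed-based functional-connectivity
profiling and ROI construction -> spectral DCM inversion of the negative-
and positive-correlation models (NCECM, PCECM) -> hierarchical empirical
Bayes with model reduction/averaging -> clinical summaries and
connectivity–outcome correlations.

Every run writes the resolved configuration and an append-only manifest
(stages, outputs with checksums, warnings) beside its outputs, and is
bit-reproducible from the seed: each stage derives its own substream by
stable hashing of the stage name, so toggling stages does not reshuffle
the randomness of the others.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clinical as clin
from . import connectivity as conn
from . import io as tio
from . import preprocess as prep
from .peb import bma, build_design, greedy_search, peb_fit
from .spdcm import ParamIndex, invert_subject
from .synthetic import EXTENDED_REGIONS, CohortConfig, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "stage_seed"]

STAGE_ORDER = ["simulate", "preprocess", "target", "fcmap", "dcm", "peb", "clinical"]


def stage_seed(seed: int, stage: str) -> int:
    """Per-stage substream seed by stable hashing of the stage name."""
    return (int(seed) * 1000003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run."""

    out_dir: str = "tmsdcm_run"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGE_ORDER))
    # cohort
    n_subjects: int = 28
    n_volumes: int = 360
    TR: float = 2.0
    region_names: tuple[str, ...] = EXTENDED_REGIONS
    volume_grid: tuple[int, int, int] | None = (16, 16, 14)
    n_motion_outliers: int = 2
    # preprocessing
    n_discard: int = 10
    band: tuple[float, float] = (0.01, 0.1)
    fwhm_mm: float = 6.0
    motion_limit_mm: float = 3.5
    motion_limit_deg: float = 3.5
    global_signal_regression: bool = True
    # statistics / models
    alpha: float = 0.05
    seed_radius_mm: float = 6.0
    ar_order: int = 8
    n_freq: int = 32
    ncecm_regions: tuple[str, ...] = ("DLPFC", "PCUN", "HIP", "INS", "sgACC")
    pcecm_regions: tuple[str, ...] = ("DLPFC", "CAU", "mPFC")
    probability_threshold: float = 0.95

    def to_yaml(self, path: str | Path | None = None) -> str:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = yaml.safe_load(text)
        for k in ("region_names", "band", "volume_grid", "ncecm_regions", "pcecm_regions"):
            if k in d and d[k] is not None:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class RunManifest:
    """Append-only record of a pipeline run."""

    config_path: str = ""
    stages: list[dict] = field(default_factory=list)
    version: str = ""

    def add(self, name: str, outputs: list[str], warnings: list[str] | None = None,
            elapsed_s: float = 0.0, skipped: bool = False) -> None:
        self.stages.append({
            "stage": name,
            "skipped": skipped,
            "outputs": [{"path": p, "sha256": tio.sha256_of(p)} for p in outputs],
            "warnings": warnings or [],
            "elapsed_s": round(elapsed_s, 3),
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        })

    def save(self, path: str | Path) -> Path:
        Path(path).write_text(json.dumps(
            {"config": self.config_path, "version": self.version, "stages": self.stages},
            indent=2,
        ))
        return Path(path)


def _preprocess_series(series, motion, cfg: PipelineConfig, keep_band: bool):
    """Temporal chain on an ROI (or voxel) series matrix."""
    cleaned, _ = prep.run_chain(
        series, motion=motion, n_discard=cfg.n_discard, TR=cfg.TR,
        band=cfg.band if keep_band else None,
        add_global=cfg.global_signal_regression,
    )
    return cleaned


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the enabled stages in fixed order; returns the manifest.

    Any stage failure halts the run with the manifest recording the stages
    already completed. Disabled stages are flagged as skipped and the
    downstream stages fall back to the raw synthetic data where possible.
    """
    from . import __version__

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_path = out / "config.yaml"
    config.to_yaml(cfg_path)
    manifest = RunManifest(config_path=str(cfg_path), version=__version__)
    enabled = {s: (s in config.stages) for s in STAGE_ORDER}
    state: dict = {}

    try:
        for stage in STAGE_ORDER:
            t0 = time.time()
            if not enabled[stage]:
                manifest.add(stage, [], skipped=True)
                continue
            outputs, warns = _STAGE_FUNCS[stage](config, state, out)
            manifest.add(stage, outputs, warns, elapsed_s=time.time() - t0)
    finally:
        manifest.save(out / "manifest.json")
    return manifest


# --------------------------------------------------------------------------
# stages


def _stage_simulate(cfg: PipelineConfig, state: dict, out: Path):
    ccfg = CohortConfig(
        n_subjects=cfg.n_subjects,
        region_names=cfg.region_names,
        TR=cfg.TR,
        n_volumes=cfg.n_volumes,
        n_motion_outliers=cfg.n_motion_outliers,
        volume_grid=cfg.volume_grid,
        seed=stage_seed(cfg.seed, "simulate"),
    )
    state["cohort"] = generate_cohort(ccfg)
    state["cohort_config"] = ccfg
    p = out / "cohort_config.json"
    p.write_text(ccfg.to_json())
    scores = pd.concat(
        [r.clinical.assign(subject_id=r.subject_id) for r in state["cohort"]],
        ignore_index=True,
    )
    sp = tio.save_scores(scores, out / "scores.tsv")
    state["scores"] = scores
    return [str(p), str(sp)], []


def _stage_preprocess(cfg: PipelineConfig, state: dict, out: Path):
    cohort = state["cohort"]
    warns = []
    kept = []
    for rec in cohort:
        decisions = {
            s: prep.motion_exclusion(sess.motion, cfg.motion_limit_mm, cfg.motion_limit_deg)
            for s, sess in rec.sessions.items()
        }
        if not all(d.keep for d in decisions.values()):
            warns.append(f"{rec.subject_id}: excluded for head motion")
            continue
        kept.append(rec)
        for sname, sess in rec.sessions.items():
            if sess.volume is not None:
                data = np.asanyarray(sess.volume.dataobj)
                data = prep.discard_initial(data, cfg.n_discard)
                motion = sess.motion[cfg.n_discard:]
                vox = np.prod(data.shape[:3])
                voxel_size = float(np.abs(sess.volume.affine[0, 0]))
                data = prep.smooth_gaussian(data, cfg.fwhm_mm, voxel_size)
                flat = data.reshape(vox, -1).T  # frames x voxels
                mask = np.asanyarray(sess.label_image.dataobj) > 0
                gs = flat[:, mask.ravel()].mean(axis=1)
                cleaned = prep.detrend(flat)
                design = prep.friston24(motion)
                cleaned = prep.regress_confounds(
                    cleaned, design,
                    add_global=cfg.global_signal_regression, global_signal=gs,
                )
                nofilt = cleaned
                filt = prep.bandpass(cleaned, *cfg.band, cfg.TR)
                sess.clean_nofilt = nofilt.T.reshape(data.shape)
                sess.clean_filt = filt.T.reshape(data.shape)
            # ROI-series version (used when volumes are disabled)
            series, motion_t = prep.discard_initial(sess.roi_series, cfg.n_discard, sess.motion)
            sess.roi_nofilt = _series_chain(series, motion_t, cfg, band=False)
            sess.roi_filt = _series_chain(series, motion_t, cfg, band=True)
    if not kept:
        raise RuntimeError("motion exclusion removed every subject")
    state["analyzable"] = kept
    p = out / "exclusions.json"
    p.write_text(json.dumps({"n_input": len(cohort), "n_kept": len(kept), "notes": warns}, indent=2))
    return [str(p)], warns


def _series_chain(series, motion, cfg: PipelineConfig, band: bool):
    cleaned = prep.detrend(series)
    design = prep.friston24(motion)
    cleaned = prep.regress_confounds(cleaned, design, add_global=cfg.global_signal_regression)
    if band:
        cleaned = prep.bandpass(cleaned, *cfg.band, cfg.TR)
    return cleaned


def _analyzable(state: dict):
    return state.get("analyzable", state["cohort"])


def _fc_volume(sess):
    """Bandpassed cleaned voxel data if preprocessed, else the raw volume."""
    if getattr(sess, "clean_filt", None) is not None:
        return (sess.clean_filt, sess.volume.affine)
    return (np.asanyarray(sess.volume.dataobj), sess.volume.affine)


def _dcm_voxel_volume(sess):
    if getattr(sess, "clean_nofilt", None) is not None:
        return (sess.clean_nofilt, sess.volume.affine)
    return (np.asanyarray(sess.volume.dataobj), sess.volume.affine)


def _stage_target(cfg: PipelineConfig, state: dict, out: Path):
    rows = []
    warns = []
    for rec in _analyzable(state):
        sess = rec.sessions["pre"]
        if sess.volume is None:
            rows.append({"subject_id": rec.subject_id, "x": rec.target_coordinate[0],
                         "y": rec.target_coordinate[1], "z": rec.target_coordinate[2], "r": np.nan})
            continue
        vol = _fc_volume(sess)
        atlas = (np.asanyarray(sess.label_image.dataobj), sess.volume.affine)
        dlpfc = np.isin(atlas[0], sess.label_map["DLPFC"])
        sgacc_labels = tuple(sess.label_map["sgACC"])
        coord, r = conn.select_target(vol, dlpfc, atlas, sgacc_labels)
        rec.selected_target = coord
        rows.append({"subject_id": rec.subject_id, "x": coord[0], "y": coord[1], "z": coord[2], "r": r})
    df = pd.DataFrame(rows)
    p = out / "targets.tsv"
    df.to_csv(p, sep="\t", index=False)
    state["targets"] = df
    return [str(p)], warns


def _stage_fcmap(cfg: PipelineConfig, state: dict, out: Path):
    import nibabel as nib

    warns = []
    recs = [r for r in _analyzable(state) if r.sessions["pre"].volume is not None]
    if not recs:
        warns.append("no volumes available; FC-map stage produced ROI masks from atlas labels only")
        state["roi_masks"] = None
        return [], warns
    z_maps = []
    for rec in recs:
        sess = rec.sessions["pre"]
        vol = _fc_volume(sess)
        center = getattr(rec, "selected_target", rec.target_coordinate)
        seed = conn.SeedSpec(tuple(center), cfg.seed_radius_mm)
        ts = conn.seed_timecourse(vol, seed)
        z_maps.append(conn.fisher_z(conn.fc_map(ts, vol)))
    tmap, pos, neg = conn.group_signed_maps(z_maps, alpha=cfg.alpha)
    sess0 = recs[0].sessions["pre"]
    atlas = (np.asanyarray(sess0.label_image.dataobj), sess0.volume.affine)
    masks = conn.build_roi_masks(pos, neg, atlas, sess0.label_map, fallback_to_atlas=True)
    state["roi_masks"] = masks
    outputs = []
    for name, m in masks.masks.items():
        img = nib.Nifti1Image(m.astype(np.uint8), masks.affine)
        outputs.append(str(tio.save_volume(img, out / f"mask_{name}.nii")))
    timg = nib.Nifti1Image(tmap.data, tmap.affine)
    outputs.append(str(tio.save_volume(timg, out / "group_t_map.nii")))
    return outputs, warns


def _stage_dcm(cfg: PipelineConfig, state: dict, out: Path):
    outputs = []
    region_index = {r: i for i, r in enumerate(cfg.region_names)}
    posts: dict[str, dict] = {"NCECM": {}, "PCECM": {}}
    for rec in _analyzable(state):
        for model, regions in (("NCECM", cfg.ncecm_regions), ("PCECM", cfg.pcecm_regions)):
            series = {}
            for sname, sess in rec.sessions.items():
                masks = state.get("roi_masks")
                if masks is not None and sess.volume is not None:
                    vol = _dcm_voxel_volume(sess)
                    cols = []
                    for rname in regions:
                        if rname == "DLPFC":
                            center = getattr(rec, "selected_target", rec.target_coordinate)
                            cols.append(conn.seed_timecourse(vol, conn.SeedSpec(tuple(center), cfg.seed_radius_mm)))
                        else:
                            cols.append(conn.extract_roi_series(vol, masks.masks[rname]))
                    series[sname] = np.column_stack(cols)
                else:
                    cols = [region_index[rname] for rname in regions]
                    src = getattr(sess, "roi_nofilt", None)
                    src = src if src is not None else sess.roi_series
                    series[sname] = src[:, cols]
            inv = invert_subject(series, cfg.TR, tuple(regions),
                                 ar_order=cfg.ar_order, n_freq=cfg.n_freq)
            for sname, post in inv.items():
                posts[model][(rec.subject_id, sname)] = post
                outputs.append(str(tio.save_posterior(
                    post, out / f"dcm_{model}_{rec.subject_id}_{sname}.json")))
    state["posteriors"] = posts
    return outputs, []


def _responder_flags(scores: pd.DataFrame, subject_id: str) -> dict:
    flags = {}
    for col, scale in (("si_responder", "BSI-CV"), ("dep_responder", "HAMD-17")):
        sub = scores[(scores["subject_id"] == subject_id) & (scores["scale"] == scale)]
        wide = sub.set_index("timepoint")["value"]
        resp, _ = clin.classify(scale, float(wide["baseline"]), float(wide["post"]))
        flags[col] = bool(resp)
    return flags


def _stage_peb(cfg: PipelineConfig, state: dict, out: Path):
    outputs = []
    scores = state["scores"]
    for model, regions in (("NCECM", cfg.ncecm_regions), ("PCECM", cfg.pcecm_regions)):
        posts = state["posteriors"][model]
        index = ParamIndex(tuple(regions))
        rows, plist = [], []
        for (sid, sname), post in sorted(posts.items()):
            rows.append({"subject_id": sid, "session": sname, **_responder_flags(scores, sid)})
            plist.append(post)
        design = build_design(pd.DataFrame(rows))
        subset = list(range(index.sl_offdiag.start, index.sl_self.stop))  # couplings + self
        model_fit = peb_fit(plist, design, param_subset=subset)
        q = len(subset)
        searchable = np.zeros(model_fit.mean.size, bool)
        searchable[q:] = True  # session and responder covariates
        models = greedy_search(model_fit, searchable=searchable)
        avg = bma(models)
        rows_out = []
        for g, gname in enumerate(model_fit.group_names):
            cov, pname = gname.split(":", 1)
            rows_out.append({
                "model": model, "covariate": cov, "parameter": pname,
                "mean": avg.mean[g], "sd": float(np.sqrt(avg.variance[g])),
                "probability": avg.prob_nonzero[g],
                "significant": bool(avg.prob_nonzero[g] > cfg.probability_threshold),
            })
        df = pd.DataFrame(rows_out)
        p = out / f"bma_edges_{model}.tsv"
        df.to_csv(p, sep="\t", index=False)
        outputs.append(str(p))
        state.setdefault("bma", {})[model] = (model_fit, avg, df)
    return outputs, []


def _stage_clinical(cfg: PipelineConfig, state: dict, out: Path):
    scores, audit = clin.impute_missing(state["scores"], "week4")
    summary = []
    for scale in ("BSI-CV", "HAMD-17", "MADRS", "BDI"):
        for tp in ("post", "week2", "week4"):
            try:
                summary.append(clin.summarize_rates(scores, scale, tp))
            except ValueError:
                pass
    p1 = out / "clinical_summary.json"
    p1.write_text(json.dumps({"rates": summary, "imputations": audit}, indent=2, default=str))

    # connectivity–outcome correlations: post-session HIP->INS coupling
    corr_rows = []
    posts = state.get("posteriors", {}).get("NCECM", {})
    if posts:
        regions = tuple(cfg.ncecm_regions)
        index = ParamIndex(regions)
        k = index.offdiag_pairs.index((regions.index("INS"), regions.index("HIP")))
        subj = sorted({sid for (sid, sn) in posts})
        est, reds = [], {}
        for scale in ("BSI-CV", "MADRS", "HAMD-17"):
            reds[scale] = []
        used = []
        for sid in subj:
            if (sid, "post") not in posts:
                continue
            est.append(posts[(sid, "post")].mean[k])
            for scale in reds:
                sub = scores[(scores["subject_id"] == sid) & (scores["scale"] == scale)]
                wide = sub.set_index("timepoint")["value"]
                reds[scale].append(clin.percent_reduction(float(wide["baseline"]), float(wide["post"])))
            used.append(sid)
        if len(used) >= 4:
            for scale, vals in reds.items():
                r, pv = clin.correlate(np.array(est), np.array(vals))
                corr_rows.append({"connection": "HIP->INS", "session": "post",
                                  "scale": scale, "r": r, "p": pv, "n": len(used)})
    p2 = out / "connectivity_correlations.tsv"
    pd.DataFrame(corr_rows).to_csv(p2, sep="\t", index=False)
    return [str(p1), str(p2)], []


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "target": _stage_target,
    "fcmap": _stage_fcmap,
    "dcm": _stage_dcm,
    "peb": _stage_peb,
    "clinical": _stage_clinical,
}
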