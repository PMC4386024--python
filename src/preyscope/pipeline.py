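"""End-to-end pipeline driver: simulate (or ingest) -> behavior -> tuning
-> NLMS -> assemblies, with a JSON report and parameter manifest."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import assemblies as asm_mod
from . import behavior, io, nlms, preprocess, tuning
from .config import ConfigError, PipelineConfig
from .rois import RegionMap
from .stimulus import generate_schedule
from .synthdata import (
    assign_assembly_events,
    generate_eye_traces,
    generate_fluorescence,
    generate_population,
)


class StageError(RuntimeError):
    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"stage '{stage}' failed: {exc}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the report bundle to ``config.out_dir``.

    A fixed seed yields byte-identical result tables.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "parameters": config.manifest()}

    # --- stage: data (simulate or ingest) ------------------------------
    try:
        if config.trace_store is not None:
            for fld in ("schedule_csv", "eyes_csv", "rois_csv"):
                if getattr(config, fld) is None:
                    raise ConfigError(f"real-data run requires '{fld}'")
            schedule = io.read_schedule(config.schedule_csv)
            eye_trace = io.read_eye_trace(config.eyes_csv)
            rois = io.read_rois(config.rois_csv)
            traces, _ = io.read_trace_store(config.trace_store)
            truth = None
        else:
            schedule = generate_schedule(config.n_planes, config.reps, config.seed)
            eye_trace, true_events = generate_eye_traces(
                schedule, config.behavior, seed=config.seed + 1
            )
            rois, truth = generate_population(
                config.geometry(), config.mixture_weights, seed=config.seed + 2
            )
            assign_assembly_events(truth, true_events)
            traces = generate_fluorescence(
                rois, truth, schedule, true_events, config.noise,
                seed=config.seed + 3,
            )
            io.write_schedule(schedule, out / "schedule.csv")
            io.write_eye_trace(eye_trace, out / "eyes.csv")
            io.write_rois(rois, out / "rois.csv")
            io.write_trace_store(
                traces, [r.roi_id for r in rois], out / "traces.npz"
            )
            io.write_ground_truth_json(truth, true_events, out / "ground_truth.json")
    except Exception as exc:
        raise StageError("data", exc) from exc

    # --- stage: behavior ------------------------------------------------
    try:
        events = behavior.detect_convergent_saccades(eye_trace, config.detector)
        behavior.classify_evoked(events, schedule)
        io.write_events(events, out / "events.csv")
        rate_tab = behavior.response_rate_table(events, schedule)
        rate_tab.to_csv(out / "response_rates.csv", index=False)
        report["behavior"] = {
            "n_events": len(events),
            "n_evoked": int(sum(e.evoked for e in events)),
        }
        evoked = [e for e in events if e.evoked]
        if evoked:
            loc = behavior.response_location_stats(events, schedule)
            report["behavior"]["median_azimuth"] = loc["median_azimuth"]
        trials = behavior.trial_table(events, schedule)
        if 0 < trials["responded"].sum() < len(trials):
            model = behavior.fit_logistic_model(trials)
            report["behavior"]["model"] = {
                "terms": list(model.terms),
                "coefficients": model.coefficients,
                "odds_ratios": model.odds_ratios,
            }
            with open(out / "behavior_model.json", "w") as f:
                json.dump(report["behavior"]["model"], f, indent=1)
    except Exception as exc:
        raise StageError("behavior", exc) from exc

    # --- stage: tuning --------------------------------------------------
    try:
        responsive_ids, vrvs, fish_ids = [], [], []
        for j, roi in enumerate(rois):
            ok, _ = preprocess.classify_visually_responsive(
                traces[:, j], schedule, config.alpha, config.snr_min
            )
            if not ok:
                continue
            vrv = tuning.build_vrv(traces[:, j], schedule)
            if np.std(vrv) == 0:
                continue
            responsive_ids.append(roi.roi_id)
            vrvs.append(tuning.normalize_vrv(vrv))
            fish_ids.append(roi.fish_id)
        clusters = []
        if len(vrvs) >= 2:
            clusters = tuning.cluster_vrvs(
                np.stack(vrvs), responsive_ids, fish_ids,
                r_min=config.r_min, min_fish=config.min_fish,
                min_cells=config.min_cluster_cells,
            )
        pd.DataFrame(
            [
                {"cluster_id": c.cluster_id, "roi_id": m}
                for c in clusters
                for m in c.member_ids
            ]
        ).to_csv(out / "clusters.csv", index=False)
        report["tuning"] = {
            "n_visually_responsive": len(responsive_ids),
            "n_clusters": len(clusters),
            "cluster_sizes": [c.size for c in clusters],
        }
    except Exception as exc:
        raise StageError("tuning", exc) from exc

    # --- stage: nlms ----------------------------------------------------
    try:
        assignments = []
        glm_rows = []
        for j, roi in enumerate(rois):
            vec = nlms.peak_response_vector(traces[:, j], schedule)
            if np.std(vec) == 0:
                continue
            hit = nlms.assign_regressor(vec, r_min=config.r_min)
            if hit is None:
                continue
            key, r = hit
            y, sids = nlms.per_trial_peaks(traces[:, j], schedule)
            res = nlms.fit_models(y, sids, n_splits=config.n_splits,
                                  seed=config.seed + 10)
            assignments.append({"roi_id": roi.roi_id, "regressor": key, "r": r})
            glm_rows.append(
                {
                    "roi_id": roi.roi_id,
                    "regressor": key,
                    "cv_r2_lin": res.cv_r2_lin,
                    "cv_r2_nlin": res.cv_r2_nlin,
                    "si_nlin": res.si_nlin,
                    **{f"nl_{k}": v for k, v in res.nonlinear_coefficients.items()},
                }
            )
        pd.DataFrame(assignments).to_csv(out / "nlms_assignments.csv", index=False)
        pd.DataFrame(glm_rows).to_csv(out / "nlms_models.csv", index=False)
        report["nlms"] = {"n_assigned": len(assignments)}
        if len(glm_rows) >= 2:
            summary = nlms.nlms_population_summary(
                [
                    nlms.GLMResult({}, {}, r["cv_r2_lin"], r["cv_r2_nlin"])
                    for r in glm_rows
                ]
            )
            report["nlms"].update(summary)
    except Exception as exc:
        raise StageError("nlms", exc) from exc

    # --- stage: assemblies ----------------------------------------------
    try:
        conv_events = asm_mod.events_from_saccades(events, schedule)
        for ce, sev in zip(conv_events, events):
            ce.kinematics = {
                "L": behavior.SaccadeEvent.eye(sev, "L"),
                "R": behavior.SaccadeEvent.eye(sev, "R"),
            }
        rmap = RegionMap.default()
        params = config.assembly_params()
        found = {}
        for window in ("pre", "peri"):
            found[window] = asm_mod.detect_event_assemblies(
                traces, rois, schedule, conv_events, window, params, rmap
            )
        rows = []
        for window, asms in found.items():
            for a in asms:
                rows.append(
                    {
                        "window": window,
                        "event_index": a.event_index,
                        "hemisphere": a.hemisphere,
                        "n_cells": a.n_cells,
                        "area_um2": a.area_um2,
                        "density": a.density_um2_per_cell,
                        "lead_frames": a.lead_frames,
                        "lead_s": a.lead_s,
                        "r_avg": a.r_avg,
                        "ap_distance_um": a.ap_distance_um,
                        "members": ";".join(map(str, a.member_ids)),
                    }
                )
        pd.DataFrame(rows).to_csv(out / "assemblies.csv", index=False)
        report["assemblies"] = {
            w: {"n": len(found[w])} for w in found
        }
        report["assemblies"]["overlap"] = asm_mod.overlap_stats(
            found["pre"], found["peri"]
        )
        for window in ("pre", "peri"):
            fdr = asm_mod.fdr_circular_permutation(
                traces, rois, schedule, conv_events, window,
                n_perm=config.n_perm, seed=config.seed + 20, params=params,
            )
            report["assemblies"][window]["fdr"] = None if fdr is None else fdr["fdr"]
    except Exception as exc:
        raise StageError("assemblies", exc) from exc

    with open(out / "report.json", "w") as f:
        json.dump(report, f, indent=1, default=_jsonable)
    return report


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)
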