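"""Premotor assembly detection around convergent saccades.

Runs the pre-conv (3-frame) and peri-conv (5-frame) modulation analyses for
every detected convergence, detects spatially compact unilateral SPV
assemblies (>= 6 cells at <= 533 um^2/cell), measures lead times and
intra-assembly correlations, estimates the circular-permutation false
discovery rate, and tests the laterality of oculomotor parameters.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from preyscope import assemblies as am
from preyscope import behavior, io
from preyscope.rois import RegionMap

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
ROOT = Path(__file__).resolve().parents[1]
RAW = ROOT / "scratch" / "session"
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    schedule = io.read_schedule(RAW / "schedule.csv")
    rois = io.read_rois(RAW / "rois.csv")
    eyes = io.read_eye_trace(RAW / "eyes.csv")
    traces, roi_ids = io.read_trace_store(RAW / "traces.npz")
    order = np.argsort(roi_ids)
    rois = sorted(rois, key=lambda r: r.roi_id)
    traces = traces[:, order]

    saccades = behavior.detect_convergent_saccades(eyes)
    behavior.classify_evoked(saccades, schedule)
    events = am.events_from_saccades(saccades, schedule)
    for ce, sev in zip(events, saccades):
        ce.kinematics = {"L": sev.eye("L"), "R": sev.eye("R")}
    print(f"{len(events)} convergence events "
          f"({sum(e.evoked for e in events)} evoked)")

    rmap = RegionMap.default()
    out = {}
    rows = []
    found = {}
    for window in ("pre", "peri"):
        asms = am.detect_event_assemblies(
            traces, rois, schedule, events, window, region_map=rmap
        )
        found[window] = asms
        leads = [a.lead_frames for a in asms if a.lead_frames is not None]
        ravg = [a.r_avg for a in asms if a.r_avg is not None]
        print(f"{window}-conv: {len(asms)} assemblies; "
              f"median lead {np.median(leads) if leads else float('nan'):.1f} frames; "
              f"median r_avg {np.median(ravg) if ravg else float('nan'):.2f}")
        fdr = am.fdr_circular_permutation(
            traces, rois, schedule, events, window, seed=SEED + 20
        )
        out[window] = {
            "n_assemblies": len(asms),
            "median_lead_frames": float(np.median(leads)) if leads else None,
            "median_r_avg": float(np.median(ravg)) if ravg else None,
            "fdr": None if fdr is None else fdr["fdr"],
        }
        if fdr is not None:
            print(f"  circular-permutation FDR: {fdr['fdr']:.2f} "
                  f"(shuffled counts {fdr['shuffled_counts']})")
        for a in asms:
            rows.append(
                {
                    "window": window,
                    "event_index": a.event_index,
                    "hemisphere": a.hemisphere,
                    "n_cells": a.n_cells,
                    "density_um2_per_cell": a.density_um2_per_cell,
                    "lead_frames": a.lead_frames,
                    "lead_s": a.lead_s,
                    "r_avg": a.r_avg,
                    "ap_distance_um": a.ap_distance_um,
                }
            )
    pd.DataFrame(rows).to_csv(RESULTS / "05_assemblies.csv", index=False)

    out["overlap"] = am.overlap_stats(found["pre"], found["peri"])
    print(f"pre/peri overlap: {out['overlap']}")

    all_asms = found["pre"] + found["peri"]
    if len(all_asms) >= 2:
        lat = am.laterality_oculomotor_stats(all_asms, events)
        lat.to_csv(RESULTS / "05_laterality.csv", index=False)
        out["laterality"] = lat.to_dict("records")
        print(lat.to_string(index=False))
    (RESULTS / "05_assemblies.json").write_text(
        json.dumps(out, indent=1, default=float)
    )


if __name__ == "__main__":
    main()
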