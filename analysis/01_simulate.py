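"""Generate the synthetic virtual-hunting experiment used by all later steps.

Writes a complete session -- stimulus schedule, 60 Hz binocular eye traces,
planted ROI population with ground truth, and 1.8 Hz ΔF/F traces.  Six
focal planes at 5 repetitions give 540 epochs, enough evoked convergences
to exercise the assembly analysis.  Bulky raw data go to scratch/session/;
the summary table of what was planted goes to results/.
"""

import json
import sys
from pathlib import Path

from preyscope import io
from preyscope.stimulus import generate_schedule
from preyscope.synthdata import (
    BehaviorParams,
    GeometryParams,
    assign_assembly_events,
    generate_eye_traces,
    generate_fluorescence,
    generate_population,
)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
ROOT = Path(__file__).resolve().parents[1]
RAW = ROOT / "scratch" / "session"
RESULTS = ROOT / "results"


def main() -> None:
    RAW.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)

    schedule = generate_schedule(n_planes=6, reps=5, seed=SEED)
    print(f"schedule: {len(schedule)} epochs ({len(schedule)*32/60:.0f} min)")

    trace, true_events = generate_eye_traces(schedule, BehaviorParams(), seed=SEED + 1)
    n_evoked = sum(e.evoked for e in true_events)
    print(f"planted saccades: {len(true_events)} ({n_evoked} evoked)")

    geometry = GeometryParams(n_rois=400, n_fish=10)
    rois, truth = generate_population(geometry, seed=SEED + 2)
    assign_assembly_events(truth, true_events)
    print(f"population: {len(rois)} ROIs, {len(truth.assemblies)} planted assemblies")

    traces = generate_fluorescence(rois, truth, schedule, true_events, seed=SEED + 3)
    print(f"fluorescence: {traces.shape[0]} frames x {traces.shape[1]} ROIs")

    io.write_schedule(schedule, RAW / "schedule.csv")
    io.write_eye_trace(trace, RAW / "eyes.csv")
    io.write_rois(rois, RAW / "rois.csv")
    io.write_trace_store(traces, [r.roi_id for r in rois], RAW / "traces.npz")
    io.write_ground_truth_json(truth, true_events, RAW / "ground_truth.json")

    summary = {
        "seed": SEED,
        "n_epochs": len(schedule),
        "n_rois": len(rois),
        "n_true_saccades": len(true_events),
        "n_evoked": int(n_evoked),
        "n_planted_assemblies": len(truth.assemblies),
    }
    (RESULTS / "01_simulation_summary.json").write_text(json.dumps(summary, indent=1))
    print(f"raw session in {RAW}; summary in results/01_simulation_summary.json")


if __name__ == "__main__":
    main()
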