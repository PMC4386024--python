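"""Visual-response clustering and feature selectivity of the population.

Builds 684-point visual response vectors for all visually responsive ROIs,
clusters them at the 0.75 correlation threshold with the six-fish gate,
and summarizes each cluster's anatomy and selectivity indices.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from preyscope import io, preprocess, tuning

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
ROOT = Path(__file__).resolve().parents[1]
RAW = ROOT / "scratch" / "session"
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    schedule = io.read_schedule(RAW / "schedule.csv")
    rois = io.read_rois(RAW / "rois.csv")
    traces, roi_ids = io.read_trace_store(RAW / "traces.npz")

    spv_or_adjacent = [r for r in rois if not r.region.startswith("OTc-Np")]
    keep_ids, vrvs, fish = [], [], []
    for r in spv_or_adjacent:
        j = int(np.flatnonzero(roi_ids == r.roi_id)[0])
        ok, _ = preprocess.classify_visually_responsive(traces[:, j], schedule)
        if not ok:
            continue
        vrv = tuning.build_vrv(traces[:, j], schedule)
        if np.std(vrv) == 0:
            continue
        keep_ids.append(r.roi_id)
        vrvs.append(tuning.normalize_vrv(vrv))
        fish.append(r.fish_id)
    print(f"{len(keep_ids)} visually responsive somatic ROIs (of {len(rois)})")

    clusters = tuning.cluster_vrvs(np.stack(vrvs), keep_ids, fish)
    print(f"{len(clusters)} clusters at r >= 0.75 with >= 6 fish")

    rows = []
    col = {int(i): j for j, i in enumerate(roi_ids)}
    for c in clusters:
        dist = tuning.anatomical_distribution(c.member_ids, rois)
        top = dist.iloc[0]
        sis = []
        for mid in c.member_ids:
            sis.append(tuning.selectivity_indices(traces[:, col[mid]], schedule))
        med = {
            k: float(np.median([s[k] for s in sis if s[k] is not None]))
            for k in ("SI_dir", "SI_sp", "SI_sz", "SI_pol")
        }
        rows.append(
            {
                "cluster_id": c.cluster_id,
                "n_cells": c.size,
                "n_fish": c.n_fish,
                "top_region": top["region"],
                "top_region_fraction": float(top["fraction"]),
                **med,
            }
        )
        print(
            f"  cluster {c.cluster_id}: {c.size} cells / {c.n_fish} fish, "
            f"mostly {top['region']}, SI_sz={med['SI_sz']:+.2f} "
            f"SI_pol={med['SI_pol']:+.2f} SI_dir={med['SI_dir']:+.2f}"
        )
    pd.DataFrame(rows).to_csv(RESULTS / "03_clusters.csv", index=False)
    (RESULTS / "03_tuning.json").write_text(
        json.dumps(
            {"n_responsive": len(keep_ids), "n_clusters": len(clusters)}, indent=1
        )
    )


if __name__ == "__main__":
    main()
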