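"""Visual response vectors, correlation clustering, selectivity indices.

A visual response vector (VRV) concatenates each cell's rep-averaged ΔF/F
time course to the 18 stimuli (38 frames per stimulus = 684 points) in
canonical stimulus order.  Visually responsive cells are grouped by a
greedy seeded-centroid procedure under a hard Pearson-correlation contract:
every retained member correlates with its cluster centroid at or above the
threshold (default 0.75), and clusters must span a minimum number of fish.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .nlms import peak_response_vector
from .rois import ROIRecord
from .stimulus import (
    FRAMES_PER_EPOCH,
    N_STIMULI,
    StimulusEpoch,
    feature_code,
)

#: frames kept per stimulus in the VRV (684 / 18)
VRV_WINDOW_FRAMES = 38
VRV_LENGTH = N_STIMULI * VRV_WINDOW_FRAMES

FEATURE_BIT = {"direction": 0, "speed": 1, "size": 2, "polarity": 3}


def build_vrv(trace: np.ndarray, schedule: Sequence[StimulusEpoch]) -> np.ndarray:
    """684-point VRV: mean over reps of the first 38 frames per stimulus."""
    trace = np.asarray(trace, dtype=float)
    n_epochs = len(schedule)
    mat = trace[: n_epochs * FRAMES_PER_EPOCH].reshape(n_epochs, FRAMES_PER_EPOCH)
    parts = []
    for sid in range(N_STIMULI):
        eps = [ep for ep in schedule if ep.stimulus_id == sid]
        if not eps:
            raise ValueError(f"stimulus {sid} missing from schedule")
        mean_resp = np.mean(
            [mat[ep.epoch_index][:VRV_WINDOW_FRAMES] for ep in eps], axis=0
        )
        parts.append(mean_resp)
    vrv = np.concatenate(parts)
    assert vrv.size == VRV_LENGTH
    return vrv


def normalize_vrv(vrv: np.ndarray) -> np.ndarray:
    """VRV divided by its SD (unit-SD variant used for clustering)."""
    sd = float(np.std(vrv))
    if sd == 0:
        raise ValueError("zero-variance VRV cannot be normalized")
    return np.asarray(vrv, float) / sd


@dataclass
class Cluster:
    cluster_id: int
    member_ids: list[int]                 # roi ids
    centroid: np.ndarray                  # mean of members' normalized VRVs
    centroid_sd: np.ndarray
    fish_counts: dict[int, int] = field(default_factory=dict)

    @property
    def n_fish(self) -> int:
        return len(self.fish_counts)

    @property
    def size(self) -> int:
        return len(self.member_ids)


def _corr_to_centroid(vrvs: np.ndarray, centroid: np.ndarray) -> np.ndarray:
    c = centroid - centroid.mean()
    v = vrvs - vrvs.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(v, axis=1) * np.linalg.norm(c)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (v @ c) / denom
    return np.where(denom > 0, r, -np.inf)


def cluster_vrvs(
    vrvs: np.ndarray,
    roi_ids: Sequence[int],
    fish_ids: Sequence[int],
    r_min: float = 0.75,
    min_fish: int = 6,
    min_cells: int = 6,
    max_iter: int = 100,
) -> list[Cluster]:
    """Greedy seeded-centroid clustering of normalized VRVs.

    The cell with the most neighbours at r >= r_min seeds a candidate;
    membership (correlation-to-centroid >= r_min) and centroid are iterated
    to a fixed point; the candidate is retained only if it has at least
    ``min_cells`` members drawn from at least ``min_fish`` distinct fish.
    Members of retained clusters are removed and the procedure repeats.
    """
    vrvs = np.asarray(vrvs, dtype=float)
    n = vrvs.shape[0]
    roi_ids = np.asarray(roi_ids)
    fish_ids = np.asarray(fish_ids)
    if n < 2:
        return []
    corr = np.corrcoef(vrvs)
    np.fill_diagonal(corr, -np.inf)
    available = np.ones(n, dtype=bool)
    excluded = np.zeros(n, dtype=bool)   # failed seeds, still joinable
    clusters: list[Cluster] = []

    while True:
        cand = available & ~excluded
        if cand.sum() < min_cells:
            break
        neigh = ((corr >= r_min) & available[None, :]).sum(axis=1)
        neigh[~cand] = -1
        seed = int(np.argmax(neigh))
        if neigh[seed] + 1 < min_cells:
            break
        members = np.flatnonzero(available & ((corr[seed] >= r_min)))
        members = np.append(members, seed)
        for _ in range(max_iter):
            centroid = vrvs[members].mean(axis=0)
            r = _corr_to_centroid(vrvs, centroid)
            new_members = np.flatnonzero(available & (r >= r_min))
            if new_members.size == 0:
                break
            if np.array_equal(np.sort(new_members), np.sort(members)):
                break
            members = new_members
        ok = members.size >= min_cells
        if ok:
            fish = fish_ids[members]
            ok = np.unique(fish).size >= min_fish
        if ok:
            centroid = vrvs[members].mean(axis=0)
            # contract: every retained member meets the threshold
            r = _corr_to_centroid(vrvs[members], centroid)
            if np.any(r < r_min):
                keep = members[r >= r_min]
                if keep.size < min_cells or np.unique(fish_ids[keep]).size < min_fish:
                    excluded[seed] = True
                    continue
                members = keep
                centroid = vrvs[members].mean(axis=0)
            counts = pd.Series(fish_ids[members]).value_counts().to_dict()
            clusters.append(
                Cluster(
                    cluster_id=len(clusters),
                    member_ids=[int(roi_ids[i]) for i in members],
                    centroid=centroid,
                    centroid_sd=vrvs[members].std(axis=0),
                    fish_counts={int(k): int(v) for k, v in counts.items()},
                )
            )
            available[members] = False
        else:
            excluded[seed] = True
    return clusters


# ---------------------------------------------------------------------------
# selectivity indices
# ---------------------------------------------------------------------------

def selectivity_index_from_peaks(
    peaks16: np.ndarray, feature: str
) -> Optional[float]:
    """SI in [-1, 1] from a 16-vector of rectified mean peak responses.

    SI magnitude = (R_pref - R_flip) / (R_pref + R_flip), where R_pref is
    the maximal response over the panel and R_flip the response to the
    stimulus differing only in the queried feature bit; the sign is
    positive when the preferred stimulus carries bit value 1.  None when
    both responses are zero after rectification.
    """
    if feature not in FEATURE_BIT:
        raise KeyError(f"unknown feature '{feature}'")
    r = np.clip(np.asarray(peaks16, dtype=float), 0.0, None)
    if r.shape != (16,):
        raise ValueError("expected a 16-vector of peak responses")
    s_pref = int(np.argmax(r))
    bitpos = 3 - FEATURE_BIT[feature]      # id = 8d + 4s + 2z + p
    s_flip = s_pref ^ (1 << bitpos)
    rp, rf = r[s_pref], r[s_flip]
    if rp + rf == 0:
        return None
    mag = (rp - rf) / (rp + rf)
    bit = (s_pref >> bitpos) & 1
    return float(mag if bit == 1 else -mag)


def selectivity_indices(
    trace: np.ndarray, schedule: Sequence[StimulusEpoch]
) -> dict[str, Optional[float]]:
    """SI_dir, SI_sp, SI_sz, SI_pol for one ROI's ΔF/F trace."""
    peaks = peak_response_vector(trace, schedule)
    return {
        "SI_dir": selectivity_index_from_peaks(peaks, "direction"),
        "SI_sp": selectivity_index_from_peaks(peaks, "speed"),
        "SI_sz": selectivity_index_from_peaks(peaks, "size"),
        "SI_pol": selectivity_index_from_peaks(peaks, "polarity"),
    }


def anatomical_distribution(
    member_ids: Sequence[int], rois: Sequence[ROIRecord]
) -> pd.DataFrame:
    """Counts and fractions of cluster members per anatomical region."""
    by_id = {r.roi_id: r for r in rois}
    regions = []
    for mid in member_ids:
        roi = by_id.get(mid)
        if roi is None or roi.region is None:
            raise ValueError(f"member {mid} lacks a region label")
        regions.append((roi.region, roi.hemisphere))
    df = (
        pd.DataFrame(regions, columns=["region", "hemisphere"])
        .value_counts()
        .rename("count")
        .reset_index()
    )
    df["fraction"] = df["count"] / df["count"].sum()
    return df
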