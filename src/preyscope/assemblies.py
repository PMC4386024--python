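"""Convergence-triggered detection of premotor tectal assemblies.

For every convergent saccade two event-triggered windows are examined on
the 1.8 Hz frame grid: the pre-conv window spans the 3 frames (~1.65 s)
immediately before the saccade frame, the peri-conv window the 5 frames
(~2.75 s) centred on it.  Cells whose windowed ΔF/F in the response trial
exceeds activity at corresponding times of non-response trials of the same
stimulus (t-test p < 0.05 and SNR > 3) are response-modulated; assemblies
are spatially compact, unilateral groups of such SPV cells (>= 6 cells at
<= 533 um^2/cell inside a 2-SD covariance ellipse).  A circular-permutation
control estimates the false-discovery rate of the whole procedure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .rois import ROIRecord, RegionMap
from .stimulus import FRAME_RATE_HZ, FRAMES_PER_EPOCH, StimulusEpoch, epoch_frame
from .preprocess import BASELINE_FRAMES

#: pre-conv window: 3 frames ending the frame before the saccade (~1.65 s)
PRE_WINDOW_FRAMES = 3
#: peri-conv window: 5 frames centred on the saccade (~2.75 s)
PERI_WINDOW_FRAMES = 5


@dataclass
class AssemblyParams:
    alpha: float = 0.05
    snr_min: float = 3.0
    min_cells: int = 6
    max_density_um2: float = 533.0
    min_comparison_trials: int = 3
    #: semi-axis floor for degenerate (collinear) centroid sets, um
    min_axis_um: float = 1.0


@dataclass
class ModulationResult:
    roi_id: int
    p: float
    snr: float
    window: str                     # 'pre' | 'peri'

    def passes(self, params: AssemblyParams) -> bool:
        return (self.p < params.alpha) and (self.snr > params.snr_min)


@dataclass
class Assembly:
    window: str
    event_index: int
    member_ids: list[int]
    hemisphere: str
    center: tuple[float, float]
    semi_axes: tuple[float, float]
    angle: float                    # radians, major-axis orientation
    area_um2: float
    density_um2_per_cell: float
    lead_frames: Optional[int] = None
    r_avg: Optional[float] = None
    r_iqr: Optional[tuple[float, float]] = None
    fraction_visually_responsive: Optional[float] = None
    ap_distance_um: Optional[float] = None

    @property
    def n_cells(self) -> int:
        return len(self.member_ids)

    @property
    def lead_s(self) -> Optional[float]:
        if self.lead_frames is None:
            return None
        return self.lead_frames / FRAME_RATE_HZ


def window_frames(saccade_frame: int, window: str) -> np.ndarray:
    """Epoch-relative frames of the analysis window (may exceed [0, 57))."""
    s = saccade_frame
    if window == "pre":
        return np.arange(s - PRE_WINDOW_FRAMES, s)
    if window == "peri":
        half = PERI_WINDOW_FRAMES // 2
        return np.arange(s - half, s + half + 1)
    raise ValueError(f"unknown window '{window}'")


def _epoch_matrix(trace: np.ndarray, n_epochs: int) -> np.ndarray:
    return np.asarray(trace, float)[: n_epochs * FRAMES_PER_EPOCH].reshape(
        n_epochs, FRAMES_PER_EPOCH
    )


def evoked_modulation(
    trace: np.ndarray,
    schedule: Sequence[StimulusEpoch],
    event_epoch: int,
    saccade_frame: int,
    response_epochs: set[int],
    window: str,
    roi_id: int = -1,
    params: Optional[AssemblyParams] = None,
) -> Optional[ModulationResult]:
    """Response- vs non-response-trial comparison for one ROI and event.

    The response trial's window-mean ΔF/F is tested (one-sided t) against
    the distribution of window means at the same epoch-relative frames
    across non-response trials of the identical stimulus; SNR is the peak
    windowed signal in units of the non-response frame spread.  The
    per-trial summary is used (rather than pooling frames) because there is
    exactly one response trial per event: a burst occupying part of the
    window should register against a quiet null regardless of its phase.
    """
    if params is None:
        params = AssemblyParams()
    mat = _epoch_matrix(trace, len(schedule))
    frames = window_frames(saccade_frame, window)
    if frames.min() < 0 or frames.max() >= FRAMES_PER_EPOCH:
        warnings.warn("analysis window truncated by epoch edge; event skipped")
        return None
    sid = schedule[event_epoch].stimulus_id
    comparison = [
        ep.epoch_index
        for ep in schedule
        if ep.stimulus_id == sid and ep.epoch_index not in response_epochs
    ]
    if len(comparison) < params.min_comparison_trials:
        raise ValueError(
            f"stimulus {sid}: need >= {params.min_comparison_trials} "
            f"non-response trials, got {len(comparison)}"
        )
    resp = mat[event_epoch, frames]
    null_trials = mat[np.asarray(comparison)][:, frames]
    null_means = null_trials.mean(axis=1)
    resp_mean = float(resp.mean())
    if np.allclose(null_means, resp_mean) or null_means.std(ddof=1) == 0:
        p = 1.0
    else:
        # one-sided prediction-interval t: is the response trial's window
        # mean an outlier of the non-response trial means?  The 1 + 1/n
        # factor keeps the null calibrated (the response mean carries the
        # same sampling variance as each null mean).
        n = null_means.size
        s = null_means.std(ddof=1)
        t = (resp_mean - null_means.mean()) / (s * np.sqrt(1.0 + 1.0 / n))
        p = float(stats.t.sf(t, df=n - 1))
    null = null_trials.ravel()
    sd = float(null.std(ddof=1))
    snr = float((resp.max() - null.mean()) / sd) if sd > 0 else np.inf
    return ModulationResult(roi_id=roi_id, p=p, snr=snr, window=window)


def spontaneous_modulation(
    trace: np.ndarray,
    schedule: Sequence[StimulusEpoch],
    event_epoch: int,
    saccade_frame: int,
    window: str,
    roi_id: int = -1,
    params: Optional[AssemblyParams] = None,
) -> Optional[ModulationResult]:
    """Within-epoch comparison for spontaneous convergences.

    The windowed frames are tested (one-sample t) against the mean signal
    over the remainder of the 32 s epoch.
    """
    if params is None:
        params = AssemblyParams()
    mat = _epoch_matrix(trace, len(schedule))
    frames = window_frames(saccade_frame, window)
    if frames.min() < 0 or frames.max() >= FRAMES_PER_EPOCH:
        warnings.warn("analysis window truncated by epoch edge; event skipped")
        return None
    rest = np.setdiff1d(np.arange(FRAMES_PER_EPOCH), frames)
    win_vals = mat[event_epoch, frames]
    rest_vals = mat[event_epoch, rest]
    if np.allclose(win_vals, rest_vals.mean()):
        p = 1.0
    else:
        p = float(stats.ttest_1samp(win_vals, rest_vals.mean())[1])
    sd = float(rest_vals.std(ddof=1))
    snr = float((win_vals.max() - rest_vals.mean()) / sd) if sd > 0 else np.inf
    return ModulationResult(roi_id=roi_id, p=p, snr=snr, window=window)


# ---------------------------------------------------------------------------
# spatial assembly detection
# ---------------------------------------------------------------------------

def _covariance_ellipse(
    pts: np.ndarray, min_axis: float
) -> tuple[np.ndarray, np.ndarray, float]:
    """2-SD covariance ellipse: (center, semi-axes, angle)."""
    center = pts.mean(axis=0)
    if pts.shape[0] < 2:
        return center, np.array([min_axis, min_axis]), 0.0
    cov = np.cov(pts.T, ddof=1)
    evals, evecs = np.linalg.eigh(np.atleast_2d(cov))
    evals = np.clip(evals, (min_axis / 2.0) ** 2, None)
    semi = 2.0 * np.sqrt(evals)[::-1]            # major first
    angle = float(np.arctan2(evecs[1, -1], evecs[0, -1]))
    return center, semi, angle


def detect_assembly(
    modulated: Sequence[ROIRecord],
    window: str,
    event_index: int,
    params: Optional[AssemblyParams] = None,
) -> dict[str, Optional[Assembly]]:
    """Per-hemisphere assembly detection among response-modulated SPV cells.

    A 2-SD covariance ellipse is fitted to the modulated-cell centroids of
    each tectal hemisphere; while the cell density is below the floor
    (ellipse area / n > max_density), the cell farthest from the ellipse
    centre (Mahalanobis) is dropped and the ellipse refitted.  The
    hemisphere yields an assembly iff >= min_cells remain at compliant
    density (boundary values accepted).
    """
    if params is None:
        params = AssemblyParams()
    out: dict[str, Optional[Assembly]] = {"L": None, "R": None}
    for hemi in ("L", "R"):
        cells = [
            r for r in modulated
            if r.region == f"OTc-SPV-{hemi}"
        ]
        if len(cells) < params.min_cells:
            continue
        pts = np.array([[c.x, c.y] for c in cells])
        ids = [c.roi_id for c in cells]
        while len(ids) >= params.min_cells:
            center, semi, angle = _covariance_ellipse(pts, params.min_axis_um)
            area = float(np.pi * semi[0] * semi[1])
            density = area / len(ids)
            if density <= params.max_density_um2:
                out[hemi] = Assembly(
                    window=window,
                    event_index=event_index,
                    member_ids=list(ids),
                    hemisphere=hemi,
                    center=(float(center[0]), float(center[1])),
                    semi_axes=(float(semi[0]), float(semi[1])),
                    angle=angle,
                    area_um2=area,
                    density_um2_per_cell=float(density),
                )
                break
            cov = np.cov(pts.T, ddof=1) + np.eye(2) * (params.min_axis_um / 2) ** 2
            inv = np.linalg.inv(cov)
            d = np.einsum("ij,jk,ik->i", pts - center, inv, pts - center)
            drop = int(np.argmax(d))
            pts = np.delete(pts, drop, axis=0)
            ids = ids[:drop] + ids[drop + 1:]
    return out


def assembly_lead_time(
    member_traces: np.ndarray,
    saccade_frame: int,
    baseline_frames: int = BASELINE_FRAMES,
) -> Optional[int]:
    """Premotor lead of the population response, in frames.

    Member epoch traces (n_members, 57) are max-normalized per cell and
    averaged; the threshold is the pre-stimulus baseline mean + 2 SD; the
    lead is the gap between the saccade frame and the onset of the
    contiguous suprathreshold run that leads into it (walking back from
    the saccade frame), so an isolated noise crossing earlier in the epoch
    does not masquerade as premotor activity.  None when the population
    response at the saccade frame never reaches threshold.
    """
    m = np.asarray(member_traces, dtype=float)
    if m.ndim != 2 or m.shape[0] < 1:
        raise ValueError("expected (n_members, n_frames) epoch traces")
    peaks = m.max(axis=1, keepdims=True)
    peaks[peaks == 0] = 1.0
    pop = (m / peaks).mean(axis=0)
    base = pop[:baseline_frames]
    thresh = base.mean() + 2.0 * base.std(ddof=1 if baseline_frames > 1 else 0)
    if pop[saccade_frame] <= thresh:
        return None
    f = saccade_frame
    while f - 1 >= 0 and pop[f - 1] > thresh:
        f -= 1
    return int(saccade_frame - f)


def intra_assembly_correlation(
    member_traces: np.ndarray,
) -> tuple[Optional[float], tuple[float, float], np.ndarray]:
    """Leave-one-out correlation of each member with the assembly mean.

    Returns (median r, interquartile range, per-cell r).  Constant-trace
    members are excluded (NaN in the per-cell vector).
    """
    m = np.asarray(member_traces, dtype=float)
    if m.shape[0] < 2:
        raise ValueError("need >= 2 members")
    rs = np.full(m.shape[0], np.nan)
    for i in range(m.shape[0]):
        rest = np.delete(m, i, axis=0).mean(axis=0)
        if np.std(m[i]) == 0 or np.std(rest) == 0:
            continue
        rs[i] = np.corrcoef(m[i], rest)[0, 1]
    valid = rs[~np.isnan(rs)]
    if valid.size == 0:
        return None, (np.nan, np.nan), rs
    q1, q3 = np.percentile(valid, [25, 75])
    return float(np.median(valid)), (float(q1), float(q3)), rs


# ---------------------------------------------------------------------------
# event-level pipeline
# ---------------------------------------------------------------------------

@dataclass
class ConvergenceEvent:
    """Frame-clock reference of one convergent saccade for assembly analysis."""

    event_index: int
    epoch_index: int
    saccade_frame: int        # epoch-relative imaging frame of onset
    evoked: bool
    hemifield: Optional[str] = None
    kinematics: Optional[dict] = None   # per-eye delta/post/peak_velocity


def events_from_saccades(
    saccades: Sequence, schedule: Sequence[StimulusEpoch]
) -> list[ConvergenceEvent]:
    """Map detected/true saccades onto epoch frame coordinates."""
    out = []
    for k, ev in enumerate(saccades):
        t = getattr(ev, "onset_time", None)
        if t is None:
            t = ev.time
        ep = next((e for e in schedule if e.contains(t)), None)
        if ep is None:
            continue
        out.append(
            ConvergenceEvent(
                event_index=k,
                epoch_index=ep.epoch_index,
                saccade_frame=epoch_frame(ep, t),
                evoked=bool(getattr(ev, "evoked", False)),
            )
        )
    return out


def detect_event_assemblies(
    traces: np.ndarray,
    rois: Sequence[ROIRecord],
    schedule: Sequence[StimulusEpoch],
    events: Sequence[ConvergenceEvent],
    window: str,
    params: Optional[AssemblyParams] = None,
    region_map: Optional[RegionMap] = None,
) -> list[Assembly]:
    """Full per-event assembly detection over a session.

    Evoked events are tested against non-response trials of their stimulus;
    spontaneous events against the remainder of their own epoch.  Detected
    assemblies carry lead time, intra-assembly correlation and, when a
    region map is given, the anterior-posterior distance of their centre
    from the posterior commissure.
    """
    if params is None:
        params = AssemblyParams()
    n_epochs = len(schedule)
    response_epochs = {e.epoch_index for e in events if e.evoked}
    spv = [r for r in rois if r.region.startswith("OTc-SPV")]
    col = {r.roi_id: j for j, r in enumerate(rois)}
    assemblies: list[Assembly] = []
    mat_all = np.asarray(traces, float)[: n_epochs * FRAMES_PER_EPOCH]

    for ev in events:
        modulated: list[ROIRecord] = []
        try:
            for roi in spv:
                tr = mat_all[:, col[roi.roi_id]]
                if ev.evoked:
                    res = evoked_modulation(
                        tr, schedule, ev.epoch_index, ev.saccade_frame,
                        response_epochs, window, roi.roi_id, params,
                    )
                else:
                    res = spontaneous_modulation(
                        tr, schedule, ev.epoch_index, ev.saccade_frame,
                        window, roi.roi_id, params,
                    )
                if res is None:
                    modulated = []
                    break
                if res.passes(params):
                    modulated.append(roi)
        except ValueError:
            # too few comparison trials for this event's stimulus
            continue
        if not modulated:
            continue
        found = detect_assembly(modulated, window, ev.event_index, params)
        for asm in found.values():
            if asm is None:
                continue
            sl = slice(
                ev.epoch_index * FRAMES_PER_EPOCH,
                (ev.epoch_index + 1) * FRAMES_PER_EPOCH,
            )
            mem = np.stack(
                [mat_all[sl, col[m]] for m in asm.member_ids]
            )
            asm.lead_frames = assembly_lead_time(mem, ev.saccade_frame)
            if len(asm.member_ids) >= 2:
                asm.r_avg, asm.r_iqr, _ = intra_assembly_correlation(mem)
            if region_map is not None:
                asm.ap_distance_um = region_map.ap_distance(*asm.center)
            assemblies.append(asm)
    return assemblies


def fdr_circular_permutation(
    traces: np.ndarray,
    rois: Sequence[ROIRecord],
    schedule: Sequence[StimulusEpoch],
    events: Sequence[ConvergenceEvent],
    window: str,
    n_perm: int = 5,
    seed: int = 0,
    params: Optional[AssemblyParams] = None,
) -> Optional[dict]:
    """False-discovery rate by circular permutation of the time base.

    Every ROI's full-session trace is circularly shifted by one common
    seeded offset (>= 2 epochs) per permutation, destroying the alignment
    between activity and convergence events while preserving inter-cell
    correlation structure; detection is re-run with identical criteria.
    FDR = mean shuffled assembly count / original count (None when no
    assembly is found in the original data).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    original = detect_event_assemblies(traces, rois, schedule, events, window, params)
    n_orig = len(original)
    if n_orig == 0:
        return None
    rng = np.random.default_rng(seed)
    n_frames = len(schedule) * FRAMES_PER_EPOCH
    lo = 2 * FRAMES_PER_EPOCH
    counts = []
    for _ in range(n_perm):
        offset = int(rng.integers(lo, n_frames - lo))
        shifted = np.roll(np.asarray(traces, float)[:n_frames], offset, axis=0)
        shuffled = detect_event_assemblies(
            shifted, rois, schedule, events, window, params
        )
        counts.append(len(shuffled))
    return {
        "window": window,
        "n_original": n_orig,
        "shuffled_counts": counts,
        "fdr": float(np.mean(counts)) / n_orig,
    }


# ---------------------------------------------------------------------------
# oculomotor statistics
# ---------------------------------------------------------------------------

_KIN_PARAMS = ("post", "delta", "peak_velocity")


def laterality_oculomotor_stats(
    assemblies: Sequence[Assembly],
    events: Sequence[ConvergenceEvent],
) -> pd.DataFrame:
    """Paired ipsi- vs contralateral eye kinematics across assemblies.

    For post-saccadic position, position change and peak nasal velocity:
    paired t-test of the eye ipsilateral to each assembly's hemisphere
    against the contralateral eye.
    """
    by_idx = {e.event_index: e for e in events}
    rows = {p: ([], []) for p in _KIN_PARAMS}
    for asm in assemblies:
        ev = by_idx.get(asm.event_index)
        if ev is None or ev.kinematics is None:
            continue
        ipsi = ev.kinematics[asm.hemisphere]
        contra = ev.kinematics["R" if asm.hemisphere == "L" else "L"]
        for p in _KIN_PARAMS:
            if p in ipsi and p in contra:
                rows[p][0].append(ipsi[p])
                rows[p][1].append(contra[p])
    records = []
    for p, (ip, co) in rows.items():
        if len(ip) < 2:
            raise ValueError(f"need >= 2 assemblies with kinematics for '{p}'")
        t, pv = stats.ttest_rel(ip, co)
        records.append(
            {
                "parameter": p,
                "n": len(ip),
                "ipsi_mean": float(np.mean(ip)),
                "contra_mean": float(np.mean(co)),
                "t": float(t),
                "p": float(pv),
            }
        )
    return pd.DataFrame(records)


def ap_location_trend(
    assemblies: Sequence[Assembly],
    events: Sequence[ConvergenceEvent],
    parameter: str = "delta",
) -> pd.DataFrame:
    """Eye kinematics vs anterior-posterior assembly location, per tectum.

    Independent OLS fits of the chosen eye parameter against AP distance
    from the posterior commissure, one line per (tectal hemisphere, eye).
    """
    by_idx = {e.event_index: e for e in events}
    records = []
    for hemi in ("L", "R"):
        for eye in ("L", "R"):
            xs, ys = [], []
            for asm in assemblies:
                if asm.hemisphere != hemi or asm.ap_distance_um is None:
                    continue
                ev = by_idx.get(asm.event_index)
                if ev is None or ev.kinematics is None:
                    continue
                if parameter not in ev.kinematics[eye]:
                    continue
                xs.append(asm.ap_distance_um)
                ys.append(ev.kinematics[eye][parameter])
            if len(xs) < 3:
                records.append(
                    {"tectum": hemi, "eye": eye, "n": len(xs), "slope": np.nan,
                     "slope_ci_low": np.nan, "slope_ci_high": np.nan, "p": np.nan}
                )
                continue
            res = stats.linregress(xs, ys)
            tcrit = stats.t.ppf(0.975, len(xs) - 2)
            records.append(
                {
                    "tectum": hemi,
                    "eye": eye,
                    "n": len(xs),
                    "slope": float(res.slope),
                    "slope_ci_low": float(res.slope - tcrit * res.stderr),
                    "slope_ci_high": float(res.slope + tcrit * res.stderr),
                    "p": float(res.pvalue),
                }
            )
    return pd.DataFrame(records)


def overlap_stats(
    pre_assemblies: Sequence[Assembly],
    peri_assemblies: Sequence[Assembly],
) -> dict:
    """Event- and cell-level overlap between pre- and peri-conv assemblies."""
    peri_by_event: dict[int, set[int]] = {}
    for asm in peri_assemblies:
        peri_by_event.setdefault(asm.event_index, set()).update(asm.member_ids)
    pre_events = {a.event_index for a in pre_assemblies}
    if not pre_events:
        return {"event_overlap": 0.0, "cell_overlap": 0.0, "n_pre_events": 0}
    matched = sum(1 for e in pre_events if e in peri_by_event)
    n_cells = 0
    n_shared = 0
    for asm in pre_assemblies:
        peri_members = peri_by_event.get(asm.event_index, set())
        n_cells += len(asm.member_ids)
        n_shared += sum(1 for m in asm.member_ids if m in peri_members)
    return {
        "event_overlap": matched / len(pre_events),
        "cell_overlap": n_shared / n_cells if n_cells else 0.0,
        "n_pre_events": len(pre_events),
    }
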