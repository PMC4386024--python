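"""Imaging front end: registration, segmentation, ΔF/F, responsiveness.

Traces live on the epoch-aligned frame grid (57 frames per 32 s epoch at
1.8 Hz) as plain arrays: a session trace is shape (n_frames,), a trace
matrix (n_frames, n_rois).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.feature import peak_local_max
from skimage.registration import phase_cross_correlation
from skimage.segmentation import watershed

from .nlms import stimulus_window_frames
from .rois import ROIRecord, RegionMap  # noqa: F401  (re-export)
from .stimulus import FRAMES_PER_EPOCH, StimulusEpoch

#: pre-stimulus baseline frames at the start of each epoch
BASELINE_FRAMES = 3


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------

def register_frames(
    stack: np.ndarray,
    template: Optional[np.ndarray] = None,
    max_shift: int = 20,
    template_alpha: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Rigid per-frame translation correction against a running template.

    Returns (shifts, corrected) where shifts[i] = (dy, dx) is the detected
    displacement of frame i (the correction applied is its negation).
    Shifts beyond ``max_shift`` are clipped and the frame flagged by NaN in
    a copy-free manner: clipped frames keep the clipped value.
    """
    stack = np.asarray(stack, dtype=float)
    n = stack.shape[0]
    if template is None:
        template = stack[0].copy()
    shifts = np.zeros((n, 2))
    corrected = np.empty_like(stack)
    for i in range(n):
        frame = stack[i]
        if np.ptp(frame) == 0 or np.ptp(template) == 0:
            warnings.warn(f"degenerate (constant) frame {i}; zero shift assumed")
            shift = np.zeros(2)
        else:
            shift, *_ = phase_cross_correlation(
                template, frame, upsample_factor=1, normalization=None
            )
        shift = np.clip(shift, -max_shift, max_shift)
        shifts[i] = shift
        corrected[i] = np.roll(
            np.roll(frame, int(shift[0]), axis=0), int(shift[1]), axis=1
        )
        template = (1 - template_alpha) * template + template_alpha * corrected[i]
    return shifts, corrected


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

@dataclass
class SegmentationParams:
    pixel_pitch_um: float = 500.0 / 128.0
    min_area_um2: float = 20.0
    max_area_um2: float = 200.0
    min_separation_px: int = 3
    activity_percentile: float = 80.0


def segment_rois(
    stack: np.ndarray,
    params: Optional[SegmentationParams] = None,
    region_map: Optional[RegionMap] = None,
) -> list[ROIRecord]:
    """Soma-scale ROI segmentation of a registered single-plane stack.

    Seeds are local maxima of the temporal-activity map (per-pixel SD over
    time, lightly smoothed); masks are grown by watershed on the inverted
    activity map and kept within soma-scale area bounds.
    """
    if params is None:
        params = SegmentationParams()
    stack = np.asarray(stack, dtype=float)
    activity = stack.std(axis=0)
    if np.ptp(activity) == 0:
        return []
    thresh = max(
        np.percentile(activity, params.activity_percentile),
        0.05 * activity.max(),
    )
    fg = activity > thresh
    if not np.any(fg):
        return []
    labels, n_blobs = ndimage.label(fg)

    px_area = params.pixel_pitch_um**2
    max_px = int(np.ceil(params.max_area_um2 / px_area))
    min_px = max(1, int(np.floor(params.min_area_um2 / px_area)))
    rois: list[ROIRecord] = []
    rid = 0
    for k in range(1, n_blobs + 1):
        pix = np.argwhere(labels == k)
        if pix.shape[0] < min_px:
            continue
        if pix.shape[0] > max_px:
            # merged somata: split by watershed on the distance transform
            sub = labels == k
            dist = ndimage.distance_transform_edt(sub)
            sub_seeds = peak_local_max(
                dist, min_distance=params.min_separation_px, labels=sub
            )
            if sub_seeds.shape[0] > 1:
                sub_markers = np.zeros(labels.shape, int)
                for kk, (r, c) in enumerate(sub_seeds, start=1):
                    sub_markers[r, c] = kk
                sub_labels = watershed(dist.max() - dist, markers=sub_markers,
                                       mask=sub)
                parts = [
                    np.argwhere(sub_labels == kk)
                    for kk in range(1, sub_labels.max() + 1)
                ]
            else:
                parts = [pix]
        else:
            parts = [pix]
        for part in parts:
            if part.shape[0] < min_px:
                continue
            # activity-weighted centroid
            w = activity[part[:, 0], part[:, 1]]
            cy, cx = (part * w[:, None]).sum(axis=0) / w.sum()
            x_um = (cx - stack.shape[2] / 2) * params.pixel_pitch_um
            y_um = cy * params.pixel_pitch_um
            if region_map is not None:
                roi = ROIRecord.from_point(rid, x_um, y_um, region_map)
            else:
                roi = ROIRecord(roi_id=rid, x=x_um, y=y_um)
            roi.mask = part
            rois.append(roi)
            rid += 1
    return rois


def extract_traces(stack: np.ndarray, rois: Sequence[ROIRecord]) -> np.ndarray:
    """Mean fluorescence inside each ROI mask, shape (n_frames, n_rois)."""
    out = np.empty((stack.shape[0], len(rois)))
    for j, roi in enumerate(rois):
        if roi.mask is None:
            raise ValueError(f"ROI {roi.roi_id} has no pixel mask")
        out[:, j] = stack[:, roi.mask[:, 0], roi.mask[:, 1]].mean(axis=1)
    return out


# ---------------------------------------------------------------------------
# ΔF/F
# ---------------------------------------------------------------------------

def compute_dff(
    raw: np.ndarray,
    schedule: Sequence[StimulusEpoch],
    baseline: str = "epoch-start",
    baseline_frames: int = BASELINE_FRAMES,
    percentile: float = 20.0,
    percentile_window_epochs: int = 3,
) -> np.ndarray:
    """ΔF/F = (F - F0) / F0 on the epoch-aligned grid.

    'epoch-start' baselines each epoch on the mean of its first
    ``baseline_frames`` frames (the pre-stimulus interval); a
    'rolling-percentile' alternative uses a low percentile of F over a
    sliding window of epochs.  ROIs whose baseline is non-positive are
    invalid: their ΔF/F is NaN.
    """
    raw = np.asarray(raw, dtype=float)
    squeeze = raw.ndim == 1
    if squeeze:
        raw = raw[:, None]
    n_epochs = len(schedule)
    n = n_epochs * FRAMES_PER_EPOCH
    if raw.shape[0] < n:
        raise ValueError("trace shorter than schedule implies")
    raw = raw[:n]
    dff = np.empty_like(raw)
    if baseline == "epoch-start":
        blocks = raw.reshape(n_epochs, FRAMES_PER_EPOCH, -1)
        f0 = blocks[:, :baseline_frames].mean(axis=1)  # (n_epochs, n_rois)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = (blocks - f0[:, None, :]) / f0[:, None, :]
        out[:, :, :] = np.where(f0[:, None, :] > 0, out, np.nan)
        dff = out.reshape(n, -1)
    elif baseline == "rolling-percentile":
        w = percentile_window_epochs * FRAMES_PER_EPOCH
        for j in range(raw.shape[1]):
            f0 = ndimage.percentile_filter(raw[:, j], percentile, size=w)
            with np.errstate(divide="ignore", invalid="ignore"):
                dff[:, j] = np.where(f0 > 0, (raw[:, j] - f0) / f0, np.nan)
    else:
        raise ValueError(f"unknown baseline definition '{baseline}'")
    return dff[:, 0] if squeeze else dff


# ---------------------------------------------------------------------------
# visually-responsive classification
# ---------------------------------------------------------------------------

def classify_visually_responsive(
    trace: np.ndarray,
    schedule: Sequence[StimulusEpoch],
    alpha: float = 0.05,
    snr_min: float = 3.0,
    baseline_frames: int = BASELINE_FRAMES,
) -> tuple[bool, pd.DataFrame]:
    """Response modulation to at least one of the 18 stimuli.

    Per stimulus: a paired t-test of per-trial stimulus-window peak ΔF/F
    against per-trial baseline means, plus SNR = (max rep-averaged window
    signal - baseline mean) / baseline SD.  The cell is responsive iff any
    stimulus passes p < alpha and SNR > snr_min.  No multiple-testing
    correction is applied across the 18 stimuli (by design: 'at least one
    stimulus' is the criterion; the false-positive cost is characterized in
    the test suite).
    """
    trace = np.asarray(trace, dtype=float)
    n_epochs = len(schedule)
    mat = trace[: n_epochs * FRAMES_PER_EPOCH].reshape(n_epochs, FRAMES_PER_EPOCH)
    rows = []
    responsive = False
    by_stim: dict[int, list[StimulusEpoch]] = {}
    for ep in schedule:
        by_stim.setdefault(ep.stimulus_id, []).append(ep)
    for sid, eps in sorted(by_stim.items()):
        if len(eps) < 3:
            raise ValueError(
                f"stimulus {sid}: need >= 3 repetitions, got {len(eps)}"
            )
        window = stimulus_window_frames(eps[0])
        trials = np.stack([mat[ep.epoch_index] for ep in eps])
        base = trials[:, :baseline_frames]
        peaks = trials[:, window].max(axis=1)
        base_means = base.mean(axis=1)
        if np.allclose(peaks, base_means):
            p = 1.0
        else:
            p = float(stats.ttest_rel(peaks, base_means)[1])
        base_sd = float(base.std(ddof=1))
        mean_resp = trials.mean(axis=0)
        num = float(mean_resp[window].max() - base.mean())
        snr = num / base_sd if base_sd > 0 else np.inf * np.sign(num or 1)
        ok = (p < alpha) and (snr > snr_min)
        responsive = responsive or bool(ok)
        rows.append(
            {"stimulus_id": sid, "p": p, "snr": snr, "responsive": bool(ok)}
        )
    return responsive, pd.DataFrame(rows)
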