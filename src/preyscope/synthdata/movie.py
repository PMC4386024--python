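"""Rendering of synthetic imaging movies from planted ROIs and traces."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ..rois import ROIRecord


@dataclass
class MovieParams:
    """Geometry and photometry of the rendered stack."""

    shape: tuple[int, int] = (128, 128)     # pixels (rows, cols)
    field_um: float = 500.0                 # physical size of the frame
    background: float = 10.0
    baseline_f: float = 50.0                # resting fluorescence of somata
    roi_radius_px: int = 2
    #: per-frame integer rigid shifts (dy, dx); default none
    shifts: Optional[np.ndarray] = None
    shift_noise_sd: float = 0.0             # photon-free additive noise


def roi_mask_pixels(
    roi: ROIRecord, params: MovieParams
) -> np.ndarray:
    """(n, 2) array of (row, col) pixels of the ROI's disk mask."""
    px = params.field_um / params.shape[1]
    c = int(round(roi.x / px + params.shape[1] / 2))
    r = int(round(roi.y / px))
    rad = params.roi_radius_px
    rows, cols = [], []
    for dr in range(-rad, rad + 1):
        for dc in range(-rad, rad + 1):
            if dr * dr + dc * dc <= rad * rad:
                rows.append(r + dr)
                cols.append(c + dc)
    pix = np.column_stack([rows, cols])
    if (
        pix[:, 0].min() < 0
        or pix[:, 1].min() < 0
        or pix[:, 0].max() >= params.shape[0]
        or pix[:, 1].max() >= params.shape[1]
    ):
        raise ValueError(f"ROI {roi.roi_id} mask out of frame bounds")
    return pix


def render_movie(
    rois: Sequence[ROIRecord],
    traces: np.ndarray,
    params: Optional[MovieParams] = None,
    seed: int = 0,
    out_path: Optional[str] = None,
) -> np.ndarray:
    """Render ΔF/F traces into a (frames, H, W) float32 stack.

    Pixel value = background + baseline_f * (1 + ΔF/F) on ROI disks; an
    optional per-frame integer rigid shift emulates motion artifacts.
    Written as a multi-page TIFF when ``out_path`` is given.
    """
    if params is None:
        params = MovieParams()
    n_frames, n_rois = traces.shape
    if n_rois != len(rois):
        raise ValueError("trace columns must match ROI count")
    if params.shifts is not None and len(params.shifts) != n_frames:
        raise ValueError("shifts must have one (dy, dx) row per frame")
    rng = np.random.default_rng(seed)

    stack = np.full((n_frames, *params.shape), params.background, dtype=np.float32)
    masks = [roi_mask_pixels(roi, params) for roi in rois]
    for j, pix in enumerate(masks):
        f = params.baseline_f * (1.0 + traces[:, j])
        stack[:, pix[:, 0], pix[:, 1]] += f[:, None].astype(np.float32)
    if params.shifts is not None:
        for i, (dy, dx) in enumerate(np.asarray(params.shifts, dtype=int)):
            if dy or dx:
                stack[i] = np.roll(np.roll(stack[i], dy, axis=0), dx, axis=1)
    if params.shift_noise_sd > 0:
        stack += rng.normal(0, params.shift_noise_sd, stack.shape).astype(np.float32)
    if out_path is not None:
        import tifffile

        tifffile.imwrite(out_path, stack)
    return stack
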