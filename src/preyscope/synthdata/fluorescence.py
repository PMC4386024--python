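"""Forward model from planted tuning to ΔF/F fluorescence traces.

Each ROI's latent drive is built on the 1.8 Hz imaging-frame grid (57
frames per 32 s epoch): spot-tuned cells respond during the traverse --
either sustained, or as a temporal bump when the spot crosses the cell's
receptive-field azimuth (which moves the response earlier or later in the
epoch exactly as retinotopy does); luminance cells follow the
background-luminance steps and whole-field flashes; assembly cells add a
burst starting a fixed number of frames before their designated convergent
saccade, in that response trial only.  The drive is convolved with a
difference-of-exponentials calcium-indicator kernel (defaults: 0.1 s rise,
1.5 s decay, peak-normalized, sampled at frame centres) and white Gaussian
noise is added.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ..rois import ROIRecord
from ..stimulus import (
    FLASH_BRIGHT_ID,
    FLASH_DIM_ID,
    FRAME_RATE_HZ,
    FRAMES_PER_EPOCH,
    StimulusEpoch,
    epoch_frame,
    time_at_azimuth,
)
from .eyes import TrueSaccade
from .population import GroundTruth


@dataclass
class NoiseParams:
    """Indicator/readout parameters of the fluorescence forward model."""

    noise_sd: float = 0.08
    kernel_rise_s: float = 0.1
    kernel_decay_s: float = 1.5
    #: convolve within epochs (no cross-epoch carryover) by default
    per_epoch: bool = True
    #: assembly burst duration, frames
    burst_frames: int = 4
    #: temporal width (SD, s) of receptive-field crossing responses
    rf_sigma_s: float = 0.7
    flash_dim_level: float = 0.6
    flash_bright_level: float = 1.0


def calcium_kernel(params: Optional[NoiseParams] = None) -> np.ndarray:
    """Peak-normalized difference-of-exponentials kernel at frame centres."""
    if params is None:
        params = NoiseParams()
    dt = 1.0 / FRAME_RATE_HZ
    n = max(2, int(np.ceil(8.0 * params.kernel_decay_s / dt)))
    t = (np.arange(n) + 0.5) * dt
    h = np.exp(-t / params.kernel_decay_s) - np.exp(-t / params.kernel_rise_s)
    peak = h.max()
    if peak <= 0:
        raise ValueError("degenerate kernel (decay must exceed rise)")
    return h / peak


def _frame_centers(epoch: StimulusEpoch) -> np.ndarray:
    """Absolute times of the epoch's 57 frame centres."""
    return epoch.epoch_onset + (np.arange(FRAMES_PER_EPOCH) + 0.5) / FRAME_RATE_HZ


def _boxcar(epoch: StimulusEpoch, t0: float, t1: float) -> np.ndarray:
    tc = _frame_centers(epoch)
    return ((tc >= t0) & (tc <= t1)).astype(float)


def _bump(epoch: StimulusEpoch, t_center: float, sigma: float) -> np.ndarray:
    tc = _frame_centers(epoch)
    return np.exp(-0.5 * ((tc - t_center) / sigma) ** 2)


def _luminance_up_intervals(epoch: StimulusEpoch, p: NoiseParams):
    """(t0, t1, level) spans of raised luminance within the epoch."""
    out = []
    if epoch.stimulus_id == FLASH_DIM_ID:
        out.append((epoch.spot_onset, epoch.spot_offset, p.flash_dim_level))
    elif epoch.stimulus_id == FLASH_BRIGHT_ID:
        out.append((epoch.spot_onset, epoch.spot_offset, p.flash_bright_level))
    elif epoch.background_step_times is not None:
        t0, t1 = epoch.background_step_times
        out.append((t0, t1, 1.0))
    return out


def assign_assembly_events(
    truth: GroundTruth,
    events: Sequence[TrueSaccade],
    prefer: str = "evoked",
) -> None:
    """Pair each planted assembly with one convergence event.

    The pairing prefers events whose contralateral eye (the one opposite
    the stimulus, which receives the larger rotation) lies on the
    assembly's side, emulating the ipsilateral bias of tectal premotor
    output.  ``prefer`` = 'evoked' pairs evoked events first, then
    spontaneous; 'spontaneous' reverses the priority.  Unpaired assemblies
    stay silent.
    """
    if prefer not in ("evoked", "spontaneous"):
        raise ValueError("prefer must be 'evoked' or 'spontaneous'")
    first = [e for e in events if e.evoked == (prefer == "evoked")]
    second = [e for e in events if e.evoked != (prefer == "evoked")]
    pool = first + second
    for asm in truth.assemblies:
        pick = next(
            (e for e in pool if e.contra_eye == asm.hemisphere), None
        )
        if pick is None and pool:
            pick = pool[0]
        if pick is None:
            asm.event_index = None
            continue
        pool.remove(pick)
        asm.event_index = events.index(pick)


def generate_fluorescence(
    rois: Sequence[ROIRecord],
    truth: GroundTruth,
    schedule: Sequence[StimulusEpoch],
    events: Sequence[TrueSaccade] = (),
    noise_params: Optional[NoiseParams] = None,
    seed: int = 0,
) -> np.ndarray:
    """ΔF/F traces, shape (n_frames, n_rois), epoch-aligned at 1.8 Hz.

    Assemblies must already be paired to events (`assign_assembly_events`);
    unpaired assemblies produce no burst.
    """
    p = noise_params if noise_params is not None else NoiseParams()
    if p.noise_sd < 0:
        raise ValueError("noise SD must be non-negative")
    rng = np.random.default_rng(seed)
    n_epochs = len(schedule)
    n_frames = n_epochs * FRAMES_PER_EPOCH
    latent = np.zeros((n_frames, len(rois)))

    # map: epoch_index -> list of (saccade frame-in-epoch, assembly ids)
    burst_by_epoch: dict[int, list[tuple[int, int]]] = {}
    for asm in truth.assemblies:
        if asm.event_index is None or asm.event_index >= len(events):
            continue
        ev = events[asm.event_index]
        ep = next((e for e in schedule if e.contains(ev.time)), None)
        if ep is None:
            continue
        f_sacc = epoch_frame(ep, ev.time)
        burst_by_epoch.setdefault(ep.epoch_index, []).append(
            (f_sacc, asm.assembly_id)
        )

    asm_by_id = {a.assembly_id: a for a in truth.assemblies}

    for j, roi in enumerate(rois):
        cell = truth.cells[roi.roi_id]
        for ep in schedule:
            sl = slice(
                ep.epoch_index * FRAMES_PER_EPOCH,
                (ep.epoch_index + 1) * FRAMES_PER_EPOCH,
            )
            drive = np.zeros(FRAMES_PER_EPOCH)
            # spot tuning
            if cell.w16 is not None and not ep.is_flash:
                w = cell.w16[ep.stimulus_id]
                if w != 0:
                    if cell.rf_azimuth is not None:
                        t_cross = time_at_azimuth(ep, cell.rf_azimuth)
                        if t_cross is not None:
                            drive += w * _bump(ep, t_cross, p.rf_sigma_s)
                    else:
                        drive += w * _boxcar(ep, ep.spot_onset, ep.spot_offset)
            # luminance responses
            if cell.lum_gain != 0.0:
                for t0, t1, level in _luminance_up_intervals(ep, p):
                    drive += cell.lum_gain * level * _boxcar(ep, t0, t1)
            if cell.dimming_gain != 0.0:
                for t0, t1, level in _luminance_up_intervals(ep, p):
                    drive += cell.dimming_gain * level * _boxcar(
                        ep, t1, t1 + 2.0 / FRAME_RATE_HZ
                    )
            # premotor burst in the response trial only
            if cell.assembly_id is not None:
                for f_sacc, a_id in burst_by_epoch.get(ep.epoch_index, ()):
                    if a_id != cell.assembly_id:
                        continue
                    lead = asm_by_id[a_id].lead_frames
                    f0 = max(0, f_sacc - lead)
                    f1 = min(FRAMES_PER_EPOCH, f0 + p.burst_frames + lead)
                    drive[f0:f1] += 1.0
            latent[sl, j] = cell.amplitude * drive

    kernel = calcium_kernel(p)
    traces = np.empty_like(latent)
    if p.per_epoch:
        for e in range(n_epochs):
            sl = slice(e * FRAMES_PER_EPOCH, (e + 1) * FRAMES_PER_EPOCH)
            block = latent[sl]
            conv = np.apply_along_axis(
                lambda col: np.convolve(col, kernel)[:FRAMES_PER_EPOCH], 0, block
            )
            traces[sl] = conv
    else:
        traces = np.apply_along_axis(
            lambda col: np.convolve(col, kernel)[:n_frames], 0, latent
        )
    if p.noise_sd > 0:
        traces = traces + rng.normal(0.0, p.noise_sd, size=traces.shape)
    return traces
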