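"""Stimulus panel, epoch schedule, and spot trajectory geometry.

The virtual hunting assay presents 18 stimuli: 16 moving spots spanning a
2x2x2x2 factorial of binary features -- direction (left-to-right = 1,
right-to-left = 0), speed (fast 30 deg/s = 1, slow 15 deg/s = 0), size
(large 13.2 deg = 1, small 3.5 deg = 0) and contrast polarity (dark spot on
bright background = 1, bright spot on dark background = 0) -- plus two
whole-field flash controls (dim, bright).  One stimulus is shown per 32 s
epoch.  Spots appear 100 deg to one side of the midline (negative = left)
and sweep 200 deg across the frontal visual field at constant speed.

Canonical stimulus ordering: ``stimulus_id = 8*direction + 4*speed +
2*size + polarity`` for the spots (0-15), then 16 = dim flash, 17 = bright
flash.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: imaging frame rate, Hz
FRAME_RATE_HZ = 1.8
#: epoch duration, s
EPOCH_S = 32.0
#: imaging frames per epoch: floor(32 * 1.8)
FRAMES_PER_EPOCH = 57
#: eye-tracking sample rate, Hz
EYE_RATE_HZ = 60.0

N_STIMULI = 18
N_SPOT_STIMULI = 16
FLASH_DIM_ID = 16
FLASH_BRIGHT_ID = 17
FLASH_DURATION_S = 3.0

#: spot appearance time within the epoch, s (leaves a >= 2 s pre-stimulus
#: baseline even after the background-luminance step of dark-spot epochs)
SPOT_ONSET_S = 4.0
#: total azimuthal sweep, deg
SWEEP_DEG = 200.0
#: start azimuth magnitude, deg
START_AZIMUTH_DEG = 100.0

SPEED_FAST_DEG_S = 30.0
SPEED_SLOW_DEG_S = 15.0
SIZE_LARGE_DEG = 13.2
SIZE_SMALL_DEG = 3.5
#: Weber contrast of bright spots on the dark background and of dark spots
#: on the raised background (stored as metadata only)
WEBER_CONTRAST_BRIGHT = 370.0
WEBER_CONTRAST_DARK = -0.97

FEATURE_NAMES = ("direction", "speed", "size", "polarity")


def feature_code(stimulus_id: int) -> Optional[tuple[int, int, int, int]]:
    """4-bit (direction, speed, size, polarity) code of a spot stimulus.

    Returns None for the flash controls (ids 16, 17).
    """
    if not 0 <= stimulus_id < N_STIMULI:
        raise ValueError(f"stimulus_id must be in [0, {N_STIMULI}), got {stimulus_id}")
    if stimulus_id >= N_SPOT_STIMULI:
        return None
    return (
        (stimulus_id >> 3) & 1,
        (stimulus_id >> 2) & 1,
        (stimulus_id >> 1) & 1,
        stimulus_id & 1,
    )


def stimulus_id_from_code(direction: int, speed: int, size: int, polarity: int) -> int:
    return 8 * direction + 4 * speed + 2 * size + polarity


def spot_speed_deg_s(speed_bit: int) -> float:
    return SPEED_FAST_DEG_S if speed_bit else SPEED_SLOW_DEG_S


def traverse_duration_s(speed_bit: int) -> float:
    """Time for the spot to sweep 200 deg (6.67 s fast, 13.33 s slow)."""
    return SWEEP_DEG / spot_speed_deg_s(speed_bit)


@dataclass
class StimulusEpoch:
    """One 32 s trial of the assay."""

    epoch_index: int
    stimulus_id: int
    epoch_onset: float          # s, absolute
    epoch_length: float = EPOCH_S
    plane: int = 0

    # spot-specific fields (None for flash epochs)
    feature_code: Optional[tuple[int, int, int, int]] = None
    spot_start_azimuth: Optional[float] = None   # deg, +right / -left
    spot_speed: Optional[float] = None           # deg/s
    spot_diameter: Optional[float] = None        # deg
    weber_contrast: Optional[float] = None
    background_step_times: Optional[tuple[float, float]] = None  # s, absolute

    def __post_init__(self) -> None:
        code = feature_code(self.stimulus_id)
        if code is None:
            return
        if self.feature_code is None:
            self.feature_code = code
        d, s, z, p = code
        if self.spot_start_azimuth is None:
            # L->R spots start on the left (negative azimuth)
            self.spot_start_azimuth = -START_AZIMUTH_DEG if d else START_AZIMUTH_DEG
        if self.spot_speed is None:
            self.spot_speed = spot_speed_deg_s(s)
        if self.spot_diameter is None:
            self.spot_diameter = SIZE_LARGE_DEG if z else SIZE_SMALL_DEG
        if self.weber_contrast is None:
            self.weber_contrast = WEBER_CONTRAST_DARK if p else WEBER_CONTRAST_BRIGHT
        if p and self.background_step_times is None:
            # background luminance rises 2 s before spot onset and falls
            # 2 s after spot offset
            on = self.epoch_onset + SPOT_ONSET_S
            off = on + traverse_duration_s(s)
            self.background_step_times = (on - 2.0, off + 2.0)

    @property
    def is_flash(self) -> bool:
        return self.stimulus_id >= N_SPOT_STIMULI

    @property
    def spot_onset(self) -> Optional[float]:
        """Absolute time the spot (or flash) appears, s."""
        return self.epoch_onset + SPOT_ONSET_S

    @property
    def spot_offset(self) -> Optional[float]:
        if self.is_flash:
            return self.epoch_onset + SPOT_ONSET_S + FLASH_DURATION_S
        s = self.feature_code[1]
        return self.epoch_onset + SPOT_ONSET_S + traverse_duration_s(s)

    def contains(self, t: float) -> bool:
        return self.epoch_onset <= t < self.epoch_onset + self.epoch_length


def generate_schedule(
    n_planes: int = 1,
    reps: int = 5,
    seed: int = 0,
) -> list[StimulusEpoch]:
    """Pseudo-random presentation schedule.

    Per focal plane, each of the 18 stimuli is presented `reps` times in a
    seeded random order, one per 32 s epoch.  Epoch onsets are consecutive
    multiples of 32 s across the whole session (planes are concatenated).
    """
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    if n_planes < 1:
        raise ValueError(f"n_planes must be >= 1, got {n_planes}")
    rng = np.random.default_rng(seed)
    epochs: list[StimulusEpoch] = []
    idx = 0
    for plane in range(n_planes):
        order = rng.permutation(np.repeat(np.arange(N_STIMULI), reps))
        for sid in order:
            epochs.append(
                StimulusEpoch(
                    epoch_index=idx,
                    stimulus_id=int(sid),
                    epoch_onset=idx * EPOCH_S,
                    plane=plane,
                )
            )
            idx += 1
    return epochs


def spot_azimuth(epoch: StimulusEpoch, t: float) -> Optional[float]:
    """Spot azimuth (deg, negative = left) at absolute time ``t``.

    None outside the traverse interval and for flash epochs.
    """
    if not epoch.contains(t):
        raise ValueError(f"t={t} outside epoch {epoch.epoch_index}")
    if epoch.is_flash:
        return None
    on, off = epoch.spot_onset, epoch.spot_offset
    if t < on or t > off:
        return None
    d = epoch.feature_code[0]
    sign = 1.0 if d else -1.0  # L->R moves rightward (+), R->L leftward (-)
    return epoch.spot_start_azimuth + sign * epoch.spot_speed * (t - on)


def time_at_azimuth(epoch: StimulusEpoch, azimuth: float) -> Optional[float]:
    """Absolute time when the spot crosses ``azimuth``; None if it never does."""
    if epoch.is_flash:
        return None
    d = epoch.feature_code[0]
    sign = 1.0 if d else -1.0
    dt = (azimuth - epoch.spot_start_azimuth) / (sign * epoch.spot_speed)
    if dt < 0 or dt > traverse_duration_s(epoch.feature_code[1]):
        return None
    return epoch.spot_onset + dt


def epoch_at(schedule: Sequence[StimulusEpoch], t: float) -> Optional[StimulusEpoch]:
    """Epoch containing absolute time ``t`` (None if out of range)."""
    for ep in schedule:
        if ep.contains(t):
            return ep
    return None


def epoch_frame(epoch: StimulusEpoch, t: float) -> int:
    """Imaging frame index within the epoch (0..56) containing time ``t``.

    Each 32 s epoch carries floor(32 * 1.8) = 57 frames; frame f spans
    [onset + f/1.8, onset + (f+1)/1.8).  The residual 0.6 frame at the end
    of the epoch is dead time assigned to the last frame.
    """
    if not epoch.contains(t):
        raise ValueError(f"t={t} outside epoch {epoch.epoch_index}")
    f = int(np.floor((t - epoch.epoch_onset) * FRAME_RATE_HZ))
    return min(f, FRAMES_PER_EPOCH - 1)


def global_frame(epoch: StimulusEpoch, t: float) -> int:
    """Frame index in the session-long 57-frames-per-epoch grid."""
    return epoch.epoch_index * FRAMES_PER_EPOCH + epoch_frame(epoch, t)


def frame_time(epoch: StimulusEpoch, frame_in_epoch: int) -> float:
    """Absolute time at the start of an epoch-relative frame."""
    return epoch.epoch_onset + frame_in_epoch / FRAME_RATE_HZ


def design_matrix(stimulus_ids: Sequence[int]) -> np.ndarray:
    """(n, 4) binary feature matrix for spot stimulus ids."""
    rows = []
    for sid in stimulus_ids:
        code = feature_code(int(sid))
        if code is None:
            raise ValueError(f"stimulus {sid} is a flash control, no feature code")
        rows.append(code)
    return np.asarray(rows, dtype=float)
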