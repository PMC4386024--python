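"""Synthetic binocular eye-position traces with planted convergent saccades.

Emulates the 60 Hz eye tracking of the tethered-fish assay.  Both channels
are nasal-positive, so the vergence angle is their sum.  Evoked convergences
are drawn per epoch from the behavioral logistic model of response rate as a
function of the stimulus feature code; spontaneous convergences follow a
slow Poisson process.  Each saccade is a fast sigmoidal nasal rotation of
both eyes (onset asynchrony well inside the 150 ms pairing rule), held for a
short plateau and then released back to baseline.

The vergence increment of each event is drawn from a normal distribution
truncated symmetrically about its mean, so the generating mean is preserved
exactly while unphysical (near-zero or negative) "convergences" are never
produced.  For evoked events the eye contralateral to the spot receives an
additive amplitude bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ..stimulus import EYE_RATE_HZ, StimulusEpoch, time_at_azimuth

#: printed best-model coefficients of the behavioral logistic regression
DEFAULT_LOGISTIC_COEFFS = {
    "intercept": -6.51,
    "size": 1.33,
    "polarity": 1.87,
    "speed:size:polarity": 0.90,
}


def logistic_response_probability(
    code: Sequence[int], coeffs: Optional[dict] = None
) -> float:
    """Hunting-response probability for a 4-bit (dir, speed, size, pol) code.

    Terms are named by ':'-joined feature products; e.g.
    ``"speed:size:polarity"`` multiplies those three bits.
    """
    if coeffs is None:
        coeffs = DEFAULT_LOGISTIC_COEFFS
    if "intercept" not in coeffs:
        raise KeyError("logistic coefficients must include 'intercept'")
    names = ("direction", "speed", "size", "polarity")
    bits = dict(zip(names, code))
    eta = 0.0
    for term, beta in coeffs.items():
        if term == "intercept":
            eta += beta
            continue
        x = 1.0
        for factor in term.split(":"):
            if factor not in bits:
                raise KeyError(f"unknown feature '{factor}' in term '{term}'")
            x *= bits[factor]
        eta += beta * x
    return 1.0 / (1.0 + np.exp(-eta))


@dataclass
class BehaviorParams:
    """Generating parameters of the oculomotor simulator."""

    logistic_coeffs: dict = field(
        default_factory=lambda: dict(DEFAULT_LOGISTIC_COEFFS)
    )
    #: vergence increment distribution, deg
    dvergence_mean: float = 19.03
    dvergence_sd: float = 9.3
    #: two-sided truncation half-width about the mean, deg
    dvergence_halfwidth: float = 10.0
    #: additive amplitude on the eye contralateral to the spot, deg
    contra_bias_deg: float = 3.0
    #: spontaneous convergence rate, events/hr
    spontaneous_rate_hr: float = 1.89
    #: white fixation/measurement noise SD, deg
    fixation_noise_sd: float = 0.15
    #: azimuth at which evoked saccades occur: truncated normal, deg
    azimuth_mean: float = -5.6
    azimuth_sd: float = 30.0
    azimuth_limit: float = 90.0
    #: onset asynchrony between the two eyes, uniform [0, max], s
    max_asynchrony_s: float = 0.08
    #: saccade duration: base + slope * per-eye amplitude, s
    saccade_duration_base_s: float = 0.020
    saccade_duration_per_deg_s: float = 0.0015
    #: vergence hold plateau and release time constant, s
    plateau_s: float = 1.0
    release_tau_s: float = 0.8
    #: minimum separation between generated events, s
    min_event_gap_s: float = 5.0

    def validate(self) -> None:
        if "intercept" not in self.logistic_coeffs:
            raise KeyError("logistic_coeffs missing 'intercept'")
        if self.fixation_noise_sd < 0:
            raise ValueError("fixation_noise_sd must be >= 0")


@dataclass
class EyeTrace:
    """Uniformly sampled binocular horizontal eye positions, nasal-positive."""

    left: np.ndarray     # deg
    right: np.ndarray    # deg
    fs: float = EYE_RATE_HZ
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        if self.left.shape != self.right.shape:
            raise ValueError("left/right channels differ in length")

    @property
    def n(self) -> int:
        return self.left.size

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    @property
    def duration(self) -> float:
        return self.n / self.fs


@dataclass
class TrueSaccade:
    """Ground-truth record of one planted convergent saccade."""

    time: float                  # onset of the earlier eye, s
    d_left: float                # nasal amplitude, deg
    d_right: float
    evoked: bool
    epoch_index: Optional[int] = None
    azimuth: Optional[float] = None       # spot azimuth at onset, deg
    contra_eye: Optional[str] = None      # 'L' or 'R'
    lead_eye: str = "L"
    asynchrony_s: float = 0.0

    @property
    def dvergence(self) -> float:
        return self.d_left + self.d_right


def _truncnorm(rng, mean, sd, lo, hi, size=None):
    """Rejection-sampled truncated normal (narrow tails, cheap)."""
    shape = () if size is None else (size,)
    out = np.empty(shape)
    flat = out.reshape(-1)
    for i in range(flat.size):
        while True:
            x = rng.normal(mean, sd)
            if lo <= x <= hi:
                flat[i] = x
                break
    return float(out) if size is None else out


def _smoothstep(x: np.ndarray) -> np.ndarray:
    s = np.clip(x, 0.0, 1.0)
    return s * s * (3.0 - 2.0 * s)


def _add_saccade(
    chan: np.ndarray,
    fs: float,
    t0_trace: float,
    onset: float,
    amplitude: float,
    duration: float,
    plateau: float,
    tau: float,
) -> None:
    """Add one nasal rotation (rise, hold, exponential release) in place."""
    span = duration + plateau + 8.0 * tau
    i0 = max(0, int(np.floor((onset - t0_trace) * fs)))
    i1 = min(chan.size, int(np.ceil((onset - t0_trace + span) * fs)) + 1)
    if i0 >= i1:
        return
    t = t0_trace + np.arange(i0, i1) / fs
    rise = _smoothstep((t - onset) / duration)
    rel_start = onset + duration + plateau
    release = np.where(t < rel_start, 1.0, np.exp(-(t - rel_start) / tau))
    chan[i0:i1] += amplitude * rise * release


def _saccade_duration(params: BehaviorParams, amplitude: float) -> float:
    return params.saccade_duration_base_s + params.saccade_duration_per_deg_s * abs(
        amplitude
    )


def generate_eye_traces(
    schedule: Sequence[StimulusEpoch],
    params: Optional[BehaviorParams] = None,
    seed: int = 0,
    duration_s: Optional[float] = None,
) -> tuple[EyeTrace, list[TrueSaccade]]:
    """Synthesize a 60 Hz binocular trace for a stimulus schedule.

    At most one evoked convergence is planted per spot epoch, Bernoulli with
    the logistic-model probability of the epoch's feature code, timed to the
    moment the spot crosses an azimuth drawn from a truncated normal centred
    near straight-ahead.  Spontaneous convergences are Poisson-placed outside
    stimulus-presentation windows.  ``duration_s`` extends (or sets, for an
    empty schedule) the trace length, enabling stimulus-free recordings.
    """
    if params is None:
        params = BehaviorParams()
    params.validate()
    rng = np.random.default_rng(seed)

    if schedule:
        end = max(ep.epoch_onset + ep.epoch_length for ep in schedule)
    else:
        end = 0.0
    if duration_s is not None:
        end = max(end, duration_s)
    n = int(round(end * EYE_RATE_HZ))
    if n == 0:
        raise ValueError("empty schedule and no duration_s given")

    events: list[TrueSaccade] = []

    # --- evoked events -------------------------------------------------
    for ep in schedule:
        if ep.is_flash:
            continue
        p = logistic_response_probability(ep.feature_code, params.logistic_coeffs)
        if rng.random() >= p:
            continue
        az = _truncnorm(
            rng,
            params.azimuth_mean,
            params.azimuth_sd,
            -params.azimuth_limit,
            params.azimuth_limit,
        )
        t_ev = time_at_azimuth(ep, az)
        if t_ev is None:  # pragma: no cover - limit < sweep range
            continue
        dv = _truncnorm(
            rng,
            params.dvergence_mean,
            params.dvergence_sd,
            params.dvergence_mean - params.dvergence_halfwidth,
            params.dvergence_mean + params.dvergence_halfwidth,
        )
        contra = "L" if az > 0 else "R"  # eye opposite the spot hemifield
        d_contra = (dv + params.contra_bias_deg) / 2.0
        d_ipsi = (dv - params.contra_bias_deg) / 2.0
        d_left, d_right = (
            (d_contra, d_ipsi) if contra == "L" else (d_ipsi, d_contra)
        )
        events.append(
            TrueSaccade(
                time=t_ev,
                d_left=d_left,
                d_right=d_right,
                evoked=True,
                epoch_index=ep.epoch_index,
                azimuth=az,
                contra_eye=contra,
                lead_eye="L" if rng.random() < 0.5 else "R",
                asynchrony_s=rng.uniform(0.0, params.max_asynchrony_s),
            )
        )

    # --- spontaneous events --------------------------------------------
    rate_s = params.spontaneous_rate_hr / 3600.0
    n_spont = rng.poisson(rate_s * end)
    stim_windows = [
        (ep.spot_onset - 1.0, ep.spot_offset + 1.0)
        for ep in schedule
        if not ep.is_flash
    ]
    candidates = np.sort(rng.uniform(0.0, end, size=n_spont))
    for t_ev in candidates:
        if any(a <= t_ev <= b for a, b in stim_windows):
            continue
        if any(abs(t_ev - e.time) < params.min_event_gap_s for e in events):
            continue
        dv = _truncnorm(
            rng,
            params.dvergence_mean,
            params.dvergence_sd,
            params.dvergence_mean - params.dvergence_halfwidth,
            params.dvergence_mean + params.dvergence_halfwidth,
        )
        events.append(
            TrueSaccade(
                time=float(t_ev),
                d_left=dv / 2.0,
                d_right=dv / 2.0,
                evoked=False,
                lead_eye="L" if rng.random() < 0.5 else "R",
                asynchrony_s=rng.uniform(0.0, params.max_asynchrony_s),
            )
        )

    events.sort(key=lambda e: e.time)
    trace = _render_trace(events, n, params, rng)
    return trace, events


def synthesize_saccade_train(
    n_events: int,
    params: Optional[BehaviorParams] = None,
    seed: int = 0,
    spacing_s: float = 8.0,
) -> tuple[EyeTrace, list[TrueSaccade]]:
    """Stimulus-free trace with exactly ``n_events`` planted convergences.

    Events are evenly spaced; amplitudes follow the configured vergence
    distribution with an even left/right split (no stimulus, no bias).
    """
    if params is None:
        params = BehaviorParams()
    params.validate()
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    rng = np.random.default_rng(seed)
    end = spacing_s * (n_events + 1)
    n = int(round(end * EYE_RATE_HZ))
    events = []
    for k in range(n_events):
        dv = _truncnorm(
            rng,
            params.dvergence_mean,
            params.dvergence_sd,
            params.dvergence_mean - params.dvergence_halfwidth,
            params.dvergence_mean + params.dvergence_halfwidth,
        )
        events.append(
            TrueSaccade(
                time=spacing_s * (k + 1),
                d_left=dv / 2.0,
                d_right=dv / 2.0,
                evoked=False,
                lead_eye="L" if rng.random() < 0.5 else "R",
                asynchrony_s=rng.uniform(0.0, params.max_asynchrony_s),
            )
        )
    trace = _render_trace(events, n, params, rng)
    return trace, events


def _render_trace(
    events: Sequence[TrueSaccade],
    n_samples: int,
    params: BehaviorParams,
    rng: np.random.Generator,
) -> EyeTrace:
    left = rng.normal(0.0, params.fixation_noise_sd, size=n_samples)
    right = rng.normal(0.0, params.fixation_noise_sd, size=n_samples)
    for ev in events:
        t_l = ev.time + (0.0 if ev.lead_eye == "L" else ev.asynchrony_s)
        t_r = ev.time + (0.0 if ev.lead_eye == "R" else ev.asynchrony_s)
        _add_saccade(
            left, EYE_RATE_HZ, 0.0, t_l, ev.d_left,
            _saccade_duration(params, ev.d_left),
            params.plateau_s, params.release_tau_s,
        )
        _add_saccade(
            right, EYE_RATE_HZ, 0.0, t_r, ev.d_right,
            _saccade_duration(params, ev.d_right),
            params.plateau_s, params.release_tau_s,
        )
    return EyeTrace(left=left, right=right)
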