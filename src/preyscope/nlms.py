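"""Non-linear mixed selectivity (NLMS) analysis.

Identifies tectal neurons tuned to conjunctions of stimulus features via
(1) correlation against a panel of six binary regressors, all selective for
large, dark spots, with or without direction and speed selectivity; and
(2) cross-validated comparison of two 5-parameter models of the per-trial
peak response y as a function of the binary feature code:

    linear:      y = b0 + bd*dir + bs*speed + bz*size + bp*pol
    non-linear:  y = b0 + b1*(size*pol) + b2*(speed*size*pol)
                    + b3*(dir*size*pol) + b4*(dir*speed*size*pol)

The non-linear interaction set carries the large-and-dark conjunction, its
speed-selective and direction-selective refinements, and the full four-way
term whose sign suppresses (or enhances) one direction; the dir*size*pol
term completes parameter parity with the linear model while carrying
speed-independent direction selectivity.  The comparison is meaningful
because both models spend exactly five free parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .stimulus import (
    FRAME_RATE_HZ,
    FRAMES_PER_EPOCH,
    N_SPOT_STIMULI,
    StimulusEpoch,
    epoch_frame,
    feature_code,
    spot_azimuth,
    time_at_azimuth,
)

REGRESSOR_KEYS = ("nDS-nSp", "nDS-Sp", "R2L-nSp", "R2L-Sp", "L2R-nSp", "L2R-Sp")


def build_regressors() -> dict[str, np.ndarray]:
    """Six binary 16-vectors over the moving-spot panel (canonical order).

    Every regressor is 1 only on large, dark stimuli; '-Sp' variants
    additionally require fast motion, and the R2L/L2R variants the matching
    direction bit (L2R = direction bit 1).
    """
    out = {}
    for key in REGRESSOR_KEYS:
        vec = np.zeros(N_SPOT_STIMULI)
        want_dir = None
        if key.startswith("R2L"):
            want_dir = 0
        elif key.startswith("L2R"):
            want_dir = 1
        want_fast = key.endswith("-Sp")
        for sid in range(N_SPOT_STIMULI):
            d, s, z, p = feature_code(sid)
            if not (z and p):
                continue
            if want_fast and not s:
                continue
            if want_dir is not None and d != want_dir:
                continue
            vec[sid] = 1.0
        out[key] = vec
    return out


def stimulus_window_frames(epoch: StimulusEpoch, pad_frames: int = 3) -> np.ndarray:
    """Epoch-relative frame indices spanning the spot/flash presentation.

    Padded a few frames past offset so slow indicator decay is captured.
    """
    f0 = epoch_frame(epoch, epoch.spot_onset)
    f1 = min(FRAMES_PER_EPOCH - 1, epoch_frame(epoch, min(
        epoch.spot_offset, epoch.epoch_onset + epoch.epoch_length - 1e-6)) + pad_frames)
    return np.arange(f0, f1 + 1)


def _epoch_matrix(trace: np.ndarray, n_epochs: int) -> np.ndarray:
    """(n_epochs, 57) view of a session-long frame trace."""
    n = n_epochs * FRAMES_PER_EPOCH
    if trace.size < n:
        raise ValueError("trace shorter than the schedule")
    return trace[:n].reshape(n_epochs, FRAMES_PER_EPOCH)


def peak_response_vector(
    trace: np.ndarray, schedule: Sequence[StimulusEpoch]
) -> np.ndarray:
    """Peak of the rep-averaged response per moving-spot stimulus (16-vector)."""
    mat = _epoch_matrix(np.asarray(trace, float), len(schedule))
    out = np.empty(N_SPOT_STIMULI)
    for sid in range(N_SPOT_STIMULI):
        eps = [ep for ep in schedule if ep.stimulus_id == sid]
        if not eps:
            raise ValueError(f"stimulus {sid} missing from schedule")
        window = stimulus_window_frames(eps[0])
        mean_resp = np.mean([mat[ep.epoch_index] for ep in eps], axis=0)
        out[sid] = float(np.max(mean_resp[window]))
    return out


def per_trial_peaks(
    trace: np.ndarray, schedule: Sequence[StimulusEpoch]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial peak responses: (y, stimulus_id) over all spot epochs."""
    mat = _epoch_matrix(np.asarray(trace, float), len(schedule))
    ys, sids = [], []
    for ep in schedule:
        if ep.is_flash:
            continue
        window = stimulus_window_frames(ep)
        ys.append(float(np.max(mat[ep.epoch_index][window])))
        sids.append(ep.stimulus_id)
    return np.asarray(ys), np.asarray(sids)


def assign_regressor(
    vec: np.ndarray,
    regressors: Optional[dict[str, np.ndarray]] = None,
    r_min: float = 0.75,
) -> Optional[tuple[str, float]]:
    """Associate a 16-vector with its best-correlated regressor.

    Returns (key, r) for the highest Pearson correlation if r >= r_min,
    else None.  Ties break in the fixed REGRESSOR_KEYS order.  A vector
    with no variance cannot be assigned.
    """
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (N_SPOT_STIMULI,) or not np.all(np.isfinite(vec)):
        raise ValueError("expected a finite 16-vector")
    if np.std(vec) == 0:
        return None
    if regressors is None:
        regressors = build_regressors()
    best: Optional[tuple[str, float]] = None
    for key in REGRESSOR_KEYS:
        if key not in regressors:
            continue
        r = float(np.corrcoef(vec, regressors[key])[0, 1])
        if best is None or r > best[1]:
            best = (key, r)
    if best is None or best[1] < r_min:
        return None
    return best


# ---------------------------------------------------------------------------
# linear vs non-linear model comparison
# ---------------------------------------------------------------------------

LINEAR_TERMS = ("direction", "speed", "size", "polarity")
NONLINEAR_TERMS = (
    "size:polarity",
    "speed:size:polarity",
    "direction:size:polarity",
    "direction:speed:size:polarity",
)


@dataclass
class GLMResult:
    """Outcome of the equal-complexity linear/non-linear comparison."""

    linear_coefficients: dict[str, float]
    nonlinear_coefficients: dict[str, float]
    cv_r2_lin: float
    cv_r2_nlin: float

    @property
    def si_nlin(self) -> float:
        a, b = self.cv_r2_nlin, self.cv_r2_lin
        denom = abs(a) + abs(b)
        if denom == 0:
            return 0.0
        return (a - b) / denom


def _design(sids: np.ndarray, terms: Sequence[str]) -> np.ndarray:
    codes = np.array([feature_code(int(s)) for s in sids], dtype=float)
    bits = dict(zip(LINEAR_TERMS, codes.T))
    cols = [np.ones(sids.size)]
    for term in terms:
        x = np.ones(sids.size)
        for f in term.split(":"):
            x = x * bits[f]
        cols.append(x)
    return np.column_stack(cols)


def _lstsq_r2(X_tr, y_tr, X_te, y_te) -> tuple[np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(X_tr, y_tr, rcond=None)
    resid = y_te - X_te @ beta
    ss_tot = float(np.sum((y_te - y_te.mean()) ** 2))
    if ss_tot == 0:
        return beta, 0.0
    return beta, 1.0 - float(np.sum(resid**2)) / ss_tot


def fit_models(
    y: np.ndarray,
    stimulus_ids: np.ndarray,
    n_splits: int = 20,
    seed: int = 0,
) -> GLMResult:
    """Fit and cross-validate the linear and non-linear 5-parameter models.

    Reps of each stimulus are randomly halved; both models are least-squares
    fitted on the training half and scored as R^2 on the held-out half,
    averaged over ``n_splits`` halvings.  Full-data coefficient estimates
    are reported.
    """
    y = np.asarray(y, dtype=float)
    sids = np.asarray(stimulus_ids)
    if y.shape != sids.shape:
        raise ValueError("y and stimulus_ids differ in length")
    counts = np.bincount(sids, minlength=N_SPOT_STIMULI)
    if np.any(counts[:N_SPOT_STIMULI] < 2):
        raise ValueError("need >= 2 reps per stimulus to cross-validate")
    rng = np.random.default_rng(seed)

    X_lin = _design(sids, LINEAR_TERMS)
    X_nlin = _design(sids, NONLINEAR_TERMS)

    r2_lin, r2_nlin = [], []
    for _ in range(n_splits):
        train = np.zeros(y.size, dtype=bool)
        for s in range(N_SPOT_STIMULI):
            idx = np.flatnonzero(sids == s)
            k = idx.size // 2 + (idx.size % 2)
            train[rng.permutation(idx)[:k]] = True
        _, r2l = _lstsq_r2(X_lin[train], y[train], X_lin[~train], y[~train])
        _, r2n = _lstsq_r2(X_nlin[train], y[train], X_nlin[~train], y[~train])
        r2_lin.append(r2l)
        r2_nlin.append(r2n)

    beta_lin, *_ = np.linalg.lstsq(X_lin, y, rcond=None)
    beta_nlin, *_ = np.linalg.lstsq(X_nlin, y, rcond=None)
    return GLMResult(
        linear_coefficients=dict(
            zip(("intercept", *LINEAR_TERMS), map(float, beta_lin))
        ),
        nonlinear_coefficients=dict(
            zip(("intercept", *NONLINEAR_TERMS), map(float, beta_nlin))
        ),
        cv_r2_lin=float(np.mean(r2_lin)),
        cv_r2_nlin=float(np.mean(r2_nlin)),
    )


def nlms_population_summary(results: Sequence[GLMResult]) -> dict:
    """Fraction of ROIs better fit by the non-linear model + signed-rank p."""
    if len(results) < 2:
        raise ValueError("need >= 2 results for a population summary")
    nlin = np.array([r.cv_r2_nlin for r in results])
    lin = np.array([r.cv_r2_lin for r in results])
    frac = float(np.mean(nlin > lin))
    diff = nlin - lin
    if np.all(diff == 0):
        p = 1.0
    else:
        p = float(stats.wilcoxon(diff)[1])
    return {"fraction_nlin_better": frac, "signed_rank_p": p, "n": len(results)}


# ---------------------------------------------------------------------------
# receptive-field estimation
# ---------------------------------------------------------------------------

@dataclass
class ReceptiveField:
    azimuth_center: float      # deg
    dispersion: float          # deg (circular SD)
    n_stimuli: int


def estimate_rf(
    trace: np.ndarray,
    schedule: Sequence[StimulusEpoch],
    eye_trace,
    hemisphere: str,
    lag_frames: int = 1,
    response_fraction: float = 0.5,
) -> Optional[ReceptiveField]:
    """Azimuthal receptive-field centre of a spot-responsive ROI.

    For every stimulus whose rep-averaged peak exceeds ``response_fraction``
    of the best stimulus, one RF sample is taken as the spot azimuth one
    indicator lag before the response peak, corrected by the mean gaze angle
    of the eye contralateral to the ROI's tectal hemisphere during those
    epochs (retinotectal input is fully crossed).  The centre is the
    circular mean of samples; dispersion the circular SD.
    """
    pvec = peak_response_vector(trace, schedule)
    if np.max(pvec) <= 0:
        return None
    responsive = np.flatnonzero(pvec >= response_fraction * np.max(pvec))
    mat = _epoch_matrix(np.asarray(trace, float), len(schedule))

    # contralateral eye: left tectum is driven by the right eye
    eye_chan = eye_trace.right if hemisphere == "L" else eye_trace.left
    # nasal-positive angles: for the right eye, nasal = leftward in screen
    # azimuth, so gaze azimuth = -nasal angle; for the left eye, +nasal.
    gaze_sign = -1.0 if hemisphere == "L" else 1.0

    samples = []
    for sid in responsive:
        eps = [ep for ep in schedule if ep.stimulus_id == sid]
        window = stimulus_window_frames(eps[0])
        mean_resp = np.mean([mat[ep.epoch_index] for ep in eps], axis=0)
        f_peak = int(window[np.argmax(mean_resp[window])])
        f_sample = max(0, f_peak - lag_frames)
        az_vals = []
        gz_vals = []
        for ep in eps:
            t = ep.epoch_onset + (f_sample + 0.5) / FRAME_RATE_HZ
            az = spot_azimuth(ep, min(t, ep.spot_offset))
            if az is None:
                continue
            i0 = int(ep.epoch_onset * eye_trace.fs)
            i1 = min(eye_chan.size, int((ep.epoch_onset + ep.epoch_length) * eye_trace.fs))
            gaze = gaze_sign * float(np.mean(eye_chan[i0:i1])) if i1 > i0 else 0.0
            az_vals.append(az)
            gz_vals.append(gaze)
        if az_vals:
            samples.append(float(np.mean(az_vals)) - float(np.mean(gz_vals)))
    if not samples:
        return None
    rad = np.deg2rad(samples)
    center = float(np.rad2deg(stats.circmean(rad, high=np.pi, low=-np.pi)))
    disp = float(np.rad2deg(stats.circstd(rad, high=np.pi, low=-np.pi)))
    return ReceptiveField(azimuth_center=center, dispersion=disp, n_stimuli=len(samples))
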